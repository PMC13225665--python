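# Methods

`mmtissue` integrates tissue images from technologies that share no channels —
multiplexed antibody imaging (tens of protein channels at ~1 µm), mass
spectrometry imaging (MSI; thousands of m/z channels at 20–50 µm), and RGB
histology — and converts the aligned stack into multimodal single-cell data.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic tests do and do not show.

## Pixel-manifold compression

High-parameter images are compressed per pixel with UMAP before registration.
The pipeline: spatial subsampling → fuzzy simplicial set (the UMAP membership
graph over pixel feature vectors) → spectral landmarks → a dimensionality
scan → final embedding with out-of-sample projection → raster reconstruction.

**Subsampling** defaults are keyed on the masked pixel count: below 50,000
pixels nothing is subsampled; 50–100k uses 55% pseudo-random sampling seeded
with a 2×2 grid; 100–150k uses 15% with a 3×3 grid; above 150k a 3×3 grid
alone. Pseudo-random = a uniform grid united with random fill up to the
target fraction, so coverage is spatially even.

**Fuzzy simplicial set.** Exact (deterministic) nearest neighbours are used
up to 20,000 points; above that the approximate search in `umap-learn` takes
over. `n_neighbors` counts the point itself (the UMAP convention).
Defaults: 15 neighbours, Euclidean metric, `min_dist` 0.1. The source
material states 15-NN/Euclidean only for the downstream cell and peak graphs;
adopting the same values for compression is this package's choice, made for
consistency.

**Spectral landmarks.** The membership matrix is reduced to 100 components by
randomized SVD; mini-batch k-means on those spectral coordinates yields 3,000
clusters (clamped to n when n is smaller); each landmark is the centroid of
its cluster's members in the *original* feature space. Landmarks exist only
to make the exact cross-entropy affordable — the final embedding always uses
the full subsample.

**Dimensionality selection.** For each candidate dimensionality i = 1..10 the
landmark graph is embedded and the exact fuzzy-set cross-entropy

    E_i = Σ_edges μ log(μ/ν) + (1−μ) log((1−μ)/(1−ν))

is evaluated over the edge support of the high-dimensional graph, where ν is
the low-dimensional membership 1/(1 + a·d^{2b}) from the embedding's (a, b)
curve. Memberships are clipped to [1e−8, 1−1e−8] to keep the logs finite
(single precision memberships reach exactly 1). The normalized E_i are fitted
by least squares to `(y0 − c)·e^{−k·i} + c`; σ is the residual SD floored at
1e−6 (so a numerically perfect fit still selects); the fitted curve is
evaluated on a dense grid of i and the selected dimensionality is the first
integer candidate at or beyond the point where the curve enters `c + 1.96σ`.
Constant entropy profiles degenerate to the smallest candidate. On rank-r
Gaussian manifolds (r = 2..4, 20 ambient dimensions, n = 400, noise SD 0.01)
the scan selects r or r+1 in every tested seed — *provided the embeddings are
run to UMAP's full default epoch count; truncating epochs inflates the
selected dimensionality*.

**Out-of-sample projection** positions a new pixel at the inverse-distance
weighted average of its 15 nearest training pixels' embedding coordinates
(exact feature-space hits return the training coordinate). No Procrustes
correction is applied; the self-projection error is a test-time diagnostic.

**Histology preprocessing** is an ordered step list — median filter, Otsu or
manual threshold, binary opening/closing with disc structuring elements, hole
filling. Opening with a disc rounds sharp convex corners; the idempotence
property holds for smooth (disc-like) foregrounds only.

## Entropic-graph α-mutual information

Similarity between modalities is the Rényi α-MI estimated from k-NN graph
lengths, which needs no channel correspondence and tolerates different
dimensionalities. With γ = d(1−α) and L_γ the sum of k-NN edge lengths to the
γ power, `Ĥ_α = (1−α)^{-1}[log(L_γ/n^α) − log β]` estimates the α-entropy up
to the BHH constant β. Two modes:

* **relative** (default inside registration): β dropped — only differences
  across candidate transforms matter;
* **calibrated**: log β estimated once per (n, d, k, α) by Monte-Carlo on
  uniform unit cubes (2 replicates, fixed internal seed, cached), making
  Ĥ_α(uniform [0,1]^d) ≈ 0 and the assembled
  MI = Ĥ(X) + Ĥ(Y) − Ĥ(X,Y) a consistent Shannon-MI estimate as α → 1.

Marginals are rescaled to unit per-axis variance before concatenation into
the joint space (the source does not state its scaling; MI is invariant to
per-marginal scaling, so this only conditions the joint graph). Defaults
α = 0.99 and k = 15 mirror the registration protocol; the Shannon-limit
checks use α = 0.999. Verified limits: the entropy gap between uniform
squares of side 2 and 1 equals ln 4 within ±0.1 at n = 10⁴; coordinate
scaling shifts Ĥ by exactly d·ln s; bivariate-Gaussian α-MI tracks
−½ln(1−ρ²) within ±0.15 nats at n = 5×10⁴ for ρ up to 0.9. k-NN queries use a
KD-tree below 9 dimensions and a dense vectorized path above (KD-trees
degrade badly in high dimensions).

## Registration

Stages (translation → rigid/affine → cubic B-spline) run in order, each
initialized from the last, over a Gaussian smoothing pyramid (level ℓ of L
smoothed with σ = 2^{L−ℓ−1}; finest level unsmoothed; no decimation). The
cost is −α-MI plus `landmark_weight ×` mean squared landmark distance. Each
iteration draws a fresh random coordinate sample in the fixed domain and
updates parameters by finite-difference gradient descent with the decaying
step a/(A+t)^0.602 (A = 10); parameter scales (0.01 for linear terms, 1 px
for offsets) condition the gradient. Low-parameter stages end with a
deterministic Powell polish on a fixed seeded sample, which supplies the
sub-pixel accuracy the stochastic iterations alone do not.

Three cost details matter and were each adopted after observing a concrete
failure mode on synthetic pairs:

1. samples are drawn where the *current* estimate maps them at least 6 px
   inside the moving image, so nearby candidates keep the whole sample in
   bounds — without this, border clamping biases the cost toward identity;
2. candidates that still push over half the sample out of bounds are
   rejected (cost 10⁶) — tiny surviving subsets have spuriously favourable
   graph lengths and attracted the polish to extreme transforms;
3. a log(n_valid) term removes the first-order sample-size dependence of the
   relative-mode estimator.

A residual flatness remains: on piecewise-constant scenes, MI-only affine
registration occasionally (≈1 in 5 seeds) prefers a mildly anisotropic
scaling whose cost is ~0.2 nats better than the truth. A handful of guide
landmarks (the workflow this package models always uses at least 4 manual
pairs per registration) removes the ambiguity; the affine recovery tests
therefore guide with 4 landmarks and evaluate on 4 held-out ones
(max error < 1 px; unguided translation recovery is < 0.1 px).

The B-spline stage is a cubic free-form deformation: `map_coordinates` with
`prefilter=False` treats the control grid as B-spline coefficients. Because
the per-coefficient MI gradient sits below the resampling noise of a
stochastic cost, this stage descends deterministically: one fixed seeded
coordinate sample, then greedy coordinate-search sweeps over the control
coefficients with shrinking pixel-scale probe steps, accepting only moves
that lower the sampled cost (monotone descent). Typical full-tissue
MSI→histology alignments use a final spacing of ~300 px, reference-stain
pairs ~5 px; the synthetic tests use 16 px on 64×64 frames. Warp sanity is
screened with the per-pixel determinant of the spatial Jacobian (analytic
for affine, central differences otherwise): values far from 1 flag
unrealistic warping; recovered mild warps stay within [0.8, 1.2]. On
piecewise-constant scenes the α-MI cost does not resolve nonlinear warps
much below ~1.5 px mean displacement — the alignment signal lives only on
region boundaries — so the nonlinear stage is a coarse corrector there;
images with continuous texture give it more to work with.

`evaluate_alignment` reproduces the benchmarking protocol: pixels on a
uniformly spaced grid (every 10th row/col at full scale; every 4th on the
80×80 test frames, keeping the sample size comparable) inside the mask
intersection, PCA per modality retaining 99% of variance, α-MI with α = 0.99
and k = 15, and the relative gain of one alignment over another.

## Single-cell quantification and spatial features

`quantify_cells` computes per-cell channel means (float64 accumulation;
matches a per-pixel oracle to 1e−12), pixel-mean centroids, and morphology
(area, eccentricity, solidity, extent) from the labelled regions. Cells
touching the raster border or leaving the contour∩image mask intersection
are dropped and labels re-indexed densely. Intensities are normalized per
channel by the 99th percentile (linear interpolation) and clipped to [0, 1]
— the clip follows the MCMICRO-style convention; a zero percentile leaves
the channel unscaled with a warning. Phenotypes come from Leiden community
detection (RB-configuration, resolution 1.0, seeded) on the 15-NN Euclidean
fuzzy simplicial set of normalized expression.

Interaction scores use a radius graph (75 µm default, boundary inclusive).
The Gaussian bandwidth is per cell: σ_i = population SD of cell i's neighbour
distances, with fallback σ_i = radius/2 when a cell has fewer than two
neighbours or zero spread — the only reading of "normalize the weights to the
SD of the distances" that keeps every weight finite. The self term is
excluded. Scores are exactly linear in features and invariant to rigid
motions of the centroids.

## Correlation-network analysis

Spearman correlations (tie-corrected ranks, then Pearson) of every m/z peak
against every protein; two-sided p from the t approximation; Bonferroni over
all peak×protein tests; a peak survives if any corrected p ≤ 0.001. Peak
modules: Pearson correlation between peaks' correlation profiles →
arccos(clip(r)) metric distance → 5-NN fuzzy simplicial set → Louvain at each
resolution in a grid (0.2–2.0 by default) → the elbow of the
resolution–modularity curve (max perpendicular distance to its chord) picks
the partition. Spatial trends are adjusted exponentially weighted moving
averages (λ = 2/(span+1)); the span is a required parameter. Differential
correlation between two cell populations uses the Fisher z statistic
`(atanh r_a − atanh r_b)/√(1/(n_a−3)+1/(n_b−3))` with |r| clipped at
1−1e−7, Bonferroni over peaks, and ranking by max(|r_a|,|r_b|)·|z|. The
default one-sided direction is fixed (group a vs b), which keeps null
p-values uniform and the type-I error at its nominal level (measured 0.048
at nominal 0.05 over 1,000 null replicates); `direction="auto"` (sign of the
observed z) is available but doubles the type-I rate and is flagged as such.

## Grade classification

One-vs-rest logistic regression with elastic-net penalty (saga solver) on
standardized features. Folds partition biopsy cores, never cells; group-fold
assignment is stratified by each core's majority class and re-drawn until
every class appears in every training split. Classes are weighted inversely
to frequency because the evaluation metric is class-balanced accuracy and
density-contrast scenes are inherently imbalanced. The grid defaults to
l1_ratio ∈ {0.1, 0.5, 0.9} × C ∈ 10^{−3..1} (5 log steps); tests use a single
grid point for speed. Feature ranking is by max |coefficient| across the
one-vs-rest models, ties broken by name. Top-n refinement retrains at
n = 1, 51, 101, … (clipped) plus n = all; leave-one-out refinement retains
features whose removal degrades CV accuracy by more than a configurable
threshold (default: any strictly positive drop).

## Synthetic data: what it does and does not show

`make_manifold` draws rank-r Gaussians (optionally sine-curved) rotated into
the ambient space with isotropic noise. `make_multimodal_pair` renders one
latent region map (Lloyd-relaxed Voronoi, 5 regions by default, so
compartments are commensurate like tissue compartments) through two
independent random channel signatures; modality B's grid is resampled through
the known transform, and landmark pairs satisfy it exactly. Noise is 5% of
the signature range. `make_cell_scene` scatters cells uniformly in spatially
disjoint cores; `single_cell_effect` shifts a feature mean per class, while
`neighborhood_effect` halves a class's density (at the default 1.0) leaving
every cell's own feature distribution class-agnostic — so the class signal
is recoverable only through neighbourhood aggregation. All generators are
bit-deterministic given a seed.

These scenes have piecewise-constant signal, isotropic Gaussian noise, and
exactly matched serial sections. Passing tests therefore demonstrate the
estimators' analytic correctness, recovery of planted structure, and
statistical error control — not robustness to stain variation, tissue
deformation between sections beyond the modelled transforms, MSI
peak-detection artefacts, or segmentation error, all of which real data
contain.

## Problem sizes

Test and acceptance runs use 64–80 px frames, 400–4,900-pixel manifolds and
scans, 500-cell scenes over 12 cores, 1,000-replicate null simulations, and
n = 10⁴–5×10⁴ samples for the analytic entropy limits. These sizes were
chosen so each property is measured well inside its stated tolerance while a
full run stays in the minutes range on a single CPU.

## Known limitations

* MI-only (unguided) affine registration can settle in a slightly better
  scoring anisotropic optimum on low-texture scenes; supply landmarks.
* The B-spline stage is a coarse corrector on low-texture inputs (see
  above); greedy sweeps over fine control grids are O(coefficients) cost
  evaluations per sweep.
* Out-of-sample projection is interpolation-only: pixels far outside the
  training manifold are pulled to its hull.
* `detect_modules` requires more kept peaks than neighbours (≥ 6 at the
  default); isolated peaks become singleton modules through Louvain itself.
* imzML reading requires processed-mode files (one shared m/z axis).
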