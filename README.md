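# mmtissue

Multimodal tissue imaging integration: compress high-parameter tissue images
into low-dimensional pixel embeddings, align them across imaging
technologies by maximizing an entropic-graph Rényi α-mutual information, and
convert the aligned stack into multimodal single-cell measurements with
spatial-neighbourhood, correlation-network, and classification analytics.

## The problem

Serial sections of the same biopsy are routinely imaged by technologies that
share no channels: multiplexed antibody imaging (20–50 protein channels at
~1 µm), mass spectrometry imaging (thousands of m/z channels at 20–50 µm),
and RGB histology. Histogram-based similarity measures cannot align such
pairs — they require equal channel counts and a known channel
correspondence, and they are not invariant to channel relabelling. This
package is for computational biologists who need to co-register such data
and extract per-cell measurements spanning modalities.

## The method

**Compression.** Each high-parameter image is reduced per pixel with UMAP.
The fuzzy simplicial set (membership graph) of a spatial pixel subsample is
embedded into Euclidean spaces of dimension 1..10; the exact fuzzy-set
cross-entropy

&nbsp;&nbsp;&nbsp;&nbsp;E_i = Σ_e μ log(μ/ν) + (1−μ) log((1−μ)/(1−ν))

is computed on spectral landmarks for each dimensionality, min-max
normalized, and fitted by least squares to (y0−c)·e^{−k·i}+c; the first
dimensionality whose fitted value enters the 95% band c ± 1.96σ of the
asymptote is selected. Remaining pixels are projected into the embedding and
written back to their coordinates as a compressed image.

**Registration.** Image similarity is the Rényi α-mutual information
estimated from k-nearest-neighbour graph lengths of the embedded pixels
(Beardwood–Halton–Hammersley): with γ = d(1−α),

&nbsp;&nbsp;&nbsp;&nbsp;Ĥ_α = (1−α)^{−1}[log(L_γ / n^α) − log β],&nbsp;&nbsp;
α-MI = Ĥ_α(X) + Ĥ_α(Y) − Ĥ_α(X,Y),

which is defined for unequal channel counts, invariant to channel
permutation, and converges to Shannon MI as α→1. A transform (translation →
affine → cubic B-spline, over a Gaussian smoothing pyramid) is optimized by
stochastic gradient descent on −α-MI with an optional manual-landmark
penalty, with α = 0.99 and k = 15 by default. Diagnostics include the
spatial-Jacobian determinant map and an alignment evaluation protocol
(uniform sample grid, 99%-variance PCA per modality, relative α-MI gain).

**Single-cell analytics.** Aligned images plus a segmentation label mask
yield per-cell multimodal mean intensities, morphology, 99th-percentile
normalization, and Leiden phenotypes; radius-graph (75 µm) Gaussian
interaction scores provide continuous spatial features; Spearman
correlation networks with Louvain modules, EWMA spatial trends, and
Fisher-z differential correlation link MSI microenvironments to protein
expression; grouped-CV one-vs-rest elastic-net logistic regression with
coefficient-based feature ranking classifies tissue grade.

## Worked example

Two synthetic serial sections of the same tissue — 12 channels for one
modality, 30 for the other, offset by (5, −3) pixels — are registered from
their compressed embeddings and scored:

```python
import numpy as np
from sklearn.decomposition import PCA
from mmtissue.images import MultichannelImage
from mmtissue.synthetic import make_multimodal_pair
from mmtissue.register import (register, RegistrationConfig,
                               apply_transform, evaluate_alignment)

scene = make_multimodal_pair(
    shape=(64, 64), channels_a=12, channels_b=30,
    transform={"kind": "translation", "offset": (5, -3)}, seed=0,
)

def compress(img, dim=3):  # PCA stand-in for the full manifold compression
    h, w, c = img.data.shape
    z = PCA(dim).fit_transform(img.data.reshape(-1, c).astype(float))
    return MultichannelImage(z.reshape(h, w, dim).astype(np.float32),
                             [f"pc{i}" for i in range(dim)])

fixed, moving = compress(scene.image_a), compress(scene.image_b)
cfg = RegistrationConfig(stages=("translation",), pyramid_levels=2,
                         iterations=25, samples_per_iteration=800, seed=0)
T = register(fixed, moving, cfg)
print("recovered offset (row, col):", np.round(T.matrix[:, 2], 3))

aligned = apply_transform(scene.image_b, T, (64, 64))
report = evaluate_alignment(scene.image_a, aligned, scene.image_b, grid_step=4)
print("alpha-MI before alignment: %.3f" % report["alpha_mi_before"])
print("alpha-MI after alignment:  %.3f" % report["alpha_mi_after"])
print("relative gain:             %.2f" % report["relative_gain"])
```

Output:

```
recovered offset (row, col): [ 5.01 -3.  ]
alpha-MI before alignment: -0.369
alpha-MI after alignment:  0.365
relative gain:             1.99
```

The registration recovers the planted 5-px shift to 0.01 px, and the aligned
pair shares substantially more information than the unaligned one — the
α-MI moves from negative (estimator noise around independence) to clearly
positive, a relative gain of ~2.

A thin CLI wraps the two pipelines and the generators
(`mmtissue compress …`, `mmtissue register …`, `mmtissue synth …`); every
run writes a JSON parameter log beside its output.

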