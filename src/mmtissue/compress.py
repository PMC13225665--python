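"""Pixel-manifold image compression with principled dimensionality selection.

High-parameter images (tens of antibody channels, thousands of m/z bins) are
compressed into a low-dimensional per-pixel embedding before cross-technology
registration.  The procedure:

1. spatially subsample pixels (grid / random / pseudo-random, with automatic
   defaults keyed on the masked pixel count);
2. build the UMAP fuzzy simplicial set (a weighted undirected graph encoding
   local manifold structure) over the sampled pixel feature vectors;
3. reduce to spectral landmarks (randomized SVD of the membership matrix
   followed by mini-batch k-means; landmark = cluster centroid in the original
   feature space) so the exact fuzzy-set cross-entropy stays affordable;
4. embed the landmark graph into Euclidean spaces of dimension 1..n_max and
   compute the exact fuzzy-set cross-entropy in each;
5. fit a least-squares exponential ``(y0 - c)·exp(-k·i) + c`` to the min-max
   normalized cross-entropies and select the first dimensionality whose fitted
   value falls within the 95% band ``c ± 1.96σ`` of the asymptote (σ = residual
   SD, floored at 1e-6);
6. embed the subsample at the selected dimensionality, project all remaining
   pixels into the embedding, and write each embedding axis back to its pixel
   location as an image channel (min-max rescaled to [0, 1]).

Low-channel histology images take a separate path: median filtering, Otsu (or
manual) thresholding, and morphological cleanup of the foreground mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import curve_fit
from sklearn.cluster import MiniBatchKMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .images import MultichannelImage

__all__ = [
    "PixelSample",
    "FuzzySimplicialSet",
    "LandmarkSet",
    "EmbeddingModel",
    "DimScanResult",
    "CompressionConfig",
    "subsample_pixels",
    "build_fuzzy_set",
    "spectral_landmarks",
    "embed",
    "fuzzy_cross_entropy",
    "dimensionality_scan",
    "select_dimensionality",
    "project_out_of_sample",
    "compress_image",
    "preprocess_histology",
]

# membership clip keeping log terms finite in the cross-entropy
_EPS = 1e-8
# exact (deterministic) nearest neighbours up to this many points
_EXACT_NN_LIMIT = 20_000


@dataclass
class PixelSample:
    """Sampled pixel coordinates and their feature vectors."""

    coords: np.ndarray  # (n, 2) int row/col
    features: np.ndarray  # (n, C)
    scheme: str
    params: dict = field(default_factory=dict)


@dataclass
class FuzzySimplicialSet:
    """Sparse symmetric membership graph over sampled points."""

    edges: sp.csr_matrix
    n_neighbors: int
    metric: str = "euclidean"
    features: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return self.edges.shape[0]


@dataclass
class LandmarkSet:
    centroids: np.ndarray  # (k, C) in original feature space
    n_svd: int
    k: int
    assignment: np.ndarray  # (n,) point → cluster
    seed: int | None = None


@dataclass
class EmbeddingModel:
    dim: int
    coords: np.ndarray  # (n, dim)
    low_dim_curve: tuple[float, float]  # (a, b)
    graph: FuzzySimplicialSet
    seed: int | None = None


@dataclass
class DimScanResult:
    dims: np.ndarray
    cross_entropy: np.ndarray
    normalized: np.ndarray
    fit: tuple[float, float, float]  # (y0, k, c)
    residual_sd: float
    selected_dim: int


@dataclass
class CompressionConfig:
    """Tunable parameters of :func:`compress_image`."""

    subsample: str = "auto"  # auto | none | grid:g | random:f | pseudo:f,g
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    dims: tuple[int, ...] = tuple(range(1, 11))
    n_svd: int = 100
    k_landmarks: int = 3000
    use_landmarks: str = "auto"  # auto | always | never
    landmark_threshold: int = 4000  # use landmarks above this many sampled pixels
    n_epochs: int | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# subsampling


def _auto_scheme(n_masked: int) -> tuple[str, dict]:
    if n_masked < 50_000:
        return "none", {}
    if n_masked < 100_000:
        return "pseudo-random", {"fraction": 0.55, "grid_step": 2}
    if n_masked < 150_000:
        return "pseudo-random", {"fraction": 0.15, "grid_step": 3}
    return "grid", {"grid_step": 3}


def subsample_pixels(
    img: MultichannelImage,
    scheme: str = "auto",
    grid_step: int = 2,
    fraction: float = 0.5,
    seed: int | None = None,
) -> PixelSample:
    """Spatially subsample masked pixels.

    Schemes: ``none`` (all masked pixels), ``grid`` (every g-th row/col),
    ``random`` (⌈f·n⌉ without replacement), ``pseudo-random`` (g×g grid union
    random fill up to fraction f) and ``auto`` (defaults keyed on the masked
    pixel count: <50k all; 50–100k f=0.55, g=2; 100–150k f=0.15, g=3;
    >150k g=3 grid).
    """
    mask = img.foreground_mask()
    n_masked = int(mask.sum())
    if n_masked == 0:
        raise ValueError("empty mask: no pixels to sample")
    params = {"grid_step": grid_step, "fraction": fraction, "seed": seed}
    if scheme == "auto":
        scheme, auto_params = _auto_scheme(n_masked)
        params.update(auto_params)
        grid_step = params["grid_step"]
        fraction = params["fraction"] if "fraction" in auto_params else fraction

    rows, cols = np.nonzero(mask)
    if scheme == "none":
        sel = np.ones(n_masked, dtype=bool)
    elif scheme == "grid":
        sel = (rows % grid_step == 0) & (cols % grid_step == 0)
    elif scheme in ("random", "pseudo-random"):
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        rng = np.random.default_rng(seed)
        target = int(np.ceil(fraction * n_masked))
        if scheme == "random":
            idx = rng.choice(n_masked, size=target, replace=False)
            sel = np.zeros(n_masked, dtype=bool)
            sel[idx] = True
        else:
            sel = (rows % grid_step == 0) & (cols % grid_step == 0)
            deficit = target - int(sel.sum())
            if deficit > 0:
                pool = np.nonzero(~sel)[0]
                extra = rng.choice(pool, size=min(deficit, pool.size), replace=False)
                sel[extra] = True
    else:
        raise ValueError(f"unknown subsampling scheme {scheme!r}")
    if not sel.any():
        sel[0] = True
    coords = np.column_stack([rows[sel], cols[sel]]).astype(int)
    features = img.data[coords[:, 0], coords[:, 1], :].astype(np.float64)
    return PixelSample(coords=coords, features=features, scheme=scheme, params=params)


# ---------------------------------------------------------------------------
# fuzzy simplicial set


def _exact_knn(features: np.ndarray, n_neighbors: int, metric: str):
    nn = NearestNeighbors(n_neighbors=n_neighbors, metric=metric)
    nn.fit(features)
    dists, idx = nn.kneighbors(features)
    return idx.astype(np.int32), dists.astype(np.float32)


def build_fuzzy_set(
    features: np.ndarray,
    n_neighbors: int = 15,
    metric: str = "euclidean",
    seed: int = 0,
) -> FuzzySimplicialSet:
    """UMAP fuzzy simplicial set (symmetric fuzzy union of local memberships).

    Exact nearest neighbours are used up to 20,000 points so the graph is
    deterministic; larger inputs fall back to approximate neighbours.
    """
    from umap.umap_ import fuzzy_simplicial_set

    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more points ({n}) than neighbours ({n_neighbors})")
    if np.allclose(features, features[0]):
        raise ValueError("degenerate input: all points identical")
    rs = np.random.RandomState(seed)
    if n <= _EXACT_NN_LIMIT:
        knn_idx, knn_d = _exact_knn(features, n_neighbors, metric)
        graph, _, _ = fuzzy_simplicial_set(
            features, n_neighbors, rs, metric,
            knn_indices=knn_idx, knn_dists=knn_d,
        )
    else:  # pragma: no cover - large-data path
        graph, _, _ = fuzzy_simplicial_set(features, n_neighbors, rs, metric)
    graph = sp.csr_matrix(graph)
    graph.setdiag(0.0)
    graph.eliminate_zeros()
    return FuzzySimplicialSet(
        edges=graph, n_neighbors=n_neighbors, metric=metric, features=features
    )


def spectral_landmarks(
    g: FuzzySimplicialSet,
    features: np.ndarray,
    n_svd: int = 100,
    k: int = 3000,
    seed: int = 0,
) -> LandmarkSet:
    """Spectral landmark selection: randomized SVD of the membership matrix,
    mini-batch k-means on the spectral coordinates, centroids taken in the
    original feature space."""
    features = np.asarray(features, dtype=np.float64)
    n = g.n_points
    if k > n:
        warnings.warn(f"k={k} exceeds n={n}; clamping (landmarks = points)")
        k = n
    if k == n:
        return LandmarkSet(
            centroids=features.copy(), n_svd=0, k=n,
            assignment=np.arange(n), seed=seed,
        )
    n_comp = int(min(n_svd, n - 1, features.shape[0] - 1))
    svd = TruncatedSVD(n_components=n_comp, algorithm="randomized", random_state=seed)
    spectral = svd.fit_transform(g.edges)
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3, batch_size=1024)
    assignment = km.fit_predict(spectral)
    centroids = []
    for c in range(k):
        members = assignment == c
        if members.any():
            centroids.append(features[members].mean(axis=0))
    return LandmarkSet(
        centroids=np.asarray(centroids), n_svd=n_comp, k=len(centroids),
        assignment=assignment, seed=seed,
    )


# ---------------------------------------------------------------------------
# embedding and cross-entropy


def embed(
    g: FuzzySimplicialSet,
    dim: int,
    seed: int = 0,
    min_dist: float = 0.1,
    n_epochs: int | None = None,
) -> EmbeddingModel:
    """Embed the fuzzy simplicial set into ``dim`` Euclidean dimensions by
    stochastic minimisation of the fuzzy-set cross-entropy (UMAP layout)."""
    from umap.umap_ import find_ab_params, simplicial_set_embedding

    if dim < 1:
        raise ValueError("dim must be ≥ 1")
    a, b = find_ab_params(1.0, min_dist)
    rs = np.random.RandomState(seed)
    data = g.features
    if data is None:
        data = np.zeros((g.n_points, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, _ = simplicial_set_embedding(
            data,
            g.edges.tocoo(),
            dim,
            initial_alpha=1.0,
            a=a,
            b=b,
            gamma=1.0,
            negative_sample_rate=5,
            n_epochs=n_epochs,
            init="spectral",
            random_state=rs,
            metric=g.metric,
            metric_kwds={},
            densmap=False,
            densmap_kwds={},
            output_dens=False,
        )
    return EmbeddingModel(
        dim=dim, coords=np.asarray(coords, dtype=np.float64),
        low_dim_curve=(float(a), float(b)), graph=g, seed=seed,
    )


def _low_dim_membership(model: EmbeddingModel, rows, cols) -> np.ndarray:
    a, b = model.low_dim_curve
    diff = model.coords[rows] - model.coords[cols]
    d2 = np.einsum("ij,ij->i", diff, diff)
    return 1.0 / (1.0 + a * d2**b)


def fuzzy_cross_entropy(high: FuzzySimplicialSet, model: EmbeddingModel) -> float:
    """Exact fuzzy-set cross-entropy over the edge support of ``high``.

    ``Σ_e μ·log(μ/ν) + (1-μ)·log((1-μ)/(1-ν))`` where μ is the
    high-dimensional membership and ν the low-dimensional membership from the
    model's (a, b) curve, clipped to [1e-8, 1-1e-8].
    """
    if model.coords.shape[0] != high.n_points:
        raise ValueError("embedding and graph have mismatched point counts")
    coo = sp.triu(high.edges, k=1).tocoo()
    mu = np.clip(coo.data.astype(np.float64), _EPS, 1.0 - _EPS)
    nu = np.clip(_low_dim_membership(model, coo.row, coo.col), _EPS, 1.0 - _EPS)
    ce = mu * np.log(mu / nu) + (1.0 - mu) * np.log((1.0 - mu) / (1.0 - nu))
    return float(ce.sum())


def dimensionality_scan(
    g: FuzzySimplicialSet,
    dims=tuple(range(1, 11)),
    seed: int = 0,
    min_dist: float = 0.1,
    n_epochs: int | None = None,
) -> DimScanResult:
    """Embed ``g`` at each candidate dimensionality, compute the exact
    cross-entropy, and select the steady-state dimensionality."""
    dims = np.asarray(sorted(dims), dtype=int)
    entropies = np.array(
        [
            fuzzy_cross_entropy(g, embed(g, int(d), seed=seed, min_dist=min_dist,
                                         n_epochs=n_epochs))
            for d in dims
        ]
    )
    return select_dimensionality(dims, entropies)


def select_dimensionality(dims, cross_entropy) -> DimScanResult:
    """Exponential-regression dimensionality selection.

    Min-max normalizes the entropies, fits ``(y0-c)·exp(-k·i)+c`` by least
    squares over the dimension index i, and selects the first dimensionality
    whose fitted value enters the 95% residual band ``c + 1.96σ`` of the
    asymptote, evaluated on a dense grid of i so the choice is insensitive to
    integer gaps.  σ is floored at 1e-6.
    """
    dims = np.asarray(dims, dtype=float)
    e = np.asarray(cross_entropy, dtype=float)
    if dims.size < 4:
        raise ValueError("need at least 4 distinct dimensionalities")
    if not np.all(np.isfinite(e)):
        raise ValueError(f"non-finite cross-entropies: {e}")
    span = e.max() - e.min()
    if span <= 0:
        norm = np.zeros_like(e)
        return DimScanResult(
            dims=dims.astype(int), cross_entropy=e, normalized=norm,
            fit=(0.0, 0.0, 0.0), residual_sd=1e-6, selected_dim=int(dims[0]),
        )
    norm = (e - e.min()) / span

    def model(i, y0, k, c):
        return (y0 - c) * np.exp(-k * i) + c

    try:
        popt, _ = curve_fit(
            model, dims, norm,
            p0=(float(norm[0]) * np.exp(0.5 * dims[0]), 0.5, float(norm[-1])),
            bounds=([-10.0, 1e-6, -1.0], [1e6, 50.0, 1.0]),
            maxfev=20000,
        )
    except Exception as exc:
        raise RuntimeError(
            f"exponential regression failed to converge on entropies {e}"
        ) from exc
    y0, k, c = (float(v) for v in popt)
    resid = norm - model(dims, y0, k, c)
    sigma = max(float(np.std(resid)), 1e-6)
    threshold = c + 1.96 * sigma
    grid = np.linspace(dims[0], dims[-1], 2048)
    inside = model(grid, y0, k, c) <= threshold
    if inside.any():
        first = grid[np.argmax(inside)]
        candidates = dims[dims >= first - 1e-9]
        selected = int(candidates[0]) if candidates.size else int(dims[-1])
    else:
        selected = int(dims[-1])
    return DimScanResult(
        dims=dims.astype(int), cross_entropy=e, normalized=norm,
        fit=(y0, k, c), residual_sd=sigma, selected_dim=selected,
    )


def project_out_of_sample(model: EmbeddingModel, features: np.ndarray) -> np.ndarray:
    """Position new points by membership-weighted combination of their
    nearest training neighbours' embedding coordinates.

    Exact feature-space hits return the training coordinate itself; other
    points get an inverse-distance weighted average of the k nearest training
    embeddings.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.size == 0:
        raise ValueError("empty input")
    train = model.graph.features
    if train is None:
        raise ValueError("model graph carries no training features")
    if features.shape[1] != train.shape[1]:
        raise ValueError("feature dimensionality does not match training data")
    k = min(model.graph.n_neighbors, train.shape[0])
    nn = NearestNeighbors(n_neighbors=k, metric=model.graph.metric)
    nn.fit(train)
    dists, idx = nn.kneighbors(features)
    out = np.empty((features.shape[0], model.dim))
    exact = dists[:, 0] <= 1e-12
    out[exact] = model.coords[idx[exact, 0]]
    rest = ~exact
    if rest.any():
        w = 1.0 / (dists[rest] + 1e-12)
        w /= w.sum(axis=1, keepdims=True)
        out[rest] = np.einsum("ij,ijk->ik", w, model.coords[idx[rest]])
    return out


# ---------------------------------------------------------------------------
# full pipeline


def _parse_subsample_spec(spec: str) -> tuple[str, dict]:
    if spec in ("auto", "none"):
        return spec, {}
    kind, _, arg = spec.partition(":")
    if kind == "grid":
        return "grid", {"grid_step": int(arg)}
    if kind == "random":
        return "random", {"fraction": float(arg)}
    if kind == "pseudo":
        f, g = arg.split(",")
        return "pseudo-random", {"fraction": float(f), "grid_step": int(g)}
    raise ValueError(f"unknown subsample spec {spec!r}")


def compress_image(
    img: MultichannelImage, config: CompressionConfig | None = None
) -> tuple[MultichannelImage, DimScanResult]:
    """Full compression pipeline: subsample → fuzzy set → (landmarks) →
    dimensionality scan → embed → out-of-sample projection → raster.

    Returns the compressed image (one channel per embedding axis, min-max
    rescaled to [0, 1], masked-out pixels exactly 0) and the scan result.
    """
    cfg = config or CompressionConfig()
    scheme, kwargs = _parse_subsample_spec(cfg.subsample)
    sample = subsample_pixels(img, scheme, seed=cfg.seed, **kwargs)
    g = build_fuzzy_set(sample.features, cfg.n_neighbors, cfg.metric, seed=cfg.seed)

    use_lm = cfg.use_landmarks == "always" or (
        cfg.use_landmarks == "auto" and sample.features.shape[0] > cfg.landmark_threshold
    )
    if use_lm:
        lm = spectral_landmarks(
            g, sample.features, n_svd=cfg.n_svd,
            k=min(cfg.k_landmarks, sample.features.shape[0]), seed=cfg.seed,
        )
        scan_graph = build_fuzzy_set(
            lm.centroids, min(cfg.n_neighbors, lm.k - 1), cfg.metric, seed=cfg.seed
        )
    else:
        scan_graph = g
    scan = dimensionality_scan(
        scan_graph, cfg.dims, seed=cfg.seed, min_dist=cfg.min_dist,
        n_epochs=cfg.n_epochs,
    )

    model = embed(g, scan.selected_dim, seed=cfg.seed, min_dist=cfg.min_dist,
                  n_epochs=cfg.n_epochs)
    mask = img.foreground_mask()
    h, w, _ = img.data.shape
    out = np.zeros((h, w, scan.selected_dim), dtype=np.float64)
    out[sample.coords[:, 0], sample.coords[:, 1]] = model.coords
    in_sample = np.zeros((h, w), dtype=bool)
    in_sample[sample.coords[:, 0], sample.coords[:, 1]] = True
    remaining = mask & ~in_sample
    if remaining.any():
        rr, cc = np.nonzero(remaining)
        out[rr, cc] = project_out_of_sample(model, img.data[rr, cc, :])
    # per-channel min-max rescale over the mask, background exactly 0
    fg = out[mask]
    lo = fg.min(axis=0)
    hi = fg.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    out = (out - lo) / rng
    out[~mask] = 0.0
    names = [f"embed{i}" for i in range(scan.selected_dim)]
    compressed = MultichannelImage(
        out.astype(np.float32), names, img.resolution_um,
        mask=mask.copy(), origin=img.origin,
    )
    return compressed, scan


# ---------------------------------------------------------------------------
# histology preprocessing


def preprocess_histology(
    img: MultichannelImage, steps, foreground: str = "bright"
) -> tuple[MultichannelImage, np.ndarray]:
    """Apply ordered preprocessing steps to a low-channel histology image.

    Steps are strings or (name, arg) pairs drawn from {grayscale,
    median(radius), otsu, manual_threshold(t), open(r), close(r), fill}.
    Returns the grayscale image and the boolean foreground mask.
    """
    from scipy.ndimage import binary_fill_holes
    from skimage import filters, morphology

    gray = img.data.mean(axis=2) if img.n_channels > 1 else img.data[:, :, 0]
    gray = gray.astype(np.float64)
    mask = img.foreground_mask().copy()

    def parse(step):
        if isinstance(step, str):
            if "(" in step:
                name, arg = step.rstrip(")").split("(")
                return name, float(arg)
            return step, None
        return step

    for step in steps:
        name, arg = parse(step)
        if name == "grayscale":
            pass  # already grayscale above
        elif name == "median":
            gray = filters.median(gray, footprint=morphology.disk(int(arg or 1)))
        elif name == "otsu":
            if np.ptp(gray) == 0:
                raise ValueError("Otsu thresholding on a constant image")
            t = filters.threshold_otsu(gray)
            mask = gray > t if foreground == "bright" else gray < t
        elif name == "manual_threshold":
            mask = gray > float(arg) if foreground == "bright" else gray < float(arg)
        elif name == "open":
            mask = morphology.binary_opening(mask, morphology.disk(int(arg or 1)))
        elif name == "close":
            mask = morphology.binary_closing(mask, morphology.disk(int(arg or 1)))
        elif name == "fill":
            mask = binary_fill_holes(mask)
        else:
            raise ValueError(f"unknown preprocessing step {name!r}")
    out = MultichannelImage(
        gray[:, :, None].astype(np.float32), ["gray"], img.resolution_um,
        mask=np.asarray(mask, dtype=bool), origin=img.origin,
    )
    return out, np.asarray(mask, dtype=bool)
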