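"""Entropic-graph registration of multichannel images.

Cross-technology alignment cannot rely on intensity histograms: the two
modalities have different, unordered channel sets (e.g. 27-plex antibody
imaging vs thousands of m/z bins).  Instead, image similarity is measured as
the Rényi α-mutual information (α-MI) estimated from k-nearest-neighbour
(KNN) graph edge lengths of per-pixel feature vectors.  By the
Beardwood–Halton–Hammersley (BHH) theorem the power-weighted length of such a
graph,

    L_γ = Σ_i Σ_{j ∈ kNN(i)} ‖x_i − x_j‖^γ,     γ = d·(1 − α),

converges so that  Ĥ_α = (1 − α)^{-1} · [log(L_γ / n^α) − log β]  estimates
the Rényi α-entropy up to the distribution-independent BHH constant β.  The
constant cancels in entropy differences; when absolute values are needed, β
is calibrated by Monte-Carlo on uniform unit cubes of matched size so that
Ĥ_α(uniform [0,1]^d) → 0.  The mutual information is assembled as
Ĥ_α(X) + Ĥ_α(Y) − Ĥ_α(X, Y), with each marginal rescaled to unit per-axis
variance before concatenation into the joint space.  As α → 1 the measure
converges to Shannon MI; it is invariant to channel permutation within each
modality and well-defined for unequal channel counts.

Registration maximises α-MI (optionally minus a landmark penalty) over
translation / rigid / affine / cubic B-spline transform stages on a Gaussian
smoothing pyramid, using stochastic gradient descent with random coordinate
sampling and a decaying step, followed by a deterministic direction-set
polish on a fixed sample for sub-pixel accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

from .images import LandmarkPointSet, MultichannelImage

__all__ = [
    "AlphaMIConfig",
    "RegistrationConfig",
    "SpatialTransform",
    "AffineTransform",
    "BSplineTransform",
    "CompositeTransform",
    "knn_alpha_entropy",
    "alpha_mutual_information",
    "histogram_mutual_information",
    "make_pyramid",
    "landmark_penalty",
    "register",
    "apply_transform",
    "compose",
    "jacobian_determinant_map",
    "evaluate_alignment",
]


# ---------------------------------------------------------------------------
# entropic-graph estimators


@dataclass
class AlphaMIConfig:
    """Parameters of the KNN entropic-graph α-MI estimator."""

    alpha: float = 0.99
    k_neighbors: int = 15
    bhh_constant_mode: str = "calibrated"  # calibrated | relative

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be ≥ 1")


def _knn_dists(points: np.ndarray, k: int) -> np.ndarray:
    """Distances to the k nearest neighbours (self excluded) of every point.

    KD-trees degrade badly above ~10 dimensions, so high-dimensional inputs
    of moderate size take a dense vectorized path instead.
    """
    n, d = points.shape
    if d > 8 and n <= 8000:
        sq = np.einsum("ij,ij->i", points, points)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (points @ points.T)
        np.maximum(d2, 0.0, out=d2)
        part = np.partition(d2, k, axis=1)[:, : k + 1]
        part.sort(axis=1)
        return np.sqrt(part[:, 1:])  # drop self (zero) distance
    tree = cKDTree(points)
    dists, _ = tree.query(points, k=k + 1)
    return dists[:, 1:]


def _knn_length(points: np.ndarray, k: int, gamma: float) -> float:
    d = _knn_dists(points, k)
    with np.errstate(divide="ignore"):
        return float(np.power(d, gamma, where=d > 0, out=np.zeros_like(d)).sum())


# BHH constant calibration cache: (n, d, k, alpha) → log β
_BETA_CACHE: dict[tuple, float] = {}
_CALIBRATION_SEED = 987_654_321
_CALIBRATION_REPS = 2


def _log_beta(n: int, d: int, k: int, alpha: float) -> float:
    key = (n, d, k, round(alpha, 12))
    if key not in _BETA_CACHE:
        gamma = d * (1.0 - alpha)
        rng = np.random.default_rng(_CALIBRATION_SEED + d)
        vals = []
        for _ in range(_CALIBRATION_REPS):
            u = rng.random((n, d))
            vals.append(np.log(_knn_length(u, k, gamma)) - alpha * np.log(n))
        _BETA_CACHE[key] = float(np.mean(vals))
    return _BETA_CACHE[key]


def knn_alpha_entropy(
    points: np.ndarray,
    k: int = 15,
    alpha: float = 0.99,
    mode: str = "relative",
) -> float:
    """KNN entropic-graph Rényi α-entropy estimate.

    ``mode="relative"`` drops the BHH constant (value is defined up to an
    additive constant shared by all point sets of equal n, d, k);
    ``mode="calibrated"`` subtracts a Monte-Carlo estimate of log β on the
    uniform unit cube so Ĥ_α(uniform [0,1]^d) ≈ 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n, d = points.shape
    if n <= k:
        raise ValueError(f"need n > k ({n} ≤ {k})")
    gamma = d * (1.0 - alpha)
    L = _knn_length(points, k, gamma)
    if L <= 0:
        raise ValueError("degenerate point cloud: all points identical")
    h = (np.log(L) - alpha * np.log(n)) / (1.0 - alpha)
    if mode == "calibrated":
        h -= _log_beta(n, d, k, alpha) / (1.0 - alpha)
    elif mode != "relative":
        raise ValueError(f"unknown mode {mode!r}")
    return float(h)


def _unit_variance(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return x / sd


def alpha_mutual_information(
    featA: np.ndarray, featB: np.ndarray, cfg: AlphaMIConfig | None = None
) -> float:
    """Entropic-graph Rényi α-MI between paired feature samples.

    Rows must correspond to the same sampled locations.  Marginals are
    rescaled to unit per-axis variance before concatenation into the joint
    space; the result is invariant to column permutation within either
    modality and converges to Shannon MI as α → 1.
    """
    cfg = cfg or AlphaMIConfig()
    a = np.asarray(featA, dtype=np.float64)
    b = np.asarray(featB, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] != b.shape[0]:
        raise ValueError("featA and featB must have the same number of rows")
    if a.shape[0] <= cfg.k_neighbors:
        raise ValueError("need more samples than neighbours")
    for x, name in ((a, "featA"), (b, "featB")):
        if np.allclose(x, x[0]):
            raise ValueError(f"degenerate marginal: {name} is constant")
    a = _unit_variance(a)
    b = _unit_variance(b)
    joint = np.hstack([a, b])
    k = cfg.k_neighbors
    al = cfg.alpha
    mode = cfg.bhh_constant_mode
    hx = knn_alpha_entropy(a, k, al, mode)
    hy = knn_alpha_entropy(b, k, al, mode)
    hxy = knn_alpha_entropy(joint, k, al, mode)
    return hx + hy - hxy


def histogram_mutual_information(
    a: np.ndarray, b: np.ndarray, bins: int = 32
) -> float:
    """Shannon MI from a joint 2-D histogram of two grayscale samples (nats)."""
    joint, _, _ = np.histogram2d(np.ravel(a), np.ravel(b), bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


# ---------------------------------------------------------------------------
# spatial transforms


class SpatialTransform:
    """Maps fixed-space (row, col) points to moving-space points."""

    kind: str = "base"

    def apply(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "SpatialTransform":
        kind = d["kind"]
        if kind == "affine":
            return AffineTransform(np.asarray(d["matrix"], dtype=float))
        if kind == "bspline":
            return BSplineTransform(
                np.asarray(d["displacements"], dtype=float),
                spacing=float(d["spacing"]),
                origin=tuple(d.get("origin", (0.0, 0.0))),
            )
        if kind == "composite":
            return CompositeTransform(
                [SpatialTransform.from_dict(c) for c in d["children"]]
            )
        raise ValueError(f"unknown transform kind {kind!r}")


class AffineTransform(SpatialTransform):
    """2-D affine map ``p ↦ A p + t`` given as a 2×3 matrix [A | t]."""

    kind = "affine"

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=float).reshape(2, 3)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]))

    @classmethod
    def translation(cls, dr: float, dc: float) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, dr], [0.0, 1.0, dc]]))

    @classmethod
    def rotation(cls, angle_rad: float, center=(0.0, 0.0)) -> "AffineTransform":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        center = np.asarray(center, dtype=float)
        t = center - rot @ center
        return cls(np.hstack([rot, t[:, None]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.matrix[:, :2].T + self.matrix[:, 2]

    def to_dict(self) -> dict:
        return {"kind": "affine", "matrix": self.matrix.tolist()}


class BSplineTransform(SpatialTransform):
    """Cubic B-spline free-form deformation on a uniform control grid.

    ``displacements`` has shape (2, gh, gw): row/col displacement coefficients
    at control points spaced ``spacing`` pixels apart, anchored at ``origin``.
    The displacement field is the cubic B-spline combination of the grid
    coefficients; the transform is ``p ↦ p + u(p)``.
    """

    kind = "bspline"

    def __init__(self, displacements: np.ndarray, spacing: float, origin=(0.0, 0.0)):
        self.displacements = np.asarray(displacements, dtype=float)
        if self.displacements.ndim != 3 or self.displacements.shape[0] != 2:
            raise ValueError("displacements must have shape (2, gh, gw)")
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        self.spacing = float(spacing)
        self.origin = tuple(float(o) for o in origin)

    @classmethod
    def identity_grid(
        cls, shape: tuple[int, int], spacing: float
    ) -> "BSplineTransform":
        h, w = shape
        gh = int(np.ceil(h / spacing)) + 4
        gw = int(np.ceil(w / spacing)) + 4
        origin = (-2.0 * spacing, -2.0 * spacing)
        return cls(np.zeros((2, gh, gw)), spacing, origin)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        gp = (p - np.asarray(self.origin)) / self.spacing
        coords = [gp[:, 0], gp[:, 1]]
        # prefilter=False treats grid values as B-spline coefficients (FFD)
        ur = ndimage.map_coordinates(
            self.displacements[0], coords, order=3, mode="nearest", prefilter=False
        )
        uc = ndimage.map_coordinates(
            self.displacements[1], coords, order=3, mode="nearest", prefilter=False
        )
        return np.column_stack([ur, uc])

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p + self.displacement(p)

    def to_dict(self) -> dict:
        return {
            "kind": "bspline",
            "displacements": self.displacements.tolist(),
            "spacing": self.spacing,
            "origin": list(self.origin),
        }


class CompositeTransform(SpatialTransform):
    """Ordered chain: ``p ↦ T_last(…T_first(p)…)``."""

    kind = "composite"

    def __init__(self, children: list[SpatialTransform]):
        if not children:
            raise ValueError("composite transform needs at least one child")
        self.children = list(children)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        for t in self.children:
            p = t.apply(p)
        return p

    def to_dict(self) -> dict:
        return {"kind": "composite", "children": [c.to_dict() for c in self.children]}


def compose(transforms: list[SpatialTransform]) -> SpatialTransform:
    """Compose an ordered list of transforms (first applied first)."""
    if not transforms:
        raise ValueError("cannot compose an empty transform list")
    if len(transforms) == 1:
        return transforms[0]
    if all(isinstance(t, AffineTransform) for t in transforms):
        m = np.eye(3)
        for t in transforms:
            m = np.vstack([t.matrix, [0, 0, 1]]) @ m
        return AffineTransform(m[:2, :])
    return CompositeTransform(transforms)


# ---------------------------------------------------------------------------
# warping and diagnostics


_ORDERS = {"nearest": 0, "linear": 1, "bspline3": 3}


def apply_transform(
    img: MultichannelImage,
    T: SpatialTransform,
    out_shape: tuple[int, int] | None = None,
    interpolation: str = "linear",
) -> MultichannelImage:
    """Backward-warp ``img`` through ``T``: output pixel p receives the
    interpolated moving-image value at T(p); out-of-bounds pixels are zero
    and masked out."""
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = _ORDERS[interpolation]
    h, w, c = img.data.shape
    oh, ow = out_shape or (h, w)
    rr, cc = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    mapped = T.apply(pts)
    coords = [mapped[:, 0], mapped[:, 1]]
    out = np.zeros((oh, ow, c), dtype=np.float32)
    for ch in range(c):
        out[:, :, ch] = ndimage.map_coordinates(
            img.data[:, :, ch].astype(np.float64), coords, order=order, cval=0.0
        ).reshape(oh, ow)
    inb = (
        (mapped[:, 0] >= 0)
        & (mapped[:, 0] <= h - 1)
        & (mapped[:, 1] >= 0)
        & (mapped[:, 1] <= w - 1)
    ).reshape(oh, ow)
    mask = inb
    if img.mask is not None:
        src_mask = ndimage.map_coordinates(
            img.mask.astype(np.float64), coords, order=0, cval=0.0
        ).reshape(oh, ow)
        mask = inb & (src_mask > 0.5)
    out[~mask] = 0.0
    return MultichannelImage(
        out, list(img.channel_names), img.resolution_um, mask=mask
    )


def jacobian_determinant_map(
    T: SpatialTransform, shape: tuple[int, int], eps: float = 0.5
) -> MultichannelImage:
    """Per-pixel determinant of the spatial Jacobian of ``T`` (analytic for
    affine, central finite differences otherwise).  Values far from 1 flag
    unrealistic warping."""
    h, w = shape
    if isinstance(T, AffineTransform):
        det = float(np.linalg.det(T.matrix[:, :2]))
        data = np.full((h, w, 1), det, dtype=np.float32)
        return MultichannelImage(data, ["det_jacobian"])
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dr = T.apply(pts + [eps, 0]) - T.apply(pts - [eps, 0])
    dc = T.apply(pts + [0, eps]) - T.apply(pts - [0, eps])
    j00 = dr[:, 0] / (2 * eps)
    j10 = dr[:, 1] / (2 * eps)
    j01 = dc[:, 0] / (2 * eps)
    j11 = dc[:, 1] / (2 * eps)
    det = (j00 * j11 - j01 * j10).reshape(h, w, 1).astype(np.float32)
    return MultichannelImage(det, ["det_jacobian"])


def landmark_penalty(T: SpatialTransform, lm: LandmarkPointSet) -> float:
    """Mean squared Euclidean distance between T(fixed) and moving points."""
    if len(lm) == 0:
        warnings.warn("empty landmark set: penalty is 0")
        return 0.0
    mapped = T.apply(lm.fixed_points)
    return float(np.mean(np.sum((mapped - lm.moving_points) ** 2, axis=1)))


def make_pyramid(img: MultichannelImage, levels: int = 1) -> list[MultichannelImage]:
    """Gaussian smoothing pyramid: level ℓ smoothed with σ = 2^(levels−ℓ−1),
    finest level unsmoothed.  Resolution is kept (no decimation)."""
    if levels < 1:
        raise ValueError("levels must be ≥ 1")
    out = []
    for lvl in range(levels):
        sigma = 0.0 if lvl == levels - 1 else float(2 ** (levels - lvl - 1))
        if sigma == 0:
            out.append(img)
        else:
            data = np.stack(
                [
                    ndimage.gaussian_filter(img.data[:, :, ch].astype(float), sigma)
                    for ch in range(img.n_channels)
                ],
                axis=-1,
            ).astype(np.float32)
            out.append(
                MultichannelImage(
                    data, list(img.channel_names), img.resolution_um, mask=img.mask
                )
            )
    return out


# ---------------------------------------------------------------------------
# registration


@dataclass
class RegistrationConfig:
    """Stage list, pyramid, metric, and optimizer schedule for :func:`register`."""

    stages: tuple[str, ...] = ("translation", "affine")
    pyramid_levels: int = 2
    metric: AlphaMIConfig = field(default_factory=AlphaMIConfig)
    iterations: int = 60
    samples_per_iteration: int = 2000
    landmark_weight: float = 0.0
    bspline_spacing: float = 32.0
    bspline_iterations: int = 40
    step0: float = 2.0  # initial step (px) at the coarsest level
    step_A: float = 10.0
    step_decay: float = 0.602
    sample_margin: float = 6.0  # px kept clear of the moving border
    polish: bool = True
    polish_samples: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be ≥ 1")
        if self.bspline_spacing <= 0:
            raise ValueError("bspline_spacing must be positive")


def _stage_params(stage: str, shape: tuple[int, int]):
    """Initial parameter vector, per-parameter scales, and builder for a stage."""
    center = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])

    if stage == "translation":
        def build(p, init):
            return compose([init, AffineTransform.translation(p[0], p[1])])
        return np.zeros(2), np.ones(2), build
    if stage == "rigid":
        def build(p, init):
            rot = AffineTransform.rotation(p[0], center=center)
            tr = AffineTransform.translation(p[1], p[2])
            return compose([init, rot, tr])
        return np.zeros(3), np.array([0.01, 1.0, 1.0]), build
    if stage == "affine":
        def build(p, init):
            lin = np.eye(2) + p[:4].reshape(2, 2)
            t = center - lin @ center + p[4:6]
            return compose([init, AffineTransform(np.hstack([lin, t[:, None]]))])
        return np.zeros(6), np.array([0.01] * 4 + [1.0] * 2), build
    raise ValueError(f"unknown stage {stage!r}")


def _sample_coords(
    mask: np.ndarray,
    n: int,
    rng,
    T=None,
    moving_shape=None,
    margin: float = 0.0,
) -> np.ndarray:
    """Random fixed-domain coordinates, optionally restricted to points the
    current transform maps at least ``margin`` pixels inside the moving
    image, so nearby candidate transforms keep the whole sample in bounds
    (no sample-size bias between candidates)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("fixed image has an empty mask")
    pts = np.column_stack([rows, cols]).astype(float)
    if T is not None and moving_shape is not None and margin > 0:
        mapped = T.apply(pts)
        h, w = moving_shape
        inside = (
            (mapped[:, 0] >= margin)
            & (mapped[:, 0] <= h - 1 - margin)
            & (mapped[:, 1] >= margin)
            & (mapped[:, 1] <= w - 1 - margin)
        )
        if inside.sum() >= max(64, n // 4):
            pts = pts[inside]
    idx = rng.choice(pts.shape[0], size=min(n, pts.shape[0]), replace=False)
    return pts[idx]


def _features_at(img_data: np.ndarray, pts: np.ndarray) -> np.ndarray:
    coords = [pts[:, 0], pts[:, 1]]
    return np.column_stack(
        [
            ndimage.map_coordinates(
                img_data[:, :, ch], coords, order=1, mode="nearest"
            )
            for ch in range(img_data.shape[2])
        ]
    )


def _cost(
    T: SpatialTransform,
    fixed_data: np.ndarray,
    moving_data: np.ndarray,
    pts: np.ndarray,
    cfg: RegistrationConfig,
    lm: LandmarkPointSet | None,
) -> float:
    mapped = T.apply(pts)
    h, w = moving_data.shape[:2]
    valid = (
        (mapped[:, 0] >= 0)
        & (mapped[:, 0] <= h - 1)
        & (mapped[:, 1] >= 0)
        & (mapped[:, 1] <= w - 1)
    )
    k = cfg.metric.k_neighbors
    n_valid = int(valid.sum())
    # transforms that push more than half the sample out of the moving
    # domain are implausible (overlapping field of view is a precondition)
    # and small surviving subsets give spuriously biased graph lengths
    if n_valid < max(k + 6, pts.shape[0] // 2):
        return 1e6
    fa = _features_at(fixed_data, pts[valid])
    fb = _features_at(moving_data, mapped[valid])
    mi_cfg = AlphaMIConfig(
        alpha=cfg.metric.alpha,
        k_neighbors=k,
        bhh_constant_mode="relative",
    )
    try:
        # subtract the sample-size part of the relative-mode constant so the
        # cost does not favour transforms that merely keep more samples inside
        cost = -(alpha_mutual_information(fa, fb, mi_cfg) - np.log(n_valid))
    except ValueError:  # degenerate sample
        cost = 0.0
    if lm is not None and len(lm) > 0 and cfg.landmark_weight > 0:
        cost += cfg.landmark_weight * landmark_penalty(T, lm)
    if not np.isfinite(cost):
        raise RuntimeError(f"non-finite registration cost for transform {T.to_dict()}")
    return cost


def _sgd_stage(
    params, scales, build, init_T, fixed_data, moving_data, mask, cfg, lm,
    iterations, step0, rng,
):
    p = params.copy()
    for t in range(iterations):
        pts = _sample_coords(
            mask, cfg.samples_per_iteration, rng,
            T=build(p, init_T), moving_shape=moving_data.shape[:2],
            margin=cfg.sample_margin,
        )

        def f(q):
            return _cost(build(q, init_T), fixed_data, moving_data, pts, cfg, lm)

        grad = np.zeros_like(p)
        for i in range(p.size):
            h = 0.25 * scales[i]
            e = np.zeros_like(p)
            e[i] = h
            grad[i] = (f(p + e) - f(p - e)) / (2 * h)
        ge = grad * scales
        norm = np.linalg.norm(ge)
        if norm > 0:
            step = step0 / (cfg.step_A + t) ** cfg.step_decay
            p = p - step * scales * (ge / norm)
    return p


def _register_bspline(
    init_T, fixed_data, moving_data, mask, cfg, lm, rng
) -> SpatialTransform:
    """Greedy coordinate search over the control grid on a fixed sample.

    The per-coefficient MI gradient is far below the resampling noise of a
    stochastic cost, so the nonlinear stage descends deterministically: one
    seeded coordinate sample, then sweeps over the control coefficients with
    shrinking pixel-scale probe steps, accepting any move that lowers the
    cost.  The sampled cost is noise-free between evaluations, so descent is
    monotone.
    """
    shape = fixed_data.shape[:2]
    bs = BSplineTransform.identity_grid(shape, cfg.bspline_spacing)
    n_params = bs.displacements.size
    flat = bs.displacements.ravel().copy()
    pts = _sample_coords(
        mask, cfg.polish_samples, rng,
        T=init_T, moving_shape=moving_data.shape[:2], margin=cfg.sample_margin,
    )

    def f(q):
        bt = BSplineTransform(
            q.reshape(bs.displacements.shape), bs.spacing, bs.origin
        )
        return _cost(compose([init_T, bt]), fixed_data, moving_data, pts, cfg, lm)

    current = f(flat)
    steps = [cfg.step0, cfg.step0 / 2, cfg.step0 / 4, cfg.step0 / 8]
    for step in steps:
        for _ in range(max(1, cfg.bspline_iterations // len(steps) // 8)):
            improved = False
            order = rng.permutation(n_params)
            for i in order:
                e = np.zeros(n_params)
                e[i] = step
                up = f(flat + e)
                if up < current:
                    flat, current, improved = flat + e, up, True
                    continue
                down = f(flat - e)
                if down < current:
                    flat, current, improved = flat - e, down, True
            if not improved:
                break
    return BSplineTransform(flat.reshape(bs.displacements.shape), bs.spacing, bs.origin)


def register(
    fixed: MultichannelImage,
    moving: MultichannelImage,
    cfg: RegistrationConfig | None = None,
    lm: LandmarkPointSet | None = None,
) -> SpatialTransform:
    """Estimate the transform mapping fixed-space points into the moving image
    by maximising α-MI (minus an optional landmark penalty).

    Stages run in order, each initialised from the previous result, over a
    Gaussian smoothing pyramid per stage.  The trajectory is fixed by
    ``cfg.seed``.
    """
    cfg = cfg or RegistrationConfig()
    rng = np.random.default_rng(cfg.seed)
    shape = fixed.data.shape[:2]
    fixed_pyr = make_pyramid(fixed, cfg.pyramid_levels)
    moving_pyr = make_pyramid(moving, cfg.pyramid_levels)
    mask = fixed.foreground_mask()
    current: SpatialTransform = AffineTransform.identity()

    for stage in cfg.stages:
        if stage == "bspline":
            # nonlinear correction estimated on the finest pyramid level only
            fdat = fixed_pyr[-1].data.astype(np.float64)
            mdat = moving_pyr[-1].data.astype(np.float64)
            bt = _register_bspline(current, fdat, mdat, mask, cfg, lm, rng)
            current = compose([current, bt])
            continue
        params, scales, build = _stage_params(stage, shape)
        init_T = current
        for lvl in range(cfg.pyramid_levels):
            fdat = fixed_pyr[lvl].data.astype(np.float64)
            mdat = moving_pyr[lvl].data.astype(np.float64)
            step0 = cfg.step0 / (2**lvl)
            params = _sgd_stage(
                params, scales, build, init_T, fdat, mdat, mask, cfg, lm,
                cfg.iterations, step0, rng,
            )
        if cfg.polish:
            fdat = fixed_pyr[-1].data.astype(np.float64)
            mdat = moving_pyr[-1].data.astype(np.float64)
            polish_rng = np.random.default_rng(cfg.seed + 1)
            pts = _sample_coords(
                mask, cfg.polish_samples, polish_rng,
                T=build(params, init_T), moving_shape=mdat.shape[:2],
                margin=cfg.sample_margin,
            )

            def f(q):
                return _cost(build(q, init_T), fdat, mdat, pts, cfg, lm)

            res = minimize(
                f, params, method="Powell",
                options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": 150 * params.size},
            )
            params = res.x
        current = build(params, init_T)
    return current


# ---------------------------------------------------------------------------
# alignment evaluation


def evaluate_alignment(
    imgA: MultichannelImage,
    imgB: MultichannelImage,
    imgB_before: MultichannelImage | None = None,
    cfg: AlphaMIConfig | None = None,
    grid_step: int = 10,
    variance_keep: float = 0.99,
) -> dict:
    """α-MI alignment report on a uniformly spaced sample grid.

    Pixels are sampled every ``grid_step`` rows/cols inside the mask
    intersection; each modality is reduced by PCA retaining
    ``variance_keep`` of its variance before the KNN graph is built.  When an
    unregistered counterpart ``imgB_before`` is supplied the report includes
    the relative α-MI gain of the aligned pair over the unaligned one.
    """
    cfg = cfg or AlphaMIConfig()
    inter = imgA.foreground_mask() & imgB.foreground_mask()
    if not inter.any():
        raise ValueError("empty mask intersection")
    h, w = inter.shape
    grid = np.zeros_like(inter)
    grid[::grid_step, ::grid_step] = True
    sel = inter & grid
    if sel.sum() <= cfg.k_neighbors:
        sel = inter  # tiny images: fall back to every masked pixel
    rr, cc = np.nonzero(sel)

    def reduced(img):
        feats = img.data[rr, cc, :].astype(np.float64)
        if feats.shape[1] > 1:
            n_comp = min(feats.shape[0] - 1, feats.shape[1])
            p = PCA(n_components=n_comp, svd_solver="full").fit(feats)
            cum = np.cumsum(p.explained_variance_ratio_)
            keep = int(np.searchsorted(cum, variance_keep) + 1)
            return p.transform(feats)[:, :keep]
        return feats

    fa = reduced(imgA)
    fb = reduced(imgB)
    mi_after = alpha_mutual_information(fa, fb, cfg)
    report = {"alpha_mi_after": mi_after, "n_samples": int(rr.size)}
    if imgB_before is not None:
        fb0 = reduced(imgB_before)
        mi_before = alpha_mutual_information(fa, fb0, cfg)
        report["alpha_mi_before"] = mi_before
        denom = abs(mi_before) if mi_before != 0 else 1.0
        report["relative_gain"] = (mi_after - mi_before) / denom
    return report
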