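"""Deterministic synthetic data with known ground truth.

Every input the pipeline consumes can be generated here: low-rank feature
manifolds for dimensionality-selection tests, co-registered multimodal image
pairs (a shared latent "tissue anatomy" viewed through two independent
channel signatures, one grid warped by a known transform), and scattered
cell scenes with class effects planted at the single-cell and/or
neighbourhood level.  All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import LandmarkPointSet, MultichannelImage
from .quantify import CellTable
from .register import AffineTransform, SpatialTransform

__all__ = [
    "SyntheticScene",
    "make_manifold",
    "make_multimodal_pair",
    "make_cell_scene",
]


@dataclass
class SyntheticScene:
    """Container for generated data plus its ground truth."""

    seed: int
    region_labels: np.ndarray | None = None
    image_a: MultichannelImage | None = None
    image_b: MultichannelImage | None = None
    image_b_aligned: MultichannelImage | None = None
    true_transform: SpatialTransform | None = None
    landmarks: LandmarkPointSet | None = None
    cell_table: CellTable | None = None
    cell_classes: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def make_manifold(
    intrinsic_dim: int,
    ambient_dim: int,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "linear",
) -> np.ndarray:
    """Rank-r point cloud rotated into D ambient dimensions plus isotropic
    noise.  ``kind="curved"`` bends the first latent axis onto a sine arc so
    the manifold is non-linear but still r-dimensional."""
    if intrinsic_dim > ambient_dim:
        raise ValueError("intrinsic_dim must not exceed ambient_dim")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, intrinsic_dim))
    if kind == "curved":
        lift = np.column_stack([z, np.sin(z[:, 0])])
        basis, _ = np.linalg.qr(
            rng.standard_normal((ambient_dim, lift.shape[1]))
        )
        x = lift @ basis.T
    elif kind == "linear":
        basis, _ = np.linalg.qr(rng.standard_normal((ambient_dim, intrinsic_dim)))
        x = z @ basis.T
    else:
        raise ValueError(f"unknown manifold kind {kind!r}")
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


def _latent_regions(shape, n_regions, rng, lloyd_iters: int = 3) -> np.ndarray:
    """Voronoi latent region map; a few Lloyd relaxation steps balance the
    compartment areas the way tissue compartments are commensurate."""
    h, w = shape
    centers = rng.uniform(0, [h, w], size=(n_regions, 2))
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rr, cc], axis=-1).astype(float)
    for _ in range(lloyd_iters + 1):
        d = np.linalg.norm(pts[:, :, None, :] - centers[None, None, :, :], axis=-1)
        labels = np.argmin(d, axis=-1)
        for i in range(n_regions):
            members = pts[labels == i]
            if len(members):
                centers[i] = members.mean(axis=0)
    return labels


def _render(labels_cont, signatures, noise, rng) -> np.ndarray:
    img = signatures[labels_cont]
    if noise > 0:
        img = img + noise * rng.standard_normal(img.shape)
    return img.astype(np.float32)


def _build_transform(spec) -> AffineTransform:
    if isinstance(spec, SpatialTransform):
        return spec
    if spec is None or spec == "identity":
        return AffineTransform.identity()
    kind = spec.get("kind", "translation")
    if kind == "identity":
        return AffineTransform.identity()
    if kind == "translation":
        dr, dc = spec["offset"]
        return AffineTransform.translation(dr, dc)
    if kind == "rigid" or kind == "affine":
        angle = float(spec.get("angle_deg", 0.0)) * np.pi / 180.0
        center = spec.get("center", (0.0, 0.0))
        rot = AffineTransform.rotation(angle, center=center)
        dr, dc = spec.get("offset", (0.0, 0.0))
        m = np.vstack([AffineTransform.translation(dr, dc).matrix, [0, 0, 1]]) @ \
            np.vstack([rot.matrix, [0, 0, 1]])
        return AffineTransform(m[:2, :])
    raise ValueError(f"unknown transform spec {spec!r}")


def make_multimodal_pair(
    shape: tuple[int, int] = (64, 64),
    channels_a: int = 12,
    channels_b: int = 30,
    transform=None,
    n_regions: int = 5,
    noise: float = 0.05,
    seed: int = 0,
    n_landmarks: int = 8,
) -> SyntheticScene:
    """Two images of the same latent region map through independent channel
    signatures, with modality B resampled through a known transform.

    ``true_transform`` maps A-grid (fixed) coordinates to B-grid (moving)
    coordinates: registering B onto A should recover it, and
    ``image_b_aligned`` (B resampled at T(p)) corresponds pixelwise to A.
    """
    rng = np.random.default_rng(seed)
    labels = _latent_regions(shape, n_regions, rng)
    sig_a = rng.uniform(0.1, 1.0, size=(n_regions, channels_a))
    sig_b = rng.uniform(0.1, 1.0, size=(n_regions, channels_b))
    T = _build_transform(transform)

    img_a = _render(labels, sig_a, noise, rng)
    aligned_b = _render(labels, sig_b, noise, rng)

    # moving grid: B(q) = signature at latent label of T^{-1}(q)
    m = np.vstack([T.matrix, [0, 0, 1]])
    minv = np.linalg.inv(m)[:2, :]
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    q = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    p = q @ minv[:, :2].T + minv[:, 2]
    src_labels = ndimage.map_coordinates(
        labels.astype(float), [p[:, 0], p[:, 1]], order=0, mode="nearest"
    ).astype(int).reshape(shape)
    img_b = _render(src_labels, sig_b, noise, rng)

    lm_pts = rng.uniform([2, 2], [h - 3, w - 3], size=(n_landmarks, 2))
    landmarks = LandmarkPointSet(lm_pts, T.apply(lm_pts))

    def as_img(data, prefix):
        names = [f"{prefix}{i}" for i in range(data.shape[2])]
        return MultichannelImage(data, names)

    return SyntheticScene(
        seed=seed,
        region_labels=labels,
        image_a=as_img(img_a, "a"),
        image_b=as_img(img_b, "b"),
        image_b_aligned=as_img(aligned_b, "b"),
        true_transform=T,
        landmarks=landmarks,
    )


def make_cell_scene(
    n_cells: int = 600,
    n_cores: int = 9,
    n_classes: int = 2,
    n_features: int = 8,
    core_size_um: float = 300.0,
    single_cell_effect: float = 0.0,
    neighborhood_effect: float = 0.0,
    noise_sd: float = 1.0,
    radius_um: float = 75.0,
    seed: int = 0,
) -> SyntheticScene:
    """Poisson-scattered cells in ``n_cores`` square cores with planted class
    effects.

    ``single_cell_effect`` shifts the first feature's mean by that many noise
    SDs per class step — a signal visible to single-cell features directly.
    ``neighborhood_effect`` scales each class's cell density (class c keeps a
    fraction ``1/(1 + neighborhood_effect·c)`` of its cells) while leaving
    every cell's own feature distribution identical across classes, so only
    neighbourhood-aggregated (interaction) features carry class signal.
    """
    rng = np.random.default_rng(seed)
    classes = np.arange(n_classes)
    core_class = np.array([classes[i % n_classes] for i in range(n_cores)])
    per_core = max(n_cells // n_cores, 10)
    rows = []
    cell_id = 1
    for core in range(n_cores):
        c = core_class[core]
        n_core = per_core
        if neighborhood_effect > 0:
            n_core = max(int(round(per_core / (1.0 + neighborhood_effect * c))), 5)
        # tile cores on a grid with gaps far beyond any neighbourhood radius
        grid_cols = int(np.ceil(np.sqrt(n_cores)))
        offset = np.array(
            [core // grid_cols, core % grid_cols], dtype=float
        ) * (core_size_um + 10.0 * radius_um)
        xy = offset + rng.uniform(0, core_size_um, size=(n_core, 2))
        feats = 1.0 + noise_sd * rng.standard_normal((n_core, n_features))
        if single_cell_effect != 0:
            feats[:, 0] += single_cell_effect * noise_sd * c
        for i in range(n_core):
            rows.append(
                {
                    "sample_id": f"core{core:02d}",
                    "cell_id": cell_id,
                    "row": xy[i, 0],
                    "col": xy[i, 1],
                    "area": 1.0,
                    "eccentricity": 0.0,
                    "solidity": 1.0,
                    "extent": 1.0,
                    "class": int(c),
                    **{f"imc_f{j}": feats[i, j] for j in range(n_features)},
                }
            )
            cell_id += 1
    df = pd.DataFrame(rows)
    table = CellTable(
        df,
        {"imc": [f"imc_f{j}" for j in range(n_features)]},
        resolution_um=(1.0, 1.0),
    )
    return SyntheticScene(
        seed=seed,
        cell_table=table,
        cell_classes=df["class"].to_numpy(),
        extras={"core_class": core_class, "radius_um": radius_um},
    )
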