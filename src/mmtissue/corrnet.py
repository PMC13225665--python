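"""Microenvironmental correlation network analysis.

Links per-cell microenvironment intensities from MSI (m/z peaks, sampled at
each cell's location from the aligned raster) with per-cell protein
expression from antibody imaging:

* pairwise Spearman correlation of every peak against every protein, with a
  Bonferroni filter (corrected p ≤ 0.001 against at least one protein keeps
  a peak);
* module detection on the kept peaks — inverse-cosine (arccos) transform of
  peak–peak correlation into a metric distance, 5-nearest-neighbour fuzzy
  simplicial set, Louvain community detection across a resolution grid with
  the elbow of the resolution–modularity curve choosing the partition;
* exponentially weighted moving-average trends of module intensities along a
  spatial ordering (e.g. distance from a wound centre);
* differential correlation between two cell populations via the Fisher
  z-transform, with Bonferroni control and ranking weighted by the larger
  absolute correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "CorrelationNetwork",
    "cross_modal_correlation",
    "detect_modules",
    "ewma_trend",
    "fisher_z",
    "differential_correlation",
]

_ATANH_CLIP = 1.0 - 1e-7


@dataclass
class CorrelationNetwork:
    rho: np.ndarray  # peaks × proteins Spearman matrix (NaN where undefined)
    pvals: np.ndarray  # matching two-sided raw p-values
    kept_peaks: np.ndarray  # boolean per peak after the Bonferroni filter
    peak_names: list[str]
    protein_names: list[str]
    modules: np.ndarray | None = None  # per kept peak, module id
    resolution: float | None = None


def _rank(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, x)


def _spearman_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between every column of a and every column of b
    (tie-corrected via average ranks then Pearson)."""
    ra = _rank(a)
    rb = _rank(b)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    sa = np.sqrt((ra**2).sum(axis=0))
    sb = np.sqrt((rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra.T @ rb) / np.outer(sa, sb)
    rho[~np.isfinite(rho)] = np.nan
    return rho


def cross_modal_correlation(
    msi: np.ndarray | pd.DataFrame,
    imc: np.ndarray | pd.DataFrame,
    p_cutoff: float = 0.001,
) -> CorrelationNetwork:
    """Spearman correlation of every m/z peak against every protein.

    Two-sided p-values come from the t approximation; the Bonferroni family
    is all peaks × proteins tests.  A peak is kept iff at least one protein
    has corrected p ≤ ``p_cutoff``.  Constant columns give undefined rho
    (recorded as NaN and excluded from the filter).
    """
    peak_names = (
        list(msi.columns) if isinstance(msi, pd.DataFrame)
        else [f"peak{i}" for i in range(np.asarray(msi).shape[1])]
    )
    protein_names = (
        list(imc.columns) if isinstance(imc, pd.DataFrame)
        else [f"protein{i}" for i in range(np.asarray(imc).shape[1])]
    )
    a = np.asarray(msi, dtype=float)
    b = np.asarray(imc, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("tables must be row-aligned (same cells)")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 cells")
    rho = _spearman_block(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals[np.abs(rho) >= 1.0] = 0.0
    pvals[np.isnan(rho)] = np.nan
    m_tests = rho.size
    corrected = np.minimum(pvals * m_tests, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kept = np.nanmin(
            np.where(np.isnan(corrected), np.inf, corrected), axis=1
        ) <= p_cutoff
    return CorrelationNetwork(
        rho=rho, pvals=pvals, kept_peaks=kept,
        peak_names=peak_names, protein_names=protein_names,
    )


def detect_modules(
    net: CorrelationNetwork,
    n_neighbors: int = 5,
    resolutions: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Cluster kept peaks into correlation modules.

    Peak–peak similarity is the Pearson correlation of their protein
    correlation profiles, turned into the metric distance
    ``d(u, v) = arccos(clip(r_uv, −1, 1))`` (0 for perfectly correlated
    profiles, π for anti-correlated).  A 5-NN fuzzy simplicial set on these
    distances feeds Louvain community detection at each resolution; the
    resolution at the elbow of the resolution–modularity curve (maximum
    perpendicular distance to the chord) is selected.
    """
    from umap.umap_ import fuzzy_simplicial_set

    kept = np.nonzero(net.kept_peaks)[0]
    if kept.size <= n_neighbors:
        raise ValueError(
            f"need more than {n_neighbors} kept peaks, have {kept.size}"
        )
    profiles = np.nan_to_num(net.rho[kept], nan=0.0)
    r = np.corrcoef(profiles)
    dist = np.arccos(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(dist, 0.0)
    order = np.argsort(dist, axis=1)
    knn_idx = order[:, : n_neighbors].astype(np.int32)
    knn_d = np.take_along_axis(dist, order, axis=1)[:, : n_neighbors].astype(
        np.float32
    )
    rs = np.random.RandomState(seed)
    graph, _, _ = fuzzy_simplicial_set(
        dist, n_neighbors, rs, "precomputed",
        knn_indices=knn_idx, knn_dists=knn_d,
    )
    graph = sp.csr_matrix(graph)
    G = nx.from_scipy_sparse_array(graph)
    if resolutions is None:
        resolutions = np.linspace(0.2, 2.0, 10)
    resolutions = np.asarray(resolutions, dtype=float)
    partitions, modularities = [], []
    for r_ in resolutions:
        parts = nx.community.louvain_communities(
            G, weight="weight", resolution=float(r_), seed=int(seed)
        )
        partitions.append(parts)
        modularities.append(
            nx.community.modularity(G, parts, weight="weight")
        )
    chosen = _elbow_index(resolutions, np.asarray(modularities))
    parts = partitions[chosen]
    labels = np.empty(kept.size, dtype=int)
    for mid, members in enumerate(parts):
        for node in members:
            labels[node] = mid
    net.modules = labels
    net.resolution = float(resolutions[chosen])
    return labels, float(resolutions[chosen])


def _elbow_index(x: np.ndarray, y: np.ndarray) -> int:
    """Index of maximum perpendicular distance to the chord through the
    first and last points of the curve."""
    if x.size == 1:
        return 0
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return 0
    pts = np.column_stack([x, y]) - p0
    perp = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(np.argmax(perp))


def ewma_trend(values: np.ndarray, span: float) -> np.ndarray:
    """Exponentially weighted moving average along an ordered series,

        y_t = Σ_{s ≤ t} (1 − λ)^{t−s} x_s / Σ_{s ≤ t} (1 − λ)^{t−s},

    with λ = 2 / (span + 1).  The series should be ordered by the spatial
    coordinate of interest (e.g. distance to a reference point).
    """
    if span < 1:
        raise ValueError("span must be ≥ 1")
    values = np.asarray(values, dtype=float)
    return (
        pd.Series(values).ewm(span=span, adjust=True).mean().to_numpy()
    )


def fisher_z(r_a, n_a: int, r_b, n_b: int) -> np.ndarray:
    """Fisher-transformed difference statistic between two correlations,

        z = (atanh r_a − atanh r_b) / sqrt(1/(n_a−3) + 1/(n_b−3)),

    with |r| clipped just below 1 to keep atanh finite.
    """
    ra = np.clip(np.asarray(r_a, dtype=float), -_ATANH_CLIP, _ATANH_CLIP)
    rb = np.clip(np.asarray(r_b, dtype=float), -_ATANH_CLIP, _ATANH_CLIP)
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    return (np.arctanh(ra) - np.arctanh(rb)) / se


def differential_correlation(
    msi: np.ndarray | pd.DataFrame,
    imc_target: np.ndarray,
    groups: np.ndarray,
    direction: str = "greater",
) -> pd.DataFrame:
    """Fisher-z differential correlation of each peak against one protein
    between two cell populations.

    Per peak: Spearman r within each group, then
    ``z = (atanh r_a − atanh r_b) / sqrt(1/(n_a−3) + 1/(n_b−3))``.
    ``direction="greater"`` tests r_a > r_b (p = P(Z > z); uniform under the
    null), ``"less"`` the reverse, and ``"auto"`` uses the sign of the
    observed z (p = P(Z > |z|); anti-conservative, flagged).  Bonferroni is
    applied over peaks; ranking weight is max(|r_a|, |r_b|) · |z|.
    """
    peak_names = (
        list(msi.columns) if isinstance(msi, pd.DataFrame)
        else [f"peak{i}" for i in range(np.asarray(msi).shape[1])]
    )
    x = np.asarray(msi, dtype=float)
    y = np.asarray(imc_target, dtype=float).ravel()
    groups = np.asarray(groups).astype(bool)
    if x.shape[0] != y.size or y.size != groups.size:
        raise ValueError("msi, imc_target and groups must be row-aligned")
    n_a = int(groups.sum())
    n_b = int((~groups).sum())
    if n_a <= 3 or n_b <= 3:
        raise ValueError("both groups need n > 3")
    r_a = _spearman_block(x[groups], y[groups, None])[:, 0]
    r_b = _spearman_block(x[~groups], y[~groups, None])[:, 0]
    if (np.abs(r_a) >= 1).any() or (np.abs(r_b) >= 1).any():
        warnings.warn("|r| = 1 encountered; atanh clipped")
    z = fisher_z(np.nan_to_num(r_a), n_a, np.nan_to_num(r_b), n_b)
    if direction == "greater":
        p = stats.norm.sf(z)
    elif direction == "less":
        p = stats.norm.cdf(z)
    elif direction == "auto":
        p = stats.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    p_corr = np.minimum(p * x.shape[1], 1.0)
    weight = np.maximum(np.abs(r_a), np.abs(r_b))
    out = pd.DataFrame(
        {
            "peak": peak_names,
            "r_a": r_a,
            "r_b": r_b,
            "n_a": n_a,
            "n_b": n_b,
            "fisher_z": z,
            "one_sided_p": p,
            "p_bonferroni": p_corr,
            "weight": weight,
            "score": weight * np.abs(z),
        }
    )
    out = out.sort_values("score", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
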