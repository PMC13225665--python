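"""Single-cell quantification of aligned multichannel images.

A label mask (0 = background, positive integers = cells) plus one or more
registered images yields a per-cell table: centroid, morphology (area,
eccentricity, solidity, extent) and the mean intensity of every channel of
every modality over the cell's pixels.  Downstream steps normalize each
channel to its 99th percentile and cluster cells into phenotypes with Leiden
community detection on a 15-nearest-neighbour fuzzy simplicial set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops_table

from .images import MultichannelImage

__all__ = [
    "CellTable",
    "quantify_cells",
    "filter_border_cells",
    "percentile_normalize",
    "cluster_phenotypes",
]


@dataclass
class CellTable:
    """Per-cell measurements for one sample.

    ``df`` columns: sample_id, cell_id, row, col, area, eccentricity,
    solidity, extent, then one ``<modality>_<channel>`` column per channel;
    ``channel_columns`` maps modality name → its intensity column names.
    """

    df: pd.DataFrame
    channel_columns: dict[str, list[str]] = field(default_factory=dict)
    resolution_um: tuple[float, float] = (1.0, 1.0)

    def intensity_columns(self) -> list[str]:
        return [c for cols in self.channel_columns.values() for c in cols]

    def intensity_matrix(self, modality: str | None = None) -> np.ndarray:
        cols = (
            self.channel_columns[modality]
            if modality is not None
            else self.intensity_columns()
        )
        return self.df[cols].to_numpy(dtype=float)

    def centroids_um(self) -> np.ndarray:
        px = self.df[["row", "col"]].to_numpy(dtype=float)
        return px * np.asarray(self.resolution_um)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def quantify_cells(
    label_mask: np.ndarray,
    images: dict[str, MultichannelImage],
    sample_id: str = "sample",
) -> CellTable:
    """Quantify every labelled cell over every channel of every modality.

    Means are computed per cell over the cell's pixels; centroids are pixel
    coordinate means; morphology comes from the labelled region.
    """
    label_mask = np.asarray(label_mask)
    if label_mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    resolution = (1.0, 1.0)
    for name, img in images.items():
        if img.data.shape[:2] != label_mask.shape:
            raise ValueError(f"image {name!r} does not share the mask's grid")
        resolution = img.resolution_um
    ids = np.unique(label_mask)
    ids = ids[ids > 0]
    if ids.size == 0:
        cols = ["sample_id", "cell_id", "row", "col", "area",
                "eccentricity", "solidity", "extent"]
        return CellTable(pd.DataFrame(columns=cols), {}, resolution)
    props = regionprops_table(
        label_mask,
        properties=("label", "centroid", "area", "eccentricity", "solidity",
                    "extent"),
    )
    order = np.argsort(props["label"])
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": props["label"][order],
            "row": props["centroid-0"][order],
            "col": props["centroid-1"][order],
            "area": props["area"][order],
            "eccentricity": props["eccentricity"][order],
            "solidity": props["solidity"][order],
            "extent": props["extent"][order],
        }
    )
    channel_columns: dict[str, list[str]] = {}
    for name, img in images.items():
        cols = []
        for ch in range(img.n_channels):
            col = f"{name}_{img.channel_names[ch]}"
            df[col] = ndimage.mean(
                img.data[:, :, ch].astype(np.float64), labels=label_mask, index=ids
            )
            cols.append(col)
        channel_columns[name] = cols
    return CellTable(df.reset_index(drop=True), channel_columns, resolution)


def filter_border_cells(
    label_mask: np.ndarray, contour_mask: np.ndarray | None = None
) -> np.ndarray:
    """Drop cells touching the raster border or extending outside the contour
    mask; remaining labels are re-indexed densely from 1."""
    label_mask = np.asarray(label_mask)
    keep_region = (
        np.ones_like(label_mask, dtype=bool)
        if contour_mask is None
        else np.asarray(contour_mask, dtype=bool)
    )
    if keep_region.shape != label_mask.shape:
        raise ValueError("contour mask shape must match the label mask")
    border = np.zeros_like(label_mask, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    bad = set(np.unique(label_mask[border | ~keep_region])) - {0}
    out = np.zeros_like(label_mask)
    next_id = 1
    for lab in np.unique(label_mask):
        if lab == 0 or lab in bad:
            continue
        out[label_mask == lab] = next_id
        next_id += 1
    return out


def percentile_normalize(table: CellTable, p: float = 99.0) -> CellTable:
    """Divide each intensity channel by its p-th percentile across cells and
    clip to [0, 1] (percentile by linear interpolation)."""
    df = table.df.copy()
    for col in table.intensity_columns():
        if df[col].size < 2:
            raise ValueError("need at least 2 cells per channel to normalize")
        scale = float(np.percentile(df[col].to_numpy(dtype=float), p))
        if scale == 0:
            warnings.warn(f"channel {col!r} has zero {p}th percentile; left unscaled")
            continue
        df[col] = np.clip(df[col].to_numpy(dtype=float) / scale, 0.0, 1.0)
    return CellTable(df, dict(table.channel_columns), table.resolution_um)


def cluster_phenotypes(
    table: CellTable, n_neighbors: int = 15, seed: int = 0,
    resolution: float = 1.0,
) -> np.ndarray:
    """Leiden phenotype clustering on the 15-NN Euclidean fuzzy simplicial
    set of the normalized expression matrix.  Labels are written into the
    table's ``phenotype`` column and returned."""
    import igraph
    import leidenalg

    from .compress import build_fuzzy_set

    X = table.intensity_matrix()
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"too few cells ({X.shape[0]}) for {n_neighbors} neighbours"
        )
    g = build_fuzzy_set(X, n_neighbors=n_neighbors, seed=seed)
    coo = g.edges.tocoo()
    upper = coo.row < coo.col
    edges = list(zip(coo.row[upper].tolist(), coo.col[upper].tolist()))
    ig = igraph.Graph(n=g.n_points, edges=edges)
    ig.es["weight"] = coo.data[upper].tolist()
    part = leidenalg.find_partition(
        ig,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership, dtype=int)
    table.df["phenotype"] = labels
    return labels
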