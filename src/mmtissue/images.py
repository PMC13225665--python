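"""Raster I/O and the canonical multichannel image container.

The pipeline moves images between several on-disk standards — OME-TIFF for
multiplexed antibody imaging, imzML for mass spectrometry imaging (MSI),
NIfTI-1 (32-bit float) as the interchange format for compressed/registered
rasters, HDF5 for intermediates, and plain RGB TIFF/PNG for histology — and a
single in-memory representation: an H×W×C float array with channel names, a
physical resolution in µm/pixel, and an optional boolean foreground mask.

Coordinate convention: (row, col), 0-based, pixel centers at integer
coordinates.  The channel axis is last throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "MultichannelImage",
    "LandmarkPointSet",
    "read_image",
    "write_image",
    "crop_roi",
    "read_landmarks",
    "write_landmarks",
]


class FormatError(ValueError):
    """Raised when a file does not parse under the named standard."""


@dataclass
class MultichannelImage:
    """H×W×C raster with channel names, µm/pixel resolution and optional mask.

    Parameters
    ----------
    data : ndarray, shape (H, W, C)
        Real-valued raster.  NaNs are rejected at construction unless
        ``nan_policy="zero"`` was used by the loader.
    channel_names : list of str, length C
    resolution_um : tuple of float
        (row, col) pixel pitch in µm.
    mask : ndarray of bool, shape (H, W), optional
        Foreground mask; None means all pixels are foreground.
    origin : tuple of int
        (row, col) offset of this raster inside its parent image; set by
        :func:`crop_roi` so coordinates can be mapped back.
    """

    data: np.ndarray
    channel_names: list[str]
    resolution_um: tuple[float, float] = (1.0, 1.0)
    mask: np.ndarray | None = None
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError(f"data must be H×W×C, got shape {self.data.shape}")
        h, w, c = self.data.shape
        if h < 1 or w < 1 or c < 1:
            raise ValueError("H, W and C must all be ≥ 1")
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN; load with nan_policy='zero' to impute")
        if np.isscalar(self.resolution_um):
            self.resolution_um = (float(self.resolution_um), float(self.resolution_um))
        else:
            self.resolution_um = tuple(float(r) for r in self.resolution_um)
        if any(r <= 0 for r in self.resolution_um):
            raise ValueError("resolution_um must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (h, w):
                raise ValueError("mask shape must match H×W")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def foreground_mask(self) -> np.ndarray:
        """Mask as an explicit boolean array (all-True when absent)."""
        if self.mask is None:
            return np.ones(self.data.shape[:2], dtype=bool)
        return self.mask

    def to_global(self, points: np.ndarray) -> np.ndarray:
        """Map local (row, col) coordinates back to the parent image frame."""
        return np.asarray(points, dtype=float) + np.asarray(self.origin, dtype=float)


@dataclass
class LandmarkPointSet:
    """Matched manual landmark pairs in fixed- and moving-image space."""

    fixed_points: np.ndarray
    moving_points: np.ndarray

    def __post_init__(self) -> None:
        self.fixed_points = np.atleast_2d(np.asarray(self.fixed_points, dtype=float))
        self.moving_points = np.atleast_2d(np.asarray(self.moving_points, dtype=float))
        if self.fixed_points.size == 0:
            self.fixed_points = self.fixed_points.reshape(0, 2)
        if self.moving_points.size == 0:
            self.moving_points = self.moving_points.reshape(0, 2)
        if self.fixed_points.shape != self.moving_points.shape:
            raise ValueError("fixed and moving landmark lists must match in shape")
        if self.fixed_points.ndim != 2 or self.fixed_points.shape[1] != 2:
            raise ValueError("landmarks must be (n, 2) (row, col) coordinates")

    def __len__(self) -> int:
        return self.fixed_points.shape[0]


# ---------------------------------------------------------------------------
# readers / writers


def _check_nan(data: np.ndarray, nan_policy: str) -> np.ndarray:
    if np.isnan(data).any():
        if nan_policy == "zero":
            data = np.nan_to_num(data, nan=0.0)
        else:
            raise FormatError("file contains NaN values (use nan_policy='zero')")
    return data


def read_image(
    path: str | os.PathLike,
    format: str,
    resolution_um: float | tuple[float, float] = 1.0,
    nan_policy: str = "error",
) -> MultichannelImage:
    """Read a raster from one of the supported standards.

    ``format`` is one of ``{"ome-tiff", "imzml", "nifti", "hdf5", "rgb"}``.
    For imzML (processed mode, uniform m/z axis) the pixel grid is rebuilt
    from spot coordinates; unvisited positions are zero-filled and excluded
    from the mask.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "nifti":
        return _read_nifti(path, resolution_um, nan_policy)
    if format == "ome-tiff":
        return _read_ome_tiff(path, resolution_um, nan_policy)
    if format == "imzml":
        return _read_imzml(path, resolution_um, nan_policy)
    if format == "hdf5":
        return _read_hdf5(path, resolution_um, nan_policy)
    if format == "rgb":
        return _read_rgb(path, resolution_um)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path, resolution_um, nan_policy) -> MultichannelImage:
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"not a readable NIfTI-1 file: {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim == 4:  # H×W×1×C volumes written by some tools
        data = data.reshape(data.shape[0], data.shape[1], -1)
    data = _check_nan(data, nan_policy)
    names = [f"ch{i}" for i in range(data.shape[2])]
    hdr = img.header.extensions
    for ext in hdr:
        if ext.get_code() == 6:  # comment extension used to stash channel names
            try:
                names = ext.get_content().decode().split("\t")
            except Exception:
                pass
    return MultichannelImage(data, names, resolution_um)


def _read_ome_tiff(path, resolution_um, nan_policy) -> MultichannelImage:
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            axes = tf.series[0].axes
    except Exception as exc:
        raise FormatError(f"not a readable OME-TIFF: {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
        axes = "C" + axes if "C" not in axes else axes
    if axes.startswith("C") or arr.shape[0] < min(arr.shape[1:]):
        data = np.moveaxis(arr, 0, -1)  # CYX → YXC
    else:
        data = arr
    data = _check_nan(np.asarray(data, dtype=np.float32), nan_policy)
    names = [f"ch{i}" for i in range(data.shape[2])]
    try:
        with tifffile.TiffFile(path) as tf:
            meta = tf.ome_metadata
        if meta:
            import re

            found = re.findall(r'Channel[^>]*Name="([^"]+)"', meta)
            if len(found) == data.shape[2]:
                names = found
    except Exception:
        pass
    return MultichannelImage(data, names, resolution_um)


def _read_imzml(path, resolution_um, nan_policy) -> MultichannelImage:
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(path)
    except Exception as exc:
        raise FormatError(f"not a readable imzML file: {path}: {exc}") from exc
    mzs0, _ = parser.getspectrum(0)
    n_bins = len(mzs0)
    coords = np.array(parser.coordinates)  # (x, y[, z]) 1-based
    xs, ys = coords[:, 0], coords[:, 1]
    w = int(xs.max())
    h = int(ys.max())
    data = np.zeros((h, w, n_bins), dtype=np.float32)
    mask = np.zeros((h, w), dtype=bool)
    for idx in range(len(parser.coordinates)):
        mzs, intens = parser.getspectrum(idx)
        if len(mzs) != n_bins or not np.allclose(mzs, mzs0):
            raise FormatError(
                "imzML spots have non-uniform m/z axes; processed-mode imzML required"
            )
        r, c = int(ys[idx]) - 1, int(xs[idx]) - 1
        data[r, c, :] = intens
        mask[r, c] = True
    data = _check_nan(data, nan_policy)
    names = [f"mz_{mz:.4f}" for mz in mzs0]
    return MultichannelImage(data, names, resolution_um, mask=mask)


def _read_hdf5(path, resolution_um, nan_policy) -> MultichannelImage:
    try:
        with h5py.File(path, "r") as f:
            data = np.asarray(f["image"], dtype=np.float32)
            names = [n.decode() if isinstance(n, bytes) else str(n)
                     for n in f["image"].attrs.get("channel_names", [])]
            res = f["image"].attrs.get("resolution_um", None)
            mask = np.asarray(f["mask"], dtype=bool) if "mask" in f else None
    except (OSError, KeyError) as exc:
        raise FormatError(f"not a readable HDF5 image: {path}: {exc}") from exc
    data = _check_nan(data, nan_policy)
    if not names:
        names = [f"ch{i}" for i in range(data.shape[2])]
    if res is not None:
        resolution_um = tuple(res)
    return MultichannelImage(data, names, resolution_um, mask=mask)


def _read_rgb(path, resolution_um) -> MultichannelImage:
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:
        raise FormatError(f"not a readable RGB image: {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[:, :, None].repeat(3, axis=2)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return MultichannelImage(arr.astype(np.float32), ["R", "G", "B"], resolution_um)


def write_image(img: MultichannelImage, path: str | os.PathLike, format: str) -> None:
    """Write ``img`` as 32-bit NIfTI-1 or OME-TIFF; ``read_image`` inverts it."""
    path = os.fspath(path)
    if format == "nifti":
        data = np.asarray(img.data, dtype=np.float32)
        nii = nib.Nifti1Image(data, affine=np.eye(4))
        nii.header.set_data_dtype(np.float32)
        content = "\t".join(img.channel_names).encode()
        nii.header.extensions.append(nib.nifti1.Nifti1Extension(6, content))
        nib.save(nii, path)
    elif format == "ome-tiff":
        data = np.moveaxis(np.asarray(img.data, dtype=np.float32), -1, 0)  # YXC → CYX
        tifffile.imwrite(
            path,
            data,
            metadata={"axes": "CYX", "Channel": {"Name": list(img.channel_names)}},
            ome=True,
        )
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("image", data=np.asarray(img.data, dtype=np.float32))
            ds.attrs["channel_names"] = [n.encode() for n in img.channel_names]
            ds.attrs["resolution_um"] = list(img.resolution_um)
            if img.mask is not None:
                f.create_dataset("mask", data=img.mask)
    else:
        raise ValueError(f"unsupported write format {format!r}")


def crop_roi(
    img: MultichannelImage, bbox: tuple[int, int, int, int], pad: int = 0
) -> MultichannelImage:
    """Crop an end-inclusive bounding box with symmetric padding.

    ``bbox`` is (row0, col0, row1, col1) with both corners inside the crop.
    Padding is clamped at the raster borders (no wraparound).  The returned
    image records its offset in ``origin`` for coordinate back-mapping.
    """
    r0, c0, r1, c1 = bbox
    if r1 < r0 or c1 < c0:
        raise ValueError(f"empty bbox {bbox}")
    if pad < 0:
        raise ValueError("pad must be non-negative")
    h, w, _ = img.data.shape
    rr0 = max(0, r0 - pad)
    cc0 = max(0, c0 - pad)
    rr1 = min(h - 1, r1 + pad)
    cc1 = min(w - 1, c1 + pad)
    if rr0 > rr1 or cc0 > cc1:
        raise ValueError(f"bbox {bbox} outside image of shape {(h, w)}")
    data = img.data[rr0 : rr1 + 1, cc0 : cc1 + 1, :]
    mask = None if img.mask is None else img.mask[rr0 : rr1 + 1, cc0 : cc1 + 1]
    return replace(
        img,
        data=data.copy(),
        mask=None if mask is None else mask.copy(),
        origin=(img.origin[0] + rr0, img.origin[1] + cc0),
    )


def read_landmarks(fixed_path, moving_path) -> LandmarkPointSet:
    """Read paired 2-column "row col" text files (paired by line number)."""
    fixed = np.loadtxt(fixed_path, ndmin=2)
    moving = np.loadtxt(moving_path, ndmin=2)
    return LandmarkPointSet(fixed, moving)


def write_landmarks(lm: LandmarkPointSet, fixed_path, moving_path) -> None:
    np.savetxt(fixed_path, lm.fixed_points, fmt="%.6f")
    np.savetxt(moving_path, lm.moving_points, fmt="%.6f")
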