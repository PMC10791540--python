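"""Reading and writing stacked-TIFF CT volumes and plain numeric series.

Volumes are ordered stacks of equally sized 2-D grayscale slices.  Intensities
are normalized to [0, 1] on read (``dtype_max`` by default, so the 0.5
foreground threshold used downstream is independent of a particular volume's
histogram).  Row indices are 1-based from the top edge throughout the package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .exceptions import InputError, VolumeFormatError, VolumeIOError

__all__ = [
    "CTVolume",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_series_csv",
    "write_series_csv",
]


@dataclass
class CTVolume:
    """An ordered stack of 2-D intensity slices.

    Parameters
    ----------
    data
        Array of shape ``(n_slices, height, width)``.
    intensity_domain
        ``"normalized"`` if all values lie in [0, 1], else ``"raw"``.
    """

    data: np.ndarray
    intensity_domain: str = "normalized"
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"volume data must be 3-D (n_slices, height, width), got shape {self.data.shape}"
            )
        if self.intensity_domain not in ("raw", "normalized"):
            raise VolumeFormatError(
                f"intensity_domain must be 'raw' or 'normalized', got {self.intensity_domain!r}"
            )
        if self.intensity_domain == "normalized":
            if self.data.size and (
                not np.isfinite(self.data).all()
                or self.data.min() < 0.0
                or self.data.max() > 1.0
            ):
                raise VolumeFormatError("normalized volume has values outside [0, 1]")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def slice(self, index: int) -> np.ndarray:
        """Return slice ``index`` (0-based stack order)."""
        return self.data[index]


def read_tiff_stack(path: str | os.PathLike, normalize_mode: str = "dtype_max") -> CTVolume:
    """Read a multi-page grayscale TIFF as a :class:`CTVolume`.

    Parameters
    ----------
    path
        Path to a multi-page TIFF file.
    normalize_mode
        ``"dtype_max"`` divides integer data by the dtype's maximum value
        (default), ``"minmax"`` maps the volume's min/max affinely onto
        [0, 1], ``"none"`` keeps raw values.

    Raises
    ------
    VolumeIOError
        If the file is missing or unreadable.
    VolumeFormatError
        If pages have inconsistent shapes or are not 2-D grayscale.
    """
    if normalize_mode not in ("dtype_max", "minmax", "none"):
        raise InputError(f"unknown normalize_mode {normalize_mode!r}")
    if not os.path.exists(path):
        raise VolumeIOError(f"volume file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            # one series per homogeneous page run; >1 series means the pages
            # do not form a single uniform stack
            arrays = [s.asarray() for s in tif.series]
    except Exception as exc:  # corrupt / non-TIFF content
        raise VolumeIOError(f"cannot read TIFF stack {path}: {exc}") from exc
    if not arrays:
        raise VolumeFormatError(f"TIFF stack {path} contains no pages")
    arrays = [a[None] if a.ndim == 2 else a for a in arrays]
    if any(a.ndim != 3 for a in arrays):
        raise VolumeFormatError(f"TIFF stack {path} is not single-channel grayscale")
    shapes = {a.shape[1:] for a in arrays}
    if len(shapes) != 1:
        raise VolumeFormatError(f"TIFF stack {path} has mixed slice shapes: {sorted(shapes)}")
    stack = arrays[0] if len(arrays) == 1 else np.concatenate(arrays, axis=0)

    if normalize_mode == "none":
        return CTVolume(stack, intensity_domain="raw", source=str(path))
    if normalize_mode == "dtype_max":
        if np.issubdtype(stack.dtype, np.integer):
            scale = float(np.iinfo(stack.dtype).max)
            data = stack.astype(np.float64) / scale
        else:
            data = stack.astype(np.float64)
            if data.size and (data.min() < 0.0 or data.max() > 1.0):
                raise VolumeFormatError(
                    f"float TIFF {path} has values outside [0, 1]; "
                    "use normalize_mode='minmax' or 'none'"
                )
    else:  # minmax
        data = stack.astype(np.float64)
        lo, hi = float(data.min()), float(data.max())
        data = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    return CTVolume(data, intensity_domain="normalized", source=str(path))


def write_tiff_stack(volume: CTVolume | np.ndarray, path: str | os.PathLike, dtype=None) -> None:
    """Write a volume as a multi-page TIFF.

    ``dtype`` may be an integer dtype, in which case normalized [0, 1]
    intensities are scaled to the dtype's full range; by default the array is
    written as-is (float data round-trips bit-identically with
    ``normalize_mode='none'``).
    """
    data = volume.data if isinstance(volume, CTVolume) else np.asarray(volume)
    if dtype is not None:
        dtype = np.dtype(dtype)
        if np.issubdtype(dtype, np.integer):
            data = np.round(data * np.iinfo(dtype).max).astype(dtype)
        else:
            data = data.astype(dtype)
    tifffile.imwrite(path, data)


def read_series_csv(path: str | os.PathLike) -> np.ndarray:
    """Read a numeric series from CSV.

    Accepts one value per line (optional header) or two columns
    ``(index, value)`` as written by :func:`write_series_csv`; returns the
    value column as a float array.
    """
    if not os.path.exists(path):
        raise VolumeIOError(f"series file not found: {path}")
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([tok.strip() for tok in line.split(",")])
    if not rows:
        raise InputError(f"series file {path} is empty")
    try:
        float(rows[0][-1])
    except ValueError:
        rows = rows[1:]  # header line
    if not rows:
        raise InputError(f"series file {path} has a header but no data")
    try:
        return np.array([float(r[-1]) for r in rows], dtype=np.float64)
    except ValueError as exc:
        raise InputError(f"series file {path} has non-numeric entries: {exc}") from exc


def write_series_csv(values, path: str | os.PathLike, header: str | None = "index,value") -> None:
    """Write a series as two-column CSV ``(index, value)`` with 0-based index."""
    values = np.asarray(values, dtype=np.float64)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for i, v in enumerate(values):
            fh.write(f"{i},{float(v)!r}\n")
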