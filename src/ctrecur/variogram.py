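"""Masked per-slice semi-variograms and per-volume semi-variogram series.

For each slice the semi-variogram at lag ``h`` is

    gamma(h) = 1 / (2 N(h)) * sum over pairs (f(i) - f(i+h))^2

where pairs are horizontally adjacent pixels ``h`` columns apart within the
same image row (no wrapping across row ends), restricted to rows >= ``row_min``
(1-based from the top) with BOTH pixels' intensities >= ``intensity_min``.
Stacking the per-slice values over the leading ``n_slices`` slices yields the
series fed to recurrence analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InputError
from .io import CTVolume

__all__ = [
    "VariogramConfig",
    "SemivariogramSeries",
    "slice_semivariogram",
    "semivariogram_series",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariogramConfig:
    """Masking and lag parameters for the per-slice semi-variogram.

    Defaults: ``h=1``, include pixels with intensity >= 0.5 from row 150
    (1-based) down, use the first 100 slices.
    """

    h: int = 1
    intensity_min: float = 0.5
    row_min: int = 150
    n_slices: int = 100

    def __post_init__(self) -> None:
        if not (isinstance(self.h, (int, np.integer)) and self.h >= 1):
            raise ConfigurationError("lag h must be an integer >= 1")
        if not 0.0 <= self.intensity_min <= 1.0:
            raise ConfigurationError("intensity_min must lie in [0, 1]")
        if self.row_min < 1:
            raise ConfigurationError("row_min must be >= 1 (rows are 1-based)")
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")


@dataclass
class SemivariogramSeries:
    """Per-slice gamma(h) values for one volume (the series x_1..x_T)."""

    values: np.ndarray
    subject_id: str | None = None
    config: VariogramConfig | None = None
    imputed: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise InputError("series values must be 1-D")
        if self.values.size and (not np.isfinite(self.values).all() or self.values.min() < 0):
            raise InputError("semi-variogram values must be finite and >= 0")

    def __len__(self) -> int:
        return self.values.size


def slice_semivariogram(slice_: np.ndarray, config: VariogramConfig) -> tuple[float, int]:
    """Masked semi-variogram of one slice.

    Returns ``(gamma, n_pairs)``; ``gamma`` is NaN when no pixel pair passes
    the masks (``n_pairs == 0``) — the caller decides the missing-value policy.
    """
    a = np.asarray(slice_, dtype=np.float64)
    if a.ndim != 2:
        raise InputError("slice must be a 2-D array")
    h = config.h
    if config.row_min > a.shape[0] or h >= a.shape[1]:
        return float("nan"), 0
    rows = a[config.row_min - 1:, :]
    left = rows[:, :-h]
    right = rows[:, h:]
    mask = (left >= config.intensity_min) & (right >= config.intensity_min)
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        return float("nan"), 0
    sq = (left - right) ** 2
    gamma = float(sq[mask].sum() / (2.0 * n_pairs))
    return gamma, n_pairs


def semivariogram_series(volume: CTVolume, config: VariogramConfig,
                         subject_id: str | None = None) -> SemivariogramSeries:
    """Per-slice semi-variogram over the leading ``config.n_slices`` slices.

    Slices with no qualifying pairs are imputed from the nearest valid slice
    (earlier one on ties); imputed indices are recorded and logged.

    Raises
    ------
    InputError
        If the volume is empty or no slice yields a valid value.
    """
    if volume.n_slices == 0:
        raise InputError("volume has zero slices")
    if volume.intensity_domain != "normalized":
        raise InputError("volume must be normalized to [0, 1] before variogram analysis")
    n = min(config.n_slices, volume.n_slices)
    values = np.empty(n, dtype=np.float64)
    for t in range(n):
        values[t], _ = slice_semivariogram(volume.data[t], config)

    missing = np.flatnonzero(np.isnan(values))
    if missing.size == n:
        raise InputError("no slice yields a valid semi-variogram under the configured masks")
    if missing.size:
        valid = np.flatnonzero(~np.isnan(values))
        for t in missing:
            nearest = valid[np.argmin(np.abs(valid - t))]
            values[t] = values[nearest]
        logger.warning("imputed %d/%d semi-variogram values from nearest valid slices",
                       missing.size, n)
    return SemivariogramSeries(values, subject_id=subject_id, config=config,
                               imputed=[int(t) for t in missing])
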