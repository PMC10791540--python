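"""Recurrence quantification of fuzzy recurrence plots.

The fuzzy matrix R is thresholded (Otsu by default) into a binary plot B;
maximal runs of ones along diagonals and columns of B give six measures:

* fRR  — mean of R with sub-threshold grades zeroed (recurrence rate)
* fDET — share of diagonal-run recurrence mass in runs >= lmin_d (determinism)
* fLAM — share of vertical-run recurrence mass in runs >= lmin_v (laminarity)
* fTT  — mean length of vertical runs >= lmin_v (trapping time)
* fDIV — reciprocal of the longest diagonal run (divergence)
* fENT — Shannon entropy (bits) of diagonal-run lengths >= lmin_d

The main diagonal (line of identity) is excluded from diagonal statistics by
default, capping diagonal run lengths at L - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .exceptions import InputError
from .recurrence import FRPMatrix

__all__ = [
    "BinaryRP",
    "LineHistograms",
    "FRQAMeasures",
    "binarize",
    "line_histograms",
    "f_rr",
    "diag_measures",
    "vert_measures",
    "frqa_measures",
]

logger = logging.getLogger(__name__)


@dataclass
class BinaryRP:
    """Binarized recurrence plot with the threshold that produced it."""

    B: np.ndarray  # (L, L) of {0, 1}
    threshold: float
    loi_excluded: bool = True

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=bool)
        if self.B.ndim != 2 or self.B.shape[0] != self.B.shape[1]:
            raise InputError("binary recurrence plot must be square")

    @property
    def L(self) -> int:
        return self.B.shape[0]


@dataclass
class LineHistograms:
    """Run-length counts: ``diagonal[l-1]`` = number of maximal diagonal runs
    of length ``l`` (up to ``N_D``), ``vertical[l-1]`` likewise up to ``K``."""

    diagonal: np.ndarray
    vertical: np.ndarray

    @property
    def N_D(self) -> int:
        return self.diagonal.size

    @property
    def K(self) -> int:
        return self.vertical.size


@dataclass
class FRQAMeasures:
    fRR: float
    fDET: float
    fLAM: float
    fTT: float
    fDIV: float
    fENT: float
    omega: float
    lmin_d: int
    lmin_v: int


def binarize(R: FRPMatrix | np.ndarray, method: str = "otsu",
             threshold: float = 0.5, exclude_loi: bool = True) -> BinaryRP:
    """Threshold a fuzzy recurrence matrix into a binary plot.

    ``method="otsu"`` picks the threshold from R's value histogram;
    ``method="fixed"`` uses ``threshold``.  A constant R (Otsu undefined)
    falls back to a fixed 0.5 threshold with a warning.  Cells with
    ``R >= threshold`` map to 1.
    """
    Rm = R.R if isinstance(R, FRPMatrix) else np.asarray(R, dtype=np.float64)
    if method == "fixed":
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(Rm) == 0.0:
            logger.warning("constant recurrence matrix: falling back to fixed threshold 0.5")
            thr = 0.5
        else:
            thr = float(threshold_otsu(Rm))
    else:
        raise InputError(f"unknown binarization method {method!r}")
    return BinaryRP(Rm >= thr, threshold=thr, loi_excluded=exclude_loi)


def _run_lengths(line: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 1-D boolean array."""
    if line.size == 0 or not line.any():
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate(([False], line, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def line_histograms(B: BinaryRP, exclude_loi: bool | None = None) -> LineHistograms:
    """Histograms of maximal diagonal and vertical run lengths of ones in B.

    When the line of identity is excluded, only off-diagonals are scanned and
    the maximum recordable diagonal length is ``L - 1``; vertical runs always
    span full columns (maximum ``L``).
    """
    if exclude_loi is None:
        exclude_loi = B.loi_excluded
    M = B.B
    L = B.L
    n_d = max(L - 1, 1) if exclude_loi else L
    diag_counts = np.zeros(n_d, dtype=np.int64)
    for offset in range(-(L - 1), L):
        if exclude_loi and offset == 0:
            continue
        for length in _run_lengths(np.diagonal(M, offset)):
            diag_counts[length - 1] += 1
    vert_counts = np.zeros(L, dtype=np.int64)
    for j in range(L):
        for length in _run_lengths(M[:, j]):
            vert_counts[length - 1] += 1
    return LineHistograms(diagonal=diag_counts, vertical=vert_counts)


def f_rr(R: FRPMatrix | np.ndarray, omega: float = 0.5) -> float:
    """Fuzzy recurrence rate: mean of R over all L^2 cells with grades below
    ``omega`` zeroed (retained cells keep their fuzzy grade)."""
    if not 0.0 <= omega <= 1.0:
        raise InputError("omega must lie in [0, 1]")
    Rm = R.R if isinstance(R, FRPMatrix) else np.asarray(R, dtype=np.float64)
    return float(np.where(Rm >= omega, Rm, 0.0).mean())


def diag_measures(hist: LineHistograms, lmin_d: int = 5,
                  entropy_mode: str = "restricted") -> tuple[float, float, float]:
    """(fDET, fDIV, fENT) from the diagonal run-length histogram.

    fDET = sum_{l >= lmin_d} l p(l) / sum_{l >= 1} l p(l); fDIV = 1 / max
    observed run length (NaN when no diagonal run exists); fENT = Shannon
    entropy in bits of run lengths >= lmin_d.  ``entropy_mode="restricted"``
    (default) renormalizes p over the l >= lmin_d bins; ``"tail"`` uses the
    global p without renormalizing.  Empty numerators/denominators yield 0.
    """
    if lmin_d < 1:
        raise InputError("lmin_d must be >= 1")
    counts = np.asarray(hist.diagonal, dtype=np.float64)
    lengths = np.arange(1, counts.size + 1, dtype=np.float64)
    total_mass = float((lengths * counts).sum())
    long_mask = lengths >= lmin_d
    fDET = float((lengths * counts)[long_mask].sum() / total_mass) if total_mass > 0 else 0.0

    observed = np.flatnonzero(counts)
    fDIV = float(1.0 / (observed[-1] + 1)) if observed.size else float("nan")

    n_total = counts.sum()
    if n_total == 0:
        return fDET, fDIV, 0.0
    if entropy_mode == "restricted":
        tail = counts[long_mask]
        n_tail = tail.sum()
        if n_tail == 0:
            return fDET, fDIV, 0.0
        p = tail[tail > 0] / n_tail
    elif entropy_mode == "tail":
        p_all = counts / n_total
        p = p_all[long_mask & (counts > 0)]
    else:
        raise InputError(f"unknown entropy_mode {entropy_mode!r}")
    fENT = float(-(p * np.log2(p)).sum()) if p.size else 0.0
    return fDET, fDIV, fENT


def vert_measures(hist: LineHistograms, lmin_v: int = 5) -> tuple[float, float]:
    """(fLAM, fTT) from the vertical run-length histogram.

    fLAM = sum_{l >= lmin_v} l p(l) / sum_{l >= 1} l p(l); fTT = mean length
    of vertical runs >= lmin_v.  0/0 cases yield 0.
    """
    if lmin_v < 1:
        raise InputError("lmin_v must be >= 1")
    counts = np.asarray(hist.vertical, dtype=np.float64)
    lengths = np.arange(1, counts.size + 1, dtype=np.float64)
    total_mass = float((lengths * counts).sum())
    long_mask = lengths >= lmin_v
    long_mass = float((lengths * counts)[long_mask].sum())
    long_n = float(counts[long_mask].sum())
    fLAM = long_mass / total_mass if total_mass > 0 else 0.0
    fTT = long_mass / long_n if long_n > 0 else 0.0
    return fLAM, fTT


def frqa_measures(R: FRPMatrix, omega: float = 0.5, lmin_d: int = 5, lmin_v: int = 5,
                  method: str = "otsu", threshold: float = 0.5,
                  exclude_loi: bool = True,
                  entropy_mode: str = "restricted") -> FRQAMeasures:
    """All six measures of one fuzzy recurrence plot."""
    B = binarize(R, method=method, threshold=threshold, exclude_loi=exclude_loi)
    hist = line_histograms(B)
    fDET, fDIV, fENT = diag_measures(hist, lmin_d, entropy_mode=entropy_mode)
    fLAM, fTT = vert_measures(hist, lmin_v)
    return FRQAMeasures(fRR=f_rr(R, omega), fDET=fDET, fLAM=fLAM, fTT=fTT,
                        fDIV=fDIV, fENT=fENT, omega=omega, lmin_d=lmin_d, lmin_v=lmin_v)
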