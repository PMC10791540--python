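"""Synthetic CT-like volumes, two-group cohorts and toy 1-D series.

The volume generator places a spatially correlated "bone" field (a Gaussian
random field with controllable variance and correlation length) in the lower
rows of each slice, over a flat sub-threshold background, so every downstream
stage — masked semi-variograms, recurrence analysis, cohort summaries — can be
exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError
from .io import CTVolume

__all__ = [
    "VolumeSpec",
    "CohortSpec",
    "ToySeries",
    "gen_toy_series",
    "gen_volume",
    "gen_cohort",
]

_FOREGROUND_MEAN = 0.75
_TOY_KINDS = ("constant", "sine", "white_noise", "drift", "disrupted")


@dataclass(frozen=True)
class VolumeSpec:
    """Parameters of one synthetic CT-like volume.

    ``bone_row_start`` is 1-based from the top edge; rows above it contain
    only background at ``background_level`` (< 0.5, so the default intensity
    mask excludes it).  ``sill`` is the variance of the foreground field and
    ``corr_range`` its correlation length in pixels.  ``drift`` adds a linear
    per-slice trend to the sill.
    """

    n_slices: int = 100
    height: int = 64
    width: int = 64
    bone_row_start: int = 17
    sill: float = 0.005
    corr_range: float = 2.0
    background_level: float = 0.1
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        if self.height < 1 or self.width < 1:
            raise ConfigurationError("height and width must be positive")
        if not 1 <= self.bone_row_start <= self.height:
            raise ConfigurationError("bone_row_start must lie within [1, height]")
        if not 0.0 <= self.background_level < 0.5:
            raise ConfigurationError("background_level must lie in [0, 0.5)")
        if self.sill < 0:
            raise ConfigurationError("sill must be >= 0")
        if self.corr_range <= 0:
            raise ConfigurationError("corr_range must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """A balanced two-group cohort: the "high" group gets ``sill + group_effect``."""

    n_per_group: int = 5
    base: VolumeSpec = field(default_factory=VolumeSpec)
    group_effect: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.group_effect < 0:
            raise ConfigurationError("group_effect must be >= 0")


@dataclass(frozen=True)
class ToySeries:
    """A 1-D series with known structure for direct recurrence analysis.

    Kinds: ``constant`` (params: value), ``sine`` (period, amplitude,
    noise_sd), ``white_noise`` (mean, sd), ``drift`` (slope, intercept,
    noise_sd), ``disrupted`` (noise_sd, jump, breakpoints).
    """

    kind: str = "white_noise"
    length: int = 100
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _TOY_KINDS:
            raise ConfigurationError(
                f"unknown toy series kind {self.kind!r}; expected one of {_TOY_KINDS}"
            )
        if self.length < 2:
            raise ConfigurationError("length must be >= 2")


def gen_toy_series(spec: ToySeries) -> np.ndarray:
    """Generate the series described by ``spec``; deterministic given its seed."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.length, dtype=np.float64)
    p = spec.params
    if spec.kind == "constant":
        x = np.full(spec.length, float(p.get("value", 1.0)))
    elif spec.kind == "sine":
        period = float(p.get("period", 10.0))
        if period <= 0:
            raise ConfigurationError("sine period must be > 0")
        x = float(p.get("amplitude", 1.0)) * np.sin(2.0 * np.pi * t / period)
        x += rng.normal(0.0, float(p.get("noise_sd", 0.0)), spec.length)
    elif spec.kind == "white_noise":
        x = rng.normal(float(p.get("mean", 0.0)), float(p.get("sd", 1.0)), spec.length)
    elif spec.kind == "drift":
        x = float(p.get("intercept", 0.0)) + float(p.get("slope", 0.01)) * t
        x += rng.normal(0.0, float(p.get("noise_sd", 0.1)), spec.length)
    else:  # disrupted: level shifts at breakpoints over a noisy baseline
        x = rng.normal(0.0, float(p.get("noise_sd", 0.1)), spec.length)
        jump = float(p.get("jump", 2.0))
        breakpoints = p.get("breakpoints", (spec.length // 2,))
        for b in breakpoints:
            if not 0 < int(b) < spec.length:
                raise ConfigurationError(f"breakpoint {b} outside series range")
            x[int(b):] += jump
    if not np.isfinite(x).all():
        raise ConfigurationError("generated series contains non-finite values")
    return x


def _foreground_slice(rng: np.random.Generator, rows: int, cols: int,
                      sill: float, corr_range: float) -> np.ndarray:
    """One slice's bone field: smoothed white noise mapped to mean 0.75 / variance sill."""
    noise = rng.standard_normal((rows, cols))
    fieldv = gaussian_filter(noise, sigma=corr_range, mode="reflect")
    if sill > 0:
        sd = fieldv.std()
        if sd == 0:  # degenerate only for pathological sizes
            fieldv = np.zeros_like(fieldv)
        else:
            fieldv = (fieldv - fieldv.mean()) / sd * np.sqrt(sill)
    else:
        fieldv = np.zeros_like(fieldv)
    return np.clip(_FOREGROUND_MEAN + fieldv, 0.5, 1.0)


def gen_volume(spec: VolumeSpec) -> CTVolume:
    """Generate a synthetic CT-like volume.

    All intensities lie in [0, 1]; rows above ``bone_row_start`` hold only
    background (< 0.5); foreground rows hold a correlated random field whose
    per-slice variance tracks ``sill`` (+ per-slice drift), clipped to
    [0.5, 1].
    """
    rng = np.random.default_rng(spec.seed)
    data = np.full((spec.n_slices, spec.height, spec.width), spec.background_level,
                   dtype=np.float64)
    r0 = spec.bone_row_start - 1  # 1-based spec row -> 0-based array row
    fg_rows = spec.height - r0
    for t in range(spec.n_slices):
        sill_t = max(spec.sill + spec.drift * t, 0.0)
        data[t, r0:, :] = _foreground_slice(rng, fg_rows, spec.width, sill_t,
                                            spec.corr_range)
    return CTVolume(data, intensity_domain="normalized", source=f"synthetic(seed={spec.seed})")


def gen_cohort(spec: CohortSpec) -> list[tuple[CTVolume, str]]:
    """Generate ``2 * n_per_group`` labelled volumes.

    Group ``"low"`` uses the base spec; group ``"high"`` uses
    ``sill + group_effect``.  Per-volume seeds are spawned deterministically
    from ``spec.seed``.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * spec.n_per_group)
    cohort: list[tuple[CTVolume, str]] = []
    for g, label in enumerate(("low", "high")):
        sill = spec.base.sill + (spec.group_effect if label == "high" else 0.0)
        for j in range(spec.n_per_group):
            vspec = replace(spec.base, sill=sill,
                            seed=int(seeds[g * spec.n_per_group + j]))
            cohort.append((gen_volume(vspec), label))
    return cohort
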