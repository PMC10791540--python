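"""Per-subject orchestration and cohort summarization.

``run_subject`` chains the full analysis for one volume — semi-variogram
series, embedding, fuzzy c-means, fuzzy recurrence plot, then recurrence
quantification, alpha-cut network properties and the largest recurrence
eigenvalue — under a single serializable configuration and seed.
``summarize_cohort`` aggregates per-subject features into group means and
sample standard deviations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eigenpool import EigenConfig, largest_recurrence_eigenvalue
from .exceptions import CTRecurError, InputError
from .io import CTVolume
from .network import alpha_cut_adjacency, cluster_similarity, graph_properties
from .recurrence import embed, fcm_partition, frp
from .rqa import frqa_measures
from .variogram import SemivariogramSeries, VariogramConfig, semivariogram_series

__all__ = [
    "PipelineConfig",
    "SubjectFeatures",
    "CohortReport",
    "FEATURE_COLUMNS",
    "run_subject",
    "run_series",
    "summarize_cohort",
]

FEATURE_COLUMNS = [
    "fRR", "fDET", "fLAM", "fTT", "fDIV", "fENT",
    "characteristic_path_length", "average_clustering_coefficient", "lambda_max",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every parameter of the per-subject pipeline, JSON-serializable."""

    variogram: VariogramConfig = field(default_factory=VariogramConfig)
    m: int = 3
    tau: int = 1
    c: int = 10
    fuzzifier: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 1000
    omega: float = 0.5
    lmin_d: int = 5
    lmin_v: int = 5
    binarize_method: str = "otsu"
    binarize_threshold: float = 0.5
    entropy_mode: str = "restricted"
    alpha: float = 0.4
    beta: float = 0.08
    eigen: EigenConfig = field(default_factory=EigenConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eigen"]["kernel"] = np.asarray(self.eigen.kernel).tolist()
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "variogram" in d and isinstance(d["variogram"], dict):
            d["variogram"] = VariogramConfig(**d["variogram"])
        if "eigen" in d and isinstance(d["eigen"], dict):
            e = dict(d["eigen"])
            if "kernel" in e:
                e["kernel"] = np.asarray(e["kernel"], dtype=np.float64)
            d["eigen"] = EigenConfig(**e)
        return cls(**d)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SubjectFeatures:
    """One subject's feature row (missing stages left as None)."""

    subject_id: str
    group: str
    fRR: float | None = None
    fDET: float | None = None
    fLAM: float | None = None
    fTT: float | None = None
    fDIV: float | None = None
    fENT: float | None = None
    characteristic_path_length: float | None = None
    average_clustering_coefficient: float | None = None
    lambda_max: float | None = None
    T: int | None = None
    L: int | None = None

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CohortReport:
    """Per-subject feature table plus per-group mean and sample SD."""

    per_subject: pd.DataFrame
    summary: pd.DataFrame  # index: group; columns: <feature>_mean, <feature>_sd

    def group_mean(self, group: str, feature: str) -> float:
        return float(self.summary.loc[group, f"{feature}_mean"])

    def group_sd(self, group: str, feature: str) -> float:
        return float(self.summary.loc[group, f"{feature}_sd"])

    def formatted(self, decimals: int = 3) -> pd.DataFrame:
        """Presentation table: 'mean ± SD' strings per group and feature."""
        out = {}
        for feat in _present_features(self.summary):
            out[feat] = [
                f"{self.summary.loc[g, feat + '_mean']:.{decimals}f} ± "
                f"{self.summary.loc[g, feat + '_sd']:.{decimals}f}"
                for g in self.summary.index
            ]
        return pd.DataFrame(out, index=self.summary.index)


def _present_features(summary: pd.DataFrame) -> list[str]:
    return [c[:-5] for c in summary.columns if c.endswith("_mean")]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CTRecurError):
                raise type(exc)(f"[stage: {name}] {exc}") from exc
            return False

    return _Ctx()


def run_series(series: SemivariogramSeries | np.ndarray, subject_id: str, group: str,
               config: PipelineConfig | None = None) -> SubjectFeatures:
    """Run the recurrence stages on an already computed scalar series."""
    if config is None:
        config = PipelineConfig()
    x = series.values if isinstance(series, SemivariogramSeries) else np.asarray(series)

    with _stage("embed"):
        ps = embed(x, config.m, config.tau)
    with _stage("fcm"):
        partition = fcm_partition(ps, c=config.c, fuzzifier=config.fuzzifier,
                                  tol=config.fcm_tol, max_iter=config.fcm_max_iter,
                                  seed=config.seed)
    with _stage("frp"):
        R = frp(partition)
    with _stage("frqa"):
        q = frqa_measures(R, omega=config.omega, lmin_d=config.lmin_d,
                          lmin_v=config.lmin_v, method=config.binarize_method,
                          threshold=config.binarize_threshold,
                          entropy_mode=config.entropy_mode)
    with _stage("network"):
        S = cluster_similarity(partition, beta=config.beta)
        props = graph_properties(alpha_cut_adjacency(S, alpha=config.alpha))
    with _stage("eigen"):
        lam = largest_recurrence_eigenvalue(R, config.eigen)

    return SubjectFeatures(
        subject_id=subject_id, group=group,
        fRR=q.fRR, fDET=q.fDET, fLAM=q.fLAM, fTT=q.fTT, fDIV=q.fDIV, fENT=q.fENT,
        characteristic_path_length=props.characteristic_path_length,
        average_clustering_coefficient=props.average_clustering_coefficient,
        lambda_max=lam, T=int(x.size), L=ps.L,
    )


def run_subject(volume: CTVolume, group: str, config: PipelineConfig | None = None,
                subject_id: str = "S1") -> SubjectFeatures:
    """Full per-subject analysis of one normalized volume."""
    if config is None:
        config = PipelineConfig()
    with _stage("variogram"):
        series = semivariogram_series(volume, config.variogram, subject_id=subject_id)
    return run_series(series, subject_id, group, config)


def summarize_cohort(features: list[SubjectFeatures]) -> CohortReport:
    """Group means and sample (n-1) standard deviations per feature.

    A single-subject group reports its value with SD 0; features missing for
    every subject are dropped from the summary.
    """
    if not features:
        raise InputError("summarize_cohort requires at least one subject")
    per_subject = pd.DataFrame([f.as_row() for f in features])
    rows = {}
    for group, sub in per_subject.groupby("group", sort=True):
        row = {}
        for feat in FEATURE_COLUMNS:
            vals = sub[feat].dropna().astype(float)
            if vals.empty:
                continue
            row[f"{feat}_mean"] = vals.mean()
            row[f"{feat}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows[group] = row
    summary = pd.DataFrame.from_dict(rows, orient="index").dropna(axis=1, how="all")
    summary.index.name = "group"
    return CohortReport(per_subject=per_subject, summary=summary)
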