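"""Domain types and delimited-text I/O for cluster-level count data.

The central container is :class:`ClusterCountTable`: one row per cluster
(hospital, ICU, ward) with an event count and the person-time (patient-days
or device-days) over which those events were observed.  All rates in this
package are daily rates — events per patient-day or device-day — with no
per-1000 scaling; reporting layers may rescale for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusterCountTable",
    "DesignSpec",
    "RateSummary",
    "SampleSizeResult",
    "ValidationError",
    "read_cluster_counts",
    "write_cluster_counts",
]


class ValidationError(ValueError):
    """Raised when an input table or design configuration violates an invariant."""


@dataclass(frozen=True)
class ClusterCountTable:
    """Per-cluster event counts and person-time exposure.

    Parameters
    ----------
    cluster_ids
        Opaque unique identifiers, one per cluster.
    events
        Non-negative integer event counts, one per cluster.
    exposure_days
        Positive person-time denominators (patient-days or device-days).
    """

    cluster_ids: tuple
    events: np.ndarray
    exposure_days: np.ndarray

    def __init__(self, cluster_ids: Sequence, events: Sequence, exposure_days: Sequence):
        ids = tuple(cluster_ids)
        ev = np.asarray(events)
        ex = np.asarray(exposure_days, dtype=float)
        if len(ids) == 0:
            raise ValidationError("cluster table must contain at least one row")
        if not (len(ids) == len(ev) == len(ex)):
            raise ValidationError("cluster_ids, events and exposure_days must have equal length")
        if len(set(ids)) != len(ids):
            raise ValidationError("cluster_id values must be unique")
        if not np.issubdtype(ev.dtype, np.number) or np.any(ev != np.floor(ev)):
            raise ValidationError("events must be integers")
        ev = ev.astype(np.int64)
        for i, (e, d) in enumerate(zip(ev, ex)):
            if e < 0:
                raise ValidationError(f"row {i} (cluster {ids[i]!r}): events must be >= 0, got {e}")
            if not math.isfinite(d) or d <= 0:
                raise ValidationError(
                    f"row {i} (cluster {ids[i]!r}): exposure_days must be > 0, got {d}"
                )
        object.__setattr__(self, "cluster_ids", ids)
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "exposure_days", ex)
        self.events.setflags(write=False)
        self.exposure_days.setflags(write=False)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def rates(self) -> np.ndarray:
        """Observed per-cluster daily rates r_i = events_i / exposure_days_i."""
        return self.events / self.exposure_days

    def subset(self, indices: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        """Events and exposures at ``indices`` (with repeats), for resampling."""
        idx = np.asarray(indices, dtype=np.intp)
        return self.events[idx], self.exposure_days[idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": list(self.cluster_ids),
                "events": self.events,
                "exposure_days": self.exposure_days,
            }
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        id_col: str = "cluster_id",
        events_col: str = "events",
        exposure_col: str = "exposure_days",
    ) -> "ClusterCountTable":
        for col in (id_col, events_col, exposure_col):
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
        ev = pd.to_numeric(df[events_col], errors="coerce")
        ex = pd.to_numeric(df[exposure_col], errors="coerce")
        if ev.isna().any():
            row = int(ev.index[ev.isna()][0])
            raise ValidationError(f"row {row}: non-numeric value in column {events_col!r}")
        if ex.isna().any():
            row = int(ex.index[ex.isna()][0])
            raise ValidationError(f"row {row}: non-numeric value in column {exposure_col!r}")
        return cls(df[id_col].tolist(), ev.to_numpy(), ex.to_numpy())


def read_cluster_counts(
    path: str | Path,
    id_col: str = "cluster_id",
    events_col: str = "events",
    exposure_col: str = "exposure_days",
) -> ClusterCountTable:
    """Read a CSV cluster-count table (header row required, UTF-8).

    Column names are configurable so that hospital-level extracts with
    site-specific headers can be ingested without rewriting the file.
    Row order is preserved.
    """
    df = pd.read_csv(path)
    return ClusterCountTable.from_dataframe(df, id_col, events_col, exposure_col)


def write_cluster_counts(table: ClusterCountTable, path: str | Path) -> None:
    """Write a cluster-count table as CSV; round-trips exactly with the reader."""
    df = table.to_dataframe()
    # repr-precision floats so exposure values survive the round trip bit-exactly
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class DesignSpec:
    """The eight parameters of the incidence-rate CRT sizing formula.

    Attributes
    ----------
    rate_control
        Anticipated daily incidence rate in the control arm (events per
        patient-day or device-day), lambda_c > 0.
    effect_size
        Proportional reduction in (0, 1); the experimental-arm rate is
        ``(1 - effect_size) * rate_control``.
    mean_cluster_size
        Person-days of exposure per cluster per day (m > 0).
    followup_days
        Planned follow-up time t in days.
    cv
        Between-cluster coefficient of variation k of the true daily rates
        (SD of cluster-specific rates divided by the mean rate), k >= 0.
    alpha
        Type-I error rate.
    power
        1 - type-II error rate.
    allocation_ratio
        Control : experimental cluster ratio (default 1, as in a balanced
        two-arm trial).
    two_tailed
        Whether alpha is split across two tails (default) or one.
    """

    rate_control: float
    effect_size: float
    mean_cluster_size: float
    followup_days: float
    cv: float
    alpha: float = 0.05
    power: float = 0.80
    allocation_ratio: float = 1.0
    two_tailed: bool = True

    def __post_init__(self):
        checks = [
            ("rate_control", self.rate_control > 0, "must be > 0"),
            ("effect_size", 0 < self.effect_size < 1, "must be in (0, 1)"),
            ("mean_cluster_size", self.mean_cluster_size > 0, "must be > 0"),
            ("followup_days", self.followup_days > 0, "must be > 0"),
            ("cv", self.cv >= 0, "must be >= 0"),
            ("alpha", 0 < self.alpha < 1, "must be in (0, 1)"),
            ("power", 0 < self.power < 1, "must be in (0, 1)"),
            ("allocation_ratio", self.allocation_ratio > 0, "must be > 0"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ValidationError(f"{name} {msg}, got {getattr(self, name)}")

    @property
    def rate_experimental(self) -> float:
        """lambda_e = (1 - effect_size) * lambda_c, strictly below lambda_c."""
        return (1.0 - self.effect_size) * self.rate_control

    @property
    def person_time_per_cluster(self) -> float:
        """y = m * t, the expected exposure accumulated by one cluster."""
        return self.mean_cluster_size * self.followup_days

    def with_(self, **kwargs) -> "DesignSpec":
        """Copy with selected fields replaced (validated on construction)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RateSummary:
    """Estimated rate parameters for one outcome.

    ``cv`` is ``sd_between / mean_rate``; ``cv_se`` is its bootstrap standard
    error (hospitals resampled with replacement).  ``mean_cluster_size`` is
    person-days per cluster per day, and may be None when study duration is
    unknown.
    """

    mean_rate: float
    sd_between: float
    cv: float
    cv_se: float
    n_clusters: int
    mean_cluster_size: float | None = None

    def __post_init__(self):
        if self.sd_between < 0:
            raise ValidationError("sd_between must be >= 0")
        if self.cv_se < 0:
            raise ValidationError("cv_se must be >= 0")
        if self.mean_rate > 0 and not math.isclose(
            self.cv, self.sd_between / self.mean_rate, rel_tol=1e-6, abs_tol=1e-12
        ):
            raise ValidationError("cv must equal sd_between / mean_rate")

    def to_dict(self) -> dict:
        return {
            "mean_rate": self.mean_rate,
            "sd_between": self.sd_between,
            "cv": self.cv,
            "cv_se": self.cv_se,
            "n_clusters": self.n_clusters,
            "mean_cluster_size": self.mean_cluster_size,
        }


@dataclass(frozen=True)
class SampleSizeResult:
    """Cluster requirement for a two-arm parallel CRT.

    ``clusters_unrounded`` is the raw Hayes–Bennett value c, including its
    finite-cluster "+1" term.  Under the standard reading c is the count per
    arm; the reporting convention used here for 1:1 allocation treats
    floor(c) as the TOTAL and splits arms ceil/floor — see
    :func:`crtplan.design.clusters_required` for why both are carried.
    """

    clusters_unrounded: float
    total_clusters: int
    n_intervention: int
    n_control: int
    spec: DesignSpec

    def __post_init__(self):
        if self.n_intervention + self.n_control != self.total_clusters:
            raise ValidationError("arm counts must sum to total_clusters")

    def to_dict(self) -> dict:
        d = {
            "clusters_unrounded": self.clusters_unrounded,
            "total_clusters": self.total_clusters,
            "n_intervention": self.n_intervention,
            "n_control": self.n_control,
        }
        d.update({f"spec_{k}": v for k, v in vars(self.spec).items()})
        return d
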