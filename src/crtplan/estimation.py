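"""Moment estimation of cluster-rate parameters from count tables.

Given per-cluster event counts c_i and exposures d_i, this module estimates:

* the pooled (exposure-weighted) mean daily rate  r_bar = sum(c_i) / sum(d_i);
* the between-cluster SD of the true daily rates via the excess-variance
  moment method: the empirical variance of observed cluster rates minus the
  variance expected from within-cluster Poisson sampling alone, truncated
  at zero;
* the coefficient of variation k = SD / r_bar and its bootstrap standard
  error (clusters resampled with replacement);
* the mean cluster size (person-days per cluster per day) and the ICC.

The excess-variance logic: even if all clusters shared one true rate
lambda, the observed rates r_i = c_i / d_i would scatter with variance
lambda / d_i.  Observed scatter beyond that average Poisson floor is
attributed to genuine between-cluster heterogeneity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data import ClusterCountTable, RateSummary, ValidationError

__all__ = [
    "BootstrapConfig",
    "VarianceDecomposition",
    "pooled_rate",
    "unweighted_mean_rate",
    "between_cluster_sd",
    "cv_of_rates",
    "bootstrap_cv_se",
    "mean_cluster_size",
    "icc_from_components",
    "summarize_rates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    """Cluster bootstrap settings: number of resamples B and the RNG seed."""

    n_resamples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")


@dataclass(frozen=True)
class VarianceDecomposition:
    """Observed variance of cluster rates split into sampling and real parts.

    ``between_variance = max(0, observed - expected_poisson)``; its square
    root is the between-cluster SD of true daily rates.
    """

    observed_variance: float
    expected_poisson_variance: float
    between_variance: float

    @property
    def sd(self) -> float:
        return math.sqrt(self.between_variance)


def pooled_rate(table: ClusterCountTable) -> float:
    """Total events over total exposure — identical to the exposure-weighted
    mean of the per-cluster rates."""
    return float(table.events.sum() / table.exposure_days.sum())


def unweighted_mean_rate(table: ClusterCountTable) -> float:
    """Simple mean of per-cluster observed rates (alternative estimator that
    gives every cluster equal weight regardless of size)."""
    return float(table.rates.mean())


def _decompose(events: np.ndarray, exposure: np.ndarray) -> VarianceDecomposition:
    h = len(events)
    rates = events / exposure
    rbar = events.sum() / exposure.sum()
    observed = float(np.sum((rates - rbar) ** 2) / (h - 1))
    # mean over clusters of Var(r_i | lambda = rbar) = rbar / d_i
    expected = float(rbar / h * np.sum(1.0 / exposure))
    between = max(0.0, observed - expected)
    return VarianceDecomposition(observed, expected, between)


def between_cluster_sd(table: ClusterCountTable) -> VarianceDecomposition:
    """Excess-over-Poisson moment decomposition of the cluster-rate variance.

    Requires at least two clusters.  The observed variance uses the pooled
    rate as centre and an H-1 denominator; the expected term is the average
    per-cluster Poisson variance at that pooled rate.
    """
    if table.n_clusters < 2:
        raise ValidationError("between-cluster variance requires >= 2 clusters")
    return _decompose(table.events, table.exposure_days)


def cv_of_rates(table: ClusterCountTable) -> float:
    """Between-cluster SD divided by the pooled mean rate (dimensionless)."""
    rbar = pooled_rate(table)
    if rbar <= 0:
        raise ValidationError("CV undefined: total event count is zero")
    return between_cluster_sd(table).sd / rbar


def bootstrap_cv_se(table: ClusterCountTable, config: BootstrapConfig) -> float:
    """Bootstrap standard error of the CV, resampling clusters with replacement.

    Draws ``config.n_resamples`` resamples of all H clusters using
    ``numpy.random.default_rng(config.seed).integers(0, H, (B, H))`` and
    returns the sample SD (B-1 denominator) of the resample CVs.  Resamples
    whose total event count is zero have no defined CV; they are skipped and
    their count logged.
    """
    if table.n_clusters < 2:
        raise ValidationError("bootstrap requires >= 2 clusters")
    h = table.n_clusters
    rng = np.random.default_rng(config.seed)
    indices = rng.integers(0, h, size=(config.n_resamples, h))
    cvs = []
    n_degenerate = 0
    for idx in indices:
        ev, ex = table.subset(idx)
        if ev.sum() == 0:
            n_degenerate += 1
            continue
        dec = _decompose(ev, ex)
        cvs.append(dec.sd / (ev.sum() / ex.sum()))
    if n_degenerate:
        logger.info(
            "bootstrap_cv_se: skipped %d/%d degenerate resamples (zero events)",
            n_degenerate,
            config.n_resamples,
        )
    if len(cvs) < 2:
        raise ValidationError("all bootstrap resamples degenerate; SE undefined")
    return float(np.std(cvs, ddof=1))


def mean_cluster_size(
    total_exposure_days: float, n_clusters: int, study_days: float
) -> float:
    """Person-days per cluster per day: total exposure / (clusters x days)."""
    if total_exposure_days <= 0 or n_clusters <= 0 or study_days <= 0:
        raise ValidationError("all arguments must be positive")
    return total_exposure_days / (n_clusters * study_days)


def icc_from_components(between_variance: float, within_variance: float) -> float:
    """Intraclass correlation: between / (between + within) variance."""
    if between_variance < 0 or within_variance < 0:
        raise ValidationError("variance components must be >= 0")
    total = between_variance + within_variance
    if total == 0:
        raise ValidationError("ICC undefined when both components are zero")
    return between_variance / total


def summarize_rates(
    table: ClusterCountTable,
    bootstrap: BootstrapConfig | None = None,
    study_days: float | None = None,
) -> RateSummary:
    """One-call estimation of all rate parameters for a cluster table.

    ``study_days`` is needed only for the mean-cluster-size conversion; when
    omitted, that field is left unset rather than guessed.
    """
    rbar = pooled_rate(table)
    dec = between_cluster_sd(table)
    cv = dec.sd / rbar if rbar > 0 else 0.0
    se = bootstrap_cv_se(table, bootstrap) if bootstrap is not None else 0.0
    mcs = (
        mean_cluster_size(float(table.exposure_days.sum()), table.n_clusters, study_days)
        if study_days is not None
        else None
    )
    return RateSummary(
        mean_rate=rbar,
        sd_between=dec.sd,
        cv=cv,
        cv_se=se,
        n_clusters=table.n_clusters,
        mean_cluster_size=mcs,
    )
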