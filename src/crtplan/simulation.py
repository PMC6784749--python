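"""Synthetic cluster-count data and Monte-Carlo power validation.

The generator emulates the structure the estimation and sizing methods
assume: each cluster has a latent true daily rate drawn from a distribution
with specified mean and between-cluster CV (gamma by default, lognormal as
a robustness alternative), an exposure in person-days, and a Poisson event
count given rate x exposure.

``simulate_trial_power`` closes the loop on the sizing formula: it runs
many synthetic two-arm trials at a given per-arm cluster count and reports
the fraction rejecting the null under a cluster-summary t test — the
analysis the Hayes–Bennett formula is calibrated to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ClusterCountTable, DesignSpec, ValidationError

__all__ = [
    "SyntheticConfig",
    "TrialSimResult",
    "generate_cluster_table",
    "simulate_trial_power",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic cluster-count table.

    Exposure is either fixed at ``exposure_days`` per cluster, or derived as
    ``mean_cluster_size * study_days`` when those are given instead;
    ``exposure_cv`` adds multiplicative (gamma) spread around that mean to
    mimic heterogeneous hospital sizes.  Cluster true rates are gamma with
    shape 1/cv^2 and scale mean*cv^2 (exactly the requested mean and CV);
    cv = 0 degenerates to identical rates.
    """

    n_clusters: int
    true_mean_rate: float
    true_cv: float
    exposure_days: float | None = None
    mean_cluster_size: float | None = None
    study_days: float | None = None
    exposure_cv: float = 0.0
    rate_distribution: str = "gamma"
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.true_mean_rate <= 0:
            raise ValidationError("true_mean_rate must be > 0")
        if self.true_cv < 0 or self.exposure_cv < 0:
            raise ValidationError("CVs must be >= 0")
        if self.rate_distribution not in ("gamma", "lognormal"):
            raise ValidationError("rate_distribution must be 'gamma' or 'lognormal'")
        if self.exposure_days is None and (
            self.mean_cluster_size is None or self.study_days is None
        ):
            raise ValidationError(
                "specify exposure_days or both mean_cluster_size and study_days"
            )

    @property
    def mean_exposure(self) -> float:
        if self.exposure_days is not None:
            return self.exposure_days
        return self.mean_cluster_size * self.study_days


@dataclass(frozen=True)
class TrialSimResult:
    """Empirical power summary from repeated simulated trials."""

    n_sims: int
    rejections: int
    empirical_power: float
    n_degenerate: int
    analysis_method: str
    seed: int


def _draw_rates(rng: np.random.Generator, n: int, mean: float, cv: float, dist: str) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    if dist == "gamma":
        shape = 1.0 / cv**2
        scale = mean * cv**2
        return rng.gamma(shape, scale, size=n)
    # lognormal with matching mean and CV: sigma^2 = log(1 + cv^2)
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _draw_exposures(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    return rng.gamma(1.0 / cv**2, mean * cv**2, size=n)


def generate_cluster_table(config: SyntheticConfig) -> ClusterCountTable:
    """Draw a synthetic cluster-count table; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    lam = _draw_rates(
        rng, config.n_clusters, config.true_mean_rate, config.true_cv, config.rate_distribution
    )
    exposure = _draw_exposures(rng, config.n_clusters, config.mean_exposure, config.exposure_cv)
    events = rng.poisson(lam * exposure)
    ids = [f"cluster_{i:05d}" for i in range(config.n_clusters)]
    return ClusterCountTable(ids, events, exposure)


def _simulate_arm(
    rng: np.random.Generator, n: int, mean_rate: float, cv: float, exposure: float
) -> np.ndarray:
    lam = _draw_rates(rng, n, mean_rate, cv, "gamma")
    events = rng.poisson(lam * exposure)
    return events / exposure


def simulate_trial_power(
    spec: DesignSpec,
    clusters_per_arm: int,
    n_sims: int,
    seed: int,
    under_null: bool = False,
) -> TrialSimResult:
    """Empirical power of the cluster-summary t test at ``clusters_per_arm``.

    Each simulated trial draws control clusters around ``spec.rate_control``
    and intervention clusters around ``spec.rate_experimental``, both with
    between-cluster CV ``spec.cv`` and exposure m*t, then compares the two
    sets of observed cluster rates with an unpaired two-sample t test
    (pooled variance, two-sided) at level alpha.  Trials where the test is
    undefined (e.g. zero variance in both arms) are counted as degenerate
    non-rejections, never dropped from the denominator.

    With ``under_null=True`` both arms are drawn at the control rate, so the
    returned ``empirical_power`` is the empirical type-I error rate.
    """
    if clusters_per_arm < 2:
        raise ValidationError("clusters_per_arm must be >= 2")
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    exposure = spec.person_time_per_cluster
    rate_int = spec.rate_control if under_null else spec.rate_experimental
    rejections = 0
    n_degenerate = 0
    for _ in range(n_sims):
        r_ctrl = _simulate_arm(rng, clusters_per_arm, spec.rate_control, spec.cv, exposure)
        r_int = _simulate_arm(rng, clusters_per_arm, rate_int, spec.cv, exposure)
        if np.ptp(r_ctrl) == 0 and np.ptp(r_int) == 0:
            n_degenerate += 1
            continue
        t, p = stats.ttest_ind(r_int, r_ctrl, equal_var=True)
        if p < spec.alpha:
            rejections += 1
    return TrialSimResult(
        n_sims=n_sims,
        rejections=rejections,
        empirical_power=rejections / n_sims,
        n_degenerate=n_degenerate,
        analysis_method="cluster-summary t test (pooled variance, two-sided)",
        seed=seed,
    )
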