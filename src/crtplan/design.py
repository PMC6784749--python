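"""Cluster counts for two-arm parallel CRTs with incidence-rate outcomes.

The core is the Hayes–Bennett closed form for comparing incidence rates
between two arms of c clusters each, with person-time y = m*t per cluster
and between-cluster coefficient of variation k:

    c = 1 + (z_alpha + z_beta)^2 * [ (l1 + l2)/y + k^2 (l1^2 + l2^2) ]
                                   / (l1 - l2)^2

The first bracket term is within-cluster Poisson sampling noise, which
vanishes as person-time grows; the k^2 term is irreducible between-cluster
heterogeneity, which caps the benefit of bigger clusters.  The "+1" term
compensates for estimating the between-cluster variance from the trial
itself.

Reporting convention: the formula defines c per arm, but the reproduction
target reports floor(c) as the TOTAL cluster count for 1:1 allocation,
split ceil/floor across arms (e.g. c = 73.97 -> 73 total, 37/36).  Both the
raw c and the convention totals are carried on every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DesignSpec, SampleSizeResult, ValidationError

__all__ = [
    "GridRequest",
    "normal_quantile",
    "clusters_required",
    "power_given_clusters",
    "sensitivity_grid",
]

DEFAULT_EFFECT_SIZES = (0.10, 0.30, 0.50)
DEFAULT_CV_OFFSETS = (-0.1, 0.0, 0.1)
DEFAULT_POWERS = (0.80, 0.90)


def normal_quantile(p: float) -> float:
    """Standard normal quantile x with Phi(x) = p, for 0 < p < 1."""
    if not 0 < p < 1:
        raise ValidationError(f"probability must be in (0, 1), got {p}")
    return float(stats.norm.ppf(p))


def _z_alpha(spec: DesignSpec) -> float:
    return normal_quantile(1 - spec.alpha / 2 if spec.two_tailed else 1 - spec.alpha)


def _variance_term(spec: DesignSpec) -> float:
    """(l_e + l_c)/(m t) + k^2 (l_e^2 + l_c^2) — the bracketed variance sum."""
    le, lc = spec.rate_experimental, spec.rate_control
    y = spec.person_time_per_cluster
    return (le + lc) / y + spec.cv**2 * (le**2 + lc**2)


def clusters_required(spec: DesignSpec) -> SampleSizeResult:
    """Hayes–Bennett cluster requirement for ``spec``.

    For 1:1 allocation the returned ``total_clusters`` is floor(c) with arms
    split ceil/floor (the reproduction convention; the standard reading of c
    is per arm and is available as ``clusters_unrounded``).  For allocation
    ratios other than 1, the experimental arm receives c clusters and the
    control arm ``allocation_ratio * c``, each rounded up independently,
    and ``total_clusters`` is their sum.
    """
    le, lc = spec.rate_experimental, spec.rate_control
    if le == lc:
        raise ValidationError("effect size must be nonzero")
    zsum = _z_alpha(spec) + normal_quantile(spec.power)
    c = 1.0 + zsum**2 * _variance_term(spec) / (lc - le) ** 2
    if spec.allocation_ratio == 1.0:
        total = math.floor(c)
        n_int = math.ceil(total / 2)
        n_ctrl = math.floor(total / 2)
    else:
        n_int = math.ceil(c)
        n_ctrl = math.ceil(spec.allocation_ratio * c)
        total = n_int + n_ctrl
    return SampleSizeResult(
        clusters_unrounded=c,
        total_clusters=total,
        n_intervention=n_int,
        n_control=n_ctrl,
        spec=spec,
    )


def power_given_clusters(spec: DesignSpec, clusters_per_arm: float) -> float:
    """Invert the sizing formula: the power achieved with ``clusters_per_arm``
    clusters in each arm (the raw formula scale, so this round-trips with
    ``clusters_required(spec).clusters_unrounded``).

    Requires ``clusters_per_arm > 1``: the formula's "+1" term consumes one
    cluster's worth of information, so at or below 1 no power is available.
    """
    if clusters_per_arm <= 1:
        raise ValidationError("clusters_per_arm must exceed 1")
    le, lc = spec.rate_experimental, spec.rate_control
    if le == lc:
        raise ValidationError("effect size must be nonzero")
    z_beta = math.sqrt((clusters_per_arm - 1) * (lc - le) ** 2 / _variance_term(spec)) - _z_alpha(
        spec
    )
    return float(stats.norm.cdf(z_beta))


@dataclass(frozen=True)
class GridRequest:
    """Sensitivity-analysis grid: effect sizes x additive CV shifts x powers."""

    base: DesignSpec
    effect_sizes: tuple = DEFAULT_EFFECT_SIZES
    cv_offsets: tuple = DEFAULT_CV_OFFSETS
    powers: tuple = DEFAULT_POWERS

    def __post_init__(self):
        for e in self.effect_sizes:
            if not 0 < e < 1:
                raise ValidationError(f"effect size must be in (0, 1), got {e}")
        for off in self.cv_offsets:
            if self.base.cv + off < 0:
                raise ValidationError(
                    f"cv offset {off} drives CV below zero (base {self.base.cv})"
                )
        for p in self.powers:
            if not 0 < p < 1:
                raise ValidationError(f"power must be in (0, 1), got {p}")


def sensitivity_grid(request: GridRequest) -> pd.DataFrame:
    """One sizing row per (effect, shifted CV, power) combination.

    Rows are ordered effect ascending, CV ascending, power ascending; each
    row echoes the full resolved spec alongside the cluster counts.
    """
    rows = []
    for effect in sorted(request.effect_sizes):
        for off in sorted(request.cv_offsets):
            for power in sorted(request.powers):
                spec = request.base.with_(
                    effect_size=effect, cv=request.base.cv + off, power=power
                )
                res = clusters_required(spec)
                rows.append(res.to_dict() | {"effect": effect, "cv": spec.cv, "power": power})
    cols = ["effect", "cv", "power", "clusters_unrounded", "total_clusters",
            "n_intervention", "n_control"]
    df = pd.DataFrame(rows)
    return df[cols + [c for c in df.columns if c not in cols]]
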