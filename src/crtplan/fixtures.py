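"""Published parameter estimates for six hospital-infection outcomes.

These are the 2016 Hospital Compare facility-level estimates (MRSA
bacteremia, CAUTI, CLABSI, CDI) and the BUGG-study baseline ICU estimates
(MRSA and VRE acquisition): total cases, person-time, number of clusters,
exposure-weighted mean daily rate, between-cluster SD of cluster-specific
rates, its CV with bootstrap SE, and mean cluster size in person-days per
cluster per day.  Values are stored exactly as published; ``cv_text`` is the
2-decimal CV quoted in the running text of the source, which differs from
the 4-decimal ``cv`` and is the value its worked sample-size numbers used.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import DesignSpec, RateSummary

__all__ = ["OutcomeFixture", "OUTCOMES", "load_paper_fixture"]


@dataclass(frozen=True)
class OutcomeFixture:
    """Published rate parameters for one outcome."""

    key: str
    label: str
    cases: int
    exposure_days: int
    n_clusters: int
    mean_rate: float  # events per patient-day or device-day
    sd_between: float
    cv: float  # 4-decimal published value
    cv_se: float
    cv_text: float  # 2-decimal value used in the source's worked examples
    mean_cluster_size: float  # person-days per cluster per day

    def rate_summary(self) -> RateSummary:
        return RateSummary(
            mean_rate=self.mean_rate,
            sd_between=self.sd_between,
            cv=self.sd_between / self.mean_rate if self.mean_rate else 0.0,
            cv_se=self.cv_se,
            n_clusters=self.n_clusters,
            mean_cluster_size=self.mean_cluster_size,
        )

    def design_spec(
        self,
        effect_size: float,
        cv: float | None = None,
        followup_days: float = 365.0,
        alpha: float = 0.05,
        power: float = 0.80,
        **kwargs,
    ) -> DesignSpec:
        """A DesignSpec for this outcome; CV defaults to the 2-decimal text value."""
        return DesignSpec(
            rate_control=self.mean_rate,
            effect_size=effect_size,
            mean_cluster_size=self.mean_cluster_size,
            followup_days=followup_days,
            cv=self.cv_text if cv is None else cv,
            alpha=alpha,
            power=power,
            **kwargs,
        )


OUTCOMES: dict[str, OutcomeFixture] = {
    f.key: f
    for f in [
        OutcomeFixture(
            key="mrsa_bacteremia",
            label="MRSA bacteremia",
            cases=7857,
            exposure_days=134_687_225,
            n_clusters=1682,
            mean_rate=0.000055,
            sd_between=0.00003,
            cv=0.5520,
            cv_se=0.0176,
            cv_text=0.55,
            mean_cluster_size=219.4,
        ),
        OutcomeFixture(
            key="cauti",
            label="CAUTI",
            cases=20_371,
            exposure_days=19_500_649,
            n_clusters=2293,
            mean_rate=0.000955,
            sd_between=0.00066,
            cv=0.6968,
            cv_se=0.0147,
            cv_text=0.70,
            mean_cluster_size=23.3,
        ),
        OutcomeFixture(
            key="clabsi",
            label="CLABSI",
            cases=15_974,
            exposure_days=18_531_845,
            n_clusters=2029,
            mean_rate=0.000815,
            sd_between=0.00044,
            cv=0.5507,
            cv_se=0.0136,
            cv_text=0.55,
            mean_cluster_size=25.0,
        ),
        OutcomeFixture(
            key="cdi",
            label="CDI",
            cases=92_886,
            exposure_days=138_491_904,
            n_clusters=3055,
            mean_rate=0.000616,
            sd_between=0.00027,
            cv=0.4417,
            cv_se=0.0058,
            cv_text=0.44,
            mean_cluster_size=124.2,
        ),
        OutcomeFixture(
            key="mrsa_acq",
            label="MRSA acquisition",
            cases=136,
            exposure_days=17_023,
            n_clusters=20,
            mean_rate=0.008320,
            sd_between=0.00486,
            cv=0.5840,
            cv_se=0.2806,
            cv_text=0.58,
            mean_cluster_size=7.1,
        ),
        OutcomeFixture(
            key="vre_acq",
            label="VRE acquisition",
            cases=230,
            exposure_days=16_510,
            n_clusters=20,
            mean_rate=0.014260,
            sd_between=0.00738,
            cv=0.5180,
            cv_se=0.2183,
            cv_text=0.52,
            mean_cluster_size=6.9,
        ),
    ]
}


def load_paper_fixture(outcome: str) -> OutcomeFixture:
    """Return the published parameter set for ``outcome``.

    Valid names: mrsa_bacteremia, cauti, clabsi, cdi, mrsa_acq, vre_acq.
    """
    try:
        return OUTCOMES[outcome]
    except KeyError:
        raise KeyError(
            f"unknown outcome {outcome!r}; valid names: {', '.join(sorted(OUTCOMES))}"
        ) from None
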