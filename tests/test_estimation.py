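import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtplan import (
    BootstrapConfig,
    ClusterCountTable,
    SyntheticConfig,
    ValidationError,
    between_cluster_sd,
    bootstrap_cv_se,
    cv_of_rates,
    generate_cluster_table,
    icc_from_components,
    mean_cluster_size,
    pooled_rate,
    summarize_rates,
    unweighted_mean_rate,
)

# frozen hand-arithmetic oracle for the 3-cluster fixture (see conftest)
HAND_OBSERVED = 4.0e-6
HAND_EXPECTED = 4.0e-7
HAND_BETWEEN = 3.6e-6
HAND_SD = math.sqrt(3.6e-6)  # 1.8973665961010275e-3
HAND_CV = HAND_SD / 0.002  # 0.9486832980505138


@st.composite
def count_tables(draw):
    n = draw(st.integers(2, 12))
    events = draw(st.lists(st.integers(0, 500), min_size=n, max_size=n))
    exposure = draw(
        st.lists(st.floats(10.0, 1e6, allow_nan=False), min_size=n, max_size=n)
    )
    return ClusterCountTable([f"c{i}" for i in range(n)], events, exposure)


class TestPooledRate:
    def test_single_cluster(self):
        t = ClusterCountTable(["a"], [5], [1000.0])
        assert pooled_rate(t) == pytest.approx(0.005)

    def test_two_clusters(self):
        t = ClusterCountTable(["a", "b"], [10, 20], [10000.0, 10000.0])
        assert pooled_rate(t) == pytest.approx(0.0015)

    @settings(deadline=None, derandomize=True)
    @given(count_tables())
    def test_equals_exposure_weighted_mean_of_rates(self, table):
        w = table.exposure_days
        r = table.rates
        assert pooled_rate(table) == pytest.approx(float(np.sum(w * r) / np.sum(w)))

    def test_unweighted_alternative_differs_when_sizes_differ(self):
        t = ClusterCountTable(["a", "b"], [10, 100], [1000.0, 100000.0])
        assert unweighted_mean_rate(t) == pytest.approx((0.01 + 0.001) / 2)
        assert unweighted_mean_rate(t) != pytest.approx(pooled_rate(t))


class TestBetweenClusterSd:
    def test_zero_spread_truncates_to_zero(self, flat_table):
        dec = between_cluster_sd(flat_table)
        assert dec.between_variance == 0.0
        assert dec.sd == 0.0

    def test_hand_arithmetic_oracle(self, hand_table):
        dec = between_cluster_sd(hand_table)
        assert dec.observed_variance == pytest.approx(HAND_OBSERVED)
        assert dec.expected_poisson_variance == pytest.approx(HAND_EXPECTED)
        assert dec.between_variance == pytest.approx(HAND_BETWEEN)
        assert dec.sd == pytest.approx(HAND_SD)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError, match="2 clusters"):
            between_cluster_sd(ClusterCountTable(["a"], [5], [100.0]))

    @settings(deadline=None, derandomize=True)
    @given(count_tables())
    def test_truncation_invariants(self, table):
        dec = between_cluster_sd(table)
        assert dec.between_variance >= 0.0
        assert dec.between_variance <= dec.observed_variance + 1e-30


class TestCvOfRates:
    def test_zero_spread(self, flat_table):
        assert cv_of_rates(flat_table) == 0.0

    def test_hand_arithmetic_oracle(self, hand_table):
        assert cv_of_rates(hand_table) == pytest.approx(HAND_CV, abs=1e-4)

    def test_zero_events_undefined(self):
        t = ClusterCountTable(["a", "b"], [0, 0], [100.0, 100.0])
        with pytest.raises(ValidationError, match="zero"):
            cv_of_rates(t)

    @pytest.mark.parametrize("true_cv", [0.3, 0.5])
    def test_parameter_recovery_on_gamma_poisson_data(self, true_cv):
        cfg = SyntheticConfig(
            n_clusters=5000, true_mean_rate=0.001, true_cv=true_cv,
            exposure_days=20000.0, seed=123,
        )
        est = cv_of_rates(generate_cluster_table(cfg))
        assert abs(est - true_cv) < 0.05

    def test_pure_poisson_data_estimates_near_zero(self):
        cfg = SyntheticConfig(
            n_clusters=5000, true_mean_rate=0.001, true_cv=0.0,
            exposure_days=20000.0, seed=7,
        )
        assert cv_of_rates(generate_cluster_table(cfg)) < 0.1

    def test_bias_shrinks_with_more_clusters(self):
        biases = []
        for h in (50, 500, 5000):
            cfg = SyntheticConfig(
                n_clusters=h, true_mean_rate=0.001, true_cv=0.5,
                exposure_days=20000.0, seed=99,
            )
            biases.append(abs(cv_of_rates(generate_cluster_table(cfg)) - 0.5))
        assert biases[-1] < 0.05


class TestBootstrapCvSe:
    def test_identical_clusters_give_zero_se(self, flat_table):
        assert bootstrap_cv_se(flat_table, BootstrapConfig(200, seed=1)) == 0.0

    def test_matches_independent_resampling_oracle(self, synthetic_table):
        """Independently coded loop using the same documented index stream."""
        cfg = BootstrapConfig(n_resamples=1000, seed=2024)
        h = synthetic_table.n_clusters
        rng = np.random.default_rng(cfg.seed)
        indices = rng.integers(0, h, size=(cfg.n_resamples, h))
        ev_all = np.asarray(synthetic_table.events, dtype=float)
        ex_all = np.asarray(synthetic_table.exposure_days, dtype=float)
        cvs = []
        for idx in indices:
            ev, ex = ev_all[idx], ex_all[idx]
            if ev.sum() == 0:
                continue
            r = ev / ex
            rbar = ev.sum() / ex.sum()
            obs = ((r - rbar) ** 2).sum() / (h - 1)
            exp = rbar / h * (1.0 / ex).sum()
            cvs.append(math.sqrt(max(0.0, obs - exp)) / rbar)
        oracle = float(np.std(cvs, ddof=1))
        assert bootstrap_cv_se(synthetic_table, cfg) == pytest.approx(oracle, rel=0, abs=0)

    def test_deterministic_given_seed(self, synthetic_table):
        cfg = BootstrapConfig(300, seed=5)
        assert bootstrap_cv_se(synthetic_table, cfg) == bootstrap_cv_se(synthetic_table, cfg)

    def test_se_shrinks_roughly_as_inverse_sqrt_clusters(self):
        ses = []
        for h, seed in ((25, 1), (400, 1)):
            cfg = SyntheticConfig(
                n_clusters=h, true_mean_rate=0.001, true_cv=0.5,
                exposure_days=20000.0, seed=seed,
            )
            table = generate_cluster_table(cfg)
            ses.append(bootstrap_cv_se(table, BootstrapConfig(400, seed=9)))
        # 16x the clusters should shrink the SE by roughly 4x; allow slack
        assert ses[1] < ses[0] / 2


class TestMeanClusterSize:
    @pytest.mark.parametrize(
        "exposure,n,expected",
        [
            (134_687_225, 1682, 219.4),
            (19_500_649, 2293, 23.3),
            (18_531_845, 2029, 25.0),
            (138_491_904, 3055, 124.2),
        ],
    )
    def test_published_hospital_values_at_one_year(self, exposure, n, expected):
        assert round(mean_cluster_size(exposure, n, 365.0), 1) == expected

    def test_trivial(self):
        assert mean_cluster_size(7300.0, 20, 365.0) == pytest.approx(1.0)

    def test_positivity_required(self):
        with pytest.raises(ValidationError):
            mean_cluster_size(0.0, 10, 365.0)


class TestIcc:
    @pytest.mark.parametrize("b,w,expected", [(0.0, 5.0, 0.0), (5.0, 0.0, 1.0), (2.0, 6.0, 0.25)])
    def test_ratio(self, b, w, expected):
        assert icc_from_components(b, w) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            icc_from_components(0.0, 0.0)


class TestSummarizeRates:
    def test_summary_consistent_with_components(self, synthetic_table):
        s = summarize_rates(synthetic_table, BootstrapConfig(200, seed=3), study_days=365.0)
        assert s.mean_rate == pytest.approx(pooled_rate(synthetic_table))
        assert s.cv == pytest.approx(cv_of_rates(synthetic_table))
        assert s.n_clusters == synthetic_table.n_clusters
        assert s.mean_cluster_size == pytest.approx(
            float(synthetic_table.exposure_days.sum()) / (synthetic_table.n_clusters * 365.0)
        )

    def test_mean_cluster_size_omitted_without_study_days(self, synthetic_table):
        assert summarize_rates(synthetic_table).mean_cluster_size is None
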