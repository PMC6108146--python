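from fractions import Fraction

import numpy as np
import pytest

from id4screen import (
    SyntheticConfig,
    dichotomize_by_median,
    generate_cohort,
    km_estimate,
    logrank_test,
    stratified_survival_analysis,
)
from id4screen.errors import DegenerateInputError, ValidationError


def logrank_chi2_oracle(ta, ea, tb, eb):
    """Exact-rational log-rank chi-square by direct 2x2 tables at event times.

    Independent of the implementation: exact Fraction arithmetic over an
    explicitly built risk-set table.
    """
    events = sorted({t for t, e in zip(ta, ea) if e}
                    | {t for t, e in zip(tb, eb) if e})
    obs = exp = var = Fraction(0)
    for u in events:
        n_a = sum(1 for t in ta if t >= u)
        n_b = sum(1 for t in tb if t >= u)
        d_a = sum(1 for t, e in zip(ta, ea) if e and t == u)
        d_b = sum(1 for t, e in zip(tb, eb) if e and t == u)
        n, d = n_a + n_b, d_a + d_b
        obs += d_a
        exp += Fraction(d * n_a, n)
        if n > 1:
            var += Fraction(d * n_a * n_b * (n - d), n * n * (n - 1))
    return float((obs - exp) ** 2 / var)


class TestDichotomize:
    def test_odd_n_strict_rule(self):
        labels = dichotomize_by_median(
            {f"S{i}": v for i, v in enumerate([1, 2, 3, 4, 5])}
        )
        assert labels.median_used == 3
        assert sorted(labels.arm("high")) == ["S3", "S4"]

    def test_even_n_uses_lower_interpolation_median(self):
        labels = dichotomize_by_median(
            {f"S{i}": v for i, v in enumerate([1, 2, 3, 4])}
        )
        # lower-interpolation median of (1,2,3,4) is 2; 3 and 4 are high
        assert labels.median_used == 2
        assert sorted(labels.arm("high")) == ["S2", "S3"]

    def test_median_ties_go_low(self):
        labels = dichotomize_by_median(
            {"A": 1.0, "B": 2.0, "C": 2.0, "D": 5.0}
        )
        assert labels.labels["B"] == labels.labels["C"] == "low"

    def test_no_split_error(self):
        with pytest.raises(DegenerateInputError):
            dichotomize_by_median({"A": 7.0, "B": 7.0, "C": 7.0})


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3], [True, False, True])
        np.testing.assert_array_equal(km.event_times, [1, 3])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.survival_at(0) == 1.0
        assert km.survival_at(2.5) == pytest.approx(2 / 3)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([4, 5, 6], [False, False, False])
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_single_event(self):
        km = km_estimate([5.0], [True])
        assert km.survival_at(5.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=57)
        km = km_estimate(times, np.ones(57, dtype=bool))
        for t in np.linspace(0, 40, 25):
            empirical = (times > t).mean()
            assert km.survival_at(t) == pytest.approx(empirical, abs=1e-12)

    def test_monotone_in_unit_interval(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(10, size=80)
        events = rng.random(80) < 0.6
        km = km_estimate(times, events)
        assert ((km.survival >= 0) & (km.survival <= 1)).all()
        assert (np.diff(km.survival) <= 1e-15).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0], [True])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(13)
        times = rng.exponential(20, size=100)
        events = rng.random(100) < 0.5
        km = km_estimate(times, events)
        fitter = lifelines.KaplanMeierFitter().fit(times, events)
        for t in km.event_times:
            assert km.survival_at(t) == pytest.approx(
                float(fitter.predict(t)), abs=1e-10
            )


class TestLogRank:
    def test_identical_groups(self):
        g = ([1.0, 2.0, 3.0], [True, True, False])
        res = logrank_test(g, g)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_hand_computable_fixture(self):
        a = ([1.0, 2.0], [True, True])
        b = ([3.0, 4.0], [True, True])
        res = logrank_test(a, b)
        assert res.chi_square == pytest.approx(49.0 / 17.0, abs=1e-10)
        assert res.chi_square == pytest.approx(
            logrank_chi2_oracle(*a, *b), abs=1e-10
        )

    def test_observed_equals_expected_in_total(self):
        rng = np.random.default_rng(21)
        a = (rng.exponential(10, 30), rng.random(30) < 0.7)
        b = (rng.exponential(15, 25), rng.random(25) < 0.7)
        res = logrank_test(a, b)
        assert sum(res.observed) == pytest.approx(sum(res.expected), abs=1e-9)
        assert res.chi_square == pytest.approx(
            logrank_chi2_oracle(list(a[0]), list(a[1]), list(b[0]), list(b[1])),
            abs=1e-10,
        )

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(22)
        a = (rng.exponential(10, 20), rng.random(20) < 0.5)
        b = (rng.exponential(5, 20), rng.random(20) < 0.5)
        assert logrank_test(a, b).chi_square == pytest.approx(
            logrank_test(b, a).chi_square, abs=1e-12
        )

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(23)
        a = (rng.exponential(10, 40), rng.random(40) < 0.6)
        b = (rng.exponential(20, 35), rng.random(35) < 0.6)
        res = logrank_test(a, b)
        ll = lifelines.statistics.logrank_test(a[0], b[0], a[1], b[1])
        assert res.chi_square == pytest.approx(ll.test_statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ll.p_value, abs=1e-8)

    def test_zero_events_undefined(self):
        with pytest.raises(DegenerateInputError):
            logrank_test(([1.0], [False]), ([2.0], [False]))

    def test_null_type_one_error(self):
        rng = np.random.default_rng(31)
        rejections = 0
        for _ in range(1000):
            a = (rng.exponential(10, 200), rng.random(200) < 0.7)
            b = (rng.exponential(10, 200), rng.random(200) < 0.7)
            rejections += logrank_test(a, b).p_value < 0.05
        assert 30 <= rejections <= 70


class TestStratifiedAnalysis:
    def test_er_positive_effect_detected_not_fabricated(self):
        config = SyntheticConfig(
            n_samples_per_stratum={"ER+": 300, "ER-": 300},
            panel_genes=("G1",), planted_correlations={}, seed=55,
        )
        cohort, _ = generate_cohort(config)
        results = {r.stratum: r for r in
                   stratified_survival_analysis(cohort, "ID4")}
        assert results["ER+"].logrank.p_value < 0.05
        # high expression is protective (HR 0.5): fewer observed than expected
        assert (results["ER+"].logrank.observed[0]
                < results["ER+"].logrank.expected[0])

    def test_flat_expression_stratum_skipped(self, tiny_cohort):
        tiny_cohort.expression.values.loc["ID4",
                                          tiny_cohort.sample_ids[:4]] = 3.0
        with pytest.warns(UserWarning, match="skipped"):
            results = stratified_survival_analysis(tiny_cohort, "ID4")
        by_stratum = {r.stratum: r for r in results}
        assert by_stratum["ER+"].skipped_reason is not None

    def test_one_record_per_stratum(self, default_cohort):
        cohort, _ = default_cohort
        results = stratified_survival_analysis(cohort, "ID4")
        assert sorted(r.stratum for r in results) == ["ER+", "ER-"]
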