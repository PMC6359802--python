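"""Contingency, Kaplan-Meier/log-rank and logistic-deviance statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import prolifsig as ps
from prolifsig.outcomes import DEFAULT_TERM_ORDER


class TestDcContingency:
    @pytest.mark.parametrize("a,b,expected_p", [
        ((22, 22), (13, 53), 0.0017),   # moderately vs poorly/highly
        ((12, 15), (4, 25), 0.0250),    # moderately vs highly, TPS < 50%
        ((7, 10), (7, 33), 0.1179),     # cold (<15) moderately vs extremes
    ])
    def test_published_comparisons(self, a, b, expected_p):
        res = ps.dc_contingency({"A": a, "B": b})
        assert round(res.p_value, 4) == expected_p
        assert res.dc_rates[0] == pytest.approx(a[0] / sum(a))

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            ps.dc_contingency({"A": (1, 2)})
        with pytest.raises(ValueError):
            ps.dc_contingency({"A": (0, 0), "B": (3, 4)})


class TestKaplanMeier:
    def test_closed_form_without_censoring(self):
        curve = ps.km_estimate([1.0, 2.0, 3.0, 4.0], [True] * 4)
        # S drops by 1/4 at each event; after the 2nd event S = 0.5
        surv_at = dict(zip(curve.times, curve.survival))
        assert surv_at[2.0] == pytest.approx(0.5)
        assert curve.median == pytest.approx(2.0)
        assert curve.n_events == 4

    def test_no_events_flat_curve(self):
        curve = ps.km_estimate([5.0, 8.0, 9.0], [False] * 3)
        assert (curve.survival == 1.0).all()
        assert np.isinf(curve.median)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, size=300)
        t = t[t < 55]  # keep inside the horizon so no truncation occurs
        curve = ps.km_estimate(t, np.ones(t.size, bool))
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(1.0 - np.mean(t <= time))

    def test_horizon_truncation(self):
        curve = ps.km_estimate([10.0, 70.0, 80.0], [True, True, True])
        assert curve.times.max() <= 60.0
        assert curve.n_events == 1  # the two late deaths become censorings

    def test_median_recovery_from_exponential(self):
        """Product-limit median of Exp(ln2/14.6) at n=10,000 is ~14.6."""
        rng = np.random.default_rng(5)
        t = rng.exponential(14.6 / np.log(2), size=10_000)
        curve = ps.km_estimate(t, np.ones(t.size, bool))
        assert curve.median == pytest.approx(14.6, abs=0.5)

    def test_tidy_frame(self):
        curve = ps.km_estimate([1.0, 2.0, 2.0, 5.0], [True, True, False, True])
        frame = curve.to_frame()
        assert list(frame.columns) == ["time", "at_risk", "survival", "censored"]
        assert (frame.survival.diff().dropna() <= 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ps.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [3.0, 6.0, 9.0, 14.0]
        e = [True, True, False, True]
        stat, p = ps.logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ps.logrank_test([], [], [1.0], [True])

    def test_invariant_under_shared_time_transform(self):
        rng = np.random.default_rng(3)
        t1 = rng.exponential(10, 60)
        t2 = rng.exponential(14, 60)
        e1 = rng.random(60) < 0.7
        e2 = rng.random(60) < 0.7
        stat, p = ps.logrank_test(t1, e1, t2, e2, horizon=np.inf)
        stat2, p2 = ps.logrank_test(np.sqrt(t1), e1, np.sqrt(t2), e2,
                                    horizon=np.inf)
        assert stat == pytest.approx(stat2)
        assert p == pytest.approx(p2)

    def test_separated_groups_reject(self):
        rng = np.random.default_rng(4)
        fast = rng.exponential(4.0, 120)
        slow = rng.exponential(20.0, 120)
        _, p = ps.logrank_test(fast, np.ones(120, bool),
                               slow, np.ones(120, bool))
        assert p < 1e-6


def _grouped_labels(n_a, dc_a, n_b, dc_b):
    data = pd.DataFrame({
        "dc": [1] * dc_a + [0] * (n_a - dc_a) + [1] * dc_b + [0] * (n_b - dc_b),
        "group": [True] * n_a + [False] * n_b,
    })
    return data


class TestLogisticDeviance:
    def test_sequential_deviance_additivity(self, study, ranks, reference):
        eligible = ps.evaluable_for_response(study.clinical)
        strata = ps.assign_strata(ranks, eligible, reference)
        merged = eligible.merge(strata, on="patient_id")
        labels = ps.classify_cohort(eligible)
        data = pd.DataFrame({
            "dc": (labels.reindex(merged.patient_id) == "DC").astype(int).to_numpy(),
            "proliferation": (merged.proliferation == "moderately").to_numpy(),
            "pd_l1": merged.pd_l1.isin(["weak_positive", "strong_positive"]).to_numpy(),
            "histology": merged.histology.to_numpy(),
            "race": merged.race.to_numpy(),
            "sex": merged.sex.to_numpy(),
            "age_category": merged.age_category.to_numpy(),
        })
        fit = ps.fit_dc_logistic(data)
        assert list(fit.deviance_table.term) == list(DEFAULT_TERM_ORDER)
        total = fit.deviance_table.deviance.sum()
        assert total == pytest.approx(fit.null_deviance - fit.residual_deviance,
                                      abs=1e-8)
        assert fit.null_deviance >= fit.residual_deviance - 1e-9
        # each sequential p is the chi-square upper tail at the term's df
        for _, row in fit.deviance_table.iterrows():
            assert row.p_value == pytest.approx(chi2.sf(row.deviance, row.df))

    def test_single_factor_deviance_equals_g_statistic(self):
        """Entered first, a binary factor's deviance is the 2x2 G-statistic."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            n_a, n_b = int(rng.integers(15, 60)), int(rng.integers(15, 60))
            dc_a = int(rng.integers(1, n_a))
            dc_b = int(rng.integers(1, n_b))
            data = _grouped_labels(n_a, dc_a, n_b, dc_b)
            fit = ps.fit_dc_logistic(data, term_order=("group",))
            observed = np.array([[dc_a, n_a - dc_a], [dc_b, n_b - dc_b]], float)
            total = observed.sum()
            expected = np.outer(observed.sum(1), observed.sum(0)) / total
            g_stat = 2.0 * np.sum(observed * np.log(observed / expected),
                                  where=observed > 0)
            assert fit.deviance_table.deviance.iloc[0] == pytest.approx(
                g_stat, rel=1e-8)

    def test_separation_is_flagged(self):
        data = pd.DataFrame({"dc": [1] * 10 + [0] * 10,
                             "group": [True] * 10 + [False] * 10})
        fit = ps.fit_dc_logistic(data, term_order=("group",))
        assert fit.separation_detected

    def test_input_validation(self):
        with pytest.raises(ValueError, match="dc"):
            ps.fit_dc_logistic(pd.DataFrame({"x": [1, 2]}), term_order=("x",))
        data = _grouped_labels(10, 4, 10, 5)
        with pytest.raises(ValueError, match="absent"):
            ps.fit_dc_logistic(data, term_order=("group", "missing_term"))
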