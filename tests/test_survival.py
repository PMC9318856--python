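"""Survival screen: product-limit curve, log-rank, Cox HR, gene screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from datcascade.simulate import SimConfig, generate_survival_cohort, make_truth
from datcascade.survival import (
    cox_hr,
    km_estimator,
    logrank_test,
    median_split,
    screen_genes,
)


class TestMedianSplit:
    def test_even_and_odd_splits_with_tie_to_low(self):
        assert median_split([1, 2, 3, 4]).tolist() == [False, False, True, True]
        assert median_split([1, 2, 3, 5]).tolist() == [False, False, True, True]
        # median value itself goes to the low group
        assert median_split([1, 2, 2, 3]).tolist() == [False, False, False, True]

    def test_constant_expression_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([5, 5, 5, 5])

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            median_split([1, 2, 3])


class TestKaplanMeier:
    def test_no_events_gives_unit_curve(self):
        km = km_estimator([1, 2, 3], [0, 0, 0])
        assert km(0) == 1.0 and km(10) == 1.0

    def test_two_event_worked_example(self):
        km = km_estimator([1, 2], [1, 1])
        assert km(0.5) == 1.0
        assert km(1) == pytest.approx(0.5)
        assert km(1.9) == pytest.approx(0.5)
        assert km(2) == pytest.approx(0.0)

    def test_censoring_after_last_event_leaves_curve_unchanged(self):
        base = km_estimator([1, 2], [1, 1])
        with_censor = km_estimator([1, 2, 5], [1, 1, 0])
        # the added at-risk subject changes early factors, but censoring
        # at t=5 adds no drop beyond t=2
        assert with_censor(4) == with_censor(10)
        assert base(10) == 0.0

    def test_exhaustive_small_case_brute_force_oracle(self):
        """Product-limit equals its definition on every dataset of <= 6
        patients over a grid of event patterns."""
        rng = np.random.default_rng(5)
        for n in (2, 3, 4, 5, 6):
            times = np.round(rng.uniform(1, 10, size=n), 1)
            for pattern in itertools.product([0, 1], repeat=n):
                if sum(pattern) == 0:
                    continue
                km = km_estimator(times, list(pattern))
                for t_query in np.unique(times):
                    s = 1.0
                    for ti in sorted(set(times[np.array(pattern) == 1])):
                        if ti <= t_query:
                            d = sum(
                                1 for tt, ee in zip(times, pattern)
                                if tt == ti and ee == 1
                            )
                            at_risk = sum(1 for tt in times if tt >= ti)
                            s *= 1 - d / at_risk
                    assert km(t_query) == pytest.approx(s)

    def test_matches_lifelines_on_moderate_data(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(6)
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        km = km_estimator(t, e)
        fitter = KaplanMeierFitter().fit(t, e)
        grid = np.quantile(t, [0.1, 0.3, 0.5, 0.7, 0.9])
        ours = km(grid)
        theirs = np.array(
            [fitter.predict(x) for x in grid]
        )
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [True, True, True, False, False, False]
        stat, p = logrank_test(g, t, e)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_worked_example(self):
        # hypergeometric O-E table computed by hand:
        # U = -0.7666..., V = 1.21222..., stat = U^2/V
        g = [True, True, True, False, False, False]
        t = [2.0, 4.0, 6.0, 1.0, 3.0, 5.0]
        e = [1, 1, 0, 1, 1, 1]
        stat, p = logrank_test(g, t, e)
        assert stat == pytest.approx(0.4848762603116407)
        assert p == pytest.approx(0.4862218338852323)

    def test_relabeling_groups_leaves_statistic_invariant(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60).astype(bool)
        if e.sum() == 0:
            e[0] = 1
        assert logrank_test(g, t, e) == pytest.approx(logrank_test(~g, t, e))

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(8)
        t = np.concatenate([rng.exponential(5, 50), rng.exponential(9, 50)])
        e = rng.integers(0, 2, 100)
        g = np.array([True] * 50 + [False] * 50)
        stat, p = logrank_test(g, t, e)
        res = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert stat == pytest.approx(res.test_statistic)
        assert p == pytest.approx(res.p_value)

    def test_no_usable_events_give_p_one(self):
        stat, p = logrank_test([True, False], [1.0, 2.0], [0, 0])
        assert (stat, p) == (0.0, 1.0)


class TestCox:
    def test_identical_groups_give_unit_hazard_ratio(self):
        t = [1.0, 2.0, 3.0, 4.0] * 2
        e = [1, 1, 1, 0] * 2
        g = [True] * 4 + [False] * 4
        hr, _, _ = cox_hr(g, t, e)
        assert hr == pytest.approx(1.0, abs=1e-6)

    def test_swapping_labels_inverts_hazard_ratio(self):
        rng = np.random.default_rng(9)
        g = np.array([True] * 40 + [False] * 40)
        t = np.where(g, rng.exponential(3, 80), rng.exponential(6, 80))
        e = np.ones(80, dtype=int)
        hr, _, _ = cox_hr(g, t, e)
        hr_swapped, _, _ = cox_hr(~g, t, e)
        assert hr_swapped == pytest.approx(1.0 / hr, rel=1e-8)

    def test_consistency_on_two_group_exponential_data(self):
        """At n = 2000 the estimate is within 10% of the true rate ratio."""
        rng = np.random.default_rng(10)
        ratio = 1.78
        g = np.array([True] * 1000 + [False] * 1000)
        t = np.where(g, rng.exponential(1.0 / ratio, 2000), rng.exponential(1.0, 2000))
        e = np.ones(2000, dtype=int)
        hr, (lo, hi), p = cox_hr(g, t, e)
        assert hr == pytest.approx(ratio, rel=0.10)
        assert lo < hr < hi
        assert p < 1e-6

    def test_matches_lifelines_fit(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(11)
        g = np.array([True] * 60 + [False] * 60)
        t = np.where(g, rng.exponential(2, 120), rng.exponential(4, 120))
        e = rng.integers(0, 2, 120)
        e[:5] = 1
        hr, _, _ = cox_hr(g, t, e)
        frame = pd.DataFrame({"t": t, "e": e, "g": g.astype(int)})
        fitter = CoxPHFitter().fit(frame, duration_col="t", event_col="e")
        assert np.log(hr) == pytest.approx(fitter.params_["g"], abs=1e-4)

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="no events"):
            cox_hr([True, False], [1.0, 2.0], [0, 0])


class TestScreen:
    def test_planted_hazard_gene_is_selected(self):
        cfg = SimConfig(seed=13, n_genes=20, n_patients=500,
                        class_counts={"concordant_up": 16},
                        n_offtarget=0, n_specific=0)
        truth = make_truth(cfg)
        truth.loc[truth["gene_id"] == "G000001", "survival_hr"] = 3.0
        cohort = generate_survival_cohort(truth, cfg)
        res = screen_genes(cohort, ["G000001"]).set_index("gene_id")
        assert bool(res.loc["G000001", "selected"])
        assert res.loc["G000001", "hr_os"] > 2.0

    def test_degenerate_expression_is_skipped_not_fatal(self):
        rng = np.random.default_rng(14)
        n = 40
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "flat": 1.0,
                "ok": rng.normal(size=n),
                "os_time": rng.exponential(10, n),
                "os_event": 1,
                "pfs_time": rng.exponential(5, n),
                "pfs_event": 1,
            }
        )
        res = screen_genes(cohort, ["flat", "ok"]).set_index("gene_id")
        assert not res.loc["flat", "selected"]
        assert np.isnan(res.loc["flat", "p_os"])
        assert np.isfinite(res.loc["ok", "p_os"])

    def test_empty_gene_list_gives_empty_result(self):
        cohort = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c", "d"],
                "os_time": [1.0, 2, 3, 4],
                "os_event": [1, 1, 1, 1],
                "pfs_time": [1.0, 2, 3, 4],
                "pfs_event": [1, 1, 0, 1],
            }
        )
        assert screen_genes(cohort, []).empty
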