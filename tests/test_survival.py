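"""Kaplan-Meier, Gehan-Breslow generalized Wilcoxon and Cox PH checks."""

from itertools import combinations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from slegrs.risk_models import SeparationError
from slegrs.scores import ScoreSet, assign_quartiles
from slegrs.survival import (SurvivalInput, analyse_two_group, cox_hr,
                             gehan_wilcoxon, km_estimate, table2_summary)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve, med = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        s = curve.set_index("time")["survival"]
        assert s.loc[2] == pytest.approx(0.5)
        assert med == 2  # smallest time with survival <= 0.5

    def test_all_censored_curve_is_one(self):
        curve, med = km_estimate([3, 5, 7], [0, 0, 0])
        assert (curve["survival"] == 1).all()
        assert med is None

    def test_hand_computed_mixed_example(self):
        # times 1, 2+, 3, 4, 5+, 6 -> product-limit by hand
        curve, med = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        s = curve.set_index("time")["survival"]
        assert s.loc[1] == pytest.approx(5 / 6)
        assert s.loc[3] == pytest.approx(5 / 6 * 3 / 4)
        assert s.loc[4] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert s.loc[6] == pytest.approx(0.0)
        assert med == 4  # first time survival reaches 0.41... <= 0.5


def naive_gehan_statistic(time, event, group):
    """Independent pairwise double-loop Gehan statistic (sum over group 1)."""
    n = len(time)
    w = 0.0
    for i in range(n):
        if not group[i]:
            continue
        for j in range(n):
            # i definitely outlives j
            if event[j] and (time[i] > time[j]
                             or (time[i] == time[j] and not event[i])):
                w += 1
            if event[i] and (time[j] > time[i]
                             or (time[j] == time[i] and not event[j])):
                w -= 1
    return w


class TestGehan:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        e = np.array([1, 1, 0, 1] * 2, bool)
        g = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        res = gehan_wilcoxon(SurvivalInput(g, t, e))
        assert res["statistic"] == 0.0
        assert res["p"] == 1.0

    def test_label_swap_negates_statistic(self):
        rng = np.random.default_rng(21)
        t = rng.exponential(1, 9) + 0.1
        e = rng.random(9) < 0.7
        g = np.zeros(9, bool)
        g[:4] = True
        a = gehan_wilcoxon(SurvivalInput(g, t, e))
        b = gehan_wilcoxon(SurvivalInput(~g, t, e))
        assert a["statistic"] == -b["statistic"]
        assert a["p"] == pytest.approx(b["p"], abs=1e-12)

    def test_exact_mode_matches_exhaustive_permutation(self):
        rng = np.random.default_rng(22)
        for _ in range(5):
            n = 8
            t = np.round(rng.exponential(5, n), 1) + 0.5
            e = np.ones(n, bool)
            g = np.zeros(n, bool)
            g[rng.choice(n, 4, replace=False)] = True
            res = gehan_wilcoxon(SurvivalInput(g, t, e), exact="always")
            w_obs = naive_gehan_statistic(t, e, g)
            assert res["statistic"] == pytest.approx(w_obs, abs=1e-12)
            hits = total = 0
            for idx in combinations(range(n), int(g.sum())):
                lab = np.zeros(n, bool)
                lab[list(idx)] = True
                total += 1
                if abs(naive_gehan_statistic(t, e, lab)) >= abs(w_obs) - 1e-12:
                    hits += 1
            assert res["p_exact"] == pytest.approx(hits / total, abs=1e-12)

    def test_normal_p_close_to_exact_no_censoring(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(3, 8) + 0.2
        e = np.ones(8, bool)
        g = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        res = gehan_wilcoxon(SurvivalInput(g, t, e), exact="always")
        assert abs(res["p"] - res["p_exact"]) < 0.1

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(24)
        t = rng.exponential(2, 30) + 0.1
        e = rng.random(30) < 0.8
        g = rng.random(30) < 0.5
        if g.all() or not g.any():
            g[0] = ~g[0]
        a = gehan_wilcoxon(SurvivalInput(g, t, e))
        b = gehan_wilcoxon(SurvivalInput(g, t + 100.0, e))
        assert a["statistic"] == b["statistic"]
        assert a["p"] == b["p"]

    def test_all_censored_degenerate(self):
        g = np.r_[np.ones(3, bool), np.zeros(3, bool)]
        res = gehan_wilcoxon(SurvivalInput(g, np.ones(6), np.zeros(6, bool)))
        assert res["statistic"] == 0.0 and res["p"] == 1.0
        assert "degenerate" in res["flag"]

    def test_one_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gehan_wilcoxon(SurvivalInput(np.ones(4, bool), np.ones(4),
                                         np.ones(4, bool)))


def hand_partial_likelihood(beta, time, event, group):
    """Breslow log partial likelihood, valid with no tied event times."""
    ll = 0.0
    for i in np.flatnonzero(event):
        at_risk = time >= time[i]
        ll += beta * group[i] - np.log(np.exp(beta * group[at_risk]).sum())
    return ll


class TestCox:
    def test_small_example_matches_brute_force_maximum(self):
        t = np.array([2.0, 3.5, 1.0, 5.0, 4.2])
        e = np.array([1, 1, 1, 0, 1], bool)
        g = np.array([0, 1, 1, 1, 0], bool)
        hr, lo, hi, p = cox_hr(SurvivalInput(g, t, e))
        res = minimize_scalar(
            lambda b: -hand_partial_likelihood(b, t, e, g.astype(float)),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10})
        assert np.log(hr) == pytest.approx(res.x, abs=1e-6)

    def test_recovers_hazard_ratio_two(self):
        rng = np.random.default_rng(25)
        n = 4000
        g = np.zeros(n, bool)
        g[: n // 2] = True
        rate = np.where(g, 2.0, 1.0)
        t = rng.exponential(1 / rate)
        censor = rng.exponential(1 / np.quantile(rate, 0.1) * 2.2, n)
        e = t <= censor
        tt = np.minimum(t, censor) + 1e-9
        assert 0.1 < 1 - e.mean() < 0.35  # roughly 20% censoring
        hr, lo, hi, p = cox_hr(SurvivalInput(g, tt, e))
        assert 1.85 < hr < 2.15

    def test_null_ci_coverage(self):
        rng = np.random.default_rng(26)
        covered = total = 0
        for _ in range(500):
            n = 60
            g = np.zeros(n, bool)
            g[: n // 2] = True
            t = rng.exponential(1.0, n) + 1e-9
            e = rng.random(n) < 0.8
            if not e.any():
                continue
            try:
                hr, lo, hi, p = cox_hr(SurvivalInput(g, t, e))
            except SeparationError:
                continue
            total += 1
            covered += lo <= 1 <= hi
        assert covered / total >= 0.93

    def test_time_shift_leaves_coefficient(self):
        rng = np.random.default_rng(27)
        n = 200
        g = rng.random(n) < 0.5
        t = rng.exponential(np.where(g, 0.5, 1.0)) + 0.01
        e = rng.random(n) < 0.85
        a = cox_hr(SurvivalInput(g, t, e))
        b = cox_hr(SurvivalInput(g, t + 50.0, e))
        assert a[0] == pytest.approx(b[0], rel=1e-6)

    def test_monotone_likelihood_flagged(self):
        # all high-group events strictly first -> diverging coefficient
        t = np.r_[np.arange(1, 11), np.arange(20, 30)].astype(float)
        e = np.ones(20, bool)
        g = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        with pytest.raises(SeparationError):
            cox_hr(SurvivalInput(g, t, e))


class TestTwoGroupSummary:
    def _cohort(self, seed=30, n=2000, effect=0.25):
        from slegrs.simulate import SimConfig, simulate_outcomes
        rng = np.random.default_rng(seed)
        grs = rng.normal(8.5, 1.2, n)
        cfg = SimConfig(seed=seed)
        if effect == 0:
            cfg = cfg.null_effects()
        else:
            cfg.event_log_hr_per_grs_unit = {k: effect for k
                                             in cfg.event_log_hr_per_grs_unit}
            cfg.onset_log_hazard_per_grs_unit = effect
        cohort = simulate_outcomes([f"c{i}" for i in range(n)], grs, cfg)
        scores = assign_quartiles(
            ScoreSet(cohort["individual_id"].tolist(),
                     np.zeros(n, int), grs))
        return cohort, scores

    def test_positive_effect_recovers_direction(self):
        cohort, scores = self._cohort(effect=0.3)
        res = table2_summary(cohort, scores, "first_cve")
        assert res.hr > 1
        assert res.mean_age_at_event_by_group["high"] \
            < res.mean_age_at_event_by_group["low"]

    def test_null_effect_balanced(self):
        cohort, scores = self._cohort(seed=31, effect=0)
        res = table2_summary(cohort, scores, "first_cve")
        diff = (res.mean_age_at_event_by_group["high"]
                - res.mean_age_at_event_by_group["low"])
        assert abs(diff) < 6
        assert res.p_gehan > 0.01

    def test_unknown_event_rejected(self):
        cohort, scores = self._cohort(seed=32, n=200)
        with pytest.raises(ValueError, match="unknown event"):
            table2_summary(cohort, scores, "bogus_event")

    def test_no_affected_flags_undefined_medians(self):
        cohort, scores = self._cohort(seed=33, n=300)
        cohort = cohort.copy()
        cohort["esrd"] = False
        cohort["age_at_esrd"] = np.nan
        res = table2_summary(cohort, scores, "esrd_onset")
        assert res.median_affected_age_by_group["high"] is None
        assert res.mean_age_at_event_by_group["high"] is None
        assert np.isnan(res.hr)

    def test_sle_onset_counts_everyone_affected(self):
        cohort, scores = self._cohort(seed=34, n=400)
        res = table2_summary(cohort, scores, "sle_onset")
        assert res.n_censored == 0
        assert res.n_affected == int(np.isin(scores.quartile, (1, 4)).sum())
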