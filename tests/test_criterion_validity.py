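"""Association machinery against independent oracles and published counts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import healthreserves as hr
from healthreserves.criterion_validity import round_half_up
from healthreserves.datasets import srh_table

#: Published indicator-by-SRH cross-tab: CWP exposed/unexposed x poor/good.
CWP_SRH = hr.ContingencyTable2x2(a=704, b=813, c=1287, d=4239)


class TestCrudeOddsRatio:
    def test_published_cwp_association_rounds_to_2_85(self):
        res = hr.crude_odds_ratio(CWP_SRH)
        assert round(res.point, 2) == 2.85

    def test_balanced_table_gives_unity(self):
        res = hr.crude_odds_ratio(hr.ContingencyTable2x2(10, 10, 10, 10))
        assert res.point == 1.0

    def test_label_swap_inversion(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 200, size=4)
            r1 = hr.crude_odds_ratio(hr.ContingencyTable2x2(a, b, c, d))
            r2 = hr.crude_odds_ratio(hr.ContingencyTable2x2(b, a, d, c))
            assert r1.point * r2.point == pytest.approx(1.0, rel=1e-12)

    def test_woolf_interval_overlaps_bootstrap_oracle(self):
        # nonparametric bootstrap of the log-OR as an independent interval
        table = hr.ContingencyTable2x2(30, 20, 25, 40)
        res = hr.crude_odds_ratio(table, ci_level=0.95)
        rng = np.random.default_rng(11)
        n = table.total
        p = np.array([table.a, table.b, table.c, table.d]) / n
        draws = rng.multinomial(n, p, size=10_000)
        ok = (draws > 0).all(axis=1)
        lors = np.log(draws[ok, 0] * draws[ok, 3] / (draws[ok, 1] * draws[ok, 2]))
        lo_b, hi_b = np.exp(np.percentile(lors, [2.5, 97.5]))
        # same point estimate; overlapping intervals
        assert res.point == pytest.approx((30 * 40) / (20 * 25), rel=1e-12)
        assert res.ci_low < hi_b and lo_b < res.ci_high

    def test_zero_cell_flags_interval_unavailable(self):
        res = hr.crude_odds_ratio(hr.ContingencyTable2x2(0, 5, 5, 5))
        assert res.point == 0.0 and math.isnan(res.ci_low)


class TestSensSpec:
    def test_published_cwp_block(self):
        se, spe = hr.sens_spec(CWP_SRH)
        assert round_half_up(100 * se.point) == 46
        assert round_half_up(100 * spe.point) == 77

    def test_published_al_specificity(self):
        t = srh_table("al_category", ("middle", "high"))
        _, spe = hr.sens_spec(t)
        assert round_half_up(100 * spe.point) == 49

    def test_perfect_classifier(self):
        cond = np.array([True, True, False, False, True])
        se, spe = hr.sens_spec(cond, cond)
        assert se.point == 1.0 and spe.point == 1.0

    def test_sensitivity_of_negation_is_specificity_flipped(self):
        rng = np.random.default_rng(8)
        pred = rng.random(500) < 0.4
        cond = rng.random(500) < 0.3
        se1, _ = hr.sens_spec(pred, cond)
        _, spe2 = hr.sens_spec(~pred, ~cond)
        assert se1.point == pytest.approx(spe2.point, abs=0)

    def test_undefined_rate_flagged(self):
        se, spe = hr.sens_spec([True, False], [False, False])
        assert math.isnan(se.point) and not math.isnan(spe.point)


def km_oracle(times, events, t):
    """Brute-force product-limit: product over risk sets at event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    s = 1.0
    for ti in sorted(set(times[events])):
        if ti > t:
            break
        n_at_risk = (times >= ti).sum()
        d = ((times == ti) & events).sum()
        s *= 1 - d / n_at_risk
    return s


class TestKaplanMeier:
    def test_four_subjects_two_deaths(self):
        km = hr.kaplan_meier([1, 2, 3, 4], [True, True, False, False])
        assert km.survival_at(1.5) == pytest.approx(0.75)

    def test_no_events_survival_is_one(self):
        km = hr.kaplan_meier([3.0, 5.0, 14.0], [False] * 3)
        for t in (0.0, 5.0, 14.0):
            assert km.survival_at(t) == 1.0

    def test_matches_product_limit_oracle_under_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, size=20).round(1)
        events = rng.random(20) < 0.6
        km = hr.kaplan_meier(times, events)
        for t in (0.5, 2.0, 5.0, 10.0):
            assert km.survival_at(t) == pytest.approx(km_oracle(times, events, t))

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(3, size=50)
        km = hr.kaplan_meier(times, [True] * 50)
        for t in (0.5, 1.0, 4.0):
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_greenwood_interval_brackets_estimate(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=100).clip(max=14)
        events = times < 14
        km = hr.kaplan_meier(times, events)
        lo, hi = km.ci_at(10.0)
        assert lo <= km.survival_at(10.0) <= hi


def logrank_oracle(times, events, groups):
    """Hand-summed observed-minus-expected two-group logrank chi-square."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    g1 = groups == np.unique(groups)[0]
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & g1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_six_subject_worked_example_matches_hand_computation(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, True, False, True, True, False]
        groups = ["a", "b", "a", "b", "a", "b"]
        res = hr.logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(
            logrank_oracle(times, events, groups), rel=1e-9
        )
        assert res.df == 1

    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4] * 2
        events = [True, False, True, False] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = hr.logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_three_groups_two_df(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(5, 30)
        res = hr.logrank_test(times, [True] * 30, np.repeat(["a", "b", "c"], 10))
        assert res.df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            hr.logrank_test([1, 2], [True, True], ["a", "a"])


class TestLogistic:
    def test_single_binary_exposure_equals_crude_or(self):
        rng = np.random.default_rng(12)
        exposed = rng.random(400) < 0.4
        case = rng.random(400) < (0.2 + 0.2 * exposed)
        table = hr.ContingencyTable2x2.from_booleans(exposed, case)
        crude = hr.crude_odds_ratio(table)
        fit = hr.fit_logistic(pd.Series(case), pd.Series(exposed, name="x"))
        assert fit[0].point == pytest.approx(crude.point, rel=1e-6)

    def test_three_level_exposure_referenced_to_declared_baseline(self):
        rng = np.random.default_rng(13)
        lvl = pd.Series(rng.choice(["a", "b", "c"], 600), name="g")
        y = pd.Series(rng.random(600) < 0.3)
        res = hr.fit_logistic(y, lvl, reference="b")
        assert {r.level for r in res} == {"a", "c"}
        assert all(r.reference == "b" for r in res)

    def test_known_effect_recovered(self):
        # logistic outcome with unit log-OR on a standard-normal exposure
        rng = np.random.default_rng(14)
        x = rng.standard_normal(20_000)
        y = rng.random(20_000) < 1 / (1 + np.exp(-(-1.5 + 1.0 * x)))
        res = hr.fit_logistic(pd.Series(y), pd.Series(x, name="x"))
        assert math.log(res[0].point) == pytest.approx(1.0, abs=0.1)

    def test_perfect_separation_raises(self):
        y = pd.Series([False] * 10 + [True] * 10)
        x = pd.Series([0.0] * 10 + [1.0] * 10, name="x")
        with pytest.raises(hr.SeparationError):
            hr.fit_logistic(y, x)


def cox_grid_oracle(times, events, x, grid=np.linspace(-4, 4, 8001)):
    """Dense grid search of the (tie-free) Cox partial log-likelihood."""
    order = np.argsort(times)
    times, events, x = np.asarray(times)[order], np.asarray(events)[order], np.asarray(x)[order]
    best, best_ll = None, -np.inf
    for b in grid:
        ll = 0.0
        for i in range(len(times)):
            if events[i]:
                risk = times >= times[i]
                ll += b * x[i] - np.log(np.exp(b * x[risk]).sum())
        if ll > best_ll:
            best, best_ll = b, ll
    return best


class TestCox:
    def test_five_subject_coefficient_matches_grid_search(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [True, True, True, False, True]
        x = pd.Series([1.0, 0.0, 1.0, 0.0, 0.0], name="x")
        res, _ = hr.fit_cox(times, events, x, reference=0.0)
        oracle = cox_grid_oracle(times, events, x)
        assert math.log(res[0].point) == pytest.approx(oracle, abs=1e-3)

    def test_known_hazard_ratio_recovered(self):
        # two groups, exponential times, true HR 2, administrative censoring
        rng = np.random.default_rng(15)
        n = 20_000
        g = rng.random(n) < 0.5
        t = rng.exponential(1 / (0.02 * np.where(g, 2.0, 1.0)))
        obs = np.minimum(t, 14.0)
        ev = t <= 14.0
        res, _ = hr.fit_cox(obs, ev, pd.Series(g, name="g"))
        assert math.log(res[0].point) == pytest.approx(math.log(2.0), abs=0.15)

    def test_null_exposure_hr_near_one_and_uniform_schoenfeld(self):
        rng = np.random.default_rng(16)
        pvals, lhrs = [], []
        for _ in range(60):
            n = 300
            x = pd.Series(rng.standard_normal(n), name="x")
            t = rng.exponential(10, n)
            obs, ev = np.minimum(t, 14.0), t <= 14.0
            res, diag = hr.fit_cox(obs, ev, x)
            lhrs.append(math.log(res[0].point))
            pvals.append(float(diag.ph_test["p"].iloc[0]))
        assert abs(np.mean(lhrs)) < 0.05
        # Schoenfeld p-values approximately uniform under proportional hazards
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_level_without_events_raises(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [True, True, False, False]
        g = pd.Series(["a", "a", "b", "b"], name="g")
        with pytest.raises(hr.SeparationError, match="no events"):
            hr.fit_cox(times, events, g)


class TestValidityReport:
    def test_report_structure_and_monotone_gradient(self, analysis_table):
        rep = hr.validity_report(analysis_table)
        est = rep.adjusted_estimates
        assert set(est["type"]) == {"OR", "HR"}
        assert (est["ci_level"] == 0.99).all()
        assert (est["adjustment"] == "sex").all()
        # positive latent effects: impaired OR > medium OR > 1 for poor SRH
        ors = est[(est["exposure"] == "category") & (est["type"] == "OR")]
        med = float(ors.loc[ors["level"] == "medium", "point"].iloc[0])
        imp = float(ors.loc[ors["level"] == "impaired", "point"].iloc[0])
        assert imp > med > 1.0
        # Se/Spe block covers all four measures against both outcomes
        assert len(rep.sens_spec) == 8
        assert rep.bivariate_mortality["logrank_p"].notna().all()

    def test_published_crosstab_sens_spec_block(self):
        # reconstruct individuals from the published indicator x SRH margins
        rows = []
        from healthreserves.datasets import SRH_CROSSTAB_COUNTS

        for lvl, (poor, good) in SRH_CROSSTAB_COUNTS["cwp"].items():
            rows += [(lvl == "yes", True)] * poor + [(lvl == "yes", False)] * good
        pred, cond = zip(*rows)
        se, spe = hr.sens_spec(list(pred), list(cond))
        assert round_half_up(100 * se.point) == 46
        assert round_half_up(100 * spe.point) == 77
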