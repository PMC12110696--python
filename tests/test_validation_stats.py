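"""Validation statistics: Deming, concordance, precision, agreement, LLOQ."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from flowmrd import synthcyto as sc
from flowmrd import validation_stats as vs


class TestDeming:
    def test_identity_line(self):
        fit = vs.deming_fit([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r == pytest.approx(1.0)

    def test_axis_swap_inverts_slope(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 3, 15)
        y = 0.8 * x + 0.1 + rng.normal(0, 0.1, 15)
        a = vs.deming_fit(x, y)
        b = vs.deming_fit(y, x)
        assert a.slope == pytest.approx(1 / b.slope, abs=1e-10)

    @pytest.mark.parametrize("lam", [1.0, 0.5, 3.0])
    def test_matches_perpendicular_distance_minimizer(self, lam):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, 20) + rng.normal(0, 0.2, 20)
        y = 0.9 * x + 0.2 + rng.normal(0, 0.2, 20)
        fit = vs.deming_fit(x, y, lam)

        def objective(p):
            a, b = p
            return np.sum((y - a - b * x) ** 2 / (lam + b**2))

        res = minimize(objective, [0.0, 1.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 50_000})
        assert fit.slope == pytest.approx(res.x[1], abs=1e-6)
        assert fit.intercept == pytest.approx(res.x[0], abs=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 2, 12)
        y = x + rng.normal(0, 0.05, 12)
        base = vs.deming_fit(x, y)
        scaled = vs.deming_fit(10 * x, 10 * y)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-10)
        assert scaled.intercept == pytest.approx(10 * base.intercept,
                                                 rel=1e-8)

    def test_large_lambda_reduces_to_ols(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 4, 25)
        y = 1.2 * x - 0.3 + rng.normal(0, 0.2, 25)
        fit = vs.deming_fit(x, y, lam=1e8)
        ols = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ols.slope, rel=1e-6)
        assert fit.intercept == pytest.approx(ols.intercept, abs=1e-5)

    def test_degenerate_covariance_rejected(self):
        with pytest.raises(ValueError, match="covariance"):
            vs.deming_fit([1, 2, 3], [5, 5, 5])


class TestCompareDeming:
    def test_identical_fits_p_one(self):
        fit = vs.deming_fit([0, 1, 2, 3], [0.1, 1.0, 2.1, 2.9])
        out = vs.compare_deming(fit, fit)
        assert out["p_slope"] == pytest.approx(1.0)
        assert out["p_intercept"] == pytest.approx(1.0)

    def test_ten_pooled_se_separation(self):
        a = vs.DemingFit(slope=1.0, intercept=0.0, r=1, se_slope=0.01,
                         se_intercept=0.01, n=20, lam=1)
        b = vs.DemingFit(slope=1.0 + 10 * math.hypot(0.01, 0.01),
                         intercept=0.0, r=1, se_slope=0.01,
                         se_intercept=0.01, n=20, lam=1)
        assert vs.compare_deming(a, b)["p_slope"] < 1e-10

    def test_null_p_values_uniform(self):
        # two groups simulated from one generating line: slope p-values
        # should be uniform (KS at alpha = 0.01 over 200 replicates)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            def group():
                x0 = rng.uniform(0, 5, 50)
                return (x0 + rng.normal(0, 0.3, 50),
                        x0 + rng.normal(0, 0.3, 50))
            xa, ya = group()
            xb, yb = group()
            ps.append(vs.compare_deming(vs.deming_fit(xa, ya),
                                        vs.deming_fit(xb, yb))["p_slope"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBinaryConcordance:
    def test_printed_method_comparison_counts(self):
        m = vs.binary_concordance(vs.ConfusionCounts(tp=129, fp=6, fn=0,
                                                     tn=105))
        assert round(m["accuracy"].percent, 1) == 97.5
        assert round(m["sensitivity"].percent, 1) == 100.0
        assert round(m["specificity"].percent, 1) == 94.6
        assert round(m["ppv"].percent, 1) == 95.6
        assert round(m["npv"].percent, 1) == 100.0

    def test_empty_table_all_absent(self):
        m = vs.binary_concordance(vs.ConfusionCounts(0, 0, 0, 0))
        assert all(v is None for v in m.values())

    def test_one_of_two_clopper_pearson_closed_form(self):
        m = vs.binary_concordance(vs.ConfusionCounts(1, 1, 1, 1))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert m[name].value == pytest.approx(0.5)
        # closed form for a 1-of-2 proportion: lower = 1 - (1-a/2)^(1/2)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert m[name].ci_low == pytest.approx(1 - math.sqrt(0.975),
                                                   abs=1e-10)
            assert m[name].ci_high == pytest.approx(math.sqrt(0.975),
                                                    abs=1e-10)
            assert round(100 * m[name].ci_low, 2) == 1.26
            assert round(100 * m[name].ci_high, 2) == 98.74

    def test_intervals_bracket_estimate(self):
        m = vs.binary_concordance(vs.ConfusionCounts(40, 3, 2, 55))
        for met in m.values():
            assert met.ci_low <= met.value <= met.ci_high


class TestNoninferiority:
    def test_printed_study_passes(self):
        out = vs.noninferiority_accuracy_test(234, 240)
        assert out["pass"]

    def test_perfect_accuracy(self):
        out = vs.noninferiority_accuracy_test(240, 240)
        assert out["pass"] and out["p_value"] == pytest.approx(1.0)

    def test_low_accuracy_fails_with_exact_tail(self):
        out = vs.noninferiority_accuracy_test(200, 240)
        assert not out["pass"]
        exact = sum(math.comb(240, k) * 0.975**k * 0.025 ** (240 - k)
                    for k in range(0, 201))
        assert out["p_value"] == pytest.approx(exact, rel=1e-9)


class TestSampleSize:
    def test_no_constraint_limits(self):
        assert vs.sample_size_quantitative(slope_tol=1e6)["n"] == 3
        assert vs.sample_size_quantitative(r_expected=0.999999)["n"] == 3

    def test_monotone_in_tolerance_and_correlation(self):
        loose = vs.sample_size_quantitative(slope_tol=0.1)["n"]
        tight = vs.sample_size_quantitative(slope_tol=0.05)["n"]
        assert tight > loose
        low_r = vs.sample_size_quantitative(r_expected=0.90)["n"]
        high_r = vs.sample_size_quantitative(r_expected=0.95)["n"]
        assert low_r > high_r

    def test_power_at_computed_n(self):
        # simulation cross-check: at the computed n, detecting a slope
        # deviation of slope_tol has the planned ~80% power. The analytic
        # power at n must clear 80%, and empirical power (jackknife-SE
        # test) must agree with it within simulation noise.
        out = vs.sample_size_quantitative(r_expected=0.95, slope_tol=0.05)
        n = out["n"]
        se_asym = math.sqrt((1 / 0.95**2 - 1) / (n - 2))
        power_theory = stats.norm.cdf(0.05 / se_asym - stats.norm.ppf(0.95))
        assert power_theory >= 0.80
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 400
        for _ in range(reps):
            # correlation ~0.95 between methods, true slope 1 + slope_tol
            x0 = rng.uniform(0, 4, n)
            sd = np.std(x0) * math.sqrt(1 / 0.95**2 - 1) / math.sqrt(2)
            x = x0 + rng.normal(0, sd, n)
            y = 1.05 * x0 + rng.normal(0, sd, n)
            fit = vs.deming_fit(x, y)
            if abs(fit.slope - 1) / fit.se_slope > stats.norm.ppf(0.95):
                rejections += 1
        assert rejections / reps == pytest.approx(power_theory, abs=0.06)


class TestPrecision:
    @staticmethod
    def _frame(values):
        rows = []
        for (op, inst), cell in values.items():
            for i, v in enumerate(cell):
                rows.append({"operator": op, "instrument": inst,
                             "replicate": i + 1, "value": v})
        import pandas as pd
        return pd.DataFrame(rows)

    def test_identical_values_zero_sds(self):
        cells = {(o, i): [0.5, 0.5, 0.5]
                 for o in ("op1", "op2") for i in ("i1", "i2")}
        res = vs.precision_components(self._frame(cells))
        assert res.sd_repeatability == 0.0
        assert res.sd_within_lab == 0.0

    def test_within_lab_at_least_repeatability(self):
        rng = np.random.default_rng(5)
        cells = {(o, i): list(0.5 + rng.normal(0, 0.05, 3))
                 for o in ("op1", "op2") for i in ("i1", "i2")}
        res = vs.precision_components(self._frame(cells))
        assert res.sd_within_lab >= res.sd_repeatability - 1e-12
        assert res.cv_repeatability == pytest.approx(
            100 * res.sd_repeatability / res.mean)

    def test_parameter_recovery_simulation(self):
        # 2 operators x 2 instruments x 3 replicates, known components:
        # mean estimated variances within 15% of truth over 2,000 designs
        s_rep, s_b = 0.02, 0.03
        rng = np.random.default_rng(6)
        n_sim = 2_000
        cell_eff = rng.normal(0, s_b, (n_sim, 4, 1))
        vals = 0.5 + cell_eff + rng.normal(0, s_rep, (n_sim, 4, 3))
        reps_rep, reps_wl = [], []
        import pandas as pd
        ops = np.repeat(["op1", "op1", "op2", "op2"], 3)
        insts = np.repeat(["i1", "i2", "i1", "i2"], 3)
        for k in range(n_sim):
            df = pd.DataFrame({"operator": ops, "instrument": insts,
                               "value": vals[k].ravel()})
            res = vs.precision_components(df)
            reps_rep.append(res.sd_repeatability**2)
            reps_wl.append(res.sd_within_lab**2)
        assert np.mean(reps_rep) == pytest.approx(s_rep**2, rel=0.15)
        assert np.mean(reps_wl) == pytest.approx(s_rep**2 + s_b**2, rel=0.15)

    def test_verification_flags_for_reported_bone_marrow_sample(self):
        # a repeatability SD just above its limit fails while the
        # within-laboratory SD below its limit passes
        assert not (0.06798 <= 0.06636)
        assert 0.07097 <= 0.16432
        res = vs.PrecisionResult(
            mean=0.75262, sd_repeatability=0.06798, sd_within_lab=0.07097,
            cv_repeatability=9.0, cv_within_lab=9.4,
            df_repeatability=8, df_within_lab=11,
            uvl_repeatability=0.06636, uvl_within_lab=0.16432,
            pass_repeatability=0.06798 <= 0.06636,
            pass_within_lab=0.07097 <= 0.16432)
        assert res.pass_repeatability is False
        assert res.pass_within_lab is True

    def test_unbalanced_design_rejected(self):
        cells = {("op1", "i1"): [1, 2, 3], ("op1", "i2"): [1, 2]}
        with pytest.raises(ValueError, match="unbalanced"):
            vs.precision_components(self._frame(cells))


class TestVerificationLimit:
    def test_chi_square_oracle(self):
        expect = 0.05 * math.sqrt(stats.chi2.ppf(0.95, 10) / 10)
        assert vs.verification_limit(0.05, 10) == pytest.approx(expect)
        assert stats.chi2.ppf(0.95, 10) == pytest.approx(18.307, abs=5e-4)

    def test_limits(self):
        assert vs.verification_limit(0.05, 10_000) == pytest.approx(
            0.05, rel=0.03)
        dfs = [2, 5, 10, 50, 200]
        uvls = [vs.verification_limit(1.0, d) for d in dfs]
        assert all(a > b for a, b in zip(uvls, uvls[1:]))


class TestAgreement:
    def test_perfect_agreement(self):
        t = sc.simulate_rater_calls([True, False], [(1, 1)] * 3,
                                    replicates=3, seed=0)
        _, by_class = vs.accordance_concordance(t)
        for s in by_class.values():
            assert s.accordance == 1 and s.concordance == 1 and s.cor == 1

    def test_two_rater_hand_example(self):
        # rater1 = (+, +), rater2 = (+, -): ACC = (1 + 0)/2 = 0.5
        calls = np.array([[[True, True], [True, False]]])
        t = sc.RaterTable(calls=calls, truth=np.array([True]))
        per_sample, _ = vs.accordance_concordance(t)
        assert per_sample.accordance.iloc[0] == pytest.approx(0.5)
        # CON by exhaustive cross-rater pair enumeration:
        # pairs (r1a,r2a),(r1a,r2b),(r1b,r2a),(r1b,r2b) agree 2/4
        assert per_sample.concordance.iloc[0] == pytest.approx(0.5)
        assert per_sample.cor.iloc[0] == 1.0

    def test_equal_acc_and_con_give_unit_odds_ratio(self):
        assert vs._odds_ratio(0.9875, 0.9875) == 1.0
        assert vs._odds_ratio(1.0, 1.0) == 1.0

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            m, n_r = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            calls = rng.random((1, m, n_r)) < 0.5
            t = sc.RaterTable(calls=calls, truth=np.array([True]))
            per_sample, _ = vs.accordance_concordance(t)
            c = calls[0]
            within = [c[a, k] == c[b, k]
                      for k in range(n_r)
                      for a, b in itertools.combinations(range(m), 2)]
            between = [c[a, i] == c[b, j]
                       for i, j in itertools.combinations(range(n_r), 2)
                       for a in range(m) for b in range(m)]
            assert per_sample.accordance.iloc[0] == pytest.approx(
                np.mean(within))
            assert per_sample.concordance.iloc[0] == pytest.approx(
                np.mean(between))


class TestEqualRates:
    def test_identical_raters_p_one(self):
        t = sc.simulate_rater_calls([True] * 6 + [False] * 4,
                                    [(1, 1)] * 4, replicates=4, seed=0)
        out = vs.equal_rates_test(t)
        for res in out.values():
            assert res["p_value"] == pytest.approx(1.0)

    def test_extreme_heterogeneity(self):
        # one rater always wrong on 40 positive samples, three always right
        calls = np.ones((40, 1, 4), dtype=bool)
        calls[:, :, 0] = False
        t = sc.RaterTable(calls=calls, truth=np.ones(40, dtype=bool))
        out = vs.equal_rates_test(t)
        assert out["sensitivity"]["p_value"] < 1e-6

    def test_monte_carlo_matches_exhaustive_permutation(self):
        # small table: MC p within 0.02 of the exact permutation null
        # (multivariate hypergeometric over per-rater correct counts)
        calls = np.array([[[True, True, False]],
                          [[True, False, False]],
                          [[True, True, True]],
                          [[False, True, False]],
                          [[True, True, False]],
                          [[True, False, True]],
                          [[True, True, True]],
                          [[True, True, False]]])
        t = sc.RaterTable(calls=calls, truth=np.ones(8, dtype=bool))
        out = vs.equal_rates_test(t, n_mc=20_000, seed=1)
        res = out["sensitivity"]
        assert res["method"] == "monte-carlo"

        correct = np.array(res["correct"])
        totals = np.array(res["totals"], dtype=int)
        X = int(correct.sum())
        obs = vs._chi2_stat(correct, totals.astype(float))
        num = den = 0.0
        for x1 in range(totals[0] + 1):
            for x2 in range(totals[1] + 1):
                x3 = X - x1 - x2
                if not 0 <= x3 <= totals[2]:
                    continue
                w = (math.comb(totals[0], x1) * math.comb(totals[1], x2)
                     * math.comb(totals[2], x3))
                den += w
                stat = vs._chi2_stat(np.array([x1, x2, x3], dtype=float),
                                     totals.astype(float))
                if stat >= obs - 1e-12:
                    num += w
        assert res["p_value"] == pytest.approx(num / den, abs=0.02)

    def test_single_rater_rejected(self):
        t = sc.simulate_rater_calls([True, False], [(1, 1)],
                                    replicates=2, seed=0)
        with pytest.raises(ValueError):
            vs.equal_rates_test(t)


class TestLLOQ:
    def test_identical_triplicate(self):
        out = vs.lloq_cv([0.002, 0.002, 0.002])
        assert out["cv"] == 0.0 and out["pass"]

    def test_hand_computed_cv(self):
        vals = [0.002, 0.002, 0.0035]
        mean = sum(vals) / 3
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 2)
        out = vs.lloq_cv(vals)
        assert out["cv"] == pytest.approx(100 * sd / mean)

    def test_boundary_is_a_failure(self):
        # CV exactly at the threshold fails the strict < 30% criterion
        out = vs.lloq_cv([1.0, 1.0, 1.0], threshold=0.0)
        assert out["cv"] == 0.0 and not out["pass"]

    def test_mean_zero_rejected(self):
        with pytest.raises(ValueError):
            vs.lloq_cv([0.0, 0.0, 0.0])
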