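"""Survival engine: KM closed forms, log-rank symmetry and calibration,
Cox against a brute-force Efron partial likelihood, cutpoint vs brute force."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from m6ascore import cox_univariate, km_fit, logrank_test, max_sel_cutpoint
from m6ascore.survival import _logrank_z, prognostic_filter


def efron_neg_loglik(beta, time, event, x):
    """Independent Efron partial log-likelihood, written from the definition.

    For each distinct event time with tied deaths D (|D| = d), the
    contribution is sum_{i in D} beta*x_i - sum_{l=0}^{d-1} log(
    sum_{j in R} e^{beta*x_j} - (l/d) * sum_{i in D} e^{beta*x_i}).
    """
    time, event, x = map(np.asarray, (time, event, x))
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = time >= t
        d = D.sum()
        theta = np.exp(beta * x)
        sum_R = theta[R].sum()
        sum_D = theta[D].sum()
        ll += beta * x[D].sum()
        for l in range(d):
            ll -= np.log(sum_R - (l / d) * sum_D)
    return -ll


class TestKM:
    def test_product_limit_by_hand(self):
        curves = km_fit([1, 2, 3], [1, 1, 1])
        c = curves["all"]
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(c.times, [1, 2, 3])
        assert (np.diff(c.at_risk) < 0).all()

    def test_all_censored_survival_stays_one(self):
        c = km_fit([5, 6, 7], [0, 0, 0])["all"]
        assert len(c.times) == 0
        assert c.survival_at(10) == 1.0

    def test_single_subject_steps_to_zero(self):
        c = km_fit([4.0], [1])["all"]
        assert c.survival_at(3.9) == 1.0 and c.survival_at(4.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 40).round(2)
        c = km_fit(t, np.ones(40, dtype=int))["all"]
        for q in (0.25, 0.5, 0.75):
            tq = np.quantile(t, q)
            assert c.survival_at(tq) == pytest.approx((t > tq).mean())


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = ["a"] * 4 + ["b"] * 4
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], ["a", "b"])

    def test_three_group_power(self, rng):
        hits = 0
        for rep in range(20):
            n = 100
            rates = np.repeat([0.02 * 2.0, 0.02, 0.02 * 0.5], n)
            t = rng.exponential(1 / rates)
            c = rng.uniform(0, 120, 3 * n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            g = np.repeat(["A", "B", "C"], n)
            _, df, p = logrank_test(time, event, g)
            assert df == 2
            hits += p < 0.001
        assert hits >= 19  # >= 95% of reps

    def test_type_one_error_calibrated(self, rng):
        rej = 0
        reps = 200
        for _ in range(reps):
            t = rng.exponential(50, 200)
            c = rng.uniform(0, 120, 200)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            g = np.repeat(["a", "b"], 100)
            _, _, p = logrank_test(time, event, g)
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.08


class TestCox:
    def test_constant_covariate_gives_null_fit(self):
        fit = cox_univariate([1, 2, 3, 4], [1, 1, 0, 1], [0, 0, 0, 0])
        assert fit.beta == 0.0 and fit.hr == 1.0

    def test_brute_force_efron_oracle_small_n(self, rng):
        """lifelines' Efron beta equals the argmax of an independently
        written Efron partial likelihood on tiny datasets with ties."""
        for trial in range(5):
            n = 6
            x = rng.normal(size=n)
            time = rng.integers(1, 4, size=n).astype(float)  # forces ties
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0:
                event[0] = 1
            fit = cox_univariate(time, event, x)
            brute = minimize_scalar(
                efron_neg_loglik, args=(time, event, x), bounds=(-10, 10), method="bounded",
                options={"xatol": 1e-10},
            )
            if not fit.converged or abs(brute.x) > 5:
                continue  # monotone likelihood: no interior maximum to compare
            assert fit.beta == pytest.approx(brute.x, abs=1e-4)

    def test_duplicated_subjects_tie_handling_matches_oracle(self, rng):
        """Duplicating every subject creates heavy ties; the fit must still
        equal the brute-force Efron likelihood maximum, and the estimate stays
        close to the untied one (Efron's correction is approximate, not exact,
        under duplication)."""
        n = 40
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x) * 20)
        c = rng.uniform(0, 60, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        f1 = cox_univariate(time, event, x)
        td, ed, xd = np.tile(time, 2), np.tile(event, 2), np.tile(x, 2)
        f2 = cox_univariate(td, ed, xd)
        brute = minimize_scalar(
            efron_neg_loglik, args=(td, ed, xd), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12},
        )
        assert f2.beta == pytest.approx(brute.x, abs=1e-5)
        assert f2.beta == pytest.approx(f1.beta, rel=0.02)

    def test_log_hr_recovery(self, rng):
        covered = 0
        reps = 40
        for _ in range(reps):
            n = 500
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.7 * x) * 50)
            c = rng.uniform(0, 200, n)
            fit = cox_univariate(np.minimum(t, c), (t <= c).astype(int), x)
            covered += abs(fit.beta - 0.7) <= 3 * fit.se
        assert covered / reps >= 0.95

    def test_affine_invariances(self, rng):
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x) * 10)
        e = np.ones(n, dtype=int)
        base = cox_univariate(t, e, x)
        rescaled_time = cox_univariate(t * 7.3, e, x)
        assert rescaled_time.beta == pytest.approx(base.beta, rel=1e-6)
        shifted = cox_univariate(t, e, x + 100)
        assert shifted.beta == pytest.approx(base.beta, rel=1e-4)
        scaled = cox_univariate(t, e, x * 2)
        assert scaled.beta == pytest.approx(base.beta / 2, rel=1e-4)
        assert scaled.se == pytest.approx(base.se / 2, rel=1e-4)


class TestCutpoint:
    @staticmethod
    def brute_force_cutpoint(time, event, score, minprop):
        """Independent exhaustive scan over all admissible midpoints."""
        distinct = np.unique(score)
        n = len(score)
        min_n = int(np.ceil(minprop * n))
        best = None
        for c in (distinct[:-1] + distinct[1:]) / 2:
            high = score > c
            if high.sum() < min_n or (~high).sum() < min_n:
                continue
            z = abs(_logrank_z(np.asarray(time, float), np.asarray(event), high.astype(int)))
            if best is None or z > best[1] + 1e-12:
                best = (c, z)
        return best

    def test_equals_brute_force_random_instances(self, rng):
        for trial in range(20):
            n = int(rng.integers(20, 51))
            score = rng.normal(size=n).round(2)
            if len(np.unique(score)) < 2:
                continue
            t = rng.exponential(20, n)
            c = rng.uniform(0, 60, n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            if event.sum() == 0:
                event[0] = 1
            try:
                res = max_sel_cutpoint(time, event, score, minprop=0.1)
            except ValueError:
                assert self.brute_force_cutpoint(time, event, score, 0.1) is None
                continue
            cut, stat = self.brute_force_cutpoint(time, event, score, 0.1)
            assert res.cutpoint == pytest.approx(cut)
            assert res.statistic == pytest.approx(stat, abs=1e-10)

    def test_recovers_median_split_under_true_hazard_jump(self, rng):
        n = 300
        score = rng.normal(size=n)
        med = np.median(score)
        rates = np.where(score > med, 0.01, 0.02)
        t = rng.exponential(1 / rates)
        c = rng.uniform(0, 120, n)
        res = max_sel_cutpoint(np.minimum(t, c), (t <= c).astype(int), score)
        grid = np.sort(np.unique(score))
        pos_med = np.searchsorted(grid, med)
        pos_cut = np.searchsorted(grid, res.cutpoint)
        assert abs(pos_cut - pos_med) <= 15  # within 5% of n around the median

    def test_constant_score_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            max_sel_cutpoint([1, 2, 3], [1, 1, 1], [5.0, 5.0, 5.0])

    def test_minprop_respected(self, rng):
        n = 50
        score = np.arange(n, dtype=float)
        t = rng.exponential(10, n)
        res = max_sel_cutpoint(t, np.ones(n, dtype=int), score, minprop=0.2)
        assert res.n_low >= 10 and res.n_high >= 10


class TestPrognosticFilter:
    def test_flags_hazard_linked_genes(self, rng):
        n = 200
        x_risk = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x_risk) * 30)
        c = rng.uniform(0, 120, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        mat = pd.DataFrame(
            {f"s{i}": [x_risk[i], rng.normal()] for i in range(n)},
            index=["RISKY", "NULLG"],
        )
        out = prognostic_filter(mat, time, event)
        assert bool(out.loc["RISKY", "selected"])
        assert out.loc["RISKY", "HR"] > 1  # higher expression, shorter survival
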