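import shutil
import subprocess
import textwrap
from itertools import combinations

import numpy as np
import pytest
from scipy import optimize, stats

from sriloc.competing_risks import (
    CompetingRisksError,
    cumulative_incidence,
    fine_gray_fit,
    gray_statistic,
    gray_test,
    kaplan_meier,
    logrank_test,
    subdistribution_cif,
)
from sriloc.synthetic_cohort import SimulationConfig, simulate_latent_events


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_hand_product_limit_with_censoring(self):
        km = kaplan_meier([1, 2, 3], [1, 0, 1])
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_all_censored_is_identity(self):
        km = kaplan_meier([5, 8, 13], [0, 0, 0])
        assert km.at(100) == 1.0


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_against_table_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 15, 30).astype(float)
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        # brute-force 2x2 tables at each distinct event time
        O = E = V = 0.0
        for u in sorted(set(t[e == 1])):
            n_j = np.sum(t >= u)
            n_0 = np.sum((t >= u) & (g == 0))
            d_j = np.sum((t == u) & (e == 1))
            d_0 = np.sum((t == u) & (e == 1) & (g == 0))
            O += d_0
            E += d_j * n_0 / n_j
            if n_j > 1:
                V += d_j * (n_0 / n_j) * (1 - n_0 / n_j) * (n_j - d_j) / (n_j - 1)
        expected = (O - E) ** 2 / V
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(CompetingRisksError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_invariance_under_monotone_time_transform(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40) + 0.1
        e = rng.integers(0, 2, 40)
        g = rng.integers(0, 2, 40)
        chi2_a, _, _ = logrank_test(t, e, g)
        chi2_b, _, _ = logrank_test(t**2, e, g)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)


class TestAalenJohansen:
    def test_hand_example(self):
        est = cumulative_incidence([1, 2, 3, 4], [1, 2, 1, 0])
        assert est.at(1, 1) == pytest.approx(0.25)
        assert est.at(3, 1) == pytest.approx(0.50)
        assert est.at(2, 2) == pytest.approx(0.25)

    def test_reduces_to_one_minus_km_without_competing_events(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(100, 80) + 1
        c = rng.choice([0, 1], 80)
        est = cumulative_incidence(t, c)
        km = kaplan_meier(t, c)
        assert np.allclose(est.cif1, 1.0 - np.asarray(km.at(est.times)), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(50, 150) + 0.5
        c = rng.choice([0, 1, 2], 150, p=[0.3, 0.4, 0.3])
        est = cumulative_incidence(t, c)
        assert np.max(np.abs(est.cif1 + est.cif2 + est.overall_survival - 1.0)) < 1e-12

    def test_cifs_are_nondecreasing_from_zero(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(50, 100) + 0.5
        c = rng.choice([0, 1, 2], 100)
        est = cumulative_incidence(t, c)
        assert est.cif1[0] >= 0 and est.cif2[0] >= 0
        assert (np.diff(est.cif1) >= 0).all() and (np.diff(est.cif2) >= 0).all()


class TestGrayTest:
    def test_identical_groups_give_null_result(self):
        t = [3, 5, 7, 9, 3, 5, 7, 9]
        c = [1, 2, 1, 0, 1, 2, 1, 0]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = gray_test(t, c, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_cause1_events_rejected(self):
        with pytest.raises(CompetingRisksError):
            gray_test([1, 2, 3, 4], [0, 2, 2, 0], [0, 0, 1, 1])

    def test_relabeling_and_time_transform_invariance(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(100, 60) + 1
        c = rng.choice([0, 1, 2], 60, p=[0.2, 0.5, 0.3])
        g = rng.integers(0, 2, 60)
        s1 = gray_statistic(t, c, g)
        s2 = gray_statistic(t, c, 1 - g)          # relabel groups
        s3 = gray_statistic(np.sqrt(t), c, g)     # monotone time transform
        assert s1 == pytest.approx(s2, rel=1e-9)
        assert s1 == pytest.approx(s3, rel=1e-9)

    def test_permutation_pvalue_matches_exact_enumeration(self):
        # 8 subjects, 4 per arm: all 70 relabelings are enumerable, so the
        # exact permutation p-value is available as an oracle
        t = np.array([3.0, 5.0, 7.0, 9.0, 4.0, 6.0, 8.0, 10.0])
        c = np.array([1, 2, 1, 0, 1, 0, 2, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        obs = gray_statistic(t, c, g)
        hits = total = 0
        for idx in combinations(range(8), 4):
            gp = np.zeros(8, dtype=int)
            gp[list(idx)] = 1
            total += 1
            hits += gray_statistic(t, c, gp) >= obs - 1e-12
        exact = hits / total
        res = gray_test(t, c, g, n_permutations=20_000, seed=101)
        assert res.p_value == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / 20_000))


class TestFineGray:
    def _cox_loglik_oracle(self, beta, t, X):
        """Explicit Cox partial likelihood, O(n^2) loops (no ties in t)."""
        ll = 0.0
        for i in range(len(t)):
            risk = t >= t[i]
            ll += X[i] @ beta - np.log(np.sum(np.exp(X[risk] @ beta)))
        return ll

    def test_reduces_to_cox_without_competing_events(self):
        rng = np.random.default_rng(5)
        n = 120
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1.0 / np.exp(X @ [0.4, -0.6]))
        c = np.ones(n, dtype=int)
        fit = fine_gray_fit(t, c, X)
        res = optimize.minimize(
            lambda b: -self._cox_loglik_oracle(b, t, X), np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        assert np.allclose(fit.coef, res.x, atol=1e-4)

    def test_single_binary_covariate_grid_search(self):
        # four subjects, no censoring or competing events: the weighted
        # partial likelihood is the plain Cox one, maximizable by grid search
        t = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([1, 1, 1, 1])
        x = np.array([[1.0], [0.0], [1.0], [0.0]])
        grid = np.linspace(-3, 3, 60_001)
        lls = [self._cox_loglik_oracle(np.array([b]), t, x) for b in grid]
        fit = fine_gray_fit(t, c, x)
        assert fit.coef[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_zero_variation_covariate_rejected(self):
        t = np.arange(1.0, 11.0)
        c = np.ones(10, dtype=int)
        X = np.ones((10, 1))
        with pytest.raises(CompetingRisksError, match="zero variation"):
            fine_gray_fit(t, c, X)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(CompetingRisksError, match="rank"):
            fine_gray_fit(np.arange(1.0, 21.0), np.ones(20, dtype=int), X)

    def test_null_model_cif_matches_aalen_johansen(self):
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(n_lesions=400, seed=7)
        truth = simulate_latent_events(cfg, None, rng)
        t = truth["event_day"].to_numpy()
        c = truth["cause"].to_numpy()
        cens = rng.uniform(100, 1460, len(t))
        c = np.where(t <= cens, c, 0)
        t = np.minimum(t, cens)
        aj = cumulative_incidence(t, c)
        sd = subdistribution_cif(t, c)
        assert np.allclose(np.asarray(aj.at(sd.times, 1)), sd.cif1, atol=1e-10)

    def test_matches_reference_r_implementation(self, tmp_path):
        """Coefficients and robust SEs agree with cmprsk::crr on mixed data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        n = 300
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
        cfg = SimulationConfig(n_lesions=n, p1=0.4, lambda1=0.004,
                               death_rate=0.002, admin_censor_day=1200, seed=1)
        truth = simulate_latent_events(cfg, X @ np.array([-0.6, 0.3]), rng)
        t = truth["event_day"].to_numpy()
        c = truth["cause"].to_numpy()
        cens = rng.uniform(50, 1200, n)
        c = np.where(t <= cens, c, 0)
        t = np.minimum(t, cens)
        data = tmp_path / "d.csv"
        np.savetxt(data, np.column_stack([t, c, X]), delimiter=",",
                   header="t,c,g,z", comments="")
        script = tmp_path / "crr.R"
        script.write_text(textwrap.dedent("""
            library(cmprsk)
            args <- commandArgs(trailingOnly = TRUE)
            df <- read.csv(args[1])
            fit <- crr(df$t, df$c, cbind(df$g, df$z))
            cat(fit$coef, sqrt(diag(fit$var)), sep = "\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script), str(data)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        ref = [float(x) for x in out.stdout.split()]
        fit = fine_gray_fit(t, c, X)
        assert np.allclose(fit.coef, ref[:2], atol=1e-4)
        assert np.allclose(fit.se, ref[2:], rtol=1e-2)

    def test_wald_pvalues_consistent_with_z(self):
        rng = np.random.default_rng(8)
        n = 150
        X = rng.normal(size=(n, 1))
        cfg = SimulationConfig(n_lesions=n, seed=8)
        truth = simulate_latent_events(cfg, X[:, 0] * 0.5, rng)
        fit = fine_gray_fit(truth["event_day"], truth["cause"], X)
        assert fit.p_values[0] == pytest.approx(2 * stats.norm.sf(abs(fit.z[0])))
        assert fit.converged and (fit.hazard_ratios > 0).all()
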