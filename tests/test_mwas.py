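import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import golden

from conftest import identity_kernel, make_standardized_matrix
from mwastools.mwas import (
    MethylationMatrix,
    RelatednessMatrix,
    beta_to_m,
    compare_effect_sets,
    compute_orm,
    reml_blup_residualize,
    run_mwas,
    standardize_probes,
)


# ---------------------------------------------------------------------------
# independent oracle: dense REML by grid + golden-section, no eigendecomposition
# ---------------------------------------------------------------------------

def dense_reml_fit(y, X, K):
    """Brute-force REML for y = Xb + u + e, u ~ N(0, s2*delta*K).

    Maximizes the restricted log-likelihood over log(delta) by a coarse grid
    followed by golden-section, using dense solves only.  Returns
    (b_last, se_last) for the last design column.
    """
    n, p = X.shape

    def negll(log_delta):
        V = np.exp(log_delta) * K + np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        b = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ b
        s2 = float(r @ Vi @ r) / (n - p)
        _, ld_v = np.linalg.slogdet(V)
        _, ld_x = np.linalg.slogdet(XtViX)
        return 0.5 * ((n - p) * np.log(s2) + ld_v + ld_x)

    grid = np.linspace(-10, 10, 81)
    vals = [negll(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    if i in (0, len(grid) - 1):
        best = grid[i]
    else:
        best = golden(negll, brack=(lo, grid[i], hi), tol=1e-12)
    V = np.exp(best) * K + np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ b
    s2 = float(r @ Vi @ r) / (n - p)
    cov = s2 * np.linalg.inv(XtViX)
    return float(b[-1]), float(np.sqrt(cov[-1, -1]))


class TestBetaToM:
    def test_symmetry_point(self):
        assert beta_to_m(0.5) == 0.0

    def test_log2_four(self):
        assert beta_to_m(0.8) == pytest.approx(2.0)

    def test_antisymmetry(self):
        assert beta_to_m(0.2) == pytest.approx(-2.0)

    def test_strictly_increasing(self):
        grid = np.linspace(0.01, 0.99, 50)
        assert np.all(np.diff(beta_to_m(grid)) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            beta_to_m(1.0)
        with pytest.raises(ValueError):
            beta_to_m(np.array([0.5, 0.0]))


class TestStandardize:
    def _mat(self, values):
        values = np.asarray(values, dtype=float)
        return MethylationMatrix(
            values,
            np.array([f"p{j}" for j in range(values.shape[0])], dtype=object),
            np.array([f"s{i}" for i in range(values.shape[1])], dtype=object),
            scale="M",
        )

    def test_constant_probe_dropped(self):
        mat = self._mat([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.warns(UserWarning):
            out, dropped = standardize_probes(mat)
        assert dropped == ["p0"]
        assert out.n_probes == 1

    def test_zero_mean_unit_variance(self, rng):
        mat = self._mat(rng.normal(3, 2, size=(5, 40)))
        out, _ = standardize_probes(mat)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10
        assert out.values.std(axis=1, ddof=1) == pytest.approx(np.ones(5))

    def test_hand_zscores(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0]])
        out, _ = standardize_probes(self._mat(values))
        expected = (values[0] - 2.5) / np.std(values[0], ddof=1)
        assert out.values[0] == pytest.approx(expected)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            standardize_probes(self._mat([[1.0, 1.0], [2.0, 2.0]]))


class TestOrm:
    def test_identical_samples(self, rng):
        col = rng.standard_normal(4)
        values = np.column_stack([col, col, rng.standard_normal(4)])
        mat = MethylationMatrix(
            values, np.array(["a", "b", "c", "d"], dtype=object),
            np.array(["s1", "s2", "s3"], dtype=object), scale="M",
        )
        Z, _ = standardize_probes(mat)
        orm = compute_orm(Z)
        assert orm.values[0, 1] == pytest.approx(orm.values[0, 0])

    def test_hand_computation(self):
        Z = MethylationMatrix(
            np.array([[1.0, -1.0], [-1.0, 1.0]]),
            np.array(["a", "b"], dtype=object),
            np.array(["s1", "s2"], dtype=object),
            scale="standardized-M",
        )
        orm = compute_orm(Z)
        # Z'Z/2 with rows (1,-1) and (-1,1): diag 1, off-diag -1
        assert orm.values == pytest.approx(np.array([[1.0, -1.0], [-1.0, 1.0]]))

    def test_psd(self, rng):
        Z = make_standardized_matrix(rng, 100, 20)
        orm = compute_orm(Z)
        assert orm.min_eigenvalue() >= -1e-8

    def test_mean_diagonal_near_one(self, rng):
        Z = make_standardized_matrix(rng, 200, 30)
        orm = compute_orm(Z)
        assert np.diag(orm.values).mean() == pytest.approx(1.0, abs=0.05)


class TestRemlBlup:
    def test_identity_kernel_residuals_are_centered_y(self, rng):
        y = rng.normal(2.0, 1.0, 80)
        K = identity_kernel([f"s{i}" for i in range(80)])
        res, sg2, se2 = reml_blup_residualize(y, K)
        centered = y - y.mean()
        corr = np.corrcoef(res, centered)[0, 1]
        assert corr > 0.999
        assert sg2 >= 0 and se2 >= 0

    def test_h2_recovery_on_sib_blocks(self):
        from mwastools.synthetic import make_families_grm

        K = make_families_grm(200, 4, 0, seed=1)
        rng = np.random.default_rng(7)
        L = np.linalg.cholesky(K.values + 1e-9 * np.eye(K.n))
        g = L @ rng.standard_normal(K.n)
        y = np.sqrt(0.5) * g + np.sqrt(0.5) * rng.standard_normal(K.n)
        _, sg2, se2 = reml_blup_residualize(y, K)
        assert sg2 / (sg2 + se2) == pytest.approx(0.5, abs=0.1)

    def test_decomposition_reconstructs_phenotype(self):
        # y == mu_hat + g_hat + residual exactly, and the GLS normal
        # equation holds: 1' V^{-1} (y - mu_hat) == 0
        from mwastools.synthetic import make_families_grm

        K = make_families_grm(100, 3, 0, seed=2)
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky(K.values + 1e-9 * np.eye(K.n))
        y = 0.8 * (L @ rng.standard_normal(K.n)) + 0.6 * rng.standard_normal(K.n)
        res, sg2, se2 = reml_blup_residualize(y, K)
        assert sg2 >= 0 and se2 >= 0
        delta = sg2 / se2
        V = delta * K.values + np.eye(K.n)
        Vi = np.linalg.inv(V)
        ones = np.ones(K.n)
        mu_gls = float(ones @ Vi @ y / (ones @ Vi @ ones))
        g_hat = y - mu_gls - res
        assert y == pytest.approx(mu_gls + g_hat + res)
        # fitted random effect equals the BLUP formula at the REML optimum
        g_ref = delta * K.values @ Vi @ (y - mu_gls)
        assert g_hat == pytest.approx(g_ref, abs=1e-6)

    def test_length_mismatch(self):
        K = identity_kernel(["a", "b"])
        with pytest.raises(ValueError):
            reml_blup_residualize(np.zeros(3), K)


class TestRunMwas:
    def test_identity_omega_equals_ols(self, rng):
        n, m = 60, 10
        Z = make_standardized_matrix(rng, m, n)
        y = rng.standard_normal(n)
        res = run_mwas(y, Z, None, identity_kernel(Z.sample_ids), mode="fast")
        for j in range(m):
            lr = sps.linregress(Z.values[j], y)
            assert res.beta[j] == pytest.approx(lr.slope, abs=1e-8)
            assert res.se[j] == pytest.approx(lr.stderr, abs=1e-8)

    def test_exact_matches_dense_oracle(self, rng):
        n, m = 40, 5
        Z = make_standardized_matrix(rng, m, n)
        # structured kernel so delta actually matters
        from mwastools.synthetic import make_families_grm

        K = make_families_grm(10, 4, 0, seed=3)
        omega = RelatednessMatrix(K.values, Z.sample_ids, kind="ORM")
        L = np.linalg.cholesky(K.values + 1e-9 * np.eye(n))
        y = 0.4 * Z.values[0] + (L @ rng.standard_normal(n)) + 0.5 * rng.standard_normal(n)
        covs = pd.DataFrame({"c1": rng.standard_normal(n)}, index=Z.sample_ids)
        res = run_mwas(y, Z, covs, omega, mode="exact")
        X_base = np.column_stack([np.ones(n), covs["c1"].to_numpy()])
        for j in range(m):
            X = np.column_stack([X_base, Z.values[j]])
            b_ref, se_ref = dense_reml_fit(y, X, K.values)
            assert res.beta[j] == pytest.approx(b_ref, abs=1e-4)
            assert res.se[j] == pytest.approx(se_ref, abs=1e-4)

    def test_null_calibration(self):
        rng = np.random.default_rng(99)
        n, m = 300, 2000
        Z = make_standardized_matrix(rng, m, n)
        y = rng.standard_normal(n)
        res = run_mwas(y, Z, None, identity_kernel(Z.sample_ids), mode="fast")
        frac = float((res.p < 0.05).mean())
        assert 0.035 <= frac <= 0.065
        ks = sps.kstest(res.p, "uniform")
        assert ks.pvalue > 0.01

    def test_scale_equivariance(self, rng):
        n, m = 50, 6
        Z = make_standardized_matrix(rng, m, n)
        from mwastools.synthetic import make_families_grm

        K = make_families_grm(25, 2, 0, seed=4)
        omega = RelatednessMatrix(K.values, Z.sample_ids, kind="ORM")
        y = rng.standard_normal(n)
        a = run_mwas(y, Z, None, omega, mode="fast")
        b = run_mwas(3.5 * y, Z, None, omega, mode="fast")
        assert b.beta.to_numpy() == pytest.approx(3.5 * a.beta.to_numpy(), rel=1e-8)
        assert b.se.to_numpy() == pytest.approx(3.5 * a.se.to_numpy(), rel=1e-8)
        assert b.p.to_numpy() == pytest.approx(a.p.to_numpy(), rel=1e-8)

    def test_fast_vs_exact_rank_agreement(self, rng):
        n, m = 80, 40
        Z = make_standardized_matrix(rng, m, n)
        from mwastools.synthetic import make_families_grm

        K = make_families_grm(20, 4, 0, seed=5)
        omega = RelatednessMatrix(K.values, Z.sample_ids, kind="ORM")
        L = np.linalg.cholesky(K.values + 1e-9 * np.eye(n))
        y = L @ rng.standard_normal(n) + rng.standard_normal(n)
        fast = run_mwas(y, Z, None, omega, mode="fast")
        exact = run_mwas(y, Z, None, omega, mode="exact")
        rho = sps.spearmanr(fast.p, exact.p).statistic
        assert rho > 0.99

    def test_spike_recovery_paper_scale(self):
        # standardized effect 0.02 at n=10,000: binary exposure, one causal probe
        rng = np.random.default_rng(1)
        n = 10_000
        x = (rng.random(n) < 0.5).astype(float)
        target = 0.02
        q = 0.25  # var of the balanced exposure
        # solve c*q/sqrt(c^2*q + 1) = target for the generative loading c
        c = target / np.sqrt(q * (q - target**2))
        probes = np.vstack([c * x + rng.standard_normal(n), rng.standard_normal(n)])
        mat = MethylationMatrix(
            probes, np.array(["causal", "null"], dtype=object),
            np.array([f"s{i}" for i in range(n)], dtype=object), scale="M",
        )
        Z, _ = standardize_probes(mat)
        res = run_mwas(x - x.mean(), Z, None, omega=None, mode="fast")
        row = res.set_index("probe_id").loc["causal"]
        assert row.beta > 0
        assert abs(row.beta - target) < 3 * row.se

    def test_rank_deficient_design_names_columns(self, rng):
        n = 30
        Z = make_standardized_matrix(rng, 3, n)
        c = rng.standard_normal(n)
        covs = pd.DataFrame({"a": c, "b": 2 * c}, index=Z.sample_ids)
        with pytest.raises(ValueError, match="collinear"):
            run_mwas(rng.standard_normal(n), Z, covs, identity_kernel(Z.sample_ids))


class TestCompareEffectSets:
    def _results(self, betas, ses, label="x"):
        m = len(betas)
        return pd.DataFrame(
            {
                "probe_id": [f"p{j}" for j in range(m)],
                "beta": betas,
                "se": ses,
                "p": np.full(m, 0.5),
                "n": 100,
                "analysis": label,
            }
        )

    def test_identity_comparison(self, rng):
        res = self._results(rng.standard_normal(20), np.full(20, 0.1))
        cmp = compare_effect_sets(res, res)
        assert cmp["pearson_r"] == pytest.approx(1.0)
        assert cmp["per_probe"]["p_diff"].to_numpy() == pytest.approx(np.ones(20))
        assert cmp["mean_effect_ratio"] == pytest.approx(1.0)

    def test_closed_form_difference_z(self):
        resA = self._results([0.3, 0.1, -0.2], [0.1, 0.1, 0.1])
        resB = self._results([0.0, 0.1, -0.2], [0.1, 0.1, 0.1])
        cmp = compare_effect_sets(resA, resB)
        z = cmp["per_probe"].set_index("probe_id").loc["p0"]
        assert z["z_diff"] == pytest.approx(0.3 / np.sqrt(0.02), abs=1e-4)
        assert z["p_diff"] == pytest.approx(0.0339, abs=1e-3)

    def test_independent_nulls_weak_correlation(self):
        rng = np.random.default_rng(42)
        resA = self._results(rng.standard_normal(500), np.full(500, 0.1))
        resB = self._results(rng.standard_normal(500), np.full(500, 0.1))
        cmp = compare_effect_sets(resA, resB)
        assert abs(cmp["pearson_r"]) < 0.15

    def test_too_few_shared_probes(self):
        a = self._results([0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ValueError):
            compare_effect_sets(a, a)
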