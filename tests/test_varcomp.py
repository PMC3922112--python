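"""AI-REML estimation, the boundary LRT, and the bivariate model."""

import numpy as np
import pandas as pd
import pytest

from gxeherit import (
    EnvFactor,
    ModelSpec,
    SimConfig,
    VarCompResult,
    assign_environments,
    bivar_reml,
    boundary_lrt_pvalue,
    compute_grm,
    design_matrix,
    gxe_grm,
    lrt,
    reml_fit,
    simulate_bivariate,
    simulate_genotypes,
    simulate_phenotype,
)
from gxeherit import test_rg as rg_lrt


def _fit_sim(cfg, factor="area"):
    G = simulate_genotypes(cfg)
    env = assign_environments(cfg, factor)
    tab, truth = simulate_phenotype(G, env, cfg)
    A = compute_grm(G)
    Age = gxe_grm(A, env)
    y = tab["PHENO"].to_numpy()
    X = design_matrix(env.levels, len(y))
    full = reml_fit(ModelSpec(y, X, [("G", A.values), ("GxE", Age.values)]))
    return full, A, Age, env, y, X, truth


def _grid_oracle(y, X, A, Age, step=0.005):
    """Independent oracle: profile-scale REML log-likelihood maximized
    over the (h_g, h_ge) simplex by dense grid search."""
    n, p = X.shape
    eye = np.eye(n)
    best, argbest = -np.inf, None
    hs = np.arange(0.0, 1.0 + step / 2, step)
    for hg in hs:
        for hge in hs:
            he = 1.0 - hg - hge
            if he < 1e-4:
                continue
            V0 = hg * A + hge * Age + he * eye
            try:
                L = np.linalg.cholesky(V0)
            except np.linalg.LinAlgError:
                continue
            logdetV0 = 2.0 * np.log(np.diag(L)).sum()
            V0inv = np.linalg.inv(V0)
            XtVX = X.T @ V0inv @ X
            s, logdetX = np.linalg.slogdet(XtVX)
            P0y = V0inv @ y - V0inv @ X @ np.linalg.solve(XtVX, X.T @ V0inv @ y)
            ypy = float(y @ P0y)
            scale = ypy / (n - p)
            ll = -0.5 * ((n - p) * np.log(scale) + logdetV0 + logdetX)
            if ll > best:
                best, argbest = ll, (hg, hge)
    return argbest


class TestRemlAgainstGridOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_small_instance_matches_grid_search(self, seed):
        cfg = SimConfig(n_individuals=22, n_snps=80, h2_g=0.3, h2_ge=0.3, seed=seed)
        full, A, Age, env, y, X, _ = _fit_sim(cfg)
        hg_hat = full.proportion("G")
        hge_hat = full.proportion("GxE")
        hg_star, hge_star = _grid_oracle(y, X, A.values, Age.values)
        assert hg_hat == pytest.approx(hg_star, abs=0.01)
        assert hge_hat == pytest.approx(hge_star, abs=0.01)


class TestRemlBasics:
    def test_proportions_valid_and_loglik_finite(self, small_cohort):
        cfg, G, env, tab, _ = small_cohort
        A = compute_grm(G)
        Age = gxe_grm(A, env)
        y = tab["PHENO"].to_numpy()
        X = design_matrix(env.levels, len(y))
        res = reml_fit(ModelSpec(y, X, [("G", A.values), ("GxE", Age.values)]))
        assert res.converged
        assert np.isfinite(res.loglik)
        assert np.all(res.proportions >= 0) and res.proportions.sum() == pytest.approx(1.0)
        assert np.all(res.variances >= 1e-6 * res.sigma_p2 * 0.99)

    def test_unidentifiable_identity_structure_flagged(self):
        rng = np.random.default_rng(0)
        n = 80
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        res = reml_fit(ModelSpec(y, X, [("G", np.eye(n))]))
        assert "flat" in res.message

    def test_singular_design_rejected(self):
        n = 30
        y = np.zeros(n)
        X = np.ones((n, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank deficient"):
            ModelSpec(y, X, [("G", np.eye(n))])

    def test_full_dominates_reduced(self, small_cohort):
        cfg, G, env, tab, _ = small_cohort
        A = compute_grm(G)
        Age = gxe_grm(A, env)
        y = tab["PHENO"].to_numpy()
        X = design_matrix(env.levels, len(y))
        full = reml_fit(ModelSpec(y, X, [("G", A.values), ("GxE", Age.values)]))
        red = reml_fit(ModelSpec(y, X, [("G", A.values)]))
        assert full.loglik >= red.loglik - 1e-6


class TestBoundaryLrt:
    @pytest.mark.parametrize(
        "stat,expected,digits",
        [(11.68, 3.2e-4, 2), (4.38, 1.8e-2, 2), (0.0, 0.5, 2)],
    )
    def test_mixture_tail_mapping(self, stat, expected, digits):
        p = boundary_lrt_pvalue(stat)
        assert float(f"%.{digits - 1}e" % p) == pytest.approx(expected, rel=1e-9)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            boundary_lrt_pvalue(-0.5)

    def _result(self, names, ll):
        k = len(names)
        return VarCompResult(
            names=names, variances=np.ones(k) / k, ses=np.zeros(k), sigma_p2=1.0,
            proportions=np.ones(k) / k, prop_ses=np.zeros(k), loglik=ll,
            n_iter=1, converged=True, n=100,
        )

    def test_lrt_statistic_and_clamping(self):
        full = self._result(["G", "GxE", "e"], -100.0)
        red = self._result(["G", "e"], -105.84)
        out = lrt(full, red)
        assert out.statistic == pytest.approx(11.68)
        assert out.p_value == pytest.approx(boundary_lrt_pvalue(11.68))
        with pytest.warns(UserWarning, match="clamped"):
            out2 = lrt(self._result(["G", "GxE", "e"], -101.0), self._result(["G", "e"], -100.0))
        assert out2.statistic == 0.0 and out2.p_value == 0.5

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            lrt(self._result(["G", "e"], -1.0), self._result(["GxE", "e"], -2.0))

    def test_type_one_error_conservative_under_null(self):
        """Under h2_ge = 0 the mixture-null LRT rejects at or below the
        nominal rate (the boundary mixture is conservative-to-exact)."""
        rejections = 0
        reps = 60
        for seed in range(100, 100 + reps):
            cfg = SimConfig(n_individuals=400, n_snps=400, h2_g=0.2, h2_ge=0.0, seed=seed)
            G = simulate_genotypes(cfg)
            env = assign_environments(cfg, "area")
            tab, _ = simulate_phenotype(G, env, cfg)
            A = compute_grm(G)
            Age = gxe_grm(A, env)
            y = tab["PHENO"].to_numpy()
            X = design_matrix(env.levels, len(y))
            full = reml_fit(ModelSpec(y, X, [("G", A.values), ("GxE", Age.values)]))
            red = reml_fit(ModelSpec(y, X, [("G", A.values)]))
            if lrt(full, red).p_value < 0.05 * 1.0:
                rejections += 1
        rate = rejections / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_recovery_off_grid_cell(self):
        """Mean REML estimates track the generating proportions for a
        cell with both components present (reduced scale)."""
        ests = []
        for seed in range(1, 7):
            cfg = SimConfig(n_individuals=800, n_snps=800, h2_g=0.1, h2_ge=0.15, seed=seed)
            full, *_ = _fit_sim(cfg)
            ests.append((full.proportion("G"), full.proportion("GxE")))
        mean = np.mean(ests, axis=0)
        assert mean[0] == pytest.approx(0.1, abs=0.1)
        assert mean[1] == pytest.approx(0.15, abs=0.1)


def _bivar_fit(cfg):
    G = simulate_genotypes(cfg)
    env = assign_environments(cfg, "area")
    tab, truth = simulate_bivariate(G, env, cfg)
    A = compute_grm(G)
    ids = np.array(G.sample_ids, dtype=object)
    y = tab["PHENO"].to_numpy()
    m1 = env.levels == env.unique_levels[0]
    s1 = pd.Series(y[m1], index=ids[m1])
    s2 = pd.Series(y[~m1], index=ids[~m1])
    return bivar_reml(s1, s2, A), truth


class TestBivariate:
    def test_disjointness_enforced(self, small_grm):
        ids = small_grm.sample_ids
        y1 = pd.Series(np.zeros(40), index=ids[:40])
        y2 = pd.Series(np.zeros(40), index=ids[30:70])
        with pytest.raises(ValueError, match="disjoint"):
            bivar_reml(y1, y2, small_grm)

    def test_minimum_group_size_enforced(self, small_grm):
        ids = small_grm.sample_ids
        y1 = pd.Series(np.zeros(10), index=ids[:10])
        y2 = pd.Series(np.zeros(40), index=ids[10:50])
        with pytest.raises(ValueError, match="at least 30"):
            bivar_reml(y1, y2, small_grm)

    def test_rg_bounded_and_se_reported(self):
        cfg = SimConfig(n_individuals=400, n_snps=400, rg=0.5, h2_env=(0.4, 0.4), seed=31)
        res, _ = _bivar_fit(cfg)
        assert -1.0 <= res.rg <= 1.0
        assert res.rg_se > 0

    def test_unlinked_traits_give_near_zero_rg(self):
        ests = []
        for seed in range(41, 49):
            cfg = SimConfig(n_individuals=500, n_snps=500, rg=0.0, h2_env=(0.4, 0.4), seed=seed)
            res, _ = _bivar_fit(cfg)
            ests.append(res.rg)
        assert np.mean(ests) == pytest.approx(0.0, abs=0.2)

    def test_constrained_loglik_below_unconstrained(self):
        cfg = SimConfig(n_individuals=400, n_snps=400, rg=0.5, h2_env=(0.4, 0.4), seed=32)
        res, _ = _bivar_fit(cfg)
        out = rg_lrt(res, 0.0)
        assert out.statistic >= 0.0
        assert 0.0 < out.p_value <= 1.0

    def test_rg_one_null_not_rejected_when_true(self):
        """Effects duplicated across environments: testing r_g = 1 gives
        a small statistic."""
        cfg = SimConfig(n_individuals=400, n_snps=400, rg=1.0, h2_env=(0.5, 0.5), seed=33)
        res, _ = _bivar_fit(cfg)
        out = rg_lrt(res, 1.0)
        assert out.p_value > 0.05

    def test_rg_zero_null_statistic_moderate_when_true(self):
        """Interior null: the LRT statistic under a true null is the
        size of a chi-square(1) draw, not systematically large."""
        stats = []
        for seed in range(61, 67):
            cfg = SimConfig(n_individuals=300, n_snps=300, rg=0.0, h2_env=(0.4, 0.4), seed=seed)
            res, _ = _bivar_fit(cfg)
            stats.append(rg_lrt(res, 0.0).statistic)
        assert np.mean(stats) < 4.0  # chi2(1) mean is 1; allow wide MC slack
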