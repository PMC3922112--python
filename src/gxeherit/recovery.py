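"""Parameter-recovery experiments on synthetic cohorts.

Because the cohort this methodology was developed on is not publicly
deposited, the package validates itself by simulation: generate cohorts
with known additive and interaction variance proportions (or a known
cross-environment genetic correlation), run the full estimation path
(genotypes -> GRM -> masked interaction GRM -> AI-REML), and compare the
replicate-mean estimates with the generating values.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .grm import compute_grm, gxe_grm
from .simulate import (
    SimConfig,
    assign_environments,
    simulate_bivariate,
    simulate_genotypes,
    simulate_phenotype,
)
from .varcomp import ModelSpec, bivar_reml, design_matrix, reml_fit

__all__ = ["univariate_recovery", "bivariate_recovery", "derive_seeds"]


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one base seed."""
    return [
        int(np.random.SeedSequence([int(base_seed), r]).generate_state(1)[0] % (2**31))
        for r in range(n)
    ]


def _one_univariate(
    h2_g: float, h2_ge: float, n: int, m: int,
    env_split: tuple[float, float], factor: str, seed: int,
) -> tuple[float, float]:
    cfg = SimConfig(
        n_individuals=n, n_snps=m, h2_g=h2_g, h2_ge=h2_ge,
        env_proportions=env_split, seed=seed,
    )
    G = simulate_genotypes(cfg)
    env = assign_environments(cfg, factor)
    table, _ = simulate_phenotype(G, env, cfg)
    A = compute_grm(G)
    A_ge = gxe_grm(A, env)
    y = table["PHENO"].to_numpy()
    X = design_matrix(env.levels, len(y))
    fit = reml_fit(ModelSpec(y, X, [("G", A.values), ("GxE", A_ge.values)]))
    return fit.proportion("G"), fit.proportion("GxE")


def univariate_recovery(
    h2_g: float,
    h2_ge: float,
    seeds: Iterable[int],
    n: int = 2000,
    m: int = 2000,
    env_split: tuple[float, float] = (0.4, 0.6),
    factor: str = "area",
) -> pd.DataFrame:
    """Fit the two-component model on replicate cohorts generated at
    (h2_g, h2_ge); one row of (V_G/V_P, V_GE/V_P) estimates per seed."""
    rows = [
        _one_univariate(h2_g, h2_ge, n, m, env_split, factor, s) for s in seeds
    ]
    return pd.DataFrame(rows, columns=["vg_vp", "vge_vp"])


def bivariate_recovery(
    rg: float,
    seeds: Iterable[int],
    h2_env: tuple[float, float] = (0.3, 0.3),
    n: int = 2000,
    m: int = 2000,
    env_split: tuple[float, float] = (0.4, 0.6),
) -> pd.DataFrame:
    """Bivariate REML genetic-correlation estimates on replicate cohorts
    generated at cross-environment correlation ``rg``."""
    rows = []
    for seed in seeds:
        cfg = SimConfig(
            n_individuals=n, n_snps=m, rg=rg, h2_env=h2_env,
            env_proportions=env_split, seed=seed,
        )
        G = simulate_genotypes(cfg)
        env = assign_environments(cfg, "area")
        table, _ = simulate_bivariate(G, env, cfg)
        A = compute_grm(G)
        ids = np.asarray(G.sample_ids, dtype=object)
        y = table["PHENO"].to_numpy()
        mask1 = env.levels == env.unique_levels[0]
        s1 = pd.Series(y[mask1], index=ids[mask1])
        s2 = pd.Series(y[~mask1], index=ids[~mask1])
        fit = bivar_reml(s1, s2, A)
        rows.append({"rg": fit.rg, "rg_se": fit.rg_se, "converged": fit.converged})
    return pd.DataFrame(rows)
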