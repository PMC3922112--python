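"""Per-SNP two-environment interaction scan.

For each SNP, the trait is regressed on dosage separately within the two
environmental strata; the interaction statistic is the difference of the
two slopes scaled by its standard error,

    z = (b1 - b2) / sqrt(se1^2 + se2^2),

referred to the standard normal (the convention of the PLINK gxe test).
A pooled single-regression slope t-test provides the main-effect
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .genio import GenotypeMatrix
from .pheno import EnvFactor

__all__ = ["GxeScanRecord", "snp_gxe_test", "scan", "bonferroni_threshold"]

SCAN_COLUMNS = [
    "SNP", "CHR", "POS", "N1", "B1", "SE1", "N2", "B2", "SE2", "Z", "P_GXE", "P_G",
]


@dataclass
class GxeScanRecord:
    snp_id: str
    b1: float
    se1: float
    n1: int
    b2: float
    se2: float
    n2: int
    z: float
    p_gxe: float
    p_g: float
    flagged: bool = False


def _stratum_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Slope and SE of y ~ 1 + x on jointly observed entries."""
    obs = ~np.isnan(x) & ~np.isnan(y)
    n = int(obs.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[obs], y[obs]
    sxx = float(np.sum((xs - xs.mean()) ** 2))
    if sxx <= 0:
        return np.nan, np.nan, n
    sxy = float(np.sum((xs - xs.mean()) * (ys - ys.mean())))
    b = sxy / sxx
    rss = float(np.sum((ys - ys.mean()) ** 2)) - b * sxy
    se = np.sqrt(max(rss, 0.0) / (n - 2) / sxx)
    return b, se, n


def snp_gxe_test(dosage: np.ndarray, y: np.ndarray, env: EnvFactor,
                 snp_id: str = "snp") -> GxeScanRecord:
    """Slope-difference interaction test for one SNP across two strata."""
    env.require_at_least(2)
    levels = env.unique_levels
    if len(levels) != 2:
        raise ValueError("the interaction scan needs exactly two environment levels")
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    b = {}
    for lev in levels:
        mask = env.levels == lev
        b[lev] = _stratum_ols(dosage[mask], y[mask])
    (b1, se1, n1), (b2, se2, n2) = b[levels[0]], b[levels[1]]

    if np.isnan(b1) or np.isnan(b2) or (se1 == 0 and se2 == 0):
        z = np.nan
        p_gxe = np.nan
        flagged = True
    else:
        z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
        p_gxe = float(2.0 * norm.sf(abs(z)))
        flagged = False

    bp, sep, np_ = _stratum_ols(dosage, y)
    if np.isnan(bp) or sep == 0:
        p_g = np.nan
    else:
        p_g = float(2.0 * t_dist.sf(abs(bp / sep), df=np_ - 2))
    return GxeScanRecord(snp_id, b1, se1, n1, b2, se2, n2, z, p_gxe, p_g, flagged)


def scan(G: GenotypeMatrix, y: np.ndarray, env: EnvFactor) -> pd.DataFrame:
    """Genome-wide slope-difference scan; rows sorted by interaction
    p-value ascending.  Vectorized across SNPs within each stratum."""
    if G.n_snps == 0:
        raise ValueError("no SNPs to scan")
    env.require_at_least(2)
    levels = env.unique_levels
    if len(levels) != 2:
        raise ValueError("the interaction scan needs exactly two environment levels")
    y = np.asarray(y, dtype=float)
    if len(y) != G.n_samples:
        raise ValueError("phenotype length does not match genotype rows")

    def stratum_stats(mask: np.ndarray):
        X = G.dosages[mask]
        ys = y[mask]
        obs = ~np.isnan(X) & ~np.isnan(ys)[:, None]
        n = obs.sum(axis=0).astype(float)
        Xo = np.where(obs, X, 0.0)
        yo = np.where(obs, ys[:, None], 0.0)
        sx = Xo.sum(axis=0)
        sy = yo.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sxx = (Xo**2).sum(axis=0) - sx**2 / n
            syy = (yo**2).sum(axis=0) - sy**2 / n
            sxy = (Xo * yo).sum(axis=0) - sx * sy / n
            b = sxy / sxx
            rss = syy - b * sxy
            se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
        bad = (n < 3) | (sxx <= 0)
        b[bad] = np.nan
        se[bad] = np.nan
        return b, se, n.astype(int)

    b1, se1, n1 = stratum_stats(env.levels == levels[0])
    b2, se2, n2 = stratum_stats(env.levels == levels[1])
    bp, sep, npool = stratum_stats(np.ones(G.n_samples, dtype=bool))

    with np.errstate(invalid="ignore", divide="ignore"):
        z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
        p_gxe = 2.0 * norm.sf(np.abs(z))
        tstat = bp / sep
        p_g = 2.0 * t_dist.sf(np.abs(tstat), df=np.maximum(npool - 2, 1))

    out = pd.DataFrame(
        {
            "SNP": G.snps["snp_id"].to_numpy(),
            "CHR": G.snps["chrom"].to_numpy(),
            "POS": G.snps["pos"].to_numpy(),
            "N1": n1, "B1": b1, "SE1": se1,
            "N2": n2, "B2": b2, "SE2": se2,
            "Z": z, "P_GXE": p_gxe, "P_G": p_g,
        }
    )
    return out.sort_values("P_GXE", kind="stable", na_position="last").reset_index(drop=True)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests
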