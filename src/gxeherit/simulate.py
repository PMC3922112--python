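"""Synthetic two-area cohort generator with known G x E architecture.

Phenotypes follow the sampling counterpart of the variance-component
model fitted downstream:

    y_j = sum_i z_ij u_i  +  sum_i z_ij v_i(env_j)  +  X beta  +  eps_j

with z the per-SNP standardized dosage (using the generating allele
frequency), shared effects u_i ~ N(0, h2_g / m), environment-specific
deviations v_i(e) ~ N(0, h2_ge / m) drawn independently per environment
level, and eps_j ~ N(0, 1 - h2_g - h2_ge).  Same-environment pairs then
have interaction covariance A_jk * sigma_ge^2 and different-environment
pairs zero, which is exactly the masked-GRM covariance assumed by the
estimator.

Defaults emulate the study design this package targets at desk scale:
two areas at a 40/60 split (a rural/urban imbalance), two sexes, three
birth-year bands, biallelic autosomal SNPs with MAF uniform on
[0.05, 0.5], n = 2000 individuals and m = 2000 SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, write_plink
from .pheno import EnvFactor

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_genotypes",
    "assign_environments",
    "simulate_phenotype",
    "simulate_bivariate",
    "spike_relatives",
    "write_dataset",
]

# fixed child-stream keys so stages can be rerun independently
_STREAM_GENO = 1
_STREAM_ENV = 2
_STREAM_EFFECTS = 3
_STREAM_RESID = 4
_STREAM_COVAR = 5
_STREAM_MISSING = 6


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    ``h2_g`` and ``h2_ge`` are the target proportions of phenotypic
    variance from additive and interaction effects (their sum at most 1);
    ``rg`` is the cross-environment genetic correlation used by the
    bivariate generator, with per-environment heritabilities ``h2_env``.
    """

    n_individuals: int = 2000
    n_snps: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    env_proportions: tuple[float, ...] = (0.4, 0.6)
    env_labels: tuple[str, ...] | None = None
    h2_g: float = 0.0
    h2_ge: float = 0.0
    rg: float = 1.0
    h2_env: tuple[float, float] = (0.3, 0.3)
    fixed_effects: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ValueError("need at least 2 individuals and 1 SNP")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < low <= high <= 0.5")
        if abs(sum(self.env_proportions) - 1.0) > 1e-12:
            raise ValueError("environment proportions must sum to 1")
        if not (0.0 <= self.h2_g <= 1.0 and 0.0 <= self.h2_ge <= 1.0):
            raise ValueError("h2_g and h2_ge must lie in [0, 1]")
        if self.h2_g + self.h2_ge > 1.0:
            raise ValueError("h2_g + h2_ge must not exceed 1")
        if abs(self.rg) > 1.0:
            raise ValueError("rg must lie in [-1, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class TruthRecord:
    """Realized effect sizes and variance shares of one simulated trait."""

    shared_effects: np.ndarray  # (m,)
    env_effects: dict  # level -> (m,) interaction (or per-env) effects
    realized_h2_g: float
    realized_h2_ge: float
    realized_resid: float
    ge_component: np.ndarray  # (n,) realized interaction genetic values
    g_component: np.ndarray  # (n,) realized shared genetic values
    seed: int

    def to_frame(self) -> pd.DataFrame:
        d = {"shared": self.shared_effects}
        for lev, v in self.env_effects.items():
            d[f"env_{lev}"] = v
        return pd.DataFrame(d)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw unlinked biallelic genotypes: per SNP a frequency uniform on
    [maf_low, maf_high], dosages binomial(2, p)."""
    rng = cfg.rng(_STREAM_GENO)
    p = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_snps)
    dos = rng.binomial(2, p, size=(cfg.n_individuals, cfg.n_snps)).astype(float)
    if cfg.missing_rate > 0:
        miss = cfg.rng(_STREAM_MISSING).random(dos.shape) < cfg.missing_rate
        dos[miss] = np.nan
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"snp{i + 1}" for i in range(cfg.n_snps)],
            "cm": 0.0,
            "pos": np.arange(1, cfg.n_snps + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )
    ids = [f"id{j + 1}" for j in range(cfg.n_individuals)]
    return GenotypeMatrix(dos, ids, snps, true_freqs=p)


def assign_environments(cfg: SimConfig, name: str = "area") -> EnvFactor:
    """Assign environment levels by the configured proportions, in a
    seed-determined random order."""
    n = cfg.n_individuals
    labels = cfg.env_labels
    if labels is None:
        labels = (
            ("A", "B", "C")[: len(cfg.env_proportions)]
            if name in ("sex", "age_group")
            else tuple(str(i + 1) for i in range(len(cfg.env_proportions)))
        )
    counts = np.floor(np.asarray(cfg.env_proportions) * n).astype(int)
    counts[-1] = n - counts[:-1].sum()
    levels = np.repeat(np.asarray(labels, dtype=object), counts)
    cfg.rng(_STREAM_ENV).shuffle(levels)
    return EnvFactor(name, levels)


def _standardized(G: GenotypeMatrix) -> np.ndarray:
    """Standardize columns with the generating frequencies (true p)."""
    if G.true_freqs is None:
        raise ValueError("genotype matrix lacks generating frequencies")
    p = G.true_freqs
    Z = (np.nan_to_num(G.dosages, nan=0.0) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z[np.isnan(G.dosages)] = 0.0
    return Z


def _covariate_table(cfg: SimConfig, env: EnvFactor) -> pd.DataFrame:
    """Sample table covariates; the interaction factor's own column is
    overwritten with the assigned levels."""
    rng = cfg.rng(_STREAM_COVAR)
    n = cfg.n_individuals
    tab = pd.DataFrame(
        {
            "IID": [f"id{j + 1}" for j in range(n)],
            "SEX": rng.choice(["A", "B"], size=n),
            "AREA": rng.choice(["1", "2"], size=n, p=[0.4, 0.6]),
            "BIRTH_YEAR": rng.integers(1931, 1964, size=n),
        }
    )
    col = {"area": "AREA", "sex": "SEX", "age_group": None}.get(env.name)
    if col is not None:
        tab[col] = env.levels
    elif env.name == "age_group":
        # back-fill birth years consistent with the assigned band
        bands = {"A": (1931, 1945), "B": (1946, 1955), "C": (1956, 1963)}
        lo = np.array([bands[l][0] for l in env.levels])
        hi = np.array([bands[l][1] for l in env.levels])
        tab["BIRTH_YEAR"] = rng.integers(lo, hi + 1)
    return tab


def _fixed_part(cfg: SimConfig, tab: pd.DataFrame) -> np.ndarray:
    """Fixed-effect contribution X beta from per-covariate coefficients.

    Supported keys: 'sex' (indicator of level B), 'area' (indicator of
    level 2), 'age' (centered birth year / 10)."""
    n = len(tab)
    out = np.zeros(n)
    for key, beta in cfg.fixed_effects.items():
        if key == "sex":
            out += beta * (tab["SEX"].to_numpy() == "B")
        elif key == "area":
            out += beta * (tab["AREA"].to_numpy() == "2")
        elif key == "age":
            by = tab["BIRTH_YEAR"].to_numpy(float)
            out += beta * (by - by.mean()) / 10.0
        else:
            raise ValueError(f"unknown fixed-effect key {key!r}")
    return out


def simulate_phenotype(
    G: GenotypeMatrix, env: EnvFactor, cfg: SimConfig, trait: str = "PHENO"
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate one trait under the additive + G x E decomposition."""
    n, m = G.n_samples, G.n_snps
    if len(env.levels) != n:
        raise ValueError("environment factor does not cover all individuals")
    Z = _standardized(G)
    rng = cfg.rng(_STREAM_EFFECTS)
    u = rng.normal(0.0, np.sqrt(cfg.h2_g / m), size=m)
    levels = env.unique_levels
    v = {lev: rng.normal(0.0, np.sqrt(cfg.h2_ge / m), size=m) for lev in levels}
    g = Z @ u
    ge = np.zeros(n)
    for lev in levels:
        mask = env.levels == lev
        ge[mask] = Z[mask] @ v[lev]
    resid_var = 1.0 - cfg.h2_g - cfg.h2_ge
    eps = cfg.rng(_STREAM_RESID).normal(0.0, np.sqrt(resid_var), size=n)

    tab = _covariate_table(cfg, env)
    y = g + ge + _fixed_part(cfg, tab) + eps
    tab[trait] = y

    var_y = float(np.var(y, ddof=1))
    truth = TruthRecord(
        shared_effects=u,
        env_effects=v,
        realized_h2_g=float(np.var(g, ddof=1)) / var_y,
        realized_h2_ge=float(np.var(ge, ddof=1)) / var_y,
        realized_resid=float(np.var(eps, ddof=1)) / var_y,
        ge_component=ge,
        g_component=g,
        seed=cfg.seed,
    )
    return tab, truth


def simulate_bivariate(
    G: GenotypeMatrix, env: EnvFactor, cfg: SimConfig, trait: str = "PHENO"
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate one trait whose genetic basis differs between two
    environments with correlation ``cfg.rg``.

    Per SNP, the effect pair (u_i(1), u_i(2)) is bivariate normal with
    variances h2_env / m and correlation rg; each individual's phenotype
    uses the effect vector of its own environment.
    """
    levels = env.unique_levels
    if len(levels) != 2:
        raise ValueError("bivariate simulation needs exactly two environment levels")
    n, m = G.n_samples, G.n_snps
    Z = _standardized(G)
    h1, h2 = cfg.h2_env
    if not (0.0 <= h1 <= 1.0 and 0.0 <= h2 <= 1.0):
        raise ValueError("per-environment heritabilities must lie in [0, 1]")
    rng = cfg.rng(_STREAM_EFFECTS)
    cov = np.array(
        [
            [h1 / m, cfg.rg * np.sqrt(h1 * h2) / m],
            [cfg.rg * np.sqrt(h1 * h2) / m, h2 / m],
        ]
    )
    L = np.linalg.cholesky(cov + 1e-18 * np.eye(2))
    effects = rng.standard_normal((m, 2)) @ L.T  # columns: env effects
    v = {levels[0]: effects[:, 0], levels[1]: effects[:, 1]}
    h_of = {levels[0]: h1, levels[1]: h2}

    g = np.zeros(n)
    eps = np.zeros(n)
    resid_rng = cfg.rng(_STREAM_RESID)
    resid_draw = resid_rng.standard_normal(n)
    for lev in levels:
        mask = env.levels == lev
        g[mask] = Z[mask] @ v[lev]
        eps[mask] = resid_draw[mask] * np.sqrt(1.0 - h_of[lev])
    tab = _covariate_table(cfg, env)
    y = g + _fixed_part(cfg, tab) + eps
    tab[trait] = y

    var_y = float(np.var(y, ddof=1))
    truth = TruthRecord(
        shared_effects=np.zeros(m),
        env_effects=v,
        realized_h2_g=0.0,
        realized_h2_ge=float(np.var(g, ddof=1)) / var_y,
        realized_resid=float(np.var(eps, ddof=1)) / var_y,
        ge_component=g,
        g_component=np.zeros(n),
        seed=cfg.seed,
    )
    return tab, truth


def spike_relatives(
    G: GenotypeMatrix, n_pairs: int, copy_fraction: float, seed: int
) -> GenotypeMatrix:
    """Plant related pairs: for pair t, individual 2t+1's genotype is
    rebuilt by copying each of individual 2t's two alleles with
    probability ``copy_fraction`` and redrawing from the allele frequency
    otherwise, giving an expected relationship of ~copy_fraction."""
    if not 0.0 <= copy_fraction <= 1.0:
        raise ValueError("copy_fraction must lie in [0, 1]")
    if n_pairs > G.n_samples // 2:
        raise ValueError("n_pairs exceeds n/2")
    p = G.true_freqs if G.true_freqs is not None else G.allele_freqs()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    dos = G.dosages.copy()
    m = G.n_snps
    for t in range(n_pairs):
        src, dst = 2 * t, 2 * t + 1
        x = dos[src]
        # split the source dosage into two allele draws
        a1 = np.where(x == 2, 1, np.where(x == 1, rng.integers(0, 2, m), 0)).astype(float)
        a2 = x - a1
        new = np.zeros(m)
        for a in (a1, a2):
            keep = rng.random(m) < copy_fraction
            fresh = (rng.random(m) < p).astype(float)
            new += np.where(keep, a, fresh)
        dos[dst] = new
    return GenotypeMatrix(dos, list(G.sample_ids), G.snps.copy(), true_freqs=G.true_freqs)


def write_dataset(
    G: GenotypeMatrix,
    table: pd.DataFrame,
    truth: TruthRecord,
    prefix: str | Path,
) -> None:
    """Write PLINK BED/BIM/FAM, the tab-separated sample table, and the
    per-SNP truth table."""
    prefix = Path(prefix)
    write_plink(G, prefix)
    table.to_csv(f"{prefix}.sample.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)
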