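"""End-to-end orchestration: QC -> adjustment -> GRM -> pruning ->
per-factor G x E REML across traits -> Bonferroni -> follow-up
(bivariate, scan, norms of reaction) for family-wise significant pairs.

Every stage writes its output under the configured directory so any
stage can be rerun in isolation, and the whole run is reproducible from
the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

from . import genio, grm, gxe_scan, nor, pheno, simulate, varcomp

__all__ = ["RunConfig", "RunSummary", "run_full_analysis", "compare_vg_with_without_gxe"]

log = logging.getLogger("gxeherit")


@dataclass
class RunConfig:
    """One analysis run, from files or from a simulation."""

    out_dir: str
    traits: list[str]
    factors: list[str] = field(default_factory=lambda: ["area"])
    transforms: dict = field(default_factory=dict)  # trait -> "identity" | "log"
    bfile: str | None = None
    pheno_file: str | None = None
    sim: simulate.SimConfig | None = None
    geno: float = 0.05
    maf: float = 0.01
    hwe: float = 1e-6
    prune: float = 0.025
    group_threshold: float = 0.020
    alpha: float = 0.05
    seed: int = 0
    follow_up: bool = True

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("at least one trait is required")
        if not self.factors:
            raise ValueError("at least one environmental factor is required")
        bad = set(self.factors) - set(pheno.VALID_FACTORS)
        if bad:
            raise ValueError(f"unknown factor(s): {sorted(bad)}")
        for name in ("geno", "maf", "hwe", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bfile is None and self.sim is None:
            raise ValueError("either a bfile prefix or a simulation config is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = simulate.SimConfig(**sim)
        return cls(sim=sim, **raw)


@dataclass
class RunSummary:
    results: pd.DataFrame  # trait, factor, estimates, LRT, p, significant
    threshold: float
    n_tests: int
    outputs: dict

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.results[self.results["significant"]]
        return list(zip(sig["trait"], sig["factor"]))


def _stage(name: str, t0: float, **info) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def _fit_pair(
    y: np.ndarray, A_g: grm.GRMatrix, factor: pheno.EnvFactor
) -> tuple[varcomp.VarCompResult, varcomp.VarCompResult, varcomp.LrtResult]:
    """Full (G + GxE) and reduced (G only) fits plus the boundary LRT."""
    factor.require_at_least(2)
    A_ge = grm.gxe_grm(A_g, factor)
    X = varcomp.design_matrix(factor.levels, len(y))
    full = varcomp.reml_fit(
        varcomp.ModelSpec(y, X, [("G", A_g.values), ("GxE", A_ge.values)])
    )
    reduced = varcomp.reml_fit(varcomp.ModelSpec(y, X, [("G", A_g.values)]))
    test = varcomp.lrt(full, reduced)
    return full, reduced, test


def run_full_analysis(cfg: RunConfig) -> RunSummary:
    """Execute the full pipeline described in the module docstring."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    t0 = time.time()

    # --- inputs -----------------------------------------------------------
    if cfg.sim is not None:
        G = simulate.simulate_genotypes(cfg.sim)
        env0 = simulate.assign_environments(cfg.sim, cfg.factors[0])
        table, truth = simulate.simulate_phenotype(G, env0, cfg.sim, trait=cfg.traits[0])
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
        for extra in cfg.traits[1:]:  # additional traits carry no interaction
            table[extra] = rng.standard_normal(G.n_samples)
        simulate.write_dataset(G, table, truth, out_dir / "sim")
        outputs["sim_prefix"] = str(out_dir / "sim")
    else:
        G, fam = genio.read_plink(cfg.bfile)
        table = pheno.read_sample_table(cfg.pheno_file)
        table = table.set_index("IID").loc[G.sample_ids].reset_index()
    _stage("input", t0, n=G.n_samples, m=G.n_snps)

    # --- marker QC --------------------------------------------------------
    t0 = time.time()
    G, report = genio.qc_filter(G, cfg.geno, cfg.maf, cfg.hwe)
    (out_dir / "qc_report.tsv").write_text(report.to_text())
    outputs["qc_report"] = str(out_dir / "qc_report.tsv")
    _stage("qc", t0, retained=report.n_retained)

    # --- phenotype adjustment --------------------------------------------
    t0 = time.time()
    strata = (
        table["AREA"].astype(str) + "x" + table["SEX"].astype(str)
    ).to_numpy()
    age = table["BIRTH_YEAR"].to_numpy(float)
    adjusted = {}
    for trait in cfg.traits:
        raw = table[trait].to_numpy(float)
        if cfg.transforms.get(trait, "identity") == "log":
            raw = np.log(raw)
        adjusted[trait] = pheno.adjust_age(raw, age, strata)
    adj_tab = table[["IID", "SEX", "AREA", "BIRTH_YEAR"]].copy()
    for trait, z in adjusted.items():
        adj_tab[trait] = z
    pheno.write_sample_table(adj_tab, out_dir / "adjusted.tsv")
    outputs["adjusted"] = str(out_dir / "adjusted.tsv")
    _stage("adjust", t0, traits=len(cfg.traits))

    # --- GRM and pruning --------------------------------------------------
    t0 = time.time()
    A = grm.compute_grm(G)
    grm.write_grm(A, out_dir / "grm")
    retained = grm.prune_related(A, cfg.prune)
    (out_dir / "unrelated.ids").write_text("\n".join(retained) + "\n")
    outputs["grm_prefix"] = str(out_dir / "grm")
    _stage("grm", t0, n_unrelated=len(retained))

    A_u = A.subset(retained)
    keep_mask = adj_tab["IID"].isin(retained).to_numpy()
    adj_u = adj_tab[keep_mask].set_index("IID").loc[retained].reset_index()

    # --- variance components per trait x factor ---------------------------
    t0 = time.time()
    n_tests = len(cfg.traits) * len(cfg.factors)
    threshold = gxe_scan.bonferroni_threshold(cfg.alpha, n_tests)
    rows = []
    fits: dict[tuple[str, str], tuple] = {}
    for factor_name in cfg.factors:
        factor = pheno.encode_env(adj_u, factor_name)
        for trait in cfg.traits:
            y = adj_u[trait].to_numpy(float)
            obs = ~np.isnan(y)
            ids_t = [s for s, o in zip(retained, obs) if o]
            full, reduced, test = _fit_pair(
                y[obs], A_u.subset(ids_t), pheno.EnvFactor(factor_name, factor.levels[obs])
            )
            fits[(trait, factor_name)] = (full, reduced, test)
            rows.append(
                {
                    "trait": trait,
                    "factor": factor_name,
                    "n": int(obs.sum()),
                    "vg_vp": full.proportion("G"),
                    "vg_vp_se": float(full.prop_ses[full.names.index("G")]),
                    "vge_vp": full.proportion("GxE"),
                    "vge_vp_se": float(full.prop_ses[full.names.index("GxE")]),
                    "vg_vp_nogxe": reduced.proportion("G"),
                    "lrt": test.statistic,
                    "p": test.p_value,
                    "significant": test.p_value < threshold,
                }
            )
            (out_dir / f"reml_{trait}_{factor_name}.hsq").write_text(
                full.to_hsq_text(test)
            )
    results = pd.DataFrame(rows)
    results.to_csv(out_dir / "varcomp_summary.tsv", sep="\t", index=False)
    outputs["varcomp_summary"] = str(out_dir / "varcomp_summary.tsv")
    _stage("varcomp", t0, n_tests=n_tests, significant=int(results["significant"].sum()))

    # --- follow-up on significant pairs -----------------------------------
    if cfg.follow_up:
        t0 = time.time()
        for trait, factor_name in zip(
            results.loc[results["significant"], "trait"],
            results.loc[results["significant"], "factor"],
        ):
            factor = pheno.encode_env(adj_u, factor_name)
            y = adj_u[trait].to_numpy(float)
            obs = ~np.isnan(y)
            lv = factor.unique_levels
            tag = f"{trait}_{factor_name}"
            if len(lv) == 2:
                ids = np.asarray(retained, dtype=object)
                s1 = pd.Series(
                    y[obs & (factor.levels == lv[0])],
                    index=ids[obs & (factor.levels == lv[0])],
                )
                s2 = pd.Series(
                    y[obs & (factor.levels == lv[1])],
                    index=ids[obs & (factor.levels == lv[1])],
                )
                try:
                    bv = varcomp.bivar_reml(s1, s2, A_u)
                    (out_dir / f"bivar_{tag}.json").write_text(
                        json.dumps(
                            {"rg": bv.rg, "rg_se": bv.rg_se, "vg1": bv.vg1,
                             "vg2": bv.vg2, "cov_g": bv.cov_g, "logL": bv.loglik},
                            indent=1,
                        )
                    )
                    outputs[f"bivar_{tag}"] = str(out_dir / f"bivar_{tag}.json")
                except ValueError as exc:
                    log.warning("bivariate follow-up skipped for %s: %s", tag, exc)
                # per-SNP scan needs genotype rows of retained samples
                pos = {s: i for i, s in enumerate(G.sample_ids)}
                ridx = [pos[s] for s in retained]
                G_u = genio.GenotypeMatrix(
                    G.dosages[ridx], retained, G.snps,
                    true_freqs=G.true_freqs,
                )
                tab = gxe_scan.scan(G_u, np.where(obs, y, np.nan), factor)
                tab.to_csv(out_dir / f"scan_{tag}.tsv", sep="\t", index=False)
                outputs[f"scan_{tag}"] = str(out_dir / f"scan_{tag}.tsv")
                n_hits = int((tab["P_GXE"] < 1e-3).sum())
                log.info("scan %s: %d SNPs with P < 0.001", tag, n_hits)
            try:
                groups = nor.build_genotype_groups(A_u, cfg.group_threshold)
                summary = nor.reaction_norm_summary(
                    groups, pd.Series(y, index=retained), factor
                )
                summary.to_csv(out_dir / f"nor_{tag}.tsv", sep="\t", index=False)
                outputs[f"nor_{tag}"] = str(out_dir / f"nor_{tag}.tsv")
            except ValueError as exc:
                log.warning("NoR follow-up skipped for %s: %s", tag, exc)
        _stage("follow_up", t0)

    summary = RunSummary(results, threshold, n_tests, outputs)
    results_path = out_dir / "run_summary.json"
    results_path.write_text(
        json.dumps(
            {
                "threshold": threshold,
                "n_tests": n_tests,
                "significant": [list(p) for p in summary.significant_pairs()],
                "outputs": outputs,
            },
            indent=1,
        )
    )
    return summary


def compare_vg_with_without_gxe(results: pd.DataFrame) -> tuple[pd.DataFrame, float | None]:
    """Paired V_G/V_P with and without the interaction component, plus
    their Pearson correlation across traits (omitted for < 3 traits)."""
    need = {"trait", "vg_vp", "vg_vp_nogxe"}
    if not need <= set(results.columns):
        raise ValueError(f"results table lacks columns {sorted(need)}")
    paired = results[["trait", "factor", "vg_vp", "vg_vp_nogxe"]].copy()
    if len(paired) < 3:
        return paired, None
    r = float(pearsonr(paired["vg_vp"], paired["vg_vp_nogxe"])[0])
    return paired, r
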