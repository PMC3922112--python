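"""Norms of reaction over GRM-derived genotype groups.

Genotypes cannot be replicated in a human cohort, but individuals with
high realized relationship can be grouped and treated as approximate
genetic replicates.  Hubs are the individuals with the most
above-threshold partners in the (pruned) GRM; each hub plus its partners
forms a genotype group, and individuals falling in more than one group
are excluded from all of them.  The norm of reaction is then the profile
of group mean phenotypes across environment levels; parallel profiles
indicate no interaction, crossing or diverging profiles indicate G x E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import GRMatrix
from .pheno import EnvFactor

__all__ = [
    "GenotypeGroup",
    "build_genotype_groups",
    "reaction_norm_summary",
    "snp_reaction_norm",
]


@dataclass
class GenotypeGroup:
    index: int
    hub_id: str
    member_ids: list[str]  # hub included


def build_genotype_groups(
    A: GRMatrix, threshold: float = 0.020, k: int = 3
) -> list[GenotypeGroup]:
    """Hub-based genotype groups from above-threshold GRM partners.

    Individuals are ranked by their number of strictly-above-threshold
    partners (one global ranking, ties by input order); the top ``k``
    become hubs.  A group is a hub plus all its partners; any individual
    appearing in two or more groups is then removed from all groups.
    """
    n = A.n
    adj = A.values > threshold
    np.fill_diagonal(adj, False)
    counts = adj.sum(axis=1)
    eligible = int((counts > 0).sum())
    if eligible < k:
        raise ValueError(
            f"only {eligible} individual(s) have an above-threshold partner; "
            f"cannot form {k} hubs"
        )
    order = np.argsort(-counts, kind="stable")  # ties keep input order
    hubs = [int(h) for h in order[:k]]

    raw_members = []
    for h in hubs:
        members = [h] + [int(j) for j in np.where(adj[h])[0]]
        raw_members.append(members)
    membership: dict[int, int] = {}
    for members in raw_members:
        for j in members:
            membership[j] = membership.get(j, 0) + 1
    groups = []
    for gi, (h, members) in enumerate(zip(hubs, raw_members)):
        kept = [j for j in members if membership[j] == 1]
        groups.append(
            GenotypeGroup(
                index=gi,
                hub_id=A.sample_ids[h],
                member_ids=[A.sample_ids[j] for j in kept],
            )
        )
    return groups


def reaction_norm_summary(
    groups: list[GenotypeGroup],
    y: pd.Series,
    env: EnvFactor,
    env_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Mean, SEM and count of the adjusted phenotype per group x level.

    ``y`` is indexed by sample id; ``env`` is aligned to ``env_ids`` (or
    to ``y``'s index if omitted).  Cells with no member in a level are
    kept with nan mean and flagged.
    """
    ids = list(y.index) if env_ids is None else list(env_ids)
    if len(ids) != len(env.levels):
        raise ValueError("environment factor does not align with sample ids")
    level_of = dict(zip(ids, env.levels))
    seen = set()
    for g in groups:
        overlap = seen & set(g.member_ids)
        if overlap:
            raise ValueError(f"groups are not disjoint (e.g. {sorted(overlap)[:3]})")
        seen |= set(g.member_ids)

    rows = []
    for g in groups:
        for lev in env.unique_levels:
            vals = np.array(
                [y.get(s, np.nan) for s in g.member_ids if level_of.get(s) == lev],
                dtype=float,
            )
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else np.nan)
            rows.append(
                {
                    "group": g.index,
                    "hub": g.hub_id,
                    "env": lev,
                    "mean": mean,
                    "sem": sem,
                    "n": n,
                    "missing_cell": n == 0,
                }
            )
    return pd.DataFrame(rows)


def snp_reaction_norm(
    dosage: np.ndarray, y: np.ndarray, env: EnvFactor
) -> pd.DataFrame:
    """Locus-specific norm of reaction: mean phenotype per genotype class
    (dosage 0/1/2) and environment level."""
    env.require_at_least(2)
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = sorted({int(d) for d in dosage[~np.isnan(dosage)]})
    if len(classes) == 1:
        import warnings

        warnings.warn("monomorphic SNP: single-class reaction norm", stacklevel=2)
    rows = []
    for c in classes:
        for lev in env.unique_levels:
            mask = (dosage == c) & (env.levels == lev) & ~np.isnan(y)
            vals = y[mask]
            n = len(vals)
            rows.append(
                {
                    "genotype": c,
                    "env": lev,
                    "mean": float(vals.mean()) if n else np.nan,
                    "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else np.nan),
                    "n": n,
                    "missing_cell": n == 0,
                }
            )
    return pd.DataFrame(rows)
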