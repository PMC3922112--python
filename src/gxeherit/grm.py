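"""Genetic relationship matrices.

The realized relationship between individuals j and k is estimated from
SNP dosages as

    A_jk = (1/N_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

summing over the N_jk SNPs non-missing in both individuals, with p_i the
sample frequency of the counted allele.  The same formula is used on the
diagonal.  The interaction relationship matrix for an environmental
factor is the same matrix with entries between individuals in different
environments set to zero.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genio import GenotypeMatrix
from .pheno import EnvFactor

__all__ = [
    "GRMatrix",
    "compute_grm",
    "prune_related",
    "gxe_grm",
    "write_grm",
    "read_grm",
]


@dataclass
class GRMatrix:
    """Symmetric n x n relationship matrix with per-pair SNP counts."""

    values: np.ndarray
    sample_ids: list[str]
    n_snps_used: np.ndarray  # per-pair count of jointly non-missing SNPs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match GRM order")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")
        self.n_snps_used = np.asarray(self.n_snps_used)
        if self.n_snps_used.shape != (n, n):
            raise ValueError("n_snps_used shape mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, ids: list[str]) -> "GRMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return GRMatrix(
            self.values[np.ix_(idx, idx)], list(ids), self.n_snps_used[np.ix_(idx, idx)]
        )


def compute_grm(G: GenotypeMatrix) -> GRMatrix:
    """Estimate the GRM from dosages with sample allele frequencies.

    SNPs monomorphic in the sample (p in {0, 1}) carry no information and
    are excluded with a warning; missing genotypes are handled through
    per-pair SNP counts rather than imputation.
    """
    p = G.allele_freqs()
    poly = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic SNP available for the GRM")
    if (~poly).any():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNP(s) from the GRM",
            stacklevel=2,
        )
    X = G.dosages[:, poly]
    p = p[poly]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    Z = (X - 2.0 * p) / denom
    obs = ~np.isnan(Z)
    Z = np.where(obs, Z, 0.0)
    raw = Z @ Z.T
    if obs.all():
        counts = np.full(raw.shape, Z.shape[1], dtype=np.int64)
    else:
        O = obs.astype(np.float64)
        counts = np.rint(O @ O.T).astype(np.int64)
    if (counts == 0).any():
        raise ValueError("some sample pair shares no non-missing SNP")
    values = raw / counts
    values = (values + values.T) / 2.0  # exact symmetry
    return GRMatrix(values, list(G.sample_ids), counts)


def prune_related(A: GRMatrix, cutoff: float = 0.025) -> list[str]:
    """Greedy pruning of related individuals.

    Repeatedly drops the individual involved in the largest number of
    above-cutoff pairs (among ties, the one latest in input order) until
    no retained pair exceeds ``cutoff``.  Returns retained sample ids in
    input order.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    n = A.n
    adj = A.values > cutoff
    np.fill_diagonal(adj, False)
    active = np.ones(n, dtype=bool)
    while True:
        counts = (adj & active[None, :]).sum(axis=1)
        counts[~active] = 0
        worst = counts.max()
        if worst == 0:
            break
        # drop the latest-indexed individual among those with max count
        drop = int(np.where(counts == worst)[0][-1])
        active[drop] = False
    if active.sum() < 2:
        raise ValueError("pruning left fewer than 2 individuals")
    return [s for s, a in zip(A.sample_ids, active) if a]


def gxe_grm(A: GRMatrix, env: EnvFactor) -> GRMatrix:
    """Environment-masked interaction GRM: entries between individuals in
    different environments are zero, same-environment entries (including
    the diagonal) equal the input."""
    if len(env.levels) != A.n:
        raise ValueError("environment factor does not cover the GRM samples")
    same = env.levels[:, None] == env.levels[None, :]
    return GRMatrix(np.where(same, A.values, 0.0), list(A.sample_ids), A.n_snps_used)


def write_grm(A: GRMatrix, prefix: str | Path) -> None:
    """Write GCTA text format: <prefix>.grm.gz (lower triangle incl.
    diagonal: j, k, N_jk, A_jk, 1-based) and <prefix>.grm.id."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = A.n
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for j in range(n):
            for k in range(j + 1):
                fh.write(f"{j + 1}\t{k + 1}\t{A.n_snps_used[j, k]}\t{A.values[j, k]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in A.sample_ids:
            fh.write(f"{s}\t{s}\n")


def read_grm(prefix: str | Path) -> GRMatrix:
    """Read the GCTA text GRM format written by :func:`write_grm`."""
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for line in fh:
            j_s, k_s, n_s, a_s = line.split()
            j, k = int(j_s) - 1, int(k_s) - 1
            values[j, k] = values[k, j] = float(a_s)
            counts[j, k] = counts[k, j] = int(n_s)
    return GRMatrix(values, ids, counts)
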