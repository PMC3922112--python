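"""PLINK 1 binary genotype IO and marker quality control.

Genotypes are held as an n x m dosage matrix counting copies of the A1
allele of the .bim file (0, 1, 2, with ``nan`` for missing).  The QC
filters are the standard marker filters applied before a GREML analysis:
per-SNP missingness, minor allele frequency, and the Hardy-Weinberg
exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "hwe_exact_p",
    "qc_filter",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 magic + SNP-major flag

# 2-bit code -> dosage of the A1 allele (PLINK 1 convention)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_BIM_COLS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]
_FAM_COLS = ["fid", "iid", "father", "mother", "sex", "pheno"]


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam file is missing or malformed."""


@dataclass
class GenotypeMatrix:
    """n individuals x m SNPs dosage matrix with marker metadata.

    Parameters
    ----------
    dosages
        Float array of shape (n, m); entries in {0, 1, 2} or nan.
    sample_ids
        Unique individual identifiers, in row order.
    snps
        DataFrame with columns chrom, snp_id, cm, pos, a1, a2 in column
        order.
    true_freqs
        Optional per-SNP generating allele frequencies; present only for
        simulated data, where the generator knows them.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snps: pd.DataFrame
    true_freqs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snps) != m:
            raise ValueError("snps table length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Sample frequency of the counted (A1) allele per SNP."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fracs(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def genotype_counts(self) -> np.ndarray:
        """(m, 3) counts of dosage 2/1/0 (A1A1, A1A2, A2A2) per SNP."""
        counts = np.empty((self.n_snps, 3), dtype=int)
        for g, col in zip((2.0, 1.0, 0.0), range(3)):
            counts[:, col] = np.sum(self.dosages == g, axis=0)
        return counts

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        tf = None if self.true_freqs is None else self.true_freqs[mask]
        return GenotypeMatrix(
            self.dosages[:, mask],
            list(self.sample_ids),
            self.snps.loc[mask].reset_index(drop=True),
            true_freqs=tf,
        )


@dataclass
class QCReport:
    """Per-filter removal counts; a SNP is attributed to the first filter
    that removes it, in the order missingness -> MAF -> HWE."""

    n_input: int
    removed_missing: int
    removed_maf: int
    removed_hwe: int
    n_retained: int
    miss_max: float
    maf_min: float
    hwe_min: float

    def __post_init__(self) -> None:
        removed = self.removed_missing + self.removed_maf + self.removed_hwe
        if removed + self.n_retained != self.n_input:
            raise ValueError("QC accounting does not balance")

    def to_text(self) -> str:
        lines = [
            "filter\tthreshold\tremoved",
            f"missingness\t>{self.miss_max}\t{self.removed_missing}",
            f"maf\t<{self.maf_min}\t{self.removed_maf}",
            f"hwe\t<{self.hwe_min}\t{self.removed_hwe}",
            f"retained\t-\t{self.n_retained}",
        ]
        return "\n".join(lines) + "\n"


def _decode_table() -> np.ndarray:
    """256 x 4 lookup: byte -> four dosages (individuals packed LSB-first)."""
    byte = np.arange(256, dtype=np.uint8)
    codes = np.stack([(byte >> (2 * i)) & 3 for i in range(4)], axis=1)
    return _CODE_TO_DOSAGE[codes]


_DECODE = _decode_table()


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PLINK 1 binary fileset ``prefix``.bed/.bim/.fam.

    Returns the genotype matrix (dosage of the A1 allele) and the .fam
    table as a sample-table stub.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise PlinkFormatError(f"missing file: {prefix.with_suffix(ext)}")

    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None, names=_BIM_COLS,
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None, names=_FAM_COLS,
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes (not SNP-major PLINK 1)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: expected {expected} bytes, got {len(raw)}"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    per_snp = payload.reshape(m, bytes_per_snp)
    dosages = _DECODE[per_snp].reshape(m, bytes_per_snp * 4)[:, :n].T.copy()
    G = GenotypeMatrix(dosages, list(fam["iid"]), bim)
    return G, fam


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``G`` as a PLINK 1 binary fileset (SNP-major, zero padding)."""
    if G.n_snps == 0 or G.n_samples == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n, m = G.n_samples, G.n_snps
    bytes_per_snp = (n + 3) // 4
    # dosage -> 2-bit code; padding individuals get code 0
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    X = G.dosages.T
    code = np.where(np.isnan(X), 1, np.select([X == 2, X == 1, X == 0], [0, 2, 3]))
    codes[:, :n] = code
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())
    G.snps[_BIM_COLS].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )
    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def hwe_exact_p(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Enumerates all heterozygote counts compatible with the observed
    allele counts and sums the conditional probabilities of tables no
    more probable than the observed one.
    """
    if min(n_aa_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("HWE test undefined for zero genotypes")
    rare = 2 * min(n_aa_hom1, n_hom2) + n_het  # rare-allele copy count
    # heterozygote counts share the parity of the rare allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    if len(het_values) == 1:
        return 1.0
    # unnormalized conditional probabilities via the standard recurrence,
    # anchored at the modal het count for numerical stability
    probs = np.zeros(len(het_values))
    mode_idx = int(np.argmin(np.abs(het_values - rare * (2 * n - rare) / (2.0 * n))))
    probs[mode_idx] = 1.0
    for i in range(mode_idx, len(het_values) - 1):
        het = het_values[i]
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        # P(het+2) / P(het)
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
    for i in range(mode_idx, 0, -1):
        het = het_values[i]
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        # P(het-2) / P(het)
        probs[i - 1] = probs[i] * het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(het_values, n_het))]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    G: GenotypeMatrix,
    miss_max: float = 0.05,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker QC: missingness > miss_max, then MAF < maf_min, then
    HWE exact p < hwe_min.  The sample set is unchanged."""
    for name, thr in (("miss_max", miss_max), ("maf_min", maf_min), ("hwe_min", hwe_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")

    m = G.n_snps
    keep = np.ones(m, dtype=bool)

    fail_miss = G.missing_fracs() > miss_max
    keep &= ~fail_miss

    freqs = G.allele_freqs()
    maf = np.minimum(freqs, 1.0 - freqs)
    maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing SNP: monomorphic by fiat
    fail_maf = keep & (maf < maf_min)
    keep &= ~fail_maf

    counts = G.genotype_counts()
    fail_hwe = np.zeros(m, dtype=bool)
    for i in np.where(keep)[0]:
        if counts[i].sum() == 0:
            continue
        if hwe_exact_p(*counts[i]) < hwe_min:
            fail_hwe[i] = True
    keep &= ~fail_hwe

    if not keep.any():
        raise ValueError("quality control removed every SNP")

    report = QCReport(
        n_input=m,
        removed_missing=int(fail_miss.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        n_retained=int(keep.sum()),
        miss_max=miss_max,
        maf_min=maf_min,
        hwe_min=hwe_min,
    )
    return G.subset_snps(keep), report
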