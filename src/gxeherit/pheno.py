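"""Phenotype adjustment and environmental-factor encoding.

Raw quantitative traits are regressed on age within each cohort x sex
stratum and the residuals standardized to z-scores, so that the mixed
model downstream needs no further fixed effects for these covariates.
Three environmental factors are supported: geographical area (levels
"1"/"2"), sex ("A" = male, "B" = female), and birth-year band
("A" 1931-45, "B" 1946-55, "C" 1956-63).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnvFactor", "adjust_age", "encode_env", "SAMPLE_TABLE_COLUMNS"]

#: canonical sample-table columns (tab-separated on disk)
SAMPLE_TABLE_COLUMNS = ["IID", "SEX", "AREA", "BIRTH_YEAR"]

VALID_FACTORS = ("area", "sex", "age_group")


@dataclass
class EnvFactor:
    """One environmental factor: a level label per sample, in sample order."""

    name: str
    levels: np.ndarray  # dtype object/str, length n

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=object)
        if self.levels.ndim != 1:
            raise ValueError("levels must be one-dimensional")

    @property
    def n_levels(self) -> int:
        return len(self.unique_levels)

    @property
    def unique_levels(self) -> list:
        # stable order of first appearance
        seen: dict = {}
        for v in self.levels:
            seen.setdefault(v, None)
        return list(seen)

    def require_at_least(self, k: int) -> None:
        if self.n_levels < k:
            raise ValueError(
                f"factor '{self.name}' has {self.n_levels} observed level(s); "
                f"{k} required"
            )

    def indicator(self, level) -> np.ndarray:
        return (self.levels == level).astype(float)


def adjust_age(
    y: np.ndarray, age: np.ndarray, strata: np.ndarray
) -> np.ndarray:
    """Regress a trait on age within each stratum and z-score the residuals.

    Within every stratum independently, fit ordinary least squares
    y = b0 + b1*age + e and return e / sd(e) (sample sd, n-1 denominator).
    Missing phenotype entries propagate as nan and are excluded from the
    fit.  A stratum with constant phenotype (zero residual variance) is an
    error, as its z-scores would be undefined.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    strata = np.asarray(strata)
    if not (len(y) == len(age) == len(strata)):
        raise ValueError("y, age, strata must have equal length")

    out = np.full(len(y), np.nan)
    for s in pd.unique(strata):
        in_s = strata == s
        obs = in_s & ~np.isnan(y) & ~np.isnan(age)
        n_obs = int(obs.sum())
        if n_obs < 3:
            raise ValueError(f"stratum {s!r}: fewer than 3 observed samples")
        X = np.column_stack([np.ones(n_obs), age[obs]])
        # lstsq handles constant age (rank-deficient -> plain centering)
        beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = y[obs] - X @ beta
        sd = resid.std(ddof=1)
        if sd < 1e-12:
            raise ValueError(
                f"stratum {s!r}: residual variance is zero; z-scores undefined"
            )
        out[obs] = resid / sd
    return out


def _age_band(birth_year: np.ndarray) -> np.ndarray:
    """Birth-year bands: <=1945 'A', 1946-1955 'B', >=1956 'C'."""
    by = np.asarray(birth_year, dtype=float)
    out = np.where(by <= 1945, "A", np.where(by <= 1955, "B", "C"))
    return out.astype(object)


def encode_env(samples: pd.DataFrame, factor_name: str) -> EnvFactor:
    """Build an :class:`EnvFactor` from a sample table.

    ``area`` and ``sex`` are taken verbatim from the AREA / SEX columns;
    ``age_group`` is derived from BIRTH_YEAR by the three-band rule.
    Birth years outside 1931-1963 are still assigned by the same band
    arithmetic, with a warning.
    """
    if factor_name not in VALID_FACTORS:
        raise ValueError(f"unknown factor {factor_name!r}; expected one of {VALID_FACTORS}")
    if factor_name == "area":
        if "AREA" not in samples:
            raise ValueError("sample table lacks an AREA column")
        levels = samples["AREA"].astype(str).to_numpy(dtype=object)
    elif factor_name == "sex":
        if "SEX" not in samples:
            raise ValueError("sample table lacks a SEX column")
        levels = samples["SEX"].astype(str).to_numpy(dtype=object)
    else:
        if "BIRTH_YEAR" not in samples:
            raise ValueError("sample table lacks a BIRTH_YEAR column")
        by = samples["BIRTH_YEAR"].to_numpy(dtype=float)
        outside = (by < 1931) | (by > 1963)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} birth year(s) outside 1931-1963; "
                "assigned by the same band arithmetic",
                stacklevel=2,
            )
        levels = _age_band(by)
    return EnvFactor(factor_name, levels)


def read_sample_table(path) -> pd.DataFrame:
    """Read the tab-separated sample table (IID, SEX, AREA, BIRTH_YEAR, traits...)."""
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    missing = [c for c in ("IID",) if c not in df.columns]
    if missing:
        raise ValueError(f"sample table lacks column(s): {missing}")
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
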