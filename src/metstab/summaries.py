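"""Annual yield and protein accumulation, correlation and PCA reporting.

Annual totals follow the accumulation rule of staged-harvest trials: the
annual total dry weight of a genotype is the sum of its per-harvest mean
TDW over the wet-season harvests plus over the dry-season (stress regime)
harvests; annual crude protein content adds the wet and dry seasonal CP
means; annual crude protein yield is their product. Unit conversions
(per-plant to per-hectare, output multiplier for CPY) are configuration
constants because they depend on planting density.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .trial_io import TrialRecord, load_table5, records_to_frame

__all__ = [
    "annual_tdw", "annual_cp", "cpy", "annual_yield_table",
    "table5_summary", "pearson_matrix", "correlation_pca",
]


def _harvest_means(frame: pd.DataFrame, genotype: str, regime: str,
                   trait: str) -> pd.Series:
    sub = frame[(frame["genotype"] == genotype) & (frame["regime"] == regime)
                & (frame["trait"] == trait)]
    if sub.empty:
        raise ContractError(
            f"no {trait} records for genotype {genotype!r} in regime {regime!r}")
    return sub.groupby("harvest")["value"].mean()


def annual_tdw(records: Iterable[TrialRecord], genotype: str,
               dry_regime: str, area_scale: float = 1.0) -> float:
    """Annual total dry weight: summed per-harvest means, wet + dry season.

    ``area_scale`` converts per-plant units to t/ha/year (planting-density
    dependent, default 1).
    """
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    wet = _harvest_means(frame, genotype, "wet", "TDW")
    dry = _harvest_means(frame, genotype, dry_regime, "TDW")
    return float(area_scale * (wet.sum() + dry.sum()))


def annual_cp(records: Iterable[TrialRecord], genotype: str,
              dry_regime: str) -> float:
    """Annual crude protein content: wet-season mean CP plus dry-season mean CP."""
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    wet = _harvest_means(frame, genotype, "wet", "CP")
    dry = _harvest_means(frame, genotype, dry_regime, "CP")
    return float(wet.mean() + dry.mean())


def cpy(annual_cp_value: float, annual_tdw_value: float,
        unit_multiplier: float = 1.0) -> float:
    """Annual crude protein yield: annual CP times annual TDW."""
    if annual_cp_value < 0 or annual_tdw_value < 0:
        raise ContractError("annual CP and TDW must be >= 0")
    return unit_multiplier * annual_cp_value * annual_tdw_value


def annual_yield_table(records: Iterable[TrialRecord], dry_regime: str,
                       area_scale: float = 1.0,
                       unit_multiplier: float = 1.0) -> pd.DataFrame:
    """Per-genotype annual TDW (and CPY when CP records exist)."""
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    genotypes = sorted(frame["genotype"].unique())
    rows = []
    has_cp = (frame["trait"] == "CP").any()
    for geno in genotypes:
        tdw = annual_tdw(frame, geno, dry_regime, area_scale)
        row = {"genotype": geno, "annual_tdw": tdw}
        if has_cp:
            cp = annual_cp(frame, geno, dry_regime)
            row["annual_cp"] = cp
            row["cpy"] = cpy(cp, tdw, unit_multiplier)
        rows.append(row)
    return pd.DataFrame(rows).set_index("genotype")


def table5_summary(fixture: pd.DataFrame | None = None,
                   regime: str = "MWS") -> tuple[float, float, float]:
    """(mean, min, max) of the published annual TDW column for one regime."""
    if fixture is None:
        fixture = load_table5()
    col = {"MWS": "mws_tdw", "SWS": "sws_tdw"}.get(regime)
    if col is None:
        raise ContractError(f"regime must be MWS or SWS, got {regime!r}")
    vals = fixture[col].to_numpy(float)
    return float(vals.mean()), float(vals.min()), float(vals.max())


def pearson_matrix(trait_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with t-test p-values (n - 2 df).

    Rows are genotypes, columns traits. Zero-variance traits yield NaN
    entries. Returns (r matrix, p matrix), both symmetric with unit /
    zero diagonals.
    """
    n, p = trait_table.shape
    if n < 3 or p < 2:
        raise ContractError("need >= 3 genotypes and >= 2 traits")
    x = trait_table.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
        t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
        pvals = 2 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(pvals, 0.0)
    cols = trait_table.columns
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(pvals, index=cols, columns=cols))


def correlation_pca(trait_table: pd.DataFrame):
    """PCA on the trait correlation matrix.

    Constant traits are dropped with a warning. Returns (scores, loadings,
    variance_explained); loadings are orthonormal eigenvectors and the
    variance-explained fractions sum to 1.
    """
    if len(trait_table) < 3:
        raise ContractError("need >= 3 genotypes")
    keep = []
    for col in trait_table.columns:
        if trait_table[col].std(ddof=1) > 0:
            keep.append(col)
        else:
            warnings.warn(f"trait {col!r} is constant and dropped from PCA",
                          stacklevel=2)
    if len(keep) < 2:
        raise ContractError("need >= 2 traits with nonzero variance")
    x = trait_table[keep].to_numpy(float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[lead, j] < 0:
            eigvec[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    scores = pd.DataFrame(z @ eigvec, index=trait_table.index, columns=pcs)
    loadings = pd.DataFrame(eigvec, index=keep, columns=pcs)
    return scores, loadings, eigval / eigval.sum()
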