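"""Variance components, coefficients of variation and broad-sense heritability.

Genotypic variance is estimated by the expected-mean-squares method from a
balanced genotype (+ harvest) ANOVA on one regime's data:

    sigma2_e = MS_residual
    sigma2_g = max(0, (MS_genotype - MS_residual) / r)

with r observations per genotype. The derived summaries are

    GCV% = 100 * sqrt(sigma2_g) / mean
    PCV% = 100 * sqrt(sigma2_g + sigma2_e) / mean
    H2%  = 100 * sigma2_g / (sigma2_g + sigma2_e)

on a plot basis (no interaction variance enters the phenotypic variance).
All three are invariant to rescaling the data by a positive constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .anova import fit_factorial_anova
from .errors import ContractError
from .trial_io import TrialRecord, records_to_frame

__all__ = [
    "VarianceComponents", "estimate_components", "gcv", "pcv", "heritability",
    "genetic_summary",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Genotypic, residual and phenotypic variance for one trait."""

    sigma2_g: float
    sigma2_e: float
    grand_mean: float
    r: int                      # observations per genotype used in estimation
    truncated: bool = False     # negative moment estimate clamped at zero

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_e


def estimate_components(anova: pd.DataFrame, r: int,
                        genotype_term: str = "genotype") -> VarianceComponents:
    """Method-of-moments variance components from a fitted ANOVA table."""
    if r < 1:
        raise ContractError("replication count r must be >= 1")
    for term in (genotype_term, "residual"):
        if term not in anova.index:
            raise ContractError(f"ANOVA table lacks required term {term!r}")
    ms_g = float(anova.loc[genotype_term, "mean_sq"])
    ms_e = float(anova.loc["residual", "mean_sq"])
    if not math.isfinite(ms_e):
        raise ContractError("residual mean square is undefined (zero df)")
    raw = (ms_g - ms_e) / r
    truncated = raw < 0
    return VarianceComponents(
        sigma2_g=max(raw, 0.0), sigma2_e=ms_e,
        grand_mean=float(anova.attrs.get("grand_mean", np.nan)),
        r=r, truncated=truncated)


def gcv(vc: VarianceComponents) -> float:
    """Genotypic coefficient of variation, percent of the grand mean."""
    if not vc.grand_mean > 0:
        raise ContractError("grand mean must be > 0 for GCV")
    return 100.0 * math.sqrt(vc.sigma2_g) / vc.grand_mean


def pcv(vc: VarianceComponents) -> float:
    """Phenotypic coefficient of variation, percent of the grand mean."""
    if not vc.grand_mean > 0:
        raise ContractError("grand mean must be > 0 for PCV")
    return 100.0 * math.sqrt(vc.sigma2_p) / vc.grand_mean


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability in percent; NaN when total variance is zero."""
    if vc.sigma2_p == 0:
        return float("nan")
    return 100.0 * vc.sigma2_g / vc.sigma2_p


def genetic_summary(records: Iterable[TrialRecord], trait: str,
                    regime: str) -> dict:
    """One row of the per-trait genetic variation summary for one regime.

    Returns mean, min, max over raw observations plus PCV%, GCV% and H2%.
    The genotype mean square comes from a genotype (x harvest, when several
    harvests are present) factorial on the regime subset.
    """
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    sub = frame[(frame["trait"] == trait) & (frame["regime"] == regime)]
    if sub.empty:
        raise ContractError(f"no observations for trait {trait!r} in regime {regime!r}")
    values = sub["value"].to_numpy(float)
    if np.ptp(values) == 0:
        # degenerate constant data: no variance of any kind
        vc = VarianceComponents(0.0, 0.0, float(values.mean()),
                                r=len(sub) // sub["genotype"].nunique())
        return {"trait": trait, "regime": regime, "mean": float(values.mean()),
                "min": float(values.min()), "max": float(values.max()),
                "pcv": 0.0, "gcv": 0.0, "h2": float("nan"),
                "sigma2_g": 0.0, "sigma2_e": 0.0, "truncated": False}
    factors = ["genotype"]
    if sub["harvest"].nunique() > 1:
        factors.append("harvest")
    table = fit_factorial_anova(sub, trait, factors)
    if table.loc["residual", "df"] == 0 and "genotype:harvest" in table.index:
        # single replicate per genotype x harvest cell: the interaction is
        # the only error stratum, so pool it into the residual
        df_pool = int(table.loc["genotype:harvest", "df"] + table.loc["residual", "df"])
        ss_pool = float(table.loc["genotype:harvest", "sum_sq"]
                        + table.loc["residual", "sum_sq"])
        table = table.drop(index="genotype:harvest")
        table.loc["residual", ["df", "sum_sq", "mean_sq"]] = [
            df_pool, ss_pool, ss_pool / df_pool if df_pool else np.nan]
    r = len(sub) // sub["genotype"].nunique()
    vc = estimate_components(table, r)
    return {"trait": trait, "regime": regime,
            "mean": float(values.mean()),
            "min": float(values.min()), "max": float(values.max()),
            "pcv": pcv(vc), "gcv": gcv(vc), "h2": heritability(vc),
            "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e,
            "truncated": vc.truncated}
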