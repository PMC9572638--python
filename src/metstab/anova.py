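"""Balanced factorial ANOVA with LSD mean separation and variance checks.

The model is the full factorial

    Y = mu + G + T + H + G:T + G:H + T:H + G:T:H + error

over genotype, water-stress treatment and harvest round, fitted on balanced
data only. Sums of squares come from the classical balanced-design
decomposition (marginal means with inclusion-exclusion); every term is
tested against the residual mean square. Wet-season analyses typically drop
the treatment factor, which is done by passing a two-factor list.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, UnbalancedDataError
from .trial_io import TrialRecord, records_to_frame

__all__ = [
    "fit_factorial_anova", "lsd_value", "letter_display", "cv_percent",
    "bartlett_check", "MeanSeparation",
]

DEFAULT_FACTORS = ("genotype", "regime", "harvest")


def _term_name(factors: Sequence[str]) -> str:
    return ":".join(factors)


def _check_balance(frame: pd.DataFrame, factors: Sequence[str]) -> int:
    counts = frame.groupby(list(factors), observed=True).size()
    full = np.prod([frame[f].nunique() for f in factors])
    if len(counts) != full or counts.nunique() != 1:
        bad = counts[counts != counts.max()]
        raise UnbalancedDataError(
            "design is not balanced over "
            f"{tuple(factors)}; offending cells: {bad.to_dict() if len(bad) else 'missing cells'}")
    return int(counts.iloc[0])


def fit_factorial_anova(records: Iterable[TrialRecord], trait: str,
                        factors: Sequence[str] = DEFAULT_FACTORS) -> pd.DataFrame:
    """Fit the balanced factorial ANOVA for one trait.

    Returns a table indexed by term (main effects, all interactions,
    ``residual`` and ``total``) with columns ``df``, ``sum_sq``,
    ``mean_sq``, ``F`` and ``p``. F statistics test each term against the
    residual mean square; with zero residual degrees of freedom they are
    reported as NaN (not applicable).
    """
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    frame = frame[frame["trait"] == trait]
    if frame.empty:
        raise ContractError(f"no observations for trait {trait!r}")
    for f in factors:
        if frame[f].nunique() < 2:
            raise ContractError(f"factor {f!r} needs >= 2 levels")
    n_per_cell = _check_balance(frame, factors)

    y = frame["value"].to_numpy(float)
    n_total = len(y)
    grand_mean = y.mean()
    total_ss = float(((y - grand_mean) ** 2).sum())

    # Effect of term S at each level combination, by inclusion-exclusion on
    # marginal means; for balanced data SS_S = (obs per combination) * sum
    # of squared effects.
    effects: dict[tuple[str, ...], pd.Series] = {}
    rows = {}
    levels = {f: frame[f].nunique() for f in factors}
    for order in range(1, len(factors) + 1):
        for subset in combinations(factors, order):
            marg = frame.groupby(list(subset), observed=True)["value"].mean() - grand_mean
            eff = marg.copy()
            for sub_order in range(1, order):
                for sub in combinations(subset, sub_order):
                    sub_eff = effects[sub]
                    idx = marg.index.to_frame(index=False)
                    aligned = sub_eff.loc[
                        pd.MultiIndex.from_frame(idx[list(sub)])
                        if len(sub) > 1 else idx[sub[0]]
                    ].to_numpy()
                    eff = eff - aligned
            effects[subset] = eff
            reps = n_total // int(np.prod([levels[f] for f in subset]))
            ss = float(reps * (eff.to_numpy() ** 2).sum())
            df = int(np.prod([levels[f] - 1 for f in subset]))
            rows[_term_name(subset)] = (df, ss)

    model_df = sum(df for df, _ in rows.values())
    model_ss = sum(ss for _, ss in rows.values())
    resid_df = n_total - 1 - model_df
    resid_ss = max(total_ss - model_ss, 0.0)
    rows["residual"] = (resid_df, resid_ss)

    table = pd.DataFrame(
        [(term, df, ss) for term, (df, ss) in rows.items()],
        columns=["term", "df", "sum_sq"]).set_index("term")
    table["mean_sq"] = table["sum_sq"] / table["df"].replace(0, np.nan)
    ms_err = table.loc["residual", "mean_sq"]
    if resid_df > 0 and ms_err > 0:
        f_stat = table["mean_sq"] / ms_err
        f_stat.loc["residual"] = np.nan
        pvals = stats.f.sf(f_stat, table["df"], resid_df)
    else:
        f_stat = pd.Series(np.nan, index=table.index)
        pvals = np.full(len(table), np.nan)
    table["F"] = f_stat
    table["p"] = pvals
    table.loc["total"] = [n_total - 1, total_ss, np.nan, np.nan, np.nan]
    table.attrs["grand_mean"] = grand_mean
    table.attrs["n_per_cell"] = n_per_cell
    return table


def lsd_value(ms_error: float, df_error: int, n_per_mean: int,
              alpha: float = 0.05) -> float:
    """Fisher's least significant difference for comparing two group means.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * ms_error / n_per_mean).
    """
    if not 0.0 < alpha < 1.0:
        raise ContractError("alpha must be in (0, 1)")
    if df_error < 1 or n_per_mean < 1:
        raise ContractError("df_error and n_per_mean must be >= 1")
    if ms_error < 0:
        raise ContractError("ms_error must be >= 0")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df_error)
    return float(t_crit * np.sqrt(2.0 * ms_error / n_per_mean))


@dataclass(frozen=True)
class MeanSeparation:
    """Compact letter display for a set of group means at a given LSD."""

    means: dict          # group -> mean, in descending mean order
    letters: dict        # group -> letter string
    lsd: float
    alpha: float


def letter_display(means: Mapping[str, float], lsd: float,
                   alpha: float = 0.05) -> MeanSeparation:
    """Assign significance letters by the insert-and-absorb algorithm.

    Means are sorted descending; two groups share a letter iff their
    difference is at most the LSD.
    """
    if not means:
        raise ContractError("at least one group is required")
    order = sorted(means, key=lambda g: -means[g])
    vals = [means[g] for g in order]
    n = len(order)
    # maximal intervals [i, j] with vals[i] - vals[j] <= lsd
    intervals = []
    for i in range(n):
        j = i
        while j + 1 < n and vals[i] - vals[j + 1] <= lsd:
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                          for o in intervals)]
    # keep first occurrence order; absorb duplicates
    seen = []
    for iv in maximal:
        if iv not in seen:
            seen.append(iv)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for idx, (i, j) in enumerate(seen):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for pos in range(i, j + 1):
            letters[order[pos]] += letter
    return MeanSeparation({g: means[g] for g in order}, letters, lsd, alpha)


def cv_percent(ms_error: float, grand_mean: float) -> float:
    """Experimental coefficient of variation, 100 * sqrt(MS_error) / mean."""
    if grand_mean == 0:
        raise ContractError("grand mean must be nonzero for CV%")
    if ms_error < 0:
        raise ContractError("ms_error must be >= 0")
    return float(100.0 * np.sqrt(ms_error) / grand_mean)


def bartlett_check(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Bartlett's test of homogeneity of variances across groups.

    Returns (chi-square statistic on k-1 df, p-value). Zero-variance groups
    are rejected because the statistic's log-variance terms are undefined.
    """
    if len(groups) < 2:
        raise ContractError("need >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    for i, arr in enumerate(arrays):
        if len(arr) < 2:
            raise ContractError(f"group {i} needs >= 2 values")
        if np.var(arr, ddof=1) == 0:
            raise ContractError(
                f"group {i} has zero variance; Bartlett's statistic is undefined")
    stat, p = stats.bartlett(*arrays)
    return float(stat), float(p)
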