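"""AMMI decomposition of genotype-by-environment tables and stability ranking.

The additive main effects and multiplicative interaction (AMMI) model for a
genotype x environment cell-mean table Y is

    Y_ij = mu + g_i + e_j + sum_k lambda_k * alpha_ik * gamma_jk + resid_ij

where mu is the grand mean, g and e are sum-to-zero genotype and
environment main effects, and the multiplicative terms are the SVD of the
doubly-centered interaction matrix Z = Y - mu - g - e. Environments here
are harvest rounds within one water regime.

Stability statistics:

    ASV_i = sqrt( ((SS_IPC1 / SS_IPC2) * s_i1)^2 + s_i2^2 )
    YSI_i = rank(ASV ascending) + rank(mean yield descending)

with s_ik the genotype score on interaction principal component k, scaled
symmetrically as alpha_ik * sqrt(lambda_k). Small ASV = stable across
environments; small YSI = both stable and high-yielding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .trial_io import TrialRecord, records_to_frame

__all__ = [
    "CellMeanMatrix", "AMMIFit", "fit_ammi", "ammi_anova", "asv",
    "stability_ranking", "cell_means",
]


@dataclass(frozen=True)
class CellMeanMatrix:
    """Genotype x environment mean-yield table (no missing cells)."""

    genotypes: tuple[str, ...]
    environments: tuple[str, ...]
    means: np.ndarray           # shape (n_genotypes, n_environments)
    replication: int = 1        # plot-level observations behind each cell

    def __post_init__(self):
        means = np.asarray(self.means, float)
        object.__setattr__(self, "means", means)
        n, m = means.shape
        if n != len(self.genotypes) or m != len(self.environments):
            raise ContractError("means shape does not match the label lists")
        if not np.isfinite(means).all():
            raise ContractError("cell-mean matrix has missing/non-finite cells")
        if n < 3 or m < 3:
            raise ContractError("need >= 3 genotypes and >= 3 environments")


def cell_means(records: Iterable[TrialRecord], trait: str, regime: str,
               ) -> CellMeanMatrix:
    """Average replicates into a genotype x harvest cell-mean matrix."""
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    sub = frame[(frame["trait"] == trait) & (frame["regime"] == regime)]
    if sub.empty:
        raise ContractError(f"no records for trait {trait!r}, regime {regime!r}")
    pivot = sub.pivot_table(index="genotype", columns="harvest",
                            values="value", aggfunc="mean")
    if pivot.isna().any().any():
        missing = [(g, h) for (g, h) in
                   zip(*np.where(pivot.isna().to_numpy()))]
        raise ContractError(f"missing genotype x harvest cells: {missing[:10]}")
    counts = sub.groupby(["genotype", "harvest"]).size()
    replication = int(counts.min())
    return CellMeanMatrix(tuple(pivot.index), tuple(str(c) for c in pivot.columns),
                          pivot.to_numpy(float), replication)


@dataclass(frozen=True)
class AMMIFit:
    """Fitted AMMI decomposition of one cell-mean matrix."""

    mu: float
    g: np.ndarray                # genotype main effects, sum 0
    e: np.ndarray                # environment main effects, sum 0
    lambdas: np.ndarray          # all singular values of Z, descending
    genotype_scores: np.ndarray  # left singular vectors (n, n_axes)
    env_scores: np.ndarray       # right singular vectors (m, n_axes)
    n_axes: int
    residual: np.ndarray         # Z minus the n_axes-term reconstruction
    interaction: np.ndarray      # the doubly-centered matrix Z

    def reconstruction(self) -> np.ndarray:
        """Cell means implied by the retained axes."""
        approx = (self.genotype_scores * self.lambdas[: self.n_axes]) @ self.env_scores.T
        return self.mu + self.g[:, None] + self.e[None, :] + approx

    def scaled_genotype_scores(self) -> np.ndarray:
        """Symmetric scaling alpha_ik * sqrt(lambda_k) for the retained axes."""
        return self.genotype_scores * np.sqrt(self.lambdas[: self.n_axes])

    def scaled_env_scores(self) -> np.ndarray:
        return self.env_scores * np.sqrt(self.lambdas[: self.n_axes])


def fit_ammi(cells: CellMeanMatrix, n_axes: int = 2) -> AMMIFit:
    """Fit the AMMI model by double centering followed by SVD.

    ``n_axes`` interaction principal components are retained (at most
    min(n, m) - 1 are estimable after double centering).
    """
    y = cells.means
    n, m = y.shape
    max_axes = min(n, m) - 1
    if not 1 <= n_axes <= max_axes:
        raise ContractError(f"n_axes must be in [1, {max_axes}]")
    mu = float(y.mean())
    g = y.mean(axis=1) - mu
    e = y.mean(axis=0) - mu
    z = y - mu - g[:, None] - e[None, :]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic sign convention: largest-|.| genotype loading positive
    for k in range(u.shape[1]):
        lead = np.argmax(np.abs(u[:, k]))
        if u[lead, k] < 0:
            u[:, k] *= -1
            vt[k, :] *= -1
    approx = (u[:, :n_axes] * s[:n_axes]) @ vt[:n_axes, :]
    return AMMIFit(mu=mu, g=g, e=e, lambdas=s,
                   genotype_scores=u[:, :n_axes], env_scores=vt[:n_axes, :].T,
                   n_axes=n_axes, residual=z - approx, interaction=z)


def ammi_anova(cells: CellMeanMatrix, fit: AMMIFit | None = None,
               ms_error: float | None = None,
               df_error: int | None = None) -> pd.DataFrame:
    """Partition the G, E and GEI sums of squares, GEI by IPC axis.

    Sums of squares are on the plot scale (multiplied by the per-cell
    replication). IPC axis k has n + m - 1 - 2k degrees of freedom. When a
    plot-level error mean square is supplied, F statistics and p-values are
    computed against it.
    """
    if fit is None:
        fit = fit_ammi(cells, n_axes=min(cells.means.shape) - 1)
    r = cells.replication
    n, m = cells.means.shape
    rows = []
    ss_g = r * m * float((fit.g ** 2).sum())
    ss_e = r * n * float((fit.e ** 2).sum())
    ss_gei = r * float((fit.interaction ** 2).sum())
    rows.append(("genotype", n - 1, ss_g))
    rows.append(("environment", m - 1, ss_e))
    rows.append(("G x E", (n - 1) * (m - 1), ss_gei))
    used_df = 0
    for k in range(fit.n_axes):
        df_k = n + m - 1 - 2 * (k + 1)
        used_df += df_k
        rows.append((f"IPC{k + 1}", df_k, r * float(fit.lambdas[k] ** 2)))
    resid_ss = ss_gei - r * float((fit.lambdas[: fit.n_axes] ** 2).sum())
    resid_df = (n - 1) * (m - 1) - used_df
    rows.append(("GEI residual", resid_df, max(resid_ss, 0.0)))
    table = pd.DataFrame(rows, columns=["term", "df", "sum_sq"]).set_index("term")
    table["mean_sq"] = table["sum_sq"] / table["df"].replace(0, np.nan)
    if ms_error is not None and ms_error > 0 and df_error:
        table["F"] = table["mean_sq"] / ms_error
        table["p"] = stats.f.sf(table["F"], table["df"], df_error)
    return table


def asv(ipc1_score, ipc2_score, ss_ipc1: float, ss_ipc2: float):
    """AMMI stability value from the first two IPC scores.

    ASV = sqrt( ((SS_IPC1 / SS_IPC2) * IPC1)^2 + IPC2^2 ); the first-axis
    score is weighted by how much more interaction it captures.
    """
    if ss_ipc2 <= 0:
        raise ContractError("SS_IPC2 must be > 0 (degenerate second axis)")
    if ss_ipc1 < 0:
        raise ContractError("SS_IPC1 must be >= 0")
    w = ss_ipc1 / ss_ipc2
    return np.sqrt((w * np.asarray(ipc1_score)) ** 2
                   + np.asarray(ipc2_score) ** 2)


def stability_ranking(fit: AMMIFit, cells: CellMeanMatrix) -> pd.DataFrame:
    """Rank genotypes by yield, ASV and their combined yield stability index.

    RY ranks mean yield descending (1 = top yielder), RASV ranks ASV
    ascending (1 = most stable); YSI = RY + RASV, low = desirable. Ties
    get average ranks.
    """
    if fit.n_axes < 2:
        raise ContractError("stability ranking needs >= 2 retained axes")
    mean_yield = cells.means.mean(axis=1)
    scores = fit.scaled_genotype_scores()
    r = cells.replication
    ss1 = r * float(fit.lambdas[0] ** 2)
    ss2 = r * float(fit.lambdas[1] ** 2)
    asv_vals = asv(scores[:, 0], scores[:, 1], ss1, ss2)
    ry = stats.rankdata(-mean_yield, method="average")
    rasv = stats.rankdata(asv_vals, method="average")
    return pd.DataFrame({
        "mean_yield": mean_yield,
        "RY": ry,
        "IPC1": scores[:, 0],
        "IPC2": scores[:, 1],
        "ASV": asv_vals,
        "RASV": rasv,
        "YSI": ry + rasv,
    }, index=list(cells.genotypes))
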