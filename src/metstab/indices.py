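"""Drought screening: water-use efficiency, stress tolerance index and
tolerance classification.

The stress tolerance index of a genotype combines its yield under optimal
conditions (Yp), its yield under stress (Ys) and the optimal-condition
grand mean (Xp):

    STI = (Yp * Ys) / Xp**2

Genotypes are then classified into highly tolerant / moderately tolerant /
susceptible groups by average-linkage hierarchical clustering under
Manhattan (city-block) distance on the standardized features
{STI, WUE, stress TDW}, with the three clusters labelled by descending
cluster-mean STI.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ContractError
from .trial_io import TrialRecord, records_to_frame

__all__ = [
    "wue", "sti", "build_index_table", "classify_tolerance",
    "tolerance_pca", "linkage_to_newick", "TOLERANCE_LABELS",
]

TOLERANCE_LABELS = ("highly_tolerant", "moderately_tolerant", "susceptible")
CLUSTER_FEATURES = ("STI", "WUE", "TDW")


def wue(total_dry_weight_per_plant: float, irrigation_volume_per_plant: float) -> float:
    """Water-use efficiency: dry weight produced per unit of irrigation water."""
    if irrigation_volume_per_plant <= 0:
        raise ContractError("irrigation volume must be > 0")
    if total_dry_weight_per_plant < 0:
        raise ContractError("dry weight must be >= 0")
    return total_dry_weight_per_plant / irrigation_volume_per_plant


def sti(yp: float, ys: float, xp: float) -> float:
    """Stress tolerance index (Yp * Ys) / Xp^2; dimensionless, >= 0."""
    if xp <= 0:
        raise ContractError("optimal-condition grand mean Xp must be > 0")
    if yp < 0 or ys < 0:
        raise ContractError("yields must be >= 0")
    return (yp * ys) / (xp * xp)


def build_index_table(records: Iterable[TrialRecord], stress_regime: str,
                      irrigation_volume_per_plant: float = 1.0,
                      trait: str = "TDW") -> pd.DataFrame:
    """Per-genotype index table for one stress regime.

    ``Yp`` is the genotype's mean wet-season yield, ``Ys`` its mean yield
    under the stress regime, ``Xp`` the wet-season grand mean over
    genotypes; WUE divides the stress yield by the irrigation volume
    applied per plant (a configuration constant of the trial).
    """
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    frame = frame[frame["trait"] == trait]
    wet = frame[frame["regime"] == "wet"].groupby("genotype")["value"].mean()
    stress = frame[frame["regime"] == stress_regime].groupby("genotype")["value"].mean()
    common = wet.index.intersection(stress.index)
    if common.empty:
        raise ContractError(
            f"no genotypes observed in both wet and {stress_regime!r} regimes")
    xp = float(wet.loc[common].mean())
    table = pd.DataFrame({
        "Yp": wet.loc[common],
        "Ys": stress.loc[common],
    })
    table["STI"] = [sti(max(a, 0.0), max(b, 0.0), xp)
                    for a, b in zip(table["Yp"], table["Ys"])]
    table["WUE"] = [wue(max(b, 0.0), irrigation_volume_per_plant)
                    for b in table["Ys"]]
    table["TDW"] = table["Ys"]
    table.attrs["Xp"] = xp
    table.attrs["stress_regime"] = stress_regime
    return table


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def classify_tolerance(table: pd.DataFrame, k: int = 3):
    """Cut an average-linkage / Manhattan-distance tree into tolerance groups.

    Features are z-scored first (they live on incommensurate scales; raw
    city-block distance would be dominated by the largest-scale feature).
    Returns (table with a ``cluster`` column, scipy linkage matrix). Groups
    are labelled highly/moderately tolerant and susceptible by descending
    cluster-mean STI; with fewer distinct clusters than ``k`` the labels
    degenerate and a warning is emitted.
    """
    n = len(table)
    if k > n:
        raise ContractError(f"cannot form {k} groups from {n} genotypes")
    feats = table[list(CLUSTER_FEATURES)].to_numpy(float)
    if not np.isfinite(feats).all():
        raise ContractError("cluster features must be finite")
    z = _standardize(feats)
    link = hierarchy.linkage(z, method="average", metric="cityblock")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    out = table.copy()
    out["cluster_id"] = labels
    means = out.groupby("cluster_id")["STI"].mean().sort_values(ascending=False)
    if len(means) < k:
        warnings.warn(
            f"only {len(means)} distinct clusters at k={k}; labels degenerate",
            stacklevel=2)
    name_map = {cid: TOLERANCE_LABELS[min(rank, len(TOLERANCE_LABELS) - 1)]
                for rank, cid in enumerate(means.index)}
    out["cluster"] = out["cluster_id"].map(name_map)
    return out, link


def tolerance_pca(table: pd.DataFrame):
    """Correlation-matrix PCA of the {STI, WUE, TDW} feature table.

    Returns (scores, loadings, variance_explained). Zero-variance features
    are dropped with a warning; variance-explained fractions sum to 1.
    """
    if len(table) < 3:
        raise ContractError("PCA needs >= 3 genotypes")
    feats = [f for f in CLUSTER_FEATURES
             if table[f].std(ddof=1) > 0 or _warn_drop(f)]
    x = table[feats].to_numpy(float)
    z = _standardize(x)
    corr = np.corrcoef(z, rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[lead, j] < 0:
            eigvec[:, j] *= -1
    scores = pd.DataFrame(z @ eigvec, index=table.index,
                          columns=[f"PC{i+1}" for i in range(eigvec.shape[1])])
    loadings = pd.DataFrame(eigvec, index=feats, columns=scores.columns)
    explained = eigval / eigval.sum()
    return scores, loadings, explained


def _warn_drop(feature: str) -> bool:
    warnings.warn(f"feature {feature!r} has zero variance and is dropped",
                  stacklevel=3)
    return False


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
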