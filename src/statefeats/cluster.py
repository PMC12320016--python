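"""Feature redundancy: 1 - |Pearson r| distances and complete linkage.

Each feature's observation vector is formed by concatenating its values
over all spatial units and subjects (one long vector per feature), so two
features that covary across epochs anywhere on the cortex are close. The
distance 1 - |r| treats perfectly anti-correlated features as redundant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .classify import FeatureTable

__all__ = ["DistanceMatrix", "LinkageTree", "feature_distance_matrix", "hierarchical_clustering"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    nan_features: list[str]  # zero-variance features whose distances are undefined

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.labels), len(self.labels)):
            raise ValueError("D must be square over labels")
        self.D = D

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


@dataclass
class LinkageTree:
    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix [n-1, 4]
    method: str = "complete"


def feature_distance_matrix(
    table: FeatureTable, impute: bool = True
) -> DistanceMatrix:
    """Pairwise 1 - |r| over per-feature vectors (units x observations stacked).

    NaNs are imputed to the column mean first (the clustering runs on the
    same imputed values the classifier sees). A zero-variance feature has
    undefined correlations; its row/column is NaN and flagged.
    """
    blocks = table.feature_blocks()
    names = list(blocks)
    if len(names) < 2:
        raise ValueError("need at least 2 features")
    vecs = []
    for f in names:
        X = table.X[:, blocks[f]]
        if impute:
            mu = np.nanmean(X, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            X = np.where(np.isnan(X), mu, X)
        vecs.append(X.T.ravel())  # concatenate spatial units' observation vectors
    V = np.stack(vecs)
    if V.shape[1] < 3:
        raise ValueError("need at least 3 observations per feature")

    sd = V.std(axis=1)
    nan_feats = [names[i] for i in np.flatnonzero(sd == 0)]
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(V)
    D = 1.0 - np.abs(r)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    for i in np.flatnonzero(sd == 0):
        D[i, :] = np.nan
        D[:, i] = np.nan
        D[i, i] = 0.0
    return DistanceMatrix(names, D, nan_feats)


def hierarchical_clustering(dm: DistanceMatrix) -> LinkageTree:
    """Complete-linkage agglomeration of the feature distance matrix."""
    if dm.nan_features or np.isnan(dm.D).any():
        bad = dm.nan_features or ["<unknown>"]
        raise ValueError(f"distance matrix has NaN rows for features: {bad}")
    merges = linkage(squareform(dm.D, checks=False), method="complete")
    return LinkageTree(list(dm.labels), merges)


def cluster_assignments(tree: LinkageTree, height: float) -> dict[str, int]:
    """Flat clusters obtained by cutting the tree at a height."""
    from scipy.cluster.hierarchy import fcluster

    flat = fcluster(tree.merges, t=height, criterion="distance")
    return dict(zip(tree.labels, map(int, flat)))
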