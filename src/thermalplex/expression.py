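"""Covariation analysis of multiplexed per-cell counts.

Counts are normalized within each cell to expression fractions, pairwise
Pearson correlation is computed across cells, and targets are clustered
agglomeratively on the correlation distance 1 - r with average linkage.
The group count is a parameter of the cut (no automatic selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["ClusterResult", "normalize_counts", "correlation_clustering"]


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each cell's counts by its total so rows sum to one.

    Cells with zero total are dropped with a warning; an all-zero matrix
    is an error.
    """
    counts = counts.astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.all():
        raise ValueError("all cells have zero total counts")
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} cell(s) with zero total counts",
            stacklevel=2,
        )
        counts = counts.loc[~zero]
        totals = totals.loc[~zero]
    return counts.div(totals, axis=0)


@dataclass
class ClusterResult:
    """Correlation-distance hierarchical clustering of targets."""

    distance: pd.DataFrame  # symmetric, zero diagonal, values in [0, 2]
    linkage: np.ndarray  # scipy linkage table (average method)
    groups: pd.Series  # target -> group id (1..n_groups)

    @property
    def n_groups(self) -> int:
        return int(self.groups.nunique())


def correlation_clustering(
    normalized: pd.DataFrame,
    n_groups: int,
    drop_constant: bool = False,
) -> ClusterResult:
    """Cluster targets by 1 - Pearson r with average linkage.

    Correlation is across cells (rows).  A constant target column makes
    its correlations undefined: this raises unless ``drop_constant``.
    """
    if normalized.shape[1] < 2:
        raise ValueError("need at least 2 targets")
    if normalized.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    constant = normalized.std(axis=0) == 0
    if constant.any():
        names = list(normalized.columns[constant])
        if not drop_constant:
            raise ValueError(
                f"constant target column(s) {names}: correlation undefined "
                "(pass drop_constant=True to exclude them)"
            )
        normalized = normalized.loc[:, ~constant]
        if normalized.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant targets remain")

    corr = normalized.corr(method="pearson")
    dist = (1.0 - corr).clip(lower=0.0)
    np.fill_diagonal(dist.values, 0.0)
    condensed = squareform(dist.values, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return ClusterResult(
        distance=dist,
        linkage=Z,
        groups=pd.Series(labels, index=normalized.columns, name="group"),
    )
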