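"""Grouping transcripts into gene families.

Two complementary rules are supported: connected components of the graph
whose edges join transcript pairs with nucleotide identity strictly above a
threshold (default 90%), and agglomerative Ward clustering of each gene's
vector of distances to all genes, cut at a fraction of the maximum dendrogram
merge height.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

__all__ = ["identity_clusters", "ward_family_clusters"]


def identity_clusters(
    pairs: dict[tuple[str, str], float],
    ids: list[str],
    threshold: float = 0.90,
) -> pd.Series:
    """Connected components at pairwise identity strictly above ``threshold``.

    ``pairs`` maps unordered id pairs to identity fractions; a missing pair
    counts as identity 0.  Returns id -> integer cluster label (labels are
    1-based, assigned in order of each cluster's lexicographically smallest
    member).  Singletons keep their own label.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ids = list(ids)
    known = set(ids)
    pos = {g: i for i, g in enumerate(ids)}
    if len(pos) != len(ids):
        raise ValueError("duplicate ids")

    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (a, b), ident in pairs.items():
        if a not in known or b not in known:
            missing = [g for g in (a, b) if g not in known]
            raise ValueError(f"pair references unknown ids: {missing}")
        if a != b and ident > threshold:
            ra, rb = find(pos[a]), find(pos[b])
            if ra != rb:
                parent[rb] = ra

    roots = [find(i) for i in range(len(ids))]
    # stable relabeling: clusters numbered by their smallest member id
    root_to_members: dict[int, list[str]] = {}
    for g, r in zip(ids, roots):
        root_to_members.setdefault(r, []).append(g)
    ordered = sorted(root_to_members.values(), key=lambda ms: min(ms))
    labels = {}
    for lab, members in enumerate(ordered, start=1):
        for g in members:
            labels[g] = lab
    return pd.Series([labels[g] for g in ids], index=ids, name="cluster")


def ward_family_clusters(
    distances: pd.DataFrame,
    cut_fraction: float = 0.90,
) -> pd.Series:
    """Ward clustering of distance-profile vectors, cut at a height fraction.

    Each gene is represented by its row of the (symmetric, zero-diagonal)
    distance table, treated as a Euclidean feature vector; the Ward dendrogram
    is cut at ``cut_fraction`` times the maximum merge height.
    """
    if not (0.0 < cut_fraction <= 1.0):
        raise ValueError("cut_fraction must be in (0, 1]")
    ids = list(distances.index)
    if list(distances.columns) != ids:
        raise ValueError("distance table must have identical row and column ids")
    x = distances.to_numpy(dtype=float)
    if x.shape[0] < 2:
        logger.warning("fewer than 2 items; returning a single cluster")
        return pd.Series([1] * len(ids), index=ids, name="cluster")
    if not np.allclose(x, x.T):
        raise ValueError("distance table must be symmetric")
    if not np.allclose(np.diag(x), 0):
        raise ValueError("distance table must have a zero diagonal")

    with warnings.catch_warnings():
        # rows of the distance table are used as observation vectors on
        # purpose; scipy's uncondensed-matrix heuristic misfires here
        warnings.simplefilter("ignore")
        z = linkage(x, method="ward", metric="euclidean")
    cut = cut_fraction * z[:, 2].max()
    labels = fcluster(z, t=cut, criterion="distance")
    return pd.Series(labels, index=ids, name="cluster")
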