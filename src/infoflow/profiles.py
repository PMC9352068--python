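"""Community content profiles: over-usage scores and co-clustering.

For the top-M communities (by user count) and top-K items (hashtags or
URL domains, by occurrence count) the joint usage distribution P(i, a) is
the normalized frequency of item a in community i over the restricted
event set.  The over-usage score

    xi_ia = P(i, a) - P(i) P(a)

compares each cell with its independence expectation: positive values
flag preferential usage of an item by a community, negative values
under-usage.  Both marginals are computed from the restricted joint, so
the scores sum to zero exactly.  Rows (communities) and columns (items)
are then clustered independently with agglomerative hierarchical
clustering on the score matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .ingest import TweetEvent

ITEM_KINDS = ("hashtag", "url")


def joint_usage(
    events: Sequence[TweetEvent],
    partition: Mapping[str, int],
    item_kind: str = "hashtag",
    top_items: int = 50,
    top_communities: int = 50,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Restricted joint distribution P(i, a) with marginals P(i), P(a).

    Items are counted once per tweet-or-retweet occurrence (a retweet
    re-counts its items; duplicates within one posting count once).  The
    restriction keeps the ``top_items`` items by global count and the
    ``top_communities`` communities by user count; if fewer are present,
    all are used.  Returns (joint frame indexed community x item, P_i,
    P_a), normalized so the joint sums to 1 over the restricted sets.
    """
    if item_kind not in ITEM_KINDS:
        raise ValueError(f"item_kind must be one of {ITEM_KINDS}")
    comm_sizes = Counter(partition.values())
    keep_comms = set(
        c for c, _ in sorted(comm_sizes.items(), key=lambda kv: (-kv[1], kv[0]))[:top_communities]
    )
    item_counts: Counter = Counter()
    pair_counts: Counter = Counter()
    for e in events:
        c = partition.get(e.user_id)
        items = e.hashtags if item_kind == "hashtag" else e.urls
        for a in items:
            item_counts[a] += 1
            if c is not None and c in keep_comms:
                pair_counts[(c, a)] += 1
    keep_items = [a for a, _ in sorted(item_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_items]]
    comms = sorted(keep_comms)
    joint = pd.DataFrame(0.0, index=pd.Index(comms, name="community"), columns=pd.Index(keep_items, name="item"))
    for (c, a), n in pair_counts.items():
        if a in joint.columns:
            joint.loc[c, a] = n
    total = joint.to_numpy().sum()
    if total == 0:
        raise ValueError("no item occurrences in the restricted sets")
    joint /= total
    p_i = joint.sum(axis=1)
    p_a = joint.sum(axis=0)
    return joint, p_i, p_a


def overusage(joint: pd.DataFrame, p_i: pd.Series, p_a: pd.Series) -> pd.DataFrame:
    """Score matrix xi = P(i, a) - P(i) P(a); sums to zero exactly."""
    return joint - np.outer(p_i.to_numpy(), p_a.to_numpy())


@dataclass
class CoclusterResult:
    """Independent hierarchical clusterings of rows and columns of xi."""

    row_labels: pd.Series  # community -> flat group id
    col_labels: pd.Series  # item -> flat group id
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cocluster(
    xi: pd.DataFrame,
    n_row_groups: int = 7,
    n_col_groups: int = 2,
    linkage: str = "average",
    metric: str = "euclidean",
) -> CoclusterResult:
    """Agglomerative clustering of communities and of items on the scores.

    Rows and columns are clustered independently; flat labels are cut at
    the requested group counts (``maxclust``).  Deterministic.
    """
    if n_row_groups > xi.shape[0]:
        raise ValueError(f"n_row_groups={n_row_groups} exceeds {xi.shape[0]} rows")
    if n_col_groups > xi.shape[1]:
        raise ValueError(f"n_col_groups={n_col_groups} exceeds {xi.shape[1]} columns")
    if not np.isfinite(xi.to_numpy()).all():
        raise ValueError("score matrix must be finite")

    def _cluster(mat, k):
        if mat.shape[0] == 1:
            return np.ones(1, dtype=int), np.empty((0, 4))
        Z = hierarchy.linkage(mat, method=linkage, metric=metric)
        return hierarchy.fcluster(Z, t=k, criterion="maxclust"), Z

    row_flat, row_Z = _cluster(xi.to_numpy(), n_row_groups)
    col_flat, col_Z = _cluster(xi.to_numpy().T, n_col_groups)
    return CoclusterResult(
        row_labels=pd.Series(row_flat, index=xi.index, name="group"),
        col_labels=pd.Series(col_flat, index=xi.columns, name="group"),
        row_linkage=row_Z,
        col_linkage=col_Z,
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a newick tree string."""
    if len(Z) == 0:
        return f"{leaf_names[0]};" if len(leaf_names) else ";"
    tree = hierarchy.to_tree(Z)

    def _render(node) -> str:
        if node.is_leaf():
            return str(leaf_names[node.id])
        parts = []
        for child in (node.get_left(), node.get_right()):
            length = (node.dist - child.dist) / 2 if not child.is_leaf() else node.dist / 2
            parts.append(f"{_render(child)}:{length:.6g}")
        return "(" + ",".join(parts) + ")"

    return _render(tree) + ";"


def xi_long(xi: pd.DataFrame) -> pd.DataFrame:
    """Long-format (community, item, score) view of the score matrix."""
    long = xi.stack().rename("score").reset_index()
    return long
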