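"""Flow-based community detection and information-flow diagnostics.

Communities are found by maximizing the one-step auto-covariance of the
hypergraph random walk projected onto the partition,

    Q = sum_C sum_{i,j in C} [ p(i, j) - gamma * p(i) p(j) ] ,

i.e. directed modularity with stationary-distribution weights (the
stability quality at unitary Markov time and resolution ``gamma``).  The
optimizer is a Louvain-style greedy multi-level scheme with a seeded node
order, so results are deterministic given the seed.

Per-community diagnostics follow the random-walk analogy of a travelling
piece of information:

* average visit probability  p(C)/|C| = (1/|C|) sum_{i in C} p(i)
* escape probability         p(Cbar|C) = sum_{i not in C, j in C} p(i,j) / p(C)

Low escape together with high internal flow is the signature of an echo
chamber.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import hypergraph as hg
from .ingest import TweetEvent, UrlCatalog, classify_events


def _sym_links(S: sparse.csr_matrix) -> sparse.csr_matrix:
    return (S + S.T).tocsr()


def detect_communities(
    flow: hg.FlowState,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Partition nodes by greedy maximization of the flow auto-covariance.

    Returns an integer label per node (aligned with the hypergraph node
    order used to build ``flow``), with communities relabelled by
    decreasing size (ties by smallest member index).
    """
    if flow.S.nnz == 0:
        raise ValueError("flow has no link mass; nothing to cluster")
    rng = np.random.default_rng(seed)
    n = flow.n
    # Node quantities of the full quality function.  The rank-one teleport
    # remainder outer(u, v) is carried exactly through aggregation.
    W = _sym_links(flow.S)
    p = flow.p.copy()
    u = np.full(n, 1.0 / n)
    v = flow.residual.copy()
    membership = np.arange(n)
    while True:
        labels, improved = _one_level(W, p, u, v, resolution, rng)
        if not improved:
            break
        membership = labels[membership]
        W, p, u, v = _aggregate(W, p, u, v, labels)
        if W.shape[0] == len(np.unique(labels)) and W.shape[0] == 1:
            break
    return _relabel_by_size(membership)


def _one_level(W, p, u, v, gamma, rng):
    """One Louvain level: local moves until no gain.  Returns (labels, moved)."""
    n = W.shape[0]
    labels = np.arange(n)
    Ptot = p.copy()
    Utot = u.copy()
    Vtot = v.copy()
    W = W.tocsr()
    indptr, indices, data = W.indptr, W.indices, W.data
    moved_any = False
    while True:
        n_moves = 0
        for x in rng.permutation(n):
            c0 = labels[x]
            Ptot[c0] -= p[x]
            Utot[c0] -= u[x]
            Vtot[c0] -= v[x]
            # link weight from x to each neighbouring community
            wx: dict[int, float] = {}
            for k in range(indptr[x], indptr[x + 1]):
                j = indices[k]
                if j == x:
                    continue
                wx[labels[j]] = wx.get(labels[j], 0.0) + data[k]
            best_c, best_gain = c0, _gain(c0, wx, x, p, u, v, Ptot, Utot, Vtot, gamma)
            for c in sorted(wx):
                if c == c0:
                    continue
                g = _gain(c, wx, x, p, u, v, Ptot, Utot, Vtot, gamma)
                if g > best_gain + 1e-15 or (abs(g - best_gain) <= 1e-15 and c < best_c):
                    best_c, best_gain = c, g
            labels[x] = best_c
            Ptot[best_c] += p[x]
            Utot[best_c] += u[x]
            Vtot[best_c] += v[x]
            if best_c != c0:
                n_moves += 1
        if n_moves == 0:
            break
        moved_any = True
    # compress labels to 0..k-1 in first-seen order for determinism
    uniq, labels = np.unique(labels, return_inverse=True)
    return labels, moved_any


def _gain(c, wx, x, p, u, v, Ptot, Utot, Vtot, gamma):
    """Quality gain of inserting node x into community c (x removed)."""
    return (
        wx.get(c, 0.0)
        + u[x] * Vtot[c]
        + v[x] * Utot[c]
        - 2.0 * gamma * p[x] * Ptot[c]
    )


def _aggregate(W, p, u, v, labels):
    """Collapse communities into super-nodes, summing weights."""
    k = labels.max() + 1
    n = W.shape[0]
    proj = sparse.csr_matrix(
        (np.ones(n), (labels, np.arange(n))), shape=(k, n)
    )
    W2 = (proj @ W @ proj.T).tocsr()
    p2 = np.bincount(labels, weights=p, minlength=k)
    u2 = np.bincount(labels, weights=u, minlength=k)
    v2 = np.bincount(labels, weights=v, minlength=k)
    return W2, p2, u2, v2


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Contiguous ids ordered by decreasing size; ties by first member."""
    ids, first = np.unique(labels, return_index=True)
    sizes = np.bincount(labels)
    order = sorted(ids, key=lambda c: (-sizes[c], first[list(ids).index(c)]))
    remap = {c: r for r, c in enumerate(order)}
    return np.array([remap[c] for c in labels])


def partition_quality(
    flow: hg.FlowState, labels: np.ndarray, resolution: float = 1.0
) -> float:
    """Auto-covariance quality Q of a partition under the flow."""
    labels = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += flow.block_flow(mask, mask) - resolution * flow.p[mask].sum() ** 2
    return float(q)


def visit_probability(labels: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-community average visit probability p(C)/|C|."""
    labels = np.asarray(labels)
    p = np.asarray(p, dtype=float)
    k = labels.max() + 1
    mass = np.bincount(labels, weights=p, minlength=k)
    sizes = np.bincount(labels, minlength=k)
    if (sizes == 0).any():
        raise ValueError("partition has empty community ids")
    return mass / sizes


def escape_probability(labels: np.ndarray, flow: hg.FlowState) -> np.ndarray:
    """Per-community escape probability p(Cbar|C).

    The probability that a walker observed inside C leaves it in one step;
    communities with zero visit mass yield NaN.
    """
    labels = np.asarray(labels)
    k = labels.max() + 1
    out = np.full(k, np.nan)
    for c in range(k):
        mask = labels == c
        mass = flow.p[mask].sum()
        if mass <= 0:
            continue
        internal = flow.block_flow(mask, mask)
        out[c] = 1.0 - internal / mass
    return np.clip(out, 0.0, 1.0, out=out, where=~np.isnan(out))


SUBGRAPHS = ("all", "vaccine_critical", "media")


def per_period_flow(
    events: Sequence[TweetEvent],
    breakpoints: Sequence[int],
    partition: Mapping[str, int],
    catalog: UrlCatalog | None = None,
    subgraphs: Sequence[str] = SUBGRAPHS,
    damping: float = hg.DEFAULT_DAMPING,
    tau_label: str | None = None,
) -> pd.DataFrame:
    """Visit/escape summaries per period and per content-restricted subgraph.

    The stream is split at the sorted ``breakpoints`` (day indices; a day d
    belongs to the period whose interval contains it, intervals being
    ``[min, b1), [b1, b2), ..., [bk, max]``).  For each period and each
    subgraph restriction the hypergraph is rebuilt on the *full* node set
    of the partition, the flow recomputed, and the diagnostics evaluated
    against the fixed full-period partition.  Periods without cascades
    yield rows with NaN values and ``empty=True``.
    """
    breakpoints = sorted(breakpoints)
    nodes = sorted(partition)
    labels_full = np.array([partition[u] for u in nodes])
    rows = []
    if not events:
        return pd.DataFrame(
            columns=["period", "subgraph", "community", "size", "avg_visit", "escape", "empty"]
        )
    lo = min(e.day for e in events)
    hi = max(e.day for e in events)
    edges = [lo] + [b for b in breakpoints if lo < b <= hi] + [hi + 1]
    for pi in range(len(edges) - 1):
        a, b = edges[pi], edges[pi + 1]
        period_events = [e for e in events if a <= e.day < b]
        for sub in subgraphs:
            if sub == "all":
                selected = period_events
            else:
                if catalog is None:
                    raise ValueError("catalog required for content-restricted subgraphs")
                selected = classify_events(period_events, catalog, sub)
            H = hg.build_hypergraph(selected, keep_nodes=nodes)
            empty = H.n_edges == 0
            if empty:
                k = labels_full.max() + 1
                visit = np.full(k, np.nan)
                esc = np.full(k, np.nan)
            else:
                flow = hg.compute_flow(H, damping=damping)
                labels = np.array(
                    [partition.get(u, -1) for u in H.nodes]
                )
                known = labels >= 0
                # nodes outside the partition (e.g. orphan tails) are ignored
                sub_flow_p = flow.p
                k = labels_full.max() + 1
                visit = np.full(k, np.nan)
                esc = np.full(k, np.nan)
                for c in range(k):
                    mask = (labels == c) & known
                    if not mask.any():
                        continue
                    mass = sub_flow_p[mask].sum()
                    visit[c] = mass / mask.sum()
                    if mass > 0:
                        esc[c] = min(1.0, max(0.0, 1.0 - flow.block_flow(mask, mask) / mass))
            sizes = np.bincount(labels_full, minlength=labels_full.max() + 1)
            for c in range(len(visit)):
                rows.append(
                    {
                        "period": pi,
                        "subgraph": sub,
                        "community": c,
                        "size": int(sizes[c]),
                        "avg_visit": visit[c],
                        "escape": esc[c],
                        "empty": bool(empty),
                    }
                )
    return pd.DataFrame(rows)


def partition_dict(H: hg.DirectedHypergraph, labels: np.ndarray) -> dict:
    """Map user ids to community labels for a hypergraph's node order."""
    return {u: int(c) for u, c in zip(H.nodes, labels)}
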