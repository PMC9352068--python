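"""Directed retweet hypergraphs and their random-walk flow.

Each original tweet together with its retweeters forms a directed
hyper-edge: the original poster is the single *tail* node, the set of
distinct retweeters the *head*.  Unlike a pairwise retweet graph this
distinguishes one tweet retweeted N times from N tweets retweeted once.

A random walker on the hypergraph (i) picks one of the hyper-edges
incident to its node's tail uniformly, then (ii) lands on a uniformly
chosen head node.  The induced effective node-to-node transition matrix is

    T[i -> j] = sum_{edges e: tail i, j in head(e)} 1/|head(e)|
                / sum_{edges e: tail i} 1 ,

row-stochastic on nodes with outgoing hyper-edges.  The stationary
distribution p and the steady-state edge flow p(i, j) (probability of a
step from node j to node i) are computed for the teleport-completed chain
so that both are well defined on weakly connected or absorbing graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .ingest import TweetEvent

logger = logging.getLogger(__name__)

DEFAULT_DAMPING = 0.85


@dataclass(frozen=True)
class Cascade:
    """A directed hyper-edge: one original poster and its retweeters."""

    root_id: str
    tail: str
    head: frozenset
    day: int

    @property
    def head_size(self) -> int:
        return len(self.head)


class DirectedHypergraph:
    """Node set plus retweet cascades, with a tail-incidence index."""

    def __init__(self, nodes: Sequence[str], cascades: Sequence[Cascade]):
        self.nodes: list[str] = sorted(set(nodes))
        self.node_index: dict[str, int] = {u: i for i, u in enumerate(self.nodes)}
        self.cascades: list[Cascade] = list(cascades)
        for c in self.cascades:
            if not c.head:
                raise ValueError("hyper-edge with empty head")
            if c.tail in c.head:
                raise ValueError("hyper-edge with tail in head")
        self._tail_index: dict[str, list[int]] = {}
        for k, c in enumerate(self.cascades):
            self._tail_index.setdefault(c.tail, []).append(k)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.cascades)

    def outgoing(self, user: str) -> list[Cascade]:
        return [self.cascades[k] for k in self._tail_index.get(user, [])]


def build_hypergraph(
    events: Sequence[TweetEvent], keep_nodes: Sequence[str] | None = None
) -> DirectedHypergraph:
    """Assemble the retweet hypergraph from an event stream.

    One hyper-edge per original tweet with at least one distinct retweeter;
    repeated retweets of the same root by one user collapse; self-retweets
    are dropped.  Originals with no retweets contribute their node only.
    Retweets whose root tweet is absent from the stream keep the retweeter
    and attach a synthetic ``unknown:<root_id>`` tail node (logged).
    ``keep_nodes`` forces extra nodes into the node set, so that restricted
    hypergraphs stay comparable with a partition of the full graph.
    """
    originals: dict[str, TweetEvent] = {}
    nodes: set[str] = set(keep_nodes) if keep_nodes is not None else set()
    for e in events:
        nodes.add(e.user_id)
        if not e.is_retweet:
            originals[e.tweet_id] = e
    heads: dict[str, set] = {}
    n_orphans = 0
    for e in events:
        if not e.is_retweet:
            continue
        root = originals.get(e.root_tweet_id)
        if root is None:
            tail = f"unknown:{e.root_tweet_id}"
            if tail not in nodes:
                n_orphans += 1
            nodes.add(tail)
            heads.setdefault(e.root_tweet_id, set()).add(e.user_id)
        else:
            if e.user_id != root.user_id:
                heads.setdefault(e.root_tweet_id, set()).add(e.user_id)
    if n_orphans:
        logger.warning("%d retweet root(s) missing from stream; synthetic tails added", n_orphans)
    cascades = []
    for root_id in sorted(heads):
        root = originals.get(root_id)
        tail = root.user_id if root is not None else f"unknown:{root_id}"
        head = frozenset(heads[root_id]) - {tail}
        if not head:
            continue
        day = root.day if root is not None else min(
            e.day for e in events if e.is_retweet and e.root_tweet_id == root_id
        )
        cascades.append(Cascade(root_id=root_id, tail=tail, head=head, day=day))
    return DirectedHypergraph(nodes, cascades)


def restrict(H: DirectedHypergraph, events_subset: Sequence[TweetEvent]) -> DirectedHypergraph:
    """Rebuild hyper-edges from an event subset, keeping the full node set."""
    return build_hypergraph(events_subset, keep_nodes=H.nodes)


def transition_matrix(H: DirectedHypergraph) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Effective node transition matrix ``T`` and the dangling-row mask.

    ``T[i, j]`` is the probability that a walker at node i steps to node j.
    Rows of nodes with no outgoing hyper-edge are zero and flagged in the
    returned boolean mask.
    """
    if H.n_edges == 0:
        raise ValueError("hypergraph has no hyper-edges")
    n = H.n_nodes
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    dangling = np.ones(n, dtype=bool)
    for tail, edge_ids in H._tail_index.items():
        i = H.node_index[tail]
        dangling[i] = False
        m = len(edge_ids)
        for k in edge_ids:
            c = H.cascades[k]
            w = 1.0 / (m * c.head_size)
            for u in c.head:
                rows.append(i)
                cols.append(H.node_index[u])
                vals.append(w)
    T = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    T.sum_duplicates()
    return T, dangling


def stationary_distribution(
    T: sparse.csr_matrix,
    damping: float = DEFAULT_DAMPING,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    dangling: np.ndarray | None = None,
) -> np.ndarray:
    """Stationary distribution of the teleport-completed chain.

    The effective chain M replaces dangling rows of T with the uniform
    distribution and mixes with uniform teleportation at rate
    ``1 - damping``.  Power iteration to L1 residual ``tol``; raises
    ``RuntimeError`` with the residual on non-convergence.
    """
    n = T.shape[0]
    if dangling is None:
        dangling = np.asarray(T.sum(axis=1)).ravel() == 0
    p = np.full(n, 1.0 / n)
    Tt = T.T.tocsr()
    for _ in range(max_iter):
        new = damping * (Tt @ p + p[dangling].sum() / n) + (1.0 - damping) / n
        new /= new.sum()
        if np.abs(new - p).sum() < tol:
            return new
        p = new
    raise RuntimeError(
        f"stationary distribution did not converge in {max_iter} iterations "
        f"(residual {np.abs(new - p).sum():.3e})"
    )


@dataclass
class FlowState:
    """Steady-state flow of the teleport-completed walk.

    ``flow(i, j) = M[j -> i] * p[j]`` is the probability of observing a
    step from node j to node i at stationarity; it decomposes into a
    sparse link part ``S`` (actual hyper-edge traversals, damped) and a
    uniform rank-one remainder ``outer(1/n, r)`` carrying teleport and
    dangling mass.  Total flow sums to 1 and both marginals equal ``p``.
    """

    T: sparse.csr_matrix
    p: np.ndarray
    damping: float
    dangling: np.ndarray

    def __post_init__(self):
        if self.T.shape[0] != self.p.shape[0]:
            raise ValueError("transition matrix and distribution sizes differ")
        # S[i, j] = damping * T[j, i] * p[j]  (flow j -> i along links)
        self.S = (self.T.T.tocsr()).multiply(self.damping * self.p[np.newaxis, :]).tocsr()
        col = np.asarray(self.S.sum(axis=0)).ravel()
        self.residual = self.p - col  # per-source teleport + dangling mass

    @property
    def n(self) -> int:
        return self.p.shape[0]

    def to_dense(self) -> np.ndarray:
        """Dense flow matrix F with F[i, j] = p(i, j); small graphs only."""
        F = self.S.toarray()
        F += np.full((self.n, 1), 1.0 / self.n) * self.residual[np.newaxis, :]
        return F

    def block_flow(self, rows: np.ndarray, cols: np.ndarray) -> float:
        """Total flow from sources ``cols`` into sinks ``rows`` (bool masks)."""
        rows = np.asarray(rows, dtype=bool)
        cols = np.asarray(cols, dtype=bool)
        link = self.S[rows][:, cols].sum()
        return float(link + rows.sum() / self.n * self.residual[cols].sum())

    def visit_probability(self) -> np.ndarray:
        """Row marginal of the flow; equals p up to iteration tolerance."""
        row = np.asarray(self.S.sum(axis=1)).ravel()
        return row + self.residual.sum() / self.n


def edge_flow(
    T: sparse.csr_matrix,
    p: np.ndarray,
    damping: float = DEFAULT_DAMPING,
    dangling: np.ndarray | None = None,
) -> FlowState:
    """Steady-state edge flow p(i, j) for a computed stationary p."""
    if dangling is None:
        dangling = np.asarray(T.sum(axis=1)).ravel() == 0
    return FlowState(T=T, p=np.asarray(p, dtype=float), damping=damping, dangling=dangling)


def compute_flow(
    H: DirectedHypergraph,
    damping: float = DEFAULT_DAMPING,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> FlowState:
    """Transition matrix, stationary distribution and edge flow in one go."""
    T, dangling = transition_matrix(H)
    p = stationary_distribution(T, damping=damping, tol=tol, max_iter=max_iter, dangling=dangling)
    return edge_flow(T, p, damping=damping, dangling=dangling)
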