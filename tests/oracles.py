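"""Independent oracles used by the tests.

Everything here re-derives quantities from first principles (explicit walk
simulation, dense eigendecomposition, brute-force enumeration, pairwise
digraphs built with networkx) without touching the implementation paths
it is used to check.
"""

from __future__ import annotations

from collections import Counter
from itertools import product

import networkx as nx
import numpy as np
from scipy.stats import chi2


def simulate_hypergraph_walk(H, n_walks: int, walk_len: int, seed: int):
    """Empirical node-transition counts of the literal hypergraph walk.

    Each step: choose a hyper-edge incident on the current node's tail
    uniformly, then land on a uniformly chosen head node.  Walks stop at
    dangling nodes.  Returns {source: Counter(target: count)}.
    """
    rng = np.random.default_rng(seed)
    nodes = H.nodes
    counts: dict = {}
    heads = {id(c): sorted(c.head) for c in H.cascades}
    for _ in range(n_walks):
        node = nodes[rng.integers(len(nodes))]
        for _ in range(walk_len):
            out = H.outgoing(node)
            if not out:
                break
            edge = out[rng.integers(len(out))]
            head = heads[id(edge)]
            nxt = head[rng.integers(len(head))]
            counts.setdefault(node, Counter())[nxt] += 1
            node = nxt
    return counts


def walk_chi2_pvalue(H, T, counts) -> float:
    """Goodness of fit of empirical walk frequencies against T's rows."""
    stat = 0.0
    dof = 0
    for src, ctr in counts.items():
        i = H.node_index[src]
        total = sum(ctr.values())
        row = T.getrow(i).toarray().ravel()
        support = np.flatnonzero(row)
        dof += len(support) - 1
        for j in support:
            exp = row[j] * total
            obs = ctr.get(H.nodes[j], 0)
            stat += (obs - exp) ** 2 / exp
    if dof == 0:
        return 1.0
    return float(chi2.sf(stat, dof))


def dense_stationary(T, damping: float) -> np.ndarray:
    """Stationary distribution from a dense eigendecomposition of M."""
    Td = T.toarray()
    n = Td.shape[0]
    dangling = Td.sum(axis=1) == 0
    M = Td.copy()
    M[dangling] = 1.0 / n
    M = damping * M + (1.0 - damping) / n
    w, v = np.linalg.eig(M.T)
    k = np.argmin(np.abs(w - 1.0))
    p = np.real(v[:, k])
    p = p / p.sum()
    return p


def digraph_transition(events, nodes):
    """Row-normalized weighted retweet digraph via networkx.

    Valid oracle only when every cascade has head size 1: each retweet is
    one poster->retweeter edge and the hypergraph walk degenerates to an
    ordinary weighted digraph walk.
    """
    from scipy import sparse

    g = nx.MultiDiGraph()
    g.add_nodes_from(nodes)
    originals = {e.tweet_id: e for e in events if not e.is_retweet}
    for e in events:
        if e.is_retweet and e.root_tweet_id in originals:
            src = originals[e.root_tweet_id].user_id
            if src != e.user_id:
                g.add_edge(src, e.user_id)
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v2 in g.edges():
        A[index[u], index[v2]] += 1.0
    out = A.sum(axis=1, keepdims=True)
    T = np.divide(A, out, out=np.zeros_like(A), where=out > 0)
    return sparse.csr_matrix(T)


def best_partition_bruteforce(flow, max_nodes: int = 10):
    """Exhaustive maximum of the flow auto-covariance over all partitions."""
    n = flow.n
    assert n <= max_nodes
    F = flow.to_dense()
    p = flow.p

    def quality(labels):
        q = 0.0
        for c in set(labels):
            idx = [i for i, l in enumerate(labels) if l == c]
            q += F[np.ix_(idx, idx)].sum() - p[idx].sum() ** 2
        return q

    best_q, best_labels = -np.inf, None
    for labels in _set_partitions(n):
        q = quality(labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return best_q, best_labels


def best_two_partition(flow):
    """Maximum quality over all partitions into at most two blocks."""
    n = flow.n
    F = flow.to_dense()
    p = flow.p
    best = -np.inf
    for bits in range(2 ** (n - 1)):  # node 0 fixed in block 0
        labels = [0] + [(bits >> k) & 1 for k in range(n - 1)]
        q = 0.0
        for c in set(labels):
            idx = [i for i, l in enumerate(labels) if l == c]
            q += F[np.ix_(idx, idx)].sum() - p[idx].sum() ** 2
        best = max(best, q)
    return best


def _set_partitions(n: int):
    """All set partitions of range(n) in restricted-growth encoding."""
    labels = [0] * n

    def rec(i, m):
        if i == n:
            yield tuple(labels)
            return
        for c in range(m + 1):
            labels[i] = c
            yield from rec(i + 1, max(m, c + 1))

    yield from rec(1, 1) if n > 1 else iter([(0,) * n])


def simulate_edge_flow(H, damping: float, n_steps: int, seed: int):
    """Monte-Carlo estimate of the steady-state edge flow p(i, j).

    Simulates the teleport-completed chain explicitly: with probability
    ``damping`` take a hypergraph step (or a uniform jump from a dangling
    node), otherwise teleport uniformly.  Returns a dense matrix of
    empirical step frequencies F[i, j] for steps j -> i.
    """
    rng = np.random.default_rng(seed)
    nodes = H.nodes
    n = len(nodes)
    F = np.zeros((n, n))
    idx = {u: i for i, u in enumerate(nodes)}
    node = nodes[rng.integers(n)]
    heads = {id(c): sorted(c.head) for c in H.cascades}
    for _ in range(n_steps):
        j = idx[node]
        out = H.outgoing(node)
        if rng.random() >= damping or not out:
            nxt = nodes[rng.integers(n)]
        else:
            edge = out[rng.integers(len(out))]
            head = heads[id(edge)]
            nxt = head[rng.integers(len(head))]
        F[idx[nxt], j] += 1
        node = nxt
    return F / n_steps
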