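"""K-order propagation-number node importance (WKPN) and comparators.

WKPN views every node as the source of an epidemic on the binary network.
The K-order propagation number of node v,

    N_v^K = #{ u in V : D(v, u) <= K },        K = 0 .. d,

counts the nodes "infected" after K propagation steps, where D is the
unweighted shortest-path length and d the largest finite distance in the
network.  Per order K the structure entropy

    H_K = - sum_i p_i ln p_i,    p_i = N_i^K / sum_j N_j^K,

measures how heterogeneous the propagation counts are.  The importance
score aggregates all orders,

    Q_v = sum_K c_K * S_v^K,

with c_K = H_K / sum H and S_v^K = N_v^K / sum_j N_j^K; hence
sum_v Q_v = 1 and Q is a proper entropy-weighted average of normalized
propagation counts.  Nodes that reach many others quickly — including
bridge nodes that pure degree measures miss — score high.

Weighted degree centrality (node strength) and weighted PageRank are
provided as baseline rankers for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import shortest_path

from .connectivity import BinaryNetwork, PLVMatrix

__all__ = [
    "ImportanceProfile", "MarkedImportance",
    "shortest_path_lengths", "k_order_numbers", "structure_entropy",
    "node_importance", "mark_nodes", "wdc", "wpr",
]


@dataclass
class ImportanceProfile:
    """Per-node propagation counts, entropy weights and importance scores.

    Attributes
    ----------
    N:
        ``(n, d+1)`` integer matrix of K-order propagation numbers.
    H:
        Structure entropy per order K (nats), length ``d + 1``.
    c:
        Normalized entropy weights, sum to 1.
    S:
        ``(n, d+1)`` normalized propagation numbers; each column sums to 1
        under the default sum-normalization.
    Q:
        Per-node importance scores.
    ranking:
        Node labels sorted by Q descending (ties broken by label order).
    d:
        Maximum finite shortest-path length of the network.
    """

    node_labels: tuple[str, ...]
    N: np.ndarray
    H: np.ndarray
    c: np.ndarray
    S: np.ndarray
    Q: np.ndarray
    ranking: tuple[str, ...]
    d: int
    meta: dict = field(default_factory=dict)

    def top(self, m: int) -> tuple[str, ...]:
        """The m highest-ranked node labels."""
        return self.ranking[:m]


@dataclass
class MarkedImportance:
    """Min-max normalized importance and the supra-threshold node set."""

    node_labels: tuple[str, ...]
    normalized_q: np.ndarray
    marked: tuple[str, ...]
    threshold: float


def _as_adjacency(net: BinaryNetwork | PLVMatrix | np.ndarray,
                  ) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(net, BinaryNetwork):
        return net.adjacency.astype(float), net.node_labels
    if isinstance(net, PLVMatrix):
        w = net.values.copy()
        np.fill_diagonal(w, 0.0)
        return w, net.node_labels
    a = np.asarray(net, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    labels = tuple(str(i) for i in range(a.shape[0]))
    return a, labels


def shortest_path_lengths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs unweighted shortest-path hop counts (inf if unreachable)."""
    return shortest_path(net.adjacency, method="D", unweighted=True,
                         directed=False)


def k_order_numbers(net: BinaryNetwork) -> tuple[np.ndarray, int]:
    """K-order propagation numbers N and maximum finite distance d.

    ``N[v, K]`` counts nodes within hop distance K of v (v itself
    included, so ``N[:, 0] == 1``).  An edgeless network has d = 0.
    """
    D = shortest_path_lengths(net)
    finite = D[np.isfinite(D)]
    d = int(finite.max()) if finite.size else 0
    ks = np.arange(d + 1)
    # N[v, K] = #{u : D[v, u] <= K}; inf never satisfies the comparison
    N = (D[:, :, None] <= ks[None, None, :]).sum(axis=1)
    return N.astype(np.int64), d


def structure_entropy(n_column: np.ndarray) -> float:
    """Shannon entropy (nats) of one order's propagation-count distribution.

    ``p_i = N_i / sum_j N_j``; every count is >= 1 so all p_i > 0 and
    ``0 < H <= ln(n)``, with equality at ln(n) for uniform counts.
    """
    col = np.asarray(n_column, dtype=float)
    if (col < 1).any():
        raise ValueError("propagation counts must be >= 1")
    p = col / col.sum()
    return float(-(p * np.log(p)).sum())


def node_importance(net: BinaryNetwork,
                    normalization: str = "sum",
                    invert_weights: bool = False) -> ImportanceProfile:
    """Full WKPN importance profile of a binary network.

    Parameters
    ----------
    normalization:
        ``"sum"`` (default): c_K = H_K / sum(H), S column-normalized to
        sum 1 — Q is then a weighted average with sum_v Q_v = 1.
        ``"minmax"``: min-max scaling of H (re-normalized to sum 1) and of
        each S column (uniform columns map to 1/n).
    invert_weights:
        Weight orders by ``1 - c_K`` (re-normalized) instead of c_K,
        down-weighting high-entropy orders where nodes are least
        distinguishable.  Off by default: the literal formulation
        up-weights high-entropy orders.
    """
    n = net.n_nodes
    if n == 1:
        # degenerate: H_0 = 0 makes the entropy weights 0/0; Q = 1 by
        # convention for the lone node
        return ImportanceProfile(
            node_labels=net.node_labels, N=np.array([[1]]),
            H=np.zeros(1), c=np.ones(1), S=np.ones((1, 1)),
            Q=np.ones(1), ranking=net.node_labels, d=0,
            meta={"normalization": normalization,
                  "invert_weights": invert_weights, "band": net.band,
                  "condition": net.condition})
    N, d = k_order_numbers(net)
    H = np.array([structure_entropy(N[:, k]) for k in range(d + 1)])

    if normalization == "sum":
        c = H / H.sum()
        S = N / N.sum(axis=0, keepdims=True)
    elif normalization == "minmax":
        span = np.ptp(H)
        c = (H - H.min()) / span if span > 0 else np.full_like(H, 1.0)
        c = c / c.sum() if c.sum() > 0 else np.full_like(H, 1 / len(H))
        S = np.empty_like(N, dtype=float)
        for k in range(d + 1):
            col = N[:, k].astype(float)
            rng_ = np.ptp(col)
            S[:, k] = (col - col.min()) / rng_ if rng_ > 0 else 1.0 / n
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    if invert_weights:
        w = 1.0 - c
        c = w / w.sum() if w.sum() > 0 else np.full_like(c, 1 / len(c))

    Q = S @ c
    order = sorted(range(n), key=lambda i: (-Q[i], net.node_labels[i]))
    ranking = tuple(net.node_labels[i] for i in order)
    return ImportanceProfile(
        node_labels=net.node_labels, N=N, H=H, c=c, S=S, Q=Q,
        ranking=ranking, d=d,
        meta={"normalization": normalization,
              "invert_weights": invert_weights, "band": net.band,
              "condition": net.condition})


def mark_nodes(profile: ImportanceProfile,
               threshold: float = 0.8) -> MarkedImportance:
    """Min-max normalize Q to [0, 1] and mark nodes strictly above the
    threshold (default 0.8) — the 'important node' marking rule."""
    q = profile.Q
    if len(q) < 2:
        raise ValueError("need at least 2 nodes to normalize")
    span = np.ptp(q)
    if span == 0:
        warnings.warn("constant importance scores: no nodes marked",
                      stacklevel=2)
        norm = np.zeros_like(q)
    else:
        norm = (q - q.min()) / span
    marked = tuple(lab for lab, v in zip(profile.node_labels, norm)
                   if v > threshold)
    return MarkedImportance(node_labels=profile.node_labels,
                            normalized_q=norm, marked=marked,
                            threshold=threshold)


def wdc(net: BinaryNetwork | PLVMatrix | np.ndarray) -> np.ndarray:
    """Weighted degree centrality: per-node strength (sum of incident edge
    weights; plain degree on a binary network)."""
    w, _ = _as_adjacency(net)
    return w.sum(axis=1)


def wpr(net: BinaryNetwork | PLVMatrix | np.ndarray,
        damping: float = 0.85, tol: float = 1e-9) -> np.ndarray:
    """Weighted PageRank on the undirected graph.

    Each edge acts as two directed arcs with transition probability
    proportional to its weight; scores sum to 1.
    """
    w, labels = _as_adjacency(net)
    g = nx.from_numpy_array(w)
    try:
        pr = nx.pagerank(g, alpha=damping, tol=tol, max_iter=10_000,
                         weight="weight")
    except nx.PowerIterationFailedConvergence as err:  # pragma: no cover
        raise RuntimeError("PageRank power iteration failed") from err
    return np.array([pr[i] for i in range(len(labels))])
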