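"""Brute-force reference implementations used only as test oracles.

Each function recomputes a quantity by direct enumeration or dense linear
algebra, independent of the library code paths under test.  They are
exponential or cubic and only meant for tiny inputs.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


def degree_rowsum(g: nx.Graph) -> dict:
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    return dict(zip(nodes, a.sum(axis=1)))


def betweenness_enumeration(g: nx.Graph) -> dict:
    """Exhaustive shortest-path counting over all unordered pairs."""
    nodes = sorted(g.nodes)
    out = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / sigma
    return out


def semilocal_bfs2(g: nx.Graph) -> dict:
    """Three-level sum via explicit BFS to depth 2."""
    def n2(w):
        seen = {w}
        frontier = {w}
        for _ in range(2):
            frontier = {v for u in frontier for v in g.neighbors(u)} - seen
            seen |= frontier
        return len(seen - {w})

    q = {u: sum(n2(w) for w in g.neighbors(u)) for u in g.nodes}
    return {v: float(sum(q[u] for u in g.neighbors(v))) for v in g.nodes}


def clustering_triangles(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        tri = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        out[v] = 2.0 * tri / (k * (k - 1))
    return out


def kshell_pruning(g: nx.Graph) -> dict:
    """Literal iterative pruning: remove all degree <= k nodes at level k."""
    h = g.copy()
    out = {}
    k = 0
    while h.number_of_nodes():
        k_level = k
        while True:
            low = [n for n, d in h.degree() if d <= k_level]
            if not low:
                break
            for n in low:
                out[n] = k_level
                h.remove_node(n)
        k += 1
    return out


def pagerank_linear_solve(g: nx.Graph, damping: float = 0.85) -> dict:
    """Direct dense solve of (I - d P^T) pi = (1-d)/n for a connected graph."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    deg = a.sum(axis=1)
    p = np.where(deg[:, None] > 0, a / np.where(deg[:, None] == 0, 1, deg[:, None]), 1.0 / n)
    pi = np.linalg.solve(np.eye(n) - damping * p.T, np.full(n, (1 - damping) / n))
    pi /= pi.sum()
    return dict(zip(nodes, pi))


def eigenvector_dense(g: nx.Graph) -> dict:
    """Principal eigenvector by full dense eigendecomposition (connected g)."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    vec /= np.linalg.norm(vec)
    return dict(zip(nodes, vec))


def fisher_2x2_enumeration(table) -> float:
    """Two-sided Fisher exact p by exhausting the hypergeometric support.

    Sums the probabilities of every 2x2 table with the observed margins
    whose probability does not exceed the observed table's.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):  # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def hypergeom_tail(k, M, n, N) -> float:
    """Upper-tail P[X >= k] by direct summation of the pmf."""
    lo, hi = max(0, n + N - M), min(n, N)
    return sum(comb(n, x) * comb(M - n, N - x) / comb(M, N)
               for x in range(max(k, lo), hi + 1))


def auc_concordance(y_pos: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the fraction of concordant (positive, negative) pairs, ties 1/2."""
    pos = scores[y_pos == 1]
    neg = scores[y_pos == 0]
    total = len(pos) * len(neg)
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / total


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg, literal definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch statistic and two-sided p from the textbook formula."""
    from scipy.stats import t as tdist

    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (mb - ma) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * tdist.sf(abs(t), df)


def random_connected_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """A uniformly messy small connected graph for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    while True:
        p = rng.uniform(0.25, 0.9)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if g.number_of_edges() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
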