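"""Per-node topological indexes.

Seven measures of node importance feed the downstream factor model, in a
fixed column order: degree, betweenness, semi-local centrality, clustering
coefficient, k-shell index, PageRank, eigenvector centrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: Fixed column order of the topology profile matrix.
MEASURES = (
    "degree",
    "betweenness",
    "semilocal",
    "clustering",
    "kshell",
    "pagerank",
    "eigenvector",
)

PAGERANK_TOL = 1e-10
POWER_TOL = 1e-10
MAX_ITER = 10_000


def degree_centrality(g: nx.Graph) -> dict[str, float]:
    """Number of incident edges per node."""
    return {n: float(d) for n, d in g.degree()}


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness.

    For node v, the sum over unordered pairs {s, t} (s != t != v) of the
    fraction of shortest s-t paths passing through v.
    """
    return nx.betweenness_centrality(g, normalized=False)


def semilocal_centrality(g: nx.Graph) -> dict[str, float]:
    """Semi-local centrality: a three-level neighbourhood sum.

    N(w) is the number of distinct nodes within distance 2 of w (w itself
    excluded); Q(u) = sum of N(w) over neighbours w of u; CL(v) = sum of
    Q(u) over neighbours u of v.  Captures influence beyond immediate degree
    at near-linear cost, unlike global measures.
    """
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    n2 = {}
    for w, nbrs in adj.items():
        reach = set(nbrs)
        for u in nbrs:
            reach |= adj[u]
        reach.discard(w)
        n2[w] = len(reach)
    q = {u: sum(n2[w] for w in adj[u]) for u in g.nodes}
    return {v: float(sum(q[u] for u in adj[v])) for v in g.nodes}


def clustering_coefficient(g: nx.Graph) -> dict[str, float]:
    """Local clustering coefficient; 0 for nodes of degree < 2."""
    return nx.clustering(g)


def kshell_index(g: nx.Graph) -> dict[str, int]:
    """k-shell (core) index by iterative pruning of degree <= k nodes."""
    h = g.copy()
    h.remove_edges_from(nx.selfloop_edges(h))
    return nx.core_number(h)


def pagerank(g: nx.Graph, damping: float = 0.85, tol: float = PAGERANK_TOL) -> dict[str, float]:
    """Stationary distribution of the damped random walk; sums to 1.

    Raises on non-convergence, naming the iteration cap.
    """
    try:
        return nx.pagerank(g, alpha=damping, tol=tol, max_iter=MAX_ITER)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"PageRank power iteration failed to converge within {MAX_ITER} iterations"
        ) from exc


def eigenvector_centrality(g: nx.Graph, tol: float = POWER_TOL) -> dict[str, float]:
    """Principal adjacency eigenvector, non-negative, unit Euclidean norm.

    Computed on the largest connected component; nodes outside it get 0,
    which keeps the measure well-defined on disconnected inputs.
    """
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = sorted(components[0])
    out = {n: 0.0 for n in g.nodes}
    if len(giant) == 1:
        out[giant[0]] = 1.0
        return out
    a = nx.to_numpy_array(g, nodelist=giant)
    # +I shift keeps the principal eigenvector but breaks the +/-lambda
    # symmetry of bipartite spectra that stalls plain power iteration
    a = a + np.eye(len(giant))
    v = np.full(len(giant), 1.0 / np.sqrt(len(giant)))
    for _ in range(MAX_ITER):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise RuntimeError("eigenvector iteration collapsed to zero")
        w /= norm
        if np.linalg.norm(w - v, 1) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError(
            f"eigenvector power iteration failed to converge within {MAX_ITER} iterations"
        )
    v = np.abs(v)
    v /= np.linalg.norm(v)
    for node, val in zip(giant, v):
        out[node] = float(val)
    return out


@dataclass
class TopologyProfile:
    """Node-by-measure matrix of the seven topological indexes.

    ``X`` has one column per entry of :data:`MEASURES`, rows aligned with
    ``nodes`` (sorted symbol order).
    """

    nodes: list[str]
    X: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.nodes, columns=list(MEASURES))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TopologyProfile":
        missing = [m for m in MEASURES if m not in df.columns]
        if missing:
            raise ValueError(f"topology table missing columns: {missing}")
        return cls(nodes=list(df.index), X=df[list(MEASURES)].to_numpy(dtype=float))


def topology_profile(g: nx.Graph, damping: float = 0.85) -> TopologyProfile:
    """Assemble all seven measures into one profile, rows in sorted node order."""
    nodes = sorted(g.nodes)
    columns = (
        degree_centrality(g),
        betweenness_centrality(g),
        semilocal_centrality(g),
        clustering_coefficient(g),
        kshell_index(g),
        pagerank(g, damping=damping),
        eigenvector_centrality(g),
    )
    x = np.column_stack([[col[n] for n in nodes] for col in columns]).astype(float)
    return TopologyProfile(nodes=nodes, X=x)
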