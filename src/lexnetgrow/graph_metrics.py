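"""Network measures for orthographic lexicon graphs.

For each lexicon the analysis reports: the number of connected nodes *n*,
the mean degree <k>, the degree distribution P(k), the average shortest
path length L, the diameter D, the average clustering coefficient C, and
the count and proportion of lexical hermits (hermit proportion is taken
over the whole lexicon, hermits included).

Conventions (the graph may be disconnected even after hermit removal):

* L averages over ordered reachable pairs only; unreachable pairs are
  excluded rather than penalized.
* D is the maximum *finite* shortest-path length.
* Local clustering C_i = 2 T_i / (k_i (k_i - 1)) is undefined for degree
  < 2; such nodes are excluded from the average C by default, with an
  explicit option to count them as zero instead.

Path lengths come from breadth-first search (scipy's sparse-graph
routines).  Exact mode runs BFS from every node; sampled mode runs BFS from
``n_sources`` uniformly drawn sources and pools distances — a ratio
estimator of L whose numerator and denominator are both unbiased — and
yields a lower bound for D.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Mapping, Protocol

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .growth_simulator import VirtualLexicon

#: Above this node count, "auto" path mode switches from exact to sampled BFS.
EXACT_PATH_NODE_LIMIT = 5_000
DEFAULT_N_SOURCES = 1_000

PathMode = Literal["exact", "sampled", "auto"]


class AdjacencyGraph(Protocol):
    """Structural interface shared by OrthoGraph and ad-hoc test graphs."""

    nodes: frozenset[str]
    hermits: frozenset[str]
    adjacency: Mapping[str, frozenset[str]]


@dataclass(frozen=True)
class NetworkMeasures:
    """Per-lexicon record of the graph measures.

    ``n + hermit_count == lexicon_size``; ``degree_distribution`` covers
    connected nodes only (so degree 0 never appears and sums to 1);
    ``path_length_mode`` records whether L and D are exact or BFS-sampled
    (sampled D is a lower bound).  Measures that are undefined on the given
    graph (e.g. on an all-hermit lexicon) are NaN/None.
    """

    lexicon_size: int
    n: int
    mean_degree: float
    degree_distribution: Mapping[int, float]
    avg_path_length: float
    diameter: int | None
    clustering: float
    hermit_count: int
    hermit_proportion: float
    path_length_mode: str


def _require_nonempty(graph: AdjacencyGraph) -> None:
    if not graph.nodes:
        raise ValueError("graph has no connected nodes")


def mean_degree(graph: AdjacencyGraph) -> float:
    """Mean number of neighbors per connected node: 2|E| / |V|."""
    _require_nonempty(graph)
    total = sum(len(vs) for vs in graph.adjacency.values())
    return total / len(graph.nodes)


def degree_distribution(graph: AdjacencyGraph) -> dict[int, float]:
    """Relative frequency P(k) of each observed degree among connected nodes."""
    _require_nonempty(graph)
    counts = Counter(len(graph.adjacency[u]) for u in graph.nodes)
    n = len(graph.nodes)
    return {k: c / n for k, c in sorted(counts.items())}


def local_clustering(graph: AdjacencyGraph, node: str) -> float | None:
    """C_i = 2 T_i / (k_i (k_i - 1)); ``None`` when the degree is below 2.

    T_i is the number of edges among the node's neighbors.
    """
    if node not in graph.adjacency:
        raise KeyError(f"node {node!r} not in graph")
    neighbors = graph.adjacency[node]
    k = len(neighbors)
    if k < 2:
        return None
    links = sum(len(graph.adjacency[v] & neighbors) for v in neighbors) // 2
    return 2.0 * links / (k * (k - 1))


def average_clustering(
    graph: AdjacencyGraph,
    *,
    count_undefined_as_zero: bool = False,
) -> float:
    """Average clustering coefficient C over connected nodes.

    By default only nodes of degree >= 2 (where C_i is defined) enter the
    mean; with ``count_undefined_as_zero`` degree-1 nodes contribute 0.
    """
    _require_nonempty(graph)
    values = []
    for u in graph.nodes:
        c = local_clustering(graph, u)
        if c is not None:
            values.append(c)
        elif count_undefined_as_zero:
            values.append(0.0)
    if not values:
        raise ValueError("no node has degree >= 2; clustering undefined")
    return float(np.mean(values))


def _node_order(graph: AdjacencyGraph) -> list[str]:
    return sorted(graph.nodes)


def _to_csr(graph: AdjacencyGraph, order: list[str]) -> csr_matrix:
    index = {u: i for i, u in enumerate(order)}
    indptr = [0]
    indices: list[int] = []
    for u in order:
        nbrs = sorted(index[v] for v in graph.adjacency[u])
        indices.extend(nbrs)
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.int8)
    n = len(order)
    return csr_matrix((data, indices, indptr), shape=(n, n))


def _bfs_distances(
    graph: AdjacencyGraph,
    sources: np.ndarray | None,
) -> np.ndarray:
    order = _node_order(graph)
    csr = _to_csr(graph, order)
    return shortest_path(
        csr,
        method="D",
        directed=False,
        unweighted=True,
        indices=sources,
    )


def _finite_offdiag(dist: np.ndarray, sources: np.ndarray | None) -> np.ndarray:
    n = dist.shape[1]
    rows = np.arange(dist.shape[0]) if sources is None else np.asarray(sources)
    mask = np.isfinite(dist)
    mask[np.arange(dist.shape[0]), rows] = False  # drop self-distances
    return dist[mask]


def _resolve_sources(
    graph: AdjacencyGraph,
    mode: PathMode,
    n_sources: int,
    rng: np.random.Generator | int | None,
) -> tuple[np.ndarray | None, str]:
    n = len(graph.nodes)
    if mode == "auto":
        mode = "exact" if n <= EXACT_PATH_NODE_LIMIT else "sampled"
    if mode == "exact":
        return None, "exact"
    if n_sources > n:
        raise ValueError(f"n_sources {n_sources} exceeds node count {n}")
    if rng is None:
        raise ValueError("sampled mode requires an rng (seed or Generator)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sources = np.sort(rng.choice(n, size=n_sources, replace=False))
    return sources, "sampled"


def average_path_length(
    graph: AdjacencyGraph,
    mode: PathMode = "exact",
    n_sources: int = DEFAULT_N_SOURCES,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Average shortest-path length L over ordered reachable node pairs.

    Exact mode runs BFS from every node.  Sampled mode pools distances from
    ``n_sources`` uniform sources (without replacement); numerator and
    denominator of the pooled ratio are each unbiased for their exact
    counterparts.  Deterministic given ``rng``.
    """
    if len(graph.nodes) < 2:
        raise ValueError("need at least 2 connected nodes for path lengths")
    sources, _ = _resolve_sources(graph, mode, n_sources, rng)
    finite = _finite_offdiag(_bfs_distances(graph, sources), sources)
    if finite.size == 0:  # pragma: no cover - impossible with degree >= 1
        raise ValueError("no reachable pairs")
    return float(finite.mean())


def diameter(
    graph: AdjacencyGraph,
    mode: PathMode = "exact",
    n_sources: int = DEFAULT_N_SOURCES,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Maximum finite shortest-path length D.

    With disconnected graphs this is the largest within-component
    eccentricity.  In sampled mode the value is a lower bound (max over the
    sampled BFS trees); :func:`compute_all_measures` records the mode.
    """
    if len(graph.nodes) < 2:
        raise ValueError("need at least 2 connected nodes for path lengths")
    sources, _ = _resolve_sources(graph, mode, n_sources, rng)
    finite = _finite_offdiag(_bfs_distances(graph, sources), sources)
    return int(finite.max())


def compute_all_measures(
    lexicon: VirtualLexicon | None,
    graph: AdjacencyGraph,
    path_mode: PathMode = "auto",
    n_sources: int = DEFAULT_N_SOURCES,
    rng: np.random.Generator | int | None = None,
    *,
    count_undefined_as_zero: bool = False,
) -> NetworkMeasures:
    """Fill a complete :class:`NetworkMeasures` record for one lexicon graph.

    ``lexicon`` is only used for consistency checking (the graph must have
    been built from its types); pass ``None`` for standalone graphs.  On an
    all-hermit lexicon every graph measure is NaN/None.  With the same seed
    and sampled mode the record is identical across reruns.
    """
    if lexicon is not None and graph.lexicon_size != lexicon.size:
        raise ValueError(
            f"graph covers {graph.lexicon_size} types but lexicon has {lexicon.size}"
        )
    lexicon_size = graph.lexicon_size
    n = len(graph.nodes)
    hermit_count = len(graph.hermits)
    hermit_proportion = hermit_count / lexicon_size if lexicon_size else float("nan")
    if n == 0:
        return NetworkMeasures(
            lexicon_size=lexicon_size,
            n=0,
            mean_degree=float("nan"),
            degree_distribution={},
            avg_path_length=float("nan"),
            diameter=None,
            clustering=float("nan"),
            hermit_count=hermit_count,
            hermit_proportion=hermit_proportion,
            path_length_mode="undefined",
        )
    sources, resolved_mode = _resolve_sources(graph, path_mode, n_sources, rng)
    if n >= 2:
        finite = _finite_offdiag(_bfs_distances(graph, sources), sources)
        L = float(finite.mean())
        D: int | None = int(finite.max())
    else:
        L, D = float("nan"), None
    try:
        C = average_clustering(graph, count_undefined_as_zero=count_undefined_as_zero)
    except ValueError:
        C = float("nan")
    return NetworkMeasures(
        lexicon_size=lexicon_size,
        n=n,
        mean_degree=mean_degree(graph),
        degree_distribution=degree_distribution(graph),
        avg_path_length=L,
        diameter=D,
        clustering=C,
        hermit_count=hermit_count,
        hermit_proportion=hermit_proportion,
        path_length_mode=resolved_mode,
    )
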