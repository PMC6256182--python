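"""Orthographic neighbor networks: Levenshtein-distance-1 graphs and hermits.

Two word types are orthographic neighbors iff their Levenshtein distance is
exactly 1 — one substitution, insertion, or deletion turns one into the
other ("hat" ~ "hot", "hat" ~ "hate").  Types with no neighbor in the
lexicon are *lexical hermits*; they are excluded from the connected graph
but counted, since their proportion is itself informative.

The graph is built without any all-pairs distance computation:

* substitution pairs (equal length) are found through single-position
  wildcard buckets — two words land in the same ``(length, position,
  prefix, suffix)`` bucket iff they agree everywhere except that position;
* insertion/deletion pairs (length difference 1) are found by checking each
  single-deletion variant of the longer word for exact membership.

The naive shared-deletion-variant shortcut is deliberately avoided: it
would also admit transpositions ("ab"/"ba"), which are distance 2.

Distances are computed over Unicode code points after NFC normalization,
case-sensitively: "ä" is one symbol, and distinct capitalizations are
distinct types.
"""

from __future__ import annotations

import unicodedata
from collections import defaultdict
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion).

    No transpositions: ``levenshtein_distance("ab", "ba") == 2``.  Operates
    on NFC-normalized Unicode code points.
    """
    a = unicodedata.normalize("NFC", a)
    b = unicodedata.normalize("NFC", b)
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(
                    previous[j] + 1,        # deletion
                    current[j - 1] + 1,     # insertion
                    previous[j - 1] + (ca != cb),  # substitution / match
                )
            )
        previous = current
    return previous[-1]


@dataclass(frozen=True)
class OrthoGraph:
    """Undirected graph of word types connected iff Levenshtein distance is 1.

    ``nodes`` holds only the connected types (degree >= 1); degree-0 types
    are in ``hermits``.  ``adjacency`` is symmetric and covers exactly
    ``nodes``.  ``lexicon_size == len(nodes) + len(hermits)``.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    hermits: frozenset[str]
    adjacency: Mapping[str, frozenset[str]]

    @property
    def lexicon_size(self) -> int:
        return len(self.nodes) + len(self.hermits)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return len(self.adjacency[node])

    @classmethod
    def from_edge_list(
        cls,
        edges: Iterable[tuple[str, str]],
        hermits: Iterable[str] = (),
    ) -> "OrthoGraph":
        """Rebuild a graph from an explicit edge list plus hermit set.

        Trusts the caller that every edge pair is at distance 1; used to
        reload graphs written to disk and to analyze externally supplied
        edge lists.
        """
        adjacency: dict[str, set[str]] = defaultdict(set)
        edge_set: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            adjacency[a].add(b)
            adjacency[b].add(a)
            edge_set.add((min(a, b), max(a, b)))
        nodes = frozenset(adjacency)
        hermit_set = frozenset(hermits) - nodes
        return cls(
            nodes=nodes,
            edges=frozenset(edge_set),
            hermits=hermit_set,
            adjacency={u: frozenset(vs) for u, vs in adjacency.items()},
        )


def _substitution_pairs(words: Collection[str]) -> set[tuple[str, str]]:
    buckets: dict[tuple[int, int, str, str], list[str]] = defaultdict(list)
    for w in words:
        L = len(w)
        for i in range(L):
            buckets[(L, i, w[:i], w[i + 1:])].append(w)
    pairs: set[tuple[str, str]] = set()
    for bucket in buckets.values():
        if len(bucket) > 1:
            bucket.sort()
            for i, a in enumerate(bucket):
                for b in bucket[i + 1:]:
                    pairs.add((a, b))
    return pairs


def _indel_pairs(words: Collection[str]) -> set[tuple[str, str]]:
    word_set = set(words)
    pairs: set[tuple[str, str]] = set()
    for w in word_set:
        for i in range(len(w)):
            shorter = w[:i] + w[i + 1:]
            if shorter in word_set:  # exact match => true insertion/deletion
                pairs.add((min(w, shorter), max(w, shorter)))
    return pairs


def build_neighbor_graph(types: Collection[str]) -> OrthoGraph:
    """Build the exact Levenshtein-1 neighbor graph over a set of word types.

    Scales to corpora of 10^5 types through the wildcard-bucket /
    deletion-variant index; the result is independent of input order.
    Raises :class:`ValueError` if the input contains an empty string.
    """
    normalized = {unicodedata.normalize("NFC", t) for t in types}
    if "" in normalized:
        raise ValueError("word types must be non-empty strings")
    edges = _substitution_pairs(normalized) | _indel_pairs(normalized)
    adjacency: dict[str, set[str]] = defaultdict(set)
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    nodes = frozenset(adjacency)
    return OrthoGraph(
        nodes=nodes,
        edges=frozenset(edges),
        hermits=frozenset(normalized - nodes),
        adjacency={u: frozenset(vs) for u, vs in adjacency.items()},
    )


def ego_network(
    graph_source: Collection[str],
    focus: str,
    max_distance: int = 2,
) -> tuple[OrthoGraph, float | None]:
    """Subgraph of types within ``max_distance`` edits of ``focus``.

    Membership uses the Levenshtein distance to the focus word; edges within
    the subgraph still require pairwise distance exactly 1.  Returns the
    subgraph together with the focus word's local clustering coefficient
    (``None`` when the focus has fewer than two neighbors).
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    focus = unicodedata.normalize("NFC", focus)
    normalized = {unicodedata.normalize("NFC", t) for t in graph_source}
    if focus not in normalized:
        raise KeyError(f"focus {focus!r} not in graph source")
    selected = {
        t
        for t in normalized
        if abs(len(t) - len(focus)) <= max_distance
        and levenshtein_distance(t, focus) <= max_distance
    }
    sub = build_neighbor_graph(selected)
    if focus in sub.nodes and sub.degree(focus) >= 2:
        from .graph_metrics import local_clustering

        focus_c: float | None = local_clustering(sub, focus)
    else:
        focus_c = None
    return sub, focus_c
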