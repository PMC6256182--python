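"""Shared fixtures and tiny oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lexnetgrow import CorpusGenConfig, FrequencyLexicon, generate_corpus
from lexnetgrow.ortho_neighbors import OrthoGraph


def graph_from_edges(edges, isolated=()):
    """Arbitrary undirected test graph in the OrthoGraph container."""
    return OrthoGraph.from_edge_list(
        [(str(a), str(b)) for a, b in edges], [str(v) for v in isolated]
    )


def path_graph(n):
    return graph_from_edges([(i, i + 1) for i in range(n - 1)])


def cycle_graph(n):
    return graph_from_edges([(i, (i + 1) % n) for i in range(n)])


def complete_graph(n):
    return graph_from_edges([(i, j) for i in range(n) for j in range(i + 1, n)])


def random_graph(n, p, seed):
    """Erdos-Renyi-style random graph; isolated vertices become hermits."""
    rng = np.random.default_rng(seed)
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    present = {v for e in edges for v in e}
    isolated = [v for v in range(n) if v not in present]
    return graph_from_edges(edges, isolated)


def random_words(n, alphabet_size, max_len, seed, min_len=1):
    """Random unique word set over the first ``alphabet_size`` letters.

    ``n`` is capped at 70% of the available string space so rejection
    sampling always terminates quickly.
    """
    rng = np.random.default_rng(seed)
    letters = "abcdefghijklmnopqrstuvwxyz"[:alphabet_size]
    capacity = sum(alphabet_size**L for L in range(min_len, max_len + 1))
    n = min(n, int(0.7 * capacity))
    words = set()
    while len(words) < n:
        length = rng.integers(min_len, max_len + 1)
        words.add("".join(rng.choice(list(letters), size=length)))
    return words


@pytest.fixture(scope="session")
def small_corpus() -> FrequencyLexicon:
    """Tiny deterministic frequency lexicon for sampling tests."""
    words = ("hat", "hot", "hate", "cold", "zz", "qqq", "mouse", "house", "mice", "dog")
    freqs = np.array([100.0, 60.0, 30.0, 20.0, 10.0, 8.0, 5.0, 3.0, 2.0, 1.0])
    return FrequencyLexicon(words, freqs)


@pytest.fixture(scope="session")
def default_corpus() -> FrequencyLexicon:
    """One 5,000-type synthetic corpus under generator defaults."""
    return generate_corpus(CorpusGenConfig(n_types=5_000, seed=42))
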