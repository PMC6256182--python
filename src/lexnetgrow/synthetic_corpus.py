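"""Synthetic frequency lexicons with the statistical structure of a print corpus.

The generator emulates the three properties of a children's print corpus that
the growth analysis relies on:

1. a Zipfian token-frequency distribution over word types
   (frequency of rank *r* proportional to ``r ** -zipf_exponent``);
2. a negative correlation between frequency and word length — high-frequency
   types tend to be short, which is what couples frequency to orthographic
   neighborhood density;
3. a substantial fraction of types without any Levenshtein-1 neighbor
   ("lexical hermits"), because most strings drawn from a large combinatorial
   space are isolated.

Word material is random strings, not German morphology; results on synthetic
corpora are therefore directional, not numerical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import FrequencyLexicon

DEFAULT_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


class CapacityError(ValueError):
    """Raised when the configured string space cannot host the requested types."""


@dataclass(frozen=True)
class CorpusGenConfig:
    """Configuration for :func:`generate_corpus`.

    Parameters
    ----------
    n_types:
        Number of distinct word types to generate.
    zipf_exponent:
        Exponent of the rank-frequency power law (1.0 is classic Zipf).
    alphabet:
        Characters words are built from; must have >= 2 distinct symbols.
    length_min, length_max:
        Inclusive bounds on word length.
    length_frequency_link:
        Strength in [0, 1] of the frequency-length coupling: 0 makes mean
        length independent of rank, 1 moves the mean linearly from
        ``length_min`` (rank 1) to ``length_max`` (last rank).
    length_sd:
        Standard deviation of the (discretized, clamped) normal from which a
        word's length is drawn around its rank-dependent mean.
    seed:
        Seed for the generator; output is fully deterministic given it.
    """

    n_types: int
    zipf_exponent: float = 1.0
    alphabet: str = DEFAULT_ALPHABET
    length_min: int = 2
    length_max: int = 7
    length_frequency_link: float = 0.6
    length_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if len(set(self.alphabet)) < 2:
            raise ValueError("alphabet must contain at least 2 distinct characters")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet characters must be distinct")
        if self.length_min < 1 or self.length_min > self.length_max:
            raise ValueError("need 1 <= length_min <= length_max")
        if not 0.0 <= self.length_frequency_link <= 1.0:
            raise ValueError("length_frequency_link must lie in [0, 1]")
        if self.length_sd < 0:
            raise ValueError("length_sd must be non-negative")

    def capacity(self) -> int:
        """Number of distinct strings available within the length bounds."""
        a = len(self.alphabet)
        return sum(a**L for L in range(self.length_min, self.length_max + 1))


def _mean_length(config: CorpusGenConfig, rank0: int) -> float:
    # rank quantile in [0, 1]; link blends a flat midpoint with a linear ramp
    q = rank0 / max(config.n_types - 1, 1)
    span = config.length_max - config.length_min
    link = config.length_frequency_link
    return config.length_min + span * ((1.0 - link) * 0.5 + link * q)


def _enumerate_fallback(config: CorpusGenConfig, seen: set[str]) -> str:
    # deterministic escape hatch for near-capacity configs: first unused
    # string, by length then lexicographically over the given alphabet order
    for length in range(config.length_min, config.length_max + 1):
        for chars in itertools.product(config.alphabet, repeat=length):
            word = "".join(chars)
            if word not in seen:
                return word
    raise CapacityError("string space exhausted")  # pragma: no cover


def generate_corpus(config: CorpusGenConfig) -> FrequencyLexicon:
    """Generate a synthetic frequency lexicon of exactly ``config.n_types`` types.

    Frequencies follow the configured power law over ranks (strictly
    decreasing, so ties are impossible).  Each word's length is drawn from a
    clamped, discretized normal whose mean shifts with rank according to
    ``length_frequency_link``; characters are i.i.d. uniform over the
    alphabet.  Collisions with already-generated strings are resolved by
    regeneration, so the output is a valid :class:`FrequencyLexicon`.

    Raises
    ------
    CapacityError
        If the alphabet/length bounds admit fewer distinct strings than
        ``n_types``.
    """
    if config.capacity() < config.n_types:
        raise CapacityError(
            f"alphabet of {len(config.alphabet)} symbols with lengths "
            f"[{config.length_min}, {config.length_max}] admits only "
            f"{config.capacity()} strings < n_types={config.n_types}"
        )
    rng = np.random.default_rng(config.seed)
    ranks = np.arange(1, config.n_types + 1, dtype=float)
    frequencies = ranks ** (-config.zipf_exponent)

    alphabet = np.array(list(config.alphabet))
    seen: set[str] = set()
    words: list[str] = []
    for rank0 in range(config.n_types):
        mu = _mean_length(config, rank0)
        for attempt in range(200):
            length = int(
                np.clip(
                    round(rng.normal(mu, config.length_sd)),
                    config.length_min,
                    config.length_max,
                )
            )
            word = "".join(rng.choice(alphabet, size=length))
            if word not in seen:
                break
        else:
            word = _enumerate_fallback(config, seen)
        seen.add(word)
        words.append(word)
    return FrequencyLexicon(tuple(words), frequencies)
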