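"""Staged lexicon growth by frequency-sensitive sampling without replacement.

A cohort of virtual participants all follow the same growth schedule: an
ordered list of grade checkpoints with target lexicon sizes (in word types).
Each participant's initial lexicon is drawn from the full corpus with
probability proportional to token frequency, without replacement
(successive sampling).  At every later checkpoint the *learning
environment* — the corpus minus the words already known — is sampled the
same way until the lexicon reaches the next target size.  Lexicons are
therefore nested along grades, sizes match the schedule exactly, and
high-frequency types enter early.

Randomness is derived from a single base seed via ``numpy`` seed sequences
keyed by (base_seed, participant_id, stage_index), so cohorts are exactly
reproducible and participants' draws are independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus_io import FrequencyLexicon
from .synthetic_corpus import CapacityError

#: Published grade-specific lexicon sizes in types (grades 1-6 and 8) for the
#: full-scale simulation against a ~180,000-type learning corpus.
PUBLISHED_GRADE_SIZES: tuple[tuple[str, int], ...] = (
    ("1", 31_570),
    ("2", 32_606),
    ("3", 46_757),
    ("4", 58_238),
    ("5", 71_344),
    ("6", 93_293),
    ("8", 130_675),
)

#: Four-stage demo schedule for a 5,000-type synthetic corpus: the published
#: sizes for grades 1, 3, 5 and 8 rescaled from the ~180k-type corpus.
DEMO_GRADE_SIZES: tuple[tuple[str, int], ...] = (
    ("1", 875),
    ("2", 1_300),
    ("3", 2_000),
    ("4", 3_630),
)


@dataclass(frozen=True)
class GrowthSchedule:
    """Ordered grade checkpoints with strictly increasing target sizes."""

    checkpoints: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.checkpoints:
            raise ValueError("schedule must have at least one checkpoint")
        labels = [label for label, _ in self.checkpoints]
        sizes = [size for _, size in self.checkpoints]
        if len(set(labels)) != len(labels):
            raise ValueError("grade labels must be unique")
        if any(s < 1 for s in sizes):
            raise ValueError("target sizes must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("target sizes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.checkpoints)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.checkpoints)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(size for _, size in self.checkpoints)

    @classmethod
    def published(cls) -> "GrowthSchedule":
        return cls(PUBLISHED_GRADE_SIZES)

    @classmethod
    def demo(cls) -> "GrowthSchedule":
        return cls(DEMO_GRADE_SIZES)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GrowthSchedule":
        """Load a schedule from a YAML list of ``{grade: <label>, size: <int>}``."""
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ValueError("schedule YAML must be a list of {grade, size} items")
        return cls(tuple((str(item["grade"]), int(item["size"])) for item in raw))


@dataclass(frozen=True)
class VirtualLexicon:
    """One virtual participant's known word types at one grade checkpoint.

    ``acquisition_stage`` maps every known type to the grade label at which
    it entered the lexicon; it is the basis of the frequency-trajectory
    diagnostic.
    """

    participant_id: int
    grade_label: str
    types: frozenset[str]
    acquisition_stage: Mapping[str, str]

    @property
    def size(self) -> int:
        return len(self.types)


def _stage_rng(base_seed: int, participant_id: int, stage_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(base_seed), int(participant_id), int(stage_index)])
    return np.random.default_rng(ss)


def weighted_sample_without_replacement(
    items: Sequence,
    weights: Sequence[float] | np.ndarray,
    m: int,
    rng: np.random.Generator | int,
) -> list:
    """Draw ``m`` items without replacement, probability proportional to weight.

    Distributionally identical to successive sampling — draw one item with
    probability proportional to its weight among the remaining, remove it,
    repeat — implemented via the exponential-race equivalence: each item gets
    the key ``E_i / w_i`` with ``E_i`` standard exponential, and the ``m``
    smallest keys are returned in key order.  Ties (probability zero) break
    by input order.  Deterministic given the generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    w = np.asarray(weights, dtype=float)
    if len(w) != len(items):
        raise ValueError("items and weights must have equal length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("all weights must be positive and finite")
    if m > len(items):
        raise CapacityError(f"cannot draw {m} items from a population of {len(items)}")
    if m < 0:
        raise ValueError("m must be non-negative")
    keys = rng.standard_exponential(len(w)) / w
    order = np.argsort(keys, kind="stable")[:m]
    return [items[i] for i in order]


def sample_initial_lexicon(
    corpus: FrequencyLexicon,
    target_size: int,
    participant_id: int,
    base_seed: int,
    grade_label: str = "1",
) -> VirtualLexicon:
    """Draw a participant's initial lexicon from the full corpus.

    Frequency-weighted without replacement; every drawn type is tagged with
    the first grade label.  Different participants under the same base seed
    use independent derived streams.
    """
    if target_size > len(corpus):
        raise CapacityError(
            f"target_size {target_size} exceeds corpus size {len(corpus)}"
        )
    rng = _stage_rng(base_seed, participant_id, 0)
    drawn = weighted_sample_without_replacement(
        corpus.words, corpus.frequencies, target_size, rng
    )
    return VirtualLexicon(
        participant_id=participant_id,
        grade_label=grade_label,
        types=frozenset(drawn),
        acquisition_stage={word: grade_label for word in drawn},
    )


def grow_lexicon(
    lexicon: VirtualLexicon,
    corpus: FrequencyLexicon,
    next_grade_label: str,
    next_target_size: int,
    rng: np.random.Generator | int,
) -> VirtualLexicon:
    """Grow a lexicon to the next checkpoint size.

    Samples exactly ``next_target_size - |lexicon|`` new types from the
    participant's learning environment (corpus minus known types),
    frequency-weighted without replacement; already-known words are never
    re-sampled.
    """
    n_new = next_target_size - lexicon.size
    if n_new <= 0:
        raise ValueError(
            f"next_target_size {next_target_size} must exceed current size {lexicon.size}"
        )
    known = lexicon.types
    env_idx = [i for i, word in enumerate(corpus.words) if word not in known]
    if n_new > len(env_idx):
        raise CapacityError(
            f"learning environment has {len(env_idx)} types, need {n_new}"
        )
    env_words = [corpus.words[i] for i in env_idx]
    env_weights = corpus.frequencies[env_idx]
    drawn = weighted_sample_without_replacement(env_words, env_weights, n_new, rng)
    stages = dict(lexicon.acquisition_stage)
    for word in drawn:
        stages[word] = next_grade_label
    return VirtualLexicon(
        participant_id=lexicon.participant_id,
        grade_label=next_grade_label,
        types=known | frozenset(drawn),
        acquisition_stage=stages,
    )


def iter_cohort(
    corpus: FrequencyLexicon,
    schedule: GrowthSchedule,
    n_participants: int,
    base_seed: int,
) -> Iterator[VirtualLexicon]:
    """Yield every (participant, grade) lexicon without retaining them all.

    Participants are numbered 1..n; lexicons are yielded participant by
    participant in schedule order, so per-participant nesting can be checked
    (and memory stays bounded) on full-scale cohorts.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if schedule.sizes[-1] > len(corpus):
        raise CapacityError(
            f"final target size {schedule.sizes[-1]} exceeds corpus size {len(corpus)}"
        )
    first_label, first_size = schedule.checkpoints[0]
    for pid in range(1, n_participants + 1):
        lex = sample_initial_lexicon(corpus, first_size, pid, base_seed, first_label)
        yield lex
        for stage_index, (label, size) in enumerate(schedule.checkpoints[1:], start=1):
            rng = _stage_rng(base_seed, pid, stage_index)
            lex = grow_lexicon(lex, corpus, label, size, rng)
            yield lex


def simulate_cohort(
    corpus: FrequencyLexicon,
    schedule: GrowthSchedule,
    n_participants: int,
    base_seed: int,
) -> dict[tuple[int, str], VirtualLexicon]:
    """Simulate the whole cohort: n_participants x len(schedule) lexicons.

    Fully reproducible from ``base_seed``; the result maps
    ``(participant_id, grade_label)`` to the lexicon at that checkpoint.
    """
    return {
        (lex.participant_id, lex.grade_label): lex
        for lex in iter_cohort(corpus, schedule, n_participants, base_seed)
    }


def new_word_frequency_trajectory(
    cohort: Mapping[tuple[int, str], VirtualLexicon],
    corpus: FrequencyLexicon,
) -> pd.DataFrame:
    """Mean corpus frequency of newly acquired words per grade.

    For each participant's final lexicon, words are grouped by the grade at
    which they entered; the per-grade means of their corpus frequencies are
    averaged over participants.  A decreasing trajectory is the signature of
    frequency-driven acquisition: high-frequency words are learned first.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    freq = corpus.frequency_of()
    # final lexicon per participant carries the full acquisition history
    finals: dict[int, VirtualLexicon] = {}
    for lex in cohort.values():
        cur = finals.get(lex.participant_id)
        if cur is None or lex.size > cur.size:
            finals[lex.participant_id] = lex
    grade_order = _grade_order(cohort)
    per_grade: dict[str, list[float]] = {g: [] for g in grade_order}
    for lex in finals.values():
        sums: dict[str, float] = {g: 0.0 for g in grade_order}
        counts: dict[str, int] = {g: 0 for g in grade_order}
        for word, grade in lex.acquisition_stage.items():
            sums[grade] += freq[word]
            counts[grade] += 1
        for g in grade_order:
            if counts[g]:
                per_grade[g].append(sums[g] / counts[g])
    rows = [
        {"grade": g, "mean_frequency": float(np.mean(per_grade[g]))}
        for g in grade_order
        if per_grade[g]
    ]
    return pd.DataFrame(rows)


def _grade_order(cohort: Mapping[tuple[int, str], VirtualLexicon]) -> list[str]:
    # grade order = order of increasing lexicon size for any one participant
    pid = min(p for p, _ in cohort)
    labeled = [(lex.size, g) for (p, g), lex in cohort.items() if p == pid]
    return [g for _, g in sorted(labeled)]
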