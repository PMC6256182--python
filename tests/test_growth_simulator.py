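"""Frequency-sensitive growth simulation: sampler law, nesting, trajectories."""

import itertools

import numpy as np
import pytest

from lexnetgrow import (
    CapacityError,
    CorpusGenConfig,
    FrequencyLexicon,
    GrowthSchedule,
    generate_corpus,
    grow_lexicon,
    iter_cohort,
    new_word_frequency_trajectory,
    sample_initial_lexicon,
    simulate_cohort,
    weighted_sample_without_replacement,
)
from lexnetgrow.growth_simulator import PUBLISHED_GRADE_SIZES


def successive_sampling_set_probability(weights, subset):
    """Exact probability that successive sampling draws exactly ``subset``.

    Enumerates every ordered draw path; the independent oracle for the
    sampler's distribution.
    """
    total_p = 0.0
    for order in itertools.permutations(subset):
        p, remaining = 1.0, dict(enumerate(weights))
        for idx in order:
            p *= remaining[idx] / sum(remaining.values())
            del remaining[idx]
        total_p += p
    return total_p


class TestWeightedSampler:
    def test_exhaustive_draw_returns_everything(self):
        out = weighted_sample_without_replacement(["a", "b", "c"], [1, 1, 1], 3, 0)
        assert sorted(out) == ["a", "b", "c"]

    def test_single_draw_proportionality(self):
        # P(first item) = 2/4 = 0.5 under weights (2,1,1)
        rng = np.random.default_rng(123)
        hits = sum(
            weighted_sample_without_replacement("xyz", [2, 1, 1], 1, rng)[0] == "x"
            for _ in range(20_000)
        )
        se = np.sqrt(0.5 * 0.5 / 20_000)
        assert abs(hits / 20_000 - 0.5) < 3 * se

    def test_pair_set_probability_matches_enumeration(self):
        # oracle: P({item0, item1}) = 1/2*1/2 + 1/4*2/3 = 5/12
        exact = successive_sampling_set_probability([2, 1, 1], (0, 1))
        assert exact == pytest.approx(5 / 12)
        rng = np.random.default_rng(7)
        n_rep = 20_000
        hits = 0
        for _ in range(n_rep):
            drawn = weighted_sample_without_replacement([0, 1, 2], [2, 1, 1], 2, rng)
            hits += set(drawn) == {0, 1}
        se = np.sqrt(exact * (1 - exact) / n_rep)
        assert abs(hits / n_rep - exact) < 3 * se

    def test_deterministic_given_seed(self):
        a = weighted_sample_without_replacement(list(range(50)), np.arange(1, 51), 10, 99)
        b = weighted_sample_without_replacement(list(range(50)), np.arange(1, 51), 10, 99)
        assert a == b

    def test_error_cases(self):
        with pytest.raises(CapacityError):
            weighted_sample_without_replacement([1, 2], [1, 1], 3, 0)
        with pytest.raises(ValueError):
            weighted_sample_without_replacement([1, 2], [1, 0], 1, 0)
        with pytest.raises(ValueError):
            weighted_sample_without_replacement([1, 2], [1, -2], 1, 0)


class TestInitialLexicon:
    def test_exhaustive_draw_is_whole_corpus(self, small_corpus):
        lex = sample_initial_lexicon(small_corpus, 10, participant_id=1, base_seed=0)
        assert lex.types == frozenset(small_corpus.words)
        assert set(lex.acquisition_stage.values()) == {"1"}

    def test_participants_draw_independently(self, small_corpus):
        a = sample_initial_lexicon(small_corpus, 5, participant_id=1, base_seed=0)
        b = sample_initial_lexicon(small_corpus, 5, participant_id=2, base_seed=0)
        assert a.types != b.types or a is not b  # same seed, distinct streams
        # a stronger check: over several seeds the lexicons differ at least once
        assert any(
            sample_initial_lexicon(small_corpus, 5, 1, s).types
            != sample_initial_lexicon(small_corpus, 5, 2, s).types
            for s in range(5)
        )

    def test_oversized_target_rejected(self, small_corpus):
        with pytest.raises(CapacityError):
            sample_initial_lexicon(small_corpus, 11, participant_id=1, base_seed=0)

    def test_high_frequency_head_nearly_always_included(self, default_corpus):
        """Top-1% types enter nearly every initial lexicon at 20% target size."""
        head = set(default_corpus.words[: len(default_corpus) // 100])
        target = len(default_corpus) // 5
        n_participants = 50
        inclusion = []
        for pid in range(1, n_participants + 1):
            lex = sample_initial_lexicon(default_corpus, target, pid, base_seed=17)
            inclusion.append(len(head & lex.types) / len(head))
        assert np.mean(inclusion) >= 0.95


class TestGrowLexicon:
    def test_exhausting_environment_gives_full_corpus(self, small_corpus):
        lex = sample_initial_lexicon(small_corpus, 4, participant_id=1, base_seed=2)
        grown = grow_lexicon(lex, small_corpus, "2", 10, np.random.default_rng(0))
        assert grown.types == frozenset(small_corpus.words)
        assert grown.grade_label == "2"

    def test_known_words_never_resampled(self, small_corpus):
        for seed in range(10):
            lex = sample_initial_lexicon(small_corpus, 4, 1, seed)
            grown = grow_lexicon(lex, small_corpus, "2", 7, np.random.default_rng(seed))
            new = grown.types - lex.types
            assert len(new) == 3
            assert lex.types <= grown.types
            assert all(grown.acquisition_stage[w] == "2" for w in new)

    def test_capacity_and_shrink_errors(self, small_corpus):
        lex = sample_initial_lexicon(small_corpus, 8, 1, 0)
        with pytest.raises(CapacityError):
            grow_lexicon(lex, small_corpus, "2", 11, 0)
        with pytest.raises(ValueError):
            grow_lexicon(lex, small_corpus, "2", 8, 0)


class TestCohort:
    def test_counts_sizes_and_nesting(self, small_corpus):
        schedule = GrowthSchedule((("1", 3), ("2", 5), ("3", 8)))
        cohort = simulate_cohort(small_corpus, schedule, n_participants=4, base_seed=5)
        assert len(cohort) == 4 * 3
        for pid in range(1, 5):
            sizes = [cohort[(pid, g)].size for g in ("1", "2", "3")]
            assert sizes == [3, 5, 8]
            assert cohort[(pid, "1")].types <= cohort[(pid, "2")].types <= cohort[(pid, "3")].types

    def test_single_checkpoint_reduces_to_initial_sample(self, small_corpus):
        schedule = GrowthSchedule((("1", 4),))
        cohort = simulate_cohort(small_corpus, schedule, 1, base_seed=9)
        direct = sample_initial_lexicon(small_corpus, 4, 1, base_seed=9)
        assert cohort[(1, "1")].types == direct.types

    def test_rerun_identical(self, small_corpus):
        schedule = GrowthSchedule((("1", 3), ("2", 6)))
        a = simulate_cohort(small_corpus, schedule, 3, base_seed=21)
        b = simulate_cohort(small_corpus, schedule, 3, base_seed=21)
        assert {k: v.types for k, v in a.items()} == {k: v.types for k, v in b.items()}

    def test_inclusion_rate_monotone_in_frequency(self, small_corpus):
        """Empirical inclusion rates, sorted by frequency, are monotone
        within binomial error: frequency-sensitivity of the sampler."""
        n_rep = 400
        counts = np.zeros(len(small_corpus))
        word_index = {w: i for i, w in enumerate(small_corpus.words)}
        for seed in range(n_rep):
            lex = sample_initial_lexicon(small_corpus, 4, 1, seed)
            for w in lex.types:
                counts[word_index[w]] += 1
        rates = counts / n_rep
        se = np.sqrt(rates * (1 - rates) / n_rep)
        # corpus words are ordered by decreasing frequency
        for i in range(len(rates) - 1):
            assert rates[i] >= rates[i + 1] - 3 * (se[i] + se[i + 1])


class TestSchedule:
    def test_published_schedule_values(self):
        schedule = GrowthSchedule.published()
        assert schedule.checkpoints == PUBLISHED_GRADE_SIZES
        assert schedule.sizes[1] - schedule.sizes[0] == 1_036

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            GrowthSchedule((("1", 5), ("2", 5)))
        with pytest.raises(ValueError):
            GrowthSchedule((("1", 5), ("1", 6)))

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "schedule.yaml"
        path.write_text("- {grade: '1', size: 10}\n- {grade: '2', size: 20}\n")
        schedule = GrowthSchedule.from_yaml(path)
        assert schedule.checkpoints == (("1", 10), ("2", 20))


class TestFrequencyTrajectory:
    def test_single_checkpoint_equals_initial_mean(self, small_corpus):
        schedule = GrowthSchedule((("1", 4),))
        cohort = simulate_cohort(small_corpus, schedule, 2, base_seed=3)
        table = new_word_frequency_trajectory(cohort, small_corpus)
        assert len(table) == 1
        freq = small_corpus.frequency_of()
        expected = np.mean([
            np.mean([freq[w] for w in cohort[(pid, "1")].types]) for pid in (1, 2)
        ])
        assert table.loc[0, "mean_frequency"] == pytest.approx(expected)

    def test_uniform_frequencies_give_flat_trajectory(self):
        words = tuple(f"w{i:03d}" for i in range(400))
        corpus = FrequencyLexicon(words, np.ones(400))
        schedule = GrowthSchedule((("1", 100), ("2", 200), ("3", 300)))
        means = []
        for seed in range(10):
            cohort = simulate_cohort(corpus, schedule, 5, base_seed=seed)
            table = new_word_frequency_trajectory(cohort, corpus)
            means.append(table["mean_frequency"].to_numpy())
        np.testing.assert_allclose(np.mean(means, axis=0), 1.0)

    def test_decreasing_under_zipf_frequencies(self):
        corpus = generate_corpus(CorpusGenConfig(n_types=2_000, seed=4))
        schedule = GrowthSchedule((("1", 300), ("2", 600), ("3", 1_000), ("4", 1_500)))
        cohort = simulate_cohort(corpus, schedule, 5, base_seed=8)
        table = new_word_frequency_trajectory(cohort, corpus)
        values = table["mean_frequency"].to_numpy()
        assert np.all(np.diff(values) < 0)


def test_iter_cohort_matches_explicit_growth_steps(small_corpus):
    schedule = GrowthSchedule((("1", 3), ("2", 6), ("3", 9)))
    streamed = {
        (lex.participant_id, lex.grade_label): lex.types
        for lex in iter_cohort(small_corpus, schedule, 2, base_seed=13)
    }
    assembled = {
        k: v.types for k, v in simulate_cohort(small_corpus, schedule, 2, 13).items()
    }
    assert streamed == assembled
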