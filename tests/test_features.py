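"""Lexicon, active cohort, cohort entropy, word frequency, feature trains."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lextrack.features import (
    Alignment,
    EmptyCohortError,
    Lexicon,
    LexiconEntry,
    PhonemeInterval,
    WordInterval,
    active_cohort,
    active_cohort_bruteforce,
    cohort_entropy,
    linguistic_train,
    onset_train,
    word_frequency,
)
from lextrack.synthetic import make_lexicon

from conftest import make_lexicon_from


class TestLexicon:
    def test_duplicate_words_rejected(self):
        entries = [LexiconEntry("A", ("a",), 0.5), LexiconEntry("A", ("a",), 0.5)]
        with pytest.raises(ValueError, match="unique"):
            Lexicon(entries)

    def test_priors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Lexicon([LexiconEntry("A", ("a",), 0.7)])

    def test_tsv_roundtrip(self, tmp_path, toy_lexicon):
        path = tmp_path / "lex.tsv"
        toy_lexicon.save_tsv(path)
        back = Lexicon.load_tsv(path)
        assert [(e.word, e.phonemes, e.prior) for e in back.entries] == [
            (e.word, e.phonemes, e.prior) for e in toy_lexicon.entries
        ]


class TestActiveCohort:
    @pytest.mark.parametrize(
        "prefix, expected",
        [(("A",), {"AB", "ABC", "AC"}), (("A", "B"), {"AB", "ABC"}),
         (("B",), {"BA"}), (("Z",), set())],
    )
    def test_definition(self, toy_lexicon, prefix, expected):
        assert {w for w, _ in active_cohort(toy_lexicon, prefix)} == expected

    def test_empty_prefix_rejected(self, toy_lexicon):
        with pytest.raises(ValueError):
            active_cohort(toy_lexicon, ())

    def test_trie_matches_bruteforce_on_random_lexicons(self):
        """Prefix-index results equal the linear-scan filter, exactly."""
        rng = np.random.default_rng(42)
        for lex_seed in range(5):
            lex = make_lexicon(200, 6, zipf_exponent=1.0, length_range=(1, 5),
                               seed=lex_seed)
            symbols = sorted(lex.phoneme_inventory)
            for _ in range(50):
                k = int(rng.integers(1, 5))
                prefix = tuple(rng.choice(symbols, size=k))
                assert sorted(active_cohort(lex, prefix)) == sorted(
                    active_cohort_bruteforce(lex, prefix)
                )


class TestCohortEntropy:
    def test_uniform_four_words_is_two_bits(self):
        assert cohort_entropy([("w", 0.25)] * 4) == pytest.approx(2.0)

    def test_singleton_is_zero(self):
        assert cohort_entropy([("w", 0.3)]) == pytest.approx(0.0)

    def test_renormalized_closed_form(self):
        # priors (0.5, 0.25, 0.25) after renormalization -> 1.5 bits
        cohort = [("a", 0.2), ("b", 0.1), ("c", 0.1)]
        assert cohort_entropy(cohort) == pytest.approx(1.5)

    def test_empty_cohort_signals(self):
        with pytest.raises(EmptyCohortError):
            cohort_entropy([])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, priors):
        cohort = [(f"w{i}", p) for i, p in enumerate(priors)]
        h = cohort_entropy(cohort)
        assert -1e-9 <= h <= math.log2(len(cohort)) + 1e-9


class TestWordFrequency:
    def test_values(self):
        lex = make_lexicon_from([("RARE", 0.01), ("SURE", 0.99)])
        assert word_frequency("RARE", lex) == pytest.approx(2.0)

    def test_prior_one_gives_zero(self):
        lex = Lexicon([LexiconEntry("ALL", ("a",), 1.0)])
        assert word_frequency("ALL", lex) == 0.0

    def test_missing_word_gives_zero(self, toy_lexicon):
        assert word_frequency("NOPE", toy_lexicon) == 0.0


class TestOnsetTrain:
    def test_rounding_to_samples(self):
        al = Alignment(
            words=[WordInterval(w, s, s + 0.04) for w, s in
                   [("X", 0.10), ("Y", 0.50), ("Z", 0.95)]],
            phonemes=[PhonemeInterval("x", s, s + 0.04, i) for i, s in
                      enumerate([0.10, 0.50, 0.95])],
        )
        stream = onset_train(al, "word", fs=64, n_samples=64)
        assert set(np.flatnonzero(stream.values)) == {6, 32, 61}
        assert stream.values.sum() == 3.0  # unit pulses, counts words

    def test_silence_only_is_all_zero(self):
        al = Alignment(words=[], phonemes=[])
        assert not onset_train(al, "phoneme", 64, 64).values.any()

    def test_onset_beyond_range_errors(self, toy_alignment):
        with pytest.raises(ValueError, match="outside"):
            onset_train(toy_alignment, "word", fs=64, n_samples=3)


class TestLinguisticTrain:
    def test_ce_amplitudes_from_cohorts(self, toy_lexicon, toy_alignment):
        ce = linguistic_train(toy_alignment, toy_lexicon, "CE", 64, 64)
        po = onset_train(toy_alignment, "phoneme", 64, 64)
        nz = np.flatnonzero(ce.values)
        # phoneme 1: cohort {AB, ABC, AC} -> log2 3; phoneme 2: {AB, ABC} -> 1
        assert ce.values[nz[0]] == pytest.approx(math.log2(3))
        assert ce.values[nz[1]] == pytest.approx(1.0)
        assert set(nz) <= set(np.flatnonzero(po.values))

    def test_wf_pulse_amplitude(self, toy_alignment):
        lex = make_lexicon_from([("AB", 0.1), ("BA", 0.9)])
        wf = linguistic_train(toy_alignment, lex, "WF", 64, 64)
        wo = onset_train(toy_alignment, "word", 64, 64)
        assert wf.values[np.flatnonzero(wo.values)[0]] == pytest.approx(1.0)

    def test_unknown_word_contributes_zero(self, toy_alignment):
        lex = make_lexicon_from([("ZZ", 1.0)])
        assert not linguistic_train(toy_alignment, lex, "CE", 64, 64).values.any()
        assert not linguistic_train(toy_alignment, lex, "WF", 64, 64).values.any()

    def test_ce_nonincreasing_along_word_for_uniform_priors(self):
        """Nested cohorts: each added phoneme can only shrink the cohort."""
        lex = make_lexicon(150, 4, zipf_exponent=0.0, length_range=(2, 6), seed=3)
        entry = max(lex.entries, key=lambda e: len(e.phonemes))
        t, phonemes = 0.0, []
        for i, p in enumerate(entry.phonemes):
            phonemes.append(PhonemeInterval(p, t, t + 0.1, 0))
            t += 0.1
        al = Alignment(words=[WordInterval(entry.word, 0.0, t)], phonemes=phonemes)
        ce = linguistic_train(al, lex, "CE", 64, int(t * 64) + 8)
        pulses = ce.values[np.flatnonzero(onset_train(al, "phoneme", 64,
                                                      int(t * 64) + 8).values)]
        assert np.all(np.diff(pulses) <= 1e-12)
        assert np.all(pulses <= math.log2(len(lex)) + 1e-12)
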