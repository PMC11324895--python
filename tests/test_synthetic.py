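"""Synthetic lexicons, stories, and TRF-driven EEG."""

import numpy as np
import pytest

from lextrack.features import Alignment
from lextrack.synthetic import (
    LexiconCapacityError,
    PauseModel,
    PhonemeDurationModel,
    SyntheticConfig,
    make_lexicon,
    make_story,
    scramble_alignment,
    simulate_eeg,
)
from lextrack.textgridio import read_textgrid, write_textgrid


class TestMakeLexicon:
    def test_zero_exponent_gives_uniform_priors(self):
        lex = make_lexicon(4, 2, zipf_exponent=0.0, length_range=(2, 3), seed=1)
        assert len(lex) == 4
        assert len({e.word for e in lex.entries}) == 4
        np.testing.assert_allclose([e.prior for e in lex.entries], 0.25)

    def test_priors_normalized(self):
        lex = make_lexicon(1000, 20, zipf_exponent=1.0, length_range=(2, 8), seed=7)
        assert len(lex) == 1000
        assert abs(sum(e.prior for e in lex.entries) - 1.0) < 1e-12

    def test_capacity_error(self):
        # only 4 distinct length-2 sequences over 2 phonemes exist
        with pytest.raises(LexiconCapacityError):
            make_lexicon(20, 2, length_range=(2, 2), seed=0)

    def test_exactly_at_capacity_succeeds(self):
        lex = make_lexicon(4, 2, length_range=(2, 2), seed=0)
        assert {e.phonemes for e in lex.entries} == {
            ("a", "a"), ("a", "b"), ("b", "a"), ("b", "b")
        }

    def test_deterministic(self):
        a = make_lexicon(50, 8, seed=5)
        b = make_lexicon(50, 8, seed=5)
        assert [(e.word, e.prior) for e in a.entries] == [
            (e.word, e.prior) for e in b.entries
        ]


class TestMakeStory:
    def test_phonemes_tile_words(self):
        lex = make_lexicon(100, 10, seed=2)
        story = make_story(lex, 30.0, "coherent", seed=2)
        # Alignment's own validator enforces tiling/contiguity
        Alignment(words=story.words, phonemes=story.phonemes, validate=True)
        assert story.end_time <= 30.0 + 1e-9

    def test_scrambled_preserves_multiset_and_speech_time(self):
        lex = make_lexicon(100, 10, seed=2)
        coherent = make_story(lex, 60.0, "coherent", seed=3)
        scrambled = scramble_alignment(coherent, seed=4)
        assert sorted(w.label for w in coherent.words) == sorted(
            w.label for w in scrambled.words
        )
        assert [w.label for w in coherent.words] != [
            w.label for w in scrambled.words
        ]
        speech = lambda al: sum(w.end - w.start for w in al.words)
        assert speech(scrambled) == pytest.approx(speech(coherent))
        assert scrambled.end_time == pytest.approx(coherent.end_time)

    def test_foreign_requires_second_lexicon(self):
        lex = make_lexicon(50, 8, seed=1)
        with pytest.raises(ValueError, match="foreign_lexicon"):
            make_story(lex, 10.0, "foreign", seed=1)

    def test_word_count_matches_renewal_rate(self):
        """Monte-Carlo: 60 s / (5 phonemes x 80 ms) ~ 150 words per story."""
        sigma = 0.25
        pdm = PhonemeDurationModel(median_s=0.08 * np.exp(-sigma**2 / 2), sigma=sigma)
        lex = make_lexicon(80, 8, length_range=(5, 5), seed=9)
        counts = [
            len(make_story(lex, 60.0, "coherent", phoneme_duration_model=pdm,
                           pause_model=PauseModel(probability=0.0), seed=s).words)
            for s in range(300)
        ]
        counts = np.asarray(counts, dtype=float)
        assert abs(counts.mean() - 150.0) < 3 * counts.std()


class TestSimulateEEG:
    def _setup(self, **overrides):
        lex = make_lexicon(150, 10, seed=0)
        kwargs = dict(
            n_subjects=1, n_channels=8, snr_db=0.0,
            condition_durations={"coherent": 60.0}, seed=0,
        )
        kwargs.update(overrides)
        cfg = SyntheticConfig(**kwargs)
        story = make_story(lex, 60.0, "coherent", seed=0)
        return lex, cfg, story

    def test_zero_gains_give_unit_variance_noise(self):
        lex, cfg, story = self._setup(
            linguistic_gains={"coherent": {"CE": 0.0, "WF": 0.0}},
            onset_gains={"coherent": {"PO": 0.0, "WO": 0.0}},
        )
        rec, gt = simulate_eeg(story, lex, cfg, "S01", "coherent", keep_clean=True)
        assert not gt.clean.any()
        assert abs(rec.data.var() - 1.0) < 0.05

    def test_infinite_snr_is_noiseless(self):
        lex, cfg, story = self._setup(snr_db=np.inf)
        rec, gt = simulate_eeg(story, lex, cfg, "S01", "coherent", keep_clean=True)
        np.testing.assert_array_equal(rec.data, gt.clean)

    def test_empirical_snr_matches_config(self):
        lex, cfg, story = self._setup(snr_db=-7.0)
        rec, gt = simulate_eeg(story, lex, cfg, "S01", "coherent", keep_clean=True)
        noise = rec.data - gt.clean
        snr = 10 * np.log10(np.mean(gt.clean**2) / np.mean(noise**2))
        assert abs(snr - (-7.0)) < 0.5

    def test_bit_identical_for_identical_seeds(self):
        lex, cfg, story = self._setup()
        rec1, _ = simulate_eeg(story, lex, cfg, "S01", "coherent")
        rec2, _ = simulate_eeg(story, lex, cfg, "S01", "coherent")
        assert np.array_equal(rec1.data, rec2.data)

    def test_trf_kernel_shape_contract(self):
        lex, cfg, story = self._setup()
        _, gt = simulate_eeg(story, lex, cfg, "S01", "coherent")
        n_lags = round(0.6 * cfg.fs_eeg)
        for kern in gt.trf_kernels.values():
            assert kern.shape == (cfg.n_channels, n_lags)
            assert np.all(np.isfinite(kern))

    def test_story_word_missing_from_lexicon_rejected(self):
        lex, cfg, story = self._setup()
        other = make_lexicon(150, 10, seed=99)
        with pytest.raises(ValueError, match="missing from lexicon"):
            simulate_eeg(story, other, cfg, "S01", "coherent")


class TestConfigValidation:
    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            SyntheticConfig(linguistic_gains={"coherent": {"CE": -1.0}})

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="fs_eeg"):
            SyntheticConfig(fs_eeg=40.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            SyntheticConfig(condition_durations={"coherent": 0.0})


class TestTextGridRoundtrip:
    def test_alignment_survives_write_read(self, tmp_path):
        lex = make_lexicon(60, 8, seed=4)
        story = make_story(lex, 20.0, "coherent", seed=4)
        path = tmp_path / "story.TextGrid"
        write_textgrid(story, path)
        back = read_textgrid(path)
        assert [w.label for w in back.words] == [w.label for w in story.words]
        assert len(back.phonemes) == len(story.phonemes)
        for a, b in zip(back.phonemes, story.phonemes):
            assert a.label == b.label
            assert a.start == pytest.approx(b.start, abs=1e-5)
            assert a.word_index == b.word_index
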