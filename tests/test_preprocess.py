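"""Preprocessing chain: resampling, MWF, re-referencing, band-pass, scaling."""

import numpy as np
import pytest

from lextrack.containers import EEGRecording
from lextrack.preprocess import (
    bandpass_ls,
    normalize_per_split,
    preprocess_recording,
    remove_eyeblinks_mwf,
    rereference_average,
    resample,
)
from lextrack.synthetic import SyntheticConfig, make_lexicon, make_story, simulate_eeg


def sine_recording(freq: float, fs: float, duration: float, channels: int = 2):
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (channels, 1))
    return EEGRecording(data=data, fs=fs)


class TestResample:
    def test_passband_tone_preserved(self):
        rec = resample(sine_recording(10.0, 128.0, 10.0), 64.0)
        assert rec.fs == 64.0
        core = rec.data[0, 64:-64]
        assert np.abs(core).max() == pytest.approx(1.0, rel=0.01)

    def test_above_nyquist_tone_suppressed(self):
        rec = resample(sine_recording(40.0, 128.0, 10.0), 64.0)
        attn = 10 * np.log10(0.5 / max(rec.data[0, 64:-64].var(), 1e-30))
        assert attn >= 30.0

    def test_white_noise_variance_halved(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(data=rng.standard_normal((2, 64000)), fs=128.0)
        out = resample(rec, 64.0)
        # ideal anti-alias keeps the passband half of the spectrum
        assert out.data.var() == pytest.approx(0.5, abs=0.05)

    def test_output_length(self):
        rec = EEGRecording(data=np.zeros((1, 1001)), fs=128.0)
        assert resample(rec, 64.0).n_samples == int(np.ceil(1001 / 2))

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            resample(sine_recording(5.0, 128.0, 2.0), 48.0)


class TestRereference:
    def test_channel_mean_zero_and_idempotent(self):
        rng = np.random.default_rng(1)
        rec = EEGRecording(data=rng.standard_normal((8, 500)) + 3.0, fs=64.0)
        out = rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12
        again = rereference_average(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-12)

    def test_common_mode_rejected(self):
        common = np.sin(np.arange(100))
        rec = EEGRecording(data=np.tile(common, (4, 1)), fs=64.0)
        assert np.abs(rereference_average(rec).data).max() < 1e-12

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_average(EEGRecording(data=np.zeros((1, 10)), fs=64.0))


class TestBandpass:
    def test_passband_stopbands(self):
        dur = 120.0
        for freq, check in ((10.0, "pass"), (0.1, "stop"), (45.0, "stop")):
            out = bandpass_ls(sine_recording(freq, 128.0, dur))
            core = out.data[0, 6000:-6000]
            if check == "pass":
                assert np.abs(core).max() == pytest.approx(1.0, abs=0.05)
            else:
                attn = 10 * np.log10(0.5 / max(core.var(), 1e-30))
                assert attn >= 20.0

    def test_group_delay_compensated(self):
        data = np.zeros((1, 128 * 120))
        data[0, 7000] = 1.0
        out = bandpass_ls(EEGRecording(data=data, fs=128.0))
        assert np.argmax(out.data[0]) == 7000

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            bandpass_ls(sine_recording(10.0, 128.0, 30.0))

    def test_wrong_rate_rejected(self):
        with pytest.raises(ValueError, match="128"):
            bandpass_ls(sine_recording(10.0, 64.0, 120.0))

    def test_commutes_with_rereferencing(self):
        rng = np.random.default_rng(2)
        rec = EEGRecording(data=rng.standard_normal((4, 128 * 60)), fs=128.0)
        a = rereference_average(bandpass_ls(rec))
        b = bandpass_ls(rereference_average(rec))
        assert np.abs(a.data - b.data).max() < 1e-6


@pytest.fixture(scope="module")
def blink_recording():
    lex = make_lexicon(150, 10, seed=0)
    story = make_story(lex, 120.0, "coherent", seed=0)
    cfg = SyntheticConfig(
        n_subjects=1, n_channels=16, snr_db=0.0,
        condition_durations={"coherent": 120.0},
        blink_rate_hz=0.25, blink_amplitude=10.0, seed=0,
    )
    rec, gt = simulate_eeg(story, lex, cfg, "S01", "coherent", keep_clean=True)
    return rec, gt


class TestMWF:
    def test_blink_power_removed_clean_preserved(self, blink_recording):
        rec, gt = blink_recording
        out = remove_eyeblinks_mwf(rec)
        uncontaminated = rec.data - gt.blink_signal
        mask = np.zeros(rec.n_samples, bool)
        for a, b in rec.blink_annotations:
            mask[int(a * rec.fs) : int(np.ceil(b * rec.fs))] = True
        reduction = 10 * np.log10(
            np.mean((rec.data[:, mask] - uncontaminated[:, mask]) ** 2)
            / np.mean((out.data[:, mask] - uncontaminated[:, mask]) ** 2)
        )
        clean_change = 10 * np.log10(
            np.mean(out.data[:, ~mask] ** 2) / np.mean(rec.data[:, ~mask] ** 2)
        )
        assert reduction >= 10.0
        assert abs(clean_change) < 1.0
        assert out.data.shape == rec.data.shape and out.fs == rec.fs

    def test_zero_amplitude_blinks_pass_through(self):
        lex = make_lexicon(150, 10, seed=0)
        story = make_story(lex, 120.0, "coherent", seed=0)
        cfg = SyntheticConfig(
            n_subjects=1, n_channels=16, snr_db=0.0,
            condition_durations={"coherent": 120.0},
            blink_rate_hz=0.25, blink_amplitude=0.0, seed=0,
        )
        rec, _ = simulate_eeg(story, lex, cfg, "S01", "coherent")
        out = remove_eyeblinks_mwf(rec)
        assert np.abs(out.data - rec.data).max() < 1e-9

    def test_no_annotations_warns_and_passes_through(self):
        rec = EEGRecording(data=np.random.default_rng(0).standard_normal((4, 256)),
                           fs=64.0)
        with pytest.warns(UserWarning, match="pass-through"):
            out = remove_eyeblinks_mwf(rec)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_mostly_annotated_rejected(self):
        rec = EEGRecording(data=np.random.default_rng(0).standard_normal((4, 640)),
                           fs=64.0)
        with pytest.raises(ValueError, match="50%"):
            remove_eyeblinks_mwf(rec, annotations=[(0.0, 9.0)])


class TestNormalize:
    def test_per_split_statistics(self):
        rng = np.random.default_rng(3)
        splits = {
            "train": EEGRecording(data=rng.standard_normal((3, 400)) + 5, fs=64.0),
            "val": EEGRecording(data=2 * rng.standard_normal((3, 200)) - 7, fs=64.0),
        }
        out = normalize_per_split(splits)
        for rec in out.values():
            assert np.abs(rec.data.mean(axis=1)).max() < 1e-9
            np.testing.assert_allclose(rec.data.std(axis=1), 1.0, atol=1e-9)

    def test_zero_variance_channel_named(self):
        data = np.random.default_rng(0).standard_normal((3, 100))
        data[1] = 4.2
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_per_split([EEGRecording(data=data, fs=64.0)])


class TestChain:
    def test_clean_band_retained_contamination_removed(self):
        rng = np.random.default_rng(4)
        fs, dur = 128.0, 120.0
        t = np.arange(int(fs * dur)) / fs
        # clean content inside 1-20 Hz
        clean = np.zeros((4, t.size))
        for f in (2.0, 7.0, 13.0, 19.0):
            clean += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi, (4, 1)))
        clean -= clean.mean(axis=0)  # re-reference invariant content
        contamination = np.sin(2 * np.pi * 45.0 * t)[None, :] * np.ones((4, 1))
        rec = EEGRecording(data=clean + contamination, fs=fs)
        out = preprocess_recording(rec, skip_mwf=True)
        ref = preprocess_recording(EEGRecording(data=clean, fs=fs), skip_mwf=True)
        sl = slice(640, -640)  # ignore edges
        retained = np.sum(ref.data[:, sl] ** 2) / np.sum(
            resample(EEGRecording(data=clean, fs=fs), 64.0).data[:, sl] ** 2
        )
        leaked = np.sum((out.data[:, sl] - ref.data[:, sl]) ** 2) / np.sum(
            contamination**2
        )
        assert retained >= 0.95
        assert leaked <= 0.01
        assert out.fs == 64.0
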