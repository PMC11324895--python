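"""MICNN architecture, training, evaluation, and condition comparisons."""

import numpy as np
import pandas as pd
import pytest

from lextrack.micnn import (
    MICNN,
    ModelConfig,
    TrainConfig,
    accuracy_table,
    build_micnn,
    compare_conditions,
    control_config,
    evaluate_mm,
    finetune,
    lc_accuracy,
    train,
)
from lextrack.nn import bce_loss

from conftest import random_dataset

SMALL = dict(eeg_channels=4, feature_set=("WO", "WF"), window_samples=64,
             filters=4, projection=3, dilations=(1, 3), time_blocks=4)


class TestArchitecture:
    def test_default_word_level_model_has_127k_parameters(self):
        model = build_micnn(ModelConfig())
        assert round(model.num_params / 1000) == 127

    def test_control_differs_only_by_linguistic_stream(self):
        lcfg = ModelConfig()
        ccfg = control_config(lcfg)
        assert ccfg.feature_set == ("WO",)
        assert ccfg.filters == lcfg.filters and ccfg.projection == lcfg.projection
        assert round(build_micnn(ccfg).num_params / 1000) == 127

    def test_candidate_swap_maps_p_to_one_minus_p(self):
        model = build_micnn(ModelConfig(**SMALL), seed=0)
        rng = np.random.default_rng(1)
        eeg = rng.standard_normal((6, 4, 64))
        cands = rng.standard_normal((6, 2, 2, 64))
        p = model.forward(eeg, cands)
        p_swapped = model.forward(eeg, cands[:, ::-1])
        assert np.abs(p + p_swapped - 1.0).max() < 1e-6

    def test_untrained_model_is_at_chance(self):
        model = build_micnn(ModelConfig(**SMALL), seed=2)
        ds = random_dataset(800, 4, 2, 64, seed=3)
        res = evaluate_mm(model, ds)
        assert res.ci_low <= 0.5 <= res.ci_high or abs(res.mm_accuracy - 0.5) < 0.06

    def test_receptive_field_must_fit_window(self):
        with pytest.raises(ValueError, match="receptive field"):
            ModelConfig(window_samples=16, dilations=(1, 3, 9, 27))

    def test_gradients_match_finite_differences(self):
        model = build_micnn(ModelConfig(**SMALL), seed=4)
        rng = np.random.default_rng(5)
        eeg = rng.standard_normal((3, 4, 64))
        cands = rng.standard_normal((3, 2, 2, 64))
        y = np.array([1.0, 0.0, 1.0])
        p = model.forward(eeg, cands)
        for par in model.params:
            par.grad[...] = 0.0
        model.backward(p, y)
        for pi in (0, 2, len(model.params) - 1):
            par = model.params[pi]
            idx = tuple(0 for _ in par.value.shape)
            eps = 1e-3
            par.value[idx] += eps
            lp = bce_loss(model.forward(eeg, cands), y)
            par.value[idx] -= 2 * eps
            lm = bce_loss(model.forward(eeg, cands), y)
            par.value[idx] += eps
            numeric = (lp - lm) / (2 * eps)
            assert par.grad[idx] == pytest.approx(numeric, abs=2e-3)

    def test_save_load_roundtrip(self, tmp_path):
        model = build_micnn(ModelConfig(**SMALL), seed=6)
        ds = random_dataset(16, 4, 2, 64, seed=7)
        path = tmp_path / "model.npz"
        model.save(path)
        back = MICNN.load(path)
        np.testing.assert_array_equal(
            model.predict_proba(ds), back.predict_proba(ds)
        )
        assert back.config == model.config


def _learnable_dataset(n: int, seed: int) -> "MMDataset":
    """EEG = matched candidate's stream projected to channels (easy task)."""
    from lextrack.matchmismatch import MMDataset

    rng = np.random.default_rng(seed)
    cands = rng.standard_normal((n, 2, 2, 64)).astype(np.float32)
    labels = rng.integers(0, 2, n)
    mix = np.random.default_rng(100).standard_normal((4, 2)).astype(np.float32)
    eeg = np.einsum("cf,nft->nct", mix, cands[np.arange(n), labels])
    eeg += 0.1 * rng.standard_normal(eeg.shape).astype(np.float32)
    return MMDataset(eeg, cands, labels,
                     pd.DataFrame({"subject": ["s"] * n}))


class TestTraining:
    def test_learns_separable_task(self):
        train_ds = _learnable_dataset(300, seed=0)
        val_ds = _learnable_dataset(100, seed=1)
        test_ds = _learnable_dataset(200, seed=2)
        model = build_micnn(ModelConfig(**SMALL), seed=0)
        model, history = train(model, train_ds, val_ds,
                               TrainConfig(max_epochs=20, seed=0))
        assert history["train_loss"][-1] < history["train_loss"][0]
        assert evaluate_mm(model, test_ds).mm_accuracy > 0.8

    def test_identical_seeds_identical_histories(self):
        ds = _learnable_dataset(120, seed=3)
        runs = []
        for _ in range(2):
            model = build_micnn(ModelConfig(**SMALL), seed=1)
            _, history = train(model, ds, ds, TrainConfig(max_epochs=3, seed=1))
            runs.append(history)
        assert runs[0]["train_loss"] == runs[1]["train_loss"]
        assert runs[0]["val_loss"] == runs[1]["val_loss"]

    def test_restores_best_validation_state(self):
        ds = _learnable_dataset(120, seed=4)
        model = build_micnn(ModelConfig(**SMALL), seed=2)
        model, history = train(model, ds, ds, TrainConfig(max_epochs=8, seed=2))
        best = history["best_epoch"]
        restored_loss, _ = (
            bce_loss(model.predict_proba(ds), (ds.labels == 0).astype(float)),
            None,
        )
        assert restored_loss == pytest.approx(history["val_loss"][best], abs=1e-6)

    def test_finetune_mode_validated(self):
        ds = _learnable_dataset(40, seed=5)
        model = build_micnn(ModelConfig(**SMALL), seed=3)
        with pytest.raises(ValueError, match="mode"):
            finetune(model, "nonsense", ds, ds)


class _StubModel:
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, ds):
        return self.probs


class TestEvaluateMM:
    def test_perfect_and_flipped_models(self):
        ds = random_dataset(50, 2, 1, 64, seed=8)
        perfect = _StubModel(np.where(ds.labels == 0, 0.9, 0.1))
        flipped = _StubModel(np.where(ds.labels == 0, 0.1, 0.9))
        assert evaluate_mm(perfect, ds).mm_accuracy == 1.0
        assert evaluate_mm(flipped, ds).mm_accuracy == 0.0

    def test_exact_ties_count_as_errors(self):
        ds = random_dataset(10, 2, 1, 64, seed=9)
        assert evaluate_mm(_StubModel(np.full(10, 0.5)), ds).mm_accuracy == 0.0

    def test_random_scorer_within_binomial_band(self):
        ds = random_dataset(1000, 2, 1, 64, seed=10)
        scorer = _StubModel(np.random.default_rng(11).uniform(size=1000))
        acc = evaluate_mm(scorer, ds).mm_accuracy
        assert 0.469 <= acc <= 0.531

    def test_wilson_interval_brackets_accuracy(self):
        ds = random_dataset(200, 2, 1, 64, seed=12)
        res = evaluate_mm(_StubModel(np.where(ds.labels == 0, 0.9, 0.6)), ds)
        assert 0 < res.mm_accuracy < 1
        assert res.ci_low < res.mm_accuracy < res.ci_high

    def test_empty_test_set_rejected(self):
        ds = random_dataset(5, 2, 1, 64, seed=13)
        with pytest.raises(ValueError):
            evaluate_mm(_StubModel(np.zeros(0)), ds.subset(np.array([], dtype=int)))


def _table_rows():
    rows = []
    for fs_name, acc in (("L", 0.62), ("C", 0.55)):
        rows.append(dict(subject="S01", condition="coherent", level="word",
                         feature_set=fs_name, finetune="FTL",
                         mm_accuracy=acc, n_examples=100))
    return rows


class TestAccuracyTable:
    def test_lc_accuracy_is_difference(self):
        table = accuracy_table(_table_rows())
        assert lc_accuracy(table, "S01", "coherent", "word", "FTL") == pytest.approx(0.07)

    def test_missing_row_errors(self):
        table = accuracy_table(_table_rows()[:1])
        with pytest.raises(KeyError, match="C row"):
            lc_accuracy(table, "S01", "coherent", "word", "FTL")

    def test_out_of_range_accuracy_rejected(self):
        rows = _table_rows()
        rows[0]["mm_accuracy"] = 1.2
        with pytest.raises(ValueError):
            accuracy_table(rows)


class TestCompareConditions:
    def test_exact_p_for_eight_positive_pairs(self):
        a = np.linspace(0.1, 0.8, 8)
        W, p = compare_conditions(a, np.zeros(8))
        assert p == pytest.approx(2 / 256)

    def test_all_zero_differences_error(self):
        x = np.full(8, 0.3)
        with pytest.raises(ValueError, match="zero"):
            compare_conditions(x, x)

    def test_swap_symmetry(self):
        # two-sided test is symmetric in its arguments (min-rank-sum statistic)
        rng = np.random.default_rng(14)
        a, b = rng.uniform(size=10), rng.uniform(size=10)
        w1, p1 = compare_conditions(a, b)
        w2, p2 = compare_conditions(b, a)
        assert p1 == pytest.approx(p2)
        assert w1 == pytest.approx(w2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="6"):
            compare_conditions(np.ones(4), np.zeros(4))
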