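"""End-to-end experiment orchestration on synthetic cohorts.

Glues the stages together: simulate a cohort, preprocess EEG to the 64 Hz
analysis rate, compute feature streams, build match-mismatch datasets under a
split geometry, train/fine-tune control (C) and linguistic (L) models, and
assemble the per-subject accuracy table consumed by the added-value statistic
and the condition classifier.

Levels follow the study convention: the word level pairs WO with WF on 10 s
windows, the phoneme level pairs PO with CE on 5 s windows.
"""

from __future__ import annotations

import copy
import logging

import numpy as np
import pandas as pd

from .containers import EEGRecording, FeatureStream
from .features import Lexicon, feature_trains
from .matchmismatch import (
    MMDataset,
    WINDOW_BY_LEVEL,
    language_finetune_pieces,
    pretrain_pieces,
    scale_pieces,
    segment_pairs,
    subject_finetune_pieces,
)
from .micnn import (
    MICNN,
    ModelConfig,
    TrainConfig,
    accuracy_table,
    evaluate_mm,
    finetune,
    train,
)
from .preprocess import preprocess_recording
from .synthetic import SyntheticConfig, _stable_seed, simulate_cohort

logger = logging.getLogger(__name__)

LEVEL_FEATURES = {"word": ("WO", "WF"), "phoneme": ("PO", "CE")}


def level_streams(
    alignment,
    lexicon: Lexicon,
    level: str,
    fs: float,
    n_samples: int,
    unit_peak: bool = True,
) -> list[FeatureStream]:
    """Feature streams for one level, control stream first.

    With ``unit_peak`` each stream is scaled by its maximum pulse so all
    model inputs share the onset features' O(1) scale; relative amplitude
    information within a stream is preserved. (Raw cohort-entropy pulses
    reach ~10 bits and saturate the network's tanh units.)
    """
    names = LEVEL_FEATURES[level]
    trains = feature_trains(alignment, lexicon, fs, n_samples, names=names)
    streams = [trains[name] for name in names]
    if unit_peak:
        streams = [
            FeatureStream(
                s.values / s.values.max() if s.values.max() > 0 else s.values,
                s.fs,
                s.feature_name,
            )
            for s in streams
        ]
    return streams


def normalize_pieces(
    rec: EEGRecording, pieces: list[tuple[str, float, float]]
) -> EEGRecording:
    """Z-score each channel within each split (union of the split's pieces)."""
    data = rec.data.copy()
    by_split: dict[str, np.ndarray] = {}
    for split, t0, t1 in pieces:
        mask = np.zeros(rec.n_samples, dtype=bool)
        mask[int(round(t0 * rec.fs)) : int(round(t1 * rec.fs))] = True
        by_split[split] = by_split.get(split, np.zeros_like(mask)) | mask
    for split, mask in by_split.items():
        seg = data[:, mask]
        std = seg.std(axis=1, keepdims=True)
        if np.any(std == 0):
            raise ValueError(f"zero-variance channel in split {split!r}")
        data[:, mask] = (seg - seg.mean(axis=1, keepdims=True)) / std
    return rec.copy_with(data=data)


def build_split_datasets(
    rec: EEGRecording,
    streams: list[FeatureStream],
    pieces: list[tuple[str, float, float]],
    window: float,
    hops: dict[str, float],
    mismatch_gap: float = 1.0,
    seed: int = 0,
    allow_cross_piece_mismatch: bool = False,
) -> dict[str, list]:
    """Per-split example lists from one recording (EEG normalized per split)."""
    rec = normalize_pieces(rec, pieces)
    out: dict[str, list] = {}
    for split in {name for name, _, _ in pieces}:
        split_pieces = [p for p in pieces if p[0] == split]
        out[split] = segment_pairs(
            rec,
            streams,
            window=window,
            hop=hops.get(split, window),
            mismatch_gap=mismatch_gap,
            seed=_stable_seed(seed, "split", split),
            pieces=split_pieces,
            allow_cross_piece_mismatch=allow_cross_piece_mismatch,
        )
    return out


# --------------------------------------------------------------------------
# Cohort preparation
# --------------------------------------------------------------------------


def prepare_cohort(
    config: SyntheticConfig,
    conditions: tuple[str, ...],
    level: str = "word",
    skip_mwf: bool = True,
) -> dict:
    """Simulate, preprocess to 64 Hz, and compute feature streams.

    Returns ``{"recordings": (subject, cond) -> EEGRecording@64Hz,
    "streams": cond -> [control, linguistic] FeatureStreams, "subjects": [...]}``.
    """
    cohort = simulate_cohort(config, conditions=conditions)
    native, foreign = cohort["lexicons"]
    recordings = {}
    for key, rec in cohort["recordings"].items():
        recordings[key] = preprocess_recording(rec, skip_mwf=skip_mwf)
    streams = {}
    for cond, alignment in cohort["alignments"].items():
        lex = foreign if cond == "foreign" else native
        n64 = next(r.n_samples for (s, c), r in recordings.items() if c == cond)
        streams[cond] = level_streams(alignment, lex, level, 64.0, n64)
    return {
        "recordings": recordings,
        "streams": streams,
        "subjects": cohort["subjects"],
        "ground_truth": cohort["ground_truth"],
    }


def _datasets_for(
    prepared: dict,
    conditions: tuple[str, ...],
    n_streams: int,
    pieces_fn,
    window: float,
    hops: dict[str, float],
    seed: int,
    subjects: list[str] | None = None,
    allow_cross_piece_mismatch: bool = False,
) -> dict[str, MMDataset]:
    per_split: dict[str, list] = {}
    subjects = subjects if subjects is not None else prepared["subjects"]
    for subject in subjects:
        for cond in conditions:
            rec = prepared["recordings"][(subject, cond)]
            streams = prepared["streams"][cond][:n_streams]
            pieces = scale_pieces(pieces_fn(), rec.duration)
            split_examples = build_split_datasets(
                rec, streams, pieces, window, hops,
                seed=_stable_seed(seed, subject, cond),
                allow_cross_piece_mismatch=allow_cross_piece_mismatch,
            )
            for split, examples in split_examples.items():
                per_split.setdefault(split, []).extend(examples)
    return {
        split: MMDataset.from_examples(examples)
        for split, examples in per_split.items()
        if examples
    }


def _model_config(
    prepared: dict, level: str, feature_set: tuple[str, ...], model_kwargs: dict
) -> ModelConfig:
    any_rec = next(iter(prepared["recordings"].values()))
    window = WINDOW_BY_LEVEL[level]
    return ModelConfig(
        eeg_channels=any_rec.n_channels,
        feature_set=feature_set,
        window_samples=int(round(window * 64.0)),
        **model_kwargs,
    )


REDUCED_MODEL = dict(filters=8, projection=4, dilations=(1, 3, 9, 27))


# --------------------------------------------------------------------------
# Experiments
# --------------------------------------------------------------------------


def run_lc_experiment(
    config: SyntheticConfig,
    conditions: tuple[str, ...] = ("coherent", "foreign"),
    level: str = "word",
    model_kwargs: dict | None = None,
    tc: TrainConfig | None = None,
    hops: dict[str, float] | None = None,
    seed: int = 0,
    prepared: dict | None = None,
) -> pd.DataFrame:
    """Train C and L models per condition and evaluate per subject.

    One (C, L) model pair is trained for each condition (the condition-
    specific training that language fine-tuning provides in the full
    pipeline), using the 60/20/20 pretraining split on every recording;
    per-subject MM accuracies come from each subject's own test stretch
    (1 s hop, to get a usable example count per subject). Returns an
    accuracy table with ``finetune='none'``.
    """
    model_kwargs = dict(REDUCED_MODEL) if model_kwargs is None else model_kwargs
    tc = tc or TrainConfig(seed=seed)
    hops = hops or {"train": 2.0, "val": 1.0, "test": 1.0}
    window = WINDOW_BY_LEVEL[level]
    if prepared is None:
        prepared = prepare_cohort(config, conditions, level=level)

    models = train_lc_models(
        prepared, conditions, level, model_kwargs, tc, hops, seed
    )
    return evaluate_lc_models(models, prepared, level, hops, seed)


def train_lc_models(
    prepared: dict,
    conditions: tuple[str, ...],
    level: str,
    model_kwargs: dict | None = None,
    tc: TrainConfig | None = None,
    hops: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[tuple[str, str], MICNN]:
    """One (C, L) model pair per condition, trained on the pretrain splits."""
    model_kwargs = dict(REDUCED_MODEL) if model_kwargs is None else model_kwargs
    tc = tc or TrainConfig(seed=seed)
    hops = hops or {"train": 2.0, "val": 1.0, "test": 1.0}
    window = WINDOW_BY_LEVEL[level]
    names = LEVEL_FEATURES[level]
    models: dict[tuple[str, str], MICNN] = {}
    for cond in conditions:
        for fs_label, n_streams in (("C", 1), ("L", 2)):
            cfg = _model_config(prepared, level, names[:n_streams], model_kwargs)
            ds = _datasets_for(
                prepared, (cond,), n_streams, pretrain_pieces, window, hops,
                seed=seed, allow_cross_piece_mismatch=True,
            )
            model = MICNN(cfg, seed=seed)
            model, _ = train(model, ds["train"], ds["val"], tc)
            models[(cond, fs_label)] = model
    return models


def evaluate_lc_models(
    models: dict[tuple[str, str], MICNN],
    prepared: dict,
    level: str,
    hops: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject MM accuracies of condition-specific C/L models on each
    subject's test stretch of the 60/20/20 layout."""
    hops = hops or {"train": 2.0, "val": 1.0, "test": 1.0}
    window = WINDOW_BY_LEVEL[level]
    rows = []
    for (cond, fs_label), model in models.items():
        n_streams = len(model.config.feature_set)
        ds = _datasets_for(
            prepared, (cond,), n_streams, pretrain_pieces, window, hops,
            seed=seed, allow_cross_piece_mismatch=True,
        )
        test = ds["test"]
        for subject in prepared["subjects"]:
            idx = np.flatnonzero(
                (test.meta.subject == subject) & (test.meta.condition == cond)
            )
            res = evaluate_mm(model, test.subset(idx))
            rows.append(
                dict(
                    subject=subject, condition=cond, level=level,
                    feature_set=fs_label, finetune="none",
                    mm_accuracy=res.mm_accuracy, n_examples=res.n_examples,
                )
            )
    return accuracy_table(rows)


def run_lc_recovery(
    config: SyntheticConfig,
    train_condition: str = "coherent",
    eval_conditions: tuple[str, ...] = ("coherent", "foreign"),
    level: str = "phoneme",
    model_kwargs: dict | None = None,
    tc: TrainConfig | None = None,
    hops: dict[str, float] | None = None,
    seed: int = 0,
    prepared: dict | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], MICNN]]:
    """Ground-truth recovery design: one C/L model pair, every condition.

    The pair is trained on ``train_condition`` only and the *same* models are
    evaluated on each condition, so model-quality fluctuations cancel in the
    within-subject between-condition contrast of L - C. This is the design
    used to test whether a condition's injected linguistic gain is
    recoverable as added value. Returns (accuracy table, models keyed by
    (condition, 'C'|'L')).
    """
    if prepared is None:
        prepared = prepare_cohort(config, eval_conditions, level=level)
    pair = train_lc_models(
        prepared, (train_condition,), level, model_kwargs, tc, hops, seed
    )
    models = {
        (cond, fs_label): pair[(train_condition, fs_label)]
        for cond in eval_conditions
        for fs_label in ("C", "L")
    }
    return evaluate_lc_models(models, prepared, level, hops, seed), models


def _clone(model: MICNN) -> MICNN:
    out = MICNN(copy.deepcopy(model.config))
    out.set_state(model.get_state())
    return out


def run_finetune_experiment(
    config: SyntheticConfig,
    conditions: tuple[str, ...] = ("coherent", "scrambled", "foreign"),
    level: str = "word",
    pretrain_condition: str = "coherent",
    model_kwargs: dict | None = None,
    tc: TrainConfig | None = None,
    hops: dict[str, float] | None = None,
    seed: int = 0,
    prepared: dict | None = None,
) -> pd.DataFrame:
    """Pretrain, then language- and subject-fine-tune, per held-out subject.

    Pretraining uses a *separate* synthetic cohort (fresh subjects and a
    fresh story under the ``pretrain_condition`` generative settings), the
    stand-in for the study's independent pretraining corpus — evaluation
    recordings never overlap pretraining material. Language
    fine-tuning (FTL) trains, per held-out subject and condition, on the
    other subjects' 30/20/20/30 splits and evaluates on the held-out
    subject's full recording. Subject fine-tuning (FTS) continues from the
    FTL model on the subject's own 12.5/25/50/12.5 split and evaluates on the
    middle 50%. Returns the completed accuracy table (FTL + FTS rows).
    """
    model_kwargs = dict(REDUCED_MODEL) if model_kwargs is None else model_kwargs
    tc = tc or TrainConfig(seed=seed)
    hops = hops or {"train": 2.0, "val": 1.0, "test": 1.0, "eval": 1.0}
    window = WINDOW_BY_LEVEL[level]
    if prepared is None:
        prepared = prepare_cohort(config, conditions, level=level)
    pretrain_config = copy.deepcopy(config)
    pretrain_config.seed = _stable_seed(config.seed, "pretrain-cohort")
    # stand-in for the larger independent pretraining corpus
    pretrain_config.n_subjects = max(config.n_subjects, 12)
    prepared_pre = prepare_cohort(
        pretrain_config, (pretrain_condition,), level=level
    )
    subjects = prepared["subjects"]
    names = LEVEL_FEATURES[level]

    rows = []
    for fs_label, n_streams in (("C", 1), ("L", 2)):
        cfg = _model_config(prepared, level, names[:n_streams], model_kwargs)
        pre_ds = _datasets_for(
            prepared_pre, (pretrain_condition,), n_streams, pretrain_pieces,
            window, hops, seed=seed, allow_cross_piece_mismatch=True,
        )
        pretrained = MICNN(cfg, seed=seed)
        pretrained, _ = train(pretrained, pre_ds["train"], pre_ds["val"], tc)

        for cond in conditions:
            for heldout in subjects:
                others = [s for s in subjects if s != heldout]
                ftl_ds = _datasets_for(
                    prepared, (cond,), n_streams, language_finetune_pieces,
                    window, hops, seed=seed, subjects=others,
                )
                ftl_model = _clone(pretrained)
                ftl_model, _ = finetune(
                    ftl_model, "language", ftl_ds["train"], ftl_ds["val"], tc
                )
                eval_ds = _datasets_for(
                    prepared, (cond,), n_streams,
                    lambda: [("eval", 0.0, 1.0)], window, hops,
                    seed=seed, subjects=[heldout],
                )["eval"]
                res = evaluate_mm(ftl_model, eval_ds)
                rows.append(
                    dict(
                        subject=heldout, condition=cond, level=level,
                        feature_set=fs_label, finetune="FTL",
                        mm_accuracy=res.mm_accuracy, n_examples=res.n_examples,
                    )
                )

                fts_ds = _datasets_for(
                    prepared, (cond,), n_streams, subject_finetune_pieces,
                    window, hops, seed=seed, subjects=[heldout],
                )
                fts_model = _clone(ftl_model)
                fts_model, _ = finetune(
                    fts_model, "subject", fts_ds["train"], fts_ds["val"], tc
                )
                res = evaluate_mm(fts_model, fts_ds["test"])
                rows.append(
                    dict(
                        subject=heldout, condition=cond, level=level,
                        feature_set=fs_label, finetune="FTS",
                        mm_accuracy=res.mm_accuracy, n_examples=res.n_examples,
                    )
                )
                logger.info("finetuned %s %s %s", fs_label, cond, heldout)
    return accuracy_table(rows)
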