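"""Match-mismatch examples and the three data-split geometries.

An example pairs a fixed-length EEG segment with two speech-feature segments:
the *matched* one is synchronized with the EEG, the *mismatched* one starts
1 second after the end of the matched segment (forward in time only). The
model must say which candidate is matched; the side the matched candidate
appears on is randomized per example.

Window lengths follow the level convention: 5 s for phoneme-level features,
10 s for word-level features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EEGRecording, FeatureStream

logger = logging.getLogger(__name__)

WINDOW_BY_LEVEL = {"phoneme": 5.0, "word": 10.0}


@dataclass
class MMExample:
    eeg: np.ndarray  # channels x window samples
    candidates: np.ndarray  # 2 x n_features x window samples
    label: int  # index of the matched candidate (0 or 1)
    meta: dict = field(default_factory=dict)


@dataclass
class MMDataset:
    """Array-packed example collection served to the network in batches."""

    eeg: np.ndarray  # (n, channels, window)
    candidates: np.ndarray  # (n, 2, n_features, window)
    labels: np.ndarray  # (n,)
    meta: pd.DataFrame

    def __len__(self) -> int:
        return self.labels.shape[0]

    @classmethod
    def from_examples(cls, examples: list[MMExample]) -> "MMDataset":
        if not examples:
            raise ValueError("no examples")
        return cls(
            eeg=np.stack([e.eeg for e in examples]),
            candidates=np.stack([e.candidates for e in examples]),
            labels=np.array([e.label for e in examples], dtype=int),
            meta=pd.DataFrame([e.meta for e in examples]),
        )

    @classmethod
    def concat(cls, datasets: list["MMDataset"]) -> "MMDataset":
        datasets = [d for d in datasets if len(d)]
        if not datasets:
            raise ValueError("no examples")
        return cls(
            eeg=np.concatenate([d.eeg for d in datasets]),
            candidates=np.concatenate([d.candidates for d in datasets]),
            labels=np.concatenate([d.labels for d in datasets]),
            meta=pd.concat([d.meta for d in datasets], ignore_index=True),
        )

    def subset(self, idx: np.ndarray) -> "MMDataset":
        return MMDataset(
            self.eeg[idx],
            self.candidates[idx],
            self.labels[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )


def _admissible_starts(
    n_start: int, n_stop: int, wn: int, gn: int, hop_n: int
) -> list[int]:
    """Window starts in [n_start, n_stop) whose mismatched segment (starting
    wn+gn after the window start) also fits before n_stop."""
    starts = []
    s = n_start
    while s + 2 * wn + gn <= n_stop:
        starts.append(s)
        s += hop_n
    return starts


def segment_pairs(
    eeg: EEGRecording,
    features: list[FeatureStream],
    window: float,
    hop: float | None = None,
    mismatch_gap: float = 1.0,
    seed: int = 0,
    pieces: list[tuple[str, float, float]] | None = None,
    allow_cross_piece_mismatch: bool = False,
) -> list[MMExample]:
    """Build labeled match-mismatch examples from one recording.

    Without ``pieces``, windows start at 0, hop, 2*hop, ... and a window is
    emitted only if its mismatched segment fits within the recording. With
    ``pieces`` (list of (split_name, start_s, end_s)), windows are generated
    within each piece and the mismatched segment must also lie in the same
    piece unless ``allow_cross_piece_mismatch`` (pretrain mode), in which
    case only the recording end bounds it.
    """
    fs = eeg.fs
    for f in features:
        if abs(f.fs - fs) > 1e-9:
            raise ValueError("EEG and features must share the sampling rate")
        if f.n_samples < eeg.n_samples:
            raise ValueError("feature stream shorter than the EEG")
    hop = window if hop is None else hop
    wn, gn, hop_n = (int(round(x * fs)) for x in (window, mismatch_gap, hop))
    n = eeg.n_samples

    if pieces is None:
        pieces = [("all", 0.0, n / fs)]
    rng = np.random.default_rng(seed)
    feat = np.stack([f.values[:n] for f in features])

    examples: list[MMExample] = []
    for split, p0, p1 in pieces:
        a, b = int(round(p0 * fs)), min(int(round(p1 * fs)), n)
        stop = n if allow_cross_piece_mismatch else b
        for s in _admissible_starts(a, stop, wn, gn, hop_n):
            if s + wn > b:  # the EEG window itself must stay inside the piece
                continue
            m0 = s + wn + gn
            matched = feat[:, s : s + wn]
            mismatched = feat[:, m0 : m0 + wn]
            label = int(rng.integers(2))
            cands = np.empty((2,) + matched.shape)
            cands[label] = matched
            cands[1 - label] = mismatched
            examples.append(
                MMExample(
                    eeg=eeg.data[:, s : s + wn].copy(),
                    candidates=cands,
                    label=label,
                    meta={
                        "subject": eeg.subject,
                        "condition": eeg.condition,
                        "start_s": s / fs,
                        "split": split,
                        "label": label,
                    },
                )
            )
    if not examples:
        logger.warning(
            "recording %s/%s too short for window=%.1fs: no examples",
            eeg.subject, eeg.condition, window,
        )
    return examples


# --------------------------------------------------------------------------
# Split geometries (fractions of a recording's timeline)
# --------------------------------------------------------------------------


def pretrain_pieces() -> list[tuple[str, float, float]]:
    """60/20/20 contiguous train/val/test layout used for pretraining."""
    return [("train", 0.0, 0.6), ("val", 0.6, 0.8), ("test", 0.8, 1.0)]


def language_finetune_pieces() -> list[tuple[str, float, float]]:
    """First and last 30% train; first half of the middle 40% val, second
    half test (applied to every non-held-out subject's recording)."""
    return [
        ("train", 0.0, 0.3),
        ("val", 0.3, 0.5),
        ("test", 0.5, 0.7),
        ("train", 0.7, 1.0),
    ]


def subject_finetune_pieces() -> list[tuple[str, float, float]]:
    """First and last 12.5% train; first third of the middle 75% val, the
    remaining two thirds test (25/25/50)."""
    return [
        ("train", 0.0, 0.125),
        ("val", 0.125, 0.375),
        ("test", 0.375, 0.875),
        ("train", 0.875, 1.0),
    ]


def scale_pieces(
    pieces: list[tuple[str, float, float]], duration: float
) -> list[tuple[str, float, float]]:
    return [(name, f0 * duration, f1 * duration) for name, f0, f1 in pieces]


def split_language_finetune(
    subjects: list[str], heldout_subject: str
) -> dict[str, list[tuple[str, float, float]]]:
    """Per-subject fractional pieces for language fine-tuning: the held-out
    subject's whole recording is reserved for final evaluation."""
    if len(subjects) < 2:
        raise ValueError("language fine-tuning needs >= 2 subjects")
    if heldout_subject not in subjects:
        raise ValueError(f"{heldout_subject!r} not in subjects")
    plan = {}
    for s in subjects:
        if s == heldout_subject:
            plan[s] = [("eval", 0.0, 1.0)]
        else:
            plan[s] = language_finetune_pieces()
    return plan


def split_subject_finetune(
    rec: EEGRecording, window: float, mismatch_gap: float = 1.0
) -> list[tuple[str, float, float]]:
    """Fractional pieces for subject fine-tuning; errors when the recording is
    too short for each train piece to admit at least one example."""
    need = 2 * (window + mismatch_gap) / 0.125
    if rec.duration < need:
        raise ValueError(
            f"recording of {rec.duration:.0f}s too short for subject fine-tuning "
            f"(needs >= {need:.0f}s for {window:.0f}s windows)"
        )
    return subject_finetune_pieces()


def manifest(examples_or_ds) -> pd.DataFrame:
    """Tabular manifest: one row per example (subject, condition, start_s,
    label, split)."""
    if isinstance(examples_or_ds, MMDataset):
        return examples_or_ds.meta.copy()
    return pd.DataFrame([e.meta for e in examples_or_ds])


def audit_split_overlap(
    man: pd.DataFrame, window: float, mismatch_gap: float = 1.0
) -> int:
    """Count pairs of examples from different splits of the same recording
    whose EEG windows overlap in time (0 = leakage-free geometry)."""
    overlaps = 0
    for (_, _), grp in man.groupby(["subject", "condition"]):
        rows = grp[["split", "start_s"]].to_numpy()
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                if rows[i][0] == rows[j][0]:
                    continue
                a, b = float(rows[i][1]), float(rows[j][1])
                if abs(a - b) < window:
                    overlaps += 1
    return overlaps
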