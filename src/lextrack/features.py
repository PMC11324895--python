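"""Speech feature streams: lexical segmentation and linguistic features.

Four pulse trains are computed from a time-aligned transcription and a
phonemized lexicon, all sampled at the EEG analysis rate (64 Hz):

* ``PO`` / ``WO`` — phoneme / word onsets, unit pulses ("lexical
  segmentation" features: they mark *when* units start, nothing more).
* ``CE`` — cohort entropy: at each phoneme, the Shannon entropy of the
  *active cohort*, i.e. the set of lexicon words sharing the phoneme prefix
  heard so far within the current word. High entropy means many candidate
  words are still competing.
* ``WF`` — word frequency: at each word onset, ``-log10`` of the word's
  prior probability in the language; rarer words give larger pulses.

Cohort priors are renormalized within the active cohort so CE is a proper
entropy bounded by ``log2 |cohort|``; words absent from the lexicon
contribute zero-amplitude pulses for both CE and WF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import FeatureStream

SILENCE_LABELS = frozenset({"", "sil", "sp", "#"})


class EmptyCohortError(ValueError):
    """Raised when cohort entropy is requested for an empty cohort."""


# --------------------------------------------------------------------------
# Lexicon
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    phonemes: tuple[str, ...]
    prior: float


class Lexicon:
    """A phonemized vocabulary with prior probabilities and a prefix index.

    The prefix index maps every phoneme prefix to the indices of entries
    beginning with it, so active-cohort queries are O(|result|) instead of a
    linear scan over the vocabulary.
    """

    def __init__(self, entries: list[LexiconEntry], prior_tol: float = 1e-9):
        words = [e.word for e in entries]
        if len(set(words)) != len(words):
            raise ValueError("lexicon words must be unique")
        if any(e.prior < 0 for e in entries):
            raise ValueError("priors must be >= 0")
        total = sum(e.prior for e in entries)
        if abs(total - 1.0) > prior_tol:
            raise ValueError(f"priors must sum to 1 (got {total!r})")
        self.entries = list(entries)
        self._by_word = {e.word: e for e in self.entries}
        self._prefix_index: dict[tuple[str, ...], list[int]] = {}
        for i, e in enumerate(self.entries):
            for k in range(1, len(e.phonemes) + 1):
                self._prefix_index.setdefault(e.phonemes[:k], []).append(i)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self._by_word

    def get(self, word: str) -> LexiconEntry | None:
        return self._by_word.get(word)

    def prefix_entries(self, prefix: tuple[str, ...]) -> list[LexiconEntry]:
        return [self.entries[i] for i in self._prefix_index.get(tuple(prefix), ())]

    @property
    def phoneme_inventory(self) -> set[str]:
        return {p for e in self.entries for p in e.phonemes}

    # ------------------------------------------------------------------ I/O

    def save_tsv(self, path: str | Path) -> None:
        """TSV columns: word, space-separated phonemes, prior."""
        lines = [
            f"{e.word}\t{' '.join(e.phonemes)}\t{e.prior:.17g}" for e in self.entries
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load_tsv(cls, path: str | Path, prior_tol: float = 1e-9) -> "Lexicon":
        entries = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            word, phones, prior = line.split("\t")
            entries.append(LexiconEntry(word, tuple(phones.split()), float(prior)))
        return cls(entries, prior_tol=prior_tol)


def active_cohort(lexicon: Lexicon, prefix: tuple[str, ...]) -> list[tuple[str, float]]:
    """All (word, prior) lexicon entries whose phonemization starts with
    ``prefix``; a word equal to the prefix is included. Unknown prefixes give
    an empty cohort."""
    if len(prefix) == 0:
        raise ValueError("prefix must be non-empty")
    return [(e.word, e.prior) for e in lexicon.prefix_entries(tuple(prefix))]


def active_cohort_bruteforce(
    lexicon: Lexicon, prefix: tuple[str, ...]
) -> list[tuple[str, float]]:
    """Linear-scan reference for :func:`active_cohort` (oracle in tests)."""
    if len(prefix) == 0:
        raise ValueError("prefix must be non-empty")
    prefix = tuple(prefix)
    k = len(prefix)
    return [
        (e.word, e.prior) for e in lexicon.entries if e.phonemes[:k] == prefix
    ]


def cohort_entropy(cohort: list[tuple[str, float]]) -> float:
    """Shannon entropy (bits) of the cohort's priors, renormalized within the
    cohort. Zero-prior members contribute nothing (p log p -> 0)."""
    if len(cohort) == 0:
        raise EmptyCohortError("cohort is empty")
    priors = np.array([p for _, p in cohort], dtype=float)
    if np.any(priors < 0):
        raise ValueError("priors must be >= 0")
    total = priors.sum()
    if total <= 0:
        raise ValueError("cohort priors sum to zero")
    p = priors / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def word_frequency(word: str, lexicon: Lexicon) -> float:
    """-log10 of the word's prior; 0.0 for words absent from the lexicon or
    with zero prior (the missing-word convention)."""
    entry = lexicon.get(word)
    if entry is None or entry.prior <= 0:
        return 0.0
    return -math.log10(entry.prior)


# --------------------------------------------------------------------------
# Alignment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WordInterval:
    label: str
    start: float
    end: float


@dataclass(frozen=True)
class PhonemeInterval:
    label: str
    start: float
    end: float
    word_index: int | None  # None for silence


@dataclass
class Alignment:
    """Time-aligned word and phoneme intervals (half-open, seconds).

    Each non-silence phoneme belongs to exactly one word; a word's phonemes
    tile its interval contiguously.
    """

    words: list[WordInterval]
    phonemes: list[PhonemeInterval]
    validate: bool = True
    _tol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        if self.validate:
            self._check()

    def _group(self) -> dict[int, list[PhonemeInterval]]:
        groups: dict[int, list[PhonemeInterval]] = {}
        for p in self.phonemes:
            if p.word_index is not None:
                groups.setdefault(p.word_index, []).append(p)
        return groups

    def _check(self) -> None:
        tol = self._tol
        for seq in (self.words, self.phonemes):
            for a, b in zip(seq, seq[1:]):
                if b.start < a.end - tol:
                    raise ValueError(f"overlapping intervals: {a} / {b}")
        groups = self._group()
        for wi, word in enumerate(self.words):
            phones = groups.get(wi, [])
            if not phones:
                raise ValueError(f"word {word.label!r} has no phonemes")
            if abs(phones[0].start - word.start) > tol or abs(
                phones[-1].end - word.end
            ) > tol:
                raise ValueError(f"phonemes of {word.label!r} do not tile its span")
            for a, b in zip(phones, phones[1:]):
                if abs(b.start - a.end) > tol:
                    raise ValueError(f"gap inside word {word.label!r}")

    @property
    def end_time(self) -> float:
        ends = [w.end for w in self.words] + [p.end for p in self.phonemes]
        return max(ends) if ends else 0.0

    def word_phonemes(self, word_index: int) -> list[PhonemeInterval]:
        return [p for p in self.phonemes if p.word_index == word_index]


# --------------------------------------------------------------------------
# Feature trains
# --------------------------------------------------------------------------


def _onset_sample(t: float, fs: float, n_samples: int, what: str) -> int:
    # nearest-sample rounding, ties to even (numpy's rint convention)
    idx = int(np.rint(t * fs))
    if idx >= n_samples or idx < 0:
        raise ValueError(
            f"{what} onset at {t:.3f}s -> sample {idx} outside 0..{n_samples - 1}"
        )
    return idx


def onset_train(
    alignment: Alignment, level: str, fs: float, n_samples: int
) -> FeatureStream:
    """Unit-pulse train of phoneme (``PO``) or word (``WO``) onsets.

    Silence contributes nothing; two onsets rounding to the same sample keep a
    single unit pulse (pulses mark presence, not counts).
    """
    if level not in {"phoneme", "word"}:
        raise ValueError("level must be 'phoneme' or 'word'")
    values = np.zeros(n_samples)
    if level == "word":
        units = [(w.label, w.start) for w in alignment.words]
        name = "WO"
    else:
        units = [
            (p.label, p.start) for p in alignment.phonemes if p.word_index is not None
        ]
        name = "PO"
    for label, start in units:
        values[_onset_sample(start, fs, n_samples, f"{level} {label!r}")] = 1.0
    return FeatureStream(values, fs, name)


def linguistic_train(
    alignment: Alignment,
    lexicon: Lexicon,
    feature: str,
    fs: float,
    n_samples: int,
) -> FeatureStream:
    """Cohort-entropy (``CE``, per phoneme) or word-frequency (``WF``, per
    word) pulse train.

    CE at the i-th phoneme of a word uses the active cohort of that word's
    first i phonemes (the first phoneme already restricts the cohort). Words
    missing from the lexicon yield zero-amplitude pulses.
    """
    if feature not in {"CE", "WF"}:
        raise ValueError("feature must be 'CE' or 'WF'")
    values = np.zeros(n_samples)
    if feature == "WF":
        for w in alignment.words:
            idx = _onset_sample(w.start, fs, n_samples, f"word {w.label!r}")
            values[idx] = word_frequency(w.label, lexicon)
        return FeatureStream(values, fs, "WF")

    groups = alignment._group()
    for wi in range(len(alignment.words)):
        phones = groups.get(wi, [])
        prefix: tuple[str, ...] = ()
        for p in phones:
            prefix = prefix + (p.label,)
            cohort = active_cohort(lexicon, prefix)
            amp = cohort_entropy(cohort) if cohort else 0.0
            idx = _onset_sample(p.start, fs, n_samples, f"phoneme {p.label!r}")
            values[idx] = amp
    return FeatureStream(values, fs, "CE")


def feature_trains(
    alignment: Alignment,
    lexicon: Lexicon,
    fs: float,
    n_samples: int,
    names: tuple[str, ...] = ("PO", "WO", "CE", "WF"),
) -> dict[str, FeatureStream]:
    """Convenience: compute several feature streams on a shared grid."""
    out: dict[str, FeatureStream] = {}
    for name in names:
        if name == "PO":
            out[name] = onset_train(alignment, "phoneme", fs, n_samples)
        elif name == "WO":
            out[name] = onset_train(alignment, "word", fs, n_samples)
        else:
            out[name] = linguistic_train(alignment, lexicon, name, fs, n_samples)
    return out
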