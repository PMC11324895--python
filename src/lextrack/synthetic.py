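"""Synthetic cohorts: lexicons, aligned stories, and TRF-driven EEG.

The generator emulates a listening study with three comprehension conditions
("coherent" speech, "scrambled" word order, and a "foreign" language sharing
the phonetic inventory but a disjoint vocabulary). EEG is produced by the
standard linear forward model of neural speech tracking: each speech feature
pulse train is convolved with a subject-specific temporal response function
(TRF) per channel, the components are mixed with per-condition gains, and 1/f
noise is added at a controlled SNR. Comprehension is encoded as recoverable
ground truth through the *linguistic* gains: conditions in which the language
is "understood" track cohort entropy and word frequency strongly, a foreign
condition only weakly, while onset (acoustic/lexical-segmentation) gains stay
equal across conditions.
"""

from __future__ import annotations

import itertools
import string
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve, firwin

from .containers import EEGRecording
from .features import (
    Alignment,
    Lexicon,
    LexiconEntry,
    PhonemeInterval,
    WordInterval,
    feature_trains,
)

CONDITIONS = ("coherent", "scrambled", "foreign")

LINGUISTIC_FEATURES = ("CE", "WF")
ONSET_FEATURES = ("PO", "WO")


class LexiconCapacityError(ValueError):
    """Not enough distinct phoneme sequences exist in the requested lengths."""


# --------------------------------------------------------------------------
# Config / ground truth
# --------------------------------------------------------------------------


def _default_linguistic_gains() -> dict[str, dict[str, float]]:
    # coherent and scrambled are both "understood" word-by-word and share
    # full linguistic tracking; the foreign condition tracks at 25%.
    return {
        "coherent": {"CE": 1.0, "WF": 1.0},
        "scrambled": {"CE": 1.0, "WF": 1.0},
        "foreign": {"CE": 0.25, "WF": 0.25},
    }


def _default_onset_gains() -> dict[str, dict[str, float]]:
    return {c: {"PO": 1.0, "WO": 1.0} for c in CONDITIONS}


@dataclass
class SyntheticConfig:
    """Study-level knobs for a synthetic cohort.

    Durations default to the study layout of 10/9/7 minutes for the
    coherent/scrambled/foreign conditions. ``snr_db`` is the ratio of the
    clean tracked mixture's power to the 1/f noise power.
    """

    n_subjects: int = 26
    n_channels: int = 64
    fs_eeg: float = 128.0
    condition_durations: dict[str, float] = field(
        default_factory=lambda: {"coherent": 600.0, "scrambled": 540.0, "foreign": 420.0}
    )
    linguistic_gains: dict[str, dict[str, float]] = field(
        default_factory=_default_linguistic_gains
    )
    onset_gains: dict[str, dict[str, float]] = field(default_factory=_default_onset_gains)
    snr_db: float = -5.0
    snr_reference_condition: str | None = None
    seed: int = 0
    trf_length_s: float = 0.6
    trf_subject_similarity: float = 0.7  # population share of each TRF
    population_seed: int = 0  # physiology (population TRFs); cohort-independent
    blink_rate_hz: float = 0.0  # > 0 adds frontal eyeblink artifacts
    blink_amplitude: float = 10.0  # relative to signal+noise RMS

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ValueError("n_subjects and n_channels must be >= 1")
        if self.fs_eeg <= 2 * 25.0:
            raise ValueError("fs_eeg must exceed twice the 25 Hz passband edge")
        for cond, dur in self.condition_durations.items():
            if dur <= 0:
                raise ValueError(f"duration for {cond!r} must be > 0")
        for gains in (self.linguistic_gains, self.onset_gains):
            for cond, per_feature in gains.items():
                for name, g in per_feature.items():
                    if g < 0:
                        raise ValueError(f"gain {name} in {cond!r} must be >= 0")
        if not 0.0 <= self.trf_subject_similarity <= 1.0:
            raise ValueError("trf_subject_similarity must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    trf_kernels: dict[str, np.ndarray]  # feature -> (n_channels, n_lags)
    gains_used: dict[str, float]  # feature -> gain for this condition
    noise_realization_seed: int
    clean: np.ndarray | None = None  # (n_channels, n_samples) noise-free mixture
    blink_signal: np.ndarray | None = None


# --------------------------------------------------------------------------
# Lexicon generation
# --------------------------------------------------------------------------


def _inventory(n_phonemes: int) -> list[str]:
    letters = string.ascii_lowercase
    if n_phonemes <= len(letters):
        return list(letters[:n_phonemes])
    return [f"p{i:02d}" for i in range(n_phonemes)]


def _capacity(n_phonemes: int, lo: int, hi: int, cap: int) -> int:
    total = 0
    for length in range(lo, hi + 1):
        total += n_phonemes**length
        if total >= cap:
            return cap
    return total


def make_lexicon(
    n_words: int,
    n_phonemes: int,
    zipf_exponent: float = 1.0,
    length_range: tuple[int, int] = (2, 8),
    seed: int = 0,
) -> Lexicon:
    """Random phonemized vocabulary with Zipf-distributed priors.

    Words are distinct random phoneme sequences with lengths uniform over
    ``length_range``; priors follow ``p(rank) ~ rank**-zipf_exponent`` with
    ranks assigned at random (exponent 0 gives uniform priors). Raises
    :class:`LexiconCapacityError` when fewer than ``n_words`` distinct
    sequences exist in the length range.
    """
    if n_words < 2 or n_phonemes < 2:
        raise ValueError("need n_words >= 2 and n_phonemes >= 2")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    capacity = _capacity(n_phonemes, lo, hi, cap=10 * n_words + 1000)
    if capacity < n_words:
        raise LexiconCapacityError(
            f"only {capacity} distinct sequences of length {lo}..{hi} exist "
            f"over {n_phonemes} phonemes; cannot make {n_words} words"
        )
    rng = np.random.default_rng(seed)
    inventory = _inventory(n_phonemes)
    sep = "" if n_phonemes <= 26 else "-"

    seqs: set[tuple[str, ...]] = set()
    if capacity <= 4 * n_words:
        # near capacity: enumerate and sample without replacement
        universe = [
            seq
            for length in range(lo, hi + 1)
            for seq in itertools.product(inventory, repeat=length)
        ]
        idx = rng.choice(len(universe), size=n_words, replace=False)
        seqs = {universe[i] for i in idx}
    else:
        while len(seqs) < n_words:
            length = int(rng.integers(lo, hi + 1))
            seqs.add(tuple(inventory[i] for i in rng.integers(0, n_phonemes, length)))
    ordered = sorted(seqs)

    ranks = rng.permutation(n_words) + 1
    priors = ranks.astype(float) ** -float(zipf_exponent)
    priors /= priors.sum()
    entries = [
        LexiconEntry(sep.join(seq), seq, float(p)) for seq, p in zip(ordered, priors)
    ]
    return Lexicon(entries)


# --------------------------------------------------------------------------
# Story generation
# --------------------------------------------------------------------------


@dataclass
class PhonemeDurationModel:
    """Lognormal phoneme durations (seconds)."""

    median_s: float = 0.08
    sigma: float = 0.25


@dataclass
class PauseModel:
    """Bernoulli pause after each word with lognormal duration."""

    probability: float = 0.2
    median_s: float = 0.3
    sigma: float = 0.4


def _markov_next(
    rng: np.random.Generator,
    lexicon: Lexicon,
    priors: np.ndarray,
    successors: dict[int, np.ndarray],
    current: int | None,
    k: int = 5,
    weight: float = 0.5,
) -> int:
    """First-order Markov word sampler: each word routes half its transition
    mass to a fixed set of k preferred successors, the rest to the priors."""
    if current is not None and rng.random() < weight:
        if current not in successors:
            sub = np.random.default_rng(
                zlib.crc32(lexicon.entries[current].word.encode()) & 0x7FFFFFFF
            )
            successors[current] = sub.integers(0, len(lexicon), size=k)
        return int(rng.choice(successors[current]))
    return int(rng.choice(len(lexicon), p=priors))


def make_story(
    lexicon: Lexicon,
    duration: float,
    condition: str = "coherent",
    phoneme_duration_model: PhonemeDurationModel | None = None,
    pause_model: PauseModel | None = None,
    seed: int = 0,
    foreign_lexicon: Lexicon | None = None,
) -> Alignment:
    """Sample a time-aligned word/phoneme sequence filling ``duration``.

    ``coherent`` draws words from a first-order Markov chain over the lexicon;
    ``scrambled`` is a seeded permutation of the coherent story's word tokens
    (word-internal durations and inter-word gaps retained); ``foreign`` draws
    from ``foreign_lexicon`` instead.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if condition == "foreign":
        if foreign_lexicon is None:
            raise ValueError("foreign condition requires foreign_lexicon")
        lexicon = foreign_lexicon
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")

    if condition == "scrambled":
        base = make_story(
            lexicon, duration, "coherent", phoneme_duration_model, pause_model, seed
        )
        return scramble_alignment(base, seed=seed + 1)

    pdm = phoneme_duration_model or PhonemeDurationModel()
    pm = pause_model or PauseModel()
    rng = np.random.default_rng(seed)
    priors = np.array([e.prior for e in lexicon.entries])
    priors = priors / priors.sum()
    successors: dict[int, np.ndarray] = {}

    words: list[WordInterval] = []
    phonemes: list[PhonemeInterval] = []
    t = 0.0
    current: int | None = None
    while True:
        current = _markov_next(rng, lexicon, priors, successors, current)
        entry = lexicon.entries[current]
        durs = np.exp(
            rng.normal(np.log(pdm.median_s), pdm.sigma, size=len(entry.phonemes))
        )
        if t + durs.sum() > duration:
            break
        wi = len(words)
        start = t
        for sym, d in zip(entry.phonemes, durs):
            phonemes.append(PhonemeInterval(sym, t, t + d, wi))
            t += d
        words.append(WordInterval(entry.word, start, t))
        if pm.probability > 0 and rng.random() < pm.probability:
            t += float(np.exp(rng.normal(np.log(pm.median_s), pm.sigma)))
    if not words:
        raise ValueError("duration too short to fit a single word")
    return Alignment(words=words, phonemes=phonemes, validate=False)


def scramble_alignment(alignment: Alignment, seed: int = 0) -> Alignment:
    """Permute word tokens (with their internal phoneme durations) while
    keeping the sequence of inter-word gaps, so the token multiset and the
    total speech time are conserved."""
    rng = np.random.default_rng(seed)
    n = len(alignment.words)
    groups = alignment._group()
    units = []
    for wi, w in enumerate(alignment.words):
        phones = groups[wi]
        units.append((w.label, [(p.label, p.end - p.start) for p in phones]))
    gaps = [
        alignment.words[i + 1].start - alignment.words[i].end for i in range(n - 1)
    ]
    order = rng.permutation(n)

    words: list[WordInterval] = []
    phonemes: list[PhonemeInterval] = []
    t = alignment.words[0].start
    for slot in range(n):
        label, phone_durs = units[order[slot]]
        start = t
        for sym, d in phone_durs:
            phonemes.append(PhonemeInterval(sym, t, t + d, slot))
            t += d
        words.append(WordInterval(label, start, t))
        if slot < n - 1:
            t += gaps[slot]
    return Alignment(words=words, phonemes=phonemes, validate=False)


# --------------------------------------------------------------------------
# EEG simulation
# --------------------------------------------------------------------------


def _stable_seed(*parts) -> int:
    h = 0
    for p in parts:
        h = zlib.crc32(str(p).encode(), h)
    return h & 0x7FFFFFFF


def _smooth_kernel(rng: np.random.Generator, n_lags: int, fs: float) -> np.ndarray:
    """Random TRF shape: white noise low-pass filtered below 8 Hz, unit norm."""
    noise = rng.standard_normal(n_lags)
    numtaps = max(5, int(fs / 4) | 1)
    lp = firwin(numtaps, 8.0, fs=fs)
    k = fftconvolve(noise, lp, mode="same")
    norm = np.linalg.norm(k)
    return k / norm if norm > 0 else k


def pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-power noise per channel, unit variance."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    out = np.fft.irfft(spec * scale, n=n, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _blink_template(fs: float) -> np.ndarray:
    t = np.arange(0, 0.4, 1 / fs)
    return np.exp(-(((t - 0.2) / 0.07) ** 2))


def simulate_eeg(
    alignment: Alignment,
    lexicon: Lexicon,
    config: SyntheticConfig,
    subject_id: str,
    condition: str,
    keep_clean: bool = False,
) -> tuple[EEGRecording, GroundTruth]:
    """Forward-model EEG for one subject x condition.

    EEG = sum over features of gain(condition, feature) x (feature pulse
    train convolved with a subject-specific TRF kernel per channel) + 1/f
    noise scaled to ``snr_db``. Each feature's clean component is normalized
    to unit RMS before its gain is applied, so gains are directly comparable
    power knobs across features. Deterministic given (config.seed,
    subject_id, condition).
    """
    fs = config.fs_eeg
    duration = config.condition_durations.get(condition)
    if duration is None:
        raise ValueError(f"no duration configured for condition {condition!r}")
    if alignment.end_time > duration + 1e-6:
        raise ValueError("alignment extends beyond the configured duration")
    missing = {w.label for w in alignment.words} - {
        e.word for e in lexicon.entries
    }
    if missing:
        raise ValueError(f"story words missing from lexicon: {sorted(missing)[:5]}")

    n = int(round(duration * fs))
    n_lags = int(round(config.trf_length_s * fs))
    gains: dict[str, float] = {}
    gains.update(config.onset_gains.get(condition, {}))
    gains.update(config.linguistic_gains.get(condition, {}))

    trains = feature_trains(alignment, lexicon, fs, n, names=tuple(gains))

    # TRFs mix a population-shared component (same for every subject of the
    # cohort) with a subject-specific one; evoked-response morphology is
    # conserved across people, which is what makes cross-subject decoding
    # possible at all.
    rho = config.trf_subject_similarity
    pop_rng = np.random.default_rng(_stable_seed(config.population_seed, "trf-pop"))
    subj_rng = np.random.default_rng(_stable_seed(config.seed, "trf", subject_id))
    clean = np.zeros((config.n_channels, n))
    kernels: dict[str, np.ndarray] = {}
    for name in sorted(gains):
        base_pop = _smooth_kernel(pop_rng, n_lags, fs)
        topo_pop = pop_rng.standard_normal(config.n_channels)
        base_subj = _smooth_kernel(subj_rng, n_lags, fs)
        topo_subj = subj_rng.standard_normal(config.n_channels)
        base = rho * base_pop + np.sqrt(1 - rho**2) * base_subj
        base /= max(np.linalg.norm(base), 1e-12)
        topo = rho * topo_pop + np.sqrt(1 - rho**2) * topo_subj
        topo /= np.linalg.norm(topo) / np.sqrt(config.n_channels)
        kernels[name] = np.outer(topo, base)
        if gains[name] == 0:
            continue
        comp_1d = fftconvolve(trains[name].values, base)[:n]
        comp = topo[:, None] * comp_1d[None, :]
        rms = np.sqrt(np.mean(comp**2))
        if rms > 0:
            clean += gains[name] * comp / rms

    # snr_db is defined against this condition's own clean power, or - when
    # snr_reference_condition is set - against the reference condition's
    # nominal clean power (sum of squared gains; components are unit-RMS).
    # A fixed reference keeps the noise floor constant across conditions, so
    # a condition with fewer active features has *less* signal rather than
    # louder renormalized components.
    noise_seed = _stable_seed(config.seed, "noise", subject_id, condition)
    noise_rng = np.random.default_rng(noise_seed)
    clean_power = np.mean(clean**2)
    ref = config.snr_reference_condition
    if ref is not None:
        ref_gains: dict[str, float] = {}
        ref_gains.update(config.onset_gains.get(ref, {}))
        ref_gains.update(config.linguistic_gains.get(ref, {}))
        reference_power = float(sum(g**2 for g in ref_gains.values()))
    else:
        reference_power = clean_power
    data = clean.copy()
    if np.isfinite(config.snr_db):
        noise = pink_noise(noise_rng, (config.n_channels, n))
        if reference_power > 0:
            target_noise_power = reference_power / 10 ** (config.snr_db / 10)
            noise *= np.sqrt(target_noise_power)
        data = data + noise

    blink_signal = None
    annotations = None
    if config.blink_rate_hz > 0:
        blink_rng = np.random.default_rng(
            _stable_seed(config.seed, "blink", subject_id, condition)
        )
        template = _blink_template(fs)
        n_front = max(2, config.n_channels // 8)
        topo = np.zeros(config.n_channels)
        topo[:n_front] = np.linspace(1.0, 0.4, n_front)
        amp = config.blink_amplitude * np.sqrt(max(np.mean(data**2), 1e-12))
        n_blinks = blink_rng.poisson(config.blink_rate_hz * duration)
        starts = np.sort(blink_rng.uniform(0, duration - 0.5, size=n_blinks))
        blink_signal = np.zeros_like(data)
        annotations = []
        for t0 in starts:
            i0 = int(round(t0 * fs))
            seg = slice(i0, min(i0 + len(template), n))
            blink_signal[:, seg] += amp * topo[:, None] * template[: seg.stop - i0]
            annotations.append((float(t0), float(t0 + len(template) / fs)))
        data = data + blink_signal

    rec = EEGRecording(
        data=data,
        fs=fs,
        subject=subject_id,
        condition=condition,
        blink_annotations=annotations,
        meta={"seed": config.seed, "snr_db": config.snr_db},
    )
    gt = GroundTruth(
        trf_kernels=kernels,
        gains_used=gains,
        noise_realization_seed=noise_seed,
        clean=clean if keep_clean else None,
        blink_signal=blink_signal,
    )
    return rec, gt


# --------------------------------------------------------------------------
# Cohort convenience
# --------------------------------------------------------------------------


def make_cohort_lexicons(
    config: SyntheticConfig,
    n_words: int = 1000,
    n_phonemes: int = 20,
    zipf_exponent: float = 1.0,
) -> tuple[Lexicon, Lexicon]:
    """Native + foreign lexicons sharing a phoneme inventory, disjoint words."""
    native = make_lexicon(
        n_words, n_phonemes, zipf_exponent, seed=_stable_seed(config.seed, "lex-nat")
    )
    native_words = {e.word for e in native.entries}
    for attempt in range(20):
        foreign = make_lexicon(
            n_words,
            n_phonemes,
            zipf_exponent,
            seed=_stable_seed(config.seed, "lex-for", attempt),
        )
        entries = [e for e in foreign.entries if e.word not in native_words]
        if len(entries) >= int(0.8 * n_words):
            total = sum(e.prior for e in entries)
            entries = [
                LexiconEntry(e.word, e.phonemes, e.prior / total) for e in entries
            ]
            return native, Lexicon(entries)
    raise RuntimeError("could not build a disjoint foreign lexicon")


def simulate_cohort(
    config: SyntheticConfig,
    conditions: tuple[str, ...] = CONDITIONS,
    lexicon_kwargs: dict | None = None,
) -> dict:
    """Full synthetic study: shared stories per condition, EEG per subject.

    Returns a dict with keys ``lexicons`` (native, foreign), ``alignments``
    (condition -> Alignment), ``recordings`` ((subject, condition) ->
    EEGRecording) and ``ground_truth`` (same keys -> GroundTruth).
    """
    native, foreign = make_cohort_lexicons(config, **(lexicon_kwargs or {}))
    alignments = {}
    for cond in conditions:
        if cond == "scrambled":
            continue
        alignments[cond] = make_story(
            native,
            config.condition_durations[cond],
            condition=cond,
            seed=_stable_seed(config.seed, "story", cond),
            foreign_lexicon=foreign,
        )
    if "scrambled" in conditions:
        # scrambled = shuffled words of *the* coherent story (same tokens,
        # same gap layout), like a word-shuffled version of the same text
        dur = config.condition_durations["scrambled"]
        base = alignments.get("coherent")
        if base is None or config.condition_durations.get("coherent") != dur:
            base = make_story(
                native, dur, "coherent",
                seed=_stable_seed(config.seed, "story", "scrambled-base"),
            )
        alignments["scrambled"] = scramble_alignment(
            base, seed=_stable_seed(config.seed, "story", "scrambled")
        )
    recordings = {}
    ground_truth = {}
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    for subject in subjects:
        for cond in conditions:
            lex = foreign if cond == "foreign" else native
            rec, gt = simulate_eeg(alignments[cond], lex, config, subject, cond)
            recordings[(subject, cond)] = rec
            ground_truth[(subject, cond)] = gt
    return {
        "lexicons": (native, foreign),
        "alignments": alignments,
        "recordings": recordings,
        "ground_truth": ground_truth,
        "subjects": subjects,
    }


def write_cohort(cohort: dict, out_dir: str | Path) -> None:
    """Write a cohort directory tree (TextGrids, lexicon TSVs, containers)."""
    from .textgridio import write_textgrid

    out = Path(out_dir)
    (out / "eeg").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)
    native, foreign = cohort["lexicons"]
    native.save_tsv(out / "lexicon_native.tsv")
    foreign.save_tsv(out / "lexicon_foreign.tsv")
    for cond, alignment in cohort["alignments"].items():
        write_textgrid(alignment, out / "alignments" / f"{cond}.TextGrid")
    for (subject, cond), rec in cohort["recordings"].items():
        rec.save(out / "eeg" / f"{subject}_{cond}")
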