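"""EEG preprocessing chain for neural speech tracking.

The fixed order is: downsample to 128 Hz (anti-aliased), multichannel Wiener
filter (MWF) eyeblink removal, average re-reference, 0.5-25 Hz least-squares
FIR band-pass with group-delay compensation, downsample to 64 Hz. Channel
normalization (zero mean, unit variance) is applied per train/val/test split,
never across splits.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import scipy.linalg
from scipy.signal import fftconvolve, firls, resample_poly

from .containers import EEGRecording


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased decimation by an integer factor (polyphase FIR)."""
    ratio = rec.fs / target_fs
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below the current rate")
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs ratio {ratio} is not an integer")
    q = int(round(ratio))
    data = resample_poly(rec.data, up=1, down=q, axis=1)
    return rec.copy_with(data=data, fs=target_fs)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean over channels (common average)."""
    if rec.n_channels < 2:
        raise ValueError("average re-reference needs >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


@lru_cache(maxsize=8)
def _bandpass_kernels(
    fs: float, low: float, high: float, hp_order: int, lp_order: int
) -> tuple[np.ndarray, np.ndarray]:
    nyq = fs / 2
    # 10% transition bands: below the high-pass edge, above the low-pass edge
    hp = firls(hp_order + 1, [0, 0.9 * low, low, nyq], [0, 0, 1, 1], fs=fs)
    lp = firls(lp_order + 1, [0, high, 1.1 * high, nyq], [1, 1, 0, 0], fs=fs)
    return hp, lp


def _filt_compensated(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Linear-phase FIR with reflect padding; 'same' alignment compensates the
    group delay of the (odd-length) kernel."""
    pad = len(taps) // 2
    padded = np.pad(data, [(0, 0), (pad, pad)], mode="reflect")
    out = fftconvolve(padded, taps[None, :], mode="same", axes=1)
    return out[:, pad:-pad]


def bandpass_ls(
    rec: EEGRecording,
    low: float = 0.5,
    high: float = 25.0,
    hp_order: int = 5000,
    lp_order: int = 500,
) -> EEGRecording:
    """0.5-25 Hz band-pass: least-squares FIR high-pass (order 5000) then
    low-pass (order 500), each with a 10% transition band and group-delay
    compensation. Requires a 128 Hz recording longer than the filters."""
    if abs(rec.fs - 128.0) > 1e-9:
        raise ValueError("band-pass stage expects a 128 Hz recording")
    hp, lp = _bandpass_kernels(rec.fs, low, high, hp_order, lp_order)
    if rec.n_samples <= max(len(hp), len(lp)):
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than filter "
            f"({max(len(hp), len(lp))} taps)"
        )
    data = _filt_compensated(rec.data, hp)
    data = _filt_compensated(data, lp)
    return rec.copy_with(data=data)


def _annotation_mask(
    annotations: list[tuple[float, float]], fs: float, n: int
) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for start, end in annotations:
        mask[max(0, int(start * fs)) : min(n, int(np.ceil(end * fs)))] = True
    return mask


def detect_blinks_zscore(
    rec: EEGRecording, channel: int = 0, threshold: float = 4.0, pad_s: float = 0.1
) -> list[tuple[float, float]]:
    """Fallback blink detector: |z| > threshold on one frontal channel,
    padded and merged into intervals."""
    x = rec.data[channel]
    z = (x - x.mean()) / x.std()
    hits = np.flatnonzero(np.abs(z) > threshold)
    intervals: list[tuple[float, float]] = []
    for i in hits:
        t0, t1 = i / rec.fs - pad_s, i / rec.fs + pad_s
        if intervals and t0 <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], t1)
        else:
            intervals.append((t0, t1))
    return [(max(0.0, a), min(rec.duration, b)) for a, b in intervals]


def remove_eyeblinks_mwf(
    rec: EEGRecording,
    annotations: list[tuple[float, float]] | None = None,
    ridge: float = 1e-9,
    eig_threshold: float | None = None,
) -> EEGRecording:
    """Multichannel Wiener filter eyeblink removal (GEVD rank truncation).

    Spatial covariances are estimated from annotated (artifact) vs remaining
    (clean) samples; the generalized eigendecomposition of (R_artifact,
    R_clean) keeps components whose artifact-to-clean eigenvalue ratio
    exceeds a noise floor, and the Wiener estimate of the artifact is
    subtracted from the whole recording. The default threshold is calibrated
    from the data themselves: a split-half GEVD of the clean segments gives
    the eigenvalue spread attributable to finite-sample fluctuation (EEG is
    strongly autocorrelated, so an i.i.d. bound would be too tight), scaled
    to the artifact-window sample count. Eigenvalue ratios within that null
    spread are not treated as artifact, so annotated-but-clean data passes
    through unchanged. Without annotations the recording passes through
    (warned).
    """
    if annotations is None:
        annotations = rec.blink_annotations
    if not annotations:
        warnings.warn("no blink annotations: MWF pass-through", stacklevel=2)
        return rec.copy_with(data=rec.data.copy())
    mask = _annotation_mask(annotations, rec.fs, rec.n_samples)
    if mask.sum() == 0:
        warnings.warn("annotations cover no samples: MWF pass-through", stacklevel=2)
        return rec.copy_with(data=rec.data.copy())
    if (~mask).mean() < 0.5:
        raise ValueError("MWF needs at least 50% clean (unannotated) data")

    y = rec.data
    ryy = np.cov(y[:, mask])
    rnn = np.cov(y[:, ~mask])
    tr = np.trace(rnn) / rec.n_channels
    if eig_threshold is None:
        # null eigenvalue spread from interleaved split halves of clean data,
        # rescaled from the half-size to the artifact-window sample count
        clean_idx = np.flatnonzero(~mask)
        block = max(1, int(rec.fs))
        half = (clean_idx // block) % 2 == 0
        r1 = np.cov(y[:, clean_idx[half]])
        r2 = np.cov(y[:, clean_idx[~half]]) + ridge * tr * np.eye(rec.n_channels)
        lam_null = scipy.linalg.eigh(r1, r2, eigvals_only=True)
        scale = np.sqrt(clean_idx[half].size / mask.sum())
        eig_threshold = 1.0 + 1.5 * scale * max(lam_null.max() - 1.0, 0.0)
    rnn_reg = rnn + ridge * tr * np.eye(rec.n_channels)
    lam, v = scipy.linalg.eigh(ryy, rnn_reg)  # v.T @ rnn @ v = I
    keep = lam > eig_threshold
    if not np.any(keep):
        return rec.copy_with(data=y.copy())
    weights = np.where(keep, np.maximum(lam - 1.0, 0.0) / lam, 0.0)
    v_inv_t = np.linalg.inv(v).T  # = rnn @ v, i.e. V^{-T}
    # artifact estimate: V^{-T} diag((lam-1)/lam) V^T y
    artifact = v_inv_t @ (weights[:, None] * (v.T @ y))
    return rec.copy_with(data=y - artifact)


def normalize_per_split(
    splits: dict[str, EEGRecording] | list[EEGRecording],
) -> dict[str, EEGRecording] | list[EEGRecording]:
    """Z-score every channel within each split independently."""
    items = splits.items() if isinstance(splits, dict) else enumerate(splits)
    out: dict = {}
    for key, rec in items:
        std = rec.data.std(axis=1, keepdims=True)
        bad = np.flatnonzero(std[:, 0] == 0)
        if bad.size:
            raise ValueError(f"zero-variance channel(s) {bad.tolist()} in split {key!r}")
        out[key] = rec.copy_with(data=(rec.data - rec.data.mean(axis=1, keepdims=True)) / std)
    if isinstance(splits, dict):
        return out
    return [out[i] for i in range(len(out))]


def normalize_channels(rec: EEGRecording) -> EEGRecording:
    """Z-score channels of a single recording (one-split convenience)."""
    return normalize_per_split([rec])[0]


def preprocess_recording(
    rec: EEGRecording,
    skip_mwf: bool = False,
    low: float = 0.5,
    high: float = 25.0,
    hp_order: int = 5000,
    lp_order: int = 500,
    target_fs: float = 64.0,
) -> EEGRecording:
    """The full fixed-order chain down to the 64 Hz analysis rate.

    Recordings already at 128 Hz skip the first resampling stage; MWF runs
    only when blink annotations are present (or is skipped explicitly).
    """
    if rec.fs > 128.0:
        rec = resample(rec, 128.0)
    if not skip_mwf and rec.blink_annotations:
        rec = remove_eyeblinks_mwf(rec)
    rec = rereference_average(rec)
    rec = bandpass_ls(rec, low=low, high=high, hp_order=hp_order, lp_order=lp_order)
    if target_fs < rec.fs:
        rec = resample(rec, target_fs)
    return rec
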