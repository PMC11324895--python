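"""In-memory containers and the package's lossless on-disk format.

EEG and feature streams are stored as float ``.npy`` arrays with a JSON
sidecar carrying sampling rate and labels, so a recording round-trips
bit-exactly (EDF quantizes to 16 bit, which would break determinism tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

FEATURE_NAMES = ("PO", "WO", "CE", "WF")


@dataclass
class FeatureStream:
    """A sampled pulse train for one speech feature.

    ``values`` is zero everywhere except at onset samples, where the pulse
    amplitude carries the feature value (1.0 for onset features, entropy in
    bits for CE, -log10 prior for WF).
    """

    values: np.ndarray
    fs: float
    feature_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature stream must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature stream contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("feature pulse amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    subject: str = ""
    condition: str = ""
    blink_annotations: list[tuple[float, float]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        return EEGRecording(
            data=data,
            fs=self.fs if fs is None else fs,
            subject=self.subject,
            condition=self.condition,
            blink_annotations=None
            if self.blink_annotations is None
            else list(self.blink_annotations),
            meta=dict(self.meta),
        )

    # ---------------------------------------------------------------- I/O

    def save(self, stem: str | Path) -> None:
        """Write ``<stem>.npy`` + ``<stem>.json`` (the internal container)."""
        stem = Path(stem)
        np.save(stem.with_suffix(".npy"), self.data)
        sidecar = {
            "fs": self.fs,
            "subject": self.subject,
            "condition": self.condition,
            "blink_annotations": self.blink_annotations,
            "meta": self.meta,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, stem: str | Path) -> "EEGRecording":
        stem = Path(stem)
        data = np.load(stem.with_suffix(".npy"))
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        blinks = sidecar.get("blink_annotations")
        if blinks is not None:
            blinks = [tuple(b) for b in blinks]
        return cls(
            data=data,
            fs=sidecar["fs"],
            subject=sidecar.get("subject", ""),
            condition=sidecar.get("condition", ""),
            blink_annotations=blinks,
            meta=sidecar.get("meta", {}),
        )

    def to_mne(self):
        """Bridge to an :class:`mne.io.RawArray` (requires mne)."""
        import mne

        info = mne.create_info(
            [f"EEG{i:03d}" for i in range(self.n_channels)], self.fs, "eeg"
        )
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")

    def export_edf(self, path: str | Path) -> None:
        """Export to EDF via mne (needs the optional ``edfio`` backend)."""
        import mne

        mne.export.export_raw(str(path), self.to_mne(), fmt="edf")


def read_raw_eeg(path: str | Path, subject: str = "", condition: str = "") -> EEGRecording:
    """Read an EDF/BDF file (via mne) or an internal-container stem."""
    path = Path(path)
    if path.suffix.lower() in {".edf", ".bdf"}:
        import mne

        raw = mne.io.read_raw(str(path), preload=True, verbose="error")
        return EEGRecording(
            data=raw.get_data() * 1e6, fs=raw.info["sfreq"],
            subject=subject, condition=condition,
        )
    return EEGRecording.load(path.with_suffix(""))


def save_feature_stream(stream: FeatureStream, stem: str | Path) -> None:
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), stream.values)
    stem.with_suffix(".json").write_text(
        json.dumps({"fs": stream.fs, "feature_name": stream.feature_name})
    )


def load_feature_stream(stem: str | Path) -> FeatureStream:
    stem = Path(stem)
    values = np.load(stem.with_suffix(".npy"))
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    return FeatureStream(values, sidecar["fs"], sidecar["feature_name"])
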