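"""The multi-input CNN (MICNN) for the match-mismatch task.

Two convolutional branches embed the EEG segment and each candidate speech
segment (stacked feature pulse trains) into a shared representation space:
a 1x1 spatial projection followed by a stack of dilated temporal convolutions
(kernel 3, dilations 1/3/9/27) and a pointwise output projection, tanh
nonlinearities throughout. The speech branch's weights are shared between the
two candidates. Per-channel cosine similarities over time between the EEG
embedding and each candidate embedding feed an antisymmetric linear head,

    logit = w . (sim(EEG, cand0) - sim(EEG, cand1)),

so swapping the candidates maps the predicted probability p to 1 - p exactly.
The default word-level configuration has 127k trainable parameters.

Also here: training with Adam/BCE and early stopping, language/subject
fine-tuning (same training parameters, different data), match-mismatch
accuracy with Wilson intervals, the linguistics-over-segmentation added-value
statistic (L - C accuracy), and paired Wilcoxon condition comparisons.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.proportion import proportion_confint

from .matchmismatch import MMDataset
from .nn import Adam, Conv1x1, CosineOverTime, DilatedConv1d, Param, Tanh, bce_loss, sigmoid

CONTROL_SETS = {("PO",), ("WO",)}
LINGUISTIC_SETS = {("PO", "CE"), ("WO", "WF")}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``feature_set`` names the speech streams stacked into the speech branch:
    C (control) models use ('PO',) or ('WO',); L (linguistic) models add the
    matching linguistic stream, ('PO','CE') or ('WO','WF'). The defaults
    (70 filters, projection width 29) put the word-level model at 127k
    trainable parameters.
    """

    eeg_channels: int = 64
    feature_set: tuple[str, ...] = ("WO", "WF")
    window_samples: int = 640
    filters: int = 70
    projection: int = 29
    dilations: tuple[int, ...] = (1, 3, 9, 27)
    time_blocks: int = 8  # cosine similarity per aligned block of the window

    def __post_init__(self) -> None:
        self.feature_set = tuple(self.feature_set)
        self.dilations = tuple(self.dilations)
        rf = self.receptive_field
        if rf > self.window_samples:
            raise ValueError(
                f"receptive field {rf} exceeds window of {self.window_samples} samples"
            )
        if self.window_samples % self.time_blocks:
            raise ValueError("window_samples must be divisible by time_blocks")

    @property
    def receptive_field(self) -> int:
        return 1 + 2 * sum(self.dilations)


@dataclass
class TrainConfig:
    """Training parameters: BCE loss, Adam at 1e-3, up to 50 epochs with
    early stopping; identical across pretraining and both fine-tuning modes.

    The batch size of 16 keeps the per-epoch update count useful on
    desk-scale datasets (a few hundred examples); patience of 10 epochs on
    the validation loss avoids stopping on early noise-driven minima.
    """

    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 10
    batch_size: int = 16
    seed: int = 0


class MICNN:
    """Weights and arithmetic are float32 (the usual CNN training precision);
    inputs are cast on entry."""

    dtype = np.float32

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f, p = config.filters, config.projection

        def temporal_stack(in_ch: int) -> list:
            layers: list = [Conv1x1(in_ch, f, rng, self.dtype), Tanh()]
            for d in config.dilations:
                layers += [DilatedConv1d(f, f, d, rng, self.dtype), Tanh()]
            layers += [Conv1x1(f, p, rng, self.dtype), Tanh()]
            return layers

        self.eeg_layers = temporal_stack(config.eeg_channels)
        self.speech_layers = temporal_stack(len(config.feature_set))
        self.cosine = CosineOverTime()
        n_sims = p * config.time_blocks
        scale = np.sqrt(1.0 / n_sims)
        self.head_w = Param(rng.uniform(-scale, scale, size=n_sims).astype(self.dtype))

    # ------------------------------------------------------------- plumbing

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.eeg_layers + self.speech_layers:
            out += layer.params
        out.append(self.head_w)
        return out

    @property
    def num_params(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params)}
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MICNN":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig(**json.loads(str(data["config"])))
            model = cls(config)
            model.set_state([data[f"p{i}"] for i in range(len(model.params))])
        return model

    # -------------------------------------------------------------- forward

    def _run(self, layers: list, x: np.ndarray) -> np.ndarray:
        for layer in layers:
            x = layer.forward(x)
        return x

    def _run_back(self, layers: list, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(layers):
            dy = layer.backward(dy)
        return dy

    def _blocked(self, x: np.ndarray) -> np.ndarray:
        """(B, P, T) -> (B, P*blocks, T/blocks): per-block similarity channels."""
        b, p, t = x.shape
        nb = self.config.time_blocks
        return np.ascontiguousarray(x).reshape(b, p * nb, t // nb)

    def forward(self, eeg: np.ndarray, candidates: np.ndarray) -> np.ndarray:
        """P(candidate 0 is the matched one); shapes (B,C,T), (B,2,F,T)."""
        b = eeg.shape[0]
        e = self._run(self.eeg_layers, eeg.astype(self.dtype, copy=False))
        # fold both candidates into the batch axis: weight sharing for free
        candidates = candidates.astype(self.dtype, copy=False)
        s_in = np.concatenate([candidates[:, 0], candidates[:, 1]], axis=0)
        s = self._run(self.speech_layers, s_in)
        sims = self.cosine.forward(
            self._blocked(np.concatenate([e, e], axis=0)), self._blocked(s)
        )
        self._sim_diff = sims[:b] - sims[b:]
        return sigmoid(self._sim_diff @ self.head_w.value)

    def backward(self, p: np.ndarray, targets: np.ndarray) -> None:
        b = p.shape[0]
        dlogit = ((p - targets) / b).astype(self.dtype)
        self.head_w.grad += self._sim_diff.T @ dlogit
        dsims = np.concatenate(
            [np.outer(dlogit, self.head_w.value), -np.outer(dlogit, self.head_w.value)]
        )
        de2, ds = self.cosine.backward(dsims)
        p = self.config.projection
        de2 = de2.reshape(2 * b, p, -1)
        ds = ds.reshape(2 * b, p, -1)
        self._run_back(self.speech_layers, ds)
        self._run_back(self.eeg_layers, de2[:b] + de2[b:])

    def predict_proba(self, ds: MMDataset, batch_size: int = 256) -> np.ndarray:
        out = np.empty(len(ds))
        for i in range(0, len(ds), batch_size):
            sl = slice(i, i + batch_size)
            out[sl] = self.forward(ds.eeg[sl], ds.candidates[sl])
        return out


def build_micnn(config: ModelConfig, seed: int = 0) -> MICNN:
    return MICNN(config, seed=seed)


def control_config(linguistic: ModelConfig) -> ModelConfig:
    """The matched control (onset-only) configuration of an L model."""
    cfg = copy.deepcopy(linguistic)
    cfg.feature_set = linguistic.feature_set[:1]
    return cfg


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


def _epoch_metrics(model: MICNN, ds: MMDataset) -> tuple[float, float]:
    p = model.predict_proba(ds)
    targets = (ds.labels == 0).astype(float)
    loss = bce_loss(p, targets)
    pred0 = p > 0.5
    acc = float(np.mean(np.where(ds.labels == 0, pred0, (p < 0.5))))
    return loss, acc


def train(
    model: MICNN,
    train_ds: MMDataset,
    val_ds: MMDataset,
    tc: TrainConfig | None = None,
) -> tuple[MICNN, dict]:
    """Adam/BCE training with early stopping on validation loss; restores the
    best-validation weights before returning. Deterministic given tc.seed."""
    tc = tc or TrainConfig()
    opt = Adam(model.params, lr=tc.learning_rate)
    targets_all = (train_ds.labels == 0).astype(float)
    history: dict = {"train_loss": [], "val_loss": [], "val_acc": []}
    best_loss, best_state, best_epoch = np.inf, model.get_state(), -1

    for epoch in range(tc.max_epochs):
        order = np.random.default_rng([tc.seed, epoch]).permutation(len(train_ds))
        losses = []
        for i in range(0, len(order), tc.batch_size):
            idx = order[i : i + tc.batch_size]
            opt.zero_grad()
            p = model.forward(train_ds.eeg[idx], train_ds.candidates[idx])
            loss = bce_loss(p, targets_all[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}"
                )
            model.backward(p, targets_all[idx])
            opt.step()
            losses.append(loss)
        val_loss, val_acc = _epoch_metrics(model, val_ds)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.get_state(), epoch
        elif epoch - best_epoch >= tc.patience:
            break
    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    return model, history


def finetune(
    model: MICNN,
    mode: str,
    train_ds: MMDataset,
    val_ds: MMDataset,
    tc: TrainConfig | None = None,
) -> tuple[MICNN, dict]:
    """Continue training on new data with the same training parameters.

    ``mode`` is 'language' (train on the other subjects' data for one
    condition) or 'subject' (train on the held-out subject's own train split);
    the split geometry is the caller's responsibility, this just trains.
    """
    if mode not in {"language", "subject"}:
        raise ValueError("mode must be 'language' or 'subject'")
    return train(model, train_ds, val_ds, tc)


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------


@dataclass
class EvalResult:
    mm_accuracy: float
    ci_low: float
    ci_high: float
    n_examples: int


def evaluate_mm(model: MICNN, test_ds: MMDataset) -> EvalResult:
    """Fraction of examples whose higher-probability candidate is the matched
    one (exact ties count as errors), with a Wilson 95% interval."""
    if len(test_ds) == 0:
        raise ValueError("empty test set")
    p = model.predict_proba(test_ds)
    correct = np.where(test_ds.labels == 0, p > 0.5, p < 0.5)
    k, n = int(correct.sum()), len(test_ds)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return EvalResult(k / n, float(lo), float(hi), n)


# --------------------------------------------------------------------------
# Accuracy table and condition comparisons
# --------------------------------------------------------------------------

TABLE_COLUMNS = [
    "subject", "condition", "level", "feature_set", "finetune",
    "mm_accuracy", "n_examples",
]


def accuracy_table(rows: list[dict]) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    bad = table[(table.mm_accuracy < 0) | (table.mm_accuracy > 1)]
    if len(bad):
        raise ValueError("mm_accuracy outside [0, 1]")
    return table


def lc_accuracy(
    table: pd.DataFrame, subject: str, condition: str, level: str, finetune: str
) -> float:
    """MM accuracy of the linguistic (L) model minus its matched control (C)
    model for one subject/condition/level/fine-tuning cell."""
    sel = table[
        (table.subject == subject)
        & (table.condition == condition)
        & (table.level == level)
        & (table.finetune == finetune)
    ]
    acc = {}
    for fs_name in ("L", "C"):
        rows = sel[sel.feature_set == fs_name]
        if len(rows) != 1:
            raise KeyError(
                f"need exactly one {fs_name} row for ({subject}, {condition}, "
                f"{level}, {finetune}); found {len(rows)}"
            )
        acc[fs_name] = float(rows.mm_accuracy.iloc[0])
    return acc["L"] - acc["C"]


def lc_per_subject(
    table: pd.DataFrame, condition: str, level: str, finetune: str
) -> pd.Series:
    subjects = sorted(table.subject.unique())
    return pd.Series(
        {s: lc_accuracy(table, s, condition, level, finetune) for s in subjects}
    )


def compare_conditions(
    lc_a: np.ndarray | pd.Series, lc_b: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-subject L-C values
    (zero differences dropped). Returns (W, p)."""
    a = np.asarray(lc_a, dtype=float)
    b = np.asarray(lc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-d arrays required")
    if a.size < 6:
        raise ValueError("need >= 6 paired subjects")
    if np.all(a == b):
        raise ValueError("all paired differences are zero: test undefined")
    res = wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
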