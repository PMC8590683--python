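"""Per-segment apnea/normal sequence classifier m(.).

Two input modes:

* ``raw_rri`` — each 60-s segment's standardized R-R intervals are fed
  beat-by-beat to the LSTM (variable length, pre-padded with zeros and
  masked up to ``max_beats``);
* ``hrv_features`` — each segment is summarized by the 11 guideline HRV
  features, standardized per-feature across the training set and fed as
  a single-timestep sequence of dimension 11.

Defaults follow the screening study's tuned configuration: one LSTM
layer with 32 hidden units, 150 epochs of Adam at learning rate 0.01.
Loss is binary cross-entropy on a final-hidden-state sigmoid read-out;
batch size 64; gradients are clipped at global norm 5 to keep the large
learning rate stable.  Training and prediction are deterministic given
the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import lstm
from .hrv import FEATURE_NAMES, hrv_features
from .io import ValidationError
from .preprocessing import APNEA_LABEL, NORMAL_LABEL, SegmentSet

__all__ = ["ModelConfig", "TrainedModel", "build_training_matrix", "train", "predict"]

MODES = ("raw_rri", "hrv_features")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the segment classifier (study defaults)."""

    hidden_units: int = 32
    epochs: int = 150
    optimizer: str = "adam"
    learning_rate: float = 0.01
    mode: str = "raw_rri"
    max_beats: int = 120  # pre-pad length for raw mode; 2 beats/s x 60 s
    batch_size: int = 64
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValidationError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")
        if self.optimizer.lower() != "adam":
            raise ValidationError("only the Adam optimizer is supported")


@dataclass
class TrainedModel:
    """Fitted classifier state plus training metadata."""

    params: lstm.LSTMParams
    config: ModelConfig
    input_dim: int
    max_beats: int
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    loss_curve: list[float] = field(default_factory=list)
    class_counts: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.config),
            "input_dim": self.input_dim,
            "max_beats": self.max_beats,
            "loss_curve": self.loss_curve,
            "class_counts": self.class_counts,
            "has_scaler": self.feature_mean is not None,
        }
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        if self.feature_mean is not None:
            arrays["feature_mean"] = self.feature_mean
            arrays["feature_sd"] = self.feature_sd
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            params = lstm.LSTMParams(
                {k[6:]: data[k] for k in data.files if k.startswith("param_")}
            )
            fm = data["feature_mean"] if meta["has_scaler"] else None
            fsd = data["feature_sd"] if meta["has_scaler"] else None
        return cls(
            params=params,
            config=ModelConfig(**meta["config"]),
            input_dim=meta["input_dim"],
            max_beats=meta["max_beats"],
            feature_mean=fm,
            feature_sd=fsd,
            loss_curve=meta["loss_curve"],
            class_counts=meta["class_counts"],
        )


def _segment_features(segset: SegmentSet) -> list[np.ndarray]:
    rows = []
    for seg in segset.segments:
        if seg.raw_values is None:
            raise ValidationError("hrv_features mode needs segments with raw intervals")
        rows.append(hrv_features(seg.raw_values).as_array())
    return rows


def build_training_matrix(
    segsets: Sequence[SegmentSet], mode: str = "raw_rri"
) -> tuple[list[np.ndarray], np.ndarray]:
    """Stack all subjects' segments (subject order, then segment order).

    Returns ``(X, y)`` where ``X`` is a list with one row per segment —
    a variable-length standardized RRI vector in ``raw_rri`` mode, or an
    11-long feature vector in ``hrv_features`` mode — and ``y`` the
    matching concatenated A/N label vector.
    """
    if not segsets:
        raise ValidationError("no subjects provided")
    widths = {s.window_width_s for s in segsets}
    if len(widths) > 1:
        raise ValidationError(f"mixed window widths: {sorted(widths)}")
    X: list[np.ndarray] = []
    y: list[str] = []
    for segset in segsets:
        if segset.labels is None:
            raise ValidationError(f"subject {segset.subject_id} has unlabeled segments")
        if mode == "raw_rri":
            X.extend(seg.values for seg in segset.segments)
        elif mode == "hrv_features":
            X.extend(_segment_features(segset))
        else:
            raise ValidationError(f"mode must be one of {MODES}")
        y.extend(segset.labels)
    return X, np.asarray(y)


def _pad_raw(rows: Sequence[np.ndarray], max_beats: int) -> tuple[np.ndarray, np.ndarray]:
    """Pre-pad variable-length rows with zeros; mask marks real beats.

    Rows longer than ``max_beats`` keep their last ``max_beats`` beats.
    """
    n = len(rows)
    X = np.zeros((n, max_beats, 1), dtype=lstm.DTYPE)
    mask = np.zeros((n, max_beats), dtype=lstm.DTYPE)
    for r, row in enumerate(rows):
        row = np.asarray(row, dtype=float)[-max_beats:]
        X[r, max_beats - row.size :, 0] = row
        mask[r, max_beats - row.size :] = 1.0
    return X, mask


def _feature_tensor(
    rows: Sequence[np.ndarray], mean: np.ndarray, sd: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    F = np.vstack(rows).astype(float)
    # undefined features (e.g. LF/HF with zero HF) impute to the training mean
    F = np.where(np.isfinite(F), F, mean)
    Z = (F - mean) / sd
    X = Z[:, None, :].astype(lstm.DTYPE)
    mask = np.ones((X.shape[0], 1), dtype=lstm.DTYPE)
    return X, mask


def _encode(y: np.ndarray) -> np.ndarray:
    bad = set(np.unique(y)) - {APNEA_LABEL, NORMAL_LABEL}
    if bad:
        raise ValidationError(f"labels must be A or N, got {sorted(bad)}")
    return (y == APNEA_LABEL).astype(lstm.DTYPE)


def train(X: Sequence[np.ndarray], y: np.ndarray, config: ModelConfig) -> TrainedModel:
    """Fit the classifier on stacked segments.

    Raises
    ------
    ValidationError
        If ``y`` contains a single class, or any input value is non-finite
        (raw mode; undefined HRV features are imputed in feature mode).
    """
    if len(X) != len(y):
        raise ValidationError("X and y must have the same number of rows")
    y_enc = _encode(np.asarray(y))
    counts = {APNEA_LABEL: int(y_enc.sum()), NORMAL_LABEL: int((1 - y_enc).sum())}
    if min(counts.values()) == 0:
        raise ValidationError("training labels contain a single class")

    if config.mode == "raw_rri":
        if any(not np.all(np.isfinite(np.asarray(row, dtype=float))) for row in X):
            raise ValidationError("non-finite value in training segments")
        Xt, mask = _pad_raw(X, config.max_beats)
        feature_mean = feature_sd = None
        input_dim = 1
    else:
        F = np.vstack(X).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            feature_mean = np.nanmean(F, axis=0)
            feature_sd = np.nanstd(F, axis=0, ddof=1)
        feature_mean = np.where(np.isfinite(feature_mean), feature_mean, 0.0)
        feature_sd = np.where(
            np.isfinite(feature_sd) & (feature_sd > 0), feature_sd, 1.0
        )
        Xt, mask = _feature_tensor(X, feature_mean, feature_sd)
        input_dim = len(FEATURE_NAMES)

    rng = np.random.default_rng(config.seed)
    params = lstm.init_params(input_dim, config.hidden_units, seed=config.seed)
    opt = lstm.AdamState(params, lr=config.learning_rate, clip_norm=config.clip_norm)
    n, T = Xt.shape[0], Xt.shape[1]
    # with pre-padding, a batch's leading all-masked columns are no-ops;
    # trimming them is exact and saves most of the padded work
    lengths = mask.sum(axis=1).astype(int)
    loss_curve: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            t0 = T - int(lengths[idx].max())
            loss, grads = lstm.loss_and_gradients(
                params, Xt[idx][:, t0:], mask[idx][:, t0:], y_enc[idx]
            )
            lstm.adam_step(params, grads, opt)
            epoch_loss += loss * idx.size
        loss_curve.append(epoch_loss / n)

    return TrainedModel(
        params=params,
        config=config,
        input_dim=input_dim,
        max_beats=config.max_beats,
        feature_mean=feature_mean,
        feature_sd=feature_sd,
        loss_curve=loss_curve,
        class_counts=counts,
    )


def predict_proba(model: TrainedModel, segments: SegmentSet) -> np.ndarray:
    """Class-A probability per segment (empty set -> empty array)."""
    if len(segments) == 0:
        return np.empty(0)
    if model.config.mode == "raw_rri":
        rows = [seg.values for seg in segments.segments]
        flat = np.concatenate(rows)
        if abs(float(flat.mean())) >= 0.5:
            warnings.warn(
                "raw-RRI model expects subject-standardized inputs "
                f"(segment mean {float(flat.mean()):.2f}); did you skip standardization?",
                stacklevel=2,
            )
        Xt, mask = _pad_raw(rows, model.max_beats)
    else:
        rows = _segment_features(segments)
        Xt, mask = _feature_tensor(rows, model.feature_mean, model.feature_sd)
    if Xt.shape[-1] != model.input_dim:
        raise ValidationError(
            f"input dimension {Xt.shape[-1]} does not match model mode {model.config.mode}"
        )
    # fixed-size batches keep prediction O(n) in memory; leading all-masked
    # columns are exact no-ops and are trimmed
    T = Xt.shape[1]
    lengths = mask.sum(axis=1).astype(int)
    out = []
    for start in range(0, Xt.shape[0], 512):
        sl = slice(start, start + 512)
        t0 = T - int(lengths[sl].max())
        out.append(lstm.forward(model.params, Xt[sl][:, t0:], mask[sl][:, t0:]))
    return np.concatenate(out).astype(float)


def predict(model: TrainedModel, segments: SegmentSet) -> list[str]:
    """Per-segment labels: ``A`` iff the class-A score exceeds 0.5."""
    probs = predict_proba(model, segments)
    return [APNEA_LABEL if p > 0.5 else NORMAL_LABEL for p in probs]
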