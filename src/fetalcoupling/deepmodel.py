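"""Two-block 1-D CNN coupling classifier.

Architecture (native 1 kHz grid, input shape ``(2, 60000)``):

* block 1: conv(2 -> 8 filters, kernel 1024, stride 1, same padding)
  + batch-norm + ReLU;
* block 2: conv(8 -> 12 filters, kernel 512, stride 1, same padding)
  + batch-norm + ReLU;
* head: flatten + fully-connected(3) + softmax over the coupling classes
  ordered ([1:2], [2:3], [3:5]).

Training: class-weighted cross-entropy minimized with ADAM (lr 0.001,
L2 1e-4 on weights, mini-batch 12, up to 15 epochs, per-epoch reshuffle
from the run seed).  Class weights are inverse-frequency, mean-1
normalized.  When the spike grid is resampled to a sampling rate fs', the
kernel lengths scale by fs'/1000 (rounded to even) so receptive fields
keep their physical duration; this makes reduced-rate runs equivalent in
architecture.

Same padding keeps the final conv activation aligned 1:1 with input
samples, which the Grad-CAM overlay requires.  Prediction uses running
batch-norm statistics, so it is deterministic and batch-size invariant.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fetalcoupling._nn import Adam, BatchNorm1d, Conv1dSame, Dense, ReLU, softmax, weighted_xent
from fetalcoupling.beat_series import EncodedSegment
from fetalcoupling.coupling_label import SUPPORTED_RATIOS, CouplingRatio

__all__ = [
    "ModelConfig",
    "CouplingClassifier",
    "Prediction",
    "build_model",
    "class_weights",
    "train",
    "predict",
    "loo_cv",
    "write_predictions_csv",
]

CLASS_ORDER = SUPPORTED_RATIOS  # ([1:2], [2:3], [3:5])


def scaled_kernel(base: int, fs: float) -> int:
    """Kernel length at sampling rate fs (base lengths defined at 1 kHz).

    Scaled by fs/1000 and rounded to the nearest even integer (minimum 2)
    so receptive fields keep their duration across grid resolutions.
    """
    k = int(round(base * fs / 1000.0 / 2.0)) * 2
    return max(k, 2)


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the coupling classifier."""

    fs: float = 1000.0  # Hz of the spike grid
    window_length: float = 60.0  # s
    base_kernels: tuple = (1024, 512)  # at 1 kHz
    filters: tuple = (8, 12)
    n_classes: int = 3
    lr: float = 1e-3
    l2: float = 1e-4
    batch_size: int = 12
    max_epochs: int = 15
    seed: int = 0
    dtype: str = "float32"

    @property
    def L(self) -> int:
        return int(round(self.window_length * self.fs))

    @property
    def kernels(self) -> tuple:
        return tuple(scaled_kernel(b, self.fs) for b in self.base_kernels)

    def __post_init__(self) -> None:
        if any(k > self.L for k in self.kernels):
            raise ValueError(f"kernel lengths {self.kernels} exceed input length {self.L}")


@dataclass(frozen=True)
class Prediction:
    """Class probabilities for one segment; predicted ratio = argmax."""

    probabilities: np.ndarray  # length 3, sums to 1
    segment_ref: tuple | None = None  # (subject_id, segment_index)

    @property
    def predicted(self) -> CouplingRatio:
        return CLASS_ORDER[int(np.argmax(self.probabilities))]


class TrainingError(RuntimeError):
    pass


class CouplingClassifier:
    """The two-block CNN; see module docstring for the architecture."""

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        k1, k2 = config.kernels
        f1, f2 = config.filters
        self.conv1 = Conv1dSame(2, f1, k1, rng, dtype=dtype)
        self.bn1 = BatchNorm1d(f1, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv1dSame(f1, f2, k2, rng, dtype=dtype)
        self.bn2 = BatchNorm1d(f2, dtype=dtype)
        self.relu2 = ReLU()
        self.head = Dense(f2 * config.L, config.n_classes, rng, dtype=dtype)
        self.layers = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2, self.head]
        self.training_log: list[float] = []
        self.trained = False

    # -- forward passes -----------------------------------------------------

    def n_parameters(self) -> int:
        return sum(int(p.size) for ly in self.layers for p in ly.params.values())

    def conv_activation(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Final convolutional activation (post-ReLU), shape (B, f2, L)."""
        a = self.conv1.forward(x, training)
        a = self.bn1.forward(a, training)
        a = self.relu1.forward(a, training)
        a = self.conv2.forward(a, training)
        a = self.bn2.forward(a, training)
        return self.relu2.forward(a, training)

    def head_scores(self, activation: np.ndarray) -> np.ndarray:
        """Pre-softmax class scores from a final conv activation."""
        B = activation.shape[0]
        return activation.reshape(B, -1) @ self.head.params["w"] + self.head.params["b"]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        a = self.conv_activation(x, training)
        flat = a.reshape(a.shape[0], -1)
        return self.head.forward(flat, training)

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class probabilities for inputs of shape (B, 2, L)."""
        X = self._check_input(X)
        out = [softmax(self.forward(X[i : i + batch_size], training=False))
               for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.config.dtype)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != 2 or X.shape[2] != self.config.L:
            raise ValueError(f"expected input of shape (B, 2, {self.config.L}), got {X.shape}")
        return X

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> "CouplingClassifier":
        """Train with the standard recipe; see module docstring.

        ``X``: (n, 2, L) spike grids; ``y``: integer class indices into
        ``CLASS_ORDER``; ``weights``: per-class loss weights (default:
        inverse-frequency via :func:`class_weights`).
        """
        X = self._check_input(X)
        y = np.asarray(y, dtype=np.int64)
        if X.shape[0] == 0:
            raise TrainingError("empty training set")
        if len(np.unique(y)) < self.config.n_classes:
            raise TrainingError("all classes must be present in the training set")
        if weights is None:
            weights = class_weights([CLASS_ORDER[c] for c in y])
        weights = np.asarray(weights, dtype=np.float64)
        cfg = self.config
        opt = Adam(self.layers, lr=cfg.lr, l2=cfg.l2)
        rng = np.random.default_rng(cfg.seed)
        n = X.shape[0]
        self.training_log = []
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self.forward(X[idx], training=True)
                loss, grad = weighted_xent(logits, y[idx], weights)
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch + 1}")
                g = self.head.backward(grad)
                g = g.reshape(len(idx), cfg.filters[1], cfg.L)
                g = self.relu2.backward(g)
                g = self.bn2.backward(g)
                g = self.conv2.backward(g)
                g = self.relu1.backward(g)
                g = self.bn1.backward(g)
                self.conv1.backward(g)
                opt.step()
                losses.append(loss)
            self.training_log.append(float(np.mean(losses)))
        self._calibrate_batchnorm(X)
        self.trained = True
        return self

    def _calibrate_batchnorm(self, X: np.ndarray, batch_size: int = 32) -> None:
        """Re-estimate batch-norm statistics over the full training set.

        Short runs leave the momentum-averaged running estimates far from
        the data statistics; inference uses the exact population mean/var
        of each normalized layer's input instead.
        """

        def accumulate(layer_out_iter, bn):
            s = s2 = None
            count = 0
            for a in layer_out_iter:
                a64 = a.astype(np.float64)
                s = a64.sum(axis=(0, 2)) if s is None else s + a64.sum(axis=(0, 2))
                s2 = (a64**2).sum(axis=(0, 2)) if s2 is None else s2 + (a64**2).sum(axis=(0, 2))
                count += a.shape[0] * a.shape[2]
            mean = s / count
            bn.running_mean = mean
            bn.running_var = s2 / count - mean**2

        def batches():
            for i in range(0, X.shape[0], batch_size):
                yield X[i : i + batch_size]

        accumulate((self.conv1.forward(xb, training=False) for xb in batches()), self.bn1)

        def second_layer():
            for xb in batches():
                a = self.conv1.forward(xb, training=False)
                a = self.bn1.forward(a, training=False)
                yield self.conv2.forward(np.maximum(a, 0), training=False)

        accumulate(second_layer(), self.bn2)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Serialize parameters + config snapshot to an .npz archive."""
        arrays = {"__config__": np.frombuffer(
            json.dumps(self.config.__dict__).encode(), dtype=np.uint8)}
        for i, ly in enumerate(self.layers):
            for k, v in ly.params.items():
                arrays[f"layer{i}/{k}"] = v
            if isinstance(ly, BatchNorm1d):
                arrays[f"layer{i}/running_mean"] = ly.running_mean
                arrays[f"layer{i}/running_var"] = ly.running_var
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CouplingClassifier":
        data = np.load(path)
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["base_kernels"] = tuple(cfg_dict["base_kernels"])
        cfg_dict["filters"] = tuple(cfg_dict["filters"])
        model = cls(ModelConfig(**cfg_dict))
        for i, ly in enumerate(model.layers):
            for k in ly.params:
                ly.params[k] = data[f"layer{i}/{k}"]
            if isinstance(ly, BatchNorm1d):
                ly.running_mean = data[f"layer{i}/running_mean"]
                ly.running_var = data[f"layer{i}/running_var"]
        model.trained = True
        return model


# ---------------------------------------------------------------------------
# module-level operations


def build_model(config: ModelConfig) -> CouplingClassifier:
    """Construct an untrained classifier from a config."""
    return CouplingClassifier(config)


def class_weights(labels: list[CouplingRatio]) -> np.ndarray:
    """Inverse-frequency class weights, mean-1 normalized: w_c = T/(3*T_c)."""
    counts = np.array([sum(1 for lb in labels if lb == r) for r in CLASS_ORDER], dtype=float)
    if np.any(counts == 0):
        missing = [str(r) for r, c in zip(CLASS_ORDER, counts) if c == 0]
        raise ValueError(f"class(es) {missing} absent; cannot compute inverse-frequency weights")
    T = counts.sum()
    return T / (len(CLASS_ORDER) * counts)


def encode_dataset(encoded: list[EncodedSegment], labels: list[CouplingRatio]) -> tuple[np.ndarray, np.ndarray]:
    """Stack encoded segments into (X, y) arrays for training."""
    X = np.stack([e.grid for e in encoded]).astype(np.float32)
    y = np.array([CLASS_ORDER.index(lb) for lb in labels], dtype=np.int64)
    return X, y


def train(
    model: CouplingClassifier,
    dataset: list[tuple[EncodedSegment, CouplingRatio]],
    weights: np.ndarray | None = None,
) -> CouplingClassifier:
    """Train a model on (encoded segment, label) pairs."""
    X, y = encode_dataset([e for e, _ in dataset], [lb for _, lb in dataset])
    return model.fit(X, y, weights=weights)


def predict(model: CouplingClassifier, seg: EncodedSegment) -> Prediction:
    """Predict the coupling class of one encoded segment."""
    proba = model.predict_proba(seg.grid[None].astype(np.float32))[0]
    ref = None
    if seg.segment is not None:
        ref = (seg.segment.subject_id, seg.segment.segment_index)
    return Prediction(probabilities=proba, segment_ref=ref)


def loo_cv(
    dataset: list[tuple[EncodedSegment, CouplingRatio]],
    config: ModelConfig,
    grouping: str = "segment",
) -> list[Prediction | None]:
    """Leave-one-out cross-validation.

    ``grouping="segment"`` holds out one segment per fold (matching the
    one-fold-per-training-sample iteration count); ``grouping="subject"``
    holds out all segments of one subject.  Each fold trains a fresh model
    seeded from the run seed + fold index.  Folds whose training split
    misses a class are skipped (their predictions are None) and logged.
    Predictions are returned in dataset order.
    """
    if grouping not in ("segment", "subject"):
        raise ValueError(f"grouping must be 'segment' or 'subject', got {grouping!r}")
    n = len(dataset)
    if n < 3:
        raise ValueError("LOO needs at least 3 items")
    if grouping == "segment":
        units = [(i,) for i in range(n)]
    else:
        subjects: dict[str, list[int]] = {}
        for i, (enc, _) in enumerate(dataset):
            sid = enc.segment.subject_id if enc.segment else str(i)
            subjects.setdefault(sid, []).append(i)
        if len(subjects) < 3:
            raise ValueError("subject-grouped LOO needs at least 3 subjects")
        units = [tuple(v) for v in subjects.values()]
    predictions: list[Prediction | None] = [None] * n
    X, y = encode_dataset([e for e, _ in dataset], [lb for _, lb in dataset])
    for fold, held in enumerate(units):
        mask = np.ones(n, dtype=bool)
        mask[list(held)] = False
        if len(np.unique(y[mask])) < config.n_classes:
            warnings.warn(f"fold {fold}: a class is missing from the training split; skipped",
                          stacklevel=2)
            continue
        model = CouplingClassifier(replace(config, seed=config.seed + fold + 1))
        model.fit(X[mask], y[mask])
        proba = model.predict_proba(X[list(held)])
        for j, i in enumerate(held):
            enc = dataset[i][0]
            ref = (enc.segment.subject_id, enc.segment.segment_index) if enc.segment else None
            predictions[i] = Prediction(probabilities=proba[j], segment_ref=ref)
    return predictions


def write_predictions_csv(
    predictions: list[Prediction], labels: list[CouplingRatio], path: str | os.PathLike
) -> pd.DataFrame:
    rows = []
    for pred, lb in zip(predictions, labels):
        sid, seg_idx = pred.segment_ref if pred.segment_ref else ("", -1)
        rows.append(
            {
                "subject_id": sid,
                "segment_index": seg_idx,
                "p_1_2": pred.probabilities[0],
                "p_2_3": pred.probabilities[1],
                "p_3_5": pred.probabilities[2],
                "predicted": str(pred.predicted),
                "label": str(lb),
            }
        )
    df = pd.DataFrame(rows, columns=["subject_id", "segment_index", "p_1_2", "p_2_3", "p_3_5", "predicted", "label"])
    df.to_csv(path, index=False)
    return df
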