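"""Multi-label CNN predicting ablation-strategy success from tissue images.

The classifier sees only the labelled tissue image (healthy / fibrotic /
background) and outputs one sigmoid score per strategy (PVI, FIBRO, ROTOR).
Architecture: four 32-filter 3x3 convolution blocks (ReLU, 2x2 max pool)
followed by linear layers of 2048, 128 and 3 units with ReLU, dropout 0.8
before the 128-unit layer and a sigmoid head.  Trained with the multi-label
mean-squared-error loss, Adam (lr 1e-4), 100 epochs at full scale, keeping
the epoch with the lowest validation loss.  Evaluation follows a fixed
hold-out plus 5-fold validation-rotation protocol with per-class AUC,
recall, precision and F1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

from . import nn
from .tissue import Label, TissueDisk

CLASS_NAMES = ("pvi", "fibro", "rotor")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture knobs; defaults give the 2048-unit flatten at 128 px."""

    input_size: int = 128
    n_conv: int = 4
    conv_filters: int = 32
    kernel: int = 3
    linear_widths: tuple[int, int, int] = (2048, 128, 3)
    dropout_rate: float = 0.8

    @property
    def flat_width(self) -> int:
        side = self.input_size // (2**self.n_conv)
        return side * side * self.conv_filters


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 16
    seed: int = 0
    #: checkpoint choice: the latest epoch whose validation loss is within
    #: this relative tolerance of the minimum (0 = strictly the minimum).
    #: at equal validation performance the longer-trained state is kept.
    selection_tolerance: float = 0.02


class Model:
    """Sequential CNN with access to the last conv block's activations.

    Inputs are centred (x - 0.5, the healthy-tissue level) at entry so the
    background does not act as a large DC component.
    """

    INPUT_OFFSET = 0.5

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        in_ch = 1
        self.conv_relu_indices: list[int] = []
        for _ in range(spec.n_conv):
            layers.append(nn.Conv2d(in_ch, spec.conv_filters, spec.kernel, rng))
            layers.append(nn.ReLU())
            self.conv_relu_indices.append(len(layers) - 1)
            layers.append(nn.MaxPool2())
            in_ch = spec.conv_filters
        self.last_conv_relu = self.conv_relu_indices[-1]
        layers.append(nn.Flatten())
        w1, w2, w3 = spec.linear_widths
        layers.append(nn.Linear(spec.flat_width, w1, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout_rate))
        layers.append(nn.Linear(w1, w2, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Linear(w2, w3, rng))
        layers.append(nn.Sigmoid())
        self.net = nn.Sequential(layers)

    def forward_train(self, X: np.ndarray, rng) -> np.ndarray:
        return self.net.forward(X - self.INPUT_OFFSET, train=True, rng=rng)

    def predict(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid scores, shape (N, 3)."""
        outs = [self.net.forward(X[i:i + batch_size] - self.INPUT_OFFSET)
                for i in range(0, len(X), batch_size)]
        return np.concatenate(outs, axis=0)

    def gradcam_ingredients(self, x: np.ndarray, class_index: int,
                            conv_block: int | None = None):
        """Forward one batch and return (A, dA) at a conv block's ReLU.

        A  : activations after the chosen conv block's ReLU, (N, C, h, w)
        dA : gradient of the selected class logit w.r.t. A

        ``conv_block`` is 1-based (None = the last block).  The class score
        is the pre-sigmoid logit, so maps are invariant to the output
        squashing.
        """
        relu_idx = (self.last_conv_relu if conv_block is None
                    else self.conv_relu_indices[conv_block - 1])
        layers = self.net.layers
        out = x - self.INPUT_OFFSET
        acts = []
        for i, layer in enumerate(layers[:-1]):  # stop before the sigmoid
            out = layer.forward(out, False, None)
            acts.append(out)
        logits = out
        dy = np.zeros_like(logits)
        dy[:, class_index] = 1.0
        for layer in reversed(layers[relu_idx + 1:-1]):
            dy = layer.backward(dy)
        return acts[relu_idx], dy

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        state = self.net.get_state()
        np.savez_compressed(path.with_suffix(".npz"),
                            **{f"p{i}": s for i, s in enumerate(state)})
        doc = {"spec": self.spec.__dict__ | {"linear_widths": list(self.spec.linear_widths)}}
        if meta:
            doc["meta"] = meta
        path.with_suffix(".json").write_text(json.dumps(doc, indent=1, default=str))

    @staticmethod
    def load(path: str | Path) -> "Model":
        path = Path(path)
        doc = json.loads(path.with_suffix(".json").read_text())
        sd = doc["spec"]
        sd["linear_widths"] = tuple(sd["linear_widths"])
        model = Model(ModelSpec(**sd))
        arrays = np.load(path.with_suffix(".npz"))
        model.net.set_state([arrays[f"p{i}"] for i in range(len(arrays.files))])
        return model


# ---------------------------------------------------------------------------
# data encoding


def disk_to_image(disk: TissueDisk, spec: ModelSpec | None = None) -> np.ndarray:
    """Encode a disk as a single-channel image: background and PV 0.0,
    healthy 0.5, fibrotic 1.0; nearest-neighbour resample to the input size."""
    spec = spec or ModelSpec()
    img = np.zeros(disk.label_grid.shape, dtype=float)
    img[disk.label_grid == Label.HEALTHY] = 0.5
    img[disk.label_grid == Label.FIBROTIC] = 1.0
    if img.shape != (spec.input_size, spec.input_size):
        img = resize(img, (spec.input_size, spec.input_size), order=0,
                     preserve_range=True, anti_aliasing=False)
    return img[None, :, :]


def image_to_labels(img: np.ndarray) -> np.ndarray:
    """Invert the encoding on non-resampled grids."""
    arr = img[0] if img.ndim == 3 else img
    out = np.full(arr.shape, Label.OUTSIDE, dtype=np.uint8)
    out[np.isclose(arr, 0.5)] = Label.HEALTHY
    out[np.isclose(arr, 1.0)] = Label.FIBROTIC
    return out


# ---------------------------------------------------------------------------
# loss


def mse_multilabel(yscore: np.ndarray, y: np.ndarray) -> float:
    """Multi-label mean-squared error: sum_i (yscore_i - y_i)^2 / N."""
    yscore = np.asarray(yscore, dtype=float)
    y = np.asarray(y, dtype=float)
    if yscore.shape != y.shape:
        raise ValueError("score and target shapes differ")
    n = yscore.shape[-1]
    return float(np.mean(np.sum((yscore - y) ** 2, axis=-1) / n))


# ---------------------------------------------------------------------------
# splits


@dataclass
class DatasetSplit:
    """Fixed hold-out plus a 5-fold partition of the remaining disks."""

    holdout_ids: list
    cv_fold_assignment: dict  # id -> fold in 1..n_folds

    @property
    def n_folds(self) -> int:
        return max(self.cv_fold_assignment.values())

    def fold_ids(self, fold: int) -> list:
        return [i for i, f in self.cv_fold_assignment.items() if f == fold]


def make_split(ids: list, n_holdout: int, n_folds: int = 5, seed: int = 0) -> DatasetSplit:
    rng = np.random.default_rng(seed)
    ids = list(ids)
    perm = rng.permutation(len(ids))
    holdout = [ids[i] for i in perm[:n_holdout]]
    rest = [ids[i] for i in perm[n_holdout:]]
    assignment = {d: (k % n_folds) + 1 for k, d in enumerate(rest)}
    return DatasetSplit(holdout_ids=holdout, cv_fold_assignment=assignment)


# ---------------------------------------------------------------------------
# training


def train_fold(
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
) -> tuple[Model, pd.DataFrame]:
    """Train one model, keeping the epoch state with minimal validation loss.

    Returns the restored-best model and a per-epoch train/val loss log.
    Reproducible bit-for-bit from ``config.seed`` under a fixed BLAS
    threading configuration.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("empty train or validation split")
    spec = spec or ModelSpec()
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    model = Model(spec, seed=config.seed)
    # start the sigmoid outputs at the class base rates: the network then
    # cannot lower the validation loss by drifting towards the prior, so
    # checkpoint selection favours genuinely discriminative epochs
    prior = np.clip(y_train.mean(axis=0), 0.05, 0.95)
    model.net.layers[-2].b[...] = np.log(prior / (1.0 - prior))
    opt = nn.Adam(model.net, lr=config.learning_rate)

    n_classes = y_train.shape[1]
    min_val, rows, states = np.inf, [], []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(X_train))
        tr_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            scores = model.forward_train(xb, rng)
            loss = mse_multilabel(scores, yb)
            dy = 2.0 * (scores - yb) / n_classes / len(xb)
            model.net.backward(dy)
            opt.step()
            tr_losses.append(loss)
        val_loss = mse_multilabel(model.predict(X_val), y_val)
        rows.append(dict(epoch=epoch, train_loss=float(np.mean(tr_losses)),
                         val_loss=float(val_loss)))
        if val_loss <= min_val * (1.0 + config.selection_tolerance):
            states.append((epoch, val_loss, model.net.get_state()))
            min_val = min(min_val, val_loss)
            # drop states that can no longer win the final selection
            states = [s for s in states
                      if s[1] <= min_val * (1.0 + config.selection_tolerance)]
    cutoff = min_val * (1.0 + config.selection_tolerance)
    epoch_sel, _, state_sel = max(
        (s for s in states if s[1] <= cutoff), key=lambda s: s[0])
    model.net.set_state(state_sel)
    log = pd.DataFrame(rows)
    log.attrs["selected_epoch"] = epoch_sel
    return model, log


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve; NaN (with a warning) if only one class."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class labels: AUC undefined", stacklevel=2)
        return float("nan")
    return float(roc_auc_score(y_true, scores))


def evaluate(model: Model, X: np.ndarray, y: np.ndarray,
             threshold: float = 0.5) -> pd.DataFrame:
    """Per-class AUC (continuous scores) and recall/precision/F1 at the
    classification threshold.  Precision of an all-negative prediction is
    reported as 1.0 (zero-false-positive convention)."""
    if len(X) == 0:
        raise ValueError("empty evaluation set")
    scores = model.predict(X)
    preds = (scores >= threshold).astype(int)
    rows = []
    for c, name in enumerate(CLASS_NAMES[: y.shape[1]]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(dict(
                strategy=name,
                auc=auc_score(y[:, c], scores[:, c]),
                recall=float(recall_score(y[:, c], preds[:, c], zero_division=0)),
                precision=float(precision_score(y[:, c], preds[:, c], zero_division=1)),
                f1=float(f1_score(y[:, c], preds[:, c], zero_division=0)),
            ))
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    per_fold: pd.DataFrame      # fold x strategy x metric, long format
    summary: pd.DataFrame       # mean +- sd per strategy/metric
    best_fold: int


def cross_validate(
    X: np.ndarray, y: np.ndarray, ids: list,
    split: DatasetSplit,
    spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
) -> tuple[EvalReport, Model]:
    """Hold-out + fold-rotation protocol.

    For each fold, a model is trained on the other folds (that fold being
    the validation set for checkpoint selection) and evaluated on the fixed
    hold-out set; the report aggregates per-class metrics across folds and
    the model from the fold with the highest mean hold-out AUC is returned.
    """
    spec = spec or ModelSpec()
    config = config or TrainConfig()
    index = {d: i for i, d in enumerate(ids)}
    ho = [index[d] for d in split.holdout_ids]
    X_ho, y_ho = X[ho], y[ho]

    frames, models, fold_aucs = [], [], []
    for fold in range(1, split.n_folds + 1):
        val_ids = split.fold_ids(fold)
        tr_ids = [d for d, f in split.cv_fold_assignment.items() if f != fold]
        vi = [index[d] for d in val_ids]
        ti = [index[d] for d in tr_ids]
        cfg = TrainConfig(epochs=config.epochs, learning_rate=config.learning_rate,
                          batch_size=config.batch_size, seed=config.seed + fold)
        model, _ = train_fold(X[ti], y[ti], X[vi], y[vi], spec, cfg)
        rep = evaluate(model, X_ho, y_ho)
        rep.insert(0, "fold", fold)
        frames.append(rep)
        models.append(model)
        fold_aucs.append(np.nanmean(rep["auc"].to_numpy()))

    per_fold = pd.concat(frames, ignore_index=True)
    summary = (per_fold.drop(columns="fold")
               .groupby("strategy", sort=False)
               .agg(["mean", "std"]))
    best = int(np.nanargmax(fold_aucs))
    report = EvalReport(per_fold=per_fold, summary=summary, best_fold=best + 1)
    return report, models[best]
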