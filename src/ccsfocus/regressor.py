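"""Feed-forward CCS regressor.

A small fully connected network maps the five-descriptor feature vector to
a collision cross section (A^2).  The default architecture has an input
layer, six hidden layers activated alternately by ReLU and GELU, and a
single linear output node; it is trained with the Adam optimiser on a mean
absolute error loss, with an 80/20 train/validation split and early
stopping on the validation MAE.

The implementation is plain numpy so that training is exactly reproducible
from a seed: the same configuration and data give the same epoch-loss
history and weights, bit for bit.  Features and labels are z-score
standardised with training-split statistics (labels are de-standardised at
prediction time); mixed-unit features (Da vs A^2) and CCS magnitudes near
180 A^2 make both rescalings necessary for the optimiser to make progress
at the default learning rate.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import erf

from .descriptors import FEATURE_NAMES, FeatureVector

ArrayLike = Union[np.ndarray, Sequence]

_ACTIVATIONS = ("relu", "gelu")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    # exact (erf-based) GELU
    return 0.5 * z * (1.0 + erf(z / np.sqrt(2.0)))


def _act_grad(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    cdf = 0.5 * (1.0 + erf(z / np.sqrt(2.0)))
    pdf = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    return cdf + z * pdf


@dataclass(frozen=True)
class RegressorConfig:
    """Hyperparameters of the CCS regressor.

    ``feature_mask`` selects which of the five descriptors feed the input
    layer (all five by default); ``group_split`` holds out whole species
    rather than individual conformers when group labels are supplied to
    :func:`train`.
    """

    hidden_layer_widths: tuple = (64, 128, 128, 64, 32, 16)
    activations: tuple = ("relu", "gelu", "relu", "gelu", "relu", "relu")
    learning_rate: float = 1e-3
    epochs: int = 400
    batch_size: int = 32
    validation_fraction: float = 0.2
    seed: int = 0
    feature_mask: tuple = FEATURE_NAMES
    early_stopping_patience: int = 40
    group_split: bool = False

    def __post_init__(self) -> None:
        if len(self.hidden_layer_widths) != len(self.activations):
            raise ValueError("need one activation per hidden layer")
        if any(w < 1 for w in self.hidden_layer_widths):
            raise ValueError("layer widths must be positive")
        if not all(a in _ACTIVATIONS for a in self.activations):
            raise ValueError(f"activations must be among {_ACTIVATIONS}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        unknown = set(self.feature_mask) - set(FEATURE_NAMES)
        if unknown or not self.feature_mask:
            raise ValueError(f"feature_mask must be a non-empty subset of {FEATURE_NAMES}")


@dataclass
class TrainedRegressor:
    """A trained CCS regressor plus everything needed to reuse it.

    Holds the layer weights, the feature/label standardisation statistics,
    the per-epoch loss history, the configuration, and the held-out
    validation predictions/labels from which batch error statistics for
    the CCS filter are derived.
    """

    weights: list  # alternating (W, b) per layer
    feature_mean: np.ndarray
    feature_std: np.ndarray
    label_mean: float
    label_std: float
    config: RegressorConfig
    history: pd.DataFrame  # columns: epoch, train_mae, val_mae (label units)
    heldout_predictions: np.ndarray
    heldout_labels: np.ndarray
    heldout_metrics: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.config.feature_mask)


def _coerce_features(features, mask: Sequence[str]) -> np.ndarray:
    """Accept FeatureVector sequences, 2D arrays, or DataFrames -> (n, k)."""
    if isinstance(features, pd.DataFrame):
        return features.loc[:, list(mask)].to_numpy(dtype=float)
    if len(features) == 0:
        return np.empty((0, len(mask)))
    if isinstance(features[0], FeatureVector):
        return np.stack([f.as_array(mask) for f in features])
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D feature array, got shape {arr.shape}")
    return arr


def _forward(weights, activations, X):
    """Return (output (n,), pre-activations, post-activations) for backprop."""
    zs, hs = [], [X]
    h = X
    n_hidden = len(activations)
    for li in range(n_hidden):
        W, b = weights[2 * li], weights[2 * li + 1]
        z = h @ W + b
        h = _act(activations[li], z)
        zs.append(z)
        hs.append(h)
    W, b = weights[-2], weights[-1]
    out = (h @ W + b).ravel()
    return out, zs, hs


def train(
    features,
    labels: ArrayLike,
    config: Optional[RegressorConfig] = None,
    groups: Optional[Sequence] = None,
) -> TrainedRegressor:
    """Train the CCS regressor.

    Parameters
    ----------
    features
        Sequence of :class:`FeatureVector`, 2D array, or DataFrame with the
        masked feature columns.
    labels
        CCS labels, A^2, all positive, same length as *features*.
    config
        Hyperparameters; defaults to :class:`RegressorConfig()`.
    groups
        Optional per-instance group (species) labels; with
        ``config.group_split`` the validation hold-out is by whole group.

    Returns
    -------
    TrainedRegressor
        With held-out MAE / mean % error / R^2 in ``heldout_metrics``.
    """
    config = config or RegressorConfig()
    X = _coerce_features(features, config.feature_mask)
    y = np.asarray(labels, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"{len(X)} feature rows vs {len(y)} labels")
    if len(y) < 10:
        raise ValueError(f"need at least 10 instances to train, got {len(y)}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("features and labels must be finite")
    if np.any(y <= 0):
        raise ValueError("CCS labels must be positive")

    rng = np.random.default_rng(config.seed)

    # --- train/validation split -----------------------------------------
    n = len(y)
    if config.group_split:
        if groups is None:
            raise ValueError("group_split requires group labels")
        uniq = pd.unique(np.asarray(groups))
        perm = rng.permutation(len(uniq))
        n_val_groups = max(1, int(round(config.validation_fraction * len(uniq))))
        val_groups = set(uniq[perm[:n_val_groups]])
        val_idx = np.array([i for i, g in enumerate(groups) if g in val_groups])
        train_idx = np.array([i for i, g in enumerate(groups) if g not in val_groups])
    else:
        perm = rng.permutation(n)
        n_val = max(1, int(round(config.validation_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("split produced an empty partition")

    Xtr, ytr = X[train_idx], y[train_idx]
    Xva, yva = X[val_idx], y[val_idx]

    # --- standardisation from training-split statistics ------------------
    f_mean = Xtr.mean(axis=0)
    f_std = Xtr.std(axis=0, ddof=0)
    if np.any(f_std == 0):
        bad = [config.feature_mask[i] for i in np.where(f_std == 0)[0]]
        raise ValueError(
            f"zero-variance feature(s) {bad} on the training split; "
            "drop them via the feature mask"
        )
    y_mean, y_std = float(ytr.mean()), float(ytr.std(ddof=0))
    if y_std == 0:
        y_std = 1.0  # constant labels: network only needs the bias
    Ztr = (Xtr - f_mean) / f_std
    Zva = (Xva - f_mean) / f_std
    ttr = (ytr - y_mean) / y_std

    # --- He-initialised weights -----------------------------------------
    widths = [len(config.feature_mask), *config.hidden_layer_widths, 1]
    weights = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        weights.append(np.zeros(fan_out))

    # --- Adam on MAE loss ------------------------------------------------
    m = [np.zeros_like(w) for w in weights]
    v = [np.zeros_like(w) for w in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    lr = config.learning_rate
    acts = config.activations

    best_val = np.inf
    best_weights = [w.copy() for w in weights]
    best_epoch = 0
    history_rows = []
    ntr = len(ttr)

    for epoch in range(config.epochs):
        order = rng.permutation(ntr)
        for start in range(0, ntr, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = Ztr[idx], ttr[idx]
            out, zs, hs = _forward(weights, acts, xb)
            # d(MAE)/d(out)
            delta = np.sign(out - tb)[:, None] / len(idx)
            grads = [None] * len(weights)
            grads[-2] = hs[-1].T @ delta
            grads[-1] = delta.sum(axis=0)
            back = delta @ weights[-2].T
            for li in range(len(acts) - 1, -1, -1):
                dz = back * _act_grad(acts[li], zs[li])
                grads[2 * li] = hs[li].T @ dz
                grads[2 * li + 1] = dz.sum(axis=0)
                if li > 0:
                    back = dz @ weights[2 * li].T
            step += 1
            b1c = 1.0 - beta1**step
            b2c = 1.0 - beta2**step
            for k in range(len(weights)):
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                weights[k] = weights[k] - lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + eps)

        tr_out, _, _ = _forward(weights, acts, Ztr)
        va_out, _, _ = _forward(weights, acts, Zva)
        train_mae = float(np.mean(np.abs(tr_out * y_std + y_mean - ytr)))
        val_mae = float(np.mean(np.abs(va_out * y_std + y_mean - yva)))
        history_rows.append({"epoch": epoch, "train_mae": train_mae, "val_mae": val_mae})

        if val_mae < best_val - 1e-12:
            best_val = val_mae
            best_weights = [w.copy() for w in weights]
            best_epoch = epoch
        elif epoch - best_epoch >= config.early_stopping_patience:
            break

    model = TrainedRegressor(
        weights=best_weights,
        feature_mean=f_mean,
        feature_std=f_std,
        label_mean=y_mean,
        label_std=y_std,
        config=config,
        history=pd.DataFrame(history_rows),
        heldout_predictions=np.empty(0),
        heldout_labels=yva,
    )
    preds_va = predict_batch(model, Zva * f_std + f_mean)
    model.heldout_predictions = preds_va
    mae, mpe, r2 = evaluate(preds_va, yva)
    model.heldout_metrics = {"mae": mae, "mean_pct_error": mpe, "r2": r2}
    return model


def predict_batch(model: TrainedRegressor, features) -> np.ndarray:
    """Predict CCS (A^2) for a batch of feature vectors, order-preserving."""
    X = _coerce_features(features, model.config.feature_mask)
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features "
            f"({model.config.feature_mask}), got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    Z = (X - model.feature_mean) / model.feature_std
    out, _, _ = _forward(model.weights, model.config.activations, Z)
    return out * model.label_std + model.label_mean


def evaluate(predictions: ArrayLike, labels: ArrayLike) -> tuple[float, float, float]:
    """(MAE / A^2, mean % error, R^2) of predictions against labels."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.size == 0:
        raise ValueError("predictions and labels must be non-empty and equal length")
    if np.any(y == 0):
        raise ValueError("labels must be nonzero for % error")
    mae = float(np.mean(np.abs(p - y)))
    mpe = float(np.mean(100.0 * np.abs(p - y) / np.abs(y)))
    ss_res = float(np.sum((p - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return mae, mpe, r2


# --- persistence ---------------------------------------------------------

def save_model(model: TrainedRegressor, path: os.PathLike | str) -> None:
    """Persist a model to a directory (weights.npz + meta.json + log CSV)."""
    os.makedirs(path, exist_ok=True)
    arrays = {f"w{k}": w for k, w in enumerate(model.weights)}
    arrays["feature_mean"] = model.feature_mean
    arrays["feature_std"] = model.feature_std
    arrays["heldout_predictions"] = model.heldout_predictions
    arrays["heldout_labels"] = model.heldout_labels
    np.savez(os.path.join(path, "weights.npz"), **arrays)
    meta = {
        "n_weight_arrays": len(model.weights),
        "label_mean": model.label_mean,
        "label_std": model.label_std,
        "config": {**asdict(model.config),
                   "hidden_layer_widths": list(model.config.hidden_layer_widths),
                   "activations": list(model.config.activations),
                   "feature_mask": list(model.config.feature_mask)},
        "heldout_metrics": model.heldout_metrics,
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    model.history.to_csv(os.path.join(path, "training_log.csv"), index=False)


def load_model(path: os.PathLike | str) -> TrainedRegressor:
    """Load a model saved by :func:`save_model`.

    ``load(save(m))`` predicts identically to ``m`` on any feature batch.
    """
    try:
        with open(os.path.join(path, "meta.json")) as fh:
            meta = json.load(fh)
        data = np.load(os.path.join(path, "weights.npz"))
        cfg_d = dict(meta["config"])
        for key in ("hidden_layer_widths", "activations", "feature_mask"):
            cfg_d[key] = tuple(cfg_d[key])
        config = RegressorConfig(**cfg_d)
        weights = [data[f"w{k}"] for k in range(meta["n_weight_arrays"])]
    except (KeyError, ValueError, OSError, json.JSONDecodeError) as exc:
        raise IOError(f"cannot load model from {path!r}: {exc}") from exc
    if weights[0].shape[0] != len(config.feature_mask):
        raise IOError(
            f"model file at {path!r} is inconsistent: first layer expects "
            f"{weights[0].shape[0]} inputs but feature mask has {len(config.feature_mask)}"
        )
    history_path = os.path.join(path, "training_log.csv")
    history = pd.read_csv(history_path) if os.path.exists(history_path) else pd.DataFrame()
    return TrainedRegressor(
        weights=weights,
        feature_mean=data["feature_mean"],
        feature_std=data["feature_std"],
        label_mean=float(meta["label_mean"]),
        label_std=float(meta["label_std"]),
        config=config,
        history=history,
        heldout_predictions=data["heldout_predictions"],
        heldout_labels=data["heldout_labels"],
        heldout_metrics=meta.get("heldout_metrics", {}),
    )
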