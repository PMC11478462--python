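"""Feed-forward surrogates inverting trap position to actuation signals.

Two small multilayer perceptrons map the 2n+2 input vector (trap position
plus the n element-centre positions) to the n per-element outputs: one
predicts time of flight (microseconds), the other arrival amplitude (Pa).
Both use ReLU activations, five hidden layers (300 total nodes for ToF,
720 for amplitude by default) and minimize the mean squared L2 loss

    L = (1/m) sum_i || x_i - x_i* ||^2

with stochastic (batch size 1) Adam updates.  Training monitors a held-out
validation split, halves the learning rate on plateaus and restores the
best-validation weights (early stopping).  The whole forward/backward/
update loop is implemented here; it is the package's core model.

Feature and output z-scoring is fitted on the training split only.
Element positions are constant within a dataset, which z-scoring maps to
zero-variance features handled by a unit scale (they are retained as
inputs so one trained model is tied to one array geometry).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from numba.typed import List as NumbaList

from sonotrap.dataset import TrainingDataset

__all__ = [
    "SurrogateModel",
    "ErrorReport",
    "build_model",
    "train",
    "predict",
    "evaluate",
    "boxplot_outliers",
    "save_model",
    "load_model",
]

DEFAULT_LAYOUTS = {"tof": (60, 60, 60, 60, 60),
                   "amplitude": (144, 144, 144, 144, 144)}


@njit(cache=True)
def _epoch_kernel(Ws, bs, mW, vW, mb, vb, X, Y, order, lr, t0,
                  beta1, beta2, eps):
    """One stochastic (batch 1) Adam epoch over ``order``; in-place.

    Returns (mean squared L2 loss over the epoch, updated Adam step count).
    """
    nl = len(Ws)
    total = 0.0
    t = t0
    for oi in range(len(order)):
        i = order[oi]
        x = X[i]
        # forward, keeping pre-activations for the backward pass
        acts = NumbaList()
        acts.append(x)
        pre = NumbaList()
        a = x
        for k in range(nl):
            z = a @ Ws[k] + bs[k]
            pre.append(z)
            if k < nl - 1:
                a = np.maximum(z, 0.0)
            else:
                a = z
            acts.append(a)
        err = a - Y[i]
        total += np.sum(err * err)
        delta = 2.0 * err
        t += 1
        corr = np.sqrt(1.0 - beta2 ** t) / (1.0 - beta1 ** t)
        for k in range(nl - 1, -1, -1):
            gw = acts[k].copy().reshape(-1, 1) * delta.reshape(1, -1)
            if k > 0:
                # propagate through the pre-update weights
                delta_next = (Ws[k] @ delta) * np.where(pre[k - 1] > 0.0, 1.0, 0.0)
            else:
                delta_next = delta
            m = mW[k]
            v = vW[k]
            m *= beta1
            m += (1.0 - beta1) * gw
            v *= beta2
            v += (1.0 - beta2) * (gw * gw)
            Ws[k] -= lr * corr * m / (np.sqrt(v) + eps)
            m2 = mb[k]
            v2 = vb[k]
            m2 *= beta1
            m2 += (1.0 - beta1) * delta
            v2 *= beta2
            v2 += (1.0 - beta2) * (delta * delta)
            bs[k] -= lr * corr * m2 / (np.sqrt(v2) + eps)
            delta = delta_next
    return total / len(order), t


class _MLP:
    """Minimal ReLU multilayer perceptron with batch-1 Adam training."""

    def __init__(self, sizes: Sequence[int], seed: int):
        self.sizes = tuple(sizes)
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization suits ReLU layers
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))
        self._mW = [np.zeros_like(w) for w in self.weights]
        self._vW = [np.zeros_like(w) for w in self.weights]
        self._mb = [np.zeros_like(b) for b in self.biases]
        self._vb = [np.zeros_like(b) for b in self.biases]
        self._adam_t = 0
        self._nb_lists = None
        self.rng = rng

    def _typed_lists(self):
        if self._nb_lists is None:
            make = lambda arrs: NumbaList(arrs)
            self._nb_lists = tuple(make(a) for a in (
                self.weights, self.biases, self._mW, self._vW,
                self._mb, self._vb))
        return self._nb_lists

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batched forward pass; ReLU on hidden layers, linear output."""
        a = x
        last = len(self.weights) - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if k < last:
                np.maximum(a, 0.0, out=a)
        return a

    def train_epoch(self, X: np.ndarray, Y: np.ndarray, lr: float,
                    batch_size: int = 1) -> float:
        """One stochastic pass over the data in a freshly shuffled order.

        ``batch_size`` > 1 is emulated by consecutive single-sample updates
        at a proportionally reduced learning rate (the study protocol is
        batch size 1, which is the native path).
        """
        order = self.rng.permutation(len(X)).astype(np.int64)
        Ws, bs, mW, vW, mb, vb = self._typed_lists()
        eff_lr = lr if batch_size == 1 else lr / batch_size
        loss, self._adam_t = _epoch_kernel(
            Ws, bs, mW, vW, mb, vb,
            np.ascontiguousarray(X), np.ascontiguousarray(Y), order,
            eff_lr, self._adam_t, 0.9, 0.999, 1e-8)
        # flush vanishing Adam moments to zero: parameters with exactly-zero
        # gradients (constant features, dead ReLU units) otherwise decay the
        # moments into subnormal floats, where arithmetic is ~100x slower
        for arrs in (self._mW, self._mb, self._vW, self._vb):
            for a in arrs:
                a[np.abs(a) < 1e-250] = 0.0
        return float(loss)

    def copy_params(self):
        return ([w.copy() for w in self.weights],
                [b.copy() for b in self.biases])

    def set_params(self, params):
        for w, src in zip(self.weights, params[0]):
            w[:] = src
        for b, src in zip(self.biases, params[1]):
            b[:] = src


@dataclass
class SurrogateModel:
    """A (possibly trained) per-element regressor for ToF or amplitude."""

    kind: str                         # "tof" | "amplitude"
    n: int                            # element count
    hidden_layout: tuple[int, ...]
    seed: int
    net: _MLP | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    y_scale: np.ndarray | None = None
    loss_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    element_positions: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return 2 * self.n + 2

    @property
    def n_outputs(self) -> int:
        return self.n

    @property
    def trained(self) -> bool:
        return self.net is not None and self.x_mean is not None


def build_model(kind: str, n: int,
                hidden_layout: Sequence[int] | None = None,
                seed: int = 0) -> SurrogateModel:
    """Untrained surrogate with the contract-conformant architecture.

    Default layouts spread the node budget evenly over the five hidden
    layers: (60,)*5 = 300 nodes for ToF, (144,)*5 = 720 for amplitude.
    """
    if kind not in DEFAULT_LAYOUTS:
        raise ValueError("kind must be 'tof' or 'amplitude'")
    if n < 1:
        raise ValueError("need at least one element")
    layout = tuple(int(v) for v in (hidden_layout or DEFAULT_LAYOUTS[kind]))
    if len(layout) != 5:
        raise ValueError(f"hidden_layout must have exactly 5 layers, got {len(layout)}")
    if any(v < 1 for v in layout):
        raise ValueError("hidden layer sizes must be positive")
    return SurrogateModel(kind=kind, n=n, hidden_layout=layout, seed=int(seed))


def _features(targets: np.ndarray, element_positions: np.ndarray) -> np.ndarray:
    """Stack [target_x, target_y, p1x, p1y, ..., pnx, pny] rows."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    flat = np.asarray(element_positions, dtype=float).ravel()
    return np.hstack([targets, np.tile(flat, (len(targets), 1))])


def _labels(ds: TrainingDataset, kind: str) -> np.ndarray:
    return ds.tof_matrix() if kind == "tof" else ds.amplitude_matrix()


def train(model: SurrogateModel, ds: TrainingDataset, batch_size: int = 1,
          seed: int | None = None, max_epochs: int = 400, patience: int = 60,
          learning_rate_init: float = 2e-3, lr_plateau: int = 12,
          lr_factor: float = 0.5, lr_min: float = 2e-5,
          tol: float = 1e-7, restore_best: bool = True) -> SurrogateModel:
    """Fit the surrogate on the train split, early-stopping on validation.

    Adam updates at the given batch size (1 by default) on z-scored
    features and labels.  The learning rate halves whenever the validation
    loss fails to improve for ``lr_plateau`` consecutive epochs; training
    stops after ``patience`` epochs without improvement or at
    ``max_epochs``, and the best-validation weights are restored.  Fully
    deterministic for a given seed.
    """
    rng_seed = model.seed if seed is None else int(seed)
    train_ds = ds.subset("train")
    val_ds = ds.subset("validation")
    if train_ds.m == 0 or val_ds.m == 0:
        raise ValueError("dataset must carry train and validation labels")
    X_tr = _features(train_ds.targets(), ds.element_positions)
    y_tr = _labels(train_ds, model.kind)
    X_va = _features(val_ds.targets(), ds.element_positions)
    y_va = _labels(val_ds, model.kind)
    if np.allclose(y_tr.std(axis=0), 0):
        import warnings
        warnings.warn("zero-variance labels: surrogate will learn a constant")

    model.x_mean = X_tr.mean(axis=0)
    model.x_scale = X_tr.std(axis=0)
    model.x_scale[model.x_scale == 0] = 1.0     # constant features -> 0
    model.y_mean = y_tr.mean(axis=0)
    model.y_scale = y_tr.std(axis=0)
    model.y_scale[model.y_scale == 0] = 1.0
    Xs_tr = (X_tr - model.x_mean) / model.x_scale
    ys_tr = (y_tr - model.y_mean) / model.y_scale
    Xs_va = (X_va - model.x_mean) / model.x_scale
    ys_va = (y_va - model.y_mean) / model.y_scale

    net = _MLP((model.n_inputs, *model.hidden_layout, model.n), seed=rng_seed)
    t0 = time.perf_counter()
    lr = learning_rate_init
    best_val = np.inf
    best_params = None
    best_epoch = -1
    since_plateau = 0
    model.loss_history = []
    model.val_history = []
    for epoch in range(max_epochs):
        train_loss = net.train_epoch(Xs_tr, ys_tr, lr, batch_size=batch_size)
        resid = net.forward(Xs_va) - ys_va
        val_loss = float(np.mean(np.sum(resid ** 2, axis=1)))
        model.loss_history.append(train_loss)
        model.val_history.append(val_loss)
        if val_loss < best_val - tol:
            best_val = val_loss
            best_epoch = epoch
            best_params = net.copy_params()
            since_plateau = 0
        else:
            since_plateau += 1
            if since_plateau >= lr_plateau and lr > lr_min:
                lr = max(lr * lr_factor, lr_min)
                since_plateau = 0
            if epoch - best_epoch >= patience:
                break
    if restore_best and best_params is not None:
        net.set_params(best_params)
    model.net = net
    model.element_positions = np.asarray(ds.element_positions, float).copy()
    model.metadata = {
        "optimizer": "adam",
        "batch_size": batch_size,
        "learning_rate_init": learning_rate_init,
        "final_learning_rate": lr,
        "epochs_run": len(model.loss_history),
        "best_epoch": best_epoch,
        "best_val_loss": best_val,
        "train_seconds": time.perf_counter() - t0,
        "seed": rng_seed,
        "m_train": train_ds.m,
        "m_validation": val_ds.m,
    }
    return model


def predict(model: SurrogateModel, target,
            element_positions=None) -> np.ndarray:
    """One forward pass: n per-element predictions for one target (or a
    batch of targets given as an (m, 2) array)."""
    if not model.trained:
        raise ValueError("model is not trained")
    if element_positions is None:
        element_positions = model.element_positions
    tgt = np.asarray(target, dtype=float)
    single = tgt.ndim == 1
    X = _features(tgt, element_positions)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    Xs = (X - model.x_mean) / model.x_scale
    y = model.net.forward(Xs) * model.y_scale + model.y_mean
    return y[0] if single else y


@dataclass
class ErrorReport:
    """Signed hold-out errors with per-element boxplot outlier analysis.

    ``errors`` is (m_holdout, n): microseconds for ToF surrogates, percent
    (100 * (pred - true) / true) for amplitude surrogates.  Outliers follow
    the 1.5 x IQR whisker rule applied per element column.
    """

    kind: str
    units: str
    errors: np.ndarray
    outlier_mask: np.ndarray
    q1: np.ndarray
    q3: np.ndarray

    @property
    def n_predictions(self) -> int:
        return self.errors.size

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_mask.sum())

    @property
    def nonoutlier_max(self) -> float:
        return float(self.errors[~self.outlier_mask].max())

    @property
    def nonoutlier_min(self) -> float:
        return float(self.errors[~self.outlier_mask].min())

    @property
    def per_element_mean(self) -> np.ndarray:
        """Signed mean error per element over the hold-out samples."""
        return self.errors.mean(axis=0)

    @property
    def median_abs_error(self) -> float:
        return float(np.median(np.abs(self.errors)))


def boxplot_outliers(errors: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column 1.5 x IQR whisker outlier mask, with Q1 and Q3."""
    q1 = np.percentile(errors, 25, axis=0)
    q3 = np.percentile(errors, 75, axis=0)
    iqr = q3 - q1
    lo = q1 - 1.5 * iqr
    hi = q3 + 1.5 * iqr
    mask = (errors < lo[None, :]) | (errors > hi[None, :])
    return mask, q1, q3


def evaluate(model: SurrogateModel, ds: TrainingDataset) -> ErrorReport:
    """Hold-out error report: signed per-element prediction errors.

    ToF errors are reported in microseconds, amplitude errors as percent
    relative to the true amplitude.
    """
    hold = ds.subset("holdout")
    if hold.m == 0:
        raise ValueError("dataset has no holdout split")
    pred = predict(model, hold.targets(), ds.element_positions)
    true = _labels(hold, model.kind)
    if model.kind == "tof":
        errors = pred - true
        units = "us"
    else:
        errors = 100.0 * (pred - true) / true
        units = "%"
    mask, q1, q3 = boxplot_outliers(errors)
    return ErrorReport(kind=model.kind, units=units, errors=errors,
                       outlier_mask=mask, q1=q1, q3=q3)


def save_model(model: SurrogateModel, path) -> None:
    """Persist architecture metadata, scalers and weights (.npz)."""
    if not model.trained:
        raise ValueError("refusing to save an untrained model")
    path = Path(path)
    arrays = {
        "x_mean": model.x_mean, "x_scale": model.x_scale,
        "y_mean": model.y_mean, "y_scale": model.y_scale,
        "element_positions": model.element_positions,
        "loss_history": np.asarray(model.loss_history),
        "val_history": np.asarray(model.val_history),
    }
    for i, (w, b) in enumerate(zip(model.net.weights, model.net.biases)):
        arrays[f"weight_{i}"] = w
        arrays[f"bias_{i}"] = b
    meta = {
        "kind": model.kind, "n": model.n,
        "hidden_layout": list(model.hidden_layout),
        "seed": model.seed, "metadata": model.metadata,
        "n_layers": len(model.net.weights),
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> SurrogateModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = build_model(meta["kind"], meta["n"],
                            meta["hidden_layout"], meta["seed"])
        net = _MLP((model.n_inputs, *model.hidden_layout, model.n),
                   seed=meta["seed"])
        net.weights = [data[f"weight_{i}"] for i in range(meta["n_layers"])]
        net.biases = [data[f"bias_{i}"] for i in range(meta["n_layers"])]
        model.net = net
        model.x_mean = data["x_mean"]
        model.x_scale = data["x_scale"]
        model.y_mean = data["y_mean"]
        model.y_scale = data["y_scale"]
        model.element_positions = data["element_positions"]
        model.loss_history = list(data["loss_history"])
        model.val_history = list(data["val_history"])
        model.metadata = meta["metadata"]
    return model
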