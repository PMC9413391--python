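"""Shrinking dense neural network for AF/non-AF classification.

Topology: input -> batch normalization (trainable scale/shift per feature)
-> one to three dense+ReLU hidden layers, each followed by dropout, with
non-increasing widths ("shrinking") -> one sigmoid output giving
P(x in AF).  Training minimizes a class-weighted binary cross-entropy with
the Adam optimizer, checkpoints the parameters at minimal validation loss,
and stops early once the validation loss has not improved for the patience
number of epochs.

The implementation is plain NumPy: the classifier is small (tens of
neurons), so explicit forward/backward passes are both transparent and
fast enough for grid searches over all admissible architectures.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: Admissible hidden-layer widths per lead set (0 = layer absent).
WIDTH_OPTIONS: dict[str, tuple[int, ...]] = {
    "single": (4, 8, 16),
    "limb": (4, 8, 16, 32, 64),
    "chest": (4, 8, 16, 32, 64),
    "twelve": (4, 8, 16, 32, 64, 128),
}

_EPS = 1e-7  # probability clipping bound for the cross-entropy
_INIT_BOUND = 0.05  # uniform kernel-initializer half-width


@dataclass(frozen=True)
class Architecture:
    """Hidden-layer widths; must be non-increasing, length 1-3."""

    widths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.widths) <= 3:
            raise ValueError("1 to 3 hidden layers required")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if any(b > a for a, b in zip(self.widths, self.widths[1:])):
            raise ValueError(f"widths must be non-increasing, got {self.widths}")

    def n_params(self, input_dim: int) -> int:
        dims = [input_dim, *self.widths, 1]
        dense = sum(a * b + b for a, b in zip(dims, dims[1:]))
        return dense + 2 * input_dim  # + BN scale/shift


def enumerate_architectures(width_options: list[int] | tuple[int, ...]) -> list[Architecture]:
    """All non-increasing width sequences of length 1-3 over ``width_options``.

    The count equals sum_{k=1..3} C(m+k-1, k) for m options (multisets of
    size k).  Ordering is canonical: by depth, then lexicographically.
    """
    opts = tuple(width_options)
    if not opts:
        raise ValueError("width_options must be non-empty")
    if list(opts) != sorted(set(opts)):
        raise ValueError("width_options must be strictly increasing")
    archs = []
    for depth in (1, 2, 3):
        for combo in itertools.combinations_with_replacement(sorted(opts, reverse=True), depth):
            archs.append(Architecture(tuple(combo)))
    archs.sort(key=lambda a: (len(a.widths), a.widths))
    return archs


@dataclass
class TrainConfig:
    """Training hyperparameters (Adam rates, dropout, class weights)."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 400
    patience: int = 10
    dropout_rate: float = 0.3
    class_weights: tuple[float, float] | None = None  # (w_AF, w_non_AF)
    batch_size: int = 256
    bn_momentum: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in (0, 1)")
        if self.class_weights is not None:
            if abs(sum(self.class_weights) - 1.0) > 1e-9:
                raise ValueError("class weights must sum to 1")


def class_weights_from_labels(labels: np.ndarray) -> tuple[float, float]:
    """Class weights proportional to the reciprocal of class prevalence.

    With the study's ~8% AF / 92% non-AF imbalance this yields
    (w_AF, w_non_AF) = (0.92, 0.08), penalizing errors on the minority
    class.  Weights are normalized to sum to 1.
    """
    labels = np.asarray(labels)
    prev_af = float(np.mean(labels))
    if prev_af in (0.0, 1.0):
        raise ValueError("both classes must be present to derive weights")
    inv = np.array([1.0 / prev_af, 1.0 / (1.0 - prev_af)])
    w_af, w_non = inv / inv.sum()
    return float(w_af), float(w_non)


def weighted_bce_loss(probs: np.ndarray, labels: np.ndarray,
                      class_weights: tuple[float, float]) -> float:
    """Class-weighted binary cross-entropy, averaged over the batch.

    Probabilities are clipped to [1e-7, 1 - 1e-7] before the logarithm.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have the same length")
    w_af, w_non = class_weights
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    terms = labels * w_af * np.log(p) + (1.0 - labels) * w_non * np.log(1.0 - p)
    return float(-np.mean(terms))


class DenseAF:
    """The dense AF/non-AF classifier: parameters, training, persistence."""

    def __init__(self, input_dim: int, architecture: Architecture | tuple[int, ...],
                 config: TrainConfig | None = None,
                 feature_names: list[str] | None = None,
                 lead_set: str = ""):
        if isinstance(architecture, (tuple, list)):
            architecture = Architecture(tuple(architecture))
        self.architecture = architecture
        self.input_dim = int(input_dim)
        self.config = config or TrainConfig()
        self.feature_names = list(feature_names or [])
        self.lead_set = lead_set
        self.p_thr = 0.5
        self.impute_means = np.zeros(self.input_dim)
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.epochs_run = 0
        self.best_val_loss = np.inf
        self._init_params(self.config.seed)

    # -- parameters ---------------------------------------------------------

    def _init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        dims = [self.input_dim, *self.architecture.widths, 1]
        self.params: dict[str, np.ndarray] = {
            "gamma": np.ones(self.input_dim),
            "beta": np.zeros(self.input_dim),
        }
        for i, (a, b) in enumerate(zip(dims, dims[1:])):
            self.params[f"W{i}"] = rng.uniform(-_INIT_BOUND, _INIT_BOUND, (a, b))
            self.params[f"b{i}"] = np.zeros(b)
        self.bn_mean = np.zeros(self.input_dim)
        self.bn_var = np.ones(self.input_dim)
        self._n_dense = len(dims) - 1

    def n_params(self) -> int:
        return self.architecture.n_params(self.input_dim)

    # -- forward / backward -------------------------------------------------

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {X.shape[1]}")
        if np.isnan(X).any():
            X = np.where(np.isnan(X), self.impute_means, X)
        return X

    def _forward(self, X: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None):
        cache: dict[str, object] = {}
        if training:
            mu = X.mean(axis=0)
            var = X.var(axis=0)
            m = self.config.bn_momentum
            self.bn_mean = m * self.bn_mean + (1 - m) * mu
            self.bn_var = m * self.bn_var + (1 - m) * var
        else:
            mu, var = self.bn_mean, self.bn_var
        xhat = (X - mu) / np.sqrt(var + 1e-5)
        h = self.params["gamma"] * xhat + self.params["beta"]
        cache["X"], cache["xhat"], cache["var"] = X, xhat, var
        cache["acts"], cache["masks"] = [], []
        for i in range(self._n_dense - 1):
            cache["acts"].append(h)
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            h = np.maximum(z, 0.0)
            if training:
                keep = 1.0 - self.config.dropout_rate
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                cache["masks"].append(mask)
            else:
                cache["masks"].append(None)
            cache.setdefault("hidden", []).append(h)
        cache["acts"].append(h)
        i = self._n_dense - 1
        z_out = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
        probs = 1.0 / (1.0 + np.exp(-z_out[:, 0]))
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        n = y.size
        w_af, w_non = self.config.class_weights
        p = np.clip(probs, _EPS, 1.0 - _EPS)
        # dL/dz_out for the weighted BCE through the sigmoid
        delta = ((-(y * w_af * (1.0 - p)) + (1.0 - y) * w_non * p) / n)[:, None]
        grads: dict[str, np.ndarray] = {}
        dh = None
        for i in range(self._n_dense - 1, -1, -1):
            grads[f"W{i}"] = cache["acts"][i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            dh = delta @ self.params[f"W{i}"].T
            if i > 0:
                mask = cache["masks"][i - 1]
                if mask is not None:
                    dh = dh * mask
                # ReLU gate; masked units carry zero gradient already
                delta = dh * (cache["hidden"][i - 1] > 0)
        # dh is now the gradient at the BN output (the inputs themselves
        # are data, so no gradient flows past gamma/beta)
        grads["gamma"] = (dh * cache["xhat"]).sum(axis=0)
        grads["beta"] = dh.sum(axis=0)
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, X_train: np.ndarray, y_train: np.ndarray,
            X_val: np.ndarray, y_val: np.ndarray) -> "DenseAF":
        """Train with Adam, early stopping, and best-validation checkpointing."""
        y_train = np.asarray(y_train, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if len(np.unique(y_train)) < 2:
            raise ValueError("training set must contain both classes")
        X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
        self.impute_means = np.nan_to_num(np.nanmean(X_train, axis=0))
        X_train = self._impute(X_train)
        X_val = self._impute(X_val)
        cfg = self.config
        if cfg.class_weights is None:
            self.config = cfg = replace(cfg, class_weights=class_weights_from_labels(y_train))

        rng = np.random.default_rng(cfg.seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(p) for k, p in self.params.items()}
        t = 0
        best = {k: p.copy() for k, p in self.params.items()}
        best_bn = (self.bn_mean.copy(), self.bn_var.copy())
        best_loss = np.inf
        stall = 0
        n = X_train.shape[0]
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if idx.size < 2:
                    continue  # BN needs at least two samples
                probs, cache = self._forward(X_train[idx], training=True, rng=rng)
                epoch_losses.append(
                    weighted_bce_loss(probs, y_train[idx], cfg.class_weights))
                grads = self._backward(probs, y_train[idx], cache)
                t += 1
                for k, g in grads.items():
                    m[k] = cfg.beta1 * m[k] + (1 - cfg.beta1) * g
                    v[k] = cfg.beta2 * v[k] + (1 - cfg.beta2) * g * g
                    mhat = m[k] / (1 - cfg.beta1 ** t)
                    vhat = v[k] / (1 - cfg.beta2 ** t)
                    self.params[k] -= cfg.lr * mhat / (np.sqrt(vhat) + 1e-8)
            val_probs, _ = self._forward(X_val, training=False)
            val_loss = weighted_bce_loss(val_probs, y_val, cfg.class_weights)
            self.history["train_loss"].append(float(np.mean(epoch_losses)))
            self.history["val_loss"].append(val_loss)
            self.epochs_run = epoch + 1
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best = {k: p.copy() for k, p in self.params.items()}
                best_bn = (self.bn_mean.copy(), self.bn_var.copy())
                stall = 0
            else:
                stall += 1
                if stall > cfg.patience:
                    break
        self.params = best
        self.bn_mean, self.bn_var = best_bn
        self.best_val_loss = float(best_loss)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(x in AF) for each row; deterministic (dropout inactive)."""
        probs, _ = self._forward(self._impute(X), training=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Thresholded class decision: AF when P(x in AF) > P_thr."""
        return (self.predict_proba(X) > self.p_thr).astype(int)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Persist parameters, feature ordering, imputation means and P_thr
        to an HDF5 archive."""
        with h5py.File(path, "w") as f:
            f.attrs["widths"] = list(self.architecture.widths)
            f.attrs["input_dim"] = self.input_dim
            f.attrs["p_thr"] = self.p_thr
            f.attrs["lead_set"] = self.lead_set
            f.attrs["seed"] = self.config.seed
            f.attrs["epochs_run"] = self.epochs_run
            f.attrs["best_val_loss"] = self.best_val_loss
            f.attrs["feature_names"] = [n.encode() for n in self.feature_names]
            f.create_dataset("impute_means", data=self.impute_means)
            f.create_dataset("bn_mean", data=self.bn_mean)
            f.create_dataset("bn_var", data=self.bn_var)
            grp = f.create_group("params")
            for k, p in self.params.items():
                grp.create_dataset(k, data=p)

    @classmethod
    def load(cls, path) -> "DenseAF":
        with h5py.File(path, "r") as f:
            model = cls(int(f.attrs["input_dim"]),
                        tuple(int(w) for w in f.attrs["widths"]),
                        TrainConfig(seed=int(f.attrs["seed"])),
                        feature_names=[n.decode() if isinstance(n, bytes) else str(n)
                                       for n in f.attrs["feature_names"]],
                        lead_set=str(f.attrs["lead_set"]))
            model.p_thr = float(f.attrs["p_thr"])
            model.epochs_run = int(f.attrs["epochs_run"])
            model.best_val_loss = float(f.attrs["best_val_loss"])
            model.impute_means = f["impute_means"][...]
            model.bn_mean = f["bn_mean"][...]
            model.bn_var = f["bn_var"][...]
            model.params = {k: f["params"][k][...] for k in f["params"]}
        return model


def grid_search(architectures: list[Architecture], runs_per_arch: int,
                X_train: np.ndarray, y_train: np.ndarray,
                X_val: np.ndarray, y_val: np.ndarray,
                config: TrainConfig | None = None,
                feature_names: list[str] | None = None,
                lead_set: str = "") -> tuple["pd.DataFrame", DenseAF]:
    """Train every architecture ``runs_per_arch`` times with distinct seeds.

    Each run selects its probability threshold at maximal validation
    balanced accuracy.  Returns the per-run results ranked by descending
    validation BAC (ties broken by fewer parameters) and the best model.
    """
    import pandas as pd

    from afsync.evaluate import balanced_accuracy, select_threshold

    config = config or TrainConfig()
    input_dim = np.atleast_2d(X_train).shape[1]
    rows = []
    best_model: DenseAF | None = None
    best_key = (-np.inf, np.inf)
    for ai, arch in enumerate(architectures):
        for run in range(runs_per_arch):
            seed = (config.seed * 7919 + ai * runs_per_arch + run) % (2 ** 31)
            model = DenseAF(input_dim, arch, replace(config, seed=seed),
                            feature_names=feature_names, lead_set=lead_set)
            model.fit(X_train, y_train, X_val, y_val)
            val_probs = model.predict_proba(X_val)
            model.p_thr = select_threshold(val_probs, y_val)
            bac = balanced_accuracy(val_probs > model.p_thr, y_val)
            rows.append({"architecture": str(list(arch.widths)), "run": run,
                         "seed": seed, "val_bac": bac,
                         "n_params": model.n_params(),
                         "epochs": model.epochs_run, "p_thr": model.p_thr})
            key = (bac, -model.n_params())
            if key > best_key:
                best_key, best_model = key, model
    results = pd.DataFrame(rows).sort_values(
        ["val_bac", "n_params"], ascending=[False, True]).reset_index(drop=True)
    assert len(results) == len(architectures) * runs_per_arch
    return results, best_model
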