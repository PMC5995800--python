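"""Two-layer perceptron and the automatic ensemble protocol.

The QSAR model is a single-hidden-layer perceptron mapping four
hypotensive predictors — ED20 (mg/kg), Index, ED20 (umol/kg), Level — to
two output units, one per IOP activity class (active / inactive).  The
ensemble protocol trains a population of networks (1000 by default) whose
architectures are sampled at random: 3-10 hidden units; hidden activation
drawn from {identity, logistic, tanh, exponential, sine}; output
activation additionally allows softmax.  Each network gets its own seeded
stratified 80/20 train/test split and weight initialization.  Networks are
ranked by test accuracy (ties: train accuracy, then fewer hidden units),
the top 50 are retained, and the top-1 is the selected model.

Training is full-batch L-BFGS on the flattened weights with analytic
gradients; the loss is categorical cross-entropy when the output layer is
softmax and mean sum-of-squares against one-hot targets otherwise.  Inputs
are z-scored with statistics fitted on the training split only.  All
randomness flows from explicit seeds, so an ensemble is bit-reproducible
from its master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import train_test_split

_EXP_CLIP = 30.0

HIDDEN_ACTIVATIONS = ("identity", "logistic", "tanh", "exponential", "sine")
OUTPUT_ACTIVATIONS = HIDDEN_ACTIVATIONS + ("softmax",)


def _activate(name: str, z: np.ndarray) -> np.ndarray:
    if name == "identity":
        return z
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -_EXP_CLIP, _EXP_CLIP)))
    if name == "tanh":
        return np.tanh(z)
    if name == "exponential":
        return np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))
    if name == "sine":
        return np.sin(z)
    if name == "softmax":
        zs = z - z.max(axis=1, keepdims=True)
        e = np.exp(zs)
        return e / e.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    """d a / d z for elementwise activations (softmax is handled jointly)."""
    if name == "identity":
        return np.ones_like(z)
    if name == "logistic":
        return a * (1.0 - a)
    if name == "tanh":
        return 1.0 - a * a
    if name == "exponential":
        return a * (np.abs(z) < _EXP_CLIP)  # zero gradient in the clipped region
    if name == "sine":
        return np.cos(z)
    raise ValueError(f"no elementwise gradient for {name!r}")


@dataclass(frozen=True)
class ANNConfig:
    """Architecture and training settings of one network."""

    n_hidden: int
    hidden_activation: str = "tanh"
    output_activation: str = "softmax"
    train_fraction: float = 0.8
    split_seed: int = 0
    init_seed: int = 0
    max_epochs: int = 500
    tol: float = 1e-8
    n_hidden_min: int = 3
    n_hidden_max: int = 10

    def validate(self) -> None:
        if not (self.n_hidden_min <= self.n_hidden <= self.n_hidden_max):
            raise ValueError(
                f"n_hidden={self.n_hidden} outside "
                f"[{self.n_hidden_min}, {self.n_hidden_max}]"
            )
        if self.hidden_activation not in HIDDEN_ACTIVATIONS:
            raise ValueError(
                f"hidden activation {self.hidden_activation!r} not allowed "
                "(softmax is output-only)"
            )
        if self.output_activation not in OUTPUT_ACTIVATIONS:
            raise ValueError(f"unknown output activation {self.output_activation!r}")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ANNModel:
    """A trained perceptron: weights, input scaling, and split accuracies."""

    config: ANNConfig
    w_hidden: np.ndarray     # (4, n_hidden)
    b_hidden: np.ndarray     # (n_hidden,)
    w_output: np.ndarray     # (n_hidden, 2)
    b_output: np.ndarray     # (2,)
    x_mean: np.ndarray       # (4,)
    x_sd: np.ndarray         # (4,)
    train_accuracy: float = np.nan
    test_accuracy: float = np.nan
    converged: bool = True

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Raw output activations, shape (n, 2)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.w_hidden.shape[0]:
            raise ValueError(
                f"X must have {self.w_hidden.shape[0]} columns, got shape {X.shape}"
            )
        Z = (X - self.x_mean) / self.x_sd
        H = _activate(self.config.hidden_activation, Z @ self.w_hidden + self.b_hidden)
        return _activate(self.config.output_activation, H @ self.w_output + self.b_output)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_output": self.w_output.tolist(),
            "b_output": self.b_output.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "converged": self.converged,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ANNModel":
        d = json.loads(text)
        return cls(
            config=ANNConfig(**d["config"]),
            w_hidden=np.array(d["w_hidden"], dtype=float),
            b_hidden=np.array(d["b_hidden"], dtype=float),
            w_output=np.array(d["w_output"], dtype=float),
            b_output=np.array(d["b_output"], dtype=float),
            x_mean=np.array(d["x_mean"], dtype=float),
            x_sd=np.array(d["x_sd"], dtype=float),
            train_accuracy=float(d["train_accuracy"]),
            test_accuracy=float(d["test_accuracy"]),
            converged=bool(d["converged"]),
        )


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta, n_in, n_hid, n_out):
    i = 0
    w1 = theta[i:i + n_in * n_hid].reshape(n_in, n_hid); i += n_in * n_hid
    b1 = theta[i:i + n_hid]; i += n_hid
    w2 = theta[i:i + n_hid * n_out].reshape(n_hid, n_out); i += n_hid * n_out
    b2 = theta[i:i + n_out]
    return w1, b1, w2, b2


def _loss_and_grad(theta, Z, Y, cfg: ANNConfig, n_in, n_hid, n_out):
    w1, b1, w2, b2 = _unpack(theta, n_in, n_hid, n_out)
    n = Z.shape[0]
    zh = Z @ w1 + b1
    H = _activate(cfg.hidden_activation, zh)
    zo = H @ w2 + b2
    A = _activate(cfg.output_activation, zo)
    if cfg.output_activation == "softmax":
        loss = -np.sum(Y * np.log(np.clip(A, 1e-300, None))) / n
        d_zo = (A - Y) / n
    else:
        loss = np.sum((A - Y) ** 2) / n
        d_zo = 2.0 * (A - Y) * _activate_grad(cfg.output_activation, zo, A) / n
    if not np.isfinite(loss):
        return 1e12, np.zeros_like(theta)
    g_w2 = H.T @ d_zo
    g_b2 = d_zo.sum(axis=0)
    d_h = d_zo @ w2.T
    d_zh = d_h * _activate_grad(cfg.hidden_activation, zh, H)
    g_w1 = Z.T @ d_zh
    g_b1 = d_zh.sum(axis=0)
    grad = _pack(g_w1, g_b1, g_w2, g_b2)
    if not np.all(np.isfinite(grad)):
        return 1e12, np.zeros_like(theta)
    return loss, grad


def _stratified_split(X, y, cfg: ANNConfig, max_retries: int = 5):
    for attempt in range(max_retries):
        idx_train, idx_test = train_test_split(
            np.arange(len(y)),
            train_size=cfg.train_fraction,
            stratify=y,
            random_state=(cfg.split_seed + attempt) % (2**31),
        )
        y_tr = y[idx_train]
        if np.sum(y_tr == 0) >= 2 and np.sum(y_tr == 1) >= 2:
            return idx_train, idx_test
    raise ValueError("could not obtain a training split with >= 2 examples per class")


def train_mlp(X: np.ndarray, y: np.ndarray, cfg: ANNConfig) -> ANNModel:
    """Train one perceptron on a seeded stratified train/test split."""
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError(f"predictor matrix must have 4 columns, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictor matrix contains missing/non-finite values")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")

    if len(np.unique(y)) == 1:
        # degenerate but legal: constant labels, no split stratification possible
        idx_train = np.arange(len(y))
        idx_test = np.arange(len(y))
    else:
        idx_train, idx_test = _stratified_split(X, y, cfg)
    X_tr, y_tr = X[idx_train], y[idx_train]
    X_te, y_te = X[idx_test], y[idx_test]

    x_mean = X_tr.mean(axis=0)
    x_sd = X_tr.std(axis=0, ddof=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    Z_tr = (X_tr - x_mean) / x_sd

    n_in, n_hid, n_out = 4, cfg.n_hidden, 2
    Y_tr = np.eye(2)[y_tr]
    rng = np.random.default_rng(cfg.init_seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_hid))
    b1 = np.zeros(n_hid)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(n_hid), size=(n_hid, n_out))
    b2 = np.zeros(n_out)

    res = minimize(
        _loss_and_grad,
        _pack(w1, b1, w2, b2),
        args=(Z_tr, Y_tr, cfg, n_in, n_hid, n_out),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": cfg.max_epochs, "ftol": cfg.tol, "gtol": 1e-10},
    )
    w1, b1, w2, b2 = _unpack(res.x, n_in, n_hid, n_out)
    model = ANNModel(
        config=cfg,
        w_hidden=w1, b_hidden=b1, w_output=w2, b_output=b2,
        x_mean=x_mean, x_sd=x_sd,
        converged=bool(res.success),
    )
    model.train_accuracy = float(np.mean(predict(model, X_tr)[1] == y_tr))
    model.test_accuracy = float(np.mean(predict(model, X_te)[1] == y_te))
    return model


def predict(model: ANNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (n, 2) and hard labels (argmax of the outputs).

    With a softmax output layer the probabilities are the outputs; for any
    other output activation the two raw outputs are passed through a
    softmax to yield a normalized score (the argmax label is unaffected
    for monotone activations).
    """
    A = model.forward(X)
    if model.config.output_activation == "softmax":
        probs = A
    else:
        probs = _activate("softmax", A)
    labels = np.argmax(A, axis=1)
    return probs, labels


@dataclass
class EnsembleResult:
    """The trained population, the retained subset, and the selected model."""

    summaries: pd.DataFrame          # one row per trained network, ranked
    retained: list[ANNModel]         # top n_retain models in rank order
    best: ANNModel                   # retained[0]
    master_seed: int
    n_failed: int = 0


def sample_configs(
    n_networks: int,
    hidden_range: tuple[int, int],
    master_seed: int,
    train_fraction: float = 0.8,
    max_epochs: int = 500,
) -> list[ANNConfig]:
    """Sample the ensemble's architectures and per-network seeds."""
    rng = np.random.default_rng(master_seed)
    lo, hi = hidden_range
    configs = []
    for _ in range(n_networks):
        configs.append(
            ANNConfig(
                n_hidden=int(rng.integers(lo, hi + 1)),
                hidden_activation=str(rng.choice(HIDDEN_ACTIVATIONS)),
                output_activation=str(rng.choice(OUTPUT_ACTIVATIONS)),
                train_fraction=train_fraction,
                split_seed=int(rng.integers(0, 2**31)),
                init_seed=int(rng.integers(0, 2**31)),
                max_epochs=max_epochs,
                n_hidden_min=lo,
                n_hidden_max=hi,
            )
        )
    return configs


def run_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    n_networks: int = 1000,
    n_retain: int = 50,
    hidden_range: tuple[int, int] = (3, 10),
    master_seed: int = 0,
    max_epochs: int = 500,
) -> EnsembleResult:
    """Train the network population and select the retained/best models.

    Ranking: test accuracy desc, then train accuracy desc, then fewer
    hidden units, then sampling order (for total determinism).  Individual
    training failures are excluded; more than 10% failures aborts.
    """
    configs = sample_configs(
        n_networks, hidden_range, master_seed, max_epochs=max_epochs
    )
    models: list[tuple[int, ANNModel]] = []
    n_failed = 0
    for i, cfg in enumerate(configs):
        try:
            models.append((i, train_mlp(X, y, cfg)))
        except (ValueError, FloatingPointError):
            n_failed += 1
    if n_failed > 0.1 * n_networks:
        raise RuntimeError(
            f"{n_failed}/{n_networks} networks failed to train; aborting"
        )
    order = sorted(
        models,
        key=lambda im: (
            -im[1].test_accuracy,
            -im[1].train_accuracy,
            im[1].config.n_hidden,
            im[0],
        ),
    )
    rows = []
    for rank, (i, m) in enumerate(order, start=1):
        rows.append(
            {
                "rank": rank,
                "network": i,
                "n_hidden": m.config.n_hidden,
                "hidden_activation": m.config.hidden_activation,
                "output_activation": m.config.output_activation,
                "train_accuracy": m.train_accuracy,
                "test_accuracy": m.test_accuracy,
                "split_seed": m.config.split_seed,
                "init_seed": m.config.init_seed,
                "converged": m.converged,
            }
        )
    summaries = pd.DataFrame(rows)
    retained = [m for _, m in order[:n_retain]]
    return EnsembleResult(
        summaries=summaries,
        retained=retained,
        best=retained[0],
        master_seed=master_seed,
        n_failed=n_failed,
    )
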