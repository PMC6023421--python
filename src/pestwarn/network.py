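"""Three-layer back-propagation classifier, written from first principles.

A fully connected input -> hidden -> output network with logistic-sigmoid
units on both layers.  Layer j's activation is ``f(sum_i w[i,j] x_i -
theta[j])`` — thresholds subtract, in the classic formulation.  Training is
full-batch gradient descent on the summed squared error

    E = 1/2 * sum_samples sum_k (y_k - d_k)^2

with the textbook deltas: output delta (y-d)*f'(net), hidden deltas
back-propagated through the output weights.  The learning rate is applied to
the per-sample-mean gradient so its scale does not depend on the training-set
size; the direction is identical to the gradient of E.  The warning level is
decoded from the one-hot output layer by argmax, ties broken toward the
lower (less severe) level.

The default topology is 5 inputs, 13 hidden units, 4 outputs — 134 free
parameters (65 + 52 input/output weights, 13 + 4 thresholds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, InputError


def count_parameters(n_in: int, n_hidden: int, n_out: int) -> int:
    """Number of free parameters: both weight matrices plus both threshold
    vectors, ``n_in*n_hidden + n_hidden*n_out + n_hidden + n_out``."""
    if n_in <= 0 or n_hidden <= 0 or n_out <= 0:
        raise ConfigError(f"dimensions must be positive, got "
                          f"({n_in}, {n_hidden}, {n_out})")
    return n_in * n_hidden + n_hidden * n_out + n_hidden + n_out


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically safe logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class BPNetwork:
    """Weights and thresholds of the three-layer network."""

    n_in: int
    n_hidden: int
    n_out: int
    w_ih: np.ndarray  # (n_in, n_hidden)
    theta_h: np.ndarray  # (n_hidden,)
    w_ho: np.ndarray  # (n_hidden, n_out)
    theta_o: np.ndarray  # (n_out,)
    labels: list[str] = field(default_factory=list)
    norm_means: np.ndarray | None = None
    norm_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.labels:
            from .preprocessing import ROMAN
            self.labels = ROMAN[: self.n_out]

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.n_in, self.n_hidden, self.n_out)

    def copy(self) -> "BPNetwork":
        return BPNetwork(self.n_in, self.n_hidden, self.n_out,
                         self.w_ih.copy(), self.theta_h.copy(),
                         self.w_ho.copy(), self.theta_o.copy(),
                         list(self.labels),
                         None if self.norm_means is None else self.norm_means.copy(),
                         None if self.norm_sds is None else self.norm_sds.copy())

    # -- persistence ------------------------------------------------------

    def to_json(self, path, extra: dict | None = None) -> None:
        doc = {"n_in": self.n_in, "n_hidden": self.n_hidden, "n_out": self.n_out,
               "w_ih": self.w_ih.ravel().tolist(),
               "theta_h": self.theta_h.tolist(),
               "w_ho": self.w_ho.ravel().tolist(),
               "theta_o": self.theta_o.tolist(),
               "labels": self.labels,
               "norm_means": None if self.norm_means is None
               else self.norm_means.tolist(),
               "norm_sds": None if self.norm_sds is None
               else self.norm_sds.tolist()}
        if extra:
            doc.update(extra)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "BPNetwork":
        with open(path) as fh:
            d = json.load(fh)
        net = cls(d["n_in"], d["n_hidden"], d["n_out"],
                  np.asarray(d["w_ih"]).reshape(d["n_in"], d["n_hidden"]),
                  np.asarray(d["theta_h"], dtype=float),
                  np.asarray(d["w_ho"]).reshape(d["n_hidden"], d["n_out"]),
                  np.asarray(d["theta_o"], dtype=float),
                  labels=list(d["labels"]))
        if d.get("norm_means") is not None:
            net.norm_means = np.asarray(d["norm_means"], dtype=float)
            net.norm_sds = np.asarray(d["norm_sds"], dtype=float)
        return net


@dataclass
class TrainConfig:
    """Gradient-descent settings."""

    learning_rate: float = 0.1
    max_epochs: int = 10_000
    error_threshold: float = 0.0
    seed: int = 0
    split_fraction: float = 0.7
    batch_size: int | None = None  # None = full batch

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be nonnegative")
        if self.max_epochs <= 0:
            raise ConfigError("max_epochs must be positive")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must lie in (0, 1)")


def init_network(n_in: int = 5, n_hidden: int = 13, n_out: int = 4,
                 seed: int = 0) -> BPNetwork:
    """All weights and thresholds i.i.d. uniform on [-1, 1], reproducible
    from ``seed``."""
    count_parameters(n_in, n_hidden, n_out)  # dimension check
    rng = np.random.default_rng(seed)
    return BPNetwork(
        n_in, n_hidden, n_out,
        rng.uniform(-1, 1, (n_in, n_hidden)),
        rng.uniform(-1, 1, n_hidden),
        rng.uniform(-1, 1, (n_hidden, n_out)),
        rng.uniform(-1, 1, n_out))


def forward(net: BPNetwork, x: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Propagate one input vector; returns (hidden activations, outputs)."""
    xv = np.asarray(list(np.atleast_1d(x)), dtype=float)
    if xv.shape != (net.n_in,):
        raise InputError(f"input length {xv.shape} != n_in {net.n_in}")
    hidden = sigmoid(xv @ net.w_ih - net.theta_h)
    output = sigmoid(hidden @ net.w_ho - net.theta_o)
    return hidden, output


def _forward_batch(net: BPNetwork, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hidden = sigmoid(X @ net.w_ih - net.theta_h)
    output = sigmoid(hidden @ net.w_ho - net.theta_o)
    return hidden, output


def batch_error(net: BPNetwork, X: np.ndarray, D: np.ndarray) -> float:
    """Summed squared error E = 1/2 sum (y - d)^2 over all samples."""
    _, Y = _forward_batch(net, X)
    return float(0.5 * np.sum((Y - D) ** 2))


def gradients(net: BPNetwork, X: np.ndarray, D: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradient of the summed error E w.r.t. every parameter.

    Returns (dE/dw_ih, dE/dtheta_h, dE/dw_ho, dE/dtheta_o); thresholds enter
    with a minus sign in the net input, so their gradients are the negated
    delta sums.
    """
    H, Y = _forward_batch(net, X)
    delta_o = (Y - D) * Y * (1.0 - Y)              # (n, n_out)
    delta_h = (delta_o @ net.w_ho.T) * H * (1.0 - H)  # (n, n_hidden)
    g_w_ho = H.T @ delta_o
    g_theta_o = -delta_o.sum(axis=0)
    g_w_ih = X.T @ delta_h
    g_theta_h = -delta_h.sum(axis=0)
    return g_w_ih, g_theta_h, g_w_ho, g_theta_o


def train(net: BPNetwork, features: np.ndarray, targets: np.ndarray,
          cfg: TrainConfig) -> tuple[BPNetwork, list[float]]:
    """Gradient-descent training; returns (trained copy, epoch error history).

    ``targets`` must be one-hot rows over ``n_out`` classes.  Stops after
    ``max_epochs`` epochs or as soon as the summed error E falls to
    ``error_threshold`` (checked before the first update, so an infinite
    threshold returns the initial network untouched).  ``batch_size`` other
    than None enables seeded-shuffle minibatch descent; the default is one
    full-batch step per epoch.

    Raises
    ------
    InputError
        non-one-hot target rows, empty data, or shape mismatch.
    """
    cfg.validate()
    X = np.asarray(features, dtype=float)
    D = np.asarray(targets, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise InputError("features must be a nonempty 2-D matrix")
    if D.shape != (len(X), net.n_out):
        raise InputError(f"targets shape {D.shape} != ({len(X)}, {net.n_out})")
    if not np.isin(D, (0.0, 1.0)).all():
        raise InputError("targets must be 0/1")
    if net.n_out > 1 and not (D.sum(axis=1) == 1).all():
        raise InputError("targets must be one-hot rows")

    net = net.copy()
    history: list[float] = []
    err = batch_error(net, X, D)
    if err <= cfg.error_threshold:
        return net, history
    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    for _ in range(cfg.max_epochs):
        if cfg.batch_size is None:
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            batches = [order[i:i + cfg.batch_size]
                       for i in range(0, n, cfg.batch_size)]
        for idx in batches:
            g_w_ih, g_th, g_w_ho, g_to = gradients(net, X[idx], D[idx])
            scale = cfg.learning_rate / len(idx)  # mean-gradient step
            net.w_ih -= scale * g_w_ih
            net.theta_h -= scale * g_th
            net.w_ho -= scale * g_w_ho
            net.theta_o -= scale * g_to
        err = batch_error(net, X, D)
        history.append(err)
        if err <= cfg.error_threshold:
            break
    return net, history


def predict_level(net: BPNetwork, x: Sequence[float]) -> str:
    """Decode the warning level for one (already normalized) input vector;
    argmax over output units, exact ties resolved to the lower level."""
    _, out = forward(net, x)
    return net.labels[int(np.argmax(out))]


def predict_levels(net: BPNetwork, X: np.ndarray) -> np.ndarray:
    """Vectorized prediction: integer level indices 0..n_out-1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.n_in:
        raise InputError(f"feature matrix must be (n, {net.n_in})")
    _, Y = _forward_batch(net, X)
    return np.argmax(Y, axis=1)


def one_hot(levels: Sequence[int], k: int) -> np.ndarray:
    """Encode integer level indices as one-hot rows."""
    lv = np.asarray(list(levels), dtype=int)
    if ((lv < 0) | (lv >= k)).any():
        raise InputError(f"level indices must lie in 0..{k - 1}")
    out = np.zeros((len(lv), k))
    out[np.arange(len(lv)), lv] = 1.0
    return out
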