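"""The light-weight classifier: input -> tanh(100) -> sigmoid(7).

A single-hidden-layer network maps a context-stacked feature row (default
513 = 3 windows x 19 channels x 9 features) through 100 tanh hidden units to
seven *independent* sigmoid outputs, one per activity.  Training minimizes
the summed binary cross-entropy of the sigmoid outputs against one-hot
labels plus an L2 penalty on non-bias weights,

    J = -(1/N) sum_{n,k} [ y log yhat + (1-y) log(1-yhat) ]
        + (lambda/2N) sum w^2,

by full-batch Polack-Ribiere conjugate gradients with a Wolfe-condition line
search (:mod:`gaitann.optim`).  Prediction takes the argmax over the seven
sigmoid activations (ties resolve to the lowest class index).

Parameters are flattened with layer 1 row-major first, then layer 2; bias
columns are the first column of each weight matrix and are excluded from the
L2 penalty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import optim
from .errors import GaitannError
from .preprocess import ScalerStats, SegmentationConfig

_CLIP = 1e-12


@dataclass
class NetworkParams:
    """Weights of the two-layer network; bias is column 0 of each matrix."""

    W1: np.ndarray  # [H, D+1]
    W2: np.ndarray  # [K, H+1]

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        if self.W1.ndim != 2 or self.W2.ndim != 2:
            raise ValueError("W1 and W2 must be matrices")
        if self.W2.shape[1] != self.W1.shape[0] + 1:
            raise ValueError("W2 columns must equal hidden units + 1")

    @property
    def D(self) -> int:
        return self.W1.shape[1] - 1

    @property
    def H(self) -> int:
        return self.W1.shape[0]

    @property
    def K(self) -> int:
        return self.W2.shape[0]

    @property
    def n_params(self) -> int:
        return self.W1.size + self.W2.size

    def pack(self) -> np.ndarray:
        """Flatten to one vector: W1 row-major, then W2 row-major."""
        return np.concatenate([self.W1.ravel(), self.W2.ravel()])

    @classmethod
    def unpack(cls, theta: np.ndarray, D: int, H: int, K: int) -> "NetworkParams":
        theta = np.asarray(theta, dtype=float)
        n1 = H * (D + 1)
        if theta.size != n1 + K * (H + 1):
            raise ValueError("flat parameter vector has the wrong length")
        return cls(
            W1=theta[:n1].reshape(H, D + 1).copy(),
            W2=theta[n1:].reshape(K, H + 1).copy(),
        )


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``lam`` is the L2 strength (the method's tuned value is 2); ``max_iters``
    counts full-batch CG iterations; ``c1``/``c2`` are the Wolfe
    sufficient-decrease and curvature constants; the remaining line-search
    limits follow the classical implementation of the CG routine.
    ``init_scale`` overrides the per-layer uniform initialization half-width
    (default: sqrt(6/(fan_in+fan_out))).
    """

    lam: float = 2.0
    max_iters: int = 1000
    c1: float = 0.01
    c2: float = 0.5
    int_limit: float = 0.1
    ext: float = 3.0
    max_evals: int = 20
    ratio: float = 100.0
    hidden_units: int = 100
    init_scale: float | None = None
    seed: int = 0
    debug_checks: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.c1 < self.c2 < 1:
            raise ValueError("need 0 < c1 < c2 < 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


def init_params(
    D: int, H: int, K: int, seed: int = 0, init_scale: float | None = None
) -> NetworkParams:
    """Seeded uniform initialization in [-eps, eps], eps = sqrt(6/(fan_in+fan_out))."""
    if min(D, H, K) < 1:
        raise ValueError("D, H, K must all be >= 1")
    rng = np.random.default_rng(seed)
    eps1 = np.sqrt(6.0 / (D + H)) if init_scale is None else init_scale
    eps2 = np.sqrt(6.0 / (H + K)) if init_scale is None else init_scale
    return NetworkParams(
        W1=rng.uniform(-eps1, eps1, size=(H, D + 1)),
        W2=rng.uniform(-eps2, eps2, size=(K, H + 1)),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _add_bias(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


def forward(params: NetworkParams, X: np.ndarray, return_hidden: bool = False):
    """Sigmoid activations ``[N, K]``; independent per class (not normalized)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.D:
        raise ValueError(f"X has {X.shape[1]} columns, network expects {params.D}")
    A1 = np.tanh(_add_bias(X) @ params.W1.T)
    Yhat = _sigmoid(_add_bias(A1) @ params.W2.T)
    return (Yhat, A1) if return_hidden else Yhat


def one_hot(y: np.ndarray, K: int) -> np.ndarray:
    y = np.asarray(y, dtype=np.int64).ravel()
    if y.size and (y.min() < 0 or y.max() >= K):
        raise ValueError("labels outside 0..K-1")
    Y = np.zeros((y.size, K))
    Y[np.arange(y.size), y] = 1.0
    return Y


def _cost_grad_prebias(
    W1: np.ndarray, W2: np.ndarray, Xb: np.ndarray, Y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Cost/gradient core on a bias-augmented design matrix ``Xb = [1 X]``."""
    N = Xb.shape[0]
    A1 = np.tanh(Xb @ W1.T)
    A1b = _add_bias(A1)
    Yhat = _sigmoid(A1b @ W2.T)

    P = np.clip(Yhat, _CLIP, 1.0 - _CLIP)
    J = -np.sum(Y * np.log(P) + (1.0 - Y) * np.log1p(-P)) / N
    J += (lam / (2.0 * N)) * (np.sum(W1[:, 1:] ** 2) + np.sum(W2[:, 1:] ** 2))

    dZ2 = (Yhat - Y) / N  # [N, K]
    gW2 = dZ2.T @ A1b
    gW2[:, 1:] += (lam / N) * W2[:, 1:]
    dA1 = dZ2 @ W2[:, 1:]
    dZ1 = dA1
    dZ1 *= 1.0 - A1 ** 2
    gW1 = dZ1.T @ Xb
    gW1[:, 1:] += (lam / N) * W1[:, 1:]

    return float(J), np.concatenate([gW1.ravel(), gW2.ravel()])


def cost_and_grad(
    params: NetworkParams, X: np.ndarray, Y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Cross-entropy + L2 cost and its backpropagated gradient (flat vector)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if np.isnan(X).any() or np.isnan(Y).any():
        raise GaitannError("NaN in training inputs")
    if X.shape[0] < 1:
        raise ValueError("need at least one row")
    return _cost_grad_prebias(params.W1, params.W2, _add_bias(X), Y, lam)


@dataclass
class TrainTrace:
    """Cost/step diagnostics per accepted CG iteration."""

    cost: np.ndarray
    grad_norm: np.ndarray
    step: np.ndarray
    n_evals: np.ndarray
    armijo_margin: np.ndarray
    curvature_margin: np.ndarray
    n_failures: int

    @classmethod
    def from_optim(cls, t: optim.OptimTrace) -> "TrainTrace":
        return cls(
            cost=np.asarray(t.cost),
            grad_norm=np.asarray(t.grad_norm),
            step=np.asarray(t.step),
            n_evals=np.asarray(t.n_evals),
            armijo_margin=np.asarray(t.armijo_margin),
            curvature_margin=np.asarray(t.curvature_margin),
            n_failures=t.n_failures,
        )


def train(
    p0: NetworkParams | None,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    K: int | None = None,
) -> tuple[NetworkParams, TrainTrace]:
    """Full-batch CG training; deterministic given (data, config).

    ``y`` may be integer codes or an already one-hot matrix.  ``p0`` of None
    initializes from ``cfg.seed`` with ``cfg.hidden_units`` hidden units.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if y.ndim == 2:
        Y = y.astype(float)
        K = Y.shape[1]
    else:
        if K is None:
            K = p0.K if p0 is not None else int(y.max()) + 1
        Y = one_hot(y, K)
    if p0 is None:
        p0 = init_params(X.shape[1], cfg.hidden_units, K, cfg.seed, cfg.init_scale)

    D, H, Kn = p0.D, p0.H, p0.K
    if np.isnan(X).any() or np.isnan(Y).any():
        raise GaitannError("NaN in training inputs")
    Xb = _add_bias(X)
    n1 = H * (D + 1)

    def objective(theta: np.ndarray):
        W1 = theta[:n1].reshape(H, D + 1)
        W2 = theta[n1:].reshape(Kn, H + 1)
        return _cost_grad_prebias(W1, W2, Xb, Y, cfg.lam)

    theta, otrace = optim.minimize(
        objective,
        p0.pack(),
        max_iters=cfg.max_iters,
        c1=cfg.c1,
        c2=cfg.c2,
        int_limit=cfg.int_limit,
        ext=cfg.ext,
        max_evals=cfg.max_evals,
        ratio=cfg.ratio,
        debug_checks=cfg.debug_checks,
    )
    return NetworkParams.unpack(theta, D, H, Kn), TrainTrace.from_optim(otrace)


def predict(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Argmax over the sigmoid outputs; ties break to the lowest class index."""
    return np.argmax(forward(params, X), axis=1).astype(np.int64)


@dataclass
class ModelContainer:
    """Everything needed for standalone inference on new circuits."""

    params: NetworkParams
    scaler: ScalerStats
    channel_subset: str | list[str]
    seg_cfg: SegmentationConfig
    activity_names: tuple[str, ...]

    def save(self, path) -> None:
        payload = {
            "format": "gaitann-model-v1",
            "W1": self.params.W1.tolist(),
            "W2": self.params.W2.tolist(),
            "dims": {"D": self.params.D, "H": self.params.H, "K": self.params.K},
            "scaler": {
                "mean": self.scaler.mean.tolist(),
                "scale": self.scaler.scale.tolist(),
                "n_fit": self.scaler.n_fit,
            },
            "channel_subset": self.channel_subset,
            "segmentation": asdict(self.seg_cfg),
            "activity_names": list(self.activity_names),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelContainer":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "gaitann-model-v1":
            raise GaitannError(f"{path}: not a gaitann model container")
        return cls(
            params=NetworkParams(np.array(payload["W1"]), np.array(payload["W2"])),
            scaler=ScalerStats(
                mean=np.array(payload["scaler"]["mean"]),
                scale=np.array(payload["scaler"]["scale"]),
                n_fit=int(payload["scaler"]["n_fit"]),
            ),
            channel_subset=payload["channel_subset"],
            seg_cfg=SegmentationConfig(**payload["segmentation"]),
            activity_names=tuple(payload["activity_names"]),
        )
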