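"""Single-hidden-layer neural network classifier trained with
Levenberg–Marquardt.

The network maps an 18-element feature vector through a tanh hidden layer to
linear outputs against one-hot targets; the decision is the argmax of the
output scores (ties broken by lowest class index).  Training minimises the
mean squared error with a damped Gauss–Newton (Levenberg–Marquardt) loop and
an analytic residual Jacobian — feasible at this network size (a few hundred
weights) and much faster-converging than first-order methods.  A plain
gradient-descent fallback is provided; the optimizer that produced a model is
recorded in its metadata.

Features are z-scored with statistics computed from the training data only,
so no test-day information leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_VARIANCE_FLOOR = 1e-12


@dataclass
class NetConfig:
    input_dim: int = 18
    hidden_units: int = 10
    output_dim: int = 5
    training_algorithm: str = "levenberg_marquardt"  # or "fallback_gradient"
    max_iterations: int = 50
    convergence_tol: float = 1e-5  # relative loss-change stopping threshold
    lm_lambda_init: float = 1e-2
    lm_lambda_factor: float = 10.0
    weight_init_seed: int = 0
    normalization: str = "zscore"  # or "none"

    def __post_init__(self):
        if min(self.input_dim, self.hidden_units, self.output_dim) < 1:
            raise ValueError("layer sizes must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.training_algorithm not in ("levenberg_marquardt", "fallback_gradient"):
            raise ValueError("unknown training_algorithm")
        if self.normalization not in ("zscore", "none"):
            raise ValueError("normalization must be 'zscore' or 'none'")


@dataclass
class TrainedModel:
    """Weights, normalization statistics and provenance of one trained net."""

    w1: np.ndarray  # (input_dim, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden, n_classes)
    b2: np.ndarray  # (n_classes,)
    mean: np.ndarray
    std: np.ndarray
    classes: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class output scores, shape (n, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w1.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model input dim {self.w1.shape[0]}"
            )
        H = np.tanh(self.normalize(X) @ self.w1 + self.b1)
        return H @ self.w2 + self.b2

    def as_decoder(self, windowing_cfg):
        """Callable ``decoder(window, intended)`` classifying one raw EMG
        window; ``intended`` is accepted for protocol compatibility with
        reference decoders and ignored.

        The z-scoring is folded into the first-layer weights once so the
        per-tick cost is two small matrix products.
        """
        from .features import window_features

        w1_folded = self.w1 / self.std[:, None]
        b1_folded = self.b1 - (self.mean / self.std) @ self.w1
        w2, b2 = self.w2, self.b2
        classes = self.classes

        def _decode(window, intended=None):
            fv = window_features(window, windowing_cfg)
            h = np.tanh(fv @ w1_folded + b1_folded)
            return classes[int(np.argmax(h @ w2 + b2))]

        return _decode


def _unpack(p: np.ndarray, d: int, h: int, k: int):
    i = 0
    w1 = p[i : i + d * h].reshape(d, h); i += d * h
    b1 = p[i : i + h]; i += h
    w2 = p[i : i + h * k].reshape(h, k); i += h * k
    b2 = p[i : i + k]
    return w1, b1, w2, b2


def _forward(p, Xz, d, h, k):
    w1, b1, w2, b2 = _unpack(p, d, h, k)
    H = np.tanh(Xz @ w1 + b1)
    return H, H @ w2 + b2


def _jacobian(p, Xz, H, d, h, k) -> np.ndarray:
    """Residual Jacobian d r_{ik} / d p, shape (n*k, P).

    Parameter layout matches ``_unpack``: [w1 (d*h), b1 (h), w2 (h*k), b2 (k)].
    """
    w1, b1, w2, b2 = _unpack(p, d, h, k)
    n = Xz.shape[0]
    P = p.size
    G = 1.0 - H * H                        # (n, h) tanh'
    A = G[:, None, :] * w2.T[None, :, :]   # (n, k, h): dr_k / d preactivation_j
    J = np.zeros((n, k, P))
    J[:, :, : d * h] = (Xz[:, None, :, None] * A[:, :, None, :]).reshape(n, k, d * h)
    J[:, :, d * h : d * h + h] = A
    off = d * h + h
    for kk in range(k):  # w2[:, kk] only affects output kk
        J[:, kk, off + kk : off + h * k : k] = H
    J[:, :, off + h * k :] = np.eye(k)[None, :, :]
    return J.reshape(n * k, P)


def _init_params(cfg: NetConfig, d: int, h: int, k: int) -> np.ndarray:
    rng = np.random.default_rng(cfg.weight_init_seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(d), (d, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(h), (h, k))
    b2 = np.zeros(k)
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _train_lm(p, Xz, T, cfg, d, h, k):
    """Damped Gauss–Newton on the MSE; accepted steps never increase the loss."""
    n = Xz.shape[0]
    lam = cfg.lm_lambda_init
    H, Y = _forward(p, Xz, d, h, k)
    loss = float(np.mean((Y - T) ** 2))
    history = [loss]
    for _ in range(cfg.max_iterations):
        R = (Y - T).reshape(-1)
        J = _jacobian(p, Xz, H, d, h, k)
        JtJ = J.T @ J
        Jtr = J.T @ R
        accepted = False
        for _try in range(10):
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(p.size), -Jtr)
            except np.linalg.LinAlgError:
                lam *= cfg.lm_lambda_factor
                continue
            p_new = p + delta
            H_new, Y_new = _forward(p_new, Xz, d, h, k)
            loss_new = float(np.mean((Y_new - T) ** 2))
            if loss_new <= loss:
                accepted = True
                lam = max(lam / cfg.lm_lambda_factor, 1e-12)
                break
            lam = min(lam * cfg.lm_lambda_factor, 1e12)
        if not accepted:
            break
        rel_change = (loss - loss_new) / max(loss, 1e-300)
        p, H, Y, loss = p_new, H_new, Y_new, loss_new
        history.append(loss)
        # stop on stagnation or once the fit is numerically perfect
        if rel_change < cfg.convergence_tol or loss < 1e-8:
            break
    return p, history


def _train_gd(p, Xz, T, cfg, d, h, k):
    """First-order fallback: full-batch Adam on the MSE."""
    n = Xz.shape[0]
    m = np.zeros_like(p)
    v = np.zeros_like(p)
    lr, beta1, beta2, eps = 0.01, 0.9, 0.999, 1e-8
    iters = cfg.max_iterations * 40
    history = []
    for t in range(1, iters + 1):
        H, Y = _forward(p, Xz, d, h, k)
        R = Y - T
        loss = float(np.mean(R**2))
        history.append(loss)
        w1, b1, w2, b2 = _unpack(p, d, h, k)
        gY = 2.0 * R / R.size
        g_w2 = H.T @ gY
        g_b2 = gY.sum(axis=0)
        gH = gY @ w2.T * (1.0 - H * H)
        g_w1 = Xz.T @ gH
        g_b1 = gH.sum(axis=0)
        g = np.concatenate([g_w1.ravel(), g_b1, g_w2.ravel(), g_b2])
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        p = p - lr * (m / (1 - beta1**t)) / (np.sqrt(v / (1 - beta2**t)) + eps)
    H, Y = _forward(p, Xz, d, h, k)
    history.append(float(np.mean((Y - T) ** 2)))
    return p, history


def train(
    features: np.ndarray,
    labels: Sequence[str],
    cfg: NetConfig | None = None,
    classes: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the classifier; deterministic given ``(data, cfg)``.

    ``classes`` fixes the output label order (defaults to first-appearance
    order in ``labels``); classes absent from the data are rejected since
    their one-hot columns would be unconstrained.
    """
    cfg = cfg or NetConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, input_dim) aligned with labels")
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"feature dim {X.shape[1]} != cfg.input_dim {cfg.input_dim}")
    present = list(dict.fromkeys(y.tolist()))
    if classes is None:
        classes = present
    classes = tuple(classes)
    if len(classes) != cfg.output_dim:
        raise ValueError(
            f"{len(classes)} classes != cfg.output_dim {cfg.output_dim}"
        )
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    missing = set(classes) - set(present)
    if missing:
        raise ValueError(f"classes absent from training data: {sorted(missing)}")
    unknown = set(present) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class vocabulary: {sorted(unknown)}")

    if cfg.normalization == "zscore":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std < _VARIANCE_FLOOR, 1.0, std)  # variance floor
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    Xz = (X - mean) / std

    idx = {c: i for i, c in enumerate(classes)}
    T = np.zeros((X.shape[0], cfg.output_dim))
    T[np.arange(X.shape[0]), [idx[c] for c in y]] = 1.0

    d, h, k = cfg.input_dim, cfg.hidden_units, cfg.output_dim
    p = _init_params(cfg, d, h, k)
    if cfg.training_algorithm == "levenberg_marquardt":
        p, history = _train_lm(p, Xz, T, cfg, d, h, k)
    else:
        p, history = _train_gd(p, Xz, T, cfg, d, h, k)
    w1, b1, w2, b2 = _unpack(p, d, h, k)
    return TrainedModel(
        w1=w1, b1=b1, w2=w2, b2=b2, mean=mean, std=std, classes=classes,
        meta={
            "optimizer": cfg.training_algorithm,
            "final_loss": history[-1],
            "loss_history": history,
            "n_train": int(X.shape[0]),
            "weight_init_seed": cfg.weight_init_seed,
            "hidden_units": h,
        },
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Argmax class labels; ``np.argmax`` keeps the lowest index on ties."""
    scores = model.scores(features)
    return np.asarray(model.classes, dtype=object)[np.argmax(scores, axis=1)]


def classification_error(model: TrainedModel, features, labels) -> float:
    """Fraction of misclassified decisions, in [0, 1]."""
    pred = predict(model, np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if pred.shape[0] != labels.shape[0]:
        raise ValueError("features and labels are misaligned")
    return float(np.mean(pred != labels))
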