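"""Extreme learning machine: random fixed hidden layer, closed-form output.

A single-hidden-layer feedforward network whose input weights and biases are
drawn once at random and never trained; the output weights B solve the linear
system H B = O in the least-squares sense via the Moore-Penrose
pseudo-inverse (or a ridge-regularized normal-equation solve when
``ridge > 0``, which conditions the large classifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from spredict.signal_io import ValidationError

PINV_RCOND = 1e-12  # singular values below rcond * sigma_max are dropped


@dataclass(frozen=True)
class ElmParams:
    L: int
    activation: str = "sigmoid"
    seed: int = 0
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValidationError("hidden-neuron count L must be >= 1")
        if self.activation != "sigmoid":
            raise ValidationError(f"unsupported activation {self.activation!r}")
        if self.ridge < 0:
            raise ValidationError("ridge must be >= 0")


@dataclass
class ElmModel:
    W: np.ndarray  # (L, n) input weights, fixed after init
    b: np.ndarray  # (L,) biases, fixed after init
    B: np.ndarray  # (L, m) output weights, solved in closed form

    @property
    def L(self) -> int:
        return self.W.shape[0]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_hidden(n: int, params: ElmParams) -> Tuple[np.ndarray, np.ndarray]:
    """Draw the fixed hidden layer: i.i.d. uniform on [-1, 1], seeded."""
    if n < 1:
        raise ValidationError("input dimension must be >= 1")
    rng = np.random.default_rng(params.seed)
    W = rng.uniform(-1.0, 1.0, size=(params.L, n))
    b = rng.uniform(-1.0, 1.0, size=params.L)
    return W, b


def hidden_matrix(model_or_Wb, S: np.ndarray) -> np.ndarray:
    """H[j, i] = g(w_i . s_j + b_i) with g the logistic sigmoid."""
    if isinstance(model_or_Wb, ElmModel):
        W, b = model_or_Wb.W, model_or_Wb.b
    else:
        W, b = model_or_Wb
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[1] != W.shape[1]:
        raise ValidationError(
            f"input dimension {S.shape[1]} does not match hidden layer {W.shape[1]}"
        )
    return _sigmoid(S @ W.T + b)


def fit(
    S: np.ndarray,
    O: np.ndarray,
    params: ElmParams,
    hidden: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> ElmModel:
    """Solve B = pinv(H) O (SVD) or the ridge normal equations if ridge > 0.

    ``hidden`` lets callers share one random hidden layer across many fits
    (required when output weights from different fits are compared as
    features).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    O = np.asarray(O, dtype=float)
    if O.ndim == 1:
        O = O[:, None]
    if S.shape[0] != O.shape[0]:
        raise ValidationError("inputs and targets disagree on sample count")
    if S.shape[0] < 1:
        raise ValidationError("need at least one training instance")
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(O))):
        raise ValidationError("non-finite values in training data")
    if hidden is None:
        hidden = init_hidden(S.shape[1], params)
    W, b = hidden
    H = hidden_matrix((W, b), S)
    if params.ridge > 0:
        L = H.shape[1]
        G = H.T @ H + params.ridge * np.eye(L)
        B = np.linalg.solve(G, H.T @ O)
    else:
        B = np.linalg.pinv(H, rcond=PINV_RCOND) @ O
    return ElmModel(W=W.copy(), b=b.copy(), B=B)


def predict(model: ElmModel, S: np.ndarray) -> np.ndarray:
    """Network output H(S) B, shape (N, m)."""
    return hidden_matrix(model, S) @ model.B


def save_model(model: ElmModel, path) -> None:
    np.savez(Path(path), W=model.W, b=model.b, B=model.B)


def load_model(path) -> ElmModel:
    with np.load(Path(path)) as f:
        return ElmModel(W=f["W"], b=f["b"], B=f["B"])
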