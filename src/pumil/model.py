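"""Attention-based multi-instance network: embedding, gated pooling, bag head.

The network maps each instance x (dimension D) through a two-layer ReLU
embedding to h in R^M, scores instances with a tanh attention head
``atts_j = w_att . tanh(V h_j)``, pools the bag with softmax attention
weights ``z = sum_j a_j h_j`` and classifies the bag with a logistic head
``P = sigmoid(c . z)``.  The MIL loss is the Bernoulli negative
log-likelihood of bag labels under P.

Implemented directly on NumPy arrays; :func:`bag_backward` carries the
analytic gradients, which are validated against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

EPS_CLIP = 1e-7  # log-argument clip used by every loss in the package


@dataclass
class AttentionParams:
    """All trainable parameters of the model.

    W1, b1, W2, b2 : two fully connected ReLU layers, D -> M -> M.
    V (L, M), w_att (L,) : attention head.
    classifier_w (M,) : bag-level logistic head.
    alpha, beta : Platt calibration of attention scores (see pooling module).
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    V: np.ndarray
    w_att: np.ndarray
    classifier_w: np.ndarray
    alpha: float = 1.0
    beta: float = 0.0

    PARAM_KEYS = ("W1", "b1", "W2", "b2", "V", "w_att", "classifier_w", "alpha", "beta")

    @property
    def dim_in(self) -> int:
        return self.W1.shape[0]

    @property
    def dim_embed(self) -> int:
        return self.W2.shape[1]

    @property
    def dim_att(self) -> int:
        return self.V.shape[0]

    def flatten(self) -> dict[str, np.ndarray]:
        return {k: np.atleast_1d(np.asarray(getattr(self, k), dtype=float))
                for k in self.PARAM_KEYS}

    def copy(self) -> "AttentionParams":
        return AttentionParams(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(),
            self.V.copy(), self.w_att.copy(), self.classifier_w.copy(),
            float(self.alpha), float(self.beta),
        )


def init_params(dim_in: int, dim_embed: int = 16, dim_att: int = 8,
                seed: int = 0) -> AttentionParams:
    """Glorot-uniform initialization, deterministic under ``seed``."""
    rng = np.random.default_rng(seed)

    def glorot(n_in: int, n_out: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out))

    # small positive biases keep ReLU units off the exact kink at init
    return AttentionParams(
        W1=glorot(dim_in, dim_embed),
        b1=np.full(dim_embed, 0.01),
        W2=glorot(dim_embed, dim_embed),
        b2=np.full(dim_embed, 0.01),
        V=glorot(dim_att, dim_embed).reshape(dim_att, dim_embed),
        w_att=glorot(dim_att, 1).ravel(),
        classifier_w=glorot(dim_embed, 1).ravel(),
        alpha=1.0,
        beta=0.0,
    )


def zero_grads(params: AttentionParams) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.flatten().items()}


# ---------------------------------------------------------------------------
# Forward pieces (each usable standalone; bag_forward composes them)


def embed(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Two-layer ReLU embedding of instances; X is (k, D) or (D,)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.dim_in:
        raise ValueError(
            f"feature dimension mismatch: expected {params.dim_in}, got {X.shape[1]}"
        )
    H1 = np.maximum(X @ params.W1 + params.b1, 0.0)
    H = np.maximum(H1 @ params.W2 + params.b2, 0.0)
    return H


def attention_scores(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """atts_j = w_att . tanh(V h_j); permutation-equivariant over rows."""
    T = np.tanh(H @ params.V.T)
    return T @ params.w_att


def attention_weights(atts: np.ndarray) -> np.ndarray:
    """Softmax over instance scores; sums to 1 for any bag size."""
    atts = np.asarray(atts, dtype=float)
    shifted = atts - atts.max()
    e = np.exp(shifted)
    return e / e.sum()


def pool(H: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention-weighted average of embeddings: z = sum_j a_j h_j."""
    return np.asarray(a, dtype=float) @ np.atleast_2d(H)


def bag_score(z: np.ndarray, params: AttentionParams) -> float:
    """Logistic bag classifier P = sigmoid(classifier_w . z), in (0, 1)."""
    s = float(np.dot(params.classifier_w, z))
    return float(1.0 / (1.0 + np.exp(-s)))


@dataclass
class BagForwardResult:
    """Per-bag forward pass with intermediates kept for backprop."""

    X: np.ndarray          # (k, D) inputs
    A1: np.ndarray         # pre-activation of layer 1
    H1: np.ndarray
    A2: np.ndarray
    H: np.ndarray          # (k, M) embeddings
    T: np.ndarray          # tanh(H V^T), (k, L)
    atts: np.ndarray       # (k,) attention scores
    a: np.ndarray          # (k,) softmax attention weights
    z: np.ndarray          # (M,) pooled embedding
    P: float               # bag classifier probability
    mean_pool: bool = False


def bag_forward(X: np.ndarray, params: AttentionParams,
                mean_pool: bool = False) -> BagForwardResult:
    """Full forward pass on one bag.

    ``mean_pool=True`` is the attention-removal ablation: the pooled z uses
    uniform 1/k weights while attention scores are still computed (they feed
    the instance-probability calibration downstream).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.dim_in:
        raise ValueError(
            f"feature dimension mismatch: expected {params.dim_in}, got {X.shape[1]}"
        )
    A1 = X @ params.W1 + params.b1
    H1 = np.maximum(A1, 0.0)
    A2 = H1 @ params.W2 + params.b2
    H = np.maximum(A2, 0.0)
    T = np.tanh(H @ params.V.T)
    atts = T @ params.w_att
    k = X.shape[0]
    a = np.full(k, 1.0 / k) if mean_pool else attention_weights(atts)
    z = a @ H
    P = bag_score(z, params)
    return BagForwardResult(X, A1, H1, A2, H, T, atts, a, z, P, mean_pool)


def loss_mil(bag_scores: Sequence[float], labels: Sequence[int],
             eps: float = EPS_CLIP) -> float:
    """Bernoulli negative log-likelihood of bag labels under scores P.

    Scores are clipped into [eps, 1-eps] before the logs.
    """
    P = np.clip(np.asarray(bag_scores, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels)
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError(f"bag labels must be 0/1, got {sorted(set(y.tolist()))}")
    return float(-np.sum(y * np.log(P) + (1 - y) * np.log(1.0 - P)))


# ---------------------------------------------------------------------------
# Backward


def bag_backward(fw: BagForwardResult, params: AttentionParams,
                 grads: dict[str, np.ndarray],
                 dP: float = 0.0, datts: np.ndarray | None = None) -> None:
    """Accumulate parameter gradients for one bag into ``grads``.

    ``dP`` is dL/dP from the bag-classifier loss; ``datts`` is dL/datts
    from any path that consumes attention scores directly (the Platt /
    Noisy-OR head).  Rank weights are treated as constants upstream, so a
    single datts vector suffices.
    """
    k = fw.X.shape[0]
    g_atts = np.zeros(k) if datts is None else np.asarray(datts, dtype=float).copy()
    gH = np.zeros_like(fw.H)

    # classifier head: P = sigmoid(c . z)
    if dP != 0.0:
        gs = dP * fw.P * (1.0 - fw.P)
        grads["classifier_w"] += gs * fw.z
        gz = gs * params.classifier_w
        # z = a @ H
        gH += np.outer(fw.a, gz)
        if not fw.mean_pool:
            ga = fw.H @ gz
            # softmax jacobian
            g_atts += fw.a * (ga - np.dot(ga, fw.a))

    # atts = T @ w_att, T = tanh(H V^T)
    if np.any(g_atts):
        grads["w_att"] += fw.T.T @ g_atts
        gT = np.outer(g_atts, params.w_att)
        gPre = gT * (1.0 - fw.T ** 2)
        grads["V"] += gPre.T @ fw.H
        gH += gPre @ params.V

    # two-layer ReLU MLP
    gA2 = gH * (fw.A2 > 0)
    grads["W2"] += fw.H1.T @ gA2
    grads["b2"] += gA2.sum(axis=0)
    gH1 = gA2 @ params.W2.T
    gA1 = gH1 * (fw.A1 > 0)
    grads["W1"] += fw.X.T @ gA1
    grads["b1"] += gA1.sum(axis=0)


# ---------------------------------------------------------------------------
# Checkpoint serialization ("pumil-v1", JSON, text-only)


def params_to_dict(params: AttentionParams, extra: dict | None = None) -> dict:
    d = {
        "format": "pumil-v1",
        "dims": {"D": params.dim_in, "M": params.dim_embed, "L": params.dim_att},
        "params": {k: np.asarray(getattr(params, k)).tolist()
                   for k in params.PARAM_KEYS},
    }
    if extra:
        d.update(extra)
    return d


def params_from_dict(d: dict) -> AttentionParams:
    if d.get("format") != "pumil-v1":
        raise ValueError(f"unrecognized checkpoint format {d.get('format')!r}")
    p = d["params"]
    return AttentionParams(
        W1=np.asarray(p["W1"], dtype=float),
        b1=np.asarray(p["b1"], dtype=float),
        W2=np.asarray(p["W2"], dtype=float),
        b2=np.asarray(p["b2"], dtype=float),
        V=np.asarray(p["V"], dtype=float),
        w_att=np.asarray(p["w_att"], dtype=float),
        classifier_w=np.asarray(p["classifier_w"], dtype=float),
        alpha=float(np.asarray(p["alpha"]).ravel()[0]),
        beta=float(np.asarray(p["beta"]).ravel()[0]),
    )
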