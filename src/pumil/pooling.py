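"""Instance-probability calibration and rank-weighted Noisy-OR bag pooling.

Attention scores are mapped to per-read modification probabilities with
Platt scaling, f_j = sigmoid(alpha * atts_j + beta).  The bag (site)
probability is a weighted Noisy-OR,

    F(B) = 1 - prod_j (1 - f_j)^{w_j},

where the exponents w_j derive from the within-bag ascending rank of f_j:
ranks are normalized to u in [0, 1] and passed through a two-peaked weight
function S(u) = N(u; 0, 0.1) + N(u; 1, 0.1) (Gaussian densities), then
normalized to sum to one.  The weighting concentrates on the most- and
least-probable reads, keeping F stable as read depth varies — the standard
Noisy-OR saturates to 1 as depth grows.

Also here: reliable-negative selection (the |R| = |P| balancing step of PU
training) and the PU loss L_p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import EPS_CLIP

RANK_SIGMA = 0.1  # std-dev of the two Gaussian peaks of the weight function

POOLING_VARIANTS = ("weighted_noisy_or", "noisy_or", "mean", "max")


@dataclass(frozen=True)
class PlattParams:
    alpha: float
    beta: float


@dataclass(frozen=True)
class NoisyORWeights:
    """Rank-derived Noisy-OR exponents for one bag."""

    ranks: np.ndarray            # ascending-probability ranks, permutation of 0..k-1
    normalized_ranks: np.ndarray  # u_j = rank_j / (k - 1), in [0, 1]
    raw_S: np.ndarray            # two-peaked weight function at u_j
    weights: np.ndarray          # normalized, sums to 1


def platt(atts: np.ndarray, params: PlattParams) -> np.ndarray:
    """Platt scaling of attention scores to probabilities."""
    atts = np.asarray(atts, dtype=float)
    return 1.0 / (1.0 + np.exp(-(params.alpha * atts + params.beta)))


def rank_weights(f: np.ndarray) -> NoisyORWeights:
    """Two-peaked rank weights for the weighted Noisy-OR.

    Ties in f are broken by instance index (stable sort), making the ranks a
    deterministic permutation.  A single-instance bag gets weight [1] by
    convention (the normalized rank is undefined at k=1).
    """
    f = np.asarray(f, dtype=float)
    k = f.shape[0]
    if k < 1:
        raise ValueError("rank_weights needs at least one instance")
    if k == 1:
        one = np.array([1.0])
        return NoisyORWeights(np.array([0]), np.array([0.0]), one.copy(), one)
    order = np.argsort(f, kind="stable")
    ranks = np.empty(k, dtype=int)
    ranks[order] = np.arange(k)
    u = ranks / (k - 1)
    S = norm.pdf(u, loc=0.0, scale=RANK_SIGMA) + norm.pdf(u, loc=1.0, scale=RANK_SIGMA)
    return NoisyORWeights(ranks, u, S, S / S.sum())


def weighted_noisy_or(f: np.ndarray, w: np.ndarray, eps: float = EPS_CLIP) -> float:
    """F = 1 - prod_j (1 - f_j)^{w_j}, with (1 - f) clipped at eps."""
    f = np.asarray(f, dtype=float)
    w = np.asarray(w, dtype=float)
    comp = np.clip(1.0 - f, eps, 1.0)
    return float(1.0 - np.exp(np.sum(w * np.log(comp))))


def standard_noisy_or(f: np.ndarray, eps: float = EPS_CLIP) -> float:
    """Unweighted Noisy-OR, F = 1 - prod_j (1 - f_j); the ablation variant."""
    f = np.asarray(f, dtype=float)
    comp = np.clip(1.0 - f, eps, 1.0)
    return float(1.0 - np.exp(np.sum(np.log(comp))))


def bag_probability(f: np.ndarray, variant: str = "weighted_noisy_or",
                    eps: float = EPS_CLIP) -> float:
    """Pool instance probabilities into a site probability F(B)."""
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if variant == "weighted_noisy_or":
        return weighted_noisy_or(f, rank_weights(f).weights, eps)
    if variant == "noisy_or":
        return standard_noisy_or(f, eps)
    if variant == "mean":
        return float(f.mean())
    if variant == "max":
        return float(f.max())
    raise ValueError(f"unknown pooling variant {variant!r}; choose from {POOLING_VARIANTS}")


def bag_probability_grad(f: np.ndarray, variant: str = "weighted_noisy_or",
                         eps: float = EPS_CLIP) -> tuple[float, np.ndarray]:
    """(F, dF/df) for the chosen pooling variant.

    Rank weights are recomputed from f but treated as constants — gradients
    do not flow through the sort.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    k = f.shape[0]
    if variant in ("weighted_noisy_or", "noisy_or"):
        w = rank_weights(f).weights if variant == "weighted_noisy_or" else np.ones(k)
        comp = np.clip(1.0 - f, eps, 1.0)
        G = np.exp(np.sum(w * np.log(comp)))
        grad = np.where((f >= 0.0) & (f <= 1.0 - eps), G * w / comp, 0.0)
        return float(1.0 - G), grad
    if variant == "mean":
        return float(f.mean()), np.full(k, 1.0 / k)
    if variant == "max":
        grad = np.zeros(k)
        grad[int(np.argmax(f))] = 1.0
        return float(f.max()), grad
    raise ValueError(f"unknown pooling variant {variant!r}; choose from {POOLING_VARIANTS}")


def select_reliable_negatives(unlabeled_bag_probs: dict[str, float],
                              n_pos: int) -> set[str]:
    """The n_pos unlabeled bags with the lowest F(B); enforces |R| = |P|.

    Ties at the cutoff are broken by bag_id order, so the selection is
    deterministic on rerun.
    """
    if len(unlabeled_bag_probs) < n_pos:
        raise ValueError(
            f"need {n_pos} reliable negatives but only "
            f"{len(unlabeled_bag_probs)} unlabeled bags available"
        )
    ordered = sorted(unlabeled_bag_probs.items(), key=lambda kv: (kv[1], kv[0]))
    return {bag_id for bag_id, _ in ordered[:n_pos]}


def loss_pu(F_pos: np.ndarray, F_relneg: np.ndarray, platt_params: PlattParams,
            lam: float, eps: float = EPS_CLIP) -> float:
    """PU negative log-likelihood over positives and reliable negatives.

    L_p = -[sum log F_pos + sum log(1 - F_relneg)] + lam * (alpha^2 + beta^2).
    The sets must be balanced (|R| = |P| is the selection contract).
    """
    F_pos = np.asarray(F_pos, dtype=float)
    F_relneg = np.asarray(F_relneg, dtype=float)
    if F_pos.shape[0] != F_relneg.shape[0]:
        raise ValueError(
            f"unbalanced PU loss: {F_pos.shape[0]} positives vs "
            f"{F_relneg.shape[0]} reliable negatives"
        )
    Fp = np.clip(F_pos, eps, 1.0 - eps)
    Fn = np.clip(F_relneg, eps, 1.0 - eps)
    nll = -(np.sum(np.log(Fp)) + np.sum(np.log(1.0 - Fn)))
    return float(nll + lam * (platt_params.alpha ** 2 + platt_params.beta ** 2))


def total_loss(L_m: float, L_p: float) -> float:
    """Overall training objective L = L_m + L_p."""
    return float(L_m) + float(L_p)
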