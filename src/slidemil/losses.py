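"""Loss and activation functions for imbalance-aware slide classification.

The three-tier recurrence-risk cohort is heavily imbalanced (the medium tier
is roughly 10% of cases), so the bag-level objective is a class-weighted
focal loss

    FL(p_t) = -alpha_t * (1 - p_t)**gamma * log(p_t)

optionally combined with label smoothing, y' = (1 - eps) * y + eps / K.
When both are active the loss is the soft-target form
``sum_c y'_c * (-alpha_c (1 - p_c)**gamma log p_c)``, which reduces to the
hard focal loss at eps = 0 and to smoothed cross-entropy at gamma = 0.

Two parallel surfaces are provided: plain-numpy scalar evaluators (used for
analysis and as oracles) and autodiff-graph versions operating on logits
(used in training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .autodiff import Tensor

EPS_NUM = 1e-7  # probability clamp before log


@dataclass
class FocalParams:
    """Per-class weights ``alpha`` and focusing exponent ``gamma`` (>= 0)."""

    alpha: np.ndarray = field(default_factory=lambda: np.array([1.0, 3.0, 1.0]))
    gamma: float = 2.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be positive elementwise")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class SmoothingParams:
    epsilon: float = 0.1
    n_classes: int = 3

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must lie in [0, 1)")


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-4:
        raise ValueError("class_probs must be a probability vector")
    return np.clip(probs, EPS_NUM, 1.0 - EPS_NUM)


def smooth_labels(onehot: np.ndarray, params: SmoothingParams) -> np.ndarray:
    """Blend a one-hot target toward uniform: y' = (1-eps) y + eps/K."""
    y = np.asarray(onehot, dtype=float)
    if y.shape != (params.n_classes,):
        raise ValueError("one-hot length does not match n_classes")
    if not (np.isclose(y.sum(), 1.0) and set(np.unique(y)) <= {0.0, 1.0}):
        raise ValueError("input is not one-hot")
    return (1.0 - params.epsilon) * y + params.epsilon / params.n_classes


def focal_loss(class_probs: np.ndarray, target, params: FocalParams) -> float:
    """Focal loss for a hard class index or a soft target vector."""
    p = _check_probs(class_probs)
    per_class = -params.alpha * (1.0 - p) ** params.gamma * np.log(p)
    if np.isscalar(target) or np.asarray(target).ndim == 0:
        return float(per_class[int(target)])
    y = np.asarray(target, dtype=float)
    if y.shape != p.shape:
        raise ValueError("soft target length mismatch")
    return float(np.dot(y, per_class))


def weighted_ce(class_probs: np.ndarray, target: int, weights: np.ndarray) -> float:
    """Class-weighted cross-entropy, -w_c log p_c, for a hard target."""
    p = _check_probs(class_probs)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(-w[int(target)] * np.log(p[int(target)]))


def gelu(x, mode: str = "exact"):
    """Gaussian error linear unit, x * Phi(x); ``mode='tanh'`` uses the
    common tanh approximation ``0.5 x (1 + tanh(sqrt(2/pi)(x + 0.044715 x^3)))``."""
    x = np.asarray(x, dtype=float)
    if mode == "exact":
        return x * ndtr(x)
    if mode == "tanh":
        return 0.5 * x * (1.0 + np.tanh(np.sqrt(2.0 / np.pi) * (x + 0.044715 * x ** 3)))
    raise ValueError(f"unknown gelu mode {mode!r}")


# ---------------------------------------------------------------------------
# Autodiff-graph losses on logits (training path)
# ---------------------------------------------------------------------------

def focal_loss_on_logits(logits: Tensor, target_soft: np.ndarray, params: FocalParams) -> Tensor:
    """Soft-target focal loss on a length-K logit tensor (differentiable)."""
    p = logits.softmax(axis=-1).clip(EPS_NUM, 1.0 - EPS_NUM)
    y = np.asarray(target_soft, dtype=float)
    modulator = (1.0 - p) ** params.gamma if params.gamma > 0 else 1.0
    per_class = -1.0 * (p.log() * modulator) * Tensor(params.alpha)
    return (per_class * Tensor(y)).sum()


def weighted_ce_on_logits(logits: Tensor, target: int, weights: np.ndarray) -> Tensor:
    """Weighted cross-entropy on logits (differentiable)."""
    p = logits.softmax(axis=-1).clip(EPS_NUM, 1.0 - EPS_NUM)
    onehot = np.zeros(logits.shape[-1])
    onehot[int(target)] = 1.0
    w = np.asarray(weights, dtype=float)
    return -1.0 * ((p.log() * Tensor(onehot * w)).sum())


def bce_on_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against 0/1 targets."""
    p = logits.sigmoid().clip(EPS_NUM, 1.0 - EPS_NUM)
    t = np.asarray(targets, dtype=float)
    losses = -1.0 * (Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log())
    return losses.mean()


def make_bag_loss(kind: str, params: FocalParams, smoothing: SmoothingParams | None):
    """Return ``loss(logits, tier) -> Tensor`` for a named bag-loss kind.

    kinds: ``focal`` (soft-target focal, optionally smoothed), ``weighted_ce``,
    ``ce`` (uniform weights), ``ce_smoothed`` (gamma=0 focal with smoothing).
    """
    n_classes = len(params.alpha)

    def target_vec(tier: int) -> np.ndarray:
        onehot = np.zeros(n_classes)
        onehot[tier] = 1.0
        if smoothing is not None and smoothing.epsilon > 0:
            return smooth_labels(onehot, smoothing)
        return onehot

    if kind == "focal":
        return lambda logits, tier: focal_loss_on_logits(logits, target_vec(tier), params)
    if kind == "weighted_ce":
        return lambda logits, tier: weighted_ce_on_logits(logits, tier, params.alpha)
    if kind == "ce":
        ones = np.ones(n_classes)
        return lambda logits, tier: weighted_ce_on_logits(logits, tier, ones)
    if kind == "ce_smoothed":
        flat = FocalParams(alpha=np.ones(n_classes), gamma=0.0)
        return lambda logits, tier: focal_loss_on_logits(logits, target_vec(tier), flat)
    raise ValueError(f"unknown loss kind {kind!r}")
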