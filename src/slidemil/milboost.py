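"""Attention-pool + gradient-boosted-tree slide classifier.

Stage 2 of the three-stage pipeline is a simple (ungated) tanh attention
network: instance scores are softmax-normalized and the slide embedding is
the attention-weighted sum ``S = sum_i a_i x_i``; a small linear head on S
yields MIL logits/probabilities and is trained with focal loss.

Stage 3 summarizes each slide as a 23-dimensional "enhanced feature" vector
(MIL logits and probabilities, patch count, attention-weight statistics and
distribution descriptors) and classifies it with an XGBoost multiclass model
(softmax objective, 200 trees, learning rate 0.1, depth 6; regularization
``Omega(f) = gamma * T + 0.5 * lambda * ||w||^2``).

The paper-style pipeline names the 23-feature set without enumerating it;
the fixed order defined in ``ENHANCED_FEATURE_NAMES`` is this package's
normative reconstruction covering every named category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .autodiff import Tensor
from .bags import FeatureBag
from .nn import AttentionOutput, Linear, Module

ENHANCED_FEATURE_NAMES: tuple[str, ...] = (
    "mil_logit_low", "mil_logit_medium", "mil_logit_high",
    "mil_prob_low", "mil_prob_medium", "mil_prob_high",
    "log1p_n_patches",
    "attn_mean", "attn_sd", "attn_min", "attn_max", "attn_median",
    "attn_entropy", "attn_entropy_norm", "attn_gini", "attn_top1", "attn_top5_mass",
    "attn_skewness", "attn_excess_kurtosis", "attn_q25", "attn_q75", "attn_iqr",
    "attn_frac_above_mean",
)
assert len(ENHANCED_FEATURE_NAMES) == 23


@dataclass
class PoolConfig:
    input_dim: int = 1024
    attn_hidden: int = 256
    n_classes: int = 3
    seed: int = 0


@dataclass
class SlideEmbedding:
    S: np.ndarray  # length-D pooled vector
    attention: AttentionOutput
    mil_logits: np.ndarray  # length-K
    mil_probs: np.ndarray  # length-K simplex


@dataclass
class BoostConfig:
    n_trees: int = 200
    learning_rate: float = 0.1
    max_depth: int = 6
    reg_gamma: float = 0.0  # tree-split penalty gamma
    reg_lambda: float = 1.0  # leaf-weight penalty lambda
    seed: int = 0


class AttentionPool(Module):
    """Ungated tanh attention pooling with a linear classification head."""

    def __init__(self, config: PoolConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.attn_hidden_layer = Linear(rng, config.input_dim, config.attn_hidden)
        self.attn_out = Linear(rng, config.attn_hidden, 1)
        self.head = Linear(rng, config.input_dim, config.n_classes)

    @classmethod
    def from_config(cls, cfg: dict) -> "AttentionPool":
        return cls(PoolConfig(**cfg))

    def parameters(self):
        return [p for layer in (self.attn_hidden_layer, self.attn_out, self.head) for p in layer.params]

    def forward(self, bag: FeatureBag | np.ndarray, mode: str = "eval"):
        """Return (logits, AttentionOutput, pooled slide tensor)."""
        x = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(f"expected N x {self.config.input_dim} features, got {x.shape}")
        xt = Tensor(x)
        raw = self.attn_out(self.attn_hidden_layer(xt).tanh()).reshape(-1)
        weights = raw.softmax(axis=-1)
        pooled = (weights.reshape(1, -1) @ xt).reshape(-1)  # S = sum a_i x_i
        logits = self.head(pooled.reshape(1, -1)).reshape(-1)
        attention = AttentionOutput(weights=weights.data.copy(), raw_scores=raw.data.copy())
        return logits, attention, pooled

    def embed(self, bag: FeatureBag | np.ndarray) -> SlideEmbedding:
        logits, attention, pooled = self.forward(bag, mode="eval")
        probs = np.exp(logits.data - logits.data.max())
        probs = probs / probs.sum()
        return SlideEmbedding(
            S=pooled.data.copy(),
            attention=attention,
            mil_logits=logits.data.copy(),
            mil_probs=probs,
        )


def _gini(w: np.ndarray) -> float:
    """Gini coefficient of a nonnegative weight vector (0 for uniform)."""
    n = len(w)
    if n == 1 or w.sum() == 0:
        return 0.0
    sorted_w = np.sort(w)
    index = np.arange(1, n + 1)
    return float((2.0 * np.sum(index * sorted_w) - (n + 1) * sorted_w.sum()) / (n * sorted_w.sum()))


def enhanced_features(emb: SlideEmbedding, n_patches: int | None = None) -> np.ndarray:
    """The fixed-order 23-vector summarizing a slide for the boosted head."""
    a = np.asarray(emb.attention.weights, dtype=float)
    n = len(a) if n_patches is None else int(n_patches)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(np.where(a > 0, a * np.log(a), 0.0)))
    entropy_norm = entropy / np.log(n) if n > 1 else 0.0
    top = np.sort(a)[::-1]
    skew = float(stats.skew(a)) if len(a) > 2 and a.std() > 0 else 0.0
    kurt = float(stats.kurtosis(a)) if len(a) > 3 and a.std() > 0 else 0.0
    q25, q75 = np.percentile(a, [25, 75])
    vec = np.concatenate([
        emb.mil_logits,
        emb.mil_probs,
        [np.log1p(n)],
        [a.mean(), a.std(), a.min(), a.max(), np.median(a),
         entropy, entropy_norm, _gini(a), top[0], top[:5].sum()],
        [skew, kurt, q25, q75, q75 - q25, float(np.mean(a > a.mean()))],
    ])
    assert vec.shape == (23,)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite enhanced feature")
    return vec


def fit_boosted(features: np.ndarray, tiers: np.ndarray, config: BoostConfig | None = None):
    """Fit the multiclass boosted-tree head on M x 23 enhanced features."""
    from xgboost import XGBClassifier

    config = config or BoostConfig()
    features = np.asarray(features, dtype=float)
    tiers = np.asarray(tiers, dtype=int)
    n_classes = 3
    present = np.unique(tiers)
    if len(present) < n_classes:
        raise ValueError(f"training data covers classes {present.tolist()}, need all of 0..{n_classes - 1}")
    clf = XGBClassifier(
        n_estimators=config.n_trees,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        gamma=config.reg_gamma,
        reg_lambda=config.reg_lambda,
        objective="multi:softprob",
        num_class=n_classes,
        random_state=config.seed,
        n_jobs=1,
        verbosity=0,
    )
    clf.fit(features, tiers)
    return clf


def boosted_importance(classifier) -> np.ndarray:
    """Per-feature gain importances, length 23 (zero for never-split features)."""
    booster = classifier.get_booster()
    score = booster.get_score(importance_type="gain")
    out = np.zeros(23)
    for key, val in score.items():
        out[int(key.lstrip("f"))] = val
    return out
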