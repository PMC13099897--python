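"""Gated multi-head attention-based MIL with class-specific attention.

Each of the (default eight) heads projects instance features into its own
representation space, forms a gated attention vector — ``tanh`` base branch
in a 256-dim attention space, modulated elementwise by a sigmoid gate — and
maps it linearly to one attention score per risk class. Head scores are
merged (elementwise mean) and normalized per class with a softmax **across
instances**, giving an N x K attention matrix whose columns are simplexes.

Aggregation is three-branch: instance features are pooled independently
under each class's attention column, yielding K class-specific bag vectors.
A shared bottleneck (D -> 512, GELU) compresses each branch, and a diagonal
per-class readout maps branch c's bottleneck output to logit c.

Mean gate activation is recorded per forward pass (``last_gate_mean``) so
training can log gate openness over epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, param
from .bags import FeatureBag
from .nn import Linear, Module


@dataclass
class AbmilConfig:
    input_dim: int = 768
    n_heads: int = 8
    attn_space: int = 256
    head_dim: int = 512
    n_classes: int = 3
    bottleneck: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")


@dataclass
class ClassAttention:
    """N x K attention matrix; every column is a simplex over instances."""

    weights: np.ndarray
    raw_scores: np.ndarray


class _Head:
    def __init__(self, rng, c: AbmilConfig):
        self.proj = Linear(rng, c.input_dim, c.head_dim)
        self.base = Linear(rng, c.head_dim, c.attn_space)  # tanh branch
        self.gate = Linear(rng, c.head_dim, c.attn_space)  # sigmoid gate
        self.score = Linear(rng, c.attn_space, c.n_classes)

    def __call__(self, x: Tensor) -> tuple[Tensor, float]:
        p = self.proj(x)
        base = self.base(p).tanh()
        gate = self.gate(p).sigmoid()
        scores = self.score(base * gate)  # N x K
        return scores, float(gate.data.mean())

    @property
    def params(self):
        return [p for layer in (self.proj, self.base, self.gate, self.score) for p in layer.params]


class Abmil(Module):
    def __init__(self, config: AbmilConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.heads = [_Head(rng, config) for _ in range(config.n_heads)]
        self.bottleneck = Linear(rng, config.input_dim, config.bottleneck)
        self.readout_w = param(rng.standard_normal((config.n_classes, config.bottleneck))
                               / np.sqrt(config.bottleneck))
        self.readout_b = param(np.zeros(config.n_classes))
        self.last_gate_mean: float = float("nan")

    @classmethod
    def from_config(cls, cfg: dict) -> "Abmil":
        return cls(AbmilConfig(**cfg))

    def parameters(self):
        out = [p for head in self.heads for p in head.params]
        out += self.bottleneck.params + [self.readout_w, self.readout_b]
        return out

    def class_attention(self, x: Tensor) -> tuple[Tensor, ClassAttention]:
        """Merged gated-head scores, softmax-normalized per class over instances."""
        scores_list, gate_means = [], []
        for head in self.heads:
            s, gm = head(x)
            scores_list.append(s)
            gate_means.append(gm)
        merged = scores_list[0]
        for s in scores_list[1:]:
            merged = merged + s
        merged = merged * (1.0 / len(scores_list))
        attn = merged.softmax(axis=0)  # columns: simplex over instances
        self.last_gate_mean = float(np.mean(gate_means))
        return attn, ClassAttention(weights=attn.data.copy(), raw_scores=merged.data.copy())

    def forward(self, bag: FeatureBag | np.ndarray, mode: str = "eval"):
        """Return (logits, ClassAttention, branch vectors K x D)."""
        x = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(f"expected N x {self.config.input_dim} features, got {x.shape}")
        xt = Tensor(x)
        attn, class_attn = self.class_attention(xt)
        branches = attn.T @ xt  # K x D, branch c = sum_i attn[i, c] x_i
        compressed = self.bottleneck(branches).gelu()  # K x bottleneck
        logits = (compressed * self.readout_w).sum(axis=1) + self.readout_b
        return logits, class_attn, branches


def three_branch_aggregate(bag_features: np.ndarray, attn: ClassAttention) -> np.ndarray:
    """Class-wise attention pooling: branch c = sum_i attn[i, c] * x_i (K x D)."""
    return np.asarray(attn.weights).T @ np.asarray(bag_features)
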