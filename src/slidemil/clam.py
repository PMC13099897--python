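"""Modified single-branch CLAM (clustering-constrained attention MIL).

The slide bag passes through three stages:

1. instance encoder: D -> 512 dense layer, GELU, dropout;
2. gated attention over instances in a 384-dim attention space,
   ``A = sigmoid(W_b h + b_b) * tanh(W_a h + b_a)``, projected to one score
   per instance and softmax-normalized across the bag;
3. a two-layer classifier on the attention-weighted slide vector
   (512 -> 256 GELU dropout -> 256 -> 3).

Relative to the canonical CLAM-SB this widens the attention space (256 ->
384), swaps ReLU for GELU, deepens the classifier with a 512 -> 256
reduction, and applies dropout independently to the encoder, attention, and
classifier modules.

The auxiliary clustering constraint pseudo-labels the k highest-attention
instances positive and the k lowest negative and scores them with a binary
instance classifier (plain BCE); the total objective mixes bag and instance
losses via ``bag_weight``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .bags import FeatureBag
from .losses import bce_on_logits
from .nn import AttentionOutput, Linear, Module, dropout


@dataclass
class ClamConfig:
    input_dim: int = 1024
    encoder_hidden: int = 512
    attn_hidden: int = 384
    cls_hidden: int = 256
    n_classes: int = 3
    dropout: float = 0.4
    k_sample: int = 8
    bag_weight: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 <= self.bag_weight <= 1.0:
            raise ValueError("bag_weight must lie in [0, 1]")


class ClamSB(Module):
    def __init__(self, config: ClamConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.enc = Linear(rng, c.input_dim, c.encoder_hidden)
        self.attn_a = Linear(rng, c.encoder_hidden, c.attn_hidden)  # tanh branch
        self.attn_b = Linear(rng, c.encoder_hidden, c.attn_hidden)  # sigmoid gate
        self.attn_out = Linear(rng, c.attn_hidden, 1)
        self.cls1 = Linear(rng, c.encoder_hidden, c.cls_hidden)
        self.cls2 = Linear(rng, c.cls_hidden, c.n_classes)
        self.inst_cls = Linear(rng, c.encoder_hidden, 1)  # binary instance classifier
        self._drop_rng = np.random.default_rng(config.seed + 1)

    @classmethod
    def from_config(cls, cfg: dict) -> "ClamSB":
        return cls(ClamConfig(**cfg))

    def parameters(self):
        layers = [self.enc, self.attn_a, self.attn_b, self.attn_out, self.cls1, self.cls2, self.inst_cls]
        return [p for layer in layers for p in layer.params]

    def forward(self, bag: FeatureBag | np.ndarray, mode: str = "eval"):
        """Return (logits, AttentionOutput, instance_embeddings).

        ``mode='eval'`` disables dropout and is deterministic; permuting bag
        rows leaves the logits unchanged.
        """
        x = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(f"expected N x {self.config.input_dim} features, got {x.shape}")
        train = mode == "train"
        rng = self._drop_rng
        rate = self.config.dropout

        h = dropout(self.enc(Tensor(x)).gelu(), rate, rng, train)
        a = dropout(self.attn_a(h).tanh(), rate, rng, train)
        g = dropout(self.attn_b(h).sigmoid(), rate, rng, train)
        raw = self.attn_out(a * g).reshape(-1)  # length N
        weights = raw.softmax(axis=-1)
        slide = weights.reshape(1, -1) @ h  # 1 x encoder_hidden
        z = dropout(self.cls1(slide).gelu(), rate, rng, train)
        logits = self.cls2(z).reshape(-1)
        attention = AttentionOutput(weights=weights.data.copy(), raw_scores=raw.data.copy())
        return logits, attention, h

    def instance_cluster_loss(
        self, attention: AttentionOutput, instance_embeddings: Tensor, k_sample: int | None = None
    ) -> Tensor:
        """BCE on top-k (pseudo-positive) / bottom-k (pseudo-negative) instances."""
        k = self.config.k_sample if k_sample is None else k_sample
        n = len(attention.raw_scores)
        k_eff = max(1, min(k, n))
        order = np.argsort(attention.raw_scores, kind="stable")
        bottom, top = order[:k_eff], order[-k_eff:]
        idx = np.concatenate([top, bottom])
        targets = np.concatenate([np.ones(k_eff), np.zeros(k_eff)])
        inst_logits = self.inst_cls(instance_embeddings.take_rows(idx)).reshape(-1)
        return bce_on_logits(inst_logits, targets)


def clam_total_loss(bag_loss: Tensor, inst_loss: Tensor, bag_weight: float) -> Tensor:
    """bag_weight * bag_loss + (1 - bag_weight) * inst_loss."""
    return bag_weight * bag_loss + (1.0 - bag_weight) * inst_loss
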