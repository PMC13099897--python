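"""Shared neural building blocks for the MIL models: dense layers, dropout,
attention output container, and single-file checkpoints (.npz with the model
config embedded as JSON)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .autodiff import Tensor, glorot, param


@dataclass
class AttentionOutput:
    """Post-softmax instance weights (simplex over the bag) and raw scores."""

    weights: np.ndarray
    raw_scores: np.ndarray


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = glorot(rng, d_in, d_out)
        self.b = param(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    """Inverted dropout; identity in eval mode or at rate 0."""
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class Module:
    """Base class handling parameter collection and checkpoint round trips."""

    config: object  # dataclass

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float64).copy()

    def save(self, path) -> None:
        from dataclasses import asdict

        cfg = json.dumps(asdict(self.config))
        np.savez(Path(path), __config__=np.array(cfg), **self.state_dict())

    @classmethod
    def load(cls, path) -> "Module":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            state = {k: data[k] for k in data.files if k != "__config__"}
        model = cls.from_config(cfg)  # type: ignore[attr-defined]
        model.load_state_dict(state)
        return model


def export_attention(path, scores: np.ndarray, coords: np.ndarray) -> None:
    """Write per-patch attention scores aligned to bag coordinates as HDF5."""
    scores = np.asarray(scores, dtype=np.float32)
    with h5py.File(Path(path), "w") as fh:
        fh.create_dataset("scores", data=scores)
        fh.create_dataset("coords", data=np.asarray(coords, dtype=np.int64))
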