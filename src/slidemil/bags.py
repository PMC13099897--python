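"""Per-slide feature bags: pluggable patch encoders and HDF5 persistence.

A slide is reduced to a *bag*: an N x D matrix of patch-feature vectors plus
the level-0 coordinate of each patch and the slide-level risk tier. The bag
is the universal currency between preprocessing and the MIL classifiers.

Encoders are pluggable behind :class:`PatchEncoder`; pathology foundation
models (UNI/CONCH-style, typically D = 1024 or 768) slot in through the same
interface via user-supplied adapters. Two deterministic stub encoders ship
with the package so the whole pipeline runs without pretrained weights:
``identity_stats`` (per-channel pixel statistics, zero-padded to D) and
``seeded_projection`` (fixed random linear map of downsampled pixels).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import h5py
import numpy as np
from skimage.transform import resize

from .preprocess import PatchGrid
from .slide import ArraySlide


class BagSchemaError(ValueError):
    """Raised when a bag container is missing required datasets/attributes."""


class PatchEncoder(Protocol):
    name: str
    output_dim: int
    expected_input: int

    def encode(self, patches: np.ndarray) -> np.ndarray:
        """Encode a B x H x W x 3 uint8 batch into B x D floats."""
        ...


@dataclass
class FeatureBag:
    case_id: str
    features: np.ndarray  # N x D float32
    coords: np.ndarray  # N x 2 int64, level-0 (x, y)
    tier: int
    encoder_name: str = "unknown"
    patch_size: int = 256
    level: int = 0

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a nonempty N x D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must align row-wise with features")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


class _IdentityStatsEncoder:
    """Per-channel mean, then SD, of each patch; zero-padded to output_dim."""

    def __init__(self, output_dim: int, expected_input: int = 256):
        if output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        self.name = "identity_stats"
        self.output_dim = output_dim
        self.expected_input = expected_input

    def encode(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float64) / 255.0
        means = x.mean(axis=(1, 2))  # B x 3
        sds = x.std(axis=(1, 2))
        stats = np.concatenate([means, sds], axis=1)
        out = np.zeros((x.shape[0], self.output_dim), dtype=np.float32)
        k = min(self.output_dim, stats.shape[1])
        out[:, :k] = stats[:, :k]
        return out


class _SeededProjectionEncoder:
    """Fixed seeded random linear map of 16x16-downsampled pixels to D dims."""

    _GRID = 16

    def __init__(self, output_dim: int, seed: int, expected_input: int = 256):
        if output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        self.name = f"seeded_projection_{seed}"
        self.output_dim = output_dim
        self.expected_input = expected_input
        rng = np.random.default_rng(seed)
        n_in = self._GRID * self._GRID * 3
        self._W = rng.standard_normal((n_in, output_dim)) / np.sqrt(n_in)

    def encode(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float64) / 255.0
        out = np.empty((x.shape[0], self.output_dim), dtype=np.float32)
        for i, patch in enumerate(x):
            small = resize(patch, (self._GRID, self._GRID), anti_aliasing=True)
            out[i] = small.ravel() @ self._W
        return out


def make_stub_encoder(kind: str, output_dim: int, seed: int = 0) -> PatchEncoder:
    if kind == "identity_stats":
        return _IdentityStatsEncoder(output_dim)
    if kind == "seeded_projection":
        return _SeededProjectionEncoder(output_dim, seed)
    raise ValueError(f"unknown stub encoder kind {kind!r}")


def encode_slide(
    slide: ArraySlide,
    grid: PatchGrid,
    encoder: PatchEncoder,
    case_id: str,
    tier: int,
    batch_size: int = 64,
) -> FeatureBag:
    """Encode every grid patch of a slide into one feature bag.

    Row order follows grid order exactly and is independent of batching.
    """
    if len(grid.coords) == 0:
        raise ValueError("patch grid is empty")
    ps = grid.patch_size
    rows = []
    for start in range(0, len(grid.coords), batch_size):
        batch_coords = grid.coords[start : start + batch_size]
        patches = []
        for x, y in batch_coords:
            try:
                region = slide.read_region((int(x), int(y)), 0, (ps, ps))
            except Exception as exc:
                raise RuntimeError(f"failed to read patch at ({x}, {y})") from exc
            if ps != encoder.expected_input:
                region = np.clip(
                    resize(region, (encoder.expected_input, encoder.expected_input),
                           anti_aliasing=True, preserve_range=True),
                    0, 255,
                ).astype(np.uint8)
            patches.append(region)
        rows.append(encoder.encode(np.stack(patches)))
    features = np.concatenate(rows, axis=0)
    return FeatureBag(
        case_id=case_id,
        features=features,
        coords=np.asarray(grid.coords, dtype=np.int64),
        tier=tier,
        encoder_name=encoder.name,
        patch_size=ps,
        level=grid.level,
    )


def write_bag(bag: FeatureBag, path) -> None:
    """Persist a bag as HDF5: datasets 'features', 'coords' + attributes."""
    with h5py.File(Path(path), "w") as fh:
        fh.create_dataset("features", data=bag.features.astype(np.float32))
        fh.create_dataset("coords", data=bag.coords.astype(np.int64))
        fh.attrs["case_id"] = bag.case_id
        fh.attrs["tier"] = int(bag.tier)
        fh.attrs["encoder_name"] = bag.encoder_name
        fh.attrs["patch_size"] = int(bag.patch_size)
        fh.attrs["level"] = int(bag.level)


def read_bag(path) -> FeatureBag:
    with h5py.File(Path(path), "r") as fh:
        for ds in ("features", "coords"):
            if ds not in fh:
                raise BagSchemaError(f"{path}: missing dataset {ds!r}")
        for attr in ("case_id", "tier"):
            if attr not in fh.attrs:
                raise BagSchemaError(f"{path}: missing attribute {attr!r}")
        return FeatureBag(
            case_id=str(fh.attrs["case_id"]),
            features=fh["features"][...],
            coords=fh["coords"][...],
            tier=int(fh.attrs["tier"]),
            encoder_name=str(fh.attrs.get("encoder_name", "unknown")),
            patch_size=int(fh.attrs.get("patch_size", 256)),
            level=int(fh.attrs.get("level", 0)),
        )
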