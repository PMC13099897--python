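"""Run configuration: YAML schema, defaults, validation, seed fan-out.

A run is described by a nested config (``preprocess``, ``encoder``,
``model``, ``train``, ``heatmap``, ``synth`` sections plus a global ``seed``
and ``output_dir``). Every key must be known — misspelled keys raise — and
the resolved config is serialized alongside run outputs. The single global
seed fans out to per-stage seeds by hashing the stage name, so stages are
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"bad value in section {section!r}: {exc}") from exc


@dataclass
class PreprocessSection:
    target_downsample: float = 32.0
    patch_size: int = 256
    tissue_coverage_min: float = 0.5
    use_morph_gradient: bool = True


@dataclass
class EncoderSection:
    kind: str = "identity_stats"  # identity_stats | seeded_projection
    dim: int = 64
    batch_size: int = 64


@dataclass
class ModelSection:
    kind: str = "clam_sb"  # clam_sb | abmil | milboost


@dataclass
class TrainSection:
    lr: float | None = None  # None -> per-model default (clam_sb 3e-5, abmil 4e-4)
    weight_decay: float = 1e-4
    max_epochs: int | None = None
    warmup_epochs: int = 5
    early_stop_patience: int | None = None
    loss_kind: str | None = None
    folds: int = 5


@dataclass
class HeatmapSection:
    render_downsample: float = 32.0
    overlay_alpha: float = 0.4
    mode: str = "gaussian"


@dataclass
class SynthSection:
    n_cases: int = 60
    dim: int = 64
    effect_size: float = 2.0
    signal_fraction: float = 0.3
    bag_min: int = 16
    bag_max: int = 64


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/default"
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    encoder: EncoderSection = field(default_factory=EncoderSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    heatmap: HeatmapSection = field(default_factory=HeatmapSection)
    synth: SynthSection = field(default_factory=SynthSection)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


_SECTIONS = {
    "preprocess": PreprocessSection,
    "encoder": EncoderSection,
    "model": ModelSection,
    "train": TrainSection,
    "heatmap": HeatmapSection,
    "synth": SynthSection,
}


def parse_and_validate(config_file=None, cli_overrides: dict | None = None) -> RunConfig:
    """Load YAML (all defaults when absent/empty), apply dotted CLI overrides."""
    data: dict = {}
    if config_file is not None:
        raw = Path(config_file).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    for dotted, value in (cli_overrides or {}).items():
        parts = dotted.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value

    top_known = {"seed", "output_dir", *_SECTIONS}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _from_dict(cls, section, name)
    return RunConfig(
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "runs/default")),
        **kwargs,
    )


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
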