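"""Run configuration: YAML in, dataclasses out, with study defaults.

Every default mirrors the simulation protocol: plug length 2-20 mm,
occlusion ratio 0.35-1.0, eligible airway caliber 1-20 mm, 50 plugs per
scan, 0.8 mm isotropic resampling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dataset_builder import TARGET_SPACING_MM
from .errors import ConfigError
from .intensity_transfer import AugmentConfig, TransferConfig
from .phantom import PhantomSpec
from .plug_synthesis import PlugSamplingConfig

__all__ = ["RunConfig", "DEFAULT_PLUGS_PER_SCAN", "COHORT_N_NEGATIVE_SCANS"]

DEFAULT_PLUGS_PER_SCAN = 50   # augmentation density selected by the count sweep
COHORT_N_NEGATIVE_SCANS = 83  # plug-negative scans used as synthesis substrate


@dataclass
class DatasetConfig:
    target_spacing_mm: float = TARGET_SPACING_MM
    patch_ratio: tuple[int, int] = (1, 1)
    patch_size: int = 96


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    plugs: PlugSamplingConfig = field(default_factory=PlugSamplingConfig)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    plugs_per_scan: int = DEFAULT_PLUGS_PER_SCAN
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, key):
            section = raw.get(key, {})
            if not isinstance(section, dict):
                raise ConfigError(f"config section '{key}' must be a mapping")
            try:
                return klass(**{k: _tupled(v) for k, v in section.items()})
            except TypeError as exc:
                raise ConfigError(f"config section '{key}': {exc}") from exc

        return cls(
            phantom=build(PhantomSpec, "phantom"),
            plugs=build(PlugSamplingConfig, "plugs"),
            transfer=build(TransferConfig, "transfer"),
            augment=build(AugmentConfig, "augment"),
            dataset=build(DatasetConfig, "dataset"),
            plugs_per_scan=int(raw.get("plugs_per_scan", DEFAULT_PLUGS_PER_SCAN)),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "phantom": asdict(self.phantom),
            "plugs": asdict(self.plugs),
            "transfer": asdict(self.transfer),
            "augment": asdict(self.augment),
            "dataset": asdict(self.dataset),
            "plugs_per_scan": self.plugs_per_scan,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self, seed: int | None = None) -> dict:
        from . import __version__

        return {
            "config_hash": self.config_hash,
            "seed": self.seed if seed is None else seed,
            "version": __version__,
        }


def _tupled(v):
    return tuple(v) if isinstance(v, list) else v
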