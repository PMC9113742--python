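"""Pipeline configuration: one JSON document with per-stage sections.

Every tunable default of the pipeline is mirrored here so a single config
file (plus one global seed) reproduces an entire run.  Unknown keys are
rejected loudly — a typo in a threshold name must not silently fall back to
a default — and configs round-trip exactly (load -> save -> load).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .segment import SegmentConfig
from .synth import WormVideoParams

__all__ = ["KymographConfig", "LeakConfig", "SurvivalConfig", "StatsConfig",
           "ConservationConfig", "PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Malformed configuration (unknown key, wrong type, bad value)."""


@dataclass
class KymographConfig:
    band_width: float = 3.0
    inset: float = 1.0
    f0_method: str = "percentile"
    f0_percentile: float = 10.0
    detrend: bool = False
    k_thresh: float = 4.0           # MAD multiples
    min_duration: float = 0.3       # s
    min_amplitude: float = 0.05     # absolute ΔF/F0 detection floor
    merge_radius: float = 0.05      # perimeter fraction
    merge_gap: float = 0.2          # s
    caffeine_window: float = 10.0   # s
    caffeine_k_thresh: float = 3.0


@dataclass
class LeakConfig:
    settle: float = 10.0            # s of sustained flatness defining plateau
    tol_frac: float = 0.01          # fraction of peak uptake slope


@dataclass
class SurvivalConfig:
    method: str = "asymptotic"
    n_perm: int = 10000


@dataclass
class StatsConfig:
    log_ratio: bool = False
    alpha: float = 0.05


@dataclass
class ConservationConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class PipelineConfig:
    """All stage settings plus the global seed and output directory."""

    seed: int = 0
    output_dir: str = "wormcal_out"
    verbosity: int = 1
    video: WormVideoParams = field(default_factory=WormVideoParams)
    segmentation: SegmentConfig = field(default_factory=SegmentConfig)
    kymograph: KymographConfig = field(default_factory=KymographConfig)
    leak: LeakConfig = field(default_factory=LeakConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    conservation: ConservationConfig = field(default_factory=ConservationConfig)

    _SECTIONS = {
        "video": WormVideoParams,
        "segmentation": SegmentConfig,
        "kymograph": KymographConfig,
        "leak": LeakConfig,
        "survival": SurvivalConfig,
        "stats": StatsConfig,
        "conservation": ConservationConfig,
    }

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "output_dir": self.output_dir,
             "verbosity": self.verbosity}
        for name in self._SECTIONS:
            sec = dataclasses.asdict(getattr(self, name))
            # tuples do not survive JSON; normalise to lists for round-trip
            d[name] = {k: list(v) if isinstance(v, tuple) else v
                       for k, v in sec.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for key in ("seed", "output_dir", "verbosity"):
            if key in data:
                kwargs[key] = data.pop(key)
        for name, section_cls in cls._SECTIONS.items():
            if name not in data:
                continue
            section = data.pop(name)
            valid = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(section) - valid
            if unknown:
                raise ConfigError(
                    f"unknown key(s) {sorted(unknown)} in config section {name!r}"
                )
            if "image_size" in section and isinstance(section["image_size"], list):
                section["image_size"] = tuple(section["image_size"])
            kwargs[name] = section_cls(**section)
        if data:
            raise ConfigError(f"unknown top-level config key(s): {sorted(data)}")
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        return cls.from_dict(data)
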