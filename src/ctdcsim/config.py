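"""Run configuration: a sectioned YAML schema with strict key checking.

Silent typos in tolerance or cap names are the classic pipeline failure mode,
so unknown keys anywhere in the file are errors, and the resolved config
(with a format-version tag and content hash) is embedded in every run report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]

FORMAT_VERSION = "ctdcsim-config-1"


@dataclass
class PhantomConfig:
    shells: list[dict] = field(
        default_factory=lambda: [
            {"name": "scalp", "outer_radius": 92.0, "conductivity": 0.465},
            {"name": "skull", "outer_radius": 86.0, "conductivity": 0.010},
            {"name": "csf", "outer_radius": 81.0, "conductivity": 1.654},
            {"name": "gray", "outer_radius": 79.0, "conductivity": 0.276},
            {"name": "white", "outer_radius": 67.0, "conductivity": 0.126},
        ]
    )
    resolution: float = 8.0
    n_lobules: int = 28
    seed: int = 0


@dataclass
class GridConfig:
    voxel_size: float = 1.0


@dataclass
class CatalogConfig:
    scheme: str = "quasi-uniform"
    n: int = 8
    reference_id: str = "Cz"
    disc_radius_cm: float = 0.5


@dataclass
class SolverConfig:
    method: str = "auto"
    tol: float = 1e-8
    maxiter: int = 10000


@dataclass
class OptimizeConfig:
    regions: list[str] = field(
        default_factory=lambda: ["Right_VIIb", "Right_VIIIa", "Right_VIIIb", "Right_IX"]
    )
    direction: str = "Z"
    magnitude: float = 0.1
    spillover_weight: float = 1.0
    total_cap_ma: float = 4.0
    per_electrode_cap_ma: float | None = None


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    optimize: OptimizeConfig = field(default_factory=OptimizeConfig)
    format_version: str = FORMAT_VERSION

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


_SECTIONS = {
    "phantom": PhantomConfig,
    "grid": GridConfig,
    "catalog": CatalogConfig,
    "solver": SolverConfig,
    "optimize": OptimizeConfig,
}


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    version = raw.pop("format_version", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported config format {version!r}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        body = raw.get(section, {}) or {}
        allowed = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        bad = set(body) - allowed
        if bad:
            raise ValueError(
                f"{path}: unknown keys {sorted(bad)} in section {section!r} "
                f"(allowed: {sorted(allowed)})"
            )
        kwargs[section] = cls(**body)
    return RunConfig(**kwargs, format_version=version)


def save_config(path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
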