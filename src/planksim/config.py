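"""YAML/JSON run configuration with strict key validation.

Every default equals the printed parameter values used throughout the
package, so an empty config file reproduces the reference runs exactly.
Unknown keys are rejected with the offending dotted path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import SchemaError


@dataclass
class SpectrumConfig:
    xi: float = 4.5
    prochlorococcus: float = 2e4  # cells ml^-1 in the calibration bin
    bin_low: float = 0.6
    bin_high: float = 0.8
    d0: float = 1.0
    dmin: float = 0.6
    dmax: float = 500.0
    carbon_model: str = "non_diatom"


@dataclass
class GrowthConfig:
    D: float = 1500.0
    capture_eff: float = 0.9
    velocity_dialect: str = "bracket_only"
    element: str = "N"
    np_ratio: float = 16.0
    s_inf_nm: float = 1.0


@dataclass
class EcosystemConfig:
    g1: float = 3.24
    g2: float = 0.5
    g3: float = 0.06
    g4: float = 1.6
    dt: float = 1.0 / 96.0
    t_max: float = 1095.0
    extinct_frac: float = 1e-6
    p_init: float = 0.18
    z_init: float = 0.04
    n_classes: int = 25
    group: str = "non_diatom"
    multispecies: bool = False
    method: str = "analytic"
    m_loss: float = 0.0
    kappa: float = 0.0
    use_g4: bool = True
    per_generation_m: float = 0.0
    ward_init: bool = False


@dataclass
class RunConfig:
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    ecosystem: EcosystemConfig = field(default_factory=EcosystemConfig)
    output: str = "results"
    seed: int = 0  # affects synthetic fixtures only; the model is deterministic


_BLOCKS = {"spectrum": SpectrumConfig, "growth": GrowthConfig,
           "ecosystem": EcosystemConfig}
_SCALARS = {"output", "seed"}


def _build_block(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in allowed:
            raise SchemaError(f"unknown key '{path}.{key}'",
                              key_path=f"{path}.{key}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise SchemaError(f"invalid block '{path}': {exc}", key_path=path)


def from_dict(data: dict | None) -> RunConfig:
    """Validated RunConfig from a (possibly partial) plain mapping."""
    data = data or {}
    if not isinstance(data, dict):
        raise SchemaError("config root must be a mapping")
    cfg = RunConfig()
    for key, value in data.items():
        if key in _BLOCKS:
            if value is None:
                continue
            if not isinstance(value, dict):
                raise SchemaError(f"block '{key}' must be a mapping",
                                  key_path=key)
            setattr(cfg, key, _build_block(_BLOCKS[key], value, key))
        elif key in _SCALARS:
            setattr(cfg, key, value)
        else:
            raise SchemaError(f"unknown key '{key}'", key_path=key)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON, a YAML subset) config file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"unparseable config: {exc}")
    return from_dict(data)


def to_dict(cfg: RunConfig) -> dict:
    """Plain-dict form of a config (inverse of ``from_dict`` on defaults)."""
    return dataclasses.asdict(cfg)


def dump(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(to_dict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
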