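"""Run configuration: species parameters, λ defaults, solver settings.

YAML (or plain dict) based; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from ..biochem import SpeciesParams
from ..marginal_cost import CITRUS_LAMBDA_CO, CITRUS_LAMBDA_VC, CITRUS_LAMBDA_VJ

__all__ = ["RunConfig", "load_config"]

_SPECIES_KEYS = {f.name for f in dc_fields(SpeciesParams)}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    species: SpeciesParams = field(default_factory=SpeciesParams)
    lambda_co: float = CITRUS_LAMBDA_CO
    lambda_vc: float = CITRUS_LAMBDA_VC
    lambda_vj: float = CITRUS_LAMBDA_VJ
    trim_lo: float = 10.0
    trim_hi: float = 90.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("lambda_co", "lambda_vc", "lambda_vj"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.trim_lo < self.trim_hi <= 100.0:
            raise ValueError("trim bounds must satisfy 0 <= lo < hi <= 100")

    @property
    def trim(self) -> tuple[float, float]:
        return (self.trim_lo, self.trim_hi)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for run logs."""
        payload = {f.name: getattr(self, f.name) for f in dc_fields(self)
                   if f.name != "species"}
        payload["species"] = {k: getattr(self.species, k) for k in sorted(_SPECIES_KEYS)}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _from_dict(raw: Mapping[str, Any]) -> RunConfig:
    raw = dict(raw)
    species_raw = raw.pop("species", {})
    if not isinstance(species_raw, Mapping):
        raise ValueError("'species' must be a mapping of parameter names to values")
    unknown = set(species_raw) - _SPECIES_KEYS
    if unknown:
        raise ValueError(f"unknown species parameter key(s): {sorted(unknown)}")
    allowed = {f.name for f in dc_fields(RunConfig)} - {"species"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(species=SpeciesParams(**species_raw), **raw)


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a YAML run configuration; None yields the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return RunConfig()
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: top level must be a mapping")
    return _from_dict(raw)
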