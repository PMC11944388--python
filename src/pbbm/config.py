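"""Configuration loading: TOML or YAML files with drug/formulation/physiology/
disposition blocks, all defaulting to the apixaban model.

Every simulation entry point accepts the parameter objects directly; the
config layer exists for the CLI and for provenance (the resolved config is
echoed into run manifests).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .params import (
    DispositionParams,
    DrugProperties,
    FormulationSpec,
    GIPhysiology,
    apixaban,
    apixaban_disposition,
    default_physiology,
)

__all__ = ["PBBMConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class PBBMConfig:
    """Bundle of the four parameter blocks plus an optional formulation."""

    drug: DrugProperties
    physiology: GIPhysiology
    disposition: DispositionParams
    formulation: FormulationSpec | None = None

    def to_dict(self) -> dict:
        out = {
            "drug": dataclasses.asdict(self.drug),
            "physiology": dataclasses.asdict(self.physiology),
            "disposition": dataclasses.asdict(self.disposition),
        }
        if self.formulation is not None:
            out["formulation"] = dataclasses.asdict(self.formulation)
        return out

    def hash(self) -> str:
        """Stable sha256 of the resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def default_config() -> PBBMConfig:
    """The frozen apixaban model configuration."""
    return PBBMConfig(
        drug=apixaban(),
        physiology=default_physiology(),
        disposition=apixaban_disposition(),
    )


def _build(cls, defaults, block: dict):
    base = dataclasses.asdict(defaults) if defaults is not None else {}
    unknown = set(block) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    base.update(block)
    return cls(**base)


def load_config(path: str | Path) -> PBBMConfig:
    """Read a TOML (.toml) or YAML (.yml/.yaml) config.

    Recognized blocks: ``[drug] [formulation] [physiology] [disposition]``;
    missing blocks and keys fall back to the apixaban defaults.
    """
    path = Path(path)
    if path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    elif path.suffix in (".yml", ".yaml"):
        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
    unknown = set(raw) - {"drug", "formulation", "physiology", "disposition"}
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    drug = _build(DrugProperties, apixaban(), raw.get("drug", {}))
    physiology = _build(GIPhysiology, default_physiology(), raw.get("physiology", {}))
    disposition = _build(
        DispositionParams, apixaban_disposition(), raw.get("disposition", {})
    )
    formulation = None
    if "formulation" in raw:
        formulation = FormulationSpec(**raw["formulation"])
    return PBBMConfig(
        drug=drug,
        physiology=physiology,
        disposition=disposition,
        formulation=formulation,
    )
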