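"""Configuration files: TOML or YAML with blocks ``pk``, ``ae``,
``regimen`` and ``study``.

Keys may use either the dataclass field names or the conventional
upper-case parameter names (CL, V, KA, ALAG, F, B01 .. B22, EMAX0, EMAX1,
EC50, IIV, EMAX_SCALE, ASSESS_INTERVAL_DAYS).  Unknown keys raise, so
typos never silently fall back to defaults.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import yaml

from .ae import AEModelParameters
from .pk import DosingRegimen, PKParameters
from .scenarios import ScenarioConfig

__all__ = ["load_config", "scenario_config_from_dict"]

_PK_ALIASES = {
    "cl": "cl_typ",
    "v": "v_typ",
    "ka": "ka_typ",
    "f": "f_bio",
    "iiv_cl": "cv_cl",
    "iiv_v": "cv_v",
    "iiv_ka": "cv_ka",
}
_AE_ALIASES = {"iiv": "cv_ae"}
_REGIMEN_ALIASES = {"dose": "dose_amount"}
_STUDY_ALIASES = {
    "assess_interval_days": "assessment_interval_days",
    "replicates": "n_replicates",
    "n": "n_subjects",
}


def _normalise(block: dict, aliases: dict, valid: set, where: str) -> dict:
    out = {}
    for key, val in block.items():
        k = aliases.get(key.lower(), key.lower())
        if k not in valid:
            raise ValueError(f"unknown key {key!r} in [{where}]")
        out[k] = val
    return out


def _fields(cls) -> set:
    return set(cls.__dataclass_fields__)


def scenario_config_from_dict(raw: dict) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from nested config dictionaries."""
    unknown = set(raw) - {"pk", "ae", "regimen", "study"}
    if unknown:
        raise ValueError(f"unknown config blocks {sorted(unknown)}")
    pk = PKParameters(
        **_normalise(raw.get("pk", {}), _PK_ALIASES, _fields(PKParameters), "pk")
    )
    ae = AEModelParameters(
        **_normalise(raw.get("ae", {}), _AE_ALIASES, _fields(AEModelParameters), "ae")
    )
    regimen = DosingRegimen(
        **_normalise(
            raw.get("regimen", {}), _REGIMEN_ALIASES, _fields(DosingRegimen), "regimen"
        )
    )
    study_fields = _fields(ScenarioConfig) - {"pk", "ae", "regimen", "policies"}
    study = _normalise(raw.get("study", {}), _STUDY_ALIASES, study_fields, "study")
    return ScenarioConfig(pk=pk, ae=ae, regimen=regimen, **study)


def load_config(path) -> ScenarioConfig:
    """Read a TOML (.toml) or YAML (.yml/.yaml) configuration file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        raw = tomllib.loads(path.read_text())
    elif path.suffix.lower() in (".yml", ".yaml"):
        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
    return scenario_config_from_dict(raw)
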