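"""Configuration resolution.

Scenarios are configured from a flat key-value mapping (a YAML-compatible
subset): every tabulated model constant is a named, overridable key.  CLI
overrides beat file values, which beat the built-in defaults; unknown keys
are rejected with the list of valid names, and range validation happens in
the parameter dataclasses themselves.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import yaml

from .engine import Arm, ScenarioConfig
from .entities import CellType, PopulationParams
from .interactions import InteractionParams
from .lattice import ChemotaxisParams
from .repertoire import AffinityParams
from .tumor_growth import GompertzParams

__all__ = ["load_config", "config_to_dict", "VALID_KEYS"]

_AFFINITY_KEYS = {f.name for f in dataclasses.fields(AffinityParams)}
_INTERACTION_KEYS = {f.name for f in dataclasses.fields(InteractionParams)}
_CHEMOTAXIS_KEYS = {f.name for f in dataclasses.fields(ChemotaxisParams)}
_POPULATION_KEYS = {
    f.name for f in dataclasses.fields(PopulationParams) if f.name != "densities"
}
_DENSITY_KEYS = {f"density_{t.value}": t for t in CellType if t is not CellType.TUMOR}
_GOMPERTZ_KEYS = {"gompertz_a", "gompertz_b"}
_SCENARIO_KEYS = {
    f.name
    for f in dataclasses.fields(ScenarioConfig)
    if f.name not in ("gompertz", "affinity", "population", "interaction", "chemotaxis")
}

VALID_KEYS = sorted(
    _SCENARIO_KEYS
    | _AFFINITY_KEYS
    | _INTERACTION_KEYS
    | _CHEMOTAXIS_KEYS
    | _POPULATION_KEYS
    | set(_DENSITY_KEYS)
    | _GOMPERTZ_KEYS
)


def load_config(
    path: Optional[str | Path] = None, overrides: Optional[Mapping[str, Any]] = None
) -> ScenarioConfig:
    """Resolve a scenario from an optional YAML file plus overrides.

    An empty configuration yields the shipped defaults (the tabulated model
    constants).  Raises ``ValueError`` on unknown keys; out-of-range values
    raise from the parameter dataclasses, naming the offending key.
    """
    flat: Dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        flat.update(loaded)
    if overrides:
        flat.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(flat) - set(VALID_KEYS)
    if unknown:
        raise ValueError(
            f"unknown configuration keys: {sorted(unknown)}; valid keys are {VALID_KEYS}"
        )

    def take(keys) -> Dict[str, Any]:
        return {k: flat[k] for k in keys if k in flat}

    affinity = AffinityParams(**take(_AFFINITY_KEYS))
    interaction = InteractionParams(**take(_INTERACTION_KEYS))
    chemotaxis = ChemotaxisParams(**take(_CHEMOTAXIS_KEYS))

    pop_kwargs = take(_POPULATION_KEYS)
    dens = {t: v for k, t in _DENSITY_KEYS.items() if (v := flat.get(k)) is not None}
    if dens:
        base = dict(PopulationParams().densities)
        base.update(dens)
        pop_kwargs["densities"] = base
    population = PopulationParams(**pop_kwargs)

    from .engine import DEFAULT_GOMPERTZ

    gompertz = GompertzParams(
        a=float(flat.get("gompertz_a", DEFAULT_GOMPERTZ.a)),
        b=float(flat.get("gompertz_b", DEFAULT_GOMPERTZ.b)),
    )

    scen_kwargs = take(_SCENARIO_KEYS)
    if "arm" in scen_kwargs:
        scen_kwargs["arm"] = Arm(str(scen_kwargs["arm"]).upper())
    if "snapshot_days" in scen_kwargs:
        scen_kwargs["snapshot_days"] = tuple(scen_kwargs["snapshot_days"])
    return ScenarioConfig(
        gompertz=gompertz,
        affinity=affinity,
        population=population,
        interaction=interaction,
        chemotaxis=chemotaxis,
        **scen_kwargs,
    )


def config_to_dict(config: ScenarioConfig) -> Dict[str, Any]:
    """Flatten a resolved config back to the key-value form (manifest echo)."""
    out: Dict[str, Any] = {}
    for f in dataclasses.fields(ScenarioConfig):
        v = getattr(config, f.name)
        if f.name == "gompertz":
            out["gompertz_a"], out["gompertz_b"] = v.a, v.b
        elif f.name in ("affinity", "interaction", "chemotaxis"):
            for ff in dataclasses.fields(v):
                out[ff.name] = getattr(v, ff.name)
        elif f.name == "population":
            for ff in dataclasses.fields(v):
                if ff.name == "densities":
                    for t, d in v.densities.items():
                        out[f"density_{t.value}"] = d
                else:
                    out[ff.name] = getattr(v, ff.name)
        elif f.name == "arm":
            out["arm"] = v.value
        elif f.name == "snapshot_days":
            out["snapshot_days"] = list(v)
        else:
            out[f.name] = v
    return out
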