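"""Scenario (de)serialisation to structured-text configs.

A scenario config is a flat mapping with a ``distributions`` table whose
keys are exactly the parameter names the Monte Carlo engine samples
(``feed_speed``, ``arc_fraction``, ``V_room``, ``ach``, ``V_NF``, ``beta``,
``epsilon``, ``Q_lev``, ``S_m``, ...).  JSON is written; JSON and TOML are
read (TOML via the standard library).  The schema is documented in
``docs/scenario_schema.md``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

from .models import InvalidConfigError, ModelKind
from .welding import (
    ParameterDistribution,
    ScenarioSpec,
    WeldingProcess,
    get_electrode,
)

try:  # Python 3.11+
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - 3.10 fallback
    tomllib = None


def scenario_to_dict(spec: ScenarioSpec) -> Dict:
    out = {
        "name": spec.name,
        "model_kind": ModelKind(spec.model_kind).value,
        "control": spec.control,
        "extraction_mode": spec.extraction_mode,
        "emission_mode": spec.emission_mode,
        "oel": spec.oel,
        "T_shift": spec.T_shift,
        "generation": spec.generation,
        "distributions": {
            name: {"kind": d.kind, "lo": d.lo, "hi": d.hi}
            for name, d in spec.distributions.items()
        },
    }
    if spec.emission_components:
        out["emission_components"] = list(spec.emission_components)
    if spec.window is not None:
        out["window"] = list(spec.window)
    if spec.process is not None:
        p = spec.process
        out["process"] = {
            "electrode_name": p.electrode_name,
            "emission_factor": p.emission_factor,
            "wire_diameter": p.wire_diameter,
            "wire_density": p.wire_density,
            "feed_speed_range": list(p.feed_speed_range),
            "shielding_gas": p.shielding_gas,
            "arc_fraction_range": list(p.arc_fraction_range),
        }
        if p.emission_rate_override is not None:
            out["process"]["emission_rate_override"] = list(p.emission_rate_override)
    return out


def scenario_from_dict(data: Dict) -> ScenarioSpec:
    try:
        dists = {
            name: ParameterDistribution(name, d["kind"], float(d["lo"]), float(d["hi"]))
            for name, d in data["distributions"].items()
        }
        process = None
        if "process" in data:
            p = dict(data["process"])
            if "feed_speed_range" in p:
                p["feed_speed_range"] = tuple(p["feed_speed_range"])
            if "arc_fraction_range" in p:
                p["arc_fraction_range"] = tuple(p["arc_fraction_range"])
            if p.get("emission_rate_override") is not None:
                p["emission_rate_override"] = tuple(p["emission_rate_override"])
            process = WeldingProcess(**p)
        generation = data.get("generation", "arc_fraction")
        if generation != "arc_fraction":
            generation = float(generation)
        return ScenarioSpec(
            name=data["name"],
            model_kind=ModelKind(data["model_kind"]),
            control=data.get("control", "none"),
            distributions=dists,
            extraction_mode=data.get("extraction_mode", "bulk"),
            emission_mode=data.get("emission_mode", "factor"),
            emission_components=tuple(data.get("emission_components", ())),
            process=process,
            generation=generation,
            oel=float(data.get("oel", 5.0)),
            T_shift=float(data.get("T_shift", 480.0)),
            window=tuple(data["window"]) if "window" in data else None,
        )
    except KeyError as exc:
        raise InvalidConfigError(f"scenario config missing required key: {exc}") from exc


def save_scenario(spec: ScenarioSpec, path) -> None:
    Path(path).write_text(json.dumps(scenario_to_dict(spec), indent=2) + "\n")


def load_scenario(path) -> ScenarioSpec:
    path = Path(path)
    if path.suffix.lower() == ".toml":
        if tomllib is None:
            raise InvalidConfigError("TOML configs need Python >= 3.11")
        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return scenario_from_dict(data)
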