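"""Welding process registry and exposure-scenario construction.

Emission rates for gas metal arc welding (GMAW) are built from published
maximum fume emission factors (mg fume per g of wire) scaled by the wire
mass feed rate, so the scenario worst case tracks how fast wire is consumed
rather than a single fixed emission number.  Shielded metal arc welding
(SMAW) validation scenarios use directly reported emission-rate ranges.

Two scenario families are provided:

* **conditions-of-use (CoU) scenarios** — one per electrode and control
  option (none / fume extraction torch / local exhaust ventilation), with
  uniform parameter distributions describing a broadly applicable workshop:
  room 30–120 m³, general ventilation 5–20 air changes per hour, near-field
  volume 1–7 m³ (a hemisphere of radius 0.8–1.5 m around the arc), NF–FF
  air exchange 9.5–30.8 m³/min, wire feed 50–250 mm/s and arc time 12–20 %
  of a 480-min shift.
* **validation scenarios** — reconstructions of published field studies
  (five single-room SMAW runs at different ventilation rates, and a
  two-zone boiler-room scenario) used for model performance testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .models import InvalidConfigError, ModelKind


class UnknownElectrodeError(KeyError):
    """Raised for an electrode name missing from the registry."""


class UnknownScenarioError(KeyError):
    """Raised for a validation-scenario name that is not defined."""


# ---------------------------------------------------------------------------
# Deterministic process arithmetic
# ---------------------------------------------------------------------------


def wire_mass_feed_rate(diameter_mm: float, density_g_cm3: float, feed_speed_mm_s: float) -> float:
    """Wire mass consumption rate, g/s, for a solid wire.

    π (d/2)² · ρ · v with the length units reconciled (cross-section from
    mm, density in g/cm³, feed speed in mm/s).
    """
    if diameter_mm <= 0 or density_g_cm3 <= 0 or feed_speed_mm_s < 0:
        raise InvalidConfigError("diameter and density must be > 0, feed speed >= 0")
    r_cm = diameter_mm / 20.0
    return math.pi * r_cm * r_cm * density_g_cm3 * (feed_speed_mm_s / 10.0)


def emission_rate_from_factor(ef_mg_g: float, mass_feed_g_s: float) -> float:
    """Fume emission rate, mg/min, from an emission factor and wire feed."""
    if ef_mg_g < 0:
        raise InvalidConfigError(f"emission factor must be >= 0, got {ef_mg_g}")
    return ef_mg_g * mass_feed_g_s * 60.0


def arc_time_minutes(arc_fraction: float, T_shift: float = 480.0) -> float:
    """Arc-on time, min, as a fraction of the shift duration."""
    if not 0.0 <= arc_fraction <= 1.0:
        raise InvalidConfigError(f"arc fraction must be in [0, 1], got {arc_fraction}")
    return arc_fraction * T_shift

def shift_wire_consumption(mass_feed_g_s: float, arc_time_min: float) -> float:
    """Wire consumed over the arc time, kg."""
    if mass_feed_g_s < 0 or arc_time_min < 0:
        raise InvalidConfigError("mass feed and arc time must be >= 0")
    return mass_feed_g_s * arc_time_min * 60.0 / 1000.0


def nf_hemisphere_volume(radius_m: float) -> float:
    """Volume, m³, of the hemispherical near field of given radius."""
    if radius_m < 0:
        raise InvalidConfigError(f"radius must be >= 0, got {radius_m}")
    return (2.0 / 3.0) * math.pi * radius_m ** 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeldingProcess:
    """One welding process: electrode, wire geometry and emission behaviour.

    Either ``emission_factor`` (mg fume / g wire, scaled by the sampled wire
    feed) or ``emission_rate_override`` (a direct mg/min range, used for the
    SMAW validation studies) must be present.
    """

    electrode_name: str
    emission_factor: Optional[float] = None
    wire_diameter: float = 1.2
    wire_density: float = 7.8
    feed_speed_range: Tuple[float, float] = (50.0, 250.0)
    shielding_gas: str = ""
    arc_fraction_range: Tuple[float, float] = (0.12, 0.20)
    emission_rate_override: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.emission_factor is None and self.emission_rate_override is None:
            raise InvalidConfigError("need an emission factor or an emission-rate override")
        if self.emission_factor is not None and self.emission_factor <= 0:
            raise InvalidConfigError(f"emission factor must be > 0, got {self.emission_factor}")
        if self.wire_diameter <= 0:
            raise InvalidConfigError(f"wire diameter must be > 0, got {self.wire_diameter}")
        lo, hi = self.feed_speed_range
        if not lo < hi:
            raise InvalidConfigError(f"feed speed range must have min < max, got {self.feed_speed_range}")

    def emission_rate_bounds(self) -> Tuple[float, float]:
        """Emission-rate range, mg/min, implied by the feed-speed range."""
        if self.emission_rate_override is not None:
            return self.emission_rate_override
        lo, hi = self.feed_speed_range
        return tuple(
            emission_rate_from_factor(
                self.emission_factor,
                wire_mass_feed_rate(self.wire_diameter, self.wire_density, v),
            )
            for v in (lo, hi)
        )


@dataclass(frozen=True)
class ParameterDistribution:
    """A sampled scenario parameter: uniform on [lo, hi] or a point value."""

    name: str
    kind: str  # "uniform" | "point"
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "point"):
            raise InvalidConfigError(f"kind must be uniform or point, got {self.kind!r}")
        if self.lo > self.hi:
            raise InvalidConfigError(f"{self.name}: lo ({self.lo}) > hi ({self.hi})")
        if self.kind == "point" and self.lo != self.hi:
            raise InvalidConfigError(f"{self.name}: point distribution needs lo == hi")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


def uniform(name: str, lo: float, hi: float) -> ParameterDistribution:
    return ParameterDistribution(name, "uniform", lo, hi)


def point(name: str, value: float) -> ParameterDistribution:
    return ParameterDistribution(name, "point", value, value)


# Emission modes understood by the Monte Carlo engine:
#   factor  — S_m = EF × mass_feed(feed_speed) × 60, needs a feed_speed column
#   direct  — S_m sampled directly from an "S_m" column
#   mixture — S_m = mean of several sampled component columns (equal arc split)
EMISSION_MODES = ("factor", "direct", "mixture")


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete, sampleable exposure scenario (the unit of CoU assessment).

    ``generation`` is either the string ``"arc_fraction"`` (the generation
    block lasts ``arc_fraction × T_shift`` minutes, sampled per iteration)
    or a fixed duration in minutes.  The worker window defaults to the whole
    shift; validation scenarios carry the study's sampling window instead.

    ``extraction_mode`` distinguishes the two kinds of local control air
    movement.  ``"bulk"`` (hood-style LEV): the control flow ``Q_lev``
    removes mixed near-field air, entering the zone air balance.
    ``"capture_stream"`` (torch-integrated extraction): the control flow is
    the capture stream at the nozzle — the ε-captured fume it carries is
    already removed from the source term, and the small airflow is not an
    additional sink for mixed NF air.
    """

    name: str
    model_kind: ModelKind
    control: str  # "none" | "FET" | "LEV"
    distributions: Dict[str, ParameterDistribution]
    extraction_mode: str = "bulk"  # "bulk" | "capture_stream"
    emission_mode: str = "factor"
    emission_components: Tuple[str, ...] = ()
    process: Optional[WeldingProcess] = None
    generation: object = "arc_fraction"
    oel: float = 5.0
    T_shift: float = 480.0
    window: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        kind = ModelKind(self.model_kind)
        object.__setattr__(self, "model_kind", kind)
        if self.control not in ("none", "FET", "LEV"):
            raise InvalidConfigError(f"control must be none, FET or LEV, got {self.control!r}")
        if self.emission_mode not in EMISSION_MODES:
            raise InvalidConfigError(f"unknown emission mode {self.emission_mode!r}")
        if self.extraction_mode not in ("bulk", "capture_stream"):
            raise InvalidConfigError(f"unknown extraction mode {self.extraction_mode!r}")
        if self.oel <= 0:
            raise InvalidConfigError(f"OEL must be > 0, got {self.oel}")
        self._check_completeness()

    def _check_completeness(self) -> None:
        kind = ModelKind(self.model_kind)
        required = {"V_room", "ach"}
        if kind in (ModelKind.TWO_BOX, ModelKind.TWO_BOX_LEV):
            required |= {"V_NF", "beta"}
        if kind is ModelKind.TWO_BOX_LEV:
            required |= {"epsilon", "Q_lev"}
        elif self.control != "none":
            raise InvalidConfigError("FET/LEV control requires the two_box_lev model")
        if self.control == "none" and (
            "epsilon" in self.distributions or "Q_lev" in self.distributions
        ):
            raise InvalidConfigError("uncontrolled scenario must not carry epsilon/Q_lev")
        if self.emission_mode == "factor":
            required.add("feed_speed")
            if self.process is None or self.process.emission_factor is None:
                raise InvalidConfigError("factor emission mode needs a process with an emission factor")
        elif self.emission_mode == "direct":
            required.add("S_m")
        else:
            if not self.emission_components:
                raise InvalidConfigError("mixture emission mode needs component names")
            required |= set(self.emission_components)
        if self.generation == "arc_fraction":
            required.add("arc_fraction")
        missing = required - set(self.distributions)
        if missing:
            raise InvalidConfigError(
                f"scenario {self.name!r} is missing distributions: {sorted(missing)}"
            )

    @property
    def effective_window(self) -> Tuple[float, float]:
        return self.window if self.window is not None else (0.0, self.T_shift)


# ---------------------------------------------------------------------------
# Electrode registry (maximum reported fume emission factors)
# ---------------------------------------------------------------------------

ELECTRODES: Dict[str, WeldingProcess] = {
    p.electrode_name: p
    for p in (
        WeldingProcess("ER316L", emission_factor=22.1, wire_diameter=1.2,
                       shielding_gas="CO2 5 LPM"),
        WeldingProcess("ER316LSi", emission_factor=5.59, wire_diameter=1.2,
                       shielding_gas="99% Ar + 1% O2 16.5 LPM"),
        WeldingProcess("ER70S-6", emission_factor=10.21, wire_diameter=1.2,
                       shielding_gas="90% Ar + 10% CO2 16.5 LPM"),
        WeldingProcess("ER70S-3", emission_factor=6.4, wire_diameter=1.14,
                       shielding_gas="90% Ar + 10% CO2 19 LPM"),
        WeldingProcess("Z3312-YGW11", emission_factor=6.0, wire_diameter=1.2,
                       shielding_gas="CO2 25 LPM"),
    )
}

_CANONICAL = {k.lower().replace("-", "").replace("_", "").replace(" ", ""): k for k in ELECTRODES}


def get_electrode(name: str) -> WeldingProcess:
    """Registry lookup, tolerant of case, dashes and underscores."""
    key = name.lower().replace("-", "").replace("_", "").replace(" ", "")
    if key not in _CANONICAL:
        raise UnknownElectrodeError(
            f"unknown electrode {name!r}; known: {sorted(ELECTRODES)}"
        )
    return ELECTRODES[_CANONICAL[key]]


# CoU operational-condition distributions shared by every electrode.
_COU_ROOM = (
    uniform("V_room", 30.0, 120.0),
    uniform("ach", 5.0, 20.0),
    uniform("V_NF", 1.0, 7.0),
    uniform("beta", 9.5, 30.8),
)
_CONTROL_RANGES = {
    "FET": {"epsilon": (0.80, 0.98), "Q_lev": (1.0, 1.5)},
    "LEV": {"epsilon": (0.40, 0.88), "Q_lev": (2.5, 20.0)},
}


def build_cou_scenario(electrode_name: str, control: str = "none",
                       oel: float = 5.0) -> ScenarioSpec:
    """Conditions-of-use scenario for one electrode and control option.

    The emission factor is held at the electrode's registry maximum (a
    worst-case assessment); wire feed speed and arc fraction are sampled,
    so the per-iteration emission rate scales with wire consumption.
    """
    process = get_electrode(electrode_name)
    if control not in ("none", "FET", "LEV"):
        raise InvalidConfigError(f"control must be none, FET or LEV, got {control!r}")
    dists: Dict[str, ParameterDistribution] = {}
    dists["feed_speed"] = uniform("feed_speed", *process.feed_speed_range)
    dists["arc_fraction"] = uniform("arc_fraction", *process.arc_fraction_range)
    for d in _COU_ROOM:
        dists[d.name] = d
    kind = ModelKind.TWO_BOX
    if control != "none":
        kind = ModelKind.TWO_BOX_LEV
        for pname, (lo, hi) in _CONTROL_RANGES[control].items():
            dists[pname] = uniform(pname, lo, hi)
    return ScenarioSpec(
        name=f"{process.electrode_name}_{control}",
        model_kind=kind,
        control=control,
        distributions=dists,
        extraction_mode="capture_stream" if control == "FET" else "bulk",
        emission_mode="factor",
        process=process,
        generation="arc_fraction",
        oel=oel,
    )


# ---------------------------------------------------------------------------
# Validation scenarios (model performance testing)
# ---------------------------------------------------------------------------

_HOBBS_ACH = (60.4, 44.6, 28.4, 14.4, 6.6)
_HOBBS_EMISSIONS = {
    # mg/min uniform ranges; E6010 also has a single-point variant
    "e6010": (387.0, 589.0),
    "e7018": (180.0, 365.0),
}
_E6010_POINT = 329.0  # mg/min at a 12.9 g/min electrode use rate
_BOELTER_V_NF = 4.0   # m³; not reported for the boiler room, NF TWA is insensitive to it


def validation_scenario_names() -> Tuple[str, ...]:
    names = [f"hobbs_{e}_{a}" for e in _HOBBS_EMISSIONS for a in _HOBBS_ACH]
    names.append("boelter_boiler_room")
    return tuple(names)


def build_validation_scenario(name: str, emission: str = "uniform") -> ScenarioSpec:
    """Reconstruct a published performance-testing scenario by name.

    ``hobbs_<electrode>_<ach>`` — single well-mixed 62.1 m³ room, SMAW with
    a continuously burning electrode, 60-min sampling window; emission
    uniform over the literature range, or (E6010 only, ``emission="point"``)
    the fixed 329 mg/min estimate.

    ``boelter_boiler_room`` — 81 m³ two-zone room, ACH 23, NF–FF exchange
    21 m³/min, 56 min of arc time split equally between two electrodes,
    325-min sampling window.
    """
    if name == "boelter_boiler_room":
        dists = {
            "S_e6010": uniform("S_e6010", *_HOBBS_EMISSIONS["e6010"]),
            "S_e7018": uniform("S_e7018", *_HOBBS_EMISSIONS["e7018"]),
            "V_room": point("V_room", 81.0),
            "ach": point("ach", 23.0),
            "beta": point("beta", 21.0),
            "V_NF": point("V_NF", _BOELTER_V_NF),
        }
        return ScenarioSpec(
            name=name, model_kind=ModelKind.TWO_BOX, control="none",
            distributions=dists, emission_mode="mixture",
            emission_components=("S_e6010", "S_e7018"),
            generation=56.0, T_shift=325.0, window=(0.0, 325.0),
        )
    parts = name.split("_")
    if len(parts) == 3 and parts[0] == "hobbs" and parts[1] in _HOBBS_EMISSIONS:
        try:
            ach = float(parts[2])
        except ValueError:
            raise UnknownScenarioError(name) from None
        if ach not in _HOBBS_ACH:
            raise UnknownScenarioError(
                f"{name}: ACH must be one of {_HOBBS_ACH}"
            )
        lo, hi = _HOBBS_EMISSIONS[parts[1]]
        if emission == "point":
            if parts[1] != "e6010":
                raise UnknownScenarioError("point emission variant exists only for E6010")
            s_dist = point("S_m", _E6010_POINT)
        elif emission == "uniform":
            s_dist = uniform("S_m", lo, hi)
        else:
            raise InvalidConfigError(f"emission must be 'uniform' or 'point', got {emission!r}")
        dists = {
            "S_m": s_dist,
            "V_room": point("V_room", 62.1),
            "ach": point("ach", ach),
        }
        return ScenarioSpec(
            name=name, model_kind=ModelKind.ONE_BOX, control="none",
            distributions=dists, emission_mode="direct",
            generation=60.0, T_shift=60.0, window=(0.0, 60.0),
        )
    raise UnknownScenarioError(
        f"unknown validation scenario {name!r}; known: {validation_scenario_names()}"
    )
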