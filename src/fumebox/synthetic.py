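"""Synthetic field-measurement generator and parameter-recovery tools.

Real model-performance testing compares model output against workplace
concentration measurements.  Published measured values are rarely printed
alongside the modelling inputs, so this module generates *synthetic*
measurements with the statistical structure industrial-hygiene data are
assumed to have — the model's window TWA perturbed by multiplicative
lognormal error with a stated geometric standard deviation — plus the
inverse operations the validation workflow needs: modelled/measured GM
ratios, steady-state inversion for the NF–FF air exchange, and
least-squares recovery of the emission rate from a concentration series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .models import (
    ConcentrationSeries,
    ExposureWindow,
    ModelConfig,
    SourceSchedule,
    solve,
    time_weighted_average,
)
from .welding import ScenarioSpec
from .montecarlo import sample_parameters, evaluate_draws


class NonIdentifiableError(ValueError):
    """Raised when the requested inversion has no information to work with."""


@dataclass(frozen=True)
class SyntheticMeasurements:
    """A batch of synthetic window-TWA measurements for one scenario zone."""

    scenario_name: str
    zone: str
    sampling_window: Tuple[float, float]
    true_concentration: float   # model TWA the noise was applied to, mg/m³
    measured_values: np.ndarray  # mg/m³, all > 0
    noise_gsd: float
    seed: int


def deterministic_twa(scenario: ScenarioSpec, zone: str = "NF") -> float:
    """Model TWA at every distribution's midpoint (a single noiseless run)."""
    mid = sample_parameters(scenario, 1, 0)
    mid = type(mid)(
        names=mid.names,
        values=np.array([[scenario.distributions[n].midpoint for n in mid.names]]),
        seed=0, n=1,
    )
    nf, ff = evaluate_draws(scenario, mid)
    if zone == "NF":
        if nf is None:
            raise ValueError("one-box scenario has no NF zone")
        return float(nf[0])
    return float(ff[0])


def generate_measurements(
    scenario: ScenarioSpec,
    zone: str,
    window: Optional[Tuple[float, float]] = None,
    noise_gsd: float = 1.5,
    m: int = 30,
    seed: int = 0,
) -> SyntheticMeasurements:
    """Draw ``m`` noisy replicates of the scenario's midpoint window TWA.

    measured = model TWA × LN(0, ln²(noise_gsd)); with ``noise_gsd = 1`` the
    measurements equal the model value exactly.
    """
    if noise_gsd < 1.0:
        raise ValueError(f"noise_gsd must be >= 1, got {noise_gsd}")
    if window is None:
        window = scenario.effective_window
    true = deterministic_twa(scenario, zone)
    rng = np.random.default_rng(seed)
    if noise_gsd == 1.0:
        noise = np.ones(m)
    else:
        noise = rng.lognormal(mean=0.0, sigma=np.log(noise_gsd), size=m)
    return SyntheticMeasurements(
        scenario_name=scenario.name, zone=zone, sampling_window=tuple(window),
        true_concentration=true, measured_values=true * noise,
        noise_gsd=noise_gsd, seed=seed,
    )


def modelled_measured_ratio(model_gm: float, measured: Sequence[float]) -> float:
    """Modelled GM divided by the geometric mean of the measured values."""
    x = np.asarray(measured, dtype=float)
    if x.size == 0:
        raise ValueError("measured sample is empty")
    if np.any(x <= 0):
        raise ValueError("measured values must all be positive")
    return float(model_gm / np.exp(np.log(x).mean()))


def estimate_beta(C_NF_ss: float, C_FF_ss: float, S_eff: float) -> float:
    """NF–FF air exchange, m³/min, from steady-state zone concentrations.

    At steady state the NF balance gives β = S_eff / (C_NF − C_FF); the
    inversion degenerates when the zone concentrations coincide.
    """
    if C_FF_ss <= 0 or C_NF_ss <= C_FF_ss:
        raise NonIdentifiableError(
            f"need C_NF > C_FF > 0, got C_NF={C_NF_ss}, C_FF={C_FF_ss}"
        )
    return S_eff / (C_NF_ss - C_FF_ss)


def recover_emission_rate(
    times: Sequence[float],
    concentrations: Sequence[float],
    config: ModelConfig,
    schedule: SourceSchedule,
    zone: str = "room",
) -> float:
    """Least-squares emission rate from a measured concentration series.

    The model response is linear in the source strength, so the fit is the
    closed-form projection of the measurements onto the unit-source
    response: Ŝ = ⟨basis, y⟩ / ⟨basis, basis⟩.  ``schedule`` supplies the
    generation timing; its ``S_m`` is ignored.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    if t.size < 3 or t.size != y.size:
        raise ValueError("need at least 3 matching time/concentration points")
    unit = SourceSchedule(S_m=1.0, t_g=schedule.t_g, t_start=schedule.t_start,
                          T_shift=schedule.T_shift)
    series = solve(config, unit, grid=t)
    if zone == "NF":
        if series.C_NF is None:
            raise ValueError("NF zone requested for a one-box configuration")
        basis = series.C_NF
    else:
        basis = series.C_FF
    denom = float(basis @ basis)
    if denom == 0.0:
        raise NonIdentifiableError("unit response is identically zero over the series")
    return float(basis @ y) / denom


def measurements_to_records(meas: SyntheticMeasurements) -> list:
    """Rows (scenario, zone, replicate, measured) for CSV export."""
    return [
        {
            "scenario": meas.scenario_name,
            "zone": meas.zone,
            "replicate": i,
            "measured_mg_m3": float(v),
            "true_mg_m3": meas.true_concentration,
            "noise_gsd": meas.noise_gsd,
            "seed": meas.seed,
        }
        for i, v in enumerate(meas.measured_values)
    ]
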