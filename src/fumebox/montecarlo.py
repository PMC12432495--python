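"""Monte Carlo propagation of scenario parameter ranges to shift exposures.

Each iteration draws one value per scenario parameter (independent uniform
or point distributions), derives the emission rate and arc-time schedule,
solves the scenario's compartment model in closed form and records the
near-field and far-field time-weighted averages over the worker window
(the full shift by default).  Everything is vectorised, so 50 000
iterations of a scenario run in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .models import ModelKind, one_box_window_twa, two_box_window_twa
from .welding import ScenarioSpec, emission_rate_from_factor, wire_mass_feed_rate


@dataclass(frozen=True)
class ParameterDraws:
    """Sampled parameter matrix with provenance.

    ``values`` is ``n × p`` with one column per name in ``names`` (the
    scenario's distribution order); columns are mutually independent.
    """

    names: tuple
    values: np.ndarray
    seed: int
    n: int

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


@dataclass(frozen=True)
class ExposureSummary:
    """GM/GSD/percentile summary of a positive exposure sample.

    ``percentiles`` are empirical (linear-interpolation) quantiles.  For
    extreme upper percentiles industrial-hygiene practice often reports the
    parametric quantile of the fitted lognormal instead,
    GM·GSD^{z_p}; :meth:`lognormal_percentile` provides that convention.
    The two differ when the simulated distribution is sub-lognormal in the
    tail (bounded parameter ranges cap the worst case).
    """

    gm: float
    gsd: float
    am: float
    percentiles: Dict[str, float]
    n: int
    nonpositive: int = 0  # values for which GM/GSD were undefined

    def percentile(self, p: str) -> float:
        return self.percentiles[p]

    def lognormal_percentile(self, q: float) -> float:
        """Parametric quantile GM·GSD^{z_q} of the fitted lognormal."""
        from scipy.stats import norm
        return self.gm * self.gsd ** norm.ppf(q / 100.0)


@dataclass(frozen=True)
class ExposureDistribution:
    """Per-iteration shift TWAs plus the draws that produced them."""

    nf_twa: Optional[np.ndarray]
    ff_twa: np.ndarray
    draws: ParameterDraws
    scenario: ScenarioSpec

    def zone(self, zone: str) -> np.ndarray:
        if zone == "NF":
            if self.nf_twa is None:
                raise ValueError("one-box scenario has no NF series; use zone='FF'")
            return self.nf_twa
        if zone in ("FF", "room"):
            return self.ff_twa
        raise ValueError(f"zone must be NF, FF or room, got {zone!r}")

    def to_frame(self) -> pd.DataFrame:
        out = self.draws.to_frame()
        if self.nf_twa is not None:
            out["nf_twa"] = self.nf_twa
        out["ff_twa"] = self.ff_twa
        return out


def sample_parameters(scenario: ScenarioSpec, n: int, seed: int) -> ParameterDraws:
    """Draw ``n`` independent parameter vectors for a scenario.

    Reproducible: the same (scenario, n, seed) triple yields bit-identical
    matrices.  Point distributions produce constant columns.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    names = tuple(scenario.distributions)
    cols = []
    for name in names:
        d = scenario.distributions[name]
        if d.kind == "point":
            cols.append(np.full(n, d.lo))
        else:
            cols.append(rng.uniform(d.lo, d.hi, size=n))
    return ParameterDraws(names=names, values=np.column_stack(cols), seed=seed, n=n)


def _emission_rates(scenario: ScenarioSpec, draws: ParameterDraws) -> np.ndarray:
    if scenario.emission_mode == "direct":
        return draws.column("S_m")
    if scenario.emission_mode == "mixture":
        comps = [draws.column(c) for c in scenario.emission_components]
        return np.mean(comps, axis=0)
    proc = scenario.process
    feed = draws.column("feed_speed")
    area_term = wire_mass_feed_rate(proc.wire_diameter, proc.wire_density, 1.0)
    return emission_rate_from_factor(1.0, area_term) * proc.emission_factor * feed


def evaluate_draws(scenario: ScenarioSpec, draws: ParameterDraws,
                   emission_factor: Optional[float] = None):
    """Closed-form NF/FF shift TWAs for every draw.

    ``emission_factor`` overrides the process's registry value (used by the
    emission-limit back-calculation, which re-evaluates the same draws at
    candidate factors).  Returns ``(nf_twa | None, ff_twa)``.
    """
    S = _emission_rates(scenario, draws)
    if emission_factor is not None:
        if scenario.emission_mode != "factor":
            raise ValueError("emission_factor override requires a factor-mode scenario")
        S = S * (emission_factor / scenario.process.emission_factor)
    if scenario.generation == "arc_fraction":
        t_g = draws.column("arc_fraction") * scenario.T_shift
    else:
        t_g = np.full(draws.n, float(scenario.generation))
    t_1, t_2 = scenario.effective_window

    V_room = draws.column("V_room")
    Q = draws.column("ach") * V_room / 60.0
    kind = ModelKind(scenario.model_kind)
    if kind is ModelKind.ONE_BOX:
        room = one_box_window_twa(V_room, Q, S, t_g, t_1, t_2)
        return None, room

    V_NF = draws.column("V_NF")
    beta = draws.column("beta")
    if np.any(V_NF >= V_room):
        raise ValueError("sampled V_NF >= V_room; check scenario ranges")
    if kind is ModelKind.TWO_BOX_LEV:
        # capture-stream controls (torch extraction) remove fume at the
        # source only; their airflow is not a bulk sink for mixed NF air.
        if scenario.extraction_mode == "capture_stream":
            q_lev = np.zeros(draws.n)
        else:
            q_lev = draws.column("Q_lev")
        s_eff = S * (1.0 - draws.column("epsilon"))
    else:
        q_lev = np.zeros(draws.n)
        s_eff = S
    nf, ff = two_box_window_twa(V_NF, V_room - V_NF, beta, Q, q_lev, s_eff, t_g, t_1, t_2)
    return nf, ff


def run_scenario(scenario: ScenarioSpec, n: int, seed: int) -> ExposureDistribution:
    """Sample a scenario and evaluate the shift-TWA exposure distribution."""
    draws = sample_parameters(scenario, n, seed)
    nf, ff = evaluate_draws(scenario, draws)
    return ExposureDistribution(nf_twa=nf, ff_twa=ff, draws=draws, scenario=scenario)


PERCENTILES = {"P50": 50.0, "P90": 90.0, "P95": 95.0, "P99": 99.0}


def summarize(values: np.ndarray) -> ExposureSummary:
    """GM, GSD, arithmetic mean and empirical percentiles of a sample.

    GM = exp(mean(ln x)) and GSD = exp(sd(ln x)) require strictly positive
    data; if any value is non-positive they are reported as NaN (with the
    offending count) while the percentiles are still returned.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("summarize expects a 1-d sample with n >= 2")
    pct = {k: float(np.percentile(x, q)) for k, q in PERCENTILES.items()}
    nonpos = int(np.count_nonzero(x <= 0))
    if nonpos:
        gm = gsd = float("nan")
    else:
        logs = np.log(x)
        gm = float(np.exp(logs.mean()))
        gsd = float(np.exp(logs.std(ddof=1)))
    return ExposureSummary(gm=gm, gsd=gsd, am=float(x.mean()),
                           percentiles=pct, n=x.size, nonpositive=nonpos)


def summarize_distribution(dist: ExposureDistribution) -> Dict[str, ExposureSummary]:
    """Zone → summary for an exposure distribution (NF omitted for one-box)."""
    out: Dict[str, ExposureSummary] = {}
    if dist.nf_twa is not None:
        out["NF"] = summarize(dist.nf_twa)
    out["FF"] = summarize(dist.ff_twa)
    return out
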