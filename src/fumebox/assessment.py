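"""Regulatory decision rules and emission-limit back-calculation.

An exposure summary is judged against an occupational exposure limit (OEL)
three ways:

* **REACH/ECHA compliance** — the distribution's P90 must fall below the
  limit; the risk characterisation ratio (RCR) is P90/OEL.
* **AIHA exposure rating** — a five-band classification of P95/OEL, from
  "non-existent" (≤ 0.01×OEL) to "poorly controlled" (> OEL), each band
  carrying its own recommended control actions.
* **EN 689 measurement interval** — periodic personal-measurement spacing
  justified by how far the geometric mean sits below the limit (GM <
  0.1×OEL → 36 months, < 0.25×OEL → 24, < 0.5×OEL → 18; otherwise no
  periodic interval can be granted and the assessment must be redone).

Where the P90 exceeds the limit, a respirator nominal protection factor is
chosen from the standard ladder {4, 10, 20, 40, 100} as the smallest factor
covering the RCR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .montecarlo import ExposureSummary, evaluate_draws, sample_parameters, summarize
from .welding import ScenarioSpec

AIHA_LABELS = {
    1: "non-existent",
    2: "highly controlled",
    3: "well controlled",
    4: "controlled",
    5: "poorly controlled",
}


@dataclass(frozen=True)
class LimitCriteria:
    """Limit value and the decision thresholds applied to it."""

    oel: float = 5.0
    echa_percentile: str = "P90"
    aiha_percentile: str = "P95"
    aiha_boundaries: Tuple[float, ...] = (0.01, 0.1, 0.5, 1.0)
    en689_gm_tiers: Tuple[Tuple[float, int], ...] = ((0.1, 36), (0.25, 24), (0.5, 18))
    npf_ladder: Tuple[int, ...] = (4, 10, 20, 40, 100)

    def __post_init__(self) -> None:
        if self.oel <= 0:
            raise ValueError(f"OEL must be > 0, got {self.oel}")
        if list(self.aiha_boundaries) != sorted(set(self.aiha_boundaries)):
            raise ValueError("AIHA boundaries must be strictly increasing")


@dataclass(frozen=True)
class CoUDecision:
    """Compliance verdicts for one zone's exposure distribution."""

    zone: str
    echa_compliant: bool
    rcr: float
    aiha_category: int
    aiha_label: str
    exceedance_ratio: float
    measurement_interval_months: Optional[int]
    required_npf: Optional[int]

    def as_dict(self) -> Dict[str, object]:
        return {
            "zone": self.zone,
            "echa_compliant": self.echa_compliant,
            "rcr": self.rcr,
            "aiha_category": self.aiha_category,
            "aiha_label": self.aiha_label,
            "exceedance_ratio": self.exceedance_ratio,
            "measurement_interval_months": self.measurement_interval_months,
            "required_npf": self.required_npf,
        }


def classify_aiha(p95: float, oel: float,
                  boundaries: Tuple[float, ...] = (0.01, 0.1, 0.5, 1.0)) -> Tuple[int, str]:
    """Five-band exposure rating of P95 relative to the OEL (upper bounds inclusive)."""
    if oel <= 0:
        raise ValueError(f"OEL must be > 0, got {oel}")
    if p95 < 0:
        raise ValueError(f"P95 must be >= 0, got {p95}")
    ratio = p95 / oel
    for cat, bound in enumerate(boundaries, start=1):
        if ratio <= bound:
            return cat, AIHA_LABELS[cat]
    return 5, AIHA_LABELS[5]


def _measurement_interval(gm: float, criteria: LimitCriteria) -> Optional[int]:
    if not math.isfinite(gm):
        return None
    for frac, months in criteria.en689_gm_tiers:
        if gm < frac * criteria.oel:
            return months
    return None


def _required_npf(rcr: float, criteria: LimitCriteria) -> Optional[int]:
    if rcr < 1.0:
        return 1
    for npf in criteria.npf_ladder:
        if npf >= rcr:
            return npf
    return None


def decide(summary: ExposureSummary, criteria: LimitCriteria, zone: str) -> CoUDecision:
    """All decision rules applied to one zone summary."""
    p90 = summary.percentile(criteria.echa_percentile)
    p95 = summary.percentile(criteria.aiha_percentile)
    rcr = p90 / criteria.oel
    cat, label = classify_aiha(p95, criteria.oel, criteria.aiha_boundaries)
    return CoUDecision(
        zone=zone,
        echa_compliant=p90 < criteria.oel,
        rcr=rcr,
        aiha_category=cat,
        aiha_label=label,
        exceedance_ratio=p95 / criteria.oel,
        measurement_interval_months=_measurement_interval(summary.gm, criteria),
        required_npf=_required_npf(rcr, criteria),
    )


def assess(summary_NF: Optional[ExposureSummary], summary_FF: Optional[ExposureSummary],
           criteria: LimitCriteria) -> Dict[str, CoUDecision]:
    """Zone → decision for whichever zone summaries are supplied."""
    out: Dict[str, CoUDecision] = {}
    if summary_NF is not None:
        out["NF"] = decide(summary_NF, criteria, "NF")
    if summary_FF is not None:
        out["FF"] = decide(summary_FF, criteria, "FF")
    if not out:
        raise ValueError("at least one zone summary is required")
    return out


class BracketError(ValueError):
    """Raised when the emission-limit target is unreachable in the search range."""


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated emission factor and its plug-back check."""

    emission_factor: float  # mg fume / g wire, rounded down to one decimal
    p95_at_ef: float        # NF P95 re-evaluated at the returned factor, mg/m³
    oel: float
    n: int
    seed: int


def back_calculate_emission_factor(
    scenario_template: ScenarioSpec,
    oel: float = 5.0,
    n: int = 50_000,
    seed: int = 0,
    ef_max: float = 100.0,
    tol: float = 0.05,
) -> BackCalcResult:
    """Largest emission factor keeping the NF P95 at or below the OEL.

    Uses common random numbers: one set of parameter draws is evaluated at
    every candidate factor, so the P95-vs-factor objective is deterministic
    and strictly increasing (the model is linear in the source term) and
    plain bisection converges.  The bracketing factor is rounded *down* to
    one decimal so the returned limit is conservative.
    """
    if scenario_template.emission_mode != "factor":
        raise ValueError("back-calculation needs a factor-mode scenario template")
    draws = sample_parameters(scenario_template, n, seed)

    def p95_at(ef: float) -> float:
        nf, _ = evaluate_draws(scenario_template, draws, emission_factor=ef)
        if nf is None:
            raise ValueError("back-calculation needs a two-box scenario (NF zone)")
        return float(np.percentile(nf, 95.0))

    lo, hi = 0.0, float(ef_max)
    if p95_at(hi) < oel:
        raise BracketError(
            f"NF P95 at EF={ef_max} mg/g is still below the OEL {oel} mg/m³"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if p95_at(mid) <= oel:
            lo = mid
        else:
            hi = mid
    ef_star = math.floor(lo * 10.0) / 10.0
    return BackCalcResult(emission_factor=ef_star, p95_at_ef=p95_at(ef_star),
                          oel=oel, n=n, seed=seed)
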