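"""Rank-correlation sensitivity analysis of simulated exposures.

The relevance of each exposure determinant is scored by the Spearman rank
correlation between its sampled values and the simulated zone TWA; its sign
says whether increasing the parameter raises or lowers exposure.  Output
variability is apportioned across determinants as normalised squared
Spearman coefficients (percentages summing to 100), which is an ordering
diagnostic rather than a formal variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelKind, two_box_window_twa
from .montecarlo import ParameterDraws, sample_parameters
from .welding import ParameterDistribution, ScenarioSpec, uniform


class UndefinedCorrelationError(ValueError):
    """Raised when the output sample is constant (ranks are degenerate)."""


@dataclass(frozen=True)
class SensitivityResult:
    """Per-parameter correlation coefficients and variability contributions.

    ``rho`` is the rank (Spearman) correlation, the primary relevance
    measure; ``pearson_r`` is the product-moment correlation on the raw
    values, reported alongside because shift-TWA distributions are strongly
    right-skewed and the two conventions differ materially for dominant
    determinants.
    """

    zone: str
    n: int
    names: Tuple[str, ...]
    rho: np.ndarray
    pearson_r: np.ndarray
    varied: np.ndarray           # False for point (non-sampled) parameters
    contribution_pct: np.ndarray  # NaN for point parameters; sums to 100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": list(self.names),
            "spearman_rho": self.rho,
            "pearson_r": self.pearson_r,
            "contribution_pct": self.contribution_pct,
            "varied": self.varied,
        })

    def rho_of(self, name: str) -> float:
        return float(self.rho[self.names.index(name)])

    def pearson_of(self, name: str) -> float:
        return float(self.pearson_r[self.names.index(name)])


def variance_contribution(rho: np.ndarray, varied: np.ndarray) -> np.ndarray:
    """Apportion variability as ρ²/Σρ² × 100 over the varying parameters."""
    rho = np.asarray(rho, dtype=float)
    varied = np.asarray(varied, dtype=bool)
    sq = np.where(varied, rho * rho, 0.0)
    total = sq.sum()
    if total <= 0:
        raise UndefinedCorrelationError("all Spearman coefficients are zero")
    out = np.full(rho.shape, np.nan)
    out[varied] = sq[varied] / total * 100.0
    return out


def spearman_sensitivity(draws: ParameterDraws, outputs: np.ndarray,
                         zone: str = "NF") -> SensitivityResult:
    """Spearman ρ of every sampled parameter against the output sample.

    Ties get average ranks.  Constant (point) parameter columns are
    reported with ρ = 0 and flagged as not varied; a constant output raises
    :class:`UndefinedCorrelationError`.
    """
    y = np.asarray(outputs, dtype=float)
    if y.shape[0] != draws.n:
        raise ValueError("draws and outputs must have the same length")
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("output sample is constant")
    ry = stats.rankdata(y)
    ry = (ry - ry.mean()) / ry.std()
    yc = (y - y.mean()) / y.std()
    rho = np.zeros(len(draws.names))
    pear = np.zeros(len(draws.names))
    varied = np.zeros(len(draws.names), dtype=bool)
    for j, name in enumerate(draws.names):
        col = draws.values[:, j]
        if np.ptp(col) == 0:
            continue
        rc = stats.rankdata(col)
        rc = (rc - rc.mean()) / rc.std()
        rho[j] = float(np.mean(rc * ry))
        xc = (col - col.mean()) / col.std()
        pear[j] = float(np.mean(xc * yc))
        varied[j] = True
    contrib = variance_contribution(rho, varied)
    return SensitivityResult(zone=zone, n=draws.n, names=draws.names,
                             rho=rho, pearson_r=pear, varied=varied,
                             contribution_pct=contrib)


_STUDY_PARAMS = ("S_m", "Q", "V_room", "V_NF", "beta")


def determinant_relevance_study(
    spans: Mapping[str, Tuple[float, float]],
    n: int,
    seed: int,
    T_shift: float = 480.0,
) -> Dict[str, SensitivityResult]:
    """Decade-span sensitivity study of the two-box model, per zone.

    Each of emission rate ``S_m`` (mg/min), general-ventilation flow ``Q``
    (m³/min), room volume, NF volume and NF–FF exchange ``beta`` is sampled
    uniformly over a one-order-of-magnitude span (hi = 10 × lo enforced);
    the source runs continuously for the whole shift and the full-shift NF
    and FF TWAs are ranked against the draws.
    """
    missing = set(_STUDY_PARAMS) - set(spans)
    if missing:
        raise ValueError(f"spans missing for parameters: {sorted(missing)}")
    dists: Dict[str, ParameterDistribution] = {}
    for name in _STUDY_PARAMS:
        lo, hi = spans[name]
        if lo <= 0 or abs(hi / lo - 10.0) > 1e-9:
            raise ValueError(f"{name}: span must be one decade (hi = 10*lo), got {spans[name]}")
        dists[name] = uniform(name, lo, hi)
    # ach is a placeholder so the spec validates; Q is used directly below.
    spec = ScenarioSpec(
        name="determinant_relevance", model_kind=ModelKind.TWO_BOX, control="none",
        distributions={**dists, "ach": uniform("ach", 1.0, 2.0)},
        emission_mode="direct", generation=T_shift, T_shift=T_shift,
    )
    draws = sample_parameters(spec, n, seed)
    V_room = draws.column("V_room")
    V_NF = np.minimum(draws.column("V_NF"), 0.5 * V_room)  # keep NF inside the room
    nf, ff = two_box_window_twa(
        V_NF, V_room - V_NF, draws.column("beta"), draws.column("Q"),
        0.0, draws.column("S_m"), T_shift, 0.0, T_shift,
    )
    keep = tuple(_STUDY_PARAMS)
    idx = [draws.names.index(p) for p in keep]
    sub = ParameterDraws(names=keep, values=draws.values[:, idx], seed=seed, n=n)
    return {
        "NF": spearman_sensitivity(sub, nf, zone="NF"),
        "FF": spearman_sensitivity(sub, ff, zone="FF"),
    }
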