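"""Compartmental mass-balance models for a point aerosol source indoors.

Three model variants are provided, all linear constant-coefficient ODE
systems driven by a single on/off emission block:

* **one-box** — the whole room is a single well-mixed volume ventilated at
  flow ``Q`` (m³/min); the only loss is the general-ventilation exhaust.
* **two-box** — the room is split into a near-field (NF) volume around the
  source and a far-field (FF) remainder, coupled by a limited air-exchange
  flow ``beta`` (m³/min); general ventilation exhausts from the FF.
* **two-box with LEV** — as two-box, but a local extraction flow ``Q_lev``
  removes air from the NF directly outdoors, and a fraction ``epsilon`` of
  the emission is captured at the source before it reaches room air.  The
  LEV flow increases the FF→NF make-up flow and the fresh-air supply to the
  FF so that air flows balance in both zones.

All solutions are exact (eigen-decomposition of the 2×2 system; scalar
exponential for one-box) and vectorise over arrays of parameters, which is
what makes Monte Carlo shift-average calculations cheap.  Concentrations
are mg/m³, flows m³/min, volumes m³ and times minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np


class ModelKind(str, Enum):
    ONE_BOX = "one_box"
    TWO_BOX = "two_box"
    TWO_BOX_LEV = "two_box_lev"


class InvalidConfigError(ValueError):
    """Raised when a model configuration violates its physical constraints."""


class InvalidRequestError(ValueError):
    """Raised when a computation is requested that the series cannot supply."""


@dataclass(frozen=True)
class ModelConfig:
    """Geometry, ventilation and control-flow parameters of one model instance.

    Parameters
    ----------
    model_kind:
        Which compartment topology to solve.
    V_room:
        Total room volume, m³.
    ach:
        General-ventilation air changes per hour (exhaust flow / room
        volume); excludes any LEV flow.
    V_NF:
        Near-field volume, m³ (two-box kinds only).
    beta:
        NF–FF air exchange flow, m³/min (two-box kinds only).
    Q_lev:
        Local extraction flow from the NF to outdoors, m³/min
        (``two_box_lev`` only).
    epsilon:
        Source capture efficiency in [0, 1]; the captured fraction of the
        emission never enters room air (``two_box_lev`` only).
    """

    model_kind: ModelKind
    V_room: float
    ach: float
    V_NF: Optional[float] = None
    beta: Optional[float] = None
    Q_lev: float = 0.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        kind = ModelKind(self.model_kind)
        object.__setattr__(self, "model_kind", kind)
        if not self.V_room > 0:
            raise InvalidConfigError(f"V_room must be > 0, got {self.V_room}")
        if not self.ach > 0:
            raise InvalidConfigError(f"ach must be > 0, got {self.ach}")
        if kind is not ModelKind.ONE_BOX:
            if self.V_NF is None or not self.V_NF > 0:
                raise InvalidConfigError(f"V_NF must be > 0, got {self.V_NF}")
            if self.V_NF >= self.V_room:
                raise InvalidConfigError(
                    f"V_NF ({self.V_NF}) must be smaller than V_room ({self.V_room})"
                )
            if self.beta is None or not self.beta > 0:
                raise InvalidConfigError(f"beta must be > 0, got {self.beta}")
        if kind is ModelKind.TWO_BOX_LEV:
            if not self.Q_lev > 0:
                raise InvalidConfigError(f"Q_lev must be > 0, got {self.Q_lev}")
            if not 0.0 <= self.epsilon <= 1.0:
                raise InvalidConfigError(
                    f"epsilon must be in [0, 1], got {self.epsilon}"
                )

    @property
    def Q(self) -> float:
        """General-ventilation flow, m³/min (= ACH × V_room / 60)."""
        return self.ach * self.V_room / 60.0

    @property
    def V_FF(self) -> float:
        """Far-field volume, m³ (= V_room − V_NF)."""
        if self.V_NF is None:
            raise InvalidRequestError("V_FF is undefined for a one-box model")
        return self.V_room - self.V_NF


@dataclass(frozen=True)
class SourceSchedule:
    """Constant-rate emission over a single on/off block within a shift.

    ``S_m`` is the emission rate (mg/min) while the source is active, from
    ``t_start`` to ``t_start + t_g`` minutes; the shift spans
    ``[0, T_shift]``.
    """

    S_m: float
    t_g: float
    t_start: float = 0.0
    T_shift: float = 480.0

    def __post_init__(self) -> None:
        if self.S_m < 0:
            raise InvalidConfigError(f"S_m must be >= 0, got {self.S_m}")
        if self.t_start < 0:
            raise InvalidConfigError(f"t_start must be >= 0, got {self.t_start}")
        if self.t_g < 0:
            raise InvalidConfigError(f"t_g must be >= 0, got {self.t_g}")
        if self.t_start + self.t_g > self.T_shift + 1e-9:
            raise InvalidConfigError(
                f"generation window [{self.t_start}, {self.t_start + self.t_g}] "
                f"exceeds shift duration {self.T_shift}"
            )


@dataclass(frozen=True)
class ExposureWindow:
    """Worker presence interval ``[t_1, t_2]`` (min) in a given zone."""

    t_1: float
    t_2: float
    zone: str = "NF"

    def __post_init__(self) -> None:
        if not 0 <= self.t_1 < self.t_2:
            raise InvalidConfigError(
                f"window must satisfy 0 <= t_1 < t_2, got [{self.t_1}, {self.t_2}]"
            )
        if self.zone not in ("NF", "FF", "room"):
            raise InvalidConfigError(f"zone must be NF, FF or room, got {self.zone!r}")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Concentration time series on a grid covering the shift.

    For one-box runs ``C_FF`` holds the single room concentration and
    ``C_NF`` is ``None``.  Volumes are carried along so that a
    volume-weighted whole-room average can be formed for two-box runs.
    """

    times: np.ndarray
    C_FF: np.ndarray
    C_NF: Optional[np.ndarray] = None
    model_kind: ModelKind = ModelKind.ONE_BOX
    V_NF: Optional[float] = None
    V_FF: Optional[float] = None


DEFAULT_DT = 0.5  # min; grid resolution used when the caller supplies none


def default_grid(T_shift: float, dt: float = DEFAULT_DT) -> np.ndarray:
    """Uniform time grid from 0 to ``T_shift`` at ``dt``-minute resolution."""
    n = int(round(T_shift / dt))
    return np.linspace(0.0, n * dt, n + 1)


# ---------------------------------------------------------------------------
# Vectorised closed-form kernels.
#
# Both kernels expose concentration(t) and cumulative_integral(t) for the
# zero-initial-state response to a source that is ON for t in [0, t_g] and
# OFF afterwards.  All parameters may be numpy arrays (Monte Carlo draws);
# time offsets (t_start) are applied by the callers.
# ---------------------------------------------------------------------------


class _OneBoxKernel:
    """Scalar exponential response of the well-mixed room model."""

    def __init__(self, V_room, Q, S, t_g):
        self.k = Q / V_room          # 1/min loss rate
        self.C_ss = S / Q            # steady-state concentration
        self.t_g = t_g
        self._C_tg = self.C_ss * -np.expm1(-self.k * t_g)
        self._I_tg = self.C_ss * (t_g + np.expm1(-self.k * t_g) / self.k)

    def concentration(self, t):
        t = np.asarray(t, dtype=float)
        on = self.C_ss * -np.expm1(-self.k * np.minimum(t, self.t_g))
        off = self._C_tg * np.exp(-self.k * np.maximum(t - self.t_g, 0.0))
        return np.where(t <= self.t_g, on, off)

    def cumulative_integral(self, t):
        """∫₀ᵗ C(s) ds, elementwise."""
        t = np.asarray(t, dtype=float)
        tc = np.minimum(t, self.t_g)
        I_on = self.C_ss * (tc + np.expm1(-self.k * tc) / self.k)
        s = np.maximum(t - self.t_g, 0.0)
        I_off = self._C_tg * -np.expm1(-self.k * s) / self.k
        return I_on + I_off


class _TwoBoxKernel:
    """Eigen-decomposed response of the NF/FF system (with optional LEV).

    System (S_eff already includes any source-capture factor):

        V_NF dC_NF/dt = S_eff + (β + Q_lev)·(C_FF − C_NF)
        V_FF dC_FF/dt = β·C_NF − (Q + β + Q_lev)·C_FF
    """

    def __init__(self, V_NF, V_FF, beta, Q, Q_lev, S_eff, t_g):
        a11 = -(beta + Q_lev) / V_NF
        a12 = (beta + Q_lev) / V_NF
        a21 = beta / V_FF
        a22 = -(Q + beta + Q_lev) / V_FF
        tr = a11 + a22
        det = a11 * a22 - a12 * a21
        disc = np.sqrt(tr * tr - 4.0 * det)   # > 0: a12·a21 > 0 keeps eigenvalues real
        lam1 = 0.5 * (tr - disc)
        lam2 = 0.5 * (tr + disc)

        C_ss_NF = S_eff * (Q + beta + Q_lev) / ((beta + Q_lev) * (Q + Q_lev))
        C_ss_FF = S_eff * beta / ((beta + Q_lev) * (Q + Q_lev))

        # Eigenvectors u_i = (a12, lam_i − a11); U = [u1 u2] columnwise.
        u1f = lam1 - a11
        u2f = lam2 - a11
        detU = a12 * (lam2 - lam1)
        # alpha = U^{-1} (−C_ss): start from rest.
        alpha1 = (a12 * C_ss_FF - u2f * C_ss_NF) / detU
        alpha2 = (u1f * C_ss_NF - a12 * C_ss_FF) / detU

        self.t_g = t_g
        self.lam1, self.lam2 = lam1, lam2
        self.a12, self.u1f, self.u2f = a12, u1f, u2f
        self.C_ss_NF, self.C_ss_FF = C_ss_NF, C_ss_FF
        self.alpha1, self.alpha2 = alpha1, alpha2

        e1, e2 = np.exp(lam1 * t_g), np.exp(lam2 * t_g)
        C_tg_NF = C_ss_NF + alpha1 * a12 * e1 + alpha2 * a12 * e2
        C_tg_FF = C_ss_FF + alpha1 * u1f * e1 + alpha2 * u2f * e2
        # gamma = U^{-1} C(t_g): pure-decay mode amplitudes.
        self.gamma1 = (u2f * C_tg_NF - a12 * C_tg_FF) / detU
        self.gamma2 = (a12 * C_tg_FF - u1f * C_tg_NF) / detU
        self._I_tg_NF, self._I_tg_FF = self._cumint_on(t_g)

    def _cumint_on(self, t):
        g1 = self.alpha1 * np.expm1(self.lam1 * t) / self.lam1
        g2 = self.alpha2 * np.expm1(self.lam2 * t) / self.lam2
        I_NF = self.C_ss_NF * t + self.a12 * (g1 + g2)
        I_FF = self.C_ss_FF * t + self.u1f * g1 + self.u2f * g2
        return I_NF, I_FF

    def concentration(self, t):
        t = np.asarray(t, dtype=float)
        ton = np.minimum(t, self.t_g)
        e1, e2 = np.exp(self.lam1 * ton), np.exp(self.lam2 * ton)
        on_NF = self.C_ss_NF + self.alpha1 * self.a12 * e1 + self.alpha2 * self.a12 * e2
        on_FF = self.C_ss_FF + self.alpha1 * self.u1f * e1 + self.alpha2 * self.u2f * e2
        s = np.maximum(t - self.t_g, 0.0)
        d1, d2 = np.exp(self.lam1 * s), np.exp(self.lam2 * s)
        off_NF = self.gamma1 * self.a12 * d1 + self.gamma2 * self.a12 * d2
        off_FF = self.gamma1 * self.u1f * d1 + self.gamma2 * self.u2f * d2
        on = t <= self.t_g
        return np.where(on, on_NF, off_NF), np.where(on, on_FF, off_FF)

    def cumulative_integral(self, t):
        t = np.asarray(t, dtype=float)
        I_on_NF, I_on_FF = self._cumint_on(np.minimum(t, self.t_g))
        s = np.maximum(t - self.t_g, 0.0)
        g1 = self.gamma1 * np.expm1(self.lam1 * s) / self.lam1
        g2 = self.gamma2 * np.expm1(self.lam2 * s) / self.lam2
        on = t <= self.t_g
        I_NF = np.where(on, I_on_NF, self._I_tg_NF + self.a12 * (g1 + g2))
        I_FF = np.where(on, I_on_FF, self._I_tg_FF + self.u1f * g1 + self.u2f * g2)
        return I_NF, I_FF


def _shifted(kernel_times: np.ndarray, t_start: float) -> np.ndarray:
    return np.maximum(np.asarray(kernel_times, dtype=float) - t_start, 0.0)


# ---------------------------------------------------------------------------
# Public solvers
# ---------------------------------------------------------------------------


def solve_one_box(
    config: ModelConfig,
    schedule: SourceSchedule,
    grid: Optional[np.ndarray] = None,
) -> ConcentrationSeries:
    """Solve the well-mixed room model on a time grid.

    The room obeys ``V_room dC/dt = S(t) − Q C`` with ``C(0) = 0``; during
    generation ``C(t) = (S/Q)(1 − e^{−Q t / V_room})`` followed by pure
    exponential decay once the source switches off.
    """
    if ModelKind(config.model_kind) is not ModelKind.ONE_BOX:
        raise InvalidConfigError(f"solve_one_box requires one_box, got {config.model_kind}")
    times = default_grid(schedule.T_shift) if grid is None else np.asarray(grid, float)
    kern = _OneBoxKernel(config.V_room, config.Q, schedule.S_m, schedule.t_g)
    C = np.maximum(kern.concentration(_shifted(times, schedule.t_start)), 0.0)
    return ConcentrationSeries(times=times, C_FF=C, C_NF=None, model_kind=ModelKind.ONE_BOX)


def _solve_two_box_generic(config, schedule, grid, S_eff, kind):
    times = default_grid(schedule.T_shift) if grid is None else np.asarray(grid, float)
    kern = _TwoBoxKernel(
        config.V_NF, config.V_FF, config.beta, config.Q,
        config.Q_lev if kind is ModelKind.TWO_BOX_LEV else 0.0,
        S_eff, schedule.t_g,
    )
    C_NF, C_FF = kern.concentration(_shifted(times, schedule.t_start))
    # closed-form evaluation can leave O(eps) negative residue at C = 0
    C_NF, C_FF = np.maximum(C_NF, 0.0), np.maximum(C_FF, 0.0)
    return ConcentrationSeries(
        times=times, C_FF=C_FF, C_NF=C_NF, model_kind=kind,
        V_NF=config.V_NF, V_FF=config.V_FF,
    )


def solve_two_box(
    config: ModelConfig,
    schedule: SourceSchedule,
    grid: Optional[np.ndarray] = None,
) -> ConcentrationSeries:
    """Solve the NF/FF model without local controls.

    Coupled balance: ``V_NF dC_NF/dt = S + β(C_FF − C_NF)`` and
    ``V_FF dC_FF/dt = β C_NF − (β + Q) C_FF`` from a zero initial state.
    """
    if ModelKind(config.model_kind) is not ModelKind.TWO_BOX:
        raise InvalidConfigError(f"solve_two_box requires two_box, got {config.model_kind}")
    return _solve_two_box_generic(config, schedule, grid, schedule.S_m, ModelKind.TWO_BOX)


def solve_two_box_lev(
    config: ModelConfig,
    schedule: SourceSchedule,
    grid: Optional[np.ndarray] = None,
) -> ConcentrationSeries:
    """Solve the NF/FF model with local exhaust extracting from the NF.

    A fraction ``epsilon`` of the emission is captured at the source; the
    remainder enters the NF.  The extraction flow ``Q_lev`` leaves the NF
    to outdoors, is made up by an increased FF→NF flow (β + Q_lev), and the
    fresh-air supply to the FF rises by the same amount, so both zones stay
    flow-balanced.
    """
    if ModelKind(config.model_kind) is not ModelKind.TWO_BOX_LEV:
        raise InvalidConfigError(f"solve_two_box_lev requires two_box_lev, got {config.model_kind}")
    S_eff = schedule.S_m * (1.0 - config.epsilon)
    return _solve_two_box_generic(config, schedule, grid, S_eff, ModelKind.TWO_BOX_LEV)


def solve(config: ModelConfig, schedule: SourceSchedule, grid=None) -> ConcentrationSeries:
    """Dispatch to the solver matching ``config.model_kind``."""
    kind = ModelKind(config.model_kind)
    if kind is ModelKind.ONE_BOX:
        return solve_one_box(config, schedule, grid)
    if kind is ModelKind.TWO_BOX:
        return solve_two_box(config, schedule, grid)
    return solve_two_box_lev(config, schedule, grid)


def time_weighted_average(series: ConcentrationSeries, window: ExposureWindow) -> float:
    """Trapezoidal TWA of a zone concentration over ``[t_1, t_2]``.

    Window endpoints off the grid are linearly interpolated in.  Zone
    ``"room"`` means the single concentration for one-box runs and the
    volume-weighted average of NF and FF for two-box runs.
    """
    kind = ModelKind(series.model_kind)
    if window.zone == "NF":
        if series.C_NF is None:
            raise InvalidRequestError("NF zone requested for a one-box series")
        values = series.C_NF
    elif window.zone == "FF":
        values = series.C_FF
    else:  # room
        if kind is ModelKind.ONE_BOX:
            values = series.C_FF
        else:
            if series.V_NF is None or series.V_FF is None:
                raise InvalidRequestError("room average needs zone volumes on the series")
            w = series.V_NF / (series.V_NF + series.V_FF)
            values = w * series.C_NF + (1.0 - w) * series.C_FF

    t = series.times
    if window.t_1 < t[0] - 1e-9 or window.t_2 > t[-1] + 1e-9:
        raise InvalidRequestError(
            f"window [{window.t_1}, {window.t_2}] outside series span [{t[0]}, {t[-1]}]"
        )
    inside = (t > window.t_1) & (t < window.t_2)
    tt = np.concatenate(([window.t_1], t[inside], [window.t_2]))
    vv = np.concatenate((
        [np.interp(window.t_1, t, values)],
        values[inside],
        [np.interp(window.t_2, t, values)],
    ))
    return float(np.trapezoid(vv, tt) / (window.t_2 - window.t_1))


# ---------------------------------------------------------------------------
# Vectorised exact window averages (Monte Carlo fast path)
# ---------------------------------------------------------------------------


def one_box_window_twa(V_room, Q, S, t_g, t_1, t_2, t_start=0.0):
    """Exact TWA of the one-box concentration over [t_1, t_2]; array-aware."""
    kern = _OneBoxKernel(np.asarray(V_room, float), np.asarray(Q, float),
                         np.asarray(S, float), np.asarray(t_g, float))
    hi = np.maximum(np.asarray(t_2, float) - t_start, 0.0)
    lo = np.maximum(np.asarray(t_1, float) - t_start, 0.0)
    return (kern.cumulative_integral(hi) - kern.cumulative_integral(lo)) / (t_2 - t_1)


def two_box_window_twa(V_NF, V_FF, beta, Q, Q_lev, S_eff, t_g, t_1, t_2, t_start=0.0):
    """Exact NF and FF TWAs of the two-box system over [t_1, t_2]; array-aware.

    Returns ``(twa_NF, twa_FF)``.  ``S_eff`` must already include any
    source-capture factor ``(1 − epsilon)``; pass ``Q_lev = 0`` for the
    uncontrolled two-box model.
    """
    kern = _TwoBoxKernel(
        np.asarray(V_NF, float), np.asarray(V_FF, float), np.asarray(beta, float),
        np.asarray(Q, float), np.asarray(Q_lev, float), np.asarray(S_eff, float),
        np.asarray(t_g, float),
    )
    hi = np.maximum(np.asarray(t_2, float) - t_start, 0.0)
    lo = np.maximum(np.asarray(t_1, float) - t_start, 0.0)
    I_NF_hi, I_FF_hi = kern.cumulative_integral(hi)
    I_NF_lo, I_FF_lo = kern.cumulative_integral(lo)
    dt = t_2 - t_1
    return (I_NF_hi - I_NF_lo) / dt, (I_FF_hi - I_FF_lo) / dt
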