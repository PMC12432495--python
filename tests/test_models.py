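"""Compartment-model solutions against an independent ODE integrator and
closed-form steady-state algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from fumebox.models import (
    ExposureWindow,
    InvalidConfigError,
    InvalidRequestError,
    ModelConfig,
    ModelKind,
    SourceSchedule,
    default_grid,
    solve,
    solve_one_box,
    solve_two_box,
    solve_two_box_lev,
    time_weighted_average,
)

from conftest import random_config, random_schedule


def oracle_series(config: ModelConfig, schedule: SourceSchedule, times: np.ndarray):
    """Independent high-accuracy numerical integration of the stated ODEs.

    The on/off source makes the right-hand side discontinuous, so each
    smooth phase (pre-source, source on, decay) is integrated separately.
    """
    kind = ModelKind(config.model_kind)

    def rhs_factory(S):
        if kind is ModelKind.ONE_BOX:
            return lambda t, y: [(S - config.Q * y[0]) / config.V_room]
        L = config.Q_lev if kind is ModelKind.TWO_BOX_LEV else 0.0
        eps = config.epsilon if kind is ModelKind.TWO_BOX_LEV else 0.0

        def rhs(t, y):
            c_nf, c_ff = y
            d_nf = (S * (1 - eps) + (config.beta + L) * (c_ff - c_nf)) / config.V_NF
            d_ff = (config.beta * c_nf - (config.Q + config.beta + L) * c_ff) / config.V_FF
            return [d_nf, d_ff]
        return rhs

    dim = 1 if kind is ModelKind.ONE_BOX else 2
    y = np.zeros(dim)
    out = np.zeros((dim, times.size))
    t_on, t_off = schedule.t_start, schedule.t_start + schedule.t_g
    phases = [(times[0], t_on, 0.0), (t_on, t_off, schedule.S_m),
              (t_off, times[-1], 0.0)]
    for a, b, S in phases:
        if b <= a:
            continue
        mask = (times >= a - 1e-12) & (times <= b + 1e-12)
        t_eval = np.clip(times[mask], a, b)
        sol = solve_ivp(rhs_factory(S), (a, b), y, t_eval=t_eval, method="LSODA",
                        rtol=1e-11, atol=1e-13)
        assert sol.success
        out[:, mask] = sol.y
        y = sol.y[:, -1]
    return out


def assert_matches_oracle(config, schedule, rel=1e-6):
    times = np.linspace(0.0, schedule.T_shift, 33)
    # avoid evaluating exactly at the source switch-off (integrator smearing)
    times = np.unique(np.concatenate([times, [schedule.t_start, schedule.t_start + schedule.t_g]]))
    series = solve(config, schedule, grid=times)
    y = oracle_series(config, schedule, times)
    scale = max(y.max(), 1e-12)
    if series.C_NF is not None:
        np.testing.assert_allclose(series.C_NF, y[0], rtol=rel, atol=rel * scale)
        np.testing.assert_allclose(series.C_FF, y[1], rtol=rel, atol=rel * scale)
    else:
        np.testing.assert_allclose(series.C_FF, y[0], rtol=rel, atol=rel * scale)


@pytest.mark.parametrize("kind", list(ModelKind))
def test_solvers_match_independent_ode_oracle(kind, rng):
    """Closed-form solutions equal a high-accuracy stiff integration of the
    stated mass balances, to 1e-6 relative, across random configurations."""
    for _ in range(34):
        assert_matches_oracle(random_config(rng, kind), random_schedule(rng))


def test_one_box_steady_state_and_transient():
    """Well-mixed room approaches S/Q; the transient follows 1 - e^{-t/tau}."""
    config = ModelConfig(ModelKind.ONE_BOX, V_room=62.1, ach=60.4)
    Q = config.Q
    assert Q == pytest.approx(62.51, abs=0.01)
    schedule = SourceSchedule(S_m=272.5, t_g=4000.0, T_shift=4000.0)
    series = solve_one_box(config, schedule, grid=np.array([0.0, 3 * 62.1 / Q, 3900.0]))
    c_ss = 272.5 / Q
    assert c_ss == pytest.approx(4.359, abs=2e-3)
    assert series.C_FF[-1] == pytest.approx(c_ss, rel=1e-9)
    assert series.C_FF[1] == pytest.approx((1 - np.exp(-3)) * c_ss, rel=1e-9)
    assert series.C_FF[0] == 0.0


def test_zero_source_is_identically_zero():
    config = ModelConfig(ModelKind.TWO_BOX, V_room=100.0, ach=10.0, V_NF=5.0, beta=15.0)
    series = solve_two_box(config, SourceSchedule(S_m=0.0, t_g=100.0))
    assert np.all(series.C_NF == 0.0)
    assert np.all(series.C_FF == 0.0)


def test_two_box_steady_state_algebra():
    """NF settles at S/beta + S/Q and FF at S/Q for a sustained source."""
    config = ModelConfig(ModelKind.TWO_BOX, V_room=81.0, ach=15.6 * 60 / 81.0,
                         V_NF=4.0, beta=20.2)
    schedule = SourceSchedule(S_m=444.0, t_g=5000.0, T_shift=5000.0)
    series = solve_two_box(config, schedule, grid=np.array([0.0, 4999.0]))
    assert series.C_NF[-1] == pytest.approx(444 / 20.2 + 444 / 15.6, rel=1e-6)
    assert series.C_FF[-1] == pytest.approx(444 / 15.6, rel=1e-6)
    assert series.C_NF[-1] == pytest.approx(50.44, abs=0.01)
    assert series.C_FF[-1] == pytest.approx(28.46, abs=0.01)


def test_two_box_lev_steady_state_and_mass_conservation(rng):
    """LEV steady state matches the flow-balance algebra, and total removal
    (FF exhaust + LEV extraction) equals the uncaptured emission."""
    config = ModelConfig(ModelKind.TWO_BOX_LEV, V_room=81.0, ach=15.6 * 60 / 81.0,
                         V_NF=4.0, beta=20.2, Q_lev=1.25, epsilon=0.89)
    schedule = SourceSchedule(S_m=444.0, t_g=5000.0, T_shift=5000.0)
    series = solve_two_box_lev(config, schedule, grid=np.array([0.0, 4999.0]))
    S_eff = 444.0 * (1 - 0.89)
    Q, beta, L = config.Q, 20.2, 1.25
    expected_nf = S_eff * (Q + beta + L) / ((beta + L) * (Q + L))
    assert expected_nf == pytest.approx(5.01, abs=0.01)
    assert series.C_NF[-1] == pytest.approx(expected_nf, rel=1e-6)
    # steady-state mass conservation, also on random configs
    for _ in range(10):
        cfg = random_config(rng, ModelKind.TWO_BOX_LEV)
        sch = SourceSchedule(S_m=500.0, t_g=50000.0, T_shift=50000.0)
        s = solve_two_box_lev(cfg, sch, grid=np.array([0.0, 49999.0]))
        removal = cfg.Q * s.C_FF[-1] + cfg.Q_lev * s.C_NF[-1]
        assert removal == pytest.approx(500.0 * (1 - cfg.epsilon), rel=1e-6)


def test_complete_capture_gives_zero_exposure():
    config = ModelConfig(ModelKind.TWO_BOX_LEV, V_room=100.0, ach=10.0, V_NF=4.0,
                         beta=20.0, Q_lev=5.0, epsilon=1.0)
    series = solve_two_box_lev(config, SourceSchedule(S_m=1000.0, t_g=400.0))
    assert np.all(series.C_NF == 0.0)
    assert np.all(series.C_FF == 0.0)


def test_well_mixed_limit_recovers_one_box():
    """With unbounded NF-FF exchange both zones track the one-box solution."""
    one = ModelConfig(ModelKind.ONE_BOX, V_room=100.0, ach=12.0)
    two = ModelConfig(ModelKind.TWO_BOX, V_room=100.0, ach=12.0, V_NF=5.0, beta=1e6)
    schedule = SourceSchedule(S_m=500.0, t_g=200.0)
    grid = default_grid(480.0)[1:]  # skip t=0 where both are exactly zero
    ref = solve_one_box(one, schedule, grid=grid).C_FF
    series = solve_two_box(two, schedule, grid=grid)
    np.testing.assert_allclose(series.C_NF, ref, rtol=1e-3)
    np.testing.assert_allclose(series.C_FF, ref, rtol=1e-3)


def test_zero_control_limit_recovers_plain_two_box():
    base = dict(V_room=90.0, ach=8.0, V_NF=6.0, beta=14.0)
    schedule = SourceSchedule(S_m=300.0, t_g=150.0)
    plain = solve_two_box(ModelConfig(ModelKind.TWO_BOX, **base), schedule)
    lev = solve_two_box_lev(
        ModelConfig(ModelKind.TWO_BOX_LEV, Q_lev=1e-9, epsilon=0.0, **base), schedule)
    np.testing.assert_allclose(lev.C_NF, plain.C_NF, rtol=0, atol=1e-9 * plain.C_NF.max())
    np.testing.assert_allclose(lev.C_FF, plain.C_FF, rtol=0, atol=1e-9 * plain.C_FF.max())


def test_concentration_linearity_in_source(rng):
    """Doubling the emission rate exactly doubles concentrations and TWA."""
    for kind in (ModelKind.ONE_BOX, ModelKind.TWO_BOX, ModelKind.TWO_BOX_LEV):
        cfg = random_config(rng, kind)
        sch = random_schedule(rng)
        sch2 = SourceSchedule(S_m=2 * sch.S_m, t_g=sch.t_g, t_start=sch.t_start,
                              T_shift=sch.T_shift)
        a, b = solve(cfg, sch), solve(cfg, sch2)
        np.testing.assert_allclose(b.C_FF, 2 * a.C_FF, rtol=1e-12)
        w = ExposureWindow(0.0, 480.0, zone="FF")
        assert time_weighted_average(b, w) == pytest.approx(
            2 * time_weighted_average(a, w), rel=1e-12)


def test_nf_dominates_ff_for_nf_source(rng):
    for _ in range(5):
        cfg = random_config(rng, ModelKind.TWO_BOX)
        series = solve_two_box(cfg, random_schedule(rng))
        assert np.all(series.C_NF >= series.C_FF - 1e-12)
        assert np.all(series.C_NF >= 0) and np.all(series.C_FF >= 0)


def test_twa_monotone_in_dilution_parameters():
    """More ventilation, exchange, extraction or capture never increases TWA."""
    base = dict(V_room=75.0, ach=12.5, V_NF=4.0, beta=20.0)
    sch = SourceSchedule(S_m=800.0, t_g=96.0)
    w = ExposureWindow(0.0, 480.0, zone="NF")

    def nf_twa(**over):
        params = {**base, "Q_lev": 5.0, "epsilon": 0.5, **over}
        cfg = ModelConfig(ModelKind.TWO_BOX_LEV, **params)
        return time_weighted_average(solve_two_box_lev(cfg, sch), w)

    for name, lo, hi in [("ach", 5.0, 20.0), ("beta", 9.5, 30.8),
                         ("Q_lev", 2.5, 20.0), ("epsilon", 0.4, 0.88)]:
        assert nf_twa(**{name: hi}) < nf_twa(**{name: lo})


def test_twa_of_transient_one_box():
    """Hour-average of the saturating transient matches the analytic integral."""
    config = ModelConfig(ModelKind.ONE_BOX, V_room=62.1, ach=60.4)
    schedule = SourceSchedule(S_m=272.5, t_g=60.0, T_shift=60.0)
    series = solve_one_box(config, schedule, grid=default_grid(60.0, dt=0.05))
    twa = time_weighted_average(series, ExposureWindow(0.0, 60.0, zone="room"))
    k = config.Q / 62.1
    analytic = (272.5 / config.Q) * (1 - (1 - np.exp(-60 * k)) / (60 * k))
    assert twa == pytest.approx(analytic, rel=1e-5)
    assert twa == pytest.approx(4.29, abs=0.01)


def test_twa_constant_window_and_decay_tail():
    cfg = ModelConfig(ModelKind.ONE_BOX, V_room=50.0, ach=30.0)
    sch = SourceSchedule(S_m=100.0, t_g=60.0, T_shift=480.0)
    series = solve_one_box(cfg, sch)
    peak = series.C_FF.max()
    # >= 10 time constants after switch-off the residual is negligible
    tau = 50.0 / cfg.Q
    late = time_weighted_average(series, ExposureWindow(60 + 12 * tau, 480.0, zone="room"))
    assert late < 1e-3 * peak
    # constant-concentration window: TWA equals the constant (steady state)
    cfg2 = ModelConfig(ModelKind.ONE_BOX, V_room=50.0, ach=60.0)
    sch2 = SourceSchedule(S_m=100.0, t_g=480.0, T_shift=480.0)
    s2 = solve_one_box(cfg2, sch2)
    c_ss = 100.0 / cfg2.Q
    assert time_weighted_average(s2, ExposureWindow(400.0, 480.0, zone="room")) == \
        pytest.approx(c_ss, rel=1e-6)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    V_room=st.floats(20.0, 500.0),
    ach=st.floats(0.5, 80.0),
    v_frac=st.floats(0.01, 0.4),
    beta=st.floats(1.0, 60.0),
    S=st.floats(1.0, 5000.0),
    t_g=st.floats(1.0, 480.0),
)
def test_two_box_steady_state_identity_property(V_room, ach, v_frac, beta, S, t_g):
    """For any valid geometry the sustained-source balance holds: FF settles
    at S/Q and NF sits exactly S/beta above it."""
    cfg = ModelConfig(ModelKind.TWO_BOX, V_room=V_room, ach=ach,
                      V_NF=v_frac * V_room, beta=beta)
    horizon = 500.0 * max(V_room / cfg.Q, cfg.V_NF / beta)
    series = solve_two_box(cfg, SourceSchedule(S_m=S, t_g=horizon, T_shift=horizon),
                           grid=np.array([0.0, horizon * 0.99]))
    assert series.C_FF[-1] == pytest.approx(S / cfg.Q, rel=1e-6)
    assert series.C_NF[-1] - series.C_FF[-1] == pytest.approx(S / beta, rel=1e-6)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(scale=st.floats(0.01, 100.0), t_g=st.floats(1.0, 400.0),
       t_start=st.floats(0.0, 80.0))
def test_twa_scale_invariance_property(scale, t_g, t_start):
    """Scaling the emission rate scales every window TWA by the same factor,
    regardless of schedule timing."""
    cfg = ModelConfig(ModelKind.TWO_BOX, V_room=75.0, ach=12.5, V_NF=4.0, beta=20.2)
    w = ExposureWindow(0.0, 480.0, zone="NF")
    base = time_weighted_average(
        solve(cfg, SourceSchedule(S_m=100.0, t_g=t_g, t_start=t_start)), w)
    scaled = time_weighted_average(
        solve(cfg, SourceSchedule(S_m=100.0 * scale, t_g=t_g, t_start=t_start)), w)
    assert scaled == pytest.approx(base * scale, rel=1e-9)


def test_invalid_configurations_rejected():
    with pytest.raises(InvalidConfigError):
        ModelConfig(ModelKind.ONE_BOX, V_room=-5.0, ach=10.0)
    with pytest.raises(InvalidConfigError):
        ModelConfig(ModelKind.ONE_BOX, V_room=50.0, ach=0.0)
    with pytest.raises(InvalidConfigError):
        ModelConfig(ModelKind.TWO_BOX, V_room=50.0, ach=10.0, V_NF=60.0, beta=10.0)
    with pytest.raises(InvalidConfigError):
        ModelConfig(ModelKind.TWO_BOX_LEV, V_room=50.0, ach=10.0, V_NF=5.0,
                    beta=10.0, Q_lev=1.0, epsilon=1.2)
    with pytest.raises(InvalidConfigError):
        SourceSchedule(S_m=10.0, t_g=400.0, t_start=200.0, T_shift=480.0)
    cfg = ModelConfig(ModelKind.TWO_BOX, V_room=50.0, ach=10.0, V_NF=5.0, beta=10.0)
    with pytest.raises(InvalidConfigError):
        solve_one_box(cfg, SourceSchedule(S_m=1.0, t_g=10.0))


def test_nf_zone_invalid_for_one_box_series():
    series = solve_one_box(ModelConfig(ModelKind.ONE_BOX, V_room=50.0, ach=10.0),
                           SourceSchedule(S_m=10.0, t_g=100.0))
    with pytest.raises(InvalidRequestError):
        time_weighted_average(series, ExposureWindow(0.0, 60.0, zone="NF"))
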