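"""Unit and property tests for the constitutive laws and the integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cardioloop as cl
from cardioloop.errors import ConfigurationError, IntegrationError
from cardioloop.network import (CompartmentSpec, HemoState, NetworkSpec,
                                ResistorSpec, RespirationSpec)


# ---------------------------------------------------------------------------
# valve_flow
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pu, pd_, r, one_way, expected", [
    (100.0, 80.0, 1.0, True, 20.0),   # hydraulic Ohm analogue
    (80.0, 100.0, 1.0, True, 0.0),    # diode: no reverse flow
    (90.0, 90.0, 0.5, False, 0.0),    # zero gradient
    (80.0, 100.0, 2.0, False, -10.0),  # two-way element may reverse
])
def test_valve_flow_examples(pu, pd_, r, one_way, expected):
    assert cl.valve_flow(pu, pd_, r, one_way) == pytest.approx(expected)


def test_valve_flow_rejects_nonpositive_resistance():
    with pytest.raises(ConfigurationError):
        cl.valve_flow(100.0, 80.0, 0.0, True)


@settings(max_examples=200, deadline=None)
@given(pu=st.floats(-50, 300), pd_=st.floats(-50, 300),
       r=st.floats(0.001, 10.0))
def test_one_way_flow_never_negative(pu, pd_, r):
    assert cl.valve_flow(pu, pd_, r, True) >= 0.0


# ---------------------------------------------------------------------------
# ventricular activation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("shape", ["half_sine", "skewed_half_sine"])
@pytest.mark.parametrize("hr", [45.0, 60.0, 120.0, 180.0])
def test_activation_support_is_exactly_systole_duration(shape, hr):
    """a > 0 on exactly (0, 0.2) s regardless of heart rate."""
    period = 60.0 / hr
    phases = np.arange(0.0, period, 1e-4)
    act = np.array([cl.ventricular_activation(p, 0.2, shape) for p in phases])
    positive = phases[act > 0]
    assert positive.min() == pytest.approx(1e-4)
    assert positive.max() == pytest.approx(0.2 - 1e-4)
    assert act[phases >= 0.2].max() == 0.0


@pytest.mark.parametrize("shape", ["half_sine", "skewed_half_sine"])
def test_activation_reaches_one_within_systole(shape):
    phases = np.linspace(0.0, 0.2, 4001)
    act = [cl.ventricular_activation(p, 0.2, shape) for p in phases]
    assert max(act) == pytest.approx(1.0, abs=1e-5)


def test_activation_zero_in_diastole():
    assert cl.ventricular_activation(0.30, 0.2) == 0.0


def test_skew_moves_peak_later():
    phases = np.linspace(0.0, 0.2, 2001)
    peak = {
        shape: phases[np.argmax([cl.ventricular_activation(p, 0.2, shape)
                                 for p in phases])]
        for shape in ("half_sine", "skewed_half_sine")
    }
    assert peak["half_sine"] == pytest.approx(0.1, abs=1e-3)
    assert peak["skewed_half_sine"] > 0.11


# ---------------------------------------------------------------------------
# effective gain (inotropic limiter)
# ---------------------------------------------------------------------------

def test_effective_gain_saturates_at_limiter():
    at_limit = cl.effective_gain(100.0, 8.0, 8.0)
    beyond = cl.effective_gain(100.0, 16.0, 8.0)
    assert at_limit == beyond


def test_effective_gain_zero_drive_identity():
    assert cl.effective_gain(100.0, 0.0, 8.0) == 100.0


def test_effective_gain_monotone_over_drive_grid():
    grid = [cl.effective_gain(100.0, d, 8.0) for d in np.linspace(0, 8, 33)]
    assert all(b >= a for a, b in zip(grid, grid[1:]))


def test_effective_gain_clips_negative_drive_with_warning():
    with pytest.warns(RuntimeWarning):
        assert cl.effective_gain(100.0, -1.0, 8.0) == 100.0


# ---------------------------------------------------------------------------
# ventricular pressure
# ---------------------------------------------------------------------------

def test_diastolic_pressure_slightly_negative_with_thoracic_reference():
    # relaxed ventricle near its unstressed volume, sub-atmospheric ITP
    p = cl.ventricular_pressure(55.0, 0.0, 3.0, 50.0, 20.0, itp=-4.0)
    assert -4.0 < p < 0.0


def test_pressure_at_unstressed_volume_is_itp_only():
    assert cl.ventricular_pressure(50.0, 0.0, 3.0, 50.0, 20.0, itp=-4.0) == -4.0


def test_pressure_increases_with_elastance():
    """dP/dE_max > 0 at fixed volume and full activation (finite difference)."""
    for e in np.linspace(0.5, 4.0, 8):
        lo = cl.ventricular_pressure(120.0, 1.0, e, 15.0, 30.0)
        hi = cl.ventricular_pressure(120.0, 1.0, e + 1e-4, 15.0, 30.0)
        assert hi > lo


# ---------------------------------------------------------------------------
# intrathoracic pressure
# ---------------------------------------------------------------------------

def test_itp_constant_when_amplitude_zero():
    resp = RespirationSpec(mean_itp=-4.0, amplitude=0.0)
    assert cl.intrathoracic_pressure(2.31, resp) == -4.0


def test_itp_mean_and_periodicity():
    resp = RespirationSpec(mean_itp=-4.0, amplitude=1.0, period=4.0)
    ts = np.linspace(0.0, 4.0, 4000, endpoint=False)
    vals = np.array([cl.intrathoracic_pressure(t, resp) for t in ts])
    assert vals.mean() == pytest.approx(-4.0, abs=1e-9)
    for t in (0.3, 1.7, 3.9):
        assert cl.intrathoracic_pressure(t, resp) == pytest.approx(
            cl.intrathoracic_pressure(t + 4.0, resp), abs=1e-9)


# ---------------------------------------------------------------------------
# derivatives on small networks
# ---------------------------------------------------------------------------

def _rc_pair(r=1.0, c1=2.0, c2=3.0, v1=40.0, v2=0.0):
    comps = [
        CompartmentSpec("a", compliance=c1, unstressed_volume=0.0,
                        initial_volume=v1),
        CompartmentSpec("b", compliance=c2, unstressed_volume=0.0,
                        initial_volume=v2),
    ]
    res = [ResistorSpec("link", "a", "b", r, one_way=False)]
    return NetworkSpec(compartments=comps, resistors=res,
                       respiration=RespirationSpec(amplitude=0.0))


def test_derivatives_conserve_volume(default_params):
    network, control = default_params
    state = HemoState(t=0.0, volumes={c.name: c.initial_volume
                                      for c in network.compartments}
                      | {v: network.ventricles[v].initial_volume
                         for v in network.ventricles},
                      cardiac_phase=0.05, sy=1.0, heart_rate=75.0)
    eff = cl.apply_effectors(1.7, control)
    dv = cl.derivatives(state, network, eff, t=0.2)
    assert abs(sum(dv.values())) < 1e-9


def test_derivatives_zero_at_pressure_equilibrium():
    net = _rc_pair(v1=20.0, v2=30.0)  # both compartments at 10 mmHg
    state = HemoState(t=0.0, volumes={"a": 20.0, "b": 30.0},
                      cardiac_phase=1.0, sy=0.0, heart_rate=60.0)
    dv = cl.derivatives(state, net)
    assert dv == {"a": 0.0, "b": 0.0}


def test_one_way_flows_never_negative_in_closed_loop(default_params):
    """Every valve of the canonical loop is an ideal diode."""
    network, control = default_params
    one_way = [r.name for r in network.resistors if r.one_way]
    rng = np.random.default_rng(7)
    names = [c.name for c in network.compartments] + list(network.ventricles)
    for _ in range(200):
        vols = {n: float(rng.uniform(5.0, 600.0)) for n in names}
        state = HemoState(t=float(rng.uniform(0, 10)), volumes=vols,
                          cardiac_phase=float(rng.uniform(0, 0.7)),
                          sy=1.0, heart_rate=75.0)
        q = cl.flows(state, network, cl.apply_effectors(1.0, control))
        assert all(q[n] >= 0.0 for n in one_way)


def test_rc_discharge_matches_closed_form():
    """Two-compartment discharge relaxes with tau = R * C_series."""
    r, c1, c2 = 1.0, 2.0, 3.0
    net = _rc_pair(r=r, c1=c1, c2=c2, v1=40.0, v2=0.0)
    times, vols = cl.integrate_passive(net, (0.0, 5.0), dt=0.001)
    tau = r * (c1 * c2) / (c1 + c2)
    # pressure difference decays exponentially from 20 mmHg
    dp = vols["a"] / c1 - vols["b"] / c2
    expected = 20.0 * np.exp(-times / tau)
    mask = expected > 1e-3
    rel = np.abs(dp[mask] - expected[mask]) / expected[mask]
    assert rel.max() < 1e-4


# ---------------------------------------------------------------------------
# integrate
# ---------------------------------------------------------------------------

def test_integrate_is_deterministic(default_params, tmp_path):
    import copy

    network, control = default_params
    outs = []
    for i in range(2):
        res = cl.integrate(copy.deepcopy(network), copy.deepcopy(control),
                           (0.0, 5.0), dt=0.001)
        p = tmp_path / f"run{i}.csv"
        cl.write_timeseries(res, p)
        outs.append(p.read_bytes())
    assert outs[0] == outs[1]


def test_engines_agree(default_params):
    """The numba kernel and the pure-Python reference share one source."""
    import copy

    network, control = default_params
    frames = {}
    for engine in ("numba", "python"):
        res = cl.integrate(copy.deepcopy(network), copy.deepcopy(control),
                           (0.0, 2.0), dt=0.001, engine=engine)
        frames[engine] = res.frame
    diff = (frames["numba"] - frames["python"]).abs().to_numpy().max()
    assert diff < 1e-8


def test_volume_conservation_short_run(default_params):
    import copy

    network, control = default_params
    res = cl.integrate(copy.deepcopy(network), copy.deepcopy(control),
                       (0.0, 30.0), dt=0.001)
    assert sum(res.final_volumes.values()) == pytest.approx(
        network.total_blood_volume, abs=0.01)


def test_integrate_rejects_bad_span(default_params):
    network, control = default_params
    with pytest.raises(ConfigurationError):
        cl.integrate(network, control, (5.0, 1.0))
    with pytest.raises(ConfigurationError):
        cl.integrate(network, control, (0.0, 1.0), dt=-0.001)


def test_instability_aborts_with_diagnostic(default_params):
    import copy

    network, control = default_params
    bad = copy.deepcopy(network)
    # absurdly stiff arterial compartment -> RK4 blows up at dt 1 ms
    bad.compartment("systemic_arteries").compliance = 1e-5
    with pytest.raises(IntegrationError, match="instability|non-finite"):
        cl.integrate(bad, copy.deepcopy(control), (0.0, 2.0), dt=0.001)


def test_no_pump_no_flow(default_params):
    """With negligible contractility in both ventricles, CO decays to ~0."""
    import copy

    network, control = default_params
    weak = copy.deepcopy(network)
    for v in weak.ventricles.values():
        v.nominal_gain = 1e-3
    con = copy.deepcopy(control)
    con.clamps = {"heart_rate": 75.0, "sy": 1.0}
    res = cl.integrate(weak, con, (0.0, 40.0), dt=0.001)
    tail = res.frame[res.frame.t > 35.0]
    assert tail.CO.abs().max() < 150.0  # mL/min; ~2% of normal output
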