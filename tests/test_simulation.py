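"""Integration, event detection, signatures and regime classification."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

import campmmo.simulation as sim
from campmmo.model_core import ModelParameters, condition_params, rhs_5d
from campmmo.simulation import (
    OscillationEvent,
    Trajectory,
    classify_regime,
    detect_events,
    firing_frequency,
    integrate,
    mmo_signature,
    trim_to_complete_blocks,
)


def _event(t, kind):
    return OscillationEvent(t, 10.0 if kind == "LAO" else -65.0, kind)


def _synthetic_trajectory(V, dt=0.01):
    t = np.arange(len(V)) * dt
    y = np.column_stack([V, *(np.full(len(V), 0.5) for _ in range(4))])
    return Trajectory(t, y, ModelParameters(), "5D")


class TestIntegrator:
    def test_rejects_bad_step(self):
        with pytest.raises(ValueError):
            integrate(ModelParameters(), 10.0, dt=0.0)

    def test_stable_equilibrium_is_preserved(self):
        """A true equilibrium state stays put to 1e-6 mV over 100 ms."""
        p = condition_params("Ctrl").with_(IApp=50.0)  # silent regime
        y_eq = fsolve(lambda y: rhs_5d(0.0, y, p),
                      integrate(p, 300.0).y[-1], full_output=False,
                      xtol=1e-13)
        traj = integrate(p, 100.0, ic=y_eq)
        assert np.max(np.abs(traj.V - y_eq[0])) < 1e-6

    def test_fixed_step_matches_adaptive_reference(self, ctrl300):
        """RK4 at 0.001 ms tracks a high-order adaptive solve to <0.1 mV."""
        traj = integrate(ctrl300, 50.0, dt=0.001, record_dt=0.05)
        sol = solve_ivp(rhs_5d, (0.0, 50.0), traj.y[0],
                        args=(ctrl300,), method="DOP853",
                        rtol=1e-10, atol=1e-12, t_eval=traj.t)
        assert np.max(np.abs(sol.y[0] - traj.V)) < 0.1

    def test_gates_stay_in_unit_interval(self, cgs300_traj_5d):
        gates = cgs300_traj_5d.y[:, 1:]
        assert gates.min() > -1e-9
        assert gates.max() < 1 + 1e-9

    def test_3d_matches_5d_with_frozen_gates(self, cgs250):
        """rhs of the reduced model is the (V,h,s) part of the full model."""
        w, r = 0.11, 0.05
        wt = w * (1 + cgs250.dgM / cgs250.gM)
        rt = r * (1 + cgs250.dgHCN / cgs250.gHCN)
        y5 = np.array([-63.0, 0.22, 0.41, r, w])
        from campmmo.reduction import rhs_3d
        d3 = rhs_3d(0.0, y5[:3], cgs250, wt, rt)
        d5 = rhs_5d(0.0, y5, cgs250)
        np.testing.assert_allclose(d3, d5[:3], rtol=1e-12)


class TestEventDetection:
    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            detect_events(_synthetic_trajectory(np.empty(0)))

    def test_damped_subthreshold_oscillation_is_all_saos(self):
        t = np.arange(0, 200, 0.01)
        V = -70 + 5 * np.exp(-t / 60) * np.sin(2 * np.pi * t / 10)
        events = detect_events(_synthetic_trajectory(V))
        assert events and all(e.kind == "SAO" for e in events)

    def test_control_spiking_is_laos_only(self, ctrl300):
        traj = integrate(ctrl300, 450.0)
        events = detect_events(traj.window(350.0))
        assert events and all(e.kind == "LAO" for e in events)

    def test_cgs_mmo_mixes_both_kinds(self, cgs250):
        traj = integrate(cgs250, 450.0)
        kinds = {e.kind for e in detect_events(traj.window(350.0))}
        assert kinds == {"LAO", "SAO"}

    def test_events_are_time_ordered(self, cgs250):
        traj = integrate(cgs250, 450.0)
        tt = [e.t_peak for e in detect_events(traj)]
        assert all(a < b for a, b in zip(tt, tt[1:]))


class TestSignature:
    def test_direct_grouping(self):
        events = [_event(float(i), k)
                  for i, k in enumerate(["LAO", "SAO", "SAO", "SAO",
                                         "LAO", "SAO", "SAO"])]
        sig = mmo_signature(events)
        assert sig.blocks == ((1, 3), (1, 2))
        assert str(sig) == "1312"

    def test_no_laos_is_silent(self):
        sig = mmo_signature([_event(1.0, "SAO"), _event(2.0, "SAO")])
        assert sig.silent and sig.blocks == ()

    def test_periodic_alternation(self):
        seq = ["LAO", "SAO", "SAO", "LAO", "SAO"] * 4
        sig = mmo_signature([_event(float(i), k) for i, k in enumerate(seq)])
        assert sig.unit == ((1, 2), (1, 1))
        assert sig.periodic

    def test_trim_drops_partial_final_block(self):
        seq = ["LAO", "SAO", "SAO", "LAO", "SAO", "SAO", "LAO"]
        events = [_event(float(i), k) for i, k in enumerate(seq)]
        trimmed = trim_to_complete_blocks(events)
        assert [e.kind for e in trimmed] == seq[:-1]

    def test_signature_stable_across_attractor_periods(self, cgs300):
        """The same block unit recurs over >= 3 consecutive periods."""
        traj = integrate(cgs300, 700.0)
        halves = [mmo_signature(trim_to_complete_blocks(
            detect_events(traj.window(a, b)))).unit
            for a, b in ((350.0, 520.0), (520.0, 700.0))]
        assert halves[0] == halves[1]
        assert len(mmo_signature(detect_events(traj.window(350.0))).blocks) >= 6


class TestFiringFrequencyAndRegimes:
    def test_silent_trace_is_zero_hz(self):
        V = np.full(60000, -72.0)
        assert firing_frequency(_synthetic_trajectory(V), t0=350.0) == 0.0

    def test_regular_spiking_rate_matches_isi(self, ctrl300):
        traj = integrate(ctrl300, 1000.0, dt=0.002)
        events = [e for e in detect_events(traj.window(350.0))
                  if e.kind == "LAO"]
        isi = np.diff([e.t_peak for e in events])
        ff = firing_frequency(traj, t0=350.0)
        assert ff == pytest.approx(1000.0 / isi.mean(), rel=0.02)

    @pytest.mark.parametrize("iapp,label", [(50.0, "silent"),
                                            (150.0, "MMO"),
                                            (400.0, "spiking")])
    def test_control_regimes(self, iapp, label):
        assert classify_regime(condition_params("Ctrl"), iapp) == label

    def test_regime_order_and_dt_refinement(self):
        """Boundaries appear in silent->MMO->spiking order and move < 1
        uA/cm^2 when the integration step is halved."""
        p = condition_params("Ctrl")
        lows = []
        for dt in (0.004, 0.002):
            scan = sim.regime_interval_scan(p, (70.0, 100.0), step=10.0,
                                            dt=dt)
            (b, lab_lo, lab_hi) = scan.boundaries[0]
            assert (lab_lo, lab_hi) == ("silent", "MMO")
            lows.append(b)
        assert abs(lows[0] - lows[1]) < 1.0
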