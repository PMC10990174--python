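"""Gating kinetics, currents and right-hand-side identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from campmmo.model_core import (
    CONDITIONS,
    ModelParameters,
    State5D,
    condition_params,
    gate_kinetics,
    ionic_currents,
    resting_state,
    rhs_5d,
    temperature_factor,
)

P0 = ModelParameters()


class TestTemperatureFactor:
    @pytest.mark.parametrize("Q,T,Tref,expected", [
        (3.0, 35.0, 35.0, 1.0),
        (3.0, 37.0, 20.0, 3.0 ** 1.7),
        (3.0, 37.0, 35.0, 3.0 ** 0.2),
        (2.9, 37.0, 20.0, 2.9 ** 1.7),
    ])
    def test_q10_law(self, Q, T, Tref, expected):
        assert temperature_factor(Q, T, Tref) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_rejects_nonpositive_q(self):
        with pytest.raises(ValueError):
            temperature_factor(0.0, 37.0, 20.0)

    def test_hcn_gate_uses_its_own_reference_temperature(self):
        # HCN kinetics were characterised at 35 C, Na+/K+ kinetics at 20 C
        assert P0.phi("r") == pytest.approx(3.0 ** 0.2, rel=1e-12)
        assert P0.phi("s") == pytest.approx(3.0 ** 1.7, rel=1e-12)
        assert P0.phi("h") == pytest.approx(2.9 ** 1.7, rel=1e-12)


class TestParameters:
    def test_defaults_are_the_published_set(self):
        assert (P0.gNaF, P0.gNaP, P0.gKS, P0.gL) == (1000.0, 1.0, 40.0, 11.3)
        assert (P0.gHCN, P0.gM, P0.dgHCN, P0.dgM) == (23.0, 50.0, 12.0, 50.0)
        assert (P0.ENa, P0.EK, P0.EL, P0.EHCN) == (50.0, -84.0, -83.38, -50.0)
        assert (P0.Cm, P0.T, P0.Tref1, P0.Tref2) == (0.9, 37.0, 20.0, 35.0)
        assert (P0.Qm, P0.Qn, P0.Qh, P0.Qs, P0.Qr) == (2.2, 2.2, 2.9, 3.0,
                                                       3.0)

    @pytest.mark.parametrize("name,row", sorted(CONDITIONS.items()))
    def test_condition_rows(self, name, row):
        p = condition_params(name)
        assert (p.gM, p.dgM, p.gHCN, p.dgHCN, p.cAMP) == row

    def test_ctrl_equals_defaults(self):
        assert condition_params("Ctrl") == P0

    def test_unknown_condition_lists_valid_names(self):
        with pytest.raises(KeyError, match="Ctrl"):
            condition_params("TTX")

    @pytest.mark.parametrize("bad", [dict(gM=-1.0), dict(Cm=0.0),
                                     dict(cAMP=2), dict(Qr=-3.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            P0.with_(**bad)

    def test_dict_roundtrip(self):
        p = condition_params("FSK+Lin").with_(IApp=123.0)
        assert ModelParameters.from_dict(p.to_dict()) == p


class TestGateKinetics:
    def test_hcn_half_activation_shift(self):
        assert P0.with_(cAMP=0).nu == 103.5
        assert P0.with_(cAMP=1).nu == 95.0

    def test_m_gate_midpoint_and_time_constant(self):
        k = gate_kinetics(-35.0, P0)
        assert k.w_inf == pytest.approx(0.5, abs=1e-14)
        assert k.tau_w == pytest.approx(400.0 / 4.3, rel=1e-12)

    def test_hcn_gate_midpoint_at_minus_nu(self):
        for camp in (0, 1):
            p = P0.with_(cAMP=camp)
            k = gate_kinetics(-p.nu, p)
            assert k.r_inf == pytest.approx(0.5, abs=1e-12)
            assert k.alpha_r == pytest.approx(0.007, abs=1e-15)
            assert k.beta_r == pytest.approx(0.007, abs=1e-15)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(V=st.floats(min_value=-120.0, max_value=60.0))
    def test_steady_state_and_tau_identities(self, V):
        """p_inf = a/(a+b), tau = 1/(phi(a+b)), p_inf in (0,1), tau > 0."""
        k = gate_kinetics(V, P0)
        for gate in "mhnsr":
            a = getattr(k, f"alpha_{gate}")
            b = getattr(k, f"beta_{gate}")
            pinf = getattr(k, f"{gate}_inf")
            tau = getattr(k, f"tau_{gate}")
            assert 0.0 < pinf < 1.0
            assert tau > 0.0
            assert pinf == pytest.approx(a / (a + b), rel=1e-12)
            assert tau == pytest.approx(1.0 / (k.phi[gate] * (a + b)),
                                        rel=1e-12)
        assert 0.0 < k.w_inf < 1.0 and k.tau_w > 0.0

    @pytest.mark.parametrize("V_sing", [-25.4, -29.7, -118.0, -48.4, -42.7,
                                        -19.5, -87.1])
    def test_removable_singularities_are_continuous(self, V_sing):
        """Rates at 1-exp(.) zeros equal the limit of nearby values."""
        k0 = gate_kinetics(V_sing, P0)
        kl = gate_kinetics(V_sing - 1e-7, P0)
        kr = gate_kinetics(V_sing + 1e-7, P0)
        for gate in "mhns":
            for pre in ("alpha", "beta"):
                v0 = getattr(k0, f"{pre}_{gate}")
                vl = getattr(kl, f"{pre}_{gate}")
                vr = getattr(kr, f"{pre}_{gate}")
                assert v0 == pytest.approx(0.5 * (vl + vr), rel=1e-6)

    def test_steady_state_monotonicity(self):
        V = np.linspace(-120.0, 60.0, 721)
        k = gate_kinetics(V, P0)
        assert np.all(np.diff(k.w_inf) > 0)
        assert np.all(np.diff(k.h_inf) < 0)
        assert np.all(np.diff(k.r_inf) < 0)


class TestCurrentsAndRhs:
    def test_leak_zero_at_reversal(self):
        st5 = State5D(P0.EL, 0.5, 0.5, 0.5, 0.5)
        assert ionic_currents(st5, P0)["I_L"] == 0.0

    def test_hcn_current_with_camp_increment(self):
        st5 = State5D(-60.0, 0.5, 0.5, 0.5, 0.5)
        I = ionic_currents(st5, P0.with_(cAMP=1))
        assert I["I_HCN"] == pytest.approx((23 + 12) * 0.5 * (-60 + 50))

    def test_m_current_reverses_at_ek(self):
        st5 = State5D(-50.0, 0.5, 0.5, 0.5, 0.1)
        I = ionic_currents(st5, P0.with_(cAMP=1))
        assert I["I_M"] == pytest.approx((50 + 50) * 0.1 * (-50 + 84))
        assert ionic_currents(State5D(P0.EK, 0.5, 0.5, 0.5, 0.9),
                              P0)["I_M"] == 0.0

    def test_rhs_vanishes_at_constructed_equilibrium(self):
        V0 = -70.0
        p = P0
        st5 = resting_state(p, V0)
        I = ionic_currents(st5, p)
        p_eq = p.with_(IApp=sum(I.values()))
        dy = rhs_5d(0.0, st5.as_array(), p_eq)
        assert np.max(np.abs(dy)) < 1e-12

    def test_compiled_rhs_matches_numpy_route(self):
        """The njit scalar RHS equals dV = (-sum I + IApp)/Cm, dp = ..."""
        rng = np.random.default_rng(7)
        p = condition_params("CGS").with_(IApp=250.0)
        for _ in range(25):
            y = np.array([rng.uniform(-100, 40), *rng.uniform(0.01, 0.99, 4)])
            I = ionic_currents(y, p)
            k = gate_kinetics(y[0], p)
            expected = np.array([
                (-sum(I.values()) + p.IApp) / p.Cm,
                (k.h_inf - y[1]) / k.tau_h,
                (k.s_inf - y[2]) / k.tau_s,
                (k.r_inf - y[3]) / k.tau_r,
                (k.w_inf - y[4]) / k.tau_w,
            ])
            np.testing.assert_allclose(rhs_5d(0.0, y, p), expected,
                                       rtol=1e-10, atol=1e-12)

    def test_blocked_channels_reduce_to_na_k_leak_core(self):
        p = P0.with_(gHCN=0.0, dgHCN=0.0, gM=0.0, dgM=0.0, IApp=100.0)
        y = np.array([-55.0, 0.3, 0.2, 0.4, 0.6])
        I = ionic_currents(y, p)
        assert I["I_HCN"] == 0.0 and I["I_M"] == 0.0
        core = I["I_NaF"] + I["I_NaP"] + I["I_KS"] + I["I_L"]
        assert rhs_5d(0.0, y, p)[0] == pytest.approx((-core + 100.0) / p.Cm)

    def test_camp_flag_only_acts_through_increments_and_nu(self):
        """With zero increments, cAMP changes only the HCN activation curve."""
        y = np.array([-65.0, 0.3, 0.2, 0.4, 0.6])
        p0 = P0.with_(dgHCN=0.0, dgM=0.0, cAMP=0)
        p1 = P0.with_(dgHCN=0.0, dgM=0.0, cAMP=1)
        I0, I1 = ionic_currents(y, p0), ionic_currents(y, p1)
        for key in I0:
            assert I0[key] == I1[key]
        k0, k1 = gate_kinetics(-65.0, p0), gate_kinetics(-65.0, p1)
        assert k0.r_inf != k1.r_inf          # the nu shift remains
        assert k0.h_inf == k1.h_inf
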