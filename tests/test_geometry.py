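"""Critical manifold, folds, folded node, canards and rotational sectors.

All geometric objects are checked against their defining identities; the
headline property is that the rotational-sector index of a return point
predicts the number of SAOs the simulated orbit then makes.
"""

import numpy as np
import pytest

import campmmo.geometry as geo
import campmmo.simulation as sim
from campmmo.model_core import gate_kinetics, rhs_3d_vec


@pytest.fixture(scope="module")
def wt_rt(cgs250_reduced):
    return cgs250_reduced.w_tilde, cgs250_reduced.r_tilde


class TestCriticalManifold:
    def test_defining_identity_on_grid(self, cgs250, wt_rt):
        """Substituting s = gamma zeroes the V-equation over a 100x100 grid."""
        wt, rt = wt_rt
        V, h = np.meshgrid(np.linspace(-83.0, 20.0, 100),
                           np.linspace(0.01, 0.99, 100))
        s = geo.gamma(V.ravel(), h.ravel(), cgs250, wt, rt)
        P = cgs250.runtime_vector_3d(wt, rt)
        res = np.array([rhs_3d_vec(0.0, np.array([v, hh, ss]), P)[0]
                        for v, hh, ss in zip(V.ravel()[::37],
                                             h.ravel()[::37], s[::37])])
        # dV/dt = (-sum I + IApp)/Cm; currents reach ~1e4 uA/cm^2
        assert np.max(np.abs(res)) * cgs250.Cm < 1e-10 * 1e4

    def test_decomposition_matches_direct_solve(self, cgs250, wt_rt):
        """gamma0 + shifts equals an independent algebraic solve for s."""
        from campmmo.model_core import ionic_currents

        wt, rt = wt_rt
        rng = np.random.default_rng(3)
        for _ in range(20):
            V = rng.uniform(-83.0, 20.0)
            h = rng.uniform(0.01, 0.99)
            g, comps = geo.gamma(V, h, cgs250, wt, rt, components=True)
            assert np.allclose(sum(comps.values()), g, rtol=1e-12)
            # oracle: solve -I_NaF-I_NaP-gKS*s*(V-EK)-I_L-I_HCN-I_M+IApp=0
            I = ionic_currents([V, h, 0.0, 0.0, 0.0], cgs250)
            fixed = (I["I_NaF"] + I["I_NaP"] + I["I_L"]
                     + cgs250.gHCN * rt * (V - cgs250.EHCN)
                     + cgs250.gM * wt * (V - cgs250.EK))
            s_direct = (cgs250.IApp - fixed) / (cgs250.gKS * (V - cgs250.EK))
            assert g == pytest.approx(s_direct, rel=1e-12)

    def test_backbone_only_when_channels_silent(self, cgs250):
        g, comps = geo.gamma(-60.0, 0.3, cgs250, 0.0, 0.0, components=True)
        assert g == comps["gamma0"]

    def test_shift_component_value(self, cgs250):
        _, comps = geo.gamma(-60.0, 0.3, cgs250, 0.0, 0.2, components=True)
        assert comps["gamma_rt"] == pytest.approx(-(23.0 / 40.0) * 0.2)

    def test_singular_at_potassium_reversal(self, cgs250, wt_rt):
        with pytest.raises(ValueError):
            geo.gamma(cgs250.EK, 0.3, cgs250, *wt_rt)


class TestFolds:
    def test_fold_identity_along_both_branches(self, cgs250, wt_rt):
        wt, rt = wt_rt
        folds = geo.fold_curves(cgs250, wt, rt)
        assert set(folds) == {"L-", "L+"}
        for br in folds.values():
            d = geo.dV_f(br["V"], br["h"], br["s"], cgs250, wt, rt)
            assert np.max(np.abs(d)) < 1e-8

    def test_psi_identity_and_r_component(self, cgs250, wt_rt):
        wt, rt = wt_rt
        V = np.linspace(-75.0, -45.0, 30)
        psi, comps = geo.fold_psi(V, cgs250, rt, components=True)
        s = geo.gamma(V, psi, cgs250, wt, rt)
        assert np.nanmax(np.abs(geo.dV_f(V, psi, s, cgs250, wt, rt))) < 1e-8
        psi0, comps0 = geo.fold_psi(V, cgs250, 0.0, components=True)
        np.testing.assert_allclose(comps0["psir"], 0.0)
        np.testing.assert_allclose(psi - psi0, comps["psir"], rtol=1e-10)

    def test_branches_split_the_manifold_into_five_parts(self, cgs250,
                                                         wt_rt):
        """Sa- | L- | Sr | L+ | Sa+ along increasing V at fixed h."""
        wt, rt = wt_rt
        folds = geo.fold_curves(cgs250, wt, rt)
        h = 0.2
        Vm = float(np.interp(h, folds["L-"]["h"], folds["L-"]["V"]))
        Vp = float(np.interp(h, folds["L+"]["h"], folds["L+"]["V"]))
        assert Vm < Vp
        assert geo.sheet(Vm - 2.0, h, cgs250, wt, rt, folds) == "Sa-"
        assert geo.sheet(0.5 * (Vm + Vp), h, cgs250, wt, rt, folds) == "Sr"
        assert geo.sheet(Vp + 2.0, h, cgs250, wt, rt, folds) == "Sa+"


class TestDesingularizedFlow:
    def test_vanishes_at_ordinary_singularity(self, cgs250, wt_rt):
        wt, rt = wt_rt
        roots = geo.ordinary_singularities(cgs250, wt, rt)
        assert len(roots) == 1
        V0, h0, _ = roots[0]
        F = geo.desingularized_rhs(V0, h0, cgs250, wt, rt)
        assert np.max(np.abs(F)) < 1e-8

    def test_ordinary_singularity_is_the_3d_equilibrium(self, cgs250,
                                                        wt_rt):
        import campmmo.bifurcation as bif

        wt, rt = wt_rt
        root = geo.ordinary_singularities(cgs250, wt, rt)[0]
        eq = bif.find_equilibrium_3d(cgs250, wt, rt)
        assert root[0] == pytest.approx(eq.V, abs=1e-8)
        assert not eq.stable  # unstable in the MMO regime

    def test_orientation_matches_slow_flow_on_attracting_sheet(self, cgs250,
                                                               wt_rt):
        """On Sa- the rescaling factor is positive, so the h-component of
        the desingularized flow has the sign of the slow h-drift."""
        wt, rt = wt_rt
        for V, h in ((-78.0, 0.2), (-76.0, 0.4)):
            k = gate_kinetics(V, cgs250)
            slow = (float(k.h_inf) - h) / float(k.tau_h)
            F = geo.desingularized_rhs(V, h, cgs250, wt, rt)
            assert np.sign(F[1]) == np.sign(slow)


class TestFoldedNode:
    def test_exists_on_hyperpolarized_fold(self, cgs250_fn):
        assert cgs250_fn.kind == "folded node"
        assert cgs250_fn.branch == "L-"

    def test_defining_residual_and_classification(self, cgs250, wt_rt,
                                                  cgs250_fn):
        wt, rt = wt_rt
        F = geo.desingularized_rhs(cgs250_fn.V, cgs250_fn.h, cgs250, wt, rt)
        assert abs(F[0]) < 1e-8          # folded-singularity condition
        lam = cgs250_fn.eigenvalues
        assert np.all(np.abs(lam.imag) < 1e-12)
        assert lam.real[0] * lam.real[1] > 0
        assert 0.0 < cgs250_fn.mu < 1.0

    def test_node_persists_under_parameter_perturbation(self, cgs250,
                                                        wt_rt):
        wt, rt = wt_rt
        for fw in (0.95, 1.05):
            for fr in (0.95, 1.05):
                nodes = [f for f in geo.folded_singularities(
                    cgs250, wt * fw, rt * fr) if f.kind == "folded node"]
                assert len(nodes) == 1

    def test_distinct_from_ordinary_singularity(self, cgs250, wt_rt,
                                                cgs250_fn):
        root = geo.ordinary_singularities(cgs250, *wt_rt)[0]
        assert abs(root[0] - cgs250_fn.V) > 0.1


class TestCanardsAndSectors:
    def test_strong_canard_passes_through_the_node(self, cgs250, wt_rt,
                                                   cgs250_fn):
        xi0 = geo.strong_canard(cgs250_fn, cgs250, *wt_rt)
        assert xi0.index == 0 and xi0.role == "strong"
        d = np.hypot(xi0.samples[:, 0] - cgs250_fn.V,
                     (xi0.samples[:, 1] - cgs250_fn.h) / 0.02)
        assert d.min() < 0.01

    def test_non_node_input_rejected(self, cgs250, wt_rt, cgs250_fn):
        import dataclasses
        saddle = dataclasses.replace(cgs250_fn, kind="folded saddle")
        with pytest.raises(ValueError):
            geo.strong_canard(saddle, cgs250, *wt_rt)

    def test_reconstruction_and_sector_consistency(self, cgs250, wt_rt,
                                                   cgs250_fn):
        """Secondary canards are recovered on the section plane and the
        sector of each funnel return predicts its SAO count exactly."""
        wt, rt = wt_rt
        smf = geo.reconstruct_slow_manifolds(cgs250, wt, rt, fn=cgs250_fn,
                                             n_seeds=60)
        assert smf.lost_fraction < 1.0
        assert len(smf.attracting_hits) >= 10
        assert len(smf.repelling_hits) >= 2
        assert smf.canards, "no secondary canards found"
        assert all(c.index >= 1 for c in smf.canards)

        smap = geo.sector_map(cgs250, wt, rt, smf, n_grid=32)
        assert len(smap.h_bounds) >= 2   # several rotational sectors

        traj = sim.integrate_3d(cgs250, wt, rt, 1300.0,
                                dt=0.001).window(700.0)
        rows = geo.rotational_sectors(smap, traj)
        funnel = [r for r in rows if np.isfinite(r["h_cross"])]
        assert len(funnel) >= 5
        for r in funnel:
            assert r["predicted_saos"] == r["measured_saos"]
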