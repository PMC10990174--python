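"""Bifurcation structure of the 3D slow-fast subsystem.

With the super-slow gates frozen, (w~, r~) act as bifurcation parameters.
Along a constraint line r~ = m*w~ + q the subsystem shows, as w~ grows, a
branch of stable relaxation cycles that destabilizes through a
period-doubling cascade (PD1 ...), a chaotic/MMO attractor appearing in a
discontinuous jump just right of PD1, and finally a Hopf bifurcation (HB)
beyond which the depolarized equilibrium is stable and the cell is silent.

The paper trail of an interactive continuation package is replaced here by
deterministic primitives: the unique equilibrium is a root of a scalar
current-balance equation, its stability comes from the Jacobian
eigenvalues, the HB is located by eigenvalue bisection, cycles and the
MMO onset are classified by long transient-discarded simulation, and PD1
can be confirmed through Floquet multipliers of the period-1 cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import ModelParameters, gate_kinetics, rhs_3d_vec
from .reduction import ConstraintLine
from .simulation import (
    MMO,
    SILENT,
    SPIKING,
    SCAN_DT,
    classify_events,
    detect_events,
    integrate_3d,
    regime_interval_scan,
)

__all__ = [
    "Equilibrium3D",
    "EquilibriumBranch",
    "HopfPoint",
    "find_equilibria_3d",
    "find_equilibrium_3d",
    "equilibrium_branch",
    "hopf_on_line",
    "hopf_curve_2p",
    "attractor_scan_on_line",
    "mmo_onset_on_line",
    "pd1_floquet",
    "dgm_threshold",
    "regime_map_idgm",
]


# ---------------------------------------------------------------------------
# equilibria of the reduced subsystem
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Equilibrium3D:
    """An equilibrium of the (V, h, s) subsystem with its spectrum."""

    V: float
    h: float
    s: float
    w_tilde: float
    r_tilde: float
    eigenvalues: np.ndarray

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigenvalues.real) < 0)

    @property
    def state(self) -> np.ndarray:
        return np.array([self.V, self.h, self.s])


def _current_balance(V: float, params: ModelParameters,
                     w_tilde: float, r_tilde: float) -> float:
    # total ionic current minus applied current with h, s at steady state
    k = gate_kinetics(V, params)
    return float(
        params.gNaF * k.m_inf ** 3 * k.h_inf * (V - params.ENa)
        + params.gNaP * k.n_inf ** 3 * (V - params.ENa)
        + params.gKS * k.s_inf * (V - params.EK)
        + params.gL * (V - params.EL)
        + params.gHCN * r_tilde * (V - params.EHCN)
        + params.gM * w_tilde * (V - params.EK)
        - params.IApp)


def jacobian_3d(y: np.ndarray, params: ModelParameters,
                w_tilde: float, r_tilde: float,
                eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the reduced right-hand side."""
    P = params.runtime_vector_3d(w_tilde, r_tilde)
    J = np.empty((3, 3))
    for j in range(3):
        e = eps * max(1.0, abs(y[j]))
        yp = y.copy(); yp[j] += e
        ym = y.copy(); ym[j] -= e
        J[:, j] = (rhs_3d_vec(0.0, yp, P) - rhs_3d_vec(0.0, ym, P)) / (2 * e)
    return J


def find_equilibria_3d(params: ModelParameters,
                       w_tilde: float,
                       r_tilde: float,
                       V_bracket: tuple[float, float] = (-100.0, 20.0),
                       dV: float = 0.5) -> list[Equilibrium3D]:
    """All equilibria in a voltage bracket.

    At equilibrium h = h_inf(V) and s = s_inf(V), so the problem reduces to
    a scalar current balance in V, scanned on a grid and refined by Brent's
    method.  Every root found is reported.
    """
    f = lambda V: _current_balance(V, params, w_tilde, r_tilde)
    grid = np.arange(V_bracket[0], V_bracket[1] + 0.5 * dV, dV)
    vals = np.array([f(V) for V in grid])
    out = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            V0 = (grid[i] if vals[i] == 0.0
                  else brentq(f, grid[i], grid[i + 1], xtol=1e-12))
            k = gate_kinetics(V0, params)
            y = np.array([V0, float(k.h_inf), float(k.s_inf)])
            lam = np.linalg.eigvals(jacobian_3d(y, params, w_tilde, r_tilde))
            out.append(Equilibrium3D(V0, y[1], y[2], w_tilde, r_tilde, lam))
    return out


def find_equilibrium_3d(params: ModelParameters,
                        w_tilde: float,
                        r_tilde: float,
                        V_bracket: tuple[float, float] = (-100.0, 20.0),
                        ) -> Equilibrium3D:
    """The unique equilibrium in the bracket; errors if zero or several."""
    eq = find_equilibria_3d(params, w_tilde, r_tilde, V_bracket)
    if not eq:
        raise RuntimeError(
            f"no equilibrium in V bracket {V_bracket}; widen the bracket")
    if len(eq) > 1:
        raise RuntimeError(
            f"{len(eq)} equilibria found at (w~={w_tilde}, r~={r_tilde}): "
            + ", ".join(f"V={e.V:.3f}" for e in eq))
    return eq[0]


@dataclass(frozen=True)
class HopfPoint:
    """Parameter location where a complex pair crosses the imaginary axis."""

    w_tilde: float
    r_tilde: float
    equilibrium: Equilibrium3D
    omega: float  # imaginary part of the crossing pair (rad/ms)


@dataclass(frozen=True)
class EquilibriumBranch:
    """Equilibria with stability along a one-parameter path."""

    points: tuple[Equilibrium3D, ...]
    hopf: tuple[HopfPoint, ...]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.points:
            lam = e.eigenvalues[np.argsort(-e.eigenvalues.real)]
            rows.append({
                "w_tilde": e.w_tilde, "r_tilde": e.r_tilde,
                "V_eq": e.V, "h_eq": e.h, "s_eq": e.s,
                "re_l1": lam[0].real, "im_l1": lam[0].imag,
                "re_l2": lam[1].real, "im_l2": lam[1].imag,
                "re_l3": lam[2].real, "im_l3": lam[2].imag,
                "stable": e.stable,
            })
        return pd.DataFrame(rows)


def _pair_real_part(eq: Equilibrium3D) -> float:
    lam = eq.eigenvalues
    cx = lam[np.abs(lam.imag) > 1e-12]
    if len(cx):
        return float(np.max(cx.real))
    return float(np.max(lam.real))


def equilibrium_branch(params: ModelParameters,
                       line: ConstraintLine,
                       w_range: tuple[float, float],
                       n: int = 101) -> EquilibriumBranch:
    """Equilibrium continuation along r~ = m*w~ + q with HB refinement."""
    ws = np.linspace(w_range[0], w_range[1], n)
    pts = [find_equilibrium_3d(params, float(w), float(line(w))) for w in ws]
    hbs = []
    for i in range(n - 1):
        a, b = _pair_real_part(pts[i]), _pair_real_part(pts[i + 1])
        if a == 0.0 or a * b < 0:
            hbs.append(_refine_hopf(params, line, ws[i], ws[i + 1]))
    return EquilibriumBranch(tuple(pts), tuple(hbs))


def _refine_hopf(params, line, w_lo, w_hi, tol=1e-9) -> HopfPoint:
    f = lambda w: _pair_real_part(
        find_equilibrium_3d(params, float(w), float(line(w))))
    w_hb = brentq(f, w_lo, w_hi, xtol=tol)
    eq = find_equilibrium_3d(params, float(w_hb), float(line(w_hb)))
    lam = eq.eigenvalues
    cx = lam[np.abs(lam.imag) > 1e-12]
    omega = float(np.max(np.abs(cx.imag))) if len(cx) else 0.0
    return HopfPoint(float(w_hb), float(line(w_hb)), eq, omega)


def hopf_on_line(params: ModelParameters,
                 line: ConstraintLine,
                 w_range: tuple[float, float],
                 n: int = 60) -> list[HopfPoint]:
    """Hopf points along a constraint line, by eigenvalue sign bisection."""
    ws = np.linspace(w_range[0], w_range[1], n)
    re = [_pair_real_part(find_equilibrium_3d(params, float(w),
                                              float(line(w)))) for w in ws]
    out = []
    for i in range(n - 1):
        if re[i] == 0.0 or re[i] * re[i + 1] < 0:
            out.append(_refine_hopf(params, line, ws[i], ws[i + 1]))
    return out


def hopf_curve_2p(params: ModelParameters,
                  r_grid,
                  w_range: tuple[float, float] = (0.0, 0.6),
                  n: int = 60) -> pd.DataFrame:
    """HB locus in the (w~, r~) plane: one w~_HB per r~ where it exists.

    The silent region (stable equilibrium) lies on the high-w~ side of the
    returned curve.  Gaps (no sign change in the scanned window) are
    reported as NaN rows rather than dropped.
    """
    rows = []
    for r in np.asarray(r_grid, dtype=float):
        line = ConstraintLine(m=0.0, q=float(r), rms=0.0)
        hbs = hopf_on_line(params, line, w_range, n)
        if hbs:
            for hb in hbs:
                rows.append({"r_tilde": float(r), "w_tilde_HB": hb.w_tilde,
                             "omega": hb.omega})
        else:
            rows.append({"r_tilde": float(r), "w_tilde_HB": np.nan,
                         "omega": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# attractor classification along a line and the MMO onset
# ---------------------------------------------------------------------------

#: attractor classes of the frozen subsystem
EQUILIBRIUM, LAO_CYCLE, MMO_ATTRACTOR = "equilibrium", "LAO-cycle", "MMO"

_CLASS_FROM_REGIME = {SILENT: EQUILIBRIUM, SPIKING: LAO_CYCLE,
                      MMO: MMO_ATTRACTOR}


def attractor_class(params: ModelParameters,
                    w_tilde: float,
                    r_tilde: float,
                    horizon: float = 1000.0,
                    analyze_last: float = 500.0,
                    dt: float = SCAN_DT) -> str:
    """Long-run attractor type at one frozen (w~, r~)."""
    traj = integrate_3d(params, w_tilde, r_tilde, horizon, dt=dt)
    ev = detect_events(traj.window(horizon - analyze_last))
    return _CLASS_FROM_REGIME[classify_events(ev)]


def attractor_scan_on_line(params: ModelParameters,
                           line: ConstraintLine,
                           w_grid,
                           **kw) -> pd.DataFrame:
    """Attractor class per w~ along a constraint line."""
    rows = [{"w_tilde": float(w), "r_tilde": float(line(w)),
             "attractor": attractor_class(params, float(w), float(line(w)),
                                          **kw)}
            for w in np.asarray(w_grid, dtype=float)]
    return pd.DataFrame(rows)


def mmo_onset_on_line(params: ModelParameters,
                      line: ConstraintLine,
                      w_lo: float,
                      w_hi: float,
                      tol: float = 1e-4,
                      **kw) -> float:
    """w~ at which SAOs first appear in the steady-state attractor.

    Below the onset the attractor is a simple (possibly period-doubled)
    relaxation cycle of full APs; slightly right of PD1 the attractor jumps
    discontinuously onto a chaotic/MMO branch.  The boundary is bisected on
    the presence of SAO events in the post-transient trace.
    """
    def has_sao(w: float) -> bool:
        return attractor_class(params, float(w), float(line(w)),
                               **kw) == MMO_ATTRACTOR

    if has_sao(w_lo):
        raise RuntimeError(f"SAOs already present at w~ = {w_lo}")
    # coarse scan: the MMO band ends at the HB (stable equilibrium beyond),
    # so bracket the first LAO-cycle -> MMO transition rather than assuming
    # SAOs persist all the way to w_hi.
    grid = np.linspace(w_lo, w_hi, 21)
    lo = hi = None
    for a, b in zip(grid[:-1], grid[1:]):
        if has_sao(float(b)):
            lo, hi = float(a), float(b)
            break
    if lo is None:
        raise RuntimeError(f"no SAOs found in w~ range ({w_lo}, {w_hi})")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_sao(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Floquet analysis of the period-1 cycle
# ---------------------------------------------------------------------------

def _find_cycle(params, w_tilde, r_tilde, transient=600.0, horizon=1200.0,
                dt=0.001, section_V=-70.0):
    """Anchor point and period of the periodic orbit, via a Poincare section.

    Uses upward crossings of V = section_V after the transient, with the
    crossing times refined by linear interpolation; the period is the
    spacing of the last two crossings (period-1).
    """
    traj = integrate_3d(params, w_tilde, r_tilde, horizon, dt=dt,
                        record_dt=dt)
    win = traj.window(transient)
    V = win.V
    up = np.where((V[:-1] < section_V) & (V[1:] >= section_V))[0]
    if len(up) < 3:
        raise RuntimeError("no periodic orbit crossing the section found")

    def cross_time(i):
        frac = (section_V - V[i]) / (V[i + 1] - V[i])
        return win.t[i] + frac * (win.t[i + 1] - win.t[i]), frac

    t0_, _ = cross_time(up[-2])
    t1_, frac = cross_time(up[-1])
    i = up[-1]
    y0 = win.y[i] + frac * (win.y[i + 1] - win.y[i])
    return y0.copy(), float(t1_ - t0_)


def pd1_floquet(params: ModelParameters,
                w_tilde: float,
                r_tilde: float,
                refine_periods: int = 1) -> np.ndarray:
    """Floquet multipliers of the stable cycle at frozen (w~, r~).

    Integrates the variational system over one period with a high-order
    adaptive scheme; the monodromy eigenvalues are sorted by decreasing
    modulus.  One multiplier is the trivial +1 of the phase direction; a
    period doubling is flagged when a real multiplier crosses -1.
    """
    y0, T1 = _find_cycle(params, w_tilde, r_tilde)
    P = params.runtime_vector_3d(w_tilde, r_tilde)

    def rhs(t, z):
        y, Phi = z[:3], z[3:].reshape(3, 3)
        J = jacobian_3d(y, params, w_tilde, r_tilde)
        return np.concatenate([rhs_3d_vec(t, y, P), (J @ Phi).ravel()])

    z0 = np.concatenate([y0, np.eye(3).ravel()])
    sol = solve_ivp(rhs, (0.0, refine_periods * T1), z0, method="DOP853",
                    rtol=1e-10, atol=1e-10, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"variational integration failed: {sol.message}")
    M = sol.y[3:, -1].reshape(3, 3)
    mult = np.linalg.eigvals(M)
    return mult[np.argsort(-np.abs(mult))]


# ---------------------------------------------------------------------------
# (I_App, dgM) regime map of the full 5D model
# ---------------------------------------------------------------------------

def _mmo_upper_endpoint(params: ModelParameters,
                        I_range=(0.0, 400.0), step=25.0,
                        resolution=1.0, **kw) -> float:
    """Upper endpoint of the MMO interval (MMO -> spiking boundary)."""
    scan = regime_interval_scan(params, I_range, step=step,
                                resolution=resolution, **kw)
    iv = scan.interval_of(MMO)
    if iv is None:
        raise RuntimeError("no MMO interval in the scanned range")
    return iv[1]


def dgm_threshold(base: ModelParameters | None = None,
                  dgm_range: tuple[float, float] = (0.0, 20.0),
                  tol: float = 0.25,
                  I_range: tuple[float, float] = (0.0, 400.0),
                  **kw) -> float:
    """Minimal cAMP-induced M-conductance increment with a net MMO gain.

    Finds the smallest dgM for which the elevated-cAMP MMO band reaches
    applied currents beyond the control band, i.e. where raising cAMP can
    turn spiking into MMOs.  The control upper endpoint does not depend on
    dgM, so the threshold is bisected on ``upper_cAMP1(dgM) >
    upper_cAMP0``.
    """
    base = base if base is not None else ModelParameters()
    u_ctrl = _mmo_upper_endpoint(base.with_(cAMP=0), I_range, **kw)

    def exceeds(dgm: float) -> bool:
        p = base.with_(cAMP=1, dgM=float(dgm))
        return _mmo_upper_endpoint(p, I_range, **kw) > u_ctrl

    lo, hi = dgm_range
    if exceeds(lo):
        raise RuntimeError(f"stimulated MMO band already wider at dgM={lo}")
    if not exceeds(hi):
        raise RuntimeError(f"stimulated MMO band never wider up to dgM={hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if exceeds(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def regime_map_idgm(base: ModelParameters | None = None,
                    dgm_values=(0.0, 5.0, 10.0, 15.0, 20.0),
                    I_range: tuple[float, float] = (0.0, 400.0),
                    **kw) -> pd.DataFrame:
    """MMO interval endpoints versus dgM for both cAMP states (5D model)."""
    base = base if base is not None else ModelParameters()
    rows = []
    for dgm in dgm_values:
        for camp in (0, 1):
            p = base.with_(cAMP=camp, dgM=float(dgm))
            scan = regime_interval_scan(p, I_range, **kw)
            iv = scan.interval_of(MMO)
            rows.append({"dgM": float(dgm), "cAMP": camp,
                         "mmo_lo": iv[0] if iv else np.nan,
                         "mmo_hi": iv[1] if iv else np.nan})
    return pd.DataFrame(rows)
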