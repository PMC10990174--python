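"""Slow-fast geometry of the reduced subsystem: critical manifold, folds,
folded singularities, canards and rotational sectors.

In the 3D subsystem V is fast and (h, s) are slow.  Setting the fast
derivative to zero defines the critical manifold C0, here an explicit graph
``s = gamma(V, h)``.  C0 is folded: two fold curves L- (hyperpolarized) and
L+ (depolarized), where the fast Jacobian ``df/dV`` vanishes, split it into
attracting sheets Sa-, Sa+ and a repelling sheet Sr.

The slow flow on C0 is singular at the folds; rescaling time by ``-df/dV``
(desingularization) removes the singularity at the cost of reversing
orientation on Sr.  Equilibria of the desingularized flow that lie on a
fold are *folded singularities*; a folded node (two real eigenvalues of
equal sign) funnels incoming orbits through small-amplitude rotations and
is the SAO engine of the mixed-mode oscillations.  The *strong canard*
(orbit tangent to the strong eigendirection) bounds the funnel together
with L-; *secondary canards* split the funnel into rotational sectors R_i
in which passing orbits make exactly i small loops.

Canards are computed by reconstructing the attracting and repelling slow
manifolds: forward orbits from a seed line on Sa- and backward orbits from
a seed line on Sa+ are stopped on a section plane near the folded node and
intersected there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import ModelParameters, gate_kinetics
from .simulation import LAO_THRESHOLD, Trajectory

__all__ = [
    "gamma",
    "dV_f",
    "sheet",
    "fold_psi",
    "fold_curves",
    "desingularized_rhs",
    "FoldedSingularity",
    "folded_singularities",
    "ordinary_singularities",
    "CanardOrbit",
    "strong_canard",
    "count_rotations",
    "reconstruct_slow_manifolds",
    "SlowManifolds",
    "rotational_sectors",
    "SectorMap",
    "sector_map",
]


# ---------------------------------------------------------------------------
# analytic rates with derivatives (needed for exact fold expressions)
# ---------------------------------------------------------------------------

def _rate_d(a: float, b: float, c: float, V):
    """Value and dV-derivative of a*(V+b)/(1-exp(-(V+b)/c))."""
    V = np.asarray(V, dtype=float)
    x = V + b
    y = x / c
    small = np.abs(y) < 1e-7
    ys = np.where(small, 1.0, y)
    with np.errstate(over="ignore"):
        E = np.exp(-np.clip(ys, -700.0, 700.0))
        u = 1.0 - E
        val = a * c * ys / u
        der = a / u - a * c * ys * E / (c * u * u)
    val = np.where(small, a * c * (1.0 + 0.5 * y + y * y / 12.0), val)
    der = np.where(small, a * (0.5 + y / 6.0), der)
    return val, der


def _m_inf_d(V):
    am, amd = _rate_d(1.86, 25.4, 10.3, V)
    bm, bmd = _rate_d(-0.086, 29.7, -9.16, V)
    tot = am + bm
    return am / tot, (amd * bm - am * bmd) / (tot * tot)


def _n_inf_d(V):
    an, and_ = _rate_d(0.186, 48.4, 10.3, V)
    bn, bnd = _rate_d(-0.0086, 42.7, -9.16, V)
    tot = an + bn
    return an / tot, (and_ * bn - an * bnd) / (tot * tot)


def _naf_factor_d(V, p: ModelParameters):
    """A(V) = gNaF * m_inf(V)^3 * (V - ENa) and its dV-derivative.

    I_NaF = A(V) * h, so A is also the h-partial of the NaF current.
    """
    m, md = _m_inf_d(V)
    A = p.gNaF * m ** 3 * (np.asarray(V, float) - p.ENa)
    Ad = p.gNaF * (3.0 * m * m * md * (np.asarray(V, float) - p.ENa)
                   + m ** 3)
    return A, Ad


def _nap_current_d(V, p: ModelParameters):
    n, nd = _n_inf_d(V)
    I = p.gNaP * n ** 3 * (np.asarray(V, float) - p.ENa)
    Id = p.gNaP * (3.0 * n * n * nd * (np.asarray(V, float) - p.ENa)
                   + n ** 3)
    return I, Id


# ---------------------------------------------------------------------------
# critical manifold
# ---------------------------------------------------------------------------

def gamma(V, h, params: ModelParameters, w_tilde: float, r_tilde: float,
          components: bool = False):
    """Critical-manifold graph s = gamma(V, h), optionally decomposed.

    ``gamma = gamma0 + gamma_rt + gamma_wt + gamma_rtheta`` where gamma0 is
    the HCN/M-free backbone, the middle two are constant shifts
    proportional to r~ and w~, and the last is the V-dependent part of the
    HCN shift.  Undefined at V = EK, where the KS driving force vanishes.
    """
    V = np.asarray(V, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(V == params.EK):
        raise ValueError("gamma is singular at V = EK")
    p = params
    A, _ = _naf_factor_d(V, p)
    InaP, _ = _nap_current_d(V, p)
    dK = V - p.EK
    g0 = -(A * h + InaP + p.gL * (V - p.EL) - p.IApp) / (p.gKS * dK)
    g_rt = -(p.gHCN / p.gKS) * r_tilde * np.ones_like(V)
    g_wt = -(p.gM / p.gKS) * w_tilde * np.ones_like(V)
    g_rtheta = (p.gHCN / p.gKS) * (p.EHCN - p.EK) / dK * r_tilde
    g = g0 + g_rt + g_wt + g_rtheta
    if components:
        return g, {"gamma0": g0, "gamma_rt": g_rt, "gamma_wt": g_wt,
                   "gamma_rtheta": g_rtheta}
    return g


def dV_f(V, h, s, params: ModelParameters, w_tilde: float, r_tilde: float):
    """Fast-subsystem Jacobian df/dV of the V-equation (1/ms).

    Negative on attracting sheets, positive on the repelling sheet, zero on
    the fold curves.
    """
    p = params
    _, Ad = _naf_factor_d(V, p)
    _, InaPd = _nap_current_d(V, p)
    gsum = (Ad * np.asarray(h, float) + InaPd + p.gKS * np.asarray(s, float)
            + p.gL + p.gHCN * r_tilde + p.gM * w_tilde)
    return -gsum / p.Cm


def sheet(V, h, params: ModelParameters, w_tilde: float, r_tilde: float,
          folds: dict | None = None):
    """Classify points of C0 as 'Sa-', 'Sr' or 'Sa+'.

    Attracting/repelling from the sign of df/dV on the manifold; the two
    attracting sheets are told apart by V relative to the repelling sheet
    (hyperpolarized side -> Sa-).
    """
    V = np.atleast_1d(np.asarray(V, dtype=float))
    h = np.atleast_1d(np.asarray(h, dtype=float))
    s = gamma(V, h, params, w_tilde, r_tilde)
    d = np.atleast_1d(dV_f(V, h, s, params, w_tilde, r_tilde))
    if folds is None:
        folds = fold_curves(params, w_tilde, r_tilde)
    v_mid = 0.5 * (folds["L-"]["V"].mean() + folds["L+"]["V"].mean())
    out = np.where(d > 0, "Sr", np.where(V < v_mid, "Sa-", "Sa+"))
    return out if out.size > 1 else str(out[0])


# ---------------------------------------------------------------------------
# fold curves
# ---------------------------------------------------------------------------

def fold_psi(V, params: ModelParameters, r_tilde: float,
             components: bool = False):
    """Fold-curve graph h = psi(V) = psi0 + psir.

    Derived by eliminating s via gamma in df/dV = 0:

        psi0 = (-[(V-EK) dV(I_NaP) - I_NaP] + gL (EK-EL) - IApp) / D
        psir = gHCN (EK - EHCN) r~ / D
        D    = (V-EK) A'(V) - A(V),  A = gNaF m_inf^3 (V-ENa)

    psir vanishes with r~; w~ does not enter (the M-current contribution to
    df/dV cancels against its gamma shift).  Points where D = 0 are
    excluded (NaN).
    """
    p = params
    V = np.asarray(V, dtype=float)
    A, Ad = _naf_factor_d(V, p)
    InaP, InaPd = _nap_current_d(V, p)
    dK = V - p.EK
    D = dK * Ad - A
    with np.errstate(divide="ignore", invalid="ignore"):
        psi0 = (-(dK * InaPd - InaP) + p.gL * (p.EK - p.EL) - p.IApp) / D
        psir = p.gHCN * (p.EK - p.EHCN) * r_tilde / D
    bad = np.abs(D) < 1e-9
    psi0 = np.where(bad, np.nan, psi0)
    psir = np.where(bad, np.nan, psir)
    if components:
        return psi0 + psir, {"psi0": psi0, "psir": psir, "D": D}
    return psi0 + psir


def fold_curves(params: ModelParameters, w_tilde: float, r_tilde: float,
                V_window: tuple[float, float] = (-90.0, -20.0),
                h_range: tuple[float, float] = (0.02, 0.98),
                n: int = 200) -> dict:
    """Trace the physical fold branches L- and L+ embedded in C0.

    The fold set is one connected curve in the (V, h) plane whose two
    steep arms are the hyperpolarized fold L- and the depolarized fold L+
    (nearly vertical in V, sweeping the physiological h range).  Both arms
    are therefore traced parametrically in h: for each h the outermost
    roots in V of df/dV on C0 give one point per branch.  Each branch is a
    dict of V, h, s arrays (s via gamma).
    """
    hs = np.linspace(h_range[0], h_range[1], n)
    grid = np.linspace(V_window[0], V_window[1], 281)
    grid = grid[np.abs(grid - params.EK) > 1e-6]  # gamma pole at V = EK
    lo_pts, hi_pts = [], []
    for h in hs:
        f = lambda v: float(dV_f(v, h, gamma(v, h, params, w_tilde,
                                             r_tilde),
                                 params, w_tilde, r_tilde))
        vals = dV_f(grid, np.full_like(grid, h),
                    gamma(grid, np.full_like(grid, h), params,
                          w_tilde, r_tilde),
                    params, w_tilde, r_tilde)
        roots = []
        for i in range(len(grid) - 1):
            if (grid[i] - params.EK) * (grid[i + 1] - params.EK) <= 0:
                continue  # bracket straddles the gamma pole at V = EK
            if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
                roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
        if len(roots) >= 2:
            lo_pts.append((roots[0], h))
            hi_pts.append((roots[-1], h))
    if len(lo_pts) < 3:
        raise RuntimeError(
            f"fold branches not found in V window {V_window}")
    out = {}
    for label, pts in (("L-", lo_pts), ("L+", hi_pts)):
        Vb = np.array([p_[0] for p_ in pts])
        hb = np.array([p_[1] for p_ in pts])
        out[label] = {"V": Vb, "h": hb,
                      "s": gamma(Vb, hb, params, w_tilde, r_tilde)}
    return out


# ---------------------------------------------------------------------------
# desingularized reduced system
# ---------------------------------------------------------------------------

def desingularized_rhs(V, h, params: ModelParameters,
                       w_tilde: float, r_tilde: float) -> np.ndarray:
    """Right-hand side of the desingularized reduced flow on C0.

    With s eliminated through gamma::

        V' = A(V) (h - h_inf)/tau_h + gKS (V-EK) (gamma - s_inf)/tau_s
        h' = -(h - h_inf)/tau_h * sum_i dV(I_i)

    Time has been rescaled by ``sum_i dV(I_i) = -Cm df/dV``; the rescaling
    factor is positive on the attracting sheets (orientation preserved) and
    negative on Sr (orientation reversed) -- the standard desingularization
    property.
    """
    p = params
    V = np.asarray(V, dtype=float)
    h = np.asarray(h, dtype=float)
    k = gate_kinetics(V, p)
    A, Ad = _naf_factor_d(V, p)
    _, InaPd = _nap_current_d(V, p)
    g = gamma(V, h, p, w_tilde, r_tilde)
    dh_slow = (h - k.h_inf) / k.tau_h
    F1 = A * dh_slow + p.gKS * (V - p.EK) * (g - k.s_inf) / k.tau_s
    sum_dv = (Ad * h + InaPd + p.gKS * g + p.gL
              + p.gHCN * r_tilde + p.gM * w_tilde)
    F2 = -dh_slow * sum_dv
    return np.array([F1, F2])


def _desing_jacobian(V: float, h: float, params, w_tilde, r_tilde,
                     eps: float = 1e-7) -> np.ndarray:
    J = np.empty((2, 2))
    for j, (dV_, dh_) in enumerate(((1.0, 0.0), (0.0, 1.0))):
        e = eps * max(1.0, abs(V) if j == 0 else 1.0)
        fp = desingularized_rhs(V + e * dV_, h + e * dh_,
                                params, w_tilde, r_tilde)
        fm = desingularized_rhs(V - e * dV_, h - e * dh_,
                                params, w_tilde, r_tilde)
        J[:, j] = (fp - fm) / (2 * e)
    return J


@dataclass(frozen=True)
class FoldedSingularity:
    """Equilibrium of the desingularized flow lying on a fold curve."""

    V: float
    h: float
    s: float
    branch: str
    eigenvalues: np.ndarray       # of the 2x2 desingularized Jacobian
    eigenvectors: np.ndarray      # columns, matching eigenvalue order
    kind: str                     # 'folded node' | 'folded saddle' | 'folded focus'

    @property
    def mu(self) -> float | None:
        """Eigenvalue ratio weak/strong of a folded node, in (0, 1)."""
        if self.kind != "folded node":
            return None
        lam = np.sort(np.abs(self.eigenvalues.real))
        return float(lam[0] / lam[1])

    @property
    def strong_eigenvector(self) -> np.ndarray:
        i = int(np.argmax(np.abs(self.eigenvalues.real)))
        v = self.eigenvectors[:, i].real
        return v / np.linalg.norm(v)

    @property
    def weak_eigenvector(self) -> np.ndarray:
        i = int(np.argmin(np.abs(self.eigenvalues.real)))
        v = self.eigenvectors[:, i].real
        return v / np.linalg.norm(v)

    @property
    def state(self) -> np.ndarray:
        return np.array([self.V, self.h, self.s])


def _classify_folded(lam: np.ndarray) -> str:
    if np.any(np.abs(lam.imag) > 1e-10 * np.max(np.abs(lam))):
        return "folded focus"
    a, b = lam.real
    return "folded node" if a * b > 0 else "folded saddle"


def folded_singularities(params: ModelParameters, w_tilde: float,
                         r_tilde: float,
                         V_window: tuple[float, float] = (-75.0, 0.0),
                         ) -> list[FoldedSingularity]:
    """Folded singularities on the traced fold branches.

    Roots along each branch of the V'-component of the desingularized flow
    (which vanishes on the fold exactly at folded singularities), refined
    by Brent's method and classified by the 2x2 Jacobian eigenvalues.
    """
    folds = fold_curves(params, w_tilde, r_tilde, V_window)
    out = []
    for label, br in folds.items():
        Vb, hb = br["V"], br["h"]

        def V_of_h(h, V_lo, V_hi):
            f = lambda v: float(dV_f(v, h, gamma(v, h, params, w_tilde,
                                                 r_tilde),
                                     params, w_tilde, r_tilde))
            return brentq(f, V_lo, V_hi, xtol=1e-13)

        def F1_at(V, h):
            return float(desingularized_rhs(V, h, params,
                                            w_tilde, r_tilde)[0])

        vals = np.array([F1_at(V, h) for V, h in zip(Vb, hb)])
        for i in range(len(hb) - 1):
            if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
                # bisect in h, re-solving the fold V at each step
                h_lo, h_hi = hb[i], hb[i + 1]
                f_lo = vals[i]
                Vban = (min(Vb[i], Vb[i + 1]) - 0.5,
                        max(Vb[i], Vb[i + 1]) + 0.5)
                for _ in range(60):
                    h_mid = 0.5 * (h_lo + h_hi)
                    V_mid = V_of_h(h_mid, *Vban)
                    f_mid = F1_at(V_mid, h_mid)
                    if f_mid == 0.0 or f_lo * f_mid < 0:
                        h_hi = h_mid
                    else:
                        h_lo, f_lo = h_mid, f_mid
                h0 = 0.5 * (h_lo + h_hi)
                V0 = V_of_h(h0, *Vban)
                s0 = float(gamma(V0, h0, params, w_tilde, r_tilde))
                J = _desing_jacobian(V0, h0, params, w_tilde, r_tilde)
                lam, vec = np.linalg.eig(J)
                out.append(FoldedSingularity(V0, h0, s0, label, lam, vec,
                                             _classify_folded(lam)))
    return out


def ordinary_singularities(params: ModelParameters, w_tilde: float,
                           r_tilde: float,
                           V_window: tuple[float, float] = (-100.0, 20.0),
                           dV: float = 0.25) -> list[np.ndarray]:
    """Equilibria of the (non-desingularized) 3D subsystem on C0.

    Solves gamma(V, h_inf(V)) = s_inf(V); each root is an equilibrium of
    the reduced vector field.
    """
    def g(V):
        k = gate_kinetics(V, params)
        return float(gamma(V, float(k.h_inf), params, w_tilde, r_tilde)
                     - k.s_inf)

    grid = np.arange(V_window[0], V_window[1] + 0.5 * dV, dV)
    grid = grid[np.abs(grid - params.EK) > 1e-9]  # gamma pole at V = EK
    vals = np.array([g(V) for V in grid])
    roots = []
    for i in range(len(grid) - 1):
        if (grid[i] - params.EK) * (grid[i + 1] - params.EK) <= 0:
            continue  # bracket straddles the gamma pole
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            V0 = (grid[i] if vals[i] == 0.0
                  else brentq(g, grid[i], grid[i + 1], xtol=1e-12))
            k = gate_kinetics(V0, params)
            roots.append(np.array([V0, float(k.h_inf),
                                   float(k.s_inf)]))
    return roots


# ---------------------------------------------------------------------------
# canards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanardOrbit:
    """A canard orbit with its rotational index (SAO count)."""

    index: int
    samples: np.ndarray            # (N, 3) in (V, h, s)
    role: str                      # 'strong' | 'secondary'
    section_point: np.ndarray | None = None  # (V, h) on the section plane


def strong_canard(fn: FoldedSingularity, params: ModelParameters,
                  w_tilde: float, r_tilde: float,
                  delta: float = 1e-3, t_max: float = 400.0,
                  V_box: tuple[float, float] = (-90.0, 10.0)) -> CanardOrbit:
    """The strong canard xi_0 of a folded node.

    Integrates the desingularized flow forward and backward from small
    offsets along the strong eigendirection and embeds the result in
    (V, h, s) through gamma.  Together with L-, xi_0 bounds the funnel.
    """
    if fn.kind != "folded node":
        raise ValueError(f"strong canard requires a folded node, "
                         f"got {fn.kind}")
    v = fn.strong_eigenvector
    # scale the offset to the coordinate magnitudes (V in mV, h in [0,1])
    scale = np.array([1.0, 0.02])

    def rhs(t, y):
        return desingularized_rhs(y[0], y[1], params, w_tilde, r_tilde)

    def leave(t, y):
        inside = (V_box[0] < y[0] < V_box[1]) and (0.0 < y[1] < 1.0)
        return 1.0 if inside else -1.0
    leave.terminal = True

    pieces = []
    for sgn in (+1.0, -1.0):
        y0 = fn.state[:2] + sgn * delta * v * scale
        for direction in (+1.0, -1.0):
            sol = solve_ivp(lambda t, y: direction * rhs(t, y),
                            (0.0, t_max), y0, method="LSODA",
                            rtol=1e-10, atol=1e-12, events=leave,
                            max_step=t_max / 50.0)
            pieces.append((sgn, direction, sol.y.T))
    # keep the two pieces that move away from the FN the farthest
    pieces.sort(key=lambda p: -np.max(np.abs(p[2][:, 0] - fn.V)))
    a, b = pieces[0][2], pieces[1][2]
    pts2 = np.vstack([a[::-1], b])
    s = gamma(pts2[:, 0], pts2[:, 1], params, w_tilde, r_tilde)
    return CanardOrbit(0, np.column_stack([pts2, s]), "strong")


def count_rotations(params: ModelParameters, w_tilde: float, r_tilde: float,
                    point: np.ndarray, t_max: float = 200.0,
                    dt: float = 0.001) -> int:
    """SAO count of a forward 3D orbit from ``point`` before its AP jump.

    Counts subthreshold voltage maxima with the same prominence filter as
    the event detector, so geometric sector indices are directly comparable
    with SAO counts measured on simulated traces.
    """
    from scipy.signal import find_peaks

    from .simulation import PEAK_PROMINENCE, integrate_3d

    traj = integrate_3d(params, w_tilde, r_tilde, t_max, dt=dt,
                        ic=np.asarray(point, dtype=float), record_dt=0.01)
    V = traj.V
    above = np.where(V >= LAO_THRESHOLD)[0]
    end = above[0] if len(above) else len(V)
    idx, _ = find_peaks(V[:end], prominence=PEAK_PROMINENCE)
    return int(len(idx))


@dataclass(frozen=True)
class SlowManifolds:
    """Reconstruction of the attracting/repelling slow manifolds.

    The two curve families are stored as their crossing points with the
    section plane s = s_plane near the folded node; their intersections are
    canard candidates.
    """

    s_plane: float
    attracting_hits: np.ndarray     # (Na, 2): (V, h) at the plane
    repelling_hits: np.ndarray      # (Nr, 2)
    canards: tuple[CanardOrbit, ...]
    lost_fraction: float


def _plane_hits(params, w_tilde, r_tilde, seeds, s_plane, direction,
                t_max=500.0, dt=0.001):
    """Integrate seeds until the orbit crosses s = s_plane; collect (V,h).

    Fixed-step RK4 (forward or time-reversed); the first crossing of the
    plane is located on the recorded trace and refined by linear
    interpolation.  Orbits that leave the voltage box or never reach the
    plane are counted as lost.
    """
    from .simulation import _rk4_3d, _rk4_3d_reversed

    P = params.runtime_vector_3d(w_tilde, r_tilde)
    stepper = _rk4_3d if direction > 0 else _rk4_3d_reversed
    n_steps = int(round(t_max / dt))
    hits, lost = [], 0
    for y0 in seeds:
        T, Y, fail = stepper(np.asarray(y0, dtype=float), P, dt, n_steps,
                             10)
        V, s = Y[:, 0], Y[:, 2]
        inside = (V > -120.0) & (V < 40.0)
        end = len(T) if inside.all() else int(np.argmin(inside))
        d = s[:end] - s_plane
        if direction > 0:
            # forward orbits approach the folded node with s decreasing;
            # upward crossings belong to the AP excursion, not the funnel
            cross = np.where((d[:-1] > 0) & (d[1:] <= 0))[0]
        else:
            cross = np.where((d[:-1] < 0) & (d[1:] >= 0))[0]
        if len(cross):
            i = int(cross[0])
            frac = d[i] / (d[i] - d[i + 1])
            hits.append([Y[i, 0] + frac * (Y[i + 1, 0] - Y[i, 0]),
                         Y[i, 1] + frac * (Y[i + 1, 1] - Y[i, 1])])
        else:
            lost += 1
    return np.asarray(hits), lost


def _segment_intersections(a: np.ndarray, b: np.ndarray,
                           scale=(50.0, 0.05)) -> list[np.ndarray]:
    """Intersections of two ordered polylines in normalized (V, h) coords."""
    if len(a) < 2 or len(b) < 2:
        return []
    an = a / np.asarray(scale)
    bn = b / np.asarray(scale)
    out = []
    for i in range(len(an) - 1):
        p, r = an[i], an[i + 1] - an[i]
        for j in range(len(bn) - 1):
            q, s = bn[j], bn[j + 1] - bn[j]
            denom = r[0] * s[1] - r[1] * s[0]
            if abs(denom) < 1e-14:
                continue
            d = q - p
            t = (d[0] * s[1] - d[1] * s[0]) / denom
            u = (d[0] * r[1] - d[1] * r[0]) / denom
            if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0:
                out.append((p + t * r) * np.asarray(scale))
    return out


def reconstruct_slow_manifolds(params: ModelParameters,
                               w_tilde: float,
                               r_tilde: float,
                               fn: FoldedSingularity | None = None,
                               n_seeds: int = 200,
                               sigma_offset: float = 0.02,
                               seed_offset_mV: float = 2.0,
                               h_margin: float = 0.3,
                               ) -> SlowManifolds:
    """Canard orbits from slow-manifold intersections on a section plane.

    Forward orbits seeded on Sa- (a line ``seed_offset_mV`` hyperpolarized
    of L-) trace the attracting slow manifold; backward orbits seeded on
    Sa+ (same offset depolarized of L+) converge onto the repelling one.
    Both families stop on the plane ``s = s_FN + sigma``, with sigma a
    fraction ``sigma_offset`` of |s_FN| on the side the slow flow comes
    from.  Family intersections on the plane are canard points; each is
    integrated forward to count its rotational index.
    """
    if fn is None:
        nodes = [f for f in folded_singularities(params, w_tilde, r_tilde)
                 if f.kind == "folded node"]
        if not nodes:
            raise RuntimeError("no folded node found")
        fn = nodes[0]
    folds = fold_curves(params, w_tilde, r_tilde)

    # upstream side: the plane sits where the slow flow arrives from, so
    # incoming orbits cross it before they start rotating around the FN
    k = gate_kinetics(fn.V, params)
    ds_dt = float(k.s_inf) - fn.s  # sign of ds/dt at the FN
    side = -math.copysign(1.0, ds_dt)
    s_plane = fn.s + side * sigma_offset * max(abs(fn.s), 1e-3)

    # seed lines at fixed V, spanning h around the FN value
    h_lo = max(1e-4, fn.h * (1.0 - h_margin))
    h_hi = min(1.0 - 1e-4, fn.h * (1.0 + h_margin))
    hs = np.linspace(h_lo, h_hi, n_seeds)
    # attracting-family seeds: a line on Sa- at the FN's h values, a small
    # V offset hyperpolarized of L-.  The offset is kept small because
    # gamma rises steeply away from L- towards EK and distant seeds
    # contract onto the weak canard before reaching the plane.
    Vm = np.interp(hs, folds["L-"]["h"], folds["L-"]["V"])
    V_a = np.maximum(Vm - seed_offset_mV, params.EK + 1.5)
    seeds_a = np.column_stack([V_a, hs,
                               gamma(V_a, hs, params, w_tilde, r_tilde)])
    # repelling-family seeds: a line on Sa+ at s values just below the
    # plane (in backward time s grows along Sr, so only these cross it).
    # gamma is linear in h, so the h giving a target s is solved exactly.
    V_r = float(folds["L+"]["V"].max()) + seed_offset_mV
    s_targets = s_plane - abs(fn.s) * np.linspace(0.003, 0.15, n_seeds)
    b0 = float(gamma(V_r, 0.0, params, w_tilde, r_tilde))
    b1 = float(gamma(V_r, 1.0, params, w_tilde, r_tilde))
    hs_r = (s_targets - b0) / (b1 - b0)
    # start slightly inside Sa+ (towards Sr): the true slow manifold is
    # O(eps) displaced from C0 and a start on its outer side escapes to
    # depolarized V in backward time
    inset = 0.5 * seed_offset_mV
    seeds_r = np.column_stack([np.full(n_seeds, V_r - inset), hs_r,
                               s_targets])

    hits_a, lost_a = _plane_hits(params, w_tilde, r_tilde, seeds_a,
                                 s_plane, +1.0)
    hits_r, lost_r = _plane_hits(params, w_tilde, r_tilde, seeds_r,
                                 s_plane, -1.0)
    lost = (lost_a + lost_r) / (2.0 * n_seeds)

    # intersection points are canard candidates; a canard's rotational
    # index is read off the sectors it separates (midpoints between
    # neighbouring intersections make i and i+1 rotations; the canard
    # between them is xi_i)
    pts = _segment_intersections(hits_a, hits_r)
    pts.sort(key=lambda q: q[1])
    canards = []
    for k, pt in enumerate(pts):
        y0 = np.array([pt[0], pt[1], s_plane])
        neighbours = []
        for other in (pts[k - 1] if k > 0 else None,
                      pts[k + 1] if k + 1 < len(pts) else None):
            if other is not None:
                mid = 0.5 * (np.asarray(pt) + np.asarray(other))
                neighbours.append(count_rotations(
                    params, w_tilde, r_tilde,
                    np.array([mid[0], mid[1], s_plane])))
        idx = min(neighbours) if neighbours else count_rotations(
            params, w_tilde, r_tilde, y0)
        traj_samples = _embed_orbit(params, w_tilde, r_tilde, y0)
        canards.append(CanardOrbit(idx, traj_samples, "secondary",
                                   section_point=pt))
    canards.sort(key=lambda c: c.index)
    return SlowManifolds(s_plane, hits_a, hits_r, tuple(canards), lost)


@dataclass(frozen=True)
class SectorMap:
    """Rotational-sector structure along the attracting curve on the plane.

    ``h_bounds[i]`` is the h coordinate of the secondary canard separating
    runs of constant SAO count; ``counts[i]`` is the count of the run
    between ``h_bounds[i-1]`` and ``h_bounds[i]``.  Built by brute force:
    forward rotation counts on a grid along the reconstructed attracting
    curve, with bisection refinement of each jump.
    """

    s_plane: float
    h_grid: np.ndarray
    grid_counts: np.ndarray
    h_bounds: np.ndarray
    bound_counts: np.ndarray      # (n_bounds, 2): counts below/above

    def predict(self, h: float) -> int:
        """SAO count of the sector containing h."""
        i = int(np.searchsorted(self.h_grid, h))
        i = min(max(i, 0), len(self.h_grid) - 1)
        return int(self.grid_counts[i])


def sector_map(params: ModelParameters, w_tilde: float, r_tilde: float,
               sm: SlowManifolds, n_grid: int = 48,
               refine_tol: float = 1e-5) -> SectorMap:
    """Brute-force rotational-sector map on the section plane.

    Samples forward rotation counts along the attracting-manifold curve
    (parametrized by h) and bisects each count jump; the jump locations
    are the secondary canards' section coordinates.
    """
    A = np.asarray(sm.attracting_hits)
    order = np.argsort(A[:, 1])
    hA, VA = A[order, 1], A[order, 0]
    hs = np.linspace(hA.min(), hA.max(), n_grid)

    def count_at(h):
        V = float(np.interp(h, hA, VA))
        return count_rotations(params, w_tilde, r_tilde,
                               np.array([V, h, sm.s_plane]))

    counts = np.array([count_at(h) for h in hs])
    bounds, bcounts = [], []
    for i in range(n_grid - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = hs[i], hs[i + 1]
            c_lo = counts[i]
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                if count_at(mid) == c_lo:
                    lo = mid
                else:
                    hi = mid
            bounds.append(0.5 * (lo + hi))
            bcounts.append((counts[i], counts[i + 1]))
    return SectorMap(sm.s_plane, hs, counts, np.asarray(bounds),
                     np.asarray(bcounts))


def _embed_orbit(params, w_tilde, r_tilde, y0, t_max=120.0):
    from .simulation import integrate_3d

    traj = integrate_3d(params, w_tilde, r_tilde, t_max, dt=0.001,
                        ic=y0, record_dt=0.02)
    return traj.y


# ---------------------------------------------------------------------------
# rotational sectors
# ---------------------------------------------------------------------------

def rotational_sectors(smap: SectorMap,
                       traj: Trajectory) -> list[dict]:
    """Sector assignment of each post-LAO return of a 3D trajectory.

    For every inter-spike passage, the first downward crossing of the
    section plane is located and placed in the sector map; the sector's
    rotation count is the predicted number of SAOs, compared with the
    count measured from the voltage trace before the next AP.  Passages
    that never reach the plane are regular jumps (0 predicted SAOs).
    """
    from .simulation import detect_events

    events = detect_events(traj)
    laos = [e for e in events if e.kind == "LAO"]
    out = []
    t, s, V, h = traj.t, traj.s, traj.V, traj.h
    for a, b in zip(laos[:-1], laos[1:]):
        m = (t > a.t_peak) & (t < b.t_peak)
        tm, sm_, hm, Vm = t[m], s[m], h[m], V[m]
        # subthreshold part of the passage only
        sub = Vm < LAO_THRESHOLD
        if not np.any(sub):
            continue
        tm, sm_, hm = tm[sub], sm_[sub], hm[sub]
        d = sm_ - smap.s_plane
        cross = np.where((d[:-1] > 0) & (d[1:] <= 0))[0]
        measured = sum(1 for e in events
                       if e.kind == "SAO" and a.t_peak < e.t_peak < b.t_peak)
        if len(cross) == 0:
            out.append({"t_return": float(tm[0]), "h_cross": np.nan,
                        "predicted_saos": 0, "measured_saos": measured})
            continue
        i0 = int(cross[0])
        frac = d[i0] / (d[i0] - d[i0 + 1])
        h_cross = float(hm[i0] + frac * (hm[i0 + 1] - hm[i0]))
        out.append({"t_return": float(tm[0]), "h_cross": h_cross,
                    "predicted_saos": smap.predict(h_cross),
                    "measured_saos": measured})
    return out
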