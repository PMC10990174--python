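"""Multiple-timescale reduction of the 5D model to its slow-fast subsystem.

The gating variables split across three timescales: the membrane potential
``V`` is fast, ``h`` and ``s`` are slow, and the HCN/M gates ``r`` and ``w``
are super-slow.  Freezing the super-slow pair at its time average over the
attractor yields a 3D (V, h, s) subsystem in which ``r`` and ``w`` act as
parameters.

To use one bifurcation analysis for both cAMP states, the frozen gates are
absorbed into scaled variables::

    w~ = (1 + cAMP * dgM / gM) * w
    r~ = (1 + cAMP * dgHCN / gHCN) * r

so the reduced currents read ``I_HCN = gHCN * r~ * (V - EHCN)`` and
``I_M = gM * w~ * (V - EK)`` and the 3D subsystem no longer depends on the
cAMP flag.  Projected onto the (w~, r~) plane, 5D trajectories hug a
straight line ``r~ = m * w~ + q``, which serves as the one-parameter
bifurcation path of the subsystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParameters, gate_kinetics, rhs_3d_vec
from .simulation import Trajectory, integrate

__all__ = [
    "ReductionResult",
    "ConstraintLine",
    "average_gates",
    "scale_gates",
    "rhs_3d",
    "fit_line",
    "reduce_condition",
    "timescale_ratios",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReductionResult:
    """Averaged and scaled super-slow gates of one 5D simulation."""

    w_bar: float
    r_bar: float
    w_tilde: float
    r_tilde: float
    t0: float
    T: float

    @property
    def dT(self) -> float:
        return self.T - self.t0


@dataclass(frozen=True)
class ConstraintLine:
    """Least-squares line r~ = m * w~ + q through a trajectory projection."""

    m: float
    q: float
    rms: float

    def __call__(self, w_tilde):
        return self.m * np.asarray(w_tilde) + self.q


def average_gates(traj: Trajectory, t0: float = 350.0,
                  T: float = 450.0) -> tuple[float, float]:
    """Trapezoidal time averages of w(t) and r(t) over [t0, T].

    The window defaults discard the initial transient (over well before
    350 ms from the standard resting start) and average over roughly
    5-10 attractor periods.
    """
    if T <= t0:
        raise ValueError("T must exceed t0")
    if traj.t[-1] < T - 1e-9:
        raise ValueError(f"trajectory ends at {traj.t[-1]} ms, before T={T}")
    win = traj.window(t0, T)
    dT = win.t[-1] - win.t[0]
    w_bar = float(np.trapezoid(win.w, win.t) / dT)
    r_bar = float(np.trapezoid(win.r, win.t) / dT)
    return w_bar, r_bar


def scale_gates(w: float, r: float,
                params: ModelParameters) -> tuple[float, float]:
    """Map (w, r) to the scaled pair (w~, r~) absorbing the cAMP increments.

    With cAMP = 0 this is the identity.  A blocked channel (zero base
    conductance) contributes no current, so its gate is passed through
    unscaled.
    """
    w = np.asarray(w, dtype=float)
    r = np.asarray(r, dtype=float)
    if params.cAMP and params.gM > 0:
        w_t = w * (1.0 + params.dgM / params.gM)
    else:
        if params.cAMP and params.dgM > 0:
            logger.info("gM = 0 with cAMP = 1: w left unscaled "
                        "(M current vanishes)")
        w_t = w
    if params.cAMP and params.gHCN > 0:
        r_t = r * (1.0 + params.dgHCN / params.gHCN)
    else:
        if params.cAMP and params.dgHCN > 0:
            logger.info("gHCN = 0 with cAMP = 1: r left unscaled "
                        "(HCN current vanishes)")
        r_t = r
    if w_t.ndim == 0:
        return float(w_t), float(r_t)
    return w_t, r_t


def rhs_3d(t: float, state, params: ModelParameters,
           w_tilde: float, r_tilde: float) -> np.ndarray:
    """Derivative of the reduced (V, h, s) subsystem at frozen (w~, r~)."""
    return rhs_3d_vec(t, state, params.runtime_vector_3d(w_tilde, r_tilde))


def reduce_condition(params: ModelParameters,
                     t0: float = 350.0,
                     T: float = 450.0,
                     dt: float = 0.001) -> ReductionResult:
    """Simulate the 5D model and freeze the super-slow gates.

    Runs the 5D system for ``T`` ms from the standard resting state,
    averages ``w`` and ``r`` over ``[t0, T]`` and applies the cAMP scaling.
    """
    traj = integrate(params, T, dt=dt)
    w_bar, r_bar = average_gates(traj, t0, T)
    w_t, r_t = scale_gates(w_bar, r_bar, params)
    return ReductionResult(w_bar, r_bar, w_t, r_t, t0, T)


def fit_line(points) -> ConstraintLine:
    """Ordinary least squares of r~ on w~ for a projected trajectory.

    ``points`` is an (N, 2) array-like of (w~, r~) samples; w~ is treated
    as the independent variable because it is the bifurcation parameter of
    the slow-fast subsystem.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (N, 2) array of (w~, r~) points, N >= 2")
    w, r = pts[:, 0], pts[:, 1]
    if np.ptp(w) == 0:
        raise ValueError("degenerate fit: constant w~")
    m, q = np.polyfit(w, r, 1)
    rms = float(np.sqrt(np.mean((r - (m * w + q)) ** 2)))
    return ConstraintLine(float(m), float(q), rms)


def projected_line(params: ModelParameters,
                   t0: float = 350.0,
                   T: float = 450.0,
                   dt: float = 0.001) -> tuple[ConstraintLine, np.ndarray]:
    """Constraint line fitted to the (w~, r~) projection of a 5D run.

    Returns the line and the projected post-transient points.
    """
    traj = integrate(params, T, dt=dt)
    win = traj.window(t0, T)
    w_t, r_t = scale_gates(win.w, win.r, params)
    pts = np.column_stack([w_t, r_t])
    return fit_line(pts), pts


@dataclass(frozen=True)
class TimescaleRatios:
    """Per-sample effective time constants and their ratio maxima.

    ``tau_V`` is the effective membrane time constant ``Cm / g_tot`` with
    ``g_tot`` the sum of instantaneous chord conductances.  Maxima are
    reported over the subthreshold (SAO) portion of the trace and over the
    full trace.
    """

    t: np.ndarray
    tau_V: np.ndarray
    tau_h: np.ndarray
    tau_s: np.ndarray
    tau_r: np.ndarray
    tau_w: np.ndarray
    subthreshold: np.ndarray  # boolean mask

    def _max(self, a: np.ndarray, b: np.ndarray, mask) -> float:
        return float(np.max(a[mask] / b[mask]))

    def max_ratios(self, where: str = "subthreshold") -> dict:
        mask = (self.subthreshold if where == "subthreshold"
                else np.ones_like(self.subthreshold))
        return {
            "tauV_tauh": self._max(self.tau_V, self.tau_h, mask),
            "tauV_taus": self._max(self.tau_V, self.tau_s, mask),
            "taus_taur": self._max(self.tau_s, self.tau_r, mask),
            "taus_tauw": self._max(self.tau_s, self.tau_w, mask),
        }


def timescale_ratios(traj: Trajectory,
                     params: ModelParameters | None = None) -> TimescaleRatios:
    """Timescale separation of a 5D trajectory.

    The gate time constants come from the kinetics at V(t); the membrane
    time constant is Cm over the summed chord conductances
    ``gNaF*m_inf^3*h + gNaP*n_inf^3 + gKS*s + gL + gHCN_eff*r + gM_eff*w``.
    """
    p = params if params is not None else traj.params
    k = gate_kinetics(traj.V, p)
    g_tot = (p.gNaF * k.m_inf ** 3 * traj.h
             + p.gNaP * k.n_inf ** 3
             + p.gKS * traj.s
             + p.gL
             + p.gHCN_eff * traj.r
             + p.gM_eff * traj.w)
    return TimescaleRatios(
        t=traj.t,
        tau_V=p.Cm / g_tot,
        tau_h=k.tau_h,
        tau_s=k.tau_s,
        tau_r=k.tau_r,
        tau_w=k.tau_w,
        # SAO segments: SAO peaks sit near -70 mV; -50 mV excludes the brief
        # AP flanks that a looser LAO-threshold mask would keep.
        subthreshold=traj.V < -50.0,
    )
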