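"""Integration of the 5D/3D models and oscillation-pattern analysis.

A mixed-mode oscillation (MMO) alternates large-amplitude oscillations
(LAOs: full action potentials) with small-amplitude subthreshold
oscillations (SAOs).  This module integrates the models with a fixed-step
fourth-order Runge-Kutta scheme, detects voltage peaks, classifies them as
LAO or SAO, extracts MMO signatures (e.g. ``"1413"`` = one LAO followed by
four SAOs, then one LAO followed by three SAOs), computes firing-frequency
(f-I) curves and locates the silent / MMO / spiking regime boundaries along
the applied current axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import find_peaks

from .model_core import (
    ModelParameters,
    State5D,
    _rhs_3d,
    _rhs_5d,
    condition_params,
    resting_state,
)

__all__ = [
    "Trajectory",
    "OscillationEvent",
    "Signature",
    "integrate",
    "integrate_3d",
    "detect_events",
    "mmo_signature",
    "trim_to_complete_blocks",
    "firing_frequency",
    "classify_regime",
    "regime_interval_scan",
    "mmo_interval",
    "ff_curve",
    "LAO_THRESHOLD",
    "PEAK_PROMINENCE",
    "DEFAULT_DT",
    "SCAN_DT",
]

#: peak-voltage threshold separating full APs (LAOs) from subthreshold SAOs.
#: APs overshoot 0 mV while SAOs stay well below -40 mV, so any value in
#: between is robust.
LAO_THRESHOLD = -20.0
#: minimum peak prominence (mV) for an extremum to count as an oscillation.
#: SAOs grow from fractions of a millivolt near the subthreshold minimum of
#: a mixed-mode cycle; spiking traces show no subthreshold maxima at all, so
#: a small prominence separates the two regimes cleanly while rejecting
#: integration ripple.
PEAK_PROMINENCE = 0.2
#: reference integration step (ms) for single-trace simulations.
DEFAULT_DT = 0.001
#: integration step (ms) used by the regime/frequency scans; boundary
#: positions move by well under 1 uA/cm^2 when this is halved.
SCAN_DT = 0.002


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


# ---------------------------------------------------------------------------
# fixed-step RK4 cores
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _rk4_5d(y0, P, dt, n_steps, rec_every):
    n_rec = n_steps // rec_every + 1
    T = np.empty(n_rec)
    Y = np.empty((n_rec, 5))
    y = y0.copy()
    k1 = np.empty(5); k2 = np.empty(5); k3 = np.empty(5); k4 = np.empty(5)
    yt = np.empty(5)
    T[0] = 0.0
    Y[0] = y
    j = 1
    for i in range(n_steps):
        _rhs_5d(y, P, k1)
        for d in range(5):
            yt[d] = y[d] + 0.5 * dt * k1[d]
        _rhs_5d(yt, P, k2)
        for d in range(5):
            yt[d] = y[d] + 0.5 * dt * k2[d]
        _rhs_5d(yt, P, k3)
        for d in range(5):
            yt[d] = y[d] + dt * k3[d]
        _rhs_5d(yt, P, k4)
        for d in range(5):
            y[d] += dt / 6.0 * (k1[d] + 2.0 * k2[d] + 2.0 * k3[d] + k4[d])
        if (i + 1) % rec_every == 0:
            if not np.isfinite(y[0]):
                return T[:j], Y[:j], (i + 1) * dt
            T[j] = (i + 1) * dt
            Y[j] = y
            j += 1
    return T[:j], Y[:j], -1.0


@njit(cache=True, fastmath=True)
def _rk4_3d(y0, P, dt, n_steps, rec_every):
    n_rec = n_steps // rec_every + 1
    T = np.empty(n_rec)
    Y = np.empty((n_rec, 3))
    y = y0.copy()
    k1 = np.empty(3); k2 = np.empty(3); k3 = np.empty(3); k4 = np.empty(3)
    yt = np.empty(3)
    T[0] = 0.0
    Y[0] = y
    j = 1
    for i in range(n_steps):
        _rhs_3d(y, P, k1)
        for d in range(3):
            yt[d] = y[d] + 0.5 * dt * k1[d]
        _rhs_3d(yt, P, k2)
        for d in range(3):
            yt[d] = y[d] + 0.5 * dt * k2[d]
        _rhs_3d(yt, P, k3)
        for d in range(3):
            yt[d] = y[d] + dt * k3[d]
        _rhs_3d(yt, P, k4)
        for d in range(3):
            y[d] += dt / 6.0 * (k1[d] + 2.0 * k2[d] + 2.0 * k3[d] + k4[d])
        if not (-150.0 < y[0] < 80.0):
            return T[:j], Y[:j], (i + 1) * dt
        if (i + 1) % rec_every == 0:
            T[j] = (i + 1) * dt
            Y[j] = y
            j += 1
    return T[:j], Y[:j], -1.0


@njit(cache=True, fastmath=True)
def _rk4_3d_reversed(y0, P, dt, n_steps, rec_every):
    """RK4 for the time-reversed reduced system (y' = -f(y))."""
    n_rec = n_steps // rec_every + 1
    T = np.empty(n_rec)
    Y = np.empty((n_rec, 3))
    y = y0.copy()
    k1 = np.empty(3); k2 = np.empty(3); k3 = np.empty(3); k4 = np.empty(3)
    yt = np.empty(3)
    T[0] = 0.0
    Y[0] = y
    j = 1
    for i in range(n_steps):
        _rhs_3d(y, P, k1)
        for d in range(3):
            yt[d] = y[d] - 0.5 * dt * k1[d]
        _rhs_3d(yt, P, k2)
        for d in range(3):
            yt[d] = y[d] - 0.5 * dt * k2[d]
        _rhs_3d(yt, P, k3)
        for d in range(3):
            yt[d] = y[d] - dt * k3[d]
        _rhs_3d(yt, P, k4)
        for d in range(3):
            y[d] -= dt / 6.0 * (k1[d] + 2.0 * k2[d] + 2.0 * k3[d] + k4[d])
        if not (-150.0 < y[0] < 80.0):
            return T[:j], Y[:j], (i + 1) * dt
        if (i + 1) % rec_every == 0:
            T[j] = (i + 1) * dt
            Y[j] = y
            j += 1
    return T[:j], Y[:j], -1.0


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """A simulated time series of the 5D or reduced 3D model."""

    t: np.ndarray
    y: np.ndarray
    params: ModelParameters
    model: str = "5D"
    w_tilde: float | None = None
    r_tilde: float | None = None
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if len(self.t) != len(self.y):
            raise ValueError("time grid and state count differ")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def V(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def h(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def s(self) -> np.ndarray:
        return self.y[:, 2]

    @property
    def r(self) -> np.ndarray:
        if self.model != "5D":
            raise AttributeError("r is frozen in the 3D model")
        return self.y[:, 3]

    @property
    def w(self) -> np.ndarray:
        if self.model != "5D":
            raise AttributeError("w is frozen in the 3D model")
        return self.y[:, 4]

    def window(self, t0: float, t1: float | None = None) -> "Trajectory":
        """Restrict to ``t0 <= t <= t1`` (end of trace if t1 is None)."""
        t1 = self.t[-1] if t1 is None else t1
        m = (self.t >= t0) & (self.t <= t1)
        return Trajectory(self.t[m], self.y[m], self.params, self.model,
                          self.w_tilde, self.r_tilde, self.dt)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t_ms": self.t, "V_mV": self.V, "h": self.h, "s": self.s}
        if self.model == "5D":
            cols["r"] = self.y[:, 3]
            cols["w"] = self.y[:, 4]
        else:
            cols["w_tilde"] = np.full(len(self.t), self.w_tilde)
            cols["r_tilde"] = np.full(len(self.t), self.r_tilde)
        return pd.DataFrame(cols)


def _n_steps(t_span: float, dt: float) -> int:
    return int(round(t_span / dt))


def integrate(params: ModelParameters,
              t_span: float,
              dt: float = DEFAULT_DT,
              ic: State5D | np.ndarray | None = None,
              record_dt: float | None = None) -> Trajectory:
    """Integrate the 5D model with fixed-step RK4.

    ``record_dt`` sub-samples the stored output (default 0.01 ms, ten times
    coarser than the integration step; action potentials last ~1 ms so peak
    detection is unaffected).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if ic is None:
        y0 = resting_state(params).as_array()
    elif isinstance(ic, State5D):
        y0 = ic.as_array()
    else:
        y0 = np.asarray(ic, dtype=float)
    rec = max(1, int(round((record_dt if record_dt else 10 * dt) / dt)))
    T, Y, fail = _rk4_5d(y0, params.runtime_vector_5d(), dt,
                         _n_steps(t_span, dt), rec)
    if fail >= 0:
        raise IntegrationError(f"non-finite state at t = {fail:.3f} ms")
    return Trajectory(T, Y, params, "5D", dt=dt)


def integrate_3d(params: ModelParameters,
                 w_tilde: float,
                 r_tilde: float,
                 t_span: float,
                 dt: float = DEFAULT_DT,
                 ic: np.ndarray | None = None,
                 record_dt: float | None = None) -> Trajectory:
    """Integrate the reduced (V, h, s) subsystem with frozen (w~, r~)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if ic is None:
        st = resting_state(params)
        y0 = np.array([st.V, st.h, st.s])
    else:
        y0 = np.asarray(ic, dtype=float)
    rec = max(1, int(round((record_dt if record_dt else 10 * dt) / dt)))
    P = params.runtime_vector_3d(w_tilde, r_tilde)
    T, Y, fail = _rk4_3d(y0, P, dt, _n_steps(t_span, dt), rec)
    if fail >= 0:
        raise IntegrationError(f"non-finite state at t = {fail:.3f} ms")
    return Trajectory(T, Y, params, "3D", w_tilde=w_tilde, r_tilde=r_tilde,
                      dt=dt)


# ---------------------------------------------------------------------------
# event detection and signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillationEvent:
    """A detected voltage maximum, classified by amplitude."""

    t_peak: float
    V_peak: float
    kind: str  # "LAO" or "SAO"


def detect_events(traj: Trajectory,
                  V_LAO: float = LAO_THRESHOLD,
                  prominence: float = PEAK_PROMINENCE) -> list[OscillationEvent]:
    """Local voltage maxima with the given prominence, tagged LAO or SAO."""
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    idx, _ = find_peaks(traj.V, prominence=prominence)
    return [
        OscillationEvent(float(traj.t[i]), float(traj.V[i]),
                         "LAO" if traj.V[i] >= V_LAO else "SAO")
        for i in idx
    ]


def events_to_dataframe(events: list[OscillationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {"t_peak_ms": [e.t_peak for e in events],
         "V_peak_mV": [e.V_peak for e in events],
         "kind": [e.kind for e in events]})


@dataclass(frozen=True)
class Signature:
    """MMO signature: (LAO count, SAO count) blocks, e.g. "2423" = 2^4 2^3.

    ``blocks`` holds the observed block sequence; ``unit`` the distinct
    blocks (rotated so the block with the most SAOs leads, the convention
    in which mixed signatures are quoted); ``periodic`` whether the
    sequence is an exact cyclic repetition of the unit.
    """

    blocks: tuple[tuple[int, int], ...]
    unit: tuple[tuple[int, int], ...] = ()
    periodic: bool = True
    silent: bool = False

    def __str__(self) -> str:
        return "".join(f"{L}{s}" for L, s in (self.unit or self.blocks))


def _block_decomposition(kinds: list[str]) -> list[tuple[int, int]]:
    # Blocks start at each LAO run ("L LAOs then s SAOs"); a leading SAO
    # run has no LAO to attach to and is dropped.
    blocks = []
    i = 0
    n = len(kinds)
    while i < n and kinds[i] == "SAO":
        i += 1
    while i < n:
        L = 0
        while i < n and kinds[i] == "LAO":
            L += 1
            i += 1
        s = 0
        while i < n and kinds[i] == "SAO":
            s += 1
            i += 1
        blocks.append((L, s))
    return blocks


def trim_to_complete_blocks(
        events: list[OscillationEvent]) -> list[OscillationEvent]:
    """Drop the final, possibly window-truncated block of an event train.

    Cuts just before the last run of LAOs so every remaining block ends
    with its full SAO tail.
    """
    kinds = [e.kind for e in events]
    last = None
    for i in range(1, len(kinds)):
        if kinds[i] == "LAO" and kinds[i - 1] == "SAO":
            last = i
    return events if last is None else events[:last]


def mmo_signature(events: list[OscillationEvent]) -> Signature:
    """Block structure of an event train.

    Consecutive LAOs and the SAOs that follow them form one block.  The
    signature unit is the set of distinct blocks, led by the block with
    the most SAOs; ``periodic`` reports whether the whole sequence is an
    exact cyclic repetition of that unit (chaotic MMOs alternate among
    the unit's blocks without exact periodicity).
    """
    kinds = [e.kind for e in events]
    if "LAO" not in kinds:
        return Signature(blocks=(), unit=(), periodic=False, silent=True)
    blocks = _block_decomposition(kinds)
    seen: list[tuple[int, int]] = []
    for b in blocks:
        if b not in seen:
            seen.append(b)
    k = max(range(len(seen)), key=lambda i: (seen[i][1], seen[i][0]))
    unit = tuple(seen[k:] + seen[:k])
    m = len(unit)
    periodic = any(
        all(blocks[i] == unit[(i + o) % m] for i in range(len(blocks)))
        for o in range(m))
    return Signature(tuple(blocks), unit, periodic)


def firing_frequency(traj: Trajectory, t0: float = 350.0) -> float:
    """Action-potential (LAO) rate in Hz over ``[t0, end]``."""
    if traj.t[-1] <= t0:
        raise ValueError("trajectory shorter than the analysis onset t0")
    events = detect_events(traj.window(t0))
    n_lao = sum(e.kind == "LAO" for e in events)
    return 1000.0 * n_lao / (traj.t[-1] - t0)


# ---------------------------------------------------------------------------
# regime classification and scans
# ---------------------------------------------------------------------------

SILENT, MMO, SPIKING = "silent", "MMO", "spiking"


def classify_events(events: list[OscillationEvent]) -> str:
    has_lao = any(e.kind == "LAO" for e in events)
    has_sao = any(e.kind == "SAO" for e in events)
    if not has_lao:
        return SILENT
    return MMO if has_sao else SPIKING


def classify_regime(params: ModelParameters,
                    I_App: float | None = None,
                    horizon: float = 1000.0,
                    analyze_last: float = 500.0,
                    dt: float = SCAN_DT,
                    model: str = "5D",
                    w_tilde: float | None = None,
                    r_tilde: float | None = None) -> str:
    """Steady-state regime at one applied current: silent, MMO or spiking.

    Simulates for ``horizon`` ms from the standard resting initial
    condition and classifies the events of the last ``analyze_last`` ms.
    """
    p = params if I_App is None else params.with_(IApp=I_App)
    if model == "5D":
        traj = integrate(p, horizon, dt=dt)
    else:
        traj = integrate_3d(p, w_tilde, r_tilde, horizon, dt=dt)
    events = detect_events(traj.window(horizon - analyze_last))
    return classify_events(events)


@dataclass(frozen=True)
class RegimeScan:
    """Regime partition of an applied-current range."""

    intervals: tuple[tuple[float, float, str], ...]  # (lo, hi, label)
    boundaries: tuple[tuple[float, str, str], ...]   # (I, label_lo, label_hi)
    resolution: float

    def interval_of(self, label: str) -> tuple[float, float] | None:
        for lo, hi, lab in self.intervals:
            if lab == label:
                return lo, hi
        return None


def _bisect_boundary(fun, lo, hi, lab_lo, lab_hi, resolution):
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if fun(mid) == lab_lo:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def regime_interval_scan(params: ModelParameters,
                         I_range: tuple[float, float] = (0.0, 400.0),
                         step: float = 20.0,
                         resolution: float = 1.0,
                         horizon: float = 1000.0,
                         analyze_last: float = 500.0,
                         dt: float = SCAN_DT) -> RegimeScan:
    """Coarse scan plus bisection of the regime boundaries along I_App.

    Returns the regime intervals with each boundary refined to
    ``+- resolution / 2``.  Non-monotone label sequences (a regime
    re-appearing after it ended) are kept as separate intervals rather than
    merged.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")

    def lab(I):
        return classify_regime(params, I, horizon, analyze_last, dt)

    grid = np.arange(I_range[0], I_range[1] + 0.5 * step, step)
    labels = [lab(I) for I in grid]
    boundaries = []
    for i in range(len(grid) - 1):
        if labels[i] != labels[i + 1]:
            b = _bisect_boundary(lab, grid[i], grid[i + 1],
                                 labels[i], labels[i + 1], resolution)
            boundaries.append((b, labels[i], labels[i + 1]))
    intervals = []
    lo = float(I_range[0])
    for b, lab_lo, _ in boundaries:
        intervals.append((lo, b, lab_lo))
        lo = b
    intervals.append((lo, float(I_range[1]), labels[-1]))
    return RegimeScan(tuple(intervals), tuple(boundaries), resolution)


def mmo_interval(condition: str,
                 I_range: tuple[float, float] = (0.0, 400.0),
                 **kw) -> tuple[float, float]:
    """MMO applied-current interval [lo, hi] for a named drug condition."""
    scan = regime_interval_scan(condition_params(condition), I_range, **kw)
    iv = scan.interval_of(MMO)
    if iv is None:
        raise RuntimeError(f"no MMO interval found for {condition} "
                           f"in {I_range}")
    return iv


def firing_limit(params: ModelParameters,
                 I_lo: float = 400.0,
                 I_hi: float = 1000.0,
                 step: float = 50.0,
                 resolution: float = 1.0,
                 horizon: float = 1000.0,
                 analyze_last: float = 500.0,
                 dt: float = SCAN_DT) -> float:
    """Upper applied-current limit of sustained firing.

    Above the mixed-mode range the action-potential amplitude shrinks
    steadily with drive until the oscillation collapses into depolarization
    block (the membrane settles at a constant depolarized potential).  The
    peak voltage crosses any fixed amplitude threshold well before firing
    actually stops, so this boundary is located by bisecting the current at
    which detected oscillation events of either kind disappear.
    """
    def fires(I: float) -> bool:
        traj = integrate(params.with_(IApp=float(I)), horizon, dt=dt)
        return len(detect_events(traj.window(horizon - analyze_last))) > 0

    if not fires(I_lo):
        raise RuntimeError(f"no sustained firing at I_App = {I_lo}")
    lo = I_lo
    hi = None
    for I in np.arange(I_lo + step, I_hi + 0.5 * step, step):
        if fires(float(I)):
            lo = float(I)
        else:
            hi = float(I)
            break
    if hi is None:
        raise RuntimeError(f"firing persists up to I_App = {I_hi}")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ff_curve(condition: str | ModelParameters,
             I_grid,
             horizon: float = 1000.0,
             t0: float = 350.0,
             dt: float = SCAN_DT) -> pd.DataFrame:
    """Firing-frequency curve: (I_app, ff_hz, regime) per grid point."""
    params = (condition_params(condition)
              if isinstance(condition, str) else condition)
    rows = []
    for I in np.asarray(I_grid, dtype=float):
        traj = integrate(params.with_(IApp=float(I)), horizon, dt=dt)
        events = detect_events(traj.window(t0))
        n_lao = sum(e.kind == "LAO" for e in events)
        ff = 1000.0 * n_lao / (horizon - t0)
        rows.append((float(I), ff, classify_events(events)))
    return pd.DataFrame(rows, columns=["I_app", "ff_hz", "regime"])


def ff_crossing(cond_a: str, cond_b: str,
                I_lo: float = 60.0, I_hi: float = 200.0,
                step: float = 5.0, **kw) -> float:
    """Applied current where the f-I curves of two conditions intersect.

    Computes both curves on a common grid and linearly interpolates the
    zero of their difference (restricted to where both cells fire).
    """
    grid = np.arange(I_lo, I_hi + 0.5 * step, step)
    fa = ff_curve(cond_a, grid, **kw)["ff_hz"].to_numpy()
    fb = ff_curve(cond_b, grid, **kw)["ff_hz"].to_numpy()
    d = fa - fb
    active = (fa > 0) & (fb > 0)
    for i in range(len(grid) - 1):
        if not (active[i] and active[i + 1]):
            continue
        if d[i] == 0.0:
            # equal FFs at a grid point: centre of the flat run
            j = i
            while j + 1 < len(grid) and d[j + 1] == 0.0 and active[j + 1]:
                j += 1
            return float(0.5 * (grid[i] + grid[j]))
        if d[i] * d[i + 1] < 0:
            return float(grid[i] - d[i] * step / (d[i + 1] - d[i]))
    raise RuntimeError("no crossing of the firing-frequency curves found")
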