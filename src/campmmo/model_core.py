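"""Closed-form right-hand side of the 5D cortical pyramidal-neuron model.

The model is a Hodgkin-Huxley-type single-compartment description with six
ionic currents: fast Na+ (NaF), persistent Na+ (NaP), slow K+ (KS), leak (L),
hyperpolarization-activated cyclic-nucleotide-gated (HCN) and M-type K+ (M).
The dynamical variables are the membrane potential ``V`` (mV) and four gating
variables: ``h`` (NaF inactivation), ``s`` (KS activation), ``r`` (HCN
activation) and ``w`` (M activation).  The activation gates of the two Na+
currents (``m``, ``n``) are instantaneous (``m_inf**3``, ``n_inf**3``).

cAMP enters as a binary flag: when raised it increments the HCN and M maximal
conductances (``dgHCN``, ``dgM``) and shifts the HCN half-activation voltage
``nu`` from 103.5 mV to 95 mV.

Units: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2, degrees C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from numba import njit

__all__ = [
    "ModelParameters",
    "GateKinetics",
    "State5D",
    "CONDITIONS",
    "condition_params",
    "temperature_factor",
    "gate_kinetics",
    "ionic_currents",
    "rhs_5d",
    "DEFAULT_V0",
    "resting_state",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Model parameters with physiological defaults.

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2,
    applied current in uA/cm^2, temperatures in degrees C.  ``Tref1`` is the
    reference temperature of the Na+/K+ channel kinetics, ``Tref2`` that of
    the HCN channel kinetics.  ``cAMP`` is the binary second-messenger flag.
    """

    Cm: float = 0.9
    gNaF: float = 1000.0
    gNaP: float = 1.0
    gKS: float = 40.0
    gL: float = 11.3
    gHCN: float = 23.0
    gM: float = 50.0
    dgHCN: float = 12.0
    dgM: float = 50.0
    ENa: float = 50.0
    EK: float = -84.0
    EL: float = -83.38
    EHCN: float = -50.0
    IApp: float = 0.0
    cAMP: int = 0
    T: float = 37.0
    Tref1: float = 20.0
    Tref2: float = 35.0
    Qm: float = 2.2
    Qn: float = 2.2
    Qh: float = 2.9
    Qs: float = 3.0
    Qr: float = 3.0

    def __post_init__(self) -> None:
        for name in ("gNaF", "gNaP", "gKS", "gL", "gHCN", "gM", "dgHCN", "dgM"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.Cm <= 0:
            raise ValueError("Cm must be > 0")
        if self.cAMP not in (0, 1):
            raise ValueError("cAMP must be 0 or 1")
        for name in ("Qm", "Qn", "Qh", "Qs", "Qr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Q factor {name} must be > 0")

    # -- derived quantities -------------------------------------------------

    @property
    def gHCN_eff(self) -> float:
        """HCN maximal conductance including the cAMP increment."""
        return self.gHCN + self.cAMP * self.dgHCN

    @property
    def gM_eff(self) -> float:
        """M maximal conductance including the cAMP increment."""
        return self.gM + self.cAMP * self.dgM

    @property
    def nu(self) -> float:
        """HCN half-activation voltage shift nu(cAMP) in mV."""
        return 95.0 * self.cAMP + 103.5 * (1 - self.cAMP)

    def phi(self, gate: str) -> float:
        """Temperature correction factor for one gate (``m n h s r``)."""
        Q = {"m": self.Qm, "n": self.Qn, "h": self.Qh, "s": self.Qs,
             "r": self.Qr}[gate]
        Tref = self.Tref2 if gate == "r" else self.Tref1
        return temperature_factor(Q, self.T, Tref)

    def with_(self, **over) -> "ModelParameters":
        """Return a copy with the given fields overridden."""
        return replace(self, **over)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: (int(v) if k == "cAMP" else float(v))
                      for k, v in d.items()})

    def runtime_vector_5d(self) -> np.ndarray:
        """Flat parameter vector consumed by the compiled 5D integrator."""
        return np.array([
            self.Cm, self.gNaF, self.gNaP, self.gKS, self.gL,
            self.gHCN_eff, self.gM_eff, self.ENa, self.EK, self.EL,
            self.EHCN, self.IApp, self.phi("h"), self.phi("s"),
            self.phi("r"), self.nu,
        ])

    def runtime_vector_3d(self, w_tilde: float, r_tilde: float) -> np.ndarray:
        """Flat parameter vector for the reduced (V, h, s) subsystem.

        The super-slow gates enter only through the chord conductances
        ``gHCN * r_tilde`` and ``gM * w_tilde``; the result is therefore
        independent of the cAMP flag by construction.
        """
        return np.array([
            self.Cm, self.gNaF, self.gNaP, self.gKS, self.gL,
            self.gHCN * r_tilde, self.gM * w_tilde, self.ENa, self.EK,
            self.EL, self.EHCN, self.IApp, self.phi("h"), self.phi("s"),
        ])


#: drug-condition presets: (gM, dgM, gHCN, dgHCN, cAMP)
CONDITIONS: dict[str, tuple[float, float, float, float, int]] = {
    "Ctrl":    (50.0, 50.0, 23.0, 12.0, 0),
    "CGS":     (50.0, 50.0, 23.0, 12.0, 1),
    "ZD":      (50.0, 50.0,  0.0,  0.0, 0),
    "ZD+CGS":  (50.0, 50.0,  0.0,  0.0, 1),
    "XE":      ( 0.0,  0.0, 23.0, 12.0, 0),
    "XE+CGS":  ( 0.0,  0.0, 23.0, 12.0, 1),
    "FSK":     (50.0, 50.0, 23.0, 12.0, 1),
    "FSK+Lin": (50.0, 20.0, 23.0, 12.0, 1),
}


def condition_params(name: str,
                     base: ModelParameters | None = None) -> ModelParameters:
    """Parameters for a named drug condition.

    The presets encode the in-silico pharmacology: ZD7288 blocks HCN
    channels (gHCN = dgHCN = 0), XE991 blocks M channels (gM = dgM = 0),
    CGS21680/Forskolin raise cAMP (flag = 1), and Linopirdine on top of
    Forskolin reduces the cAMP-induced M increment to 20 mS/cm^2.
    """
    if name not in CONDITIONS:
        raise KeyError(
            f"unknown condition {name!r}; valid names: "
            + ", ".join(sorted(CONDITIONS)))
    gM, dgM, gHCN, dgHCN, cAMP = CONDITIONS[name]
    base = base if base is not None else ModelParameters()
    return base.with_(gM=gM, dgM=dgM, gHCN=gHCN, dgHCN=dgHCN, cAMP=cAMP)


def temperature_factor(Q: float, T: float, Tref: float) -> float:
    """Q10-style temperature correction ``Q ** ((T - Tref) / 10)``."""
    if Q <= 0:
        raise ValueError("Q must be > 0")
    return Q ** ((T - Tref) / 10.0)


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _rate(a: float, b: float, c: float, V: float) -> float:
    # a*(V+b) / (1 - exp(-(V+b)/c)); removable singularity at V = -b
    # resolved by the analytic limit a*c (l'Hopital).
    x = V + b
    y = x / c
    if abs(y) < 1e-7:
        return a * c * (1.0 + 0.5 * y)
    if y < -700.0:
        return 0.0
    return a * c * y / (-math.expm1(-y))


@njit(cache=True, fastmath=True)
def _m_inf(V: float) -> float:
    am = _rate(1.86, 25.4, 10.3, V)
    bm = _rate(-0.086, 29.7, -9.16, V)
    return am / (am + bm)


@njit(cache=True, fastmath=True)
def _n_inf(V: float) -> float:
    an = _rate(0.186, 48.4, 10.3, V)
    bn = _rate(-0.0086, 42.7, -9.16, V)
    return an / (an + bn)


@njit(cache=True, fastmath=True)
def _h_rates(V: float) -> tuple:
    ah = _rate(-0.0336, 118.0, -11.0, V)
    bh = 2.3 / (1.0 + math.exp(-(V + 35.8) / 13.4))
    return ah, bh


@njit(cache=True, fastmath=True)
def _s_rates(V: float) -> tuple:
    as_ = _rate(0.00122, 19.5, 23.6, V)
    bs = _rate(-0.000739, 87.1, -21.8, V)
    return as_, bs


@njit(cache=True, fastmath=True)
def _r_rates(V: float, nu: float) -> tuple:
    ar = 0.007 * math.exp(-(V + nu) / 19.0)
    br = 0.007 * math.exp((V + nu) / 22.0)
    return ar, br


@njit(cache=True, fastmath=True)
def _w_inf(V: float) -> float:
    return 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))


@njit(cache=True, fastmath=True)
def _tau_w(V: float) -> float:
    return 400.0 / (3.3 * math.exp((V + 35.0) / 20.0)
                    + math.exp(-(V + 35.0) / 20.0))


@dataclass(frozen=True)
class GateKinetics:
    """All transition rates, steady states and time constants at a voltage.

    ``tau_*`` include the temperature correction; the M gate has no
    temperature factor defined and ``tau_w`` is used as printed.
    """

    V: np.ndarray
    nu: float
    alpha_m: np.ndarray
    beta_m: np.ndarray
    alpha_h: np.ndarray
    beta_h: np.ndarray
    alpha_n: np.ndarray
    beta_n: np.ndarray
    alpha_s: np.ndarray
    beta_s: np.ndarray
    alpha_r: np.ndarray
    beta_r: np.ndarray
    m_inf: np.ndarray
    h_inf: np.ndarray
    n_inf: np.ndarray
    s_inf: np.ndarray
    r_inf: np.ndarray
    w_inf: np.ndarray
    tau_m: np.ndarray
    tau_h: np.ndarray
    tau_n: np.ndarray
    tau_s: np.ndarray
    tau_r: np.ndarray
    tau_w: np.ndarray
    phi: dict = field(repr=False, default_factory=dict)


def _rate_np(a: float, b: float, c: float, V: np.ndarray) -> np.ndarray:
    x = np.asarray(V, dtype=float) + b
    y = x / c
    small = np.abs(y) < 1e-7
    ys = np.where(small, 1.0, y)
    with np.errstate(over="ignore"):
        out = a * c * ys / (-np.expm1(-np.clip(ys, -700.0, None)))
    return np.where(small, a * c * (1.0 + 0.5 * y), out)


def gate_kinetics(V, params: ModelParameters | None = None) -> GateKinetics:
    """Evaluate every gate's rates, steady state and time constant at ``V``.

    Accepts scalars or arrays.  Removable singularities of the rate
    expressions (where ``1 - exp(.)`` vanishes) are filled with their
    analytic limits, so the result is continuous in ``V``.
    """
    p = params if params is not None else ModelParameters()
    V = np.asarray(V, dtype=float)
    nu = p.nu
    am = _rate_np(1.86, 25.4, 10.3, V)
    bm = _rate_np(-0.086, 29.7, -9.16, V)
    ah = _rate_np(-0.0336, 118.0, -11.0, V)
    bh = 2.3 / (1.0 + np.exp(-(V + 35.8) / 13.4))
    an = _rate_np(0.186, 48.4, 10.3, V)
    bn = _rate_np(-0.0086, 42.7, -9.16, V)
    as_ = _rate_np(0.00122, 19.5, 23.6, V)
    bs = _rate_np(-0.000739, 87.1, -21.8, V)
    ar = 0.007 * np.exp(-(V + nu) / 19.0)
    br = 0.007 * np.exp((V + nu) / 22.0)
    phi = {g: p.phi(g) for g in "mnhsr"}
    winf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    tw = 400.0 / (3.3 * np.exp((V + 35.0) / 20.0)
                  + np.exp(-(V + 35.0) / 20.0))
    return GateKinetics(
        V=V, nu=nu,
        alpha_m=am, beta_m=bm, alpha_h=ah, beta_h=bh, alpha_n=an, beta_n=bn,
        alpha_s=as_, beta_s=bs, alpha_r=ar, beta_r=br,
        m_inf=am / (am + bm), h_inf=ah / (ah + bh), n_inf=an / (an + bn),
        s_inf=as_ / (as_ + bs), r_inf=ar / (ar + br), w_inf=winf,
        tau_m=1.0 / (phi["m"] * (am + bm)),
        tau_h=1.0 / (phi["h"] * (ah + bh)),
        tau_n=1.0 / (phi["n"] * (an + bn)),
        tau_s=1.0 / (phi["s"] * (as_ + bs)),
        tau_r=1.0 / (phi["r"] * (ar + br)),
        tau_w=tw, phi=phi,
    )


# ---------------------------------------------------------------------------
# state, currents and right-hand side
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class State5D:
    """One point of the 5D phase space: (V, h, s, r, w)."""

    V: float
    h: float
    s: float
    r: float
    w: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.s, self.r, self.w])

    @classmethod
    def from_array(cls, y) -> "State5D":
        return cls(*np.asarray(y, dtype=float))


DEFAULT_V0 = -70.0


def resting_state(params: ModelParameters, V0: float = DEFAULT_V0) -> State5D:
    """Standard initial condition: V0 with every gate at its steady state."""
    k = gate_kinetics(V0, params)
    return State5D(V0, float(k.h_inf), float(k.s_inf), float(k.r_inf),
                   float(k.w_inf))


def ionic_currents(state, params: ModelParameters) -> dict:
    """Per-channel current densities (uA/cm^2) at one state.

    The instantaneous gates enter as ``m_inf(V)**3`` and ``n_inf(V)**3``;
    the M current reverses at the K+ Nernst potential.
    """
    if isinstance(state, State5D):
        V, h, s, r, w = state.V, state.h, state.s, state.r, state.w
    else:
        V, h, s, r, w = np.asarray(state, dtype=float)
    k = gate_kinetics(V, params)
    return {
        "I_NaF": params.gNaF * k.m_inf ** 3 * h * (V - params.ENa),
        "I_NaP": params.gNaP * k.n_inf ** 3 * (V - params.ENa),
        "I_KS": params.gKS * s * (V - params.EK),
        "I_L": params.gL * (V - params.EL),
        "I_HCN": params.gHCN_eff * r * (V - params.EHCN),
        "I_M": params.gM_eff * w * (V - params.EK),
    }


@njit(cache=True, fastmath=True)
def _rhs_5d(y: np.ndarray, P: np.ndarray, out: np.ndarray) -> None:
    V, h, s, r, w = y[0], y[1], y[2], y[3], y[4]
    Cm = P[0]
    minf = _m_inf(V)
    ninf = _n_inf(V)
    I = (P[1] * minf * minf * minf * h * (V - P[7])     # NaF
         + P[2] * ninf * ninf * ninf * (V - P[7])       # NaP
         + P[3] * s * (V - P[8])                        # KS
         + P[4] * (V - P[9])                            # leak
         + P[5] * r * (V - P[10])                       # HCN
         + P[6] * w * (V - P[8]))                       # M
    out[0] = (-I + P[11]) / Cm
    ah, bh = _h_rates(V)
    out[1] = (ah / (ah + bh) - h) * P[12] * (ah + bh)
    as_, bs = _s_rates(V)
    out[2] = (as_ / (as_ + bs) - s) * P[13] * (as_ + bs)
    ar, br = _r_rates(V, P[15])
    out[3] = (ar / (ar + br) - r) * P[14] * (ar + br)
    out[4] = (_w_inf(V) - w) / _tau_w(V)


@njit(cache=True, fastmath=True)
def _rhs_3d(y: np.ndarray, P: np.ndarray, out: np.ndarray) -> None:
    V, h, s = y[0], y[1], y[2]
    Cm = P[0]
    minf = _m_inf(V)
    ninf = _n_inf(V)
    I = (P[1] * minf * minf * minf * h * (V - P[7])
         + P[2] * ninf * ninf * ninf * (V - P[7])
         + P[3] * s * (V - P[8])
         + P[4] * (V - P[9])
         + P[5] * (V - P[10])                           # gHCN * r_tilde
         + P[6] * (V - P[8]))                           # gM * w_tilde
    out[0] = (-I + P[11]) / Cm
    ah, bh = _h_rates(V)
    out[1] = (ah / (ah + bh) - h) * P[12] * (ah + bh)
    as_, bs = _s_rates(V)
    out[2] = (as_ / (as_ + bs) - s) * P[13] * (as_ + bs)


def rhs_5d(t: float, y, params: ModelParameters) -> np.ndarray:
    """Time derivative of (V, h, s, r, w); signature matches solve_ivp."""
    out = np.empty(5)
    _rhs_5d(np.asarray(y, dtype=float), params.runtime_vector_5d(), out)
    return out


def rhs_3d_vec(t: float, y, P: np.ndarray) -> np.ndarray:
    """Reduced-system derivative given a precomputed 3D runtime vector."""
    out = np.empty(3)
    _rhs_3d(np.asarray(y, dtype=float), P, out)
    return out
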