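"""Human atrial myocyte model (Courtemanche–Ramirez–Nattel 1998) with scalable
maximum conductances.

The model has 21 state variables: membrane voltage ``V`` (mV), 15 gating
variables in [0, 1], and 5 concentrations (mM).  All membrane currents are
expressed as densities in pA/pF (equivalently uA/cm^2 at 1 uF/cm^2), so the
voltage equation reads ``dV/dt = -(I_ion) + J_stim`` with a depolarizing
stimulus density ``J_stim`` in uA/cm^2.

Nine maximum conductances / transporter maxima can be rescaled per cell
(:class:`ConductanceScale`): g_Na, g_K1, g_to, g_Kur, g_Kr, g_Ks, g_CaL,
I_pCa(max) and I_NaCa(max).  The control preset (all ones) reproduces the
published baseline model.

Two evaluation paths are provided:

* :func:`ionic_rhs` — a plain, readable NumPy implementation of the full
  right-hand side, used as the in-package reference and by the tests.
* :class:`RateTables` + the numba kernels in :mod:`atrialerp.engine` — a
  tabulated Rush–Larsen stepper used by the tissue solver.  Voltage-dependent
  gate steady states / time constants and current factors are pre-tabulated
  on a fine voltage grid and linearly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
import numpy as np

__all__ = [
    "CellState",
    "ConductanceScale",
    "RemodelingPreset",
    "CONTROL",
    "INFLAMMATION",
    "AF_DIRECTION",
    "ionic_rhs",
    "RateTables",
    "rest_state",
    "pace_to_limit_cycle",
    "apd90",
    "NoBeat",
    "STATE_NAMES",
    "N_STATES",
]

# ---------------------------------------------------------------------------
# constants (units: mV, ms, mM, pA/pF, um^3)
# ---------------------------------------------------------------------------
R = 8.3143          # J / (mol K)
T = 310.0           # K
F = 96.4867         # C / mmol
RTF = R * T / F     # ~26.71 mV

CM = 100.0          # pF, whole-cell capacitance (converts densities to pA)
V_CELL = 20100.0    # um^3
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

NA_O = 140.0        # mM
K_O = 5.4
CA_O = 1.8

G_NA = 7.8          # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_NA = 0.0006744375
G_B_CA = 0.001131

I_NAK_MAX = 0.59933874
KM_NA_I = 10.0
KM_K_O = 1.5
I_NACA_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275

K_REL = 30.0
TAU_TR = 180.0
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

KQ10 = 3.0
TAU_U = 8.0
TAU_FCA = 2.0

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel",
)
N_STATES = 21

# published resting initial conditions of the baseline model
_Y0 = np.array([
    -81.18, 2.908e-3, 0.9649, 0.9775, 3.043e-2, 0.9992, 4.966e-3, 0.9986,
    3.296e-5, 1.869e-2, 1.367e-4, 0.9996, 0.7755, 0.0, 1.0, 0.9992,
    11.17, 139.0, 1.013e-4, 1.488, 1.488,
])

SCALE_NAMES = ("gNa", "gK1", "gto", "gKur", "gKr", "gKs", "gCaL", "IpCa", "INaCa")


def rest_state() -> np.ndarray:
    """Published resting state of the control model (copy)."""
    return _Y0.copy()


# kept for type clarity in signatures; the engine works on raw arrays
CellState = np.ndarray


@dataclass(frozen=True)
class ConductanceScale:
    """Multiplicative factors applied to the scalable maximum conductances."""

    gNa: float = 1.0
    gK1: float = 1.0
    gto: float = 1.0
    gKur: float = 1.0
    gKr: float = 1.0
    gKs: float = 1.0
    gCaL: float = 1.0
    IpCa: float = 1.0
    INaCa: float = 1.0

    def __post_init__(self):
        for name in SCALE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"conductance multiplier {name} must be >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SCALE_NAMES], dtype=np.float64)

    @staticmethod
    def from_array(a) -> "ConductanceScale":
        return ConductanceScale(**{n: float(v) for n, v in zip(SCALE_NAMES, a)})

    def compose(self, other: "ConductanceScale") -> "ConductanceScale":
        """Multiplicative (commutative) composition of two scalings."""
        return ConductanceScale.from_array(self.as_array() * other.as_array())

    def to_json(self) -> str:
        return json.dumps({n: getattr(self, n) for n in SCALE_NAMES})

    @staticmethod
    def from_json(s: str) -> "ConductanceScale":
        return ConductanceScale(**json.loads(s))


@dataclass(frozen=True)
class RemodelingPreset:
    name: str
    scale: ConductanceScale


CONTROL = RemodelingPreset("control", ConductanceScale())

#: electrical remodeling attributed to inflammation in fibrotic (low-voltage)
#: tissue: gCaL x22.5%, gNa x60%, gKur x50%, gto x35%, gKs x200%,
#: IpCa x150%, INaCa x160%
INFLAMMATION = RemodelingPreset(
    "inflammation",
    ConductanceScale(gCaL=0.225, gNa=0.60, gKur=0.50, gto=0.35,
                     gKs=2.0, IpCa=1.5, INaCa=1.6),
)

#: direction of chronic-AF electrical remodeling over the eight currents the
#: ERP ladder rescales (g_Na is untouched by the ladder).  The magnitudes
#: follow the persistent-AF literature consensus (IK1 up, Ito/ICaL/IKur down,
#: IKs up, Ca handling up); the terminal point of the ladder is *calibrated*
#: so that the 40 mm cable ERP equals the remodeled target (see
#: :mod:`atrialerp.calibration`), since only the endpoint ERP is constrained.
AF_DIRECTION = ConductanceScale(
    gK1=2.0, gto=0.35, gKur=0.50, gKr=1.6, gKs=2.0,
    gCaL=0.35, IpCa=1.5, INaCa=1.6,
)


# ---------------------------------------------------------------------------
# vectorized rate functions (shared by the reference RHS and the tables)
# ---------------------------------------------------------------------------

def _safe_ratio(num, den, limit):
    """num/den with a supplied limit where den ~ 0 (removable singularity)."""
    den = np.asarray(den, dtype=np.float64)
    small = np.abs(den) < 1e-10
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def gate_inf_tau(V):
    """Steady states and time constants for the 12 voltage-gated variables.

    Returns two arrays of shape ``(12,) + V.shape`` ordered
    (m, h, j, oa, oi, ua, ui, xr, xs, d, f, w).
    """
    V = np.asarray(V, dtype=np.float64)

    # fast Na+ gates
    a_m = _safe_ratio(0.32 * (V + 47.13), 1.0 - np.exp(-0.1 * (V + 47.13)), 3.2)
    b_m = 0.08 * np.exp(-V / 11.0)
    lo = V < -40.0
    a_h = np.where(lo, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b_h = np.where(
        lo,
        3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
        1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    a_j = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    b_j = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )

    # transient outward
    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    oa_inf = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    oi_inf = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))

    # ultrarapid delayed rectifier (activation rates shared with oa)
    ua_inf = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    ui_inf = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))

    # rapid delayed rectifier
    a_xr = _safe_ratio(0.0003 * (V + 14.1), 1.0 - np.exp(-(V + 14.1) / 5.0),
                       0.0003 * 5.0)
    b_xr = _safe_ratio(7.3898e-5 * (V - 3.3328),
                       np.exp((V - 3.3328) / 5.1237) - 1.0, 7.3898e-5 * 5.1237)
    xr_inf = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))

    # slow delayed rectifier
    a_xs = _safe_ratio(4e-5 * (V - 19.9), 1.0 - np.exp(-(V - 19.9) / 17.0),
                       4e-5 * 17.0)
    b_xs = _safe_ratio(3.5e-5 * (V - 19.9), np.exp((V - 19.9) / 9.0) - 1.0,
                       3.5e-5 * 9.0)
    xs_inf = (1.0 + np.exp(-(V - 19.9) / 12.7)) ** -0.5

    # L-type Ca2+
    d_inf = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    e624 = np.exp(-(V + 10.0) / 6.24)
    tau_d = _safe_ratio(1.0 - e624, 0.035 * (V + 10.0) * (1.0 + e624),
                        1.0 / (0.035 * 6.24 * 2.0))
    f_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)

    # SR release inactivation gate driven by voltage
    w_inf = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    e79 = np.exp(-(V - 7.9) / 5.0)
    tau_w = _safe_ratio(6.0 * (1.0 - e79), (1.0 + 0.3 * e79) * (V - 7.9),
                        6.0 * 0.2 / 1.3)

    inf = np.stack([
        a_m / (a_m + b_m),
        a_h / (a_h + b_h),
        a_j / (a_j + b_j),
        oa_inf, oi_inf, ua_inf, ui_inf, xr_inf, xs_inf, d_inf, f_inf, w_inf,
    ])
    tau = np.stack([
        1.0 / (a_m + b_m),
        1.0 / (a_h + b_h),
        1.0 / (a_j + b_j),
        1.0 / ((a_oa + b_oa) * KQ10),
        1.0 / ((a_oi + b_oi) * KQ10),
        1.0 / ((a_oa + b_oa) * KQ10),   # ua shares oa activation rates
        1.0 / ((a_ui + b_ui) * KQ10),
        1.0 / (a_xr + b_xr),
        1.0 / (a_xs + b_xs) * 0.5,
        tau_d, tau_f, tau_w,
    ])
    return inf, tau


_SIGMA_NAK = (np.exp(NA_O / 67.3) - 1.0) / 7.0


def current_factors(V):
    """Voltage-only factors of the membrane currents.

    Returns an array of shape ``(6,) + V.shape`` with rows
    (K1 rectification, g_Kur(V), Kr rectification, f_NaK,
    exp(gamma*V*F/RT), exp((gamma-1)*V*F/RT)).
    """
    V = np.asarray(V, dtype=np.float64)
    k1f = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))
    gkur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    krf = 1.0 / (1.0 + np.exp((V + 15.0) / 22.4))
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF)
                  + 0.0365 * _SIGMA_NAK * np.exp(-V / RTF))
    e1 = np.exp(GAMMA * V / RTF)
    e2 = np.exp((GAMMA - 1.0) * V / RTF)
    return np.stack([k1f, gkur, krf, fnak, e1, e2])


def ionic_rhs(state, scale: ConductanceScale | np.ndarray = None):
    """Time derivative of the full cell state and total ionic current density.

    Parameters
    ----------
    state : array of 21 floats
    scale : ConductanceScale or 9-array, optional (default control)

    Returns
    -------
    (dstate, I_ion) : derivative array (per ms) and summed ionic current
    density (pA/pF, positive outward).
    """
    y = np.asarray(state, dtype=np.float64)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} entries")
    if not np.all(np.isfinite(y)):
        bad = int(np.argmax(~np.isfinite(y)))
        raise ValueError(f"non-finite state variable {STATE_NAMES[bad]!r}")
    if scale is None:
        s = np.ones(9)
    elif isinstance(scale, ConductanceScale):
        s = scale.as_array()
    else:
        s = np.asarray(scale, dtype=np.float64)

    (V, m, h, jj, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
     Nai, Ki, Cai, Caup, Carel) = y

    E_Na = RTF * np.log(NA_O / Nai)
    E_K = RTF * np.log(K_O / Ki)
    E_Ca = 0.5 * RTF * np.log(CA_O / Cai)

    k1f, gkur, krf, fnak, e1, e2 = current_factors(V)

    i_Na = s[0] * G_NA * m ** 3 * h * jj * (V - E_Na)
    i_K1 = s[1] * G_K1 * (V - E_K) * k1f
    i_to = s[2] * G_TO * oa ** 3 * oi * (V - E_K)
    i_Kur = s[3] * gkur * ua ** 3 * ui * (V - E_K)
    i_Kr = s[4] * G_KR * xr * (V - E_K) * krf
    i_Ks = s[5] * G_KS * xs ** 2 * (V - E_K)
    i_CaL = s[6] * G_CAL * d * f * fca * (V - 65.0)
    i_pCa = s[7] * I_PCA_MAX * Cai / (0.0005 + Cai)
    i_NaCa = s[8] * I_NACA_MAX * (
        e1 * Nai ** 3 * CA_O - e2 * NA_O ** 3 * Cai
    ) / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * e2))
    i_NaK = (I_NAK_MAX * fnak * K_O / (K_O + KM_K_O)
             / (1.0 + (KM_NA_I / Nai) ** 1.5))
    i_bNa = G_B_NA * (V - E_Na)
    i_bCa = G_B_CA * (V - E_Ca)

    i_ion = (i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_CaL + i_pCa
             + i_NaK + i_NaCa + i_bNa + i_bCa)

    # SR calcium fluxes (mM/ms)
    i_rel = K_REL * u ** 2 * v * w * (Carel - Cai)
    i_tr = (Caup - Carel) / TAU_TR
    i_up = I_UP_MAX / (1.0 + K_UP / Cai)
    i_up_leak = I_UP_MAX * Caup / CA_UP_MAX

    Fn = 1e-12 * V_REL * i_rel - (5e-13 / F) * (0.5 * i_CaL - 0.2 * i_NaCa) * CM
    u_inf = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 * u_inf
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)

    inf, tau = gate_inf_tau(V)
    gates = np.array([m, h, jj, oa, oi, ua, ui, xr, xs, d, f, w])
    dgates = (inf - gates) / tau

    dNai = CM * (-3.0 * i_NaK - 3.0 * i_NaCa - i_bNa - i_Na) / (F * V_I)
    dKi = CM * (2.0 * i_NaK - i_K1 - i_to - i_Kur - i_Kr - i_Ks) / (F * V_I)
    B1 = (CM * (2.0 * i_NaCa - i_pCa - i_CaL - i_bCa) / (2.0 * F * V_I)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    B2 = (1.0 + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (Cai + KM_CMDN) ** 2)
    dCaup = i_up - i_up_leak - i_tr * V_REL / V_UP
    dCarel = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN / (Carel + KM_CSQN) ** 2)

    dy = np.empty(N_STATES)
    dy[0] = -i_ion
    dy[1:12] = dgates[:11]
    dy[15] = dgates[11]
    dy[12] = (fca_inf - fca) / TAU_FCA
    dy[13] = (u_inf - u) / TAU_U
    dy[14] = (v_inf - v) / tau_v
    dy[16] = dNai
    dy[17] = dKi
    dy[18] = B1 / B2
    dy[19] = dCaup
    dy[20] = dCarel
    return dy, i_ion


# ---------------------------------------------------------------------------
# tabulated rates for the fast stepper
# ---------------------------------------------------------------------------

class RateTables:
    """Voltage-grid tables for one time step size.

    Columns 0..11: gate steady states; 12..23: exp(-dt/tau) per gate;
    24..29: the six voltage-only current factors.  The engine interpolates
    linearly in V and clamps outside [vmin, vmax].
    """

    V_MIN = -120.0
    V_MAX = 80.0
    DV = 0.05

    def __init__(self, dt: float):
        self.dt = float(dt)
        grid = np.arange(self.V_MIN, self.V_MAX + self.DV / 2, self.DV)
        inf, tau = gate_inf_tau(grid)
        cf = current_factors(grid)
        tab = np.empty((grid.size, 30))
        tab[:, 0:12] = inf.T
        tab[:, 12:24] = np.exp(-self.dt / tau).T
        tab[:, 24:30] = cf.T
        self.grid = grid
        self.table = np.ascontiguousarray(tab)
        self.inv_dv = 1.0 / self.DV
        # constant-tau Rush-Larsen factors
        self.rl_fca = float(np.exp(-self.dt / TAU_FCA))
        self.rl_u = float(np.exp(-self.dt / TAU_U))


# ---------------------------------------------------------------------------
# single-cell protocols
# ---------------------------------------------------------------------------

class NoBeat(Exception):
    """Raised when a voltage trace contains no action-potential upstroke."""


def apd90(t, V):
    """Action potential duration at 90% repolarization.

    ``t`` in ms, ``V`` in mV, for a trace containing exactly one upstroke.
    Measured from the time of maximum dV/dt to the crossing of
    ``V_dias + 0.1 * (V_peak - V_dias)`` where ``V_dias`` is the
    pre-upstroke diastolic voltage.  Raises :class:`NoBeat` if there is no
    depolarization above -40 mV or no clear upstroke.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.size < 3 or V.max() < -40.0:
        raise NoBeat("trace contains no depolarization")
    dVdt = np.diff(V) / np.diff(t)
    k_up = int(np.argmax(dVdt))
    if dVdt[k_up] <= 1.0:
        raise NoBeat("no upstroke (max dV/dt <= 1 mV/ms)")
    t_up = t[k_up]
    v_dias = V[:k_up + 1].min() if k_up > 0 else V[0]
    v_peak = V[k_up:].max()
    v90 = v_dias + 0.1 * (v_peak - v_dias)
    k_peak = k_up + int(np.argmax(V[k_up:]))
    below = np.nonzero(V[k_peak:] <= v90)[0]
    if below.size == 0:
        raise NoBeat("trace does not repolarize to 90%")
    k = k_peak + below[0]
    # linear interpolation of the crossing time
    if k > 0 and V[k - 1] > v90:
        frac = (V[k - 1] - v90) / (V[k - 1] - V[k])
        t_cross = t[k - 1] + frac * (t[k] - t[k - 1])
    else:
        t_cross = t[k]
    return float(t_cross - t_up)


@dataclass
class PacingResult:
    state: np.ndarray
    apd90_last: float
    apd90_prev: float
    repolarization_ok: bool
    t: np.ndarray = field(repr=False, default=None)
    V: np.ndarray = field(repr=False, default=None)


def pace_to_limit_cycle(scale: ConductanceScale | np.ndarray = None,
                        bcl: float = 500.0, n_beats: int = 100,
                        dt: float = 0.02, stim_amp: float = 30.0,
                        stim_dur: float = 3.0,
                        y0: np.ndarray | None = None) -> PacingResult:
    """Pace a single cell to its limit cycle.

    Default protocol: 100 beats at a basic cycle length of 500 ms with
    3 ms / 30 uA/cm^2 stimuli.  Returns the state at the end of the last
    beat together with the APD90 of the final two beats and a flag that is
    False when the cell failed to repolarize below -60 mV before a stimulus.
    """
    from . import engine  # local import: numba compilation on first use

    if bcl <= 0:
        raise ValueError("bcl must be positive")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if scale is None:
        s = np.ones(9)
    elif isinstance(scale, ConductanceScale):
        s = scale.as_array()
    else:
        s = np.asarray(scale, dtype=np.float64)

    y = (rest_state() if y0 is None else np.array(y0, dtype=float))
    states = y.reshape(1, -1).copy()
    tbl = engine.get_tables(dt)
    repol_ok = True
    rec_stride = max(1, int(round(0.5 / dt)))  # 0.5 ms sampling

    # record the last two beats for APD90 diagnostics
    n_quiet = max(0, n_beats - 2)
    if n_quiet:
        code = engine.run_single_cell(states, s, dt, n_quiet * bcl, bcl,
                                      stim_dur, stim_amp, tbl)
        if code != 0:
            raise FloatingPointError("single-cell integration diverged")
    apds = []
    t_all, v_all = [], []
    for b in range(min(2, n_beats)):
        if states[0, 0] > -60.0:
            repol_ok = False
        t, V, code = engine.run_single_cell_recorded(
            states, s, dt, bcl, bcl, stim_dur, stim_amp, tbl, rec_stride)
        if code != 0:
            raise FloatingPointError("single-cell integration diverged")
        try:
            apds.append(apd90(t, V))
        except NoBeat:
            apds.append(np.nan)
        t_all.append(t + (n_quiet + b) * bcl)
        v_all.append(V)
    while len(apds) < 2:
        apds.insert(0, np.nan)
    return PacingResult(state=states[0].copy(), apd90_last=apds[-1],
                        apd90_prev=apds[-2], repolarization_ok=repol_ok,
                        t=np.concatenate(t_all), V=np.concatenate(v_all))
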