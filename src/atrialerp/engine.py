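"""Numba kernels for the atrial cell model and the monodomain stepper.

All kernels advance the 21-state atrial myocyte model with Rush-Larsen
updates for the gating variables (voltage-dependent steady states and decay
factors read from a precomputed table, linearly interpolated in V) and
forward-Euler updates for voltage and concentrations.  Diffusion enters as
an explicit per-node term ``-(K v) / m`` built from a sparse stiffness
matrix ``K`` and lumped mass ``m``; a single fused loop per time step keeps
the solver deterministic and cache friendly.

Sign conventions: ionic current positive outward, stimulus density positive
depolarizing, so ``dV/dt = diff - I_ion + J_stim``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .courtemanche import (
    RateTables, RTF, NA_O, K_O, CA_O, G_NA, G_K1, G_TO, G_KR, G_KS, G_CAL,
    G_B_NA, G_B_CA, I_NAK_MAX, KM_NA_I, KM_K_O, I_NACA_MAX, KM_NA, KM_CA,
    K_SAT, I_PCA_MAX, K_REL, TAU_TR, I_UP_MAX, K_UP, CA_UP_MAX, CMDN_MAX,
    TRPN_MAX, CSQN_MAX, KM_CMDN, KM_TRPN, KM_CSQN, CM, F, V_I, V_UP, V_REL,
)

_TABLE_CACHE: dict[float, RateTables] = {}

#: default reaction time step (ms) for cable calibration work
DT_DEFAULT = 0.02

#: time step (ms) for 2D sheet work; cable ERP and CV change by <= 2 ms /
#: < 1% relative to DT_DEFAULT at sheet resolutions
DT_SHEET = 0.05

#: upstroke detector: V crossing this value (mV) with dV/dt above threshold
ACT_V = -20.0
ACT_DVDT = 20.0  # mV/ms


def get_tables(dt: float) -> RateTables:
    key = round(float(dt), 9)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = RateTables(key)
    return _TABLE_CACHE[key]


_GATE_IDX = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 15], dtype=np.int64)


@njit(cache=True, fastmath=True, inline="always")
def _clamp_exp(x):
    if x > 80.0:
        x = 80.0
    elif x < -80.0:
        x = -80.0
    return np.exp(x)


@njit(cache=True, fastmath=True, inline="always")
def _node_step(y, s, tab, vmin, inv_dv, rl_fca, rl_u, dt, dvd, jext):
    """Advance one node by dt.  ``y``: 21-state row, ``s``: 9 multipliers."""
    V = y[0]
    x = (V - vmin) * inv_dv
    if x < 0.0:
        x = 0.0
    i0 = int(x)
    if i0 > tab.shape[0] - 2:
        i0 = tab.shape[0] - 2
    fr = x - i0

    Nai = y[16] if y[16] > 1e-6 else 1e-6
    Ki = y[17] if y[17] > 1e-6 else 1e-6
    Cai = y[18] if y[18] > 1e-9 else 1e-9
    Caup = y[19]
    Carel = y[20]

    E_Na = RTF * np.log(NA_O / Nai)
    E_K = RTF * np.log(K_O / Ki)
    E_Ca = 0.5 * RTF * np.log(CA_O / Cai)

    k1f = tab[i0, 24] + fr * (tab[i0 + 1, 24] - tab[i0, 24])
    gkur = tab[i0, 25] + fr * (tab[i0 + 1, 25] - tab[i0, 25])
    krf = tab[i0, 26] + fr * (tab[i0 + 1, 26] - tab[i0, 26])
    fnak = tab[i0, 27] + fr * (tab[i0 + 1, 27] - tab[i0, 27])
    e1 = tab[i0, 28] + fr * (tab[i0 + 1, 28] - tab[i0, 28])
    e2 = tab[i0, 29] + fr * (tab[i0 + 1, 29] - tab[i0, 29])

    i_Na = s[0] * G_NA * y[1] * y[1] * y[1] * y[2] * y[3] * (V - E_Na)
    i_K1 = s[1] * G_K1 * (V - E_K) * k1f
    i_to = s[2] * G_TO * y[4] * y[4] * y[4] * y[5] * (V - E_K)
    i_Kur = s[3] * gkur * y[6] * y[6] * y[6] * y[7] * (V - E_K)
    i_Kr = s[4] * G_KR * y[8] * (V - E_K) * krf
    i_Ks = s[5] * G_KS * y[9] * y[9] * (V - E_K)
    i_CaL = s[6] * G_CAL * y[10] * y[11] * y[12] * (V - 65.0)
    i_pCa = s[7] * I_PCA_MAX * Cai / (0.0005 + Cai)
    i_NaCa = s[8] * I_NACA_MAX * (
        e1 * Nai * Nai * Nai * CA_O - e2 * NA_O * NA_O * NA_O * Cai
    ) / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * e2))
    i_NaK = (I_NAK_MAX * fnak * K_O / (K_O + KM_K_O)
             / (1.0 + (KM_NA_I / Nai) ** 1.5))
    i_bNa = G_B_NA * (V - E_Na)
    i_bCa = G_B_CA * (V - E_Ca)

    i_ion = (i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_CaL + i_pCa
             + i_NaK + i_NaCa + i_bNa + i_bCa)

    # SR calcium subsystem
    i_rel = K_REL * y[13] * y[13] * y[14] * y[15] * (Carel - Cai)
    i_tr = (Caup - Carel) / TAU_TR
    i_up = I_UP_MAX / (1.0 + K_UP / Cai)
    i_up_leak = I_UP_MAX * Caup / CA_UP_MAX

    Fn = 1e-12 * V_REL * i_rel - (5e-13 / F) * (0.5 * i_CaL - 0.2 * i_NaCa) * CM
    eu = _clamp_exp(-(Fn - 3.4175e-13) / 13.67e-16)
    u_inf = 1.0 / (1.0 + eu)
    ev = _clamp_exp(-(Fn - 6.835e-14) / 13.67e-16)
    v_inf = 1.0 - 1.0 / (1.0 + ev)
    tau_v = 1.91 + 2.09 * u_inf
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)

    # Rush-Larsen gate updates (table columns: inf 0..11, decay 12..23)
    y[1] = _rl(y[1], tab, i0, fr, 0)
    y[2] = _rl(y[2], tab, i0, fr, 1)
    y[3] = _rl(y[3], tab, i0, fr, 2)
    y[4] = _rl(y[4], tab, i0, fr, 3)
    y[5] = _rl(y[5], tab, i0, fr, 4)
    y[6] = _rl(y[6], tab, i0, fr, 5)
    y[7] = _rl(y[7], tab, i0, fr, 6)
    y[8] = _rl(y[8], tab, i0, fr, 7)
    y[9] = _rl(y[9], tab, i0, fr, 8)
    y[10] = _rl(y[10], tab, i0, fr, 9)
    y[11] = _rl(y[11], tab, i0, fr, 10)
    y[15] = _rl(y[15], tab, i0, fr, 11)

    y[12] = fca_inf + (y[12] - fca_inf) * rl_fca
    y[13] = u_inf + (y[13] - u_inf) * rl_u
    y[14] = v_inf + (y[14] - v_inf) * np.exp(-dt / tau_v)

    # concentrations (forward Euler)
    y[16] = Nai + dt * CM * (-3.0 * i_NaK - 3.0 * i_NaCa - i_bNa - i_Na) / (F * V_I)
    y[17] = Ki + dt * CM * (2.0 * i_NaK - i_K1 - i_to - i_Kur - i_Kr - i_Ks) / (F * V_I)
    B1 = (CM * (2.0 * i_NaCa - i_pCa - i_CaL - i_bCa) / (2.0 * F * V_I)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    B2 = (1.0 + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (Cai + KM_CMDN) ** 2)
    y[18] = Cai + dt * B1 / B2
    y[19] = Caup + dt * (i_up - i_up_leak - i_tr * V_REL / V_UP)
    y[20] = Carel + dt * (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN / (Carel + KM_CSQN) ** 2)

    y[0] = V + dt * (dvd - i_ion + jext)


@njit(cache=True, fastmath=True, inline="always")
def _rl(g, tab, i0, fr, col):
    inf = tab[i0, col] + fr * (tab[i0 + 1, col] - tab[i0, col])
    d = tab[i0, col + 12] + fr * (tab[i0 + 1, col + 12] - tab[i0, col + 12])
    return inf + (g - inf) * d


@njit(cache=True, fastmath=True)
def _run_cell(states, s, dt, n_steps, bcl, stim_dur, stim_amp,
              tab, vmin, inv_dv, rl_fca, rl_u, rec_stride, rec_V):
    """Single cell paced periodically (stimulus whenever t mod bcl < dur)."""
    y = states[0]
    n_rec = rec_V.shape[0]
    k = 0
    for step in range(n_steps):
        if rec_stride > 0 and step % rec_stride == 0 and k < n_rec:
            rec_V[k] = y[0]
            k += 1
        t = step * dt
        ph = t - bcl * np.floor(t / bcl)
        jext = stim_amp if ph < stim_dur else 0.0
        _node_step(y, s, tab, vmin, inv_dv, rl_fca, rl_u, dt, 0.0, jext)
        if step % 5000 == 0:
            if not np.isfinite(y[0]) or abs(y[0]) > 200.0:
                return 1
    if not np.isfinite(y[0]) or abs(y[0]) > 200.0:
        return 1
    return 0


@njit(cache=True, fastmath=True)
def _run_tissue(states, scales, kptr, kidx, kval, invm,
                dt, n_steps, t0,
                ev_on, ev_off, ev_amp, ev_nptr, ev_nodes,
                tab, vmin, inv_dv, rl_fca, rl_u,
                probes, rec_stride, rec_V,
                last_act, act_count):
    """Fused explicit monodomain step over all nodes.

    Returns 0 on success, 1 on numerical divergence (|V| > 200 mV or
    non-finite).  ``last_act`` (ms) and ``act_count`` are updated in place
    using the upstroke detector (V crossing ACT_V upward with
    dV/dt > ACT_DVDT).
    """
    n = states.shape[0]
    n_ev = ev_on.shape[0]
    jst = np.zeros(n)
    active = np.zeros(n_ev, np.uint8)
    Vold = np.empty(n)
    k = 0
    n_rec = rec_V.shape[0]
    dvdt_min = ACT_DVDT * dt

    for step in range(n_steps):
        t = t0 + step * dt
        if rec_stride > 0 and step % rec_stride == 0 and k < n_rec:
            for p in range(probes.shape[0]):
                rec_V[k, p] = states[probes[p], 0]
            k += 1
        for e in range(n_ev):
            on = (t >= ev_on[e]) and (t < ev_off[e])
            if on and active[e] == 0:
                for q in range(ev_nptr[e], ev_nptr[e + 1]):
                    jst[ev_nodes[q]] += ev_amp[e]
                active[e] = 1
            elif (not on) and active[e] == 1:
                for q in range(ev_nptr[e], ev_nptr[e + 1]):
                    jst[ev_nodes[q]] -= ev_amp[e]
                active[e] = 0
        for i in range(n):
            Vold[i] = states[i, 0]
        for i in range(n):
            kv = 0.0
            for p in range(kptr[i], kptr[i + 1]):
                kv += kval[p] * Vold[kidx[p]]
            dvd = -kv * invm[i]
            _node_step(states[i], scales[i], tab, vmin, inv_dv,
                       rl_fca, rl_u, dt, dvd, jst[i])
            vn = states[i, 0]
            if Vold[i] < ACT_V <= vn and (vn - Vold[i]) > dvdt_min:
                last_act[i] = t + dt
                act_count[i] += 1
        if step % 500 == 0:
            bad = False
            for i in range(n):
                vv = states[i, 0]
                if not np.isfinite(vv) or abs(vv) > 200.0:
                    bad = True
                    break
            if bad:
                return 1
    return 0


# ---------------------------------------------------------------------------
# python wrappers
# ---------------------------------------------------------------------------

def run_single_cell(states, s, dt, duration, bcl, stim_dur, stim_amp, tbl):
    n_steps = int(round(duration / dt))
    rec = np.empty((0,), dtype=np.float64)
    return _run_cell(states, np.ascontiguousarray(s, dtype=np.float64), dt,
                     n_steps, bcl, stim_dur, stim_amp,
                     tbl.table, tbl.V_MIN, tbl.inv_dv, tbl.rl_fca, tbl.rl_u,
                     0, rec)


def run_single_cell_recorded(states, s, dt, duration, bcl, stim_dur,
                             stim_amp, tbl, rec_stride):
    n_steps = int(round(duration / dt))
    n_rec = (n_steps + rec_stride - 1) // rec_stride
    rec = np.empty(n_rec, dtype=np.float64)
    code = _run_cell(states, np.ascontiguousarray(s, dtype=np.float64), dt,
                     n_steps, bcl, stim_dur, stim_amp,
                     tbl.table, tbl.V_MIN, tbl.inv_dv, tbl.rl_fca, tbl.rl_u,
                     rec_stride, rec)
    t = np.arange(n_rec) * rec_stride * dt
    return t, rec, code


def run_tissue(states, scales, operator, events, dt, duration, t0=0.0,
               probes=None, rec_dt=0.5, tbl=None,
               last_act=None, act_count=None):
    """Advance a tissue state in place.

    Parameters
    ----------
    states : (n, 21) array, modified in place
    scales : (n, 9) array of per-node conductance multipliers
    operator : (kptr, kidx, kval, inv_mass) sparse diffusion operator
    events : list of (onset_ms, duration_ms, amplitude, node_index_array)
    probes : node indices whose V(t) is recorded every ``rec_dt`` ms

    Returns (t, rec_V, last_act, act_count, code).
    """
    kptr, kidx, kval, invm = operator
    if tbl is None:
        tbl = get_tables(dt)
    n = states.shape[0]
    if probes is None:
        probes = np.empty(0, dtype=np.int64)
    else:
        probes = np.asarray(probes, dtype=np.int64)
    if last_act is None:
        last_act = np.full(n, -np.inf)
    if act_count is None:
        act_count = np.zeros(n, dtype=np.int64)

    n_ev = len(events)
    ev_on = np.empty(n_ev)
    ev_off = np.empty(n_ev)
    ev_amp = np.empty(n_ev)
    ev_nptr = np.zeros(n_ev + 1, dtype=np.int64)
    nodes_list = []
    for e, (onset, dur, amp, nds) in enumerate(events):
        ev_on[e] = onset
        ev_off[e] = onset + dur
        ev_amp[e] = amp
        nds = np.asarray(nds, dtype=np.int64)
        ev_nptr[e + 1] = ev_nptr[e] + nds.size
        nodes_list.append(nds)
    ev_nodes = (np.concatenate(nodes_list) if nodes_list
                else np.empty(0, dtype=np.int64))

    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(rec_dt / dt)))
    n_rec = (n_steps + rec_stride - 1) // rec_stride if probes.size else 0
    rec_V = np.empty((n_rec, probes.size), dtype=np.float64)

    code = _run_tissue(states, scales, kptr, kidx, kval, invm,
                       dt, n_steps, t0,
                       ev_on, ev_off, ev_amp, ev_nptr, ev_nodes,
                       tbl.table, tbl.V_MIN, tbl.inv_dv, tbl.rl_fca, tbl.rl_u,
                       probes, rec_stride, rec_V,
                       last_act, act_count)
    t = t0 + np.arange(n_rec) * rec_stride * dt
    return t, rec_V, last_act, act_count, code
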