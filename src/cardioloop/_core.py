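"""Numba-compiled numerical kernels.

Everything in this module works on plain float64 arrays so the hot loops can
be jitted.  The public modules (:mod:`cardioloop.membrane_ep`,
:mod:`cardioloop.half_sarcomere`, :mod:`cardioloop.hemodynamics`,
:mod:`cardioloop.engine`) wrap these kernels with typed, documented APIs.

State/parameter vector layouts
------------------------------
EP state ``y`` (17 entries)::

    0  V      membrane voltage (mV)
    1  m, 2 h, 3 j          fast Na+ gates
    4  d, 5 f, 6 fCa        L-type Ca2+ gates
    7  r, 8 s               transient outward gates
    9  xs                   slow delayed rectifier gate
    10 xr1, 11 xr2          rapid delayed rectifier gates
    12 g                    Ca2+ release gate
    13 Cai   (mM), 14 CaSR (mM), 15 Nai (mM), 16 Ki (mM)

EP parameter vector ``p`` — see ``EP_PARAM_NAMES``.

Sarcomere parameter vector ``sp`` — see ``SARC_PARAM_NAMES``.

Circulation parameter vector ``cp`` — see ``CIRC_PARAM_NAMES``.

All sarcomere rates are s^-1, lengths nm, stresses N m^-2.  Circulation
volumes are liters, pressures mmHg, resistances mmHg s L^-1.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# physical constants
# ---------------------------------------------------------------------------
GAS_R = 8314.472        # J kmol^-1 K^-1
TEMP = 310.0            # K
FARADAY = 96485.3415    # C mol^-1
RTONF = GAS_R * TEMP / FARADAY   # mV
KB_T = 1.380649e-23 * TEMP       # J
MMHG_PER_PA = 1.0 / 133.322

EP_PARAM_NAMES = [
    "g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL", "g_bNa", "g_bCa",
    "g_pK", "g_pCa", "P_NaK", "K_mK", "K_mNa", "k_NaCa", "K_mCa", "K_mNai",
    "k_sat", "alpha_NaCa", "gamma_NaCa", "Ca_Vmaxup", "K_up", "Ca_Vleak",
    "a_rel", "b_rel", "c_rel", "Buf_c", "K_bufc", "Buf_sr", "K_bufsr",
    "K_o", "Na_o", "Ca_o", "p_KNa", "Cm", "V_c", "V_sr", "K_pCa",
]

# Published base values, mid-myocardial (M cell) variant.
EP_BASE_VALUES = np.array([
    14.838,     # g_Na        nS/pF
    5.405,      # g_K1
    0.294,      # g_to (M cell)
    0.096,      # g_Kr
    0.062,      # g_Ks (M cell)
    1.75e-4,    # g_CaL       cm^3 uF^-1 ms^-1
    2.9e-4,     # g_bNa
    5.92e-4,    # g_bCa
    0.0146,     # g_pK
    0.825,      # g_pCa       pA/pF
    1.362,      # P_NaK       pA/pF
    1.0,        # K_mK        mM
    40.0,       # K_mNa       mM
    1000.0,     # k_NaCa      pA/pF
    1.38,       # K_mCa       mM
    87.5,       # K_mNai      mM
    0.1,        # k_sat
    2.5,        # alpha_NaCa
    0.35,       # gamma_NaCa
    4.25e-4,    # Ca_Vmaxup   mM/ms
    2.5e-4,     # K_up        mM
    8.0e-5,     # Ca_Vleak    ms^-1
    0.016464,   # a_rel       mM/ms
    0.25,       # b_rel       mM
    0.008232,   # c_rel       mM/ms
    0.15,       # Buf_c       mM
    0.001,      # K_bufc      mM
    10.0,       # Buf_sr      mM
    0.3,        # K_bufsr     mM
    5.4,        # K_o         mM
    140.0,      # Na_o        mM
    2.0,        # Ca_o        mM
    0.03,       # p_KNa
    0.185,      # Cm          uF
    0.016404,   # V_c         (CellML volume units)
    0.001094,   # V_sr
    5.0e-4,     # K_pCa       mM
], dtype=np.float64)

# indices of the adjustable EP parameters (multiplier-scaled)
EP_ADJUSTABLE = {
    "Ca_Vleak": 21,
    "Ca_Vmaxup": 19,
    "g_CaL": 5,
    "g_to": 2,
    "g_Kr": 3,
    "g_Ks": 4,
}

# Published resting initial condition.
EP_INITIAL_STATE = np.array([
    -86.2,      # V
    0.0,        # m
    0.75,       # h
    0.75,       # j
    0.0,        # d
    1.0,        # f
    1.0,        # fCa
    0.0,        # r
    1.0,        # s
    0.0,        # xs
    0.0,        # xr1
    1.0,        # xr2
    1.0,        # g
    2.0e-4,     # Cai   mM
    0.2,        # CaSR  mM
    11.6,       # Nai   mM
    138.3,      # Ki    mM
], dtype=np.float64)

EP_STATE_NAMES = [
    "V", "m", "h", "j", "d", "f", "fCa", "r", "s", "xs", "xr1", "xr2", "g",
    "Cai", "CaSR", "Nai", "Ki",
]

SARC_PARAM_NAMES = [
    "k_on",      # 0  thin-filament Ca2+ on rate, mM^-1 s^-1
    "k_off",     # 1  thin-filament off rate, s^-1
    "k_coop",    # 2  cooperativity coefficient, dimensionless
    "k_1",       # 3  OFF->ON base rate, s^-1
    "k_2",       # 4  ON->OFF rate, s^-1
    "k_3",       # 5  attachment rate density, s^-1 nm^-1
    "k_4_0",     # 6  strain-independent detachment rate, s^-1
    "k_4_1",     # 7  strain-dependent detachment, s^-1 nm^-4
    "k_cb",      # 8  cross-bridge stiffness, N m^-1
    "x_ps",      # 9  power-stroke displacement, nm
    "N_0",       # 10 head number density, m^-2
    "sigma",     # 11 passive stress scale, N m^-2
    "L",         # 12 passive curvature length constant, nm
    "L_slack",   # 13 half-sarcomere slack length, nm
    "k_force",   # 14 force dependence of recruitment, m^2 N^-1
    "n_overlap", # 15 maximal available fraction of thin-filament sites
    "w_ascending",       # 16 nm, length constant of the ascending limb
    "hsl_full_overlap",  # 17 nm, full overlap at this length (plateau start)
    "hsl_desc_start",    # 18 nm, descending limb starts (plateau end)
    "hsl_desc_end",      # 19 nm, overlap vanishes again at this length
    "hsl_zero_overlap",  # 20 nm, ascending limb reaches zero here
]

CIRC_PARAM_NAMES = [
    "V_slack",       # 0  L
    "W_volume",      # 1  L
    "C_aorta",       # 2  L/mmHg
    "C_arteries",    # 3
    "C_arterioles",  # 4
    "C_capillaries", # 5
    "C_veins",       # 6
    "R_aortic_valve",   # 7  mmHg s/L
    "R_arteries",       # 8
    "R_arterioles",     # 9
    "R_capillaries",    # 10
    "R_veins",          # 11
    "R_venous_return",  # 12
    "V_total",          # 13 L
    "V_residual",       # 14 L, minimal (residual) cavity volume
]

# log column layout for run_coupled
LOG_COLUMNS = [
    "time", "membrane_voltage", "Ca_i", "N_on", "N_bound", "M_OFF", "M_ON",
    "M_FG", "hs_length", "active_stress", "passive_stress", "total_stress",
    "P_ventricle", "V_ventricle", "P_aorta", "P_arteries", "P_arterioles",
    "P_capillaries", "P_veins", "V_aorta", "V_arteries", "V_arterioles",
    "V_capillaries", "V_veins", "flow_aortic_valve", "flow_venous_return",
    "atp_cum", "V_system_total",
]
N_LOG = len(LOG_COLUMNS)


# ---------------------------------------------------------------------------
# electrophysiology (ten Tusscher-type human M cell, 17 states)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gate_inf_tau(V, Cai, fCa_old, g_old):
    """Steady-state values and time constants for the 12 gates.

    Returns (inf, tau) arrays ordered as the gate slots 1..12 of the state
    vector.  fCa and g use fixed 2 ms time constants; their update is
    conditionally frozen by the caller.
    """
    inf = np.empty(12)
    tau = np.empty(12)

    # m
    inf[0] = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau[0] = am * bm
    # h
    inf[1] = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    tau[1] = 1.0 / (ah + bh)
    # j
    inf[2] = inf[1]
    if V < -40.0:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78)) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    tau[2] = 1.0 / (aj + bj)
    # d
    inf[3] = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau[3] = ad * bd + gd
    # f
    inf[4] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau[4] = 1125.0 * np.exp(-(V + 27.0) ** 2 / 240.0) + 80.0 \
        + 165.0 / (1.0 + np.exp((25.0 - V) / 10.0))
    # fCa (Cai-gated)
    afca = 1.0 / (1.0 + (Cai / 3.25e-4) ** 8)
    bfca = 0.1 / (1.0 + np.exp((Cai - 5.0e-4) / 1.0e-4))
    gfca = 0.2 / (1.0 + np.exp((Cai - 7.5e-4) / 8.0e-4))
    inf[5] = (afca + bfca + gfca + 0.23) / 1.46
    tau[5] = 2.0
    # r
    inf[6] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau[6] = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    # s (M cell / epicardial form)
    inf[7] = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    tau[7] = 85.0 * np.exp(-(V + 45.0) ** 2 / 320.0) \
        + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0
    # xs
    inf[8] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau[8] = axs * bxs
    # xr1
    inf[9] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau[9] = axr1 * bxr1
    # xr2
    inf[10] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau[10] = axr2 * bxr2
    # g (Ca2+ release gate)
    if Cai < 3.5e-4:
        inf[11] = 1.0 / (1.0 + (Cai / 3.5e-4) ** 6)
    else:
        inf[11] = 1.0 / (1.0 + (Cai / 3.5e-4) ** 16)
    tau[11] = 2.0
    return inf, tau


@njit(cache=True)
def _ep_currents(y, p, i_stim):
    """All membrane currents (pA/pF) and SR fluxes (mM/ms)."""
    V = y[0]
    m = y[1]; h = y[2]; j = y[3]; d = y[4]; f = y[5]; fCa = y[6]
    r = y[7]; s = y[8]; xs = y[9]; xr1 = y[10]; xr2 = y[11]; g = y[12]
    Cai = y[13]; CaSR = y[14]; Nai = y[15]; Ki = y[16]

    Ko = p[29]; Nao = p[30]; Cao = p[31]

    E_Na = RTONF * np.log(Nao / Nai)
    E_K = RTONF * np.log(Ko / Ki)
    E_Ks = RTONF * np.log((Ko + p[32] * Nao) / (Ki + p[32] * Nai))
    E_Ca = 0.5 * RTONF * np.log(Cao / Cai)

    I_Na = p[0] * m ** 3 * h * j * (V - E_Na)

    # GHK-type driving term; 4 V F / RTONF * u/(e^u - 1) -> 2F as V -> 0
    vfrt2 = 2.0 * V / RTONF
    if np.abs(vfrt2) < 1.0e-6:
        I_CaL = p[5] * d * f * fCa * 2.0 * FARADAY * (Cai - 0.341 * Cao)
    else:
        expv = np.exp(vfrt2)
        I_CaL = p[5] * d * f * fCa * 4.0 * V * (FARADAY / RTONF) * \
            (Cai * expv - 0.341 * Cao) / (expv - 1.0)

    I_to = p[2] * r * s * (V - E_K)
    I_Ks = p[4] * xs ** 2 * (V - E_Ks)
    sqko = np.sqrt(Ko / 5.4)
    I_Kr = p[3] * sqko * xr1 * xr2 * (V - E_K)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - E_K - 200.0)))
    bk1 = (3.0 * np.exp(2.0e-4 * (V - E_K + 100.0))
           + np.exp(0.1 * (V - E_K - 10.0))) / (1.0 + np.exp(-0.5 * (V - E_K)))
    I_K1 = p[1] * sqko * (ak1 / (ak1 + bk1)) * (V - E_K)

    egv = np.exp(p[18] * V / RTONF)
    egv1 = np.exp((p[18] - 1.0) * V / RTONF)
    I_NaCa = p[13] * (egv * Nai ** 3 * Cao - egv1 * Nao ** 3 * Cai * p[17]) / \
        ((p[15] ** 3 + Nao ** 3) * (p[14] + Cao) * (1.0 + p[16] * egv1))

    I_NaK = p[10] * Ko * Nai / ((Ko + p[11]) * (Nai + p[12])) / \
        (1.0 + 0.1245 * np.exp(-0.1 * V / RTONF) + 0.0353 * np.exp(-V / RTONF))

    I_pCa = p[9] * Cai / (p[36] + Cai)
    I_pK = p[8] * (V - E_K) / (1.0 + np.exp((25.0 - V) / 5.98))
    I_bNa = p[6] * (V - E_Na)
    I_bCa = p[7] * (V - E_Ca)

    I_leak = p[21] * (CaSR - Cai)
    I_up = p[19] / (1.0 + (p[20] / Cai) ** 2)
    I_rel = (p[22] * CaSR ** 2 / (p[23] ** 2 + CaSR ** 2) + p[24]) * d * g

    I_ion = I_Na + I_CaL + I_to + I_Ks + I_Kr + I_K1 + I_NaCa + I_NaK + \
        I_pCa + I_pK + I_bNa + I_bCa + i_stim

    return (I_ion, I_Na, I_CaL, I_to, I_Ks, I_Kr, I_K1, I_NaCa, I_NaK,
            I_pCa, I_pK, I_bNa, I_bCa, I_leak, I_up, I_rel)


@njit(cache=True)
def ep_rhs(y, p, i_stim):
    """Full time derivative of the 17-entry EP state (per ms)."""
    V = y[0]; Cai = y[13]; CaSR = y[14]
    (I_ion, I_Na, I_CaL, I_to, I_Ks, I_Kr, I_K1, I_NaCa, I_NaK,
     I_pCa, I_pK, I_bNa, I_bCa, I_leak, I_up, I_rel) = _ep_currents(y, p, i_stim)

    inf, tau = _gate_inf_tau(V, Cai, y[6], y[12])
    dy = np.empty(17)
    dy[0] = -I_ion
    for k in range(12):
        dy[1 + k] = (inf[k] - y[1 + k]) / tau[k]
    # conditional freeze of Ca-gated inactivation below threshold voltage
    if inf[5] > y[6] and V > -60.0:
        dy[6] = 0.0
    if inf[11] > y[12] and V > -60.0:
        dy[12] = 0.0

    Cm = p[33]; Vc = p[34]; Vsr = p[35]
    bufc = 1.0 / (1.0 + p[25] * p[26] / (Cai + p[26]) ** 2)
    bufsr = 1.0 / (1.0 + p[27] * p[28] / (CaSR + p[28]) ** 2)
    dy[13] = bufc * (I_leak - I_up + I_rel
                     - (I_CaL + I_bCa + I_pCa - 2.0 * I_NaCa)
                     * Cm / (2.0 * Vc * FARADAY))
    dy[14] = bufsr * (Vc / Vsr) * (I_up - I_rel - I_leak)
    dy[15] = -(I_Na + I_bNa + 3.0 * I_NaK + 3.0 * I_NaCa) * Cm / (Vc * FARADAY)
    dy[16] = -(I_K1 + I_to + I_Kr + I_Ks + I_pK + i_stim - 2.0 * I_NaK) \
        * Cm / (Vc * FARADAY)
    return dy


@njit(cache=True)
def ep_step_rl(y, p, i_stim, dt):
    """One hybrid step: exponential (Rush-Larsen) gates, Euler V and
    concentrations.  Returns the new state vector."""
    V = y[0]; Cai = y[13]; CaSR = y[14]
    (I_ion, I_Na, I_CaL, I_to, I_Ks, I_Kr, I_K1, I_NaCa, I_NaK,
     I_pCa, I_pK, I_bNa, I_bCa, I_leak, I_up, I_rel) = _ep_currents(y, p, i_stim)
    inf, tau = _gate_inf_tau(V, Cai, y[6], y[12])

    out = np.empty(17)
    out[0] = V - dt * I_ion
    for k in range(12):
        out[1 + k] = inf[k] + (y[1 + k] - inf[k]) * np.exp(-dt / tau[k])
    if inf[5] > y[6] and V > -60.0:
        out[6] = y[6]
    if inf[11] > y[12] and V > -60.0:
        out[12] = y[12]

    Cm = p[33]; Vc = p[34]; Vsr = p[35]
    bufc = 1.0 / (1.0 + p[25] * p[26] / (Cai + p[26]) ** 2)
    bufsr = 1.0 / (1.0 + p[27] * p[28] / (CaSR + p[28]) ** 2)
    out[13] = Cai + dt * bufc * (I_leak - I_up + I_rel
                                 - (I_CaL + I_bCa + I_pCa - 2.0 * I_NaCa)
                                 * Cm / (2.0 * Vc * FARADAY))
    out[14] = CaSR + dt * bufsr * (Vc / Vsr) * (I_up - I_rel - I_leak)
    out[15] = y[15] - dt * (I_Na + I_bNa + 3.0 * I_NaK + 3.0 * I_NaCa) \
        * Cm / (Vc * FARADAY)
    out[16] = y[16] - dt * (I_K1 + I_to + I_Kr + I_Ks + I_pK + i_stim
                            - 2.0 * I_NaK) * Cm / (Vc * FARADAY)
    # Euler overshoot guards for extreme Ca-handling parameterizations:
    # concentrations are physically positive
    if out[13] < 1.0e-9:
        out[13] = 1.0e-9
    if out[14] < 1.0e-9:
        out[14] = 1.0e-9
    return out


@njit(cache=True)
def ep_advance(y, p, i_stim, dt_total):
    """Advance the EP state by ``dt_total`` ms.

    Uses 0.25 ms hybrid steps, re-done as 0.025 ms sub-steps whenever the
    trial step moves the membrane voltage by more than 0.5 mV (upstroke and
    fast repolarization).  The scheme keeps gates in [0, 1] by construction.
    """
    remaining = dt_total
    while remaining > 1.0e-12:
        dt = 0.25 if remaining > 0.25 else remaining
        trial = ep_step_rl(y, p, i_stim, dt)
        if np.abs(trial[0] - y[0]) > 0.5:
            n = 10
            ddt = dt / n
            for _ in range(n):
                y = ep_step_rl(y, p, i_stim, ddt)
        else:
            y = trial
        remaining -= dt
    return y


@njit(cache=True)
def ep_prepace(y0, p, n_beats, period_ms, stim_dur_ms, stim_amp):
    """Pace the EP model alone for ``n_beats`` and return the end-diastolic
    state plus the L2 norm of the last beat-to-beat state difference."""
    y = y0.copy()
    prev = y0.copy()
    diff = 0.0
    for b in range(n_beats):
        prev[:] = y
        t = 0.0
        while t < period_ms - 1.0e-9:
            stim = stim_amp if t < stim_dur_ms else 0.0
            y = ep_advance(y, p, stim, 1.0)
            t += 1.0
        num = 0.0
        for k in range(17):
            num += (y[k] - prev[k]) ** 2
        diff = np.sqrt(num)
        for k in range(17):
            if not np.isfinite(y[k]):
                return y, -1.0 - b  # signal divergence with beat index
    return y, diff


# ---------------------------------------------------------------------------
# half-sarcomere
# ---------------------------------------------------------------------------

@njit(cache=True)
def passive_stress_core(hsl, sigma, L, L_slack):
    if hsl <= L_slack:
        return 0.0
    arg = (hsl - L_slack) / L
    if arg > 40.0:
        arg = 40.0  # guards overflow in extreme parameter sweeps
    return sigma * (np.exp(arg) - 1.0)


@njit(cache=True)
def active_stress_core(fg, x, dx, k_cb, x_ps, N0):
    s = 0.0
    for i in range(fg.shape[0]):
        s += fg[i] * (x[i] + x_ps)
    # k_cb is N/m per head; strain in nm -> 1e-9 m
    return N0 * k_cb * s * dx * 1.0e-9


@njit(cache=True)
def advect_fg(fg, x, dx, shift):
    """Shift the bound-head strain distribution by ``shift`` nm (linear
    interpolation).  Heads advected past the grid edges are returned as a
    population fraction (caller adds them back to M_ON)."""
    n = fg.shape[0]
    out = np.zeros(n)
    s = shift / dx
    for i in range(n):
        pos = i - s
        j0 = int(np.floor(pos))
        w = pos - j0
        v = 0.0
        if 0 <= j0 < n:
            v += (1.0 - w) * fg[j0]
        if 0 <= j0 + 1 < n:
            v += w * fg[j0 + 1]
        out[i] = v
    lost = 0.0
    for i in range(n):
        lost += fg[i] - out[i]
    return out, lost * dx


@njit(cache=True)
def overlap_fraction_core(hsl, n_max, w_asc, hsl_full, hsl_desc0, hsl_desc1,
                          hsl_zero):
    """Available thin-filament site fraction vs half-sarcomere length.

    Force-length shape: exponential ascending limb with length constant
    ``w_asc`` (near-constant logarithmic slope through the operating
    range), shifted so it reaches exactly zero at ``hsl_zero``; full
    overlap between ``hsl_full`` and ``hsl_desc0``; then a linear
    descending limb reaching zero at ``hsl_desc1``.
    """
    if hsl >= hsl_desc1:
        return 0.0
    if hsl < hsl_full:
        eps = np.exp((hsl_zero - hsl_full) / w_asc)
        e = np.exp((hsl - hsl_full) / w_asc)
        f = (e - eps) / (1.0 - eps)
        return n_max * f if f > 0.0 else 0.0
    if hsl <= hsl_desc0:
        return n_max
    return n_max * (hsl_desc1 - hsl) / (hsl_desc1 - hsl_desc0)


@njit(cache=True)
def sarc_substep(N_on, m_off, m_on, fg, x, dx, Ca_mM, hsl, sp, dt_s,
                 freeze_thin=False):
    """One kinetic sub-step of the thin filament + myosin system.

    Fluxes are computed from the current state and applied with per-source
    limiting so no population goes negative and total head number is
    conserved exactly.  Returns the updated scalars plus the ATP consumed
    (detachment flux, per head).
    """
    n = fg.shape[0]
    n_bound = 0.0
    for i in range(n):
        n_bound += fg[i]
    n_bound *= dx

    s_act = active_stress_core(fg, x, dx, sp[8], sp[9], sp[10])
    s_pas = passive_stress_core(hsl, sp[11], sp[12], sp[13])
    force = s_act + s_pas
    if force < 0.0:
        force = 0.0

    # thin filament
    n_ov = overlap_fraction_core(hsl, sp[15], sp[16], sp[17], sp[18], sp[19],
                                 sp[20])
    if freeze_thin:
        # activation treated as an external input (cell-level protocols)
        N_on_new = N_on if N_on > n_bound else n_bound
    else:
        d_on = sp[0] * Ca_mM * (n_ov - N_on) * (1.0 + sp[2] * N_on) \
            - sp[1] * (N_on - n_bound) * (1.0 + sp[2] * (n_ov - N_on))
        N_on_new = N_on + dt_s * d_on
        if N_on_new < n_bound:
            N_on_new = n_bound
        if N_on_new > n_ov and N_on_new > n_bound:
            N_on_new = n_ov if n_ov > n_bound else n_bound

    # myosin fluxes
    j1 = sp[3] * (1.0 + sp[14] * force) * m_off
    j2 = sp[4] * m_on
    avail = N_on_new - n_bound
    if avail < 0.0:
        avail = 0.0

    attach_tot = 0.0
    atp = 0.0
    d_fg = np.empty(n)
    wfac = sp[8] * 1.0e-18 / (2.0 * KB_T)   # k_cb x^2 / (2 kB T), x in nm
    for i in range(n):
        a = sp[5] * np.exp(-wfac * x[i] * x[i]) * avail * m_on
        det = (sp[6] + sp[7] * x[i] ** 4) * fg[i]
        # per-bin limiting: detachment cannot exceed bin content
        if det * dt_s > fg[i]:
            det = fg[i] / dt_s
        d_fg[i] = a - det
        attach_tot += a
        atp += det
    attach_tot *= dx
    atp *= dx

    # source limiting for OFF and ON pools
    if j1 * dt_s > m_off:
        scale = m_off / (j1 * dt_s)
        j1 *= scale
    out_on = (j2 + attach_tot) * dt_s
    if out_on > m_on:
        # scale the ON-pool outflows so the pool cannot go negative
        scale = m_on / out_on
        j2 *= scale
        for i in range(n):
            a = sp[5] * np.exp(-wfac * x[i] * x[i]) * avail * m_on * scale
            det = (sp[6] + sp[7] * x[i] ** 4) * fg[i]
            if det * dt_s > fg[i]:
                det = fg[i] / dt_s
            d_fg[i] = a - det
        attach_tot *= scale

    m_off_new = m_off + dt_s * (j2 - j1)
    m_on_new = m_on + dt_s * (j1 - j2 + atp - attach_tot)
    for i in range(n):
        fg[i] = fg[i] + dt_s * d_fg[i]
        if fg[i] < 0.0:
            fg[i] = 0.0
    if m_off_new < 0.0:
        m_off_new = 0.0
    if m_on_new < 0.0:
        m_on_new = 0.0

    return N_on_new, m_off_new, m_on_new, atp * dt_s


# ---------------------------------------------------------------------------
# ventricle geometry / circulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def radius_from_volume_core(V_liters):
    """Internal radius (m) of a hemisphere of volume V (liters)."""
    return (3.0 * V_liters * 1.0e-3 / (2.0 * np.pi)) ** (1.0 / 3.0)


@njit(cache=True)
def wall_thickness_core(r, W_volume_liters):
    return W_volume_liters * 1.0e-3 / (2.0 * np.pi * r * r)


V_FLOOR = 8.0e-3  # L; default residual cavity volume — an over-contracting
                  # ventricle cannot be squeezed below this, keeping the wall
                  # geometry well-defined and diastolic refilling possible


@njit(cache=True)
def hs_length_from_volume_core(V, V_slack, W_volume, L_slack):
    # mid-wall radius = radius of the hemisphere enclosing the chamber plus
    # half the wall volume; equals r + W_thickness/2 to first order in
    # thickness/r and stays monotone in V down to an empty chamber
    rm = radius_from_volume_core(V + 0.5 * W_volume)
    rm0 = radius_from_volume_core(V_slack + 0.5 * W_volume)
    return L_slack * rm / rm0


@njit(cache=True)
def ventricular_pressure_core(S, W_thickness, r):
    """Laplace-law chamber pressure (mmHg) from wall stress S (N/m^2).

    Uses the thick-shell form 2 S ln(1 + t/r), which reduces to the
    thin-wall 2 S t / r for t << r but stays log-bounded when the
    over-contracting chamber becomes thick-walled (t ~ r and beyond).
    """
    return 2.0 * S * np.log(1.0 + W_thickness / r) * MMHG_PER_PA


@njit(cache=True)
def flows_core(P_v, P, R):
    """Flows (L/s) around the series loop.

    ``P`` holds the 5 vascular compartment pressures (aorta .. veins), ``R``
    the 6 connection resistances ordered as in ``CIRC_PARAM_NAMES``.  Flow 0
    (aortic valve) and flow 5 (venous return) are rectified by the one-way
    valves; inter-vascular flows may run backwards.
    """
    f = np.empty(6)
    f[0] = (P_v - P[0]) / R[0]
    if f[0] < 0.0:
        f[0] = 0.0
    f[1] = (P[0] - P[1]) / R[1]
    f[2] = (P[1] - P[2]) / R[2]
    f[3] = (P[2] - P[3]) / R[3]
    f[4] = (P[3] - P[4]) / R[4]
    f[5] = (P[4] - P_v) / R[5]
    if f[5] < 0.0:
        f[5] = 0.0
    return f


@njit(cache=True)
def limit_flows_core(f, vols, dt_s):
    """Cap each flow so its source compartment cannot be driven negative.

    ``vols`` is the 6-entry volume vector (ventricle first).  Returns the
    limited flow vector and a flag that is 1 when any limiting occurred.
    """
    out = f.copy()
    limited = 0
    # connection k (k = 0..5) carries volume from vols[k] to vols[(k+1) % 6]
    # when positive; a negative inter-vascular flow drains the downstream
    # compartment instead.  Valve flows (k = 0, 5) are already non-negative.
    for k in range(6):
        if out[k] >= 0.0:
            src = k
        else:
            src = (k + 1) % 6
        cap = vols[src] / dt_s
        if np.abs(out[k]) > cap:
            out[k] = cap if out[k] > 0.0 else -cap
            limited = 1
    return out, limited


@njit(cache=True)
def apply_flows_core(vols, f, dt_s, wd_rate):
    """Forward-Euler volume update; withdrawal drains the venous pool."""
    wd = wd_rate
    if (f[4] - f[5] - wd) * dt_s < -vols[5]:
        wd = vols[5] / dt_s + f[4] - f[5]
        if wd < 0.0:
            wd = 0.0
    vols[0] += dt_s * (f[5] - f[0])
    vols[1] += dt_s * (f[0] - f[1])
    vols[2] += dt_s * (f[1] - f[2])
    vols[3] += dt_s * (f[2] - f[3])
    vols[4] += dt_s * (f[3] - f[4])
    vols[5] += dt_s * (f[4] - f[5] - wd)
    return wd


# ---------------------------------------------------------------------------
# fused closed-loop simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_coupled(ep_y0, ep_p, sp, cp, x_grid,
                n_beats, period_ms, stim_dur_ms, stim_amp,
                fill_frac, withdraw_frac, wd_start_ms, wd_end_ms,
                dt_ms, n_sarc_sub, n_hemo_sub):
    """Run the full multiscale closed-loop simulation.

    Returns (log, status).  ``log`` has one row per outer time step (plus the
    initial sample) with columns ``LOG_COLUMNS``.  ``status`` is 0 on success
    or the 1-based outer step index at which a non-finite value appeared.
    """
    dx = x_grid[1] - x_grid[0]
    nx = x_grid.shape[0]

    V_slack = cp[0]; W_vol = cp[1]
    C = cp[2:7]
    R_conn = cp[7:13]
    V_total = cp[13]
    v_floor = cp[14] if cp.shape[0] > 14 else V_FLOOR
    L_slack = sp[13]

    total_ms = n_beats * period_ms
    n_steps = int(np.round(total_ms / dt_ms))
    log = np.zeros((n_steps + 1, N_LOG))

    # initial conditions
    ep = ep_y0.copy()
    N_on = 0.0
    m_off = 1.0
    m_on = 0.0
    fg = np.zeros(nx)
    atp_cum = 0.0

    vols = np.zeros(6)           # ventricle, aorta, arteries, arterioles, caps, veins
    vols[0] = fill_frac * V_slack
    vols[5] = V_total - vols[0]

    hsl = hs_length_from_volume_core(vols[0], V_slack, W_vol, L_slack)

    wd_rate = 0.0
    if withdraw_frac > 0.0 and wd_end_ms > wd_start_ms:
        wd_rate = withdraw_frac * V_total / ((wd_end_ms - wd_start_ms) * 1.0e-3)

    dt_s = dt_ms * 1.0e-3
    hemo_dt_s = dt_s / n_hemo_sub
    sub_dt_s = hemo_dt_s / n_sarc_sub

    # log initial sample
    row = log[0]
    row[0] = 0.0
    row[1] = ep[0]; row[2] = ep[13]
    row[8] = hsl
    row[13] = vols[0]
    for k in range(5):
        row[14 + k] = vols[1 + k] / C[k]
        row[19 + k] = vols[1 + k]
    row[27] = vols.sum()
    row[5] = 1.0

    status = 0
    for step in range(1, n_steps + 1):
        t_ms = (step - 1) * dt_ms
        phase = t_ms % period_ms
        stim = stim_amp if phase < stim_dur_ms else 0.0

        # (1) electrophysiology -> Ca
        ep = ep_advance(ep, ep_p, stim, dt_ms)
        Ca = ep[13]
        if not np.isfinite(ep[0]) or not np.isfinite(Ca):
            status = step
            break

        # (2)-(5) hemodynamics and sarcomere advance on an inner grid
        # (the explicit stress-pressure-flow coupling needs finer steps
        # than the 1 ms outer step to be converged)
        f_av = 0.0
        f_vr = 0.0
        s_act = 0.0
        s_pas = 0.0
        S = 0.0
        P_v = 0.0
        for _h in range(n_hemo_sub):
            s_act = active_stress_core(fg, x_grid, dx, sp[8], sp[9], sp[10])
            s_pas = passive_stress_core(hsl, sp[11], sp[12], sp[13])
            S = s_act + s_pas
            v_geom = vols[0] if vols[0] > v_floor else v_floor
            r = radius_from_volume_core(v_geom)
            th = wall_thickness_core(r, W_vol)
            P_v = ventricular_pressure_core(S, th, r)
            if P_v < 0.0:
                P_v = 0.0

            P = np.empty(5)
            for k in range(5):
                P[k] = vols[1 + k] / C[k]

            # flows with one-way valves, limited to keep volumes >= 0
            f = flows_core(P_v, P, R_conn)
            f, _ = limit_flows_core(f, vols, hemo_dt_s)
            # the ventricle keeps its residual cavity volume
            cap = (vols[0] - v_floor) / hemo_dt_s + f[5]
            if f[0] > cap:
                f[0] = cap if cap > 0.0 else 0.0

            wd = 0.0
            if wd_rate > 0.0 and wd_start_ms <= t_ms < wd_end_ms:
                wd = wd_rate

            # volume updates (exact bookkeeping)
            apply_flows_core(vols, f, hemo_dt_s, wd)
            f_av += f[0] / n_hemo_sub
            f_vr += f[5] / n_hemo_sub

            # sarcomere advances with the resulting length change
            hsl_new = hs_length_from_volume_core(vols[0], V_slack, W_vol,
                                                 L_slack)
            dhsl = hsl_new - hsl
            hsl = hsl_new

            fg, lost = advect_fg(fg, x_grid, dx, dhsl)
            m_on += lost
            for _ in range(n_sarc_sub):
                N_on, m_off, m_on, atp = sarc_substep(
                    N_on, m_off, m_on, fg, x_grid, dx, Ca, hsl, sp, sub_dt_s)
                atp_cum += atp

        # (6) log
        n_bound = 0.0
        fg_tot = 0.0
        for i in range(nx):
            fg_tot += fg[i]
        fg_tot *= dx
        n_bound = fg_tot
        row = log[step]
        row[0] = step * dt_s
        row[1] = ep[0]
        row[2] = Ca
        row[3] = N_on
        row[4] = n_bound
        row[5] = m_off
        row[6] = m_on
        row[7] = fg_tot
        row[8] = hsl
        row[9] = s_act
        row[10] = s_pas
        row[11] = S
        row[12] = P_v
        row[13] = vols[0]
        for k in range(5):
            row[14 + k] = vols[1 + k] / C[k]
            row[19 + k] = vols[1 + k]
        row[24] = f_av
        row[25] = f_vr
        row[26] = atp_cum
        row[27] = vols.sum()

        if not np.isfinite(vols[0]) or not np.isfinite(hsl):
            status = step
            break

    return log, status
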