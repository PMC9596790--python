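"""Numba kernels for the monodomain tissue integrator.

The myocyte membrane model is a human atrial formulation of the
Nygren/Koivumaki family with AF-remodelled conductances and a
small-conductance Ca2+-activated K+ current; the fibroblast is the
MacCannell/Maleckar four-current active fibroblast.  Voltage-dependent gate
steady states and Rush-Larsen decay factors are pre-tabulated on a uniform
voltage grid and linearly interpolated inside the kernel.

All kernels use mV / ms / pA / nS / pF / mM / nL / cm units.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._constants import (
    RTF, FVOL,
    I_V, I_M, I_H1, I_H2, I_D, I_F1, I_F2, I_RT, I_ST, I_RSUS, I_SSUS,
    I_NKS, I_PA, I_FREL1, I_FREL2, I_OC, I_OTC, I_OTMGC, I_OTMGMG, I_OCALSE,
    I_NAI, I_KI, I_CAI, I_CAD, I_CAUP, I_CAREL,
    IF_V, IF_R, IF_S,
    P_PNA, P_GCAL, P_GT, P_GKUR, P_GKS, P_GKR, P_GK1, P_GSK, P_INAK,
    P_KNACA, P_ICAP, P_GNAB, P_GCAB, P_KO, P_NAO, P_CAO, P_CM, P_IUP,
    P_PHINA,
    FP_GKV, FP_GK1, FP_INAK, FP_GNAB, FP_KO, FP_NAO, FP_CM, FP_NAI, FP_KI,
    E_CA_APP, K_CA_D, K_NAK_K, K_NAK_NA, K_CAP, GAMMA_NACA, D_NACA,
    SK_EC50, VOL_I, VOL_D, VOL_UP, VOL_REL, TAU_DI, TAU_TR, ALPHA_REL,
    K_REL_I, K_REL_D, R_RECOV, K_CYCA, K_SRCA, K_XCS, MG_I,
)

# ---------------------------------------------------------------------------
# Rate tables
# ---------------------------------------------------------------------------

# table row indices
(T_MINF, T_MEDT, T_HINF, T_H1EDT, T_H2EDT, T_DINF, T_DEDT, T_FINF, T_F1EDT,
 T_F2EDT, T_RTINF, T_RTEDT, T_STINF, T_STEDT, T_RSINF, T_RSEDT, T_SSINF,
 T_SSEDT, T_NINF, T_NEDT, T_PAINF, T_PAEDT, T_PIINF, T_EXPVF) = range(24)
N_TABLES = 24

TABLE_VMIN = -200.0
TABLE_VMAX = 150.0
TABLE_DV = 0.05


def gate_rates(v):
    """Steady states and time constants (ms) of all myocyte gates at voltage
    ``v`` (mV, scalar or array).  Returns a dict name -> (inf, tau)."""
    v = np.asarray(v, dtype=float)
    rates = {}
    rates["m"] = (1.0 / (1.0 + np.exp(-(v + 27.12) / 8.21)),
                  0.042 * np.exp(-(((v + 25.57) / 28.8) ** 2)) + 0.024)
    h_inf = 1.0 / (1.0 + np.exp((v + 63.6) / 5.3))
    rates["h1"] = (h_inf, 30.0 / (1.0 + np.exp((v + 35.1) / 3.2)) + 0.3)
    rates["h2"] = (h_inf, 120.0 / (1.0 + np.exp((v + 35.1) / 3.2)) + 3.0)
    rates["d"] = (1.0 / (1.0 + np.exp(-(v + 9.0) / 5.8)),
                  2.7 * np.exp(-(((v + 35.0) / 30.0) ** 2)) + 2.0)
    f_inf = 1.0 / (1.0 + np.exp((v + 27.4) / 7.1))
    rates["f1"] = (f_inf, 161.0 * np.exp(-(((v + 40.0) / 14.4) ** 2)) + 10.0)
    rates["f2"] = (f_inf, 1332.3 * np.exp(-(((v + 40.0) / 14.2) ** 2)) + 62.6)
    rates["r_t"] = (1.0 / (1.0 + np.exp(-(v - 1.0) / 11.0)),
                    3.5 * np.exp(-((v / 30.0) ** 2)) + 1.5)
    rates["s_t"] = (1.0 / (1.0 + np.exp((v + 40.5) / 11.5)),
                    481.2 * np.exp(-(((v + 52.45) / 14.97) ** 2)) + 14.14)
    rates["r_sus"] = (1.0 / (1.0 + np.exp(-(v + 4.3) / 8.0)),
                      9.0 / (1.0 + np.exp((v + 5.0) / 12.0)) + 0.5)
    rates["s_sus"] = (0.4 / (1.0 + np.exp((v + 20.0) / 10.0)) + 0.6,
                      47.0 / (1.0 + np.exp((v + 60.0) / 10.0)) + 300.0)
    rates["n_ks"] = (1.0 / (1.0 + np.exp(-(v - 19.9) / 12.7)),
                     700.0 + 400.0 * np.exp(-(((v - 20.0) / 20.0) ** 2)))
    rates["pa"] = (1.0 / (1.0 + np.exp(-(v + 15.0) / 6.0)),
                   31.18 + 217.18 *
                   np.exp(-(((v + 20.1376) / 22.1996) ** 2)))
    return rates


def build_rate_tables(dt_ms, vmin=TABLE_VMIN, vmax=TABLE_VMAX, dv=TABLE_DV):
    """Tabulate gate steady states, per-step Rush-Larsen decay factors
    ``exp(-dt/tau)`` and the GHK voltage exponential on a uniform V grid."""
    n = int(round((vmax - vmin) / dv)) + 1
    v = vmin + dv * np.arange(n)
    tab = np.empty((N_TABLES, n), dtype=np.float64)
    r = gate_rates(v)

    def put(inf_row, edt_row, key):
        inf, tau = r[key]
        if inf_row >= 0:
            tab[inf_row] = inf
        tab[edt_row] = np.exp(-dt_ms / tau)

    put(T_MINF, T_MEDT, "m")
    put(T_HINF, T_H1EDT, "h1")
    put(-1, T_H2EDT, "h2")
    put(T_DINF, T_DEDT, "d")
    put(T_FINF, T_F1EDT, "f1")
    put(-1, T_F2EDT, "f2")
    put(T_RTINF, T_RTEDT, "r_t")
    put(T_STINF, T_STEDT, "s_t")
    put(T_RSINF, T_RSEDT, "r_sus")
    put(T_SSINF, T_SSEDT, "s_sus")
    put(T_NINF, T_NEDT, "n_ks")
    put(T_PAINF, T_PAEDT, "pa")
    tab[T_PIINF] = 1.0 / (1.0 + np.exp((v + 55.0) / 24.0))
    tab[T_EXPVF] = np.exp(v / RTF)
    return np.ascontiguousarray(tab), float(vmin), float(dv)


# ---------------------------------------------------------------------------
# Node update kernels
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True, inline="always")
def _lin(tab, row, i0, fr):
    a = tab[row, i0]
    return a + fr * (tab[row, i0 + 1] - a)


@njit(cache=False, fastmath=True)
def myocyte_node_step(S, j, v, mp, tab, tab_v0, tab_idv, dt,
                      i_ext_pApF, i_gap_na, i_gap_k):
    """Advance myocyte node ``j`` of state array ``S`` (shape (N, 26)) one
    step of length ``dt`` from membrane potential ``v``.

    ``i_ext_pApF`` collects the diffusion term plus stimulus (mV/ms, i.e.
    pA/pF, positive = depolarizing); ``i_gap_na``/``i_gap_k`` are outward
    gap-junction currents (pA) to fibroblast neighbours.  Returns dV/dt.
    """
    # table lookup coordinates
    x = (v - tab_v0) * tab_idv
    if x < 0.0:
        x = 0.0
    nmax = tab.shape[1] - 2
    i0 = int(x)
    if i0 > nmax:
        i0 = nmax
    fr = x - i0

    m = S[j, I_M]
    h1 = S[j, I_H1]
    h2 = S[j, I_H2]
    dl = S[j, I_D]
    f1 = S[j, I_F1]
    f2 = S[j, I_F2]
    rt = S[j, I_RT]
    st = S[j, I_ST]
    rsus = S[j, I_RSUS]
    ssus = S[j, I_SSUS]
    nks = S[j, I_NKS]
    pa = S[j, I_PA]
    nai = S[j, I_NAI]
    ki = S[j, I_KI]
    cai = S[j, I_CAI]
    cad = S[j, I_CAD]
    caup = S[j, I_CAUP]
    carel = S[j, I_CAREL]

    # --- gates first (staggered Rush-Larsen): currents below use the
    # updated gate values, which markedly improves dV/dt convergence ---
    m = _rl(tab, T_MINF, T_MEDT, i0, fr, m)
    hinf = _lin(tab, T_HINF, i0, fr)
    h1 = hinf + (h1 - hinf) * _lin(tab, T_H1EDT, i0, fr)
    h2 = hinf + (h2 - hinf) * _lin(tab, T_H2EDT, i0, fr)
    dl = _rl(tab, T_DINF, T_DEDT, i0, fr, dl)
    finf = _lin(tab, T_FINF, i0, fr)
    f1 = finf + (f1 - finf) * _lin(tab, T_F1EDT, i0, fr)
    f2 = finf + (f2 - finf) * _lin(tab, T_F2EDT, i0, fr)
    rt = _rl(tab, T_RTINF, T_RTEDT, i0, fr, rt)
    st = _rl(tab, T_STINF, T_STEDT, i0, fr, st)
    rsus = _rl(tab, T_RSINF, T_RSEDT, i0, fr, rsus)
    ssus = _rl(tab, T_SSINF, T_SSEDT, i0, fr, ssus)
    nks = _rl(tab, T_NINF, T_NEDT, i0, fr, nks)
    pa = _rl(tab, T_PAINF, T_PAEDT, i0, fr, pa)
    S[j, I_M] = m
    S[j, I_H1] = h1
    S[j, I_H2] = h2
    S[j, I_D] = dl
    S[j, I_F1] = f1
    S[j, I_F2] = f2
    S[j, I_RT] = rt
    S[j, I_ST] = st
    S[j, I_RSUS] = rsus
    S[j, I_SSUS] = ssus
    S[j, I_NKS] = nks
    S[j, I_PA] = pa

    ko = mp[P_KO]
    nao = mp[P_NAO]
    cao = mp[P_CAO]

    ek = RTF * np.log(ko / ki)
    ena = RTF * np.log(nao / nai)
    eca = 0.5 * RTF * np.log(cao / cai)

    # --- currents (pA) ---
    expvf = _lin(tab, T_EXPVF, i0, fr)
    hh = 0.9 * h1 + 0.1 * h2
    if -0.01 < v < 0.01:
        # limit of the GHK flux as V -> 0
        ina = mp[P_PNA] * m * m * m * hh * nao * 9.6487e4 \
            * (nai / nao - 1.0)
    else:
        ina = mp[P_PNA] * m * m * m * hh * nao * 9.6487e4 * (v / RTF) \
            * (expvf * nai / nao - 1.0) / (expvf - 1.0)

    fca = cad / (cad + K_CA_D)
    ical = mp[P_GCAL] * dl * (fca * f1 + (1.0 - fca) * f2) * (v - E_CA_APP)

    it = mp[P_GT] * rt * st * (v - ek)
    ikur = mp[P_GKUR] * rsus * ssus * (v - ek)
    iks = mp[P_GKS] * nks * (v - ek)
    pi_kr = _lin(tab, T_PIINF, i0, fr)
    ikr = mp[P_GKR] * pa * pi_kr * (v - ek)
    ik1 = mp[P_GK1] * (ko ** 0.4457) * (v - ek) \
        / (1.0 + np.exp(1.5 * (v - ek + 3.6) / RTF))
    isk = mp[P_GSK] * (cai * cai / (cai * cai + SK_EC50 * SK_EC50)) * (v - ek)

    na15 = nai * np.sqrt(nai)
    inak = mp[P_INAK] * (ko / (ko + K_NAK_K)) \
        * (na15 / (na15 + K_NAK_NA ** 1.5)) * (v + 150.0) / (v + 200.0)

    eg = np.exp(GAMMA_NACA * v / RTF)
    eg1 = np.exp((GAMMA_NACA - 1.0) * v / RTF)
    nai3 = nai * nai * nai
    nao3 = nao * nao * nao
    inaca = mp[P_KNACA] * (nai3 * cao * eg - nao3 * cai * eg1) \
        / (1.0 + D_NACA * (nao3 * cai + nai3 * cao))

    icap = mp[P_ICAP] * cai / (cai + K_CAP)
    inab = mp[P_GNAB] * (v - ena)
    icab = mp[P_GCAB] * (v - eca)

    i_ion = (ina + ical + it + ikur + iks + ikr + ik1 + isk + inab + icab
             + icap + inak + inaca + mp[P_PHINA]
             + i_gap_na + i_gap_k)

    dvdt = i_ext_pApF - i_ion / mp[P_CM]

    # --- SR Ca release machinery ---
    F1r = S[j, I_FREL1]
    F2r = S[j, I_FREL2]
    ract = 0.2038 * ((cai / (cai + K_REL_I)) ** 4 +
                     (cad / (cad + K_REL_D)) ** 4)
    rinact = 0.03396 + 0.3396 * (cai / (cai + K_REL_I)) ** 4
    S[j, I_FREL1] = F1r + dt * (R_RECOV * (1.0 - F1r - F2r) - ract * F1r)
    S[j, I_FREL2] = F2r + dt * (ract * F1r - rinact * F2r)
    frel = F2r / (F2r + 0.25)
    irel = ALPHA_REL * frel * frel * (carel - cai)

    iup = mp[P_IUP] * (cai / K_CYCA - K_XCS * K_XCS * caup / K_SRCA) \
        / ((cai + K_CYCA) / K_CYCA + K_XCS * (caup + K_SRCA) / K_SRCA)
    itr = (caup - carel) * 2.0 * FVOL * VOL_REL / TAU_TR
    idi = (cad - cai) * 2.0 * FVOL * VOL_D / TAU_DI

    # --- Ca buffers ---
    oc = S[j, I_OC]
    otc = S[j, I_OTC]
    otmgc = S[j, I_OTMGC]
    otmgmg = S[j, I_OTMGMG]
    ocalse = S[j, I_OCALSE]
    d_oc = 200.0 * cai * (1.0 - oc) - 0.476 * oc
    d_otc = 78.4 * cai * (1.0 - otc) - 0.392 * otc
    d_otmgc = 200.0 * cai * (1.0 - otmgc - otmgmg) - 0.0066 * otmgc
    d_otmgmg = 2.0 * MG_I * (1.0 - otmgc - otmgmg) - 0.666 * otmgmg
    d_ocalse = 0.48 * carel * (1.0 - ocalse) - 0.4 * ocalse
    S[j, I_OC] = oc + dt * d_oc
    S[j, I_OTC] = otc + dt * d_otc
    S[j, I_OTMGC] = otmgc + dt * d_otmgc
    S[j, I_OTMGMG] = otmgmg + dt * d_otmgmg
    S[j, I_OCALSE] = ocalse + dt * d_ocalse
    phi_cai = 0.045 * d_oc + 0.08 * d_otc + 0.16 * d_otmgc

    # --- concentrations ---
    S[j, I_NAI] = nai - dt * (ina + inab + 3.0 * inak + 3.0 * inaca
                              + mp[P_PHINA] + i_gap_na) / (VOL_I * FVOL)
    S[j, I_KI] = ki - dt * (it + ikur + ik1 + iks + ikr + isk
                            - 2.0 * inak + i_gap_k) / (VOL_I * FVOL)
    S[j, I_CAI] = cai - dt * ((-idi + icab + icap - 2.0 * inaca + iup - irel)
                              / (2.0 * VOL_I * FVOL) + phi_cai)
    S[j, I_CAD] = cad - dt * (ical + idi) / (2.0 * VOL_D * FVOL)
    S[j, I_CAUP] = caup + dt * (iup - itr) / (2.0 * VOL_UP * FVOL)
    S[j, I_CAREL] = carel + dt * ((itr - irel) / (2.0 * VOL_REL * FVOL)
                                  - 31.0 * d_ocalse)

    S[j, I_V] = v + dt * dvdt
    return dvdt


@njit(cache=False, fastmath=True, inline="always")
def _rl(tab, inf_row, edt_row, i0, fr, w):
    winf = _lin(tab, inf_row, i0, fr)
    return winf + (w - winf) * _lin(tab, edt_row, i0, fr)


@njit(cache=False, fastmath=True)
def fibroblast_node_step(SF, j, v, fp, dt, i_gap_in_pA):
    """Advance fibroblast node ``j`` one step from potential ``v``.

    ``i_gap_in_pA`` is the total gap-junction current flowing INTO the
    fibroblast (pA, positive = depolarizing).  Returns dV/dt.
    """
    r = SF[j, IF_R]
    s = SF[j, IF_S]
    ko = fp[FP_KO]
    nao = fp[FP_NAO]
    nai = fp[FP_NAI]
    ki = fp[FP_KI]
    ek = RTF * np.log(ko / ki)
    ena = RTF * np.log(nao / nai)

    ikv = fp[FP_GKV] * r * s * (v - ek)
    # inward rectifier, Luo-Rudy style rectification
    dvk = v - ek
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (dvk - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (dvk + 100.0)) + np.exp(0.1 * (dvk - 10.0))) \
        / (1.0 + np.exp(-0.5 * dvk))
    ik1 = fp[FP_GK1] * (ak1 / (ak1 + bk1)) * np.sqrt(ko / 5.4) * dvk
    na15 = nai * np.sqrt(nai)
    inak = fp[FP_INAK] * (ko / (ko + K_NAK_K)) \
        * (na15 / (na15 + K_NAK_NA ** 1.5)) * (v + 150.0) / (v + 200.0)
    inab = fp[FP_GNAB] * (v - ena)

    dvdt = (i_gap_in_pA - (ikv + ik1 + inak + inab)) / fp[FP_CM]

    rinf = 1.0 / (1.0 + np.exp(-(v + 20.0) / 11.0))
    taur = 20.3 + 138.0 * np.exp(-(((v + 20.0) / 25.9) ** 2))
    sinf = 1.0 / (1.0 + np.exp((v + 23.0) / 7.0))
    taus = 1574.0 + 5268.0 * np.exp(-(((v + 23.0) / 22.7) ** 2))
    SF[j, IF_R] = rinf + (r - rinf) * np.exp(-dt / taur)
    SF[j, IF_S] = sinf + (s - sinf) * np.exp(-dt / taus)
    SF[j, IF_V] = v + dt * dvdt
    return dvdt


# ---------------------------------------------------------------------------
# Tissue integrator
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def integrate_tissue(S, SF, is_fib, nx, ny, dx, D, mp, fp,
                     ggap_na, ggap_k, tab, tab_v0, tab_dv, dt, n_steps,
                     stim_amp, stim_dur, stim_period, n_pulses, stim_cols,
                     probe_idx, record_stride, traces,
                     act_t, rmp_b, vmax_b, apd_end, depol_b, repol_b,
                     dvdt_thresh, v_cross):
    """Forward-Euler / Rush-Larsen integration of the 2D monodomain sheet.

    Node (ix, iy) has flat index iy*nx + ix; columns advance along the
    propagation (x) direction.  Fibroblast nodes replace myocytes, are
    excluded from diffusion, and exchange species-resolved ohmic gap currents
    with their von-Neumann myocyte neighbours.

    Per-beat, per-node action-potential markers are extracted online:
    diastolic minimum (RMP), activation time (maximum dV/dt with upstroke
    validation), peak voltage, APD90 end (linear interpolation) and a
    repolarization flag.

    Returns (status, t_fail): status 0 = ok, 1 = non-finite state.
    """
    n_nodes = nx * ny
    idv = 1.0 / tab_dv
    dinv = D / (dx * dx)
    n_beats = act_t.shape[0]

    vold = np.empty(n_nodes)
    vold_f = np.empty(n_nodes)

    # online beat-marker working arrays
    cur_rmp = np.empty(n_nodes)
    cur_mdvdt = np.empty(n_nodes)
    cur_tact = np.empty(n_nodes)
    cur_vpk = np.empty(n_nodes)
    cur_cross = np.zeros(n_nodes, dtype=np.uint8)
    cur_apd = np.empty(n_nodes)
    cur_rep = np.zeros(n_nodes, dtype=np.uint8)
    for j in range(n_nodes):
        cur_rmp[j] = 1e30
        cur_mdvdt[j] = -1e30
        cur_tact[j] = np.nan
        cur_vpk[j] = -1e30
        cur_apd[j] = np.nan

    beat = 0
    rec_i = 0
    status = 0
    t_fail = -1.0

    for step in range(n_steps):
        t = step * dt

        # beat bookkeeping
        b = int(t / stim_period)
        if b >= n_beats:
            b = n_beats - 1
        if b != beat:
            for j in range(n_nodes):
                _finalize_beat(j, beat, act_t, rmp_b, vmax_b, apd_end,
                               depol_b, repol_b, cur_rmp, cur_mdvdt, cur_tact,
                               cur_vpk, cur_cross, cur_apd, cur_rep,
                               dvdt_thresh)
            beat = b

        # record traces
        if step % record_stride == 0:
            for p in range(probe_idx.shape[0]):
                jj = probe_idx[p]
                if is_fib[jj]:
                    traces[rec_i, p] = SF[jj, IF_V]
                else:
                    traces[rec_i, p] = S[jj, I_V]
            rec_i += 1

        # stimulus window
        pulse = int(t / stim_period)
        stim_on = (pulse < n_pulses) and (t - pulse * stim_period) < stim_dur

        # snapshot membrane potentials
        for j in range(n_nodes):
            if is_fib[j]:
                vold_f[j] = SF[j, IF_V]
            else:
                vold[j] = S[j, I_V]

        # fibroblast pass
        for j in range(n_nodes):
            if not is_fib[j]:
                continue
            vf = vold_f[j]
            gap_in = 0.0
            ix = j % nx
            iy = j // nx
            if ix > 0 and not is_fib[j - 1]:
                gap_in += (ggap_na + ggap_k) * (vold[j - 1] - vf)
            if ix < nx - 1 and not is_fib[j + 1]:
                gap_in += (ggap_na + ggap_k) * (vold[j + 1] - vf)
            if iy > 0 and not is_fib[j - nx]:
                gap_in += (ggap_na + ggap_k) * (vold[j - nx] - vf)
            if iy < ny - 1 and not is_fib[j + nx]:
                gap_in += (ggap_na + ggap_k) * (vold[j + nx] - vf)
            fibroblast_node_step(SF, j, vf, fp, dt, gap_in)

        # myocyte pass
        for j in range(n_nodes):
            if is_fib[j]:
                continue
            v = vold[j]
            ix = j % nx
            iy = j // nx
            lap = 0.0
            gna = 0.0
            gk = 0.0
            # west
            if ix > 0:
                if is_fib[j - 1]:
                    dvf = v - vold_f[j - 1]
                    gna += ggap_na * dvf
                    gk += ggap_k * dvf
                else:
                    lap += vold[j - 1] - v
            # east
            if ix < nx - 1:
                if is_fib[j + 1]:
                    dvf = v - vold_f[j + 1]
                    gna += ggap_na * dvf
                    gk += ggap_k * dvf
                else:
                    lap += vold[j + 1] - v
            # south
            if iy > 0:
                if is_fib[j - nx]:
                    dvf = v - vold_f[j - nx]
                    gna += ggap_na * dvf
                    gk += ggap_k * dvf
                else:
                    lap += vold[j - nx] - v
            # north
            if iy < ny - 1:
                if is_fib[j + nx]:
                    dvf = v - vold_f[j + nx]
                    gna += ggap_na * dvf
                    gk += ggap_k * dvf
                else:
                    lap += vold[j + nx] - v

            i_ext = dinv * lap
            if stim_on and ix < stim_cols:
                i_ext += stim_amp

            dvdt = myocyte_node_step(S, j, v, mp, tab, tab_v0, idv, dt,
                                     i_ext, gna, gk)

            # --- online AP markers ---
            if not cur_cross[j] and v < cur_rmp[j]:
                cur_rmp[j] = v
            if dvdt > cur_mdvdt[j]:
                cur_mdvdt[j] = dvdt
                cur_tact[j] = t
            vnew = S[j, I_V]
            if vnew > v_cross:
                cur_cross[j] = 1
            if cur_cross[j]:
                if vnew > cur_vpk[j]:
                    cur_vpk[j] = vnew
                elif not cur_rep[j]:
                    v90 = cur_rmp[j] + 0.1 * (cur_vpk[j] - cur_rmp[j])
                    if vnew < v90 <= v:
                        # linear interpolation of the crossing time
                        frac = (v - v90) / (v - vnew)
                        cur_apd[j] = t + frac * dt
                        cur_rep[j] = 1

        # periodic blow-up check
        if step % 2000 == 0:
            for j in range(n_nodes):
                vj = SF[j, IF_V] if is_fib[j] else S[j, I_V]
                if not np.isfinite(vj):
                    status = 1
                    t_fail = t
                    break
            if status == 1:
                break

    if status == 0:
        for j in range(n_nodes):
            _finalize_beat(j, beat, act_t, rmp_b, vmax_b, apd_end,
                           depol_b, repol_b, cur_rmp, cur_mdvdt, cur_tact,
                           cur_vpk, cur_cross, cur_apd, cur_rep, dvdt_thresh)
    return status, t_fail


@njit(cache=False, fastmath=True, inline="always")
def _finalize_beat(j, beat, act_t, rmp_b, vmax_b, apd_end, depol_b, repol_b,
                   cur_rmp, cur_mdvdt, cur_tact, cur_vpk, cur_cross, cur_apd,
                   cur_rep, dvdt_thresh):
    activated = cur_cross[j] == 1 and cur_mdvdt[j] > dvdt_thresh
    if activated:
        act_t[beat, j] = cur_tact[j]
        vmax_b[beat, j] = cur_vpk[j]
        apd_end[beat, j] = cur_apd[j]
        depol_b[beat, j] = 1
        repol_b[beat, j] = cur_rep[j]
    else:
        act_t[beat, j] = np.nan
        vmax_b[beat, j] = np.nan
        apd_end[beat, j] = np.nan
        depol_b[beat, j] = 0
        repol_b[beat, j] = 0
    rmp_b[beat, j] = cur_rmp[j] if cur_rmp[j] < 1e29 else np.nan
    # reset working slots
    cur_rmp[j] = 1e30
    cur_mdvdt[j] = -1e30
    cur_tact[j] = np.nan
    cur_vpk[j] = -1e30
    cur_cross[j] = 0
    cur_apd[j] = np.nan
    cur_rep[j] = 0
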