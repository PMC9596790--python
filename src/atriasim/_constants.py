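"""Physical constants, state-vector and parameter-vector layouts.

Units used throughout the numerical core: mV, ms, pA, nS, pF, mM, nL, cm.
"""

# Physical constants (temperature 306.15 K as in the human atrial model family)
FARADAY = 96487.0          # C / mol
GAS_CONST = 8314.0         # mJ / (mol K)
TEMPERATURE = 306.15       # K
RTF = GAS_CONST * TEMPERATURE / FARADAY  # ~26.38 mV

# Conversion: d[conc mM]/dt[ms] = I[pA] / (CONC_FACTOR_DENOM * Vol[nL])
# 1 pA * 1 ms = 1e-15 C -> /F mol -> /(Vol nL = 1e-9 L) -> mol/L
# => dC[mM] = I[pA] * dt[ms] / (F * Vol[nL] * 1e3)
FVOL = FARADAY * 1.0e3     # use as F_eff with Vol in nL, I in pA, t in ms

# --- Myocyte state vector layout -------------------------------------------
MYO_STATE_NAMES = (
    "V", "m", "h1", "h2", "d", "f1", "f2", "r_t", "s_t", "r_sus", "s_sus",
    "n_ks", "pa", "F1", "F2", "O_C", "O_TC", "O_TMgC", "O_TMgMg", "O_Calse",
    "Na_i", "K_i", "Ca_i", "Ca_d", "Ca_up", "Ca_rel",
)
N_MYO_STATES = len(MYO_STATE_NAMES)  # 26

(I_V, I_M, I_H1, I_H2, I_D, I_F1, I_F2, I_RT, I_ST, I_RSUS, I_SSUS,
 I_NKS, I_PA, I_FREL1, I_FREL2, I_OC, I_OTC, I_OTMGC, I_OTMGMG, I_OCALSE,
 I_NAI, I_KI, I_CAI, I_CAD, I_CAUP, I_CAREL) = range(N_MYO_STATES)

# --- Fibroblast state vector layout ----------------------------------------
FIB_STATE_NAMES = ("V", "r_kv", "s_kv")
N_FIB_STATES = len(FIB_STATE_NAMES)
(IF_V, IF_R, IF_S) = range(N_FIB_STATES)

# --- Myocyte parameter vector layout (passed to the kernel) ----------------
MYO_PARAM_NAMES = (
    "p_na",        # nL/s        INa permeability
    "g_cal",       # nS          L-type Ca
    "g_t",         # nS          transient outward
    "g_kur",       # nS          ultrarapid delayed rectifier (sustained outward)
    "g_ks",        # nS          slow delayed rectifier
    "g_kr",        # nS          rapid delayed rectifier
    "g_k1",        # nS          inward rectifier
    "g_sk",        # nS          small-conductance Ca-activated K (I_KCa)
    "i_nak_max",   # pA          Na/K pump maximum
    "k_naca",      # pA/mM^4     Na/Ca exchanger scale
    "i_cap_max",   # pA          sarcolemmal Ca pump maximum
    "g_nab",       # nS          background Na
    "g_cab",       # nS          background Ca
    "k_o",         # mM          extracellular K
    "na_o",        # mM          extracellular Na
    "ca_o",        # mM          extracellular Ca
    "cm",          # pF          membrane capacitance
    "i_up_max",    # pA          SERCA uptake maximum
    "phi_na_en",   # pA          constant Na electroneutral influx
)
N_MYO_PARAMS = len(MYO_PARAM_NAMES)

(P_PNA, P_GCAL, P_GT, P_GKUR, P_GKS, P_GKR, P_GK1, P_GSK, P_INAK, P_KNACA,
 P_ICAP, P_GNAB, P_GCAB, P_KO, P_NAO, P_CAO, P_CM, P_IUP, P_PHINA) = \
    range(N_MYO_PARAMS)

# --- Fibroblast parameter vector layout -------------------------------------
FIB_PARAM_NAMES = (
    "g_kv",        # nS   time/voltage dependent fibroblast K current
    "g_k1",        # nS   inward rectifier
    "i_nak_max",   # pA   Na/K pump maximum
    "g_nab",       # nS   background Na
    "k_o",         # mM
    "na_o",        # mM
    "cm",          # pF
    "na_i",        # mM   (held constant)
    "k_i",         # mM   (held constant)
)
N_FIB_PARAMS = len(FIB_PARAM_NAMES)
(FP_GKV, FP_GK1, FP_INAK, FP_GNAB, FP_KO, FP_NAO, FP_CM, FP_NAI, FP_KI) = \
    range(N_FIB_PARAMS)

# --- Fixed myocyte model constants (not varied by profiles or drugs) --------
E_CA_APP = 60.0        # mV   apparent ICaL reversal
K_CA_D = 0.025         # mM   ICaL Ca-dependent inactivation half-point
K_NAK_K = 1.0          # mM
K_NAK_NA = 11.0        # mM
K_CAP = 0.0002         # mM
GAMMA_NACA = 0.45
D_NACA = 0.0003        # mM^-4
MG_I = 2.5             # mM
SK_EC50 = 0.0007       # mM   I_KCa half-activation [Ca]_i
# intracellular volumes (nL)
VOL_I = 5.884
VOL_D = 0.11768
VOL_UP = 0.3969
VOL_REL = 0.0441
TAU_DI = 10.0          # ms   subspace <-> cytosol Ca diffusion
TAU_TR = 10.0          # ms   SR uptake -> release transfer
ALPHA_REL = 200000.0   # pA/mM
K_REL_I = 0.0003       # mM
K_REL_D = 0.003        # mM
R_RECOV = 0.000815     # 1/ms
K_CYCA = 0.0003        # mM
K_SRCA = 0.5           # mM
K_XCS = 0.4
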