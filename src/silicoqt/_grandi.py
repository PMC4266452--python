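"""Grandi, Pasqualini & Bers (2010) human ventricular myocyte model, epicardial.

Transcription of the published ODE system (39 state variables).  The membrane
is split into junctional-cleft and bulk sarcolemmal compartments; calcium
buffering is explicit (troponin, calmodulin, myosin, SR membrane,
sarcolemmal sites, calsequestrin).  The transient outward current has
distinct fast (Kv4.3-like) and slow components, so Kv4.3-screen block scales
only the fast conductance.

State layout:
  0 V (mV), 1 m, 2 h, 3 j, 4 d, 5 f, 6 fcaBj, 7 fcaBsl,
  8 xtos, 9 ytos, 10 xtof, 11 ytof, 12 xkr, 13 xks,
  14 RyRr, 15 RyRo, 16 RyRi,
  17 NaBj, 18 NaBsl, 19 TnCL, 20 TnCHc, 21 TnCHm, 22 CaM, 23 Myoc, 24 Myom,
  25 SRB, 26 SLLj, 27 SLLsl, 28 SLHj, 29 SLHsl, 30 Csqnb,
  31 Casr, 32 Naj, 33 Nasl, 34 Nai, 35 Ki, 36 Caj, 37 Casl, 38 Cai  (mM)
"""

from __future__ import annotations

import numpy as np
from numba import njit

NAME = "grandi2010"
CELL_VARIANT = "epicardial"
CITATION = "Grandi E, Pasqualini FS, Bers DM (2010) J Mol Cell Cardiol 48:112-121 (epicardial)"
N_STATE = 39
V_INDEX = 0

STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "fcaBj", "fcaBsl",
    "xtos", "ytos", "xtof", "ytof", "xkr", "xks",
    "RyRr", "RyRo", "RyRi",
    "NaBj", "NaBsl", "TnCL", "TnCHc", "TnCHm", "CaM", "Myoc", "Myom",
    "SRB", "SLLj", "SLLsl", "SLHj", "SLHsl", "Csqnb",
    "Casr", "Naj", "Nasl", "Nai", "Ki", "Caj", "Casl", "Cai",
)

# Gto here is the FAST component conductance (the Kv4.3 screen target).
PARAM_NAMES = ("GNa", "GKr", "GKs", "PCa", "GtoFast", "GK1", "GtoSlow",
               "stim_amplitude", "stim_duration", "stim_period")
HANDLES = {"INa": 0, "IKr": 1, "IKs": 2, "ICaL": 3, "Ito": 4, "IK1": 5}

P0 = np.array([
    23.0,        # GNa  mS/uF
    0.035,       # GKr  mS/uF (before sqrt(Ko/5.4) factor)
    0.0035,      # GKs  mS/uF
    2.7e-4,      # PCa = 0.5*5.4e-4 cm/s
    0.1144,      # GtoFast mS/uF (epi)
    0.35,        # GK1  mS/uF (before sqrt(Ko/5.4) factor)
    0.0156,      # GtoSlow mS/uF (epi)
    9.5,         # stimulus amplitude uA/uF (applied as inward/depolarising)
    5.0,         # stimulus duration ms
    1000.0,      # stimulus period ms
])

# Published epicardial initial conditions.
Y0 = np.array([
    -8.09763e1,    # V
    1.405627e-3,   # m
    9.867005e-1,   # h
    9.915620e-1,   # j
    7.175662e-6,   # d
    1.000681,      # f
    2.421991e-2,   # fcaBj
    1.452605e-2,   # fcaBsl
    4.051574e-3,   # xtos
    9.945511e-1,   # ytos
    4.051574e-3,   # xtof
    9.945511e-1,   # ytof
    8.641386e-3,   # xkr
    5.412034e-3,   # xks
    8.884332e-1,   # RyRr
    8.156628e-7,   # RyRo
    1.024274e-7,   # RyRi
    3.539892,      # NaBj
    7.720854e-1,   # NaBsl
    8.773191e-3,   # TnCL
    1.078283e-1,   # TnCHc
    1.524002e-2,   # TnCHm
    2.911916e-4,   # CaM
    1.298754e-3,   # Myoc
    1.381982e-1,   # Myom
    2.143165e-3,   # SRB
    9.566355e-3,   # SLLj
    1.110363e-1,   # SLLsl
    7.347888e-3,   # SLHj
    7.297378e-2,   # SLHsl
    1.242988,      # Csqnb
    5.545201e-1,   # Casr
    9.06,          # Naj
    9.06,          # Nasl
    9.06,          # Nai
    120.0,         # Ki
    1.737475e-4,   # Caj
    1.031812e-4,   # Casl
    8.597401e-5,   # Cai
])

GATE_INDICES = (1, 2, 3, 4, 8, 9, 10, 11, 12, 13)  # HH gates in [0,1]


@njit(cache=True)
def rhs(t, y, p):
    # Constants
    R = 8314.0
    Frdy = 96485.0
    Temp = 310.0
    FoRT = Frdy / (R * Temp)
    Cmem = 1.3810e-10   # F, membrane capacitance
    Qpow = 0.0          # (Temp-310)/10

    # Cell geometry
    cellLength = 100.0
    cellRadius = 10.25
    Vcell = 3.141592653589793 * cellRadius ** 2 * cellLength * 1.0e-15  # L
    Vmyo = 0.65 * Vcell
    Vsr = 0.035 * Vcell
    Vsl = 0.02 * Vcell
    Vjunc = 0.0539 * 0.01 * Vcell
    J_ca_juncsl = 1.0 / 1.2134e12
    J_ca_slmyo = 1.0 / 2.68510e11
    J_na_juncsl = 1.0 / (1.6382e12 / 3.0 * 100.0)
    J_na_slmyo = 1.0 / (1.8308e10 / 3.0 * 100.0)

    Fjunc = 0.11
    Fsl = 1.0 - Fjunc
    Fjunc_CaL = 0.9
    Fsl_CaL = 1.0 - Fjunc_CaL

    # Fixed ionic concentrations
    Cli = 15.0
    Clo = 150.0
    Ko = 5.4
    Nao = 140.0
    Cao = 1.8
    Mgi = 1.0

    GNa = p[0]
    gkr_base = p[1]
    gks_base = p[2]
    pCa = p[3]
    GtoFast = p[4]
    gk1_base = p[5]
    GtoSlow = p[6]
    stim_amp = p[7]
    stim_dur = p[8]
    stim_period = p[9]

    GNaB = 0.597e-3
    IbarNaK = 1.8
    KmNaip = 11.0
    KmKo = 1.5

    pNaK = 0.01833
    gkp = 0.002

    GClCa = 0.5 * 0.109625
    GClB = 9.0e-3
    KdClCa = 100.0e-3

    pNa = 0.50 * 1.5e-8
    pK = 0.50 * 2.7e-7
    Q10CaL = 1.8

    IbarNCX = 4.5
    KmCai = 3.59e-3
    KmCao = 1.3
    KmNai = 12.29
    KmNao = 87.5
    ksat = 0.32
    nu = 0.27
    Kdact = 0.150e-3
    Q10NCX = 1.57
    IbarSLCaP = 0.0673
    KmPCa = 0.5e-3
    GCaB = 5.513e-4
    Q10SLCaP = 2.35

    # SR parameters
    Q10SRCaP = 2.6
    Vmax_SRCaP = 5.3114e-3
    Kmf = 0.246e-3
    Kmr = 1.7
    hillSRCaP = 1.787
    ks = 25.0
    koCa = 10.0
    kom = 0.06
    kiCa = 0.5
    kim = 0.005
    ec50SR = 0.45

    # Buffering parameters
    Bmax_Naj = 7.561
    Bmax_Nasl = 1.65
    koff_na = 1.0e-3
    kon_na = 0.1e-3
    Bmax_TnClow = 70.0e-3
    koff_tncl = 19.6e-3
    kon_tncl = 32.7
    Bmax_TnChigh = 140.0e-3
    koff_tnchca = 0.032e-3
    kon_tnchca = 2.37
    koff_tnchmg = 3.33e-3
    kon_tnchmg = 3.0e-3
    Bmax_CaM = 24.0e-3
    koff_cam = 238.0e-3
    kon_cam = 34.0
    Bmax_myosin = 140.0e-3
    koff_myoca = 0.46e-3
    kon_myoca = 13.8
    koff_myomg = 0.057e-3
    kon_myomg = 0.0157
    Bmax_SR = 19.0 * 0.9e-3
    koff_sr = 60.0e-3
    kon_sr = 100.0
    Bmax_SLlowsl = 37.4e-3 * Vmyo / Vsl
    Bmax_SLlowj = 4.6e-3 * Vmyo / Vjunc * 0.1
    koff_sll = 1300.0e-3
    kon_sll = 100.0
    Bmax_SLhighsl = 13.4e-3 * Vmyo / Vsl
    Bmax_SLhighj = 1.65e-3 * Vmyo / Vjunc * 0.1
    koff_slh = 30.0e-3
    kon_slh = 100.0
    Bmax_Csqn = 140.0e-3 * Vmyo / Vsr
    koff_csqn = 65.0
    kon_csqn = 100.0

    V = y[0]
    m = y[1]
    h = y[2]
    j = y[3]
    d = y[4]
    f = y[5]
    fcaBj = y[6]
    fcaBsl = y[7]
    xtos = y[8]
    ytos = y[9]
    xtof = y[10]
    ytof = y[11]
    xkr = y[12]
    xks = y[13]
    RyRr = y[14]
    RyRo = y[15]
    RyRi = y[16]
    NaBj = y[17]
    NaBsl = y[18]
    TnCL = y[19]
    TnCHc = y[20]
    TnCHm = y[21]
    CaM = y[22]
    Myoc = y[23]
    Myom = y[24]
    SRB = y[25]
    SLLj = y[26]
    SLLsl = y[27]
    SLHj = y[28]
    SLHsl = y[29]
    Csqnb = y[30]
    Casr = y[31]
    Naj = y[32]
    Nasl = y[33]
    Nai = y[34]
    Ki = y[35]
    Caj = y[36]
    Casl = y[37]
    Cai = y[38]

    # Nernst potentials
    ena_junc = (1.0 / FoRT) * np.log(Nao / Naj)
    ena_sl = (1.0 / FoRT) * np.log(Nao / Nasl)
    ek = (1.0 / FoRT) * np.log(Ko / Ki)
    eca_junc = (1.0 / FoRT / 2.0) * np.log(Cao / Caj)
    eca_sl = (1.0 / FoRT / 2.0) * np.log(Cao / Casl)
    ecl = (1.0 / FoRT) * np.log(Cli / Clo)

    # INa gates (ten Tusscher-style)
    mss = 1.0 / (1.0 + np.exp(-(56.86 + V) / 9.03)) ** 2
    taum = 0.1292 * np.exp(-((V + 45.79) / 15.54) ** 2) + 0.06487 * np.exp(-((V - 4.823) / 51.12) ** 2)
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78)) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tauh = 1.0 / (ah + bh)
    hss = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    tauj = 1.0 / (aj + bj)
    jss = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2

    I_Na_junc = Fjunc * GNa * m ** 3 * h * j * (V - ena_junc)
    I_Na_sl = Fsl * GNa * m ** 3 * h * j * (V - ena_sl)

    # Background Na
    I_nabk_junc = Fjunc * GNaB * (V - ena_junc)
    I_nabk_sl = Fsl * GNaB * (V - ena_sl)

    # Na/K pump
    sigma = (np.exp(Nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V * FoRT) + 0.0365 * sigma * np.exp(-V * FoRT))
    I_nak_junc = Fjunc * IbarNaK * fnak * Ko / (1.0 + (KmNaip / Naj) ** 4) / (Ko + KmKo)
    I_nak_sl = Fsl * IbarNaK * fnak * Ko / (1.0 + (KmNaip / Nasl) ** 4) / (Ko + KmKo)
    I_nak = I_nak_junc + I_nak_sl

    # IKr
    gkr = gkr_base * np.sqrt(Ko / 5.4)
    xrss = 1.0 / (1.0 + np.exp(-(V + 10.0) / 5.0))
    tauxr = (550.0 / (1.0 + np.exp((-22.0 - V) / 9.0)) * 6.0 / (1.0 + np.exp((V + 11.0) / 9.0))
             + 230.0 / (1.0 + np.exp((V + 40.0) / 20.0)))
    rkr = 1.0 / (1.0 + np.exp((V + 74.0) / 24.0))
    I_kr = gkr * xkr * rkr * (V - ek)

    # IKs
    eks = (1.0 / FoRT) * np.log((Ko + pNaK * Nao) / (Ki + pNaK * Nai))
    gks_junc = gks_base
    gks_sl = gks_base
    xsss = 1.0 / (1.0 + np.exp(-(V + 3.8) / 14.25))
    tauxs = 990.1 / (1.0 + np.exp(-(V + 2.436) / 14.12))
    I_ks_junc = Fjunc * gks_junc * xks ** 2 * (V - eks)
    I_ks_sl = Fsl * gks_sl * xks ** 2 * (V - eks)
    I_ks = I_ks_junc + I_ks_sl

    # IKp (plateau K)
    kp_kp = 1.0 / (1.0 + np.exp(7.488 - V / 5.98))
    I_kp = gkp * kp_kp * (V - ek)

    # Ito: slow and fast components
    xtoss = 1.0 / (1.0 + np.exp(-(V - 19.0) / 13.0))
    ytoss = 1.0 / (1.0 + np.exp((V + 19.5) / 5.0))
    tauxtos = 9.0 / (1.0 + np.exp((V + 3.0) / 15.0)) + 0.5
    tauytos = 800.0 / (1.0 + np.exp((V + 60.0) / 10.0)) + 30.0
    tauxtof = 8.5 * np.exp(-((V + 45.0) / 50.0) ** 2) + 0.5
    tauytof = 85.0 * np.exp(-((V + 40.0) ** 2) / 220.0) + 7.0
    I_tos = GtoSlow * xtos * ytos * (V - ek)
    I_tof = GtoFast * xtof * ytof * (V - ek)
    I_to = I_tos + I_tof

    # IK1
    aki = 1.02 / (1.0 + np.exp(0.2385 * (V - ek - 59.215)))
    bki = ((0.49124 * np.exp(0.08032 * (V - ek + 5.476))
            + np.exp(0.06175 * (V - ek - 594.31)))
           / (1.0 + np.exp(-0.5143 * (V - ek + 4.753))))
    kiss = aki / (aki + bki)
    I_ki = gk1_base * np.sqrt(Ko / 5.4) * kiss * (V - ek)

    # Ca-activated Cl and background Cl
    I_ClCa_junc = Fjunc * GClCa / (1.0 + KdClCa / Caj) * (V - ecl)
    I_ClCa_sl = Fsl * GClCa / (1.0 + KdClCa / Casl) * (V - ecl)
    I_ClCa = I_ClCa_junc + I_ClCa_sl
    I_Clbk = GClB * (V - ecl)

    # ICaL gates
    dss = 1.0 / (1.0 + np.exp(-(V + 5.0) / 6.0))
    if abs(V + 5.0) < 1e-6:
        taud = 1.0 / (0.035 * 6.0)  # limit of dss*(1-exp(-(V+5)/6))/(0.035*(V+5))
    else:
        taud = dss * (1.0 - np.exp(-(V + 5.0) / 6.0)) / (0.035 * (V + 5.0))
    fss = 1.0 / (1.0 + np.exp((V + 35.0) / 9.0)) + 0.6 / (1.0 + np.exp((50.0 - V) / 20.0))
    tauf = 1.0 / (0.0197 * np.exp(-(0.0337 * (V + 14.5)) ** 2) + 0.02)
    dfcaBj = 1.7 * Caj * (1.0 - fcaBj) - 11.9e-3 * fcaBj
    dfcaBsl = 1.7 * Casl * (1.0 - fcaBsl) - 11.9e-3 * fcaBsl

    if abs(V) < 1e-6:
        ibarca_j = pCa * 2.0 * Frdy * (0.341 * Caj - 0.341 * Cao)
        ibarca_sl = pCa * 2.0 * Frdy * (0.341 * Casl - 0.341 * Cao)
        ibark = pK * Frdy * (0.75 * Ki - 0.75 * Ko)
        ibarna_j = pNa * Frdy * (0.75 * Naj - 0.75 * Nao)
        ibarna_sl = pNa * Frdy * (0.75 * Nasl - 0.75 * Nao)
    else:
        ibarca_j = (pCa * 4.0 * (V * Frdy * FoRT)
                    * (0.341 * Caj * np.exp(2.0 * V * FoRT) - 0.341 * Cao)
                    / (np.exp(2.0 * V * FoRT) - 1.0))
        ibarca_sl = (pCa * 4.0 * (V * Frdy * FoRT)
                     * (0.341 * Casl * np.exp(2.0 * V * FoRT) - 0.341 * Cao)
                     / (np.exp(2.0 * V * FoRT) - 1.0))
        ibark = (pK * (V * Frdy * FoRT)
                 * (0.75 * Ki * np.exp(V * FoRT) - 0.75 * Ko)
                 / (np.exp(V * FoRT) - 1.0))
        ibarna_j = (pNa * (V * Frdy * FoRT)
                    * (0.75 * Naj * np.exp(V * FoRT) - 0.75 * Nao)
                    / (np.exp(V * FoRT) - 1.0))
        ibarna_sl = (pNa * (V * Frdy * FoRT)
                     * (0.75 * Nasl * np.exp(V * FoRT) - 0.75 * Nao)
                     / (np.exp(V * FoRT) - 1.0))
    q10f = Q10CaL ** Qpow
    I_Ca_junc = Fjunc_CaL * ibarca_j * d * f * (1.0 - fcaBj) * q10f * 0.45
    I_Ca_sl = Fsl_CaL * ibarca_sl * d * f * (1.0 - fcaBsl) * q10f * 0.45
    I_CaK = ibark * d * f * (Fjunc_CaL * (1.0 - fcaBj) + Fsl_CaL * (1.0 - fcaBsl)) * q10f * 0.45
    I_CaNa_junc = Fjunc_CaL * ibarna_j * d * f * (1.0 - fcaBj) * q10f * 0.45
    I_CaNa_sl = Fsl_CaL * ibarna_sl * d * f * (1.0 - fcaBsl) * q10f * 0.45

    # Na/Ca exchanger
    Ka_junc = 1.0 / (1.0 + (Kdact / Caj) ** 2)
    Ka_sl = 1.0 / (1.0 + (Kdact / Casl) ** 2)
    s1_junc = np.exp(nu * V * FoRT) * Naj ** 3 * Cao
    s1_sl = np.exp(nu * V * FoRT) * Nasl ** 3 * Cao
    s2_junc = np.exp((nu - 1.0) * V * FoRT) * Nao ** 3 * Caj
    s3_junc = (KmCai * Nao ** 3 * (1.0 + (Naj / KmNai) ** 3)
               + KmNao ** 3 * Caj * (1.0 + Caj / KmCai)
               + KmCao * Naj ** 3 + Naj ** 3 * Cao + Nao ** 3 * Caj)
    s2_sl = np.exp((nu - 1.0) * V * FoRT) * Nao ** 3 * Casl
    s3_sl = (KmCai * Nao ** 3 * (1.0 + (Nasl / KmNai) ** 3)
             + KmNao ** 3 * Casl * (1.0 + Casl / KmCai)
             + KmCao * Nasl ** 3 + Nasl ** 3 * Cao + Nao ** 3 * Casl)
    q10n = Q10NCX ** Qpow
    I_ncx_junc = (Fjunc * IbarNCX * q10n * Ka_junc * (s1_junc - s2_junc) / s3_junc
                  / (1.0 + ksat * np.exp((nu - 1.0) * V * FoRT)))
    I_ncx_sl = (Fsl * IbarNCX * q10n * Ka_sl * (s1_sl - s2_sl) / s3_sl
                / (1.0 + ksat * np.exp((nu - 1.0) * V * FoRT)))

    # Sarcolemmal Ca pump
    I_pca_junc = Fjunc * Q10SLCaP ** Qpow * IbarSLCaP * Caj ** 1.6 / (KmPCa ** 1.6 + Caj ** 1.6)
    I_pca_sl = Fsl * Q10SLCaP ** Qpow * IbarSLCaP * Casl ** 1.6 / (KmPCa ** 1.6 + Casl ** 1.6)

    # Background Ca
    I_cabk_junc = Fjunc * GCaB * (V - eca_junc)
    I_cabk_sl = Fsl * GCaB * (V - eca_sl)

    # SR fluxes
    MaxSR = 15.0
    MinSR = 1.0
    kCaSR = MaxSR - (MaxSR - MinSR) / (1.0 + (ec50SR / Casr) ** 2.5)
    koSRCa = koCa / kCaSR
    kiSRCa = kiCa * kCaSR
    RI = 1.0 - RyRr - RyRo - RyRi
    dRyRr = (kim * RI - kiSRCa * Caj * RyRr) - (koSRCa * Caj ** 2 * RyRr - kom * RyRo)
    dRyRo = (koSRCa * Caj ** 2 * RyRr - kom * RyRo) - (kiSRCa * Caj * RyRo - kim * RyRi)
    dRyRi = (kiSRCa * Caj * RyRo - kim * RyRi) - (kom * RyRi - koSRCa * Caj ** 2 * RI)
    J_SRCarel = ks * RyRo * (Casr - Caj)
    J_serca = (Q10SRCaP ** Qpow * Vmax_SRCaP
               * ((Cai / Kmf) ** hillSRCaP - (Casr / Kmr) ** hillSRCaP)
               / (1.0 + (Cai / Kmf) ** hillSRCaP + (Casr / Kmr) ** hillSRCaP))
    J_SRleak = 5.348e-6 * (Casr - Caj)

    # Na buffering
    dNaBj = kon_na * Naj * (Bmax_Naj - NaBj) - koff_na * NaBj
    dNaBsl = kon_na * Nasl * (Bmax_Nasl - NaBsl) - koff_na * NaBsl

    # Cytosolic Ca buffers
    dTnCL = kon_tncl * Cai * (Bmax_TnClow - TnCL) - koff_tncl * TnCL
    dTnCHc = kon_tnchca * Cai * (Bmax_TnChigh - TnCHc - TnCHm) - koff_tnchca * TnCHc
    dTnCHm = kon_tnchmg * Mgi * (Bmax_TnChigh - TnCHc - TnCHm) - koff_tnchmg * TnCHm
    dCaM = kon_cam * Cai * (Bmax_CaM - CaM) - koff_cam * CaM
    dMyoc = kon_myoca * Cai * (Bmax_myosin - Myoc - Myom) - koff_myoca * Myoc
    dMyom = kon_myomg * Mgi * (Bmax_myosin - Myoc - Myom) - koff_myomg * Myom
    dSRB = kon_sr * Cai * (Bmax_SR - SRB) - koff_sr * SRB
    J_CaB_cytosol = dTnCL + dTnCHc + dCaM + dMyoc + dSRB

    # Junctional and SL Ca buffers
    dSLLj = kon_sll * Caj * (Bmax_SLlowj - SLLj) - koff_sll * SLLj
    dSLLsl = kon_sll * Casl * (Bmax_SLlowsl - SLLsl) - koff_sll * SLLsl
    dSLHj = kon_slh * Caj * (Bmax_SLhighj - SLHj) - koff_slh * SLHj
    dSLHsl = kon_slh * Casl * (Bmax_SLhighsl - SLHsl) - koff_slh * SLHsl
    J_CaB_junction = dSLLj + dSLHj
    J_CaB_sl = dSLLsl + dSLHsl

    # SR Ca concentration
    dCsqnb = kon_csqn * Casr * (Bmax_Csqn - Csqnb) - koff_csqn * Csqnb
    dCasr = J_serca - (J_SRleak * Vmyo / Vsr + J_SRCarel) - dCsqnb

    # Stimulus (depolarising, applied as in the published code: dV += I_app)
    tmod = t % stim_period
    I_app = stim_amp if tmod < stim_dur else 0.0

    # Sodium concentrations
    I_Na_tot_junc = I_Na_junc + I_nabk_junc + 3.0 * I_ncx_junc + 3.0 * I_nak_junc + I_CaNa_junc
    I_Na_tot_sl = I_Na_sl + I_nabk_sl + 3.0 * I_ncx_sl + 3.0 * I_nak_sl + I_CaNa_sl
    dNaj = (-I_Na_tot_junc * Cmem / (Vjunc * Frdy)
            + J_na_juncsl / Vjunc * (Nasl - Naj) - dNaBj)
    dNasl = (-I_Na_tot_sl * Cmem / (Vsl * Frdy)
             + J_na_juncsl / Vsl * (Naj - Nasl)
             + J_na_slmyo / Vsl * (Nai - Nasl) - dNaBsl)
    dNai = J_na_slmyo / Vmyo * (Nasl - Nai)

    # Potassium concentration (clamped in the published implementation)
    dKi = 0.0

    # Calcium concentrations
    I_Ca_tot_junc = I_Ca_junc + I_cabk_junc + I_pca_junc - 2.0 * I_ncx_junc
    I_Ca_tot_sl = I_Ca_sl + I_cabk_sl + I_pca_sl - 2.0 * I_ncx_sl
    dCaj = (-I_Ca_tot_junc * Cmem / (Vjunc * 2.0 * Frdy)
            + J_ca_juncsl / Vjunc * (Casl - Caj) - J_CaB_junction
            + J_SRCarel * Vsr / Vjunc + J_SRleak * Vmyo / Vjunc)
    dCasl = (-I_Ca_tot_sl * Cmem / (Vsl * 2.0 * Frdy)
             + J_ca_juncsl / Vsl * (Caj - Casl)
             + J_ca_slmyo / Vsl * (Cai - Casl) - J_CaB_sl)
    dCai = (-J_serca * Vsr / Vmyo - J_CaB_cytosol
            + J_ca_slmyo / Vmyo * (Casl - Cai))

    # Membrane potential
    I_Na_tot = I_Na_tot_junc + I_Na_tot_sl
    I_Cl_tot = I_ClCa + I_Clbk
    I_Ca_tot = I_Ca_tot_junc + I_Ca_tot_sl
    I_K_tot = I_to + I_kr + I_ks + I_ki - 2.0 * I_nak + I_CaK + I_kp
    I_tot = I_Na_tot + I_Cl_tot + I_Ca_tot + I_K_tot
    dV = -(I_tot - I_app)

    dy = np.empty(39)
    dy[0] = dV
    dy[1] = (mss - m) / taum
    dy[2] = (hss - h) / tauh
    dy[3] = (jss - j) / tauj
    dy[4] = (dss - d) / taud
    dy[5] = (fss - f) / tauf
    dy[6] = dfcaBj
    dy[7] = dfcaBsl
    dy[8] = (xtoss - xtos) / tauxtos
    dy[9] = (ytoss - ytos) / tauytos
    dy[10] = (xtoss - xtof) / tauxtof
    dy[11] = (ytoss - ytof) / tauytof
    dy[12] = (xrss - xkr) / tauxr
    dy[13] = (xsss - xks) / tauxs
    dy[14] = dRyRr
    dy[15] = dRyRo
    dy[16] = dRyRi
    dy[17] = dNaBj
    dy[18] = dNaBsl
    dy[19] = dTnCL
    dy[20] = dTnCHc
    dy[21] = dTnCHm
    dy[22] = dCaM
    dy[23] = dMyoc
    dy[24] = dMyom
    dy[25] = dSRB
    dy[26] = dSLLj
    dy[27] = dSLLsl
    dy[28] = dSLHj
    dy[29] = dSLHsl
    dy[30] = dCsqnb
    dy[31] = dCasr
    dy[32] = dNaj
    dy[33] = dNasl
    dy[34] = dNai
    dy[35] = dKi
    dy[36] = dCaj
    dy[37] = dCasl
    dy[38] = dCai
    return dy
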