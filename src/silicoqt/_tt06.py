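"""ten Tusscher & Panfilov (2006) human ventricular myocyte model, epicardial.

Transcription of the published ODE system (19 state variables: membrane
potential, 12 Hodgkin–Huxley gates, SR release adaptation, and 5
concentrations).  Maximal conductances that the pipeline may scale are carried
in the parameter vector; all other constants are inlined.

State layout (index: name, unit):
  0 V (mV), 1 m, 2 h, 3 j, 4 d, 5 f, 6 f2, 7 fCass, 8 r, 9 s,
  10 xr1, 11 xr2, 12 xs, 13 Rbar (SR release adaptation),
  14 Cai (mM), 15 CaSR (mM), 16 Cass (mM), 17 Nai (mM), 18 Ki (mM)
"""

from __future__ import annotations

import numpy as np
from numba import njit

NAME = "tentusscher2006"
CELL_VARIANT = "epicardial"
CITATION = "ten Tusscher KHWJ & Panfilov AV (2006) Am J Physiol 291:H1088-H1100 (epicardial)"
N_STATE = 19
V_INDEX = 0

STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s",
    "xr1", "xr2", "xs", "Rbar", "Cai", "CaSR", "Cass", "Nai", "Ki",
)

# Scalable maximal conductances (model-native units), then stimulus.
PARAM_NAMES = ("GNa", "GKr", "GKs", "GCaL", "Gto", "GK1",
               "stim_amplitude", "stim_duration", "stim_period")
HANDLES = {"INa": 0, "IKr": 1, "IKs": 2, "ICaL": 3, "Ito": 4, "IK1": 5}

P0 = np.array([
    14.838,     # GNa  nS/pF
    0.153,      # GKr  nS/pF
    0.392,      # GKs  nS/pF (epi)
    3.980e-5,   # GCaL cm^3 uF^-1 ms^-1
    0.294,      # Gto  nS/pF (epi)
    5.405,      # GK1  nS/pF
    -52.0,      # stimulus amplitude uA/uF (depolarising)
    1.0,        # stimulus duration ms
    1000.0,     # stimulus period ms
])

# Published epicardial initial conditions (resting, 1 Hz).
Y0 = np.array([
    -85.23,      # V
    1.72e-3,     # m
    7.444e-1,    # h
    7.045e-1,    # j
    3.373e-5,    # d
    7.888e-1,    # f
    9.755e-1,    # f2
    9.953e-1,    # fCass
    2.42e-8,     # r
    9.99998e-1,  # s
    6.21e-3,     # xr1
    4.712e-1,    # xr2
    3.03e-3,     # xs
    9.073e-1,    # Rbar
    1.26e-4,     # Cai
    3.64,        # CaSR
    3.6e-4,      # Cass
    8.604,       # Nai
    136.89,      # Ki
])

GATE_INDICES = tuple(range(1, 14))  # m..Rbar are bounded in [0,1]


@njit(cache=True)
def rhs(t, y, p):
    # Physical constants and fixed parameters
    R = 8314.472
    T = 310.0
    F = 96485.3415
    RTF = R * T / F
    Cm = 0.185          # uF ... membrane capacitance per cell volume scaling
    Vc = 0.016404       # cytoplasmic volume (units consistent with Cm)
    Vsr = 0.001094
    Vss = 0.00005468
    Ko = 5.4
    Nao = 140.0
    Cao = 2.0
    pKNa = 0.03

    GNa = p[0]
    GKr = p[1]
    GKs = p[2]
    GCaL = p[3]
    Gto = p[4]
    GK1 = p[5]
    stim_amp = p[6]
    stim_dur = p[7]
    stim_period = p[8]

    GpCa = 0.1238
    KpCa = 0.0005
    GpK = 0.0146
    GbNa = 0.00029
    GbCa = 0.000592
    PNaK = 2.724
    KmK = 1.0
    KmNa = 40.0
    kNaCa = 1000.0
    Ksat = 0.1
    alpha_ncx = 2.5
    gamma_ncx = 0.35
    KmCa = 1.38
    KmNai = 87.5
    Vmaxup = 0.006375
    Kup = 0.00025
    Vrel = 0.102
    k1p = 0.15
    k2p = 0.045
    k3 = 0.060
    k4 = 0.005
    EC = 1.5
    max_sr = 2.5
    min_sr = 1.0
    Vleak = 0.00036
    Vxfer = 0.0038
    Bufc = 0.2
    Kbufc = 0.001
    Bufsr = 10.0
    Kbufsr = 0.3
    Bufss = 0.4
    Kbufss = 0.00025

    V = y[0]
    m = y[1]
    h = y[2]
    j = y[3]
    d = y[4]
    f = y[5]
    f2 = y[6]
    fCass = y[7]
    r = y[8]
    s = y[9]
    xr1 = y[10]
    xr2 = y[11]
    xs = y[12]
    Rbar = y[13]
    Cai = y[14]
    CaSR = y[15]
    Cass = y[16]
    Nai = y[17]
    Ki = y[18]

    ENa = RTF * np.log(Nao / Nai)
    EK = RTF * np.log(Ko / Ki)
    EKs = RTF * np.log((Ko + pKNa * Nao) / (Ki + pKNa * Nai))
    ECa = 0.5 * RTF * np.log(Cao / Cai)

    # Fast sodium current
    INa = GNa * m ** 3 * h * j * (V - ENa)
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau_m = am * bm
    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    tau_h = 1.0 / (ah + bh)
    j_inf = h_inf
    if V < -40.0:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78)) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    tau_j = 1.0 / (aj + bj)

    # L-type calcium current (GHK-like driving term about +15 mV)
    vf = (V - 15.0) * F / (R * T)
    if abs(V - 15.0) < 1e-6:
        ICaL = GCaL * d * f * f2 * fCass * 2.0 * F * (0.25 * Cass - Cao)  # limit of the GHK term
    else:
        ICaL = (GCaL * d * f * f2 * fCass * 4.0 * (V - 15.0) * F ** 2 / (R * T)
                * (0.25 * Cass * np.exp(2.0 * vf) - Cao) / (np.exp(2.0 * vf) - 1.0))
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau_d = ad * bd + gd
    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    fCass_inf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    tau_fCass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0

    # Transient outward (epicardial r/s gates)
    Ito = Gto * r * s * (V - EK)
    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    tau_s = (85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
             + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)

    # Rapid delayed rectifier
    IKr = GKr * np.sqrt(Ko / 5.4) * xr1 * xr2 * (V - EK)
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1
    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2

    # Slow delayed rectifier
    IKs = GKs * xs ** 2 * (V - EKs)
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0

    # Inward rectifier
    aK1 = 0.1 / (1.0 + np.exp(0.06 * (V - EK - 200.0)))
    bK1 = ((3.0 * np.exp(0.0002 * (V - EK + 100.0)) + np.exp(0.1 * (V - EK - 10.0)))
           / (1.0 + np.exp(-0.5 * (V - EK))))
    xK1_inf = aK1 / (aK1 + bK1)
    IK1 = GK1 * np.sqrt(Ko / 5.4) * xK1_inf * (V - EK)

    # Exchangers, pumps, backgrounds
    vfrt = V * F / (R * T)
    INaCa = (kNaCa
             * (np.exp(gamma_ncx * vfrt) * Nai ** 3 * Cao
                - np.exp((gamma_ncx - 1.0) * vfrt) * Nao ** 3 * Cai * alpha_ncx)
             / ((KmNai ** 3 + Nao ** 3) * (KmCa + Cao)
                * (1.0 + Ksat * np.exp((gamma_ncx - 1.0) * vfrt))))
    INaK = (PNaK * Ko * Nai
            / ((Ko + KmK) * (Nai + KmNa)
               * (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt))))
    IpCa = GpCa * Cai / (KpCa + Cai)
    IpK = GpK * (V - EK) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = GbNa * (V - ENa)
    IbCa = GbCa * (V - ECa)

    # Stimulus
    tm = t % stim_period
    Istim = stim_amp if tm < stim_dur else 0.0

    # Calcium handling
    kcasr = max_sr - (max_sr - min_sr) / (1.0 + (EC / CaSR) ** 2)
    k1 = k1p / kcasr
    k2 = k2p * kcasr
    O = k1 * Cass ** 2 * Rbar / (k3 + k1 * Cass ** 2)
    Irel = Vrel * O * (CaSR - Cass)
    Ileak = Vleak * (CaSR - Cai)
    Iup = Vmaxup / (1.0 + Kup ** 2 / Cai ** 2)
    Ixfer = Vxfer * (Cass - Cai)

    dRbar = -k2 * Cass * Rbar + k4 * (1.0 - Rbar)

    Cai_buf = 1.0 / (1.0 + Bufc * Kbufc / (Cai + Kbufc) ** 2)
    Casr_buf = 1.0 / (1.0 + Bufsr * Kbufsr / (CaSR + Kbufsr) ** 2)
    Cass_buf = 1.0 / (1.0 + Bufss * Kbufss / (Cass + Kbufss) ** 2)

    dCai = Cai_buf * ((Ileak - Iup) * Vsr / Vc + Ixfer
                      - (IbCa + IpCa - 2.0 * INaCa) * Cm / (2.0 * Vc * F))
    dCaSR = Casr_buf * (Iup - Irel - Ileak)
    dCass = Cass_buf * (-ICaL * Cm / (2.0 * Vss * F) + Irel * Vsr / Vss - Ixfer * Vc / Vss)

    dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * Cm / (Vc * F)
    dKi = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK + Istim) * Cm / (Vc * F)

    dV = -(IK1 + Ito + IKr + IKs + ICaL + INaK + INa + IbNa + INaCa + IbCa + IpK + IpCa + Istim)

    dy = np.empty(19)
    dy[0] = dV
    dy[1] = (m_inf - m) / tau_m
    dy[2] = (h_inf - h) / tau_h
    dy[3] = (j_inf - j) / tau_j
    dy[4] = (d_inf - d) / tau_d
    dy[5] = (f_inf - f) / tau_f
    dy[6] = (f2_inf - f2) / tau_f2
    dy[7] = (fCass_inf - fCass) / tau_fCass
    dy[8] = (r_inf - r) / tau_r
    dy[9] = (s_inf - s) / tau_s
    dy[10] = (xr1_inf - xr1) / tau_xr1
    dy[11] = (xr2_inf - xr2) / tau_xr2
    dy[12] = (xs_inf - xs) / tau_xs
    dy[13] = dRbar
    dy[14] = dCai
    dy[15] = dCaSR
    dy[16] = dCass
    dy[17] = dNai
    dy[18] = dKi
    return dy
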