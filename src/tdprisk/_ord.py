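"""O'Hara-Rudy (ORd) human ventricular myocyte model — numba kernel.

Full 41-state ORd dynamic model (fast/late Na+, transient-outward, L-type
Ca2+, rapid/slow delayed-rectifier and inward-rectifier K+ currents, NCX,
NaK pump, SR release/uptake, CaMK signalling) with per-channel conductance
multipliers for static drug block and the CiPA conductance re-optimization
of IKr, IKs, IK1, ICaL and INaL.

The single algebra routine ``_compute`` fills, for one state vector:
  * dy    — time derivatives of the non-gate states (V, 8 concentrations,
            CaMK trap),
  * gss/gtau — steady-state value and time constant for every gating state
            (indices 9..39), consumed by the Rush-Larsen exponential update,
  * cur   — the individual ionic currents for diagnostics.

State vector layout (units mV, mM, dimensionless):
   0 v     1 nai   2 nass  3 ki    4 kss   5 cai   6 cass  7 cansr 8 cajsr
   9 m    10 hf   11 hs   12 j    13 hsp  14 jp   15 mL   16 hL   17 hLp
  18 a    19 iF   20 iS   21 ap   22 iFp  23 iSp  24 d    25 ff   26 fs
  27 fcaf 28 fcas 29 jca  30 nca  31 ffp  32 fcafp 33 xrf 34 xrs  35 xs1
  36 xs2  37 xk1  38 Jrelnp 39 Jrelp 40 CaMKt
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATES = 41

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp", "d", "ff", "fs",
    "fcaf", "fcas", "jca", "nca", "ffp", "fcafp", "xrf", "xrs", "xs1",
    "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
)

# gating states updated by Rush-Larsen (have a (steady state, tau) form)
GATE_LO, GATE_HI = 9, 40  # indices 9..39 inclusive

# Published model initial conditions (endocardial cell, drug free).
INITIAL_STATE = np.array([
    -87.5, 7.0, 7.0, 145.0, 145.0, 1.0e-4, 1.0e-4, 1.2, 1.2,
    0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 1.0, 1.0,
    0.0, 1.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 1.0,
    1.0, 1.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0,
    0.0, 1.0, 0.0, 0.0, 0.0,
])

CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "IKb", "IpCa", "ICab",
    "Jrel", "Jup",
)
N_CURRENTS = len(CURRENT_NAMES)

# params vector layout consumed by the kernel (assembled in cell_sim from
# base conductances x cell-type factor x CiPA rescale x drug scale)
PARAM_NAMES = (
    "GNa", "GNaL", "PCa", "GKr", "GKs", "GK1", "Gto",       # drug targets
    "Gncx", "Pnak", "GKb", "PNab", "PCab", "GpCa",
    "cmdnmax", "jrel_scale", "jup_scale", "epi_ito_flag",
)
N_PARAMS = len(PARAM_NAMES)


@njit(cache=True)
def _compute(y, ist, p, dy, gss, gtau, cur):  # pragma: no cover - numba
    # extracellular concentrations and physical constants
    nao = 140.0
    cao = 1.8
    ko = 5.4
    R = 8314.0
    T = 310.0
    F = 96485.0

    # cell geometry
    L = 0.01
    rad = 0.0011
    vcell = 1000.0 * 3.14 * rad * rad * L
    Ageo = 2.0 * 3.14 * rad * rad + 2.0 * 3.14 * rad * L
    Acap = 2.0 * Ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    m = y[9]
    hf = y[10]
    hs = y[11]
    j = y[12]
    hsp = y[13]
    jp = y[14]
    mL = y[15]
    hL = y[16]
    hLp = y[17]
    a = y[18]
    iF = y[19]
    iS = y[20]
    ap = y[21]
    iFp = y[22]
    iSp = y[23]
    d = y[24]
    ff = y[25]
    fs = y[26]
    fcaf = y[27]
    fcas = y[28]
    jca = y[29]
    nca = y[30]
    ffp = y[31]
    fcafp = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    xk1 = y[37]
    Jrelnp = y[38]
    Jrelp = y[39]
    CaMKt = y[40]

    GNa = p[0]
    GNaL = p[1]
    PCa = p[2]
    GKr = p[3]
    GKs = p[4]
    GK1 = p[5]
    Gto = p[6]
    Gncx = p[7]
    Pnak = p[8]
    GKb = p[9]
    PNab = p[10]
    PCab = p[11]
    GpCa = p[12]
    cmdnmax = p[13]
    jrel_scale = p[14]
    jup_scale = p[15]
    epi_flag = p[16]

    # CaMK signalling
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt
    fp_frac = 1.0 / (1.0 + KmCaMK / CaMKa)  # CaMK-phosphorylated fraction

    # reversal potentials
    ENa = (R * T / F) * math.log(nao / nai)
    EK = (R * T / F) * math.log(ko / ki)
    PKNa = 0.01833
    EKs = (R * T / F) * math.log((ko + PKNa * nao) / (ki + PKNa * nai))
    vfrt = v * F / (R * T)
    vffrt = v * F * F / (R * T)

    # INa (fast sodium)
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    INa = (GNa * (v - ENa) * m * m * m
           * ((1.0 - fp_frac) * h * j + fp_frac * hp * jp))
    gss[9] = mss; gtau[9] = tm
    gss[10] = hss; gtau[10] = thf
    gss[11] = hss; gtau[11] = ths
    gss[12] = jss; gtau[12] = tj
    gss[13] = hssp; gtau[13] = thsp
    gss[14] = jss; gtau[14] = tjp

    # INaL (late sodium)
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tmL = tm
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fp_frac) * hL + fp_frac * hLp)
    gss[15] = mLss; gtau[15] = tmL
    gss[16] = hLss; gtau[16] = thL
    gss[17] = hLssp; gtau[17] = thLp

    # Ito (transient outward K+)
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if epi_flag > 0.5:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ip = AiF * iFp + AiS * iSp
    Ito = (Gto * (v - EK)
           * ((1.0 - fp_frac) * a * i_gate + fp_frac * ap * ip))
    gss[18] = ass; gtau[18] = ta
    gss[19] = iss; gtau[19] = tiF
    gss[20] = iss; gtau[20] = tiS
    gss[21] = assp; gtau[21] = ta
    gss[22] = iss; gtau[22] = tiFp
    gss[23] = iss; gtau[23] = tiSp

    # ICaL / ICaNa / ICaK (L-type channel)
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                           + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    tffp = 2.5 * tff
    fp = Aff * ffp + Afs * fs
    tfcafp = 2.5 * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    # nca relaxes toward anca*k2n/km2n with rate km2n
    gss[30] = anca * k2n / km2n
    gtau[30] = 1.0 / km2n

    x2 = 2.0 * vfrt
    if abs(x2) < 1.0e-7:
        e2m1 = x2 * (1.0 + 0.5 * x2)
    else:
        e2m1 = math.exp(x2) - 1.0
    if abs(vfrt) < 1.0e-7:
        e1m1 = vfrt * (1.0 + 0.5 * vfrt)
    else:
        e1m1 = math.exp(vfrt) - 1.0
    PhiCaL = 4.0 * vffrt * (cass * math.exp(x2) - 0.341 * cao) / e2m1
    PhiCaNa = vffrt * (0.75 * nass * math.exp(vfrt) - 0.75 * nao) / e1m1
    PhiCaK = vffrt * (0.75 * kss * math.exp(vfrt) - 0.75 * ko) / e1m1
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fp_frac) * PCa * PhiCaL * gate_np + fp_frac * PCap * PhiCaL * gate_p
    ICaNa = ((1.0 - fp_frac) * PCaNa * PhiCaNa * gate_np
             + fp_frac * PCaNap * PhiCaNa * gate_p)
    ICaK = ((1.0 - fp_frac) * PCaK * PhiCaK * gate_np
            + fp_frac * PCaKp * PhiCaK * gate_p)
    gss[24] = dss; gtau[24] = td
    gss[25] = fss; gtau[25] = tff
    gss[26] = fss; gtau[26] = tfs
    gss[27] = fcass; gtau[27] = tfcaf
    gss[28] = fcass; gtau[28] = tfcas
    gss[29] = fcass; gtau[29] = tjca
    gss[31] = fss; gtau[31] = tffp
    gss[32] = fcass; gtau[32] = tfcafp

    # IKr (rapid delayed rectifier)
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))
           * 1.0 / (1.0 + math.exp((v - 10.0) / 30.0)))
    IKr = GKr * math.sqrt(ko / 5.4) * xr * rkr * (v - EK)
    gss[33] = xrss; gtau[33] = txrf
    gss[34] = xrss; gtau[34] = txrs

    # IKs (slow delayed rectifier)
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)
    gss[35] = xs1ss; gtau[35] = txs1
    gss[36] = xs2ss; gtau[36] = txs2

    # IK1 (inward rectifier)
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59)
                                  / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    IK1 = GK1 * math.sqrt(ko) * rk1 * xk1 * (v - EK)
    gss[37] = xk1ss; gtau[37] = txk1

    # INaCa (Na+/Ca2+ exchanger, myoplasmic and subspace components)
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    zca = 2.0
    zna = 1.0
    KmCaAct = 150.0e-6

    # myoplasmic
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p_ = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p_ + k3pp
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1_ = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2_ = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3_ = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4_ = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1_ / (x1_ + x2_ + x3_ + x4_)
    E2 = x2_ / (x1_ + x2_ + x3_ + x4_)
    E3 = x3_ / (x1_ + x2_ + x3_ + x4_)
    E4 = x4_ / (x1_ + x2_ + x3_ + x4_)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1_ = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2_ = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3_ = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4_ = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1_ / (x1_ + x2_ + x3_ + x4_)
    E2 = x2_ / (x1_ + x2_ + x3_ + x4_)
    E3 = x3_ / (x1_ + x2_ + x3_ + x4_)
    E4 = x4_ / (x1_ + x2_ + x3_ + x4_)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # INaK (Na+/K+ pump)
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_ = 1899.0
    k3m = 79300.0
    k4p_ = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.155
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    Knai = Knai0 * math.exp(delta * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3
          / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0))
    a3 = (k3p_ * (ko / Kko) ** 2
          / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0))
    b3 = k3m * P * H / (1.0 + MgATP / Kmgatp)
    a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * ki * ki / (Kki * Kki)
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    x1_ = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2_ = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3_ = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4_ = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1_ / (x1_ + x2_ + x3_ + x4_)
    E2 = x2_ / (x1_ + x2_ + x3_ + x4_)
    E3 = x3_ / (x1_ + x2_ + x3_ + x4_)
    E4 = x4_ / (x1_ + x2_ + x3_ + x4_)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # background / pump currents
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    IKb = GKb * xkb * (v - EK)
    INab = PNab * vffrt * (nai * math.exp(vfrt) - nao) / e1m1
    ICab = PCab * 4.0 * vffrt * (cai * math.exp(x2) - 0.341 * cao) / e2m1
    IpCa = GpCa * cai / (0.0005 + cai)

    # diffusion fluxes between subspace and myoplasm
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # SR calcium release (RyR), CaMK-dependent component
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = jrel_scale * a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = jrel_scale * a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    Jrel = (1.0 - fp_frac) * Jrelnp + fp_frac * Jrelp
    gss[38] = Jrel_inf; gtau[38] = tau_rel
    gss[39] = Jrel_infp; gtau[39] = tau_relp

    # SR calcium uptake (SERCA) and translocation
    Jupnp = jup_scale * 0.004375 * cai / (cai + 0.00092)
    Jupp = jup_scale * 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fp_frac) * Jupnp + fp_frac * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # membrane potential
    dy[0] = -(INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
              + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + ist)

    # intracellular concentrations (with Ca2+ buffering)
    dy[1] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * Acap
             / (F * vmyo) + JdiffNa * vss / vmyo)
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * Acap / (F * vss) - JdiffNa
    dy[3] = (-(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK) * Acap
             / (F * vmyo) + JdiffK * vss / vmyo)
    dy[4] = -ICaK * Acap / (F * vss) - JdiffK

    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * Acap / (2.0 * F * vmyo)
                    - Jup * vnsr / vmyo + Jdiff * vss / vmyo)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dy[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * Acap / (2.0 * F * vss)
                     + Jrel * vjsr / vss - Jdiff)
    dy[7] = Jup - Jtr * vjsr / vnsr
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = Bcajsr * (Jtr - Jrel)

    cur[0] = INa
    cur[1] = INaL
    cur[2] = Ito
    cur[3] = ICaL
    cur[4] = ICaNa
    cur[5] = ICaK
    cur[6] = IKr
    cur[7] = IKs
    cur[8] = IK1
    cur[9] = INaCa_i
    cur[10] = INaCa_ss
    cur[11] = INaK
    cur[12] = INab
    cur[13] = IKb
    cur[14] = IpCa
    cur[15] = ICab
    cur[16] = Jrel
    cur[17] = Jup


@njit(cache=True)
def rhs(y, ist, p):  # pragma: no cover - numba
    """Full derivative vector (gates converted from (ss, tau) form)."""
    dy = np.zeros(N_STATES)
    gss = np.zeros(N_STATES)
    gtau = np.ones(N_STATES)
    cur = np.zeros(N_CURRENTS)
    _compute(y, ist, p, dy, gss, gtau, cur)
    for i in range(GATE_LO, GATE_HI):
        dy[i] = (gss[i] - y[i]) / gtau[i]
    return dy


@njit(cache=True)
def currents(y, ist, p):  # pragma: no cover - numba
    dy = np.zeros(N_STATES)
    gss = np.zeros(N_STATES)
    gtau = np.ones(N_STATES)
    cur = np.zeros(N_CURRENTS)
    _compute(y, ist, p, dy, gss, gtau, cur)
    return cur


@njit(cache=True)
def pace(y, n_beats, cl, dt, rec_dt, stim_amp, stim_dur, p, record_v,
         fine_window, fine_substeps):  # pragma: no cover - numba
    """Paced fixed-step integration: forward Euler for V, concentrations and
    CaMK trap; Rush-Larsen exponential update for every gating state.

    The stimulus/upstroke window (first ``fine_window`` ms of each cycle)
    is integrated with ``fine_substeps`` substeps per dt: the ~1 ms Na+
    upstroke is the one phase where dV/dt outruns the base step.

    Mutates ``y`` in place.  Returns (recorded V [n_beats x n_rec],
    per-beat end-state snapshot [n_beats x N_STATES], status).  status is 0
    on success, or 1-based beat index of a numerical blowup.
    """
    nsteps = int(round(cl / dt))
    rec_every = int(round(rec_dt / dt))
    nrec = int(round(cl / rec_dt))
    if record_v:
        out = np.empty((n_beats, nrec))
    else:
        out = np.empty((0, 0))
    snaps = np.empty((n_beats, N_STATES))
    dy = np.zeros(N_STATES)
    gss = np.zeros(N_STATES)
    gtau = np.ones(N_STATES)
    cur = np.zeros(N_CURRENTS)
    status = 0
    for b in range(n_beats):
        for k in range(nsteps):
            if record_v and (k % rec_every == 0):
                out[b, k // rec_every] = y[0]
            t = k * dt
            sub = fine_substeps if t < fine_window else 1
            h = dt / sub
            for s in range(sub):
                ts = t + s * h
                ist = stim_amp if ts < stim_dur - 1.0e-9 else 0.0
                _compute(y, ist, p, dy, gss, gtau, cur)
                for i in range(9):
                    y[i] += h * dy[i]
                y[40] += h * dy[40]
                for i in range(GATE_LO, GATE_HI):
                    y[i] = gss[i] + (y[i] - gss[i]) * math.exp(-h / gtau[i])
        snaps[b, :] = y
        if (not np.isfinite(y[0])) or y[0] < -150.0 or y[0] > 100.0:
            status = b + 1
            break
    return out, snaps, status
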