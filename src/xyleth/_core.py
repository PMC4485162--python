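"""Jitted numerical core of the coupled PBPK model.

Everything here operates on flat float64 arrays so it can be compiled by
numba and called thousands of times during sensitivity analysis and MCMC.
The state layout and packed-parameter layout are defined by the index
constants below; :meth:`xyleth.parameters.DerivedPhysiology.pack` produces
the parameter vector.

Within one integration segment the inhaled air concentration (mg/L) and the
oral drink rate (mg/h) are constant; the scenario driver splits the timeline
at every discontinuity (exposure on/off, drink window, micturition) and
restarts the integrator.
"""

import numpy as np
from numba import njit

# ---- state indices (amounts in mg, volumes in L) ----
IX_FA = 0       # m-xylene in adipose
IX_RPD = 1      # m-xylene in rapidly perfused tissue
IX_SPD = 2      # m-xylene in slowly perfused tissue
IX_LI = 3       # m-xylene in liver
IX_INH = 4      # cumulative m-xylene inhaled
IX_EXH = 5      # cumulative m-xylene exhaled
IX_MET = 6      # cumulative m-xylene metabolised
IX_MHA = 7      # 3-MHA in the body pool
IX_MHAB = 8     # 3-MHA in the bladder
IX_UVOL = 9     # urine volume in the bladder
IE_STL = 10     # ethanol in stomach lumen
IE_GUL = 11     # ethanol in gut lumen
IE_ST = 12      # ethanol in stomach tissue
IE_GU = 13      # ethanol in gut tissue
IE_FA = 14      # ethanol in adipose
IE_RPD = 15     # ethanol in rapidly perfused tissue
IE_SPD = 16     # ethanol in slowly perfused tissue
IE_LI = 17      # ethanol in liver
IE_ING = 18     # cumulative ethanol ingested
IE_ABS = 19     # cumulative ethanol absorbed from the gut lumen
IE_MET = 20     # cumulative ethanol metabolised
IE_EXH = 21     # cumulative ethanol exhaled
NSTATE = 22

# ---- packed-parameter indices ----
IP_QC = 0; IP_QALV = 1
IP_QFA = 2; IP_QRPD = 3; IP_QSPD = 4; IP_QLI = 5
IP_VFA = 6; IP_VRPD = 7; IP_VSPDX = 8; IP_VLI = 9
IP_PBAX = 10; IP_PFABX = 11; IP_PRPDBX = 12; IP_PSPDBX = 13; IP_PLIBX = 14
IP_VMAXX = 15; IP_KMX = 16; IP_KI = 17; IP_MODE = 18
IP_FMHA = 19; IP_MWRATIO = 20; IP_K1 = 21; IP_RURINE = 22
IP_QST = 23; IP_QGU = 24; IP_QLIA = 25
IP_VST = 26; IP_VGU = 27; IP_VSPDE = 28
IP_PBAE = 29; IP_PFABE = 30; IP_PRPDBE = 31; IP_PSPDBE = 32
IP_PLIBE = 33; IP_PSTBE = 34; IP_PGUBE = 35
IP_VMAXE0 = 36  # ..39: CYP2E1, ADH alpha-alpha, beta-beta, gamma-gamma
IP_KME0 = 40    # ..43
IP_BELLY = 44; IP_GI = 45; IP_KEMAX = 46; IP_KEMIN = 47; IP_A50 = 48; IP_HILL = 49
NPAR = 50

# inhibition mode codes (match parameters.INHIBITION_MODES order)
MODE_NONE = 0.0
MODE_COMPETITIVE = 1.0
MODE_NONCOMPETITIVE = 2.0
MODE_UNCOMPETITIVE = 3.0


@njit(cache=True)
def inhibition_factors(km, vmax, inhibitor, ki, mode):
    """Apparent (Km, Vmax) under competitive / noncompetitive / uncompetitive
    inhibition at inhibitor concentration ``inhibitor`` (mg/L)."""
    if inhibitor <= 0.0 or mode == MODE_NONE:
        return km, vmax
    f = 1.0 + inhibitor / ki
    if mode == MODE_COMPETITIVE:
        return km * f, vmax
    elif mode == MODE_NONCOMPETITIVE:
        return km, vmax / f
    else:  # uncompetitive
        return km / f, vmax / f


@njit(cache=True)
def gastric_rate(a_stomach, ke_max, ke_min, a50, hill):
    """Gastric emptying rate constant, inhibited by the ethanol load."""
    if a_stomach <= 0.0:
        return ke_max
    x = (a_stomach / a50) ** hill
    return ke_min + (ke_max - ke_min) / (1.0 + x)


@njit(cache=True)
def rhs(y, p, c_inh, drink, dy):
    """Time derivative of the full coupled state.

    ``c_inh``: inhaled m-xylene concentration (mg/L air);
    ``drink``: oral ethanol input rate (mg/h).
    """
    qc = p[IP_QC]
    qalv = p[IP_QALV]

    # ---------- ethanol submodel (provides the liver inhibitor level) ----------
    cv_fa_e = y[IE_FA] / (p[IP_VFA] * p[IP_PFABE])
    cv_rpd_e = y[IE_RPD] / (p[IP_VRPD] * p[IP_PRPDBE])
    cv_spd_e = y[IE_SPD] / (p[IP_VSPDE] * p[IP_PSPDBE])
    cv_li_e = y[IE_LI] / (p[IP_VLI] * p[IP_PLIBE])
    cv_st_e = y[IE_ST] / (p[IP_VST] * p[IP_PSTBE])
    cv_gu_e = y[IE_GU] / (p[IP_VGU] * p[IP_PGUBE])

    cven_e = (p[IP_QFA] * cv_fa_e + p[IP_QRPD] * cv_rpd_e
              + p[IP_QSPD] * cv_spd_e + p[IP_QLI] * cv_li_e) / qc
    cart_e = (qc * cven_e) / (qalv / p[IP_PBAE] + qc)

    ke = gastric_rate(y[IE_STL], p[IP_KEMAX], p[IP_KEMIN], p[IP_A50], p[IP_HILL])
    absorb_st = p[IP_BELLY] * y[IE_STL]
    absorb_gu = p[IP_GI] * y[IE_GUL]

    ram_e = 0.0
    for i in range(4):
        ram_e += p[IP_VMAXE0 + i] * cv_li_e / (p[IP_KME0 + i] + cv_li_e)

    dy[IE_STL] = drink - ke * y[IE_STL] - absorb_st
    dy[IE_GUL] = ke * y[IE_STL] - absorb_gu
    dy[IE_ST] = absorb_st + p[IP_QST] * (cart_e - cv_st_e)
    dy[IE_GU] = absorb_gu + p[IP_QGU] * (cart_e - cv_gu_e)
    dy[IE_FA] = p[IP_QFA] * (cart_e - cv_fa_e)
    dy[IE_RPD] = p[IP_QRPD] * (cart_e - cv_rpd_e)
    dy[IE_SPD] = p[IP_QSPD] * (cart_e - cv_spd_e)
    dy[IE_LI] = (p[IP_QLIA] * cart_e + p[IP_QST] * cv_st_e + p[IP_QGU] * cv_gu_e
                 - p[IP_QLI] * cv_li_e - ram_e)
    dy[IE_ING] = drink
    dy[IE_ABS] = absorb_st + absorb_gu
    dy[IE_MET] = ram_e
    dy[IE_EXH] = qalv * cart_e / p[IP_PBAE]

    # ---------- m-xylene submodel ----------
    cv_fa = y[IX_FA] / (p[IP_VFA] * p[IP_PFABX])
    cv_rpd = y[IX_RPD] / (p[IP_VRPD] * p[IP_PRPDBX])
    cv_spd = y[IX_SPD] / (p[IP_VSPDX] * p[IP_PSPDBX])
    cv_li = y[IX_LI] / (p[IP_VLI] * p[IP_PLIBX])

    cven = (p[IP_QFA] * cv_fa + p[IP_QRPD] * cv_rpd
            + p[IP_QSPD] * cv_spd + p[IP_QLI] * cv_li) / qc
    cart = (qalv * c_inh + qc * cven) / (qalv / p[IP_PBAX] + qc)

    km_eff, vmax_eff = inhibition_factors(
        p[IP_KMX], p[IP_VMAXX], cv_li_e, p[IP_KI], p[IP_MODE])
    ram = vmax_eff * cv_li / (km_eff + cv_li)

    dy[IX_FA] = p[IP_QFA] * (cart - cv_fa)
    dy[IX_RPD] = p[IP_QRPD] * (cart - cv_rpd)
    dy[IX_SPD] = p[IP_QSPD] * (cart - cv_spd)
    dy[IX_LI] = p[IP_QLI] * (cart - cv_li) - ram
    dy[IX_INH] = qalv * c_inh
    dy[IX_EXH] = qalv * cart / p[IP_PBAX]
    dy[IX_MET] = ram
    dy[IX_MHA] = p[IP_FMHA] * ram * p[IP_MWRATIO] - p[IP_K1] * y[IX_MHA]
    dy[IX_MHAB] = p[IP_K1] * y[IX_MHA]
    dy[IX_UVOL] = p[IP_RURINE]


@njit(cache=True)
def integrate_segment(y, t0, t1, dt, p, c_inh, drink, t_eval, out, ptr):
    """Fixed-step RK4 over [t0, t1]; ``y`` is advanced in place.

    Rows of ``out`` are filled (by linear interpolation between steps) for
    every entry of ``t_eval`` falling in (t0, t1], starting at index ``ptr``;
    the updated pointer is returned.  ``t_eval`` must be sorted.
    """
    span = t1 - t0
    n = int(np.ceil(span / dt))
    if n < 1:
        n = 1
    h = span / n
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    ytmp = np.empty(NSTATE)
    yprev = np.empty(NSTATE)
    t = t0
    for step in range(n):
        for j in range(NSTATE):
            yprev[j] = y[j]
        rhs(y, p, c_inh, drink, k1)
        for j in range(NSTATE):
            ytmp[j] = y[j] + 0.5 * h * k1[j]
        rhs(ytmp, p, c_inh, drink, k2)
        for j in range(NSTATE):
            ytmp[j] = y[j] + 0.5 * h * k2[j]
        rhs(ytmp, p, c_inh, drink, k3)
        for j in range(NSTATE):
            ytmp[j] = y[j] + h * k3[j]
        rhs(ytmp, p, c_inh, drink, k4)
        for j in range(NSTATE):
            y[j] += (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        tnew = t0 + (step + 1) * h
        while ptr < t_eval.size and t_eval[ptr] <= tnew + 1e-12:
            w = (t_eval[ptr] - t) / h
            if w < 0.0:
                w = 0.0
            elif w > 1.0:
                w = 1.0
            for j in range(NSTATE):
                out[ptr, j] = yprev[j] + w * (y[j] - yprev[j])
            ptr += 1
        t = tnew
    return ptr


@njit(cache=True)
def arterial_xylene(y_row, p, c_inh):
    """Arterial m-xylene concentration (mg/L) implied by one state row."""
    qc = p[IP_QC]
    qalv = p[IP_QALV]
    cv_fa = y_row[IX_FA] / (p[IP_VFA] * p[IP_PFABX])
    cv_rpd = y_row[IX_RPD] / (p[IP_VRPD] * p[IP_PRPDBX])
    cv_spd = y_row[IX_SPD] / (p[IP_VSPDX] * p[IP_PSPDBX])
    cv_li = y_row[IX_LI] / (p[IP_VLI] * p[IP_PLIBX])
    cven = (p[IP_QFA] * cv_fa + p[IP_QRPD] * cv_rpd
            + p[IP_QSPD] * cv_spd + p[IP_QLI] * cv_li) / qc
    return (qalv * c_inh + qc * cven) / (qalv / p[IP_PBAX] + qc), cven


@njit(cache=True)
def venous_ethanol(y_row, p):
    """Mixed venous ethanol concentration (mg/L) for one state row."""
    qc = p[IP_QC]
    cv_fa = y_row[IE_FA] / (p[IP_VFA] * p[IP_PFABE])
    cv_rpd = y_row[IE_RPD] / (p[IP_VRPD] * p[IP_PRPDBE])
    cv_spd = y_row[IE_SPD] / (p[IP_VSPDE] * p[IP_PSPDBE])
    cv_li = y_row[IE_LI] / (p[IP_VLI] * p[IP_PLIBE])
    return (p[IP_QFA] * cv_fa + p[IP_QRPD] * cv_rpd
            + p[IP_QSPD] * cv_spd + p[IP_QLI] * cv_li) / qc
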