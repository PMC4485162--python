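"""PBPK right-hand sides and observable maps for the binary model.

The two submodels — a 4-compartment flow-limited description of inhaled
m-xylene with hepatic CYP2E1 oxidation and a bladder compartment for the
urinary metabolite, and a 6-compartment ethanol model with a two-stage
gastric/gut lumen and four saturable hepatic pathways — are coupled solely
at the liver: the ethanol liver-venous concentration acts as the inhibitor
in the apparent Michaelis–Menten constants of m-xylene oxidation.

Functions here are written for clarity and unit testing; the batch path is
the numba core in :mod:`xyleth._core`, which tests verify agrees with these
reference implementations to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _core
from .parameters import INHIBITION_MODES, DerivedPhysiology
from .units import MW_CREATININE, mg_per_l_to_ppm, mg_per_l_to_umol_per_l

__all__ = [
    "km_apparent",
    "michaelis_menten_rate",
    "arterial_concentration",
    "gastric_emptying_rate",
    "xylene_rhs",
    "ethanol_rhs",
    "coupled_rhs",
    "observables",
    "ObservableSet",
]


def km_apparent(km: float, vmax: float, inhibitor_conc: float, ki: float, mode: str):
    """Apparent (Km, Vmax) under the selected inhibition mechanism.

    competitive: Km*(1+I/KI), Vmax unchanged;
    noncompetitive: Km unchanged, Vmax/(1+I/KI);
    uncompetitive: both divided by (1+I/KI);
    none: identity.
    """
    if mode not in INHIBITION_MODES:
        raise ValueError(f"unknown inhibition mode {mode!r}; expected one of {INHIBITION_MODES}")
    if km <= 0 or vmax <= 0 or ki <= 0:
        raise ValueError("Km, Vmax and KI must be positive")
    if inhibitor_conc < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    if mode == "none" or inhibitor_conc == 0.0:
        return km, vmax
    f = 1.0 + inhibitor_conc / ki
    if mode == "competitive":
        return km * f, vmax
    if mode == "noncompetitive":
        return km, vmax / f
    return km / f, vmax / f


def michaelis_menten_rate(conc, vmax: float, km: float):
    """Saturable metabolic rate Vmax*C/(Km+C), mg/h."""
    c = np.asarray(conc, dtype=float)
    out = vmax * c / (km + c)
    return float(out) if out.ndim == 0 else out


def arterial_concentration(c_inh, c_ven, q_alv: float, qc: float, pba: float):
    """Steady-state lung gas-exchange closure for a flow-limited model.

    C_art = (Q_alv*C_inh + QC*C_ven) / (Q_alv/Pba + QC); the instantaneous
    alveolar (end-exhaled) concentration is C_art/Pba.
    """
    if q_alv <= 0 or qc <= 0 or pba <= 0:
        raise ValueError("flows and the blood:air coefficient must be positive")
    c_inh = np.asarray(c_inh, dtype=float)
    out = (q_alv * c_inh + qc * np.asarray(c_ven, dtype=float)) / (q_alv / pba + qc)
    return float(out) if out.ndim == 0 else out


def gastric_emptying_rate(stomach_amount_mg, ke_max: float, ke_min: float,
                          a50_mg: float = 10000.0, hill: float = 2.0):
    """Ethanol-load-dependent gastric emptying rate constant (1/h).

    A sigmoidal (Hill) inhibition of gastric peristalsis: the rate falls
    from KE_max on an empty stomach towards KE_min as the ethanol load
    grows, passing through the midpoint at ``a50_mg``.
    """
    if not ke_min < ke_max:
        raise ValueError("KE_min must be smaller than KE_max")
    if a50_mg <= 0 or hill <= 0:
        raise ValueError("A50 and the Hill exponent must be positive")
    a = np.asarray(stomach_amount_mg, dtype=float)
    out = ke_min + (ke_max - ke_min) / (1.0 + (np.maximum(a, 0.0) / a50_mg) ** hill)
    return float(out) if out.ndim == 0 else out


def xylene_rhs(state: np.ndarray, phys: DerivedPhysiology,
               ethanol_liver_venous_conc: float, c_inh: float) -> np.ndarray:
    """Derivatives of the m-xylene sub-state (indices 0..9 of the full state).

    Flow-limited tissue exchange, hepatic metabolism with apparent constants
    set by the ethanol liver-venous concentration, and first-order transfer
    of the 3-MHA body pool into a bladder filling at the urine flow rate.
    """
    p = phys.pack()
    ps = phys.params
    c = _core
    dy = np.zeros(c.NSTATE)
    cv = {
        "fat": state[c.IX_FA] / (p[c.IP_VFA] * p[c.IP_PFABX]),
        "rapid": state[c.IX_RPD] / (p[c.IP_VRPD] * p[c.IP_PRPDBX]),
        "slow": state[c.IX_SPD] / (p[c.IP_VSPDX] * p[c.IP_PSPDBX]),
        "liver": state[c.IX_LI] / (p[c.IP_VLI] * p[c.IP_PLIBX]),
    }
    c_ven = sum(phys.flows[k] * cv[k] for k in cv) / phys.cardiac_output
    c_art = arterial_concentration(c_inh, c_ven, phys.alveolar_ventilation,
                                   phys.cardiac_output, ps["PBAXYL"])
    km_eff, vmax_eff = km_apparent(phys.km_xyl, phys.vmax_xyl,
                                   ethanol_liver_venous_conc, ps["KI"],
                                   ps.inhibition_mode)
    ram = michaelis_menten_rate(cv["liver"], vmax_eff, km_eff)
    dy[c.IX_FA] = phys.flows["fat"] * (c_art - cv["fat"])
    dy[c.IX_RPD] = phys.flows["rapid"] * (c_art - cv["rapid"])
    dy[c.IX_SPD] = phys.flows["slow"] * (c_art - cv["slow"])
    dy[c.IX_LI] = phys.flows["liver"] * (c_art - cv["liver"]) - ram
    dy[c.IX_INH] = phys.alveolar_ventilation * c_inh
    dy[c.IX_EXH] = phys.alveolar_ventilation * c_art / ps["PBAXYL"]
    dy[c.IX_MET] = ram
    dy[c.IX_MHA] = ps["f_MHA"] * ram * (ps["MW_MHA"] / ps["MW_xyl"]) - ps["K_1"] * state[c.IX_MHA]
    dy[c.IX_MHAB] = ps["K_1"] * state[c.IX_MHA]
    dy[c.IX_UVOL] = ps["R_urine"]
    return dy


def ethanol_rhs(state: np.ndarray, phys: DerivedPhysiology, drink_rate: float) -> np.ndarray:
    """Derivatives of the ethanol sub-state (indices 10..21 of the full state).

    Drink input feeds the stomach lumen; gastric emptying (inhibited by the
    stomach ethanol load) moves lumen contents to the gut lumen; first-order
    absorption moves lumen ethanol into the stomach/gut tissues, whose
    venous blood drains through the portal circulation into the liver.
    """
    p = phys.pack()
    ps = phys.params
    c = _core
    dy = np.zeros(c.NSTATE)
    cv = {
        "fat": state[c.IE_FA] / (p[c.IP_VFA] * p[c.IP_PFABE]),
        "rapid": state[c.IE_RPD] / (p[c.IP_VRPD] * p[c.IP_PRPDBE]),
        "slow": state[c.IE_SPD] / (p[c.IP_VSPDE] * p[c.IP_PSPDBE]),
        "liver": state[c.IE_LI] / (p[c.IP_VLI] * p[c.IP_PLIBE]),
        "stomach": state[c.IE_ST] / (p[c.IP_VST] * p[c.IP_PSTBE]),
        "gut": state[c.IE_GU] / (p[c.IP_VGU] * p[c.IP_PGUBE]),
    }
    # only the four systemic outflows mix into the pulmonary return
    c_ven = (phys.flows["fat"] * cv["fat"] + phys.flows["rapid"] * cv["rapid"]
             + phys.flows["slow"] * cv["slow"] + phys.flows["liver"] * cv["liver"]
             ) / phys.cardiac_output
    c_art = arterial_concentration(0.0, c_ven, phys.alveolar_ventilation,
                                   phys.cardiac_output, ps["Pba_eth"])
    ke = gastric_emptying_rate(state[c.IE_STL], ps["KE_max"], ps["KE_min"],
                               ps["A50_gastric"], ps["hill_gastric"])
    absorb_st = ps["BELLYPERM"] * state[c.IE_STL]
    absorb_gu = ps["GIPERM"] * state[c.IE_GUL]
    ram = sum(michaelis_menten_rate(cv["liver"], v, k)
              for v, k in zip(phys.vmax_eth, phys.km_eth))
    dy[c.IE_STL] = drink_rate - ke * state[c.IE_STL] - absorb_st
    dy[c.IE_GUL] = ke * state[c.IE_STL] - absorb_gu
    dy[c.IE_ST] = absorb_st + phys.flows["stomach"] * (c_art - cv["stomach"])
    dy[c.IE_GU] = absorb_gu + phys.flows["gut"] * (c_art - cv["gut"])
    dy[c.IE_FA] = phys.flows["fat"] * (c_art - cv["fat"])
    dy[c.IE_RPD] = phys.flows["rapid"] * (c_art - cv["rapid"])
    dy[c.IE_SPD] = phys.flows["slow"] * (c_art - cv["slow"])
    dy[c.IE_LI] = (phys.flows["liver_arterial"] * c_art
                   + phys.flows["stomach"] * cv["stomach"]
                   + phys.flows["gut"] * cv["gut"]
                   - phys.flows["liver"] * cv["liver"] - ram)
    dy[c.IE_ING] = drink_rate
    dy[c.IE_ABS] = absorb_st + absorb_gu
    dy[c.IE_MET] = ram
    dy[c.IE_EXH] = phys.alveolar_ventilation * c_art / ps["Pba_eth"]
    return dy


def coupled_rhs(state: np.ndarray, phys: DerivedPhysiology,
                c_inh: float, drink_rate: float) -> np.ndarray:
    """Full coupled derivative: ethanol drives the xylene inhibition term."""
    p = phys.pack()
    cv_li_e = state[_core.IE_LI] / (p[_core.IP_VLI] * p[_core.IP_PLIBE])
    return (xylene_rhs(state, phys, cv_li_e, c_inh)
            + ethanol_rhs(state, phys, drink_rate))


# --------------------------------------------------------------------------
# Observables
# --------------------------------------------------------------------------

@dataclass
class ObservableSet:
    """Monitored outputs evaluated on a time grid (all non-negative).

    cv_xyl: venous blood m-xylene, mg/L (``cv_xyl_umol`` in µmol/L);
    cx_ppm: end-exhaled (alveolar) m-xylene, ppm;
    cx_mixed_ppm: optional mixed-exhaled output, 70% alveolar + 30% inspired;
    c_urine: urinary 3-MHA, g per g creatinine (NaN where the bladder is empty);
    c_blood_eth: venous blood ethanol, mg/L.
    """

    t: np.ndarray
    cv_xyl: np.ndarray
    cv_xyl_umol: np.ndarray
    cx_ppm: np.ndarray
    cx_mixed_ppm: np.ndarray
    c_urine: np.ndarray
    c_blood_eth: np.ndarray


def observables(states: np.ndarray, t: np.ndarray, phys: DerivedPhysiology,
                c_inh: np.ndarray, creatinine_mmol: Optional[float] = None,
                dead_space: float = 0.3) -> ObservableSet:
    """Map a state trajectory to the monitored channels.

    ``states`` is (n, NSTATE); ``c_inh`` the inhaled concentration (mg/L)
    at each time.  The urinary channel is the running bladder concentration
    (step profile between voids) and is NaN wherever the bladder is empty.
    """
    p = phys.pack()
    ps = phys.params
    cre = ps["CREmmol"] if creatinine_mmol is None else creatinine_mmol
    c = _core
    qc, qalv = p[c.IP_QC], p[c.IP_QALV]
    cven = (
        p[c.IP_QFA] * states[:, c.IX_FA] / (p[c.IP_VFA] * p[c.IP_PFABX])
        + p[c.IP_QRPD] * states[:, c.IX_RPD] / (p[c.IP_VRPD] * p[c.IP_PRPDBX])
        + p[c.IP_QSPD] * states[:, c.IX_SPD] / (p[c.IP_VSPDX] * p[c.IP_PSPDBX])
        + p[c.IP_QLI] * states[:, c.IX_LI] / (p[c.IP_VLI] * p[c.IP_PLIBX])
    ) / qc
    cart = (qalv * np.asarray(c_inh, dtype=float) + qc * cven) / (qalv / p[c.IP_PBAX] + qc)
    calv = cart / ps["PBAXYL"]
    cx_ppm = mg_per_l_to_ppm(calv, ps["MW_xyl"])
    cx_mixed = mg_per_l_to_ppm((1.0 - dead_space) * calv, ps["MW_xyl"]) \
        + dead_space * mg_per_l_to_ppm(c_inh, ps["MW_xyl"])
    uvol = states[:, c.IX_UVOL]
    with np.errstate(divide="ignore", invalid="ignore"):
        mha_mg_l = np.where(uvol > 1e-12, states[:, c.IX_MHAB] / uvol, np.nan)
    c_urine = mha_mg_l / (cre * MW_CREATININE)
    cveth = (
        p[c.IP_QFA] * states[:, c.IE_FA] / (p[c.IP_VFA] * p[c.IP_PFABE])
        + p[c.IP_QRPD] * states[:, c.IE_RPD] / (p[c.IP_VRPD] * p[c.IP_PRPDBE])
        + p[c.IP_QSPD] * states[:, c.IE_SPD] / (p[c.IP_VSPDE] * p[c.IP_PSPDBE])
        + p[c.IP_QLI] * states[:, c.IE_LI] / (p[c.IP_VLI] * p[c.IP_PLIBE])
    ) / qc
    return ObservableSet(
        t=np.asarray(t, dtype=float),
        cv_xyl=cven,
        cv_xyl_umol=mg_per_l_to_umol_per_l(cven, ps["MW_xyl"]),
        cx_ppm=cx_ppm,
        cx_mixed_ppm=cx_mixed,
        c_urine=c_urine,
        c_blood_eth=cveth,
    )
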