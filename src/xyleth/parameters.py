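"""Parameters and priors for the coupled m-xylene + ethanol PBPK model.

This module owns the parameter catalogue (central values plus population
prior distributions), sampling with mass-balance/blood-flow rebalancing,
per-individual physiology, the in-vitro-to-in-vivo scaling of metabolic
capacities, and the small pieces of dose-planning arithmetic used when
preparing an oral ethanol dose.

Conventions
-----------
* Internal units are mg, L and h.  Tissue density is taken as 1 kg/L so
  tissue masses (kg) and volumes (L) are numerically interchangeable.
* m-Xylene tissue partition coefficients are tissue:air and are divided by
  the blood:air coefficient to obtain tissue:blood values.  Ethanol tissue
  partition coefficients are tissue:blood directly (rat surrogate values).
* Cardiac output scales allometrically, QC = QCMC * BW^0.75.
* Whole-liver maximal metabolic rates are scaled from in-vitro microsomal
  rates: Vmax[mg/h] = Vmax[pmol/min/mg] * 60 * MPY[mg/g] * liver[g]
  * MW[g/mol] * 1e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Optional

import numpy as np
import yaml
from scipy import stats

from .units import ETHANOL_DENSITY

__all__ = [
    "PriorSpec",
    "ParameterSet",
    "DerivedPhysiology",
    "DosePlan",
    "IndividualPhysiology",
    "builtin_priors",
    "parameter_catalogue",
    "central_values",
    "sample_parameter_set",
    "derive_physiology",
    "ethanol_dose_plan",
    "INHIBITION_MODES",
]

INHIBITION_MODES = ("none", "competitive", "noncompetitive", "uncompetitive")

_REBALANCED = ("QRPDC", "VSPDC")


# --------------------------------------------------------------------------
# Prior specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Distributional specification for one model parameter.

    ``family`` is one of ``point`` (fixed constant), ``normal``,
    ``lognormal``, ``uniform`` or ``derived`` (closed by rebalancing, never
    sampled).  Normal/lognormal specs may carry truncation bounds; sampling,
    quantiles and densities all respect them.
    """

    name: str
    family: str
    central: float
    mean: Optional[float] = None
    sd: Optional[float] = None
    mu: Optional[float] = None
    sigma: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None
    unit: str = ""
    group: str = "shared"

    def __post_init__(self):
        if self.family not in ("point", "normal", "lognormal", "uniform", "derived"):
            raise ValueError(f"unknown prior family {self.family!r} for {self.name}")
        if self.family == "uniform":
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(f"uniform prior for {self.name} needs lower < upper")
        if self.family == "normal" and (self.sd is None or self.sd <= 0):
            raise ValueError(f"normal prior for {self.name} needs sd > 0")
        if self.family == "lognormal" and (self.sigma is None or self.sigma <= 0):
            raise ValueError(f"lognormal prior for {self.name} needs sigma > 0")

    @property
    def varying(self) -> bool:
        return self.family in ("normal", "lognormal", "uniform")

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(self.mean, self.sd)
        if self.family == "lognormal":
            return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))
        if self.family == "uniform":
            return stats.uniform(self.lower, self.upper - self.lower)
        raise ValueError(f"{self.name}: family {self.family} has no distribution")

    def _trunc_cdfs(self, dist):
        lo = 0.0 if self.lower is None else float(dist.cdf(self.lower))
        hi = 1.0 if self.upper is None else float(dist.cdf(self.upper))
        if not lo < hi:
            raise ValueError(f"{self.name}: empty truncation region")
        return lo, hi

    def ppf(self, q):
        """Quantile function (truncation-aware); maps [0,1] to the support."""
        if self.family in ("point", "derived"):
            return np.full_like(np.asarray(q, dtype=float), self.central)
        dist = self._frozen()
        lo, hi = self._trunc_cdfs(dist)
        q = np.clip(np.asarray(q, dtype=float), 1e-12, 1.0 - 1e-12)
        return dist.ppf(lo + q * (hi - lo))

    def sample(self, rng: np.random.Generator, size=None):
        if self.family in ("point", "derived"):
            return self.central if size is None else np.full(size, self.central)
        u = rng.uniform(size=size)
        out = self.ppf(u)
        return float(out) if size is None else out

    def logpdf(self, x):
        if self.family in ("point", "derived"):
            return 0.0
        x = np.asarray(x, dtype=float)
        dist = self._frozen()
        lo, hi = self._trunc_cdfs(dist)
        out = dist.logpdf(x) - math.log(hi - lo)
        inside = np.ones_like(x, dtype=bool)
        if self.lower is not None:
            inside &= x >= self.lower
        if self.upper is not None:
            inside &= x <= self.upper
        out = np.where(inside, out, -np.inf)
        return float(out) if out.ndim == 0 else out

    @property
    def support(self):
        if self.family == "uniform":
            return (self.lower, self.upper)
        lo = self.lower if self.lower is not None else (0.0 if self.family == "lognormal" else -np.inf)
        hi = self.upper if self.upper is not None else np.inf
        return (lo, hi)


def _load_catalogue() -> Dict[str, PriorSpec]:
    text = resources.files("xyleth.data").joinpath("priors.yaml").read_text()
    raw = yaml.safe_load(text)
    cat: Dict[str, PriorSpec] = {}
    for name, entry in raw["parameters"].items():
        cat[name] = PriorSpec(
            name=name,
            family=entry["family"],
            central=float(entry["central"]),
            mean=entry.get("mean"),
            sd=entry.get("sd"),
            mu=entry.get("mu"),
            sigma=entry.get("sigma"),
            lower=entry.get("lower"),
            upper=entry.get("upper"),
            unit=entry.get("unit", ""),
            group=entry.get("group", "shared"),
        )
    return cat


_CATALOGUE: Optional[Dict[str, PriorSpec]] = None


def parameter_catalogue() -> Dict[str, PriorSpec]:
    """The full parameter catalogue (fixed constants and priors)."""
    global _CATALOGUE
    if _CATALOGUE is None:
        _CATALOGUE = _load_catalogue()
    return dict(_CATALOGUE)


def builtin_priors(name: Optional[str] = None):
    """Return the built-in prior specs, or a single one by parameter name.

    Raises ``KeyError`` with an explicit message for unknown names.
    """
    cat = parameter_catalogue()
    if name is None:
        return cat
    try:
        return cat[name]
    except KeyError:
        raise KeyError(
            f"no parameter named {name!r} in the catalogue; known names: "
            + ", ".join(sorted(cat))
        ) from None


def central_values() -> Dict[str, float]:
    return {k: v.central for k, v in parameter_catalogue().items()}


# --------------------------------------------------------------------------
# Parameter set
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """One individual's complete parameter vector for the binary model.

    ``values`` maps catalogue names to numbers; ``inhibition_mode`` selects
    how hepatic ethanol inhibits m-xylene oxidation.
    """

    values: Dict[str, float]
    inhibition_mode: str = "competitive"

    def __post_init__(self):
        if self.inhibition_mode not in INHIBITION_MODES:
            raise ValueError(
                f"inhibition_mode must be one of {INHIBITION_MODES}, "
                f"got {self.inhibition_mode!r}"
            )
        missing = set(parameter_catalogue()) - set(self.values)
        if missing:
            raise ValueError(f"parameter set is missing {sorted(missing)}")
        for k, v in self.values.items():
            if not v > 0:
                raise ValueError(f"parameter {k} must be positive, got {v}")

    @classmethod
    def central(cls, inhibition_mode: str = "competitive", **overrides) -> "ParameterSet":
        """The deterministic set: every parameter at its central value."""
        vals = central_values()
        vals.update(overrides)
        return cls(values=vals, inhibition_mode=inhibition_mode)

    def copy(self, inhibition_mode: Optional[str] = None, **updates) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return ParameterSet(
            values=vals,
            inhibition_mode=self.inhibition_mode if inhibition_mode is None else inhibition_mode,
        )

    def for_individual(self, phys: "IndividualPhysiology") -> "ParameterSet":
        """Pin the measured quantities of one volunteer."""
        updates = {
            "BW": phys.body_mass,
            "VFAC": phys.fat_fraction,
            "QPMC": phys.alveolar_ventilation,
            "R_urine": phys.urine_flow,
            "CREmmol": phys.urinary_creatinine,
        }
        if phys.blood_air_pc_xylene is not None:
            updates["PBAXYL"] = phys.blood_air_pc_xylene
        return self.copy(**updates)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)


@dataclass(frozen=True)
class IndividualPhysiology:
    """Measured physiology of one study volunteer."""

    body_mass: float           # kg
    height: float              # m
    fat_fraction: float        # fraction of BW
    alveolar_ventilation: float  # L/h
    urine_flow: float          # L/h
    urinary_creatinine: float  # mmol/L
    blood_air_pc_xylene: Optional[float] = None  # dimensionless; may be missing
    age: Optional[float] = None
    volunteer: str = ""

    def __post_init__(self):
        for name in ("body_mass", "height", "fat_fraction", "alveolar_ventilation",
                     "urine_flow", "urinary_creatinine"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.fat_fraction < 0.6:
            raise ValueError("fat_fraction must lie in (0, 0.6)")
        if self.blood_air_pc_xylene is not None and not self.blood_air_pc_xylene > 0:
            raise ValueError("blood_air_pc_xylene must be positive when present")

    @property
    def bmi(self) -> float:
        return self.body_mass / self.height**2


# --------------------------------------------------------------------------
# Sampling with rebalancing
# --------------------------------------------------------------------------

def sample_parameter_set(
    priors: Optional[Mapping[str, PriorSpec]] = None,
    seed: int | np.random.Generator = 0,
    inhibition_mode: str = "competitive",
    fixed: Optional[Mapping[str, float]] = None,
    max_rejections: int = 1000,
) -> ParameterSet:
    """Draw one parameter set from the priors and rebalance it.

    After drawing every varying parameter, the aggregated fractions are
    closed so the constraints hold exactly:

    * flow fractions: ``QRPDC = 1 - (QSPDC + QFAC + QLIC)`` (the hepatic
      fraction QLIC is total liver outflow and already contains the portal
      stomach/gut flows, which must satisfy ``QSTC + QGUC < QLIC``);
    * volume fractions: ``VSPDC = VT - (VRPDC + VFAC + VLIC)`` for the
      4-compartment (xylene) topology; the ethanol topology additionally
      carves VSTC and VGUC out of the slowly perfused pool.

    Draws violating positivity of a closed remainder are rejected and
    redrawn; more than ``max_rejections`` consecutive rejections raises.
    """
    cat = parameter_catalogue()
    if priors is None:
        priors = cat
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fixed = dict(fixed or {})

    n_reject = 0
    while True:
        vals = {}
        for name, spec in cat.items():
            if name in fixed:
                vals[name] = float(fixed[name])
            elif name in _REBALANCED:
                vals[name] = spec.central  # replaced below
            else:
                spec_eff = priors.get(name, spec)
                vals[name] = float(spec_eff.sample(rng))

        q_rem = 1.0 - (vals["QSPDC"] + vals["QFAC"] + vals["QLIC"])
        v_rem = vals["VT"] - (vals["VRPDC"] + vals["VFAC"] + vals["VLIC"])
        v_rem_eth = v_rem - (vals["VSTC"] + vals["VGUC"])
        q_li_arterial = vals["QLIC"] - (vals["QSTC"] + vals["QGUC"])
        if min(q_rem, v_rem, v_rem_eth, q_li_arterial) <= 0:
            n_reject += 1
            if n_reject > max_rejections:
                raise RuntimeError(
                    f"rejected {n_reject} consecutive draws; the priors are "
                    "inconsistent with the mass/flow balance constraints"
                )
            continue
        vals["QRPDC"] = q_rem
        vals["VSPDC"] = v_rem
        ps = ParameterSet(values=vals, inhibition_mode=inhibition_mode)
        object.__setattr__(ps, "n_rejections", n_reject)
        return ps


# --------------------------------------------------------------------------
# Derived physiology
# --------------------------------------------------------------------------

_ETH_PATHWAYS = (
    ("V_max2E1eth", "K_M2E1eth"),
    ("V_maxaa", "K_Maa"),
    ("V_maxbb", "K_Mbb"),
    ("V_maxgg", "K_Mgg"),
)


@dataclass(frozen=True)
class DerivedPhysiology:
    """Absolute flows, volumes and scaled kinetic constants for one set."""

    params: ParameterSet
    cardiac_output: float                 # QC, L/h
    alveolar_ventilation: float           # L/h
    flows: Dict[str, float]               # L/h
    volumes: Dict[str, float]             # L (tissue density 1 kg/L)
    liver_mass_g: float
    vmax_xyl: float                       # mg/h, whole liver
    km_xyl: float                         # mg/L
    vmax_eth: tuple                       # mg/h per pathway (4)
    km_eth: tuple                         # mg/L per pathway (4)
    pc_blood_xyl: Dict[str, float]        # tissue:blood, m-xylene
    pc_blood_eth: Dict[str, float]        # tissue:blood, ethanol

    def max_rate_constant(self) -> float:
        """Fastest first-order rate constant (1/h) in the coupled system.

        Bounds the stiffness of the ODEs: the per-compartment perfusion
        rates Q/(V*P), the low-concentration hepatic clearance rates
        (sum Vmax/Km scaled by the liver pool), and the lumen transfer
        constants.  Used to cap the explicit integrator's step size.
        """
        ps = self.params
        rates = [ps["GIPERM"], ps["BELLYPERM"], ps["KE_max"], ps["K_1"]]
        for tis in ("fat", "rapid", "liver"):
            rates.append(self.flows[tis] / (self.volumes[tis] * self.pc_blood_xyl[tis]))
            rates.append(self.flows[tis] / (self.volumes[tis] * self.pc_blood_eth[tis]))
        rates.append(self.flows["slow"] / (self.volumes["slow_xyl"] * self.pc_blood_xyl["slow"]))
        rates.append(self.flows["slow"] / (self.volumes["slow_eth"] * self.pc_blood_eth["slow"]))
        for tis in ("stomach", "gut"):
            rates.append(self.flows[tis] / (self.volumes[tis] * self.pc_blood_eth[tis]))
        li_pool_eth = self.volumes["liver"] * self.pc_blood_eth["liver"]
        rates.append((self.flows["liver"]
                      + sum(v / k for v, k in zip(self.vmax_eth, self.km_eth)))
                     / li_pool_eth)
        li_pool_xyl = self.volumes["liver"] * self.pc_blood_xyl["liver"]
        rates.append((self.flows["liver"] + self.vmax_xyl / self.km_xyl) / li_pool_xyl)
        return float(max(rates))

    def pack(self) -> np.ndarray:
        """Pack into the flat array consumed by the jitted ODE core."""
        from . import _core as c

        p = np.zeros(c.NPAR)
        ps = self.params
        p[c.IP_QC] = self.cardiac_output
        p[c.IP_QALV] = self.alveolar_ventilation
        p[c.IP_QFA] = self.flows["fat"]
        p[c.IP_QRPD] = self.flows["rapid"]
        p[c.IP_QSPD] = self.flows["slow"]
        p[c.IP_QLI] = self.flows["liver"]
        p[c.IP_VFA] = self.volumes["fat"]
        p[c.IP_VRPD] = self.volumes["rapid"]
        p[c.IP_VSPDX] = self.volumes["slow_xyl"]
        p[c.IP_VLI] = self.volumes["liver"]
        p[c.IP_PBAX] = ps["PBAXYL"]
        p[c.IP_PFABX] = self.pc_blood_xyl["fat"]
        p[c.IP_PRPDBX] = self.pc_blood_xyl["rapid"]
        p[c.IP_PSPDBX] = self.pc_blood_xyl["slow"]
        p[c.IP_PLIBX] = self.pc_blood_xyl["liver"]
        p[c.IP_VMAXX] = self.vmax_xyl
        p[c.IP_KMX] = self.km_xyl
        p[c.IP_KI] = ps["KI"]
        p[c.IP_MODE] = float(INHIBITION_MODES.index(ps.inhibition_mode))
        p[c.IP_FMHA] = ps["f_MHA"]
        p[c.IP_MWRATIO] = ps["MW_MHA"] / ps["MW_xyl"]
        p[c.IP_K1] = ps["K_1"]
        p[c.IP_RURINE] = ps["R_urine"]
        p[c.IP_QST] = self.flows["stomach"]
        p[c.IP_QGU] = self.flows["gut"]
        p[c.IP_QLIA] = self.flows["liver_arterial"]
        p[c.IP_VST] = self.volumes["stomach"]
        p[c.IP_VGU] = self.volumes["gut"]
        p[c.IP_VSPDE] = self.volumes["slow_eth"]
        p[c.IP_PBAE] = ps["Pba_eth"]
        p[c.IP_PFABE] = self.pc_blood_eth["fat"]
        p[c.IP_PRPDBE] = self.pc_blood_eth["rapid"]
        p[c.IP_PSPDBE] = self.pc_blood_eth["slow"]
        p[c.IP_PLIBE] = self.pc_blood_eth["liver"]
        p[c.IP_PSTBE] = self.pc_blood_eth["stomach"]
        p[c.IP_PGUBE] = self.pc_blood_eth["gut"]
        for i in range(4):
            p[c.IP_VMAXE0 + i] = self.vmax_eth[i]
            p[c.IP_KME0 + i] = self.km_eth[i]
        p[c.IP_BELLY] = ps["BELLYPERM"]
        p[c.IP_GI] = ps["GIPERM"]
        p[c.IP_KEMAX] = ps["KE_max"]
        p[c.IP_KEMIN] = ps["KE_min"]
        p[c.IP_A50] = ps["A50_gastric"]
        p[c.IP_HILL] = ps["hill_gastric"]
        return p


def scale_vmax(vmax_invitro: float, mpy: float, liver_mass_g: float, mw: float) -> float:
    """In-vitro to in-vivo scaling of a maximal metabolic rate.

    pmol/min/mg microsomal protein -> mg/h whole liver:
    x 60 min/h, x MPY mg protein per g liver, x liver mass in g,
    x MW g/mol, x 1e-12 mol/pmol, x 1e3 mg/g.
    """
    return vmax_invitro * 60.0 * mpy * liver_mass_g * mw * 1e-9


def derive_physiology(params: ParameterSet) -> DerivedPhysiology:
    """Absolute per-individual physiology from a fractional parameter set.

    The aggregated remainders are always closed here — the rapidly perfused
    flow fraction is 1 minus the other flow fractions and the slowly
    perfused volume fraction is VT minus the other volume fractions — so
    the circulation conserves mass for *any* admissible combination of the
    varying fractions (the stored QRPDC/VSPDC entries are informational).
    """
    bw = params["BW"]
    qc = params["QCMC"] * bw**0.75
    liver_l = params["VLIC"] * bw
    liver_g = liver_l * 1000.0

    qrpdc = 1.0 - (params["QSPDC"] + params["QFAC"] + params["QLIC"])
    if qrpdc <= 0:
        raise ValueError("flow fractions exceed 1 (QSPDC+QFAC+QLIC >= 1)")
    flows = {
        "fat": params["QFAC"] * qc,
        "rapid": qrpdc * qc,
        "slow": params["QSPDC"] * qc,
        "liver": params["QLIC"] * qc,
        "stomach": params["QSTC"] * qc,
        "gut": params["QGUC"] * qc,
    }
    flows["liver_arterial"] = flows["liver"] - flows["stomach"] - flows["gut"]
    if flows["liver_arterial"] <= 0:
        raise ValueError("portal flows exceed total hepatic flow (QSTC+QGUC >= QLIC)")

    vspdc = params["VT"] - (params["VRPDC"] + params["VFAC"] + params["VLIC"])
    if vspdc <= 0:
        raise ValueError("volume fractions exceed VT")
    vspd_x = vspdc * bw
    volumes = {
        "fat": params["VFAC"] * bw,
        "rapid": params["VRPDC"] * bw,
        "slow_xyl": vspd_x,
        "slow_eth": vspd_x - (params["VSTC"] + params["VGUC"]) * bw,
        "liver": liver_l,
        "stomach": params["VSTC"] * bw,
        "gut": params["VGUC"] * bw,
    }
    if volumes["slow_eth"] <= 0:
        raise ValueError("stomach+gut volumes exceed the slowly perfused pool")

    pba = params["PBAXYL"]
    pc_blood_xyl = {
        "fat": params["PFAAXYL"] / pba,
        "rapid": params["PRPDAXYL"] / pba,
        "slow": params["PSPDAXYL"] / pba,
        "liver": params["PLIAXYL"] / pba,
    }
    pc_blood_eth = {
        "fat": params["Pfaa_eth"],
        "rapid": params["Prpda_eth"],
        "slow": params["Pspda_eth"],
        "liver": params["Plia_eth"],
        "stomach": params["Pst_eth"],
        "gut": params["PGU_eth"],
    }

    mpy = params["MPY"]
    vmax_xyl = scale_vmax(params["V_max2E1xyl"], mpy, liver_g, params["MW_xyl"])
    km_xyl = params["K_M2E1xyl"] * params["MW_xyl"] / 1000.0  # µmol/L -> mg/L
    vmax_eth = tuple(
        scale_vmax(params[v], mpy, liver_g, params["MW_eth"]) for v, _ in _ETH_PATHWAYS
    )
    km_eth = tuple(params[k] * params["MW_eth"] for _, k in _ETH_PATHWAYS)  # mM -> mg/L

    return DerivedPhysiology(
        params=params,
        cardiac_output=qc,
        alveolar_ventilation=params["QPMC"],
        flows=flows,
        volumes=volumes,
        liver_mass_g=liver_g,
        vmax_xyl=vmax_xyl,
        km_xyl=km_xyl,
        vmax_eth=vmax_eth,
        km_eth=km_eth,
        pc_blood_xyl=pc_blood_xyl,
        pc_blood_eth=pc_blood_eth,
    )


# --------------------------------------------------------------------------
# Dose planning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DosePlan:
    """Oral ethanol dose prepared for one volunteer."""

    ethanol_mass_g: float
    absolute_volume_ml: float
    final_volume_ml: float

    @property
    def dilution_factor(self) -> float:
        if self.absolute_volume_ml == 0:
            return 0.0
        return self.final_volume_ml / self.absolute_volume_ml


def ethanol_dose_plan(
    body_mass_kg: float,
    dose_per_kg: float = 0.8,
    density: float = ETHANOL_DENSITY,
    dilution_factor: float = 4.0,
) -> DosePlan:
    """Dose arithmetic for an oral ethanol dose diluted 1:4 in fruit juice.

    The dispensed mass is rounded to the gram; the measured-out volume of
    absolute ethanol is rounded to the mL from the *unrounded* mass.
    """
    if body_mass_kg < 0 or dose_per_kg < 0:
        raise ValueError("body mass and dose must be non-negative")
    mass_unrounded = body_mass_kg * dose_per_kg
    mass = round(mass_unrounded)
    abs_vol = round(mass_unrounded / density)
    return DosePlan(
        ethanol_mass_g=float(mass),
        absolute_volume_ml=float(abs_vol),
        final_volume_ml=float(abs_vol * dilution_factor),
    )
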