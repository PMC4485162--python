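"""Synthetic biological-monitoring data with the study's sampling structure.

The volunteer study's raw measurements were never deposited, so every
pipeline stage is exercised against synthetic datasets that emulate the
protocol: the blood/breath/urine sampling schedules, multiplicative
lognormal assay noise at the published coefficients of variation, detection
limits, and the per-volunteer channel-availability pattern (most
no-ethanol-day blood samples were lost to imperfect vial sealing).

This module also hosts the embedded measured tables (per-volunteer
physiology and dose planning) and their cohort summaries.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import IndividualPhysiology, ParameterSet
from .simulate import (ExposureScenario, SolverConfig, default_study_scenario,
                       simulate)
from .units import MW_CREATININE

__all__ = [
    "AssaySpec",
    "ChannelData",
    "BMDataset",
    "embedded_study_tables",
    "load_volunteers",
    "volunteer_physiology",
    "cohort_summary",
    "generate_cohort",
    "generate_bm",
    "write_bm_csv",
    "read_bm_csv",
]

CHANNELS = ("blood_xylene", "breath_xylene", "urine_mha")

#: m-xylene molar mass (g/mol), for the blood-channel µmol/L conversion.
_MW_XYL = 106.17
#: 3-MHA molar mass (g/mol), for the urine LOD conversion.
_MW_MHA = 193.2


@dataclass(frozen=True)
class AssaySpec:
    """Detection limits and coefficients of variation per channel.

    Blood m-xylene: LOD 0.1 µmol/L, intra/inter-assay CV 5 %/10 %.
    Urinary 3-MHA: LOD 40 µmol/L (converted to g/g at the individual's
    creatinine), intra/inter CV 2 %/5 %.  The breath channel has no
    published CV; 10 % is assumed.  The effective noise CV per channel is
    sqrt(intra^2 + inter^2) by default.
    """

    blood_lod_umol: float = 0.1
    blood_cv_intra: float = 0.05
    blood_cv_inter: float = 0.10
    urine_lod_umol: float = 40.0
    urine_cv_intra: float = 0.02
    urine_cv_inter: float = 0.05
    breath_cv: float = 0.10
    combine_cv: bool = True

    def __post_init__(self):
        for name in ("blood_cv_intra", "blood_cv_inter", "urine_cv_intra",
                     "urine_cv_inter", "breath_cv"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.blood_lod_umol < 0 or self.urine_lod_umol < 0:
            raise ValueError("detection limits must be non-negative")

    def cv(self, channel: str) -> float:
        if channel == "blood_xylene":
            intra, inter = self.blood_cv_intra, self.blood_cv_inter
        elif channel == "urine_mha":
            intra, inter = self.urine_cv_intra, self.urine_cv_inter
        elif channel == "breath_xylene":
            return self.breath_cv
        else:
            raise KeyError(f"unknown channel {channel!r}")
        return math.hypot(intra, inter) if self.combine_cv else intra

    def lod(self, channel: str, creatinine_mmol: float) -> float:
        """LOD in the channel's reporting unit."""
        if channel == "blood_xylene":
            return self.blood_lod_umol
        if channel == "urine_mha":
            mg_l = self.urine_lod_umol * _MW_MHA / 1000.0
            return mg_l / (creatinine_mmol * MW_CREATININE)
        return 0.0

    @classmethod
    def uniform_cv(cls, cv: float) -> "AssaySpec":
        """All channels at one noise CV, detection limits disabled."""
        return cls(blood_lod_umol=0.0, urine_lod_umol=0.0,
                   blood_cv_intra=cv, blood_cv_inter=0.0,
                   urine_cv_intra=cv, urine_cv_inter=0.0,
                   breath_cv=cv, combine_cv=True)

    @classmethod
    def with_cv(cls, cvs: Mapping[str, float]) -> "AssaySpec":
        return cls(blood_lod_umol=0.0, urine_lod_umol=0.0,
                   blood_cv_intra=cvs.get("blood_xylene", 0.0), blood_cv_inter=0.0,
                   urine_cv_intra=cvs.get("urine_mha", 0.0), urine_cv_inter=0.0,
                   breath_cv=cvs.get("breath_xylene", 0.0))


@dataclass
class ChannelData:
    """One monitored channel of one dataset."""

    times: np.ndarray
    values: np.ndarray
    below_lod: np.ndarray
    unit: str
    lod: float = 0.0
    cv: float = 0.0
    available: bool = True


@dataclass
class BMDataset:
    """Per-volunteer biological-monitoring time series.

    ``truth`` retains the generating parameter set for synthetic data.
    """

    volunteer_id: str
    ethanol: bool
    exposure_ppm: float
    channels: Dict[str, ChannelData]
    truth: Optional[ParameterSet] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, ch in self.channels.items():
            if not ch.available:
                continue
            for t, v, f in zip(ch.times, ch.values, ch.below_lod):
                rows.append({"volunteer_id": self.volunteer_id, "channel": name,
                             "time_h": t, "value": v, "unit": ch.unit,
                             "below_lod": bool(f)})
        return pd.DataFrame(rows, columns=["volunteer_id", "channel", "time_h",
                                           "value", "unit", "below_lod"])


_CHANNEL_UNITS = {"blood_xylene": "umol/L", "breath_xylene": "ppm",
                  "urine_mha": "g/g", "blood_ethanol": "mg/L"}


# --------------------------------------------------------------------------
# Embedded measured tables
# --------------------------------------------------------------------------

def _read_resource(name: str) -> pd.DataFrame:
    text = resources.files("xyleth.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text))


def load_volunteers() -> pd.DataFrame:
    """The eight volunteers' measured physiology (one has no blood:air PC)."""
    return _read_resource("volunteers.csv")


def load_dose_table() -> pd.DataFrame:
    """Per-volunteer oral ethanol dose planning and gastric-emptying rates."""
    return _read_resource("ethanol_doses.csv")


def load_protocols() -> pd.DataFrame:
    """Exposure concentration and channel availability per volunteer/day."""
    df = _read_resource("protocols.csv")
    df["ethanol"] = df["ethanol"].map({"yes": True, "no": False})
    return df


def embedded_study_tables() -> Dict[str, pd.DataFrame]:
    return {"volunteers": load_volunteers(), "doses": load_dose_table(),
            "protocols": load_protocols()}


def volunteer_physiology(volunteer: str) -> IndividualPhysiology:
    df = load_volunteers().set_index("volunteer")
    if volunteer not in df.index:
        raise KeyError(f"unknown volunteer {volunteer!r}; have {list(df.index)}")
    r = df.loc[volunteer]
    pba = None if pd.isna(r["blood_air_pc_xylene"]) else float(r["blood_air_pc_xylene"])
    return IndividualPhysiology(
        body_mass=float(r["body_mass_kg"]), height=float(r["height_m"]),
        fat_fraction=float(r["fat_fraction"]),
        alveolar_ventilation=float(r["alveolar_ventilation_L_h"]),
        urine_flow=float(r["urine_flow_L_h"]),
        urinary_creatinine=float(r["urinary_creatinine_mmol_L"]),
        blood_air_pc_xylene=pba, age=float(r["age"]), volunteer=volunteer)


def cohort_summary(records: pd.DataFrame | Sequence[float], field_name: Optional[str] = None
                   ) -> Dict[str, float]:
    """Mean, sample sd (n-1) and CV of one measured field across a cohort."""
    if isinstance(records, pd.DataFrame):
        if field_name is None:
            raise ValueError("field_name is required with a DataFrame")
        values = records[field_name].dropna().to_numpy(dtype=float)
    else:
        values = np.asarray([v for v in records if v is not None and np.isfinite(v)],
                            dtype=float)
    if values.size < 2:
        raise ValueError("need at least two non-missing values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return {"mean": mean, "sd": sd, "cv": sd / mean if mean else np.nan,
            "n": int(values.size)}


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def generate_cohort(n: int, seed: int = 0,
                    bmi_range: tuple = (18.5, 30.0)) -> List[IndividualPhysiology]:
    """Draw a virtual cohort around the measured volunteers' statistics.

    Body mass and height are drawn jointly with accept/reject enforcement
    of the BMI plausibility range; the remaining fields use normal or
    lognormal distributions parameterised by the cohort mean/SD.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    vols = load_volunteers()
    stats = {f: cohort_summary(vols, f) for f in
             ("body_mass_kg", "height_m", "fat_fraction",
              "alveolar_ventilation_L_h", "urine_flow_L_h",
              "urinary_creatinine_mmol_L", "blood_air_pc_xylene")}

    def trunc_normal(mean, sd, lo=1e-6):
        while True:
            v = rng.normal(mean, sd)
            if v > lo:
                return v

    def lognormal(mean, sd):
        sigma = math.sqrt(math.log(1.0 + (sd / mean) ** 2))
        mu = math.log(mean) - 0.5 * sigma**2
        return float(rng.lognormal(mu, sigma))

    out = []
    for i in range(n):
        while True:
            bw = trunc_normal(stats["body_mass_kg"]["mean"], stats["body_mass_kg"]["sd"])
            h = trunc_normal(stats["height_m"]["mean"], stats["height_m"]["sd"])
            if bmi_range[0] <= bw / h**2 <= bmi_range[1]:
                break
        while True:
            fat = lognormal(stats["fat_fraction"]["mean"], stats["fat_fraction"]["sd"])
            if fat < 0.6:
                break
        out.append(IndividualPhysiology(
            body_mass=bw, height=h, fat_fraction=fat,
            alveolar_ventilation=trunc_normal(
                stats["alveolar_ventilation_L_h"]["mean"],
                stats["alveolar_ventilation_L_h"]["sd"]),
            urine_flow=trunc_normal(stats["urine_flow_L_h"]["mean"],
                                    stats["urine_flow_L_h"]["sd"], lo=0.005),
            urinary_creatinine=trunc_normal(
                stats["urinary_creatinine_mmol_L"]["mean"],
                stats["urinary_creatinine_mmol_L"]["sd"]),
            blood_air_pc_xylene=trunc_normal(
                stats["blood_air_pc_xylene"]["mean"],
                stats["blood_air_pc_xylene"]["sd"]),
            age=float(rng.integers(16, 66)),
            volunteer=f"V{i:03d}"))
    return out


# --------------------------------------------------------------------------
# Synthetic BM generation
# --------------------------------------------------------------------------

def generate_bm(params: ParameterSet, scenario: ExposureScenario,
                assay: Optional[AssaySpec] = None,
                seed: int = 0,
                volunteer_id: str = "synthetic",
                availability: Optional[Mapping[str, bool]] = None,
                solver: Optional[SolverConfig] = None) -> BMDataset:
    """Simulate a scenario and sample it like the volunteer protocol.

    Each sampled value is multiplied by lognormal noise exp(sigma*Z) with
    sigma = sqrt(ln(1+cv^2)) (median-unbiased, matching the calibration
    error model); values under the channel's detection limit are flagged.
    ``availability`` can blank whole channels to mimic lost samples.
    """
    assay = assay or AssaySpec()
    rng = np.random.default_rng(seed)
    out = simulate(params, scenario, solver)
    cre = params["CREmmol"]
    channels: Dict[str, ChannelData] = {}
    for name in CHANNELS:
        tab = out.channel(name)
        times = tab["time_h"].to_numpy(dtype=float)
        pred = tab["value"].to_numpy(dtype=float)
        cv = assay.cv(name)
        if cv > 0:
            sigma = math.sqrt(math.log(1.0 + cv**2))
            noise = np.exp(sigma * rng.standard_normal(times.size))
        else:
            noise = np.ones(times.size)
        values = pred * noise
        lod = assay.lod(name, cre)
        # non-positive values (pre-exposure baselines) are always censored
        below = (values < lod) | (values <= 0.0)
        avail = True if availability is None else bool(availability.get(name, True))
        channels[name] = ChannelData(times=times, values=values,
                                     below_lod=below, unit=_CHANNEL_UNITS[name],
                                     lod=lod, cv=cv, available=avail)
    return BMDataset(volunteer_id=volunteer_id, ethanol=scenario.ethanol,
                     exposure_ppm=scenario.exposure_ppm, channels=channels,
                     truth=params, meta={"seed": seed})


def generate_study(seed: int = 0, assay: Optional[AssaySpec] = None,
                   apply_missingness: bool = True,
                   solver: Optional[SolverConfig] = None) -> List[BMDataset]:
    """Both study days for all eight volunteers, with the availability
    pattern of the real campaign applied to the no-ethanol blood channel."""
    proto = load_protocols()
    rng = np.random.default_rng(seed)
    datasets = []
    for _, row in proto.iterrows():
        vol = row["volunteer"]
        phys = volunteer_physiology(vol)
        ps = ParameterSet.central().for_individual(phys)
        scen = default_study_scenario(with_ethanol=bool(row["ethanol"]),
                                      exposure_ppm=float(row["exposure_ppm"]))
        availability = None
        if apply_missingness:
            availability = {ch: bool(row[ch]) for ch in CHANNELS}
        ds = generate_bm(ps, scen, assay=assay, seed=int(rng.integers(2**31)),
                         volunteer_id=vol, availability=availability,
                         solver=solver)
        datasets.append(ds)
    return datasets


# --------------------------------------------------------------------------
# CSV round trip
# --------------------------------------------------------------------------

def write_bm_csv(datasets: BMDataset | Sequence[BMDataset], path) -> pd.DataFrame:
    if isinstance(datasets, BMDataset):
        datasets = [datasets]
    df = pd.concat([ds.to_frame() for ds in datasets], ignore_index=True)
    meta = {ds.volunteer_id: {"ethanol": ds.ethanol, "exposure_ppm": ds.exposure_ppm}
            for ds in datasets}
    df.to_csv(path, index=False, float_format="%.12g")
    manifest = str(path) + ".meta.json"
    with open(manifest, "w") as fh:
        json.dump(meta, fh, indent=1)
    return df


def read_bm_csv(path, volunteer_id: Optional[str] = None,
                ethanol: Optional[bool] = None,
                exposure_ppm: Optional[float] = None) -> BMDataset:
    """Rebuild a BMDataset from a long-format CSV (one volunteer)."""
    from .simulate import read_timeseries

    df = read_timeseries(path)
    if volunteer_id is not None:
        df = df[df["volunteer_id"] == volunteer_id]
    if df.empty:
        raise ValueError(f"no rows for volunteer {volunteer_id!r}")
    if ethanol is None or exposure_ppm is None:
        try:
            with open(str(path) + ".meta.json") as fh:
                meta = json.load(fh)
            vid = volunteer_id or df["volunteer_id"].iloc[0]
            ethanol = meta[vid]["ethanol"] if ethanol is None else ethanol
            exposure_ppm = meta[vid]["exposure_ppm"] if exposure_ppm is None else exposure_ppm
        except (OSError, KeyError):
            raise ValueError(
                "ethanol flag and exposure_ppm must be given when no manifest "
                "is present")
    channels = {}
    for name, grp in df.groupby("channel"):
        channels[name] = ChannelData(
            times=grp["time_h"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
            below_lod=grp["below_lod"].to_numpy(dtype=bool),
            unit=grp["unit"].iloc[0])
    for name in CHANNELS:
        if name not in channels:
            channels[name] = ChannelData(times=np.empty(0), values=np.empty(0),
                                         below_lod=np.empty(0, bool),
                                         unit=_CHANNEL_UNITS[name], available=False)
    return BMDataset(volunteer_id=volunteer_id or df["volunteer_id"].iloc[0],
                     ethanol=bool(ethanol), exposure_ppm=float(exposure_ppm),
                     channels=channels)
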