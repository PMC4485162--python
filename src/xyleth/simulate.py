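"""Exposure scenarios and the scenario integrator.

A scenario describes the inhalation profile (piecewise-constant ppm), the
optional oral ethanol dose, the micturition (void) schedule and the
observation schedules of the three monitored channels.  The integrator
splits the timeline at every discontinuity — exposure on/off, the drinking
window, and each void — and restarts the solver across each segment; at a
void the bladder metabolite mass and urine volume are recorded and reset.

Two solver backends are provided: a fixed-step RK4 driver compiled with
numba (default; fast enough for sensitivity analysis and MCMC, where the
model is evaluated thousands of times) and scipy's LSODA as a stiff-capable
reference.  A convergence test in the suite checks they agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _core
from .engine import ObservableSet, observables
from .parameters import ParameterSet, derive_physiology
from .units import ppm_to_mg_per_l

__all__ = [
    "ExposureScenario",
    "SolverConfig",
    "SimulationOutput",
    "default_study_scenario",
    "simulate",
    "export_timeseries",
    "read_timeseries",
    "BLOOD_TIMES",
    "BREATH_TIMES",
    "URINE_TIMES",
    "MEASURED_EXPOSURE_PPM",
]

logger = logging.getLogger(__name__)

#: Venous blood sampling schedule of the volunteer protocol (h).
BLOOD_TIMES = (0.0, 0.3, 0.7, 1.0, 2.0, 3.0, 4.0, 4.33, 4.67, 5.0, 6.0, 7.0, 8.0, 23.0)
#: End-exhaled breath sampling schedule (h).
BREATH_TIMES = (0.0, 4.017, 4.33, 4.67, 5.0, 6.0, 7.0, 8.0, 24.0)
#: Urine collection / void schedule (h).
URINE_TIMES = (0.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 24.0, 27.0, 31.0)

#: Measured chamber concentrations by volunteer and day (ppm).
MEASURED_EXPOSURE_PPM = {
    ("A", False): 45.5, ("B", False): 45.5, ("C", False): 45.5, ("D", False): 45.5,
    ("E", False): 44.1, ("F", False): 44.1, ("G", False): 44.1, ("H", False): 44.1,
    ("A", True): 43.0, ("B", True): 43.0, ("C", True): 45.1, ("D", True): 43.0,
    ("E", True): 45.1, ("F", True): 45.1, ("G", True): 43.0, ("H", True): 45.1,
}

_CHANNEL_UNITS = {
    "blood_xylene": "umol/L",
    "breath_xylene": "ppm",
    "urine_mha": "g/g",
    "blood_ethanol": "mg/L",
}


@dataclass(frozen=True)
class ExposureScenario:
    """One exposure day: inhalation profile, oral dose, schedules."""

    exposure_ppm: float = 50.0
    exposure_start: float = 0.0
    exposure_duration: float = 4.0
    ethanol: bool = False
    #: g/kg; None means "use the PORALDOSE parameter" when ``ethanol`` is set.
    ethanol_dose_g_per_kg: Optional[float] = None
    drink_start: float = -0.5
    drink_duration: Optional[float] = None   # None -> DRINKTIME parameter
    void_times: Tuple[float, ...] = URINE_TIMES
    horizon: float = 31.0
    blood_times: Tuple[float, ...] = BLOOD_TIMES
    breath_times: Tuple[float, ...] = BREATH_TIMES

    def __post_init__(self):
        vt = np.asarray(self.void_times)
        if vt.size and np.any(np.diff(vt) <= 0):
            raise ValueError("void_times must be strictly increasing")
        last_obs = max(
            [self.exposure_start + self.exposure_duration]
            + list(self.blood_times) + list(self.breath_times) + list(self.void_times)
        )
        if self.horizon < last_obs:
            raise ValueError("horizon must cover every observation time")
        if self.exposure_ppm < 0:
            raise ValueError("exposure concentration must be non-negative")

    @property
    def t_start(self) -> float:
        t0 = min(0.0, self.exposure_start)
        if self.ethanol:
            t0 = min(t0, self.drink_start)
        return t0

    def inhaled_ppm(self, t: float) -> float:
        # half-open at the start: samples taken at the nominal start time are
        # pre-exposure (the volunteer has not yet entered the chamber)
        if self.exposure_start < t <= self.exposure_start + self.exposure_duration:
            return self.exposure_ppm
        return 0.0


def default_study_scenario(with_ethanol: bool = False, exposure_ppm: float = 50.0,
                           volunteer: Optional[str] = None) -> ExposureScenario:
    """The study protocol: 4 h inhalation with the standard sampling grids.

    With ethanol, 0.8 g/kg (the PORALDOSE central value) is drunk over
    15 min starting 30 min before the exposure.  Passing ``volunteer``
    substitutes the measured chamber concentration for that volunteer/day.
    """
    if volunteer is not None:
        exposure_ppm = MEASURED_EXPOSURE_PPM[(volunteer.upper(), bool(with_ethanol))]
    return ExposureScenario(exposure_ppm=exposure_ppm, ethanol=with_ethanol)


@dataclass(frozen=True)
class SolverConfig:
    """Integration settings.

    method: "rk4" (fixed-step, jitted; default) or "lsoda" (scipy, adaptive).
    dt: RK4 step (h).  rtol/atol: LSODA tolerances.  dense_dt: spacing of the
    dense output grid (h).
    """

    method: str = "rk4"
    dt: float = 0.005
    rtol: float = 1e-8
    atol: float = 1e-10
    dense_dt: float = 0.01

    def __post_init__(self):
        if self.method not in ("rk4", "lsoda"):
            raise ValueError("method must be 'rk4' or 'lsoda'")
        if min(self.dt, self.dense_dt) <= 0:
            raise ValueError("steps must be positive")


@dataclass
class SimulationOutput:
    """Trajectories, per-void urine records and balance diagnostics."""

    t: np.ndarray                    # dense grid (h)
    states: np.ndarray               # (n, NSTATE) on the dense grid
    obs: ObservableSet               # observables on the dense grid
    channels: Dict[str, pd.DataFrame]  # per-channel observation-time tables
    voids: pd.DataFrame              # per-void records
    balance: Dict[str, float]        # relative mass-balance residuals
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def channel(self, name: str) -> pd.DataFrame:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; have {sorted(self.channels)}") from None


def _segment_inputs(scenario: ExposureScenario, params: ParameterSet, t0: float, t1: float):
    """Constant (inhaled mg/L, drink mg/h) inputs for segment [t0, t1]."""
    tm = 0.5 * (t0 + t1)
    c_inh = ppm_to_mg_per_l(scenario.inhaled_ppm(tm), params["MW_xyl"])
    drink = 0.0
    if scenario.ethanol:
        dur = scenario.drink_duration if scenario.drink_duration is not None \
            else params["DRINKTIME"]
        dose_per_kg_mg = (
            params["PORALDOSE"] if scenario.ethanol_dose_g_per_kg is None
            else scenario.ethanol_dose_g_per_kg * 1000.0
        )
        if scenario.drink_start <= tm < scenario.drink_start + dur:
            drink = dose_per_kg_mg * params["BW"] / dur
    return c_inh, drink


def _breakpoints(scenario: ExposureScenario, params: ParameterSet) -> np.ndarray:
    pts = {scenario.t_start, scenario.horizon,
           scenario.exposure_start,
           scenario.exposure_start + scenario.exposure_duration}
    if scenario.ethanol:
        dur = scenario.drink_duration if scenario.drink_duration is not None \
            else params["DRINKTIME"]
        pts |= {scenario.drink_start, scenario.drink_start + dur}
    pts |= set(scenario.void_times)
    arr = np.array(sorted(p for p in pts
                          if scenario.t_start <= p <= scenario.horizon))
    return arr


def _integrate_lsoda(y, t0, t1, p, c_inh, drink, t_eval, out, ptr, cfg):
    def f(t, yy):
        dy = np.empty(_core.NSTATE)
        _core.rhs(yy, p, c_inh, drink, dy)
        return dy

    sub = []
    while ptr + len(sub) < t_eval.size and t_eval[ptr + len(sub)] <= t1 + 1e-12:
        sub.append(t_eval[ptr + len(sub)])
    eval_pts = list(sub)
    if not eval_pts or abs(eval_pts[-1] - t1) > 1e-12:
        eval_pts.append(t1)  # always land exactly on the segment end
    sol = solve_ivp(f, (t0, t1), y, method="LSODA", t_eval=eval_pts,
                    rtol=cfg.rtol, atol=cfg.atol)
    if not sol.success:
        raise RuntimeError(
            f"LSODA failed in segment [{t0}, {t1}]: {sol.message}; "
            f"last good state at t={sol.t[-1] if sol.t.size else t0}")
    for k in range(len(sub)):
        out[ptr + k, :] = sol.y[:, k]
    y[:] = sol.y[:, -1]
    return ptr + len(sub)


def simulate(params: ParameterSet, scenario: ExposureScenario,
             solver: Optional[SolverConfig] = None,
             extra_times: Optional[Sequence[float]] = None) -> SimulationOutput:
    """Integrate the coupled model over one scenario.

    Returns trajectories on a dense grid that always contains the channel
    observation times (and any ``extra_times``), per-void urine records, and
    mass-balance residuals for both chemicals and the metabolite.
    """
    cfg = solver or SolverConfig()
    phys = derive_physiology(params)
    p = phys.pack()
    # cap the explicit step so the fastest mode stays well inside the RK4
    # stability region (lambda * dt <= 2) for any parameter draw
    dt_eff = min(cfg.dt, 2.0 / phys.max_rate_constant())

    t0 = scenario.t_start
    grid = np.arange(t0, scenario.horizon + 0.5 * cfg.dense_dt, cfg.dense_dt)
    t_eval = np.unique(np.concatenate([
        grid,
        np.asarray(scenario.blood_times, dtype=float),
        np.asarray(scenario.breath_times, dtype=float),
        np.asarray(scenario.void_times, dtype=float),
        np.asarray(extra_times if extra_times is not None else (), dtype=float),
        [scenario.horizon],
    ]))
    t_eval = t_eval[(t_eval >= t0) & (t_eval <= scenario.horizon)]

    y = np.zeros(_core.NSTATE)
    out = np.zeros((t_eval.size, _core.NSTATE))
    ptr = 0
    # observation points exactly at the start
    while ptr < t_eval.size and t_eval[ptr] <= t0 + 1e-12:
        out[ptr] = y
        ptr += 1

    void_set = set(np.round(np.asarray(scenario.void_times, dtype=float), 9))
    void_rows = []
    voided_mha = 0.0
    bps = _breakpoints(scenario, params)
    n_segments = 0
    for a, b in zip(bps[:-1], bps[1:]):
        if b <= a + 1e-12:
            continue
        c_inh, drink = _segment_inputs(scenario, params, a, b)
        if cfg.method == "rk4":
            ptr = _core.integrate_segment(y, a, b, dt_eff, p, c_inh, drink,
                                          t_eval, out, ptr)
        else:
            ptr = _integrate_lsoda(y, a, b, p, c_inh, drink, t_eval, out, ptr, cfg)
        n_segments += 1
        if round(b, 9) in void_set:
            vol = y[_core.IX_UVOL]
            mha = y[_core.IX_MHAB]
            conc = np.nan
            if vol > 1e-12:
                from .units import MW_CREATININE
                conc = (mha / vol) / (params["CREmmol"] * MW_CREATININE)
            void_rows.append({"t": b, "volume_L": vol, "mha_mg": mha,
                              "c_urine_gg": conc})
            voided_mha += mha
            y[_core.IX_MHAB] = 0.0
            y[_core.IX_UVOL] = 0.0
            # state rows recorded exactly at the void keep pre-void contents

    # fill any trailing points (t == horizon edge cases)
    while ptr < t_eval.size:
        out[ptr] = y
        ptr += 1

    c_inh_grid = np.array([ppm_to_mg_per_l(scenario.inhaled_ppm(t), params["MW_xyl"])
                           for t in t_eval])
    obs = observables(out, t_eval, phys, c_inh_grid)

    balance = _mass_balance(out, y, params, voided_mha)
    for chem, res in balance.items():
        if res > 1e-3:
            logger.warning("mass balance residual %.2e for %s exceeds 1e-3", res, chem)

    channels = _channel_tables(scenario, t_eval, obs, void_rows)
    voids = pd.DataFrame(void_rows, columns=["t", "volume_L", "mha_mg", "c_urine_gg"])
    return SimulationOutput(
        t=t_eval, states=out, obs=obs, channels=channels, voids=voids,
        balance=balance,
        diagnostics={"method": cfg.method, "n_segments": n_segments,
                     "solver_config": cfg},
    )


def _mass_balance(states: np.ndarray, y_end: np.ndarray, params: ParameterSet,
                  voided_mha: float) -> Dict[str, float]:
    c = _core
    body_x = y_end[c.IX_FA] + y_end[c.IX_RPD] + y_end[c.IX_SPD] + y_end[c.IX_LI]
    intake_x = y_end[c.IX_INH]
    res_x = abs(intake_x - (body_x + y_end[c.IX_MET] + y_end[c.IX_EXH]))
    res_x /= max(intake_x, 1e-12)

    body_e = (y_end[c.IE_STL] + y_end[c.IE_GUL] + y_end[c.IE_ST] + y_end[c.IE_GU]
              + y_end[c.IE_FA] + y_end[c.IE_RPD] + y_end[c.IE_SPD] + y_end[c.IE_LI])
    intake_e = y_end[c.IE_ING]
    res_e = abs(intake_e - (body_e + y_end[c.IE_MET] + y_end[c.IE_EXH]))
    res_e = res_e / max(intake_e, 1e-12) if intake_e > 0 else res_e

    produced = params["f_MHA"] * y_end[c.IX_MET] * (params["MW_MHA"] / params["MW_xyl"])
    held = y_end[c.IX_MHA] + y_end[c.IX_MHAB] + voided_mha
    res_m = abs(produced - held) / max(produced, 1e-12) if produced > 0 else 0.0
    return {"xylene": float(res_x), "ethanol": float(res_e), "mha": float(res_m)}


def _channel_tables(scenario, t_eval, obs: ObservableSet, void_rows):
    def pick(times, values):
        idx = np.searchsorted(t_eval, np.asarray(times, dtype=float))
        idx = np.clip(idx, 0, t_eval.size - 1)
        return values[idx]

    channels = {}
    bt = np.asarray(scenario.blood_times, dtype=float)
    channels["blood_xylene"] = pd.DataFrame(
        {"time_h": bt, "value": pick(bt, obs.cv_xyl_umol), "unit": "umol/L"})
    channels["blood_ethanol"] = pd.DataFrame(
        {"time_h": bt, "value": pick(bt, obs.c_blood_eth), "unit": "mg/L"})
    rt = np.asarray(scenario.breath_times, dtype=float)
    channels["breath_xylene"] = pd.DataFrame(
        {"time_h": rt, "value": pick(rt, obs.cx_ppm), "unit": "ppm"})
    vr = [r for r in void_rows if np.isfinite(r["c_urine_gg"])]
    channels["urine_mha"] = pd.DataFrame(
        {"time_h": [r["t"] for r in vr], "value": [r["c_urine_gg"] for r in vr],
         "unit": "g/g"})
    return channels


# --------------------------------------------------------------------------
# Long-format CSV I/O
# --------------------------------------------------------------------------

def export_timeseries(output: SimulationOutput, path, volunteer_id: str = "sim",
                      channels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Write the channel tables as a long-format CSV.

    Columns: volunteer_id, channel, time_h, value, unit, below_lod.
    Values are written with 12 significant digits so a read-back round trip
    is lossless at that precision.
    """
    rows = []
    if channels is None:
        channels = sorted(output.channels)
    for name in channels:
        tab = output.channel(name)
        for _, r in tab.iterrows():
            rows.append({"volunteer_id": volunteer_id, "channel": name,
                         "time_h": r["time_h"], "value": r["value"],
                         "unit": r["unit"], "below_lod": False})
    df = pd.DataFrame(rows, columns=["volunteer_id", "channel", "time_h",
                                     "value", "unit", "below_lod"])
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_timeseries(path) -> pd.DataFrame:
    """Read a long-format biological-monitoring CSV, validating each row."""
    df = pd.read_csv(path)
    required = ["volunteer_id", "channel", "time_h", "value", "unit", "below_lod"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"malformed timeseries CSV: missing columns {missing}")
    for i, row in df.iterrows():
        if row["channel"] in _CHANNEL_UNITS and row["unit"] != _CHANNEL_UNITS[row["channel"]]:
            raise ValueError(
                f"malformed timeseries CSV at row {i}: channel {row['channel']!r} "
                f"should carry unit {_CHANNEL_UNITS[row['channel']]!r}, "
                f"got {row['unit']!r}")
        if not np.isfinite(row["time_h"]):
            raise ValueError(f"malformed timeseries CSV at row {i}: bad time")
    return df
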