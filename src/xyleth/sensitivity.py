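"""Two-phase global sensitivity analysis: Morris screening, then eFAST.

Phase one uses the Morris elementary-effects design to discard parameters
with negligible influence; phase two computes variance-based main (Si) and
total (STi) effect indices with the extended Fourier Amplitude Sensitivity
Test on the surviving subset, over time, for each monitored channel.
Parameters are varied over their prior *distributions*: the space-filling
designs live on the unit hypercube and are pushed through each prior's
(truncation-aware) quantile function.

The eFAST estimator follows the standard cyclic frequency-assignment
scheme: the parameter of interest takes the largest frequency
``omega_max = (N-1)//(2M)``; the complementary set takes frequencies no
larger than ``omega_max/(2M)``.  Si sums the spectral power at the first M
harmonics of ``omega_max``; STi is one minus the share of power below
``omega_max/2``.  Indices are averaged over ``Nr`` random-phase resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .parameters import ParameterSet, PriorSpec
from .simulate import ExposureScenario, SimulationOutput, SolverConfig, simulate

__all__ = [
    "MorrisResult",
    "FastResult",
    "LowryData",
    "morris_screen",
    "select_for_efast",
    "efast",
    "timewise_sa",
    "lowry",
    "plot_lowry",
    "make_pbpk_model_fn",
    "CHANNEL_WINDOWS",
    "SUMMARY_TIMES",
]

logger = logging.getLogger(__name__)

#: SA evaluation window per channel (h): the phases of greatest change.
CHANNEL_WINDOWS = {"cv_xyl": (0.0, 8.0), "cx_ppm": (0.0, 10.0), "c_urine": (0.0, 15.0)}
#: Representative snapshot times per channel (h).
SUMMARY_TIMES = {"cv_xyl": (3.0, 6.0), "cx_ppm": (3.0, 6.0), "c_urine": (6.0, 10.0)}


# --------------------------------------------------------------------------
# Morris elementary-effects screening
# --------------------------------------------------------------------------

@dataclass
class MorrisResult:
    """mu* (mean absolute elementary effect) and sigma per parameter.

    ``mu_star``/``sigma`` have shape (k, n_out) where n_out is the number of
    model outputs (e.g. time points, possibly across channels).
    """

    names: List[str]
    mu_star: np.ndarray
    sigma: np.ndarray
    r: int
    p: int
    output_labels: Optional[List[str]] = None

    def score(self) -> pd.Series:
        """Max mu* across outputs — the screening score."""
        return pd.Series(self.mu_star.max(axis=1), index=self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mu_star_max": self.mu_star.max(axis=1),
            "mu_star_mean": self.mu_star.mean(axis=1),
            "sigma_max": self.sigma.max(axis=1),
        }, index=self.names)


def morris_screen(model_fn: Callable[[np.ndarray], np.ndarray],
                  priors: Mapping[str, PriorSpec],
                  r: int = 10, p: int = 4,
                  seed: int | np.random.Generator = 0,
                  quantile_bounds: Tuple[float, float] = (0.0, 1.0)) -> MorrisResult:
    """Morris one-at-a-time screening over the priors' quantile space.

    ``model_fn`` maps a natural-scale parameter vector (ordered as
    ``priors``) to a scalar or 1-d output array.  ``r`` trajectories on a
    ``p``-level grid with step ``delta = p/(2(p-1))``; elementary effects
    are computed on the quantile scale so parameters are comparable.
    ``quantile_bounds`` restricts the scanned band of each distribution
    (useful to keep unbounded priors away from their extreme tails).
    """
    if r < 2:
        raise ValueError("at least 2 trajectories are required")
    if p < 2 or p % 2:
        raise ValueError("the number of levels p must be even and >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(priors)
    k = len(names)
    delta = p / (2.0 * (p - 1.0))
    levels = np.arange(p) / (p - 1.0)
    base_levels = levels[levels <= 1.0 - delta + 1e-12]
    qlo, qhi = quantile_bounds

    def evaluate(u: np.ndarray) -> np.ndarray:
        q = qlo + u * (qhi - qlo)
        x = np.array([priors[n].ppf(q[j]) for j, n in enumerate(names)], dtype=float)
        return np.atleast_1d(np.asarray(model_fn(x), dtype=float))

    ees: List[List[np.ndarray]] = [[] for _ in range(k)]
    for _ in range(r):
        u = rng.choice(base_levels, size=k)
        sign = np.where(rng.random(k) < 0.5, -1.0, 1.0)
        # flip directions that would leave the cube
        for j in range(k):
            if u[j] + sign[j] * delta > 1.0 + 1e-12 or u[j] + sign[j] * delta < -1e-12:
                sign[j] = -sign[j]
        y = evaluate(u)
        for j in rng.permutation(k):
            u2 = u.copy()
            u2[j] = u[j] + sign[j] * delta
            y2 = evaluate(u2)
            ees[j].append((y2 - y) / (sign[j] * delta))
            u, y = u2, y2
    n_out = ees[0][0].size
    mu_star = np.empty((k, n_out))
    sig = np.empty((k, n_out))
    n_bad = 0
    for j in range(k):
        arr = np.vstack(ees[j])
        n_bad += int(np.isnan(arr).any(axis=1).sum())
        with np.errstate(invalid="ignore"):
            mu_star[j] = np.nanmean(np.abs(arr), axis=0)
            sig[j] = np.nanstd(arr, axis=0, ddof=1)
    if n_bad:
        logger.warning("%d elementary effects were non-finite and ignored", n_bad)
    return MorrisResult(names=names, mu_star=mu_star, sigma=sig, r=r, p=p)


def select_for_efast(morris: MorrisResult, k: int = 12,
                     threshold: Optional[float] = None) -> List[str]:
    """Top-k parameters by max mu* (ties broken by catalogue order).

    With ``threshold`` given, parameters scoring at least ``threshold`` times
    the best score are kept instead (capped at ``k``).
    """
    score = morris.score()
    if k > len(score):
        raise ValueError(f"k={k} exceeds the {len(score)} screened parameters")
    order = np.argsort(-score.values, kind="stable")  # stable => name-order ties
    selected = [morris.names[i] for i in order]
    if threshold is not None:
        best = score.values[order[0]]
        selected = [n for n in selected if score[n] >= threshold * best]
    selected = selected[:k]
    logger.info("Morris screening selected %d parameters: %s",
                len(selected), ", ".join(selected))
    return selected


# --------------------------------------------------------------------------
# eFAST
# --------------------------------------------------------------------------

@dataclass
class FastResult:
    """Main (Si) and total (STi) effect indices per parameter.

    Arrays have shape (k,) for scalar outputs or (k, T) for time-resolved
    outputs with ``times`` of length T.  Entries are NaN where the output
    variance vanished (no information).
    """

    names: List[str]
    si: np.ndarray
    sti: np.ndarray
    times: Optional[np.ndarray] = None
    channel: Optional[str] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def at_time(self, t: float) -> pd.DataFrame:
        if self.times is None:
            raise ValueError("scalar-output result has no time axis")
        i = int(np.argmin(np.abs(self.times - t)))
        return pd.DataFrame({"Si": self.si[:, i], "STi": self.sti[:, i]},
                            index=self.names)

    def to_frame(self) -> pd.DataFrame:
        if self.times is None:
            return pd.DataFrame({"Si": self.si, "STi": self.sti}, index=self.names)
        rows = []
        for j, t in enumerate(self.times):
            for i, n in enumerate(self.names):
                rows.append({"parameter": n, "time_h": t,
                             "Si": self.si[i, j], "STi": self.sti[i, j]})
        return pd.DataFrame(rows)


def _efast_frequencies(k: int, omega_max: int, m_harm: int) -> np.ndarray:
    """Complementary frequencies for the k-1 other parameters (cyclic).

    Candidates are bounded by ``omega_max/(2M)`` and restricted to values
    coprime with ``omega_max``: a complementary frequency sharing a factor
    with the interest frequency has a low-order harmonic landing exactly on
    the interest harmonics, which biases Si upward for inactive parameters.
    """
    import math as _math

    omega2_max = max(1, omega_max // (2 * m_harm))
    cand = [f for f in range(1, omega2_max + 1) if _math.gcd(f, omega_max) == 1]
    if not cand:
        cand = [1]
    cand = np.asarray(cand, dtype=int)
    if k <= 1:
        return np.empty(0, int)
    if len(cand) >= k - 1:
        idx = np.linspace(0, len(cand) - 1, k - 1).round().astype(int)
        return cand[idx]
    return cand[np.arange(k - 1) % len(cand)]


def efast(model_fn: Callable[[np.ndarray], np.ndarray],
          priors: Mapping[str, PriorSpec],
          N: int = 257, M: int = 4, Nr: int = 1,
          seed: int | np.random.Generator = 0,
          quantile_bounds: Tuple[float, float] = (0.0, 1.0)) -> FastResult:
    """Extended FAST main and total effect indices.

    ``model_fn`` maps a natural-scale parameter vector to a scalar or 1-d
    array (vector outputs give time-resolved indices computed from a single
    shared design).  ``N`` samples per search curve, ``M`` harmonics,
    ``Nr`` random-phase resamples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(priors)
    k = len(names)
    if (N - 1) // (2 * M) < 1:
        raise ValueError(
            f"N={N} is too small for M={M} harmonics; need N >= {2 * M + 1}")
    # leave a sideband margin below Nyquist: with omega = (N-1)/(2M) the
    # upper sidebands of the M-th harmonic alias straight back onto it,
    # biasing Si by interaction power
    omega_max = max(1, (N - 1) // (2 * M + 1))
    while omega_max > 1 and N % omega_max == 0:
        omega_max -= 1          # omega dividing N folds harmonics onto bins
    s = (2.0 * np.pi / N) * np.arange(N)

    si_acc = None
    sti_acc = None
    for i in range(k):
        freqs = np.empty(k, dtype=int)
        freqs[i] = omega_max
        others = _efast_frequencies(k, omega_max, M)
        freqs[[j for j in range(k) if j != i]] = others
        si_r = None
        sti_r = None
        for _ in range(Nr):
            phi = rng.uniform(0.0, 2.0 * np.pi, size=k)
            u = 0.5 + (1.0 / np.pi) * np.arcsin(np.sin(freqs[None, :] * s[:, None]
                                                       + phi[None, :]))
            q = quantile_bounds[0] + u * (quantile_bounds[1] - quantile_bounds[0])
            x = np.empty_like(q)
            for j, n in enumerate(names):
                x[:, j] = priors[n].ppf(q[:, j])
            y = np.vstack([np.atleast_1d(np.asarray(model_fn(row), dtype=float))
                           for row in x])               # (N, n_out)
            omega2_max = max(1, omega_max // (2 * M))
            cutoff = min(max(omega_max // 2, M * omega2_max), omega_max - 1)
            s1, st = _spectral_indices(y, omega_max, M, max(cutoff, 1))
            si_r = s1 if si_r is None else si_r + s1
            sti_r = st if sti_r is None else sti_r + st
        si_r /= Nr
        sti_r /= Nr
        if si_acc is None:
            n_out = si_r.size
            si_acc = np.empty((k, n_out))
            sti_acc = np.empty((k, n_out))
        si_acc[i] = si_r
        sti_acc[i] = sti_r

    meta = {"N": N, "M": M, "Nr": Nr, "omega_max": omega_max}
    res = FastResult(names=names, si=si_acc, sti=sti_acc, meta=meta)
    if si_acc.shape[1] == 1:
        res.si = si_acc[:, 0]
        res.sti = sti_acc[:, 0]
    return res


def _spectral_indices(y: np.ndarray, omega_max: int, m_harm: int,
                      comp_cutoff: int) -> Tuple[np.ndarray, np.ndarray]:
    """Si and STi for every output column from the periodogram of y.

    Si sums power at the first ``m_harm`` harmonics of ``omega_max``; the
    complementary variance for STi sums power up to ``comp_cutoff``.
    """
    n = y.shape[0]
    f = np.fft.rfft(y - y.mean(axis=0, keepdims=True), axis=0)
    power = 2.0 * np.abs(f) ** 2 / n**2                 # one-sided spectrum
    nyq = (n - 1) // 2
    total = power[1:nyq + 1].sum(axis=0)
    harmonics = [h * omega_max for h in range(1, m_harm + 1) if h * omega_max <= nyq]
    d1 = power[harmonics].sum(axis=0)
    dcomp = power[1:comp_cutoff + 1].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.where(total > 1e-30, d1 / total, np.nan)
        sti = np.where(total > 1e-30, 1.0 - dcomp / total, np.nan)
    return si, sti


# --------------------------------------------------------------------------
# Time-resolved SA of the PBPK model
# --------------------------------------------------------------------------

def make_pbpk_model_fn(base: ParameterSet, names: Sequence[str],
                       scenario: ExposureScenario,
                       channel_times: Mapping[str, np.ndarray],
                       solver: Optional[SolverConfig] = None):
    """Build a vector model function for SA over the PBPK simulator.

    Returns ``(fn, slices)``: ``fn`` maps a parameter vector (values for
    ``names``; all other parameters pinned at ``base``) to the concatenated
    channel outputs at the requested times; ``slices`` locates each channel
    in that vector.  One simulation serves every channel and time point.
    """
    solver = solver or SolverConfig(dense_dt=0.05)
    channel_times = {ch: np.asarray(t, dtype=float) for ch, t in channel_times.items()}
    slices: Dict[str, slice] = {}
    start = 0
    for ch, t in channel_times.items():
        slices[ch] = slice(start, start + t.size)
        start += t.size
    all_extra = np.unique(np.concatenate(list(channel_times.values())))

    def fn(x: np.ndarray) -> np.ndarray:
        ps = base.copy(**dict(zip(names, x)))
        out = simulate(ps, scenario, solver, extra_times=all_extra)
        vec = np.empty(start)
        for ch, t in channel_times.items():
            vec[slices[ch]] = _channel_on_grid(out, ch, t)
        return vec

    return fn, slices


def _channel_on_grid(out: SimulationOutput, channel: str, times: np.ndarray) -> np.ndarray:
    arrays = {"cv_xyl": out.obs.cv_xyl_umol, "cx_ppm": out.obs.cx_ppm,
              "c_urine": out.obs.c_urine, "c_blood_eth": out.obs.c_blood_eth}
    try:
        values = arrays[channel]
    except KeyError:
        raise KeyError(f"unknown SA channel {channel!r}; have {sorted(arrays)}") from None
    idx = np.searchsorted(out.t, times)
    idx = np.clip(idx, 0, out.t.size - 1)
    got = values[idx]
    # urine channel: NaN while the bladder is empty -> treat as zero signal
    if channel == "c_urine":
        got = np.nan_to_num(got, nan=0.0)
    return got


def timewise_sa(base: ParameterSet, priors: Mapping[str, PriorSpec],
                scenario: ExposureScenario,
                channels: Optional[Sequence[str]] = None,
                grid_dt: float = 0.25,
                N: int = 257, M: int = 4, Nr: int = 1,
                seed: int = 0,
                solver: Optional[SolverConfig] = None,
                windows: Optional[Mapping[str, Tuple[float, float]]] = None,
                quantile_bounds: Tuple[float, float] = (0.0, 1.0)
                ) -> Dict[str, FastResult]:
    """eFAST indices over time for the monitored channels.

    The same parameter design is evaluated once per design point; all
    channels and time points are extracted from each simulation.  Times
    where the output variance vanishes (e.g. before uptake begins) yield
    NaN indices with a warning.
    """
    channels = list(channels or CHANNEL_WINDOWS)
    windows = dict(windows or CHANNEL_WINDOWS)
    channel_times = {}
    for ch in channels:
        lo, hi = windows[ch]
        # offset the grid half a step so void instants are never sampled
        channel_times[ch] = np.arange(lo + grid_dt / 2.0, hi, grid_dt)
    fn, slices = make_pbpk_model_fn(base, list(priors), scenario, channel_times,
                                    solver=solver)
    res = efast(fn, priors, N=N, M=M, Nr=Nr, seed=seed,
                quantile_bounds=quantile_bounds)
    results: Dict[str, FastResult] = {}
    for ch in channels:
        sl = slices[ch]
        si = np.atleast_2d(res.si)[:, sl]
        sti = np.atleast_2d(res.sti)[:, sl]
        if np.isnan(si).any():
            logger.warning("channel %s: %d time points with vanishing variance",
                           ch, int(np.isnan(si[0]).sum()))
        results[ch] = FastResult(names=res.names, si=si, sti=sti,
                                 times=channel_times[ch], channel=ch,
                                 meta=dict(res.meta))
    return results


# --------------------------------------------------------------------------
# Lowry data
# --------------------------------------------------------------------------

@dataclass
class LowryData:
    """Ordered main-effect/interaction decomposition for a Lowry plot.

    Parameters are ordered by descending total effect.  The cumulative
    "plume" is bounded below by the running sum of main effects and above
    by the smaller of the running sum of total effects and one minus the
    main effects still to come.
    """

    names: List[str]
    si: np.ndarray
    interaction: np.ndarray
    cum_lower: np.ndarray
    cum_upper: np.ndarray
    time: Optional[float] = None
    channel: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names, "Si": self.si,
            "interaction": self.interaction,
            "cum_lower": self.cum_lower, "cum_upper": self.cum_upper,
        })


def lowry(fast: FastResult, time: Optional[float] = None,
          channel: Optional[str] = None) -> LowryData:
    """Build Lowry-plot data from an eFAST result (at ``time`` if resolved)."""
    if fast.times is not None:
        if time is None:
            raise ValueError("a time point is required for time-resolved results")
        i = int(np.argmin(np.abs(fast.times - time)))
        si = fast.si[:, i].copy()
        sti = fast.sti[:, i].copy()
        t_used = float(fast.times[i])
    else:
        si = np.atleast_1d(fast.si).astype(float).copy()
        sti = np.atleast_1d(fast.sti).astype(float).copy()
        t_used = time
    if np.isnan(si).any() or np.isnan(sti).any():
        raise ValueError("sensitivity indices are missing at the requested time")
    si = np.clip(si, 0.0, 1.0)
    sti = np.maximum(sti, si)            # estimator noise can put STi < Si
    order = np.argsort(-sti, kind="stable")
    si_o = si[order]
    sti_o = sti[order]
    total_si = si_o.sum()
    cum_si = np.cumsum(si_o)
    cum_sti = np.cumsum(sti_o)
    upper = np.minimum(cum_sti, 1.0 - (total_si - cum_si))
    upper = np.maximum(upper, cum_si)
    return LowryData(
        names=[fast.names[i] for i in order],
        si=si_o, interaction=sti_o - si_o,
        cum_lower=cum_si, cum_upper=upper,
        time=t_used, channel=channel or fast.channel,
    )


def plot_lowry(data: LowryData, ax=None, title: Optional[str] = None):
    """Stacked-bar Lowry plot with the cumulative-variance plume."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.6 * len(data.names), 4.0))
    x = np.arange(len(data.names))
    ax.bar(x, data.si, color="#2c6fbb", label="main effect")
    ax.bar(x, data.interaction, bottom=data.si, color="#a8c8e8", label="interaction")
    ax.fill_between(x, data.cum_lower, data.cum_upper, color="0.8", alpha=0.6,
                    label="cumulative variance")
    ax.plot(x, data.cum_lower, color="0.4", lw=1)
    ax.plot(x, data.cum_upper, color="0.4", lw=1)
    ax.set_xticks(x)
    ax.set_xticklabels(data.names, rotation=60, ha="right")
    ax.set_ylabel("proportion of variance")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="center right", fontsize=8)
    if title or data.channel:
        t = title or f"{data.channel} at {data.time} h"
        ax.set_title(t)
    return ax
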