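"""High-level SA workflow: screen the full catalogue, then quantify.

These functions bind the generic Morris/eFAST machinery to the PBPK
simulator for the standard study scenarios, using one shared design per
phase so that all channels and time points come from the same batch of
simulations.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .parameters import ParameterSet, PriorSpec, parameter_catalogue
from .sensitivity import (CHANNEL_WINDOWS, SUMMARY_TIMES, FastResult,
                          MorrisResult, make_pbpk_model_fn, morris_screen,
                          timewise_sa)
from .simulate import ExposureScenario, SolverConfig

__all__ = ["varying_priors", "run_morris_phase", "run_efast_phase"]

#: Default solver for SA batches: coarser dense grid, same RK4 step.
SA_SOLVER = SolverConfig(method="rk4", dt=0.005, dense_dt=0.05)

#: Quantile band scanned by the SA designs.  Unbounded priors are scanned
#: between their 0.5th and 99.5th percentiles: the extreme tails of the
#: truncated normals (e.g. a blood:air coefficient approaching zero) are
#: physiologically meaningless and numerically hostile.
SA_QUANTILE_BOUNDS = (0.005, 0.995)


def varying_priors(ethanol: bool = True) -> Dict[str, PriorSpec]:
    """The varying subset of the catalogue for one model configuration.

    Without ethanol, the ethanol-model parameters (including KI, which only
    acts through the inhibitor) have no pathway to the outputs and are
    excluded from screening.
    """
    cat = parameter_catalogue()
    out = {}
    for name, spec in cat.items():
        if not spec.varying:
            continue
        if not ethanol and (spec.group == "ethanol" or name == "KI"):
            continue
        out[name] = spec
    return out


def run_morris_phase(base: ParameterSet, scenario: ExposureScenario,
                     channels: Optional[Sequence[str]] = None,
                     r: int = 10, p: int = 4, seed: int = 0,
                     solver: Optional[SolverConfig] = None,
                     priors: Optional[Mapping[str, PriorSpec]] = None
                     ) -> MorrisResult:
    """Morris screening of every varying parameter at the summary times."""
    channels = list(channels or CHANNEL_WINDOWS)
    priors = dict(priors or varying_priors(ethanol=scenario.ethanol))
    channel_times = {ch: np.asarray(SUMMARY_TIMES[ch], dtype=float)
                     for ch in channels}
    fn, _ = make_pbpk_model_fn(base, list(priors), scenario, channel_times,
                               solver=solver or SA_SOLVER)
    res = morris_screen(fn, priors, r=r, p=p, seed=seed,
                        quantile_bounds=SA_QUANTILE_BOUNDS)
    labels = [f"{ch}@{t:g}h" for ch in channels for t in SUMMARY_TIMES[ch]]
    res.output_labels = labels
    return res


def run_efast_phase(base: ParameterSet, scenario: ExposureScenario,
                    selected: Sequence[str],
                    channels: Optional[Sequence[str]] = None,
                    N: int = 257, M: int = 4, Nr: int = 1,
                    grid_dt: float = 0.25, seed: int = 0,
                    solver: Optional[SolverConfig] = None
                    ) -> Dict[str, FastResult]:
    """Time-resolved eFAST over the Morris-selected parameters.

    Unselected parameters stay pinned at their values in ``base``.
    """
    cat = parameter_catalogue()
    priors = {n: cat[n] for n in selected}
    return timewise_sa(base, priors, scenario, channels=channels,
                       grid_dt=grid_dt, N=N, M=M, Nr=Nr, seed=seed,
                       solver=solver or SA_SOLVER,
                       quantile_bounds=SA_QUANTILE_BOUNDS)
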