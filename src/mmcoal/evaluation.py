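"""Performance metrics for Ne(t) and alpha estimates, and the simulation-
study driver (coverage / bias / deviance / MSE per trajectory-method cell)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .demography import DEFAULT_D
from .inference import (
    PosteriorResult,
    estimate_blocksize,
    estimate_hybrid,
    run_mcmc,
)
from .measures import RateTable, beta_measure
from .simulate import SimulationSpec, simulate, study_schedule, trajectory

__all__ = ["NeMetrics", "ne_metrics", "StudyConfig", "run_study", "aggregate_study"]


class NeMetrics(NamedTuple):
    coverage: float
    bias: float
    deviance: float
    mse: float


def ne_metrics(result: PosteriorResult, truth: Callable[[float], float]) -> NeMetrics:
    """Evaluate an Ne(t) reconstruction against the true trajectory.

    Computed at the grid-cell midpoints: coverage is the fraction of points
    whose 95% band contains the truth; bias, deviance and MSE are the mean
    signed, absolute and squared errors of log Ne-hat vs log Ne-true
    (log-scale definitions; coverage is scale-free).
    """
    x = result.grid.x
    mids = 0.5 * (x[:-1] + x[1:])
    true_ne = np.array([truth(t) for t in mids], dtype=float)
    if np.any(true_ne <= 0):
        raise ValueError("true trajectory must be positive on the grid")
    covered = (result.ne_lower95 <= true_ne) & (true_ne <= result.ne_upper95)
    err = np.log(result.ne_median) - np.log(true_ne)
    return NeMetrics(
        coverage=float(np.mean(covered)),
        bias=float(np.mean(err)),
        deviance=float(np.mean(np.abs(err))),
        mse=float(np.mean(err**2)),
    )


@dataclass
class StudyConfig:
    """Reduced-scale rerun of the simulation study design.

    Defaults are desk-scale (5 replicates per cell); the full design used
    50 replicates per (alpha, n, schedule, trajectory) cell and 20 000
    MCMC iterations.
    """

    alphas: Sequence[float] = (1.0, 1.5, 1.8)
    ns: Sequence[int] = (20, 50, 100)
    trajectories: Sequence[str] = ("uniform", "exponential", "boombust")
    schedules: Sequence[str] = ("iso", "split2", "split4")
    replicates: int = 5
    methods: Sequence[str] = ("blocksize", "hybrid", "mcmc")
    mcmc_iterations: int = 5000
    D: int = DEFAULT_D


def _run_method(method: str, data, config: StudyConfig, seed: int) -> PosteriorResult:
    if method == "blocksize":
        return estimate_blocksize(data, D=config.D)
    if method == "hybrid":
        return estimate_hybrid(data, D=config.D)
    if method == "mcmc":
        _, res = run_mcmc(data, D=config.D, iterations=config.mcmc_iterations,
                          seed=seed)
        return res
    raise ValueError(f"unknown method {method!r}")


def run_study(config: StudyConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate and score every cell of the study design.

    Returns one row per (replicate x method) with the alpha estimate and
    the four Ne(t) metrics; deterministic for a fixed seed.
    """
    rows = []
    cell_no = 0
    for alpha in config.alphas:
        measure = beta_measure(alpha)
        for n in config.ns:
            rt = RateTable(measure, n)
            for traj_name in config.trajectories:
                for sched_name in config.schedules:
                    cell_no += 1
                    sched = study_schedule(sched_name, n)
                    for rep in range(config.replicates):
                        sim_seed = seed + 1000 * cell_no + rep
                        ne_sim, truth = trajectory(traj_name)
                        spec = SimulationSpec(measure, ne_sim, sched, sim_seed)
                        _, data = simulate(spec, rate_table=rt)
                        for method in config.methods:
                            res = _run_method(method, data, config, sim_seed)
                            met = ne_metrics(res, truth)
                            rows.append(
                                {
                                    "alpha_true": alpha,
                                    "n": n,
                                    "trajectory": traj_name,
                                    "schedule": sched_name,
                                    "replicate": rep,
                                    "method": method,
                                    "alpha_estimate": res.alpha_estimate,
                                    "coverage": met.coverage,
                                    "bias": met.bias,
                                    "deviance": met.deviance,
                                    "mse": met.mse,
                                }
                            )
    return pd.DataFrame(rows)


def aggregate_study(df: pd.DataFrame) -> pd.DataFrame:
    """Summary table: mean coverage, median deviance and median MSE per
    (alpha, n, trajectory, method), pooling the sampling schedules."""
    return (
        df.groupby(["alpha_true", "n", "trajectory", "method"])
        .agg(
            coverage=("coverage", "mean"),
            deviance=("deviance", "median"),
            mse=("mse", "median"),
            alpha_mean=("alpha_estimate", "mean"),
            replicates=("replicate", "count"),
        )
        .reset_index()
    )
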