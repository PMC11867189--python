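"""Backward-in-time simulation of Lambda-coalescent genealogies under
piecewise-constant Ne(t) and heterochronous sampling.

Waiting times to the next coalescent event are drawn by analytic inversion
of the time-inhomogeneous exponential: within an Ne cell the hazard
lambda_A / Ne is constant, so the cumulative hazard is accumulated cell by
cell until the target exponential deviate is consumed (no thinning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .demography import NeGrid
from .genealogy import CoalescentData, SamplingSchedule, TimedTree, TreeNode
from .measures import LambdaMeasure, RateTable

__all__ = [
    "PiecewiseNe",
    "constant_ne",
    "trajectory",
    "study_schedule",
    "SimulationSpec",
    "simulate",
    "average_block_size",
]

_NE_FLOOR = 1e-12
_TRAJ_CELLS = 2000


class PiecewiseNe:
    """Piecewise-constant Ne(t) used by the simulator.

    Built either from a constant, from an :class:`NeGrid`, or by
    discretizing a positive callable onto a fine grid; the grid is
    extended on demand (re-discretizing the callable, or carrying the
    last value) when a waiting-time draw runs past the horizon.
    """

    def __init__(self, x: np.ndarray, values: np.ndarray,
                 extend: Callable[[float], float] | None = None):
        self.x = np.asarray(x, dtype=float)
        self.values = np.maximum(np.asarray(values, dtype=float), _NE_FLOOR)
        if self.x.size != self.values.size + 1:
            raise ValueError("need len(x) == len(values) + 1")
        if np.any(self.values <= 0):
            raise ValueError("Ne must be strictly positive")
        self._extend = extend

    @classmethod
    def constant(cls, value: float) -> "PiecewiseNe":
        return cls(np.array([0.0, 1.0]), np.array([value]))

    @classmethod
    def from_callable(cls, f: Callable[[float], float], horizon: float,
                      cells: int = _TRAJ_CELLS) -> "PiecewiseNe":
        x = np.linspace(0.0, horizon, cells + 1)
        mids = 0.5 * (x[:-1] + x[1:])
        return cls(x, np.array([f(t) for t in mids]), extend=f)

    @classmethod
    def from_grid(cls, grid: NeGrid) -> "PiecewiseNe":
        return cls(grid.x, np.exp(grid.gamma))

    def at(self, t: float) -> float:
        idx = int(np.clip(np.searchsorted(self.x, t, side="right") - 1, 0,
                          self.values.size - 1))
        return float(self.values[idx])

    def _grow(self) -> None:
        """Append cells past the current horizon (doubling the span)."""
        width = self.x[-1] - self.x[-2]
        old_end = self.x[-1]
        n_new = max(self.values.size, 16)
        new_x = old_end + width * np.arange(1, n_new + 1)
        if self._extend is not None:
            mids = new_x - width / 2.0
            new_v = np.maximum([self._extend(t) for t in mids], _NE_FLOOR)
        else:
            new_v = np.full(n_new, self.values[-1])
        self.x = np.concatenate([self.x, new_x])
        self.values = np.concatenate([self.values, new_v])

    def cumulative_inverse(self, a: float, b: float) -> float:
        """int_a^b du / Ne(u) (extending the grid to cover b if needed)."""
        while b > self.x[-1] and self._extend is not None:
            self._grow()
        lo = np.clip(self.x[:-1], a, b)
        hi = np.clip(self.x[1:], a, b)
        total = float(np.sum((hi - lo) / self.values))
        if b > self.x[-1]:
            total += (b - max(a, self.x[-1])) / self.values[-1]
        return total

    def solve_hazard(self, t0: float, rate: float, target: float) -> float:
        """Time t > t0 at which rate * int_{t0}^{t} du/Ne reaches ``target``."""
        if rate <= 0:
            return math.inf
        pos = t0
        idx = int(np.clip(np.searchsorted(self.x, t0, side="right") - 1, 0,
                          self.values.size - 1))
        remaining = target
        while True:
            if idx >= self.values.size:
                if self._extend is not None:
                    self._grow()
                else:
                    # constant tail: solve analytically
                    return pos + remaining * self.values[-1] / rate
            v = float(self.values[idx])
            end = float(self.x[idx + 1])
            cap = rate * (end - pos) / v
            if cap >= remaining:
                return pos + remaining * v / rate
            remaining -= cap
            pos = end
            idx += 1


def constant_ne(value: float = 100.0) -> PiecewiseNe:
    return PiecewiseNe.constant(value)


def trajectory(name: str) -> tuple[PiecewiseNe, Callable[[float], float]]:
    """Named study trajectories: returns (simulator Ne, truth callable).

    uniform: Ne(t) = 100; exponential: Ne(t) = 1000 e^{-t};
    boombust: Ne(t) = 1000 e^{-|t - 1|}.
    """
    if name == "uniform":
        f = lambda t: 100.0
        return PiecewiseNe.constant(100.0), f
    if name == "exponential":
        f = lambda t: 1000.0 * math.exp(-t)
        return PiecewiseNe.from_callable(f, horizon=10.0), f
    if name in ("boombust", "boom-bust"):
        f = lambda t: 1000.0 * math.exp(-abs(t - 1.0))
        return PiecewiseNe.from_callable(f, horizon=10.0), f
    raise ValueError(f"unknown trajectory {name!r}")


def study_schedule(name: str, n: int, spacing: float = 0.2) -> SamplingSchedule:
    """Sampling schedules of the simulation study.

    iso: all n at time 0; split2: 50/50 over two times; split4: 50/30/10/10
    over four times.  The times are multiples of ``spacing`` (the split
    proportions are fixed by the study design; the spacings are not, so
    they are configurable).
    """
    if name == "iso":
        return SamplingSchedule.isochronous(n)
    if name == "split2":
        fracs = [0.5, 0.5]
    elif name == "split4":
        fracs = [0.5, 0.3, 0.1, 0.1]
    else:
        raise ValueError(f"unknown schedule {name!r}")
    counts = np.maximum(np.round(np.array(fracs) * n).astype(int), 1)
    counts[0] += n - counts.sum()
    times = spacing * np.arange(len(fracs), dtype=float)
    return SamplingSchedule(times, counts)


@dataclass
class SimulationSpec:
    """Everything a single genealogy draw needs."""

    measure: LambdaMeasure
    ne: PiecewiseNe
    schedule: SamplingSchedule
    seed: int | np.random.Generator = 0


def simulate(spec: SimulationSpec,
             rate_table: RateTable | None = None) -> tuple[TimedTree, CoalescentData]:
    """Draw one genealogy; deterministic under a fixed seed."""
    rng = (spec.seed if isinstance(spec.seed, np.random.Generator)
           else np.random.default_rng(spec.seed))
    sched = spec.schedule
    n_total = sched.total
    rt = rate_table if rate_table is not None else RateTable(spec.measure, max(n_total, 2))

    active: list[TreeNode] = []
    pending = list(zip(sched.s.tolist(), sched.n.tolist()))
    times: list[float] = []
    sizes: list[int] = []
    cur = 0.0
    tip_no = 0

    # first sampling batch at time 0
    s0, n0 = pending.pop(0)
    for _ in range(n0):
        tip_no += 1
        active.append(TreeNode(s0, label=f"t{tip_no}"))

    while len(active) > 1 or pending:
        a = len(active)
        if a < 2:
            s_next, n_next = pending.pop(0)
            for _ in range(n_next):
                tip_no += 1
                active.append(TreeNode(s_next, label=f"t{tip_no}"))
            cur = s_next
            continue
        target = rng.exponential()
        t_cand = spec.ne.solve_hazard(cur, rt.total_rate(a), target)
        if pending and t_cand >= pending[0][0]:
            s_next, n_next = pending.pop(0)
            for _ in range(n_next):
                tip_no += 1
                active.append(TreeNode(s_next, label=f"t{tip_no}"))
            cur = s_next
            continue
        # coalescent event: block size from the conditional pmf, members uniform
        m = 2 if a == 2 else int(2 + rng.choice(a - 1, p=rt.pmf(a)))
        picks = rng.choice(a, size=m, replace=False)
        children = [active[i] for i in picks]
        for i in sorted(picks, reverse=True):
            active.pop(i)
        active.append(TreeNode(t_cand, children=children))
        times.append(t_cand)
        sizes.append(m)
        cur = t_cand

    tree = TimedTree(active[0])
    data = CoalescentData(sched, np.array(times), np.array(sizes))
    return tree, data


def average_block_size(measure: LambdaMeasure, n: int, replicates: int,
                       seed: int = 0) -> float:
    """Mean merger size across isochronous constant-Ne genealogies."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rt = RateTable(measure, n)
    sched = SamplingSchedule.isochronous(n)
    total = 0.0
    count = 0
    for r in range(replicates):
        spec = SimulationSpec(measure, PiecewiseNe.constant(1.0), sched, seed + r)
        _, data = simulate(spec, rate_table=rt)
        total += float(np.sum(data.m))
        count += data.m.size
    return total / count
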