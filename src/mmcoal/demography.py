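"""Piecewise-constant effective population size on a regular grid, with an
intrinsic first-order Gaussian Markov random field prior on the log values."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genealogy import CoalescentData

__all__ = [
    "NeGrid",
    "build_grid",
    "gmrf_precision",
    "gmrf_logprior",
    "DEFAULT_D",
    "TAU_PRIOR_SHAPE",
    "TAU_PRIOR_RATE",
]

DEFAULT_D = 100
TAU_PRIOR_SHAPE = 0.001
TAU_PRIOR_RATE = 0.001


@dataclass
class NeGrid:
    """Regular grid x_1 < ... < x_D with Ne(t) = exp(gamma_d) on (x_d, x_{d+1}].

    Beyond x_D the last value extends, so the likelihood stays defined if
    numerical jitter places an event past the grid.
    """

    x: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.x.ndim != 1 or self.x.size < 3:
            raise ValueError("grid needs D >= 3 points")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if self.gamma.shape != (self.x.size - 1,):
            raise ValueError("gamma must have length D - 1")

    @property
    def D(self) -> int:
        return int(self.x.size)

    def cell_index(self, t) -> np.ndarray:
        """Index d of the cell (x_d, x_{d+1}] containing t (clipped to ends)."""
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="left") - 1
        return np.clip(idx, 0, self.D - 2)

    def ne_at(self, t) -> np.ndarray:
        return np.exp(self.gamma[self.cell_index(t)])

    def with_gamma(self, gamma: np.ndarray) -> "NeGrid":
        return NeGrid(self.x, np.asarray(gamma, dtype=float))

    def integrate_inverse_ne(self, a: float, b: float) -> float:
        """Exact piecewise integral of 1/Ne over [a, b]."""
        if a < 0 or b < a:
            raise ValueError("need 0 <= a <= b")
        if a == b:
            return 0.0
        lo = np.clip(self.x[:-1], a, b)
        hi = np.clip(self.x[1:], a, b)
        total = float(np.sum((hi - lo) * np.exp(-self.gamma)))
        # head [a, x_1) uses the first cell, tail (x_D, b] the last
        if a < self.x[0]:
            total += (min(b, self.x[0]) - a) * np.exp(-self.gamma[0])
        if b > self.x[-1]:
            total += (b - max(a, self.x[-1])) * np.exp(-self.gamma[-1])
        return total

    def integrate_inverse_ne_riemann(self, a: float, b: float, cells: int = 256) -> float:
        """Midpoint Riemann-sum variant, kept for comparability with the
        grid-approximation scheme; the exact version is the default."""
        if a == b:
            return 0.0
        mids = a + (np.arange(cells) + 0.5) * (b - a) / cells
        return float(np.sum((b - a) / cells / self.ne_at(mids)))


def build_grid(data: CoalescentData | float, D: int = DEFAULT_D) -> NeGrid:
    """Regular grid skeleton from 0 to the TMRCA (gamma initialized to 0)."""
    if D < 3:
        raise ValueError("D must be >= 3")
    tmax = data.tmrca if isinstance(data, CoalescentData) else float(data)
    if tmax <= 0:
        raise ValueError("largest coalescent time must be positive")
    return NeGrid(np.linspace(0.0, tmax, D), np.zeros(D - 1))


def gmrf_precision(size: int) -> np.ndarray:
    """Intrinsic RW1 structure matrix Q of dimension ``size``.

    Tridiagonal with free boundaries: zero row sums, rank ``size - 1``,
    quadratic form gamma' Q gamma = sum_d (gamma_{d+1} - gamma_d)^2.
    """
    if size < 2:
        raise ValueError("GMRF needs at least 2 grid cells")
    q = np.diag(np.full(size, 2.0))
    q[0, 0] = q[-1, -1] = 1.0
    off = np.full(size - 1, -1.0)
    q += np.diag(off, 1) + np.diag(off, -1)
    return q


def gmrf_logprior(gamma: np.ndarray, tau: float, Q: np.ndarray | None = None) -> float:
    """Log density of the intrinsic RW1 prior, up to its fixed constant.

    For gamma of length D-1 the structure matrix has rank D-2, giving
    ((D-2)/2) log tau - (tau/2) gamma' Q gamma.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    gamma = np.asarray(gamma, dtype=float)
    if Q is None:
        quad = float(np.sum(np.diff(gamma) ** 2))
    else:
        quad = float(gamma @ Q @ gamma)
    rank = gamma.size - 1
    return 0.5 * rank * np.log(tau) - 0.5 * tau * quad
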