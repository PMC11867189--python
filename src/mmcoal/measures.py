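"""Base measures on [0, 1] and the merger rates of the Lambda-coalescent.

A finite measure ``Lambda`` on the unit interval generates the rates

    lambda_{b,k} = int_0^1 x^(k-2) (1-x)^(b-k) Lambda(dx),   2 <= k <= b,

at which a specific set of k lineages out of b merges.  This module
provides the named measure families (Kingman, star, Beta), user-supplied
discrete and continuous measures, and all derived quantities: single
merger rates, total coalescent rates, the block-size distribution of a
merger event, and a cached :class:`RateTable` for repeated evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import truncnorm

__all__ = [
    "LambdaMeasure",
    "KingmanMeasure",
    "StarMeasure",
    "BetaMeasure",
    "DiscreteMeasure",
    "ContinuousMeasure",
    "beta_measure",
    "truncated_normal_measure",
    "demo_discrete_measure",
    "RateTable",
    "merger_rate",
    "total_rate",
    "block_size_pmf",
    "total_rate_approx",
    "log_binom",
]

_QUAD_ABS_TOL = 1e-10


def log_binom(b, k):
    """log C(b, k) via log-gamma (vectorized, overflow-safe)."""
    b = np.asarray(b, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(b + 1.0) - gammaln(k + 1.0) - gammaln(b - k + 1.0)


def _check_bk(b: int, k: int) -> None:
    if b < 2:
        raise ValueError(f"need b >= 2 lineages, got b={b}")
    if k < 2 or k > b:
        raise ValueError(f"merger size k must satisfy 2 <= k <= b, got k={k}, b={b}")


class LambdaMeasure:
    """Abstract base: a finite measure on [0, 1] generating merger rates."""

    kind: str = "abstract"

    def log_rate(self, b: int, k: int) -> float:
        """Return log lambda_{b,k} (``-inf`` when the rate is zero)."""
        raise NotImplementedError

    def rate(self, b: int, k: int) -> float:
        _check_bk(b, k)
        return float(np.exp(self.log_rate(b, k)))

    def log_rate_row(self, b: int) -> np.ndarray:
        """log lambda_{b,k} for k = 2..b as an array of length b-1."""
        return np.array([self.log_rate(b, k) for k in range(2, b + 1)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}()"


class KingmanMeasure(LambdaMeasure):
    """Point mass at 0: only binary mergers, each at rate 1."""

    kind = "kingman_delta0"

    def log_rate(self, b: int, k: int) -> float:
        _check_bk(b, k)
        return 0.0 if k == 2 else -np.inf


class StarMeasure(LambdaMeasure):
    """Point mass at 1: all extant lineages merge at once at rate 1."""

    kind = "star_delta1"

    def log_rate(self, b: int, k: int) -> float:
        _check_bk(b, k)
        return 0.0 if k == b else -np.inf


class BetaMeasure(LambdaMeasure):
    """Beta(2-alpha, alpha) probability measure, alpha in (0, 2].

    Rates use the closed form lambda_{b,k} = B(k-alpha, alpha+b-k) / B(2-alpha, alpha)
    evaluated through log-gamma, so that the divergent normalizer near
    alpha = 2 cancels; alpha == 2 is the Kingman limit exactly.
    """

    kind = "beta"

    def __init__(self, alpha: float):
        alpha = float(alpha)
        if not (0.0 < alpha <= 2.0):
            raise ValueError(f"beta measure needs alpha in (0, 2], got {alpha}")
        self.alpha = alpha

    def log_rate(self, b: int, k: int) -> float:
        _check_bk(b, k)
        a = self.alpha
        if a == 2.0:
            return 0.0 if k == 2 else -np.inf
        return float(betaln(k - a, a + b - k) - betaln(2.0 - a, a))

    def log_rate_row(self, b: int) -> np.ndarray:
        a = self.alpha
        if a == 2.0:
            row = np.full(b - 1, -np.inf)
            row[0] = 0.0
            return row
        ks = np.arange(2, b + 1, dtype=float)
        return betaln(ks - a, a + b - ks) - betaln(2.0 - a, a)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMeasure(alpha={self.alpha})"


class DiscreteMeasure(LambdaMeasure):
    """Finite atomic measure: atoms x_i in [0, 1] with weights w_i > 0."""

    kind = "discrete"

    def __init__(self, atoms: Sequence[tuple[float, float]]):
        xs = np.array([a[0] for a in atoms], dtype=float)
        ws = np.array([a[1] for a in atoms], dtype=float)
        if xs.size == 0:
            raise ValueError("discrete measure needs at least one atom")
        if np.any((xs < 0.0) | (xs > 1.0)):
            raise ValueError("atoms must lie in [0, 1]")
        if np.any(ws <= 0.0) or not np.all(np.isfinite(ws)):
            raise ValueError("atom weights must be strictly positive and finite")
        self.x = xs
        self.w = ws

    def log_rate(self, b: int, k: int) -> float:
        _check_bk(b, k)
        # x^(k-2) (1-x)^(b-k) with the convention 0^0 = 1 at the endpoints
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.where(k == 2, 0.0, (k - 2) * np.log(self.x))
            l1x = np.where(k == b, 0.0, (b - k) * np.log1p(-self.x))
        terms = np.log(self.w) + lx + l1x
        terms = terms[np.isfinite(terms)]
        if terms.size == 0:
            return -np.inf
        return float(logsumexp(terms))


class ContinuousMeasure(LambdaMeasure):
    """Measure with a density on [0, 1], integrated by adaptive quadrature."""

    kind = "continuous"

    def __init__(self, density: Callable[[float], float]):
        self.density = density

    def log_rate(self, b: int, k: int) -> float:
        _check_bk(b, k)

        def integrand(x: float) -> float:
            return x ** (k - 2) * (1.0 - x) ** (b - k) * self.density(x)

        val, err = quad(integrand, 0.0, 1.0, epsabs=_QUAD_ABS_TOL, limit=200)
        if not np.isfinite(val) or (val > 0 and err > max(1e-6 * val, 1e-8)):
            raise ArithmeticError(
                f"quadrature did not converge for (b={b}, k={k}): value={val}, err={err}"
            )
        return math.log(val) if val > 0.0 else -np.inf


def beta_measure(alpha: float) -> LambdaMeasure:
    """Beta(2-alpha, alpha) measure; alpha == 2 returns the Kingman measure."""
    if float(alpha) == 2.0:
        return KingmanMeasure()
    return BetaMeasure(alpha)


def truncated_normal_measure() -> ContinuousMeasure:
    """Standard normal truncated to [0, 1] and renormalized."""
    rv = truncnorm(0.0, 1.0)
    return ContinuousMeasure(rv.pdf)


def demo_discrete_measure() -> DiscreteMeasure:
    """Discrete pmf on {0.2, 0.7, 0.9, 1} with equal probability."""
    return DiscreteMeasure([(0.2, 0.25), (0.7, 0.25), (0.9, 0.25), (1.0, 0.25)])


def merger_rate(measure: LambdaMeasure, b: int, k: int) -> float:
    """Rate lambda_{b,k} at which a specific k-subset of b lineages merges."""
    return measure.rate(b, k)


def _log_total_rate_from_row(b: int, log_row: np.ndarray) -> float:
    ks = np.arange(2, b + 1, dtype=float)
    return float(logsumexp(log_binom(b, ks) + log_row))


def total_rate(measure: LambdaMeasure, b: int) -> float:
    """Total coalescent rate lambda_b = sum_k C(b,k) lambda_{b,k}."""
    if b < 2:
        raise ValueError(f"need b >= 2, got {b}")
    return float(np.exp(_log_total_rate_from_row(b, measure.log_rate_row(b))))


def block_size_pmf(measure: LambdaMeasure, b: int) -> np.ndarray:
    """P(X = k) for k = 2..b: the size distribution of a merger event.

    Returns an array of length b-1 indexed by k-2.
    """
    if b < 2:
        raise ValueError(f"need b >= 2, got {b}")
    log_row = measure.log_rate_row(b)
    ks = np.arange(2, b + 1, dtype=float)
    log_terms = log_binom(b, ks) + log_row
    log_tot = logsumexp(log_terms)
    if not np.isfinite(log_tot):
        raise ValueError("degenerate measure: total coalescent rate is zero")
    return np.exp(log_terms - log_tot)


def total_rate_approx(alpha: float, b: int) -> float:
    """Closed-form approximation (b-1)(b/2)^(alpha-1) to the Beta total rate.

    Diagnostic only; exact at alpha = 2 (Kingman, C(b,2)) and alpha = 1
    (Bolthausen-Sznitman, b-1).  Not used inside any likelihood.
    """
    if not (0.0 < alpha <= 2.0):
        raise ValueError(f"alpha must be in (0, 2], got {alpha}")
    if b < 2:
        raise ValueError(f"need b >= 2, got {b}")
    return (b - 1) * (b / 2.0) ** (alpha - 1.0)


@dataclass
class RateTable:
    """Cached log merger rates, total rates and block-size pmfs up to b_max.

    Rates depend on the measure only (not on time or population size), so a
    single table is shared across all likelihood evaluations and simulator
    draws for a given measure.
    """

    measure: LambdaMeasure
    b_max: int
    log_lam: np.ndarray = field(init=False, repr=False)
    log_total: np.ndarray = field(init=False, repr=False)
    _pmfs: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.b_max < 2:
            raise ValueError("b_max must be >= 2")
        n = self.b_max
        self.log_lam = np.full((n + 1, n + 1), -np.inf)
        self.log_total = np.full(n + 1, -np.inf)
        for b in range(2, n + 1):
            row = self.measure.log_rate_row(b)
            self.log_lam[b, 2 : b + 1] = row
            self.log_total[b] = _log_total_rate_from_row(b, row)

    def log_rate(self, b: int, k: int) -> float:
        _check_bk(b, k)
        return float(self.log_lam[b, k])

    def log_total_rate(self, b: int) -> float:
        return float(self.log_total[b])

    def total_rate(self, b: int) -> float:
        return float(np.exp(self.log_total[b]))

    def pmf(self, b: int) -> np.ndarray:
        """Block-size pmf over k = 2..b (cached)."""
        got = self._pmfs.get(b)
        if got is None:
            ks = np.arange(2, b + 1, dtype=float)
            got = np.exp(log_binom(b, ks) + self.log_lam[b, 2 : b + 1] - self.log_total[b])
            self._pmfs[b] = got
        return got

    def check_consistency(self, rtol: float = 1e-8) -> float:
        """Max relative violation of lambda_{b,k} = lambda_{b+1,k} + lambda_{b+1,k+1}."""
        worst = 0.0
        for b in range(2, self.b_max):
            lhs = np.exp(self.log_lam[b, 2 : b + 1])
            rhs = np.exp(self.log_lam[b + 1, 2 : b + 1]) + np.exp(
                self.log_lam[b + 1, 3 : b + 2]
            )
            scale = np.maximum(np.abs(lhs), 1e-300)
            worst = max(worst, float(np.max(np.abs(lhs - rhs) / scale)))
        if worst > rtol:
            raise AssertionError(f"rate consistency violated: max rel err {worst:g}")
        return worst
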