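"""Coalescent log-likelihood for a heterochronous multifurcating genealogy
under a Lambda measure and piecewise-constant Ne(t).

The log density of the sufficient statistics (t, m) given (s, n) is

    sum_k [ log C(A(t_k), m_k) + log lambda_{A(t_k), m_k} - log Ne(t_k) ]
      - sum_intervals lambda_A * int du / Ne(u),

where the intervals tile [0, t_K] so that both A(t) and Ne(t) are constant
on each one; intervals with A < 2 contribute nothing to the integral.
The topology-only factor (the product of block-size probabilities) is
exposed separately: it depends on m and the lineage counts but not on the
coalescent times or Ne.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, logsumexp

from .demography import NeGrid
from .genealogy import CoalescentData, lineage_count
from .measures import BetaMeasure, KingmanMeasure, LambdaMeasure, RateTable, log_binom

__all__ = [
    "LikelihoodWorkspace",
    "loglik",
    "topology_loglik",
    "loglik_grad_gamma",
    "BetaLikelihoodCache",
]


@dataclass(frozen=True)
class LikelihoodWorkspace:
    """Interval decomposition of [0, t_K] for a (data, grid) pair.

    Change points are the sampling times, coalescent times and grid
    boundaries; within each interval both A(t) and the Ne cell are fixed.
    """

    event_A: np.ndarray       # A(t_k) just before each coalescent event
    event_m: np.ndarray
    event_cell: np.ndarray    # Ne grid cell containing t_k
    event_logC: np.ndarray    # log C(A(t_k), m_k)
    int_A: np.ndarray         # lineage count per interval (only A >= 2 kept)
    int_cell: np.ndarray
    int_len: np.ndarray
    n_cells: int

    @classmethod
    def build(cls, data: CoalescentData, grid: NeGrid) -> "LikelihoodWorkspace":
        t_max = data.tmrca
        cuts = np.concatenate(
            [
                [0.0, t_max],
                data.schedule.s,
                data.t,
                grid.x[(grid.x > 0.0) & (grid.x < t_max)],
            ]
        )
        cuts = np.unique(cuts)
        cuts = cuts[(cuts >= 0.0) & (cuts <= t_max)]
        mids = 0.5 * (cuts[:-1] + cuts[1:])
        a_mid = lineage_count(data, mids)
        keep = a_mid >= 2
        event_a = lineage_count(data, data.t)
        if np.any(data.m > event_a):
            raise ValueError("block size exceeds extant lineages")
        return cls(
            event_A=np.asarray(event_a, dtype=int),
            event_m=np.asarray(data.m, dtype=int),
            event_cell=np.asarray(grid.cell_index(data.t), dtype=int),
            event_logC=log_binom(event_a, data.m),
            int_A=np.asarray(a_mid[keep], dtype=int),
            int_cell=np.asarray(grid.cell_index(mids[keep]), dtype=int),
            int_len=np.diff(cuts)[keep],
            n_cells=grid.D - 1,
        )

    @property
    def b_max(self) -> int:
        return int(self.event_A.max())


def _rate_table(measure: LambdaMeasure, b_max: int,
                table: RateTable | None) -> RateTable:
    if table is not None:
        if table.b_max < b_max:
            raise ValueError("rate table too small for this genealogy")
        return table
    return RateTable(measure, b_max)


def loglik(
    data: CoalescentData,
    measure: LambdaMeasure,
    grid: NeGrid,
    rate_table: RateTable | None = None,
    workspace: LikelihoodWorkspace | None = None,
) -> float:
    """Full heterochronous variable-Ne log-likelihood."""
    ws = workspace if workspace is not None else LikelihoodWorkspace.build(data, grid)
    rt = _rate_table(measure, ws.b_max, rate_table)
    log_rates = rt.log_lam[ws.event_A, ws.event_m]
    if np.any(~np.isfinite(log_rates)):
        return -np.inf
    events = float(np.sum(ws.event_logC + log_rates - grid.gamma[ws.event_cell]))
    lam_tot = np.exp(rt.log_total[ws.int_A])
    integral = float(np.sum(lam_tot * ws.int_len * np.exp(-grid.gamma[ws.int_cell])))
    return events - integral


def topology_loglik(
    data: CoalescentData,
    alpha: float,
    rate_table: RateTable | None = None,
) -> float:
    """Log pseudo-likelihood of the block sizes only (no times, no Ne).

    Each coalescent event of size m_k when A lineages are extant
    contributes log[ C(A, m_k) lambda_{A, m_k} / lambda_A ].
    """
    event_a = np.asarray(lineage_count(data, data.t), dtype=int)
    if alpha == 2.0:
        if np.any(data.m > 2):
            return -np.inf
        measure: LambdaMeasure = KingmanMeasure()
    else:
        measure = BetaMeasure(alpha)
    rt = _rate_table(measure, int(event_a.max()), rate_table)
    log_rates = rt.log_lam[event_a, data.m]
    return float(
        np.sum(log_binom(event_a, data.m) + log_rates - rt.log_total[event_a])
    )


def loglik_grad_gamma(
    data: CoalescentData,
    measure: LambdaMeasure,
    grid: NeGrid,
    rate_table: RateTable | None = None,
    workspace: LikelihoodWorkspace | None = None,
) -> np.ndarray:
    """Gradient of :func:`loglik` with respect to gamma (length D - 1).

    d/d gamma_d = -(#events in cell d) + sum_{intervals in cell d}
    lambda_A * length * exp(-gamma_d).  Cells past t_K get exactly 0.
    """
    ws = workspace if workspace is not None else LikelihoodWorkspace.build(data, grid)
    rt = _rate_table(measure, ws.b_max, rate_table)
    counts = np.bincount(ws.event_cell, minlength=ws.n_cells).astype(float)
    lam_tot = np.exp(rt.log_total[ws.int_A])
    s = np.bincount(ws.int_cell, weights=lam_tot * ws.int_len, minlength=ws.n_cells)
    return -counts + s * np.exp(-grid.gamma)


class BetaLikelihoodCache:
    """Vectorized Beta-coalescent likelihood in (alpha, gamma) for fixed data.

    Precomputes the interval decomposition and, on demand, merger-rate
    sums over a whole grid of alpha values at once; used by the samplers
    and optimizers, where the same genealogy is evaluated many times.
    """

    def __init__(self, data: CoalescentData, grid: NeGrid):
        self.data = data
        self.grid = grid
        self.ws = LikelihoodWorkspace.build(data, grid)
        ws = self.ws
        self.n_cells = ws.n_cells
        self.event_counts = np.bincount(ws.event_cell, minlength=ws.n_cells).astype(float)
        # distinct interval lineage counts, padded (uA, k) matrices for the
        # total-rate sums lambda_b = sum_k C(b,k) lambda_{b,k}
        self.uA, self.int_A_idx = np.unique(ws.int_A, return_inverse=True)
        kmax = int(self.uA.max())
        ks = np.arange(2, kmax + 1, dtype=float)
        self._K = np.broadcast_to(ks, (self.uA.size, ks.size))
        self._B = np.broadcast_to(self.uA[:, None].astype(float), self._K.shape)
        self._mask = self._K <= self._B
        self._logC = np.where(self._mask, log_binom(self._B, self._K), -np.inf)
        self._alpha_grid_cache: tuple | None = None

    # -- alpha-dependent pieces ------------------------------------------

    def _log_total_rates(self, alphas: np.ndarray) -> np.ndarray:
        """log lambda_b for b in self.uA, for each alpha: shape (n_alpha, n_uA)."""
        a = alphas[:, None, None]
        with np.errstate(invalid="ignore"):
            terms = self._logC[None] + betaln(self._K - a, a + self._B - self._K)
        terms = np.where(self._mask[None], terms, -np.inf)
        out = logsumexp(terms, axis=2) - betaln(2.0 - alphas, alphas)[:, None]
        return out

    def _event_log_rates_sum(self, alphas: np.ndarray) -> np.ndarray:
        """sum_k [logC + log lambda_{A_k,m_k}] for each alpha: shape (n_alpha,)."""
        ws = self.ws
        a = alphas[:, None]
        s = np.sum(betaln(ws.event_m - a, a + ws.event_A - ws.event_m), axis=1)
        return float(np.sum(ws.event_logC)) + s - ws.event_m.size * betaln(
            2.0 - alphas, alphas
        )

    def _cell_weights(self, gamma: np.ndarray) -> np.ndarray:
        """w[i] = sum of length * exp(-gamma_cell) over intervals with A = uA[i]."""
        ws = self.ws
        return np.bincount(
            self.int_A_idx,
            weights=ws.int_len * np.exp(-gamma[ws.int_cell]),
            minlength=self.uA.size,
        )

    # -- public evaluations ----------------------------------------------

    def loglik(self, alpha: float, gamma: np.ndarray) -> float:
        return float(self.loglik_alpha_grid(np.array([alpha]), gamma)[0])

    def loglik_alpha_grid(self, alphas: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        """Full log-likelihood at each alpha (shared gamma), vectorized.

        The alpha-dependent rate sums are memoized per alpha grid, so
        repeated calls with the same grid (as in the MCMC alpha update)
        cost one matrix-vector product.
        """
        alphas = np.asarray(alphas, dtype=float)
        cached = self._alpha_grid_cache
        if cached is not None and cached[0].shape == alphas.shape and np.array_equal(
            cached[0], alphas
        ):
            _, lam, event_sums = cached
        else:
            lam = np.exp(self._log_total_rates(alphas))
            event_sums = self._event_log_rates_sum(alphas)
            if alphas.size >= 16:  # keep scalar probes from evicting the grid
                self._alpha_grid_cache = (alphas.copy(), lam, event_sums)
        events = event_sums - float(np.sum(gamma[self.ws.event_cell]))
        return events - lam @ self._cell_weights(gamma)

    def lam_totals(self, alpha: float) -> np.ndarray:
        """Total rates lambda_b for b in ``uA`` at a single alpha."""
        return np.exp(self._log_total_rates(np.array([alpha]))[0])

    def cell_rate_mass(self, alpha: float, gamma: np.ndarray,
                       lam_totals: np.ndarray | None = None) -> np.ndarray:
        """S_d = sum over intervals in cell d of lambda_A * length (no Ne)."""
        ws = self.ws
        lam = self.lam_totals(alpha) if lam_totals is None else lam_totals
        return np.bincount(
            ws.int_cell, weights=lam[self.int_A_idx] * ws.int_len,
            minlength=self.n_cells,
        )

    def loglik_gamma(self, gamma: np.ndarray, s_d: np.ndarray,
                     event_const: float) -> float:
        """Gamma-dependent part given cached alpha pieces (for HMC inner loops)."""
        return (
            event_const
            - float(np.sum(gamma[self.ws.event_cell]))
            - float(np.sum(s_d * np.exp(-gamma)))
        )

    def grad_gamma(self, gamma: np.ndarray, s_d: np.ndarray) -> np.ndarray:
        return -self.event_counts + s_d * np.exp(-gamma)
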