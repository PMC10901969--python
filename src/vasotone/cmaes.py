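"""Covariance matrix adaptation evolution strategy (CMA-ES).

A self-contained (mu/mu_w, lambda)-CMA-ES with cumulative step-size
adaptation and rank-one plus rank-mu covariance updates, following the
standard strategy-parameter settings of Hansen's tutorial formulation.
Written for the low-dimensional (< 30) parameter-identification problems
in this package; sampling uses an eigendecomposition refreshed every
generation, which is cheap at these sizes.

Deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

__all__ = ["CMAES", "minimize"]


class CMAES:
    """Ask/tell interface to the evolution strategy.

    Parameters
    ----------
    x0 : array
        Initial distribution mean.
    sigma0 : float
        Initial global step size (should not exceed 1 on the scaled
        search spaces used in this package).
    seed : int, optional
        Seed of the sampling RNG.
    popsize : int, optional
        Offspring per generation; default ``4 + floor(3 ln n)``.
    """

    def __init__(self, x0, sigma0: float, seed: Optional[int] = None,
                 popsize: Optional[int] = None):
        self.mean = np.asarray(x0, float).copy()
        n = self.mean.size
        self.n = n
        self.sigma = float(sigma0)
        self.rng = np.random.default_rng(seed)

        self.lam = popsize or 4 + int(3 * np.log(n))
        self.mu = self.lam // 2
        w = np.log((self.lam + 1) / 2.0) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights ** 2)

        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2.0 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.damps = (1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1)
                      + self.cs)
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.iteration = 0
        self.best_x = self.mean.copy()
        self.best_f = np.inf
        self._eigen()

    def _eigen(self):
        self.C = (self.C + self.C.T) / 2.0
        d2, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(d2, 1e-30))

    def ask(self) -> np.ndarray:
        """Sample one generation of candidate solutions, shape (lam, n)."""
        z = self.rng.standard_normal((self.lam, self.n))
        y = z @ np.diag(self.D) @ self.B.T
        self._last_y = y
        return self.mean + self.sigma * y

    def tell(self, X: np.ndarray, f: np.ndarray):
        """Update the search distribution from evaluated candidates."""
        f = np.asarray(f, float)
        order = np.argsort(f)
        if f[order[0]] < self.best_f:
            self.best_f = float(f[order[0]])
            self.best_x = X[order[0]].copy()

        y_sel = (X[order[: self.mu]] - self.mean) / self.sigma
        y_w = self.weights @ y_sel
        self.mean = self.mean + self.sigma * y_w

        # step-size path (in the isotropic coordinates)
        C_inv_half = self.B @ np.diag(1.0 / self.D) @ self.B.T
        self.ps = ((1 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2 - self.cs) * self.mueff)
                   * (C_inv_half @ y_w))
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * (self.iteration + 1)))
                < (1.4 + 2 / (self.n + 1)) * self.chiN)

        self.pc = ((1 - self.cc) * self.pc
                   + hsig * np.sqrt(self.cc * (2 - self.cc) * self.mueff) * y_w)

        rank_mu = sum(wk * np.outer(yk, yk)
                      for wk, yk in zip(self.weights, y_sel))
        delta_hsig = (1 - hsig) * self.cc * (2 - self.cc)
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc) + delta_hsig * self.C)
                  + self.cmu * rank_mu)

        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chiN - 1))
        self.sigma = min(self.sigma, 1e8)

        self.iteration += 1
        self._eigen()


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    nit: int
    nfev: int
    seed: Optional[int]
    trace: List[float] = field(default_factory=list)


def minimize(func: Callable[[np.ndarray], float], x0, sigma0: float,
             maxiter: int = 1000, seed: Optional[int] = None,
             popsize: Optional[int] = None, ftarget: float = -np.inf,
             keep_trace: bool = False) -> OptimizeResult:
    """Run CMA-ES for at most ``maxiter`` generations.

    Stops early when the best objective falls below ``ftarget``.
    """
    es = CMAES(x0, sigma0, seed=seed, popsize=popsize)
    nfev = 0
    trace: List[float] = []
    for _ in range(maxiter):
        X = es.ask()
        f = np.array([func(x) for x in X])
        nfev += len(f)
        es.tell(X, f)
        if keep_trace:
            trace.append(es.best_f)
        if es.best_f <= ftarget:
            break
    return OptimizeResult(x=es.best_x, fun=es.best_f, nit=es.iteration,
                          nfev=nfev, seed=seed, trace=trace)
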