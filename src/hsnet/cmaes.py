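"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A compact (mu/mu_w, lambda)-CMA-ES minimizer following the standard
formulation (rank-one plus rank-mu covariance update, cumulative
step-size adaptation).  Derivative-free and invariant to monotone
transformations of the objective, it is the calibrator's workhorse for
the box-constrained, non-convex parameter-estimation problem.

Box constraints are handled by projection repair: sampled candidates
are clipped onto the box before evaluation, and the repaired point is
what gets reported when it is the best seen so far.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["CMAES", "minimize_cmaes", "CMAResult"]


@dataclass
class CMAResult:
    x_best: np.ndarray
    f_best: float
    n_evals: int
    trace: list[float] = field(default_factory=list)  # best-so-far per generation
    termination: str = "budget"


class CMAES:
    """Ask/tell CMA-ES with optional box repair.

    Parameters
    ----------
    x0 : initial mean.
    sigma0 : initial global step size.
    seed : seeds the internal generator; identical seeds give identical
        sampling sequences.
    popsize : offspring per generation; default ``4 + floor(3 ln n)``.
    bounds : optional ``(lower, upper)`` arrays for projection repair.
    """

    def __init__(
        self,
        x0: Sequence[float],
        sigma0: float,
        seed: int = 0,
        popsize: int | None = None,
        bounds: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        if sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        self.m = np.asarray(x0, dtype=float).copy()
        n = self.m.size
        self.n = n
        self.sigma = float(sigma0)
        self.rng = np.random.default_rng(seed)
        self.lam = popsize or (4 + int(3 * np.log(n)))
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.w = w / w.sum()
        self.mueff = 1.0 / np.sum(self.w**2)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.damps = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))
        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.bounds = bounds
        self._decompose()
        self._z: np.ndarray | None = None
        self.n_evals = 0

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2.0
        d, B = np.linalg.eigh(self.C)
        d = np.maximum(d, 1e-20)
        self.B = B
        self.D = np.sqrt(d)
        self.invsqrtC = B @ np.diag(1.0 / self.D) @ B.T

    def ask(self) -> np.ndarray:
        """Sample ``popsize`` candidates, shape ``(popsize, n)`` (repaired)."""
        self._z = self.rng.standard_normal((self.lam, self.n))
        y = self._z @ np.diag(self.D) @ self.B.T
        X = self.m[None, :] + self.sigma * y
        if self.bounds is not None:
            lo, hi = self.bounds
            X = np.clip(X, lo, hi)
        return X

    def tell(self, X: np.ndarray, fitness: Sequence[float]) -> None:
        """Rank candidates and update mean, paths, covariance and sigma."""
        f = np.asarray(fitness, dtype=float)
        order = np.argsort(f, kind="stable")
        self.n_evals += len(f)
        # recompute displacement from possibly repaired X
        ysel = (X[order[: self.mu]] - self.m[None, :]) / self.sigma
        yw = self.w @ ysel
        self.m = self.m + self.sigma * yw
        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (self.invsqrtC @ yw)
        hsig = float(
            np.linalg.norm(self.ps)
            / np.sqrt(1 - (1 - self.cs) ** (2 * self.n_evals / self.lam))
            / self.chiN
            < 1.4 + 2 / (self.n + 1)
        )
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * yw
        rank_mu = sum(wi * np.outer(yi, yi) for wi, yi in zip(self.w, ysel))
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1
            * (np.outer(self.pc, self.pc) + (1 - hsig) * self.cc * (2 - self.cc) * self.C)
            + self.cmu * rank_mu
        )
        self.sigma *= np.exp(
            (self.cs / self.damps) * (np.linalg.norm(self.ps) / self.chiN - 1)
        )
        self.sigma = float(min(self.sigma, 1e6))
        self._decompose()


def minimize_cmaes(
    fun: Callable[[np.ndarray], float],
    x0: Sequence[float],
    sigma0: float,
    seed: int = 0,
    max_evals: int = 10_000,
    popsize: int | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    ftarget: float | None = None,
    restarts: int = 0,
    stagnation_gens: int = 30,
    stagnation_rtol: float = 1e-3,
    refine_frac: float = 0.4,
) -> CMAResult:
    """Minimize ``fun`` with CMA-ES under an evaluation budget.

    Tracks the best-so-far point; the returned trace (one entry per
    generation) is non-increasing by construction.

    With ``restarts > 0`` the budget splits into an exploration phase and
    a refinement phase.  Exploration launches up to ``restarts + 1``
    runs: the first from ``x0``, later ones from seeded draws around
    ``x0`` (scatter ``2*sigma0``); a run is abandoned once its best
    value stagnates (relative improvement below ``stagnation_rtol``
    over ``stagnation_gens`` generations).  Starts scatter around
    ``x0`` rather than uniformly over ``bounds`` because the box is a
    safety region orders of magnitude wider than plausible kinetics and
    uniform draws mostly land on degenerate models.  The final
    ``refine_frac`` of the budget reruns CMA-ES from the best point
    found with a third of the step size.  The whole schedule is driven
    by one seeded generator, hence reproducible.
    """
    x0 = np.asarray(x0, dtype=float)
    if max_evals <= 0:
        f0 = float(fun(x0))
        return CMAResult(x_best=x0.copy(), f_best=f0, n_evals=1, trace=[f0], termination="budget")
    rng = np.random.default_rng(seed)
    x_best = x0.copy()
    f_best = np.inf
    trace: list[float] = []
    n_evals = 0

    def run_cma(mean, sigma, budget, stagnate: bool) -> str | None:
        nonlocal x_best, f_best, n_evals
        es = CMAES(mean, sigma, seed=int(rng.integers(2**31)), popsize=popsize, bounds=bounds)
        run_trace: list[float] = []
        while n_evals < budget:
            X = es.ask()
            f = np.array([fun(xi) for xi in X])
            es.tell(X, f)
            n_evals += len(f)
            i = int(np.argmin(f))
            if f[i] < f_best:
                f_best = float(f[i])
                x_best = X[i].copy()
            trace.append(f_best)
            run_trace.append(f_best)
            if ftarget is not None and f_best <= ftarget:
                return "ftarget"
            if (
                stagnate
                and len(run_trace) > stagnation_gens
                and run_trace[-stagnation_gens - 1] - run_trace[-1]
                <= stagnation_rtol * max(abs(run_trace[-1]), 1e-12)
            ):
                return None
        return "budget"

    if restarts == 0:
        status = run_cma(x0, sigma0, max_evals, stagnate=False)
        return CMAResult(x_best, f_best, n_evals, trace, status or "budget")

    explore_budget = int(max_evals * (1.0 - refine_frac))
    for run in range(restarts + 1):
        if n_evals >= explore_budget:
            break
        if run == 0:
            mean = x0
        else:
            mean = x0 + 2.0 * sigma0 * rng.standard_normal(x0.size)
            if bounds is not None:
                mean = np.clip(mean, bounds[0], bounds[1])
        status = run_cma(mean, sigma0, explore_budget, stagnate=True)
        if status == "ftarget":
            return CMAResult(x_best, f_best, n_evals, trace, status)
    status = run_cma(x_best.copy(), sigma0 / 3.0, max_evals, stagnate=False)
    return CMAResult(x_best, f_best, n_evals, trace, status or "budget")
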