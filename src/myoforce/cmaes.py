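"""Minimal covariance matrix adaptation evolution strategy (CMA-ES).

Standard (mu/mu_w, lambda) CMA-ES with cumulative step-size adaptation and
rank-one plus rank-mu covariance updates, following Hansen's reference
formulation.  Box constraints are handled by projecting sampled candidates
onto the box before evaluation.  Deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CMAResult", "cma_es_minimize", "default_popsize"]


def default_popsize(n_dim: int) -> int:
    return 4 + int(3 * np.log(n_dim))


@dataclass
class CMAResult:
    x_best: np.ndarray
    f_best: float
    n_iterations: int
    n_evals: int
    trace: list = field(default_factory=list)  # best-so-far per generation
    converged: bool = True
    message: str = ""


def cma_es_minimize(
    func,
    x0,
    sigma0: float,
    n_iter: int,
    bounds: tuple | None = None,
    popsize: int | None = None,
    seed=None,
) -> CMAResult:
    """Minimize ``func`` over ``n_iter`` generations from ``x0``.

    ``bounds`` is an optional ``(lower, upper)`` pair of arrays; candidates
    are clipped into the box before evaluation.  Non-finite objective
    values are treated as a large penalty so the search continues.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    lam = popsize if popsize is not None else default_popsize(n)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    if bounds is not None:
        lower = np.asarray(bounds[0], dtype=float)
        upper = np.asarray(bounds[1], dtype=float)
    else:
        lower = upper = None

    rng = np.random.default_rng(seed)
    mean = x0.copy()
    sigma = float(sigma0)
    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    B = np.eye(n)
    D = np.ones(n)
    invsqrt_c = np.eye(n)
    eigen_stale = 0

    def _eval(x):
        f = func(x)
        return float(f) if np.isfinite(f) else 1e12

    x_best = np.clip(x0, lower, upper) if lower is not None else x0.copy()
    f_best = _eval(x_best)
    n_evals = 1
    trace: list[float] = []
    message = ""

    for gen in range(n_iter):
        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T  # rows: B @ diag(D) @ z_i
        x = mean + sigma * y
        if lower is not None:
            x = np.clip(x, lower, upper)
        f = np.array([_eval(xi) for xi in x])
        n_evals += lam
        order = np.argsort(f)
        if f[order[0]] < f_best:
            f_best = float(f[order[0]])
            x_best = x[order[0]].copy()
        trace.append(f_best)

        sel = x[order[:mu]]
        old_mean = mean
        mean = w @ sel
        y_w = (mean - old_mean) / sigma

        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (invsqrt_c @ y_w)
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (gen + 1))) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        artmp = (sel - old_mean) / sigma
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * artmp.T @ (w[:, None] * artmp)
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        if not np.isfinite(sigma) or sigma > 1e8:
            message = "step size diverged"
            break

        eigen_stale += lam
        if eigen_stale > lam / (c1 + cmu) / n / 10:
            eigen_stale = 0
            C = np.triu(C) + np.triu(C, 1).T
            vals, B = np.linalg.eigh(C)
            if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
                message = "covariance degenerate"
                break
            D = np.sqrt(vals)
            invsqrt_c = B @ np.diag(1.0 / D) @ B.T

    return CMAResult(
        x_best=x_best,
        f_best=f_best,
        n_iterations=n_iter,
        n_evals=n_evals,
        trace=trace,
        converged=message == "",
        message=message,
    )
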