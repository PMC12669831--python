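"""Fit the six Hill parameters to trials by CMA-ES on the mean squared
normalized-force error.

Parameters with strong positivity/scale disparity (W, v_max, A_rel, k_pee)
are optimized in log-space; g_max and l_slack_pee in linear space.  All
coordinates are additionally rescaled to the unit box so a single initial
step size applies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cmaes import cma_es_minimize, default_popsize
from .hill import PARAM_NAMES, HillParams, hill_force

__all__ = [
    "FitResult",
    "DEFAULT_INIT",
    "DEFAULT_BOUNDS",
    "mse_objective",
    "fit_cmaes",
    "refit_width_only",
]

#: Mid-literature initial guess.
DEFAULT_INIT = HillParams(W=0.2, v_max=7.0, A_rel=0.27, g_max=1.5, k_pee=3.0, l_slack_pee=1.0)

#: Box bounds per parameter, wide enough to contain reported fitted values.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "W": (0.02, 0.6),
    "v_max": (1.0, 20.0),
    "A_rel": (0.01, 1.0),
    "g_max": (0.8, 2.5),
    "k_pee": (1e-6, 50.0),
    "l_slack_pee": (0.7, 1.3),
}

LOG_PARAMS = ("W", "v_max", "A_rel", "k_pee")


@dataclass
class FitResult:
    params: HillParams
    objective: float
    n_iterations: int
    seed: int | None
    trace: list = field(default_factory=list)
    popsize: int | None = None
    converged: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": self.objective,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "trace": list(map(float, self.trace)),
            "popsize": self.popsize,
            "converged": self.converged,
            "message": self.message,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _stack_trials(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate (a, lce, vce, force) over a Trial list or array tuples."""
    if not trials:
        raise ValueError("trials must be nonempty")
    a, l, v, f = [], [], [], []
    for tr in trials:
        if hasattr(tr, "activation"):
            a.append(tr.activation)
            l.append(tr.lce)
            v.append(tr.vce)
            f.append(tr.force)
        else:
            ai, li, vi, fi = tr
            a.append(np.asarray(ai, float))
            l.append(np.asarray(li, float))
            v.append(np.asarray(vi, float))
            f.append(np.asarray(fi, float))
    return tuple(np.concatenate(x) for x in (a, l, v, f))


def mse_objective(params: HillParams, trials, f_max: float) -> float:
    """Mean over all samples of (F_hill/f_max - F_meas/f_max)**2."""
    a, l, v, f_meas = _stack_trials(trials)
    f_hat = hill_force(a, l, v, params, f_max)
    err = (f_hat - f_meas) / f_max
    mse = float(np.mean(err**2))
    return mse if np.isfinite(mse) else float("inf")


# -- parameter encoding ------------------------------------------------------

def _encode_bounds(bounds: dict) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in PARAM_NAMES:
        b_lo, b_hi = bounds[name]
        if name in LOG_PARAMS:
            b_lo, b_hi = np.log(b_lo), np.log(b_hi)
        lo.append(b_lo)
        hi.append(b_hi)
    return np.asarray(lo), np.asarray(hi)


def _encode(params: HillParams, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    raw = []
    for name in PARAM_NAMES:
        val = getattr(params, name)
        raw.append(np.log(val) if name in LOG_PARAMS else val)
    return (np.asarray(raw) - lo) / (hi - lo)


def _decode(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> HillParams:
    raw = lo + np.clip(u, 0.0, 1.0) * (hi - lo)
    vals = {}
    for i, name in enumerate(PARAM_NAMES):
        vals[name] = float(np.exp(raw[i]) if name in LOG_PARAMS else raw[i])
    return HillParams(**vals)


def fit_cmaes(
    trials,
    f_max: float,
    init: HillParams = DEFAULT_INIT,
    bounds: dict | None = None,
    n_iter: int = 100,
    seed: int | None = None,
    sigma0: float = 0.25,
    popsize: int | None = None,
) -> FitResult:
    """CMA-ES fit of all six Hill parameters (default 100 generations).

    ``n_iter`` counts CMA-ES generations at the default population size
    ``4 + floor(3 ln n)``.  Reproducible under a fixed seed; returns the
    best-seen parameters and the best-so-far objective trace.
    """
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    lo, hi = _encode_bounds(bounds)
    u0 = _encode(init, lo, hi)
    if np.any(u0 < -1e-12) or np.any(u0 > 1 + 1e-12):
        raise ValueError("init must lie within bounds")
    a, l, v, f_meas = _stack_trials(trials)
    f_norm = f_meas / f_max

    def objective(u: np.ndarray) -> float:
        p = _decode(u, lo, hi)
        err = hill_force(a, l, v, p, f_max) / f_max - f_norm
        mse = float(np.mean(err**2))
        return mse if np.isfinite(mse) else float("inf")

    if n_iter == 0:
        return FitResult(
            params=init,
            objective=objective(u0),
            n_iterations=0,
            seed=seed,
            popsize=popsize or default_popsize(len(PARAM_NAMES)),
        )
    res = cma_es_minimize(
        objective,
        u0,
        sigma0=sigma0,
        n_iter=n_iter,
        bounds=(np.zeros(u0.size), np.ones(u0.size)),
        popsize=popsize,
        seed=seed,
    )
    return FitResult(
        params=_decode(res.x_best, lo, hi),
        objective=res.f_best,
        n_iterations=res.n_iterations,
        seed=seed,
        trace=res.trace,
        popsize=popsize or default_popsize(len(PARAM_NAMES)),
        converged=res.converged,
        message=res.message,
    )


def refit_width_only(
    base: HillParams,
    trials,
    f_max: float,
    bounds: dict | None = None,
    n_iter: int = 100,
    seed: int | None = None,
    sigma0: float = 0.25,
) -> FitResult:
    """Re-optimize only the force-length width W, all other parameters frozen."""
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    w_lo, w_hi = np.log(bounds["W"][0]), np.log(bounds["W"][1])
    a, l, v, f_meas = _stack_trials(trials)
    f_norm = f_meas / f_max

    def objective(u: np.ndarray) -> float:
        w = float(np.exp(w_lo + np.clip(u[0], 0.0, 1.0) * (w_hi - w_lo)))
        p = base.replace(W=w)
        err = hill_force(a, l, v, p, f_max) / f_max - f_norm
        mse = float(np.mean(err**2))
        return mse if np.isfinite(mse) else float("inf")

    u0 = np.array([(np.log(base.W) - w_lo) / (w_hi - w_lo)])
    if n_iter == 0:
        return FitResult(params=base, objective=objective(u0), n_iterations=0, seed=seed)
    res = cma_es_minimize(
        objective,
        u0,
        sigma0=sigma0,
        n_iter=n_iter,
        bounds=(np.zeros(1), np.ones(1)),
        seed=seed,
    )
    w_best = float(np.exp(w_lo + np.clip(res.x_best[0], 0.0, 1.0) * (w_hi - w_lo)))
    return FitResult(
        params=base.replace(W=w_best),
        objective=res.f_best,
        n_iterations=res.n_iterations,
        seed=seed,
        trace=res.trace,
        popsize=4,
        converged=res.converged,
        message=res.message,
    )
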