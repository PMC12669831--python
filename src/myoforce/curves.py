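"""Force-length and force-velocity curve extraction by probing an estimator.

A trained network (or an analytic Hill model wrapped in the same protocol)
is evaluated on a grid of lengths (isometric, v = 0) or velocities (at
optimal length, l = 1) for a set of activation levels; outputs are
normalized force.  Grid points whose z-scored inputs lie far outside the
training distribution are flagged as extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hill import HillParams, hill_force
from .nn import NNModel, predict
from .preprocessing import NormStats, apply_norm

__all__ = [
    "CurveSet",
    "HillProbe",
    "extract_fl",
    "extract_fv",
    "curve_summary",
    "default_fl_grid",
    "default_fv_grid",
    "ACTIVATION_LEVELS",
]

ACTIVATION_LEVELS = (0.2, 0.4, 0.6, 0.8, 1.0)
FL_RANGE = (0.6, 1.4)
FV_RANGE = (-10.0, 10.0)
FL_STEP = 0.01
FV_STEP = 0.1
EXTRAPOLATION_Z = 3.0


def default_fl_grid() -> np.ndarray:
    n = int(round((FL_RANGE[1] - FL_RANGE[0]) / FL_STEP)) + 1
    return np.linspace(*FL_RANGE, n)


def default_fv_grid() -> np.ndarray:
    n = int(round((FV_RANGE[1] - FV_RANGE[0]) / FV_STEP)) + 1
    return np.linspace(*FV_RANGE, n)


@dataclass
class CurveSet:
    """Extracted curves: force matrix of shape (n_levels, n_grid)."""

    kind: str  # "FL" or "FV"
    grid: np.ndarray
    activation_levels: tuple
    force: np.ndarray
    extrapolated: np.ndarray | None = field(default=None)  # same shape as force

    def __post_init__(self) -> None:
        if self.kind not in ("FL", "FV"):
            raise ValueError("kind must be 'FL' or 'FV'")
        self.grid = np.asarray(self.grid, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.force.shape != (len(self.activation_levels), self.grid.size):
            raise ValueError("force matrix shape must be (n_levels, n_grid)")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")
        lo, hi = FL_RANGE if self.kind == "FL" else FV_RANGE
        if self.grid.min() < lo - 1e-9 or self.grid.max() > hi + 1e-9:
            raise ValueError(f"{self.kind} grid must lie within [{lo}, {hi}]")

    def to_frame(self) -> pd.DataFrame:
        """Long format: kind, activation, x, force, extrapolated."""
        rows = []
        for i, a in enumerate(self.activation_levels):
            for j, x in enumerate(self.grid):
                rows.append(
                    {
                        "kind": self.kind,
                        "activation": a,
                        "x": float(x),
                        "force": float(self.force[i, j]),
                        "extrapolated": bool(self.extrapolated[i, j])
                        if self.extrapolated is not None
                        else False,
                    }
                )
        return pd.DataFrame(rows)


class HillProbe:
    """Adapter exposing an analytic Hill model through the probe protocol.

    Serves as the machine-precision oracle for the extraction machinery.
    """

    def __init__(self, params: HillParams, norm_stats: NormStats | None = None):
        self.params = params
        self.norm_stats = norm_stats

    def predict_normalized(self, a, lce, vce) -> np.ndarray:
        return np.asarray(hill_force(a, lce, vce, self.params, f_max=1.0))


def _probe(model, a, lce, vce) -> np.ndarray:
    if isinstance(model, NNModel):
        return predict(model, a, lce, vce)
    if hasattr(model, "predict_normalized"):
        return np.asarray(model.predict_normalized(a, lce, vce), dtype=float)
    raise TypeError("model must be an NNModel or expose predict_normalized")


def _norm_stats_of(model) -> NormStats | None:
    return getattr(model, "norm_stats", None)


def _extrapolation_mask(stats: NormStats | None, lce, vce, n_levels: int) -> np.ndarray | None:
    if stats is None:
        return None
    zl, zv = apply_norm(lce, vce, stats)
    mask = (np.abs(zl) > EXTRAPOLATION_Z) | (np.abs(zv) > EXTRAPOLATION_Z)
    return np.tile(mask, (n_levels, 1))


def _extract(model, kind: str, grid, levels) -> CurveSet:
    grid = np.asarray(grid, dtype=float)
    levels = tuple(levels)
    if isinstance(model, NNModel) and model.norm_stats is None:
        raise ValueError("model carries no normalization statistics")
    if kind == "FL":
        lce, vce = grid, np.zeros_like(grid)
    else:
        lce, vce = np.ones_like(grid), grid
    force = np.empty((len(levels), grid.size))
    for i, a_level in enumerate(levels):
        force[i] = _probe(model, np.full(grid.size, a_level), lce, vce)
    mask = _extrapolation_mask(_norm_stats_of(model), lce, vce, len(levels))
    return CurveSet(kind=kind, grid=grid, activation_levels=levels, force=force, extrapolated=mask)


def extract_fl(model, grid=None, levels=ACTIVATION_LEVELS) -> CurveSet:
    """Force-length curves at v = 0 (the PEE contribution is included)."""
    return _extract(model, "FL", default_fl_grid() if grid is None else grid, levels)


def extract_fv(model, grid=None, levels=ACTIVATION_LEVELS) -> CurveSet:
    """Force-velocity curves at l = 1 (optimal fiber length)."""
    return _extract(model, "FV", default_fv_grid() if grid is None else grid, levels)


def curve_summary(curves: CurveSet) -> pd.DataFrame:
    """Per activation level: argmax location on the grid and maximum force."""
    if curves.force.size == 0:
        raise ValueError("empty curve set")
    rows = []
    for i, a in enumerate(curves.activation_levels):
        j = int(np.argmax(curves.force[i]))
        rows.append(
            {
                "activation": a,
                "argmax_x": float(curves.grid[j]),
                "max_force": float(curves.force[i, j]),
            }
        )
    return pd.DataFrame(rows)
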