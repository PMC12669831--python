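"""Two-element Hill-type muscle model (contractile + parallel elastic element).

The tendon force is the sum of the contractile element (CE) force and the
parallel elastic element (PEE) force::

    F(a, l, v) = F_max * (a * f(l) * g(v) + F_pee(l))

with length ``l`` and velocity ``v`` normalized to optimal fiber length
(L0 and L0/s respectively).  The closed forms are

* force-length:  ``f(l) = max(0, 1 - ((l - 1) / W)**2)``  (parabola of
  width ``W``, unity at the optimum),
* force-velocity, shortening branch (``v <= 0``):
  ``g(v) = (v_max + v) / (v_max - v / A_rel)``, clipped at 0 below
  ``-v_max``,
* force-velocity, lengthening branch (``v > 0``):
  ``g(v) = g_max - (g_max - 1) * c3 / (v + c3)`` with
  ``c3 = (g_max - 1) * A_rel * v_max / (1 + A_rel)`` chosen so that the
  curve is continuous in value and slope at ``v = 0`` and approaches the
  asymptote ``g_max``,
* PEE: ``F_pee(l) = k_pee * max(0, l - l_slack_pee)**2`` (quadratic above
  slack, C1-continuous at the slack length).

All operations are pure and vectorize over NumPy arrays.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "HillParams",
    "continuity_factor",
    "force_length",
    "force_velocity",
    "pee_force",
    "hill_force",
]

#: Parameter names optimized when fitting the model to data.
PARAM_NAMES = ("W", "v_max", "A_rel", "g_max", "k_pee", "l_slack_pee")


def continuity_factor(v_max: float, A_rel: float, g_max: float) -> float:
    """Factor making the force-velocity curve C1-continuous at v = 0.

    The lengthening hyperbola ``g_max - (g_max - 1) * c3 / (v + c3)`` equals
    1 at v = 0 for any c3; this value additionally matches the shortening
    branch slope ``(1 + A_rel) / (A_rel * v_max)``.
    """
    return (g_max - 1.0) * A_rel * v_max / (1.0 + A_rel)


@dataclass(frozen=True)
class HillParams:
    """The six optimized Hill parameters plus the derived continuity factor.

    Attributes
    ----------
    W : width of the force-length parabola (L0 units).
    v_max : maximum shortening velocity (L0/s, positive).
    A_rel : curvature of the shortening force-velocity hyperbola.
    g_max : asymptotic force amplification during lengthening.
    k_pee : PEE stiffness (F_max per L0**2).
    l_slack_pee : PEE slack length (L0).
    """

    W: float
    v_max: float
    A_rel: float
    g_max: float
    k_pee: float
    l_slack_pee: float
    c3: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.W > 0):
            raise ValueError(f"W must be positive, got {self.W}")
        if not (self.v_max > 0):
            raise ValueError(f"v_max must be positive, got {self.v_max}")
        if not (self.A_rel > 0):
            raise ValueError(f"A_rel must be positive, got {self.A_rel}")
        if not (self.g_max > 0):
            raise ValueError(f"g_max must be positive, got {self.g_max}")
        if self.k_pee < 0:
            raise ValueError(f"k_pee must be non-negative, got {self.k_pee}")
        if not (self.l_slack_pee > 0):
            raise ValueError(
                f"l_slack_pee must be positive, got {self.l_slack_pee}"
            )
        c3 = continuity_factor(self.v_max, self.A_rel, self.g_max)
        if not np.isfinite(c3):
            raise ValueError("derived continuity factor is not finite")
        object.__setattr__(self, "c3", c3)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        return cls(**{k: float(d[k]) for k in PARAM_NAMES})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HillParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HillParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **changes) -> "HillParams":
        d = {k: getattr(self, k) for k in PARAM_NAMES}
        d.update(changes)
        return HillParams(**d)


def force_length(l, W: float):
    """Normalized active force-length relationship.

    Parabolic with width ``W``: unity at l = 1, zero for ``|l - 1| >= W``.
    """
    if not W > 0:
        raise ValueError("W must be positive")
    l = np.asarray(l, dtype=float)
    f = 1.0 - ((l - 1.0) / W) ** 2
    out = np.maximum(f, 0.0)
    return out if out.ndim else float(out)


def force_velocity(v, v_max: float, A_rel: float, g_max: float):
    """Normalized force-velocity relationship, continuous in value and slope.

    Shortening (``v <= 0``) follows the Hill hyperbola
    ``(v_max + v) / (v_max - v / A_rel)``, clipped at 0 for ``v < -v_max``.
    Lengthening (``v > 0``) follows a hyperbola with asymptote ``g_max``
    whose continuity factor c3 matches the shortening branch at v = 0.
    """
    if not (v_max > 0 and A_rel > 0):
        raise ValueError("v_max and A_rel must be positive")
    if not g_max > 0:
        raise ValueError("g_max must be positive")
    v = np.asarray(v, dtype=float)
    c3 = continuity_factor(v_max, A_rel, g_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (v_max + v) / (v_max - v / A_rel)
        if c3 == 0.0:  # g_max == 1: flat lengthening branch
            ecc = np.ones_like(v)
        else:
            ecc = g_max - (g_max - 1.0) * c3 / (v + c3)
    g = np.where(v > 0.0, ecc, conc)
    g = np.maximum(g, 0.0)
    return g if g.ndim else float(g)


def pee_force(l, k_pee: float, l_slack_pee: float):
    """Normalized parallel-elastic force: quadratic above the slack length."""
    if k_pee < 0:
        raise ValueError("k_pee must be non-negative")
    if not l_slack_pee > 0:
        raise ValueError("l_slack_pee must be positive")
    l = np.asarray(l, dtype=float)
    stretch = np.maximum(l - l_slack_pee, 0.0)
    out = k_pee * stretch**2
    return out if out.ndim else float(out)


def hill_force(a, l, v, params: HillParams, f_max: float):
    """Tendon force in Newtons from activation, CE length and CE velocity.

    ``F = f_max * (a * f(l) * g(v) + F_pee(l))``; activation values above 1
    are passed through unclamped.
    """
    a = np.asarray(a, dtype=float)
    l = np.asarray(l, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(l)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite inputs to hill_force")
    if np.any(a < 0):
        raise ValueError("activation must be non-negative")
    fl = force_length(l, params.W)
    gv = force_velocity(v, params.v_max, params.A_rel, params.g_max)
    fp = pee_force(l, params.k_pee, params.l_slack_pee)
    out = f_max * (a * fl * gv + fp)
    out = np.maximum(out, 0.0)
    return out if np.ndim(out) else float(out)
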