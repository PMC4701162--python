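"""Lanchester attrition laws as one-step difference equations.

Four variants of the classical two-force attrition model are supported,
each defined by how the per-step casualties of a force depend on the two
current strengths ``B`` (blue) and ``R`` (red):

* ``linear``       — losses proportional to the product of both sizes
  (hand-to-hand combat: every soldier engages one opponent);
* ``squared``      — losses proportional to the *enemy's* size (ranged
  fire: every soldier can engage many opponents);
* ``logarithmic``  — losses proportional to a force's *own* size;
* ``fatigue``      — the logarithmic law with per-step losses damped by
  ``ln(e + t)``, modelling a gradual decline in combat efficiency as an
  engagement drags on.

Fighting values are per-soldier lethality coefficients.  Blue's value
``b`` is scaled so that, at the initial strengths, a fighting value of 1
inflicts at most 100 casualties per step; red's value is ``r = b * P``
where the odds ratio ``P`` expresses a red soldier's lethality as a
multiple of a blue soldier's (``P = 2``: each red soldier is as lethal
as two blue soldiers).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

__all__ = [
    "Model",
    "ForceState",
    "FightingValues",
    "scale_fighting_value",
    "enemy_value",
    "step",
    "closed_form_log",
]


class Model(enum.Enum):
    """Enumerated attrition-model index (the model-selection variable)."""

    LINEAR = 1
    SQUARED = 2
    LOGARITHMIC = 3
    FATIGUE = 4

    @classmethod
    def from_name(cls, name: "str | Model") -> "Model":
        if isinstance(name, cls):
            return name
        try:
            return cls[str(name).upper()]
        except KeyError:
            raise ValueError(
                f"unknown model {name!r}; expected one of "
                f"{[m.name.lower() for m in cls]}"
            ) from None

    @property
    def label(self) -> str:
        return self.name.lower()

    def __str__(self) -> str:  # serialized by name everywhere
        return self.label


ALL_MODELS: tuple[Model, ...] = tuple(Model)


@dataclass(frozen=True)
class ForceState:
    """Current strengths and cumulative casualties of the two forces.

    Conservation holds at every step: ``B + cum_cas_blue`` equals the
    initial blue strength, and likewise for red.  ``clamped`` records
    whether a per-step loss ever had to be capped at the remaining
    strength (no negative armies).
    """

    B: float
    R: float
    t: int = 0
    cum_cas_blue: float = 0.0
    cum_cas_red: float = 0.0
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.B < 0 or self.R < 0:
            raise ValueError("force strengths must be non-negative")
        if self.t < 0:
            raise ValueError("step counter must be non-negative")


@dataclass(frozen=True)
class FightingValues:
    """Per-soldier lethality pair with ``r = b * P`` exactly."""

    b: float
    P: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("fighting value b must be positive")
        if self.P <= 0:
            raise ValueError("odds ratio P must be positive")

    @property
    def r(self) -> float:
        return self.b * self.P


def scale_fighting_value(m: Model, B0: float, R0: float) -> float:
    """Blue fighting value scaled to the initial force sizes.

    The scaling bounds the casualties blue can inflict on red in one
    step at full strength to 100, keeping coefficients comparable
    across laws whose loss terms have different dimensions: the linear
    law's loss term is ``b*R*B`` so ``b = 100/(B0*R0)``; the other
    three have loss terms proportional to a single strength, so
    ``b = 100/max(B0, R0)``.
    """
    m = Model.from_name(m)
    if B0 <= 0 or R0 <= 0:
        raise ValueError("initial sizes must be positive")
    if m is Model.LINEAR:
        return 100.0 / (B0 * R0)
    return 100.0 / max(B0, R0)


def enemy_value(b: float, P: float) -> float:
    """Red fighting value ``r = b * P``."""
    if b <= 0 or P <= 0:
        raise ValueError("b and P must be positive")
    return b * P


def _per_step_losses(m: Model, B: float, R: float, b: float, r: float, t: int) -> tuple[float, float]:
    """Raw (unclamped) per-step losses (blue loss, red loss)."""
    if m is Model.LINEAR:
        return r * B * R, b * R * B
    if m is Model.SQUARED:
        return r * R, b * B
    if m is Model.LOGARITHMIC:
        return r * B, b * R
    # fatigue: logarithmic losses damped by ln(e + t); equals the
    # logarithmic law exactly at t = 0 since ln(e) = 1
    damp = math.log(math.e + t)
    return r * B / damp, b * R / damp


def step(m: Model, s: ForceState, fv: FightingValues) -> ForceState:
    """Apply one difference-equation update of model ``m``.

    Losses are computed from the current state (simultaneous update),
    clamped at the remaining strength, and the step counter advances.
    """
    m = Model.from_name(m)
    if s.B <= 0 or s.R <= 0:
        raise ValueError("step requires positive current strengths")
    loss_b, loss_r = _per_step_losses(m, s.B, s.R, fv.b, fv.r, s.t)
    clamped = loss_b > s.B or loss_r > s.R
    loss_b = min(loss_b, s.B)
    loss_r = min(loss_r, s.R)
    return replace(
        s,
        B=s.B - loss_b,
        R=s.R - loss_r,
        t=s.t + 1,
        cum_cas_blue=s.cum_cas_blue + loss_b,
        cum_cas_red=s.cum_cas_red + loss_r,
        clamped=s.clamped or clamped,
    )


def closed_form_log(B0: float, R0: float, fv: FightingValues, t: int) -> tuple[float, float]:
    """Exact solution of the logarithmic recurrence (testing oracle).

    Each side decays geometrically and independently:
    ``B_t = B0 * (1 - r)**t`` and ``R_t = R0 * (1 - b)**t``
    (clamping ignored, hence the ``0 < b, r < 1`` requirement).
    """
    if not (0 < fv.r < 1 and 0 < fv.b < 1):
        raise ValueError("closed form requires coefficients in (0, 1)")
    if t < 0:
        raise ValueError("t must be non-negative")
    return B0 * (1.0 - fv.r) ** t, R0 * (1.0 - fv.b) ** t
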