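"""Simulate single battles under an attrition law.

The fitting loop replays each historical battle forward from its
recorded initial sizes and stops at the first step where either side's
cumulative casualties reach that side's historical total.  Per-step
casualty quanta are of order 100 soldiers under the fighting-value
scaling, so by default the final step is linearly interpolated: the
triggering side lands exactly on its historical total and the other
side's final-step loss is scaled by the same fraction.  Without
interpolation the triggering side overshoots by at most one step's
loss.

Two interfaces are provided: a scalar one built on
:func:`lanchester_abc.models.step` (the readable reference), and
:func:`simulate_batch`, a vectorised engine over arrays of battles that
the ABC loop uses.  Both implement identical semantics and are checked
against each other in the test suite.  Neither draws random numbers:
simulation is a deterministic function of its inputs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .battle_data import Battle
from .models import (
    FightingValues,
    ForceState,
    Model,
    _per_step_losses,
    scale_fighting_value,
    step,
)

__all__ = [
    "Termination",
    "SimOptions",
    "SimOutcome",
    "BatchOutcome",
    "simulate_to_casualties",
    "simulate_trajectory",
    "simulate_batch",
]

#: a side is considered annihilated once its strength falls below this
#: fraction of its initial size (proportional-loss laws decay
#: geometrically and never reach exactly zero)
STRENGTH_EPS_REL = 1e-9


class Termination(enum.Enum):
    HISTORICAL = "historical_casualties_reached"
    ANNIHILATION = "annihilation"
    MAX_STEPS = "max_steps"


@dataclass(frozen=True)
class SimOptions:
    max_steps: int = 100_000
    interpolate_final_step: bool = True

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass(frozen=True)
class SimOutcome:
    sim_cas_blue: float
    sim_cas_red: float
    steps: int
    termination: Termination


def simulate_to_casualties(
    m: Model,
    battle: Battle,
    P: float,
    opts: SimOptions | None = None,
) -> SimOutcome:
    """Replay one battle until a side reaches its historical casualties.

    The battle must be in canonical orientation (red = lower historical
    casualty ratio); ``P`` is the red side's per-soldier lethality as a
    multiple of blue's.
    """
    m = Model.from_name(m)
    opts = opts or SimOptions()
    if P <= 0:
        raise ValueError("odds ratio P must be positive")
    b = scale_fighting_value(m, battle.size_blue, battle.size_red)
    fv = FightingValues(b=b, P=P)
    tgt_b, tgt_r = battle.cas_blue, battle.cas_red
    eps_b = battle.size_blue * STRENGTH_EPS_REL
    eps_r = battle.size_red * STRENGTH_EPS_REL

    s = ForceState(B=float(battle.size_blue), R=float(battle.size_red))
    for _ in range(opts.max_steps):
        nxt = step(m, s, fv)
        loss_b = s.B - nxt.B
        loss_r = s.R - nxt.R
        hit_b = nxt.cum_cas_blue >= tgt_b
        hit_r = nxt.cum_cas_red >= tgt_r
        if hit_b or hit_r:
            if opts.interpolate_final_step:
                f_b = (tgt_b - s.cum_cas_blue) / loss_b if hit_b else math.inf
                f_r = (tgt_r - s.cum_cas_red) / loss_r if hit_r else math.inf
                f = min(f_b, f_r)
                return SimOutcome(
                    sim_cas_blue=s.cum_cas_blue + f * loss_b,
                    sim_cas_red=s.cum_cas_red + f * loss_r,
                    steps=nxt.t,
                    termination=Termination.HISTORICAL,
                )
            return SimOutcome(nxt.cum_cas_blue, nxt.cum_cas_red, nxt.t, Termination.HISTORICAL)
        s = nxt
        if s.B < eps_b or s.R < eps_r:
            return SimOutcome(s.cum_cas_blue, s.cum_cas_red, s.t, Termination.ANNIHILATION)
    return SimOutcome(s.cum_cas_blue, s.cum_cas_red, s.t, Termination.MAX_STEPS)


def simulate_trajectory(
    m: Model,
    B0: float,
    R0: float,
    P: float,
    n_steps: int = 0,
    opts: SimOptions | None = None,
) -> list[ForceState]:
    """Free-running state time series (no stopping at casualties).

    ``n_steps = 0`` runs until a side is effectively annihilated or the
    ``max_steps`` guard fires.  The returned sequence includes the
    initial state.
    """
    m = Model.from_name(m)
    opts = opts or SimOptions()
    if B0 <= 0 or R0 <= 0:
        raise ValueError("initial sizes must be positive")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    fv = FightingValues(b=scale_fighting_value(m, B0, R0), P=P)
    limit = n_steps if n_steps > 0 else opts.max_steps
    eps_b, eps_r = B0 * STRENGTH_EPS_REL, R0 * STRENGTH_EPS_REL

    states = [ForceState(B=float(B0), R=float(R0))]
    for _ in range(limit):
        s = states[-1]
        if s.B < eps_b or s.R < eps_r:
            break
        states.append(step(m, s, fv))
    return states


@dataclass(frozen=True)
class BatchOutcome:
    """Vectorised simulation results (one entry per battle)."""

    sim_cas_blue: np.ndarray
    sim_cas_red: np.ndarray
    steps: np.ndarray
    termination: np.ndarray  # int codes: Termination indices

    TERM_CODES = (Termination.HISTORICAL, Termination.ANNIHILATION, Termination.MAX_STEPS)

    def termination_of(self, i: int) -> Termination:
        return self.TERM_CODES[int(self.termination[i])]


_T_HIST, _T_ANN, _T_MAX = 0, 1, 2


def _batch_losses(m: Model, B, R, b, r, t: int):
    if m is Model.LINEAR:
        prod = B * R
        return r * prod, b * prod
    if m is Model.SQUARED:
        return r * R, b * B
    if m is Model.LOGARITHMIC:
        return r * B, b * R
    damp = math.log(math.e + t)
    return r * B / damp, b * R / damp


def simulate_batch(
    m: Model,
    B0: np.ndarray,
    R0: np.ndarray,
    P: np.ndarray,
    target_blue: np.ndarray,
    target_red: np.ndarray,
    opts: SimOptions | None = None,
) -> BatchOutcome:
    """Stop-at-historical-casualties simulation of many battles at once.

    All arguments are broadcastable 1-D arrays.  Battles that finish
    drop out of the working set, so the cost is the total number of
    battle-steps, not battles x max-steps.  Results are identical to
    calling :func:`simulate_to_casualties` per battle.
    """
    m = Model.from_name(m)
    opts = opts or SimOptions()
    B0, R0, P, tb, tr = np.broadcast_arrays(
        np.asarray(B0, float),
        np.asarray(R0, float),
        np.asarray(P, float),
        np.asarray(target_blue, float),
        np.asarray(target_red, float),
    )
    n = B0.size
    if np.any(B0 <= 0) or np.any(R0 <= 0):
        raise ValueError("initial sizes must be positive")
    if np.any(P <= 0):
        raise ValueError("odds ratios must be positive")
    if np.any(tb <= 0) or np.any(tr <= 0):
        raise ValueError("casualty targets must be positive")

    if m is Model.LINEAR:
        b = 100.0 / (B0 * R0)
    else:
        b = 100.0 / np.maximum(B0, R0)
    r = b * P

    out_cb = np.empty(n)
    out_cr = np.empty(n)
    out_steps = np.zeros(n, dtype=np.int64)
    out_term = np.full(n, _T_MAX, dtype=np.int8)

    # working (compressed) copies; idx maps back to original positions
    idx = np.arange(n)
    B, R = B0.astype(float).copy(), R0.astype(float).copy()
    cb, cr = np.zeros(n), np.zeros(n)
    eps_b, eps_r = B0 * STRENGTH_EPS_REL, R0 * STRENGTH_EPS_REL
    tb, tr, b, r = tb.copy(), tr.copy(), b.copy(), r.copy()

    t = 0
    while idx.size and t < opts.max_steps:
        lb, lr = _batch_losses(m, B, R, b, r, t)
        np.minimum(lb, B, out=lb)
        np.minimum(lr, R, out=lr)
        hit_b = cb + lb >= tb
        hit_r = cr + lr >= tr
        hit = hit_b | hit_r
        if hit.any():
            h = np.nonzero(hit)[0]
            g = idx[h]
            if opts.interpolate_final_step:
                den_b = np.where(hit_b[h], lb[h], 1.0)
                den_r = np.where(hit_r[h], lr[h], 1.0)
                f_b = np.where(hit_b[h], (tb[h] - cb[h]) / den_b, np.inf)
                f_r = np.where(hit_r[h], (tr[h] - cr[h]) / den_r, np.inf)
                f = np.minimum(f_b, f_r)
            else:
                f = 1.0
            out_cb[g] = cb[h] + f * lb[h]
            out_cr[g] = cr[h] + f * lr[h]
            out_steps[g] = t + 1
            out_term[g] = _T_HIST
            keep = ~hit
            idx, B, R, cb, cr = idx[keep], B[keep], R[keep], cb[keep], cr[keep]
            tb, tr, b, r = tb[keep], tr[keep], b[keep], r[keep]
            eps_b, eps_r = eps_b[keep], eps_r[keep]
            lb, lr = lb[keep], lr[keep]
        B = B - lb
        R = R - lr
        cb = cb + lb
        cr = cr + lr
        ann = (B < eps_b) | (R < eps_r)
        if ann.any():
            a = np.nonzero(ann)[0]
            g = idx[a]
            out_cb[g] = cb[a]
            out_cr[g] = cr[a]
            out_steps[g] = t + 1
            out_term[g] = _T_ANN
            keep = ~ann
            idx, B, R, cb, cr = idx[keep], B[keep], R[keep], cb[keep], cr[keep]
            tb, tr, b, r = tb[keep], tr[keep], b[keep], r[keep]
            eps_b, eps_r = eps_b[keep], eps_r[keep]
        t += 1

    if idx.size:  # max_steps backstop
        out_cb[idx] = cb
        out_cr[idx] = cr
        out_steps[idx] = t
    return BatchOutcome(out_cb, out_cr, out_steps, out_term)


def trajectory_frame(states: list[ForceState], m: Model, P: float):
    """Trajectory as a table with columns t, B, R, cas_blue, cas_red, model, P."""
    import pandas as pd

    return pd.DataFrame(
        {
            "t": [s.t for s in states],
            "B": [s.B for s in states],
            "R": [s.R for s in states],
            "cas_blue": [s.cum_cas_blue for s in states],
            "cas_red": [s.cum_cas_red for s in states],
            "model": Model.from_name(m).label,
            "P": P,
        }
    )
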