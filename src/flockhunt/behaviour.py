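"""Prey agitation and the predator's four-stage hunting state machine.

Predation runs through SEARCH (detection & target selection), WAIT,
HUNT and SATISFY (handling time).  A hunt fails when the target leaves
the detection zone during the wait, or when the time-out limit expires
during pursuit; either failure returns the predator to SEARCH.  Whenever
the *marked* target enters the sure-kill zone the predator kills it and
jumps straight to SATISFY, whatever stage it was in.  Non-target prey
inside the kill zone are immune — the predator is locked onto a single
prey ("predator confusion").

All zone boundary tests are inclusive (<=); distances are centre to centre.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np


class InternalStateError(RuntimeError):
    """The FSM reached a state its invariants forbid."""


class Stage(enum.IntEnum):
    SEARCH = 0
    WAIT = 1
    HUNT = 2
    SATISFY = 3


# event names, in the order a successful hunt emits them
EVENT_SELECT = "select"
EVENT_BEGIN_WAIT = "begin_wait"
EVENT_BEGIN_HUNT = "begin_hunt"
EVENT_TARGET_LOST = "target_lost"
EVENT_TIMEOUT = "timeout"
EVENT_KILL = "kill"
EVENT_SATISFIED = "satisfied"

_LEGAL_TRANSITIONS = {
    (Stage.SEARCH, Stage.WAIT),
    (Stage.WAIT, Stage.SEARCH),
    (Stage.WAIT, Stage.HUNT),
    (Stage.WAIT, Stage.SATISFY),
    (Stage.HUNT, Stage.SEARCH),
    (Stage.HUNT, Stage.SATISFY),
    (Stage.SATISFY, Stage.SEARCH),
}


@dataclass
class PredatorFSM:
    stage: Stage = Stage.SEARCH
    target_id: int | None = None
    stage_clock: float = 0.0
    kills: int = 0

    def check(self) -> None:
        has_target = self.target_id is not None
        if has_target != (self.stage in (Stage.WAIT, Stage.HUNT)):
            raise InternalStateError(
                f"target_id must be set iff stage is WAIT/HUNT "
                f"(stage={self.stage.name}, target={self.target_id})")


def update_agitation(prey_positions, alive_mask, predator_pos, r_d: float,
                     active: bool, out=None) -> np.ndarray:
    """Flag live prey whose centre lies within r_d of the predator.

    Before activation (tau < tau_h), or once the predator leaves a prey's
    detection zone, the flag is cleared: the escape force stops acting.
    """
    prey_positions = np.asarray(prey_positions, float)
    n = len(prey_positions)
    if out is None:
        out = np.zeros(n, dtype=bool)
    if not active:
        out[:] = False
        return out
    delta = prey_positions - np.asarray(predator_pos, float)
    d2 = delta[:, 0] ** 2 + delta[:, 1] ** 2
    np.less_equal(d2, r_d * r_d, out=out)
    out &= np.asarray(alive_mask, bool)
    return out


def select_target(predator_pos, prey_positions, alive_mask, R_d: float) -> int | None:
    """Nearest live prey within R_d; None if the zone is empty.

    Exact distance ties resolve to the lowest prey index.
    """
    prey_positions = np.asarray(prey_positions, float)
    alive = np.asarray(alive_mask, bool)
    if not alive.any():
        return None
    delta = prey_positions - np.asarray(predator_pos, float)
    d2 = delta[:, 0] ** 2 + delta[:, 1] ** 2
    d2 = np.where(alive, d2, np.inf)
    idx = int(np.argmin(d2))  # argmin returns the first (lowest) index on ties
    if d2[idx] <= R_d * R_d:
        return idx
    return None


def fsm_step(fsm: PredatorFSM, prey_positions, alive_mask, predator_pos,
             dt: float, t_w: float, t_TO: float, t_s: float,
             R_d: float, R_k: float, active: bool) -> list[tuple[str, int | None]]:
    """Advance the hunting state machine by one step of size dt.

    Returns the list of (event_name, target_id) emitted this step and
    mutates ``fsm`` in place.  Kills are emitted as events only — the
    caller applies them to the population (see :func:`apply_kill`).
    Hunting behaviour is inert before activation.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    fsm.check()
    if not active:
        return []
    events: list[tuple[str, int | None]] = []
    fsm.stage_clock += dt

    px, py = float(predator_pos[0]), float(predator_pos[1])

    # exclusive target lock: only the marked target can ever be killed
    if fsm.target_id is not None:
        tx, ty = prey_positions[fsm.target_id]
        dist = math.hypot(tx - px, ty - py)
        if dist <= R_k and alive_mask[fsm.target_id]:
            events.append((EVENT_KILL, fsm.target_id))
            fsm.kills += 1
            fsm.stage = Stage.SATISFY
            fsm.target_id = None
            fsm.stage_clock = 0.0
            return events

    if fsm.stage == Stage.SEARCH:
        target = select_target((px, py), prey_positions, alive_mask, R_d)
        if target is not None:
            fsm.stage = Stage.WAIT
            fsm.target_id = target
            fsm.stage_clock = 0.0
            events.append((EVENT_SELECT, target))
            events.append((EVENT_BEGIN_WAIT, target))
    elif fsm.stage == Stage.WAIT:
        tx, ty = prey_positions[fsm.target_id]
        if math.hypot(tx - px, ty - py) > R_d:
            events.append((EVENT_TARGET_LOST, fsm.target_id))
            fsm.stage = Stage.SEARCH
            fsm.target_id = None
            fsm.stage_clock = 0.0
        elif fsm.stage_clock >= t_w:
            fsm.stage = Stage.HUNT
            fsm.stage_clock = 0.0
            events.append((EVENT_BEGIN_HUNT, fsm.target_id))
    elif fsm.stage == Stage.HUNT:
        if fsm.stage_clock >= t_TO:
            events.append((EVENT_TIMEOUT, fsm.target_id))
            fsm.stage = Stage.SEARCH
            fsm.target_id = None
            fsm.stage_clock = 0.0
    elif fsm.stage == Stage.SATISFY:
        if fsm.stage_clock >= t_s:
            fsm.stage = Stage.SEARCH
            fsm.stage_clock = 0.0
            events.append((EVENT_SATISFIED, None))
    return events


def apply_kill(xi: np.ndarray, agitated: np.ndarray, present: np.ndarray,
               prey_index: int, consuming: bool) -> None:
    """Mark a prey dead in place.

    Non-consuming predator: the prey becomes a passive disk (xi=0) that
    stays in the arena.  Consuming predator: the prey is removed from every
    subsequent force and observable computation.
    """
    if not xi[prey_index] or not present[prey_index]:
        raise InternalStateError(f"prey {prey_index} is already dead")
    xi[prey_index] = 0
    agitated[prey_index] = False
    if consuming:
        present[prey_index] = False
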