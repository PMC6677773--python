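"""File formats, event logs, and the scripted behavioural scenarios.

Trajectory and time-series files are plain columnar CSV; the event log is
tab-separated text with one line per state-machine transition or kill.
Scripted scenarios replay externally imposed positions through the
behaviour module, so every hunting rule is exercised without the physics
engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behaviour
from .behaviour import PredatorFSM, Stage
from .engine import EventRecord, SimulationResult


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_timeseries(result_or_df, path) -> None:
    df = result_or_df.timeseries if isinstance(result_or_df, SimulationResult) \
        else result_or_df
    # default float formatting is repr-precision: exact round trip
    df.to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_events(events: list[EventRecord], path, truncated: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write("step\ttau\tevent\ttarget_id\tpred_x\tpred_y\n")
        for e in events:
            tid = "" if e.target_id is None else str(e.target_id)
            fh.write(f"{e.step}\t{e.tau!r}\t{e.event}\t{tid}\t{e.x!r}\t{e.y!r}\n")
        if truncated:
            fh.write("# TRUNCATED\n")


def read_events(path) -> list[EventRecord]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            if line.startswith("#"):
                continue
            step, tau, event, tid, x, y = line.rstrip("\n").split("\t")
            out.append(EventRecord(int(step), float(tau), event,
                                   None if tid == "" else int(tid),
                                   float(x), float(y)))
    return out


def write_trajectory(result: SimulationResult, path) -> None:
    """Columnar CSV: step, tau, agent_id, kind, xi, x, y, vx, vy.

    Wall particles are emitted once in a header block (step -1)."""
    if result.trajectory is None:
        raise ValueError("run the simulation with trajectory_stride set")
    rows = []
    walls = result.final_state.walls.particle_positions
    for w_id, (x, y) in enumerate(walls):
        rows.append((-1, 0.0, w_id, "wall", 1, x, y, 0.0, 0.0))
    for snap in result.trajectory:
        step, tau = snap["step"], snap["tau"]
        pos, vel = snap["positions"], snap["velocities"]
        xi, present = snap["xi"], snap["present"]
        for i in range(len(pos)):
            if not present[i]:
                continue
            rows.append((step, tau, i, "prey", int(xi[i]),
                         pos[i, 0], pos[i, 1], vel[i, 0], vel[i, 1]))
        pp, pv = snap["predator_position"], snap["predator_velocity"]
        rows.append((step, tau, len(pos), "predator", 1,
                     pp[0], pp[1], pv[0], pv[1]))
    df = pd.DataFrame(rows, columns=["step", "tau", "agent_id", "kind",
                                     "xi", "x", "y", "vx", "vy"])
    df.to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def timeseries_from_trajectory(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute the per-sample observables from a trajectory table."""
    from . import observables

    prey = df[df.kind == "prey"]
    n0 = prey[prey.step == prey.step.min()].shape[0]
    rows = []
    for step, grp in prey.groupby("step"):
        vel = np.column_stack([grp.vx, grp.vy])
        pos = np.column_stack([grp.x, grp.y])
        alive = grp.xi.to_numpy().astype(bool)
        phi = observables.polarization(vel, alive) if alive.any() else np.nan
        psi = observables.rotational_order(pos, vel, alive) \
            if alive.sum() >= 2 else np.nan
        n_l = int(alive.sum())
        rows.append((float(grp.tau.iloc[0]), phi, psi, n_l, n0 - n_l))
    return pd.DataFrame(rows, columns=["tau", "phi", "psi_rot", "N_l", "N_d"])


# ---------------------------------------------------------------------------
# scripted scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScriptedScenario:
    """Externally imposed positions per step, with the expected FSM events.

    ``frames`` is a list of (predator_xy, prey_positions) tuples applied in
    order; prey stay alive unless a kill event fires during playback.
    """
    name: str
    dt: float
    t_w: float
    t_TO: float
    t_s: float
    R_d: float
    R_k: float
    frames: list = field(default_factory=list)
    expected_events: list = field(default_factory=list)


@dataclass
class ScenarioOutcome:
    events: list            # (event_name, target_id) in order
    stage_history: list     # Stage after every frame
    fsm: PredatorFSM
    alive: np.ndarray


def play_scenario(sc: ScriptedScenario) -> ScenarioOutcome:
    """Drive the behaviour module with the scenario's scripted positions."""
    n = len(sc.frames[0][1])
    alive = np.ones(n, dtype=bool)
    agitated = np.zeros(n, dtype=bool)
    present = np.ones(n, dtype=bool)
    xi = np.ones(n, dtype=np.uint8)
    fsm = PredatorFSM()
    events = []
    history = []
    for ppos, prey in sc.frames:
        prey = np.asarray(prey, float)
        evs = behaviour.fsm_step(fsm, prey, xi.astype(bool) & present,
                                 np.asarray(ppos, float), sc.dt,
                                 sc.t_w, sc.t_TO, sc.t_s, sc.R_d, sc.R_k,
                                 active=True)
        for name, target in evs:
            if name == behaviour.EVENT_KILL:
                behaviour.apply_kill(xi, agitated, present, target, consuming=False)
        events.extend(evs)
        history.append(fsm.stage)
    return ScenarioOutcome(events, history, fsm, xi.astype(bool))


def generate_scenarios(dt: float = 0.01, t_w: float = 0.08, t_TO: float = 0.32,
                       t_s: float = 0.08, R_d: float = 0.5,
                       R_k: float = 0.05) -> list[ScriptedScenario]:
    """The behavioural test suite: every hunting rule in isolation.

    Scenarios: wait-then-hunt success with contact kill; target escape
    during the wait; hunt time-out; contact kill straight from the wait
    stage; predator confusion (non-target inside the kill zone is immune);
    satisfaction-stage handling with continued prey agitation.
    """
    pred = (0.0, 0.0)
    near = [(0.3, 0.0), (0.45, 0.0)]        # prey 0 nearer -> target
    far = [(2 * R_d, 0.0), (2.2 * R_d, 0.0)]  # both outside the detection zone
    contact0 = [(R_k * 0.5, 0.0), (0.45, 0.0)]  # target inside the kill zone
    wait_steps = int(round(t_w / dt))       # frames from begin_wait to begin_hunt
    to_steps = int(round(t_TO / dt))
    s_steps = int(round(t_s / dt))
    out = []

    # 1. full success: wait -> hunt -> target drifts into R_k -> kill -> satisfied
    frames = [(pred, near)] * (1 + wait_steps)   # select at frame 1, hunt begins
    frames += [(pred, near)] * 3                 # pursuit, no contact yet
    frames += [(pred, contact0)]                 # target at contact -> kill
    frames += [(pred, far)] * s_steps            # satisfaction runs out quietly
    out.append(ScriptedScenario(
        "wait_then_hunt_success", dt, t_w, t_TO, t_s, R_d, R_k, frames,
        [behaviour.EVENT_SELECT, behaviour.EVENT_BEGIN_WAIT,
         behaviour.EVENT_BEGIN_HUNT, behaviour.EVENT_KILL,
         behaviour.EVENT_SATISFIED]))

    # 2. target teleports outside R_d during the wait
    frames = [(pred, near)] * 3
    frames += [(pred, [(2 * R_d, 0.0), (2.2 * R_d, 0.0)])]
    out.append(ScriptedScenario(
        "target_escape_during_wait", dt, t_w, t_TO, t_s, R_d, R_k, frames,
        [behaviour.EVENT_SELECT, behaviour.EVENT_BEGIN_WAIT,
         behaviour.EVENT_TARGET_LOST]))

    # 3. target stays in R_d but out of reach until the time-out
    frames = [(pred, near)] * (1 + wait_steps + to_steps)
    out.append(ScriptedScenario(
        "hunt_timeout", dt, t_w, t_TO, t_s, R_d, R_k, frames,
        [behaviour.EVENT_SELECT, behaviour.EVENT_BEGIN_WAIT,
         behaviour.EVENT_BEGIN_HUNT, behaviour.EVENT_TIMEOUT]))

    # 4. target enters R_k while the predator is still waiting: immediate kill
    frames = [(pred, near)] * 2
    frames += [(pred, contact0)]
    out.append(ScriptedScenario(
        "contact_kill_skip_from_wait", dt, t_w, t_TO, t_s, R_d, R_k, frames,
        [behaviour.EVENT_SELECT, behaviour.EVENT_BEGIN_WAIT,
         behaviour.EVENT_KILL]))

    # 5. confusion: a non-target sits inside R_k during the hunt -> immune
    frames = [(pred, near)] * (1 + wait_steps)
    frames += [(pred, [(0.3, 0.0), (R_k * 0.5, 0.0)])] * 3
    frames += [(pred, near)] * (to_steps - 3)
    out.append(ScriptedScenario(
        "confusion_nontarget_immune", dt, t_w, t_TO, t_s, R_d, R_k, frames,
        [behaviour.EVENT_SELECT, behaviour.EVENT_BEGIN_WAIT,
         behaviour.EVENT_BEGIN_HUNT, behaviour.EVENT_TIMEOUT]))

    # 6. satisfaction: prey inside R_k and R_d draw no response until t_s lapses
    frames = [(pred, near)] * 2
    frames += [(pred, contact0)]                              # kill from wait
    frames += [(pred, [(0.45, 0.0), (R_k * 0.5, 0.0)])] * (s_steps - 1)
    frames += [(pred, [(0.45, 0.0), (0.3, 0.0)])] * 2         # satisfied, re-select
    out.append(ScriptedScenario(
        "satisfaction_immunity", dt, t_w, t_TO, t_s, R_d, R_k, frames,
        [behaviour.EVENT_SELECT, behaviour.EVENT_BEGIN_WAIT,
         behaviour.EVENT_KILL, behaviour.EVENT_SATISFIED,
         behaviour.EVENT_SELECT, behaviour.EVENT_BEGIN_WAIT]))
    return out
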