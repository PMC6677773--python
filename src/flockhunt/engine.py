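"""World construction, neighbour search, Velocity-Verlet stepping, main loop.

The arena is a square box of side L whose walls are rows of fixed disks.
Prey start uniformly placed without overlap, moving at the saturation
speed sqrt(beta/alpha) in random directions; the predator starts at rest
at a configured position.  Each step runs: agitation update -> hunting
FSM -> force assembly (numba kernel) -> Velocity-Verlet update -> death
handling -> sampled observables.  The whole run is a pure function of
(config, seed, predator start).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behaviour, observables
from ._kernel import MODE_CODES, cell_list_pairs, compute_forces_alloc, fused_step
from .behaviour import PredatorFSM, Stage
from .config import InvalidParameterError, SimulationConfig
from .forces import EPS_SPEED_FACTOR


class InfeasibleDensityError(RuntimeError):
    """Non-overlapping placement failed within the attempt budget."""


class NumericalBlowupError(RuntimeError):
    """A non-finite force or velocity appeared during integration."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WallGeometry:
    particle_positions: np.ndarray  # (n_wall, 2)
    r_w: float
    spacing: float


def build_walls(L: float, r_w: float) -> WallGeometry:
    """Four rows of fixed disks tiling the box sides, corners shared once.

    Per-side spacing is L / ceil(L / (2 r_w)) <= 2 r_w so adjacent disks
    touch or overlap, leaving no gap a prey disk could slip through.
    """
    if L <= 4 * r_w:
        raise InvalidParameterError("need L > 4 r_w for a meaningful arena")
    K = math.ceil(L / (2 * r_w))
    s = L / K
    ticks = np.arange(K + 1) * s
    bottom = np.column_stack([ticks, np.zeros(K + 1)])
    top = np.column_stack([ticks, np.full(K + 1, L)])
    inner = ticks[1:-1]
    left = np.column_stack([np.zeros(K - 1), inner])
    right = np.column_stack([np.full(K - 1, L), inner])
    return WallGeometry(np.vstack([bottom, top, left, right]), r_w, s)


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class AgentPopulation:
    positions: np.ndarray   # (n, 2)
    velocities: np.ndarray  # (n, 2)
    headings: np.ndarray    # (n, 2) persistent unit directions
    masses: np.ndarray      # (n,)
    diameters: np.ndarray   # (n,)
    xi: np.ndarray          # (n,) uint8 state of living
    agitated: np.ndarray    # (n,) bool
    present: np.ndarray     # (n,) bool; False once a consuming kill removes


@dataclass
class PredatorState:
    position: np.ndarray
    velocity: np.ndarray
    heading: np.ndarray
    fsm: PredatorFSM = field(default_factory=PredatorFSM)


@dataclass
class WorldState:
    population: AgentPopulation
    predator: PredatorState
    walls: WallGeometry
    step: int = 0
    time: float = 0.0


@dataclass
class EventRecord:
    step: int
    tau: float
    event: str
    target_id: int | None
    x: float
    y: float


@dataclass
class SimulationResult:
    config: SimulationConfig
    seed: int
    timeseries: pd.DataFrame          # tau, phi, psi_rot, N_l, N_d
    events: list[EventRecord]
    final_state: WorldState
    trajectory: list[dict] | None = None
    truncated: bool = False


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def neighbor_search(positions, cutoff: float, L: float) -> np.ndarray:
    """All unordered pairs with centre distance <= cutoff (cell linked list)."""
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be > 0")
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    return cell_list_pairs(positions, float(cutoff), float(L))


def init_population(cfg: SimulationConfig, seed: int | None = None,
                    predator_start=None) -> WorldState:
    """Seeded overlap-free placement; deterministic for a given seed."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    walls = build_walls(cfg.L, cfg.r_w)
    if predator_start is None:
        predator_start = cfg.predator_init[0]
    ppos = np.asarray(predator_start, dtype=float)

    n = cfg.n
    margin = cfg.r + cfg.r_w
    lo, hi = margin, cfg.L - margin
    if hi <= lo:
        raise InfeasibleDensityError("prey radius too large for the arena")
    placed = np.empty((n, 2))
    # grid of occupancy cells sized for the contact diameter
    cell = 2 * cfg.r
    ncell = max(int(cfg.L / cell), 1)
    cell = cfg.L / ncell
    buckets: dict[tuple[int, int], list[int]] = {}
    count = 0
    attempts = 0
    max_attempts = 300 * n + 1000
    while count < n:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasibleDensityError(
                f"placed only {count}/{n} prey after {attempts} attempts")
        p = rng.uniform(lo, hi, size=2)
        if np.hypot(*(p - ppos)) < cfg.R + cfg.r:
            continue
        cx, cy = int(p[0] / cell), int(p[1] / cell)
        ok = True
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for j in buckets.get((cx + ox, cy + oy), ()):
                    if np.hypot(*(p - placed[j])) < 2 * cfg.r:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        placed[count] = p
        buckets.setdefault((cx, cy), []).append(count)
        count += 1

    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    headings = np.column_stack([np.cos(theta), np.sin(theta)])
    speed0 = math.sqrt(cfg.beta / cfg.alpha) if cfg.alpha > 0 else 0.0
    velocities = speed0 * headings
    ptheta = rng.uniform(0.0, 2.0 * np.pi)

    pop = AgentPopulation(
        positions=placed,
        velocities=velocities.copy(),
        headings=headings.copy(),
        masses=np.full(n, cfg.m),
        diameters=np.full(n, 2 * cfg.r),
        xi=np.ones(n, dtype=np.uint8),
        agitated=np.zeros(n, dtype=bool),
        present=np.ones(n, dtype=bool),
    )
    pred = PredatorState(
        position=ppos.astype(float).copy(),
        velocity=np.zeros(2),
        heading=np.array([math.cos(ptheta), math.sin(ptheta)]),
    )
    return WorldState(population=pop, predator=pred, walls=walls)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def verlet_step(x, v, m, force_fn, dt: float):
    """One Velocity-Verlet step for arbitrary arrays.

    ``force_fn(x, v)`` returns the force; the closing force evaluation uses
    the predicted velocity ``v + a0*dt`` (exact classical VV for
    position-only forces).
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    m = np.asarray(m, dtype=float)
    minv = 1.0 / m if m.ndim == 0 else (1.0 / m)[..., None]
    a0 = force_fn(x, v) * minv
    x1 = x + v * dt + 0.5 * a0 * dt * dt
    a1 = force_fn(x1, v + a0 * dt) * minv
    v1 = v + 0.5 * (a0 + a1) * dt
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(v1))):
        raise NumericalBlowupError("non-finite state after Verlet step")
    return x1, v1


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class Simulation:
    """Owns a world and advances it; :func:`run` is the one-shot helper."""

    def __init__(self, cfg: SimulationConfig, seed: int | None = None,
                 predator_start=None):
        self.cfg = cfg
        self.seed = cfg.seed if seed is None else seed
        self.state = init_population(cfg, self.seed, predator_start)
        self.eps_speed = EPS_SPEED_FACTOR * math.sqrt(cfg.beta / cfg.alpha) \
            if cfg.alpha > 0 else EPS_SPEED_FACTOR
        self._mode = MODE_CODES[cfg.interaction_mode]
        self._t_h = cfg.physical_time(cfg.t_h)
        self._t_w = cfg.physical_time(cfg.t_w)
        self._t_s = cfg.physical_time(cfg.t_s)
        self._t_TO = cfg.physical_time(cfg.t_TO)
        self.events: list[EventRecord] = []
        self._escape_active = False
        # caller-owned kernel workspace + cached accelerations
        n = cfg.n
        ncell = max(int(cfg.L / cfg.r_i), 1)
        self._ws = dict(
            F=np.zeros((n, 2)), Fp=np.zeros(2), Vp=np.zeros((n, 2)),
            cnt=np.zeros(n, dtype=np.int64), svx=np.zeros(n), svy=np.zeros(n),
            nxt=np.zeros(n, dtype=np.int64), cix=np.zeros(n, dtype=np.int64),
            ciy=np.zeros(n, dtype=np.int64),
            cell_head=np.zeros(ncell * ncell, dtype=np.int64),
        )
        self._a0 = np.zeros((n, 2))
        self._pa0 = np.zeros(2)
        self._prime_acceleration()
        self._alive_buf = np.zeros(n, dtype=bool)

    # -- forces ----------------------------------------------------------

    def _force_args(self, hunting: bool, target: int):
        cfg = self.cfg
        pop = self.state.population
        pred = self.state.predator
        return (pop.xi, pop.present, pop.agitated, pop.masses, pop.diameters,
                2 * cfg.R, cfg.M,
                cfg.beta, cfg.alpha, cfg.beta_e, cfg.beta_h, cfg.gamma, cfg.C_v,
                cfg.k_n, cfg.k_a, cfg.r_i, self._mode, cfg.dead_drag,
                cfg.coordination_live_only,
                self._escape_active, hunting, target,
                cfg.L, cfg.r_w, self.eps_speed)

    def _prime_acceleration(self) -> None:
        """Seed the cached accelerations from the current state."""
        cfg = self.cfg
        pop = self.state.population
        pred = self.state.predator
        (xi, present, agitated, masses, diameters, P_diam, M_mass,
         *rest) = self._force_args(False, -1)
        F, Fp = compute_forces_alloc(
            pop.positions, pop.velocities, pop.headings, xi, present, agitated,
            masses, diameters, pred.position, pred.velocity, pred.heading,
            P_diam, M_mass, *rest)
        self._a0[:] = F / masses[:, None]
        self._pa0[:] = Fp / cfg.M

    # -- one step --------------------------------------------------------

    def step(self) -> list[EventRecord]:
        cfg = self.cfg
        st = self.state
        pop = st.population
        pred = st.predator
        dt = cfg.dt
        t = st.time
        active = t >= self._t_h
        self._escape_active = active

        np.logical_and(pop.xi.view(bool), pop.present, out=self._alive_buf)
        alive_mask = self._alive_buf
        behaviour.update_agitation(pop.positions, alive_mask, pred.position,
                                   cfg.r_d, active, out=pop.agitated)
        raw_events = behaviour.fsm_step(
            pred.fsm, pop.positions, alive_mask, pred.position, dt,
            self._t_w, self._t_TO, self._t_s, cfg.R_d, cfg.R_k, active)
        step_events = []
        if raw_events:
            tau = cfg.tau(t)
            for name, target in raw_events:
                if name == behaviour.EVENT_KILL:
                    behaviour.apply_kill(pop.xi, pop.agitated, pop.present,
                                         target, cfg.consuming)
                step_events.append(EventRecord(st.step, tau, name, target,
                                               float(pred.position[0]),
                                               float(pred.position[1])))
            self.events.extend(step_events)

        hunting = pred.fsm.stage == Stage.HUNT
        target = pred.fsm.target_id if pred.fsm.target_id is not None else -1
        ws = self._ws
        bad = fused_step(
            pop.positions, pop.velocities, pop.headings, self._a0,
            pred.position, pred.velocity, pred.heading, self._pa0,
            *self._force_args(hunting, target), dt,
            ws["F"], ws["Fp"], ws["Vp"], ws["cnt"], ws["svx"], ws["svy"],
            ws["nxt"], ws["cix"], ws["ciy"], ws["cell_head"])
        if bad:
            raise NumericalBlowupError(
                f"non-finite state at step {st.step} (tau={cfg.tau(t):.3f})")

        st.step += 1
        st.time += dt
        return step_events

    # -- full run --------------------------------------------------------

    def run(self, sample_stride: int = 20,
            trajectory_stride: int | None = None) -> SimulationResult:
        cfg = self.cfg
        st = self.state
        pop = st.population
        n_steps = int(round(cfg.t_end / cfg.dt))
        rows = []
        traj: list[dict] | None = [] if trajectory_stride else None
        truncated = False

        def sample():
            alive = pop.xi.astype(bool) & pop.present
            tau = cfg.tau(st.time)
            if alive.any():
                phi = observables.polarization(pop.velocities, alive,
                                               pop.headings, self.eps_speed)
                psi = observables.rotational_order(pop.positions, pop.velocities,
                                                   alive, pop.headings,
                                                   self.eps_speed) \
                    if alive.sum() >= 2 else 0.0
            else:
                phi = np.nan
                psi = np.nan
            n_l = int(pop.xi[pop.present].sum()) if not cfg.consuming \
                else int(alive.sum())
            n_d = cfg.n - int(pop.xi.sum()) if not cfg.consuming \
                else self.state.predator.fsm.kills
            rows.append((tau, phi, psi, n_l, n_d))
            if traj is not None and st.step % trajectory_stride == 0:
                traj.append(dict(step=st.step, tau=tau,
                                 positions=pop.positions.copy(),
                                 velocities=pop.velocities.copy(),
                                 xi=pop.xi.copy(), present=pop.present.copy(),
                                 predator_position=self.state.predator.position.copy(),
                                 predator_velocity=self.state.predator.velocity.copy()))

        try:
            sample()
            for k in range(n_steps):
                self.step()
                if (k + 1) % sample_stride == 0 or k + 1 == n_steps:
                    sample()
        except NumericalBlowupError:
            truncated = True

        ts = pd.DataFrame(rows, columns=["tau", "phi", "psi_rot", "N_l", "N_d"])
        return SimulationResult(config=cfg, seed=self.seed, timeseries=ts,
                                events=self.events, final_state=st,
                                trajectory=traj, truncated=truncated)


def run(cfg: SimulationConfig, seed: int | None = None, predator_start=None,
        sample_stride: int = 20,
        trajectory_stride: int | None = None) -> SimulationResult:
    """Run a full simulation; deterministic in (config, seed, start)."""
    sim = Simulation(cfg, seed=seed, predator_start=predator_start)
    return sim.run(sample_stride=sample_stride, trajectory_stride=trajectory_stride)
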