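"""Pure force laws of the model and their gated assembly.

Each agent is a self-propelled disk.  Live prey carry a thrust saturating
at speed :math:`\\sqrt{\\beta/\\alpha}`, a local velocity-alignment
(coordination) force, linear-spring disk interactions, and — when agitated —
a constant-magnitude escape thrust directed away from the predator.  The
predator carries the same saturating thrust, a friction-like coordination
term, wall contacts, and a Rayleigh-damped hunting thrust toward its target.

A prey's state of living ``xi`` (1 alive, 0 dead) gates every active term:
a dead disk keeps only its contact forces (plus an optional linear drag).

These functions are the readable reference implementation; the engine's
vectorised kernel is pinned to them by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig

#: relative speed below which the persistent heading replaces v-hat
EPS_SPEED_FACTOR = 1e-9


class DegenerateGeometryError(ValueError):
    """Two agents occupy the same point where a direction is required."""


def _unit(vec: np.ndarray) -> tuple[np.ndarray, float]:
    norm = float(np.hypot(vec[0], vec[1]))
    if norm == 0.0:
        raise DegenerateGeometryError("coincident positions")
    return vec / norm, norm


def self_propulsion(mass: float, velocity, heading, beta: float,
                    alpha: float, eps_speed: float | None = None) -> np.ndarray:
    """Saturating thrust m*(beta - alpha*|v|^2) along v-hat.

    Below ``eps_speed`` the direction falls back to the persistent heading,
    so an agent at rest still accelerates along its last known direction.
    """
    velocity = np.asarray(velocity, dtype=float)
    if eps_speed is None:
        eps_speed = EPS_SPEED_FACTOR * np.sqrt(beta / alpha) if alpha > 0 else EPS_SPEED_FACTOR
    speed = float(np.hypot(velocity[0], velocity[1]))
    direction = velocity / speed if speed > eps_speed else np.asarray(heading, dtype=float)
    return mass * (beta - alpha * speed * speed) * direction


def coordination_prey(C_v: float, d_i: float, v_bar, v_i) -> np.ndarray:
    """Alignment force C_v * d_i * (v_bar - v_i) toward the local mean velocity."""
    return C_v * d_i * (np.asarray(v_bar, float) - np.asarray(v_i, float))


def predator_friction(C_v: float, d_P: float, v_P) -> np.ndarray:
    """For the lone predator the coordination term reduces to -C_v * d_P * v_P."""
    return -C_v * d_P * np.asarray(v_P, float)


def pair_interaction(r_i_pos, r_j_pos, d_i: float, d_j: float, k_n: float,
                     mode: str = "full_spring", cutoff: float = np.inf) -> np.ndarray:
    """Linear-spring disk force on agent i from agent j.

    ``lambda = |r_i - r_j| - (d_i + d_j)/2`` is the surface separation; the
    force is ``-k_n * lambda * n_ij`` with ``n_ij`` the unit vector from j
    to i.  Modes restrict the active branch:

    * ``full_spring`` — active whenever the centre distance is within
      ``cutoff`` (repulsive on overlap, attractive up to the cutoff);
    * ``literal_attraction`` — only the ``lambda > 0`` attractive branch;
    * ``contact_only`` — only the overlapping ``lambda < 0`` branch
      (always used for walls).
    """
    ri = np.asarray(r_i_pos, float)
    rj = np.asarray(r_j_pos, float)
    n_ij, dist = _unit(ri - rj)
    lam = dist - 0.5 * (d_i + d_j)
    if mode == "full_spring":
        active = dist <= cutoff
    elif mode == "literal_attraction":
        active = lam > 0.0 and dist <= cutoff
    elif mode == "contact_only":
        active = lam < 0.0
    else:
        raise ValueError(f"unknown interaction mode {mode!r}")
    if not active:
        return np.zeros(2)
    return -k_n * lam * n_ij


def wall_contact_force(pos, rad: float, L: float, r_w: float,
                       k_n: float) -> np.ndarray:
    """Contact force from the wall-disk rows on a disk at ``pos``.

    Inside the arena this is the plain sum of ``pair_interaction`` contacts
    with the wall particles.  A centre that has crossed a wall line (possible
    at finite dt for a fast impact, since the disk row is only one particle
    deep) is pushed back by the continuation of the spring law,
    ``k_n * (p + rad + r_w)`` toward the interior at outside depth ``p`` —
    without this rule a sufficiently fast agent would tunnel between wall
    disks and leave the arena for good.
    """
    pos = np.asarray(pos, float)
    out = np.zeros(2)
    reach = rad + r_w
    K = int(np.ceil(L / (2.0 * r_w)))
    s = L / K
    # each side contributes its disk contacts while the centre is on the
    # interior side of its line, and the half-plane continuation beyond it
    sides = [
        (1, 0.0, +1.0, range(0, K + 1)),      # bottom: disks k=0..K
        (1, L, -1.0, range(0, K + 1)),        # top
        (0, 0.0, +1.0, range(1, K)),          # left: corners belong to
        (0, L, -1.0, range(1, K)),            # bottom/top rows
    ]
    for axis, line, inward, ks in sides:
        p = (line - pos[axis]) * inward  # outside depth, > 0 beyond the line
        if p > 0.0:
            out[axis] += inward * k_n * (p + reach)
            continue
        if -p > reach:
            continue
        for k in ks:
            w = np.array([k * s, line]) if axis == 1 else np.array([line, k * s])
            if 0.0 < np.hypot(*(pos - w)) < reach:
                out += pair_interaction(pos, w, 2 * rad, 2 * r_w, k_n,
                                        "contact_only")
    return out


def escape(mass: float, beta_e: float, prey_pos, predator_pos,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Constant-magnitude escape thrust m*beta_e away from the predator.

    If prey and predator coincide (measure-zero), a seeded random unit
    direction is substituted so the force stays defined.
    """
    delta = np.asarray(prey_pos, float) - np.asarray(predator_pos, float)
    try:
        x_hat, _ = _unit(delta)
    except DegenerateGeometryError:
        rng = rng or np.random.default_rng(0)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        x_hat = np.array([np.cos(theta), np.sin(theta)])
    return mass * beta_e * x_hat


def hunting(M: float, beta_h: float, gamma: float, v_P,
            predator_pos, target_pos) -> np.ndarray:
    """Rayleigh-damped pursuit thrust M*(beta_h - gamma*|v_P|^2) toward the target."""
    if M <= 0:
        raise ValueError("M must be > 0")
    x_hat, _ = _unit(np.asarray(target_pos, float) - np.asarray(predator_pos, float))
    v_P = np.asarray(v_P, float)
    speed2 = float(v_P @ v_P)
    return M * (beta_h - gamma * speed2) * x_hat


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class ForceBreakdown:
    f_sp: np.ndarray
    f_c: np.ndarray
    f_pp: np.ndarray
    f_e: np.ndarray
    f_h: np.ndarray
    total: np.ndarray


def _zero() -> np.ndarray:
    return np.zeros(2)


def _interaction_stiffness(lam_negative: bool, cfg: SimulationConfig) -> float:
    # contact overlap always uses k_n; the attractive branch uses k_a
    return cfg.k_n if lam_negative else cfg.k_a


def _prey_pair_force(i: int, j: int, positions, diameters, cfg) -> np.ndarray:
    dist = float(np.hypot(*(positions[i] - positions[j])))
    lam = dist - 0.5 * (diameters[i] + diameters[j])
    k = _interaction_stiffness(lam < 0.0, cfg)
    return pair_interaction(positions[i], positions[j], diameters[i], diameters[j],
                            k, cfg.interaction_mode, cutoff=cfg.r_i)


def neighbourhood_mean_velocity(i: int, positions, velocities, xi, present,
                                r_i: float, live_only: bool) -> np.ndarray:
    """Arithmetic mean velocity over prey within r_i of agent i, self included."""
    d = np.hypot(*(positions - positions[i]).T)
    sel = (d <= r_i) & present
    if live_only:
        sel &= xi.astype(bool)
        sel[i] = True  # self always included
    if not sel.any():
        return velocities[i].copy()
    return velocities[sel].mean(axis=0)


def assemble_prey_force(i: int, positions, velocities, headings, xi, agitated,
                        masses, diameters, predator_pos, predator_diam,
                        cfg: SimulationConfig, escape_active: bool,
                        present=None) -> ForceBreakdown:
    """Gated total force on prey i (reference implementation).

    ``total = xi*(f_sp + f_c + f_e) + f_pp`` with f_pp summed over prey
    neighbours within r_i (configured mode), wall particles (contact only)
    and the predator disk (contact only, one-sided).  Dead prey optionally
    feel a linear drag ``-dead_drag * v``.
    """
    n = len(positions)
    if present is None:
        present = np.ones(n, dtype=bool)
    alive = bool(xi[i])

    f_sp = self_propulsion(masses[i], velocities[i], headings[i],
                           cfg.beta, cfg.alpha) if alive else _zero()
    if alive:
        v_bar = neighbourhood_mean_velocity(i, positions, velocities, xi, present,
                                            cfg.r_i, cfg.coordination_live_only)
        f_c = coordination_prey(cfg.C_v, diameters[i], v_bar, velocities[i])
    else:
        f_c = _zero()

    f_pp = _zero()
    for j in range(n):
        if j == i or not present[j]:
            continue
        dist = float(np.hypot(*(positions[i] - positions[j])))
        if dist <= cfg.r_i:
            f_pp = f_pp + _prey_pair_force(i, j, positions, diameters, cfg)
    f_pp = f_pp + wall_contact_force(positions[i], 0.5 * diameters[i],
                                     cfg.L, cfg.r_w, cfg.k_n)
    f_pp = f_pp + pair_interaction(positions[i], predator_pos, diameters[i],
                                   predator_diam, cfg.k_n, "contact_only")

    f_e = (escape(masses[i], cfg.beta_e, positions[i], predator_pos)
           if alive and agitated[i] and escape_active else _zero())

    total = xi[i] * (f_sp + f_c + f_e) + f_pp
    if not alive and cfg.dead_drag > 0:
        total = total - cfg.dead_drag * velocities[i]
    return ForceBreakdown(f_sp=f_sp, f_c=f_c, f_pp=f_pp, f_e=f_e,
                          f_h=_zero(), total=total)


def assemble_predator_force(predator_pos, predator_vel, predator_heading,
                            target_pos, cfg: SimulationConfig,
                            hunting_stage: bool) -> ForceBreakdown:
    """Total force on the predator: thrust + friction + wall contacts (+ hunt)."""
    f_sp = self_propulsion(cfg.M, predator_vel, predator_heading, cfg.beta, cfg.alpha)
    f_c = predator_friction(cfg.C_v, 2 * cfg.R, predator_vel)
    f_pp = wall_contact_force(predator_pos, cfg.R, cfg.L, cfg.r_w, cfg.k_n)
    f_h = (hunting(cfg.M, cfg.beta_h, cfg.gamma, predator_vel, predator_pos, target_pos)
           if hunting_stage and target_pos is not None else _zero())
    return ForceBreakdown(f_sp=f_sp, f_c=f_c, f_pp=f_pp, f_e=_zero(), f_h=f_h,
                          total=f_sp + f_c + f_pp + f_h)
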