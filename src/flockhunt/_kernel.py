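"""Vectorised physics kernels (numba) used by the engine's inner loop.

``compute_forces`` re-implements the force assembly of
:mod:`flockhunt.forces` over the whole population in one pass: a cell
linked list collects prey pairs within the influence radius, accumulating
both the spring interactions and the neighbourhood velocity sums for the
alignment force.  Wall contacts use the analytic wall-disk lattice
(identical to the particle list emitted by ``build_walls``: per-side
spacing L/ceil(L/(2 r_w)); corner disks belong to the horizontal sides).
``fused_step`` wraps one Velocity-Verlet update around it, reusing the
acceleration cached from the previous step so each step costs a single
force evaluation.  The test suite pins these kernels to the pure
reference functions in :mod:`flockhunt.forces`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_FULL_SPRING = 0
MODE_LITERAL_ATTRACTION = 1
MODE_CONTACT_ONLY = 2

MODE_CODES = {
    "full_spring": MODE_FULL_SPRING,
    "literal_attraction": MODE_LITERAL_ATTRACTION,
    "contact_only": MODE_CONTACT_ONLY,
}


@njit(cache=True, fastmath=True)
def _wall_force(x, y, rad, L, r_w, k_n, F, row):
    """Accumulate the wall contact force onto row of F.

    Disk-row contacts while the centre is on the interior side of each wall
    line; beyond the line the spring continues as a half-plane restoring
    force k_n*(depth + reach) so fast impacts cannot tunnel between disks
    (same rule as forces.wall_contact_force).
    """
    K = int(np.ceil(L / (2.0 * r_w)))
    s = L / K
    reach = rad + r_w
    span = int(np.ceil(reach / s)) + 1
    # horizontal sides y=0 and y=L carry disks k=0..K (corners included)
    for side in range(2):
        wy = 0.0 if side == 0 else L
        inward = 1.0 if side == 0 else -1.0
        p = (wy - y) * inward
        if p > 0.0:
            F[row, 1] += inward * k_n * (p + reach)
        elif -p <= reach:
            k0 = int(np.floor(x / s))
            for k in range(k0 - span, k0 + span + 1):
                if k < 0 or k > K:
                    continue
                dx = x - k * s
                dy = y - wy
                dist = np.sqrt(dx * dx + dy * dy)
                if 0.0 < dist < reach:
                    scale = -k_n * (dist - reach) / dist
                    F[row, 0] += scale * dx
                    F[row, 1] += scale * dy
    # vertical sides x=0 and x=L carry disks k=1..K-1 (corners excluded)
    for side in range(2):
        wx = 0.0 if side == 0 else L
        inward = 1.0 if side == 0 else -1.0
        p = (wx - x) * inward
        if p > 0.0:
            F[row, 0] += inward * k_n * (p + reach)
        elif -p <= reach:
            k0 = int(np.floor(y / s))
            for k in range(k0 - span, k0 + span + 1):
                if k < 1 or k > K - 1:
                    continue
                dx = x - wx
                dy = y - k * s
                dist = np.sqrt(dx * dx + dy * dy)
                if 0.0 < dist < reach:
                    scale = -k_n * (dist - reach) / dist
                    F[row, 0] += scale * dx
                    F[row, 1] += scale * dy


@njit(cache=True, fastmath=True)
def compute_forces(pos, vel, head, xi, present, agitated, mass, diam,
                   ppos, pvel, phead, P_diam, M_mass,
                   beta, alpha, beta_e, beta_h, gamma, C_v,
                   k_n, k_a, r_i, mode, dead_drag, live_only,
                   escape_active, hunt_active, target_id,
                   L, r_w, eps_speed,
                   F, Fp, cnt, svx, svy, nxt, cix, ciy, cell_head):
    """Fill F (n,2) and Fp (2,) with the forces on prey and predator.

    The trailing arguments are caller-owned workspace; ``cell_head`` sizes
    the cell grid (must hold ncell*ncell entries with ncell >= 1 and cell
    size >= r_i).
    """
    n = pos.shape[0]
    ncell = int(np.sqrt(cell_head.shape[0]))
    cell_size = L / ncell
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        cnt[i] = 1  # self always included in the velocity average
        svx[i] = vel[i, 0]
        svy[i] = vel[i, 1]
    for c in range(ncell * ncell):
        cell_head[c] = -1

    # --- cell linked list over present prey -----------------------------
    for i in range(n):
        if not present[i]:
            nxt[i] = -1
            continue
        cx = int(np.floor(pos[i, 0] / cell_size))
        cy = int(np.floor(pos[i, 1] / cell_size))
        if cx < 0:
            cx = 0
        elif cx >= ncell:
            cx = ncell - 1
        if cy < 0:
            cy = 0
        elif cy >= ncell:
            cy = ncell - 1
        cix[i] = cx
        ciy[i] = cy
        c = cy * ncell + cx
        nxt[i] = cell_head[c]
        cell_head[c] = i

    # --- pair interactions + velocity-average sums (half-cell scan) -----
    r_i2 = r_i * r_i
    for i in range(n):
        if not present[i]:
            continue
        for k in range(5):  # self cell + E, NE, N, NW neighbours
            if k == 0:
                cx, cy = cix[i], ciy[i]
            elif k == 1:
                cx, cy = cix[i] + 1, ciy[i]
            elif k == 2:
                cx, cy = cix[i] + 1, ciy[i] + 1
            elif k == 3:
                cx, cy = cix[i], ciy[i] + 1
            else:
                cx, cy = cix[i] - 1, ciy[i] + 1
            if cx < 0 or cx >= ncell or cy < 0 or cy >= ncell:
                continue
            j = cell_head[cy * ncell + cx]
            while j != -1:
                if k > 0 or j > i:  # own cell deduped by index order
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    d2 = dx * dx + dy * dy
                    if d2 <= r_i2 and d2 > 0.0:
                        dist = np.sqrt(d2)
                        lam = dist - 0.5 * (diam[i] + diam[j])
                        if mode == MODE_FULL_SPRING:
                            spring = True
                        elif mode == MODE_LITERAL_ATTRACTION:
                            spring = lam > 0.0
                        else:
                            spring = lam < 0.0
                        if spring:
                            kk = k_n if lam < 0.0 else k_a
                            scale = -kk * lam / dist
                            fx = scale * dx
                            fy = scale * dy
                            F[i, 0] += fx
                            F[i, 1] += fy
                            F[j, 0] -= fx
                            F[j, 1] -= fy
                        if (not live_only) or xi[j] == 1:
                            cnt[i] += 1
                            svx[i] += vel[j, 0]
                            svy[i] += vel[j, 1]
                        if (not live_only) or xi[i] == 1:
                            cnt[j] += 1
                            svx[j] += vel[i, 0]
                            svy[j] += vel[i, 1]
                j = nxt[j]

    # --- per-agent gated terms -------------------------------------------
    for i in range(n):
        if not present[i]:
            continue
        # wall contacts (felt dead or alive)
        _wall_force(pos[i, 0], pos[i, 1], 0.5 * diam[i], L, r_w, k_n, F, i)
        # predator disk contact (one-sided: the predator feels walls only)
        dx = pos[i, 0] - ppos[0]
        dy = pos[i, 1] - ppos[1]
        dist = np.sqrt(dx * dx + dy * dy)
        reach = 0.5 * (diam[i] + P_diam)
        if 0.0 < dist < reach:
            scale = -k_n * (dist - reach) / dist
            F[i, 0] += scale * dx
            F[i, 1] += scale * dy
        if xi[i] == 1:
            # self-propulsion, saturating at sqrt(beta/alpha)
            sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2)
            coef = mass[i] * (beta - alpha * sp * sp)
            if sp > eps_speed:
                F[i, 0] += coef * vel[i, 0] / sp
                F[i, 1] += coef * vel[i, 1] / sp
            else:
                F[i, 0] += coef * head[i, 0]
                F[i, 1] += coef * head[i, 1]
            # coordination toward the neighbourhood mean velocity
            cd = C_v * diam[i]
            F[i, 0] += cd * (svx[i] / cnt[i] - vel[i, 0])
            F[i, 1] += cd * (svy[i] / cnt[i] - vel[i, 1])
            # escape thrust away from the predator
            if escape_active and agitated[i]:
                ex = pos[i, 0] - ppos[0]
                ey = pos[i, 1] - ppos[1]
                ed = np.sqrt(ex * ex + ey * ey)
                if ed > 0.0:
                    F[i, 0] += mass[i] * beta_e * ex / ed
                    F[i, 1] += mass[i] * beta_e * ey / ed
                else:  # coincident centres: fall back to the heading
                    F[i, 0] += mass[i] * beta_e * head[i, 0]
                    F[i, 1] += mass[i] * beta_e * head[i, 1]
        elif dead_drag > 0.0:
            F[i, 0] -= dead_drag * vel[i, 0]
            F[i, 1] -= dead_drag * vel[i, 1]

    # --- predator ----------------------------------------------------------
    Fp[0] = 0.0
    Fp[1] = 0.0
    sp = np.sqrt(pvel[0] ** 2 + pvel[1] ** 2)
    coef = M_mass * (beta - alpha * sp * sp)
    if sp > eps_speed:
        Fp[0] += coef * pvel[0] / sp
        Fp[1] += coef * pvel[1] / sp
    else:
        Fp[0] += coef * phead[0]
        Fp[1] += coef * phead[1]
    Fp[0] -= C_v * P_diam * pvel[0]
    Fp[1] -= C_v * P_diam * pvel[1]
    wrow = Fp.reshape(1, 2)
    _wall_force(ppos[0], ppos[1], 0.5 * P_diam, L, r_w, k_n, wrow, 0)
    if hunt_active and target_id >= 0:
        hx = pos[target_id, 0] - ppos[0]
        hy = pos[target_id, 1] - ppos[1]
        hd = np.sqrt(hx * hx + hy * hy)
        if hd > 0.0:
            hcoef = M_mass * (beta_h - gamma * sp * sp)
            Fp[0] += hcoef * hx / hd
            Fp[1] += hcoef * hy / hd


def compute_forces_alloc(pos, vel, head, xi, present, agitated, mass, diam,
                         ppos, pvel, phead, P_diam, M_mass,
                         beta, alpha, beta_e, beta_h, gamma, C_v,
                         k_n, k_a, r_i, mode, dead_drag, live_only,
                         escape_active, hunt_active, target_id,
                         L, r_w, eps_speed):
    """Allocating convenience wrapper around :func:`compute_forces`."""
    n = pos.shape[0]
    ncell = max(int(np.floor(L / r_i)), 1)
    F = np.zeros((n, 2))
    Fp = np.zeros(2)
    cnt = np.zeros(n, dtype=np.int64)
    svx = np.zeros(n)
    svy = np.zeros(n)
    nxt = np.zeros(n, dtype=np.int64)
    cix = np.zeros(n, dtype=np.int64)
    ciy = np.zeros(n, dtype=np.int64)
    cell_head = np.zeros(ncell * ncell, dtype=np.int64)
    compute_forces(pos, vel, head, xi, present, agitated, mass, diam,
                   ppos, pvel, phead, P_diam, M_mass,
                   beta, alpha, beta_e, beta_h, gamma, C_v,
                   k_n, k_a, r_i, mode, dead_drag, live_only,
                   escape_active, hunt_active, target_id,
                   L, r_w, eps_speed,
                   F, Fp, cnt, svx, svy, nxt, cix, ciy, cell_head)
    return F, Fp


@njit(cache=True, fastmath=True)
def fused_step(pos, vel, head, a0, ppos, pvel, phead, pa0,
               xi, present, agitated, mass, diam, P_diam, M_mass,
               beta, alpha, beta_e, beta_h, gamma, C_v,
               k_n, k_a, r_i, mode, dead_drag, live_only,
               escape_active, hunt_active, target_id,
               L, r_w, eps_speed, dt,
               F, Fp, Vp, cnt, svx, svy, nxt, cix, ciy, cell_head):
    """One Velocity-Verlet step in place; a0/pa0 carry the cached acceleration.

    Positions advance with the cached acceleration, the single new force
    evaluation uses the predicted velocities v + a0*dt, and the cache is
    overwritten with the new acceleration.  Returns 0, or 1 if a
    non-finite value appeared.
    """
    n = pos.shape[0]
    half = 0.5 * dt * dt
    for i in range(n):
        if not present[i]:
            continue
        pos[i, 0] += vel[i, 0] * dt + a0[i, 0] * half
        pos[i, 1] += vel[i, 1] * dt + a0[i, 1] * half
        Vp[i, 0] = vel[i, 0] + a0[i, 0] * dt
        Vp[i, 1] = vel[i, 1] + a0[i, 1] * dt
    ppos[0] += pvel[0] * dt + pa0[0] * half
    ppos[1] += pvel[1] * dt + pa0[1] * half
    pvx = pvel[0] + pa0[0] * dt
    pvy = pvel[1] + pa0[1] * dt
    pvp = np.empty(2)
    pvp[0] = pvx
    pvp[1] = pvy

    compute_forces(pos, Vp, head, xi, present, agitated, mass, diam,
                   ppos, pvp, phead, P_diam, M_mass,
                   beta, alpha, beta_e, beta_h, gamma, C_v,
                   k_n, k_a, r_i, mode, dead_drag, live_only,
                   escape_active, hunt_active, target_id,
                   L, r_w, eps_speed,
                   F, Fp, cnt, svx, svy, nxt, cix, ciy, cell_head)

    bad = 0
    for i in range(n):
        if not present[i]:
            continue
        ax = F[i, 0] / mass[i]
        ay = F[i, 1] / mass[i]
        vel[i, 0] += 0.5 * (a0[i, 0] + ax) * dt
        vel[i, 1] += 0.5 * (a0[i, 1] + ay) * dt
        a0[i, 0] = ax
        a0[i, 1] = ay
        sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2)
        if sp > eps_speed:
            head[i, 0] = vel[i, 0] / sp
            head[i, 1] = vel[i, 1] / sp
        if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                and np.isfinite(vel[i, 0]) and np.isfinite(vel[i, 1])):
            bad = 1
    pax = Fp[0] / M_mass
    pay = Fp[1] / M_mass
    pvel[0] += 0.5 * (pa0[0] + pax) * dt
    pvel[1] += 0.5 * (pa0[1] + pay) * dt
    pa0[0] = pax
    pa0[1] = pay
    sp = np.sqrt(pvel[0] ** 2 + pvel[1] ** 2)
    if sp > eps_speed:
        phead[0] = pvel[0] / sp
        phead[1] = pvel[1] / sp
    if not (np.isfinite(ppos[0]) and np.isfinite(ppos[1])
            and np.isfinite(pvel[0]) and np.isfinite(pvel[1])):
        bad = 1
    return bad


@njit(cache=True)
def cell_list_pairs(pos, cutoff, L):
    """Unordered pairs (i < j) with centre distance <= cutoff.

    Cell linked list with cell size >= cutoff; returns an (m, 2) int array.
    """
    n = pos.shape[0]
    ncell = max(int(np.floor(L / cutoff)), 1)
    cell_size = L / ncell
    head_arr = -np.ones(ncell * ncell, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    cix = np.zeros(n, dtype=np.int64)
    ciy = np.zeros(n, dtype=np.int64)
    for i in range(n):
        cx = min(max(int(np.floor(pos[i, 0] / cell_size)), 0), ncell - 1)
        cy = min(max(int(np.floor(pos[i, 1] / cell_size)), 0), ncell - 1)
        cix[i] = cx
        ciy[i] = cy
        c = cy * ncell + cx
        nxt[i] = head_arr[c]
        head_arr[c] = i
    out = np.empty((max(n * 16, 64), 2), dtype=np.int64)
    m = 0
    c2 = cutoff * cutoff
    for i in range(n):
        for ox in range(-1, 2):
            cx = cix[i] + ox
            if cx < 0 or cx >= ncell:
                continue
            for oy in range(-1, 2):
                cy = ciy[i] + oy
                if cy < 0 or cy >= ncell:
                    continue
                j = head_arr[cy * ncell + cx]
                while j != -1:
                    if j > i:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        if dx * dx + dy * dy <= c2:
                            if m >= out.shape[0]:
                                grown = np.empty((out.shape[0] * 2, 2), dtype=np.int64)
                                grown[:m] = out[:m]
                                out = grown
                            out[m, 0] = i
                            out[m, 1] = j
                            m += 1
                    j = nxt[j]
    return out[:m]
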