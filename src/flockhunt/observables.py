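"""Order parameters, survival statistics and regime diagnostics.

The polarization order parameter is the magnitude of the mean unit
velocity over prey,

.. math:: \\varphi = \\Big| \\frac{1}{n} \\sum_i \\hat v_i \\Big|,

with :math:`\\Phi` its temporal average after a burn-in.  A standard
rotational order parameter :math:`\\psi_{rot}` (mean tangential alignment
about the group centroid) diagnoses milling, which the polarization alone
cannot separate from disordered motion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np


class UndefinedObservableError(ValueError):
    """The observable is undefined for the given input (e.g. empty mask)."""


def _unit_directions(velocities, mask, headings, eps_speed: float) -> np.ndarray:
    v = np.asarray(velocities, float)[mask]
    speed = np.hypot(v[:, 0], v[:, 1])
    if headings is not None:
        h = np.asarray(headings, float)[mask]
    else:
        if np.any(speed <= eps_speed):
            raise UndefinedObservableError(
                "agent below eps_speed but no persistent headings supplied")
        h = v
    out = np.where(speed[:, None] > eps_speed, v / np.maximum(speed, 1e-300)[:, None], h)
    return out


def polarization(velocities, mask, headings=None, eps_speed: float = 1e-12) -> float:
    """phi = |mean unit velocity| over the masked agents, in [0, 1].

    Agents slower than ``eps_speed`` contribute their persistent heading.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise UndefinedObservableError("polarization of an empty set")
    u = _unit_directions(velocities, mask, headings, eps_speed)
    mean = u.mean(axis=0)
    return float(np.hypot(mean[0], mean[1]))


def rotational_order(positions, velocities, mask, headings=None,
                     eps_speed: float = 1e-12) -> float:
    """psi_rot = |mean z-component of r_hat x v_hat| about the centroid.

    1 for a perfect mill (all tangential, same sense), ~0 for radial or
    incoherent motion.  Agents sitting exactly at the centroid are excluded.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        raise UndefinedObservableError("rotational order needs >= 2 agents")
    pos = np.asarray(positions, float)[mask]
    u = _unit_directions(velocities, mask, headings, eps_speed)
    centroid = pos.mean(axis=0)
    rel = pos - centroid
    rad = np.hypot(rel[:, 0], rel[:, 1])
    ok = rad > 0.0
    if not ok.any():
        raise UndefinedObservableError("all agents at the centroid")
    r_hat = rel[ok] / rad[ok, None]
    cross_z = r_hat[:, 0] * u[ok, 1] - r_hat[:, 1] * u[ok, 0]
    return float(abs(cross_z.mean()))


def temporal_average_phi(tau, phi, burn_in_tau: float) -> float:
    """Phi: arithmetic mean of phi over samples with tau >= burn_in_tau."""
    tau = np.asarray(tau, float)
    phi = np.asarray(phi, float)
    sel = tau >= burn_in_tau
    if not sel.any():
        raise UndefinedObservableError("no samples after the burn-in window")
    return float(np.nanmean(phi[sel]))


def survival_counts(xi_flags) -> tuple[int, int]:
    """(N_l, N_d) from the state-of-living flags (non-consuming bookkeeping)."""
    xi = np.asarray(xi_flags)
    n_l = int(xi.sum())
    return n_l, int(xi.size - n_l)


def corner_accumulation(dead_positions, L: float, corner_fraction: float) -> float:
    """Fraction of dead agents inside the four corner squares of side f*L."""
    if not 0.0 < corner_fraction < 0.5:
        raise UndefinedObservableError("corner_fraction must lie in (0, 0.5)")
    pos = np.atleast_2d(np.asarray(dead_positions, float))
    if pos.size == 0:
        raise UndefinedObservableError("no dead agents")
    s = corner_fraction * L
    near_x = (pos[:, 0] <= s) | (pos[:, 0] >= L - s)
    near_y = (pos[:, 1] <= s) | (pos[:, 1] >= L - s)
    return float((near_x & near_y).mean())


class Regime(str, enum.Enum):
    THERMAL = "thermal"
    MILLING = "milling"
    TRANSITIONAL = "transitional"
    DYNAMICALLY_PARALLEL = "dynamically_parallel"


@dataclass(frozen=True)
class RegimeLabel:
    label: Regime
    phi_bar: float
    psi_bar: float


def classify_regime(phi_bar: float, psi_bar: float,
                    low: float = 0.3, high: float = 0.7) -> RegimeLabel:
    """Label a run from its time-averaged order parameters.

    thermal: both low; milling: rotational order high, polarization not
    high; dynamically parallel: polarization high, rotational order not
    high; transitional otherwise.  Thresholds are explicit arguments.
    """
    if not (0 <= phi_bar <= 1 and 0 <= psi_bar <= 1):
        raise UndefinedObservableError("order parameters must lie in [0, 1]")
    if phi_bar < low and psi_bar < low:
        label = Regime.THERMAL
    elif psi_bar >= high and phi_bar < high:
        label = Regime.MILLING
    elif phi_bar >= high and psi_bar < high:
        label = Regime.DYNAMICALLY_PARALLEL
    else:
        label = Regime.TRANSITIONAL
    return RegimeLabel(label, phi_bar, psi_bar)


@dataclass(frozen=True)
class EnsembleStats:
    mean: float
    sd: float
    ci95: float
    n_runs: int


def ensemble_stats(values) -> EnsembleStats:
    """Mean, sample sd and 1.96*sd/sqrt(k) half-width over ensemble runs."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise UndefinedObservableError("ensemble statistics need >= 2 runs")
    sd = float(v.std(ddof=1))
    return EnsembleStats(float(v.mean()), sd, 1.96 * sd / math.sqrt(v.size), v.size)
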