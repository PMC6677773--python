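"""Ensemble/sweep runner over the dimensionless groups chi, aleph, kappa.

The published protocol repeats every case over multiple predator starting
positions and averages; only the first start (0.93 L, 0.43 L) is given, so
the remaining ensemble members are drawn once from a dedicated ensemble
seed, uniformly inside the inner 80% of the arena, and recorded in the
manifest.  A manifest is sufficient to regenerate every run byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import engine, observables
from .config import SimulationConfig

SWEEPABLE = ("chi", "aleph", "kappa")


def predator_start_positions(k: int, L: float = 1.0,
                             ensemble_seed: int = 2024) -> list[tuple[float, float]]:
    """First start is the canonical (0.93 L, 0.43 L); the rest are seeded
    uniform draws in the inner 80% of the box."""
    rng = np.random.default_rng(ensemble_seed)
    pts = [(0.93 * L, 0.43 * L)]
    while len(pts) < k:
        x, y = rng.uniform(0.1 * L, 0.9 * L, size=2)
        pts.append((float(x), float(y)))
    return pts[:k]


def nd_slope(tau, n_d, burn_in_tau: float) -> tuple[float, float]:
    """Least-squares slope and R^2 of N_d(tau) over the post-activation window."""
    tau = np.asarray(tau, float)
    n_d = np.asarray(n_d, float)
    sel = tau >= burn_in_tau
    x, y = tau[sel], n_d[sel]
    if x.size < 3:
        raise observables.UndefinedObservableError("too few samples for a slope")
    slope, intercept = np.polyfit(x, y, 1)
    fit = slope * x + intercept
    ss_res = float(((y - fit) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


@dataclass
class SweepManifest:
    param: str                       # chi | aleph | kappa
    grid: list
    n_members: int = 20
    ensemble_seed: int = 2024
    base: dict = field(default_factory=dict)  # kwargs to SimulationConfig.from_groups
    predator_starts: list = field(default_factory=list)
    seeds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.param not in SWEEPABLE:
            raise ValueError(f"param must be one of {SWEEPABLE}")
        L = self.base.get("L", 1.0)
        if not self.predator_starts:
            self.predator_starts = predator_start_positions(
                self.n_members, L, self.ensemble_seed)
        if not self.seeds:
            # per-member placement seeds derived once from the ensemble seed
            rng = np.random.default_rng(self.ensemble_seed + 1)
            self.seeds = [int(s) for s in
                          rng.integers(0, 2**31 - 1, size=self.n_members)]

    def config_for(self, value) -> SimulationConfig:
        kw = dict(self.base)
        kw[self.param] = value
        return SimulationConfig.from_groups(**kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SweepManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["predator_starts"] = [tuple(p) for p in d.get("predator_starts", [])]
        return cls(**d)


def run_one(cfg: SimulationConfig, seed: int, predator_start,
            sample_stride: int = 20) -> dict:
    """One run reduced to its summary metrics."""
    res = engine.run(cfg, seed=seed, predator_start=predator_start,
                     sample_stride=sample_stride)
    ts = res.timeseries
    # averages start at the activation time unless the run is shorter
    burn_in = cfg.t_h if cfg.tau_end > cfg.t_h else 0.0
    phi_bar = observables.temporal_average_phi(ts.tau, ts.phi, burn_in)
    psi_bar = observables.temporal_average_phi(ts.tau, ts.psi_rot, burn_in)
    slope, r2 = nd_slope(ts.tau, ts.N_d, burn_in)
    return dict(phi_bar=phi_bar, psi_bar=psi_bar,
                n_live_end=int(ts.N_l.iloc[-1]), n_dead_end=int(ts.N_d.iloc[-1]),
                nd_slope=slope, nd_r2=r2, kills=res.final_state.predator.fsm.kills,
                truncated=res.truncated)


def run_sweep(manifest: SweepManifest, sample_stride: int = 20,
              progress=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute every (grid value x ensemble member) run.

    Returns (aggregate, per_run) tables.  Failed runs are recorded,
    excluded from the aggregate, and flag the grid point as partial.
    """
    per_run = []
    for value in manifest.grid:
        cfg = manifest.config_for(value)
        for k in range(manifest.n_members):
            row = dict(param=manifest.param, value=value, member=k,
                       seed=manifest.seeds[k],
                       start_x=manifest.predator_starts[k][0],
                       start_y=manifest.predator_starts[k][1])
            try:
                row.update(run_one(cfg, manifest.seeds[k],
                                   manifest.predator_starts[k], sample_stride))
                row["failed"] = bool(row.pop("truncated"))
            except Exception as exc:  # pragma: no cover - defensive
                row["failed"] = True
                row["error"] = str(exc)
            per_run.append(row)
            if progress is not None:
                progress(value, k)
    per_run = pd.DataFrame(per_run)

    agg_rows = []
    for value, grp in per_run.groupby("value", sort=False):
        ok = grp[~grp.failed]
        row = dict(param=manifest.param, value=value, n_runs=len(ok),
                   partial=bool(grp.failed.any()))
        for metric in ("phi_bar", "psi_bar", "n_live_end", "nd_slope", "nd_r2"):
            if len(ok) >= 2:
                st = observables.ensemble_stats(ok[metric])
                row[f"{metric}_mean"] = st.mean
                row[f"{metric}_sd"] = st.sd
                row[f"{metric}_ci95"] = st.ci95
            else:
                row[f"{metric}_mean"] = float(ok[metric].iloc[0]) if len(ok) else np.nan
                row[f"{metric}_sd"] = np.nan
                row[f"{metric}_ci95"] = np.nan
        agg_rows.append(row)
    return pd.DataFrame(agg_rows), per_run
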