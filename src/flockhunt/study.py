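"""Scaled-down trend studies over the dimensionless groups.

The full published protocol (n = 2808 prey, tau = 316, twenty predator
starts per case) is a cluster-scale computation; these helpers run the
same protocol at desk scale — n = 300 prey, tau_end = 60, five ensemble
members per case — which is enough to resolve the qualitative trends:
polarization rising with chi and with kappa, survival rising with aleph,
near-linear growth of the death count, and the milling-to-parallel
hand-off visible in the rotational order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import engine, observables
from .config import SimulationConfig
from .sweep import SweepManifest, nd_slope, predator_start_positions, run_sweep

#: regime-band representatives: milling band, transitional band, parallel band
CHI_LEVELS = (604.0, 3020.0, 6039.0)
KAPPA_LEVELS = (2.0, 5.0, 8.0)
ALEPH_LEVELS = (0.1, 0.5, 1.0)

STUDY_N = 300
STUDY_TAU_END = 60.0
STUDY_MEMBERS = 5
#: chi held fixed where a single coordination level is needed (milling band)
STUDY_CHI_FIXED = 604.0
STUDY_ALEPH_FIXED = 0.5
STUDY_KAPPA_FIXED = 5.0


def trend_manifest(param: str, seed: int, members: int = STUDY_MEMBERS,
                   grid=None, **base_overrides) -> SweepManifest:
    """Manifest for a single-parameter sweep at study scale."""
    grids = {"chi": CHI_LEVELS, "aleph": ALEPH_LEVELS, "kappa": KAPPA_LEVELS}
    base = dict(n=STUDY_N, tau_end=STUDY_TAU_END, aleph=STUDY_ALEPH_FIXED,
                kappa=STUDY_KAPPA_FIXED, chi=STUDY_CHI_FIXED, seed=seed)
    base.update(base_overrides)
    base.pop(param, None)
    return SweepManifest(param=param, grid=list(grid or grids[param]),
                         n_members=members, ensemble_seed=seed, base=base)


def run_trend_study(param: str, seed: int, members: int = STUDY_MEMBERS,
                    grid=None, sample_stride: int = 20,
                    **base_overrides) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one sweep (chi, aleph or kappa); returns (aggregate, per_run)."""
    manifest = trend_manifest(param, seed, members, grid, **base_overrides)
    return run_sweep(manifest, sample_stride=sample_stride)


def run_full_study(seed: int, members: int = STUDY_MEMBERS, n: int = STUDY_N,
                   tau_end: float = STUDY_TAU_END, sample_stride: int = 20,
                   progress=None) -> dict:
    """The three trend sweeps of the scaled study, sharing the common case.

    chi is swept over the three regime bands at (aleph, kappa) fixed;
    kappa and aleph are swept at the milling-band chi.  The case
    (chi=604, aleph=0.5, kappa=5) is common to all three sweeps and is
    simulated once.  Every run is deterministic in ``seed``.

    Returns a dict with per-sweep aggregate tables (ensemble mean, sd and
    95% CI per grid point), the per-run table, and the straight-line fit
    of the ensemble-mean death count at the fixed chi.
    """
    starts = predator_start_positions(members, 1.0, seed)
    member_seeds = [int(s) for s in
                    np.random.default_rng(seed + 1).integers(0, 2**31 - 1,
                                                             members)]
    cache: dict = {}

    def ensemble(chi, aleph, kappa):
        key = (chi, aleph, kappa)
        if key in cache:
            return cache[key]
        cfg = SimulationConfig.from_groups(n=n, chi=chi, aleph=aleph,
                                           kappa=kappa, tau_end=tau_end,
                                           seed=seed)
        rows = []
        nd_curves = []
        for k in range(members):
            res = engine.run(cfg, seed=member_seeds[k], predator_start=starts[k],
                             sample_stride=sample_stride)
            ts = res.timeseries
            slope, r2 = nd_slope(ts.tau, ts.N_d, cfg.t_h)
            rows.append(dict(
                chi=chi, aleph=aleph, kappa=kappa, member=k,
                phi_bar=observables.temporal_average_phi(ts.tau, ts.phi, cfg.t_h),
                psi_bar=observables.temporal_average_phi(ts.tau, ts.psi_rot,
                                                         cfg.t_h),
                n_live_end=int(ts.N_l.iloc[-1]), n_dead_end=int(ts.N_d.iloc[-1]),
                nd_slope=slope, nd_r2=r2, truncated=res.truncated))
            nd_curves.append((ts.tau.to_numpy(), ts.N_d.to_numpy()))
            if progress is not None:
                progress(key, k)
        cache[key] = (pd.DataFrame(rows), nd_curves)
        return cache[key]

    def aggregate(param, values, fixed):
        agg = []
        for v in values:
            kw = dict(fixed)
            kw[param] = v
            df, _ = ensemble(kw["chi"], kw["aleph"], kw["kappa"])
            row = dict(param=param, value=v)
            for metric in ("phi_bar", "psi_bar", "n_live_end", "nd_slope",
                           "nd_r2"):
                st = observables.ensemble_stats(df[metric])
                row[f"{metric}_mean"] = st.mean
                row[f"{metric}_sd"] = st.sd
                row[f"{metric}_ci95"] = st.ci95
            agg.append(row)
        return pd.DataFrame(agg)

    fixed = dict(chi=STUDY_CHI_FIXED, aleph=STUDY_ALEPH_FIXED,
                 kappa=STUDY_KAPPA_FIXED)
    out = {
        "chi": aggregate("chi", CHI_LEVELS, fixed),
        "kappa": aggregate("kappa", KAPPA_LEVELS, fixed),
        "aleph": aggregate("aleph", ALEPH_LEVELS, fixed),
    }
    # straight-line character of the ensemble-mean death count at fixed chi
    _, nd_curves = ensemble(**fixed)
    tau = nd_curves[0][0]
    mean_nd = np.mean([c[1] for c in nd_curves], axis=0)
    cfg_t_h = 3.95
    out["nd_mean_slope"], out["nd_mean_r2"] = nd_slope(tau, mean_nd, cfg_t_h)
    out["per_run"] = pd.concat([df for df, _ in cache.values()],
                               ignore_index=True)
    return out
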