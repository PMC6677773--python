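"""Survival versus escape acceleration (an aleph sweep).

aleph is the ratio of the escape-force magnitude to the zero-velocity
hunting-force magnitude; stronger escape thrust should leave more prey
alive at the end of the run.
"""

from flockhunt.study import run_trend_study

agg, per_run = run_trend_study("aleph", seed=0, members=2, n=150,
                               tau_end=30.0, chi=604.0)

print(agg[["value", "n_live_end_mean", "nd_slope_mean", "nd_r2_mean"]]
      .to_string(index=False))
# n_live_end_mean should be non-decreasing in aleph; nd_slope_mean is the
# straight-line kill rate dN_d/dtau fitted after the activation time.
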