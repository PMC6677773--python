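"""Polarization versus coordination strength (a small chi sweep).

Two ensemble members per chi level at reduced size, enough to see the
ordering rise from the milling band toward the dynamically parallel band.
"""

from flockhunt.study import run_trend_study

agg, per_run = run_trend_study("chi", seed=0, members=2, n=150, tau_end=30.0)

print(agg[["value", "phi_bar_mean", "phi_bar_sd", "psi_bar_mean",
           "n_live_end_mean"]].to_string(index=False))
# phi_bar_mean should increase with chi while psi_bar_mean (milling)
# decreases; n_live_end_mean counts surviving prey at the end of each run.
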