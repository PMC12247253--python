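"""Cumulative trend scan over a three-phase colony history.

The colony is simulated with no relatedness effects before 1985, with
inbreeding depression plus compensatory faster breeding from 1985-2015,
and with no effects again afterwards.  Recomputing the relatedness-loss
correlation on every cumulative window 1963..Y exposes that structure:
the correlation is flat in phase I, climbs through phase II and is
attenuated (diluted by effect-free pairs) in phase III.
"""

import numpy as np

from colonykin import SimConfig, cumulative_scan, detect_changepoints, make_three_phase_colony

sim = make_three_phase_colony(
    SimConfig(n_years=61, start_year=1963, n_pairs=12, rng_seed=3)
)
series = cumulative_scan(
    sim.records, sim.relatedness_map(), outcome="loss_by_mice",
    start_year=1963, end_year=2023, min_pairs=10,
)

frame = series.to_frame().dropna(subset=["r"])
print(frame[["cutoff_year", "n_pairs", "r", "r_p", "mcfadden_r2", "phase"]]
      .iloc[::6].to_string(index=False))

live = frame.reset_index(drop=True)
peak = live.loc[live["r"].abs().idxmax()]
print(f"\npeak |r| = {peak['r']:.3f} at cutoff {int(peak['cutoff_year'])} "
      f"(era 2 runs 1985-2015); final r = {live['r'].iloc[-1]:.3f}")
cp = detect_changepoints(series, k=2)
print(f"piecewise-constant breaks at {cp.years} (true era boundaries 1985, 2015;")
print("the second break lands mid-rise because cumulative windows smooth the")
print("era-2/era-3 transition -- see docs/methods.md).")
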