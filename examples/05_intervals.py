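"""Breeding-frequency compensation: intervals vs relatedness.

In a colony where more-related pairs shorten their inter-litter interval
(25 days per relatedness proportion here), the pooled correlation between
relatedness and the per-pair mean delivery interval is negative: related
pairs breed faster, which offsets the pups they lose to inbreeding
depression.
"""

from colonykin import SimConfig, simulate
from colonykin.intervals import compute_intervals, interval_relatedness_association

sim = simulate(
    SimConfig(
        n_pairs=30, n_years=18, rng_seed=21,
        mortality_slope=1.4, interval_slope=25.0,
    )
)
records, tally = compute_intervals(sim.records, sim.relatedness_map())
print(f"pairs with intervals: {len(records)} (excluded gaps: {tally})")

for mode, label in [("delivery", "mean delivery interval"),
                    ("first", "mating -> first litter")]:
    corr = interval_relatedness_association(records, mode=mode, scope="pooled")
    print(f"relatedness vs {label:24s}: r = {corr.r:+.4f}, p = {corr.p:.3g}, n = {corr.n}")

print("\nNegative correlations mean more-related pairs breed on a faster")
print("schedule -- the compensation mechanism that keeps weaned output stable.")
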