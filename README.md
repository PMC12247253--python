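# colonykin

Pedigree kinship and inbreeding-depression analysis for closed-colony
breeding records.

Closed captive colonies — bred for decades from a small founder set with
no outside animals — inevitably accumulate parental relatedness, and with
it inbreeding depression: offspring of related parents die more often
before weaning.  Yet such colonies can stay productive for sixty years.
`colonykin` is a toolkit for asking *why*, using nothing but the breeding
records a stock centre already keeps (one row per litter: cage, dam, sire,
dates, pups born, pups weaned by sex).  It is written for colony managers
and population-genetics researchers analysing studbook-style archives.

The pipeline:

1. **QC** — duplicate removal, completeness/consistency filtering,
   capping `weaned ≤ born`, and the derived per-litter loss
   `dead = born − weaned`, every action tallied in a `CleaningReport`.
2. **Kinship** — the classical recursion
   φ(x,x) = ½(1+φ(f,m)), φ(a,b) = ½(φ(f(a),b)+φ(m(a),b)),
   with ancestor tracing truncated at five generations; pair relatedness
   r = 2φ in percent.  Cross-validated against path counting and
   gene-dropping Monte Carlo.
3. **Inbreeding-depression statistics** — weighted binomial-logit GLMs
   (McFadden's R², likelihood-ratio test), Pearson correlations, and a
   five-bin relatedness ANOVA on two loss metrics (per mouse, per litter).
4. **Cumulative trend scan** — every statistic recomputed on windows
   [first year .. Y] for each cutoff year Y, exposing phase structure in
   the colony's history (with an exhaustive changepoint utility).
5. **Breeding intervals** — mating-to-first-litter and inter-litter day
   gaps vs relatedness: the compensation mechanism by which related pairs
   breed *faster* and offset their pup losses.
6. **Synthetic colony** — a discrete-event simulator (founder-seeded,
   kin-avoiding pairing, interval-scheduled litters, logistic pup
   mortality, binomial sex) whose known parameters make every stage
   testable by recovery.

## Worked example

Simulate 18 years of a closed colony in which pup mortality rises with
parental relatedness (logit slope 1.4 per unit relatedness proportion),
then recover the effect:

```bash
python examples/03_inbreeding_glm.py
```

```
pairs analyzed        : 308
GLM slope (per % rel) : 0.01707  -> 1.707 per proportion (truth 1.4)
McFadden R^2          : 0.0027
LRT p                 : 4.8e-13
Pearson r (p)         : 0.3351 (1.62e-09)

loss ratio by relatedness bin (pairs with >= 3 litters):
  <25      n=294  mean loss = 0.211
  25-29.9  n=  4  mean loss = 0.299
  30-34.9  n=  4  mean loss = 0.284
  35-39.9  n=  1  mean loss = 0.286
  >=40     empty
ANOVA F = 5.31, p = 0.00141
```

The fitted slope is positive and the likelihood-ratio test decisive: more
related pairs lose a larger fraction of their pups before weaning —
inbreeding depression, recovered close to the generative truth.  The tiny
McFadden R² alongside a clearly significant test is the expected signature
for proportion outcomes dominated by binomial noise.  The other example
scripts walk through cleaning (`01`), kinship (`02`), the three-phase
cumulative scan (`04`) and interval compensation (`05`).

Python API in one breath:

```python
from colonykin import (read_records, clean_records, summarize_pairs,
                       build_pedigree, attach_relatedness, fit_binomial_glm)

records, report = clean_records(read_records("records.csv"))
pairs = summarize_pairs(records, min_litters=1)
ped = build_pedigree(records, registry=...)   # individual parentage table
attach_relatedness(pairs, ped, max_generations=5)
fit = fit_binomial_glm([p.relatedness_pct for p in pairs],
                       [p.total_dead for p in pairs],
                       [p.total_born for p in pairs])
```

A thin CLI wraps the same functions: `colonykin qc|kinship|stats|scan|
intervals|simulate|run-all` (see `colonykin --help`).

## Layout

```
src/colonykin/     records_io, pedigree, ibd_stats, trend_scan,
                   intervals, synthetic_colony, validation (independent
                   reference implementations), pipeline, cli
examples/          one short narrative script per capability
tests/             pytest suite (unit, property and end-to-end recovery)
docs/methods.md    models, defaults, design decisions, limitations
```
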