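# Methods

`colonykin` analyses the breeding records of a closed captive colony — one
row per litter with cage ID, dam/sire IDs, mating and birth dates, pups
born, pups weaned and weaned counts by sex — for the signature of
inbreeding depression and of the breeding-frequency compensation that can
offset it.  This note documents the models, the defaults and the design
decisions, in the order the pipeline runs.

## Quality control (`records_io`)

Sixty-year archives mix formats and accumulate entry errors, so cleaning
is explicit and fully tallied rather than silent:

1. **Duplicates**: rows identical on *all* mapped fields are collapsed.
   This is the safest reading of "duplicate"; because the tally is
   reported, stricter keys can be compared externally.  Capping (step 3)
   can render previously distinct rows identical, so a second dedup pass
   runs afterwards — this keeps the output duplicate-free and makes
   cleaning idempotent.
2. **Completeness/consistency**: rows lacking a valid cage ID, stock
   label, birth date, born or weaned count are removed, as are rows with
   negative counts or sex counts that do not sum to the weaned count.  The
   archive names the fields checked but not the rules; these
   operationalisations are deliberately conservative.  Both row-wise
   (default) and whole-pair exclusion are available (`pair_level=True`),
   since a curator may prefer to distrust an entire cage's record.
3. **Capping**: `weaned > born` can only be an entry error (or untracked
   fostering); weaned is capped at born without further interpretation.
   If sex counts then no longer reconcile they are cleared (tallied), not
   re-apportioned.
4. **Derived loss**: `dead = born − weaned`, exactly.  Post-weaning fates
   were never recorded, so "loss" always means pre-weaning loss; it
   cannot distinguish death from parental cannibalism.

Dates are parsed under an explicit dialect flag (ISO or US month/day/year)
— never guessed per row, because silent dialect mixing is the classic
failure mode of long-lived archives.  A litter's year is the calendar year
of its birth date.

## Kinship and relatedness (`pedigree`)

The kinship coefficient φ(a, b) follows the classical recursion with
founders (no recorded parents) taken as mutually unrelated and non-inbred:

    φ(x, x) = ½ (1 + φ(father(x), mother(x)))
    φ(a, b) = ½ (φ(father(a), b) + φ(mother(a), b)),  a ≠ b

with φ = 0 for unknown parents.  Evaluation is memoised and ordered
topologically, recursing always on the individual that appears later in a
topological sort — that individual can never be an ancestor of the other,
which is the condition the second line needs.  Pair relatedness is
reported as r = 2φ in percent: 0 is no shared ancestry, 50 a
parent–offspring or full-sibling pairing of outbred parents, 100 genetic
identity.

**Five-generation truncation.**  Ancestor tracing is truncated (default 5
parent edges from the focal pair, counting parents as generation 1) before
kinship is computed: ancestors at exactly the cutoff depth are treated as
founders.  Old records carry ambiguous entries, and truncation bounds
their influence; it can only *remove* shared paths, so φ is non-decreasing
in the cutoff (a property the tests assert).  The window is anchored at
the mating pair, not the litter.  Unresolvable parent references are
treated as unknown, which truncation then handles uniformly.

Two independent implementations guard the recursion: Wright's
path-counting formula (sum of (½)^(L_a+L_b+1)(1+F_A) over common ancestors
A and node-disjoint path pairs) must agree exactly, and gene-dropping
Monte Carlo (founder alleles transmitted randomly down the pedigree,
2×10⁵ drops) must agree within sampling error.

## Loss statistics (`ibd_stats`)

Two per-pair loss metrics: **by mice** (total dead / total born) and
**by litter** (fraction of the pair's litters with ≥ 1 pup lost).  Their
association with relatedness is quantified by:

- a **binomial GLM with logit link**, fitted on (successes, trials) counts
  so that pairs are weighted by their number of events; per-litter rows
  and per-pair totals give the identical fit (sufficiency of the totals
  under the model — asserted numerically).  Reported log-likelihoods are
  the binomial kernel Σ s·log p + (t−s)·log(1−p); the combinatorial
  constant is omitted since it affects neither the maximiser nor the LRT.
  McFadden's R² = 1 − llₘ/ll₀ against the intercept-only null (whose MLE
  is the pooled proportion, closed form), significance by the 1-df
  likelihood-ratio test.  Complete separation sets an honest
  `converged=False` flag (statsmodels' separation diagnostics plus a
  linear-predictor bound); coefficients are never silently trusted.
- **Pearson's r** on the per-pair (relatedness, loss ratio) values,
  unweighted: the archive's convention pairs weighted GLMs with plain
  correlations, and the per-pair framing matches its scatter plots.
  p-values are two-sided throughout.
- **binned ANOVA** over five relatedness categories.  The printed labels
  (<25, 25–29.9, 30–34.9, 35–39.9, ≥40) leave a gap between 24.9 and 25;
  the bins are implemented half-open at 25/30/35/40, which is exhaustive,
  non-overlapping and reproduces the labels.  Per-bin n, mean and standard
  error are emitted for bar-plot reproduction.

The GLM covariate is relatedness in percent; a scale-invariance test
(percent vs proportion leaves McFadden's R² and the LRT unchanged) guards
against scale bugs.  Pairs with zero births are excluded from both metrics
with a logged count.  No multiple-testing correction is applied across
scans, deliberately matching the descriptive character of the analysis.

## Cumulative trend scan (`trend_scan`)

For each cutoff year Y (default 1963–2024) the association statistics are
recomputed on all litters with birth year ≤ Y.  The point at Y therefore
uses exactly the data of Y−1 plus the year-Y litters (nested windows; the
final point must equal the pooled analysis — asserted).  Cutoffs with
fewer than `min_pairs` eligible pairs (default 10) or degenerate inputs
yield *missing* statistics, never zeros; `min_pairs=1` mimics plotting
from the first year of records.  Implementation is vectorised: per-pair
per-year aggregates are cumulated once, so a 60-cutoff scan costs one
group-by plus 60 correlation evaluations.

Outcomes: the two loss ratios (Pearson + GLM), total born/weaned (Pearson
only — counts, not proportions), sex-specific losses, and the per-pair
mean delivery interval.

**Sex-specific losses** assume a 1:1 sex ratio at birth (sex was recorded
only at weaning): expected males = expected females = born/2, fractional
for odd litters.  Per-sex losses are floored at zero by default — negative
deaths are uninterpretable — with flooring events counted and an
unfloored variant behind a flag for sensitivity.

**Phases.**  The colony narrative divides its history into three phases
with boundaries 1985 and 2015 (no effect / depression + compensation /
decoupling).  These are descriptive annotations; a boundary year belongs
to the later phase.  `detect_changepoints` makes the by-eye segmentation
reproducible: an exhaustive least-squares piecewise-constant fit (k ≤ 2
breaks) to the Pearson-r sequence, ties broken toward the earliest breaks
and flagged.

*Known limitation*: on a *cumulative* scan the r-sequence keeps rising
throughout the effect era — the share of effect-era pairs grows as
(Y−b₁)/(Y−y₀) and never plateaus before the era ends — so the
piecewise-constant segmentation places its second break in the mid-rise,
not at the effect-era/late-era boundary.  The onset boundary is recovered
well (typically within ±1 year); the offset boundary is not recoverable
at ±2-year precision from cumulative statistics, by construction rather
than by noise.  The changepoint utility is validated instead on directly
constructed piecewise series, where it recovers both breaks within ±2
positions in >90% of replicates at signal/noise 3.

-log₁₀(p) columns floor p at 1e-300 to avoid infinities in exports.

## Breeding intervals (`intervals`)

Per pair: the mating-to-first-litter interval (days from recorded mating
date to first birth; missing — never zero — without a mating date) and the
day gaps between consecutive births, summarised by their per-pair mean.
The per-pair mean is the correlation unit (matching "average delivery
interval" summaries); a per-gap variant is available from the raw lists.
Same-day repeat births are excluded as data errors and tallied.  The gap
list always satisfies Σ gaps = last − first birth date.  The phrase
"interval between matings" is read as the same quantity as "mating date to
first birth" where the two are contrasted with inter-litter gaps.

## Synthetic colony (`synthetic_colony`)

The simulator generates records with exactly the structure the pipeline
assumes, so every stage can be verified by parameter recovery.  It is a
discrete-event model in continuous day time — intervals are the mechanism
under study, so they are first-class, not a by-product of a generational
loop:

- **Founders**: 40 (the colony's historical founder count), mutually
  unrelated; the colony is closed thereafter, so relatedness drifts upward
  naturally.
- **Pairing**: managers' kin avoidance is mimicked by rejecting candidate
  pairs with r ≥ 50% (full-sib/parent–offspring exclusion) over up to 30
  draws, then accepting the least-related candidate found (best effort —
  a real manager must also pair *something*).  Breeders retire after
  1.5–2 years (uniform) and are replaced from weaned offspring at least
  60 days old.
- **Litters**: scheduled at Δ = max(Δ_min, δ₀ − γ·r + N(0, σ)) days with
  δ₀ = 40, Δ_min = 21 (a gestation floor), σ = 10; γ > 0 is the
  compensation mechanism.  Litter size is zero-truncated Poisson(λ = 4) —
  a recorded litter implies ≥ 1 pup.  These are plausible deer-mouse
  magnitudes, not claims about the archive.
- **Mortality**: each pup dies pre-weaning independently with probability
  logistic(β₀ + β₁·r), β₀ = −1.4 (baseline ≈ 0.20); β₁ > 0 is inbreeding
  depression.  Survivors are sexed Binomial(weaned, ½).
- **Eras**: (β₁, γ) can switch by calendar era;
  `make_three_phase_colony` uses (0,0) / (2.5, 25) / (0,0) with
  boundaries 1985 and 2015 over 1963–2024, reproducing the
  rise-then-attenuate scan signature.
- **Kinship bookkeeping**: the tabular recursion is applied online — a
  registered individual's kinship row is the mean of its parents' rows,
  its self-kinship ½(1+φ(parents)) — and must agree *exactly* with the
  pedigree module run on the emitted parent map (asserted).
- All randomness flows from one seeded generator; identical configs give
  byte-identical output.  Extinction (no cage can be refilled and none
  remain) is reported with its year, never raised.

What the simulator deliberately does **not** emulate: demand-driven
culling and colony-size management, seasonality of breeding, litter-size
dependence on parity or age, non-random mate selection beyond the kin
cap, and any allele-level process (no explicit purging model).  Passing
tests therefore show the *statistical machinery* is correct and calibrated
under the stated generative assumptions — not that the real colony
satisfies those assumptions.

## Validation suite and problem sizes

The test suite verifies, among others: exact agreement of the kinship
recursion with path counting on 50 random pedigrees and with gene
dropping (2×10⁵ drops, 3 SE) — classical values exact; GLM coefficients
against grid-search likelihood maximisation (|Δβ| ≤ 1e-4) on 20 random
datasets; type-I error of the relatedness–loss LRT and of the pooled
interval correlation within 5% ± 3 points over 500 null replicates of
~220 pairs; median mortality-slope recovery within ±30% over 100
replicates of ~340 pairs with β₁ = 1.4 (odds ratio ≈ 2 across a 0.5 span
of relatedness proportion); and the three-phase scan signature over 100
replicates of a 61-year colony.  These replicate counts and colony sizes
are the package's chosen validation conditions and complete in a few
minutes on a single core.

## Numerical choices

- Probabilities inside log-likelihood kernels are clipped to
  [1e-12, 1−1e-12]; the LRT statistic is clipped at 0 (the model nests
  the null, so negative values can only be rounding).
- The grid oracle shrinks its window slowly (halving, 41×41 lattice, 60
  rounds) and re-centres without shrinking on edge hits, so it can track
  the diagonal intercept/slope likelihood ridge to ~1e-7.
- Changepoint ties are broken toward the earliest breakpoints and
  flagged.
- Pedigree cycles raise an error naming the offending chain; unknown IDs
  raise lookup errors rather than returning 0.
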