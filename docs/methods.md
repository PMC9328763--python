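# Methods

## The measurement problem

In *Xenopus* egg extracts, sperm nuclei replicate synchronously and the
replication program can be probed at three scales: single molecules (DNA
combing of biotin-labelled fibers), whole nuclei (fluorescent nucleotide
incorporation per nucleus), and bulk (radioactive nucleotide incorporation
over time). Immunodepleting a late-origin repressor (Yap, Rif1) from the
extract and comparing against a mock depletion asks one question at each
scale: does removing the brake increase origin firing? This package
implements the complete measurement calculus for all three readouts, plus a
stochastic single-fiber simulator that generates mock/depleted datasets
with the statistical structure the calculus assumes, so every estimator can
be validated against known ground truth.

## Single-fiber replication model

Each fiber is an independent 1-D nucleation-and-growth (KJMA) realisation:

- **Licensing.** Potential origins form a homogeneous Poisson process with
  mean spacing `lic_spacing_kb` (default 3 kb). The default is deliberately
  denser than the 5–15 kb spacing of *activated* origins in this system:
  passive replication prunes licensed origins, so activated spacing emerges
  larger than licensed spacing.
- **Timing domains.** Fibers alternate between early- and late-firing
  domains with exponentially distributed lengths. The late-domain mean is
  scaled so that the expected proportion of fiber length in late domains is
  `late_cluster_fraction` (default 0.5) while the overall mean domain
  length stays `cluster_mean_length_kb` (default 150 kb). The domain phase
  at the fiber's left end is drawn length-biased.
- **Firing.** Each origin's firing time is exponential with rate `I0`
  (default 0.01/min) in early domains and `I0 * s` in late domains, where
  the suppression multiplier `s` is 0.1 for mock and 1.0 for depleted
  extracts. Depletion is modelled *only* as this derepression; fork speed
  and licensing are untouched, matching the observation that eye lengths at
  early times are unchanged by depletion.
- **Growth and passive replication.** A fired origin grows an eye
  bidirectionally at `v` = 0.5 kb/min. With equal fork speeds, the interval
  grown from an origin that is overrun before its own firing time is always
  a subset of the overrunning eye (the covering fork passed the origin's
  position earlier and has been moving at the same speed since), so the
  replicated region is exactly the union of all individually grown
  intervals. `replicate_from_events` exploits this: no passive-firing
  bookkeeping is needed for the *geometry*. The equivalence is verified in
  the tests against an event-driven simulator that processes origins in
  firing order and explicitly discards passively replicated ones.
- **Labelling.** The label is present from `label_start_min` (default 0),
  so by default every replicated base is labelled. A positive start time
  subtracts the region already replicated when labelling began.

Fork speed and firing rate are not measured quantities in this system at
single-origin resolution; the defaults were chosen once so that early
S-phase spans tens of minutes and the default sampling times (10, 20,
30 min) cover early to mid S-phase, and are exposed as parameters.

### Closed-form validation

For a homogeneous infinite fiber with nucleation rate `I` per kb per min
and fork speed `v`, the replicated fraction is `f(t) = 1 − exp(−I v t²)`
and the active fork density is `2 I t exp(−I v t²)` per kb. The validation
helper `kjma_validation_run` simulates the homogeneous configuration
(spacing 1 kb, no late domains) and compares the Monte-Carlo means against
these forms. Finite fibers bias the comparison at the ends — origins
outside the molecule do not exist, and boundary-touching tracts lose their
outgoing fork — so the helper licenses origins on a margin of `v·t_max`
beyond each fiber end while scoring only the fiber proper; the scoring
window then behaves as a segment of an unbounded fiber and the comparison
is unbiased. Raw fork counts are tract boundaries strictly inside the
fiber, before any combing threshold.

## Combing calculus

The scoring rules, in the order applied (the order matters and is fixed by
the principle that gap-merging *defines* the tract before it is scored):

1. an unlabelled gap shorter than `min_gap_kb` (default 1 kb) is not a real
   gap; the flanking labelled tracts are merged;
2. a surviving tract shorter than `min_eye_kb` (default 1 kb) is detection
   noise and is discarded from every count — including terminal tracts,
   which the threshold's rationale (detection noise) covers equally;
3. a tract touching one fiber extremity (within `terminal_tolerance_kb`,
   default 0) is a terminal track: one fork, included in replicated length,
   excluded from eyes; a tract spanning both extremities carries zero
   on-fiber forks; every interior tract is an eye: two forks.

Eye lengths (EL) and origins (eye midpoints) are taken from eyes only;
eye-to-eye distances (ETED) are midpoint distances between adjacent eyes on
the same fiber. Aggregation per condition × time is pooled
(length-weighted): replicated fraction = Σ labelled kb / Σ fiber kb, fork
density = 100 · Σ forks / Σ kb. Fork density is reported as forks per
100 kb throughout; per-fiber summaries are also emitted for scatter-style
analyses. The percentage of unreplicated fibers counts fibers whose scored
replicated length is zero.

A note on threshold monotonicity: lowering `min_eye_kb` can only rescue
discarded tracts and therefore never decreases the fork count, but
lowering `min_gap_kb` can — splitting a merged ≥1 kb eye can leave two
sub-threshold fragments that step 2 then discards. The tests assert the
former and document the latter.

## Incorporation kinetics

Raw incorporation time courses are not comparable across extracts (each
replicates with its own kinetics), so every series is normalised to its own
maximum. The normalised scale is partitioned into four S-phase bins —
early (0–25], mid (25–50], late (50–75], very late (75–100] percent, with
exact boundary values in the lower bin. Depleted/mock ratios of *raw*
values are formed at shared time points, binned by the **mock** series'
normalised percentage (the control defines the reference kinetics), and
each bin is tested against 1 with a two-tailed Wilcoxon signed-rank test.
A bin whose ratios are all exactly 1 reports p = 1; an empty bin reports
NaN. The fraction-to-mass conversion for total synthesis is
ng/µl = 4 × pool(µM) × fraction × 0.330, with a 50 µM default endogenous
dCTP pool.

The synthetic generator draws mock cumulative incorporation as
`1 − exp(−(t/τ)²)` with τ jittered ~10% per experiment (default 75 min,
measured every 15 min to 180 min), applies a per-bin depleted/mock fold
effect (defaults 1.8/1.7/1.6/1.2 from early to very late, emulating
derepression that is strongest early and nearly exhausted once both
conditions approach completion), and multiplies every measurement by
log-normal noise (scale 0.1). Because binning uses the *noisy* normalised
mock series, points near bin boundaries can land in the neighbouring bin;
recovered per-bin means are therefore slightly shrunk toward their
neighbours, which is a property of the binning procedure itself, not a
bug.

## Nucleus fluorescence

CTF = integrated density − area × mean slide background, one background per
slide. Negative CTFs are retained in means (truncation would bias condition
ratios upward) and flagged. "Positive" nuclei are CTF > threshold with
threshold 0 by default; the criterion is configurable since no standard
definition exists. The depletion effect is the per-experiment ratio of mean
CTFs (means, not medians), tested across experiments with a two-tailed
one-sample t-test against 1. The generator draws per-nucleus area and
intensity log-normally, applies the condition effect multiplicatively, and
adds the slide background to the integrated density so that CTF recovers
the true signal; the realised fold change converges to `condition_effect`.

## Statistics

- One-sample t vs 1: requires n ≥ 2 and nonzero variance.
- Mann–Whitney: exact null when the smaller group has ≤ 8 tie-free
  observations, otherwise normal approximation with tie correction.
- Wilcoxon signed-rank vs 1: values equal to 1 dropped; exact null for
  ≤ 25 tie-free nonzero differences, otherwise normal approximation with
  continuity correction.
- All tests two-tailed; no multiple-testing correction (the analyses are
  single planned comparisons per figure-level question).

The exact branches are implemented by scipy behind these wrappers; the
wrappers own the branch points and the ratio-vs-1 conventions. The test
suite checks both branches against full-enumeration null distributions and
calibrates the Wilcoxon type-I error at α = 0.05 against the enumerated
size of the discrete test (which is below 0.05 by construction; comparing
against the nominal level would be the wrong target).

Co-IP enrichment keeps proteins with target/control ≥ 3 (threshold
configurable); proteins absent from the control are infinitely enriched
and kept if the target abundance reaches a configurable floor (default 1),
since a 0/0 or trace/0 ratio is evidence of nothing. Foci-pattern analysis
reduces each retina to (mid + late)/early pattern counts — undefined and
excluded, with a warning, when no early-like cells were scored — and
compares conditions by Mann–Whitney.

## Problem sizes and determinism

Default analysis sizes: 100 fibers of 100 kb per condition per time point
(three time points), 8 incorporation experiments, 6 nucleus experiments of
80 nuclei per condition, 20 replicate simulated combing experiments for
ratio distributions; the KJMA validation uses 500 fibers of 1,000 kb.
These sizes put Monte-Carlo standard errors well below the effects being
measured while keeping any run in seconds to a few minutes.

All randomness flows from a single integer seed. Fiber-level substreams are
derived from (seed, condition index, time index, fiber index) via numpy's
`SeedSequence`, so datasets are byte-identical across runs and independent
of iteration order.

## What the synthetic data does and does not show

The generators reproduce the statistical *structure* the estimators assume:
Poisson licensing, exponential firing within timing domains, multiplicative
measurement noise, per-slide backgrounds. They do not model checkpoint
feedback, fork stalling or re-replication, sequence-specific origin
preference, nuclear geometry (foci are reduced to pattern counts), or
optical artefacts of combing (stretching variability, breakage bias toward
long unreplicated molecules). Passing tests therefore demonstrate that the
measurement chain is correct and well-calibrated on data satisfying its own
assumptions — not that those assumptions hold in any particular extract.

## Known limitations

- The tract table stores coordinates on a 1 bp (3-decimal kb) grid; tracts
  narrower than 1 bp vanish on write.
- Exact Mann-Whitney is skipped in the presence of ties even below n = 8.
- `ratio_of_stats` requires exactly matched time points; experiments with
  unequal sampling grids must be interpolated upstream.
- The fiber simulator treats molecules as independent; it cannot reproduce
  correlations between fibers from the same nucleus.
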