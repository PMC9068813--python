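# Methods

`nelfkit` re-implements, as a tested library, the quantitative procedures
used to show that enhancer RNAs (eRNAs) detach NELF from paused RNA
polymerase II: quadratic binding fits of gel-shift release curves,
pausing-index analysis of nascent transcription, crosslink-site positional
statistics, single-nucleotide TSS assignment, SHAPE-MaP reactivity
classification, and crosslinking-MS spectral-count aggregation.  This note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Coordinate and strand conventions

All genomic coordinates are 0-based half-open (`core.GenomicInterval`),
matching BED/bedGraph; 1-based labels appear only in report text, e.g. the
crosslink distance window "1–200".  Coverage (`core.CoverageTrack`) always
stores both strands at single-base resolution; display conventions such as
"sense at promoters / forward at enhancers" belong to reporting, never to
the data model.  bedGraph is read tolerantly (tab or space separated,
overlapping lines summed) and written canonically (tab separated,
run-length collapsed).  Statistics are computed on raw counts;
`CoverageTrack.scaled` exposes a multiplicative factor for normalized
display, and every pausing index is invariant under such rescaling.

## Quadratic single-site binding fits (`emsa`)

The released fraction per gel lane is

    f = I(Pol II–DSIF) / (I(Pol II–DSIF) + I(Pol II–DSIF–NELF)),

undefined (NaN, with a warning) when both bands are empty.  Plotted against
eRNA concentration this gives a pseudo-binding curve.  Because eRNA (L,
0.15–1.8 µM) and PEC (R, 0.1 µM) concentrations are comparable, ligand
depletion is not negligible and the quadratic form of the single-site model
is fitted:

    f(L) = A · (R + L + Kd − sqrt((R + L + Kd)² − 4RL)) / (2R).

The fitter (`fit_binding`) is a bounded nonlinear least-squares over
(Kd, A), initialized at A = max fraction and Kd = the concentration nearest
half-maximal release, with a 5-point log-spaced Kd multistart; the best
residual wins.  Design choices:

- **Amplitude is fitted by default** (bounded in (0, 1.2]); gels rarely
  reach complete conversion.  `fix_amplitude=1` gives the constrained
  variant.  Noiseless round trips recover Kd and A to <1% relative error
  for Kd anywhere in [0.05, 20] µM at the standard six-point series — this
  includes Kd values well above the largest tested concentration, where the
  curve is still identifiably non-hyperbolic.
- **Kd standard error** comes from the Jacobian curvature at the optimum
  (σ² · (JᵀJ)⁻¹); it is a local linearization, not a profile likelihood.
- **Flat curves** (zero range) are declared unidentifiable rather than
  fitted; `converged=False` with a diagnostic message.
- **Replicates** can be fitted on the pointwise mean (matching
  quantification that averages replicate gels before fitting) or pooled
  into one residual vector.
- For Kd ≫ R the quadratic model converges to the hyperbolic
  A·L/(L + Kd); the suite checks <1% deviation at Kd = 100·R.

Pause-release time courses divide the intensity of the first band above the
pause site by the total intensity of the same lane, per time point; lanes
with zero total are flagged NaN.

## Pausing index (`pausing`)

PI = (read density over TSS−100..TSS+200) / (density over TSS+400..TSS+800),
on the unit's own strand, windows flipped in transcript orientation on
minus-strand units.  A zero body density leaves the PI **undefined** rather
than infinite; undefined units are excluded from distribution comparisons
and their number reported (`pausing_index_table` keeps them as flagged
rows).  Windows falling off the chromosome skip the unit with a warning.
Distribution shifts between groups or time points use the two-sample
Kolmogorov–Smirnov test on defined PIs only, with ECDF tables exported for
cumulative-probability plots.

NELF occupancy grouping: a unit is *bound* when its promoter ChIP score
reaches a threshold or its id appears in a peak-overlap set; bound units
are split at configurable score quantiles into low/mid/high.  The tertile
default is a surrogate — published group sizes (216/133/199) imply some
other, unstated partition — and is therefore exposed as a parameter.

## TSS calling and enhancer assignment (`tss`)

5′-end site tables are clustered strand-wise by single linkage with an
explicit merge gap (default 25 nt); clusters with fewer than
`min_cluster_reads` (default 5, mirroring csRNA-style tag thresholds) are
dropped; the called TSS is the maximum-count position, ties broken toward
the 5′-most position in transcript orientation.  The ">20 reads"
well-defined flag is exactly that — a flag, not a filter — and counts the
called position by default (`well_defined_on="cluster"` switches to the
cluster total, since the original rule's basis is ambiguous).

Extragenic filtering removes calls inside any gene ±2 kb, strand-agnostic,
with half-open extension (a call exactly at gene_end + flank survives).
Enhancer assignment considers same-strand calls within the unit ±200 nt and
keeps exactly one winner per unit: highest read count, then smallest
absolute distance to the unit 5′-end, then 5′-most.  A call inside two
overlapping units may be assigned to both; resolving such conflicts is left
to the caller because no principled tiebreak exists.  Activity induction is
strict: max over stimulated conditions of (expression + ε)/(baseline + ε)
**>** 1.5; with the default ε = 0, a zero-baseline unit with any stimulated
signal counts as induced.  Pervasive/convergent transcription — originally
curated by eye — is approximated by an explicit rule
(`filter_convergent`): reject calls whose antisense signal within ±200 nt
exceeds half the sense signal.

## eCLIP crosslink statistics (`eclip`)

The crosslink site is the first nucleotide of the R2 read; extraction
accumulates counts per (chrom, position, strand), with an optional
collapse of byte-identical records (PCR-duplicate removal proper is
upstream).  Sites are assigned to containing same-strand units with 1-based
distances from the unit 5′-end (distance 1 = the 5′ nucleotide); sites in
no unit are dropped and counted, sites in several units assigned to all and
flagged.  Window distributions count distances per half-open window
(prev, edge] with default edges 200/400/600/800/1000/2000 nt; distances
beyond the last edge are dropped and counted.  Two distributions are
compared by Pearson chi-squared on the 2×k **count** table (never on
proportions), without continuity correction; expected cells below 1 warn
but still return the statistic.  Raw p-values are what the analysis
reports; Benjamini–Hochberg adjusted values are additionally available
(`bh_adjust`) for many-group report tables.

The expression-normalized meta-profile divides each unit's per-position
crosslink counts by that unit's nascent-transcription density (reads/bp),
averages across units with at least one crosslink, and bins the curve.
The loosely-specified normalization is thus made explicit: per-unit density
division, with zero-expression units excluded and counted.

## SHAPE-MaP reactivities (`shape`)

Raw reactivity = modified-channel mutation rate − untreated-channel rate,
kept unclamped by default (clamping is an option).  Positions with either
channel below `min_depth` are masked and excluded from every summary.  The
default `min_depth` of 1000 is deliberately below read-aligner defaults of
5000: profiles here come from count tables, and the suite's synthetic
depths (10⁴) make 1000 a safe floor.  There is no denatured-control
channel: probing was 1M7 vs DMSO only, so the two-channel difference is the
implemented quantity.

Normalization uses the box-plot variant of the 2–8% rule: values above
Q3 + 1.5·IQR are excluded as outliers — capped at the top 10% of positions,
so a largely single-stranded RNA cannot have its entire reactive signal
discarded — and the scale is the mean of the remaining values between their
90th and 98th percentiles.  Without the cap, any profile with more than
~10% unpaired positions normalizes against its paired baseline and
misclassifies as flexible; with it, a profile of identical raw values
self-normalizes to exactly 1.  Classification by median normalized
reactivity over unmasked positions: structured < 0.1, intermediate < 0.15,
flexible otherwise (both cutoffs strict and configurable; medians can be
switched to raw reactivities).

Positional G-content: alternative TSSs closer than 40 nt are collapsed
(5′-most retained), sequences are split into 200-nt bins over the first
kilobase, and per-bin base frequencies are compared by paired t-tests of G
against each other base across RNAs (identical frequencies short-circuit to
t = 0, p = 1 rather than a 0/0 statistic).  Sequences shorter than the full
extent contribute only complete bins unless partial bins are requested;
genomic extension to 1 kb requires genome sequence and is the caller's
responsibility.

## Crosslinking-MS aggregation (`xlms`)

Search-result rows are filtered by minions ≥ 7, TIC subscore ≥ 0.15 and ID
score ≥ 20 (all boundaries inclusive, all configurable); an optional
|mass error| ≤ ppm window has no default because observed mass deviation is
dataset-specific.  Decoy rows survive filtering flagged and feed the
decoy/target FDR estimate, but never enter aggregation.  Redundant spectral
counts (nseen) are summed per (subunit, residue); Met1 of NELF-E is
excluded by default as a known overrepresented outlier, with the removed
mass reported.  Subunit proportions sum to 1; within a subunit, domain
shares (defaults: NELF-E N-terminal 1–137 / tentacle 138–380, NELF-A lobe
1–187 / tentacle 188–528, kept disjoint so shares add up) sum to the
subunit's share, with residues outside every span in an `other` row.

## Synthetic data (`simulate`)

Generators emit the statistical structure each stage assumes, plus a
ground-truth sidecar, so the whole pipeline is testable offline.  All
generators are deterministic for a fixed seed, with per-generator
substreams derived by fixed offsets so stages stay reproducible when run
alone.  What is emulated — and what is not:

- **Nascent coverage**: reads split between promoter window and gene
  remainder so the expected PI equals `pausing_index_true`; PI = 1 reduces
  to a flat profile.  Real nascent data has termination peaks and
  antisense signal; recovery tests therefore show estimator correctness,
  not robustness to those features.
- **5′-end reads**: Poisson counts (mean 50) at true TSSs with a 20% jitter
  mass within ±2 nt, over uniform background (0.01 reads/bp).  Real
  5′-end libraries have heavier-tailed background and recapping artifacts.
- **Crosslink sites**: a mixture placing 70% of sites uniformly in the
  first 200 nt and the rest uniformly over the remaining length.  Uniform
  within-window placement keeps the null analytic; empirical profiles are
  steeper near the TSS, which does not affect window-proportion recovery.
- **Binding curves**: quadratic-model values at the standard series plus
  additive Gaussian noise (sd 0.05) truncated to [0, 1].  No densitometry
  error model exists to emulate; 0.05 is a choice, not a measurement.
- **Mutation counts**: Binomial(depth 10⁴) with rates 0.05 (unpaired),
  0.005 (paired), 0.002 (untreated) — generous depth, no PCR jackpots.
- **Search tables**: a planted fraction of rows falls below exactly one
  quality threshold, making pass/fail bookkeeping exactly checkable.

## Problem sizes

Recovery experiments run at the sizes the checks state: 10⁵ reads/gene for
PI recovery (tolerance 5%), 10⁴ crosslinks for mixture recovery (99%
binomial interval), 100 TSSs at mean 50 reads over 0.01/bp background
(≥95% within 2 nt), 200 Monte-Carlo binding curves at 5% noise (median Kd
within 15%), 10⁴-row tables for the filtering/aggregation oracles.  These
sizes make every stochastic check comfortably reproducible under its
stated tolerance with the fixed seeds used in the suite.

## Known limitations

Read alignment, transcript/peak calling, duplicate removal and structure
prediction are out of scope by design: the package starts from site
tables, coverage tracks, count tables and interval annotations.  The
surrogate rules above (merge gap, convergent-transcription filter, tier
quantiles, well-defined basis) are explicit stand-ins for published
procedures whose parameters were not fully specified; each is a keyword
argument, so a different reading is one call away.
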