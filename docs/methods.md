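# Methods

This note documents the models behind `varmap`: what the synthetic
experiment emulates, how counting and scoring work, the choices made where
the design was genuinely open, and what the tests do and do not show.

## The synthetic experiment

The generator stands in for a yeast-complementation MAVE of a human enzyme:
a codon-randomized library of the target ORF is expressed in a strain whose
growth under restrictive conditions requires the human protein's activity,
grown under selection, and sequenced as short duplex amplicon tiles before
and after.

**Ground truth.** Every substitution at every residue gets a true score:
synonymous variants exactly 1; nonsense variants exactly 0 except within
the 14 C-terminal residues (truncations there rarely matter and score 1);
missense scores from a two-Gaussian mixture with modes near 0 and 1
(weights 0.35/0.65, s.d. 0.08, out-of-range draws reflected at the [0, 1]
boundaries so the distribution has no artificial atoms).  A configurable
fraction of missense variants (default 2.5%) is hyper-complementing, drawn
uniformly on (1.05, 1.5); only these exceed 1.  The reference coding
sequence is drawn uniformly over sense codons.

**Library.** Each clone carries a Poisson number of amino-acid changes
(default mean 1.7) at distinct positions inside its mutagenesis region
(default: two equal halves of the protein, one pool per region, 10^6
clones per pool).  Each change is realised by one canonical codon: the
codon for the target residue with the fewest nucleotide edits from the
reference codon, ties broken alphabetically.  Synonymous changes exist
only at residues with a second codon.

**Selection.** A clone's fitness is the *minimum* true score among its
variants — loss of function is epistatically dominant when the assay
requires an essential activity.  Abundances are multiplied by
`exp(generations * gap * fitness)` times per-clone log-normal noise
(s.d. `noise_sd`) and renormalised, so a score-1 clone gains a factor
`exp(gap * generations)` over a score-0 clone.  Defaults: 6 generations,
gap 0.5 per generation (about 20-fold depletion of null variants, strong
enough to separate the classes cleanly while slow-growing clones remain
well above the count filters), noise 0.05.

**Sequencing.** Tiles are codon-aligned, gap-free, and covered by read
pairs carrying constant Phred qualities matching the per-base error rate
(default 0.001, i.e. Q30; paper-scale depth default 2x10^6 pairs/tile).
Errors are injected independently per read of a pair.  Two paths exist:

* `simulate_read_pairs` emits individual `ReadPair` objects for the duplex
  caller (used in tests at modest depth);
* `simulate_tile_counts` samples the count table the caller would produce
  directly from the closed-form per-pair probabilities — a carried variant
  with a `k`-nucleotide codon change survives duplex concordance with
  probability `(1-eps)^(2k)`, and every (position, alternate base) cell
  accrues concordant double errors at `(eps/3)^2` per pair — gated by the
  identical duplex-posterior rule.  The two paths are distributionally
  equivalent at the count level (asserted in tests); the fast path makes
  million-pair depths practical.  It neglects partial recovery of
  multi-nucleotide codon changes, which is epsilon-suppressed relative to
  the double-error background.

## Counting

A substitution is considered only where both reads of a pair agree on the
same non-reference base.  The posterior that the call is real assumes
symmetric errors spread uniformly over the three other bases, independent
reads, and a uniform prior over the four true bases:
`P = (1-e1)(1-e2) / [(1-e1)(1-e2) + e1*e2/3]`.  Calls at or below the 90%
threshold are dropped; at two Phred-3 reads the posterior is 0.748
(suppressed), at two Phred-40 reads it is ~1 (called).  Multiple calls in
one codon within a pair are translated jointly under the standard genetic
code.  Frequencies are counts over the covering tile's pair depth.
Coordinates are 0-based half-open internally; residue positions are
1-based in keys and outputs.

## Scoring

Per mutagenesis region and replicate:

1. variants with a raw count below 10 in the selective *or* non-selective
   library, or a frequency strictly below the 90th percentile of the
   frequencies observed in the matched wild-type control, are removed;
2. wild-type-control frequencies are subtracted per condition; a
   non-positive adjusted selective frequency is floored at half a read
   over the tile depth (phi defined but strongly null-like); a
   non-positive adjusted non-selective frequency makes the record
   unusable;
3. `Φ = f_sel_adj / f_nonsel_adj`; `Φ_STOP`/`Φ_SYN` are the medians of
   usable nonsense/synonymous records (nonsense within 14 residues of the
   C terminus excluded); `FS = ln(Φ/Φ_STOP) / ln(Φ_SYN/Φ_STOP)`.
   Because the median commutes with the monotone log transform, nonsense
   and synonymous medians anchor at exactly 0 and 1 per region and
   replicate.  Scores above 1 and below 0 are permitted.

**Error model.** The replicate s.d. of FS is shrunk toward a trend — a
centred running median (window 51) of replicate deviations over variants
ordered by log pre-selection frequency — with `m = 2` prior
pseudo-replicates: `sd = (m*t + n*s)/(m+n)`, `sigma = sd/sqrt(n)`.  With
`m = 0` and corrections off this is exactly the empirical standard error.
Small-sample calibration: the raw 2-replicate s.d. underestimates the true
deviation by the normal-theory factor c4 ≈ 0.80 and its running median by
the chi-distribution median ≈ 0.67, so both terms are rescaled before
blending.  Quality filters: σ strictly above 0.3, or pre-selection
frequency strictly below 0.005%, fails (equality passes); failures are
flagged, not deleted.

Known limitation: the trend conditions on pre-selection frequency only, as
the method prescribes, but true error also depends on post-selection
depletion (null variants have fewer selective reads and larger true error).
In simulation, `fs ± 2σ` covers the truth for ~86% of variants even when
clones carry a single variant — below the nominal 95% — and multi-variant
clones add clone-context noise that sequencing replicates of the same pool
cannot see (the replicates share the library), further reducing coverage
of the truth.  σ should be read as a *measurement* error, not a total
error against an external truth.

**Combination.** The first (erythroid-style) map is rescaled onto the
second by affine least squares over shared well-measured variants — the
simplest transform minimising the mean squared distance between maps; the
fitted transform is reported, and a monotone-spline alternative could be
slotted in where the scale distortion is non-linear.  Shared variants are
combined with inverse-variance weights, `sigma_c^2 = 1/(1/s1^2 + 1/s2^2)`
(the standard form for a weighted mean; a printed formula equivalent to
`s1^2 + s2^2` circulates but contradicts inverse-variance weighting);
singletons pass through; `delta = fs_1 - fs_2` where both exist.

**Preference transforms.**  WT-normalised score matrices are turned into
per-position amino-acid preferences (rows summing to 1) under three models
of hyper-complementation — advantageous (scores unchanged), neutral
(scores above 1 capped at 1), damaging (scores above 1 inverted to 1/s) —
with non-positive scores clipped to 1e-6 so preferences stay defined.
Phylogenetic fitting of the three models is out of scope.

## Clinical calibration

Reference sets: positive = pathogenic/likely pathogenic; negative =
benign/likely benign without conflicting interpretations, plus
proxy-benign population variants (MAF < 0.0005, at least one homozygote,
no annotations).  Score densities are Gaussian KDEs (Silverman bandwidth
per set by default; explicit bandwidths supported), floored at 1e-6 of
their own maximum before ratio-taking so the LLR stays finite; no boundary
reflection, since scores are not bounded (hyper-complementation exceeds
1).  `LLRp(s) = log10(pi+(s)/pi-(s))`; base 10 throughout — the
very-strong cut then equals log10 of the solver's combining odds.

The threshold solver models posterior odds as `prior_odds * X^w` with
exponent weights very-strong 1, strong 1/2, moderate 1/4, supporting 1/8
(benign negative, mirrored).  The ACMG/AMP combining rules are data, not
code (auditable in `ACMG_COMBINING_RULES`), each at its minimum-strength
instantiation; pathogenic rules must exceed 99% posterior, likely
pathogenic 90%, likely benign below 10%, benign below 1%.  One deliberate
reading: the two-Strong combination is held to the likely-pathogenic
bound — at prior 0.1 it cannot reach 99% for any X consistent with the
published calibration, whose internally consistent solution (combining
odds ~350, very-strong cut 2.54) requires it at the 90% bound.  All
constraints are lower bounds on X, so "most conservative" means the
smallest feasible X (the weakest evidence claim); the solver scans a log
grid and bisects.  At prior 0.1 the cuts are 2.54 / 1.27 / 0.64 / 0.32 /
-0.32 / -1.27 (the moderate and supporting cuts round to 0.64/0.32 and
truncate to 0.63/0.31).  Evidence assignment is strict: an LLR exactly at
a cut takes the weaker category.

## Evaluation

Lower score = positive (pathogenic) class, fixed by an explicit
orientation argument.  AUROC equals the normalised Mann-Whitney U on the
same data (cross-checked in tests); paired AUROC comparison uses the
DeLong variance estimator.  Balanced precision is `TPR/(TPR+FPR)` —
precision under equal class priors; curves are evaluated at the empirical
operating points without interpolation, AUBPRC is the trapezoid over
recall (the value depends on this convention), and R90BP is the maximum
recall over thresholds at 90%+ balanced precision.  `delta_median` is
median(second set) - median(first set), positive when the benign-style set
sits above the pathogenic-style set.  Positional profiles are centred
running means truncated at the termini with missing positions skipped.
ASA classes: buried < 20% <= intermediate <= 40% < exposed; interfacial
iff the ASA change on complex formation strictly exceeds 1 A^2,
independent of the ASA class, absent (not false) where no change value is
given.  Odds ratios use a Haldane correction of 0.5 on zero cells; p
values are exact hypergeometric, unadjusted.  A region-exclusion helper
flags residues 160-215, 255 and 355, windows where this assay family is
suspected to under-call damage and benignity should not be inferred.

## Problem sizes and determinism

Desk-scale runs use a 120-residue protein (4 tiles of 90 bp), two
mutagenesis regions, two replicates, two isoforms, 10^6 clones per
regional pool and 5x10^5 pairs per tile; a full recovery takes ~10 s and
yields Spearman ~0.97 and RMSE ~0.03 against the truth, with class
medians anchored at 0/1.  Clone-pool size matters: the dominant recovery
noise is clone-context sampling (which co-occurring variants a clone
carries under the minimum rule), scaling as one over the square root of
clones per variant.  Every stochastic operation takes an explicit seed and
derives any internal seeds from it; identical inputs and configuration
give bit-identical outputs.

## Non-goals

No read alignment (inputs carry tile offsets), no indels, no quality
recalibration, no phylogenetic likelihood fitting, no score imputation, no
retrieval from population or clinical databases, and no
posterior-probability classification of variants — only evidence
strengths are emitted.
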