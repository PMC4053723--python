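# Methods

## Model

`xcical` models bulk allele-resolved expression of an X-linked gene in a
female as a two-population mixture. A fraction *s* ∈ [0.5, 1] of cells (the
*skew*) carries one parental X as the inactive X (Xi); the rest carry the
other. With Xa expression normalised to 1 and Xi expression at a relative
level *e* ≥ 0 (the Xi/Xa ratio, "%Xi"), the allele-1 expression fraction is

    f(s, e) = (s · 1 + e · (1 − s)) / (1 + e)

and the allelic imbalance is AI = |f − 0.5| ∈ [0, 0.5]. The absolute value
makes every result invariant to which allele is labelled "allele 1".
Assumptions: Xi expression is the same whichever parental X is inactive;
expression adds linearly over cells; probe intensities have already been
normalised so that a heterozygote's genomic DNA reads ~0.5.

Internally all quantities are unitless fractions (skew in [0.5, 1], %Xi with
Xa ≡ 1); percent formatting happens only in reports.

### Identifiability

Three structural limits shape the pipeline and are worth stating explicitly.

1. **Random XCI is uninformative.** At *s* = 0.5, f = 0.5 for every *e*, so
   no XCI status can be assigned. Females are therefore gated into groups:
   group 1 (strongly skewed, subject-training AI above the 99.5th autosomal
   percentile), group 2 (detectably skewed via regression), group R (the
   rest), and statuses are called only in groups 1 and 2.
2. **The reciprocal fold.** f(s, e) + f(s, 1/e) = 1, so AI cannot
   distinguish *e* from 1/*e*: Xi expression *above* the Xa level is
   indistinguishable from its reciprocal. The inversion
   `e = (f − s)/(1 − s − f)` with f = 0.5 + AI takes the major-allele
   branch and always returns *e* ≤ 1. Round-trip recovery
   `xi_from_ai(expected_ai(s, e), s) = e` is therefore exact (to 1e-9) on
   *e* ∈ [0, 1] and mathematically impossible beyond it; the suite carries
   one deliberately failing assertion over *e* ∈ [0, 2] to document the
   limit.
3. **Skew underestimation clamps at zero.** Any residual Xi expression in
   the subject training set underestimates *s*, which can push the inverted
   %Xi of strongly imbalanced genes negative; negative solutions are
   clamped to 0 inside `xi_from_ai` so no consumer ever sees a negative
   %Xi.

### Direction of the escape/subject comparison

Low AI means high Xi expression. A gene is **subject** in a female when its
mean AI is **at or above** the AI corresponding to 10% Xi expression at her
skew (`expected_ai(skew, 0.10)`), and escapes otherwise. The boundary tie
breaks to subject ("escape" requires strictly more than 10% Xi expression in
AI space); the choice is config-overridable (`xi_escape_cutoff`) and
surfaced in run metadata.

## Pipeline stages and their decision rules

All thresholds live once, in `PipelineConfig`; modules never hard-code them.

**Probe QC.** (1) *Intensity (Tau) filter*: the AI of homozygous probes —
defined as the deviation min(f, 1 − f) from the clean mono-allelic signal —
is fitted per sample set against total cDNA intensity with a one-phase
exponential decay, AI(I) = plateau + (y0 − plateau)·exp(−I/τ), by nonlinear
least squares (initialisation: y0 from the lowest-intensity decile mean,
plateau from the highest, τ where the decile profile crosses halfway). Only
probes with intensity **strictly greater** than the set's τ survive.
(2) *Genomic-DNA ratio*: a probe is dropped in **all** sets if in any one
set ≥ 50% of its informative females show max(r, 1 − r) > 0.7 — the
symmetric form keeps the rule allele-label invariant. (3) *Two-probe
concordance*: for genes with exactly two surviving probes, the probes are
concordant in a female when they fall on the same side of her
escape/subject boundary (alternative definition |ΔAI| < 0.1 selectable via
`concordance_mode`); each gene's discordant count is tested against the
cohort discordance rate by a df = 1 chi-square, flagging enrichment at
α = 0.05. Filters are idempotent and monotone in τ.

**Female grouping.** Skew is estimated as 0.5 + (mean over subject-training
genes with ≥ 2 informative probes of the per-gene mean AI). Group 1 requires
that mean to exceed the set's q99.5 of autosomal AI strictly. Every other
female is regressed (per-gene AI response, ordinary least squares) on the
group-1 reference — the mean per-gene AI of the set's group-1 females over
genes whose group-1 genic call is consistent (subject or escape, never
variable) — and joins group 2 when the slope is significant at p ≤ 0.05
(two-sided), else group R. Under the model the relationship is exactly
linear: AI(s, e) = (s − 0.5)(1 − e)/(1 + e), so a group-2 female's profile
is the reference scaled by (s₂ − 0.5)/(s₁ − 0.5).

**Boundaries.** Group 1: E1:E2 and E2:E3 at the set's autosomal 90th/95th
AI percentiles, E3:S at `expected_ai(skew, 0.10)`. Group 2: all three
group-1-level boundaries mapped through the female's regression line
(slope·b + intercept, the subject boundary taken at the group-1 reference
skew), clipped to [0, 0.5] and re-sorted (with a log entry) if the
regression inverts them.

**Genic aggregation.** Fraction escaping = (# E1/E2/E3 calls)/(#
informative females), compared as exact rationals: escape iff ≥ 7/9,
subject iff ≤ 2/9, else variable escape — 7-of-9 informative samples is the
motivating case, so rounding to 78%/22% is deliberately avoided.
Variable-escape subtypes: *bimodal* when ≥ 75% of calls are E1 or S and
both occur; else *borderline* when every call is S or E3; else
*heterogeneous*. Expression classes anchor on the PAR1 genes (which escape
by construction): escape genes at or above the minimum PAR1 mean %Xi are
"within the PAR1 range"; subject genes split at 5% Xi (inclusive above).

**Chromosome analyses.** *Adjacency*: unordered status pairs over
consecutive classified genes (PAR1 excluded; position ties break by gene
id); per-pair chi-square components (o − e)²/e and standardized residuals
(o − e)/√e; expected counts default to permutation means (status labels
shuffled over fixed positions, seeded), with an add-one empirical p for the
total statistic alongside a chi-square p at df = #pairs − 1
(config-overridable); user-supplied expected counts are accepted directly.
*Cross-set comparison* (per-set statuses from sets with ≥ 5 informative
females): all informative sets agreeing → consistent; the two
same-cell-type sets disagreeing → population-specific, unless the third set
differs from both → population-and-cell-line; a consistent same-cell-type
pair differing from the other cell type → cell-line-specific; remaining
patterns → inconsistent; fewer than two informative sets → not
classifiable. The rule is symmetric in the two same-cell-type sets.
*Group-R screen*: per set, a single-outlier Grubbs test (one-sided toward
high AI — the direction an imprinting-like signal pulls; two-sided
selectable) on the average subject-training AI excludes at most one extreme
female; then a gene is mono-allelic in a female when its mean AI exceeds
that set's own q99.5 (no cross-set rescaling), and the genic category
applies the 2/9–7/9 rule to the bi-allelic fraction (mostly mono-allelic
genes are imprinting candidates). *ChIP classes*: probes are assigned to
the promoter ([TSS − 1 kb, TSS + 1 kb), strand-resolved TSS, BED 0-based
half-open coordinates) and/or the gene body ([start, end)); per mark ×
region, class means of |AI| are compared by all pairwise two-tailed Welch
t-tests with Holm correction (Bonferroni/BH selectable); classes with < 2
probes are excluded and reported.

## The synthetic cohort

`simulate_cohort` generates the structure the analysis assumes, with full
ground truth. Defaults define the standard test cohort:

* **Samples**: 3 sample sets (two emulating lymphoblastoid populations, one
  another cell type) × 20 females. Skew is a three-component mixture,
  skew = 0.5 + 0.5·Beta(a, b): 35% highly skewed (Beta(9, 1.5), mode ≈
  0.95), 35% moderately skewed (Beta(4, 4), ≈ 0.75), 30% near-random
  (Beta(1, 12), ≈ 0.54). An explicit `skew_values` override supports exact
  scenarios (e.g. all-random cohorts).
* **Genes**: 200 X-linked genes, 8 in a PAR1-like region (true %Xi uniform
  on [0.49, 0.75]); non-PAR genes 60% subject (75% at %Xi = 0, the rest
  uniform [0.02, 0.09]), 12% escape (uniform [0.20, 0.75]), the rest
  variable escape, laid out in geometric runs (mean length 6) so statuses
  cluster positionally. Variable subtypes: 17% bimodal (per-female %Xi 0 or
  uniform [0.3, 0.6]), 22% borderline (uniform [0.05, 0.16], straddling the
  10% cutoff), 61% heterogeneous (uniform [0, 0.30]). Four genes flip
  status in the second same-cell-type set (population-specific), four in
  the other cell type (cell-line-specific), and one non-training subject
  gene is imprinted — mono-allelic in every female regardless of skew, with
  the maximum probe count so the planted signal is observable in the small
  group-R subset.
* **Training sets**: 100 subject-training genes drawn preferentially from
  the %Xi = 0 subject pool (emulating genes vetted as silenced across
  studies) and 30 escape-training genes (all PAR1 plus sampled escapees);
  divergent and imprinted genes are never training genes.
* **Probes and noise**: 1–10 probes per gene, heterozygosity 0.3 per
  probe × female, 2000 autosomal background probes (10% carrying a fixed
  cis imbalance uniform on [0.05, 0.35] — this minority is what places the
  autosomal q90/q95/q99.5 where the calling rules need them). Intensities
  are log-normal (per-probe mean exp N(8, 0.8), per-row spread 0.6). AI
  noise is Gaussian with sd(I) = 0.02 + 0.15·exp(−I/300): the analysis
  noise on probes surviving the Tau filter is ≈ 0.02, and the decay
  component is confined to the low-intensity regime the filter exists to
  remove. Observed fractions truncate to [0, 1]. Heterozygote genomic-DNA
  ratios are N(0.5, 0.01) except a 2% artifact minority at 0.75–0.92.
* **ChIP**: per mark, promoter (2 probes) and gene-body (80 probes — 40×
  more) |AI| drawn per expression class with means decreasing from the most
  silenced class (0.30) to PAR1-range escapees (0.08), sd 0.05 — the
  anticorrelation with %Xi the class comparison is designed to detect.

All randomness flows from one seeded generator; identical config + seed
gives byte-identical tables.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-specific affinity biases and cross-
hybridisation, linkage between nearby SNPs, expression-level differences
between genes beyond the intensity model, population allele-frequency
structure (heterozygosity is i.i.d.), raw two-channel fluorescence and its
polynomial normalisation, and read-count (binomial) noise. Recovery rates
on this cohort are best-case figures for a well-normalised array.

## Numerical choices

Round-trip tolerance 1e-9 absolute on the identifiable domain; comparisons
against published 4-decimal values at printed precision. The decay fit
bounds parameters to [0, 0.5] × [0, 0.5] × (0, ∞) and raises a degenerate-
fit error for constant AI or a non-decaying optimum. Regression-based
group-2 boundaries clip into [0, 0.5] and re-sort on inversion. Zero-spread
Grubbs defines Z = 0 (nothing flagged); n < 3 returns a not-applicable
marker. Zero expected adjacency counts exclude the pair with a warning.
Genic-fraction comparisons use `fractions.Fraction`. Output tables are
written with fixed float formatting (`%.6g`) and a config-hash + seed
header so identical inputs give byte-identical files.

Test problem sizes: the standard cohort (60 females, 200 X genes, ~3100
probes, ~184k rows) exercises end-to-end recovery; reduced cohorts (5–8
females/set, 40–80 genes) cover determinism, degenerate and CLI paths; the
null calibrations use 2000 two-probe genes and 20 ChIP replicates; the Tau
recovery fit uses 5000 probes.

## Known limitations

* %Xi above the Xa level is unidentifiable (reciprocal fold); reported %Xi
  saturates at 1.
* Weakly skewed group-2 females (s ≲ 0.6) carry an escape/subject margin of
  ~0.01 AI at the 10% cutoff, so their individual calls are noise-limited;
  the genic fraction rule absorbs most, but not all, of this.
* The group-2 regression inherits the linearity of the model; strong
  per-gene intensity-noise heterogeneity would bias its slope.
* The decision tree for cross-set categories assumes exactly two
  same-cell-type sets plus one other.
* Imprinting detection requires the gene to be informative (≥ 2 probes) in
  group-R females, a small subset of any skew-rich cohort.
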