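# Methods

This note records the models and procedures `ctcdx` implements, the
conventions chosen where a published description leaves room, and what the
synthetic data does and does not establish.

## CTC identification and enumeration

A candidate cell is scored on six criteria: (c1) abnormal karyotype,
(c2) nucleus-to-cell area ratio > 0.8, (c3) diameter > 15 µm,
(c4) hyperchromatic/unevenly stained nucleus, (c5) irregular nuclear
membrane, (c6) large nucleoli. The call is CTC when ≥ 4 criteria hold, or
when an override feature — large nucleoli or abnormal nuclear division —
co-occurs with ≥ 2 of the criteria *other than* the trigger. Abnormal
nuclear division is an override feature only, not a seventh criterion, so
when it triggers, any two of c1–c6 qualify; when large nucleoli triggers,
two of c1–c5 are required.

Conventions adopted:

* **Ratio semantics.** The "nucleoplasma ratio" is read as the
  nucleus-to-whole-cell area ratio, which is the only reading under which a
  0.8 threshold below 1 expresses nuclear dominance. Values outside [0, 1]
  are rejected as data errors rather than clamped.
* **Strict thresholds.** c2 and c3 use strict inequalities: a ratio of
  exactly 0.8 or a diameter of exactly 15.0 µm does not satisfy the
  criterion.
* **Cluster handling.** Cells sharing a cluster id (cluster size ≥ 2) form
  one circulating tumour microembolus (CTM), counted once; cluster members
  are excluded from the single-cell CTC count, and downstream diagnostics
  use the CTC count only. An orphan cluster id (one cell) is treated as a
  singleton. Whether cluster members should also increment the CTC count is
  genuinely open; this choice keeps the two counts disjoint and auditable.

No imputation is performed: a missing feature is an error naming the field.

## Diagnostic statistics

ROC curves are empirical, one operating point per distinct score, with
trapezoidal AUC. This equals the tie-corrected Mann–Whitney statistic
U/(n₁n₂) exactly — an identity the test suite asserts to 1 × 10⁻¹² across
random cohorts. AUC confidence intervals use the Hanley–McNeil standard
error. Paired AUC comparison is DeLong's covariance-based z test (verified
against a sign-flip permutation oracle); unpaired comparison uses a normal
test on Hanley–McNeil SEs.

The operating cutoff maximises the Youden index J = se + sp − 1 over
midpoints between consecutive distinct observed scores (plus the degenerate
all-positive/all-negative rules). Cutoffs are therefore half-integers over
integer counts, e.g. 2.5 cells/5 mL means positive = ≥ 3 cells. Ties in J
break toward the lower cutoff — the more sensitive rule, appropriate in a
screening context. Positivity is always strict: score > cutoff.

Confusion-matrix ratios with zero denominators are reported as NaN
(undefined), never 0. PPV and NPV equal the Bayes-rule values at the
cohort's prevalence by construction (asserted in tests).

Logistic co-factor models are maximum-likelihood fits (statsmodels), with
object-typed columns dummy-coded against a caller-chosen reference level
(conventionally solid nodules, CTC-negative, Lung-RADS 2). Perfect or
quasi-separation is detected (failed Newton step, or standard errors above
50 on the log-OR scale) and flagged; affected intervals are reported as
unbounded rather than silently truncated. Group comparisons use the
chi-squared test without continuity correction by default (matching common
statistical-package defaults; a flag enables it) and the two-sided
Mann–Whitney U for count data.

## Somatic filter cascade

Read tier, per read overlapping a candidate site: reject when MAPQ < 20,
when the alignment is secondary, when fewer than 20 aligned bases flank the
site on either side within the read (SHORT_FLANK), or when any covered
flank base mismatches the reference (FLANK_MISMATCH). The variant base
itself is exempt from the mismatch check; an insertion or deletion touching
the flank counts as a mismatch (strictest reading of "no mismatches").
SHORT_FLANK and FLANK_MISMATCH are deliberately disjoint: positions beyond
the read's span are a flank-length failure, not a mismatch, so disabling
one filter never implicitly disables the other.

Depth, alt count and VAF are then recomputed from qualifying reads only —
read-tier failures disqualify individual reads, not whole variants. Variant
tier: DEPTH when qualifying depth < 20 (configurable to count alt reads
instead; the depth-based reading is consistent with observed call tables
whose total depths range 24–2028 while alt counts go as low as 8), LOW_VAF
when VAF < 0.2, POP_AF when any of the four population databases exceeds
0.01, IN_CONTROL when an identical chrom/pos/ref/alt record exists in the
matched white-blood-cell control (any VAF — germline subtraction),
SYNONYMOUS by annotated consequence. All applicable flags accumulate, so
the outcome is independent of filter order, and every removed variant
carries at least one reason.

**Failure attribution.** When recomputed support sinks a variant, the
cascade attributes the failure to any single read filter whose disabling
alone would rescue it and records that filter's code as the reason;
otherwise DEPTH/LOW_VAF are recorded from the fully filtered values. This
makes audit tables actionable (a variant killed by low-MAPQ support says
so) and gives "disable one filter, re-admit its artifact" semantics exactly.

LOH is flagged at VAF ≥ 0.95, boundary inclusive — "approximately 1" is not
quantified anywhere, and 0.95 keeps e.g. 192/193 = 0.995 and 48/49 = 0.980
in while excluding ordinary heterozygous fractions. Coordinates are 1-based
VCF convention throughout.

## Cross-sample comparison

Gene-level presence means ≥ 1 passing variant in the gene; multiplicity is
ignored (the shared/exclusive Venn logic is presence-based). Shared genes
are the intersection over included malignant samples; exclusive genes
subtract the union over benign samples. Locus concordance requires exact
(chrom, pos, ref, alt) agreement in *every* included malignant sample and
absence from every benign sample. Sample QC keeps samples whose fraction of
target covered ≥ 20× is at least 0.3 by default — a stipulated convention
(no published threshold exists); the threshold is configurable, and raising
it never enlarges the included set (asserted as a property).

Enrichment is one-sided over-representation: Fisher's exact test
(hypergeometric upper tail) per pathway over the user-supplied GMT's
background, Benjamini–Hochberg correction across tested pathways. Genes
outside the background are dropped with a warning rather than silently
shrinking the universe.

## Meta-analysis

Default pooling is Mantel–Haenszel fixed effect — the conventional default
for dichotomous outcomes — with the Robins–Breslow–Greenland variance for
the pooled log-OR; inverse-variance fixed and DerSimonian–Laird random
effects are available. Per-study ORs use ad/bc with Woolf CIs and the
Haldane–Anscombe 0.5 correction (flagged) when a cell is zero. Q, I² and τ²
are reported for every method. Exposure arrives pre-dichotomised (e.g. a
dominant genotype model), keeping the module genotype-model-agnostic.
Source 2×2 tables for any particular published pooled estimate must be
supplied by the user as TSV; none ship with the package.

## Synthetic data: what it emulates, and what it does not

* **Cell tables** construct each cell to satisfy an exact number of
  criteria (tumour-like ≥ 4, background ≤ 2, background never carrying
  abnormal nuclear division), so classification truth is known per row.
  Real cells do not come with guaranteed criterion counts; passing tests
  show the rule is implemented correctly, not that the rule separates real
  cell populations.
* **Cohorts** default to negative-binomial counts (malignant mean 3.0,
  benign mean 1.2, dispersion 1.0 — stipulated; no per-patient counts are
  published) and offer a deterministic mode placing counts of 4 above and 1
  below the cutoff so the 2×2 at 2.5 (by default 51/97 and 5/25, a
  122-patient screening design) is exact and the Youden midpoint is exactly
  2.5. Lung-RADS and nodule-nature covariates follow clinical-cohort-like
  frequencies.
* **Read sets** are 100-bp perfect-match reads on a 2-kb random contig
  (sites spaced 120 bp so flanks never interact), 30 reads per site, alt
  fraction rounded to the designed VAF. Each of the eight artifact classes
  violates exactly one filter: all-reads MAPQ 10; all-reads secondary;
  variant at read offset 10; a designed mismatch 5 bp into the left flank;
  12-read coverage; alt fraction 1/6; population AF 0.05 in all four
  databases; synonymous consequence. Germline sites appear in both VCFs at
  VAF 0.5 with population AF 0.001, so control subtraction — not the
  population filter — removes them. There is no sequencing-error model, no
  amplification bias (real whole-genome-amplified CTC libraries are far
  noisier), and no FASTQ/alignment step; genomic coordinates are opaque toy
  labels, never mapped to a real assembly.
* **Multi-sample sets** give 6 malignant + 2 benign samples, two malignant
  with designed low coverage (excluded by QC), the remaining four sharing
  three TP53-like loci with one VAF-1 locus per sample.

## Problem sizes and numerical choices

Default problem sizes (122-patient cohorts, 30× site depth, 2-kb contigs,
100-cohort property sweeps, n = 2000 × 10 seeds for logistic recovery) were
chosen so every designed effect is comfortably detectable while the whole
suite runs in seconds. Determinism: every generator and the end-to-end
pipeline are exact functions of their seed; the acceptance script derives
all sub-seeds from its `--seed` (kept below 2³¹). Floating-point identities
(AUC = U statistic, MH OR = formula) are asserted to 1 × 10⁻¹²; stochastic
recoveries (logistic log-OR) to the design tolerance ±0.15 on the mean.

## Known limitations

* The morphology stage consumes pathologist-scored features; there is no
  image processing, and inter-observer variability is out of scope.
* Published cohort-level AUCs and logistic odds ratios from any particular
  clinical dataset are not reproduction targets — they require per-patient
  data that is not public; the statistics are validated on synthetic
  cohorts and against internal oracles instead.
* The cascade consumes caller output (VCF) and alignments (SAM); it does
  not realign, call variants, or compute annotations.
* The enrichment stage treats the supplied GMT as the annotation universe;
  results depend entirely on that input.
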