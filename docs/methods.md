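# Methods

## Model and assumptions

The package operationalizes a repression model of enhancer methylation:
maximal expression of a target gene requires both an unmethylated promoter
and an unmethylated super-enhancer (SE), so methylation gained over an SE
in disease should *reduce* the expression of its in-cis targets, and
methylation lost should increase it. Three consequences shape the design:

1. methylation–expression linkage is tested by **rank correlation with a
   negative-sign requirement**, not by symmetric association;
2. sequencing-derived methylation (peak intersection bp) and expression
   (normalized counts) live on incommensurable scales, so **only
   rank-based statistics** (Wilcoxon, Kendall tau-b) are used across data
   types;
3. candidate SEs come from an external catalog of related tissues; the
   pipeline's job is to *filter* that catalog with the cohort's own
   methylation and expression data, not to call SEs de novo.

## Quantification

Coordinates are 0-based half-open (BED) everywhere; readers convert on
input. Peak sets are normalized by merging overlapping **and touching**
intervals — base-pair coverage is unchanged and downstream counts never
double-count. Per-SE methylation of sample *s* is the net intersection
length of the SE with the sample's merged peaks, stored as raw bp (not a
fraction; the rank tests are invariant to per-region scaling). Genome
tiles (default width 100 bp, last tile truncated) get a binary status: 1
iff any peak overlaps the tile. Promoter windows are strand-relative,
−1500/+500 bp around the TSS, mirrored on the minus strand and clamped to
chromosome bounds (small simulated genomes hit edges often; clamping keeps
those genes testable). Catalog entries that repeat the same coordinates
(the same SE contributed by different source cell lines) keep separate
rows and pair with genes independently.

## Statistical tests

* **Fisher exact (tiles).** Two-sided p sums the probabilities of all
  margin-matched tables whose hypergeometric probability is at most the
  observed table's (the common exact-test convention; conventions differ,
  so this one is stated). A zero margin yields p = 1. Tiles methylated in
  no sample or in every sample are excluded *before* FDR so uninformative
  tiles do not dilute the correction; the exclusion count is logged.
* **Wilcoxon rank-sum (SEs).** Exact by enumeration when there are no ties
  and n₁+n₂ ≤ 12; otherwise the normal approximation with tie and
  continuity corrections. All-identical inputs give p = 1. Direction
  (hyper/hypo) comes from the group mean difference; an exact mean tie
  falls back to the median, and a full tie leaves direction "none" even at
  q < α (logged).
* **Kendall tau-b (pairs).** Tau-b is used because intersection-length
  data are tie-heavy (many exact zeros). The p-value is the tie-adjusted
  normal approximation on S with a continuity correction of 1 — chosen and
  implemented in-package because scipy's asymptotic mode applies no
  continuity correction. Pairs with missing values are dropped pairwise
  (≥3 complete pairs required); a zero-variance vector gives a missing
  statistic with p = 1. Because the approximation is used throughout,
  borderline calls with q ≈ α may differ from an exact-enumeration
  implementation.
* **BH FDR.** Step-up, computed within each scan separately (tiles, SEs,
  SE–gene correlations, promoter correlations are four separate
  corrections). For SE–gene pairs the default scope is one **joint**
  correction across all candidate pairs with complete data; a per-SE scope
  is available (`fdr_scope="per-se"`) since either reading of
  "FDR-corrected" is defensible. Missing p propagate missing q and do not
  count toward the number of tests.
* **Projection overlap test.** The enrichment of regions in a catalog is
  measured by projecting each query interval to its midpoint and counting
  hits in the (merged) reference; under uniform placement the hit
  probability is the reference's genome-coverage fraction, giving a
  binomial upper-tail p and an observed/expected ratio. This is one of
  several defensible overlap statistics; it was chosen for having an exact
  finite-sample null and no tuning constants.

## Pairing conventions

Eligibility uses **TSS-to-nearest-SE-edge** distance (0 inside the SE) with
a 1 Mb window. The TSS-to-SE-midpoint distance is reported as a separate
descriptive column because descriptive distances in the literature can
exceed the eligibility window, implying a midpoint-style metric; keeping
both avoids ambiguity. Cross-chromosome distances are infinite sentinels,
never errors — such gene–SE combinations are simply skipped.

Validation reads "minimum correlation coefficient" as the most-negative
tau and additionally requires tau < 0, because a positively correlated
probe cannot support the repression model even at small p; the sign
requirement is switchable (`require_negative=False`) for sensitivity
analyses. Validation uses unadjusted p < 0.05 (no FDR at this stage) and
only annotates pairs — discovery pass/fail flags are never altered.

## Synthetic cohorts

The generator emulates the statistical structure of a methylation-capture
cohort, not its sequence content. Per SE and sample, a methylated fraction
is drawn from a Beta distribution with mean f₀ (controls and null SEs) or
f₀ ± δ (cases at hyper-/hypomethylated SEs) and concentration κ = 50
(per-sample sd ≈ 0.065 at f₀ = 0.3), then realized *exactly* as
non-overlapping peaks covering round(f·L) bp of the SE — so rank tests
face realistic sampling overlap while the planted signal is not diluted by
placement error. Background peaks (3 per Mb, 0.5–2 kb) are placed away
from SEs and promoter windows so planted fractions stay exact. Target-gene
expression is a − b·f + N(0, σ) (defaults a = 10, b = 10, σ = 1.6, giving
tau ≈ −0.5 between methylation and expression at the default effect size);
artifact genes use +b·f (planted positive links that the sign filter must
remove); decoys are independent noise. Promoter methylation is low
(mean 0.05) for most genes with a 10% hypermethylated subset (mean 0.5).
The validation cohort is re-drawn from the same truth with fresh samples;
probes (4 per SE, uniform positions) report the per-sample SE fraction
plus N(0, 0.05) clipped to [0, 1].

Default scale mirrors a 47-case / 25-control discovery cohort with a
22/6 validation cohort and 200 SEs of 5–20 kb on 2 × 10 Mb chromosomes.
The recovery-study configuration (`acceptance_config`) enlarges the genome
to 6 × 30 Mb and enforces ≥ 2.2 Mb spacing between planted DM-SEs so that
each target gene's 1 Mb window contains exactly one DM-SE; without the
spacing, two same-direction DM-SEs near one gene would correlate with it
equally (their methylation co-varies with disease status), and pair-level
false-discovery accounting against the planted truth would be ill-posed.
This is a property of the evaluation design, not of the method.

What the simulator does **not** model: CpG density and sequence
composition, read-level noise and peak-caller artifacts, copy-number or
purity effects on methylation signal, correlated gene networks, batch
effects, or array probe biases. Passing recovery tests therefore shows the
pipeline's statistics behave correctly under the stated generative model —
monotone repression with independent noise — not that real cohorts meet
those assumptions.

## Numerical and reproducibility choices

* Exact-vs-approximate thresholds: Wilcoxon enumerates ≤ 12 observations
  without ties; Fisher delegates to scipy's exact hypergeometric
  summation at any size.
* Result tables are written with 6-significant-digit floats, fixed column
  order, and rows sorted by (chrom, start, gene_id), so identical inputs
  give byte-identical files; `run-all` is fully deterministic and the
  `--workers` flag is an opaque contract (accepted, results identical for
  any value). Partial outputs are removed when a stage fails.
* The simulator derives all randomness from a single `numpy` Generator
  seeded from the config; identical config + seed reproduce every file
  byte-for-byte.
* Degenerate inputs are defined, not errors: Jaccard of two empty sets is
  0; an empty query gives a missing overlap ratio; a chromosome absent
  from a peak set contributes 0 bp.

## Known limitations

* The 1 Mb window and the promoter geometry are heuristics; no
  chromatin-contact data is used to assign targets.
* Per-SE testing ignores spatial structure — adjacent DM tiles are not
  merged into regions, and SE boundaries are taken as given.
* Kendall p-values are approximate (see above); with n < ~10 samples the
  approximation is rough and the pipeline is not recommended at such
  sizes.
* The tile scan's Fisher test treats samples as exchangeable within
  groups; covariates (age, batch, purity) are not adjusted for.
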