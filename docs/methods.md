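# Methods

This note documents the models, conventions and design decisions behind
`csfbench`, in the order the pipeline runs.

## Input conventions

Zero or empty intensity cells mean "not detected"; every downstream
computation treats detection as the presence of a quantified intensity
and carries missing values explicitly (never imputed). Reverse-decoy
(`REV__`), contaminant (`CON__`) and spike-in standard accessions
(invertase SUC2, iRT peptides) are stripped at parse time — they are
process controls, not analytes. All analysis is performed on
log2-transformed intensities; wherever intensities are aggregated
(protein groups, glycoproteins, duplicate peptide rows) the summation
happens on the raw scale first, and the log2 is taken of the sum.

## Protein grouping

Search-engine output assigns peptides to (possibly many) protein
accessions; the grouping algorithm here is the package's own definition
of parsimony-style assembly and is deliberately order-independent:

1. proteins with identical observed peptide sets merge into one group
   (group id = lexicographically smallest member accession);
2. a protein whose peptide set is a strict subset of another's is
   absorbed into it (largest superset wins, ties lexicographic);
3. peptides still shared between surviving groups are assigned uniquely
   to the group with the most distinct candidate peptides (ties
   lexicographic);
4. groups with fewer than two assigned peptides are dropped.

Step 3 makes group peptide sets disjoint, so the per-sample group
intensity (sum of assigned peptide intensities) never double-counts and
total group intensity is bounded by total peptide intensity — an
invariant the tests re-check from written files.

## Glycosite calling

PNGase F converts glycosylated Asn to Asp (+0.984 Da), so a deamidation
site marks a candidate glycosite. A site is accepted iff its
localization probability is **strictly** greater than the threshold
(default 0.8) and its protein position starts a sequon N-[!P]-[S/T/C] in
the reference sequence. The motif is evaluated on the protein, not the
peptide, so sequons spanning peptide C-termini are handled; Cys at +2 is
accepted even though N-X-C sequons are rare. Glycoproteins keep
single-site representation (no two-peptide rule): glyco enrichment
characteristically yields one peptide per site.

## Physicochemical profiles

* Molecular weight: sum of monoisotopic residue masses plus one water
  (mass-spectrometry context).
* GRAVY: arithmetic mean of Kyte–Doolittle hydropathy — this scale is
  the definition of the score, so it is fixed.
* pI: root of the Henderson–Hasselbalch net charge (N/C termini plus
  D, E, C, Y, H, K, R side chains) found by bisection on pH ∈ [0, 14] to
  a width of 1e-6; the pKa table defaults to Bjellqvist values and can
  be swapped (the table ships as TSV alongside the masses and
  hydropathies in `csfbench/data/`).
* Reference digest: trypsin cleaves after K/R, by default not before P
  (toggleable, since search engines differ), with up to two missed
  cleavages matching a typical search configuration; peptides are
  filtered to a 7–35-residue detectability window and deduplicated
  proteome-wide by default. Whether a published reference digest
  deduplicated or which window it used is generally unknowable, so both
  are configuration.
* Distribution comparisons use the package's rank-sum test per
  (property, method) against the pooled other methods and against the
  reference, with a difference-of-medians shift estimate and BH across
  the whole comparison family.

## Statistics

The Wilcoxon signed-rank test drops zero differences (the classic
convention and the default of R's `wilcox.test`), uses the exact
sign-assignment null when n ≤ 12 without ties, and otherwise a tie- and
continuity-corrected normal approximation; the mode used is recorded in
the result. The rank-sum test mirrors this with the labeling null.
Fisher's exact test reports the two-sided hypergeometric-tail p (with
R's 1 + 1e-7 relative tolerance) and the conditional maximum-likelihood
odds ratio, with ±∞ kept honest for zero off-diagonal cells (display
layers may clamp; analysis tables do not). BH adjustment is the step-up
procedure. Spearman is mid-rank Pearson on pairwise-complete pairs,
undefined (NaN) below 3 pairs or under zero rank variance.

## Fraction classification

"Unique" = detected (≥ 1 sample) in exactly one workflow. "Elevated in
W" requires, against **each** other workflow V: both-side detection in
≥ 50% of samples, at least 4 complete patient pairs, BH-adjusted
signed-rank p < 0.05 *within the (W, V) protein family*, and a positive
mean paired log2 difference (the log2FC definition). The BH family is
per workflow-pair across proteins — this matches the testing structure
and keeps families homogeneous; the ≥ 50% rule is applied within the
two workflows being compared rather than all five simultaneously.
A protein can be elevated in at most one workflow, since the mean paired
difference cannot be positive in both directions.

Over-representation uses per-category 2×2 tables of the enriched set
against the union of proteins detected across all workflows, Fisher's
exact test, BH across categories, and log2 conditional-MLE odds ratios
(sign = direction). Raw subcellular labels are first consolidated into
eleven categories (Nucleus, Cytoskeleton, Cell adhesion, Cytoplasmic
bodies etc. absorb their constituent structures; the packaged scheme
TSV lists the mapping); unmapped labels are dropped with a logged
count. Gene-set (GMT) over-representation reuses the same machinery —
no ontology traversal.

## Variance partitioning

Per protein, y = μ + a_method + b_patient + ε with independent zero-mean
random intercepts, estimated by EM-REML (non-negative by construction;
convergence at |ΔlogLik| < 1e-8, ≤ 500 iterations). Missing cells are
omitted observations. Proteins with a single represented method or
patient, or fewer than 6 observations, are skipped with a reason; a
constant response returns fractions (0, 0, 1) flagged degenerate. For
complete balanced designs the two incidence Gram matrices commute, so
the fit runs in a fixed common eigenbasis at O(n) per iteration
(verified by an explicit commutation check); unbalanced designs use
dense Cholesky algebra. Balanced fits agree with lme4 and with Henderson
ANOVA moments to numerical precision.

Two summaries are reported: per-component distribution statistics across
proteins (medians of the three components need not sum to 100% — a
documented non-property), and a dataset-level *pooled* fraction (sum of
per-protein components, then the ratio). Averaging per-protein
*fractions* is biased low for the method component (a Jensen effect:
with only five method levels the per-protein method variance estimate is
noisy and the ratio is concave in it), so parameter-recovery comparisons
against a generative truth use the pooled fraction.

## NTA

Bin counts are multiplied by the sample's dilution factor, then
summarized per bin as mean and standard error (sd/√n, n−1 denominator)
across video replicates; SE is missing for a single video. Fractions are
merged by exact bin-center match (instrument grids are fixed; no
interpolation), as an outer join.

## Synthetic cohorts

The generator emulates the structure the analyses assume, not raw
spectra:

* **Abundance model.** Protein log2 abundance y = μ_p + a_m + b_i + δ +
  ε with μ_p ~ N(25, 2²) (typical label-free log2 intensity scale) and
  the three components drawn to match configured variance fractions of a
  configured within-protein variance. Defaults are fractions
  (0.6, 0.2, 0.2) of variance 1.0 — method-dominated, as observed in
  real multi-workflow comparisons.
* **Peptides.** Each protein's raw intensity is split over its in-range
  tryptic peptides by a Dirichlet(1) share vector, so summation recovers
  the protein exactly in the noise-free limit (a tested degenerate
  case).
* **Dropout.** Missing-not-at-random: detection probability is a
  logistic function of peptide log2 intensity (midpoint 18, steepness 1
  by default), mimicking MS detection limits; this drives realistic
  tier and overlap structure.
* **Glyco evidence.** Deamidation sites are emitted at every sequon with
  localization probabilities from a mixture (Beta(20, 1) with weight
  0.75, else Beta(2, 2)) plus non-sequon decoy sites with Beta(2, 2)
  probabilities; the truth records all sequons of the final sequence,
  including chance-formed ones.
* **Experiment configs.** Three canned configurations define the
  simulation studies. *Recovery*: balanced complete 5 × 19 design,
  fractions (0.6, 0.2, 0.2), no dropout. *Planted*: 10% of proteins
  shifted +1.5 log2 units in one workflow; because planted shifts are
  the only admissible method-level signal for elevated-calling, the
  random method component is zero and patient/residual split a
  within-protein variance of 0.5 (residual log2 sd ≈ 0.5, a typical
  label-free replicate spread). *Null*: the same structure without
  planted effects — the correct null for checking BH control of
  elevated calls.
* **Determinism.** One seed feeds a `SeedSequence` tree with one child
  stream per artifact; the same seed reproduces every file byte for
  byte.

What the generator does **not** emulate: peptide-level measurement error
independent of the protein (peptide intensities are exact shares),
correlated proteins, isoform ambiguity / shared peptides across
proteins, chromatographic or charge-state effects, and real annotation
noise. Passing tests therefore demonstrate correctness of the
implemented procedures and their calibration under the stated model, not
performance on any particular real cohort.

## Problem sizes

Simulation studies use 200 proteins × 19 patients × 5 workflows per
dataset; the variance recovery uses 20 replicate datasets, the null
calibration 100, chosen as the smallest sizes at which the Monte-Carlo
error of the reported summaries is comfortably below the tolerances
asserted. Exhaustive oracle sweeps cover all digest inputs over
{G, K, R, P} up to length 7–8, all 2×2 tables with grand total ≤ 30, and
full enumeration nulls for both Wilcoxon tests up to n = 10.

## Known limitations

* The grouping algorithm is one defensible parsimony definition;
  razor-peptide or multi-assignment variants would shift shared-peptide
  quantification.
* The elevated-protein test family (per workflow pair) is one of
  several defensible BH families.
* EM-REML is slow near the boundary of the parameter space; degenerate
  designs are gated rather than fitted.
* No normalization between samples is applied anywhere — intentionally,
  since group quantification feeds directly off summed raw intensities.
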