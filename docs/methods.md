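# Methods

## Copy-number quantification

Standard curves are ordinary least squares of mean Ct on log10 of the known
plasmid quantity (copies/reaction). The slope determines amplification
efficiency, `E = 10^(−1/slope) − 1`; a perfectly doubling assay has slope
−1/log10(2) ≈ −3.3219 and E = 1. Curves with non-negative slope are
rejected as invalid rather than silently inverted. The linear range is
recorded as the span of fitted quantities and inversions outside it can be
flagged as extrapolation.

Copy number per cell uses the duplex design: target and the APOB reference
(assumed exactly 2 copies per diploid genome) are measured in one
reaction, each Ct is inverted through its own curve, and

    copies = 2 × mean(q_target over replicates) / mean(q_APOB over replicates).

Replicates are averaged on the **quantity** scale for copy number but on
the **Ct** scale for expression ΔCt, mirroring instrument-software
convention; the replicate CV is reported for QC. The integer call is the
nearest integer; estimates farther than 0.3 copies from it keep the call
but carry `within_tolerance=False`, and downstream genotype interpretation
should treat those as low-confidence. Undetected wells are represented
explicitly (`undetected_flag`), never as a sentinel Ct, and an undetected
target is called 0 copies. RNA input above or at 200 ng/reaction fails the
linear-range QC gate (the bound is strict).

Relative expression is the comparative ΔCt method without a calibrator
sample: `RQ = 2^(−(Ct_target − Ct_GAPDH))`, reported ×1000. This is a
documented convention choice — instrument software is not emulated — and
it reproduces the panel's published scale.

## Deletion-history classification

The classifier is a total map on the 3×3 grid of
(polymorphic-gene copies, neighbor-gene copies), both in {0,1,2}; see the
README table. Design points:

* **Somatic loss** is inferred purely from the neighbor gene: copies
  `2 − n` imply `n` somatic arm losses, because no germline deletion
  polymorphism is known for the neighbor.
* **Variant D** (1,1) is flagged ambiguous with germline set {1,2}: the
  somatically lost haplotype may have carried either allele.
* **Variant B** (0,1) is likewise reported with compatible germline set
  {0,1}. The modal reading — one inherited null plus one somatic loss — is
  what the surviving-null observation suggests under realistic allele
  frequencies, but an inherited double-null that lost one null haplotype
  somatically is observationally identical, and an exhaustive enumeration
  of (germline pair × somatic loss) confirms both generate (0,1). Variant
  labels and counts are unaffected by this bookkeeping.
* **Impossible cells** (2,1), (2,0), (1,0) — more present copies than
  surviving haplotypes — are reported as `INCONSISTENT` and excluded (with
  a count) from variant summaries rather than raised, since they indicate
  assay noise or an unrecognized reference/neighbor polymorphism.
* **Null genotype** is zero polymorphic-gene copies. Concordance with
  expression uses a zero tolerance of 0.5 on the ×1000 scale, chosen to
  sit between true zeros (0.00) and the smallest genuine signal in the
  cohort panel (1.97) with margin on both sides.
* **Cytogenetic reconciliation** treats reported loss intervals as
  advisory: when interval coverage of the locus band contradicts the
  neighbor-copy evidence the call is kept and a discordance flag appended,
  because the classification chain is driven by measured copy numbers.

Cytoband coverage uses static telomere→centromere band-order lists for
chr1p and chr22q restricted to bands occurring in the cohort descriptors
plus the two gene loci; any other band yields `"unknown"` rather than a
guess. Median summaries use the mean-of-central-order-statistics rule,
with a separate one-decimal convenience value rounded half away from zero
(this reproduces a printed 9.2 from a raw 9.15; the raw value is always
reported alongside).

## Expression statistics

* **DE calling**: upstream pipelines for the original RNA-seq were
  external, so the package defines its own documented procedure: log2 fold
  change of group means with pseudocount c (default 1 for FPKM), Welch's
  t-test on `log2(x + c)`, Benjamini–Hochberg adjustment across all tested
  genes, and significance only when |log2FC| ≥ 1 **and** FDR ≤ 0.05.
  Constant genes get p = 1. Published DEG counts depend on the deposited
  RNA-seq data and are not recomputed here.
* **Presence/absence**: a gene is "expressed" in a group when its group
  mean exceeds a threshold (default 1.0 FPKM — a conventional choice, not
  stated by the source study; exposed as a parameter).
* **Correlation**: sample Pearson r; 95% CI by Fisher z-transform
  `atanh(r) ± z_{0.975}/√(n−3)`; two-sided p from the t distribution with
  n−2 df. Requires n ≥ 4 and non-constant vectors.
* **Dosage**: group means keyed by integer copy and ratios of adjacent
  populated groups; exactly proportional input gives exactly proportional
  ratios.
* **Mutual exclusivity**: quadrant counts at per-gene "low" thresholds
  (default: 0 on the ×1000 scale for a deletion-polymorphic gene, lower
  quartile otherwise); exclusivity means an empty low/low quadrant.
* **PCA**: samples as observations, centered, SVD-based, with a
  deterministic sign convention (largest-magnitude loading positive per
  component) so embeddings are reproducible across backends.

## Synthetic cohorts

The generator emulates the structure the inference assumes: germline
haplotypes carry the polymorphic gene's null allele independently with
frequency q (HWE genotype frequencies q², 2q(1−q), (1−q)²; default
q = 0.5, a testing default, not a population estimate); a somatic event
removes exactly one uniformly chosen haplotype with probability
`p_somatic_arm_loss` (default 1.0 — the modeled subtype carries the arm
loss), with a separate `p_second_loss` for the rare double-loss history;
recurrent tumors are drawn conditional on the final null genotype with
probability `recurrence_null_enrichment` (default 1.0, matching the
observed perfect association in a 16-tumor cohort — an assumption of the
simulation, not an estimate). Panel expression is copies ×
`per_copy_expression` × lognormal noise (CV default 0.2), with zero copies
producing exactly zero transcript; plates draw Ct from per-assay
log-linear curves with Gaussian noise (default sd 0.15, chosen for test
power — the source protocol reports replicate counts but not noise
magnitudes) and 3 replicates; each assay also emits a 5-point 10-fold
dilution series. One seed drives independent spawned streams per stage,
so bundles are bit-for-bit reproducible and stages can be rerun in
isolation.

What the simulator does **not** model: read-level RNA-seq, sequence
content, batch effects, tumor purity/subclonality (copy numbers are
clonal integers), qPCR inhibitors or efficiency drift, and
reference-gene polymorphism. Passing recovery tests therefore demonstrate
correctness of the inference chain under its stated assumptions, not
robustness to those real-data complications.

## Problem sizes and numerical choices

Statistical guarantees are exercised at sizes chosen to make sampling
error negligible while keeping the suite quick: 1,000 simulated assays
for copy-call recovery (≥95% at Ct sd 0.15), 10,000 individuals for HWE
recovery (3 SE bands), 200 fully null simulations of 2,000 genes × 8 vs 8
samples for FDR calibration, and 200 planted genes across 10 cohorts of
20 vs 20 for power (≥90% at |log2FC| = 2, log-scale sd 0.3). BH
adjustment is verified against the brute-force step-up definition on
seeded vectors of length ≤ 10. Floating-point conventions: medians snap
sub-1e-9 binary noise before half-away rounding; Pearson p is clamped to
0 at |r| = 1; copy-call tie-breaks follow Python's banker-rounding only
through `round()` on a continuous estimate whose tolerance flag makes
0.5-adjacent calls visible.

## Known limitations

* The variant scheme assumes the neighbor gene is never deleted in the
  germline; a rare neighbor polymorphism would masquerade as somatic loss.
* Integer copy calls assume near-diploid tumors and high tumor purity;
  admixture biases the continuous estimate toward 2.
* Variant D (and the B germline set) cannot be resolved without germline
  material; the package deliberately reports ranges instead of guessing.
* Cytoband parsing covers only the descriptor dialects found in the
  cohort tables, not full ISCN nomenclature.
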