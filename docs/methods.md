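# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Simulated experimental design

The generators emulate a knockdown experiment in `n_cell_lines` (default
2) cultured cell lines, each with one scrambled-shRNA control sample and
`n_kd_replicates` (default 2) knockdown samples — two independent shRNA
constructs, modeled as independent draws around the same shifted
expectation. All generators are pure functions of
(`SimulationConfig`, seed): each draws from its own seed stream, so
bit-identical outputs do not depend on which other generators ran.

Planted effects are chosen per gene, deterministically from the seed:

* every gene's CpGs share a baseline state — methylated (probability
  `meth_fraction` = 0.5) or unmethylated — so CpG-level planting
  fractions equal gene-level fractions;
* hypomethylation effects (`effect_fraction_hypo` = 0.10 of genes) are
  planted on baseline-methylated genes, hypermethylation
  (`effect_fraction_hyper` = 0.02) on unmethylated ones: a methylation
  change must have somewhere to go;
* a configurable fraction (`inverse_overlap_fraction` = 0.5) of the
  hypomethylated genes is also planted as upregulated, so the
  inverse-correlation candidate set has a known size;
* both cell lines carry the same planted sets (one perturbation applied
  to two lines); cross-line differences in the *calls* therefore reflect
  detection noise, which is exactly what the unique/shared Venn
  categories measure on synthetic data.

## Beta-value model

Array beta values are bimodal. Baseline betas are Beta distributed,
parameterized by mode and concentration: modes 0.70 (methylated) and 0.15
(unmethylated), concentration `beta_concentration` = 100, i.e. a
replicate s.d. of ≈ 0.03–0.05 — the scale of replicate scatter between
arrays of cultured isogenic lines. At planted CpGs the knockdown
expectation is the control expectation shifted by `delta_beta_effect`
(clipped into (0, 1)); knockdown draws are mean-parameterized at the
shifted value with the same concentration. The default effect is 0.5: an
effect locus moves from the methylated mode (~0.7) into the unmethylated
band (~0.2), the contrast a bisulfite lollipop validation shows for a
demethylated promoter.

**Boundary behaviour worth knowing.** The screen calls hypo only when the
knockdown mean crosses below the 0.35 methylation threshold. A planted
shift of exactly 0.35 from the 0.70 methylated mode places the knockdown
expectation *on* that threshold, so per-CpG sensitivity is ≈ 0.5–0.6
regardless of the noise level (more precision does not help — the
expectation itself sits on the decision boundary; the detection z-score
scales as 1.19/√concentration). Sensitivity at Δβ = 0.5 is ≈ 1.0 and the
false-call rate on null CpGs is ≈ 0 throughout; both are measured by the
acceptance script. Shifts below ~0.37 from a 0.70 baseline are
structurally hard for this rule; that is a property of the published
thresholds, not of the implementation.

## Differential-methylation screen

Methylated iff β ≥ 0.35 (boundary inclusive; the published wording is
contradictory at exactly 0.35, and with the Δβ ≥ 0.15 requirement the
convention never decides a differential call). Knockdown replicates are
averaged arithmetically. Missing betas exclude the probe from calling and
are counted. Gene aggregation: ≥ 1 supporting probe and no opposing probe;
genes with conflicting probes are excluded and reported (avoids listing a
gene as both hypo and hyper). Probes mapping to several genes
(semicolon-separated manifests) contribute to each. Promoter-only
filtering is available but off by default. QC clustering uses average
linkage on 1 − Pearson correlation (the Cluster 3.0 convention), drops
incomplete and constant rows, and never gates candidate selection.

## RNA-seq stage

* **TMM**: reference = sample whose upper-quartile count rate is closest
  to the mean; per-pair weighted trimmed mean of M-values (30% two-sided
  trim on M, 5% on A, delta-method binomial weights); factors rescaled to
  geometric mean 1. Matches edgeR's calcNormFactors to 8 decimals on a
  fixed fixture (frozen in the tests). Invariance to scaling a column is
  first-order only (the weights depend weakly on depth), as in edgeR.
* **RPKM** is computed from raw counts and raw library sizes (column
  sums; no effective-length correction).
* **Exact test**: conditional on the two group sums after linearly
  scaling counts to the geometric-mean effective library size and
  rounding (a simplification of quantile-based equalization; adequate
  because factors are near 1 in matched designs). Dispersion φ is fixed
  at 0.16 (BCV 0.4) by default — a deliberately conservative choice when
  the control arm is a single sample and φ cannot be estimated; with
  replicates in both arms a common φ can be estimated by conditional
  maximum likelihood (`dispersion="estimate"`). When analyzing simulated
  data whose φ is known, pass it: the test is then exactly calibrated
  (null rejection ≈ 5%, measured). A fixed 0.16 applied to data with true
  φ = 0.1 is conservative: the observed fold needed for p ≤ 0.05 in a
  1-vs-2 design rises from ≈ 2.6 to ≈ 3.3, and triple-filter sensitivity
  at planted log2FC = 2 drops from ≈ 0.90 to ≈ 0.69.
* **Filter**: RPKM ≥ 1 in ≥ 1 sample, |FC| ≥ 2 on TMM-scaled means with a
  prior count of 0.5 (no division by zero), raw p ≤ 0.05 as published; a
  BH-FDR column is emitted for users but does not gate.

## Integration

Gene identity is exact string match after upper-casing (no alias
resolution). Venn counts satisfy unique_a = n_a − shared and
union = n_a + n_b − shared by construction. Candidate ranking is purely
numeric — mean Δβ (descending), then mean |log2FC|, then gene ID — with
the fold ≥ 2.5-in-every-line shortlist rule; "biological function and
novelty" judgments are out of scope, so the shortlist length is just a
parameter (default 6).

## Bisulfite methylation index

Reads are clonal molecules over one unconverted amplicon. Per CpG:
CG → methylated, TG → unmethylated, anything else ambiguous (excluded
from both MI counts). Equal-length reads are compared in place; real
Sanger-derived reads within 20 bp of the reference length are aligned
end-to-end by edit distance (no affine gaps) with CpG positions lifted
through the alignment and indel-overlapping CpGs ambiguous. Two-sidedness
of the Fisher comparison is the standard convention (sum of all tables
with probability ≤ observed). Conversion failure is simulated only at
non-CpG cytosines (it biases conversion QC, not MI — a documented
simplification) at rate 0.005; the QC readout is the non-CpG C retention
rate. Default 20 reads per condition reflects a typical clone count for
Sanger validation and is configurable.

## qPCR

Expression: replicate Cts averaged arithmetically, then
fold = 2^−ΔΔCt against an internal reference gene and a calibrator
sample. ChIP: percent input is the primary readout with the input Ct
adjusted for its dilution (default 1%, a convention — echoed in the
output); fold-over-IgG reported when an IgG control exists; the
knockdown/control ratio of mean percent input is labeled "dis-enriched"
below 1. Reported spreads are delta-method approximations (ln2·SD(Ct)
relative error) and are labeled approximate. Ct model in simulation:
baseline − log2(quantity) + Gaussian cycle noise (s.d. 0.15 cycles),
which is multiplicative efficiency noise on the template scale.

## Survival

Patients split at the median (or lower/upper quartile) of a single gene
or of the unweighted mean of a gene set, after per-gene z-scaling by
default (cross-gene scales differ; scaling is a flag). Ties go to the low
group. Curves are product-limit estimates; tied event times are processed
in one step; the log-rank test is the standard one-df
observed-minus-expected form (both via lifelines). No events in either
group returns p = 1 with a warning. The simulator draws exponential times
with the low-expression group's hazard multiplied by `survival_hr`
(default 2; base hazard 0.02/month) and independent uniform censoring
over a 120-month horizon — proportional hazards by construction, so the
log-rank test is the right instrument and its type-I error and power are
meaningful operating characteristics.

## What the generators do not emulate

Probe-chemistry (Infinium I/II) effects, intensity-level artifacts,
cross-reactive or SNP-overlapping probes, batch effects, gene-length
biases in counts beyond RPKM's own normalization, sequencing errors other
than conversion failure, non-proportional hazards, and covariate-driven
censoring. Tests passing on these simulations show the *rules and
statistics* are implemented correctly and recover planted truth under
idealized noise — not that the pipeline is robust to the artifacts real
arrays and libraries carry.

## Problem sizes

The test-suite and acceptance-script simulations use 500-gene × 3-CpG
manifests, 500-gene count matrices at library size 10⁶, 20 seeds for
screen recovery, 4,000 null genes for exact-test calibration, 200-clone
read sets for MI recovery, 10,000 permutations for the log-rank oracle,
and 400–1,000 replicates for survival operating characteristics — sizes
at which every Monte-Carlo bound in the tests has comfortable standard
error while the whole suite stays quick on one CPU.
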