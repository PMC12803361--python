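# Methods

This note records the statistical conventions, the synthetic-data models
behind the test suite and acceptance script, and the design choices made
where more than one reasonable convention exists. It states no empirical
result that the tests or `scripts/acceptance.py` do not themselves
compute.

## Cell quality control

Cells are partitioned into exactly four flags, in this order of
precedence:

1. `discard_mito` — mitochondrial UMI fraction strictly greater than
   `mito_max` (default 0.25). The boundary value 0.25 is kept.
2. `discard_ambiguous_species` — mouse-aligned UMI fraction strictly
   inside (`mouse_low`, `mouse_high`) = (0.10, 0.95): putative
   human–mouse doublets or heavy ambient contamination.
3. `mouse_control` — mouse fraction ≥ 0.95: the deliberately spiked
   mouse cells used to estimate ambient signal. They are removed from
   analysis but kept distinct from discards in the audit table.
4. `keep` — everything else.

Flag counts always sum to the input size; the audit table retains one
row per input cell.

## ADT normalization and enrichment

The centered log-ratio transform is applied within each cell's ADT
vector `x` of length `n`: `g = exp(n⁻¹ Σ_{j: x_j>0} ln x_j)` and
`value_i = ln(1 + x_i / g)`. Zeros contribute nothing to the log sum but
still count in `n`, and an all-zero vector maps to the zero vector. The
transform depends only on the ratios `x_i / g`, so scaling a cell's
counts by a positive constant leaves positive entries' ratios unchanged
(asserted numerically in the tests).

The total-ADT outlier rule computes, per cluster, the median of per-cell
total ADT counts and discards cells whose total exceeds `fold × median`
(default fold 10, strict inequality). The cluster MAD of totals is
computed and reported but is not used for the cut: the rule is a
fold-over-median threshold, which is the reading of the source protocol
we adopted; the MAD is logged so the choice can be audited.

Enrichment calls are one-vs-rest two-sided Wilcoxon rank-sum tests on
CLR values, run separately per sample, with Benjamini–Hochberg
adjustment across ADTs within each (sample, cluster) family; an ADT is
enriched when `p_adj < 0.01` and the CLR location shift is positive.
Clusters with fewer than 3 cells yield rows with absent p-values and
`enriched = False`. The original analysis used a hurdle-model test for
these calls; a rank-based test is used here as a distribution-free
substitute consistent with the rank-sum tests used in every other stage.

## Module scores, HVGs, subsampling

RNA is log-normalized as counts scaled per cell to `target_sum = 1e4`
followed by `log1p`; the same recipe backs module scoring, HVG selection
and DE. Module scores bin genes into 24 equal-frequency bins by
dataset-mean expression, draw 100 control genes per signature gene from
its bin (with replacement when the bin is smaller), and report
`mean(signature) − mean(pooled controls)` per cell, so identical
expression across genes gives exactly 0. HVG selection z-scores the
dispersion (variance/mean of the log-normalized values) within 20
equal-frequency mean bins and returns the top genes by normalized
dispersion; singleton or zero-variance bins get z = 0. Per-type
subsampling drops types below 25 members, keeps 25–250 whole
(inclusive bounds), and samples exactly 250 without replacement above.

## Cluster-quality metrics

Silhouette uses the textbook definition with Euclidean distances on the
supplied embedding; singleton-cluster members get `s = 0`. Bootstrap
co-assignment resamples cells with replacement, counts each sampled
identity once, reclusters the resampled embedding with a caller-supplied
deterministic function, and averages, over replicates, the fraction of
co-sampled original-cluster pairs assigned to the same new cluster;
pairs with an absent member are excluded from that replicate's
denominator. Clustering itself is deliberately a contract (a reference
nearest-centroid clusterer ships for tests) so the metric is independent
of any specific community-detection algorithm.

## Spatial niches

All distance thresholds are inclusive at the stated boundary (a Tfh with
its nearest B cell at exactly 50 μm is `close_to_B`; a cell at exactly
200 μm is inside the microenvironment). Ties in the cancer-vs-B
microenvironment count (including 0 = 0) yield `ambiguous` rather than a
forced label. The index cell is always excluded from its own
neighborhood, and a cell of the reference type is excluded from its own
nearest-reference search. Neighbor queries run through a KD-tree but are
exact Euclidean results, verified against O(n²) brute-force scans in the
tests. Tfh eligibility defaults to T-lineage cells scored on
{CXCL13, BCL6, CD4}; both the marker set and the eligible-type set are
parameters, since marker listings for this population vary. The top-10%
rule takes the (1 − 0.10) quantile per sample and includes threshold
ties.

Grouped expression within a cell subset rescales each cell's panel total
to the subset median total, applies `log1p`, and z-scales each gene
across subset cells (zero-variance genes map to 0), so the size-weighted
group means sum to zero per gene by construction.

## Clonal repertoire

Clone size is counted within (patient, timepoint) across all subsets by
default, so a clone spanning two subsets contributes its full size to
every member cell's category; this keeps the expansion and sharing
statistics mutually consistent (a per-subset scope is available as a
switch). The % expanded is computed per timepoint. Jaccard sharing pools
timepoints within a patient by default (a per-timepoint mode is
available); an entry is absent, not zero, when both clonotype sets are
empty, and the cross-patient mean averages only defined entries with the
contributing n reported.

## Paired dynamics

Frequencies use a Haldane–Anscombe pseudocount of 0.5 in both numerator
and denominator over the full subset vocabulary, so `log2(On/Pre)` and
the per-patient abundance ratio are always finite; the pseudocount is a
parameter and 0 is allowed. Patients lacking either timepoint are
excluded from every paired statistic. Rank-sum tests are exact for group
sizes ≤ 25 without ties and use the continuity-corrected normal
approximation otherwise. The DE fold change is
`log2((mean expm1(on) + 1) / (mean expm1(pre) + 1))` on log-normalized
expression — a documented convention, since only the test is specified
upstream. BH families are: ADTs within (sample, cluster) for enrichment,
and all genes within one (subset, response-group) contrast for DE. The
three-way response-gene scheme is extended with a `Discordant` category
for genes significant in both groups with opposite fold-change signs,
which the original scheme leaves undefined; the "non-parametric t-test"
of the proportion comparison is implemented as the Wilcoxon rank-sum
test, matching the rank-sum usage everywhere else.

## Synthetic-data models

The generators plant known structure and always emit truth labels, so
every downstream stage's recovery is assertable. Same spec + same seed
gives bit-identical output.

- **Multimodal**: RNA counts are negative binomial with lognormal
  gene-level means and a single dispersion θ = 2 (var = μ + μ²/θ), with
  cluster markers multiplied by a fold change (default 4). ADT counts
  are Poisson background (rate 20) plus lognormal-scaled Poisson signal
  at a 10-fold scale for planted cluster markers. 3% of cells are mouse
  spike-ins (mouse fraction ≥ 0.95), 2% are planted ambiguous-species
  cells, and 5% carry a mitochondrial fraction above 0.25 — the
  QC categories the filters must separate.
- **Tissue**: homogeneous Poisson point processes per region (disc-
  shaped cancer nests and lymphoid aggregates at 3×10⁻³ cells/μm²,
  background at 5×10⁻⁴), with cell types drawn from per-region mixtures
  (nests cancer-dominated with no B cells, aggregates B-dominated) and
  panel-gene counts Poisson with per-type rates. Region membership is
  the recorded truth.
- **Cohort**: 12 patients (one third expanders), 300 T cells per
  patient-timepoint across five subsets, with on-treatment frequency
  multipliers (Tfh_LAG3 ×2 in expanders, Tfh_IGFL2 ×1.5 in
  non-expanders). Clonotype sizes are geometric per subset; under
  geometric(p) the expected expanded-cell fraction is 1 − p², and the
  defaults (0.613, 0.520, 0.803, 0.85) place the cytotoxic Tfh,
  exhausted CD8 and helper Tfh compartments at roughly 62%, 73% and 36%
  expanded cells — the scale reported for these compartments in
  anti-PD-1-treated breast cancer. Cross-subset sharing replaces a
  second subset's clonotype with one from the first at the planted
  probability. Planted treatment-response genes get a fixed modest base
  abundance (mean 0.3) so their induction is gene-specific rather than a
  library-size artifact.

What the generators do **not** emulate: transcriptome-wide correlation
structure, batch and ambient effects, doublets beyond the mouse-fraction
mechanism, cell segmentation error in tissue, and V(D)J sequence
structure (clonotypes are opaque identifiers). Passing tests therefore
demonstrate correctness of the statistics and classifiers under the
stated models, not robustness to those real-data artifacts.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale by design: 2,000
cells for the multimodal stage, tissues of ~800–1,500 cells, cohorts of
12 patients × 2 timepoints × 300 cells, 20-seed Monte-Carlo loops for
recovery properties, and 100–200 replicates for permutation-null error
control. Matrices are dense NumPy arrays, appropriate at these sizes.
Degenerate inputs are handled explicitly: empty clusters are skipped
with warnings, clusters under 3 cells are untestable rather than wrong,
isolated spatial cells get empty (flagged) neighborhoods, and absent
subsets keep defined frequencies through the pseudocount.
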