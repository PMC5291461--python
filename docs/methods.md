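# Methods

This note documents the models, conventions and free parameters behind
`senemeth`, the assumptions of the synthetic-data generator, and the known
limitations of both.

## Methylation model

β values summarise per-probe methylation as M/(U + M + 100); the +100 offset
regularises low-intensity probes so β ∈ [0, 1). No variance model is fitted:
the arrays this pipeline targets carry one sample per condition, so
differential methylation is a plain Δβ threshold call (inclusive,
|Δβ| ≥ 0.2 by default), exactly as in threshold-based BeadChip analyses.
Threshold comparisons carry a 1e-12 absolute guard so that values that are
exactly on the boundary in decimal (e.g. 0.7 − 0.5) are not lost to binary
floating-point representation.

**QC filtering** is analysis-set-wide: a probe whose detection p exceeds 0.05
(strictly) or whose β is missing in *any* analysed sample is removed from all
samples. This matches the per-dataset probe-count bookkeeping of array
studies and keeps every downstream contrast on one probe universe.

**Sequential (stepwise) change** across an ordered passage series uses
non-strict monotonicity with a configurable tolerance ε (default 0): a
hyper-called probe is sequential iff β_{i+1} ≥ β_i − ε for every consecutive
passage pair, mirrored for hypo. Non-strict was chosen because equal
consecutive β values are compatible with accumulating drift measured at
array precision; ε > 0 lets users absorb technical jitter explicitly rather
than silently.

**Subcategory summaries.** On the CpG-context axis each probe counts exactly
once (the six contexts partition probes). On the gene-feature axis a probe
annotated to several genes or features counts once per annotation, because
the annotation relation is genuinely many-to-many; probes with no gene
annotation form the seventh, intergenic bucket. Rates are called/total per
subcategory; the hyper:hypo ratio is left missing when the hypo rate is 0.

## Expression model

Normalization is the standard one-colour chain: replace intensities below
the low-signal cutoff (default 1.0) by the cutoff, log₂, then subtract each
sample's 75th percentile. The percentile uses **linear interpolation between
order statistics** (the numpy default); this convention is fixed and the
percentile-shift step is idempotent. Fold change is computed in log₂ space
and exponentiated — equivalently a ratio of geometric means — which makes
calls invariant to any per-sample rescaling of raw intensities. Probe→gene
aggregation is the mean of log₂ values over probes sharing a RefSeq ID.
Sample clustering uses uncentered correlation r_u = Σxy/√(Σx²·Σy²),
distance 1 − r_u, with average linkage (the linkage was an open choice; it
is documented and configurable).

## Promoter classification

GC fraction and the Gardiner–Garden CpG observed/expected ratio
(CpG·L)/(C·G) are computed over the whole promoter window; thresholds
GC ≥ 0.5 and O/E ≥ 0.6 are inclusive. N bases are excluded from the
effective length and break CpG dinucleotides; soft-masked lowercase bases
count. Both statistics are strand-symmetric, so a window and its reverse
complement always classify identically. The promoter extent is a free
parameter of the analysis (the criteria do not fix one); the default is
[TSS − 1000, TSS + 500) on the + strand. On the − strand the mirrored
window is [TSS − 500, TSS + 1001): the mirror includes the TSS base
symmetrically, making the − window one base longer — an explicit convention,
reported with the window coordinates in the output. Whole-window statistics
(no sliding sub-windows) are the simplest consistent reading; full-scale
counts of CGI vs non-CGI promoters on real genomes are sensitive to both
choices.

## Nearest-TSS integration

Each probe maps to the minimum-|cpg_pos − tss| transcript on its chromosome
within 8 kb; isoform TSSs compete independently and the winning accession is
reported. Ties break to the lexicographically smallest gene_id, which makes
the mapping deterministic and invariant to gene-table row order. Distance is
unsigned (a signed version is emitted for diagnostics). Joint calls
(hyper_down / hypo_up) count CpG *sites*, not genes — several probes may hit
one gene — and a separate deduplicated per-gene summary is provided. CpG
probe strand is ignored for distances (CpG sites are strand-symmetric); gene
strand is used only to derive the TSS.

## miRNA axis

Probes whose manifest gene symbol matches the MIR naming pattern ("MIR"
followed by a digit, or "MIRLET") are miRNA probes; word-boundary awareness
keeps lookalikes (e.g. MIRROR1) out. The promoter restriction defaults to
TSS1500 ∪ TSS200 — "promoter" is not otherwise defined for these entries —
and is configurable. miRNA expression uses a 90-percentile shift in log₂
space. Concordance requires ≥ 1 promoter probe past the Δβ cutoff *and* an
opposite expression change past 1.5-fold; both directions are evaluated.
Manifest symbols are harmonized to mature array names (MIR7-1 →
hsa-miR-7-5p) through a user-supplied alias table only; no nomenclature
logic is hard-coded, because that mapping is array- and release-specific.
The triad filter requires ≥ 2 supporting concordant miRNAs: curated
senescence triad tables contain many genes supported by exactly two miRNAs,
so the threshold is inclusive at two. Target predictions are always an input
table (they are version-drifting external predictions, never recomputed
here).

## Synthetic-data generator

The generator emulates the study design the pipeline assumes: a four-passage
methylation series (PDL 36/49/69/85) over 1,000 probes with 10 % planted
hyper- and 10 % hypo-drift at 0.1 β per step, β noise σ = 0.01 (truncated to
[0, 1] by clipping), 100 protein-coding genes with 4-fold planted
expression effects (10 % up, 10 % down, log₂ noise 0.1) across three
senescence contrasts, and 100 miRNA loci of which ~7 % are planted
concordant. Noise levels are free parameters — no variance estimates exist
to calibrate them against — and were chosen once so that planted effects sit
well clear of the decision thresholds while noise still exercises the
arithmetic. Gene loci sit every 20 kb on one synthetic chromosome, which
guarantees that a probe within 8 kb of its own TSS is nearest to that TSS.

CGI and non-CGI promoter windows are built compositionally by tiling 10-mer
motifs (ACGTGCTAGC: GC = 0.6, O/E ≈ 1.1; AGTCATGACT: GC = 0.4, O/E = 0)
rather than by rejection sampling, so the planted class holds by
construction. The non-CGI windows carry *zero* CpG dinucleotides: a motif
with O/E near 0.2 at GC 0.4 drifts toward the 0.6 decision boundary on
short windows, and the generator's job is guaranteed ground truth, not
boundary realism (boundary behaviour is tested with purpose-built
sequences).

Detection p-values are Uniform(0, 0.04) for good entries and
Uniform(0.06, 1) for planted failures (0.5 % of entries), leaving no mass on
the 0.05 boundary. miRNA promoter probes are exempt from planted failures:
each miRNA has a single evidence probe, and removing it would make the
planted concordance truth unevaluable rather than testing the filter.
Drifting probes start at a β where the full drift fits inside [0, 1], so
zero-noise recovery is exact; recovery metrics are evaluated over probes
that pass QC, since filtering is itself part of the pipeline under test.

**What the generator does not emulate:** array normalization artefacts
(dye bias, batch effects, probe-type chemistry differences), correlated
noise between neighbouring probes, realistic β bimodality, genome-scale
gene density, or biologically structured target networks. Passing tests
therefore demonstrate the correctness of the calling, classification and
filtering logic under the stated statistical structure — not robustness to
real-array technical artefacts, which upstream preprocessing is assumed to
have handled.

## Problem sizes

The default synthetic study (1,100 methylation probes, 120 expression
probes, 100 miRNAs, a 4 Mb toy genome) runs the full pipeline in well under
a second; the test suite and the acceptance script use this scale, with
oracle-equivalence checks at 1,000 items across 10 seeds.

## Known limitations

* Single-sample contrasts: no replicate-aware statistics, by design.
* The gene-level deduplication of concordant pairs is a plain per-gene
  collapse; no rule is claimed for reproducing any particular published
  gene-level count.
* Functional-group ratios consume a user-supplied gene→group map (digested
  externally, e.g. from GO clustering output); enrichment statistics are out
  of scope.
* GEO series-matrix ingest and full-scale reproduction on deposited data are
  not implemented; all I/O is file-based and offline.
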