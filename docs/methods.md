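# Methods

This note documents the statistical model behind `exonarh`, the choices
made where the method leaves room, and what the synthetic-data generator
does and does not emulate.

## Data model

The pipeline consumes a probe × sample matrix of log2 intensities together
with a probe annotation mapping each probe to an exon and gene (1-based
inclusive coordinates, Ensembl convention; BED input is converted on read).
Background control probes — probes without a genomic target — carry only a
G+C count (an integer, 0–25 for 25-mers; stored as a count rather than a
fraction so that "same GC content" matching is discrete).  Exactly two
conditions are supported; exon order within a gene follows genomic position
and strand is ignored.

## Normalization and presence calling

Intra-chip correction subtracts, per array, the median log2 value of the
background probes in the probe's GC bin.  This is a deliberate
simplification of full sequence-based background models (which fit
position-specific base effects of the 25-mer): the dominant nonspecific
term is GC content, and a per-bin median reproduces the correction using
only the GC class of each probe.  Bins with fewer than 30 background probes
(configurable) fall back to the global background median; the correction
then absorbs any per-bin constant offset of an array, a property the tests
exercise.

Inter-chip normalization is standard quantile normalization: the reference
distribution is the per-rank mean of the column-sorted values, and ties
within a column receive the mean of the reference values at their tied
ranks (so tied probes remain tied).  A single-sample matrix is returned
unchanged with a warning.

Summarization is the median of a unit's probe values — all probes of all
exons for gene level, the exon's probes for exon level.  Medians rather
than means keep single aberrant probes from dominating a summary.

Presence is judged per condition: background values are pooled over the
condition's replicates, each GC bin's threshold is their 75th percentile
(linear interpolation between order statistics, h = (n−1)q; the most common
convention, fixed for reproducibility), and a gene is present when strictly
more than 50% of its pooled exon-probe values are strictly above the
threshold.  Pooling replicates before thresholding (rather than voting per
sample) keeps the call symmetric in the replicates; both the strict ">"
and the strict majority follow the selection rule's literal wording.

## Differential expression

Three conjunctive criteria, thresholds inclusive: present in at least one
condition; ratio ≥ 1.33 or ≤ 0.75; exact two-sided Wilcoxon p ≤ 0.05.
The condition summary entering the ratio is the arithmetic mean of the
replicate log2 values (a geometric mean on the linear scale); the median is
available via `center="median"`.  The ratio orientation
(numerator/denominator) is explicit in the API.

The Wilcoxon test is exact: pooled values are midranked and all
C(n+m, n) group assignments enumerated; p is the fraction of assignments
whose rank sum deviates from its expectation n(N+1)/2 by at least the
observed deviation.  For n = m = 5 the 252 splits give a p-value resolution
of 2/252 ≈ 0.0079 — no gene can reach p ≤ 0.05 spuriously below that
granularity.  Enumeration is restricted to group sizes 2–12.

No multiple-testing correction gates the DE call (the three-criterion rule
is used as stated); a Benjamini–Hochberg q-value column is emitted
alongside for modern practice but never enters the flag.

Inclusive threshold comparisons use a 1e-9 tolerance so that a ratio
constructed to equal 1.33 exactly is not rejected by last-bit rounding.

The qPCR arm implements 2^−ΔΔCt relative quantification: per group,
ΔCt = mean target Ct − mean reference Ct; ΔΔCt is the sample group's ΔCt
minus the calibrator's; the fold change is 2^−ΔΔCt.

## The ARH splicing statistic

Per gene, exon-level log2 ratios r_i are centered on their median,
s_i = r_i − median(r), and transformed into a splicing probability
distribution p_i ∝ 2^|s_i|.  The score is the divergence from uniformity,

    ARH = log2(n) − H(p) = KL(p ‖ uniform)  ∈ [0, log2 n).

Design choices worth recording:

* **Sign of the score.**  ARH is defined so that a *dominating* exon — a
  concentrated, low-entropy probability distribution — yields a *high*
  score.  This orientation makes single-exon events rank highest, which is
  the intended detection target.
* **Absolute deviations.**  |s_i| enters the weight so inclusion and
  skipping count equally; a flipped condition orientation (r → −r) leaves
  the score unchanged.
* **Median centering** makes the score invariant to any constant shift of
  all r_i, i.e. to gene-level differential expression, and robust to up to
  half the exons moving.
* **Degenerate sizes.**  For n = 2 the two deviations have equal magnitude
  by construction, forcing p = (½, ½) and ARH ≡ 0; genes with fewer than
  3 exons are therefore reported but exempt from testing (p = 1).

### Resampling significance

The null distribution of ARH depends on the exon count, so p-values are
computed per exon-count stratum: deviations s are pooled across all genes,
and for stratum n, B draws of n deviations (with replacement) are
re-centered on their median and pushed through the same transform to give a
null ARH sample.  p = (1 + #{null ≥ observed}) / (B + 1) with the add-one
correction, so p ∈ (0, 1] and an observed score of 0 gets p = 1 exactly.
B defaults to 10,000 and the seed is mandatory.  Re-centering each draw
mirrors the construction of the observed statistic and is what makes the
test calibrate: on a simulated null world the type-I error at nominal 0.05
lands within the binomial band of 0.05 (the acceptance suite checks
[0.035, 0.065] at 2000 genes).

When true splicing events are present they contaminate the pooled
deviations and inflate the null, making the test mildly conservative —
visible as a sub-nominal empirical FPR in spiked simulations.  This is the
usual price of a pooled empirical null and is preferred over assuming a
parametric deviation distribution.

### Exon attribution

Within a significant gene, exons with p_i ≥ c/n (c = 2 by default,
configurable) — at least c times the uniform mass — are flagged as the
splicing event.  With c = 2 a diffusely deviating gene can be significant
yet flag no exon; for 3-exon genes the bar (2/3) is intentionally high.

## Synthetic data

The generator emulates the structure of a two-strain, five-replicate
exon-array study: genes with 3–16 exons, 1–4 probes per exon, GC counts
uniform on 8–17, background probes 30 per GC bin, ~10% of genes expressed
near background ("absent").  A probe value is additive on the log2 scale:
gene baseline (N(8, 1.5²), or N(4, 0.8²) for absent genes), condition
effect (±1 log2 for DE genes), cassette-exon shift (±2 log2 on one exon of
one condition for AS genes), probe affinity N(0, 0.5²), a linear GC effect
(slope 0.1 per G+C), an array effect N(0, 0.1²) removed by quantile
normalization, and replicate noise N(0, 0.25²).  Defaults reflect typical
exon-array effect and noise magnitudes; DE and AS fractions default to 0
(a null world) and are set explicitly in analyses.  One global random
stream drives a run, so a seed reproduces the dataset byte for byte.

What the simulator does *not* model: probe cross-hybridization, spatial
array artifacts, correlated probe noise within exons, intensity-dependent
variance, or tissue-composition mixtures.  Passing tests on this generator
therefore demonstrate correctness and calibration of the algorithms under
an additive Gaussian probe model, not performance on raw array data with
those artifacts.

## Orchestration and reproducibility

`run_all` executes simulate/ingest → GC correction → quantile
normalization → presence → DE → ARH → overlap → top tables → optional QTL
localization, failing fast with the stage name on any error, and writes a
manifest (config hash, seed, package and library versions).  All TSV output
uses a fixed float format; rerunning a config yields byte-identical files.
Result tables are sorted by p-value then id; top tables use strict
thresholds (log2 ratio < low, > high) sorted by |log2 ratio| descending.
QTL intervals are marker position ± a symmetric window (default ±10 Mb
when read from Mb-scaled input) with inclusive endpoints, since published
marker positions rarely come with confidence intervals; the window is a
parameter, not an inference.

Problem sizes in the test and acceptance runs (2000-gene worlds, B =
10,000 resamples, 5 spike-in seeds at 600 genes) were chosen to give
stable Monte-Carlo estimates — binomial 3σ bands at these sizes are well
inside the asserted ranges — while completing in seconds.

## Known limitations

* Resampling p-values depend on the analyzed gene set through the pooled
  deviations; they are not comparable across runs with different gene
  universes, and they will not numerically match p-values produced by
  analytic null models.
* The GC-bin background correction ignores position-specific sequence
  effects within the probe.
* The exact Wilcoxon test is limited to 2–12 replicates per group by
  enumeration cost; larger designs would need the normal approximation,
  which is out of scope here.
* Two conditions only; no batch structure, no covariates.
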