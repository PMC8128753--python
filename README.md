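# exonarh

Two-condition exon-array analysis: normalization against GC-matched
background probes, present/absent calling, differential expression with an
exact rank-sum test, and entropy-based alternative-splicing detection.

## The problem

Exon arrays (e.g. the Affymetrix Gene 1.0 ST design) tile individual exons
with short probes, so a single hybridization measures both gene-level
expression and exon-level splicing differences.  A typical design contrasts
two groups with a handful of replicate arrays each — for instance pancreatic
islets from diabetes-prone NZO and diabetes-resistant C3H mice, five
replicates per strain.  At that sample size, asymptotic tests are unreliable
and splicing signals are easily confounded with expression changes.  This
package implements a complete probe-to-report pipeline for that setting,
plus a spike-in simulator so every stage can be validated against known
ground truth.

## The methods

**Normalization and presence.**  Per array, each probe's log2 intensity is
corrected by the median of background-control probes with the same G+C
count (nonspecific signal grows with GC), then arrays are quantile
normalized.  A gene is called *present* in a condition when more than 50%
of its exon-probe values, pooled over that condition's replicates, exceed
the 75th percentile of the GC-matched background distribution.

**Differential expression.**  A gene is differentially expressed when it is
present in at least one condition, its expression ratio satisfies
R ≥ 1.33 or R ≤ 0.75 (R = 2^(mean log2 B − mean log2 A)), and an exact
two-sided Wilcoxon rank-sum test over the replicates gives p ≤ 0.05.  The
test enumerates all C(n+m, n) rank assignments (252 for 5 vs 5, so the
smallest attainable p is 2/252 ≈ 0.008).

**Alternative splicing (ARH).**  For a gene with n exons, let r_i be the
exon-level log2 expression ratio between conditions and
s_i = r_i − median_j(r_j) its deviation from the gene's median ratio.  The
deviations define a splicing probability distribution

&nbsp;&nbsp;&nbsp;&nbsp;p_i = 2^|s_i| / Σ_j 2^|s_j|,

and the gene is scored by the Kullback–Leibler divergence of p from the
uniform distribution,

&nbsp;&nbsp;&nbsp;&nbsp;ARH = log2(n) − H(p),&nbsp;&nbsp;H(p) = −Σ p_i log2 p_i&nbsp;&nbsp;[bits].

A cassette exon shifted in one condition concentrates probability mass on
one exon and yields a high ARH; a gene whose exons all move together (plain
differential expression) has uniform p and ARH = 0.  Significance comes
from a stratified resampling null (deviations pooled across genes), and
exons carrying at least twice the uniform probability mass are attributed
to the splicing event.  Significant genes can finally be localized inside
QTL intervals (marker position ± window).

## Worked example

```python
from exonarh import (
    SimParams, simulate_experiment, gc_baseline_correct, quantile_normalize,
    presence_call, summarize_probes, select_de, exon_ratio_profiles,
    arh_pvalues, overlap_de_as,
)

params = SimParams(n_genes=500, frac_de=0.10, frac_as=0.10, seed=42)
matrix, annotation, truth = simulate_experiment(params)

corrected = gc_baseline_correct(matrix, annotation)
normalized = quantile_normalize(corrected)
presence = presence_call(corrected, annotation)

gene_expr = summarize_probes(normalized, annotation, "gene")
de = select_de(gene_expr, presence, matrix.condition_of,
               denominator="NZO", numerator="C3H")

exon_expr = summarize_probes(normalized, annotation, "exon")
profiles = exon_ratio_profiles(exon_expr, annotation.gene_models(),
                               matrix.condition_of, "NZO", "C3H")
arh = arh_pvalues(profiles, B=10_000, seed=42)

de_only, as_only, both = overlap_de_as(de, arh)
print(f"DE genes: {int(de['de_flag'].sum())} (truth: {int(truth['de_flag'].sum())})")
print(f"AS genes: {int(arh['significant'].sum())} (truth: {int(truth['as_flag'].sum())})")
print(f"DE and AS: {len(both)}")
top = arh.sort_values("arh", ascending=False).iloc[0]
print(f"top AS gene: {top.name}  ARH={top['arh']:.2f} bits  "
      f"p={top['p_value']:.2e}  exons={int(top['n_exons'])}")
```

prints

```
DE genes: 41 (truth: 40)
AS genes: 30 (truth: 37)
DE and AS: 4
top AS gene: G367  ARH=0.37 bits  p=8.00e-04  exons=9
```

Out of 500 simulated genes, 40 carried a true two-fold expression change
and the three-criterion selection recovered 41 calls; 37 carried a spiked
cassette exon of which 30 passed the ARH test at p ≤ 0.05 (small 3-exon
genes are the hardest); four genes were both DE and AS.  The top-ranked
gene concentrates over a third of a bit of divergence from the uniform
splicing distribution on its nine exons.

The same pipeline runs from the shell:

```sh
exonarh run --config tests/data/toy_config.yaml --outdir out/
```

writing the normalized matrix, presence calls, DE table, AS gene and exon
tables, DE/AS overlap, ranked top tables and a run manifest.

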