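"""Synthetic two-condition exon-array experiments with known truth.

Emulates the structure of a two-strain islet exon-array study: two
conditions with five replicate arrays each, genes of 3-16 exons tiled by
1-4 probes per exon, GC-stratified background control probes, a fraction
of genes expressed near background (absent), a fraction differentially
expressed between conditions, and a fraction carrying a cassette-exon
splicing event (one exon shifted in one condition only).

The generative model for a probe value (log2 scale) is additive:

    value = gene baseline + condition effect (DE genes)
          + exon shift (affected exons of AS genes, one condition)
          + probe affinity + GC slope * (gc - mean gc)
          + array effect + replicate noise

Background probes replace the gene terms with a background baseline.
One global random stream drives the whole run, so an identical seed
reproduces the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from exonarh.annotation_io import ProbeAnnotation, ProbeMatrix

try:  # AUROC; fall back to a rank-based computation if sklearn is absent
    from sklearn.metrics import roc_auc_score
except ImportError:  # pragma: no cover
    roc_auc_score = None


@dataclass
class SimParams:
    """Parameters of the synthetic experiment (log2 scale throughout)."""

    n_genes: int = 2000
    exon_count_range: tuple[int, int] = (3, 16)
    probes_per_exon_range: tuple[int, int] = (1, 4)
    n_replicates: int = 5
    conditions: tuple[str, str] = ("NZO", "C3H")
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    probe_affinity_sd: float = 0.5
    gc_slope: float = 0.1
    gc_range: tuple[int, int] = (8, 17)
    noise_sd: float = 0.25
    array_effect_sd: float = 0.1
    frac_absent: float = 0.1
    frac_de: float = 0.0
    de_log2_fc: float = 1.0
    frac_as: float = 0.0
    as_delta: float = 2.0
    as_exons_per_event: int = 1
    background_mean: float = 4.0
    background_sd: float = 0.8
    background_per_bin: int = 30
    seed: int | None = None

    def validate(self) -> None:
        bad: list[str] = []
        if self.seed is None:
            bad.append("seed (mandatory)")
        if self.n_genes < 1:
            bad.append("n_genes")
        for name in ("frac_absent", "frac_de", "frac_as"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(name)
        for name in (
            "baseline_sd", "probe_affinity_sd", "noise_sd",
            "array_effect_sd", "background_sd",
        ):
            if getattr(self, name) < 0:
                bad.append(name)
        for name in ("exon_count_range", "probes_per_exon_range", "gc_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                bad.append(name)
        if self.n_replicates < 2:
            bad.append("n_replicates")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            bad.append("conditions")
        if self.as_exons_per_event < 1:
            bad.append("as_exons_per_event")
        if self.background_per_bin < 1:
            bad.append("background_per_bin")
        if bad:
            raise ValueError(f"invalid simulation parameters: {', '.join(bad)}")


def simulate_experiment(
    params: SimParams,
) -> tuple[ProbeMatrix, ProbeAnnotation, pd.DataFrame]:
    """Generate (probe matrix, annotation, ground truth) for one experiment.

    The truth table has one row per gene: ``absent_flag``, ``de_flag`` with
    the signed true log2 fold change (numerator = second condition), and
    ``as_flag`` with the affected exon ids and the signed exon shift.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cond_a, cond_b = params.conditions
    n_rep = params.n_replicates
    samples = [f"{cond_a}_{i + 1}" for i in range(n_rep)] + [
        f"{cond_b}_{i + 1}" for i in range(n_rep)
    ]
    condition_of = {s: (cond_a if i < n_rep else cond_b) for i, s in enumerate(samples)}
    is_b = np.array([condition_of[s] == cond_b for s in samples])

    gc_lo, gc_hi = params.gc_range
    gc_mid = 0.5 * (gc_lo + gc_hi)
    width = len(str(params.n_genes))

    # --- gene architecture -------------------------------------------------
    n = params.n_genes
    exon_counts = rng.integers(
        params.exon_count_range[0], params.exon_count_range[1] + 1, size=n
    )
    absent = rng.random(n) < params.frac_absent
    # DE/AS status is only assigned to expressed genes
    de_flag = (~absent) & (rng.random(n) < params.frac_de)
    as_flag = (~absent) & (rng.random(n) < params.frac_as)
    de_sign = rng.choice([-1.0, 1.0], size=n)
    as_sign = rng.choice([-1.0, 1.0], size=n)

    ann_rows: list[tuple] = []
    probe_effects: list[np.ndarray] = []  # per probe: full length-2n sample vector
    truth_rows: list[tuple] = []
    pos = 1
    chrom = "chr1"
    for g in range(n):
        gene_id = f"G{g + 1:0{width}d}"
        k = int(exon_counts[g])
        base = (
            rng.normal(params.background_mean, params.background_sd)
            if absent[g]
            else rng.normal(params.baseline_mean, params.baseline_sd)
        )
        fc = float(de_sign[g] * params.de_log2_fc) if de_flag[g] else 0.0
        affected: list[int] = []
        if as_flag[g]:
            n_aff = min(params.as_exons_per_event, k)
            affected = sorted(rng.choice(k, size=n_aff, replace=False).tolist())
        delta = float(as_sign[g] * params.as_delta) if as_flag[g] else 0.0

        n_probes_per_exon = rng.integers(
            params.probes_per_exon_range[0],
            params.probes_per_exon_range[1] + 1,
            size=k,
        )
        for e in range(k):
            exon_id = f"{gene_id}.E{e + 1:02d}"
            start, end = pos, pos + 199
            pos += 2000
            shift = delta if e in affected else 0.0
            for p in range(int(n_probes_per_exon[e])):
                probe_id = f"{exon_id}.P{p + 1}"
                gc = int(rng.integers(gc_lo, gc_hi + 1))
                affinity = rng.normal(0.0, params.probe_affinity_sd)
                mu = base + affinity + params.gc_slope * (gc - gc_mid)
                sample_mu = mu + is_b * (fc + shift)
                ann_rows.append(
                    (probe_id, gene_id, exon_id, chrom, start, end, gc, False)
                )
                probe_effects.append(sample_mu)
        truth_rows.append(
            (
                gene_id,
                bool(absent[g]),
                bool(de_flag[g]),
                fc,
                bool(as_flag[g]),
                ";".join(f"{gene_id}.E{e + 1:02d}" for e in affected),
                delta,
            )
        )
        pos += 10_000  # intergenic gap

    # --- background control probes ----------------------------------------
    for gc in range(gc_lo, gc_hi + 1):
        for i in range(params.background_per_bin):
            probe_id = f"BG.GC{gc:02d}.{i + 1}"
            mu = rng.normal(params.background_mean, params.background_sd)
            mu += params.gc_slope * (gc - gc_mid)
            ann_rows.append((probe_id, "", "", "", 0, 0, gc, True))
            probe_effects.append(np.full(2 * n_rep, mu))

    mu_matrix = np.vstack(probe_effects)
    array_effect = rng.normal(0.0, params.array_effect_sd, size=2 * n_rep)
    noise = rng.normal(0.0, params.noise_sd, size=mu_matrix.shape)
    X = mu_matrix + array_effect[None, :] + noise

    ann = ProbeAnnotation(
        pd.DataFrame(
            ann_rows,
            columns=[
                "probe_id", "gene_id", "exon_id", "chrom",
                "exon_start", "exon_end", "gc_count", "is_background",
            ],
        )
    )
    matrix = ProbeMatrix(
        values=pd.DataFrame(
            X, index=pd.Index([r[0] for r in ann_rows], name="probe_id"),
            columns=samples,
        ),
        condition_of=condition_of,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "absent_flag", "de_flag", "true_log2_fc",
            "as_flag", "affected_exons", "as_delta",
        ],
    ).set_index("gene_id")
    return matrix, ann, truth


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        return float("nan")
    if roc_auc_score is not None:
        return float(roc_auc_score(labels, scores))
    # rank-based Mann-Whitney fallback
    from scipy.stats import rankdata

    r = rankdata(scores)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def truth_eval(
    truth: pd.DataFrame,
    de_results: pd.DataFrame | None = None,
    as_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score DE and AS calls against the simulation ground truth.

    Sensitivity and specificity are computed over expressed (non-absent)
    genes; the false-positive rate over expressed genes that are truly
    negative.  AUROC ranks genes by |log2 ratio| (DE) or ARH score (AS).
    Undefined metrics (e.g. sensitivity with no true positives) come back
    as NaN.

    Returns a tidy table with columns analysis, metric, value.
    """
    rows: list[tuple[str, str, float]] = []

    def add_block(name: str, called: pd.Series, score: pd.Series, truth_col: str):
        idx = truth.index
        missing = idx.difference(called.index)
        if len(missing):
            raise ValueError(
                f"{name}: gene universes differ (e.g. {list(missing[:3])})"
            )
        expressed = ~truth["absent_flag"]
        pos = truth[truth_col] & expressed
        neg = ~truth[truth_col] & expressed
        c = called.reindex(idx).astype(bool)
        tp = (c & pos).sum()
        fp = (c & neg).sum()
        sens = tp / pos.sum() if pos.sum() else float("nan")
        spec = (neg & ~c).sum() / neg.sum() if neg.sum() else float("nan")
        fpr = fp / neg.sum() if neg.sum() else float("nan")
        sub = expressed
        auroc = _auroc(
            score.reindex(idx)[sub].to_numpy(dtype=float),
            pos[sub].to_numpy(),
        )
        rows.extend(
            [
                (name, "sensitivity", float(sens)),
                (name, "specificity", float(spec)),
                (name, "fpr", float(fpr)),
                (name, "auroc", float(auroc)),
            ]
        )

    if de_results is not None:
        de = de_results.set_index("gene_id")
        add_block("de", de["de_flag"], de["log2_ratio"].abs(), "de_flag")
    if as_results is not None:
        add_block("as", as_results["significant"], as_results["arh"], "as_flag")
    return pd.DataFrame(rows, columns=["analysis", "metric", "value"])
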