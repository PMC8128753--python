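"""Normalization, probe summarization and present/absent calling.

Processing order is intra-chip first, inter-chip second: per-array GC-bin
background-median subtraction, then quantile normalization across arrays,
then median summarization of probes to exons or genes.  Presence is judged
per condition against the 75th percentile of GC-matched background probes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from exonarh.annotation_io import ProbeAnnotation, ProbeMatrix

logger = logging.getLogger(__name__)

#: a GC bin needs at least this many background probes to get its own
#: baseline / presence threshold; smaller bins fall back to the global pool
DEFAULT_MIN_BIN_SIZE = 30


def _check_alignment(m: ProbeMatrix, ann: ProbeAnnotation) -> pd.DataFrame:
    t = ann.table.set_index("probe_id")
    missing = [p for p in m.probe_ids if p not in t.index]
    if missing:
        raise ValueError(f"probes missing from annotation: {missing[:5]}")
    return t.loc[m.probe_ids]


def gc_baseline_correct(
    m: ProbeMatrix,
    ann: ProbeAnnotation,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
) -> ProbeMatrix:
    """Subtract, per array, the median background signal of each probe's GC bin.

    Nonspecific hybridization grows with probe GC content; background control
    probes stratified by G+C count estimate that baseline per array.  Bins
    with fewer than ``min_bin_size`` background probes fall back to the
    global background median.  Background probes are corrected the same way,
    so downstream presence thresholds see corrected background too.
    """
    t = _check_alignment(m, ann)
    is_bg = t["is_background"].to_numpy()
    if not is_bg.any():
        raise ValueError("no background probes in annotation; cannot GC-correct")
    gc = t["gc_count"].to_numpy()
    X = m.values.to_numpy(dtype=float)

    bg_gc = gc[is_bg]
    bg_vals = X[is_bg]  # (n_bg, n_samples)
    global_med = np.median(bg_vals, axis=0)  # per array
    correction = np.tile(global_med, (X.shape[0], 1))
    for b in np.unique(bg_gc):
        sel = bg_gc == b
        if sel.sum() >= min_bin_size:
            med = np.median(bg_vals[sel], axis=0)
            correction[gc == b] = med
    out = pd.DataFrame(X - correction, index=m.values.index, columns=m.values.columns)
    return m.with_values(out)


def quantile_normalize(m: ProbeMatrix) -> ProbeMatrix:
    """Force all arrays onto a common intensity distribution by rank.

    The reference distribution is the per-rank mean of the column-sorted
    values.  Ties within a column receive the mean of the reference values
    at their tied ranks, so tied probes stay tied after normalization.
    """
    X = m.values.to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        warnings.warn("quantile normalization skipped: single-sample matrix")
        return m
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        order = np.argsort(X[:, j], kind="mergesort")
        sc = X[order, j]
        # tie runs in the sorted column share the mean reference value
        run_id = np.concatenate([[0], np.cumsum(sc[1:] != sc[:-1])])
        run_mean = np.bincount(run_id, weights=ref) / np.bincount(run_id)
        out[order, j] = run_mean[run_id]
    return m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    )


def summarize_probes(
    m: ProbeMatrix, ann: ProbeAnnotation, level: str = "gene"
) -> pd.DataFrame:
    """Median-summarize probe values to exons or genes.

    Gene-level summaries pool all probes of all the gene's exons; the
    expression estimate per replicate is the median of those probe values.
    Returns a unit x sample DataFrame of log2 expression.
    """
    if level not in ("gene", "exon"):
        raise ValueError(f"level must be 'gene' or 'exon', got {level!r}")
    t = _check_alignment(m, ann)
    fg = ~t["is_background"].to_numpy()
    unit = t["gene_id" if level == "gene" else "exon_id"].to_numpy()[fg]
    vals = m.values.to_numpy(dtype=float)[fg]
    out = (
        pd.DataFrame(vals, index=unit, columns=m.values.columns)
        .groupby(level=0, sort=True)
        .median()
    )
    out.index.name = "gene_id" if level == "gene" else "exon_id"
    return out


def presence_call(
    m: ProbeMatrix,
    ann: ProbeAnnotation,
    q: float = 0.75,
    fraction: float = 0.5,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
) -> pd.DataFrame:
    """Call genes present/absent against GC-matched background, per condition.

    For each condition, background probe values are pooled over that
    condition's replicates and the threshold of a GC bin is their ``q``-th
    quantile (linear interpolation between order statistics; bins below
    ``min_bin_size`` background probes use the pooled global quantile).  A
    probe-sample value is "above" when strictly greater than its bin's
    threshold, and a gene is present in a condition when strictly more than
    ``fraction`` of its pooled exon probe values are above.

    Returns a DataFrame indexed by gene_id with columns ``present_<cond>``
    and ``frac_above_<cond>`` for each condition.
    """
    t = _check_alignment(m, ann)
    is_bg = t["is_background"].to_numpy()
    if not is_bg.any():
        raise ValueError("no background probes in annotation; cannot call presence")
    gc = t["gc_count"].to_numpy()
    genes = t["gene_id"].to_numpy()
    X = m.values

    result: dict[str, pd.Series] = {}
    for cond in m.conditions:
        cols = m.samples_of(cond)
        V = X[cols].to_numpy(dtype=float)
        bg_vals = V[is_bg]
        bg_gc = gc[is_bg]
        global_thr = np.quantile(bg_vals, q)
        thr_of: dict[int, float] = {}
        for b in np.unique(bg_gc):
            sel = bg_gc == b
            thr_of[int(b)] = (
                float(np.quantile(bg_vals[sel], q))
                if sel.sum() >= min_bin_size
                else float(global_thr)
            )
        thr = np.array([thr_of.get(int(g), float(global_thr)) for g in gc])
        above = V > thr[:, None]
        fg = ~is_bg
        frac = (
            pd.DataFrame(
                {"gene_id": genes[fg], "above": above[fg].mean(axis=1)}
            )
            .groupby("gene_id", sort=True)["above"]
            .mean()
        )
        result[f"frac_above_{cond}"] = frac
        result[f"present_{cond}"] = frac > fraction
    out = pd.DataFrame(result)
    out.index.name = "gene_id"
    return out


def gc_bin_quantile(values: np.ndarray, q: float) -> float:
    """Quantile by linear interpolation between closest order statistics."""
    return float(np.quantile(np.asarray(values, dtype=float), q))
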