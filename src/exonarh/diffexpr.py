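"""Gene-level differential expression and qPCR fold-change quantification.

A gene is called differentially expressed when (1) it is present in at
least one condition, (2) its linear expression ratio between conditions is
>= 1.33 or <= 0.75, and (3) an exact two-sided Wilcoxon rank-sum test on
the replicate expression values gives p <= 0.05.  With five replicates per
group the exact test has 252 distinct assignments, so the smallest
attainable p-value is 2/252.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

#: tolerance used when comparing against inclusive thresholds, so that a
#: ratio constructed to equal 1.33 is not rejected by a last-bit rounding
_EPS = 1e-9

_MAX_GROUP = 12  # exact enumeration regime


@lru_cache(maxsize=32)
def _split_indices(n: int, m: int) -> np.ndarray:
    """All C(n+m, n) ways to pick group-a indices from the pooled sample."""
    return np.array(list(combinations(range(n + m), n)), dtype=np.intp)


def _rank_sum_pvalues(ranks: np.ndarray, n: int) -> np.ndarray:
    """Exact two-sided p for each row of pooled midranks; group a = first n.

    p is the fraction of assignments whose group-a rank sum deviates from
    its null expectation n(N+1)/2 by at least the observed deviation.
    """
    ranks = np.atleast_2d(ranks)
    total = ranks.shape[1]
    m = total - n
    idx = _split_indices(n, m)
    expect = n * (total + 1) / 2.0
    obs = ranks[:, :n].sum(axis=1)
    null = ranks[:, idx].sum(axis=2)  # (genes, C(n+m, n))
    dev_obs = np.abs(obs - expect)
    dev_null = np.abs(null - expect)
    hits = (dev_null >= dev_obs[:, None] - _EPS).sum(axis=1)
    return hits / idx.shape[0]


def wilcoxon_exact(a, b) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value by full enumeration.

    Pooled values are midranked (ties share the average rank), and every
    C(|a|+|b|, |a|) assignment of the midranks to the two groups is
    enumerated.  Valid for group sizes 2..12; the small-replicate regime of
    two-condition array designs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (2 <= a.size <= _MAX_GROUP and 2 <= b.size <= _MAX_GROUP):
        raise ValueError(
            f"group sizes must be in [2, {_MAX_GROUP}] for exact enumeration"
        )
    ranks = rankdata(np.concatenate([a, b]))
    return float(_rank_sum_pvalues(ranks, a.size)[0])


def wilcoxon_exact_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise exact Wilcoxon p-values for many genes at once.

    ``A`` and ``B`` are genes x replicates matrices for the two conditions.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    pooled = np.concatenate([A, B], axis=1)
    ranks = rankdata(pooled, axis=1)
    return _rank_sum_pvalues(ranks, A.shape[1])


def select_de(
    gene_expr: pd.DataFrame,
    presence: pd.DataFrame,
    condition_of: dict[str, str],
    denominator: str,
    numerator: str,
    ratio_low: float = 0.75,
    ratio_high: float = 1.33,
    p_threshold: float = 0.05,
    center: str = "mean",
) -> pd.DataFrame:
    """Apply the three-criterion differential-expression selection.

    Parameters
    ----------
    gene_expr
        Gene x sample log2 expression summaries.
    presence
        Output of :func:`exonarh.preprocess.presence_call`.
    denominator, numerator
        Condition labels defining the ratio orientation:
        ``ratio = 2^(mean log2[numerator] - mean log2[denominator])``.
    center
        ``"mean"`` (default) or ``"median"`` of the replicate log2 values
        as the per-condition summary entering the ratio.
    ratio_low, ratio_high, p_threshold
        Inclusive selection thresholds (ratio <= low or >= high; p <= threshold).

    Returns a DataFrame with one row per gene: condition means, linear
    ratio and log2 ratio, exact Wilcoxon p, Benjamini-Hochberg q
    (supplementary only, never gating the call), presence flags, the DE
    flag and the direction of change.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    missing = [g for g in gene_expr.index if g not in presence.index]
    if missing:
        raise ValueError(f"genes missing from presence table: {missing[:5]}")
    samples_a = [s for s in gene_expr.columns if condition_of[s] == denominator]
    samples_b = [s for s in gene_expr.columns if condition_of[s] == numerator]
    if not samples_a or not samples_b:
        raise ValueError("both conditions need at least one sample")

    A = gene_expr[samples_a].to_numpy(dtype=float)
    B = gene_expr[samples_b].to_numpy(dtype=float)
    agg = np.mean if center == "mean" else np.median
    mean_a = agg(A, axis=1)
    mean_b = agg(B, axis=1)
    log2_ratio = mean_b - mean_a
    ratio = np.exp2(log2_ratio)
    pvals = wilcoxon_exact_matrix(A, B)

    pres = presence.loc[gene_expr.index]
    present_a = pres[f"present_{denominator}"].to_numpy(dtype=bool)
    present_b = pres[f"present_{numerator}"].to_numpy(dtype=bool)

    ratio_hit = (ratio >= ratio_high - _EPS) | (ratio <= ratio_low + _EPS)
    de_flag = (present_a | present_b) & ratio_hit & (pvals <= p_threshold + _EPS)
    direction = np.where(
        ~de_flag,
        "none",
        np.where(log2_ratio > 0, f"up_in_{numerator}", f"up_in_{denominator}"),
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene_id": gene_expr.index,
            f"mean_log2_{denominator}": mean_a,
            f"mean_log2_{numerator}": mean_b,
            "log2_ratio": log2_ratio,
            "ratio": ratio,
            "wilcoxon_p": pvals,
            "bh_q": qvals,
            f"present_{denominator}": present_a,
            f"present_{numerator}": present_b,
            "de_flag": de_flag,
            "direction": direction,
        }
    ).reset_index(drop=True)


def ddct_fold_change(sample: pd.DataFrame, calibrator: pd.DataFrame) -> float:
    """Relative expression by the 2^-ddCt method.

    Each DataFrame needs columns ``ct_target`` and ``ct_reference`` (cycle
    thresholds of the gene of interest and the endogenous control, e.g.
    Tbp).  dCt = mean(ct_target) - mean(ct_reference) per group;
    ddCt = dCt(sample) - dCt(calibrator); the fold change is 2^-ddCt.
    """
    for name, df in (("sample", sample), ("calibrator", calibrator)):
        if len(df) == 0:
            raise ValueError(f"{name} group is empty")
        for col in ("ct_target", "ct_reference"):
            if col not in df.columns:
                raise ValueError(f"{name} group missing column {col!r}")
            vals = df[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all() or (vals <= 0).any():
                raise ValueError(f"{name} group has invalid {col} values")
    dct_sample = sample["ct_target"].mean() - sample["ct_reference"].mean()
    dct_cal = calibrator["ct_target"].mean() - calibrator["ct_reference"].mean()
    return float(2.0 ** -(dct_sample - dct_cal))
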