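"""Entropy-based alternative-splicing detection (ARH).

For each gene, exon-level log2 condition ratios r_i are centered on their
median; the deviations s_i = r_i - median(r) are turned into a splicing
probability distribution p_i proportional to 2^|s_i|, and the gene is
scored by how far that distribution is from uniform:

    ARH = log2(n) - H(p) = KL(p || uniform)   [bits]

A single strongly deviating exon concentrates probability mass and yields
a high ARH; a gene whose exons all shift together (plain differential
expression) has uniform p and ARH = 0.  Median centering makes the score
robust: up to half the exons may shift before the baseline moves.

Significance comes from a resampling null: deviations are pooled across
all genes, and for each exon-count stratum n the statistic is rebuilt on
random draws of n deviations.  Genes with fewer than three exons are
reported but exempt from testing — with two exons the two deviations are
forced equal in magnitude by median centering, so ARH is identically 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from exonarh.annotation_io import GeneModel

#: genes need at least this many exons to be testable
DEFAULT_MIN_EXONS = 3


@dataclass(frozen=True)
class ExonRatioProfile:
    """Per-exon condition ratios and splicing probabilities for one gene.

    Exons follow genomic order.  ``r`` are log2 ratios (numerator over
    denominator condition), ``s`` their deviations from the gene's median
    ratio, and ``p`` the splicing probability distribution (sums to 1).
    """

    gene_id: str
    exon_ids: tuple[str, ...]
    mean_a: np.ndarray  # per-exon mean log2 expression, denominator condition
    mean_b: np.ndarray  # numerator condition
    r: np.ndarray
    s: np.ndarray
    p: np.ndarray

    @property
    def n_exons(self) -> int:
        return len(self.exon_ids)


def _profile_from_ratios(
    gene_id: str,
    exon_ids: tuple[str, ...],
    mean_a: np.ndarray,
    mean_b: np.ndarray,
) -> ExonRatioProfile:
    r = mean_b - mean_a
    s = r - np.median(r)
    w = np.exp2(np.abs(s))
    return ExonRatioProfile(
        gene_id=gene_id,
        exon_ids=exon_ids,
        mean_a=mean_a,
        mean_b=mean_b,
        r=r,
        s=s,
        p=w / w.sum(),
    )


def exon_ratio_profile(
    exon_expr: pd.DataFrame,
    gene: GeneModel,
    condition_of: dict[str, str],
    denominator: str,
    numerator: str,
    center: str = "mean",
) -> ExonRatioProfile:
    """Build the exon log2-ratio profile of one gene.

    ``exon_expr`` is an exon x sample log2 expression table covering the
    gene's exons.  Exon order follows the gene model (genomic position).
    """
    if gene.n_exons == 0:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    exon_ids = tuple(e.exon_id for e in gene.exons)
    missing = [e for e in exon_ids if e not in exon_expr.index]
    if missing:
        raise ValueError(f"exons missing from expression table: {missing[:5]}")
    samples_a = [s for s in exon_expr.columns if condition_of[s] == denominator]
    samples_b = [s for s in exon_expr.columns if condition_of[s] == numerator]
    agg = np.mean if center == "mean" else np.median
    sub = exon_expr.loc[list(exon_ids)]
    mean_a = agg(sub[samples_a].to_numpy(dtype=float), axis=1)
    mean_b = agg(sub[samples_b].to_numpy(dtype=float), axis=1)
    return _profile_from_ratios(gene.gene_id, exon_ids, mean_a, mean_b)


def exon_ratio_profiles(
    exon_expr: pd.DataFrame,
    genes: dict[str, GeneModel],
    condition_of: dict[str, str],
    denominator: str,
    numerator: str,
    center: str = "mean",
) -> dict[str, ExonRatioProfile]:
    """Profiles for a whole gene-model collection (genes sorted by id)."""
    return {
        gid: exon_ratio_profile(
            exon_expr, gm, condition_of, denominator, numerator, center
        )
        for gid, gm in sorted(genes.items())
    }


def arh_score(profile: ExonRatioProfile) -> float:
    """ARH in bits: log2(n) minus the entropy of the splicing probabilities.

    Equals the Kullback-Leibler divergence of p from the uniform
    distribution over the gene's n exons; 0 <= ARH < log2(n).
    """
    p = profile.p
    h = float(-(p * np.log2(p)).sum())
    return float(np.log2(len(p)) - h)


def _null_arh(pool: np.ndarray, n: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """Null ARH distribution for n-exon genes by resampling pooled deviations.

    Each draw mimics the statistic's construction: n values from the pool,
    re-centered on their median, |.|-weighted and normalized.
    """
    draws = rng.choice(pool, size=(B, n), replace=True)
    s = draws - np.median(draws, axis=1, keepdims=True)
    w = np.exp2(np.abs(s))
    p = w / w.sum(axis=1, keepdims=True)
    h = -(p * np.log2(p)).sum(axis=1)
    return np.log2(n) - h


def arh_pvalues(
    profiles: dict[str, ExonRatioProfile],
    B: int = 10_000,
    seed: int = 0,
    min_exons: int = DEFAULT_MIN_EXONS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every gene and attach resampling p-values.

    The deviation pool gathers the s values of all genes; for each
    exon-count stratum n >= ``min_exons`` a null ARH distribution of size
    ``B`` is built from that pool and p = (1 + #{null >= observed})/(B+1).
    Genes below ``min_exons`` get p = 1 (their ARH is still reported).

    Returns a DataFrame indexed by gene_id with columns n_exons, entropy,
    arh, p_value, significant.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(profiles) < 50:
        raise ValueError(
            f"need >= 50 genes to form a deviation pool, got {len(profiles)}"
        )
    rng = np.random.default_rng(seed)
    gene_ids = sorted(profiles)
    pool = np.concatenate([profiles[g].s for g in gene_ids])

    n_exons = np.array([profiles[g].n_exons for g in gene_ids])
    arh = np.array([arh_score(profiles[g]) for g in gene_ids])
    pvals = np.ones(len(gene_ids))
    for n in sorted(set(n_exons[n_exons >= min_exons])):
        null_sorted = np.sort(_null_arh(pool, int(n), B, rng))
        sel = np.flatnonzero(n_exons == n)
        # count of null >= observed, with a small tolerance for float ties
        ge = B - np.searchsorted(null_sorted, arh[sel] - 1e-12, side="left")
        pvals[sel] = (1.0 + ge) / (B + 1.0)
    entropy = np.log2(n_exons) - arh
    out = pd.DataFrame(
        {
            "n_exons": n_exons,
            "entropy": entropy,
            "arh": arh,
            "p_value": pvals,
            "significant": pvals <= alpha,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return out


def flag_exons(
    profile: ExonRatioProfile, multiplier: float = 2.0
) -> tuple[str, ...]:
    """Exons carrying at least ``multiplier`` times the uniform probability mass.

    Within a gene called significant, an exon is attributed to the splicing
    event when p_i >= multiplier / n_exons.
    """
    n = profile.n_exons
    hit = profile.p >= multiplier / n - 1e-12
    return tuple(e for e, h in zip(profile.exon_ids, hit) if h)


def exon_profile_table(
    gene: GeneModel,
    profile: ExonRatioProfile,
    denominator: str,
    numerator: str,
) -> pd.DataFrame:
    """Plot-ready table: one row per exon in genomic order.

    Carries exon position, mean log2 expression per condition and the
    splicing probability — everything needed to draw the classic
    exon-expression-profile panel with probability bars.
    """
    if tuple(e.exon_id for e in gene.exons) != profile.exon_ids:
        raise ValueError(
            f"profile exons do not match gene model for {gene.gene_id}"
        )
    return pd.DataFrame(
        {
            "gene_id": gene.gene_id,
            "exon_id": list(profile.exon_ids),
            "order_index": np.arange(1, gene.n_exons + 1),
            "chrom": [e.chrom for e in gene.exons],
            "exon_start": [e.start for e in gene.exons],
            "exon_end": [e.end for e in gene.exons],
            f"mean_log2_{denominator}": profile.mean_a,
            f"mean_log2_{numerator}": profile.mean_b,
            "log2_ratio": profile.r,
            "deviation": profile.s,
            "splicing_prob": profile.p,
        }
    )


def as_exon_table(
    profiles: dict[str, ExonRatioProfile],
    results: pd.DataFrame,
    genes: dict[str, GeneModel],
    denominator: str,
    numerator: str,
    multiplier: float = 2.0,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Exon-level splicing table across genes.

    One row per flagged exon of each (by default significant) gene, with
    the gene's ARH and p-value attached.
    """
    rows = []
    for gid in results.index:
        if significant_only and not bool(results.loc[gid, "significant"]):
            continue
        prof = profiles[gid]
        flagged = set(flag_exons(prof, multiplier))
        t = exon_profile_table(genes[gid], prof, denominator, numerator)
        t = t[t["exon_id"].isin(flagged)].copy()
        t["gene_arh"] = float(results.loc[gid, "arh"])
        t["gene_p"] = float(results.loc[gid, "p_value"])
        t["significant"] = bool(results.loc[gid, "significant"])
        rows.append(t)
    if not rows:
        cols = [
            "gene_id", "exon_id", "order_index", "chrom", "exon_start",
            "exon_end", f"mean_log2_{denominator}", f"mean_log2_{numerator}",
            "log2_ratio", "deviation", "splicing_prob", "gene_arh", "gene_p",
            "significant",
        ]
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


def overlap_de_as(
    de_genes: set[str] | pd.DataFrame,
    as_genes: set[str] | pd.DataFrame,
) -> tuple[set[str], set[str], set[str]]:
    """Partition flagged genes into (DE only, AS only, both)."""
    if isinstance(de_genes, pd.DataFrame):
        de_genes = set(de_genes.loc[de_genes["de_flag"], "gene_id"])
    if isinstance(as_genes, pd.DataFrame):
        as_genes = set(as_genes.index[as_genes["significant"]])
    both = de_genes & as_genes
    return de_genes - both, as_genes - both, both
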