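"""QTL localization, ranked top-tables and end-to-end orchestration."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import exonarh
from exonarh import arh as arh_mod
from exonarh.annotation_io import (
    FLOAT_FORMAT,
    ProbeAnnotation,
    ProbeMatrix,
    QTLInterval,
    read_probe_annotation,
    read_probe_matrix,
    read_qtl_table,
    write_probe_matrix,
    write_results,
)
from exonarh.diffexpr import select_de
from exonarh.preprocess import (
    gc_baseline_correct,
    presence_call,
    quantile_normalize,
    summarize_probes,
)
from exonarh.simulate import SimParams, simulate_experiment, truth_eval


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def gene_loci_from_annotation(ann: ProbeAnnotation) -> pd.DataFrame:
    """Derive gene intervals (min exon start, max exon end) from annotation."""
    genes = ann.gene_models()
    return pd.DataFrame(
        {
            "gene_id": list(genes),
            "chrom": [g.chrom for g in genes.values()],
            "start": [g.start for g in genes.values()],
            "end": [g.end for g in genes.values()],
        }
    )


def qtl_overlap(
    loci: pd.DataFrame,
    qtls: list[QTLInterval],
    de_genes: set[str],
    as_genes: set[str],
) -> pd.DataFrame:
    """List, per QTL, the DE and AS genes inside marker_pos ± window.

    A gene intersects the QTL when it lies on the same chromosome and its
    interval touches [marker_pos - window, marker_pos + window]; endpoints
    are inclusive, so a gene straddling the boundary by a single base is
    still listed.
    """
    rows = []
    known_chroms = set(loci["chrom"])
    for q in qtls:
        if q.chrom not in known_chroms:
            warnings.warn(f"QTL {q.name}: chromosome {q.chrom!r} absent from loci")
            rows.append((q.name, q.chrom, q.start, q.end, "", ""))
            continue
        sub = loci[
            (loci["chrom"] == q.chrom)
            & (loci["start"] <= q.end)
            & (loci["end"] >= q.start)
        ]
        hits = sub.sort_values(["start", "gene_id"])["gene_id"]
        de_hits = [g for g in hits if g in de_genes]
        as_hits = [g for g in hits if g in as_genes]
        rows.append(
            (q.name, q.chrom, q.start, q.end, ";".join(de_hits), ";".join(as_hits))
        )
    return pd.DataFrame(
        rows, columns=["qtl", "chrom", "start", "end", "de_genes", "as_genes"]
    )


def top_table(
    de: pd.DataFrame, low: float = -1.5, high: float = 1.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked top tables of strong DE genes.

    Returns (down, up): genes with log2 ratio strictly below ``low`` and
    strictly above ``high``, each sorted by |log2 ratio| descending.
    """
    flagged = de[de["de_flag"].astype(bool)] if "de_flag" in de.columns else de
    flagged = flagged.astype({"log2_ratio": float})
    down = flagged[flagged["log2_ratio"] < low]
    up = flagged[flagged["log2_ratio"] > high]

    def ranked(t: pd.DataFrame) -> pd.DataFrame:
        return (
            t.assign(_mag=t["log2_ratio"].abs())
            .sort_values(["_mag", "gene_id"], ascending=[False, True], kind="mergesort")
            .drop(columns="_mag")
            .reset_index(drop=True)
        )

    return ranked(down), ranked(up)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_all(config: dict, outdir: str | Path) -> dict[str, Path]:
    """Run the full pipeline from a config mapping and write all outputs.

    The config must carry a ``seed`` and either a ``simulate`` block
    (forwarded to :class:`exonarh.simulate.SimParams`) or an ``inputs``
    block with ``matrix``, ``annotation`` and ``condition_map``.  Optional
    blocks ``orientation``, ``presence``, ``de``, ``arh``, ``top_table``
    and ``qtl`` tune the stages.  Outputs are deterministic byte-for-byte
    for a fixed config.
    """
    if "seed" not in config or config["seed"] is None:
        raise ValueError("config is missing the mandatory 'seed'")
    seed = int(config["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- ingest or simulate ------------------------------------------------
    truth = None
    if "simulate" in config:
        params = SimParams(**{**config["simulate"], "seed": seed})
        matrix, ann, truth = stage("simulate", simulate_experiment, params)
        truth_path = outdir / "sim_truth.tsv"
        truth.to_csv(truth_path, sep="\t", float_format=FLOAT_FORMAT)
        written["sim_truth"] = truth_path
    elif "inputs" in config:
        inp = config["inputs"]
        ann = stage(
            "ingest", read_probe_annotation, inp["annotation"],
            bed=bool(inp.get("bed", False)),
        )
        matrix = stage(
            "ingest", read_probe_matrix, inp["matrix"],
            dict(inp["condition_map"]),
            already_log2=bool(inp.get("already_log2", False)),
        )
    else:
        raise ValueError("config needs a 'simulate' or an 'inputs' block")

    orientation = config.get("orientation", {})
    denom = orientation.get("denominator", matrix.conditions[0])
    numer = orientation.get("numerator", matrix.conditions[1])

    # --- normalize ---------------------------------------------------------
    pres_cfg = config.get("presence", {})
    corrected = stage(
        "gc_correct", gc_baseline_correct, matrix, ann,
        min_bin_size=int(pres_cfg.get("min_bin_size", 30)),
    )
    normalized = stage("quantile_normalize", quantile_normalize, corrected)
    norm_path = outdir / "normalized_matrix.tsv"
    write_probe_matrix(normalized, norm_path)
    written["normalized_matrix"] = norm_path

    presence = stage(
        "presence", presence_call, corrected, ann,
        q=float(pres_cfg.get("q", 0.75)),
        fraction=float(pres_cfg.get("fraction", 0.5)),
        min_bin_size=int(pres_cfg.get("min_bin_size", 30)),
    )
    pres_path = outdir / "presence.tsv"
    presence.to_csv(pres_path, sep="\t", float_format=FLOAT_FORMAT)
    written["presence"] = pres_path

    # --- differential expression ------------------------------------------
    gene_expr = stage("summarize", summarize_probes, normalized, ann, "gene")
    de_cfg = config.get("de", {})
    de = stage(
        "de", select_de, gene_expr, presence, matrix.condition_of,
        denominator=denom, numerator=numer,
        ratio_low=float(de_cfg.get("ratio_low", 0.75)),
        ratio_high=float(de_cfg.get("ratio_high", 1.33)),
        p_threshold=float(de_cfg.get("p_threshold", 0.05)),
        center=de_cfg.get("center", "mean"),
    )

    # --- alternative splicing ---------------------------------------------
    exon_expr = stage("summarize", summarize_probes, normalized, ann, "exon")
    genes = ann.gene_models()
    arh_cfg = config.get("arh", {})
    profiles = stage(
        "arh", arh_mod.exon_ratio_profiles, exon_expr, genes,
        matrix.condition_of, denom, numer,
    )
    arh_results = stage(
        "arh", arh_mod.arh_pvalues, profiles,
        B=int(arh_cfg.get("resamples", 10_000)),
        seed=seed,
        min_exons=int(arh_cfg.get("min_exons", 3)),
        alpha=float(arh_cfg.get("alpha", 0.05)),
    )
    as_exons = stage(
        "arh", arh_mod.as_exon_table, profiles, arh_results, genes, denom, numer,
        multiplier=float(arh_cfg.get("exon_flag_multiplier", 2.0)),
    )
    written.update(stage("write", write_results, de, as_exons, outdir))
    arh_path = outdir / "as_genes.tsv"
    arh_results.to_csv(arh_path, sep="\t", float_format=FLOAT_FORMAT)
    written["as_genes"] = arh_path

    # --- overlap, top tables, QTL -----------------------------------------
    de_only, as_only, both = arh_mod.overlap_de_as(de, arh_results)
    overlap_path = outdir / "overlap.json"
    overlap_path.write_text(
        json.dumps(
            {
                "de_only": sorted(de_only),
                "as_only": sorted(as_only),
                "both": sorted(both),
                "n_de": len(de_only) + len(both),
                "n_as": len(as_only) + len(both),
                "n_both": len(both),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    written["overlap"] = overlap_path

    tt_cfg = config.get("top_table", {})
    down, up = stage(
        "top_table", top_table, de,
        low=float(tt_cfg.get("low", -1.5)), high=float(tt_cfg.get("high", 1.2)),
    )
    for name, t in (("top_down", down), ("top_up", up)):
        p = outdir / f"{name}.tsv"
        t.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written[name] = p

    if "qtl" in config and config["qtl"]:
        qtl_cfg = config["qtl"]
        qtls = stage(
            "qtl", read_qtl_table, qtl_cfg["path"],
            positions_in_mb=bool(qtl_cfg.get("positions_in_mb", True)),
        )
        loci = gene_loci_from_annotation(ann)
        qtl_table = stage(
            "qtl", qtl_overlap, loci, qtls,
            set(de.loc[de["de_flag"], "gene_id"]),
            set(arh_results.index[arh_results["significant"]]),
        )
        p = outdir / "qtl_overlap.tsv"
        qtl_table.to_csv(p, sep="\t", index=False)
        written["qtl_overlap"] = p

    if truth is not None:
        metrics = stage("truth_eval", truth_eval, truth, de, arh_results)
        p = outdir / "truth_metrics.tsv"
        metrics.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written["truth_metrics"] = p

    manifest = {
        "config_sha256": _config_hash(config),
        "seed": seed,
        "package": {"exonarh": exonarh.__version__},
        "libraries": {"numpy": np.__version__, "pandas": pd.__version__},
        "outputs": {k: v.name for k, v in sorted(written.items())},
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = man_path
    return written
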