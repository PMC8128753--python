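"""Tables in, tables out: probe annotation, probe intensities, results.

All external formats are header-carrying TSV (gzip transparently supported
through the file extension).  Coordinates are 1-based inclusive internally,
the Ensembl convention; BED-style half-open input can be converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "probe_id",
    "gene_id",
    "exon_id",
    "chrom",
    "exon_start",
    "exon_end",
    "gc_count",
    "is_background",
]

#: canonical float format for every TSV we write; fixes byte-level output
FLOAT_FORMAT = "%.10g"


class AnnotationError(ValueError):
    """Raised when a probe annotation violates the data model."""


@dataclass(frozen=True)
class Exon:
    exon_id: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered list of exons, each carrying its probes.

    Exons are ordered by genomic position (chrom, start); strand is ignored.
    """

    gene_id: str
    exons: tuple[Exon, ...]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p for e in self.exons for p in e.probe_ids)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)


@dataclass(frozen=True)
class QTLInterval:
    """A quantitative-trait locus, represented as marker position ± window."""

    name: str
    chrom: str
    marker_pos: int
    window: int
    phenotypes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.marker_pos <= 0:
            raise ValueError(f"QTL {self.name}: marker_pos must be > 0")
        if self.window <= 0:
            raise ValueError(f"QTL {self.name}: window must be > 0")

    @property
    def start(self) -> int:
        return self.marker_pos - self.window

    @property
    def end(self) -> int:
        return self.marker_pos + self.window


class ProbeAnnotation:
    """Validated probe -> exon -> gene mapping with GC classes.

    Parameters
    ----------
    table
        One row per probe with columns ``probe_id, gene_id, exon_id, chrom,
        exon_start, exon_end, gc_count, is_background``.  Background control
        probes (no genomic target, used to estimate nonspecific signal per
        GC class) carry empty gene/exon ids.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
        if missing:
            raise AnnotationError(f"annotation missing columns: {missing}")
        table = table[ANNOTATION_COLUMNS].copy()
        table["probe_id"] = table["probe_id"].astype(str)
        for col in ("gene_id", "exon_id", "chrom"):
            table[col] = table[col].fillna("").astype(str)
        for col in ("exon_start", "exon_end", "gc_count"):
            table[col] = table[col].astype(np.int64)
        table["is_background"] = table["is_background"].astype(bool)
        self._validate(table)
        self.table = table.reset_index(drop=True)
        self._genes: dict[str, GeneModel] | None = None

    @staticmethod
    def _validate(t: pd.DataFrame) -> None:
        dup = t.loc[t["probe_id"].duplicated(), "probe_id"]
        if len(dup):
            raise AnnotationError(f"duplicate probe_id: {dup.iloc[0]!r}")
        fg = t[~t["is_background"]]
        bad = fg.loc[(fg["gene_id"] == "") | (fg["exon_id"] == ""), "probe_id"]
        if len(bad):
            raise AnnotationError(
                f"non-background probe without gene/exon id: {bad.iloc[0]!r}"
            )
        bg = t[t["is_background"]]
        bad = bg.loc[(bg["gene_id"] != "") | (bg["exon_id"] != ""), "probe_id"]
        if len(bad):
            raise AnnotationError(
                f"background probe with gene/exon id: {bad.iloc[0]!r}"
            )
        rev = t.loc[t["exon_start"] > t["exon_end"], "probe_id"]
        if len(rev):
            raise AnnotationError(f"exon_start > exon_end for probe {rev.iloc[0]!r}")
        neg = t.loc[t["gc_count"] < 0, "probe_id"]
        if len(neg):
            raise AnnotationError(f"negative gc_count for probe {neg.iloc[0]!r}")

    @property
    def background(self) -> pd.DataFrame:
        return self.table[self.table["is_background"]]

    @property
    def foreground(self) -> pd.DataFrame:
        return self.table[~self.table["is_background"]]

    def gene_models(self) -> dict[str, GeneModel]:
        """Assemble GeneModel objects, exons ordered by genomic position."""
        if self._genes is None:
            genes: dict[str, GeneModel] = {}
            fg = self.foreground
            for gene_id, gt in fg.groupby("gene_id", sort=True):
                exons = []
                keys = gt.groupby(
                    ["chrom", "exon_start", "exon_end", "exon_id"], sort=True
                )
                for (chrom, start, end, exon_id), et in keys:
                    exons.append(
                        Exon(
                            exon_id=exon_id,
                            chrom=chrom,
                            start=int(start),
                            end=int(end),
                            probe_ids=tuple(et["probe_id"]),
                        )
                    )
                genes[gene_id] = GeneModel(gene_id=gene_id, exons=tuple(exons))
            self._genes = genes
        return self._genes


@dataclass
class ProbeMatrix:
    """Probe x sample log2-intensity matrix with a sample -> condition map."""

    values: pd.DataFrame
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition_of = dict(self.condition_of)
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if len(self.conditions) != 2:
            raise ValueError(
                f"exactly two conditions required, got {sorted(self.conditions)}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("probe matrix contains non-finite values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.condition_of.values():
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def with_values(self, values: pd.DataFrame) -> "ProbeMatrix":
        return ProbeMatrix(values=values, condition_of=self.condition_of)


def read_probe_annotation(path: str | Path, bed: bool = False) -> ProbeAnnotation:
    """Read a probe annotation TSV.

    With ``bed=True`` exon coordinates are interpreted as 0-based half-open
    and converted to the internal 1-based inclusive convention.
    """
    t = pd.read_csv(path, sep="\t", dtype={"probe_id": str}, keep_default_na=False)
    if bed:
        t["exon_start"] = t["exon_start"].astype(np.int64) + 1
    return ProbeAnnotation(t)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_probe_matrix(
    path: str | Path,
    condition_map: dict[str, str],
    already_log2: bool = False,
) -> ProbeMatrix:
    """Read a probe intensity TSV (first column probe_id, one column per sample).

    Raw intensities must be strictly positive and are log2-transformed on
    ingestion; pass ``already_log2=True`` for pre-transformed data.  Samples
    are restricted to the keys of ``condition_map``.
    """
    t = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    t.index = t.index.astype(str)
    missing = [s for s in condition_map if s not in t.columns]
    if missing:
        raise ValueError(f"samples in condition map missing from file: {missing}")
    t = t[list(condition_map)]
    if not already_log2:
        vals = t.to_numpy(dtype=float)
        if (vals <= 0).any():
            bad = t.index[(vals <= 0).any(axis=1)][0]
            raise ValueError(f"non-positive raw intensity (probe {bad!r})")
        t = pd.DataFrame(np.log2(vals), index=t.index, columns=t.columns)
    return ProbeMatrix(values=t.astype(float), condition_of=condition_map)


def write_probe_matrix(m: ProbeMatrix, path: str | Path) -> None:
    """Write log2 intensities as TSV (full precision, round-trip safe)."""
    out = m.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_qtl_table(path: str | Path, positions_in_mb: bool = True) -> list[QTLInterval]:
    """Read QTL intervals from TSV: name, chrom, marker_pos, window, phenotypes.

    Positions are megabases by default (converted to bp); phenotypes are a
    semicolon-separated list and may be empty.
    """
    t = pd.read_csv(path, sep="\t", keep_default_na=False)
    scale = 1_000_000 if positions_in_mb else 1
    out = []
    for row in t.itertuples(index=False):
        phen = tuple(p for p in str(getattr(row, "phenotypes", "")).split(";") if p)
        out.append(
            QTLInterval(
                name=str(row.name),
                chrom=str(row.chrom),
                marker_pos=int(round(float(row.marker_pos) * scale)),
                window=int(round(float(row.window) * scale)),
                phenotypes=phen,
            )
        )
    return out


def write_results(
    de_table: pd.DataFrame | None,
    as_exon_table: pd.DataFrame | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the gene-level DE table and the exon-level splicing table.

    Row order is deterministic: p-value ascending, then id.  Returns the
    paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if de_table is not None:
        de = de_table.sort_values(
            ["wilcoxon_p", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        paths["de"] = outdir / "de_genes.tsv"
        de.to_csv(paths["de"], sep="\t", index=False, float_format=FLOAT_FORMAT)
    if as_exon_table is not None:
        as_ = as_exon_table.sort_values(
            ["gene_p", "gene_id", "order_index"], kind="mergesort"
        ).reset_index(drop=True)
        paths["as_exons"] = outdir / "as_exons.tsv"
        as_.to_csv(paths["as_exons"], sep="\t", index=False, float_format=FLOAT_FORMAT)
    return paths
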