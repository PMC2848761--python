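"""Readers and writers for the pipeline's on-disk formats.

Everything tabular is tab-separated with a header line; readers validate the
header against the documented schema and refuse files that do not match.
Coordinates are 1-based inclusive internally (GFF3 convention) and converted
to 0-based half-open only on BED output.  Gene models travel as GFF3
(gene/mRNA/exon); alignments travel either as a minimal SAM subset (via
pysam, with mismatch base qualities in an ``XQ`` tag or derived from MD) or
as a plain TSV.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
import pysam

from .htts import GeneCountTable, ReadAlignment
from .microarray import ProbeIntensityMatrix
from .region import Region

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["name", "chromosome", "position", "polymorphic", "segregating"]
INTENSITY_COLUMNS = ["probeset", "probe", "array", "intensity"]
ARRAY_DESIGN_COLUMNS = ["array", "genotype", "stage", "replicate"]
LIBRARY_DESIGN_COLUMNS = ["library", "genotype", "stage"]
ALIGNMENT_COLUMNS = [
    "library",
    "read_id",
    "chromosome",
    "start",
    "length",
    "mapq",
    "mismatch_quals",
]
COORD_COLUMNS = ["feature", "chromosome", "start", "end", "strand", "platform"]
GO_COLUMNS = ["category", "gene"]
QPCR_COLUMNS = ["genotype", "stage", "replicate", "target_ct", "reference_ct"]


@dataclass
class GeneModels:
    """Gene models with a designated longest splice variant per gene.

    ``genes``: DataFrame with columns ``gene_id, chromosome, start, end,
    strand, lv_id, lv_start, lv_end`` (lv = longest splice variant span).
    ``transcripts``: DataFrame with ``transcript_id, gene_id, chromosome,
    start, end, strand``.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame

    def __len__(self) -> int:
        return len(self.genes)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def _read_tsv(path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, required, what)
    return df


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3(path) -> GeneModels:
    """Read gene models from GFF3 and designate longest splice variants.

    Per gene the mRNA with the largest genomic span is the longest splice
    variant; a gene without mRNA children uses its own span.  An mRNA whose
    Parent is not a gene in the file is an error reported with its line
    number.  An empty file yields an empty annotation with a warning.
    """
    path = Path(path)
    text = path.read_text()
    feature_lines = [
        (i + 1, ln)
        for i, ln in enumerate(text.splitlines())
        if ln.strip() and not ln.startswith("#")
    ]
    if not feature_lines:
        warnings.warn(f"{path}: no GFF3 features; empty annotation", stacklevel=2)
        empty_g = pd.DataFrame(
            columns=[
                "gene_id", "chromosome", "start", "end", "strand",
                "lv_id", "lv_start", "lv_end",
            ]
        )
        empty_t = pd.DataFrame(
            columns=["transcript_id", "gene_id", "chromosome", "start", "end", "strand"]
        )
        return GeneModels(genes=empty_g, transcripts=empty_t)

    gene_ids = set()
    for _, ln in feature_lines:
        f = ln.split("\t")
        if len(f) >= 9 and f[2] == "gene":
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            if "ID" in attrs:
                gene_ids.add(attrs["ID"])
    for lineno, ln in feature_lines:
        f = ln.split("\t")
        if len(f) >= 9 and f[2] == "mRNA":
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            parent = attrs.get("Parent")
            if parent is None or parent not in gene_ids:
                raise ValueError(
                    f"{path}:{lineno}: mRNA without a parent gene in this file"
                )

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    t_rows, g_rows = [], []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        for m in mrnas:
            t_rows.append(
                {
                    "transcript_id": m.id,
                    "gene_id": gene.id,
                    "chromosome": m.seqid,
                    "start": m.start,
                    "end": m.end,
                    "strand": m.strand,
                }
            )
        if mrnas:
            longest = max(mrnas, key=lambda m: (m.end - m.start, m.id))
            lv_id, lv_start, lv_end = longest.id, longest.start, longest.end
        else:
            lv_id, lv_start, lv_end = gene.id, gene.start, gene.end
        g_rows.append(
            {
                "gene_id": gene.id,
                "chromosome": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand,
                "lv_id": lv_id,
                "lv_start": lv_start,
                "lv_end": lv_end,
            }
        )
    genes = pd.DataFrame(g_rows).sort_values(["chromosome", "start"]).reset_index(
        drop=True
    )
    transcripts = pd.DataFrame(
        t_rows,
        columns=["transcript_id", "gene_id", "chromosome", "start", "end", "strand"],
    )
    return GeneModels(genes=genes, transcripts=transcripts)


def write_gff3(models: GeneModels, path) -> None:
    """Write gene models as GFF3 with gene/mRNA/exon features."""
    lines = ["##gff-version 3"]
    tx_by_gene = (
        models.transcripts.groupby("gene_id")
        if len(models.transcripts)
        else None
    )
    for g in models.genes.itertuples():
        lines.append(
            f"{g.chromosome}\tseedqtl\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
            f"\tID={g.gene_id}"
        )
        txs = (
            tx_by_gene.get_group(g.gene_id).itertuples()
            if tx_by_gene is not None and g.gene_id in tx_by_gene.groups
            else []
        )
        for t in txs:
            lines.append(
                f"{t.chromosome}\tseedqtl\tmRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t."
                f"\tID={t.transcript_id};Parent={g.gene_id}"
            )
            lines.append(
                f"{t.chromosome}\tseedqtl\texon\t{t.start}\t{t.end}\t.\t{t.strand}\t."
                f"\tID={t.transcript_id}.exon1;Parent={t.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Markers and region


def read_markers(path) -> pd.DataFrame:
    """Read a marker table (``name chromosome position polymorphic segregating``
    plus optional ``call_*`` genotype columns)."""
    df = pd.read_csv(path, sep="\t")
    has_calls = any(c.startswith("call_") for c in df.columns)
    required = MARKER_COLUMNS[:-2] if has_calls else MARKER_COLUMNS
    _require_columns(df, required, "marker table")
    return df


def write_markers(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_region_bed(region: Region, path, name: str = "qtl_region") -> None:
    """Write a region as BED (0-based half-open)."""
    Path(path).write_text(
        f"{region.chromosome}\t{region.start - 1}\t{region.end}\t{name}\n"
    )


def read_region_bed(path) -> Region:
    fields = Path(path).read_text().strip().split("\t")
    return Region(chromosome=fields[0], start=int(fields[1]) + 1, end=int(fields[2]))


# ---------------------------------------------------------------------------
# Probe intensities and array design


def read_intensities(intensity_path, design_path) -> ProbeIntensityMatrix:
    """Read a long-format probe intensity table plus its array design."""
    long = _read_tsv(intensity_path, INTENSITY_COLUMNS, "intensity table")
    design = _read_tsv(design_path, ARRAY_DESIGN_COLUMNS, "array design").set_index(
        "array"
    )
    wide = long.pivot_table(
        index=["probeset", "probe"], columns="array", values="intensity", sort=True
    )
    wide.columns.name = None
    # preserve the design's array order
    wide = wide[[a for a in design.index if a in wide.columns]]
    return ProbeIntensityMatrix(values=wide, design=design)


def write_intensities(matrix: ProbeIntensityMatrix, intensity_path, design_path) -> None:
    long = (
        matrix.values.stack()
        .rename("intensity")
        .reset_index()
        .rename(columns={"level_2": "array"})
    )
    long.columns = INTENSITY_COLUMNS
    long.to_csv(intensity_path, sep="\t", index=False)
    matrix.design.reset_index(names="array").to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts and library design


def read_counts(counts_path, design_path) -> GeneCountTable:
    """Read a gene × library count matrix plus its library design."""
    df = pd.read_csv(counts_path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("count table: missing required column 'gene'")
    design = _read_tsv(design_path, LIBRARY_DESIGN_COLUMNS, "library design").set_index(
        "library"
    )
    counts = df.set_index("gene")
    counts = counts[[c for c in design.index if c in counts.columns]].astype(int)
    return GeneCountTable(counts=counts, design=design)


def write_counts(table: GeneCountTable, counts_path, design_path) -> None:
    table.counts.reset_index(names="gene").to_csv(counts_path, sep="\t", index=False)
    table.design.reset_index(names="library").to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments (TSV subset and SAM subset)


def read_alignments_tsv(path) -> dict[str, list[ReadAlignment]]:
    """Read alignments from the package's TSV subset, grouped by library.

    Records with chromosome ``*`` are unmapped and skipped (count logged);
    a malformed row raises with its line number.
    """
    df = _read_tsv(path, ALIGNMENT_COLUMNS, "alignment table")
    out: dict[str, list[ReadAlignment]] = {}
    n_unmapped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            chrom = str(row.chromosome)
            if chrom == "*":
                n_unmapped += 1
                continue
            quals = (
                ()
                if pd.isna(row.mismatch_quals) or str(row.mismatch_quals) == ""
                else tuple(int(q) for q in str(row.mismatch_quals).split(","))
            )
            rec = ReadAlignment(
                read_id=str(row.read_id),
                chromosome=chrom,
                start=int(row.start),
                length=int(row.length),
                mapq=int(row.mapq),
                mismatch_quals=quals,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed alignment record: {exc}")
        out.setdefault(str(row.library), []).append(rec)
    if n_unmapped:
        logger.info("skipped %d unmapped records", n_unmapped)
    return out


def write_alignments_tsv(records_by_library, path) -> None:
    rows = [
        {
            "library": lib,
            "read_id": r.read_id,
            "chromosome": r.chromosome,
            "start": r.start,
            "length": r.length,
            "mapq": r.mapq,
            "mismatch_quals": ",".join(str(q) for q in r.mismatch_quals),
        }
        for lib, recs in records_by_library.items()
        for r in recs
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignments_sam(path, library: str | None = None) -> list[ReadAlignment]:
    """Read a minimal SAM file into alignment records.

    Mismatch base qualities come from an ``XQ:Z`` tag (comma-separated
    Phred scores) when present, otherwise from the MD tag and the base
    qualities at mismatched positions.  Unmapped records are skipped with a
    logged count.
    """
    records = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.has_tag("XQ"):
                raw = str(rec.get_tag("XQ"))
                quals = tuple(int(q) for q in raw.split(",")) if raw else ()
            elif rec.has_tag("MD") and rec.query_qualities is not None:
                quals = tuple(
                    rec.query_qualities[qpos]
                    for qpos, _, ref in rec.get_aligned_pairs(with_seq=True)
                    if qpos is not None and ref is not None and ref.islower()
                )
            else:
                quals = ()
            records.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    chromosome=rec.reference_name,
                    start=rec.reference_start + 1,
                    length=rec.query_length or rec.reference_length or 0,
                    mapq=rec.mapping_quality,
                    mismatch_quals=quals,
                )
            )
    if n_unmapped:
        logger.info("skipped %d unmapped SAM records", n_unmapped)
    return records


def write_alignments_sam(records, chrom_lengths: dict[str, int], path) -> None:
    """Write alignment records as a minimal SAM subset.

    Sequences are emitted as ``*``; mismatch base qualities ride in an
    ``XQ:Z`` tag so the retention filter round-trips without MD bookkeeping.
    """
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    for r in records:
        xq = ",".join(str(q) for q in r.mismatch_quals)
        lines.append(
            f"{r.read_id}\t0\t{r.chromosome}\t{r.start}\t{r.mapq}\t{r.length}M"
            f"\t*\t0\t0\t*\t*\tXQ:Z:{xq}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Misc tables


def read_coordinate_map(path) -> pd.DataFrame:
    """Feature → genome coordinate map (probesets and gene models)."""
    return _read_tsv(path, COORD_COLUMNS, "coordinate map")


def read_go_map(path) -> pd.DataFrame:
    return _read_tsv(path, GO_COLUMNS, "GO annotation map")


def read_qpcr(path) -> pd.DataFrame:
    return _read_tsv(path, QPCR_COLUMNS, "qRT-PCR CT table")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
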