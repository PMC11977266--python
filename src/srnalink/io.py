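"""Readers and writers for the standard formats the toolkit touches.

Formats: FASTA (mature small RNAs, TE references, 3'UTRs), GTF (gene
annotation and the RepeatMasker/TEtranscripts rmsk-TE dialect), UCSC
chrom.sizes, and DESeq2/TEtranscripts-style results tables (TSV/CSV).

Sequence normalisation happens at read time: upper-case, U -> T, so all
downstream matching runs over a single DNA alphabet.  Significance is
always the strict ``padj < alpha`` rule (adjusted p only; raw p never
substitutes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ContractError, ParseError
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "DEGeneRecord",
    "DETEFamilyRecord",
    "TELocus",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "parse_te_fasta_header",
    "parse_te_family_name",
    "read_bed6",
    "write_bed6",
    "read_te_gtf",
    "write_te_gtf",
    "read_gene_gtf",
    "write_gene_gtf",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_de_gene_table",
    "read_de_te_table",
    "write_de_gene_table",
    "write_de_te_table",
    "attach_gene_coordinates",
    "write_table",
]

# IUPAC nucleotide codes accepted on read (post U->T normalisation).
_IUPAC = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A FASTA record, normalised to upper-case DNA alphabet."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class DEGeneRecord:
    """One row of a DESeq2-style gene results table.

    ``significant`` is True iff padj is present and strictly below the
    alpha the reader was given.  ``interval`` is attached later from a
    gene annotation (DE tables carry IDs only).
    """

    gene_id: str
    log2_fold_change: float | None
    pvalue: float | None
    padj: float | None
    significant: bool
    interval: GenomicInterval | None = None


@dataclass(frozen=True)
class DETEFamilyRecord:
    """One row of a TEtranscripts-style TE family results table."""

    family_name: str
    te_family: str
    te_class: str
    log2_fold_change: float | None
    padj: float | None
    significant: bool


@dataclass(frozen=True)
class TELocus:
    """A single annotated TE insertion with family/class taxonomy.

    ``is_de`` and the ``family_*`` statistics are inherited from the
    family-level differential expression call: locus-level DE is NOT
    implied (TEtranscripts quantifies at family resolution).
    """

    interval: GenomicInterval
    te_name: str
    te_family: str
    te_class: str
    is_de: bool = False
    family_log2fc: float | None = None
    family_padj: float | None = None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse FASTA; multi-line sequences joined, U->T, upper-cased.

    Raises :class:`ParseError` naming the line number for sequence data
    before the first header, characters outside the IUPAC alphabet, an
    empty file, or a header with an empty sequence.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has an empty sequence")
        sid, _, desc = header.partition(" ")
        records.append(SequenceRecord(sid, desc, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before first header")
                seq = line.upper().replace("U", "T")
                bad = set(seq) - _IUPAC
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal sequence characters {sorted(bad)}"
                    )
                chunks.append(seq)
    flush()
    if not records:
        raise ParseError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TE naming conventions


def parse_te_fasta_header(name: str) -> tuple[str, str, str]:
    """RepeatMasker-style ``name#class/family`` -> (name, class, family).

    Falls back to (name, "Unknown", name) for a bare name; a missing
    family token inherits the class label.
    """
    if "#" in name:
        base, _, tail = name.partition("#")
        cls, _, fam = tail.partition("/")
        cls = cls or "Unknown"
        return base, cls, fam or cls
    return name, "Unknown", name


def parse_te_family_name(composite: str) -> tuple[str, str, str]:
    """TEtranscripts row name ``name:family:class`` -> (name, family, class).

    Also accepts ``family:class`` and the RepeatMasker ``name#class/family``
    form; a bare token becomes its own family with class Unknown.
    """
    if "#" in composite:
        name, cls, fam = parse_te_fasta_header(composite)
        return name, fam, cls
    parts = composite.split(":")
    if len(parts) >= 3:
        return parts[0], parts[1], parts[2]
    if len(parts) == 2:
        return parts[0], parts[0], parts[1]
    return composite, composite, "Unknown"


# ---------------------------------------------------------------------------
# GTF

_TE_GTF_REQUIRED = ("gene_id", "transcript_id", "family_id", "class_id")


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _iter_gtf(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            yield lineno, fields


def read_te_gtf(path: str | Path) -> list[TELocus]:
    """TEtranscripts rmsk-TE dialect: per-locus records whose attributes
    carry gene_id (TE name), transcript_id (locus id), family_id, class_id.

    GTF 1-based inclusive coordinates become 0-based half-open.
    """
    path = Path(path)
    loci: list[TELocus] = []
    for feature_index, (lineno, f) in enumerate(_iter_gtf(path)):
        attrs = _parse_gtf_attributes(f[8])
        missing = [k for k in _TE_GTF_REQUIRED if k not in attrs]
        if missing:
            raise ParseError(
                f"{path}: feature {feature_index} (line {lineno}) missing "
                f"required attribute(s) {missing}"
            )
        interval = GenomicInterval(
            f[0], int(f[3]) - 1, int(f[4]), f[6] if f[6] in "+-" else ".",
            name=attrs["transcript_id"],
        )
        loci.append(
            TELocus(
                interval=interval,
                te_name=attrs["gene_id"],
                te_family=attrs["family_id"],
                te_class=attrs["class_id"],
            )
        )
    return loci


def write_te_gtf(loci: Iterable[TELocus], path: str | Path, source: str = "srnalink") -> None:
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            attrs = (
                f'gene_id "{locus.te_name}"; transcript_id "{iv.name}"; '
                f'family_id "{locus.te_family}"; class_id "{locus.te_class}";'
            )
            fh.write(
                "\t".join(
                    [
                        iv.chrom, source, "exon", str(iv.start + 1), str(iv.end),
                        ".", iv.strand if iv.strand != "." else ".", ".", attrs,
                    ]
                )
                + "\n"
            )


def read_gene_gtf(path: str | Path) -> dict[str, GenomicInterval]:
    """Map gene_id -> genomic span from a gene annotation GTF.

    ``gene`` features are used directly; if a gene_id only appears on
    sub-features (exon/transcript), their union span is taken.
    """
    path = Path(path)
    spans: dict[str, GenomicInterval] = {}
    from_gene_feature: set[str] = set()
    for feature_index, (lineno, f) in enumerate(_iter_gtf(path)):
        attrs = _parse_gtf_attributes(f[8])
        gid = attrs.get("gene_id")
        if gid is None:
            raise ParseError(
                f"{path}: feature {feature_index} (line {lineno}) has no gene_id"
            )
        iv = GenomicInterval(
            f[0], int(f[3]) - 1, int(f[4]), f[6] if f[6] in "+-" else ".", name=gid
        )
        is_gene = f[2] == "gene"
        if gid not in spans:
            spans[gid] = iv
            if is_gene:
                from_gene_feature.add(gid)
        elif is_gene:
            spans[gid] = iv
            from_gene_feature.add(gid)
        elif gid not in from_gene_feature:
            prev = spans[gid]
            if prev.chrom == iv.chrom:
                spans[gid] = replace(
                    prev, start=min(prev.start, iv.start), end=max(prev.end, iv.end)
                )
    return spans


def write_gene_gtf(
    genes: Mapping[str, GenomicInterval], path: str | Path, source: str = "srnalink"
) -> None:
    with open(path, "w") as fh:
        for gid, iv in genes.items():
            attrs = f'gene_id "{gid}"; gene_name "{gid}";'
            fh.write(
                "\t".join(
                    [
                        iv.chrom, source, "gene", str(iv.start + 1), str(iv.end),
                        ".", iv.strand if iv.strand != "." else ".", ".", attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 (0-based half-open, as internal coordinates: read/written verbatim)


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected at least 3 BED fields")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            try:
                intervals.append(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}")
    return intervals


def write_bed6(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    path = Path(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: size {parts[1]!r} is not an integer")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# DE results tables (DESeq2 / TEtranscripts dialects)

_LFC_ALIASES = ("log2FoldChange", "log2_fold_change", "logFC")
_ID_ALIASES = ("id", "gene_id", "gene", "name")


def _read_results_frame(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA", "NaN", ""])
    # DESeq2 write.csv leaves the id column unnamed
    first = df.columns[0]
    if first.startswith("Unnamed") or first == "":
        df = df.rename(columns={first: "id"})
    return df


def _pick_column(df: pd.DataFrame, aliases: Sequence[str], path: Path) -> str:
    for name in aliases:
        if name in df.columns:
            return name
    raise ParseError(
        f"{path}: no column named any of {list(aliases)}; found {list(df.columns)}"
    )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_de_gene_table(path: str | Path, alpha: float = 0.05) -> list[DEGeneRecord]:
    """DESeq2 results dialect: id, log2FoldChange, [pvalue], padj.

    Every row is returned; rows are flagged significant iff padj is
    present and strictly below ``alpha``.
    """
    path = Path(path)
    df = _read_results_frame(path)
    id_col = _pick_column(df, _ID_ALIASES, path)
    lfc_col = _pick_column(df, _LFC_ALIASES, path)
    padj_col = _pick_column(df, ("padj", "p_adj", "FDR"), path)
    has_p = "pvalue" in df.columns
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        padj = _opt_float(d[padj_col])
        records.append(
            DEGeneRecord(
                gene_id=str(d[id_col]),
                log2_fold_change=_opt_float(d[lfc_col]),
                pvalue=_opt_float(d["pvalue"]) if has_p else None,
                padj=padj,
                significant=padj is not None and padj < alpha,
            )
        )
    n_sig = sum(r.significant for r in records)
    logger.info("read %d gene records from %s; %d significant at padj < %g",
                len(records), path, n_sig, alpha)
    return records


def read_de_te_table(path: str | Path, alpha: float = 0.05) -> list[DETEFamilyRecord]:
    """TEtranscripts family-level results: composite name, log2FoldChange, padj."""
    path = Path(path)
    df = _read_results_frame(path)
    id_col = _pick_column(df, _ID_ALIASES, path)
    lfc_col = _pick_column(df, _LFC_ALIASES, path)
    padj_col = _pick_column(df, ("padj", "p_adj", "FDR"), path)
    records = []
    for _, row in df.iterrows():
        composite = str(row[id_col])
        _, family, te_class = parse_te_family_name(composite)
        padj = _opt_float(row[padj_col])
        records.append(
            DETEFamilyRecord(
                family_name=composite,
                te_family=family,
                te_class=te_class,
                log2_fold_change=_opt_float(row[lfc_col]),
                padj=padj,
                significant=padj is not None and padj < alpha,
            )
        )
    logger.info("read %d TE family records from %s; %d significant at padj < %g",
                len(records), path, sum(r.significant for r in records), alpha)
    return records


def attach_gene_coordinates(
    genes: Sequence[DEGeneRecord], annotation: Mapping[str, GenomicInterval]
) -> tuple[list[DEGeneRecord], list[str]]:
    """Join DE gene records to their annotated spans by gene_id.

    Returns (records with intervals, ids dropped for lacking annotation).
    """
    kept, dropped = [], []
    for g in genes:
        iv = annotation.get(g.gene_id)
        if iv is None:
            dropped.append(g.gene_id)
        else:
            kept.append(replace(g, interval=replace(iv, name=g.gene_id)))
    if dropped:
        logger.warning("%d DE gene ids absent from the gene annotation (dropped)",
                       len(dropped))
    return kept, dropped


# ---------------------------------------------------------------------------
# generic TSV table writing (deterministic columns, NA for missing)


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        if math.isinf(value):
            return "inf" if value > 0 else "-inf"
        return f"{value:.6g}"
    return str(value)


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str],
    header_comments: Sequence[str] = (),
) -> None:
    """Write rows as TSV with a fixed column order; missing -> NA; floats
    at 6 significant digits; optional ``#``-prefixed provenance lines."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row.get(col)) for col in columns) + "\n")


def write_de_gene_table(records: Iterable[DEGeneRecord], path: str | Path) -> None:
    write_table(
        (
            {
                "id": r.gene_id,
                "log2FoldChange": r.log2_fold_change,
                "pvalue": r.pvalue,
                "padj": r.padj,
            }
            for r in records
        ),
        path,
        columns=["id", "log2FoldChange", "pvalue", "padj"],
    )


def write_de_te_table(records: Iterable[DETEFamilyRecord], path: str | Path) -> None:
    write_table(
        (
            {
                "id": r.family_name,
                "log2FoldChange": r.log2_fold_change,
                "padj": r.padj,
            }
            for r in records
        ),
        path,
        columns=["id", "log2FoldChange", "padj"],
    )
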