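"""The five-step DE-gene / DE-TE integration pipeline (FishTEA).

TE differential expression arrives at *family* resolution (the output of
multi-mapping-aware quantifiers); TE *loci* come from a RepeatMasker-
derived annotation.  The pipeline:

1. propagates family-level DE calls onto every annotated locus,
2. overlaps significantly DE genes with loci of significantly DE families,
3. lays the features out on a concatenated-chromosome axis for plotting,
4. hypergeometric-tests each DE gene's genic region for enrichment of
   DE-family loci against the genome-wide locus population, and
5. tallies the overlapping loci by family and class.

The enrichment unit is the genic region of a significantly DE gene with
at least one overlapping TE locus: within that region, k loci of DE
families out of n total loci, drawn from a genome with K DE-family loci
out of N annotated.  Regions of overlapping genes are scored
independently, so a locus under two genes contributes to both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ContractError
from .fishpi import class_group
from .intervals import GenomicInterval, OverlapRecord, find_overlaps, natural_chrom_key
from .io import DEGeneRecord, DETEFamilyRecord, TELocus
from .stats import bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "expand_families_to_loci",
    "overlap_de_genes_tes",
    "genic_region_enrichment",
    "chromosomal_layout",
    "family_class_counts",
    "write_te_loci_table",
    "read_te_loci_table",
    "write_overlap_table",
    "read_overlap_table",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of DE-family TE loci in one genic region.

    k of the region's n loci belong to DE families; K of the genome's N
    annotated loci do.  K and N are identical across all results of a
    run.  ``significant`` uses raw p by default; with BH correction it
    uses p_adj.
    """

    region_id: str
    k: int
    n: int
    K: int
    N: int
    p: float
    p_adj: float | None = None
    significant: bool = False


def expand_families_to_loci(
    de_families: Sequence[DETEFamilyRecord],
    annotation: Sequence[TELocus],
) -> list[TELocus]:
    """Step 1: propagate family-level DE status onto every annotated locus.

    Every locus is returned; loci whose family is significantly DE carry
    ``is_de=True`` plus the family's statistics.  DE families with zero
    annotated loci are logged.
    """
    if not annotation:
        raise ContractError("empty TE annotation")
    de_by_family = {f.te_family: f for f in de_families if f.significant}
    out = []
    seen_families = set()
    for locus in annotation:
        seen_families.add(locus.te_family)
        fam = de_by_family.get(locus.te_family)
        if fam is None:
            out.append(locus)
        else:
            out.append(
                TELocus(
                    interval=locus.interval,
                    te_name=locus.te_name,
                    te_family=locus.te_family,
                    te_class=locus.te_class,
                    is_de=True,
                    family_log2fc=fam.log2_fold_change,
                    family_padj=fam.padj,
                )
            )
    orphans = set(de_by_family) - seen_families
    if orphans:
        logger.warning("%d significantly DE families have no annotated loci: %s",
                       len(orphans), sorted(orphans)[:10])
    return out


def _require_coordinates(genes: Sequence[DEGeneRecord]) -> list[DEGeneRecord]:
    with_iv = [g for g in genes if g.interval is not None]
    if genes and not with_iv:
        raise ContractError(
            "no DE gene carries coordinates; join the DE table to a gene "
            "annotation first (attach_gene_coordinates)"
        )
    return with_iv


def overlap_de_genes_tes(
    de_genes: Sequence[DEGeneRecord],
    te_loci: Sequence[TELocus],
    min_bp: int = 1,
) -> tuple[list[OverlapRecord], tuple[int, int]]:
    """Step 2: overlap significantly DE genes with DE-family TE loci.

    Only significant genes and ``is_de`` loci enter the overlap.  Returns
    the pair records plus (number of distinct DE genes with at least one
    overlap, number of distinct DE TE families represented).
    """
    sig_genes = [g for g in _require_coordinates(de_genes) if g.significant]
    de_loci = [t for t in te_loci if t.is_de]
    records = find_overlaps(
        [g.interval for g in sig_genes],
        [t.interval for t in de_loci],
        min_bp=min_bp,
    )
    family_of_locus = {t.interval.name: t.te_family for t in de_loci}
    genes_hit = {r.query_name for r in records}
    families_hit = {family_of_locus[r.subject_name] for r in records}
    summary = (len(genes_hit), len(families_hit))
    logger.info("step 2: %d DE genes overlap loci of %d DE TE families", *summary)
    return records, summary


def genic_region_enrichment(
    genes: Sequence[DEGeneRecord],
    all_loci: Sequence[TELocus],
    alpha: float = 0.05,
    flank: int = 0,
    correction: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[EnrichmentResult]:
    """Step 4: hypergeometric test of each DE gene's genic region.

    ``all_loci`` must contain both DE and non-DE loci: N (population) and
    K (successes) are taken genome-wide from it.  A region is tested iff
    its gene is significantly DE and overlaps at least one locus.  With
    ``correction='bh'`` significance uses BH-adjusted p; default is raw
    p < alpha (no correction).  Results sorted by p then region id.
    """
    if correction not in (None, "none", "bh"):
        raise ContractError(f"correction must be None or 'bh', got {correction!r}")
    sig_genes = [g for g in _require_coordinates(genes) if g.significant]
    N = len(all_loci)
    K = sum(t.is_de for t in all_loci)
    if K == 0:
        logger.warning("no DE TE locus genome-wide: all enrichment p-values are 1")
    regions = []
    for g in sig_genes:
        size = chrom_sizes.get(g.interval.chrom) if chrom_sizes else None
        regions.append(g.interval.expanded(flank, size) if flank else g.interval)
    hits = find_overlaps(regions, [t.interval for t in all_loci])
    de_names = {t.interval.name for t in all_loci if t.is_de}
    n_by_region: dict[str, int] = {}
    k_by_region: dict[str, int] = {}
    for r in hits:
        n_by_region[r.query_name] = n_by_region.get(r.query_name, 0) + 1
        if r.subject_name in de_names:
            k_by_region[r.query_name] = k_by_region.get(r.query_name, 0) + 1
    results = []
    for region in regions:
        n = n_by_region.get(region.name, 0)
        if n == 0:
            continue
        k = k_by_region.get(region.name, 0)
        p = hypergeom_upper_tail(k, n, K, N)
        results.append(EnrichmentResult(region.name, k, n, K, N, p))
    if correction == "bh" and results:
        adj = bh_adjust([r.p for r in results])
        results = [
            EnrichmentResult(r.region_id, r.k, r.n, r.K, r.N, r.p, p_adj=float(a),
                             significant=float(a) < alpha)
            for r, a in zip(results, adj)
        ]
    else:
        results = [
            EnrichmentResult(r.region_id, r.k, r.n, r.K, r.N, r.p,
                             significant=r.p < alpha)
            for r in results
        ]
    results.sort(key=lambda r: (r.p, r.region_id))
    logger.info("step 4: %d of %d tested regions significant",
                sum(r.significant for r in results), len(results))
    return results


def chromosomal_layout(
    genes: Sequence[DEGeneRecord],
    te_loci: Sequence[TELocus],
    chrom_sizes: Mapping[str, int],
    significant_regions: set[str] | None = None,
    nomenclature: str = "paper",
) -> pd.DataFrame:
    """Step 3: features on a concatenated-chromosome axis for plotting.

    Chromosomes are laid end to end in natural-sort order; each feature's
    cumulative coordinate is the chromosome offset plus its midpoint.
    Tracks: "DE gene", "DE TE Class I", "DE TE Class II" (per the chosen
    nomenclature); genes whose region is in ``significant_regions`` get
    the marker flag.
    """
    significant_regions = significant_regions or set()
    order = sorted(chrom_sizes, key=natural_chrom_key)
    offsets: dict[str, int] = {}
    acc = 0
    for chrom in order:
        offsets[chrom] = acc
        acc += chrom_sizes[chrom]
    rows = []
    for g in genes:
        if not (g.significant and g.interval is not None):
            continue
        iv = g.interval
        if iv.chrom not in offsets:
            raise ContractError(f"chromosome {iv.chrom!r} absent from chrom.sizes")
        rows.append(
            {
                "name": g.gene_id,
                "chrom": iv.chrom,
                "cumulative_pos": offsets[iv.chrom] + iv.midpoint,
                "track": "DE gene",
                "significant_region": g.gene_id in significant_regions,
            }
        )
    for t in te_loci:
        if not t.is_de:
            continue
        iv = t.interval
        if iv.chrom not in offsets:
            raise ContractError(f"chromosome {iv.chrom!r} absent from chrom.sizes")
        rows.append(
            {
                "name": iv.name,
                "chrom": iv.chrom,
                "cumulative_pos": offsets[iv.chrom] + iv.midpoint,
                "track": f"DE TE {class_group(t.te_class, nomenclature)}",
                "significant_region": False,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["name", "chrom", "cumulative_pos", "track", "significant_region"],
    )
    return df.sort_values(
        ["cumulative_pos", "track", "name"], kind="mergesort"
    ).reset_index(drop=True)


def family_class_counts(
    overlaps: Sequence[OverlapRecord],
    te_loci: Sequence[TELocus],
    nomenclature: str = "paper",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Step 5: overlapping DE TE loci tallied by family and by class.

    Each overlapping locus is counted once even if it overlaps several
    genes, so family-table and class-table totals agree.
    """
    info = {t.interval.name: (t.te_family, t.te_class) for t in te_loci}
    counted = {r.subject_name for r in overlaps if r.subject_name in info}
    fam_counts: dict[str, int] = {}
    cls_counts: dict[str, int] = {}
    for name in counted:
        family, te_class = info[name]
        fam_counts[family] = fam_counts.get(family, 0) + 1
        group = class_group(te_class, nomenclature)
        cls_counts[group] = cls_counts.get(group, 0) + 1
    fam_df = pd.DataFrame(
        sorted(fam_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["family", "count"],
    )
    cls_df = pd.DataFrame(
        sorted(cls_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["class", "count"],
    )
    return fam_df, cls_df


# ---------------------------------------------------------------------------
# pipeline intermediate tables (step outputs; each step can resume from disk)

from .io import write_table as _write_table  # noqa: E402

_TE_LOCI_COLUMNS = [
    "chrom", "start", "end", "strand", "locus_id", "te_name", "family",
    "class", "is_de", "family_log2fc", "family_padj",
]


def write_te_loci_table(loci: Sequence[TELocus], path, header_comments=()) -> None:
    _write_table(
        (
            {
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "strand": t.interval.strand,
                "locus_id": t.interval.name,
                "te_name": t.te_name,
                "family": t.te_family,
                "class": t.te_class,
                "is_de": t.is_de,
                "family_log2fc": t.family_log2fc,
                "family_padj": t.family_padj,
            }
            for t in loci
        ),
        path,
        columns=_TE_LOCI_COLUMNS,
        header_comments=header_comments,
    )


def read_te_loci_table(path) -> list[TELocus]:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    loci = []
    for row in df.to_dict("records"):
        loci.append(
            TELocus(
                GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]),
                                str(row["strand"]), str(row["locus_id"])),
                te_name=str(row["te_name"]),
                te_family=str(row["family"]),
                te_class=str(row["class"]),
                is_de=bool(row["is_de"]),
                family_log2fc=None if pd.isna(row["family_log2fc"]) else float(row["family_log2fc"]),
                family_padj=None if pd.isna(row["family_padj"]) else float(row["family_padj"]),
            )
        )
    return loci


_OVERLAP_COLUMNS = [
    "chrom", "gene_id", "gene_start", "gene_end", "locus_id", "locus_start",
    "locus_end", "overlap_bp",
]


def write_overlap_table(records, path, header_comments=()) -> None:
    _write_table(
        (
            {
                "chrom": r.query.chrom,
                "gene_id": r.query_name,
                "gene_start": r.query.start,
                "gene_end": r.query.end,
                "locus_id": r.subject_name,
                "locus_start": r.subject.start,
                "locus_end": r.subject.end,
                "overlap_bp": r.overlap_bp,
            }
            for r in records
        ),
        path,
        columns=_OVERLAP_COLUMNS,
        header_comments=header_comments,
    )


def read_overlap_table(path):
    from .intervals import OverlapRecord

    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    records = []
    for row in df.itertuples(index=False):
        q = GenomicInterval(str(row.chrom), int(row.gene_start), int(row.gene_end),
                            name=str(row.gene_id))
        s = GenomicInterval(str(row.chrom), int(row.locus_start), int(row.locus_end),
                            name=str(row.locus_id))
        records.append(OverlapRecord(q, s, int(row.overlap_bp)))
    return records


_ENRICHMENT_COLUMNS = ["region_id", "k", "n", "K", "N", "p", "p_adj", "significant"]


def write_enrichment_table(results: Sequence[EnrichmentResult], path,
                           header_comments=()) -> None:
    _write_table(
        (
            {
                "region_id": r.region_id,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ),
        path,
        columns=_ENRICHMENT_COLUMNS,
        header_comments=header_comments,
    )
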