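"""Seed-based miRNA target prediction in 3'UTRs and Fisher-exact linking
of targets to differentially expressed genes.

Canonical seed-site classes (positions on the mature miRNA, 5'->3'):

* 6mer     — perfect match to seed positions 2-7,
* 7mer-m8  — perfect match to positions 2-8,
* 7mer-A1  — positions 2-7 plus an A opposite position 1,
* 8mer     — positions 2-8 plus an A opposite position 1;

a UTR site is the reverse complement of the seed window (the A1 adenosine
is matched as a literal A on the UTR, per target-site convention).  No
alignment or duplex-energy scoring is performed: the statistic of
interest is the 2x2 association between "targeted by a DE miRNA" and
"differentially expressed", tested with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ContractError
from .fishpi import SmallRNA, _find_all
from .io import DEGeneRecord, SequenceRecord, reverse_complement
from .stats import ContingencyTable, fisher_exact_two_sided

logger = logging.getLogger(__name__)

__all__ = ["TargetHit", "LinkResult", "SITE_TYPES", "site_pattern", "find_targets",
           "link_targets_to_de"]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class TargetHit:
    """One predicted miRNA site in a gene's 3'UTR."""

    mirna_id: str
    gene_id: str
    site_position: int
    site_type: str


@dataclass(frozen=True)
class LinkResult:
    """Fisher-exact association of miRNA targeting with DE status.

    The contingency table is gene-level: a gene targeted by two miRNAs
    counts once (union), while ``per_mirna_hits`` counts DE-gene hits
    under each miRNA separately.
    """

    contingency: ContingencyTable
    targeted_de_genes: int
    de_total: int
    per_mirna_hits: dict[str, int]


def site_pattern(mirna: SmallRNA, site_type: str) -> str:
    """The UTR sequence (5'->3') that constitutes a site of this type."""
    if site_type not in SITE_TYPES:
        raise ContractError(f"site_type must be one of {SITE_TYPES}, got {site_type!r}")
    if len(mirna.sequence) < 8:
        raise ContractError(f"miRNA {mirna.id!r} shorter than 8 nt")
    seed27 = mirna.sequence[1:7]
    seed28 = mirna.sequence[1:8]
    if site_type == "6mer":
        return reverse_complement(seed27)
    if site_type == "7mer-m8":
        return reverse_complement(seed28)
    if site_type == "7mer-A1":
        return reverse_complement(seed27) + "A"
    return reverse_complement(seed28) + "A"  # 8mer


def find_targets(
    mirnas: Sequence[SmallRNA],
    utrs: Sequence[SequenceRecord],
    site_rule: str = "7mer-m8",
) -> list[TargetHit]:
    """All sites of the configured class in every UTR.

    UTR records are keyed by gene id and must be unique; a gene counts
    as targeted by a miRNA iff it has at least one site.  Deterministic
    order: miRNA input order, then UTR input order, then position.
    """
    seen: set[str] = set()
    for u in utrs:
        if u.id in seen:
            raise ContractError(f"duplicate UTR id {u.id!r}")
        seen.add(u.id)
    hits: list[TargetHit] = []
    for m in mirnas:
        pattern = site_pattern(m, site_rule)
        for u in utrs:
            for pos in _find_all(pattern, u.sequence):
                hits.append(TargetHit(m.id, u.id, pos, site_rule))
    return hits


def link_targets_to_de(
    hits: Sequence[TargetHit],
    de_genes: Sequence[DEGeneRecord],
    background: Iterable[str],
) -> LinkResult:
    """Fisher-exact enrichment of miRNA targets among DE genes.

    ``background`` is the gene universe (e.g. all genes with a p-value in
    the DE results); it must contain the DE gene ids.  Hits to genes
    outside the background are logged and dropped.  Cells: a = targeted
    and DE, b = targeted not DE, c = DE not targeted, d = neither.
    """
    bg = set(background)
    if not bg:
        raise ContractError("empty background gene universe")
    de_ids = {g.gene_id for g in de_genes if g.significant}
    outside_de = de_ids - bg
    if outside_de:
        raise ContractError(
            f"{len(outside_de)} DE gene ids are missing from the background "
            f"(e.g. {sorted(outside_de)[:5]})"
        )
    targeted: set[str] = set()
    per_mirna: dict[str, set[str]] = {}
    n_dropped = 0
    for h in hits:
        if h.gene_id not in bg:
            n_dropped += 1
            continue
        targeted.add(h.gene_id)
        per_mirna.setdefault(h.mirna_id, set()).add(h.gene_id)
    if n_dropped:
        logger.warning("%d target hits to genes outside the background dropped", n_dropped)
    a = len(targeted & de_ids)
    b = len(targeted - de_ids)
    c = len(de_ids - targeted)
    d = len(bg) - a - b - c
    table = fisher_exact_two_sided(a, b, c, d)
    return LinkResult(
        contingency=table,
        targeted_de_genes=a,
        de_total=len(de_ids),
        per_mirna_hits={m: len(g & de_ids) for m, g in sorted(per_mirna.items())},
    )
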