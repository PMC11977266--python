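"""piRNA-to-TE seed complementarity matching (the FishPi method).

A piRNA silences a transposable element through complementarity of its
5' seed window (positions 1-10 of the mature sequence for teleosts) to
the TE transcript.  A TE "matches" a piRNA when the reverse complement
of the seed occurs verbatim in the TE reference sequence (sense strand)
or the seed itself occurs (i.e. it is complementary to the minus
strand); matching is exact — no mismatch or G:U wobble model — and a TE
is counted once per piRNA regardless of how many sites it carries.

TE class nomenclature is configurable: ``paper`` mode labels DNA
transposons "Class I" and retroelements "Class II" (the usage of the
zebrafish study this tool reproduces), ``standard`` mode follows the
conventional taxonomy (Class I = retroelements via an RNA intermediate,
Class II = DNA transposons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ContractError
from .io import SequenceRecord, parse_te_fasta_header, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSpec",
    "SmallRNA",
    "TEMatch",
    "TEClassSummary",
    "extract_seed",
    "seed_sites",
    "match_pirnas_to_tes",
    "summarize_class_chart",
    "class_group",
]

#: superfamilies that mobilise via a DNA intermediate ("cut and paste")
_DNA_CLASSES = frozenset(
    {"DNA", "DNA?", "RC", "TcMar", "hAT", "PIF", "Harbinger", "CMC", "Kolobok",
     "Crypton", "Merlin", "P", "PiggyBac", "Zator", "Ginger", "Dada", "Maverick",
     "Academ", "IS3EU", "Sola", "Zisupton", "Novosib"}
)
#: superfamilies that mobilise via an RNA intermediate ("copy and paste")
_RETRO_CLASSES = frozenset(
    {"LTR", "LTR?", "LINE", "LINE?", "SINE", "SINE?", "Retroposon", "DIRS",
     "Penelope", "PLE", "ERV", "Gypsy", "BEL", "Pao", "Copia", "Ngaro"}
)

MIN_SEED_LENGTH = 6


@dataclass(frozen=True)
class SeedSpec:
    """1-based inclusive window [first, last] on the mature 5' end.

    The default 1-10 is the teleost piRNA seed convention.  ``min_length``
    is the floor on the window width (exact matching of very short seeds
    is uninformative).
    """

    first: int = 1
    last: int = 10
    min_length: int = MIN_SEED_LENGTH

    def __post_init__(self) -> None:
        if not (1 <= self.first <= self.last):
            raise ContractError(f"require 1 <= first <= last, got {self.first}..{self.last}")
        if self.length < self.min_length:
            raise ContractError(
                f"seed window {self.first}..{self.last} is shorter than the "
                f"minimum of {self.min_length} nt"
            )

    @property
    def length(self) -> int:
        return self.last - self.first + 1


@dataclass(frozen=True)
class SmallRNA:
    """A mature small RNA (DNA alphabet after read-time normalisation)."""

    id: str
    sequence: str
    rna_type: Literal["miRNA", "piRNA"] = "piRNA"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ContractError(f"small RNA {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class TEMatch:
    """One exact seed-complementary site in a TE sequence."""

    srna_id: str
    te_id: str
    te_family: str
    te_class: str
    position: int
    orientation: Literal["sense", "antisense"]


@dataclass(frozen=True)
class TEClassSummary:
    """Per-sRNA tally of distinct complementary TEs by class and family.

    ``class_by_family`` records which two-class group each matched family
    was counted under, so charts can colour families by class.
    """

    srna_id: str
    total_matched_tes: int
    count_by_class: dict[str, int]
    count_by_family: dict[str, int]
    class_by_family: dict[str, str] = field(default_factory=dict)


def extract_seed(srna: SmallRNA, spec: SeedSpec) -> str:
    """The seed window of the mature 5'->3' sequence (1-based inclusive)."""
    if len(srna.sequence) < spec.last:
        raise ContractError(
            f"small RNA {srna.id!r} is {len(srna.sequence)} nt, shorter than "
            f"seed window end {spec.last}"
        )
    return srna.sequence[spec.first - 1 : spec.last]


def _find_all(pattern: str, text: str) -> list[int]:
    """All 0-based offsets of ``pattern`` in ``text``, overlapping included."""
    hits = []
    pos = text.find(pattern)
    while pos != -1:
        hits.append(pos)
        pos = text.find(pattern, pos + 1)
    return hits


def seed_sites(seed: str, target: SequenceRecord) -> list[tuple[int, str]]:
    """All complementary sites of ``seed`` in a target sequence.

    Sense sites are occurrences of the reverse complement of the seed in
    the target; antisense sites are occurrences of the seed itself
    (complementary to the target's minus strand).  Sorted by offset then
    orientation.
    """
    if len(seed) < MIN_SEED_LENGTH:
        raise ContractError(f"seed {seed!r} shorter than {MIN_SEED_LENGTH} nt")
    if set(seed) - set("ACGT"):
        raise ContractError(f"seed {seed!r} contains ambiguous characters; exact matching only")
    rc = reverse_complement(seed)
    sites = [(pos, "sense") for pos in _find_all(rc, target.sequence)]
    sites += [(pos, "antisense") for pos in _find_all(seed, target.sequence)]
    sites.sort()
    return sites


def class_group(te_class: str, nomenclature: str = "paper") -> str:
    """Collapse a TE class/superfamily label to a two-class nomenclature.

    ``paper``: DNA transposons -> "Class I", retroelements -> "Class II"
    (the zebrafish study's usage).  ``standard``: the conventional
    inverse.  Unrecognised labels map to "Unknown".
    """
    if nomenclature not in ("paper", "standard"):
        raise ContractError(f"nomenclature must be 'paper' or 'standard', got {nomenclature!r}")
    token = te_class.split("/")[0].split("?")[0] or "Unknown"
    if token in _DNA_CLASSES or te_class.split("/")[0] in _DNA_CLASSES:
        return "Class I" if nomenclature == "paper" else "Class II"
    if token in _RETRO_CLASSES or te_class.split("/")[0] in _RETRO_CLASSES:
        return "Class II" if nomenclature == "paper" else "Class I"
    return "Unknown"


def match_pirnas_to_tes(
    pirnas: Sequence[SmallRNA],
    te_db: Sequence[SequenceRecord],
    spec: SeedSpec = SeedSpec(),
    nomenclature: str = "paper",
) -> tuple[list[TEClassSummary], list[TEMatch]]:
    """Scan every piRNA seed against every TE reference sequence.

    Returns per-piRNA class/family summaries (each TE counted once per
    piRNA even with multiple sites) plus the full site-level match list,
    both deterministically ordered (piRNA input order, then TE id).
    """
    if not te_db:
        raise ContractError("empty TE reference database")
    if nomenclature == "paper":
        logger.warning(
            "TE class nomenclature 'paper': DNA transposons are labelled "
            "'Class I' and retroelements 'Class II' (NOT the conventional "
            "taxonomy; pass nomenclature='standard' to invert)"
        )
    te_info = []
    for rec in te_db:
        name, cls, family = parse_te_fasta_header(rec.id)
        if cls == "Unknown":
            logger.warning("TE header %r not classifiable; counted under class Unknown", rec.id)
        te_info.append((rec, name, cls, family))

    summaries: list[TEClassSummary] = []
    matches: list[TEMatch] = []
    for pirna in pirnas:
        seed = extract_seed(pirna, spec)
        by_class: dict[str, int] = {}
        by_family: dict[str, int] = {}
        class_by_family: dict[str, str] = {}
        total = 0
        for rec, name, cls, family in te_info:
            sites = seed_sites(seed, rec)
            if not sites:
                continue
            group = class_group(cls, nomenclature)
            total += 1
            by_class[group] = by_class.get(group, 0) + 1
            by_family[family] = by_family.get(family, 0) + 1
            class_by_family[family] = group
            for pos, orientation in sites:
                matches.append(TEMatch(pirna.id, rec.id, family, cls, pos, orientation))
        summaries.append(
            TEClassSummary(pirna.id, total, by_class, by_family, class_by_family)
        )
    return summaries, matches


def summarize_class_chart(summary: TEClassSummary) -> pd.DataFrame:
    """Plot-ready (class, family, count) table, sorted by count descending.

    Row order is count descending then family name, so bar charts are
    stable; the count column sums to ``total_matched_tes``.
    """
    rows = [
        {
            "class": summary.class_by_family.get(family, "Unknown"),
            "family": family,
            "count": count,
        }
        for family, count in summary.count_by_family.items()
    ]
    df = pd.DataFrame(rows, columns=["class", "family", "count"])
    if df.empty:
        return df
    df = df.sort_values(["count", "family"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)
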