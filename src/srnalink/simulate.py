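"""Seeded generators for every input the toolkit reads, with planted truth.

One integer seed drives everything; identical configurations are
byte-identical on disk.  The generator emulates the *shape* of the study
this toolkit reproduces — a TE-rich teleost genome, DESeq2 gene results
with a few hundred significant genes, TEtranscripts family-level TE
results, mature small-RNA and UTR FASTA — with planted structure
(enriched genic regions, seed-complementary TE sites, a target/DE
association of chosen odds ratio) recorded in a :class:`SimTruth` object
so every pipeline can be tested end to end against known ground truth.

What it does NOT emulate: read-level noise, expression counts (padj
values are drawn directly, DE calling being upstream of this toolkit),
TE nesting/fragmentation, or phylogenetic structure among TE consensus
sequences.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError
from .fishpi import SeedSpec, SmallRNA, extract_seed
from .intervals import GenomicInterval, find_overlaps
from .io import (
    DEGeneRecord,
    DETEFamilyRecord,
    SequenceRecord,
    TELocus,
    reverse_complement,
    write_chrom_sizes,
    write_de_gene_table,
    write_de_te_table,
    write_fasta,
    write_gene_gtf,
    write_te_gtf,
)
from .mirlink import site_pattern

__all__ = ["SimConfig", "SimTruth", "default_te_catalog", "simulate_annotation",
           "simulate_de_tables", "simulate_sequences", "simulate_all"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def default_te_catalog(n_families: int = 1000) -> dict[str, tuple[str, float]]:
    """family -> (class label, sampling weight).

    A TE-rich teleost-like catalogue: mostly DNA-transposon superfamilies
    (hAT, TcMar, PIF-Harbinger, CMC, PiggyBac) with a retroelement
    minority (Gypsy/BEL/ERV LTRs, L1/Rex LINEs, SINEs); power-law (1/rank)
    weights so a few families dominate the locus count, as in real repeat
    annotations.  Two thirds of the families are DNA transposons.
    """
    catalog: dict[str, tuple[str, float]] = {}
    dna_superfamilies = ["hAT", "TcMar", "PIF", "CMC", "PiggyBac", "Kolobok"]
    retro_superfamilies = ["LTR/Gypsy", "LTR/BEL", "LTR/ERV", "LINE/L1", "LINE/Rex", "SINE"]
    n_dna = (2 * n_families) // 3
    rank = 0
    for i in range(n_dna):
        sf = dna_superfamilies[i % len(dna_superfamilies)]
        rank += 1
        catalog[f"{sf}-{i + 1}_DR"] = ("DNA/" + sf, 1.0 / rank)
    for i in range(n_families - n_dna):
        sf = retro_superfamilies[i % len(retro_superfamilies)]
        rank += 1
        catalog[f"{sf.split('/')[-1]}-{i + 1}_DR"] = (sf, 1.0 / rank)
    return catalog


@dataclass
class SimConfig:
    """Dimensions and planted effects of one synthetic study.

    Defaults mirror the reference study's result shape: ~25k expressed
    genes of which 612 are DE, a TE catalogue with 116 DE families, 12
    enriched genic regions, 7 DE miRNAs; genome and sequence sizes are
    scaled to desk-compute (25 chromosomes of 10 Mb, 1 kb TE consensus,
    300 nt UTRs) — all fields, not constants.
    """

    seed: int = 1234
    # genome
    n_chroms: int = 25
    chrom_length: int = 10_000_000
    # genes
    n_genes: int = 25_000
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    n_de_genes: int = 612
    # TE annotation
    n_te_loci: int = 120_000
    te_locus_length_range: tuple[int, int] = (150, 1_500)
    te_family_catalog: Mapping[str, tuple[str, float]] = field(
        default_factory=default_te_catalog
    )
    n_de_families: int = 116
    # planted region enrichment
    n_enriched_regions: int = 12
    enrichment_multiplier: float = 10.0
    # sequences
    n_te_seqs: int = 400
    te_seq_length: int = 1_000
    n_pirnas: int = 3
    pirna_length: int = 28
    seed_window: SeedSpec = field(default_factory=SeedSpec)
    fraction_te_with_site: float = 0.25
    n_mirnas: int = 7
    mirna_length: int = 22
    utr_length: int = 300
    site_rule: str = "7mer-m8"
    # planted miRNA-target association
    planted_or: float = 20.0
    n_target_genes: int = 500
    # significance convention
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ContractError("seed must be non-negative")
        if self.n_de_genes > self.n_genes:
            raise ContractError("n_de_genes exceeds n_genes")
        if self.n_de_families > len(self.te_family_catalog):
            raise ContractError("n_de_families exceeds the family catalogue size")
        if self.n_enriched_regions > self.n_de_genes:
            raise ContractError("n_enriched_regions exceeds n_de_genes")
        if self.n_target_genes > self.n_genes:
            raise ContractError("n_target_genes exceeds n_genes")
        if not 0.0 <= self.fraction_te_with_site <= 1.0:
            raise ContractError("fraction_te_with_site must lie in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth, re-derivable by parsing the emitted files."""

    de_gene_ids: list[str] = field(default_factory=list)
    de_family_names: list[str] = field(default_factory=list)
    enriched_region_ids: list[str] = field(default_factory=list)
    #: region id -> {"k": DE-family loci overlapping, "n": all loci overlapping}
    region_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    #: family -> number of annotated loci
    family_locus_counts: dict[str, int] = field(default_factory=dict)
    #: te sequence id -> {pirna id -> planted site offset}
    te_site_offsets: dict[str, dict[str, int]] = field(default_factory=dict)
    targeted_gene_ids: list[str] = field(default_factory=list)
    #: gene id -> miRNA id planted in its UTR
    target_mirna_of_gene: dict[str, str] = field(default_factory=dict)
    #: planted 2x2 (a = targeted & DE, b, c, d)
    planted_contingency: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _random_dna_batch(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n == 0:
        return []
    block = _BASES[rng.integers(0, 4, size=(n, length))]
    return [row.tobytes().decode() for row in block]


def _place_nonoverlapping(
    rng: np.random.Generator, lengths: np.ndarray, chrom_length: int
) -> np.ndarray:
    """Uniform non-overlapping starts for segments of the given lengths."""
    total = int(lengths.sum())
    slack = chrom_length - total
    if slack < 0:
        raise ContractError(
            f"cannot place {len(lengths)} features totalling {total} bp on a "
            f"{chrom_length} bp chromosome; increase chrom_length"
        )
    gaps = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
    return gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])


def _rng_for(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([cfg.seed, stream])


def simulate_annotation(
    cfg: SimConfig, outdir: str | Path
) -> tuple[dict[str, GenomicInterval], list[TELocus], dict[str, int], SimTruth]:
    """Emit gene GTF, rmsk-style TE GTF and chrom.sizes with planted truth.

    Genes are placed without overlap; TE loci land uniformly except in
    the chosen enriched regions, which additionally receive
    ``enrichment_multiplier`` times the genome-wide density of DE-family
    loci.  Identical configurations are byte-identical on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng_for(cfg, 0)
    truth = SimTruth()

    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    chrom_names = list(chrom_sizes)

    # --- genes, spread evenly across chromosomes, non-overlapping ---
    genes: dict[str, GenomicInterval] = {}
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    gene_index = 0
    for chrom, count in zip(chrom_names, per_chrom):
        if count == 0:
            continue
        lengths = rng.integers(
            cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=count
        )
        starts = _place_nonoverlapping(rng, lengths, cfg.chrom_length)
        strands = rng.choice(np.array(["+", "-"]), size=count)
        for s, ln, strand in zip(starts, lengths, strands):
            gene_index += 1
            gid = f"gene{gene_index:05d}"
            genes[gid] = GenomicInterval(chrom, int(s), int(s + ln), str(strand), gid)

    gene_ids = list(genes)
    de_gene_ids = sorted(
        rng.choice(gene_ids, size=cfg.n_de_genes, replace=False).tolist()
    ) if cfg.n_de_genes else []
    enriched_ids = sorted(
        rng.choice(de_gene_ids, size=cfg.n_enriched_regions, replace=False).tolist()
    ) if cfg.n_enriched_regions else []
    truth.de_gene_ids = de_gene_ids
    truth.enriched_region_ids = enriched_ids

    # --- TE families ---
    families = list(cfg.te_family_catalog)
    weights = np.array([cfg.te_family_catalog[f][1] for f in families], dtype=float)
    weights /= weights.sum()
    # DE status is independent of family abundance (uniform choice)
    de_families = sorted(
        rng.choice(families, size=cfg.n_de_families, replace=False).tolist()
    ) if cfg.n_de_families else []
    truth.de_family_names = de_families
    de_family_set = set(de_families)

    # --- baseline TE loci, uniform over the genome ---
    loci: list[TELocus] = []
    lengths = rng.integers(
        cfg.te_locus_length_range[0], cfg.te_locus_length_range[1] + 1,
        size=cfg.n_te_loci,
    )
    chrom_idx = rng.integers(0, cfg.n_chroms, size=cfg.n_te_loci)
    fam_idx = rng.choice(len(families), size=cfg.n_te_loci, p=weights)
    strands = rng.choice(np.array(["+", "-"]), size=cfg.n_te_loci)
    for i in range(cfg.n_te_loci):
        chrom = chrom_names[int(chrom_idx[i])]
        ln = int(lengths[i])
        start = int(rng.integers(0, cfg.chrom_length - ln))
        family = families[int(fam_idx[i])]
        cls = cfg.te_family_catalog[family][0]
        name = f"te{i + 1:06d}"
        loci.append(
            TELocus(
                GenomicInterval(chrom, start, start + ln, str(strands[i]), name),
                te_name=family, te_family=family, te_class=cls,
            )
        )

    # --- planted enrichment: extra DE-family loci inside enriched regions ---
    genome_bp = cfg.n_chroms * cfg.chrom_length
    de_weights = np.array(
        [weights[i] if families[i] in de_family_set else 0.0 for i in range(len(families))]
    )
    density = cfg.n_te_loci / genome_bp if genome_bp else 0.0
    de_density = density * de_weights.sum()
    if de_weights.sum() > 0:
        de_weights = de_weights / de_weights.sum()
    K0 = sum(1 for t in loci if t.te_family in de_family_set)
    extra_index = cfg.n_te_loci
    for gid in enriched_ids:
        region = genes[gid]
        expected = de_density * len(region)
        expected_n = int(np.ceil(density * len(region)))
        n_extra = max(4, int(round(cfg.enrichment_multiplier * expected)))
        # floor: the planted signal must be analytically unambiguous
        # (upper-tail p below 1e-6 at the expected region composition)
        if cfg.n_te_loci:
            from .stats import hypergeom_upper_tail

            while (
                n_extra < 100
                and hypergeom_upper_tail(
                    n_extra, n_extra + expected_n, K0 + n_extra, cfg.n_te_loci + n_extra
                )
                > 1e-6
            ):
                n_extra += 1
        for _ in range(n_extra):
            family = families[int(rng.choice(len(families), p=de_weights))]
            cls = cfg.te_family_catalog[family][0]
            ln = int(rng.integers(*cfg.te_locus_length_range))
            lo = max(0, region.start - ln + 1)
            hi = max(lo + 1, region.end - 1)
            start = int(rng.integers(lo, hi))
            extra_index += 1
            name = f"te{extra_index:06d}"
            end = min(start + ln, cfg.chrom_length)
            loci.append(
                TELocus(
                    GenomicInterval(region.chrom, start, end, "+", name),
                    te_name=family, te_family=family, te_class=cls,
                )
            )

    for locus in loci:
        truth.family_locus_counts[locus.te_family] = (
            truth.family_locus_counts.get(locus.te_family, 0) + 1
        )

    # realized per-region counts for the enriched regions
    if enriched_ids:
        region_ivs = [genes[g] for g in enriched_ids]
        de_locus_names = {
            t.interval.name for t in loci if t.te_family in de_family_set
        }
        for rec in find_overlaps(region_ivs, [t.interval for t in loci]):
            counts = truth.region_counts.setdefault(
                rec.query_name, {"k": 0, "n": 0}
            )
            counts["n"] += 1
            if rec.subject_name in de_locus_names:
                counts["k"] += 1

    write_gene_gtf(genes, outdir / "genes.gtf")
    write_te_gtf(loci, outdir / "te_loci.gtf")
    write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")
    return genes, loci, chrom_sizes, truth


def simulate_de_tables(
    cfg: SimConfig, truth: SimTruth, outdir: str | Path
) -> tuple[list[DEGeneRecord], list[DETEFamilyRecord]]:
    """Emit DESeq2-style gene results and TEtranscripts-style TE results.

    padj for planted DE members is alpha * Beta(1, 50) (strictly below
    alpha); non-members get alpha + (1 - alpha) * U.  Fold changes of DE
    members are drawn away from zero with random sign.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng_for(cfg, 1)
    de_genes = set(truth.de_gene_ids)

    gene_records = []
    for i in range(cfg.n_genes):
        gid = f"gene{i + 1:05d}"
        if gid in de_genes:
            padj = cfg.alpha * min(float(rng.beta(1, 50)), 0.999999)
            lfc = float(rng.choice([-1, 1]) * rng.normal(2.0, 0.6))
        else:
            padj = cfg.alpha + (1 - cfg.alpha) * float(rng.uniform())
            lfc = float(rng.normal(0.0, 0.3))
        pvalue = padj * float(rng.uniform(0.05, 1.0))
        gene_records.append(
            DEGeneRecord(gid, lfc, pvalue, padj, significant=padj < cfg.alpha)
        )

    de_families = set(truth.de_family_names)
    te_records = []
    for family in cfg.te_family_catalog:
        cls = cfg.te_family_catalog[family][0]
        if family in de_families:
            padj = cfg.alpha * min(float(rng.beta(1, 50)), 0.999999)
            lfc = float(rng.choice([-1, 1]) * rng.normal(1.5, 0.5))
        else:
            padj = cfg.alpha + (1 - cfg.alpha) * float(rng.uniform())
            lfc = float(rng.normal(0.0, 0.3))
        te_records.append(
            DETEFamilyRecord(
                family_name=f"{family}:{family}:{cls.split('/')[0]}",
                te_family=family,
                te_class=cls.split("/")[0],
                log2_fold_change=lfc,
                padj=padj,
                significant=padj < cfg.alpha,
            )
        )

    write_de_gene_table(gene_records, outdir / "de_genes.tsv")
    write_de_te_table(te_records, outdir / "de_te_families.tsv")
    return gene_records, te_records


def _excise(sequence: str, patterns: Sequence[str], rng: np.random.Generator) -> str:
    """Destroy every occurrence of the patterns by point substitution."""
    seq = list(sequence)
    changed = True
    while changed:
        changed = False
        text = "".join(seq)
        for pat in patterns:
            pos = text.find(pat)
            if pos != -1:
                mid = pos + len(pat) // 2
                alternatives = [b for b in "ACGT" if b != seq[mid]]
                seq[mid] = alternatives[int(rng.integers(0, 3))]
                changed = True
                break
    return "".join(seq)


def _solve_planted_a(odds_ratio: float, T: int, D: int, N: int) -> int:
    """The in-both cell a for which (a*d)/(b*c) equals the planted OR."""
    if odds_ratio == 1.0:
        a = T * D / N
    else:
        # (1-OR) a^2 + (N - T - D + OR (T + D)) a - OR T D = 0
        A = 1.0 - odds_ratio
        B = (N - T - D) + odds_ratio * (T + D)
        C = -odds_ratio * T * D
        disc = B * B - 4 * A * C
        a = (-B + np.sqrt(disc)) / (2 * A)
        if not (0 <= a <= min(T, D)):
            a = (-B - np.sqrt(disc)) / (2 * A)
    a = int(round(float(a)))
    return int(np.clip(a, max(0, T + D - N), min(T, D)))


def simulate_sequences(
    cfg: SimConfig, truth: SimTruth, outdir: str | Path
) -> dict[str, list[SequenceRecord]]:
    """Emit TE, piRNA, miRNA and 3'UTR FASTA with planted sites.

    A configured fraction of TE consensus sequences receives a sense
    seed-complementary site for each planted piRNA (and accidental sites
    are excised elsewhere, so FishPi truth is exact).  UTRs of genes
    chosen to realise the planted odds ratio receive one miRNA site each;
    all other UTRs are scrubbed of accidental sites.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng_for(cfg, 2)

    # --- small RNAs ---
    pirnas = [
        SmallRNA(f"piR-sim-{i + 1}", _random_dna(rng, cfg.pirna_length), "piRNA")
        for i in range(cfg.n_pirnas)
    ]
    mirnas = [
        SmallRNA(f"sim-miR-{i + 1}", _random_dna(rng, cfg.mirna_length), "miRNA")
        for i in range(cfg.n_mirnas)
    ]

    # --- TE reference sequences with planted piRNA sites ---
    seeds = [extract_seed(p, cfg.seed_window) for p in pirnas]
    pirna_patterns = [reverse_complement(s) for s in seeds] + list(seeds)
    families = list(cfg.te_family_catalog)
    n_with_site = int(round(cfg.fraction_te_with_site * cfg.n_te_seqs))
    te_seqs: list[SequenceRecord] = []
    raw_te = _random_dna_batch(rng, cfg.n_te_seqs, cfg.te_seq_length)
    weights = np.array([cfg.te_family_catalog[f][1] for f in families], dtype=float)
    weights /= weights.sum()
    fam_choice = rng.choice(len(families), size=cfg.n_te_seqs, p=weights)
    for i in range(cfg.n_te_seqs):
        family = families[int(fam_choice[i])]
        cls = cfg.te_family_catalog[family][0]
        header = f"{family}-cons{i + 1}#{cls.split('/')[0]}/{family}"
        seq = _excise(raw_te[i], pirna_patterns, rng)
        if i < n_with_site:
            offsets = {}
            for pirna, seed in zip(pirnas, seeds):
                site = reverse_complement(seed)
                pos = int(rng.integers(0, cfg.te_seq_length - len(site) + 1))
                seq = seq[:pos] + site + seq[pos + len(site):]
                offsets[pirna.id] = pos
            # late insertions may clobber earlier ones; keep verified offsets
            offsets = {
                pid: pos
                for pid, pos in offsets.items()
                if seq[pos : pos + cfg.seed_window.length]
                == reverse_complement(seeds[[p.id for p in pirnas].index(pid)])
            }
            truth.te_site_offsets[header] = offsets
        te_seqs.append(SequenceRecord(header, "", seq))

    # --- targeted genes realising the planted odds ratio ---
    de_set = set(truth.de_gene_ids)
    gene_ids = [f"gene{i + 1:05d}" for i in range(cfg.n_genes)]
    N, D, T = cfg.n_genes, len(de_set), cfg.n_target_genes
    utr_records: list[SequenceRecord] = []
    if cfg.n_genes:
        a = _solve_planted_a(cfg.planted_or, T, D, N) if T else 0
        de_list = sorted(de_set)
        non_de_list = [g for g in gene_ids if g not in de_set]
        targeted = set(
            rng.choice(de_list, size=a, replace=False).tolist()
            + rng.choice(non_de_list, size=T - a, replace=False).tolist()
        )
        truth.targeted_gene_ids = sorted(targeted)
        truth.planted_contingency = {
            "a": a, "b": T - a, "c": D - a, "d": N - T - D + a,
        }

        mir_patterns = [site_pattern(m, cfg.site_rule) for m in mirnas]
        raw_utr = _random_dna_batch(rng, len(gene_ids), cfg.utr_length)
        for gid, raw in zip(gene_ids, raw_utr):
            seq = _excise(raw, mir_patterns, rng)
            if gid in targeted:
                j = int(rng.integers(0, len(mirnas)))
                pat = mir_patterns[j]
                pos = int(rng.integers(0, cfg.utr_length - len(pat) + 1))
                seq = seq[:pos] + pat + seq[pos + len(pat):]
                truth.target_mirna_of_gene[gid] = mirnas[j].id
            utr_records.append(SequenceRecord(gid, "", seq))

    write_fasta(pirnas_to_records(pirnas), outdir / "pirnas.fa")
    write_fasta(pirnas_to_records(mirnas), outdir / "mirnas.fa")
    write_fasta(te_seqs, outdir / "te_reference.fa")
    if utr_records:
        write_fasta(utr_records, outdir / "utrs.fa")
    return {
        "pirnas": pirnas_to_records(pirnas),
        "mirnas": pirnas_to_records(mirnas),
        "te_reference": te_seqs,
        "utrs": utr_records,
    }


def pirnas_to_records(srnas: Sequence[SmallRNA]) -> list[SequenceRecord]:
    return [SequenceRecord(s.id, s.rna_type, s.sequence) for s in srnas]


def simulate_all(cfg: SimConfig, outdir: str | Path) -> SimTruth:
    """Run all three generator stages and write ``truth.json``."""
    outdir = Path(outdir)
    _, _, _, truth = simulate_annotation(cfg, outdir)
    simulate_de_tables(cfg, truth, outdir)
    simulate_sequences(cfg, truth, outdir)
    truth.to_json(outdir / "truth.json")
    return truth
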