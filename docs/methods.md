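# Methods

## Scope and model

`srnalink` operates strictly downstream of read processing: differential
expression of genes (DESeq2-style results tables) and of TE families
(TEtranscripts-style tables) are *inputs*, never recomputed. The toolkit
contributes the integrative layer: sequence-level complementarity between
small RNAs and their putative targets, interval-level co-location of DE
genes and DE TE loci, and the exact-test statistics that decide whether
either association exceeds chance.

Significance of an input DE record is always the strict rule
`padj < alpha` (default alpha = 0.05); a missing padj is never
significant and raw p-values never substitute for adjusted ones.

### piRNA–TE complementarity (fishpi)

The seed is a 1-based inclusive window on the mature 5' end, default
1–10 (the teleost piRNA convention); windows shorter than 6 nt are
rejected because exact matches of very short patterns are uninformative.
Matching is exact string matching over the DNA alphabet (U→T and
upper-casing happen at read time): a *sense* site is an occurrence of
the seed's reverse complement in the TE sequence, an *antisense* site an
occurrence of the seed itself (equivalently, complementarity to the TE's
minus strand — TE consensus orientation in reference FASTAs is
arbitrary, so both strands are scanned). There is no mismatch or G:U
wobble model and no thermodynamic scoring. A TE counts as matched by a
piRNA if it has at least one site in either orientation, and each TE is
counted once per piRNA regardless of site multiplicity, because the
quantity of interest is "how many TEs could this piRNA engage".

TE class nomenclature is explicitly two-valued. `paper` mode (default,
announced loudly in the log) labels DNA transposons "Class I" and
retroelements "Class II", matching the zebrafish study whose outputs
this tool reproduces; `standard` mode is the conventional taxonomy
(Class I = RNA-intermediate retroelements). The mapping from
RepeatMasker class/superfamily strings to the two groups covers the
common superfamilies; unrecognised labels are reported as "Unknown"
rather than silently guessed.

### DE-gene / DE-TE integration (fishtea)

TE differential expression arrives at family resolution, while the
RepeatMasker-derived annotation is per locus. Step 1 therefore
propagates each significantly DE family's statistics onto all of its
annotated loci, with explicit provenance that locus-level DE is *not*
implied. Step 2 overlaps significantly DE genes with DE-family loci;
overlap is strand-blind (TE insertions act on genes from either strand)
with a `--same-strand` option, requires at least `min_bp = 1` shared
base, and uses 0-based half-open coordinates internally (GTF input is
shifted on read, shifted back on write). Step 3 lays features out on a
concatenated-chromosome axis (natural sort order; feature position =
chromosome offset + interval midpoint) for the genome-wide plot. Step 4
is the enrichment test below. Step 5 tallies overlapping DE loci by
family and class, counting each locus once even when it overlaps
several genes.

**Enrichment unit.** A tested region is the genomic footprint of a
significantly DE gene (optionally flanked, clipped to the chromosome)
that overlaps at least one annotated TE locus. Within the region, k of
the n overlapping loci belong to DE families; genome-wide, K of the N
annotated loci do. The p-value is the exact hypergeometric upper tail
P(X ≥ k). K and N are identical across all regions of a run; regions of
overlapping genes are scored independently, so a shared locus
contributes to both (documented, and asserted in the tests). Raw
p < 0.05 is the default call — matching the convention of the analyses
this reproduces — with Benjamini–Hochberg adjustment behind
`--correction bh`. Output is sorted by p, ties broken by region id.

### miRNA target linking (mirlink)

Alignment-based target scoring is deliberately out of scope; canonical
seed-site classes stand in for it, since the statistic of interest is
the association, not the per-site score. For a mature miRNA m (5'→3'),
a UTR site is the reverse complement of seed positions 2–7 (6mer) or
2–8 (7mer-m8), optionally followed by a literal A opposite position 1
(7mer-A1, 8mer). Default rule: 7mer-m8. A gene is targeted by a miRNA
iff its UTR has ≥ 1 site.

The 2×2 table is gene-level: a = targeted ∧ DE, b = targeted ∧ not DE,
c = DE ∧ not targeted, d = neither, over a declared background universe
(default: all genes with a p-value in the DE table; an external list can
be supplied for cross-tissue designs). A gene targeted by several
miRNAs counts once in the table, while the per-miRNA report counts it
under each miRNA — the union and the per-miRNA tallies answer different
questions and both are emitted. The odds ratio is the sample
cross-product ratio ad/bc (+∞ when bc = 0 with ad > 0; flagged
undefined when both products vanish), matching the default of the
scripting-stack Fisher implementations practitioners use; a
Haldane–Anscombe (+0.5) variant is available behind a flag.

## Exact statistics (stats)

All combinatorics run in log-gamma space so genome-scale margins never
overflow. The hypergeometric upper tail sums exact log-binomial terms
over the support with a log-sum-exp reduction. The two-sided Fisher p
uses the point-probability method — the sum over all tables with the
observed margins whose point probability is at most the observed one —
with a relative slack of 1e-7 when comparing point probabilities to
absorb floating-point rounding of log-space terms. BH adjustment is the
textbook step-up with a cumulative minimum, capped at 1. Conditional-MLE
odds ratios, mid-p variants and chi-square approximations are
non-goals. The test suite checks both tests against exhaustive
integer-arithmetic enumeration (all hypergeometric parameters with
N ≤ 30 to 1e-12; all 2×2 tables with total ≤ 40 to 1e-10) and against
scipy as an independent implementation at genome-scale margins.

## Synthetic data (simulate)

The generator emulates the *shape* of the reference study and emits
every input format: gene GTF, rmsk-dialect TE GTF, chrom.sizes, DESeq2-
and TEtranscripts-style results tables, and piRNA/miRNA/TE/3'UTR FASTA,
plus a `truth.json` with the planted structure. One integer seed drives
independent, reproducible streams per stage; identical configurations
are byte-identical on disk.

Default dimensions mirror the study's result shape and were chosen once:
25 chromosomes × 10 Mb; 25,000 genes (2–8 kb) of which 612 DE; a
1,000-family TE catalogue (two-thirds DNA transposons, 1/rank weights so
a few families dominate, as in real repeat annotations) with 116 DE
families chosen uniformly (DE status independent of abundance); 120,000
TE loci (150–1,500 bp), giving each gene on the order of a couple of
loci so ~90% of DE genes have TE context; 12 enriched regions; 7
miRNAs; 3 piRNAs with 28-nt sequences; 1 kb TE consensus and 300-nt
UTRs (sequence lengths are compute-scaled, not biological medians; all
are config fields).

Planted structure and what it guarantees:

* **Enriched regions** receive `enrichment_multiplier` (default 10×) the
  genome-wide density of DE-family loci, with a floor that raises the
  planted count until the region's expected composition has an analytic
  upper-tail p below 1e-6 — so planted signal is unambiguous by
  construction, not by luck.
* **piRNA sites**: a configured fraction of TE consensus sequences gets
  one sense site per piRNA at a recorded offset; accidental occurrences
  of any seed pattern are excised everywhere by point substitution, so
  FishPi ground truth is exact (at fraction 0, exactly zero matches).
* **Target/DE association**: the in-both cell a solving
  ad/bc = planted OR for the configured margins is realised *exactly* —
  that many DE genes and (targets − a) non-DE genes receive one miRNA
  site each, and all other UTRs are scrubbed of accidental sites. The
  pipeline therefore recovers the planted odds ratio up to the integer
  rounding of a.

What the generator does **not** emulate: read-level noise or counts
(padj values are drawn directly — alpha·Beta(1,50) for planted DE
members, uniform above alpha otherwise — because DE calling is upstream
of this toolkit), TE nesting and fragmentation, sequence composition
bias, homology between TE families, or UTR length variation. Passing
tests therefore demonstrate correctness of the matching, overlap and
testing machinery under clean planted signal, not robustness to
alignment artefacts or annotation errors in real data.

## Numerical and design notes

* Coordinates: one internal convention (0-based half-open) with
  conversion only at format boundaries, preventing off-by-one drift.
* Overlap engine: per-chromosome interval trees; results are invariant
  to input order and reported in a deterministic (chrom, query start,
  subject start, names) order. Verified against the all-pairs oracle.
* Deterministic ordering everywhere: enrichment sorted by (p, region
  id); matches by input order then position; summaries by count then
  name — so reruns are checksum-identical.
* Degenerate inputs: K = 0 (no DE locus genome-wide) yields p = 1 with
  a warning rather than an error; an all-zero 2×2 table, an empty TE
  database and an empty background are contract violations.
* The FishTEA chromosomal plot recomputes enrichment internally for its
  significance markers, so running step 3 before or after step 4
  produces identical bytes and full runs equal chained per-step runs.
* Null calibration: the region test is exact and therefore
  conservative; with few loci per region the realised false-positive
  rate sits well below alpha (the expected behaviour for sparse real
  genomes), and approaches alpha as regions carry more loci. The
  calibration test uses regions with tens to hundreds of loci, where
  the discrete test is close to its nominal level.

## Problem sizes used by the checks

The acceptance script simulates the full default shape above (~10 s).
The test suite's heavier checks use: exhaustive enumeration sweeps
(N ≤ 30, table totals ≤ 40); 200 random 1,000×1,000 interval instances;
1,000 random seed/target scans with targets up to 5 kb; a 2,000-region
null with ~200,000 loci; a ~1,900-region planted-recovery study; and
3 × 20 seeded replicates of the odds-ratio recovery at a 20,000-gene
background. The whole suite runs in well under five minutes on one CPU.

## Known limitations

* Exact matching only: a single mismatch or wobble pair abolishes a
  piRNA–TE match, which understates biological targeting breadth.
* Family-level DE propagated to loci can only support locus-resolution
  claims as "a locus of a DE family", never "a DE locus".
* The enrichment test treats loci as exchangeable draws; clustered TE
  insertions violate this mildly and make the test anti-conservative in
  heavily nested repeat regions.
* The two-class TE taxonomy is a deliberate simplification; superfamily
  resolution is preserved in the per-family outputs.
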