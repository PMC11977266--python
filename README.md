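# srnalink

Link sperm small RNAs to transposable elements (TEs) and embryonic gene
expression. `srnalink` is a desk-scale toolkit for the downstream,
integrative half of a sperm sRNA-seq / embryo RNA-seq study — it starts
where DESeq2 and TEtranscripts stop, and answers three questions:

1. **Which TEs could a piRNA silence?** Exact complementarity matching of
   a piRNA's 5' seed window (positions 1–10 for teleosts) against a TE
   reference FASTA, summarised by TE family and class (`srnalink.fishpi`).
2. **Do differentially expressed genes co-locate with differentially
   expressed TEs?** A five-step pipeline that attaches RepeatMasker locus
   coordinates to family-level TE DE calls, overlaps them with DE genes,
   plots everything on a concatenated-chromosome axis, and tests each
   genic region for enrichment (`srnalink.fishtea`).
3. **Are miRNA targets enriched among DE genes?** Canonical seed-site
   prediction (8mer / 7mer-m8 / 7mer-A1 / 6mer) in 3'UTRs, linked to DE
   status with Fisher's exact test (`srnalink.mirlink`).

A seeded synthetic-data generator (`srnalink.simulate`) emulates every
input format with planted ground truth, so the whole toolkit is testable
end to end without downloading any reference data.

## The statistics at the core

**Genic-region enrichment.** For the genic region of a significantly DE
gene overlapping n TE loci, of which k belong to significantly DE
families, drawn from a genome with N annotated loci of which K are
DE-family, the enrichment p-value is the hypergeometric upper tail

    p = P(X ≥ k),  X ~ Hypergeom(N, K, n)
      = Σ_{i=k..min(n,K)} C(K,i) C(N−K, n−i) / C(N,n)

computed exactly in log-gamma space. A region is called enriched at raw
p < 0.05 by default (Benjamini–Hochberg correction is available).

**Target/DE association.** With a = genes both miRNA-targeted and DE,
b = targeted only, c = DE only, d = neither (over a declared background
gene universe), the association is summarised by the sample odds ratio
OR = ad/bc and the two-sided Fisher exact p (point-probability method,
all tables with the observed margins whose probability does not exceed
the observed table's).

Both tests, plus BH adjustment, live in `srnalink.stats` and are checked
against exhaustive enumeration in the test suite.

## Worked example

`examples/02_te_gene_overlap_enrichment.py` simulates a 5-chromosome
genome with 200 DE genes, 10,000 TE loci, 116 DE TE families and 4
planted enriched regions, then runs the overlap/enrichment pipeline:

```
51 of 200 DE genes overlap loci of 47 of 116 DE TE families
8 of 193 tested genic regions enriched at raw p < 0.05
planted enriched regions: ['gene00291', 'gene00320', 'gene00607', 'gene00793']
top regions (k = DE-family loci in region, n = all loci in region):
  gene00793: k=7 n=7 (K=610, N=10031) p=2.98e-09
  gene00320: k=8 n=12 (K=610, N=10031) p=7.12e-08
  gene00291: k=8 n=14 (K=610, N=10031) p=3.87e-07
  gene00607: k=8 n=16 (K=610, N=10031) p=1.49e-06
  gene00004: k=2 n=3 (K=610, N=10031) p=0.0106
```

The four planted regions (about 10× the genome-wide density of DE-family
loci) surface at the top with p far below 0.05; the remaining tested
regions behave like a 0.05-level null, so the handful of extra calls is
the expected false-positive count. The other examples print the piRNA→TE
class summary and the recovered planted odds ratio (planted 20.0,
estimated 20.13, Fisher p ≈ 1e-77).

## Command line

Every stage is also a subcommand writing TSV outputs with provenance
headers and a JSON run manifest:

```bash
srnalink simulate --config sim.yaml --seed 42 --out inputs/
srnalink fishpi   --pirnas pir.fa --te-db te.fa --seed 1:10 --out run/fp
srnalink fishtea  --genes de_genes.tsv --gene-gtf genes.gtf \
                  --te-families de_tes.tsv --te-gtf rmsk.gtf \
                  --chrom-sizes chrom.sizes --out run/ft   # or --step 1..5
srnalink mirlink  --mirnas mir.fa --utrs utr.fa --de-genes de_genes.tsv \
                  --out run/ml
srnalink stats    --table 15,15,5,65   # spot-check the exact tests
```

Exit codes: 0 success, 2 usage, 3 input-contract violation, 4 internal
error.

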