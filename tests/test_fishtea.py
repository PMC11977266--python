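"""Family-to-locus DE propagation, gene/TE overlap, layout and enrichment."""

import numpy as np
import pytest

from srnalink.errors import ContractError
from srnalink.fishtea import (
    chromosomal_layout,
    expand_families_to_loci,
    family_class_counts,
    genic_region_enrichment,
    overlap_de_genes_tes,
)
from srnalink.intervals import GenomicInterval
from srnalink.io import DEGeneRecord, DETEFamilyRecord, TELocus

from oracles import hypergeom_tail_oracle


def fam(name, cls="LTR", significant=True, lfc=2.0, padj=0.001):
    return DETEFamilyRecord(f"{name}:{name}:{cls}", name, cls, lfc, padj, significant)


def locus(chrom, start, end, name, family="Gypsy", cls="LTR", is_de=False):
    return TELocus(GenomicInterval(chrom, start, end, "+", name),
                   te_name=family, te_family=family, te_class=cls, is_de=is_de)


def gene(gid, chrom, start, end, significant=True, padj=0.001):
    return DEGeneRecord(gid, 1.0, None, padj, significant,
                        GenomicInterval(chrom, start, end, "+", gid))


class TestExpandFamiliesToLoci:
    def test_family_join(self):
        annotation = [locus("chr1", i * 100, i * 100 + 50, f"g{i}") for i in range(3)]
        annotation += [locus("chr1", 1000 + i * 100, 1000 + i * 100 + 50, f"h{i}",
                             family="hAT", cls="DNA") for i in range(2)]
        out = expand_families_to_loci([fam("Gypsy")], annotation)
        assert len(out) == 5
        de = [t for t in out if t.is_de]
        assert len(de) == 3 and all(t.te_family == "Gypsy" for t in de)
        assert all(t.family_padj == 0.001 for t in de)

    def test_no_de_families(self):
        annotation = [locus("chr1", 0, 50, "a")]
        out = expand_families_to_loci([fam("Gypsy", significant=False)], annotation)
        assert not any(t.is_de for t in out)

    def test_empty_annotation_rejected(self):
        with pytest.raises(ContractError):
            expand_families_to_loci([fam("Gypsy")], [])

    def test_generator_family_sizes_recovered(self, small_dataset):
        from srnalink.io import read_te_gtf

        cfg, outdir, truth = small_dataset
        loci = read_te_gtf(outdir / "te_loci.gtf")
        counts = {}
        for t in loci:
            counts[t.te_family] = counts.get(t.te_family, 0) + 1
        assert counts == truth.family_locus_counts


class TestOverlapDeGenesTes:
    def test_disjoint_chromosomes(self):
        genes = [gene("g1", "chr1", 0, 1000)]
        loci = [locus("chr2", 0, 500, "t1", is_de=True)]
        records, summary = overlap_de_genes_tes(genes, loci)
        assert records == [] and summary == (0, 0)

    def test_one_gene_two_de_families(self):
        genes = [gene("g1", "chr1", 0, 10_000)]
        loci = [
            locus("chr1", 100, 200, "t1", family="Gypsy", is_de=True),
            locus("chr1", 300, 400, "t2", family="hAT", cls="DNA", is_de=True),
            locus("chr1", 500, 600, "t3", family="L1", cls="LINE", is_de=False),
        ]
        records, summary = overlap_de_genes_tes(genes, loci)
        assert summary == (1, 2)
        assert {r.subject_name for r in records} == {"t1", "t2"}  # non-DE excluded

    def test_non_significant_genes_excluded(self):
        genes = [gene("g1", "chr1", 0, 1000, significant=False, padj=0.5)]
        loci = [locus("chr1", 0, 500, "t1", is_de=True)]
        _, summary = overlap_de_genes_tes(genes, loci)
        assert summary == (0, 0)

    def test_coordinate_free_genes_rejected(self):
        bare = [DEGeneRecord("g1", 1.0, None, 0.01, True)]
        with pytest.raises(ContractError, match="annotation"):
            overlap_de_genes_tes(bare, [locus("chr1", 0, 10, "t", is_de=True)])


class TestGenicRegionEnrichment:
    def test_certain_event(self):
        genes = [gene("g1", "chr1", 0, 1000)]
        loci = [locus("chr1", i * 10, i * 10 + 5, f"t{i}", is_de=True) for i in range(4)]
        (res,) = genic_region_enrichment(genes, loci)
        assert (res.k, res.n, res.K, res.N) == (4, 4, 4, 4)
        assert res.p == 1.0

    def test_reference_value(self):
        # region holds 5 of the genome's 20 loci, 4 of its 8 DE loci
        loci = []
        for i in range(8):
            inside = i < 4
            loci.append(locus("chr1", 100 + i * 10 if inside else 50_000 + i * 10,
                              105 + i * 10 if inside else 50_005 + i * 10,
                              f"de{i}", is_de=True))
        for i in range(12):
            inside = i < 1
            loci.append(locus("chr1", 300 + i * 10 if inside else 80_000 + i * 10,
                              305 + i * 10 if inside else 80_005 + i * 10,
                              f"bg{i}"))
        (res,) = genic_region_enrichment([gene("g1", "chr1", 0, 1000)], loci)
        assert (res.k, res.n, res.K, res.N) == (4, 5, 8, 20)
        assert res.p == pytest.approx(896 / 15504, abs=1e-12)
        assert res.p == pytest.approx(hypergeom_tail_oracle(4, 5, 8, 20), abs=1e-12)

    def test_zero_de_loci_gives_p_one(self):
        genes = [gene("g1", "chr1", 0, 1000)]
        loci = [locus("chr1", 10, 50, "t1")]
        (res,) = genic_region_enrichment(genes, loci)
        assert res.p == 1.0 and not res.significant

    def test_alpha_extremes(self):
        genes = [gene("g1", "chr1", 0, 1000)]
        loci = [locus("chr1", 10, 50, "t1", is_de=True),
                locus("chr1", 5000, 5100, "t2")]
        (hi,) = genic_region_enrichment(genes, loci, alpha=1.0)
        (lo,) = genic_region_enrichment(genes, loci, alpha=0.0)
        assert hi.significant and not lo.significant

    def test_overlapping_regions_count_independently(self):
        # two genes share a locus: each region's (k, n) includes it
        genes = [gene("g1", "chr1", 0, 1000), gene("g2", "chr1", 500, 1500)]
        loci = [locus("chr1", 700, 800, "shared", is_de=True),
                locus("chr1", 90_000, 90_100, "far")]
        results = genic_region_enrichment(genes, loci)
        assert {(r.region_id, r.k, r.n) for r in results} == {
            ("g1", 1, 1), ("g2", 1, 1),
        }

    def test_sorted_by_p_then_region_id(self):
        genes = [gene("gB", "chr1", 0, 1000), gene("gA", "chr1", 2000, 3000),
                 gene("gC", "chr1", 4000, 5000)]
        loci = [locus("chr1", 10, 20, "t1", is_de=True),
                locus("chr1", 2010, 2020, "t2", is_de=True),
                locus("chr1", 4010, 4020, "t3"),
                locus("chr1", 99_000, 99_100, "t4")]
        results = genic_region_enrichment(genes, loci)
        assert [r.region_id for r in results] == ["gA", "gB", "gC"]

    def test_bh_correction_mode(self):
        genes = [gene(f"g{i}", "chr1", i * 10_000, i * 10_000 + 1000)
                 for i in range(5)]
        loci = []
        for i in range(5):
            loci.append(locus("chr1", i * 10_000 + 10, i * 10_000 + 50, f"t{i}",
                              is_de=(i == 0)))
        results = genic_region_enrichment(genes, loci, correction="bh")
        assert all(r.p_adj is not None and r.p_adj >= r.p for r in results)


class TestChromosomalLayout:
    SIZES = {"chr1": 10_000, "chr2": 5_000}

    def test_single_chromosome_midpoint(self):
        df = chromosomal_layout([gene("g1", "chr1", 100, 200)], [], self.SIZES)
        assert df.loc[0, "cumulative_pos"] == 150.0
        assert df.loc[0, "track"] == "DE gene"

    def test_second_chromosome_offset(self):
        df = chromosomal_layout([gene("g1", "chr2", 0, 2)], [], self.SIZES)
        assert df.loc[0, "cumulative_pos"] == 10_000 + 1.0

    def test_tracks_and_significance_markers(self):
        loci = [locus("chr1", 0, 10, "t1", family="hAT", cls="DNA", is_de=True),
                locus("chr1", 20, 30, "t2", family="Gypsy", cls="LTR", is_de=True),
                locus("chr1", 40, 50, "t3", is_de=False)]
        df = chromosomal_layout([gene("g1", "chr1", 100, 200)], loci, self.SIZES,
                                significant_regions={"g1"})
        assert set(df["track"]) == {"DE gene", "DE TE Class I", "DE TE Class II"}
        assert df[df["name"] == "g1"]["significant_region"].item()

    def test_shuffle_invariance(self):
        genes = [gene(f"g{i}", "chr1", i * 100, i * 100 + 10) for i in range(10)]
        a = chromosomal_layout(genes, [], self.SIZES)
        b = chromosomal_layout(list(reversed(genes)), [], self.SIZES)
        assert a.equals(b)

    def test_unknown_chromosome_named(self):
        with pytest.raises(ContractError, match="chrX"):
            chromosomal_layout([gene("g1", "chrX", 0, 10)], [], self.SIZES)


class TestFamilyClassCounts:
    def test_empty(self):
        fam_df, cls_df = family_class_counts([], [])
        assert fam_df.empty and cls_df.empty

    def test_totals_conserved_and_deduplicated(self):
        genes = [gene("g1", "chr1", 0, 1000), gene("g2", "chr1", 500, 1500)]
        loci = [locus("chr1", 700, 800, "shared", family="Gypsy", is_de=True),
                locus("chr1", 100, 200, "t2", family="hAT", cls="DNA", is_de=True)]
        records, _ = overlap_de_genes_tes(genes, loci)
        fam_df, cls_df = family_class_counts(records, loci)
        # "shared" overlaps two genes but is one locus
        assert fam_df["count"].sum() == cls_df["count"].sum() == 2
        assert dict(zip(cls_df["class"], cls_df["count"])) == {
            "Class I": 1, "Class II": 1,
        }
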