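"""piRNA seed extraction, complementarity scanning and TE summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnalink.errors import ContractError
from srnalink.fishpi import (
    SeedSpec,
    SmallRNA,
    class_group,
    extract_seed,
    match_pirnas_to_tes,
    seed_sites,
    summarize_class_chart,
)
from srnalink.io import SequenceRecord, reverse_complement

from oracles import naive_seed_scan

PIRNA = SmallRNA("piR-x", "TGGAACCGAGAGCGATACGATTTTCGCA", "piRNA")


class TestSeedSpec:
    def test_default_is_teleost_window(self):
        assert (SeedSpec().first, SeedSpec().last) == (1, 10)

    @pytest.mark.parametrize("first,last", [(0, 10), (5, 4), (1, 4)])
    def test_rejects_bad_windows(self, first, last):
        with pytest.raises(ContractError):
            SeedSpec(first, last)


class TestExtractSeed:
    def test_prefix_window(self):
        assert extract_seed(PIRNA, SeedSpec(1, 10)) == "TGGAACCGAG"

    def test_mirna_style_window_skips_position_one(self):
        mir = SmallRNA("miR", "TAGCTTATCAGACTGATGTTGA", "miRNA")
        assert extract_seed(mir, SeedSpec(2, 8)) == "AGCTTAT"

    def test_short_srna_rejected_by_name(self):
        with pytest.raises(ContractError, match="piR-short"):
            extract_seed(SmallRNA("piR-short", "ACGTACGTA"), SeedSpec(1, 10))


class TestSeedSites:
    def test_planted_sense_site(self):
        seed = "TGGAACCGAG"
        target = SequenceRecord("te", "", "GCTCGAT" + reverse_complement(seed) + "AAT")
        assert seed_sites(seed, target) == [(7, "sense")]

    def test_orientation_roles(self):
        seed = "TGGAACCGAG"
        # a target that IS the reverse complement of the seed: sense site
        assert seed_sites(seed, SequenceRecord("t", "", reverse_complement(seed))) == [
            (0, "sense")
        ]
        # a target that IS the seed: its minus strand is complementary
        assert seed_sites(seed, SequenceRecord("t", "", seed)) == [(0, "antisense")]
        # a reverse-complement palindromic seed yields both at once
        pal = "AACGCGCGTT"
        assert reverse_complement(pal) == pal
        assert seed_sites(pal, SequenceRecord("t", "", pal)) == [
            (0, "antisense"), (0, "sense"),
        ]

    def test_no_occurrence(self):
        assert seed_sites("TGGAACCGAG", SequenceRecord("t", "", "A" * 50)) == []

    def test_overlapping_occurrences_counted(self):
        # revcomp of AAAAAAAA is TTTTTTTT: three overlapping hits in T^10
        sites = seed_sites("AAAAAAAA", SequenceRecord("t", "", "T" * 10))
        assert sites == [(0, "sense"), (1, "sense"), (2, "sense")]

    def test_ambiguous_seed_rejected(self):
        with pytest.raises(ContractError):
            seed_sites("ACGTNACGT", SequenceRecord("t", "", "ACGT" * 5))

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        s = "".join(rng.choice(list("ACGT"), size=rng.integers(6, 12)))
        target = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 600)))
        # plant the pattern sometimes so matches are not vanishingly rare
        if rng.random() < 0.7 and len(target) > len(s):
            pos = rng.integers(0, len(target) - len(s))
            ins = reverse_complement(s) if rng.random() < 0.5 else s
            target = target[:pos] + ins + target[pos + len(s):]
        got = seed_sites(s, SequenceRecord("t", "", target))
        assert got == naive_seed_scan(s, target)


class TestClassGroup:
    @pytest.mark.parametrize(
        "te_class,paper,standard",
        [
            ("DNA", "Class I", "Class II"),
            ("DNA/hAT", "Class I", "Class II"),
            ("LTR/Gypsy", "Class II", "Class I"),
            ("LINE", "Class II", "Class I"),
            ("SINE", "Class II", "Class I"),
            ("Simple_repeat", "Unknown", "Unknown"),
        ],
    )
    def test_two_nomenclatures(self, te_class, paper, standard):
        assert class_group(te_class, "paper") == paper
        assert class_group(te_class, "standard") == standard


def _te(name, cls, family, seq):
    return SequenceRecord(f"{name}#{cls}/{family}", "", seq)


class TestMatchPirnasToTes:
    def _db_with_planted(self, rng, n_total, n_with_site, seed_seq, cls="DNA",
                         family="hAT"):
        site = reverse_complement(seed_seq)
        db = []
        for i in range(n_total):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            while site in seq or seed_seq in seq:  # scrub accidentals
                seq = "".join(rng.choice(list("ACGT"), size=300))
            if i < n_with_site:
                pos = int(rng.integers(0, 300 - len(site)))
                seq = seq[:pos] + site + seq[pos + len(site):]
            db.append(_te(f"te{i}", cls, family, seq))
        return db

    def test_planted_sites_counted_per_te(self):
        rng = np.random.default_rng(0)
        seed_seq = extract_seed(PIRNA, SeedSpec())
        db = self._db_with_planted(rng, 10, 4, seed_seq)
        (summary,), matches = match_pirnas_to_tes([PIRNA], db)
        assert summary.total_matched_tes == 4
        assert sum(summary.count_by_class.values()) == 4
        assert sum(summary.count_by_family.values()) == 4

    def test_te_counted_once_despite_multiple_sites(self):
        seed_seq = extract_seed(PIRNA, SeedSpec())
        site = reverse_complement(seed_seq)
        db = [_te("te0", "DNA", "hAT", site + "ACGT" + site + "TT" + seed_seq)]
        (summary,), matches = match_pirnas_to_tes([PIRNA], db)
        assert summary.total_matched_tes == 1
        assert len(matches) == 3  # two sense + one antisense site

    def test_class_mixture_under_both_nomenclatures(self):
        rng = np.random.default_rng(1)
        seed_seq = extract_seed(PIRNA, SeedSpec())
        dna = self._db_with_planted(rng, 30, 30, seed_seq, cls="DNA", family="hAT")
        ltr = [
            _te(f"ltr{i}", "LTR", "Gypsy", rec.sequence)
            for i, rec in enumerate(self._db_with_planted(rng, 10, 10, seed_seq))
        ]
        (paper,), _ = match_pirnas_to_tes([PIRNA], dna + ltr, nomenclature="paper")
        assert paper.count_by_class == {"Class I": 30, "Class II": 10}
        (std,), _ = match_pirnas_to_tes([PIRNA], dna + ltr, nomenclature="standard")
        assert std.count_by_class == {"Class II": 30, "Class I": 10}

    def test_no_pirnas_gives_empty_output(self):
        summaries, matches = match_pirnas_to_tes([], [_te("t", "DNA", "hAT", "ACGTACGT")])
        assert summaries == [] and matches == []

    def test_empty_database_rejected(self):
        with pytest.raises(ContractError):
            match_pirnas_to_tes([PIRNA], [])

    def test_shorter_prefix_seed_matches_superset(self):
        rng = np.random.default_rng(2)
        seed10 = extract_seed(PIRNA, SeedSpec(1, 10))
        db = self._db_with_planted(rng, 20, 8, seed10)
        (long_sum,), long_matches = match_pirnas_to_tes([PIRNA], db, SeedSpec(1, 10))
        (short_sum,), short_matches = match_pirnas_to_tes([PIRNA], db, SeedSpec(1, 8))
        long_tes = {m.te_id for m in long_matches}
        short_tes = {m.te_id for m in short_matches}
        assert long_tes <= short_tes
        assert short_sum.total_matched_tes >= long_sum.total_matched_tes


class TestSummarizeClassChart:
    def test_empty_summary(self):
        from srnalink.fishpi import TEClassSummary

        df = summarize_class_chart(TEClassSummary("p", 0, {}, {}, {}))
        assert list(df.columns) == ["class", "family", "count"] and df.empty

    def test_sorted_and_conserving(self):
        from srnalink.fishpi import TEClassSummary

        s = TEClassSummary(
            "p", 6,
            {"Class I": 5, "Class II": 1},
            {"hAT": 3, "TcMar": 2, "Gypsy": 1},
            {"hAT": "Class I", "TcMar": "Class I", "Gypsy": "Class II"},
        )
        df = summarize_class_chart(s)
        assert list(df["count"]) == [3, 2, 1]
        assert df["count"].sum() == s.total_matched_tes
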