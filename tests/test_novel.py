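"""Hairpin folding, duplex metrics and the nine novel-miRNA criteria."""

import pytest

from fruitmir import novel
from fruitmir._seq import revcomp_rna
from fruitmir.annotate import GenomeHit
from fruitmir.novel import (DuplexMetrics, DuplexUndefinedError,
                            HairpinCandidate, NovelCriteria, pair_table)


def _perfect_hairpin(stem=21, loop=12):
    mature = ("GCAUCGGAUCCGAUGCAUGCAUCGGAUCCG" * 2)[:stem]
    return mature + "A" * loop + revcomp_rna(mature), mature


class TestFoldRNA:
    def test_perfect_stem_folds_stably(self):
        seq, mature = _perfect_hairpin(stem=30, loop=4)
        structure, mfe = novel.fold_rna(seq)
        paired = sum(1 for c in structure if c != ".")
        assert paired >= 2 * 28
        assert mfe < -18.0

    def test_homopolymer_has_no_structure(self):
        structure, mfe = novel.fold_rna("A" * 60)
        assert structure == "." * 60
        assert mfe == 0.0

    def test_deterministic(self):
        seq, _ = _perfect_hairpin()
        assert novel.fold_rna(seq) == novel.fold_rna(seq)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            novel.fold_rna("ACGT" + "A" * 30)  # T is not RNA

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            novel.fold_rna("ACGUACGUACGU")


class TestPairTable:
    def test_roundtrip_partnering(self):
        pt = pair_table("((..))")
        assert pt == [5, 4, -1, -1, 1, 0]

    @pytest.mark.parametrize("bad", ["((", "))((", "(.))"])
    def test_unbalanced_rejected(self, bad):
        with pytest.raises(ValueError):
            pair_table(bad)


def _candidate_from(structure, precursor, ms, me):
    return HairpinCandidate(
        "s", 1, len(precursor), "+", precursor, structure, -30.0, ms, me
    )


class TestDuplexMetrics:
    def test_perfect_duplex(self):
        seq, mature = _perfect_hairpin(stem=21, loop=12)
        structure, mfe = novel.fold_rna(seq)
        cand = _candidate_from(structure, seq, 0, 20)
        m = novel.duplex_metrics(cand)
        assert (m.paired_bases, m.max_bulge, m.asymmetry) == (21, 0, 0)
        assert m.loop_space == 12
        assert cand.star_sequence is not None

    def test_hand_built_mature_bulge(self):
        # 8 pairs, 2-nt mature-side bulge, 8 pairs; loop of 6
        structure = "((((((((..((((((((......))))))))))))))))"
        precursor = "GGGGGGGGAAGGGGGGGGAAAAAACCCCCCCCCCCCCCCC"
        cand = _candidate_from(structure, precursor, 0, 17)
        m = novel.duplex_metrics(cand)
        assert m.paired_bases == 16
        assert m.max_bulge == 2
        assert m.asymmetry == 2

    def test_unpaired_mature_is_rejected(self):
        structure = "......((((....))))"
        precursor = "AAAAAACCCCUUUUGGGG"
        cand = _candidate_from(structure, precursor, 0, 5)
        with pytest.raises(DuplexUndefinedError):
            novel.duplex_metrics(cand)

    def test_star_has_two_nt_three_prime_overhang(self):
        seq, mature = _perfect_hairpin(stem=21, loop=12)
        structure, _ = novel.fold_rna(seq)
        cand = _candidate_from(structure, seq, 0, 20)
        novel.duplex_metrics(cand)
        # raw partner span is [21+12, 21+12+20]; star shifts +2 toward 3'
        assert cand.star_start == 21 + 12 + 2
        assert cand.star_end == len(seq) - 1


class TestCriteria:
    def _base(self, **over):
        cand = HairpinCandidate(
            "s", 1, 120, "+", "A" * 120, "." * 120, over.pop("mfe", -30.0),
            20, 40, ref_span=over.pop("ref_span", 21),
            genome_copies=over.pop("copies", 1),
        )
        metrics = DuplexMetrics(
            paired_bases=over.pop("paired", 18),
            max_bulge=over.pop("bulge", 1),
            asymmetry=over.pop("asym", 1),
            loop_space=over.pop("loop", 40),
            flank5=over.pop("flank5", 25), flank3=over.pop("flank3", 25),
        )
        return cand, metrics, over.pop("count", 20)

    def test_all_pass(self):
        cand, m, n = self._base()
        report = novel.apply_novel_criteria(cand, m, n)
        assert novel.report_passes(report)
        assert novel.failed_criteria(report) == []

    @pytest.mark.parametrize("tweak,criterion", [
        ({"paired": 15}, "paired_bases"),
        ({"mfe": -17.5}, "mfe"),
        ({"loop": 301}, "loop_space"),
        ({"bulge": 5}, "bulge"),
        ({"asym": 5}, "asymmetry"),
        ({"flank5": 10}, "flank"),
        ({"ref_span": 24}, "ref_len"),
        ({"copies": 21}, "ref_copies"),
    ])
    def test_single_threshold_violations(self, tweak, criterion):
        cand, m, n = self._base(**tweak)
        report = novel.apply_novel_criteria(cand, m, n)
        assert novel.failed_criteria(report) == [criterion]

    def test_mature_length_bounds(self):
        cand, m, n = self._base()
        cand.mature_end = cand.mature_start + 25  # 26 nt
        cand.ref_span = 21
        report = novel.apply_novel_criteria(cand, m, n)
        assert "mature_len" in novel.failed_criteria(report)

    def test_boundary_mfe_values(self):
        cand, m, n = self._base(mfe=-18.32)
        assert novel.apply_novel_criteria(cand, m, n)["mfe"]["passed"]
        cand, m, n = self._base(mfe=-18.0)
        assert novel.apply_novel_criteria(cand, m, n)["mfe"]["passed"]

    def test_read_count_floor_reported_separately(self):
        cand, m, _ = self._base()
        report = novel.apply_novel_criteria(cand, m, 4)
        assert novel.report_passes(report)  # nine criteria unaffected
        assert not report["read_count"]["passed"]

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            NovelCriteria(mature_len_min=26, mature_len_max=25)


class TestClustering:
    def test_distant_loci_split(self):
        hits = [
            GenomeHit("A" * 21, "s", 1000, 1020, "+"),
            GenomeHit("C" * 21, "s", 11000, 11020, "+"),
        ]
        clusters = novel._cluster_hits(hits, gap=200)
        assert len(clusters) == 2

    def test_nearby_hits_merge_and_strands_split(self):
        hits = [
            GenomeHit("A" * 21, "s", 1000, 1020, "+"),
            GenomeHit("C" * 21, "s", 1100, 1120, "+"),
            GenomeHit("G" * 21, "s", 1100, 1120, "-"),
        ]
        clusters = novel._cluster_hits(hits, gap=200)
        assert sorted(len(c) for c in clusters) == [1, 2]


class TestPredictionOnSyntheticTruth:
    def test_emitted_set_is_sound(self, world, predictions):
        """Every emitted novel miRNA re-passes the criteria when its
        precursor is re-folded from scratch."""
        assert predictions, "expected predictions on the synthetic world"
        for p in predictions:
            c = p.candidate
            structure, mfe = novel.fold_rna(c.precursor)
            refolded = HairpinCandidate(
                c.scaffold, c.start, c.end, c.strand, c.precursor,
                structure, mfe, c.mature_start, c.mature_end,
                ref_span=c.ref_span, genome_copies=c.genome_copies,
            )
            metrics = novel.duplex_metrics(refolded)
            report = novel.apply_novel_criteria(
                refolded, metrics, p.read_count
            )
            assert novel.report_passes(report), (p.id, report)

    def test_ids_assigned_in_genome_order(self, predictions):
        loci = [(p.candidate.scaffold, p.candidate.start) for p in predictions]
        assert loci == sorted(loci)
        assert [p.id for p in predictions] == [
            f"m{i + 1:04d}" for i in range(len(predictions))
        ]

    def test_empty_input_gives_empty_output(self, world):
        assert novel.predict_novel(world["genome"], [], []) == []
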