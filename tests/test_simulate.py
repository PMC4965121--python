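"""Generator contracts: determinism, conservation, self-verification."""

import numpy as np
import pytest

from fruitmir import novel, targets
from fruitmir import simulate as sim


class TestSpecValidation:
    def test_bad_fraction_rejected(self):
        spec = sim.SimulationSpec(first_nt_u_bias=1.5)
        with pytest.raises(ValueError):
            spec.validate()

    def test_fractions_over_one_rejected(self):
        spec = sim.SimulationSpec()
        spec.contaminant_fractions = {"rRNA": 0.9, "tRNA": 0.2}
        with pytest.raises(ValueError):
            spec.validate()

    def test_unknown_violation_kind_rejected(self):
        spec = sim.SimulationSpec(decoy_violations=("gc_content",),
                                  n_decoy_hairpins=1)
        with pytest.raises(ValueError):
            spec.validate()


class TestGenerateGenome:
    def test_scaffold_count_and_length(self):
        spec = sim.SimulationSpec(seed=2, n_scaffolds=2, scaffold_length=5000)
        genome, _ = sim.generate_genome(spec)
        assert len(genome) == 2
        assert all(len(s) == 5000 for s in genome.values())

    def test_seeded_rerun_is_identical(self):
        spec = sim.SimulationSpec(seed=3, n_scaffolds=2, scaffold_length=4000)
        g1, f1 = sim.generate_genome(spec)
        g2, f2 = sim.generate_genome(spec)
        assert g1 == g2 and f1 == f2

    def test_zero_fraction_class_absent(self):
        spec = sim.SimulationSpec(seed=2, n_scaffolds=2, scaffold_length=8000)
        spec.annotation_fractions = dict(spec.annotation_fractions, rRNA=0.0)
        _, features = sim.generate_genome(spec)
        assert not any(f.ftype == "rRNA" for f in features)

    def test_features_do_not_overlap(self):
        spec = sim.SimulationSpec(seed=4, n_scaffolds=2, scaffold_length=20000)
        _, features = sim.generate_genome(spec)
        by_scaffold = {}
        for f in features:
            by_scaffold.setdefault(f.seqid, []).append((f.start, f.end))
        for spans in by_scaffold.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_undersized_scaffold_raises(self):
        spec = sim.SimulationSpec(seed=2, n_scaffolds=1, scaffold_length=300)
        with pytest.raises(ValueError):
            sim.generate_genome(spec)


class TestPlantHairpins:
    def test_truth_labels_cover_requested_design(self, spec, world):
        truth = world["truth"]
        labels = [h.label for h in truth.planted_hairpins]
        assert labels.count("pass") == spec.n_true_hairpins
        assert labels.count("fail") == spec.n_decoy_hairpins
        violated = [h.violated_criterion for h in truth.planted_hairpins
                    if h.label == "fail"]
        assert sorted(violated) == sorted(spec.decoy_violations)

    def test_every_fail_names_exactly_one_criterion(self, world):
        for h in world["truth"].planted_hairpins:
            if h.label == "fail":
                assert h.violated_criterion in sim.DECOY_KINDS
            else:
                assert h.violated_criterion is None

    def test_pass_hairpins_refold_and_satisfy_all_criteria(self, world):
        """Self-consistency: re-excising a planted pass hairpin from the
        final genome reproduces a fully passing criterion report."""
        genome, truth = world["genome"], world["truth"]
        for h in truth.planted_hairpins:
            if h.label != "pass":
                continue
            out = novel.excise_locus(
                genome[h.scaffold], h.scaffold,
                h.mature_start - 1, h.mature_end - 1, h.strand,
            )
            assert out is not None
            cand, metrics = out
            cand.ref_span = h.ref_span
            cand.genome_copies = h.genome_copies
            report = novel.apply_novel_criteria(cand, metrics, h.tags[0][1])
            assert novel.report_passes(report), (h.hairpin_id, report)

    def test_mature_sequence_present_in_genome(self, world):
        for h in world["truth"].planted_hairpins:
            region = world["genome"][h.scaffold][
                h.mature_start - 1:h.mature_end - 1 + len(h.mature_seq)
            ]
            assert region[:len(h.mature_seq)] == h.mature_seq

    def test_deterministic_replant(self, spec):
        g0, feats = sim.generate_genome(spec)
        g1, t1 = sim.plant_hairpins(g0, spec, feats)
        g2, t2 = sim.plant_hairpins(g0, spec, feats)
        assert g1 == g2
        assert [h.mature_seq for h in t1.planted_hairpins] == [
            h.mature_seq for h in t2.planted_hairpins
        ]


class TestLibrary:
    def test_class_counts_conserve_depth(self, spec, library):
        assert len(library["reads"]) == spec.read_depth
        assert len(library["sidecar"]) == spec.read_depth

    def test_seeded_rerun_is_byte_identical(self, spec, world):
        r1, s1 = sim.simulate_srna_library(
            world["truth"], spec, world["genome"], world["features"],
            world["known_db"],
        )
        r2, s2 = sim.simulate_srna_library(
            world["truth"], spec, world["genome"], world["features"],
            world["known_db"],
        )
        assert r1 == r2 and s1.equals(s2)

    def test_depth_zero_is_empty_valid_library(self, spec, world):
        empty_spec = sim.SimulationSpec(seed=1, read_depth=0)
        reads, sidecar = sim.simulate_srna_library(
            world["truth"], empty_spec, world["genome"], world["features"],
            world["known_db"],
        )
        assert reads == [] and len(sidecar) == 0

    def test_contaminant_class_counts_within_binomial_noise(self, spec, library):
        """Multinomial class counts stay within 4 SD of expectation."""
        counts = library["sidecar"]["class"].value_counts()
        n = spec.read_depth
        for cls in ("shorter_than_min", "rRNA", "tRNA", "mirna"):
            p = spec.contaminant_fractions[cls]
            sd = np.sqrt(n * p * (1 - p))
            assert abs(int(counts.get(cls, 0)) - n * p) <= 4 * sd + 1, cls

    def test_length_distribution_peaks_at_21_then_24(self, library, processed):
        lengths = {}
        for t in processed["tags"]:
            lengths[len(t.sequence)] = lengths.get(len(t.sequence), 0) + t.count
        ordered = sorted(lengths, key=lengths.get, reverse=True)
        assert ordered[0] == 21 and ordered[1] == 24


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(21)
    mirnas = {
        f"m{i:04d}": "".join(rng.choice(list("ACGT"), size=21))
        for i in range(1, 4)
    }
    rules = targets.TargetRules()
    tx, truth = sim.simulate_transcriptome_with_targets(mirnas, rules, seed=21)
    return mirnas, rules, tx, truth


class TestTranscriptomeTargets:

    def test_perfect_sites_pass_all_rules(self, planted):
        _, _, _, truth = planted
        for t in truth.planted_targets:
            if t.kind == "pass":
                assert t.rule_labels["overall"]
                assert all(t.rule_labels[r] for r in targets.RULE_NAMES)

    def test_rule4_decoy_mismatch_at_position_ten(self, planted):
        mirnas, _, tx, truth = planted
        for t in truth.planted_targets:
            if t.kind != "fail_rule4":
                continue
            m = mirnas[t.mirna_id].replace("T", "U")
            window = tx[t.transcript_id][t.site_start - 1:t.site_end]
            states = targets.align_site(m, window.replace("T", "U"))
            assert states[9] == "MM"
            assert not t.rule_labels["rule4"]

    def test_decoys_fail_their_primary_rule(self, planted):
        _, _, _, truth = planted
        for t in truth.planted_targets:
            if t.kind.startswith("fail_rule") and t.kind != "fail_rule6":
                rule = t.kind.replace("fail_", "")
                assert not t.rule_labels[rule], (t.kind, t.rule_labels)

    def test_scan_recovers_exactly_the_passing_truth(self, planted):
        mirnas, rules, tx, truth = planted
        found = {
            (a.mirna_id, a.transcript_id, a.site_start)
            for a in targets.scan_transcriptome(mirnas, tx, rules)
        }
        expected = {
            (t.mirna_id, t.transcript_id, t.site_start)
            for t in truth.planted_targets if t.rule_labels["overall"]
        }
        assert found == expected

    def test_mirna_length_bounds_checked(self):
        with pytest.raises(ValueError):
            sim.simulate_transcriptome_with_targets(
                {"m1": "ACGT"}, targets.TargetRules(), seed=1
            )


@pytest.fixture(scope="module")
def cleavage_world():
    rng = np.random.default_rng(8)
    tx = {"tx1": "".join(rng.choice(list("ACGT"), size=900))}
    cleavages = [sim.PlantedCleavage("tx1", 300, "m0001", 50)]
    return tx, cleavages


class TestDegradomeSimulator:

    def test_zero_background_single_sharp_peak(self, cleavage_world):
        from fruitmir import degradome
        tx, cleavages = cleavage_world
        reads = sim.simulate_degradome(tx, cleavages, 0.0, seed=5)
        density = degradome.build_density(reads, tx)["tx1"]
        assert density[299] == 50
        assert density.sum() == 50

    def test_seeded_rerun_identical(self, cleavage_world):
        tx, cleavages = cleavage_world
        a = sim.simulate_degradome(tx, cleavages, 0.4, seed=5)
        b = sim.simulate_degradome(tx, cleavages, 0.4, seed=5)
        assert a == b

    def test_out_of_bounds_cleavage_rejected(self, cleavage_world):
        tx, _ = cleavage_world
        bad = [sim.PlantedCleavage("tx1", 2000, "m0001", 10)]
        with pytest.raises(ValueError):
            sim.simulate_degradome(tx, bad, 0.0, seed=5)

    def test_peak_dominates_background(self, cleavage_world):
        from fruitmir import degradome
        tx, cleavages = cleavage_world
        reads = sim.simulate_degradome(tx, cleavages, 0.5, seed=5)
        density = degradome.build_density(reads, tx)["tx1"]
        background = np.delete(density, 299)
        assert density[299] >= 50
        assert density[299] > 5 * max(background.max(), 1)
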