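"""Six-rule target prediction: states, scoring, energies, scanning."""

import numpy as np
import pytest

from fruitmir import targets
from fruitmir._seq import revcomp_rna
from fruitmir.targets import TargetAlignment, TargetRules

MIR156 = "UUGACAGAAGAAAGAGAGCAC"
M0233 = "CUGACAGAAGAGAGUGAGCAC"

# --- independent brute-force oracle (plain per-offset re-implementation) ---

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def oracle_states(mirna, window):
    out = []
    L = len(mirna)
    for i in range(1, L + 1):
        m, t = mirna[i - 1], window[L - i]
        if _COMP[m] == t:
            out.append("WC")
        elif (m, t) in (("G", "U"), ("U", "G")):
            out.append("GU")
        else:
            out.append("MM")
    return out


def oracle_passes(mirna, window, min_ratio=0.75):
    st = oracle_states(mirna, window)
    score = sum(1.0 if s == "MM" else 0.5 if s == "GU" else 0.0 for s in st)
    if score > 4.0:
        return False
    run = best = 0
    for s in st:
        run = run + 1 if s == "MM" else 0
        best = max(best, run)
    if best > 2:
        return False
    for i in range(2, 12):  # adjacent MM pairs fully inside positions 2..12
        if st[i - 1] == "MM" and st[i] == "MM":
            return False
    if st[9] == "MM" or st[10] == "MM":
        return False
    head = st[:12]
    if sum(1.0 if s == "MM" else 0.5 if s == "GU" else 0.0 for s in head) > 2.5:
        return False
    ratio = targets.duplex_mfe(mirna, window) / targets.perfect_mfe(mirna)
    return ratio >= min_ratio


def oracle_scan(mirnas, transcripts):
    found = set()
    for mid in mirnas:
        m = mirnas[mid].replace("T", "U")
        L = len(m)
        for tid in transcripts:
            t = transcripts[tid].replace("T", "U")
            for s in range(len(t) - L + 1):
                if oracle_passes(m, t[s:s + L]):
                    found.add((mid, tid, s + 1))
    return found


class TestAlignSite:
    def test_exact_complement_is_all_wc(self):
        site = revcomp_rna(MIR156)
        assert targets.align_site(MIR156, site) == ["WC"] * 21

    def test_wobble_states(self):
        # miRNA G facing target U, and U facing G
        assert targets.align_site("G", "U") == ["GU"]
        assert targets.align_site("U", "G") == ["GU"]
        assert targets.align_site("A", "C") == ["MM"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            targets.align_site("ACGU", "ACG")

    def test_published_sequence_pair_states(self):
        """A novel miRNA printed alongside its conserved counterpart:
        against the site complementary to the conserved sequence the duplex
        shows mismatches at positions 1 and 15 and a G:U wobble at 12
        (wobbles count half a mismatch), total score 2.5."""
        site = revcomp_rna(MIR156)
        states = targets.align_site(M0233, site)
        assert states[0] == "MM"
        assert states[11] == "GU"
        assert states[14] == "MM"
        others = [s for i, s in enumerate(states) if i not in (0, 11, 14)]
        assert others == ["WC"] * 18
        assert targets.mismatch_score(states) == 2.5
        # no mismatch at the cleavage-defining positions, none adjacent
        assert states[9] != "MM" and states[10] != "MM"


class TestMismatchScore:
    def test_arithmetic(self):
        states = ["MM"] * 3 + ["GU"] * 2 + ["WC"] * 16
        assert targets.mismatch_score(states) == 4.0
        assert targets.mismatch_score(["WC"] * 21) == 0.0

    def test_range_restriction(self):
        states = ["GU"] * 2 + ["WC"] * 10 + ["MM"] * 2 + ["WC"] * 7
        assert targets.mismatch_score(states, (1, 12)) == 1.0
        assert targets.mismatch_score(states) == 3.0


class TestEnergies:
    def test_perfect_site_ratio_is_one(self):
        site = revcomp_rna(MIR156)
        assert targets.duplex_mfe(MIR156, site) == targets.perfect_mfe(MIR156)

    def test_central_mismatch_block_destabilises(self):
        site = list(revcomp_rna(MIR156))
        for i in range(8, 12):
            site[i] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[i]]
        weakened = targets.duplex_mfe(MIR156, "".join(site))
        assert weakened > targets.perfect_mfe(MIR156)


class TestRules:
    def _aln(self, mirna, site):
        states = targets.align_site(mirna, site)
        return TargetAlignment(
            "m", mirna, "t", 1, len(mirna), states,
            targets.mismatch_score(states),
            duplex_mfe=targets.duplex_mfe(mirna, site),
            perfect_mfe=targets.perfect_mfe(mirna),
        )

    def test_perfect_complement_passes_all(self):
        verdict = targets.apply_target_rules(self._aln(MIR156, revcomp_rna(MIR156)))
        assert verdict["overall"]
        assert all(verdict[r] for r in targets.RULE_NAMES)

    def test_single_mismatch_at_position_ten_fails_rule4_only(self):
        site = list(revcomp_rna(MIR156))
        # miRNA position 10 faces site index L-10
        site[21 - 10] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[21 - 10]]
        verdict = targets.apply_target_rules(self._aln(MIR156, "".join(site)))
        failed = [r for r in targets.RULE_NAMES if not verdict[r]]
        assert failed == ["rule4"]

    def test_gu_only_scores_pass_positional_rules(self):
        states = (["GU", "WC", "GU"] + ["WC"] * 9 + ["MM", "WC", "MM"]
                  + ["WC"] * 6)
        aln = TargetAlignment("m", "A" * 21, "t", 1, 21, states,
                              targets.mismatch_score(states),
                              duplex_mfe=-30.0, perfect_mfe=-32.0)
        verdict = targets.apply_target_rules(aln)
        assert targets.mismatch_score(states, (1, 12)) == 1.0
        assert targets.mismatch_score(states) == 3.0
        assert verdict["rule1"] and verdict["rule5"]

    def test_gu_breaks_adjacency_by_default_but_not_in_strict_mode(self):
        states = ["WC"] * 13 + ["MM", "GU", "MM"] + ["WC"] * 5
        aln = TargetAlignment("m", "A" * 21, "t", 1, 21, states,
                              targets.mismatch_score(states),
                              duplex_mfe=-30.0, perfect_mfe=-32.0)
        assert targets.apply_target_rules(aln)["rule2"]
        strict = TargetRules(gu_breaks_adjacency=False)
        assert not targets.apply_target_rules(aln, strict)["rule2"]

    def test_gu_to_wc_substitution_never_flips_pass_to_fail(self):
        """Score monotonicity: promoting a wobble to a Watson-Crick pair
        cannot make a positionally passing site fail rules 1-5."""
        rng = np.random.default_rng(0)
        rules = TargetRules()
        for _ in range(200):
            states = list(rng.choice(["WC", "GU", "MM"], size=21,
                                     p=[0.7, 0.2, 0.1]))
            aln = TargetAlignment("m", "A" * 21, "t", 1, 21, states,
                                  targets.mismatch_score(states),
                                  duplex_mfe=-30.0, perfect_mfe=-30.0)
            before = targets.apply_target_rules(aln, rules)
            if not before["overall"]:
                continue
            gu_positions = [i for i, s in enumerate(states) if s == "GU"]
            for i in gu_positions:
                flipped = states.copy()
                flipped[i] = "WC"
                aln2 = TargetAlignment("m", "A" * 21, "t", 1, 21, flipped,
                                       targets.mismatch_score(flipped),
                                       duplex_mfe=-30.0, perfect_mfe=-30.0)
                assert targets.apply_target_rules(aln2, rules)["overall"]


class TestScan:
    def _transcripts_with_sites(self, mirnas, seed=0, n=4, length=600):
        rng = np.random.default_rng(seed)
        tx = {}
        for i in range(n):
            seq = "".join(rng.choice(list("ACGU"), size=length))
            tx[f"t{i}"] = seq
        # embed one perfect site per miRNA
        for j, mid in enumerate(sorted(mirnas)):
            tid = f"t{j % n}"
            site = revcomp_rna(mirnas[mid].replace("T", "U"))
            pos = 50 + 60 * j
            tx[tid] = tx[tid][:pos] + site + tx[tid][pos + len(site):]
        return tx

    def test_scan_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        mirnas = {
            f"m{i}": "".join(rng.choice(list("ACGU"), size=21))
            for i in range(5)
        }
        tx = self._transcripts_with_sites(mirnas)
        found = {
            (a.mirna_id, a.transcript_id, a.site_start)
            for a in targets.scan_transcriptome(mirnas, tx)
        }
        assert found == oracle_scan(mirnas, tx)
        assert found  # the embedded perfect sites are recovered

    def test_no_complementarity_gives_zero_targets(self):
        mirnas = {"m0": "A" * 21}
        tx = {"t0": "A" * 500}  # A cannot pair A
        assert targets.scan_transcriptome(mirnas, tx) == []

    def test_identical_mirna_sequences_share_targets(self):
        seq = "AAAGACUAAAAUACCCUUGA"
        mirnas = {f"m{i:04d}": seq for i in (4, 15, 52)}
        tx = self._transcripts_with_sites({"x": seq}, seed=9, n=2)
        alns = targets.scan_transcriptome(mirnas, tx)
        per_mirna = {}
        for a in alns:
            per_mirna.setdefault(a.mirna_id, set()).add(
                (a.transcript_id, a.site_start)
            )
        assert len(per_mirna) == 3
        sets = list(per_mirna.values())
        assert sets[0] == sets[1] == sets[2] != set()

    def test_output_sorted_and_renderable(self):
        mirnas = {"m1": MIR156}
        tx = self._transcripts_with_sites(mirnas, seed=5, n=1)
        alns = targets.scan_transcriptome(mirnas, tx)
        keys = [(a.mirna_id, a.transcript_id, a.site_start) for a in alns]
        assert keys == sorted(keys)
        text = targets.render_alignment(alns[0])
        assert MIR156[::-1] in text and alns[0].transcript_id in text
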