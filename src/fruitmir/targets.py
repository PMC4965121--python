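"""Plant miRNA target prediction with G:U wobble scoring.

A candidate site is an ungapped antiparallel duplex between a miRNA
(5'->3', positions numbered from the miRNA 5' end) and a transcript window
of the same length: miRNA position i faces transcript position
``site_end - i + 1``.  Each position is in one of three states — WC
(Watson–Crick pair), GU (G:U wobble, scored as half a mismatch) or MM
(mismatch) — and six rules decide acceptance:

1. total mismatch score (#MM + 0.5·#GU) <= 4.0;
2. longest run of consecutive mismatches <= 2;
3. no two adjacent mismatches within miRNA positions 2–12;
4. no mismatch at miRNA positions 10 or 11;
5. mismatch score over positions 1–12 <= 2.5;
6. duplex MFE >= 75% of the MFE of the miRNA bound to its perfect
   complement (the MFE-ratio filter).

By default G:U wobbles do not form or extend "adjacent mismatch" runs in
rules 2–3 (they are half-mismatches for scoring only); a strict mode makes
them adjacency-forming.  Duplex energies come from a nearest-neighbour
two-sequence hybridisation model with no intramolecular structure.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import RNA

from ._seq import dna_to_rna, revcomp_rna, validate_rna

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# state code matrix: rows = miRNA base, cols = target base; 0 WC, 1 GU, 2 MM
_STATE_MATRIX = np.full((4, 4), 2, dtype=np.uint8)
for (m, t) in WC_PAIRS:
    _STATE_MATRIX[_BASE_CODE[m], _BASE_CODE[t]] = 0
for (m, t) in GU_PAIRS:
    _STATE_MATRIX[_BASE_CODE[m], _BASE_CODE[t]] = 1


@dataclasses.dataclass
class TargetRules:
    max_total: float = 4.0
    max_adjacent_mm: int = 2
    no_adjacent_mm_range: tuple[int, int] = (2, 12)
    no_mm_positions: tuple[int, int] = (10, 11)
    max_score_1_12: float = 2.5
    min_mfe_ratio: float = 0.75
    gu_breaks_adjacency: bool = True  # strict mode: False

RULE_NAMES = ("rule1", "rule2", "rule3", "rule4", "rule5", "rule6")


@dataclasses.dataclass
class TargetAlignment:
    mirna_id: str
    mirna_sequence: str  # RNA, 5'->3'
    transcript_id: str
    site_start: int  # 1-based inclusive transcript coordinates
    site_end: int
    states: list[str]  # index 0 = miRNA position 1
    mismatch_score: float
    duplex_mfe: float | None = None
    perfect_mfe: float | None = None
    site_sequence: str | None = None  # transcript window, 5'->3'

    @property
    def mfe_ratio(self) -> float | None:
        if self.duplex_mfe is None or self.perfect_mfe is None:
            return None
        if self.perfect_mfe >= 0:
            return 0.0
        return self.duplex_mfe / self.perfect_mfe


def align_site(mirna: str, transcript_window: str) -> list[str]:
    """Position-wise duplex states for one candidate site (both RNA)."""
    validate_rna(mirna)
    validate_rna(transcript_window)
    if len(mirna) != len(transcript_window):
        raise ValueError("window length must equal miRNA length")
    L = len(mirna)
    states = []
    for i in range(1, L + 1):
        m = mirna[i - 1]
        t = transcript_window[L - i]  # antiparallel
        if (m, t) in WC_PAIRS:
            states.append("WC")
        elif (m, t) in GU_PAIRS:
            states.append("GU")
        else:
            states.append("MM")
    return states


def mismatch_score(
    states: Sequence[str], position_range: tuple[int, int] | None = None
) -> float:
    """#MM + 0.5·#GU over a 1-based inclusive position range."""
    lo, hi = position_range if position_range else (1, len(states))
    chunk = states[lo - 1:hi]
    return chunk.count("MM") + 0.5 * chunk.count("GU")


def duplex_mfe(mirna: str, site: str) -> float:
    """Hybridisation MFE (kcal/mol) of the miRNA against a site sequence."""
    validate_rna(mirna)
    validate_rna(site)
    return round(float(RNA.duplexfold(mirna, site).energy), 2)


def perfect_mfe(mirna: str) -> float:
    """Hybridisation MFE of the miRNA against its exact complement."""
    return duplex_mfe(mirna, revcomp_rna(mirna))


def _longest_mm_run(states: Sequence[str], gu_breaks: bool) -> int:
    run = best = 0
    for s in states:
        if s == "MM" or (s == "GU" and not gu_breaks):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def apply_target_rules(
    alignment: TargetAlignment, rules: TargetRules = TargetRules()
) -> dict[str, bool]:
    """Per-rule verdicts plus ``overall``; rule 6 requires energies to be
    present on the alignment."""
    st = alignment.states
    r = rules
    lo, hi = r.no_adjacent_mm_range
    adjacent_in_seed = any(
        st[i - 1] == "MM" and st[i] == "MM"
        for i in range(lo, hi)
        if i + 1 <= len(st) and i + 1 <= hi
    )
    p10, p11 = r.no_mm_positions
    ratio = alignment.mfe_ratio
    verdict = {
        "rule1": mismatch_score(st) <= r.max_total,
        "rule2": _longest_mm_run(st, r.gu_breaks_adjacency) <= r.max_adjacent_mm,
        "rule3": not adjacent_in_seed,
        "rule4": st[p10 - 1] != "MM" and st[p11 - 1] != "MM",
        "rule5": mismatch_score(st, (1, 12)) <= r.max_score_1_12,
        "rule6": ratio is not None and ratio >= r.min_mfe_ratio,
    }
    verdict["overall"] = all(verdict[k] for k in RULE_NAMES)
    return verdict


def _positional_pass_windows(
    mirna: str, transcript: str, rules: TargetRules
) -> np.ndarray:
    """Offsets (0-based) of windows passing rules 1–5 (vectorised)."""
    L = len(mirna)
    T = len(transcript)
    W = T - L + 1
    if W <= 0:
        return np.empty(0, dtype=int)
    tcode = np.fromiter(
        (_BASE_CODE.get(b, 0) for b in transcript), dtype=np.uint8, count=T
    )
    valid = np.fromiter(
        (b in _BASE_CODE for b in transcript), dtype=bool, count=T
    )
    mcode = np.fromiter((_BASE_CODE[b] for b in mirna), dtype=np.uint8, count=L)
    # states[i, s] = state of miRNA position i+1 in window starting at s
    states = np.empty((L, W), dtype=np.uint8)
    window_ok = np.ones(W, dtype=bool)
    for i in range(1, L + 1):
        sl = slice(L - i, L - i + W)
        states[i - 1] = _STATE_MATRIX[mcode[i - 1], tcode[sl]]
        window_ok &= valid[sl]
    mm = states == 2
    gu = states == 1
    total = mm.sum(axis=0) + 0.5 * gu.sum(axis=0)
    ok = window_ok & (total <= rules.max_total)
    # rule 2: no run of > max_adjacent_mm consecutive mismatches
    runlen = rules.max_adjacent_mm
    adj = mm if rules.gu_breaks_adjacency else (mm | gu)
    if L > runlen:
        run = np.ones(W, dtype=bool)
        over = np.zeros(W, dtype=bool)
        for i in range(L - runlen):
            block = adj[i]
            for j in range(1, runlen + 1):
                block = block & adj[i + j]
            over |= block
        ok &= ~over
    lo, hi = rules.no_adjacent_mm_range
    seed_adj = np.zeros(W, dtype=bool)
    for i in range(lo, hi):
        if i + 1 <= L and i + 1 <= hi:
            seed_adj |= mm[i - 1] & mm[i]
    ok &= ~seed_adj
    p10, p11 = rules.no_mm_positions
    ok &= ~mm[p10 - 1] & ~mm[p11 - 1]
    ok &= (mm[:12].sum(axis=0) + 0.5 * gu[:12].sum(axis=0)) <= rules.max_score_1_12
    return np.nonzero(ok)[0]


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    rules: TargetRules = TargetRules(),
) -> list[TargetAlignment]:
    """All accepted target sites of all miRNAs over all transcripts.

    Positional rules 1–5 are evaluated for every window; the energy rule 6
    is evaluated only on survivors.  Output is deduplicated per
    (miRNA, transcript, site) and sorted by (mirna_id, transcript_id,
    site_start).  Identical miRNA sequences necessarily yield identical
    target lists.
    """
    out: list[TargetAlignment] = []
    perfect_cache: dict[str, float] = {}
    seen: set[tuple[str, str, int]] = set()
    for mid in sorted(mirnas):
        mseq = dna_to_rna(mirnas[mid]).upper()
        validate_rna(mseq)
        if mseq not in perfect_cache:
            perfect_cache[mseq] = perfect_mfe(mseq)
        pmfe = perfect_cache[mseq]
        L = len(mseq)
        for tid in sorted(transcripts):
            tseq = dna_to_rna(transcripts[tid]).upper()
            for s in _positional_pass_windows(mseq, tseq, rules):
                key = (mid, tid, int(s) + 1)
                if key in seen:
                    continue
                window = tseq[s:s + L]
                states = align_site(mseq, window)
                aln = TargetAlignment(
                    mid, mseq, tid, int(s) + 1, int(s) + L, states,
                    mismatch_score(states),
                    duplex_mfe=duplex_mfe(mseq, window),
                    perfect_mfe=pmfe,
                    site_sequence=window,
                )
                if apply_target_rules(aln, rules)["overall"]:
                    seen.add(key)
                    out.append(aln)
    out.sort(key=lambda a: (a.mirna_id, a.transcript_id, a.site_start))
    return out


def render_alignment(aln: TargetAlignment) -> str:
    """Text rendering of one duplex: miRNA on top (written 3'->5' so it
    lines up with the site), pairing row (| = WC, o = G:U), target site on
    the bottom (5'->3')."""
    marks = [
        "|" if s == "WC" else ("o" if s == "GU" else " ") for s in aln.states
    ]
    mirna_rev = aln.mirna_sequence[::-1]
    marks_rev = "".join(marks)[::-1]
    site = aln.site_sequence or "?" * len(aln.mirna_sequence)
    return (
        f"3' {mirna_rev} 5'  {aln.mirna_id}\n"
        f"   {marks_rev}\n"
        f"5' {site} 3'  {aln.transcript_id}:{aln.site_start}-{aln.site_end}"
    )
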