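"""Synthetic data with planted ground truth.

Generates genome scaffolds with annotated ncRNA/exon/intron/repeat
features, plants miRNA hairpins that satisfy — or violate exactly one of —
the nine novel-miRNA criteria, simulates adapter-ligated small-RNA
libraries with the contaminant classes and length/first-nucleotide biases
of a real fruit library, plants miRNA target sites obeying or violating
each of the six target rules, simulates degradome 5'-end pileups opposite
miRNA nucleotides 10–11, and produces Ct tables with known fold changes.

Every planted object is verified with the downstream modules' own
predicates before it is emitted (hairpins are excised and folded with the
prediction module's excision code; target sites are labelled with the
target module's rule checks), so truth labels are self-consistent with the
pipeline by construction.  All generators are pure functions of
(spec, seed); independent stages use independently keyed substreams.

Defaults emulate the composition of a deep fruit small-RNA library:
contaminant fractions follow the published accounting of such a library
(3' adaptor null 0.04%, insert null 0.02%, 5' adaptor contaminants 0.18%,
shorter than 18 nt 2.26%, poly(A) trace), clean reads split between
miRNA (21.9%), rRNA (14.1%), tRNA (4.4%), sn/snoRNA (0.1%), exon/intron
fragments (9.6%) and unannotated sequence (49.9%), with a length
distribution peaked at 21 nt (38%) with a secondary 24-nt mode (30%) and a
5'-U bias of 0.8 on mature miRNAs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import novel as novel_mod
from . import targets as targets_mod
from ._seq import dna_to_rna, revcomp_dna, rna_to_dna
from .io import Feature

ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
READ_LENGTH = 49

DECOY_KINDS = novel_mod.CRITERION_NAMES  # one decoy per criterion

DEFAULT_CONTAMINANT_FRACTIONS = {
    "adaptor3_null": 6753 / 17103178,
    "insert_null": 3712 / 17103178,
    "adaptor5_contaminant": 31246 / 17103178,
    "shorter_than_min": 386179 / 17103178,
    "polyA": 115 / 17103178,
}

# clean-read class fractions of total depth (clean total ~0.975 of
# high-quality; splits follow the category shares of a real fruit library)
_CLEAN = 16675173 / 17103178
DEFAULT_CLASS_FRACTIONS = {
    **DEFAULT_CONTAMINANT_FRACTIONS,
    "mirna": _CLEAN * 0.2192,
    "rRNA": _CLEAN * 0.1405,
    "tRNA": _CLEAN * 0.0442,
    "snRNA": _CLEAN * 0.0007,
    "snoRNA": _CLEAN * 0.0002,
    "exon_sense": _CLEAN * 0.0309,
    "exon_antisense": _CLEAN * 0.0150,
    "intron_sense": _CLEAN * 0.0343,
    "intron_antisense": _CLEAN * 0.0158,
    # remainder (~0.4991 * clean) is unannotated: planted hairpin reads
    # plus count-1 background tags
}

DEFAULT_LENGTH_FRACTIONS = {
    18: 0.040, 19: 0.030, 20: 0.070, 21: 0.3802, 22: 0.080, 23: 0.060,
    24: 0.2981, 25: 0.023, 26: 0.008, 27: 0.004, 28: 0.003, 29: 0.002,
    30: 0.0017,
}

DEFAULT_ANNOTATION_FRACTIONS = {
    "rRNA": 0.015, "tRNA": 0.008, "snRNA": 0.003, "snoRNA": 0.002,
    "exon": 0.06, "intron": 0.06, "repeat": 0.02,
}

_FEATURE_LENGTHS = {
    "rRNA": (200, 600), "tRNA": (70, 90), "snRNA": (100, 200),
    "snoRNA": (70, 130), "exon": (150, 400), "intron": (200, 700),
    "repeat": (150, 400),
}

# non-pairing substitution used for mismatched/bulged positions: the
# chosen base can neither Watson-Crick- nor wobble-pair the original
_NO_PAIR = {"A": "C", "C": "A", "G": "A", "U": "C"}


@dataclasses.dataclass
class SimulationSpec:
    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length: int = 30000
    n_true_hairpins: int = 10
    n_decoy_hairpins: int = 9
    decoy_violations: tuple[str, ...] = DECOY_KINDS
    read_depth: int = 50000
    n_known_mirnas: int = 20
    contaminant_fractions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    length_mode_fractions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LENGTH_FRACTIONS)
    )
    annotation_fractions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ANNOTATION_FRACTIONS)
    )
    first_nt_u_bias: float = 0.8
    low_quality_fraction: float = 0.002

    def validate(self) -> None:
        for name, frac in {
            **self.contaminant_fractions,
            "first_nt_u_bias": self.first_nt_u_bias,
            "low_quality": self.low_quality_fraction,
        }.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {name} outside [0, 1]")
        total = sum(self.contaminant_fractions.values()) + self.low_quality_fraction
        if total > 1.0 + 1e-9:
            raise ValueError("class fractions exceed 1")
        if self.n_decoy_hairpins > len(self.decoy_violations):
            raise ValueError("more decoys requested than violation kinds listed")
        for kind in self.decoy_violations:
            if kind not in DECOY_KINDS:
                raise ValueError(f"unknown criterion identifier: {kind}")


@dataclasses.dataclass
class PlantedHairpin:
    hairpin_id: str
    kind: str  # "pass" or the violated criterion name
    label: str  # "pass" / "fail"
    violated_criterion: str | None
    scaffold: str
    start: int  # 1-based inclusive genomic span of the inserted cassette
    end: int
    strand: str
    mature_start: int  # 1-based genomic coordinates of the mature tag
    mature_end: int
    mature_seq: str  # DNA
    star_seq: str | None
    ref_span: int
    genome_copies: int
    tags: list[tuple[str, int]]  # (DNA sequence, read count) incl. mature
    extra_copies: list[tuple[str, int]] = dataclasses.field(
        default_factory=list
    )  # (scaffold, 0-based start) of bare extra mature copies


@dataclasses.dataclass
class PlantedTarget:
    transcript_id: str
    site_start: int
    site_end: int
    mirna_id: str
    kind: str  # "pass" or "fail_ruleN"
    rule_labels: dict[str, bool]  # rule1..rule6 + overall


@dataclasses.dataclass
class PlantedCleavage:
    transcript_id: str
    cleavage_position: int
    mirna_id: str
    expected_peak_count: int


@dataclasses.dataclass
class SyntheticTruth:
    planted_hairpins: list[PlantedHairpin] = dataclasses.field(default_factory=list)
    planted_targets: list[PlantedTarget] = dataclasses.field(default_factory=list)
    planted_cleavages: list[PlantedCleavage] = dataclasses.field(default_factory=list)

    def hairpin_frame(self) -> pd.DataFrame:
        rows = [
            {k: v for k, v in dataclasses.asdict(h).items()
             if k not in ("tags", "extra_copies")}
            for h in self.planted_hairpins
        ]
        return pd.DataFrame(rows)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _random_seq(rng: np.random.Generator, length: int,
                alphabet: str = "ACGT",
                weights: Sequence[float] | None = None) -> str:
    letters = list(alphabet)
    return "".join(rng.choice(letters, size=length, p=weights))


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome(
    spec: SimulationSpec,
) -> tuple[dict[str, str], list[Feature]]:
    """Random scaffolds plus non-overlapping feature annotation.

    Feature classes cover the configured genome fractions; a sizing error
    is raised when the scaffolds cannot host the requested features.
    """
    spec.validate()
    rng = _rng(spec.seed, 0)
    base_p = [0.31, 0.19, 0.19, 0.31]  # AT-rich plant-like composition
    genome = {
        f"scaffold_{i + 1}": _random_seq(rng, spec.scaffold_length, "ACGT", base_p)
        for i in range(spec.n_scaffolds)
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in genome}
    # keep scaffold_1's head free: the flank-violation decoy needs the edge
    occupied["scaffold_1"].append((0, 600))
    features: list[Feature] = []
    counter = 0
    for ftype in sorted(spec.annotation_fractions):
        frac = spec.annotation_fractions[ftype]
        if frac == 0:
            continue
        target_bp = frac * spec.n_scaffolds * spec.scaffold_length
        lo, hi = _FEATURE_LENGTHS[ftype]
        placed_bp = 0
        attempts = 0
        while placed_bp < target_bp:
            attempts += 1
            if attempts > 50000:
                raise ValueError(
                    f"scaffolds too small to host requested {ftype} fraction"
                )
            name = f"scaffold_{int(rng.integers(spec.n_scaffolds)) + 1}"
            length = int(rng.integers(lo, hi + 1))
            if length + 2 >= spec.scaffold_length:
                raise ValueError("scaffold_length too small for feature sizes")
            start = int(rng.integers(0, spec.scaffold_length - length))
            span = (start - 2, start + length + 1)  # 2-nt buffer
            if any(a < span[1] and span[0] < b for a, b in occupied[name]):
                continue
            occupied[name].append(span)
            strand = "+" if rng.random() < 0.5 else "-"
            counter += 1
            features.append(
                Feature(name, ftype, start + 1, start + length, strand,
                        f"ID={ftype}_{counter}")
            )
            placed_bp += length
    features.sort(key=lambda f: (f.seqid, f.start, f.ftype))
    return genome, features


# ---------------------------------------------------------------------------
# hairpin construction


def _star_arm(mature: str, plan: Sequence[tuple]) -> tuple[str, str]:
    """Build (possibly modified) mature and the star arm from a duplex plan.

    Plan segments (consumed along the mature 5'->3'):
      ("pair", n)       — n Watson-Crick pairs;
      ("iloop", nm, ns) — internal loop: nm mature + ns star unpaired bases
                          (mature bases are overwritten with 'A', star gets
                          'C': no canonical or wobble pairing possible);
      ("bulge_m", n)    — n unpaired mature bases (overwritten with 'A');
      ("bulge_s", n)    — n unpaired star bases ('C').
    Returns (mature', star_arm) in RNA, star arm 5'->3'.
    """
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    m = list(mature)
    segments: list[str] = []
    pos = 0
    for seg in plan:
        if seg[0] == "pair":
            n = seg[1]
            segments.append("".join(comp[b] for b in m[pos:pos + n]))
            pos += n
        elif seg[0] == "iloop":
            nm, ns = seg[1], seg[2]
            for k in range(pos, pos + nm):
                m[k] = "A"
            segments.append("C" * ns)
            pos += nm
        elif seg[0] == "bulge_m":
            n = seg[1]
            for k in range(pos, pos + n):
                m[k] = "A"
            pos += n
        elif seg[0] == "bulge_s":
            segments.append("C" * seg[1])
        else:
            raise ValueError(f"unknown plan segment {seg[0]!r}")
    if pos != len(m):
        raise ValueError("plan does not consume the whole mature sequence")
    return "".join(m), "".join(segments)[::-1]


def _sample_mature(rng: np.random.Generator, length: int, u_bias: float,
                   alphabet: str = "ACGU",
                   weights: Sequence[float] | None = None) -> str:
    if weights is None:
        weights = [0.22, 0.28, 0.28, 0.22]  # slightly GC-rich stems
    seq = list(_random_seq(rng, length, alphabet, weights))
    if rng.random() < u_bias:
        seq[0] = "U"
    return "".join(seq)


def _insert_is_clean(dna: str) -> bool:
    """A planted insert must not be mistakable for a filter category.

    The adapter-seed check runs on the insert *plus* the start of the 3'
    adapter, so a suffix of the insert cannot complete an adapter seed
    across the ligation junction and truncate trimming.
    """
    if ADAPTER3[:6] in dna + ADAPTER3[:5]:
        return False
    if dna.startswith(ADAPTER5[:8]):
        return False
    if dna and dna.count("A") / len(dna) >= 0.8:
        return False
    return True


@dataclasses.dataclass
class _HairpinDesign:
    kind: str
    cassette: str  # DNA inserted into the scaffold
    mature_offset: int  # 0-based within cassette
    mature_len: int
    ref_span: int
    genome_copies: int
    tags: list[tuple[str, int, int]]  # (dna, count, offset within cassette)
    expected_failures: tuple[str, ...]
    extra_copy_seq: str | None = None  # planted elsewhere n_extra times
    n_extra_copies: int = 0


def _design_hairpin(rng: np.random.Generator, kind: str,
                    u_bias: float) -> _HairpinDesign:
    """One attempt at a cassette for a pass hairpin or a named decoy."""
    margin_alpha, margin_w = "AC", [0.7, 0.3]
    loop_alpha, loop_w = "AC", [0.7, 0.3]
    margin_len = 30
    loop_len = 15
    arm_alpha, arm_w = "ACGU", None
    plan: list[tuple] = [("pair", 21)]
    mature_len = 21
    arm_len = 21
    copies = 1
    n_extra = 0
    expected: tuple[str, ...] = ()
    count = int(rng.integers(20, 41))
    tags_extra: list[tuple[int, int, int]] = []  # (offset, length, count)

    if kind == "pass":
        pass
    elif kind == "mature_len":
        # dominant 26-nt tag (survives the 18-30 nt size selection but
        # exceeds the mature bound); a 21-nt minor tag defines the valid
        # reference span, so only the tag-length bound trips
        mature_len = 26
        arm_len = 26
        plan = [("pair", 26)]
        tags_extra = [(0, 21, 5)]
        expected = ("mature_len",)
    elif kind == "ref_len":
        arm_len = 25
        plan = [("pair", 25)]
        tags_extra = [(4, 21, 5)]
        expected = ("ref_len",)
    elif kind == "ref_copies":
        copies = 21
        n_extra = 20
        expected = ("ref_copies",)
    elif kind == "mfe":
        arm_alpha, arm_w = "AU", [0.5, 0.5]
        margin_alpha, margin_w = "C", None
        loop_alpha, loop_w = "C", None
        margin_len = 60
        loop_len = 12
        expected = ("mfe",)
    elif kind == "loop_space":
        loop_len = 310
        expected = ("loop_space",)
    elif kind == "paired_bases":
        plan = [("pair", 7), ("iloop", 3, 3), ("pair", 4),
                ("iloop", 3, 3), ("pair", 4)]
        margin_len = 60
        expected = ("paired_bases",)
    elif kind == "bulge":
        plan = [("pair", 6), ("bulge_m", 5), ("pair", 6),
                ("bulge_s", 5), ("pair", 4)]
        expected = ("bulge",)
    elif kind == "asymmetry":
        plan = [("pair", 7), ("bulge_s", 3), ("pair", 7),
                ("bulge_s", 2), ("pair", 7)]
        expected = ("asymmetry",)
    elif kind == "flank":
        margin_len = 30  # upstream margin truncated at insertion time
        expected = ("flank",)
    else:
        raise ValueError(f"unknown hairpin kind {kind!r}")

    arm = _sample_mature(rng, arm_len, u_bias, arm_alpha, arm_w)
    arm, star = _star_arm(arm, plan)
    f5 = _random_seq(rng, 5 if kind == "flank" else margin_len,
                     margin_alpha, margin_w)
    f3 = _random_seq(rng, margin_len, margin_alpha, margin_w)
    loop = _random_seq(rng, loop_len, loop_alpha, loop_w)
    cassette_rna = f5 + arm + loop + star + f3
    cassette = rna_to_dna(cassette_rna)
    moff = len(f5)
    mature_dna = cassette[moff:moff + mature_len]
    tags = [(mature_dna, count, moff)]
    for toff, tlen, tcount in tags_extra:
        tags.append((cassette[moff + toff:moff + toff + tlen], tcount, moff + toff))
    valid = [(s, c, o) for s, c, o in tags if 18 <= len(s) <= 25] or tags
    ref_span = (max(o + len(s) for s, _, o in valid)
                - min(o for _, _, o in valid))
    # star reads at low count (below the expression floor on their own)
    star_off = moff + arm_len + loop_len
    star_dna = cassette[star_off:star_off + len(star)]
    tags.append((star_dna, 2, star_off))
    return _HairpinDesign(
        kind, cassette, moff, mature_len, ref_span, copies, tags, expected,
        extra_copy_seq=mature_dna if n_extra else None, n_extra_copies=n_extra,
    )


#: scaffold_1 head reserved for the edge-planted (flank-violation) decoy
_EDGE_RESERVATION = (0, 600)


def _free_slot(rng: np.random.Generator, genome: dict[str, bytearray],
               occupied: dict[str, list[tuple[int, int]]],
               size: int, at_edge: bool = False,
               scaffold: str | None = None) -> tuple[str, int]:
    names = [scaffold] if scaffold else sorted(genome)
    for _ in range(2000):
        name = names[int(rng.integers(len(names)))]
        L = len(genome[name])
        if at_edge:
            start = 0
            blockers = [iv for iv in occupied[name] if iv != _EDGE_RESERVATION]
        else:
            if L - size - 400 <= 400:
                continue
            start = int(rng.integers(400, L - size - 400))
            blockers = occupied[name]
        span = (start - 250, start + size + 250)  # clearance vs clusters
        if any(a < span[1] and span[0] < b for a, b in blockers):
            continue
        return name, start
    raise ValueError("no unannotated genomic space left for planting")


def plant_hairpins(
    genome: Mapping[str, str],
    spec: SimulationSpec,
    annotation: Sequence[Feature],
    criteria: novel_mod.NovelCriteria | None = None,
    max_attempts: int = 60,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Plant pass hairpins and single-violation decoys, verifying each by
    excising and folding it with the prediction module itself."""
    spec.validate()
    criteria = criteria or novel_mod.NovelCriteria()
    rng = _rng(spec.seed, 1)
    gbytes = {name: bytearray(genome[name], "ascii") for name in genome}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in genome}
    for f in annotation:
        occupied[f.seqid].append((f.start - 1, f.end))
    if "scaffold_1" in occupied:
        occupied["scaffold_1"].append(_EDGE_RESERVATION)

    truth = SyntheticTruth()
    jobs = [("pass", i) for i in range(spec.n_true_hairpins)] + [
        (spec.decoy_violations[i], i) for i in range(spec.n_decoy_hairpins)
    ]
    for kind, idx in jobs:
        ok = False
        for _ in range(max_attempts):
            design = _design_hairpin(rng, kind, spec.first_nt_u_bias)
            if not all(_insert_is_clean(s) for s, _, _ in design.tags):
                continue
            at_edge = kind == "flank"
            scaffold = "scaffold_1" if at_edge else None
            name, start = _free_slot(
                rng, gbytes, occupied, len(design.cassette), at_edge, scaffold
            )
            chrom_preview = gbytes[name][:]
            chrom_preview[start:start + len(design.cassette)] = (
                design.cassette.encode()
            )
            tstart = start + design.mature_offset
            tend = tstart + design.mature_len - 1
            excised = novel_mod.excise_locus(
                chrom_preview.decode(), name, tstart, tend, "+",
                flank_length=criteria.flank_length,
            )
            if excised is None:
                continue
            cand, metrics = excised
            cand.ref_span = design.ref_span
            cand.genome_copies = design.genome_copies
            report = novel_mod.apply_novel_criteria(
                cand, metrics, design.tags[0][1], criteria
            )
            if tuple(novel_mod.failed_criteria(report)) != design.expected_failures:
                continue
            # committed: write the cassette (and any extra mature copies)
            gbytes[name][start:start + len(design.cassette)] = (
                design.cassette.encode()
            )
            occupied[name].append((start, start + len(design.cassette)))
            copy_loci: list[tuple[str, int]] = []
            if design.n_extra_copies:
                placed = 0
                while placed < design.n_extra_copies:
                    cname, cstart = _free_slot(
                        rng, gbytes, occupied, len(design.extra_copy_seq)
                    )
                    gbytes[cname][cstart:cstart + len(design.extra_copy_seq)] = (
                        design.extra_copy_seq.encode()
                    )
                    occupied[cname].append(
                        (cstart, cstart + len(design.extra_copy_seq))
                    )
                    copy_loci.append((cname, cstart))
                    placed += 1
            truth.planted_hairpins.append(
                PlantedHairpin(
                    hairpin_id=f"hp_{kind}_{idx + 1}",
                    kind=kind,
                    label="pass" if kind == "pass" else "fail",
                    violated_criterion=None if kind == "pass" else kind,
                    scaffold=name,
                    start=start + 1,
                    end=start + len(design.cassette),
                    strand="+",
                    mature_start=tstart + 1,
                    mature_end=tend + 1,
                    mature_seq=design.tags[0][0],
                    star_seq=rna_to_dna(cand.star_sequence or ""),
                    ref_span=design.ref_span,
                    genome_copies=design.genome_copies,
                    tags=[(s, c) for s, c, _ in design.tags],
                    extra_copies=copy_loci,
                )
            )
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not construct a verified {kind} hairpin in "
                f"{max_attempts} attempts"
            )
    return {name: gbytes[name].decode() for name in sorted(gbytes)}, truth


# ---------------------------------------------------------------------------
# known-miRNA reference set

_FAMILY_NUMBERS = (156, 159, 160, 162, 164, 166, 167, 169, 172, 396, 397, 398)


def make_known_mirna_db(
    seed: int, n: int, avoid: Sequence[str] = (), min_distance: int = 3
) -> dict[str, str]:
    """miRBase-style mature set (DNA alphabet, ids like ppe-miR156a).

    Sequences keep at least ``min_distance`` substitutions from every
    sequence in ``avoid`` (e.g. planted novel matures), so the annotation
    cascade cannot confuse the two classes.
    """
    rng = _rng(seed, 5)
    db: dict[str, str] = {}
    i = 0
    while len(db) < n:
        fam = _FAMILY_NUMBERS[len(db) % len(_FAMILY_NUMBERS)]
        letter = chr(ord("a") + len(db) // len(_FAMILY_NUMBERS))
        length = int(rng.integers(20, 23))
        seq = rna_to_dna(_sample_mature(rng, length, 0.8))
        i += 1
        if i > 10000:
            raise RuntimeError("cannot satisfy known-miRNA distance constraint")
        if not _insert_is_clean(seq):
            continue
        if any(
            _hamming_min(seq, other) < min_distance
            for other in list(db.values()) + list(avoid)
        ):
            continue
        db[f"ppe-miR{fam}{letter}"] = seq
    return db


def _hamming_min(a: str, b: str) -> int:
    """Minimum substitution distance over containment alignments, counting
    the length difference as distance when no containment exists."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = len(short)
    for off in range(len(long_) - len(short) + 1):
        mm = sum(x != y for x, y in zip(short, long_[off:off + len(short)]))
        best = min(best, mm)
    return best


def make_species_dbs(
    known_db: Mapping[str, str],
    seed: int,
    species: Sequence[str] = ("ath", "ptc", "osa", "bna", "vvi"),
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Ortholog sets per species with a truth table of conservation states
    (identical / variant / absent per family and species)."""
    rng = _rng(seed, 6)
    from .known import parse_family

    dbs: dict[str, dict[str, str]] = {sp: {} for sp in species}
    rows = []
    families: dict[str, str] = {}
    for mid in sorted(known_db):
        families.setdefault(parse_family(mid), mid)
    for fam in sorted(families):
        mid = families[fam]
        seq = known_db[mid]
        for sp in species:
            state = rng.choice(["identical", "variant", "absent"],
                               p=[0.5, 0.3, 0.2])
            if state == "identical":
                dbs[sp][f"{sp}-{fam}"] = seq
            elif state == "variant":
                pos = int(rng.integers(len(seq)))
                alt = rna_to_dna(_NO_PAIR[dna_to_rna(seq[pos])])
                dbs[sp][f"{sp}-{fam}"] = seq[:pos] + alt + seq[pos + 1:]
            rows.append({"family": fam, "species": sp, "state": state})
    return dbs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sRNA library

_PHRED_HIGH = "I" * READ_LENGTH  # Q40
_PHRED_LOW = "#" * READ_LENGTH  # Q2


def _assemble_read(insert: str) -> str:
    read = insert + ADAPTER3
    while len(read) < READ_LENGTH:
        read += ADAPTER3
    return read[:READ_LENGTH]


def _draw_length(rng: np.random.Generator, fractions: Mapping[int, float],
                 lo: int = 18, hi: int = 30) -> int:
    lengths = sorted(k for k in fractions if lo <= k <= hi)
    probs = np.array([fractions[k] for k in lengths], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(lengths, p=probs))


def simulate_srna_library(
    truth: SyntheticTruth,
    spec: SimulationSpec,
    genome: Mapping[str, str],
    annotation: Sequence[Feature],
    known_db: Mapping[str, str],
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Adapter-ligated raw reads plus a truth sidecar.

    Returns ``(reads, sidecar)`` where reads are (id, sequence, quality)
    and the sidecar records each read's true class and origin.  Planted
    hairpin tag counts are fixed by the truth; the remaining unannotated
    share is filled with count-1 background tags from unannotated genomic
    space.
    """
    spec.validate()
    rng = _rng(spec.seed, 2)
    depth = spec.read_depth
    if depth == 0:
        return [], pd.DataFrame(columns=["read_id", "class", "origin"])
    planted = [
        (h.hairpin_id, seq, count)
        for h in truth.planted_hairpins
        for seq, count in h.tags
    ]
    n_planted = sum(c for _, _, c in planted)

    fractions = dict(spec.contaminant_fractions)
    class_names = sorted(fractions)
    probs = np.array([fractions[c] for c in class_names])
    lowq = spec.low_quality_fraction
    unannot_frac = 1.0 - probs.sum() - lowq
    if unannot_frac < 0:
        raise ValueError("class fractions leave no room for unannotated reads")
    n_rest = depth - n_planted
    if n_rest < 0:
        raise ValueError("read_depth too small for the planted tag counts")
    all_names = class_names + ["low_quality", "unannotated"]
    all_probs = np.concatenate([probs, [lowq, unannot_frac]])
    all_probs = all_probs / all_probs.sum()
    counts = rng.multinomial(n_rest, all_probs)
    class_counts = dict(zip(all_names, counts))

    feats_by_type: dict[str, list[Feature]] = {}
    for f in annotation:
        feats_by_type.setdefault(f.ftype, []).append(f)

    blocked: dict[str, list[tuple[int, int]]] = {n: [] for n in genome}
    for f in annotation:
        blocked[f.seqid].append((f.start - 1, f.end))
    for h in truth.planted_hairpins:
        blocked[h.scaffold].append((h.start - 1 - 250, h.end + 250))
        for cname, cstart in h.extra_copies:
            blocked[cname].append((cstart - 30, cstart + 30 + 30))

    records: list[tuple[str, str, str, str]] = []  # class, origin, seq, qual

    def add(cls: str, origin: str, raw: str, qual: str = _PHRED_HIGH) -> None:
        records.append((cls, origin, raw, qual))

    for hid, seq, count in planted:
        for _ in range(count):
            add("unannotated", hid, _assemble_read(seq))

    mirna_ids = sorted(known_db)
    for cls in all_names:
        n = int(class_counts[cls])
        if cls == "adaptor3_null":
            for _ in range(n):
                while True:
                    raw = _random_seq(rng, READ_LENGTH)
                    if ADAPTER3[:6] not in raw:
                        break
                add(cls, "", raw)
        elif cls == "insert_null":
            for _ in range(n):
                add(cls, "", _assemble_read(""))
        elif cls == "adaptor5_contaminant":
            for _ in range(n):
                insert = ADAPTER5[:10] + _random_seq(rng, 15)
                add(cls, "", _assemble_read(insert))
        elif cls == "shorter_than_min":
            for _ in range(n):
                while True:
                    insert = _random_seq(rng, int(rng.integers(10, 18)))
                    if _insert_is_clean(insert):
                        break
                add(cls, "", _assemble_read(insert))
        elif cls == "polyA":
            for _ in range(n):
                add(cls, "", _assemble_read("A" * int(rng.integers(20, 27))))
        elif cls == "low_quality":
            for _ in range(n):
                add(cls, "", _random_seq(rng, READ_LENGTH), _PHRED_LOW)
        elif cls == "mirna":
            for _ in range(n):
                mid = mirna_ids[int(rng.integers(len(mirna_ids)))]
                add(cls, mid, _assemble_read(known_db[mid]))
        elif cls == "unannotated":
            tag_counts: dict[str, int] = {}
            made = 0
            guard = 0
            while made < n:
                guard += 1
                if guard > 50 * max(n, 1):
                    raise RuntimeError("cannot place background unannotated reads")
                name = sorted(genome)[int(rng.integers(len(genome)))]
                L = _draw_length(rng, spec.length_mode_fractions)
                start = int(rng.integers(0, len(genome[name]) - L))
                span = (start, start + L)
                if any(a < span[1] and span[0] < b for a, b in blocked[name]):
                    continue
                insert = genome[name][start:start + L]
                if not _insert_is_clean(insert) or "N" in insert:
                    continue
                # keep background tags below the expression floor
                if tag_counts.get(insert, 0) >= 4:
                    continue
                tag_counts[insert] = tag_counts.get(insert, 0) + 1
                add(cls, f"{name}:{start + 1}", _assemble_read(insert))
                made += 1
        else:  # annotated ncRNA / exon / intron fragment classes
            base = cls.split("_")[0] if cls.startswith(("exon", "intron")) else cls
            feats = feats_by_type.get(base, [])
            if not feats and n > 0:
                raise ValueError(f"no {base} features to draw {cls} reads from")
            antisense = cls.endswith("_antisense")
            for _ in range(n):
                guard = 0
                while True:
                    guard += 1
                    if guard > 1000:
                        raise RuntimeError(f"cannot draw a clean {cls} fragment")
                    f = feats[int(rng.integers(len(feats)))]
                    flen = f.end - f.start + 1
                    L = min(_draw_length(rng, spec.length_mode_fractions), flen)
                    off = int(rng.integers(0, flen - L + 1))
                    frag = genome[f.seqid][f.start - 1 + off:f.start - 1 + off + L]
                    if f.strand == "-":
                        frag = revcomp_dna(frag)
                    if antisense:
                        frag = revcomp_dna(frag)
                    if _insert_is_clean(frag) and "N" not in frag:
                        break
                add(cls, f.attributes, _assemble_read(frag))

    order = rng.permutation(len(records))
    out_reads = []
    rows = []
    for new_idx, old_idx in enumerate(order):
        cls, origin, raw, qual = records[old_idx]
        rid = f"r{new_idx + 1:07d}"
        out_reads.append((rid, raw, qual))
        rows.append({"read_id": rid, "class": cls, "origin": origin})
    sidecar = pd.DataFrame(rows, columns=["read_id", "class", "origin"])
    return out_reads, sidecar


# ---------------------------------------------------------------------------
# transcriptome with planted target sites

_MM_TARGET = {"A": "C", "C": "A", "G": "A", "U": "C"}
_WC_TARGET = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_TARGET = {"G": "U", "U": "G"}

_RULE_DECOY_POSITIONS = {
    "fail_rule1": (13, 15, 17, 19, 21),
    "fail_rule2": (14, 15, 16),
    "fail_rule3": (6, 7),
    "fail_rule4": (10,),
    "fail_rule5": (2, 4, 6),
}


def _build_site(mirna_rna: str, kind: str) -> str:
    """Target-site sequence (RNA, 5'->3') for a miRNA and a site kind."""
    L = len(mirna_rna)
    opp = [_WC_TARGET[b] for b in mirna_rna]  # opp[i] faces miRNA pos i+1
    if kind == "pass":
        pass
    elif kind in _RULE_DECOY_POSITIONS:
        for p in _RULE_DECOY_POSITIONS[kind]:
            if p <= L:
                opp[p - 1] = _MM_TARGET[mirna_rna[p - 1]]
    elif kind == "fail_rule6":
        wobble_positions = [i for i in range(1, L + 1)
                            if mirna_rna[i - 1] in _WOBBLE_TARGET]
        chosen: list[int] = []
        in_seed = 0
        for p in sorted(wobble_positions, key=lambda q: abs(q - (L + 1) / 2)):
            if len(chosen) >= 8:
                break
            if p <= 12 and in_seed >= 5:
                continue
            chosen.append(p)
            if p <= 12:
                in_seed += 1
        for p in chosen:
            opp[p - 1] = _WOBBLE_TARGET[mirna_rna[p - 1]]
    else:
        raise ValueError(f"unknown site kind {kind!r}")
    return "".join(reversed(opp))


def _label_site(mirna_rna: str, site_rna: str,
                rules: targets_mod.TargetRules) -> dict[str, bool]:
    states = targets_mod.align_site(mirna_rna, site_rna)
    aln = targets_mod.TargetAlignment(
        "x", mirna_rna, "x", 1, len(mirna_rna), states,
        targets_mod.mismatch_score(states),
        duplex_mfe=targets_mod.duplex_mfe(mirna_rna, site_rna),
        perfect_mfe=targets_mod.perfect_mfe(mirna_rna),
        site_sequence=site_rna,
    )
    return targets_mod.apply_target_rules(aln, rules)


def simulate_transcriptome_with_targets(
    mirnas: Mapping[str, str],
    rules: targets_mod.TargetRules,
    seed: int,
    n_transcripts: int = 12,
    transcript_length: int = 1200,
    peak_count: int = 50,
    max_attempts: int = 8,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Random transcripts with planted target sites per rule label.

    Each miRNA (18–25 nt) gets one perfect site plus one decoy per target
    rule; every planted site's per-rule label is computed with the target
    module's own rule check before emission, and the emitted transcriptome
    is rescanned exhaustively to confirm no unplanted passing site exists.
    Planted cleavages (for degradome simulation) sit at the transcript
    position pairing miRNA nucleotide 10 of each passing planted site.
    """
    for mid in sorted(mirnas):
        if not 18 <= len(mirnas[mid]) <= 25:
            raise ValueError(f"miRNA {mid} outside 18-25 nt")
    rng = _rng(seed, 3)
    kinds = ["pass"] + sorted(_RULE_DECOY_POSITIONS) + ["fail_rule6"]

    for attempt in range(max_attempts):
        transcripts = {
            f"tx{i + 1:03d}": _random_seq(rng, transcript_length)
            for i in range(n_transcripts)
        }
        truth = SyntheticTruth()
        occupied: dict[str, list[tuple[int, int]]] = {t: [] for t in transcripts}
        tx_names = sorted(transcripts)
        ok = True
        for j, mid in enumerate(sorted(mirnas)):
            mrna = dna_to_rna(mirnas[mid]).upper()
            L = len(mrna)
            for k, kind in enumerate(kinds):
                site_rna = _build_site(mrna, kind)
                labels = _label_site(mrna, site_rna, rules)
                tid = tx_names[(j * len(kinds) + k) % len(tx_names)]
                placed = False
                for _ in range(200):
                    start = int(rng.integers(30, transcript_length - L - 30))
                    span = (start - 25, start + L + 25)
                    if any(a < span[1] and span[0] < b for a, b in occupied[tid]):
                        continue
                    occupied[tid].append(span)
                    seq = transcripts[tid]
                    transcripts[tid] = (
                        seq[:start] + rna_to_dna(site_rna) + seq[start + L:]
                    )
                    truth.planted_targets.append(
                        PlantedTarget(
                            tid, start + 1, start + L, mid, kind,
                            {k2: bool(v) for k2, v in labels.items()},
                        )
                    )
                    if labels["overall"]:
                        truth.planted_cleavages.append(
                            PlantedCleavage(tid, start + L - 9, mid, peak_count)
                        )
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        # exhaustive self-check: scanning must recover exactly the planted
        # passing sites (per distinct miRNA sequence)
        found = {
            (a.mirna_id, a.transcript_id, a.site_start)
            for a in targets_mod.scan_transcriptome(mirnas, transcripts, rules)
        }
        expected = {
            (t.mirna_id, t.transcript_id, t.site_start)
            for t in truth.planted_targets
            if t.rule_labels["overall"]
        }
        # identical miRNA sequences legitimately claim each other's sites
        seq_of = {mid: dna_to_rna(mirnas[mid]).upper() for mid in mirnas}
        expanded = {
            (mid2, tid, s)
            for (mid, tid, s) in expected
            for mid2 in mirnas
            if seq_of[mid2] == seq_of[mid]
        }
        if found == expanded:
            return transcripts, truth
    raise RuntimeError(
        "could not generate a transcriptome whose scan matches the planted truth"
    )


# ---------------------------------------------------------------------------
# degradome reads


def simulate_degradome(
    transcripts: Mapping[str, str],
    cleavages: Sequence[PlantedCleavage],
    background_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 20,
    min_read_length: int = 15,
) -> list[str]:
    """5'-monophosphate fragment reads: a pileup of ``expected_peak_count``
    reads at each planted cleavage position plus Poisson(background_rate)
    uniform background per position."""
    rng = _rng(seed, 4)
    reads: list[str] = []
    for c in cleavages:
        seq = transcripts.get(c.transcript_id)
        if seq is None:
            raise ValueError(f"unknown transcript {c.transcript_id}")
        if not 1 <= c.cleavage_position <= len(seq):
            raise ValueError(
                f"cleavage position {c.cleavage_position} outside "
                f"{c.transcript_id}"
            )
        frag = seq[c.cleavage_position - 1:c.cleavage_position - 1 + read_length]
        if len(frag) < min_read_length:
            raise ValueError("cleavage fragment too short to sequence")
        reads.extend([frag] * c.expected_peak_count)
    if background_rate > 0:
        for tid in sorted(transcripts):
            seq = transcripts[tid]
            last = len(seq) - min_read_length
            counts = rng.poisson(background_rate, size=last + 1)
            for pos0 in np.nonzero(counts)[0]:
                frag = seq[pos0:pos0 + read_length]
                reads.extend([frag] * int(counts[pos0]))
    return reads


# ---------------------------------------------------------------------------
# Ct tables


def simulate_ct_table(
    design: Mapping,
    effects: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table with planted log2 fold changes.

    ``design`` keys: samples (list), replicates (int), target_gene,
    reference_gene; ``effects`` maps sample -> true log2 fold change
    relative to the calibrator (whose effect should be 0).  Ct(target) =
    baseline − log2FC + noise; the reference gene is constant up to noise.
    """
    n_rep = int(design["replicates"])
    if n_rep < 1:
        raise ValueError("replicate count must be >= 1")
    samples = list(design["samples"])
    target = design["target_gene"]
    reference = design["reference_gene"]
    base_target = float(design.get("target_baseline_ct", 25.0))
    base_ref = float(design.get("reference_baseline_ct", 15.0))
    rng = _rng(seed, 7)
    rows = []
    for sample in samples:
        effect = float(effects.get(sample, 0.0))
        for rep in range(1, n_rep + 1):
            noise_t = rng.normal(0, noise_sd) if noise_sd else 0.0
            noise_r = rng.normal(0, noise_sd) if noise_sd else 0.0
            rows.append({"sample": sample, "gene": target, "replicate": rep,
                         "ct": base_target - effect + noise_t})
            rows.append({"sample": sample, "gene": reference, "replicate": rep,
                         "ct": base_ref + noise_r})
    return pd.DataFrame(rows)
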