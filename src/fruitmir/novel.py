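"""Novel miRNA prediction from unannotated, genome-mapped tags.

The approach is the classic hairpin-excision one: cluster unannotated tag
hits into loci, excise a genomic window around the dominant tag, fold it
with a nearest-neighbour thermodynamic model (ViennaRNA), trim the window
to the miRNA/miRNA* duplex plus a fixed flank, and accept the candidate
only if all nine structural/expression criteria hold:

1.  mature_len     — mature tag length 18–25 nt;
2.  ref_len        — mature-arm reference span (union of overlapping tag
                     alignments at the locus) 20–23 nt;
3.  ref_copies     — the mature tag maps to at most 20 genomic loci
                     (repeat-likeness cap);
4.  mfe            — precursor minimum free energy <= −18 kcal/mol;
5.  loop_space     — at most 300 nt between miRNA and miRNA*;
6.  paired_bases   — at least 16 miRNA/miRNA* base pairs;
7.  bulge          — longest unpaired run inside the duplex <= 4 nt on
                     either strand;
8.  asymmetry      — |unpaired(mature side) − unpaired(star side)| <= 4 nt;
9.  flank          — >= 20 nt of precursor flank on both sides of the
                     duplex.

A tenth, expression, filter requires the mature tag to have been sequenced
at least ``min_read_count`` times (default 5).  The miRNA* is inferred
from the pairing partner of the mature arm with the canonical 2-nt 3'
overhang left by Dicer.

Excision is independent of the criteria thresholds (fixed window ladder,
fixed internal pairing heuristic), so tightening any threshold can only
shrink the prediction set.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import RNA

from ._seq import dna_to_rna, revcomp_dna, validate_rna
from .annotate import GenomeHit
from .preprocess import SmallRNATag

CRITERION_NAMES = (
    "mature_len", "ref_len", "ref_copies", "mfe", "loop_space",
    "paired_bases", "bulge", "asymmetry", "flank",
)

#: window extension ladder tried on each arm orientation (nt)
WINDOW_EXTENSIONS = (80, 160, 260, 380)
#: extension stops early once this many mature bases pair (excision
#: heuristic; deliberately a constant, not a criteria field)
_EXCISION_MIN_PAIRED = 16
#: plausible mature-length window used to define the reference span
_REF_VALID = (18, 25)
_WINDOW_PAD = 40  # nt kept behind the mature tag before trimming


class DuplexUndefinedError(ValueError):
    """Raised when the mature region has no pairing partner outside itself."""


@dataclasses.dataclass
class NovelCriteria:
    mature_len_min: int = 18
    mature_len_max: int = 25
    ref_len_min: int = 20
    ref_len_max: int = 23
    max_ref_copies: int = 20
    mfe_max: float = -18.0
    max_loop_space: int = 300
    min_paired: int = 16
    max_bulge: int = 4
    max_asymmetry: int = 4
    flank_length: int = 20
    min_read_count: int = 5

    def __post_init__(self) -> None:
        if self.mature_len_min > self.mature_len_max:
            raise ValueError("mature length bounds inverted")
        if self.ref_len_min > self.ref_len_max:
            raise ValueError("reference length bounds inverted")


@dataclasses.dataclass
class HairpinCandidate:
    scaffold: str
    start: int  # 1-based inclusive genomic span of the precursor
    end: int
    strand: str
    precursor: str  # RNA alphabet, 5'->3'
    structure: str  # dot-bracket
    mfe: float  # kcal/mol
    mature_start: int  # 0-based inclusive, within precursor
    mature_end: int
    star_start: int | None = None
    star_end: int | None = None
    ref_span: int | None = None  # mature-arm reference span (nt)
    genome_copies: int | None = None  # genomic loci of the mature tag
    read_count: int = 0

    @property
    def mature_sequence(self) -> str:
        return self.precursor[self.mature_start:self.mature_end + 1]

    @property
    def star_sequence(self) -> str | None:
        if self.star_start is None or self.star_end is None:
            return None
        return self.precursor[self.star_start:self.star_end + 1]


@dataclasses.dataclass
class DuplexMetrics:
    paired_bases: int
    max_bulge: int
    asymmetry: int
    loop_space: int
    flank5: int
    flank3: int

    @property
    def flank_length(self) -> int:
        return min(self.flank5, self.flank3)


@dataclasses.dataclass
class NovelMiRNA:
    id: str
    mature_sequence: str
    star_sequence: str | None
    candidate: HairpinCandidate
    read_count: int
    criterion_report: dict[str, bool]


def fold_rna(sequence: str) -> tuple[str, float]:
    """Dot-bracket MFE structure of an RNA sequence (nearest-neighbour
    thermodynamics via ViennaRNA); deterministic."""
    validate_rna(sequence)
    if len(sequence) < 30:
        raise ValueError("sequence too short to fold as a precursor (< 30 nt)")
    structure, mfe = RNA.fold(sequence)
    return structure, round(float(mfe), 2)


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position; -1 when unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def duplex_metrics(candidate: HairpinCandidate) -> DuplexMetrics:
    """Geometry of the miRNA/miRNA* duplex; also fills the candidate's star
    coordinates (2-nt 3' overhang convention)."""
    pt = pair_table(candidate.structure)
    ms, me = candidate.mature_start, candidate.mature_end
    partners = {
        i: pt[i]
        for i in range(ms, me + 1)
        if pt[i] >= 0 and not (ms <= pt[i] <= me)
    }
    if not partners:
        raise DuplexUndefinedError("mature region has no external pairing")

    paired_positions = sorted(partners)
    paired = len(paired_positions)
    pmin = min(partners.values())
    pmax = max(partners.values())

    # interior unpaired runs between consecutive paired mature positions
    mature_gaps: list[int] = []
    star_gaps: list[int] = []
    for a, b in zip(paired_positions, paired_positions[1:]):
        mature_gaps.append(b - a - 1)
        star_gaps.append(abs(partners[a] - partners[b]) - 1)
    max_bulge = max(mature_gaps + star_gaps, default=0)
    asymmetry = abs(sum(mature_gaps) - sum(star_gaps))

    star_downstream = pmin > me
    if star_downstream:
        loop_space = pmin - me - 1
    else:
        loop_space = ms - pmax - 1
    loop_space = max(loop_space, 0)

    # Dicer 2-nt 3' overhang: shift the raw partner span by +2 toward the
    # star strand's 3' end (ascending precursor coordinates either way).
    L = len(candidate.precursor)
    candidate.star_start = max(0, min(L - 1, pmin + 2))
    candidate.star_end = max(0, min(L - 1, pmax + 2))

    dmin = min(paired_positions[0], pmin)
    dmax = max(paired_positions[-1], pmax)
    return DuplexMetrics(
        paired_bases=paired,
        max_bulge=max_bulge,
        asymmetry=asymmetry,
        loop_space=loop_space,
        flank5=dmin,
        flank3=L - 1 - dmax,
    )


def apply_novel_criteria(
    candidate: HairpinCandidate,
    metrics: DuplexMetrics,
    read_count: int,
    criteria: NovelCriteria = NovelCriteria(),
) -> dict[str, dict]:
    """Evaluate the nine criteria independently.

    Returns a report ``{criterion: {"passed": bool, "value": measured}}``;
    the overall verdict is the conjunction (plus the expression floor,
    which is reported under ``read_count`` but is not one of the nine).
    """
    mature_len = candidate.mature_end - candidate.mature_start + 1
    ref_span = candidate.ref_span if candidate.ref_span is not None else mature_len
    copies = candidate.genome_copies if candidate.genome_copies is not None else 1
    c = criteria
    report = {
        "mature_len": (c.mature_len_min <= mature_len <= c.mature_len_max, mature_len),
        "ref_len": (c.ref_len_min <= ref_span <= c.ref_len_max, ref_span),
        "ref_copies": (copies <= c.max_ref_copies, copies),
        "mfe": (candidate.mfe <= c.mfe_max, candidate.mfe),
        "loop_space": (metrics.loop_space <= c.max_loop_space, metrics.loop_space),
        "paired_bases": (metrics.paired_bases >= c.min_paired, metrics.paired_bases),
        "bulge": (metrics.max_bulge <= c.max_bulge, metrics.max_bulge),
        "asymmetry": (metrics.asymmetry <= c.max_asymmetry, metrics.asymmetry),
        "flank": (metrics.flank_length >= c.flank_length, metrics.flank_length),
    }
    out = {k: {"passed": bool(p), "value": v} for k, (p, v) in report.items()}
    out["read_count"] = {"passed": read_count >= c.min_read_count, "value": read_count}
    return out


def report_passes(report: Mapping[str, dict]) -> bool:
    return all(report[name]["passed"] for name in CRITERION_NAMES)


def failed_criteria(report: Mapping[str, dict]) -> list[str]:
    return [name for name in CRITERION_NAMES if not report[name]["passed"]]


def _oriented_window(
    chrom: str, wstart: int, wend: int, strand: str
) -> str:
    """Extract [wstart, wend] 0-based inclusive, oriented 5'->3'."""
    seq = chrom[wstart:wend + 1]
    return revcomp_dna(seq) if strand == "-" else seq


def excise_locus(
    chrom: str,
    scaffold: str,
    tag_start: int,
    tag_end: int,
    strand: str,
    flank_length: int = 20,
) -> tuple[HairpinCandidate, DuplexMetrics] | None:
    """Excise, fold and trim the best hairpin candidate for one mature
    locus (0-based inclusive tag coordinates on the + strand reference).

    Tries both arm orientations with a fixed extension ladder, keeps the
    window with the most paired mature bases (ties: smaller window), then
    trims to duplex +/- ``flank_length`` and refolds.  Returns ``None``
    when no window yields a defined duplex.
    """
    L = len(chrom)
    tlen = tag_end - tag_start + 1
    best: tuple[tuple[int, int], int, int] | None = None  # score, wstart, wend
    fold_cache: dict[str, tuple[str, float]] = {}

    def cached_fold(rna: str) -> tuple[str, float]:
        if rna not in fold_cache:
            fold_cache[rna] = fold_rna(rna)
        return fold_cache[rna]

    def evaluate(wstart: int, wend: int) -> int | None:
        wstart, wend = max(0, wstart), min(L - 1, wend)
        if wend - wstart + 1 < tlen + 30:
            return None
        window = _oriented_window(chrom, wstart, wend, strand)
        if strand == "+":
            moff = tag_start - wstart
        else:
            moff = wend - tag_end
        rna = dna_to_rna(window)
        if len(rna) < 30:
            return None
        structure, mfe = cached_fold(rna)
        cand = HairpinCandidate(
            scaffold, wstart + 1, wend + 1, strand, rna, structure, mfe,
            moff, moff + tlen - 1,
        )
        try:
            m = duplex_metrics(cand)
        except DuplexUndefinedError:
            return None
        return m.paired_bases

    for ext in WINDOW_EXTENSIONS:
        for wstart, wend in (
            (tag_start - _WINDOW_PAD, tag_end + ext),   # star 3' of mature
            (tag_start - ext, tag_end + _WINDOW_PAD),   # star 5' of mature
        ):
            paired = evaluate(wstart, wend)
            if paired is None:
                continue
            size = wend - wstart
            key = (-paired, size)
            if best is None or key < best[0]:
                best = (key, wstart, wend)
        if best is not None and -best[0][0] >= _EXCISION_MIN_PAIRED:
            break
    if best is None:
        return None

    # fold the chosen window once more to locate the duplex span, then trim
    _, wstart, wend = best
    wstart, wend = max(0, wstart), min(L - 1, wend)
    window = _oriented_window(chrom, wstart, wend, strand)
    moff = (tag_start - wstart) if strand == "+" else (wend - tag_end)
    rna = dna_to_rna(window)
    structure, mfe = cached_fold(rna)
    cand = HairpinCandidate(
        scaffold, wstart + 1, wend + 1, strand, rna, structure, mfe,
        moff, moff + tlen - 1,
    )
    try:
        duplex_metrics(cand)
    except DuplexUndefinedError:
        return None
    pt = pair_table(structure)
    partners = [
        pt[i] for i in range(moff, moff + tlen)
        if pt[i] >= 0 and not (moff <= pt[i] < moff + tlen)
    ]
    dmin = min(min(partners), moff)
    dmax = max(max(partners) + 2, moff + tlen - 1)  # keep the 2-nt overhang
    pstart = max(0, dmin - flank_length)
    pend = min(len(window) - 1, dmax + flank_length)

    # map the trimmed window back to genomic coordinates
    if strand == "+":
        gstart, gend = wstart + pstart, wstart + pend
        new_moff = moff - pstart
    else:
        gstart, gend = wend - pend, wend - pstart
        new_moff = moff - pstart
    precursor = dna_to_rna(_oriented_window(chrom, gstart, gend, strand))
    structure, mfe = fold_rna(precursor)
    final = HairpinCandidate(
        scaffold, gstart + 1, gend + 1, strand, precursor, structure, mfe,
        new_moff, new_moff + tlen - 1,
    )
    try:
        metrics = duplex_metrics(final)
    except DuplexUndefinedError:
        return None
    return final, metrics


def _cluster_hits(
    hits: Sequence[GenomeHit], gap: int
) -> list[list[GenomeHit]]:
    groups: dict[tuple[str, str], list[GenomeHit]] = {}
    for h in hits:
        groups.setdefault((h.scaffold, h.strand), []).append(h)
    clusters: list[list[GenomeHit]] = []
    for key in sorted(groups):
        block = sorted(groups[key], key=lambda h: (h.start, h.end))
        current = [block[0]]
        for h in block[1:]:
            if h.start - max(x.end for x in current) - 1 <= gap:
                current.append(h)
            else:
                clusters.append(current)
                current = [h]
        clusters.append(current)
    return clusters


def evaluate_candidates(
    genome: Mapping[str, str],
    tags: Sequence[SmallRNATag],
    hits: Sequence[GenomeHit],
    criteria: NovelCriteria = NovelCriteria(),
    cluster_gap: int = 200,
) -> list[tuple[HairpinCandidate, DuplexMetrics, dict[str, dict]]]:
    """Excise and score one candidate per read locus.

    Loci whose dominant tag was sequenced fewer than
    ``criteria.min_read_count`` times are skipped before folding (they can
    never be emitted, and raising the floor only removes loci).
    """
    counts = {t.sequence: t.count for t in tags}
    hit_loci: dict[str, int] = {}
    for h in hits:
        hit_loci[h.tag_sequence] = hit_loci.get(h.tag_sequence, 0) + 1

    results = []
    for cluster in _cluster_hits(hits, cluster_gap):
        dominant = max(
            cluster,
            key=lambda h: (counts.get(h.tag_sequence, 0), h.tag_sequence),
        )
        read_count = counts.get(dominant.tag_sequence, 0)
        if read_count < criteria.min_read_count:
            continue
        # reference span: union of hits overlapping the dominant alignment,
        # restricted to plausible mature lengths (the library's credible
        # miRNA size range, a fixed constant so excision and scoring do not
        # shift when criteria thresholds move)
        arm = [
            h for h in cluster
            if h.start <= dominant.end and h.end >= dominant.start
            and _REF_VALID[0] <= h.end - h.start + 1 <= _REF_VALID[1]
        ] or [dominant]
        ref_span = max(h.end for h in arm) - min(h.start for h in arm) + 1
        excised = excise_locus(
            genome[dominant.scaffold], dominant.scaffold,
            dominant.start - 1, dominant.end - 1, dominant.strand,
            flank_length=criteria.flank_length,
        )
        if excised is None:
            continue
        candidate, metrics = excised
        candidate.ref_span = ref_span
        candidate.genome_copies = hit_loci.get(dominant.tag_sequence, 1)
        candidate.read_count = read_count
        report = apply_novel_criteria(candidate, metrics, read_count, criteria)
        results.append((candidate, metrics, report))
    return results


def excise_candidates(
    genome: Mapping[str, str],
    tags: Sequence[SmallRNATag],
    hits: Sequence[GenomeHit],
    criteria: NovelCriteria = NovelCriteria(),
    cluster_gap: int = 200,
) -> list[HairpinCandidate]:
    """Excised, folded and trimmed hairpin candidates, one per read locus
    (see :func:`evaluate_candidates` for the scored form)."""
    return [
        cand for cand, _, _ in
        evaluate_candidates(genome, tags, hits, criteria, cluster_gap)
    ]


def predict_novel(
    genome: Mapping[str, str],
    tags: Sequence[SmallRNATag],
    hits: Sequence[GenomeHit],
    criteria: NovelCriteria = NovelCriteria(),
    cluster_gap: int = 200,
) -> list[NovelMiRNA]:
    """Full prediction: excise -> fold -> metrics -> criteria -> expression
    floor.  Ids ``m0001, m0002, ...`` are assigned in (scaffold, start)
    order over the emitted set."""
    evaluated = evaluate_candidates(genome, tags, hits, criteria, cluster_gap)
    emitted = [
        (cand, report)
        for cand, _, report in evaluated
        if report_passes(report) and report["read_count"]["passed"]
    ]
    emitted.sort(key=lambda cr: (cr[0].scaffold, cr[0].start, cr[0].strand))
    out = []
    for i, (cand, report) in enumerate(emitted, start=1):
        out.append(
            NovelMiRNA(
                id=f"m{i:04d}",
                mature_sequence=cand.mature_sequence,
                star_sequence=cand.star_sequence,
                candidate=cand,
                read_count=cand.read_count,
                criterion_report={k: v["passed"] for k, v in report.items()},
            )
        )
    return out
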