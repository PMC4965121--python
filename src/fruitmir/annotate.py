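"""Genome mapping of tags and classification into small-RNA categories.

Tags are mapped to the genome by exact (or bounded-mismatch) search on both
strands, then assigned exactly one category by a configurable precedence
order.  The default order

    miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > exon > intron > unannotated

removes structural ncRNA classes before anything is considered a candidate
for novel-miRNA prediction.  Known-miRNA membership is decided by sequence
match against a mature reference set (tolerating one substitution by
default); the other categories are decided by >= 1 nt overlap between a
genomic hit and an annotated feature, with exon/intron split into sense and
antisense by strand comparison.  Tags with no genomic hit and no category
are counted as unannotated (and flagged unmapped), so the summary always
partitions the tag set.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._seq import revcomp_dna
from .io import Feature
from .preprocess import SmallRNATag, percent

DEFAULT_PRECEDENCE = (
    "miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron",
)

#: categories appearing in the summary table, in report order
SUMMARY_CATEGORIES = (
    "exon_antisense", "exon_sense", "intron_antisense", "intron_sense",
    "miRNA", "rRNA", "snRNA", "snoRNA", "tRNA", "repeat", "unannotated",
)


@dataclasses.dataclass
class GenomeHit:
    tag_sequence: str
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    mismatches: int = 0


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i >= 0:
        yield i
        i = haystack.find(needle, i + 1)


def map_tags(
    tags: Sequence[SmallRNATag],
    genome: dict[str, str],
    max_mismatches: int = 0,
) -> list[GenomeHit]:
    """Report every genomic occurrence of every tag on both strands.

    Exact matching (``max_mismatches=0``, the default) uses substring
    search; the bounded-mismatch mode scans every offset and is intended
    only for small inputs.
    """
    if not genome:
        raise ValueError("empty genome")
    hits: list[GenomeHit] = []
    if max_mismatches == 0:
        # seed index on the first 12 nt, then verify the full match
        k = 12
        index: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(genome):
            chrom = genome[name]
            for i in range(len(chrom) - k + 1):
                index.setdefault(chrom[i:i + k], []).append((name, i))
        for tag in tags:
            for query, strand in (
                (tag.sequence, "+"), (revcomp_dna(tag.sequence), "-")
            ):
                L = len(query)
                if L < k:
                    continue
                for name, i in index.get(query[:k], ()):
                    if genome[name][i:i + L] == query:
                        hits.append(
                            GenomeHit(tag.sequence, name, i + 1, i + L, strand, 0)
                        )
        hits.sort(key=lambda h: (h.tag_sequence, h.scaffold, h.start, h.strand))
        return hits
    for tag in tags:  # bounded-mismatch mode: exhaustive scan, small inputs
        seq = tag.sequence
        rc = revcomp_dna(seq)
        L = len(seq)
        for name in sorted(genome):
            chrom = genome[name]
            for i in range(len(chrom) - L + 1):
                window = chrom[i:i + L]
                for query, strand in ((seq, "+"), (rc, "-")):
                    mm = sum(a != b for a, b in zip(query, window))
                    if mm <= max_mismatches:
                        hits.append(GenomeHit(seq, name, i + 1, i + L, strand, mm))
    hits.sort(key=lambda h: (h.tag_sequence, h.scaffold, h.start, h.strand))
    return hits


def _hamming_within(tag: str, ref: str) -> int | None:
    """Substitution distance with the shorter sequence fully contained in
    the longer; ``None`` when no containment alignment exists."""
    short, long_ = (tag, ref) if len(tag) <= len(ref) else (ref, tag)
    best: int | None = None
    for off in range(len(long_) - len(short) + 1):
        mm = sum(a != b for a, b in zip(short, long_[off:off + len(short)]))
        if best is None or mm < best:
            best = mm
    return best


def matches_known_mirna(
    sequence: str, known_mirnas: dict[str, str], max_mismatches: int = 1
) -> bool:
    for ref in known_mirnas.values():
        d = _hamming_within(sequence, ref)
        if d is not None and d <= max_mismatches:
            return True
    return False


@dataclasses.dataclass
class CategorySummary:
    table: pd.DataFrame  # category, unique_count, redundant_count, pcts

    def validate(self, n_tags: int, n_reads: int) -> None:
        if int(self.table["unique_count"].sum()) != n_tags:
            raise ValueError("unique counts do not partition the tag set")
        if int(self.table["redundant_count"].sum()) != n_reads:
            raise ValueError("redundant counts do not partition the reads")


def category_summary_from_counts(
    counts: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Build a summary table (with 2-dp percentages) from per-category
    (unique, redundant) counts — also the arithmetic used to recompute
    published category percentages."""
    total_u = sum(u for u, _ in counts.values())
    total_r = sum(r for _, r in counts.values())
    rows = []
    for cat in SUMMARY_CATEGORIES:
        u, r = counts.get(cat, (0, 0))
        rows.append((cat, u, percent(u, total_u), r, percent(r, total_r)))
    rows.append(("total", total_u, percent(total_u, total_u) if total_u else 0.0,
                 total_r, percent(total_r, total_r) if total_r else 0.0))
    return pd.DataFrame(
        rows,
        columns=["category", "unique_count", "unique_pct",
                 "redundant_count", "redundant_pct"],
    )


def classify_tags(
    tags: Sequence[SmallRNATag],
    hits: Sequence[GenomeHit],
    annotation: Sequence[Feature],
    known_mirnas: dict[str, str] | None = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    mirna_max_mismatches: int = 1,
) -> tuple[dict[str, str], CategorySummary]:
    """Assign each tag exactly one category and summarise the partition.

    Returns a map ``tag sequence -> category`` (category names as in
    ``SUMMARY_CATEGORIES``) and the Table-3-style summary.
    """
    known_cats = set(DEFAULT_PRECEDENCE)
    for cat in precedence:
        if cat not in known_cats:
            raise ValueError(f"unknown category in precedence list: {cat}")

    trees: dict[str, IntervalTree] = {}
    for f in annotation:
        trees.setdefault(f.seqid, IntervalTree())[f.start:f.end + 1] = f

    hits_by_tag: dict[str, list[GenomeHit]] = {}
    for h in hits:
        hits_by_tag.setdefault(h.tag_sequence, []).append(h)

    assignment: dict[str, str] = {}
    for tag in tags:
        overlaps: dict[str, set[str]] = {}  # ftype -> strands relation
        for h in hits_by_tag.get(tag.sequence, ()):  # genome evidence
            tree = trees.get(h.scaffold)
            if tree is None:
                continue
            for iv in tree.overlap(h.start, h.end + 1):
                f: Feature = iv.data
                rel = "sense" if f.strand == h.strand else "antisense"
                overlaps.setdefault(f.ftype, set()).add(rel)
        category = None
        for cat in precedence:
            if cat == "miRNA":
                if known_mirnas and matches_known_mirna(
                    tag.sequence, known_mirnas, mirna_max_mismatches
                ):
                    category = "miRNA"
                    break
            elif cat in overlaps:
                if cat in ("exon", "intron"):
                    rel = "sense" if "sense" in overlaps[cat] else "antisense"
                    category = f"{cat}_{rel}"
                else:
                    category = cat
                break
        assignment[tag.sequence] = category or "unannotated"

    counts: dict[str, tuple[int, int]] = {}
    for tag in tags:
        cat = assignment[tag.sequence]
        u, r = counts.get(cat, (0, 0))
        counts[cat] = (u + 1, r + tag.count)
    summary = CategorySummary(category_summary_from_counts(counts))
    summary.table = summary.table  # noqa: B018 (keep explicit)
    n_reads = sum(t.count for t in tags)
    CategorySummary(summary.table[summary.table.category != "total"]).validate(
        len(tags), n_reads
    )
    return assignment, summary


def unannotated_tags(
    tags: Sequence[SmallRNATag], assignment: dict[str, str]
) -> list[SmallRNATag]:
    """The input pool for novel-miRNA prediction."""
    return [t for t in tags if assignment.get(t.sequence) == "unannotated"]
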