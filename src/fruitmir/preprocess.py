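"""Raw small-RNA read cleaning and accounting.

Reads are assigned to exactly one category, tested in a fixed order:

    low-quality -> 3' adaptor null -> insert null -> 5' adaptor contaminant
    -> shorter than min length -> poly(A) -> clean

so the categories partition the high-quality reads and the accounting
identity

    clean = high_quality - (a3_null + insert_null + a5_contaminant
                            + shorter_than_min + polyA)

holds on any input.  Percentages are reported against the high-quality
total (the "100.00" row), to two decimals with half-up rounding.

Category definitions (the upstream study names the categories without
defining them; these are the standard Illumina small-RNA conventions):

* low quality: mean Phred < threshold (default 20) or > 10% N calls;
* 3' adaptor null: no occurrence of the first 6 nt of the 3' adapter
  (also used for trimmed inserts longer than the selected size window,
  where the apparent adapter hit is spurious);
* insert null: the 3' adapter starts at position 0 (empty insert);
* 5' adaptor contaminant: the trimmed insert begins with >= 8 nt of the
  5' adapter;
* poly(A): >= 80% A after trimming (configurable).
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator

import pandas as pd

#: categories of removed reads, in assignment order after the quality gate
REMOVAL_CATEGORIES = (
    "adaptor3_null",
    "insert_null",
    "adaptor5_contaminant",
    "shorter_than_min",
    "polyA",
)


def percent(numerator: int | float, denominator: int | float) -> float:
    """Percentage to 2 dp with half-up rounding (report convention)."""
    if denominator == 0:
        return 0.0
    frac = Decimal(numerator) / Decimal(denominator) * 100
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class SmallRNATag:
    """A collapsed unique read sequence with its redundant count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclasses.dataclass
class FilterSummary:
    total_reads: int
    high_quality: int
    adaptor3_null: int
    insert_null: int
    adaptor5_contaminant: int
    shorter_than_min: int
    polyA: int
    clean_reads: int

    @classmethod
    def from_counts(
        cls,
        total_reads: int,
        high_quality: int,
        adaptor3_null: int,
        insert_null: int,
        adaptor5_contaminant: int,
        shorter_than_min: int,
        polyA: int,
    ) -> "FilterSummary":
        """Build a summary from category counts via the accounting identity."""
        removed = (
            adaptor3_null + insert_null + adaptor5_contaminant
            + shorter_than_min + polyA
        )
        return cls(
            total_reads, high_quality, adaptor3_null, insert_null,
            adaptor5_contaminant, shorter_than_min, polyA,
            clean_reads=high_quality - removed,
        )

    def validate(self) -> None:
        removed = (
            self.adaptor3_null + self.insert_null + self.adaptor5_contaminant
            + self.shorter_than_min + self.polyA
        )
        if self.clean_reads != self.high_quality - removed:
            raise ValueError("filter accounting identity violated")
        for name in REMOVAL_CATEGORIES + ("clean_reads",):
            if getattr(self, name if name != "clean_reads" else "clean_reads") > self.high_quality:
                raise ValueError(f"category {name} exceeds high-quality total")

    @property
    def percentages(self) -> dict[str, float]:
        base = self.high_quality
        out = {"high_quality": percent(self.high_quality, base)}
        for name in REMOVAL_CATEGORIES:
            out[name] = percent(getattr(self, name), base)
        out["clean_reads"] = percent(self.clean_reads, base)
        return out

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        rows = [("total_reads", self.total_reads, "")]
        rows.append(("high_quality", self.high_quality, f"{pct['high_quality']:.2f}"))
        for name in REMOVAL_CATEGORIES:
            rows.append((name, getattr(self, name), f"{pct[name]:.2f}"))
        rows.append(("clean_reads", self.clean_reads, f"{pct['clean_reads']:.2f}"))
        return pd.DataFrame(rows, columns=["type", "count", "percentage"])


@dataclasses.dataclass
class CompositionTable:
    """Length and first-nucleotide composition of a tag set.

    ``first_nt_by_length`` uses RNA letters (U not T), matching the usual
    presentation of small-RNA first-nucleotide tables.
    """

    length_counts_redundant: dict[int, int]
    length_counts_unique: dict[int, int]
    first_nt_redundant: dict[tuple[int, str], int]
    first_nt_unique: dict[tuple[int, str], int]
    positional_nt_fraction: dict[tuple[int, str], float]


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def filter_reads(
    raw: Iterable[tuple[str, str, str]],
    adapter3: str,
    adapter5: str,
    quality_threshold: float = 20.0,
    max_n_fraction: float = 0.10,
    min_length: int = 18,
    max_length: int = 30,
    polya_fraction: float = 0.80,
    adapter3_seed: int = 6,
    adapter5_seed: int = 8,
) -> tuple[list[str], FilterSummary]:
    """Classify raw reads and trim the 3' adapter from the clean ones.

    Parameters
    ----------
    raw
        Iterable of ``(read_id, sequence, phred_string)``.
    adapter3, adapter5
        Ligated adapter sequences (DNA alphabet); must be non-empty.

    Returns
    -------
    (clean_inserts, summary)
        Trimmed insert sequences of the clean reads, and the category
        accounting.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapter sequences must be non-empty")
    seed3 = adapter3[:adapter3_seed]
    seed5 = adapter5[:adapter5_seed]

    total = high_quality = 0
    counts = dict.fromkeys(REMOVAL_CATEGORIES, 0)
    clean: list[str] = []

    for idx, (rid, seq, qual) in enumerate(raw):
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record #{idx} ({rid})")
        total += 1
        n_frac = seq.count("N") / len(seq) if seq else 1.0
        if _mean_phred(qual) < quality_threshold or n_frac > max_n_fraction:
            continue
        high_quality += 1
        pos = seq.find(seed3)
        if pos < 0:
            counts["adaptor3_null"] += 1
            continue
        insert = seq[:pos]
        if len(insert) > max_length:
            counts["adaptor3_null"] += 1  # spurious adapter hit beyond window
            continue
        if not insert:
            counts["insert_null"] += 1
            continue
        if len(insert) >= adapter5_seed and insert.startswith(seed5):
            counts["adaptor5_contaminant"] += 1
            continue
        if len(insert) < min_length:
            counts["shorter_than_min"] += 1
            continue
        if insert.count("A") / len(insert) >= polya_fraction:
            counts["polyA"] += 1
            continue
        clean.append(insert)

    summary = FilterSummary.from_counts(
        total, high_quality, counts["adaptor3_null"], counts["insert_null"],
        counts["adaptor5_contaminant"], counts["shorter_than_min"],
        counts["polyA"],
    )
    summary.validate()
    return clean, summary


def collapse_tags(clean_reads: Iterable[str]) -> list[SmallRNATag]:
    """Collapse identical inserts into unique tags with redundant counts.

    Output order is deterministic: descending count, then sequence.
    """
    counts: dict[str, int] = {}
    for seq in clean_reads:
        counts[seq] = counts.get(seq, 0) + 1
    return [
        SmallRNATag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def expand_tags(tags: Iterable[SmallRNATag]) -> Iterator[str]:
    """Inverse of :func:`collapse_tags` up to read order."""
    for tag in tags:
        for _ in range(tag.count):
            yield tag.sequence


def composition_stats(
    tags: Iterable[SmallRNATag],
    first_nt_window: tuple[int, int] = (18, 25),
) -> CompositionTable:
    """Length distribution, first-nucleotide table, and positional bias.

    Counts are computed both redundantly (count-weighted) and on unique
    tags.  The first-nucleotide table is restricted to ``first_nt_window``
    (default 18-25 nt, the conventional reporting window); positional
    fractions are count-weighted and sum to 1 at every position covered by
    at least one tag.
    """
    lo, hi = first_nt_window
    len_red: dict[int, int] = {}
    len_uni: dict[int, int] = {}
    fnt_red: dict[tuple[int, str], int] = {}
    fnt_uni: dict[tuple[int, str], int] = {}
    pos_counts: dict[tuple[int, str], int] = {}
    pos_totals: dict[int, int] = {}

    for tag in tags:
        L = len(tag.sequence)
        len_red[L] = len_red.get(L, 0) + tag.count
        len_uni[L] = len_uni.get(L, 0) + 1
        first = tag.sequence[0].replace("T", "U")
        if lo <= L <= hi:
            fnt_red[(L, first)] = fnt_red.get((L, first), 0) + tag.count
            fnt_uni[(L, first)] = fnt_uni.get((L, first), 0) + 1
        for i, base in enumerate(tag.sequence, start=1):
            b = base.replace("T", "U")
            pos_counts[(i, b)] = pos_counts.get((i, b), 0) + tag.count
            pos_totals[i] = pos_totals.get(i, 0) + tag.count

    pos_frac = {
        (i, b): n / pos_totals[i] for (i, b), n in pos_counts.items()
    }
    return CompositionTable(len_red, len_uni, fnt_red, fnt_uni, pos_frac)
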