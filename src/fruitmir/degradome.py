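"""Degradome (PARE) cleavage-site validation of predicted targets.

Degradome reads are 5' ends of uncapped cleavage fragments.  They are
mapped sense-only and exactly to the transcriptome, and summarised into a
per-transcript density of 5'-end counts.  miRNA-guided cleavage cuts the
target between the positions pairing miRNA nucleotides 10 and 11, so for a
site at transcript coordinates [s, e] (e pairs miRNA position 1) the
expected cleavage position is ``e - 9``; an event is called when the
density there reaches ``min_peak``.

Peak categories (the established degradome convention, frozen here):

* 0 — the position holds the unique transcript maximum and count > 1;
* 1 — shares the maximum (tie) and count > 1;
* 2 — above the transcript median but not a maximum;
* 3 — at or below the median but count > 1;
* 4 — count == 1.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .targets import TargetAlignment


@dataclasses.dataclass
class CleavageEvent:
    mirna_id: str
    transcript_id: str
    cleavage_position: int  # 1-based transcript coordinate (pairs miRNA nt 10)
    peak_count: int
    category: int
    alignment: TargetAlignment


def build_density(
    degradome_reads: Iterable[str],
    transcripts: Mapping[str, str],
    mode: str = "all",
) -> dict[str, np.ndarray]:
    """Per-transcript, per-position counts of degradome-read 5' ends.

    Reads are matched as exact sense-strand substrings (cleavage fragments
    are exact transcript suffixes/prefixes of suffixes).  ``mode="all"``
    adds one count per occurrence; ``mode="fractional"`` splits a read's
    weight evenly over its occurrences across the transcriptome.
    """
    if mode not in ("all", "fractional"):
        raise ValueError("mode must be 'all' or 'fractional'")
    names = sorted(transcripts)
    density = {t: np.zeros(len(transcripts[t]), dtype=float) for t in names}
    for read in degradome_reads:
        occurrences: list[tuple[str, int]] = []
        for t in names:
            seq = transcripts[t]
            i = seq.find(read)
            while i >= 0:
                occurrences.append((t, i))
                i = seq.find(read, i + 1)
        if not occurrences:
            continue
        w = 1.0 if mode == "all" else 1.0 / len(occurrences)
        for t, i in occurrences:
            density[t][i] += w
    return density


def categorize_peak(density_vector: np.ndarray, position: int) -> int | None:
    """Category 0-4 of the peak at a 1-based position; None if count is 0."""
    if len(density_vector) == 0:
        raise ValueError("empty density vector")
    count = density_vector[position - 1]
    if count == 0:
        return None
    if count == 1:
        return 4
    mx = density_vector.max()
    if count == mx:
        ties = int((density_vector == mx).sum())
        return 0 if ties == 1 else 1
    if count > float(np.median(density_vector)):
        return 2
    return 3


def detect_cleavage(
    targets: Sequence[TargetAlignment],
    density: Mapping[str, np.ndarray],
    min_peak: float = 1,
) -> list[CleavageEvent]:
    """Call cleavage events at the position pairing miRNA nucleotide 10.

    Events are emitted per (miRNA, target site) without suppression, so a
    position may be claimed by several miRNAs sharing a sequence.
    """
    events: list[CleavageEvent] = []
    for aln in targets:
        vec = density.get(aln.transcript_id)
        if vec is None:
            continue
        pos = aln.site_end - 9
        if not (1 <= pos <= len(vec)) or not (1 <= aln.site_start <= len(vec)):
            raise ValueError(
                f"target site {aln.transcript_id}:{aln.site_start}-{aln.site_end}"
                " outside transcript bounds"
            )
        count = vec[pos - 1]
        if count < min_peak or count == 0:
            continue
        category = categorize_peak(vec, pos)
        events.append(
            CleavageEvent(
                aln.mirna_id, aln.transcript_id, pos,
                int(count), category, aln,
            )
        )
    return events


def tplot_data(
    transcript_id: str,
    density: Mapping[str, np.ndarray],
    events: Sequence[CleavageEvent],
) -> pd.DataFrame:
    """Per-position table for a t-plot: (position, count, is_cleavage_site)."""
    if transcript_id not in density:
        raise KeyError(f"no density for transcript {transcript_id}")
    vec = density[transcript_id]
    marked = {e.cleavage_position for e in events if e.transcript_id == transcript_id}
    return pd.DataFrame(
        {
            "position": np.arange(1, len(vec) + 1),
            "count": vec,
            "is_cleavage_site": [p in marked for p in range(1, len(vec) + 1)],
        }
    )


def events_to_frame(events: Sequence[CleavageEvent]) -> pd.DataFrame:
    rows = [
        (e.mirna_id, e.transcript_id, e.alignment.site_start,
         e.alignment.site_end, e.cleavage_position, e.peak_count, e.category)
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "transcript_id", "site_start", "site_end",
                 "cleavage_position", "peak_count", "category"],
    )
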