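"""Known-miRNA assignment and cross-species conservation.

Tags are aligned (substitutions only, no indels; a shorter sequence must be
fully contained in the longer) against a miRBase-style mature reference
set, and optionally against hairpin precursors for tags that miss every
mature entry.  Each tag is reported once, with its best (fewest-mismatch)
hit; ties break to the lexicographically smallest miRNA id so results are
order-invariant.  Family names are parsed from the id as ``miR`` plus the
leading integer run of the numeric suffix (ppe-miR156a -> miR156).
"""

from __future__ import annotations

import dataclasses
import re
from typing import Mapping, Sequence

import pandas as pd

from .annotate import _hamming_within
from .preprocess import SmallRNATag

_FAMILY_RE = re.compile(r"(?:miR|MIR)[-]?(\d+)", re.IGNORECASE)


def parse_family(mirna_id: str) -> str:
    m = _FAMILY_RE.search(mirna_id)
    return f"miR{m.group(1)}" if m else mirna_id


def parse_species(mirna_id: str) -> str:
    head, sep, _ = mirna_id.partition("-")
    return head if sep else ""


@dataclasses.dataclass
class KnownMiRNAHit:
    tag_sequence: str
    mirna_id: str
    family: str
    source_species: str
    mismatches: int
    count: int


def _best_hit(seq: str, db: Mapping[str, str], limit: int) -> tuple[int, str] | None:
    best: tuple[int, str] | None = None
    for mid in sorted(db):
        d = _hamming_within(seq, db[mid])
        if d is None or d > limit:
            continue
        if best is None or (d, mid) < best:
            best = (d, mid)
    return best


def identify_known(
    tags: Sequence[SmallRNATag],
    mature_db: Mapping[str, str],
    hairpin_db: Mapping[str, str] | None = None,
    max_mismatches: int = 2,
) -> list[KnownMiRNAHit]:
    """Assign tags to known miRNAs; one best hit per tag, counts carried."""
    if not mature_db:
        raise ValueError("empty mature miRNA database")
    hits: list[KnownMiRNAHit] = []
    for tag in tags:
        best = _best_hit(tag.sequence, mature_db, max_mismatches)
        if best is None and hairpin_db:
            best = _best_hit(tag.sequence, hairpin_db, max_mismatches)
        if best is None:
            continue
        mm, mid = best
        hits.append(
            KnownMiRNAHit(
                tag.sequence, mid, parse_family(mid), parse_species(mid),
                mm, tag.count,
            )
        )
    return hits


def hits_to_frame(hits: Sequence[KnownMiRNAHit]) -> pd.DataFrame:
    df = pd.DataFrame(
        [dataclasses.asdict(h) for h in hits],
        columns=["tag_sequence", "mirna_id", "family", "source_species",
                 "mismatches", "count"],
    )
    return df.sort_values(["mirna_id", "tag_sequence"]).reset_index(drop=True)


def family_counts(hits: Sequence[KnownMiRNAHit]) -> pd.DataFrame:
    """Exact-id and family-aggregated redundant counts."""
    df = hits_to_frame(hits)
    if df.empty:
        return pd.DataFrame(columns=["family", "n_mirnas", "count"])
    out = (
        df.groupby("family")
        .agg(n_mirnas=("mirna_id", "nunique"), count=("count", "sum"))
        .reset_index()
        .sort_values("family")
        .reset_index(drop=True)
    )
    return out


def conservation_matrix(
    hits: Sequence[KnownMiRNAHit],
    species_dbs: Mapping[str, Mapping[str, str]],
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Family x species conservation states.

    ``identical`` — some member tag exactly equals a mature sequence of
    that species; ``variant`` — best match within ``max_mismatches``
    substitutions; ``absent`` otherwise.  The conventional rendering is
    ``++`` / ``+`` / blank (see :func:`render_conservation`).
    """
    tags_by_family: dict[str, set[str]] = {}
    for h in hits:
        tags_by_family.setdefault(h.family, set()).add(h.tag_sequence)
    rows = {}
    for family in sorted(tags_by_family):
        row = {}
        for species in sorted(species_dbs):
            db = {
                mid: seq for mid, seq in species_dbs[species].items()
                if parse_family(mid) == family
            }
            state = "absent"
            for seq in tags_by_family[family]:
                best = _best_hit(seq, db, max_mismatches) if db else None
                if best is None:
                    continue
                if best[0] == 0:
                    state = "identical"
                    break
                state = "variant"
            row[species] = state
        rows[family] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("family")


def render_conservation(matrix: pd.DataFrame) -> pd.DataFrame:
    symbols = {"identical": "++", "variant": "+", "absent": ""}
    return matrix.map(symbols.get)
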