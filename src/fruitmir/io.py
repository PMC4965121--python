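"""File-format boundaries: FASTA/FASTQ via Biopython, GFF3 and TSV via pandas.

All genomic coordinates on disk are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


@dataclasses.dataclass
class Feature:
    """One annotation record (rRNA/tRNA/snRNA/snoRNA/exon/intron/repeat...)."""

    seqid: str
    ftype: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    attributes: str = "."


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, phred_string) triples."""
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals)


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch for {rid}")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_gff3(path: str | Path, features: Iterable[Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.seqid}\tfruitmir\t{f.ftype}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{f.attributes}\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "attributes": str},
    )
    return [
        Feature(r.seqid, r.type, int(r.start), int(r.end), r.strand, r.attributes)
        for r in df.itertuples()
    ]


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
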