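"""Small sequence helpers shared across the pipeline.

DNA (T) is the on-disk alphabet; RNA (U) is used inside folding and duplex
logic.  Conversion happens at module boundaries only.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def validate_rna(seq: str) -> None:
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"not an RNA sequence (offending symbols: {sorted(bad)})")


def validate_dna(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"not a DNA sequence (offending symbols: {sorted(bad)})")
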