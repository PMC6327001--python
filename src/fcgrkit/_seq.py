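"""Small shared sequence helpers used across modules."""

from __future__ import annotations

from typing import Iterable

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter", "X": "Xaa",
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a CDS (no trailing stop handling; Biopython table 1)."""
    return str(Seq(cds).translate())


def aa3(residue: str) -> str:
    """Three-letter code for a one-letter amino-acid residue."""
    try:
        return _AA3[residue.upper()]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r}") from None


def check_dna(seq: str, what: str = "sequence") -> str:
    """Uppercase and validate a DNA string over A/C/G/T/N."""
    if not seq:
        raise ValueError(f"{what} is empty")
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")
    return s


def as_fasta(records: Iterable[tuple[str, str]]) -> str:
    """Render (id, seq) pairs as FASTA text, 70 columns per line."""
    out = []
    for name, seq in records:
        out.append(f">{name}")
        for i in range(0, len(seq), 70):
            out.append(seq[i : i + 70])
    return "\n".join(out) + "\n"
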