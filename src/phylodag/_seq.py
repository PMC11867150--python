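"""Nucleotide sequence helpers shared across modules.

Sequences are uppercase strings over the unambiguous alphabet ``ACGT`` plus
the IUPAC ambiguity codes.  Site indices in documentation are 1-based.
"""

from __future__ import annotations

from itertools import product

BASES = "ACGT"

#: IUPAC nucleotide code -> set of compatible unambiguous bases.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: frozenset of bases -> IUPAC code (inverse of the above).
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}


def is_ambiguous(sequence: str) -> bool:
    """Return True if any site carries a non-ACGT IUPAC code."""
    return any(ch not in "ACGT" for ch in sequence)


def validate_sequence(sequence: str, *, allow_ambiguity: bool = True) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in IUPAC_TO_BASES:
            raise ValueError(f"invalid nucleotide character {ch!r}")
        if not allow_ambiguity and ch not in "ACGT":
            raise ValueError(f"ambiguity code {ch!r} not allowed here")


def n_disambiguations(sequence: str) -> int:
    n = 1
    for ch in sequence:
        n *= len(IUPAC_TO_BASES[ch])
    return n


def disambiguations(sequence: str):
    """Yield every unambiguous sequence compatible with ``sequence``."""
    options = [sorted(IUPAC_TO_BASES[ch]) for ch in sequence]
    for combo in product(*options):
        yield "".join(combo)


def hamming(a: str, b: str) -> int:
    """Number of differing sites between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))
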