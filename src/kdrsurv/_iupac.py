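"""IUPAC nucleotide ambiguity codes and set arithmetic.

A diploid Sanger consensus represents a heterozygous position as the
ambiguity code of the two underlying bases (Y = C/T, W = A/T, ...).
"""

from __future__ import annotations

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

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

ALPHABET = "".join(IUPAC_TO_BASES)  # ACGTRYSWKMBDHVN


def bases_of(code: str) -> frozenset[str]:
    """Return the set of bases encoded by one IUPAC letter."""
    try:
        return IUPAC_TO_BASES[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_of(bases) -> str:
    """Return the IUPAC letter for a set of plain bases."""
    key = frozenset(b.upper() for b in bases)
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from None


def compatible(a: str, b: str) -> bool:
    """True when two IUPAC letters share at least one base (alignment match)."""
    return not bases_of(a).isdisjoint(bases_of(b))


def merge(a: str, b: str) -> str:
    """Consensus letter for a diploid position carrying bases ``a`` and ``b``."""
    return code_of(bases_of(a) | bases_of(b))
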