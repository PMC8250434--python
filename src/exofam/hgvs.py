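"""Minimal HGVS-style notation parsing and codon arithmetic.

Only single-nucleotide coding substitutions and single-residue protein
substitutions are supported; anything else (dup/del/ins/fs, genomic
``g.`` positions, intronic offsets) raises :class:`HgvsError` rather
than guessing. Amino-acid identity is not verified — no transcript
sequences ship with this package — only the codon arithmetic linking a
cDNA position to a residue index is checked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import ExofamError

NUCLEOTIDES = frozenset("ACGT")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY*X")


class HgvsError(ExofamError):
    """Unsupported or malformed notation."""


@dataclass(frozen=True)
class CodingChange:
    """A single-nucleotide substitution at a 1-based cDNA coordinate."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise HgvsError(f"cDNA position must be >= 1, got {self.position}")
        for base in (self.ref_base, self.alt_base):
            if base not in NUCLEOTIDES:
                raise HgvsError(f"invalid nucleotide {base!r}")
        if self.ref_base == self.alt_base:
            raise HgvsError("reference and alternate bases must differ")


@dataclass(frozen=True)
class ProteinChange:
    """A single-residue substitution at a 1-based residue index."""

    residue: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise HgvsError(f"residue index must be >= 1, got {self.residue}")
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AMINO_ACIDS:
                raise HgvsError(f"invalid amino-acid code {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise HgvsError("reference and alternate residues must differ")


# Standard "c.904C>T" and the transposed letter-position-letter form
# "c.G848A" that appears in some published variant lists.
_CDNA_STANDARD = re.compile(r"^c\.\s*(\d+)\s*([A-Za-z])\s*>\s*([A-Za-z])$")
_CDNA_TRANSPOSED = re.compile(r"^c\.\s*([A-Za-z])\s*(\d+)\s*([A-Za-z])$")
_PROTEIN = re.compile(r"^p\.\s*([A-Za-z*])\s*(\d+)\s*([A-Za-z*])$")


def parse_cdna(text: str) -> CodingChange:
    """Parse a coding substitution in either accepted spelling.

    >>> parse_cdna("c.904C>T")
    CodingChange(position=904, ref_base='C', alt_base='T')
    >>> parse_cdna("c.G848A")
    CodingChange(position=848, ref_base='G', alt_base='A')
    """
    if not text or not text.strip():
        raise HgvsError("empty cDNA notation")
    s = text.strip()
    m = _CDNA_STANDARD.match(s)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2).upper(), m.group(3).upper()
        return CodingChange(position=pos, ref_base=ref, alt_base=alt)
    m = _CDNA_TRANSPOSED.match(s)
    if m:
        ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        return CodingChange(position=pos, ref_base=ref, alt_base=alt)
    raise HgvsError(f"unsupported cDNA notation {text!r}")


def parse_protein(text: str) -> ProteinChange:
    """Parse a one-letter protein substitution such as ``p.R302C``."""
    if not text or not text.strip():
        raise HgvsError("empty protein notation")
    m = _PROTEIN.match(text.strip())
    if not m:
        raise HgvsError(f"unsupported protein notation {text!r}")
    return ProteinChange(
        residue=int(m.group(2)),
        ref_aa=m.group(1).upper(),
        alt_aa=m.group(3).upper(),
    )


def codon_index(cdna_position: int) -> int:
    """1-based index of the codon containing a 1-based cDNA position.

    ``codon_index(p) == floor((p - 1) / 3) + 1``, so positions 1–3 map
    to codon 1, 4–6 to codon 2, and so on.
    """
    if cdna_position < 1:
        raise HgvsError(f"cDNA position must be >= 1, got {cdna_position}")
    return (cdna_position - 1) // 3 + 1


def check_protein_consistency(c: CodingChange, p: ProteinChange) -> bool:
    """True iff the cDNA position falls in the codon of the protein residue."""
    return codon_index(c.position) == p.residue
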