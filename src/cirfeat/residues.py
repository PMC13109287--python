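"""Residue chemistry: the hydrophobic/polar/charged partition and pair classes.

The 20 standard amino acids are partitioned into three chemical classes —
hydrophobic (H), polar (P) and charged (C) — which drive both the interface
composition analysis (hydrophobic core, charged rim) and the stratification
of classifier scores by pair type.
"""

from __future__ import annotations

from typing import Iterable

HYDROPHOBIC = frozenset({"GLY", "ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TYR", "TRP"})
POLAR = frozenset({"SER", "PRO", "THR", "CYS", "ASN", "GLN"})
CHARGED = frozenset({"HIS", "LYS", "ARG", "ASP", "GLU"})

STANDARD_RESIDUES = HYDROPHOBIC | POLAR | CHARGED

#: The six unordered chemical pair classes.
PAIR_CLASSES = ("HH", "HP", "HC", "PP", "PC", "CC")


def residue_class(resname: str) -> str:
    """Return 'H', 'P' or 'C' for a standard residue name.

    Nonstandard residues raise ``KeyError``; callers that tolerate them
    should check membership in :data:`STANDARD_RESIDUES` first.
    """
    name = resname.upper()
    if name in HYDROPHOBIC:
        return "H"
    if name in POLAR:
        return "P"
    if name in CHARGED:
        return "C"
    raise KeyError(f"nonstandard residue name: {resname!r}")


def pair_class(resname_a: str, resname_b: str) -> str:
    """Unordered chemical class of a residue pair (HP == PH).

    Classes are canonicalised to the order listed in :data:`PAIR_CLASSES`.
    """
    ab = residue_class(resname_a) + residue_class(resname_b)
    if ab in PAIR_CLASSES:
        return ab
    ba = ab[::-1]
    if ba in PAIR_CLASSES:
        return ba
    raise ValueError(f"unrecognised pair class {ab!r}")


def is_standard(resnames: Iterable[str]) -> list[bool]:
    return [r.upper() in STANDARD_RESIDUES for r in resnames]
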