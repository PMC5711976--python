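"""Residue alphabet: 20 standard amino acids plus three chemically distinct variants.

The extended 23-letter alphabet covers oxidized cysteine, cis-proline and
protonated histidine, which have systematically different shifts from their
parent residues and are therefore treated as separate categories throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

AA1 = "ACDEFGHIKLMNPQRSTVWY"

VARIANT_NONE = "none"
VARIANTS = ("cys_oxidized", "pro_cis", "his_protonated")
VARIANT_PARENT = {"cys_oxidized": "C", "pro_cis": "P", "his_protonated": "H"}
_VARIANT_KEY = {"cys_oxidized": "C_ox", "pro_cis": "P_cis", "his_protonated": "H_plus"}
_KEY_VARIANT = {v: k for k, v in _VARIANT_KEY.items()}

#: the 23 residue categories, in fixed encoding order
ALPHABET23 = list(AA1) + [_VARIANT_KEY[v] for v in VARIANTS]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueState:
    """An amino-acid category: one-letter code plus an optional variant flag."""

    aa: str
    variant: str = VARIANT_NONE

    def __post_init__(self):
        if self.aa not in AA1:
            raise ValueError(f"unknown amino-acid letter {self.aa!r}")
        if self.variant != VARIANT_NONE:
            if self.variant not in VARIANT_PARENT:
                raise ValueError(f"unknown variant {self.variant!r}")
            if VARIANT_PARENT[self.variant] != self.aa:
                raise ValueError(
                    f"variant {self.variant!r} not permitted for residue {self.aa!r}"
                )

    @property
    def key(self) -> str:
        """Compact category key, e.g. ``A``, ``C_ox``, ``P_cis``, ``H_plus``."""
        if self.variant == VARIANT_NONE:
            return self.aa
        return _VARIANT_KEY[self.variant]

    @classmethod
    def from_key(cls, key: str) -> "ResidueState":
        if key in _KEY_VARIANT:
            variant = _KEY_VARIANT[key]
            return cls(VARIANT_PARENT[variant], variant)
        return cls(key)

    def __str__(self) -> str:
        return self.key


def nucleus_of(atom: str) -> str:
    """Nucleus type of an atom name, from its first letter (C/H/N)."""
    first = atom[0].upper()
    if first == "C":
        return "13C"
    if first == "H":
        return "1H"
    if first == "N":
        return "15N"
    raise ValueError(f"cannot infer nucleus for atom {atom!r}")


@lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=None)
def blosum_row(key: str) -> tuple:
    """23-element BLOSUM-62 encoding of a residue category.

    Slots 0-19 carry the parent residue's BLOSUM-62 scores against the 20
    standard letters. Slots 20-22 are the variant slots (oxidized C, cis P,
    protonated H): zero everywhere except that a variant residue carries its
    parent's self-score in its own slot, which is what distinguishes it from
    the unmodified parent.
    """
    m = _blosum62()
    state = ResidueState.from_key(key)
    parent = state.aa
    row = [float(m[parent, a]) for a in AA1]
    variant_slots = [0.0, 0.0, 0.0]
    if state.variant != VARIANT_NONE:
        idx = VARIANTS.index(state.variant)
        variant_slots[idx] = float(m[parent, parent])
    return tuple(row + variant_slots)


def blosum_vector(key: str) -> np.ndarray:
    return np.asarray(blosum_row(key), dtype=float)
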