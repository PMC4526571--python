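"""Residue-level lookup tables shared across the package.

The five-class chemical grouping drives PMScore binning; the coarser
polar/non-polar/positive/negative classing drives the consensus merge rule.
Both are plain dictionaries so a user can inspect or rebind them.
"""

from __future__ import annotations

from enum import Enum


class ChemicalGroup(Enum):
    """Five-way physicochemical residue classes used by the PMScore bins."""

    ALIPHATIC = 0
    AROMATIC = 1
    POLAR = 2
    POSITIVE = 3
    NEGATIVE = 4


#: Fixed five-group mapping. HIS is treated as polar, CYS/PRO/GLY as
#: aliphatic; scores are sensitive to these placements (see docs/methods.md).
GROUP_OF: dict[str, ChemicalGroup] = {
    **{r: ChemicalGroup.ALIPHATIC for r in
       ("GLY", "ALA", "VAL", "LEU", "ILE", "MET", "CYS", "PRO")},
    **{r: ChemicalGroup.AROMATIC for r in ("PHE", "TYR", "TRP")},
    **{r: ChemicalGroup.POLAR for r in ("SER", "THR", "ASN", "GLN", "HIS")},
    **{r: ChemicalGroup.POSITIVE for r in ("LYS", "ARG")},
    **{r: ChemicalGroup.NEGATIVE for r in ("ASP", "GLU")},
}

STANDARD_RESIDUES: frozenset[str] = frozenset(GROUP_OF)

#: Coarse class used when merging consensus points.
PHYSCHEM_CLASS_OF_GROUP: dict[ChemicalGroup, str] = {
    ChemicalGroup.ALIPHATIC: "non-polar",
    ChemicalGroup.AROMATIC: "non-polar",
    ChemicalGroup.POLAR: "polar",
    ChemicalGroup.POSITIVE: "positive",
    ChemicalGroup.NEGATIVE: "negative",
}

BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

#: Expected side-chain heavy atoms per residue type (everything except the
#: backbone). Used to reject incomplete residues before computing centroids.
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "CYS": ("CB", "SG"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
}

WATER_CODES: frozenset[str] = frozenset({"HOH"})
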