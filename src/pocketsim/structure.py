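"""PDB structure handling: parsing, ligand selection, pocket extraction.

A *binding site* here is ligand-defined: every residue with at least one
heavy atom within a stated distance of any ligand heavy atom. Distances are
atomic contact distances (any heavy atom to any heavy atom), not Calpha or
centroid distances, and hydrogens never participate — docked or modelled
structures rarely carry reproducible protonation.

Parsing is delegated to gemmi; this module only enforces the conventions
needed for deterministic pocket work: first MODEL only, blank/'A' altlocs
only, waters dropped, author residue numbering kept as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .constants import STANDARD_RESIDUES, WATER_CODES
from .errors import (
    AmbiguousLigandError,
    EmptySiteError,
    EmptyStructureError,
    LigandNotFoundError,
    PDBParseError,
)

logger = logging.getLogger(__name__)

_KEPT_ALTLOCS = ("\x00", "", "A")


@dataclass(frozen=True)
class Atom:
    """A named atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """One residue (or HET group) with its atoms in file order."""

    res_name: str
    chain_id: str
    res_seq: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.res_name)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms()], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """Polymer residues plus HET groups (waters already removed)."""

    residues: list[Residue] = field(default_factory=list)
    hetero_groups: dict[tuple[str, str, int], Residue] = field(default_factory=dict)


@dataclass
class LigandPose:
    """Heavy atoms of one bound ligand copy."""

    code: str
    atoms: list[Atom]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class BindingSite:
    """Pocket residues selected at `cutoff` Angstrom from the ligand."""

    residues: list[Residue]
    ligand: LigandPose
    cutoff: float
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def _validate_coordinate_records(text: str) -> int:
    """Pre-scan ATOM/HETATM lines; gemmi is lenient, we are not.

    Returns the number of coordinate records seen.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record shorter than 54 columns")
        try:
            int(line[22:26])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed fixed-column fields: {exc}") from exc
    return n


def read_structure(pdb_text: str) -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    Only the first MODEL is kept; altlocs other than blank/'A' are dropped;
    waters are discarded entirely. HETATM groups land in `hetero_groups`
    keyed by (res_name, chain_id, res_seq).
    """
    if _validate_coordinate_records(pdb_text) == 0:
        raise EmptyStructureError("no ATOM or HETATM records found")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports line context itself
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise EmptyStructureError("no model in PDB text")

    out = Structure()
    model = st[0]
    for chain in model:
        for res in chain:
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    is_hetero=(res.het_flag == "H"),
                )
                for a in res
                if a.altloc in _KEPT_ALTLOCS
            ]
            if not atoms:
                continue
            r = Residue(res.name, chain.name, res.seqid.num, atoms)
            if res.het_flag == "H":
                if res.name in WATER_CODES:
                    continue
                out.hetero_groups[(res.name, chain.name, res.seqid.num)] = r
            else:
                out.residues.append(r)
    if not out.residues and not out.hetero_groups:
        raise EmptyStructureError("structure contains no atoms after filtering")
    return out


def extract_ligand(
    structure: Structure,
    code: str,
    chain_id: str | None = None,
    res_seq: int | None = None,
) -> LigandPose:
    """Select one HET group by code, disambiguated by chain/res_seq if needed."""
    matches = [
        (key, grp)
        for key, grp in structure.hetero_groups.items()
        if key[0] == code
        and (chain_id is None or key[1] == chain_id)
        and (res_seq is None or key[2] == res_seq)
    ]
    if not matches:
        raise LigandNotFoundError(f"no HET group with code {code!r}")
    if len(matches) > 1:
        cands = ", ".join(f"{k[0]}/{k[1]}/{k[2]}" for k, _ in matches)
        raise AmbiguousLigandError(
            f"HET code {code!r} is ambiguous; candidates: {cands}; "
            "pass chain_id/res_seq to select one"
        )
    _, grp = matches[0]
    heavy = grp.heavy_atoms()
    if not heavy:
        raise LigandNotFoundError(f"HET group {code!r} has no heavy atoms")
    return LigandPose(code=code, atoms=heavy)


def extract_pocket(structure: Structure, ligand: LigandPose, cutoff: float) -> BindingSite:
    """All standard residues with any heavy atom within `cutoff` of the ligand."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_xyz = ligand.coords()
    kept: list[Residue] = []
    for res in structure.residues:
        coords = res.heavy_coords()
        if coords.size == 0:
            continue
        if cdist(coords, lig_xyz).min() <= cutoff:
            if res.res_name not in STANDARD_RESIDUES:
                logger.warning(
                    "skipping non-standard residue %s %s%d in pocket",
                    res.res_name, res.chain_id, res.res_seq,
                )
                continue
            kept.append(res)
    if not kept:
        raise EmptySiteError(f"no residue within {cutoff:g} A of ligand {ligand.code}")
    kept.sort(key=lambda r: (r.chain_id, r.res_seq))
    return BindingSite(residues=kept, ligand=ligand, cutoff=cutoff)


def _format_atom_name(name: str, element: str) -> str:
    # Standard PDB alignment: 1-char elements start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _pdb_line(record: str, serial: int, atom: Atom, res: str, chain: str, seq: int) -> str:
    x, y, z = atom.coord
    return (
        f"{record:<6}{serial:5d} {_format_atom_name(atom.name, atom.element)} "
        f"{res:>3} {chain:1}{seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2}"
    )


def write_site(site: BindingSite, remarks: list[str] | None = None) -> str:
    """Serialize a binding site: residues as ATOM, ligand as HETATM records."""
    lines: list[str] = [f"REMARK 300 {r}" for r in (remarks or [])]
    serial = 1
    for res in site.residues:
        for atom in res.atoms:
            lines.append(_pdb_line("ATOM", serial, atom, res.res_name, res.chain_id, res.res_seq))
            serial += 1
    if site.residues:
        lines.append(f"TER   {serial:5d}")
        serial += 1
    for atom in site.ligand.atoms:
        lines.append(_pdb_line("HETATM", serial, atom, site.ligand.code, "L", 900))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(structure: Structure, remarks: list[str] | None = None) -> str:
    """Serialize a full structure (polymer + HET groups) as PDB text."""
    lines: list[str] = [f"REMARK 300 {r}" for r in (remarks or [])]
    serial = 1
    for res in structure.residues:
        for atom in res.atoms:
            lines.append(_pdb_line("ATOM", serial, atom, res.res_name, res.chain_id, res.res_seq))
            serial += 1
    if structure.residues:
        lines.append(f"TER   {serial:5d}")
        serial += 1
    for (name, chain, seq), grp in structure.hetero_groups.items():
        for atom in grp.atoms:
            lines.append(_pdb_line("HETATM", serial, atom, name, chain, seq))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
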