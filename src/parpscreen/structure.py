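"""Minimal protein-structure I/O and geometry.

Covers exactly what the screening pipeline needs from a PDB file: atoms with
coordinates and B-factors, ligand mass centroids (binding-pocket centers),
residue shells around a point, and heavy-atom pose RMSD.

The reader is a strict fixed-column ATOM/HETATM parser: a malformed
coordinate or B-factor field raises :class:`~parpscreen.errors.FormatError`
naming the offending line instead of being silently coerced.  Only the first
MODEL is kept and only blank/'A' alternate locations are retained.  Atomic
masses come from gemmi's element tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import FormatError, PairingError, SelectionError

__all__ = [
    "Atom",
    "Structure",
    "read_pdb",
    "write_pdb",
    "ligand_centroid",
    "pocket_residues",
    "heavy_atom_rmsd",
    "atomic_mass",
    "is_hydrogen",
]


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record.

    ``residue_number`` keeps the integer author numbering; an insertion code,
    when present, is appended as a text suffix in :attr:`residue_id`.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    coordinates: np.ndarray
    b_factor: float
    is_hetero: bool
    insertion_code: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coordinates", coords)
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")

    @property
    def residue_id(self) -> str:
        """Residue number with insertion-code suffix, e.g. ``"863"`` or ``"100A"``."""
        return f"{self.residue_number}{self.insertion_code}"


@dataclass
class Structure:
    """An ordered collection of atoms from one PDB file (first model only)."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    def residue_index(self) -> dict[tuple[str, str], list[Atom]]:
        """Map (chain, residue_id) -> atoms, preserving file order."""
        index: dict[tuple[str, str], list[Atom]] = {}
        for atom in self.atoms:
            index.setdefault((atom.chain, atom.residue_id), []).append(atom)
        return index

    def select(self, residue_name: str, chain: str | None = None) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.residue_name == residue_name.upper() and (chain is None or a.chain == chain)
        ]


_TWO_LETTER = {
    "CL", "BR", "FE", "ZN", "MG", "NA", "MN", "CA", "SE", "CU", "NI", "CO",
}


def _infer_element(name: str, residue_name: str) -> str:
    """Guess the element from an atom name when columns 77-78 are blank.

    Convention: a leading digit marks a hydrogen variant (1HB etc.); a
    two-letter symbol is only accepted when it is a common hetero element,
    so CA in an amino acid stays carbon.
    """
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        return "H"
    if stripped[0] == "H":
        return "H"
    two = stripped[:2].upper()
    if two in _TWO_LETTER and (len(residue_name) < 3 or residue_name in {"HOH"} or two == residue_name[:2]):
        return two.capitalize()
    return stripped[0].upper()


def atomic_mass(element: str) -> float:
    """Standard atomic mass in Da via gemmi's element table."""
    el = gemmi.Element(element.capitalize())
    weight = el.weight
    if weight <= 0 or el.name == "X":
        raise ValueError(f"unknown element {element!r}")
    return weight


def is_hydrogen(atom: Atom) -> bool:
    return atom.element.upper() == "H"


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"line {lineno}: unparsable {what} field {text.strip()!r}") from None


def read_pdb(path: str | Path, structure_id: str | None = None) -> Structure:
    """Read ATOM/HETATM records from a PDB file.

    Keeps the first MODEL only and alternate locations blank or 'A'.
    Raises ``FileNotFoundError`` for a missing file and
    :class:`FormatError` when no atom records are present or a numeric
    field cannot be parsed (the message names the line).
    """
    path = Path(path)
    text = path.read_text()
    atoms: list[Atom] = []
    in_model = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("MODEL"):
            in_model += 1
            if in_model > 1:
                break
            continue
        if record.startswith("ENDMDL"):
            break
        if record not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise FormatError(f"line {lineno}: truncated ATOM/HETATM record")
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        serial = int(_parse_float(line[6:11], "serial", lineno))
        name = line[12:16].strip()
        residue_name = line[17:20].strip().upper()
        chain = line[21].strip()
        residue_number = int(_parse_float(line[22:26], "residue number", lineno))
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        b_factor = _parse_float(line[60:66], "B-factor", lineno) if len(line) >= 66 and line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(name, residue_name)
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element.capitalize(),
                residue_name=residue_name,
                chain=chain,
                residue_number=residue_number,
                coordinates=np.array([x, y, z]),
                b_factor=b_factor,
                is_hetero=record == "HETATM",
                insertion_code=icode,
            )
        )
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return Structure(id=structure_id or path.stem, atoms=atoms)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure back to PDB fixed-column format (round-trip safe)."""
    lines = []
    for atom in structure.atoms:
        record = "HETATM" if atom.is_hetero else "ATOM  "
        # standard name alignment: 1-letter elements start in column 14
        name = atom.name
        if len(name) < 4 and len(atom.element) < 2 and not name[:1].isdigit():
            name = " " + name
        x, y, z = atom.coordinates
        lines.append(
            f"{record}{atom.serial:>5} {name:<4} {atom.residue_name:>3} {atom.chain:1}"
            f"{atom.residue_number:>4}{atom.insertion_code or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{atom.b_factor:6.2f}          "
            f"{atom.element.upper():>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def ligand_centroid(
    structure: Structure, residue_name: str, chain: str | None = None
) -> np.ndarray:
    """Mass-weighted centroid of a ligand residue (all atoms, H included).

    This is the pocket-center definition used for grid placement: the mass
    centroid of the bound ligand.
    """
    atoms = structure.select(residue_name, chain)
    if not atoms:
        where = f"chain {chain!r}" if chain else "any chain"
        raise SelectionError(f"no atoms match residue {residue_name!r} in {where}")
    masses = np.array([atomic_mass(a.element) for a in atoms])
    coords = np.stack([a.coordinates for a in atoms])
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def pocket_residues(
    structure: Structure, center: Sequence[float], cutoff: float
) -> set[tuple[str, str, str]]:
    """Protein residues with any atom within ``cutoff`` Å of ``center``.

    The boundary is closed (distance == cutoff is inside); hetero residues
    (ligands, waters) are excluded.  Returns (chain, residue_id, residue_name)
    triples, residue_id carrying any insertion-code suffix.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    center = np.asarray(center, dtype=float)
    hits: set[tuple[str, str, str]] = set()
    for atom in structure.atoms:
        if atom.is_hetero:
            continue
        if np.linalg.norm(atom.coordinates - center) <= cutoff:
            hits.add((atom.chain, atom.residue_id, atom.residue_name))
    return hits


def heavy_atom_rmsd(
    reference: Iterable[Sequence[float]], probe: Iterable[Sequence[float]]
) -> float:
    """RMSD between two pre-matched coordinate lists, no superposition.

    Poses produced by redocking share the receptor frame, so fitting would
    hide real displacement; the lists must be in matching atom order.
    """
    ref = np.atleast_2d(np.asarray(list(reference), dtype=float))
    prb = np.atleast_2d(np.asarray(list(probe), dtype=float))
    if ref.shape != prb.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise PairingError(
            f"coordinate lists must have matching (n, 3) shapes, got {ref.shape} vs {prb.shape}"
        )
    if ref.shape[0] < 1:
        raise PairingError("coordinate lists must contain at least one atom")
    return float(math.sqrt(np.mean(np.sum((ref - prb) ** 2, axis=1))))
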