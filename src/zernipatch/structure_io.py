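"""Read and write molecular structures (PDB, PQR) and select residue-range patches.

PQR files carry per-atom partial charges (elementary-charge units) and radii
(Angstrom) and are the preferred input: the electrostatic channels of a patch
descriptor are only meaningful when charges are populated.  PDB files carry
coordinates only; radii are attached from a bundled van der Waals table and
charges are set to zero.

A *patch* is declared as a union of inclusive residue-number intervals,
optionally chain-qualified (e.g. ``"252-257; 275-291; 339-362"``), mirroring
how binding sites are tabulated in the structural literature.  Residue numbers
are taken verbatim from the file; no renumbering is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, SelectionError

__all__ = [
    "Atom",
    "AtomSet",
    "ResidueSelection",
    "VDW_RADII",
    "read_pqr",
    "read_pdb",
    "read_pdb_models",
    "select_patch",
    "write_pqr",
    "write_pdb_models",
]

#: Bondi-style van der Waals radii in Angstrom, keyed by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "FE": 1.94,
    "MN": 2.05,
    "CU": 1.40,
}

WILDCARD_CHAIN = "*"


@dataclass(frozen=True)
class Atom:
    """A single atom: identity, position (A), radius (A) and partial charge (e)."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    position: np.ndarray  # shape (3,)
    radius: float
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class AtomSet:
    """An ordered collection of atoms with a provenance label."""

    atoms: list[Atom]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def with_positions(self, positions: np.ndarray, label: str | None = None) -> "AtomSet":
        """Return a copy with replaced coordinates (same identity, radii, charges)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("positions shape mismatch")
        atoms = [replace(a, position=p.copy()) for a, p in zip(self.atoms, positions)]
        return AtomSet(atoms, label if label is not None else self.source_label)

    def with_charges(self, charges: Sequence[float]) -> "AtomSet":
        if len(charges) != len(self.atoms):
            raise ValueError("charges length mismatch")
        atoms = [replace(a, partial_charge=float(q)) for a, q in zip(self.atoms, charges)]
        return AtomSet(atoms, self.source_label)


@dataclass(frozen=True)
class ResidueSelection:
    """A union of inclusive residue-number intervals, each with a chain or wildcard.

    ``ranges`` is a tuple of ``(chain, start, end)`` triples; chain ``"*"``
    matches any chain.
    """

    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise SelectionError("empty residue selection")
        for chain, start, end in self.ranges:
            if start > end:
                raise SelectionError(f"range {start}-{end}: start > end")

    @classmethod
    def from_string(cls, text: str) -> "ResidueSelection":
        """Parse ``"252-257; 275-291; 339-362"`` (en-dash accepted, optional
        ``chain:`` prefix per range, a bare number is a single-residue range)."""
        ranges: list[tuple[str, int, int]] = []
        for part in text.replace("–", "-").split(";"):
            part = part.strip()
            if not part:
                continue
            chain = WILDCARD_CHAIN
            if ":" in part:
                chain, part = (s.strip() for s in part.split(":", 1))
            # split on the *interior* hyphen so negative residue numbers survive
            body = part.strip()
            idx = body.find("-", 1)
            if idx == -1:
                start = end = int(body)
            else:
                start, end = int(body[:idx]), int(body[idx + 1 :])
            ranges.append((chain, start, end))
        return cls(tuple(ranges))

    def matches(self, chain: str, residue_number: int) -> bool:
        return any(
            (c == WILDCARD_CHAIN or c == chain) and start <= residue_number <= end
            for c, start, end in self.ranges
        )

    def __str__(self) -> str:
        parts = []
        for chain, start, end in self.ranges:
            prefix = "" if chain == WILDCARD_CHAIN else f"{chain}:"
            parts.append(f"{prefix}{start}-{end}")
        return "; ".join(parts)


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> AtomSet:
    """Read a PQR file (whitespace-delimited ATOM/HETATM records).

    Field layout follows PDB2PQR output::

        ATOM serial name resName [chainID] resNum x y z charge radius

    The chain column is optional (PDB2PQR omits it for single-chain input).

    Raises
    ------
    ParseError
        On a missing file, an empty file, or any record with non-numeric
        charge/radius or radius <= 0; the message names the line.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"PQR file not found: {path}")
    atoms: list[Atom] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            try:
                atoms.append(_parse_pqr_record(rec))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}, line {lineno}: bad PQR record ({exc})") from exc
    if not atoms:
        raise ParseError(f"{path}: no atoms")
    return AtomSet(atoms, source_label=path.name)


def _parse_pqr_record(rec: list[str]) -> Atom:
    if len(rec) == 11:  # chain column present
        chain, resnum_field = rec[4], rec[5]
        x, y, z, charge, radius = (float(v) for v in rec[6:11])
    elif len(rec) == 10:  # chain column absent
        chain, resnum_field = WILDCARD_CHAIN, rec[4]
        x, y, z, charge, radius = (float(v) for v in rec[5:10])
    else:
        raise ValueError(f"expected 10 or 11 fields, got {len(rec)}")
    if not resnum_field.lstrip("-").isdigit():
        raise ValueError(f"residue number {resnum_field!r} carries an insertion code")
    if radius <= 0:
        raise ValueError(f"radius {radius} <= 0")
    return Atom(
        serial=int(rec[1]),
        name=rec[2],
        residue_name=rec[3],
        chain=chain,
        residue_number=int(resnum_field),
        position=np.array([x, y, z]),
        radius=radius,
        partial_charge=charge,
    )


def write_pqr(atoms: AtomSet, path: str | Path) -> None:
    """Write an AtomSet as a PQR file (PDB2PQR-style column alignment)."""
    path = Path(path)
    with path.open("w") as fh:
        for a in atoms:
            chain = a.chain if a.chain != WILDCARD_CHAIN else "A"
            fh.write(
                f"ATOM  {a.serial:5d} {a.name:<4s} {a.residue_name:<4s}"
                f"{chain:1s} {a.residue_number:4d}    "
                f"{a.position[0]:10.4f}{a.position[1]:10.4f}{a.position[2]:10.4f} "
                f"{a.partial_charge:8.4f} {a.radius:7.4f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb_models(
    path: str | Path, radius_table: dict[str, float] | None = None
) -> list[AtomSet]:
    """Read a (possibly multi-model) PDB file; one AtomSet per MODEL in file order.

    Radii come from ``radius_table`` (element symbol -> Angstrom; defaults to the
    bundled van der Waals table); partial charges are zero.  Insertion codes are
    rejected: merging residues that differ only by insertion code would silently
    corrupt range selections.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise ParseError(f"PDB file not found: {path}")
    table = {k.upper(): v for k, v in (radius_table or VDW_RADII).items()}
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise ParseError(f"{path}: {exc}") from exc

    models: list[AtomSet] = []
    for model in structure:
        atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                hetflag, resnum, icode = residue.id
                if icode.strip():
                    raise ParseError(
                        f"{path}: residue {chain.id}{resnum}{icode} carries an "
                        "insertion code; renumber the structure first"
                    )
                for atom in residue:
                    element = (atom.element or "").strip().upper()
                    if element not in table:
                        raise ParseError(
                            f"{path}: no radius for element {element!r} "
                            f"(atom {atom.serial_number} {atom.get_name()})"
                        )
                    atoms.append(
                        Atom(
                            serial=int(atom.serial_number),
                            name=atom.get_name(),
                            residue_name=residue.get_resname().strip(),
                            chain=str(chain.id).strip() or WILDCARD_CHAIN,
                            residue_number=int(resnum),
                            position=np.asarray(atom.coord, dtype=float),
                            radius=table[element],
                            partial_charge=0.0,
                        )
                    )
        if not atoms:
            raise ParseError(f"{path}: model {model.id} has no atoms")
        models.append(AtomSet(atoms, source_label=f"{path.name}#model{model.serial_num}"))
    if not models:
        raise ParseError(f"{path}: no atoms")
    return models


def read_pdb(path: str | Path, radius_table: dict[str, float] | None = None) -> AtomSet:
    """Read a single-model PDB file (first model of a multi-model file)."""
    return read_pdb_models(path, radius_table)[0]


def write_pdb_models(models: Iterable[AtomSet], path: str | Path) -> None:
    """Write one or more AtomSets as a (multi-model) fixed-column PDB file."""
    models = list(models)
    path = Path(path)
    with path.open("w") as fh:
        multi = len(models) > 1
        for i, atomset in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {i:4d}\n")
            for a in atomset:
                chain = a.chain if a.chain != WILDCARD_CHAIN else "A"
                element = _element_from_name(a.name)
                fh.write(
                    f"ATOM  {a.serial:5d} {a.name:<4.4s} {a.residue_name:<3.3s} "
                    f"{chain:1.1s}{a.residue_number:4d}    "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _element_from_name(name: str) -> str:
    """Infer an element symbol from an atom name per PDB convention."""
    stripped = name.strip()
    if len(stripped) >= 2 and stripped[:2].upper() in VDW_RADII and not stripped[0].isdigit():
        two = stripped[:2].upper()
        # two-letter symbols only when the name is genuinely two-letter (e.g. FE, CL)
        if two in ("CL", "BR", "SE", "ZN", "MG", "NA", "FE", "MN", "CU"):
            return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


# ---------------------------------------------------------------------------
# Patch selection
# ---------------------------------------------------------------------------

def select_patch(atoms: AtomSet, selection: ResidueSelection) -> AtomSet:
    """Return the atoms whose (chain, residue number) fall in the selection.

    Order is preserved.  Raises :class:`SelectionError` if nothing matches.
    """
    picked = [a for a in atoms if selection.matches(a.chain, a.residue_number)]
    if not picked:
        raise SelectionError(f"selection matches no atoms: {selection}")
    return AtomSet(picked, source_label=f"{atoms.source_label}[{selection}]")
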