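"""Point-charge protein structures: PQR I/O, charge descriptors, entry-atom
selection.

A structure is an ordered collection of atoms, each carrying Cartesian
coordinates (Å), a partial charge (e) and a van der Waals radius (Å) — the
content of a PQR file.  One atom may be marked as the electron-transfer entry
site (for a hydrogenase, the iron of the distal [4Fe4S] cluster); downstream
modules measure its distance to the electrode.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .constants import E_ANGSTROM_PER_DEBYE

__all__ = [
    "Atom",
    "Structure",
    "DipoleMoment",
    "PQRParseError",
    "SelectionError",
    "read_pqr",
    "write_pqr",
    "net_charge",
    "dipole_moment",
    "mark_entry_atom",
]


class PQRParseError(ValueError):
    """Raised when a PQR file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when an entry-atom selector matches zero or several atoms."""


@dataclass(frozen=True)
class Atom:
    """A single point charge with a van der Waals radius.

    Coordinates in Å, charge in e, radius in Å.
    """

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_seq: int
    position: np.ndarray
    charge: float
    radius: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not math.isfinite(self.charge):
            raise ValueError(f"atom {self.serial}: non-finite charge")
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: negative radius")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """An ordered, non-empty collection of atoms.

    ``et_entry_serial``, when set, names the atom used as the electron-transfer
    entry point; it must refer to an existing atom.
    """

    atoms: list[Atom]
    et_entry_serial: Optional[int] = None
    label: str = ""

    def __post_init__(self):
        self.atoms = list(self.atoms)
        if not self.atoms:
            raise ValueError("a Structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in structure")
        if self.et_entry_serial is not None and self.et_entry_serial not in set(
            serials
        ):
            raise ValueError(
                f"et_entry_serial {self.et_entry_serial} not among atom serials"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) array of positions, Å."""
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        """(N,) array of partial charges, e."""
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        """(N,) array of van der Waals radii, Å."""
        return np.array([a.radius for a in self.atoms])

    @property
    def entry_atom(self) -> Atom:
        if self.et_entry_serial is None:
            raise ValueError("no electron-transfer entry atom marked")
        return next(a for a in self.atoms if a.serial == self.et_entry_serial)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, position=coords[i]) for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, self.et_entry_serial, self.label)


DipoleMoment = namedtuple("DipoleMoment", ["vector", "e_angstrom", "debye"])


def _parse_pqr_line(line: str, lineno: int) -> Atom:
    fields = line.split()
    # Two dialects: with a chain column (11 fields) or without (10 fields).
    if len(fields) == 11:
        chain = fields[4]
        rest = fields[5:]
    elif len(fields) == 10:
        chain = ""
        rest = fields[4:]
    else:
        raise PQRParseError(
            f"line {lineno}: expected 10 or 11 whitespace-delimited fields, "
            f"got {len(fields)}"
        )
    try:
        serial = int(fields[1])
        residue_seq = int(rest[0])
        x, y, z, charge, radius = (float(v) for v in rest[1:6])
    except ValueError as exc:
        raise PQRParseError(f"line {lineno}: malformed record ({exc})") from None
    return Atom(
        serial=serial,
        name=fields[2],
        residue_name=fields[3],
        chain=chain,
        residue_seq=residue_seq,
        position=np.array([x, y, z]),
        charge=charge,
        radius=radius,
    )


def read_pqr(path) -> Structure:
    """Read a whitespace-delimited PQR file into a :class:`Structure`.

    Both the 10-field (no chain) and 11-field (with chain) record layouts are
    accepted, auto-detected per line.  Non-ATOM/HETATM lines (REMARK, TER,
    END, …) are skipped.
    """
    path = Path(path)
    atoms: list[Atom] = []
    entry_serial = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            record = line.split(None, 1)[0].upper()
            if record == "REMARK" and "ET_ENTRY" in line:
                # non-standard annotation written by write_pqr to persist
                # the entry-atom mark across round trips
                try:
                    entry_serial = int(line.split()[-1])
                except ValueError:
                    raise PQRParseError(
                        f"line {lineno}: malformed ET_ENTRY remark"
                    ) from None
                continue
            if record not in ("ATOM", "HETATM"):
                continue
            atoms.append(_parse_pqr_line(line, lineno))
    if not atoms:
        raise PQRParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, et_entry_serial=entry_serial, label=path.stem)


def write_pqr(structure: Structure, path) -> None:
    """Write a structure as a whitespace-delimited PQR file.

    Numeric fields carry 4 decimals so a read/write round trip reproduces
    coordinates, charges and radii to 1e-4.
    """
    if not isinstance(structure, Structure) or not structure.atoms:
        raise ValueError("refusing to write an empty or invalid structure")
    with open(path, "w") as fh:
        if structure.et_entry_serial is not None:
            fh.write(f"REMARK ET_ENTRY serial {structure.et_entry_serial}\n")
        for a in structure.atoms:
            chain = f" {a.chain}" if a.chain else ""
            fh.write(
                f"ATOM {a.serial:6d} {a.name:<4s} {a.residue_name:<4s}{chain} "
                f"{a.residue_seq:5d} {a.position[0]:10.4f} {a.position[1]:10.4f} "
                f"{a.position[2]:10.4f} {a.charge:9.4f} {a.radius:7.4f}\n"
            )


def net_charge(structure: Structure) -> float:
    """Total charge of the structure in e (sum of partial charges)."""
    return float(structure.charges.sum())


def dipole_moment(structure: Structure) -> DipoleMoment:
    """Dipole moment about the center of charge.

    For a molecule with non-zero net charge the dipole depends on the chosen
    pole.  The pole used here is the center of *absolute* charge,
    Σ|qᵢ|rᵢ/Σ|qᵢ|: unlike the signed-charge-weighted mean (about which the
    dipole of a charged molecule vanishes identically), it gives a
    well-defined, translation- and rotation-covariant pole for mixed-sign
    charge distributions.  When all charges are negligible (Σ|q| ≤ 1e-6 e)
    the unweighted centroid is used; for a neutral molecule the dipole is
    pole-independent anyway.

    Returns the dipole vector (e·Å), its modulus in e·Å and in debye
    (1 e·Å ≈ 4.803 D).
    """
    q = structure.charges
    r = structure.coordinates
    total_abs = np.abs(q).sum()
    if total_abs > 1e-6:
        pole = (np.abs(q)[:, None] * r).sum(axis=0) / total_abs
    else:
        pole = r.mean(axis=0)
    vec = (q[:, None] * (r - pole)).sum(axis=0)
    mod = float(np.linalg.norm(vec))
    return DipoleMoment(vec, mod, mod * E_ANGSTROM_PER_DEBYE)


def _match_selector(atom: Atom, selector: str) -> bool:
    sel = selector.strip()
    if sel.startswith("serial="):
        return atom.serial == int(sel.split("=", 1)[1])
    parts = sel.split(":")
    if len(parts) != 4:
        raise SelectionError(
            f"selector {selector!r}: expected 'serial=N' or "
            "'chain:resname:resseq:atomname' (use * as wildcard)"
        )
    chain, resname, resseq, atomname = parts
    if chain != "*" and atom.chain != chain:
        return False
    if resname != "*" and atom.residue_name.upper() != resname.upper():
        return False
    if resseq != "*" and atom.residue_seq != int(resseq):
        return False
    if atomname != "*" and atom.name.upper() != atomname.upper():
        return False
    return True


def mark_entry_atom(structure: Structure, selector: str) -> Structure:
    """Return a copy with the electron-transfer entry atom set.

    ``selector`` is either ``"serial=N"`` or ``"chain:resname:resseq:atomname"``
    with ``*`` wildcards.  Exactly one atom must match.
    """
    matches = [a for a in structure.atoms if _match_selector(a, selector)]
    if len(matches) != 1:
        listing = ", ".join(
            f"serial {a.serial} ({a.chain or '-'}:{a.residue_name}:"
            f"{a.residue_seq}:{a.name})"
            for a in matches
        )
        raise SelectionError(
            f"selector {selector!r} matched {len(matches)} atoms"
            + (f": {listing}" if matches else "")
        )
    return Structure(list(structure.atoms), matches[0].serial, structure.label)
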