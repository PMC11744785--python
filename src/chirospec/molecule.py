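"""Molecular geometries, XYZ I/O and MM point-charge lists.

Coordinates are stored internally in Bohr; XYZ files and MM-charge files are
read and written in Å following the usual conventions of those formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

ELEMENTS = [
    "X", "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca",
]
_Z_OF = {sym.lower(): z for z, sym in enumerate(ELEMENTS) if z > 0}


class ParseError(ValueError):
    """Raised for malformed geometry / basis / charge files."""


@dataclass(frozen=True)
class Atom:
    symbol: str
    Z: int
    position: np.ndarray  # (3,) Bohr

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError("nuclear charge must be >= 1")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Molecule:
    """A QM region plus an optional classical point-charge environment."""

    atoms: list[Atom]
    charge: int = 0
    mm_charges: list[tuple[float, np.ndarray]] = field(default_factory=list)

    @property
    def n_electrons(self) -> int:
        n = sum(a.Z for a in self.atoms) - self.charge
        if n <= 0 or n % 2 != 0:
            raise ValueError(
                f"closed-shell formalism requires a positive even electron "
                f"count, got {n}"
            )
        return n

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([float(a.Z) for a in self.atoms])

    def nuclear_repulsion(self) -> float:
        """Classical Coulomb energy: nucleus–nucleus plus nucleus–MM.

        The MM–MM self-energy is a constant of the embedding and is excluded.
        """
        coords = self.coordinates
        z = self.nuclear_charges
        e = 0.0
        for i in range(len(z)):
            for j in range(i + 1, len(z)):
                e += z[i] * z[j] / np.linalg.norm(coords[i] - coords[j])
        for q, pos in self.mm_charges:
            for i in range(len(z)):
                e += z[i] * q / np.linalg.norm(coords[i] - pos)
        return e

    def center_of_nuclear_charge(self) -> np.ndarray:
        z = self.nuclear_charges
        return z @ self.coordinates / z.sum()

    def translated(self, shift) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        atoms = [Atom(a.symbol, a.Z, a.position + shift) for a in self.atoms]
        mm = [(q, p + shift) for q, p in self.mm_charges]
        return Molecule(atoms, self.charge, mm)

    def rotated(self, rotation) -> "Molecule":
        r = np.asarray(rotation, dtype=float)
        atoms = [Atom(a.symbol, a.Z, r @ a.position) for a in self.atoms]
        mm = [(q, r @ p) for q, p in self.mm_charges]
        return Molecule(atoms, self.charge, mm)


def element_number(symbol: str) -> int:
    try:
        return _Z_OF[symbol.strip().lower()]
    except KeyError:
        raise ParseError(f"unknown element symbol {symbol!r}") from None


def read_xyz(path) -> Molecule:
    """Read a standard XYZ file (count line, comment, ``El x y z`` in Å)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: malformed atom count") from None
    body = [l for l in lines[2 : 2 + n]]
    if len(body) != n or any(not l.strip() for l in body):
        raise ParseError(f"{path}: atom count {n} does not match body")
    atoms = []
    for k, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {k}: expected 'El x y z'")
        z = element_number(parts[0])
        try:
            pos = np.array([float(v) for v in parts[1:4]]) * ANGSTROM_TO_BOHR
        except ValueError:
            raise ParseError(f"{path}: line {k}: bad coordinate") from None
        atoms.append(Atom(parts[0].capitalize(), z, pos))
    return Molecule(atoms)


def write_xyz(molecule: Molecule, path, comment: str = "") -> None:
    lines = [str(len(molecule.atoms)), comment.replace("\n", " ")]
    for a in molecule.atoms:
        x, y, z = a.position * BOHR_TO_ANGSTROM
        lines.append(f"{a.symbol:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mm_charges(path) -> list[tuple[float, np.ndarray]]:
    """Read MM point charges from 4-column text: ``q x y z`` with x,y,z in Å."""
    out = []
    for k, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.split("#")[0].strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != 4:
            raise ParseError(f"{path}: line {k}: expected 'q x y z'")
        try:
            vals = [float(v) for v in parts]
        except ValueError:
            raise ParseError(f"{path}: line {k}: bad number") from None
        out.append((vals[0], np.array(vals[1:]) * ANGSTROM_TO_BOHR))
    return out
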