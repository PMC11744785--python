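"""Synthetic molecular fixtures.

Two families are generated programmatically:

* spherical water droplets at liquid-like density (rigid TIP3P-geometry
  monomers, random orientations) for screening / scaling studies, and
* small chiral molecules — hydrogen peroxide at ±112.5° dihedral, whose two
  enantiomers are exact coordinate-wise mirror images — plus planar water as
  an achiral control for CD calculations.
"""

from __future__ import annotations

import numpy as np

from .constants import ANGSTROM_TO_BOHR
from .molecule import Atom, Molecule

# rigid TIP3P monomer geometry
OH_ANGSTROM = 0.9572
HOH_DEGREES = 104.52
# liquid water number density, molecules per Å³ (≈ 0.997 g/cm³)
WATER_NUMBER_DENSITY = 0.03334
MIN_OO_ANGSTROM = 2.5


class GenerationError(RuntimeError):
    """Raised when random placement fails within the retry budget."""


def _water_template_bohr() -> np.ndarray:
    """O at origin, H's in the xz plane, Bohr."""
    r = OH_ANGSTROM * ANGSTROM_TO_BOHR
    half = np.deg2rad(HOH_DEGREES) / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [r * np.sin(half), 0.0, r * np.cos(half)],
            [-r * np.sin(half), 0.0, r * np.cos(half)],
        ]
    )


def water_molecule() -> Molecule:
    """A single gas-phase water (O–H 0.9572 Å, ∠HOH 104.52°)."""
    pos = _water_template_bohr()
    return Molecule(
        [
            Atom("O", 8, pos[0]),
            Atom("H", 1, pos[1]),
            Atom("H", 1, pos[2]),
        ]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def droplet_radius_angstrom(n_molecules: int) -> float:
    """Smallest sphere radius giving liquid density for n molecules."""
    volume = n_molecules / WATER_NUMBER_DENSITY
    return (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)


def generate_water_droplet(n_molecules: int, seed: int = 0,
                           max_retries: int = 20000) -> Molecule:
    """Spherical water droplet: rigid waters, random orientations, O centers
    inside the liquid-density sphere, minimum O–O separation 2.5 Å.

    Deterministic for a fixed seed.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    radius = droplet_radius_angstrom(n_molecules) * ANGSTROM_TO_BOHR
    min_oo = MIN_OO_ANGSTROM * ANGSTROM_TO_BOHR
    template = _water_template_bohr()

    oxygens: list[np.ndarray] = []
    atoms: list[Atom] = []
    tries = 0
    while len(oxygens) < n_molecules:
        tries += 1
        if tries > max_retries:
            raise GenerationError(
                f"could not place {n_molecules} waters in radius "
                f"{radius:.2f} Bohr after {max_retries} tries"
            )
        # uniform point in the sphere
        point = rng.uniform(-1.0, 1.0, size=3)
        if point @ point > 1.0:
            continue
        o_pos = point * radius
        if any(np.linalg.norm(o_pos - o) < min_oo for o in oxygens):
            continue
        rot = _random_rotation(rng)
        mol = template @ rot.T + o_pos
        oxygens.append(o_pos)
        atoms.append(Atom("O", 8, mol[0]))
        atoms.append(Atom("H", 1, mol[1]))
        atoms.append(Atom("H", 1, mol[2]))
    return Molecule(atoms)


# --- chiral fixtures -----------------------------------------------------

OO_ANGSTROM = 1.475
OOH_DEGREES = 94.8
HOOH_DIHEDRAL_DEGREES = 112.5


def _h2o2(dihedral_deg: float) -> Molecule:
    d_oo = OO_ANGSTROM * ANGSTROM_TO_BOHR
    r_oh = OH_ANGSTROM * ANGSTROM_TO_BOHR
    theta = np.deg2rad(OOH_DEGREES)
    # azimuth of the second H; with H1 at azimuth 0 the H–O–O–H torsion is
    # φ − 180°, so place H2 at φ = dihedral − 180°
    phi = np.deg2rad(dihedral_deg - 180.0)
    o1 = np.zeros(3)
    o2 = np.array([0.0, 0.0, d_oo])
    # H on O1 in the xz plane; H on O2 rotated by the dihedral about the O–O axis
    h1 = o1 + r_oh * np.array([np.sin(theta), 0.0, np.cos(theta)])
    h2 = o2 + r_oh * np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), -np.cos(theta)]
    )
    return Molecule(
        [Atom("O", 8, o1), Atom("O", 8, o2), Atom("H", 1, h1), Atom("H", 1, h2)]
    )


def generate_chiral_fixture(name: str) -> Molecule:
    """Named CD test molecules.

    ``h2o2_P`` / ``h2o2_M``: hydrogen peroxide at +112.5° / −112.5° H–O–O–H
    dihedral; the two are exact mirror images through the xz plane.
    ``h2o_planar``: water (achiral control).
    """
    if name == "h2o2_P":
        return _h2o2(+HOOH_DIHEDRAL_DEGREES)
    if name == "h2o2_M":
        return _h2o2(-HOOH_DIHEDRAL_DEGREES)
    if name == "h2o_planar":
        return water_molecule()
    raise ValueError(f"unknown fixture {name!r}")


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def mm_water_charges(molecule: Molecule) -> list[tuple[float, np.ndarray]]:
    """Classical point charges for the atoms of a water geometry: −0.6690 on
    O and +0.3345 on each H (a neutral embedding water)."""
    out = []
    for a in molecule.atoms:
        q = -0.6690 if a.symbol == "O" else 0.3345
        out.append((q, a.position.copy()))
    return out
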