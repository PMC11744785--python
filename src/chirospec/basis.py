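"""Gaussian basis sets: Gaussian94 parsing, Cartesian AO indexing and the
primitive → contracted expansion table.

Conventions
-----------
* Cartesian components are ordered lexicographically by exponent tuple with
  x ≥ y ≥ z precedence: s; x, y, z; xx, xy, xz, yy, yz, zz.
* Cartesian d components are used as-is (no solid-harmonic transformation);
  every contracted Cartesian AO is individually normalized to unit
  self-overlap.
* Primitive Cartesian functions in the expansion table are unit-normalized;
  the table coefficients absorb contraction coefficients, primitive norms
  and the contracted normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .molecule import Molecule, ParseError

MAX_L = 2
_L_OF = {"S": 0, "P": 1, "D": 2}


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Lexicographic (x≥y≥z) Cartesian exponent tuples for shell momentum l."""
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def n_cartesian(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, lx: int, ly: int, lz: int) -> float:
    """Normalization constant of a primitive Cartesian Gaussian."""
    l = lx + ly + lz
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = np.sqrt(
        double_factorial(2 * lx - 1)
        * double_factorial(2 * ly - 1)
        * double_factorial(2 * lz - 1)
    )
    return num / den


@dataclass(frozen=True)
class ContractedShell:
    center: int  # atom index
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray  # unnormalized, as read from the basis file

    def __post_init__(self):
        e = np.asarray(self.exponents, dtype=float)
        c = np.asarray(self.coefficients, dtype=float)
        if e.ndim != 1 or e.shape != c.shape or e.size < 1:
            raise ValueError("exponents/coefficients must be equal-length 1D")
        if np.any(e <= 0):
            raise ValueError("exponents must be positive")
        if not 0 <= self.l <= MAX_L:
            raise ValueError(f"angular momentum {self.l} unsupported (max {MAX_L})")
        object.__setattr__(self, "exponents", e)
        object.__setattr__(self, "coefficients", c)

    @property
    def n_primitives(self) -> int:
        return self.exponents.size


def load_basis(name_or_path) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Parse a Gaussian94-format basis file into per-element shell templates.

    Returns ``{element_symbol: [(l, exponents, coefficients), ...]}``. SP
    shells are split into separate S and P shells. Shipped fixtures are
    available by name: ``"sto-3g"`` and ``"def2-svp"``.
    """
    p = Path(str(name_or_path))
    if p.is_file():
        text = p.read_text()
    else:
        ref = resources.files("chirospec.data") / f"{str(name_or_path).lower()}.g94"
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise ParseError(f"basis set {name_or_path!r} not found") from None

    lines = [
        l.rstrip() for l in text.splitlines()
        if l.strip() and not l.lstrip().startswith("!")
    ]
    basis: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    i = 0
    # skip leading separators
    while i < len(lines) and lines[i].strip() == "****":
        i += 1
    while i < len(lines):
        header = lines[i].split()
        element = header[0].capitalize()
        i += 1
        shells = []
        while i < len(lines) and lines[i].strip() != "****":
            parts = lines[i].split()
            ltag = parts[0].upper()
            try:
                nprim = int(parts[1])
            except (IndexError, ValueError):
                raise ParseError(f"malformed shell header: {lines[i]!r}") from None
            if ltag not in _L_OF and ltag != "SP":
                raise ParseError(f"unsupported shell type {ltag!r}")
            rows = []
            for j in range(nprim):
                rows.append([float(v.replace("D", "E").replace("d", "e"))
                             for v in lines[i + 1 + j].split()])
            i += 1 + nprim
            arr = np.array(rows)
            if ltag == "SP":
                shells.append((0, arr[:, 0], arr[:, 1]))
                shells.append((1, arr[:, 0], arr[:, 2]))
            else:
                shells.append((_L_OF[ltag], arr[:, 0], arr[:, 1]))
        basis[element] = shells
        while i < len(lines) and lines[i].strip() == "****":
            i += 1
    return basis


def shells_for(molecule: Molecule, basis_map) -> list[ContractedShell]:
    shells = []
    for idx, atom in enumerate(molecule.atoms):
        if atom.symbol not in basis_map:
            raise ParseError(f"element {atom.symbol!r} missing from basis set")
        for l, e, c in basis_map[atom.symbol]:
            shells.append(ContractedShell(idx, l, e, c))
    return shells


@dataclass
class AOBasis:
    """Contracted Cartesian AO basis with its primitive expansion table.

    ``expansion`` is the (n_prim_cart × n_ao) matrix ``P`` such that a
    contracted-basis one-electron matrix is obtained from the primitive one
    as ``M_contr = Pᵀ M_prim P`` — and a contracted density expands to the
    primitive basis as ``D_prim = P D Pᵀ``.
    """

    molecule: Molecule
    shells: list[ContractedShell]
    # per contracted AO: (shell index, component tuple)
    ao_shell: np.ndarray
    ao_component: list[tuple[int, int, int]]
    # per primitive Cartesian function:
    prim_shell: np.ndarray
    prim_exponent: np.ndarray
    prim_component: list[tuple[int, int, int]]
    prim_center: np.ndarray  # (n_prim_cart, 3)
    expansion: np.ndarray  # (n_prim_cart, n_ao)

    @property
    def n_ao(self) -> int:
        return self.expansion.shape[1]

    @property
    def n_primitive_cartesian(self) -> int:
        return self.expansion.shape[0]

    def ao_centers(self) -> np.ndarray:
        coords = self.molecule.coordinates
        return coords[[self.shells[s].center for s in self.ao_shell]]


def contracted_self_overlap(exponents, coeffs, comp) -> float:
    """⟨φ|φ⟩ for a contracted Cartesian Gaussian with *unnormalized*
    primitive coefficients ``coeffs`` (primitive norms already folded in by
    the caller when desired)."""
    lx, ly, lz = comp
    l = lx + ly + lz
    a = np.asarray(exponents)[:, None]
    b = np.asarray(exponents)[None, :]
    c = np.asarray(coeffs)
    ang = (
        double_factorial(2 * lx - 1)
        * double_factorial(2 * ly - 1)
        * double_factorial(2 * lz - 1)
    )
    s = ang / (2.0 * (a + b)) ** l * (np.pi / (a + b)) ** 1.5
    return float(c @ s @ c)


def build_ao_basis(molecule: Molecule, basis_map) -> AOBasis:
    """Expand shells into contracted Cartesian AOs and primitive functions."""
    shells = shells_for(molecule, basis_map)
    coords = molecule.coordinates

    ao_shell, ao_component = [], []
    prim_shell, prim_exp, prim_comp, prim_center = [], [], [], []
    rows, cols, vals = [], [], []

    ao = 0
    for s_idx, sh in enumerate(shells):
        comps = cartesian_components(sh.l)
        # contracted normalization is component-dependent for l >= 2
        for comp in comps:
            norm_prims = np.array(
                [primitive_norm(a, *comp) for a in sh.exponents]
            )
            c_eff = sh.coefficients * norm_prims
            self_ov = contracted_self_overlap(sh.exponents, c_eff, comp)
            c_eff = c_eff / np.sqrt(self_ov)
            for k, alpha in enumerate(sh.exponents):
                rows.append(len(prim_exp))
                cols.append(ao)
                # primitive stored unit-normalized; table absorbs the rest
                vals.append(c_eff[k] / norm_prims[k])
                prim_shell.append(s_idx)
                prim_exp.append(alpha)
                prim_comp.append(comp)
                prim_center.append(coords[sh.center])
            ao_shell.append(s_idx)
            ao_component.append(comp)
            ao += 1

    n_prim = len(prim_exp)
    expansion = np.zeros((n_prim, ao))
    expansion[rows, cols] = vals
    return AOBasis(
        molecule=molecule,
        shells=shells,
        ao_shell=np.array(ao_shell),
        ao_component=ao_component,
        prim_shell=np.array(prim_shell),
        prim_exponent=np.array(prim_exp),
        prim_component=prim_comp,
        prim_center=np.array(prim_center),
        expansion=expansion,
    )
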