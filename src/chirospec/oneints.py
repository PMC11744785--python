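"""One-electron integrals over contracted Cartesian Gaussians.

Overlap, kinetic, nuclear/point-charge attraction, electric-dipole (length),
linear-momentum and angular-momentum matrices, all via the
McMurchie–Davidson Hermite expansion (E-coefficients; Hermite–Coulomb
recursion for the attraction integrals).

Operator conventions for the velocity gauge
-------------------------------------------
The momentum operator is p̂ = −i∇ and the (orbital) magnetic-dipole
operator is m̂ = −(1/2c)·L̂ with L̂ = −i·(r−O)×∇ (Hartree atomic units,
electron charge −e).  For a real AO basis both ⟨μ|∇|ν⟩ and
⟨μ|(r−O)×∇|ν⟩ are real antisymmetric; these *real* matrices are what this
module returns, the factors −i being reinstated where physical quantities
are assembled (`spectra`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import AOBasis, cartesian_components, n_cartesian
from .boys import boys
from .molecule import Molecule


def _E(i: int, j: int, t: int, ab: float, a: float, b: float, memo) -> float:
    """Hermite expansion coefficient E_t^{ij} for a 1D Gaussian pair with
    A−B = ab and exponents a, b."""
    if t < 0 or t > i + j:
        return 0.0
    key = (i, j, t)
    if key in memo:
        return memo[key]
    p = a + b
    if i == j == t == 0:
        val = np.exp(-a * b / p * ab * ab)
    elif i > 0:
        pa = -b / p * ab  # P − A
        val = (
            _E(i - 1, j, t - 1, ab, a, b, memo) / (2 * p)
            + pa * _E(i - 1, j, t, ab, a, b, memo)
            + (t + 1) * _E(i - 1, j, t + 1, ab, a, b, memo)
        )
    else:
        pb = a / p * ab  # P − B
        val = (
            _E(i, j - 1, t - 1, ab, a, b, memo) / (2 * p)
            + pb * _E(i, j - 1, t, ab, a, b, memo)
            + (t + 1) * _E(i, j - 1, t + 1, ab, a, b, memo)
        )
    memo[key] = val
    return val


def _R(t: int, u: int, v: int, n: int, p: float, PC, memo) -> float:
    """Hermite–Coulomb integral R^n_{tuv}(p, P−C)."""
    key = (t, u, v, n)
    if key in memo:
        return memo[key]
    if t == u == v == 0:
        T = p * (PC[0] ** 2 + PC[1] ** 2 + PC[2] ** 2)
        val = (-2.0 * p) ** n * boys(n, T)[n]
    elif t > 0:
        val = PC[0] * _R(t - 1, u, v, n + 1, p, PC, memo)
        if t > 1:
            val += (t - 1) * _R(t - 2, u, v, n + 1, p, PC, memo)
    elif u > 0:
        val = PC[1] * _R(t, u - 1, v, n + 1, p, PC, memo)
        if u > 1:
            val += (u - 1) * _R(t, u - 2, v, n + 1, p, PC, memo)
    else:
        val = PC[2] * _R(t, u, v - 1, n + 1, p, PC, memo)
        if v > 1:
            val += (v - 1) * _R(t, u, v - 2, n + 1, p, PC, memo)
    memo[key] = val
    return val


class _Pair1D:
    """1D integral table for one primitive pair along one axis."""

    def __init__(self, ab: float, a: float, b: float, l_max: int):
        self.ab, self.a, self.b = ab, a, b
        self.p = a + b
        self.memo: dict = {}
        self.root = np.sqrt(np.pi / self.p)

    def S(self, i, j):
        if i < 0 or j < 0:
            return 0.0
        return _E(i, j, 0, self.ab, self.a, self.b, self.memo) * self.root

    def D(self, i, j):
        """⟨i| d/dx |j⟩ (derivative on the ket)."""
        return j * self.S(i, j - 1) - 2.0 * self.b * self.S(i, j + 1)

    def M(self, i, j, bo: float):
        """⟨i| (x − O) |j⟩ with bo = B − O."""
        return self.S(i, j + 1) + bo * self.S(i, j)

    def MD(self, i, j, bo: float):
        """⟨i| (x − O) d/dx |j⟩ — same axis moment × derivative."""
        return (
            j * self.M(i, j - 1, bo) - 2.0 * self.b * self.M(i, j + 1, bo)
        )

    def K(self, i, j):
        """1D kinetic-energy factor −½⟨i|d²/dx²|j⟩."""
        b = self.b
        return (
            -2.0 * b * b * self.S(i, j + 2)
            + b * (2 * j + 1) * self.S(i, j)
            - 0.5 * j * (j - 1) * self.S(i, j - 2)
        )


@dataclass
class OneElectronMatrices:
    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    momentum: np.ndarray  # (3, N, N): real matrices ⟨μ|∇|ν⟩
    angular_momentum: np.ndarray  # (3, N, N): real matrices ⟨μ|(r−O)×∇|ν⟩
    origin: np.ndarray

    @property
    def core_hamiltonian(self) -> np.ndarray:
        return self.T + self.V


def _pair_loop(basis: AOBasis, fill):
    """Drive the shell-pair / primitive-pair loops; ``fill(block, ...)`` gets
    per-pair 1D tables and writes a (n1, n2) component block."""
    from .basis import contracted_self_overlap, primitive_norm

    shells = basis.shells
    coords = basis.molecule.coordinates
    nao = basis.n_ao
    ao0 = []
    ao = 0
    for sh in shells:
        ao0.append(ao)
        ao += n_cartesian(sh.l)

    # effective per-component primitive coefficients (normalized contraction)
    coefs = []
    for sh in shells:
        percomp = []
        for comp in cartesian_components(sh.l):
            ce = sh.coefficients * np.array(
                [primitive_norm(al, *comp) for al in sh.exponents]
            )
            so = contracted_self_overlap(sh.exponents, ce, comp)
            percomp.append(ce / np.sqrt(so))
        coefs.append(percomp)

    out = []
    for s1 in range(len(shells)):
        for s2 in range(s1, len(shells)):
            sh1, sh2 = shells[s1], shells[s2]
            A, B = coords[sh1.center], coords[sh2.center]
            c1 = cartesian_components(sh1.l)
            c2 = cartesian_components(sh2.l)
            block = None
            for k, al in enumerate(sh1.exponents):
                for l, be in enumerate(sh2.exponents):
                    tabs = [
                        _Pair1D(A[x] - B[x], al, be, sh1.l + sh2.l + 2)
                        for x in range(3)
                    ]
                    pb = fill(tabs, al, be, A, B, c1, c2)
                    w = np.outer(
                        [coefs[s1][i][k] for i in range(len(c1))],
                        [coefs[s2][j][l] for j in range(len(c2))],
                    )
                    pb = pb * w[..., None] if pb.ndim == 3 else pb * w
                    block = pb if block is None else block + pb
            out.append((s1, s2, ao0[s1], ao0[s2], block))
    return nao, out


def _assemble(basis, fill, n_mat: int, signs) -> np.ndarray:
    nao, blocks = _pair_loop(basis, fill)
    M = np.zeros((n_mat, nao, nao))
    for s1, s2, a0, b0, block in blocks:
        n1, n2 = block.shape[0], block.shape[1]
        for m in range(n_mat):
            sub = block[..., m] if block.ndim == 3 else block
            M[m, a0 : a0 + n1, b0 : b0 + n2] = sub
            if s1 != s2:
                M[m, b0 : b0 + n2, a0 : a0 + n1] = signs[m] * sub.T
    return M


def compute_overlap_kinetic(basis: AOBasis):
    """Overlap and kinetic-energy matrices."""

    def fill(tabs, al, be, A, B, c1, c2):
        n1, n2 = len(c1), len(c2)
        out = np.empty((n1, n2, 2))
        for i, (ix, iy, iz) in enumerate(c1):
            for j, (jx, jy, jz) in enumerate(c2):
                sx, sy, sz = tabs[0].S(ix, jx), tabs[1].S(iy, jy), tabs[2].S(iz, jz)
                out[i, j, 0] = sx * sy * sz
                out[i, j, 1] = (
                    tabs[0].K(ix, jx) * sy * sz
                    + sx * tabs[1].K(iy, jy) * sz
                    + sx * sy * tabs[2].K(iz, jz)
                )
        return out

    M = _assemble(basis, fill, 2, [1.0, 1.0])
    return M[0], M[1]


def compute_nuclear_attraction(
    basis: AOBasis,
    molecule: Molecule | None = None,
    mm_charges=None,
) -> np.ndarray:
    """V = −Σ_c q_c ⟨μ| 1/|r−R_c| |ν⟩ over nuclei and MM point charges.

    MM charges enter exactly like nuclei, with their fractional charges.
    """
    molecule = molecule or basis.molecule
    centers = [(float(a.Z), a.position) for a in molecule.atoms]
    centers += [(q, pos) for q, pos in (
        mm_charges if mm_charges is not None else molecule.mm_charges
    )]

    def fill(tabs, al, be, A, B, c1, c2):
        p = al + be
        P = (al * A + be * B) / p
        n1, n2 = len(c1), len(c2)
        out = np.zeros((n1, n2))
        if not centers:
            return out
        ememo = [t.memo for t in tabs]
        for q, C in centers:
            rmemo: dict = {}
            PC = P - C
            for i, (ix, iy, iz) in enumerate(c1):
                for j, (jx, jy, jz) in enumerate(c2):
                    val = 0.0
                    for t in range(ix + jx + 1):
                        Et = _E(ix, jx, t, A[0] - B[0], al, be, ememo[0])
                        if Et == 0.0:
                            continue
                        for u in range(iy + jy + 1):
                            Eu = _E(iy, jy, u, A[1] - B[1], al, be, ememo[1])
                            if Eu == 0.0:
                                continue
                            for v in range(iz + jz + 1):
                                Ev = _E(
                                    iz, jz, v, A[2] - B[2], al, be, ememo[2]
                                )
                                if Ev == 0.0:
                                    continue
                                val += Et * Eu * Ev * _R(
                                    t, u, v, 0, p, PC, rmemo
                                )
                    out[i, j] += -q * 2.0 * np.pi / p * val
        return out

    return _assemble(basis, fill, 1, [1.0])[0]


def compute_dipole(basis: AOBasis, origin) -> np.ndarray:
    """Length-gauge moment matrices ⟨μ|(r−O)|ν⟩ (3, N, N), symmetric."""
    origin = np.asarray(origin, dtype=float)

    def fill(tabs, al, be, A, B, c1, c2):
        bo = B - origin
        out = np.empty((len(c1), len(c2), 3))
        for i, ci in enumerate(c1):
            for j, cj in enumerate(c2):
                s = [tabs[x].S(ci[x], cj[x]) for x in range(3)]
                for x in range(3):
                    m = tabs[x].M(ci[x], cj[x], bo[x])
                    out[i, j, x] = m * s[(x + 1) % 3] * s[(x + 2) % 3]
        return out

    return _assemble(basis, fill, 3, [1.0, 1.0, 1.0])


def compute_velocity_gauge_operators(basis: AOBasis, origin):
    """Real matrices of ∇ and (r−O)×∇ (each (3, N, N), antisymmetric).

    The ∇ matrices are origin-independent; the angular-momentum matrices
    shift as L' = L − d×∇ under an origin translation by d.
    """
    origin = np.asarray(origin, dtype=float)

    def fill(tabs, al, be, A, B, c1, c2):
        bo = B - origin
        out = np.empty((len(c1), len(c2), 6))
        for i, ci in enumerate(c1):
            for j, cj in enumerate(c2):
                s = [tabs[x].S(ci[x], cj[x]) for x in range(3)]
                d = [tabs[x].D(ci[x], cj[x]) for x in range(3)]
                m = [tabs[x].M(ci[x], cj[x], bo[x]) for x in range(3)]
                for x in range(3):
                    y, z = (x + 1) % 3, (x + 2) % 3
                    out[i, j, x] = d[x] * s[y] * s[z]
                    # (r×∇)_x = (y−Oy)∂z − (z−Oz)∂y
                    out[i, j, 3 + x] = s[x] * (m[y] * d[z] - d[y] * m[z])
        return out

    M = _assemble(basis, fill, 6, [-1.0] * 6)
    return M[:3], M[3:]


def compute_one_electron(
    basis: AOBasis,
    origin=None,
    mm_charges=None,
) -> OneElectronMatrices:
    """All one-electron matrices; origin defaults to the center of nuclear
    charge."""
    if origin is None:
        origin = basis.molecule.center_of_nuclear_charge()
    S, T = compute_overlap_kinetic(basis)
    V = compute_nuclear_attraction(basis, mm_charges=mm_charges)
    p, L = compute_velocity_gauge_operators(basis, origin)
    return OneElectronMatrices(
        S=S, T=T, V=V, momentum=p, angular_momentum=L,
        origin=np.asarray(origin, dtype=float),
    )
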