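"""Numerical exchange–correlation integration.

A Becke-partitioned molecular grid (Gauss–Chebyshev radial points with the
[−1,1] → [0,∞) Becke map, Gauss–Legendre × uniform-azimuth angular product
shells) is split by recursive box bisection into even-sized batches of
spatially adjacent points.  Densities on a batch and the XC contribution to
the Fock matrix are formed by matrix multiplication over the AOs surviving
a per-batch screening, so the per-batch cost shrinks as the system grows.

Built-in functionals are LDA-level: Slater exchange and the VWN (form V)
local correlation.  Hybrid/range-separated exchange is handled exactly
through attenuated ERIs in `fock`, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import AOBasis, cartesian_components, primitive_norm
from .molecule import Molecule

# Bragg–Slater-like atomic radii (Bohr) for the radial map and partition
_ATOM_RADII = {1: 0.6614, 6: 1.2283, 7: 1.2283, 8: 1.1338}
_DEFAULT_RADIUS = 1.2

_LEVELS = {
    "coarse": (40, 8),
    "medium": (60, 14),
    "fine": (80, 16),
}


@dataclass
class MolecularGrid:
    points: np.ndarray  # (n, 3) Bohr
    weights: np.ndarray  # (n,)
    level: str
    provenance: dict = field(default_factory=dict)


@dataclass
class GridBatch:
    points: np.ndarray
    weights: np.ndarray
    bbox: tuple
    ao_indices: np.ndarray | None = None  # surviving AOs (filled on screen)


def _radial_shell(n_rad: int, r_map: float):
    """Gauss–Chebyshev (2nd kind) radial points with the Becke map
    r = R(1+x)/(1−x); returns radii and weights including r² dr."""
    i = np.arange(1, n_rad + 1)
    x = np.cos(i * np.pi / (n_rad + 1))
    w_cheb = np.pi / (n_rad + 1) * np.sin(i * np.pi / (n_rad + 1)) ** 2
    # undo the Chebyshev weight function √(1−x²)
    w = w_cheb / np.sqrt(1.0 - x**2)
    r = r_map * (1.0 + x) / (1.0 - x)
    dr = 2.0 * r_map / (1.0 - x) ** 2
    return r, w * dr * r**2


def _angular_shell(n_theta: int):
    """Product angular grid: Gauss–Legendre in cosθ × uniform φ; weights sum
    to 4π."""
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    st = np.sqrt(1.0 - ct**2)
    n_phi = 2 * n_theta
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    dirs, w = [], []
    for c, s, wq in zip(ct, st, wt):
        for ph in phi:
            dirs.append((s * np.cos(ph), s * np.sin(ph), c))
            w.append(wq * 2.0 * np.pi / n_phi)
    return np.array(dirs), np.array(w)


def _becke_weights(points: np.ndarray, coords: np.ndarray, iatom: int):
    """Becke fuzzy-cell partition weight of atom ``iatom`` at each point
    (k = 3 iterations of the smoothing polynomial, no size adjustment)."""
    n_at = len(coords)
    if n_at == 1:
        return np.ones(len(points))
    dist = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    rij = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    cell = np.ones((len(points), n_at))
    for a in range(n_at):
        for b in range(n_at):
            if a == b:
                continue
            mu = (dist[:, a] - dist[:, b]) / rij[a, b]
            f = mu
            for _ in range(3):
                f = 1.5 * f - 0.5 * f**3
            cell[:, a] *= 0.5 * (1.0 - f)
    tot = cell.sum(axis=1)
    return cell[:, iatom] / tot


def build_grid(molecule: Molecule, level: str = "medium") -> MolecularGrid:
    """Atom-centered molecular integration grid with Becke partitioning."""
    if level not in _LEVELS:
        raise ValueError(f"unknown grid level {level!r}")
    n_rad, n_theta = _LEVELS[level]
    coords = molecule.coordinates
    dirs, w_ang = _angular_shell(n_theta)
    pts_all, w_all = [], []
    for ia, atom in enumerate(molecule.atoms):
        r_map = _ATOM_RADII.get(atom.Z, _DEFAULT_RADIUS)
        r, w_rad = _radial_shell(n_rad, r_map)
        pts = (r[:, None, None] * dirs[None, :, :]).reshape(-1, 3) + coords[ia]
        w = (w_rad[:, None] * w_ang[None, :]).ravel()
        w = w * _becke_weights(pts, coords, ia)
        keep = w > 1e-18
        pts_all.append(pts[keep])
        w_all.append(w[keep])
    return MolecularGrid(
        points=np.concatenate(pts_all),
        weights=np.concatenate(w_all),
        level=level,
        provenance={"n_rad": n_rad, "n_theta": n_theta, "partition": "becke-k3"},
    )


def partition_boxes(grid: MolecularGrid, max_points: int = 256) -> list[GridBatch]:
    """Recursively bisect the grid's bounding box along its longest axis at
    the median point until every batch holds ≤ max_points points.  The
    batches partition the grid exactly."""
    if max_points < 1:
        raise ValueError("max_points must be >= 1")
    out: list[GridBatch] = []

    def rec(idx):
        pts = grid.points[idx]
        if idx.size <= max_points:
            out.append(
                GridBatch(
                    points=pts,
                    weights=grid.weights[idx],
                    bbox=(pts.min(axis=0), pts.max(axis=0)),
                )
            )
            return
        spans = pts.max(axis=0) - pts.min(axis=0)
        axis = int(np.argmax(spans))
        order = np.argsort(pts[:, axis], kind="stable")
        half = idx.size // 2
        rec(idx[order[:half]])
        rec(idx[order[half:]])

    rec(np.arange(len(grid.points)))
    return out


# --- AO evaluation and screening ----------------------------------------


def evaluate_aos(basis: AOBasis, points: np.ndarray,
                 ao_indices=None) -> np.ndarray:
    """Contracted AO values at grid points, shape (n_ao_sel, n_points)."""
    sel = np.arange(basis.n_ao) if ao_indices is None else np.asarray(ao_indices)
    need = np.zeros(basis.n_ao, dtype=bool)
    need[sel] = True
    vals = np.zeros((basis.n_ao, len(points)))
    P = basis.expansion
    for k in range(basis.n_primitive_cartesian):
        cols = np.nonzero(P[k])[0]
        if not need[cols].any():
            continue
        al = basis.prim_exponent[k]
        lx, ly, lz = basis.prim_component[k]
        d = points - basis.prim_center[k]
        f = (
            primitive_norm(al, lx, ly, lz)
            * d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz
            * np.exp(-al * (d * d).sum(axis=1))
        )
        for c in cols:
            vals[c] += P[k, c] * f
    return vals[sel]


def shell_extents(basis: AOBasis, cutoff: float = 1e-10) -> np.ndarray:
    """Radius per shell beyond which every AO of the shell is < cutoff."""
    r = np.linspace(0.0, 40.0, 2001)
    from .basis import contracted_self_overlap

    out = []
    for sh in basis.shells:
        comp0 = cartesian_components(sh.l)[0]
        ce = sh.coefficients * np.array(
            [primitive_norm(a, *comp0) for a in sh.exponents]
        )
        so = contracted_self_overlap(sh.exponents, ce, comp0)
        ce = np.abs(ce) / np.sqrt(so)
        amp = r[None, :] ** sh.l * np.exp(
            -sh.exponents[:, None] * r[None, :] ** 2
        )
        a = ce @ amp
        beyond = np.nonzero(a >= cutoff)[0]
        out.append(r[beyond[-1] + 1] if beyond.size else 0.0)
    return np.array(out)


def screen_batches(basis: AOBasis, batches: list[GridBatch],
                   cutoff: float = 1e-10) -> None:
    """Attach to each batch the list of AOs whose shell can reach the batch
    box (conservative radial-extent screening)."""
    extents = shell_extents(basis, cutoff)
    centers = basis.molecule.coordinates
    shell_center = np.array([centers[sh.center] for sh in basis.shells])
    ao_shell = basis.ao_shell
    for batch in batches:
        lo, hi = batch.bbox
        # distance from each shell center to the batch box
        d = np.maximum(lo - shell_center, 0.0) + np.maximum(
            shell_center - hi, 0.0
        )
        dist = np.linalg.norm(d, axis=1)
        alive = dist <= extents
        batch.ao_indices = np.nonzero(alive[ao_shell])[0]


# --- functionals ---------------------------------------------------------

_CX = 0.75 * (3.0 / np.pi) ** (1.0 / 3.0)  # Slater/Dirac exchange constant


def _slater(rho):
    e = -_CX * rho ** (4.0 / 3.0)
    v = -(4.0 / 3.0) * _CX * rho ** (1.0 / 3.0)
    return e, v


# VWN (form V) paramagnetic parametrization
_VWN = dict(A=0.0310907, x0=-0.10498, b=3.72744, c=12.9352)


def _vwn(rho):
    A, x0, b, c = _VWN["A"], _VWN["x0"], _VWN["b"], _VWN["c"]
    rho = np.maximum(rho, 1e-250)
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    x = np.sqrt(rs)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Qq = np.sqrt(4.0 * c - b * b)
    atn = np.arctan(Qq / (2.0 * x + b))
    ec = A * (
        np.log(x * x / X)
        + 2.0 * b / Qq * atn
        - b * x0 / X0
        * (np.log((x - x0) ** 2 / X) + 2.0 * (b + 2.0 * x0) / Qq * atn)
    )
    # d ec / dx
    dX = 2.0 * x + b
    datn = -2.0 * Qq / (Qq * Qq + dX * dX)
    dec = A * (
        2.0 / x - dX / X
        + 2.0 * b / Qq * datn
        - b * x0 / X0
        * (2.0 / (x - x0) - dX / X + 2.0 * (b + 2.0 * x0) / Qq * datn)
    )
    # v_c = ec + rho d ec/d rho; d rs/d rho = −rs/(3ρ); dx/dρ = −x/(6ρ)
    vc = ec - x / 6.0 * dec
    return ec * rho, vc


@dataclass(frozen=True)
class XCFunctionalSpec:
    """LDA-level built-in functionals keyed by name.

    ``slater_x``: Dirac/Slater exchange only; ``slater_vwn``: Slater
    exchange + VWN-V local correlation.  ``scale`` multiplies the exchange
    part (used by the hybrid demo assemblies).
    """

    name: str
    scale: float = 1.0

    def evaluate(self, rho: np.ndarray):
        if self.name not in ("slater_x", "slater_vwn"):
            raise ValueError(f"unknown functional {self.name!r}")
        rho = np.maximum(rho, 0.0)
        e, v = _slater(rho)
        e, v = self.scale * e, self.scale * v
        if self.name == "slater_vwn":
            mask = rho > 1e-30
            ec = np.zeros_like(rho)
            vc = np.zeros_like(rho)
            ec[mask], vc[mask] = _vwn(rho[mask])
            e, v = e + ec, v + vc
        return e, v


def density_on_batch(D: np.ndarray, batch: GridBatch,
                     basis: AOBasis) -> np.ndarray:
    """Electron density at batch points: ρ = 2·Σ_μν φ_μ D_μν φ_ν (closed
    shell, D normalized to tr(DS) = N/2)."""
    sel = batch.ao_indices
    phi = evaluate_aos(basis, batch.points, sel)
    Dsub = D if sel is None else D[np.ix_(sel, sel)]
    return 2.0 * np.einsum("mp,mn,np->p", phi, Dsub, phi, optimize=True)


def xc_fock_and_energy(
    D: np.ndarray,
    batches: list[GridBatch],
    basis: AOBasis,
    functional: XCFunctionalSpec,
):
    """E_xc = Σ w e(ρ) and its matrix V_xc[μν] = Σ w v(ρ) φ_μ φ_ν."""
    nao = basis.n_ao
    V = np.zeros((nao, nao))
    E = 0.0
    for batch in batches:
        sel = (
            batch.ao_indices
            if batch.ao_indices is not None
            else np.arange(nao)
        )
        if sel.size == 0:
            continue
        phi = evaluate_aos(basis, batch.points, sel)
        rho = 2.0 * np.einsum(
            "mp,mn,np->p", phi, D[np.ix_(sel, sel)], phi, optimize=True
        )
        e, v = functional.evaluate(rho)
        E += float(batch.weights @ e)
        Vb = (phi * (batch.weights * v)[None, :]) @ phi.T
        V[np.ix_(sel, sel)] += Vb
    return V, E


def integrate_density(D: np.ndarray, batches: list[GridBatch],
                      basis: AOBasis) -> float:
    """Σ_batches Σ_points w·ρ — the grid electron count."""
    return float(
        sum(b.weights @ density_on_batch(D, b, basis) for b in batches)
    )
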