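"""Closed-shell self-consistent-field driver.

Restricted formalism on an even electron count: the density is
D = C_occ C_occᵀ (tr(DS) = N/2) and the Fock matrix is

    F = h + 2J − c_x K − c_lr K_ω + V_xc

with the closed-shell total electronic energy
E = tr(D·(2h + 2J − c_x K − c_lr K_ω)) + E_xc.  Convergence is accelerated
by DIIS on the commutator FDS − SDF.  MM point charges enter h (attraction
term) and the classical nuclear-repulsion term.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .basis import AOBasis, build_ao_basis, load_basis
from .fock import (
    DensityMatrix,
    FockWeights,
    ScreeningConfig,
    TwoElectronEngine,
    assemble_two_electron_fock,
)
from .molecule import Molecule
from .oneints import OneElectronMatrices, compute_one_electron
from .xc import (
    XCFunctionalSpec,
    build_grid,
    partition_boxes,
    screen_batches,
    xc_fock_and_energy,
)

# CAM-type range-separation defaults
CAM_ALPHA, CAM_BETA, CAM_OMEGA = 0.19, 0.46, 0.33

_S_CONDITION_LIMIT = 1e10


class SCFError(RuntimeError):
    pass


@dataclass
class MethodConfig:
    """Electronic-structure method: 'hf', 'lda-demo' or 'cam-lda-demo'.

    'lda-demo' is pure Slater+VWN Kohn–Sham; 'cam-lda-demo' combines
    CAM-style global (α) plus erf-attenuated long-range (β, ω) exact
    exchange with a complementarily scaled Slater exchange and VWN
    correlation — an LDA-level demonstration of range-separated hybrids.
    """

    name: str = "hf"
    alpha: float = CAM_ALPHA
    beta: float = CAM_BETA
    omega: float = CAM_OMEGA
    grid_level: str = "medium"
    grid_box_size: int = 256
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)

    def fock_weights(self) -> FockWeights:
        if self.name == "hf":
            return FockWeights(1.0, 1.0, 0.0, None)
        if self.name == "lda-demo":
            return FockWeights(1.0, 0.0, 0.0, None)
        if self.name == "cam-lda-demo":
            return FockWeights(1.0, self.alpha, self.beta, self.omega)
        raise ValueError(f"unknown method {self.name!r}")

    def functional(self) -> XCFunctionalSpec | None:
        if self.name == "hf":
            return None
        if self.name == "lda-demo":
            return XCFunctionalSpec("slater_vwn")
        return XCFunctionalSpec(
            "slater_vwn", scale=1.0 - self.alpha - self.beta
        )


@dataclass
class SCFState:
    molecule: Molecule
    basis: AOBasis
    method: MethodConfig
    C: np.ndarray
    orbital_energies: np.ndarray
    density: np.ndarray
    energy: float
    energy_terms: dict
    iterations: list
    converged: bool
    ints: OneElectronMatrices
    engine: TwoElectronEngine
    grid_batches: list | None
    counters: dict

    @property
    def n_occ(self) -> int:
        return self.molecule.n_electrons // 2


def diagonalize_fock(F: np.ndarray, S: np.ndarray):
    """Solve FC = SCε (S-orthonormal columns, ε ascending)."""
    s_eigs = np.linalg.eigvalsh(S)
    if s_eigs[0] <= 0 or s_eigs[-1] / s_eigs[0] > _S_CONDITION_LIMIT:
        raise SCFError(
            f"overlap condition number {s_eigs[-1] / max(s_eigs[0], 1e-300):.2e} "
            "too large; prune near-linear-dependent basis functions"
        )
    eps, C = sla.eigh(F, S)
    return C, eps


def run_scf(
    molecule: Molecule,
    basis_name: str = "sto-3g",
    method: MethodConfig | None = None,
    tol_energy: float = 1e-8,
    tol_density: float = 1e-6,
    max_iterations: int = 100,
    diis_window: int = 8,
    verbose: bool = False,
) -> SCFState:
    """Optimize the closed-shell SCF reference state."""
    method = method or MethodConfig()
    n_occ = molecule.n_electrons // 2
    ao = build_ao_basis(molecule, load_basis(basis_name))
    ints = compute_one_electron(ao)
    h = ints.core_hamiltonian
    S = ints.S
    engine = TwoElectronEngine(ao)
    weights = method.fock_weights()
    functional = method.functional()
    batches = None
    if functional is not None:
        grid = build_grid(molecule, method.grid_level)
        batches = partition_boxes(grid, method.grid_box_size)
        screen_batches(ao, batches)

    e_nuc = molecule.nuclear_repulsion()
    counters: dict = {}

    C, eps = diagonalize_fock(h, S)
    D = C[:, :n_occ] @ C[:, :n_occ].T

    diis_F, diis_e = [], []
    log = []
    energy = 0.0
    converged = False
    for it in range(1, max_iterations + 1):
        t0 = time.perf_counter()
        dm = DensityMatrix(D, "symmetric")
        F2e = assemble_two_electron_fock(
            engine, dm, weights, method.screening, counters
        )
        t_eri = time.perf_counter() - t0
        t0 = time.perf_counter()
        E_xc = 0.0
        V_xc = 0.0
        if functional is not None:
            V_xc, E_xc = xc_fock_and_energy(D, batches, ao, functional)
        t_xc = time.perf_counter() - t0
        F = h + F2e + V_xc
        e_elec = float(np.sum(D * (2.0 * h + F2e))) + E_xc
        e_tot = e_elec + e_nuc

        # DIIS on the AO-basis gradient FDS − SDF
        err = F @ D @ S - S @ D @ F
        diis_F.append(F.copy())
        diis_e.append(err.ravel())
        if len(diis_F) > diis_window:
            diis_F.pop(0)
            diis_e.pop(0)
        if len(diis_F) > 1:
            n = len(diis_F)
            B = -np.ones((n + 1, n + 1))
            B[n, n] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = diis_e[i] @ diis_e[j]
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:n]
                F = sum(c * Fi for c, Fi in zip(coef, diis_F))
            except np.linalg.LinAlgError:
                pass

        t0 = time.perf_counter()
        C, eps = diagonalize_fock(F, S)
        t_diag = time.perf_counter() - t0
        D_new = C[:, :n_occ] @ C[:, :n_occ].T
        d_energy = e_tot - energy
        d_density = float(np.linalg.norm(D_new - D))
        energy = e_tot
        log.append(
            dict(
                iteration=it, energy=e_tot, d_energy=d_energy,
                d_density=d_density, t_eri=t_eri, t_xc=t_xc, t_diag=t_diag,
                grad_norm=float(np.linalg.norm(err)),
            )
        )
        if verbose:
            print(
                f"iter {it:3d}  E = {e_tot: .10f}  dE = {d_energy: .2e}  "
                f"|dD| = {d_density:.2e}  (eri {t_eri:.2f}s xc {t_xc:.2f}s "
                f"diag {t_diag:.3f}s)"
            )
        D = D_new
        if it > 1 and abs(d_energy) < tol_energy and d_density < tol_density:
            converged = True
            break

    if not converged:
        raise SCFError(
            f"SCF did not converge in {max_iterations} iterations "
            f"(last dE = {log[-1]['d_energy']:.2e}, "
            f"|dD| = {log[-1]['d_density']:.2e})"
        )
    return SCFState(
        molecule=molecule,
        basis=ao,
        method=method,
        C=C,
        orbital_energies=eps,
        density=D,
        energy=energy,
        energy_terms=dict(
            electronic=energy - e_nuc, nuclear_repulsion=e_nuc
        ),
        iterations=log,
        converged=True,
        ints=ints,
        engine=engine,
        grid_batches=batches,
        counters=counters,
    )
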