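"""Linear response on the closed-shell SCF reference.

The electronic-Hessian structure is the paired RPA problem

    E[2] = [[A, B], [B, A]],   S[2] = [[1, 0], [0, −1]]

over occupied–virtual amplitude pairs (X, Y).  All iterative solvers work
in the symmetric/antisymmetric trial-vector representation
g = X + Y, u = X − Y, whose actions

    (A+B)·g   →  Fock build on a *symmetric* transition density (J, K, XC)
    (A−B)·u   →  Fock build on an *antisymmetric* density (K only, J skipped)

are auxiliary Fock matrices contracted back to the MO basis.  Two solvers
are provided: a Davidson-type reduced-space eigensolver for excitation
energies and velocity-gauge transition moments, and a damped (complex
polarization propagator, CPP) solver for response functions
⟨⟨Â;B̂⟩⟩_{ω+iγ} on a frequency grid.

Operators are supplied as real antisymmetric AO matrices (the real parts of
−i·p̂ and −i·L̂, see `oneints`); property gradients carry the closed-shell
√2 factor so that transition moments and response functions follow the
usual restricted conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fock import DensityMatrix, ScreeningConfig, assemble_two_electron_fock
from .scf import SCFState
from .xc import xc_fock_and_energy

_FD_STEP = 1e-5  # finite-difference step for the XC kernel


class ResponseError(RuntimeError):
    pass


@dataclass
class ExcitedStateRecord:
    index: int
    energy: float  # Hartree
    energy_ev: float
    electric_velocity_tm: np.ndarray  # ⟨0|∇|n⟩-type real vector (3,)
    magnetic_tm: np.ndarray  # ⟨0|(r−O)×∇|n⟩-type real vector (3,)
    norm_residual: float


@dataclass
class CPPSolution:
    frequency: float  # Hartree
    gamma: float  # Hartree
    values: dict  # (name_a, name_b) -> complex ⟨⟨A;B⟩⟩
    residual: float
    n_iterations: int


class HessianAction:
    """Applies (A+B) and (A−B) through auxiliary Fock builds without ever
    materializing the matrices."""

    def __init__(self, state: SCFState, screening: ScreeningConfig | None = None):
        if not state.converged:
            raise ResponseError("response requires a converged SCF reference")
        self.state = state
        self.screening = screening or state.method.screening
        self.weights = state.method.fock_weights()
        self.functional = state.method.functional()
        no = state.n_occ
        self.Co = state.C[:, :no]
        self.Cv = state.C[:, no:]
        self.no, self.nv = no, state.C.shape[1] - no
        eps = state.orbital_energies
        self.delta = eps[no:][None, :] - eps[:no][:, None]  # (no, nv)
        self.counters = {"J_builds": 0, "K_builds": 0, "fock_builds": 0}

    @property
    def n_pairs(self) -> int:
        return self.no * self.nv

    def _to_mat(self, z: np.ndarray) -> np.ndarray:
        return z.reshape(self.no, self.nv)

    def apply_plus(self, z: np.ndarray) -> np.ndarray:
        """(A+B)·z — symmetric transition density, J + K (+ XC kernel)."""
        Z = self._to_mat(z)
        Dao = self.Co @ Z @ self.Cv.T
        Ds = DensityMatrix(Dao + Dao.T, "symmetric")
        st = self.state
        G = assemble_two_electron_fock(
            st.engine, Ds, self.weights, self.screening
        )
        if self.functional is not None:
            t = _FD_STEP / max(np.abs(Ds.matrix).max(), 1e-12)
            Vp, _ = xc_fock_and_energy(
                st.density + 0.5 * t * Ds.matrix, st.grid_batches, st.basis,
                self.functional,
            )
            Vm, _ = xc_fock_and_energy(
                st.density - 0.5 * t * Ds.matrix, st.grid_batches, st.basis,
                self.functional,
            )
            G = G + (Vp - Vm) / t
        self.counters["J_builds"] += 1
        self.counters["K_builds"] += 1
        self.counters["fock_builds"] += 1
        sig = self.delta * Z + self.Co.T @ G @ self.Cv
        return sig.ravel()

    def apply_minus(self, z: np.ndarray) -> np.ndarray:
        """(A−B)·z — antisymmetric transition density, K only (J skipped)."""
        Z = self._to_mat(z)
        Dao = self.Co @ Z @ self.Cv.T
        Da = DensityMatrix(Dao - Dao.T, "antisymmetric")
        st = self.state
        G = assemble_two_electron_fock(
            st.engine, Da, self.weights, self.screening
        )
        self.counters["K_builds"] += 1
        self.counters["fock_builds"] += 1
        sig = self.delta * Z + self.Co.T @ G @ self.Cv
        return sig.ravel()

    def operator_gradient(self, ao_matrix: np.ndarray) -> np.ndarray:
        """√2·(CoᵀVCv) for a real antisymmetric one-electron operator; the
        paired gradient is (v, −v), i.e. purely antisymmetric (u-type)."""
        return np.sqrt(2.0) * (self.Co.T @ ao_matrix @ self.Cv).ravel()


# --- explicit dense construction (oracle mode) ---------------------------


def explicit_hessian(action: HessianAction):
    """Materialize (A+B) and (A−B) column-by-column via the Fock-build
    action.  Only sensible for small occupied–virtual spaces."""
    n = action.n_pairs
    if n > 400:
        raise ResponseError("explicit Hessian restricted to small systems")
    apb = np.empty((n, n))
    amb = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        apb[:, j] = action.apply_plus(e)
        amb[:, j] = action.apply_minus(e)
    apb = 0.5 * (apb + apb.T)
    amb = 0.5 * (amb + amb.T)
    return apb, amb


def dense_eigenstates(apb: np.ndarray, amb: np.ndarray):
    """All RPA excitation energies and paired eigenvectors from the dense
    (A±B) matrices: (A−B)^{1/2}(A+B)(A−B)^{1/2} y = ω² y."""
    w, U = np.linalg.eigh(amb)
    if w.min() <= 0:
        raise ResponseError("(A−B) not positive definite (unstable reference)")
    half = U @ np.diag(np.sqrt(w)) @ U.T
    w2, Y = np.linalg.eigh(half @ apb @ half)
    omegas = np.sqrt(np.clip(w2, 0.0, None))
    # g = (A−B)^{1/2} y / √ω, u = (A−B)^{-1/2} y·√ω  → gᵀu = 1
    gs, us = [], []
    ihalf = U @ np.diag(1.0 / np.sqrt(w)) @ U.T
    for k in range(len(omegas)):
        y = Y[:, k]
        om = omegas[k]
        gs.append(half @ y / np.sqrt(om))
        us.append(ihalf @ y * np.sqrt(om))
    return omegas, np.array(gs).T, np.array(us).T


def dense_response(apb, amb, grad_u, z: complex):
    """Solve the damped response equations explicitly:
    (A+B)g − z·u = 0, (A−B)u − z·g = −grad_u; returns (g, u)."""
    n = apb.shape[0]
    M = np.zeros((2 * n, 2 * n), dtype=complex)
    M[:n, :n] = apb
    M[:n, n:] = -z * np.eye(n)
    M[n:, :n] = -z * np.eye(n)
    M[n:, n:] = amb
    rhs = np.concatenate([np.zeros(n), -grad_u]).astype(complex)
    sol = np.linalg.solve(M, rhs)
    return sol[:n], sol[n:]


# --- iterative eigensolver ----------------------------------------------


def _orthonormalize(V: list[np.ndarray], vec: np.ndarray, tol=1e-10):
    """Modified Gram–Schmidt with re-orthogonalization."""
    w = vec.copy()
    for _ in range(2):
        for b in V:
            w -= (b @ w) * b
    nrm = np.linalg.norm(w)
    if nrm < tol * max(1.0, np.linalg.norm(vec)):
        return None
    return w / nrm


def solve_eigenstates(
    state_or_action,
    n_states: int,
    momentum=None,
    angular_momentum=None,
    tol: float = 1e-5,
    max_subspace_factor: int = 50,
    max_iterations: int = 100,
) -> list[ExcitedStateRecord]:
    """Lowest RPA excitations by a Davidson-type paired reduced-space
    iteration; transition moments from the supplied velocity-gauge operator
    matrices (real antisymmetric AO matrices)."""
    action = (
        state_or_action
        if isinstance(state_or_action, HessianAction)
        else HessianAction(state_or_action)
    )
    n = action.n_pairs
    if n_states > n:
        raise ResponseError(f"requested {n_states} states but only {n} pairs")
    delta = action.delta.ravel()

    # initial guesses: lowest orbital-energy differences
    order = np.argsort(delta)
    V: list[np.ndarray] = []
    for k in order[:n_states]:
        e = np.zeros(n)
        e[k] = 1.0
        V.append(e)
    AV_p: list[np.ndarray] = []
    AV_m: list[np.ndarray] = []

    for _ in range(max_iterations):
        while len(AV_p) < len(V):
            AV_p.append(action.apply_plus(V[len(AV_p)]))
            AV_m.append(action.apply_minus(V[len(AV_m)]))
        Vm = np.array(V).T
        Pp = np.array(AV_p).T
        Pm = np.array(AV_m).T
        Mp = Vm.T @ Pp
        Mm = Vm.T @ Pm
        Mp = 0.5 * (Mp + Mp.T)
        Mm = 0.5 * (Mm + Mm.T)
        try:
            omegas, gr, ur = dense_eigenstates(Mp, Mm)
        except ResponseError:
            raise
        sel = np.argsort(omegas)[:n_states]
        converged = True
        new_dirs = []
        residuals = []
        for k in sel:
            om = omegas[k]
            g = Vm @ gr[:, k]
            u = Vm @ ur[:, k]
            r1 = Pp @ gr[:, k] - om * u
            r2 = Pm @ ur[:, k] - om * g
            res = np.sqrt(np.linalg.norm(r1) ** 2 + np.linalg.norm(r2) ** 2)
            residuals.append(res)
            if res > tol:
                converged = False
                for r in (r1, r2):
                    pre = r / np.where(np.abs(delta - om) > 1e-3,
                                       delta - om, 1e-3)
                    w = _orthonormalize(V, pre)
                    if w is not None and len(V) < max_subspace_factor * n_states:
                        V.append(w)
                        new_dirs.append(w)
        if converged:
            break
        if not new_dirs:
            break
    else:
        raise ResponseError("eigensolver did not converge")

    records = []
    from .constants import HARTREE_EV

    for i, k in enumerate(sel):
        om = omegas[k]
        u = Vm @ ur[:, k]
        tm_p = np.zeros(3)
        tm_l = np.zeros(3)
        for x in range(3):
            if momentum is not None:
                tm_p[x] = action.operator_gradient(momentum[x]) @ u
            if angular_momentum is not None:
                tm_l[x] = action.operator_gradient(angular_momentum[x]) @ u
        records.append(
            ExcitedStateRecord(
                index=i,
                energy=float(om),
                energy_ev=float(om * HARTREE_EV),
                electric_velocity_tm=tm_p,
                magnetic_tm=tm_l,
                norm_residual=float(residuals[i]) if i < len(residuals) else 0.0,
            )
        )
    return records


# --- damped (CPP) solver -------------------------------------------------


def solve_cpp(
    state_or_action,
    operators: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    frequencies,
    gamma: float,
    tol: float = 1e-6,
    max_iterations: int = 200,
) -> list[CPPSolution]:
    """Damped response functions ⟨⟨A;B⟩⟩_{ω+iγ} for the requested operator
    pairs on a frequency grid.

    Solves (A+B)g = z·u, (A−B)u − z·g = −g_B for each B operator by a
    reduced-space iteration over real trial vectors shared across the g/u
    components, then contracts ⟨⟨A;B⟩⟩ = g_Aᵀ·u_B (the operators being
    u-type/antisymmetric gradients).
    """
    action = (
        state_or_action
        if isinstance(state_or_action, HessianAction)
        else HessianAction(state_or_action)
    )
    if gamma <= 0:
        raise ResponseError("gamma must be > 0")
    n = action.n_pairs
    delta = action.delta.ravel()
    grads = {k: action.operator_gradient(m) for k, m in operators.items()}
    rhs_names = sorted({b for _, b in pairs})

    out = []
    V: list[np.ndarray] = []
    AV_p: list[np.ndarray] = []
    AV_m: list[np.ndarray] = []
    # seed with normalized gradients
    for name in rhs_names:
        w = _orthonormalize(V, grads[name])
        if w is not None:
            V.append(w)

    for om in np.atleast_1d(frequencies):
        z = om + 1j * gamma
        it = 0
        while True:
            it += 1
            while len(AV_p) < len(V):
                AV_p.append(action.apply_plus(V[len(AV_p)]))
                AV_m.append(action.apply_minus(V[len(AV_m)]))
            Vm = np.array(V).T
            Pp = np.array(AV_p).T
            Pm = np.array(AV_m).T
            Mp = 0.5 * ((Vm.T @ Pp) + (Vm.T @ Pp).T)
            Mm = 0.5 * ((Vm.T @ Pm) + (Vm.T @ Pm).T)
            k = len(V)
            Msys = np.zeros((2 * k, 2 * k), dtype=complex)
            Msys[:k, :k] = Mp
            Msys[:k, k:] = -z * np.eye(k)
            Msys[k:, :k] = -z * np.eye(k)
            Msys[k:, k:] = Mm
            sols = {}
            max_res = 0.0
            new_dirs = []
            for name in rhs_names:
                b = Vm.T @ grads[name]
                # paired gradient (v, −v) → rhs (0, −2v) in the g/u split
                rhs = np.concatenate([np.zeros(k), -2.0 * b]).astype(complex)
                sol = np.linalg.solve(Msys, rhs)
                a_r, b_r = sol[:k], sol[k:]
                g = Vm @ a_r
                u = Vm @ b_r
                r1 = Pp @ a_r - z * u
                r2 = Pm @ b_r - z * g + 2.0 * grads[name]
                res = np.sqrt(
                    np.linalg.norm(r1) ** 2 + np.linalg.norm(r2) ** 2
                ) / max(np.linalg.norm(grads[name]), 1e-300)
                max_res = max(max_res, res)
                sols[name] = (g, u)
                if res > tol:
                    for r in (r1, r2):
                        pre = r / (delta - z)
                        for part in (pre.real, pre.imag):
                            w = _orthonormalize(V, part)
                            if w is not None:
                                V.append(w)
                                new_dirs.append(w)
            if max_res <= tol:
                break
            if not new_dirs or it > max_iterations:
                raise ResponseError(
                    f"CPP solver stalled at ω={om:.4f} (residual {max_res:.2e})"
                )
        values = {}
        for a, bname in pairs:
            g, u = sols[bname]
            # ⟨⟨A;B⟩⟩_z = Σ_n t_A t_B [1/(ωn−z) + 1/(ωn+z)]·(−1): with the
            # doubled u-type rhs this is the plain contraction grad_A·u_B
            values[(a, bname)] = complex(grads[a] @ u)
        out.append(
            CPPSolution(
                frequency=float(om), gamma=float(gamma), values=values,
                residual=float(max_res), n_iterations=it,
            )
        )
    return out
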