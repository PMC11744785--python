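"""Response solvers against explicit dense E[2]/S[2] oracles: sigma-vector
structure, Davidson eigensolver, and the damped (CPP) solver."""

import numpy as np
import pytest

from chirospec.fock import contracted_eri_tensor
from chirospec.oneints import compute_velocity_gauge_operators
from chirospec.response import (
    HessianAction,
    ResponseError,
    dense_eigenstates,
    dense_response,
    explicit_hessian,
    solve_cpp,
    solve_eigenstates,
)


@pytest.fixture(scope="module")
def water_action(water_scf):
    return HessianAction(water_scf)


@pytest.fixture(scope="module")
def water_dense(water_action):
    return explicit_hessian(water_action)


@pytest.fixture(scope="module")
def water_ops(water_scf):
    p, L = compute_velocity_gauge_operators(
        water_scf.basis, water_scf.molecule.center_of_nuclear_charge()
    )
    return p, L


class TestSigmaVector:
    def test_zero_trial(self, water_action):
        z = np.zeros(water_action.n_pairs)
        assert np.abs(water_action.apply_plus(z)).max() == 0.0
        assert np.abs(water_action.apply_minus(z)).max() == 0.0

    def test_linearity(self, water_action):
        rng = np.random.default_rng(0)
        x = rng.normal(size=water_action.n_pairs)
        y = rng.normal(size=water_action.n_pairs)
        lhs = water_action.apply_plus(2.0 * x - 3.0 * y)
        rhs = 2.0 * water_action.apply_plus(x) - 3.0 * water_action.apply_plus(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_h2_explicit_columns_vs_mo_integrals(self, h2_scf):
        """On H2 (one ov pair) the action must reproduce the textbook
        A±B built from MO-transformed integrals."""
        action = HessianAction(h2_scf)
        apb, amb = explicit_hessian(action)
        T = contracted_eri_tensor(h2_scf.basis)
        C = h2_scf.C
        mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", T, C, C, C, C)
        d = h2_scf.orbital_energies[1] - h2_scf.orbital_energies[0]
        A = d + 2.0 * mo[0, 1, 0, 1] - mo[0, 0, 1, 1]
        B = 2.0 * mo[0, 1, 0, 1] - mo[0, 1, 1, 0]
        assert apb[0, 0] == pytest.approx(A + B, abs=1e-10)
        assert amb[0, 0] == pytest.approx(A - B, abs=1e-10)

    def test_build_bookkeeping(self, water_scf):
        """Symmetric components trigger J builds; antisymmetric ones are
        K-only — the counters must reflect exactly that."""
        action = HessianAction(water_scf)
        rng = np.random.default_rng(1)
        n_sym, n_anti = 3, 2
        for _ in range(n_sym):
            action.apply_plus(rng.normal(size=action.n_pairs))
        for _ in range(n_anti):
            action.apply_minus(rng.normal(size=action.n_pairs))
        assert action.counters["J_builds"] == n_sym
        assert action.counters["K_builds"] == n_sym + n_anti
        assert action.counters["fock_builds"] == n_sym + n_anti

    def test_unconverged_reference_rejected(self, water_scf):
        import copy

        bad = copy.copy(water_scf)
        bad.converged = False
        with pytest.raises(ResponseError):
            HessianAction(bad)


class TestEigensolver:
    def test_h2_two_level_closed_form(self, h2_scf):
        action = HessianAction(h2_scf)
        apb, amb = explicit_hessian(action)
        expected = np.sqrt(apb[0, 0] * amb[0, 0])
        recs = solve_eigenstates(h2_scf, 1, tol=1e-8)
        assert recs[0].energy == pytest.approx(expected, abs=1e-8)

    def test_water_vs_dense_oracle(self, water_scf, water_dense, water_ops):
        apb, amb = water_dense
        om, g, u = dense_eigenstates(apb, amb)
        recs = solve_eigenstates(
            water_scf, 5, momentum=water_ops[0],
            angular_momentum=water_ops[1], tol=1e-7,
        )
        got = np.array([r.energy for r in recs])
        np.testing.assert_allclose(got, np.sort(om)[:5], atol=1e-8)

    def test_energies_positive_ascending(self, water_scf):
        recs = solve_eigenstates(water_scf, 6, tol=1e-6)
        e = [r.energy for r in recs]
        assert all(v > 0 for v in e)
        assert np.all(np.diff(e) >= -1e-12)

    def test_too_many_states_rejected(self, water_scf):
        with pytest.raises(ResponseError):
            solve_eigenstates(water_scf, 1000)

    def test_transition_moments_match_dense(
        self, water_scf, water_action, water_dense, water_ops
    ):
        apb, amb = water_dense
        om, g, u = dense_eigenstates(apb, amb)
        order = np.argsort(om)
        recs = solve_eigenstates(
            water_scf, 4, momentum=water_ops[0],
            angular_momentum=water_ops[1], tol=1e-8,
        )
        for i, r in enumerate(recs):
            un = u[:, order[i]]
            for x in range(3):
                ref = water_action.operator_gradient(water_ops[0][x]) @ un
                assert abs(abs(ref) - abs(r.electric_velocity_tm[x])) < 1e-6


class TestCPP:
    def test_damping_dominated_limit(self, water_action, water_dense, water_ops):
        """At huge γ the response is damping-dominated; compare against the
        explicit-matrix solve."""
        apb, amb = water_dense
        gma = 10.0
        ops = {"p0": water_ops[0][0]}
        sols = solve_cpp(water_action, ops, [("p0", "p0")], [0.1], gma,
                         tol=1e-9)
        grad = water_action.operator_gradient(water_ops[0][0])
        g, uu = dense_response(apb, amb, 2.0 * grad, 0.1 + 1j * gma)
        expected = complex(grad @ uu)
        got = sols[0].values[("p0", "p0")]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_below_resonance_real_limit(self, water_action, water_dense,
                                        water_ops):
        """Far below the first excitation with small γ the real part matches
        the undamped solve and the imaginary part is ∝ γ."""
        apb, amb = water_dense
        om, _, _ = dense_eigenstates(apb, amb)
        w = 0.25 * om.min()
        grad = water_action.operator_gradient(water_ops[0][2])
        ops = {"p2": water_ops[0][2]}
        small = 1e-4
        sols = solve_cpp(water_action, ops, [("p2", "p2")], [w], small,
                         tol=1e-10)
        g0, u0 = dense_response(apb, amb, 2.0 * grad, w + 0j)
        undamped = float(np.real(grad @ u0))
        got = sols[0].values[("p2", "p2")]
        assert got.real == pytest.approx(undamped, rel=1e-6)
        sols2 = solve_cpp(water_action, ops, [("p2", "p2")], [w], 2 * small,
                          tol=1e-10)
        ratio = sols2[0].values[("p2", "p2")].imag / got.imag
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_sum_over_states_identity(self, water_action, water_dense,
                                      water_ops):
        apb, amb = water_dense
        om, g, u = dense_eigenstates(apb, amb)
        p, L = water_ops
        ops = {"p1": p[1], "L1": L[1]}
        gamma = 0.005
        w = 0.35
        sols = solve_cpp(water_action, ops, [("p1", "L1")], [w], gamma,
                         tol=1e-9)
        gp = water_action.operator_gradient(p[1])
        gl = water_action.operator_gradient(L[1])
        z = w + 1j * gamma
        sos = 0.0 + 0.0j
        for n in range(len(om)):
            tp = gp @ u[:, n]
            tl = gl @ u[:, n]
            sos += -tp * tl * (1.0 / (om[n] - z) + 1.0 / (om[n] + z))
        assert sols[0].values[("p1", "L1")] == pytest.approx(sos, abs=1e-8)

    def test_invalid_gamma(self, water_action, water_ops):
        with pytest.raises(ResponseError):
            solve_cpp(water_action, {"p0": water_ops[0][0]},
                      [("p0", "p0")], [0.1], gamma=0.0)
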