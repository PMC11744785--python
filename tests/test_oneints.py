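"""One-electron integrals against independent quadrature oracles, operator
symmetries and the MM point-charge behavior."""

import numpy as np
import pytest

from chirospec.basis import build_ao_basis, primitive_norm
from chirospec.fixtures import mm_water_charges, water_molecule
from chirospec.molecule import Atom, Molecule
from chirospec.oneints import (
    compute_dipole,
    compute_nuclear_attraction,
    compute_one_electron,
    compute_overlap_kinetic,
    compute_velocity_gauge_operators,
)

from .oracles import attraction_quadrature, overlap_like_1d, overlap_quadrature


@pytest.fixture(scope="module")
def tiny(sto3g):
    """H2O / STO-3G (7 AOs) — small enough for dense oracle comparison."""
    ao = build_ao_basis(water_molecule(), sto3g)
    return ao


def _prim_pairs(basis):
    for k in range(basis.n_primitive_cartesian):
        for l in range(k, basis.n_primitive_cartesian):
            yield k, l


def _contract(basis, prim_matrix):
    P = basis.expansion
    return P.T @ prim_matrix @ P


class TestOverlapKinetic:
    def test_single_primitive_normalized(self):
        basis_map = {"H": [(0, np.array([0.7]), np.array([1.0]))]}
        mol = Molecule([Atom("H", 1, np.zeros(3))], charge=-1)
        ao = build_ao_basis(mol, basis_map)
        S, T = compute_overlap_kinetic(ao)
        assert S[0, 0] == pytest.approx(1.0, rel=1e-14)

    def test_two_s_primitives_gaussian_product(self):
        alpha, R = 0.9, 1.7
        basis_map = {"H": [(0, np.array([alpha]), np.array([1.0]))]}
        mol = Molecule(
            [Atom("H", 1, np.zeros(3)), Atom("H", 1, np.array([0, 0, R]))]
        )
        ao = build_ao_basis(mol, basis_map)
        S, _ = compute_overlap_kinetic(ao)
        assert S[0, 1] == pytest.approx(np.exp(-alpha * R * R / 2.0), rel=1e-12)

    def test_overlap_vs_quadrature(self, tiny):
        S, _ = compute_overlap_kinetic(tiny)
        # quadrature through the primitive expansion
        n = tiny.n_primitive_cartesian
        Sp = np.zeros((n, n))
        for k, l in _prim_pairs(tiny):
            val = overlap_quadrature(
                tiny.prim_component[k], tiny.prim_component[l],
                tiny.prim_center[k], tiny.prim_center[l],
                tiny.prim_exponent[k], tiny.prim_exponent[l],
            )
            norm = primitive_norm(
                tiny.prim_exponent[k], *tiny.prim_component[k]
            ) * primitive_norm(tiny.prim_exponent[l], *tiny.prim_component[l])
            Sp[k, l] = Sp[l, k] = val * norm
        np.testing.assert_allclose(S, _contract(tiny, Sp), atol=1e-8)

    def test_matrices_symmetric_and_definite(self, tiny):
        S, T = compute_overlap_kinetic(tiny)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        np.testing.assert_allclose(T, T.T, atol=1e-12)
        assert np.linalg.eigvalsh(S).min() > 0
        assert np.linalg.eigvalsh(T).min() > -1e-12


class TestNuclearAttraction:
    def test_no_centers_gives_zero(self, tiny):
        empty = Molecule([], 0, [])
        V = compute_nuclear_attraction(tiny, molecule=empty)
        assert np.abs(V).max() == 0.0

    def test_single_s_function_boys_closed_form(self):
        alpha = 1.3
        basis_map = {"H": [(0, np.array([alpha]), np.array([1.0]))]}
        mol = Molecule([Atom("H", 1, np.zeros(3))], charge=-1)
        ao = build_ao_basis(mol, basis_map)
        V = compute_nuclear_attraction(ao)
        # ⟨s|−1/r|s⟩ = −2π/α · N² · F0(0) with N the s-primitive norm
        norm2 = primitive_norm(alpha, 0, 0, 0) ** 2
        expected = -2.0 * np.pi / (2 * alpha) * norm2
        assert V[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_vs_quadrature(self, tiny):
        V = compute_nuclear_attraction(tiny)
        n = tiny.n_primitive_cartesian
        Vp = np.zeros((n, n))
        mol = tiny.molecule
        for k, l in _prim_pairs(tiny):
            val = 0.0
            for at in mol.atoms:
                val -= at.Z * attraction_quadrature(
                    tiny.prim_component[k], tiny.prim_component[l],
                    tiny.prim_center[k], tiny.prim_center[l],
                    tiny.prim_exponent[k], tiny.prim_exponent[l], at.position,
                )
            norm = primitive_norm(
                tiny.prim_exponent[k], *tiny.prim_component[k]
            ) * primitive_norm(tiny.prim_exponent[l], *tiny.prim_component[l])
            Vp[k, l] = Vp[l, k] = val * norm
        np.testing.assert_allclose(V, _contract(tiny, Vp), atol=1e-7)

    def test_neutral_mm_water_dipolar_falloff(self, tiny):
        """A distant neutral MM water (charges −0.6690/+0.3345) perturbs V
        faster-decaying than a monopole: ‖V(R)‖ ~ R⁻² not R⁻¹."""
        direction = np.array([1.0, 0.3, -0.2])
        direction /= np.linalg.norm(direction)

        def v_at(R):
            mm_mol = water_molecule().translated(direction * R)
            charges = mm_water_charges(mm_mol)
            assert sum(q for q, _ in charges) == pytest.approx(0.0)
            return compute_nuclear_attraction(
                tiny, mm_charges=charges
            ) - compute_nuclear_attraction(tiny, mm_charges=[])

        n40 = np.abs(v_at(40.0)).max()
        n80 = np.abs(v_at(80.0)).max()
        ratio = n40 / n80
        assert ratio > 3.0  # dipole: ≈ 4; monopole would give ≈ 2


class TestVelocityGaugeOperators:
    def test_same_center_s_functions_zero_by_parity(self):
        basis_map = {"H": [(0, np.array([0.5]), np.array([1.0])),
                           (0, np.array([1.5]), np.array([1.0]))]}
        mol = Molecule([Atom("H", 1, np.zeros(3))], charge=-1)
        ao = build_ao_basis(mol, basis_map)
        p, _ = compute_velocity_gauge_operators(ao, np.zeros(3))
        assert np.abs(p).max() < 1e-14

    def test_antisymmetry(self, tiny):
        p, L = compute_velocity_gauge_operators(tiny, np.zeros(3))
        for x in range(3):
            np.testing.assert_allclose(p[x], -p[x].T, atol=1e-12)
            np.testing.assert_allclose(L[x], -L[x].T, atol=1e-12)

    def test_origin_shift_identity(self, tiny):
        d = np.array([5.0, -3.0, 2.0])
        p, L = compute_velocity_gauge_operators(tiny, np.zeros(3))
        p2, L2 = compute_velocity_gauge_operators(tiny, d)
        np.testing.assert_allclose(p2, p, atol=1e-12)
        for x in range(3):
            y, z = (x + 1) % 3, (x + 2) % 3
            np.testing.assert_allclose(
                L2[x], L[x] - (d[y] * p[z] - d[z] * p[y]), atol=1e-12
            )

    def test_momentum_vs_quadrature(self, tiny):
        p, _ = compute_velocity_gauge_operators(tiny, np.zeros(3))
        n = tiny.n_primitive_cartesian
        Pz = np.zeros((n, n))
        for k in range(n):
            for l in range(n):
                val = 1.0
                for x in range(3):
                    val *= overlap_like_1d(
                        tiny.prim_component[k][x], tiny.prim_component[l][x],
                        tiny.prim_center[k][x], tiny.prim_center[l][x],
                        tiny.prim_exponent[k], tiny.prim_exponent[l],
                        derivative=(x == 2),
                    )
                norm = primitive_norm(
                    tiny.prim_exponent[k], *tiny.prim_component[k]
                ) * primitive_norm(
                    tiny.prim_exponent[l], *tiny.prim_component[l]
                )
                Pz[k, l] = val * norm
        np.testing.assert_allclose(p[2], _contract(tiny, Pz), atol=1e-8)

    def test_dipole_symmetric(self, tiny):
        mu = compute_dipole(tiny, np.zeros(3))
        for x in range(3):
            np.testing.assert_allclose(mu[x], mu[x].T, atol=1e-12)


def test_bundle_defaults_to_charge_center(tiny):
    ints = compute_one_electron(tiny)
    np.testing.assert_allclose(
        ints.origin, tiny.molecule.center_of_nuclear_charge()
    )
    assert ints.core_hamiltonian.shape == (tiny.n_ao, tiny.n_ao)
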