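"""ERI engine: kernel-class enumeration, unrolled plans vs the recursive
reference vs independent quadrature, permutational symmetry, attenuation
limits and Schwarz factors."""

import itertools

import numpy as np
import pytest

from chirospec.basis import build_ao_basis, cartesian_components, n_cartesian
from chirospec.eri import (
    KernelClass,
    enumerate_kernel_classes,
    eri_class_batch,
    eri_reference,
    generate_unrolled_plan,
    get_plan,
    primitive_eri,
)
from chirospec.fixtures import generate_water_droplet
from chirospec.fock import TwoElectronEngine, contracted_eri_tensor

from .oracles import eri_quadrature


def _random_quartet(rng, scale=1.5):
    centers = rng.normal(scale=scale, size=(4, 3))
    exps = rng.uniform(0.15, 3.0, size=4)
    return centers, exps


class TestKernelClasses:
    @pytest.mark.parametrize(
        "l_max,mode,count",
        [
            (1, "coulomb", 9),
            (2, "coulomb", 36),
            (1, "exchange", 12),
            (2, "exchange", 54),
            (0, "coulomb", 1),
            (0, "exchange", 1),
        ],
    )
    def test_counts(self, l_max, mode, count):
        classes = enumerate_kernel_classes(l_max, mode)
        assert len(classes) == count
        assert len(set(classes)) == count  # all distinct

    def test_coulomb_pairs_unordered(self):
        for kc in enumerate_kernel_classes(2, "coulomb"):
            assert kc.bra[0] <= kc.bra[1]
            assert kc.ket[0] <= kc.ket[1]

    def test_exchange_summed_pair_ordered(self):
        kets = {kc.ket for kc in enumerate_kernel_classes(1, "exchange")}
        assert kets == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_unsupported(self):
        with pytest.raises(ValueError):
            enumerate_kernel_classes(3, "coulomb")
        with pytest.raises(ValueError):
            enumerate_kernel_classes(1, "other")


class TestUnrolledPlans:
    @pytest.mark.parametrize(
        "key,n_out",
        [
            ((0, 1, 0, 1), 9),  # the [sp|sp] → 9 split
            ((0, 0, 0, 0), 1),
            ((2, 2, 2, 2), 1296),
        ],
    )
    def test_output_slot_counts(self, key, n_out):
        plan = get_plan(*key)
        assert plan.n_outputs == n_out
        expected = np.prod([n_cartesian(l) for l in key])
        assert plan.n_outputs == expected

    def test_ssss_reduces_to_boys(self):
        plan = generate_unrolled_plan(0, 0, 0, 0)
        assert len(plan.statements) == 1
        assert plan.statements[0][1] == "pref*F[0]"

    def test_plan_self_contained(self):
        plan = get_plan(1, 1, 1, 1)
        defined = set()
        inputs = {
            f"{n}{i}" for n in ("PA", "WP", "QC", "WQ", "AB", "CD")
            for i in range(3)
        } | {"i2p", "i2q", "i2pq", "rop", "roq", "pref"}
        import re

        for var, expr in plan.statements:
            for tok in re.findall(r"[A-Za-z_]\w*", expr):
                if tok == "F":
                    continue
                assert tok in inputs or tok in defined, tok
            defined.add(var)

    def test_json_dump(self):
        d = get_plan(0, 1, 0, 0).to_json()
        assert d["class"] == [0, 1, 0, 0]
        assert len(d["outputs"]) == 3


class TestPrimitiveERI:
    def test_same_center_ssss_closed_form(self):
        z = np.zeros(3)
        val = primitive_eri(
            (0, 0, 0), (0, 0, 0), (0, 0, 0), (0, 0, 0),
            z, z, z, z, 1.0, 1.0, 1.0, 1.0,
        )
        # [00|00] = 2π^{5/2}/(pq√(p+q)) F0(0)
        assert val == pytest.approx(2.0 * np.pi**2.5 / (2 * 2 * 2), rel=1e-13)

    def test_plan_matches_recursive_reference(self):
        rng = np.random.default_rng(11)
        for key in [(0, 1, 1, 0), (1, 2, 0, 1), (2, 0, 2, 2)]:
            centers, exps = _random_quartet(rng)
            batch = eri_class_batch(*key, *centers, *exps)
            comps = [cartesian_components(l) for l in key]
            idx = 0
            for ca, cb, cc, cd in itertools.product(*comps):
                ref = eri_reference(ca, cb, cc, cd, *centers, *exps)
                assert batch[idx, 0] == pytest.approx(
                    ref, rel=1e-11, abs=1e-14
                )
                idx += 1

    def test_matches_quadrature(self):
        rng = np.random.default_rng(3)
        for key in [(0, 0, 0, 0), (1, 1, 0, 1), (2, 1, 1, 0)]:
            centers, exps = _random_quartet(rng)
            comps = [cartesian_components(l)[rng.integers(n_cartesian(l))]
                     for l in key]
            ref = eri_quadrature(*comps, *centers, *exps)
            val = eri_reference(*comps, *centers, *exps)
            assert val == pytest.approx(ref, rel=1e-7, abs=1e-13)

    def test_distant_pair_negligible(self):
        # the two members of the *bra pair* 100 Bohr apart: the Gaussian
        # product prefactor kills every component
        rng = np.random.default_rng(4)
        centers = np.array(
            [[0, 0, 0], [100.0, 0, 0], [0.3, 0.2, 0], [0.1, 0, 0.4]]
        )
        exps = rng.uniform(0.5, 2.0, 4)
        vals = eri_class_batch(1, 1, 1, 1, *centers, *exps)
        assert np.abs(vals).max() < 1e-30

    def test_eightfold_symmetry(self):
        rng = np.random.default_rng(7)
        centers, exps = _random_quartet(rng)
        A, B, C, D = centers
        a, b, c, d = exps
        ca, cb, cc, cd = (1, 0, 0), (0, 1, 1), (0, 0, 1), (2, 0, 0)
        ref = eri_reference(ca, cb, cc, cd, A, B, C, D, a, b, c, d)
        perms = [
            ((cb, ca, cc, cd), (B, A, C, D), (b, a, c, d)),
            ((ca, cb, cd, cc), (A, B, D, C), (a, b, d, c)),
            ((cc, cd, ca, cb), (C, D, A, B), (c, d, a, b)),
            ((cd, cc, cb, ca), (D, C, B, A), (d, c, b, a)),
        ]
        for comps, cent, ex in perms:
            val = eri_reference(*comps, *cent, *ex)
            assert val == pytest.approx(ref, rel=1e-11, abs=1e-15)


class TestAttenuatedERI:
    def test_large_omega_limit(self):
        rng = np.random.default_rng(9)
        centers, exps = _random_quartet(rng)
        z = (0, 0, 0)
        full = eri_reference(z, z, z, z, *centers, *exps)
        att = eri_reference(z, z, z, z, *centers, *exps, omega=1e6)
        assert att == pytest.approx(full, rel=1e-6)

    def test_small_omega_limit(self):
        # same-center unit exponents: attenuation factor ω/√(ω²+ρ) < 1e-6
        z3 = np.zeros(3)
        z = (0, 0, 0)
        full = eri_reference(z, z, z, z, z3, z3, z3, z3, 1, 1, 1, 1)
        att = eri_reference(z, z, z, z, z3, z3, z3, z3, 1, 1, 1, 1,
                            omega=1e-6)
        assert abs(att) < 1e-6 * abs(full)

    def test_omega_quadrature(self):
        z3 = np.zeros(3)
        zc = (0, 0, 0)
        ref = eri_quadrature(zc, zc, zc, zc, z3, z3, z3, z3,
                             1.0, 1.0, 1.0, 1.0, omega=0.33)
        val = eri_reference(zc, zc, zc, zc, z3, z3, z3, z3,
                            1.0, 1.0, 1.0, 1.0, omega=0.33)
        assert val == pytest.approx(ref, rel=1e-8)

    def test_attenuated_plan_matches_reference(self):
        rng = np.random.default_rng(12)
        key = (1, 1, 1, 0)
        centers, exps = _random_quartet(rng)
        batch = eri_class_batch(*key, *centers, *exps, omega=0.33)
        comps = [cartesian_components(l) for l in key]
        idx = 0
        for ca, cb, cc, cd in itertools.product(*comps):
            ref = eri_reference(ca, cb, cc, cd, *centers, *exps, omega=0.33)
            assert batch[idx, 0] == pytest.approx(ref, rel=1e-10, abs=1e-15)
            idx += 1


class TestSchwarz:
    def test_same_center_ss_pair_definition(self):
        basis_map = {"H": [(0, np.array([1.0]), np.array([1.0]))]}
        from chirospec.molecule import Atom, Molecule

        mol = Molecule([Atom("H", 1, np.zeros(3))], charge=-1)
        engine = TwoElectronEngine(build_ao_basis(mol, basis_map))
        blk = engine.blocks[(0, 0)]
        z3 = np.zeros(3)
        zc = (0, 0, 0)
        diag = eri_reference(zc, zc, zc, zc, z3, z3, z3, z3, 1, 1, 1, 1)
        norm = (2.0 / np.pi) ** 0.75  # primitive norm at α = 1
        assert blk.Q[0] == pytest.approx(np.sqrt(diag * norm**4), rel=1e-12)

    def test_bound_never_violated(self, def2svp):
        mol = generate_water_droplet(3, seed=3)
        ao = build_ao_basis(mol, def2svp)
        engine = TwoElectronEngine(ao)
        Qc = engine.contracted_schwarz()
        T = None
        rng = np.random.default_rng(0)
        # sample contracted quartets from a small subsystem tensor instead of
        # the full N⁴ object: use water/STO-3G exact tensor
        from chirospec.fixtures import water_molecule

        ao_w = build_ao_basis(water_molecule(), def2svp)
        T = contracted_eri_tensor(ao_w)
        Qw = TwoElectronEngine(ao_w).contracted_schwarz()
        n = ao_w.n_ao
        idx = rng.integers(0, n, size=(10000, 4))
        lhs = np.abs(T[idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]])
        rhs = Qw[idx[:, 0], idx[:, 1]] * Qw[idx[:, 2], idx[:, 3]]
        assert np.all(lhs <= rhs * (1 + 1e-10) + 1e-300)

    def test_distant_pair_decay(self, sto3g):
        from chirospec.molecule import Atom, Molecule

        mol = Molecule(
            [Atom("H", 1, np.zeros(3)), Atom("H", 1, np.array([50.0, 0, 0]))]
        )
        engine = TwoElectronEngine(build_ao_basis(mol, sto3g))
        blk = engine.blocks[(0, 0)]
        cross = blk.ao1 != blk.ao2
        assert blk.Q[cross].max() < 1e-20

    def test_pair_lists_sorted_reproducibly(self, water_engine):
        # descending Q with deterministic tie-breaking is what build_J uses
        for blk in water_engine.blocks.values():
            order = np.argsort(-blk.Q, kind="stable")
            assert np.all(np.diff(blk.Q[order]) <= 0.0)
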