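"""Shared fixtures: small reference systems and their (cached) SCF states
and ERI tensors, so expensive objects are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from chirospec.basis import build_ao_basis, load_basis
from chirospec.fixtures import generate_chiral_fixture, water_molecule
from chirospec.fock import TwoElectronEngine, contracted_eri_tensor
from chirospec.molecule import Atom, Molecule
from chirospec.scf import run_scf


@pytest.fixture(scope="session")
def sto3g():
    return load_basis("sto-3g")


@pytest.fixture(scope="session")
def def2svp():
    return load_basis("def2-svp")


@pytest.fixture(scope="session")
def h2_molecule():
    return Molecule(
        [Atom("H", 1, np.zeros(3)), Atom("H", 1, np.array([0.0, 0.0, 1.4]))]
    )


@pytest.fixture(scope="session")
def water_ao(sto3g):
    return build_ao_basis(water_molecule(), sto3g)


@pytest.fixture(scope="session")
def water_engine(water_ao):
    return TwoElectronEngine(water_ao)


@pytest.fixture(scope="session")
def water_tensor(water_ao):
    return contracted_eri_tensor(water_ao)


@pytest.fixture(scope="session")
def water_scf(sto3g):
    return run_scf(water_molecule(), "sto-3g")


@pytest.fixture(scope="session")
def h2_scf(h2_molecule):
    return run_scf(h2_molecule, "sto-3g")


@pytest.fixture(scope="session")
def h2o2_scf():
    return run_scf(generate_chiral_fixture("h2o2_P"), "sto-3g")


@pytest.fixture(scope="session")
def h2o2_m_scf():
    return run_scf(generate_chiral_fixture("h2o2_M"), "sto-3g")
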