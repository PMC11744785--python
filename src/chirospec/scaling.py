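"""Screened-work scaling experiments on water droplets.

The hardware-independent work measure is the number of primitive-pair
quartets surviving the density-weighted Schwarz bound
Q_μν · Q_λσ·|D_λσ| ≥ τ — the quantity the Coulomb build would evaluate.
Counting uses the presorted pair lists (sort once, binary-search per bra
pair), so droplets far beyond what a J build would touch remain cheap.

The screening density is a superposition-of-monomers proxy: the converged
density of a single water replicated block-diagonally over the droplet.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .basis import build_ao_basis, load_basis
from .fixtures import generate_water_droplet, water_molecule
from .fock import TwoElectronEngine, component_norms, n_cartesian
from .scf import run_scf


@dataclass
class ScalingRow:
    n_molecules: int
    n_basis: int
    n_pairs: int
    quartets: int
    t_setup: float
    t_count: float


@dataclass
class ScalingResult:
    threshold: float
    basis: str
    seed: int
    rows: list[ScalingRow]
    slope: float | None = None
    slope_stderr: float | None = None
    fit_log: dict = field(default_factory=dict)


def _monomer_density(basis_name: str) -> np.ndarray:
    state = run_scf(water_molecule(), basis_name)
    return state.density


def count_j_quartets(engine: TwoElectronEngine, D: np.ndarray,
                     threshold: float) -> tuple[int, int]:
    """Number of (bra, ket) primitive-pair quartets with
    Q_bra · (Q_ket·|D_ket|) ≥ τ, over the full presorted pair lists."""
    qs, qds = [], []
    for key, blk in engine.blocks.items():
        n1, n2 = n_cartesian(blk.l1), n_cartesian(blk.l2)
        dmax = np.zeros(blk.n)
        for i in range(n1):
            for j in range(n2):
                dmax = np.maximum(dmax, np.abs(D[blk.ao1 + i, blk.ao2 + j]))
        qs.append(blk.Q)
        qds.append(blk.Q * dmax)
    q = np.concatenate(qs)
    qd = np.sort(np.concatenate(qds))[::-1]
    # for each bra pair, how many sorted ket keys exceed τ / Q_bra
    lim = threshold / np.maximum(q, 1e-300)
    counts = np.searchsorted(-qd, -lim, side="right")
    return int(counts.sum()), q.size


def run_scaling_experiment(
    sizes,
    seed: int = 0,
    basis: str = "def2-svp",
    threshold: float = 1e-8,
) -> ScalingResult:
    """Quartet-count scaling over droplet sizes; fits the log–log slope of
    surviving quartets versus basis-set size."""
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("sizes must be ascending")
    basis_map = load_basis(basis)
    d_mono = _monomer_density(basis)
    nmono = d_mono.shape[0]
    rows = []
    for n in sizes:
        mol = generate_water_droplet(n, seed=seed)
        ao = build_ao_basis(mol, basis_map)
        t0 = time.perf_counter()
        engine = TwoElectronEngine(ao)
        t_setup = time.perf_counter() - t0
        D = np.zeros((ao.n_ao, ao.n_ao))
        for k in range(n):
            sl = slice(k * nmono, (k + 1) * nmono)
            D[sl, sl] = d_mono
        t0 = time.perf_counter()
        quartets, n_pairs = count_j_quartets(engine, D, threshold)
        t_count = time.perf_counter() - t0
        rows.append(
            ScalingRow(
                n_molecules=n, n_basis=ao.n_ao, n_pairs=n_pairs,
                quartets=quartets, t_setup=t_setup, t_count=t_count,
            )
        )
    result = ScalingResult(
        threshold=threshold, basis=basis, seed=seed, rows=rows
    )
    if len(rows) >= 2:
        x = np.log([r.n_basis for r in rows])
        y = np.log([max(r.quartets, 1) for r in rows])
        if len(rows) > 2:
            coef, cov = np.polyfit(x, y, 1, cov=True)
            result.slope_stderr = float(np.sqrt(cov[0, 0]))
        else:
            coef = np.polyfit(x, y, 1)
        result.slope = float(coef[0])
        result.fit_log = {"log_n": x.tolist(), "log_q": y.tolist()}
    return result
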