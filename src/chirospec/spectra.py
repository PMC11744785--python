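"""ECD spectrum assembly: velocity-gauge rotatory strengths, Cauchy
broadening, and Δε directly from the damped mixed electric–magnetic
response — plus spectrum file I/O.

Conventions (fixed here, used consistently throughout):

* ``tp = ⟨0|∇|n⟩`` and ``tL = ⟨0|(r−O)×∇|n⟩`` are the *real* contractions
  returned by the response solvers; the physical moments carry −i (and the
  magnetic moment −1/2c).  The velocity-gauge rotatory strength is

      R_n = −(1/(2c·ω_n)) · tp·tL      (atomic units)

  which is independent of the coordinate origin O (the shift term is a
  vanishing triple product tp·(d×tp)).
* The Cauchy (Lorentzian) profile f(Δω) = (γ/π)/(Δω² + γ²) is normalized
  on the angular-frequency axis and γ is its HWHM.
* Broadened sticks:   Δε(ω) = C₀ · ω · Σ_n R_n f(ω−ω_n0)
  with C₀ assembled from CODATA constants (`constants`); Δε is in
  L mol⁻¹ cm⁻¹ with ω in Hartree and R in atomic units.
* CPP route: G̃_ab(ω) = −(1/(2cω)) ⟨⟨p_a;L_b⟩⟩_{ω+iγ},
  β(ω) = −(1/3π)·Tr Im G̃, and Δε(ω) = 3·C₀·ω·β(ω), which reduces to the
  broadened-stick form when all contributing states are resolved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import (
    DELTA_EPS_PREFACTOR_CGS,
    EV_TO_HARTREE,
    HARTREE_EV,
    HC_EV_NM,
    ROTATORY_AU_TO_CGS,
    SPEED_OF_LIGHT_AU,
    convert_damping,
)
from .oneints import compute_velocity_gauge_operators
from .response import (
    CPPSolution,
    ExcitedStateRecord,
    HessianAction,
    solve_cpp,
    solve_eigenstates,
)

# Δε [L mol⁻¹ cm⁻¹] = C0 · ω[Ha] · Σ R[au] · f[1/Ha]
DELTA_EPS_AU = DELTA_EPS_PREFACTOR_CGS * ROTATORY_AU_TO_CGS


def rotatory_strength(record: ExcitedStateRecord) -> float:
    """Velocity-gauge rotatory strength R_n0 in atomic units."""
    if record.energy <= 0:
        raise ValueError("velocity-gauge factor 1/ω singular at ω = 0")
    return float(
        -np.dot(record.electric_velocity_tm, record.magnetic_tm)
        / (2.0 * SPEED_OF_LIGHT_AU * record.energy)
    )


def cauchy_profile(delta_omega, gamma: float):
    """HWHM-γ Cauchy distribution, unit area on the ω axis."""
    return (gamma / np.pi) / (np.asarray(delta_omega) ** 2 + gamma**2)


@dataclass
class RotatorySpectrum:
    energies: np.ndarray  # stick positions ω_n0, Hartree
    strengths: np.ndarray  # R_n0, atomic units
    grid: np.ndarray  # ω grid, Hartree
    delta_epsilon: np.ndarray  # L mol⁻¹ cm⁻¹
    gamma: float  # HWHM, Hartree
    meta: dict = field(default_factory=dict)


@dataclass
class GTensorResult:
    grid: np.ndarray  # ω, Hartree
    g_tensor: np.ndarray  # (n_freq, 3, 3) complex G̃
    beta: np.ndarray  # (n_freq,)
    delta_epsilon: np.ndarray
    gamma: float
    meta: dict = field(default_factory=dict)


def delta_epsilon_sticks(
    energies, strengths, grid, gamma: float
) -> np.ndarray:
    """Cauchy-broadened Δε(ω) from (ω_n0, R_n0) sticks; linear in each R."""
    energies = np.asarray(energies, dtype=float)
    strengths = np.asarray(strengths, dtype=float)
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for om_n, r_n in zip(energies, strengths):
        out += r_n * cauchy_profile(grid - om_n, gamma)
    return DELTA_EPS_AU * grid * out


def delta_epsilon_cpp(solutions: list[CPPSolution]) -> GTensorResult:
    """Assemble G̃(ω), β(ω) and Δε(ω) from CPP solutions that contain the
    nine (p_a, L_b) response-function values at each frequency."""
    grid = np.array([s.frequency for s in solutions])
    gamma = solutions[0].gamma if solutions else 0.0
    G = np.zeros((len(solutions), 3, 3), dtype=complex)
    for k, sol in enumerate(solutions):
        for a in range(3):
            for b in range(3):
                key = (f"p{a}", f"L{b}")
                if key not in sol.values:
                    raise ValueError(
                        f"missing operator pair {key} in CPP solution"
                    )
                G[k, a, b] = -sol.values[key] / (
                    2.0 * SPEED_OF_LIGHT_AU * sol.frequency
                )
    beta = -np.trace(G.imag, axis1=1, axis2=2) / (3.0 * np.pi)
    deps = 3.0 * DELTA_EPS_AU * grid * beta
    return GTensorResult(
        grid=grid, g_tensor=G, beta=beta, delta_epsilon=deps, gamma=gamma
    )


# --- end-to-end pipelines ------------------------------------------------


def ecd_eigen(
    scf_state,
    n_states: int,
    grid,
    gamma: float,
    origin=None,
    tol: float = 1e-5,
) -> RotatorySpectrum:
    """Eigenstate route: resolve the lowest n states, form velocity-gauge
    rotatory strengths, broaden with the Cauchy profile of HWHM γ (Hartree)."""
    origin = (
        scf_state.molecule.center_of_nuclear_charge()
        if origin is None
        else np.asarray(origin, dtype=float)
    )
    p, L = compute_velocity_gauge_operators(scf_state.basis, origin)
    records = solve_eigenstates(
        scf_state, n_states, momentum=p, angular_momentum=L, tol=tol
    )
    energies = np.array([r.energy for r in records])
    strengths = np.array([rotatory_strength(r) for r in records])
    grid = np.asarray(grid, dtype=float)
    return RotatorySpectrum(
        energies=energies,
        strengths=strengths,
        grid=grid,
        delta_epsilon=delta_epsilon_sticks(energies, strengths, grid, gamma),
        gamma=gamma,
        meta=dict(
            n_states=n_states,
            origin=list(map(float, origin)),
            gamma_ev=gamma * HARTREE_EV,
            route="eigen",
        ),
    )


def ecd_cpp(
    scf_state,
    grid,
    gamma: float,
    origin=None,
    tol: float = 1e-6,
) -> GTensorResult:
    """CPP route: damped response for the nine (p_a, L_b) pairs on the
    frequency grid (Hartree), then Δε from the isotropic average."""
    origin = (
        scf_state.molecule.center_of_nuclear_charge()
        if origin is None
        else np.asarray(origin, dtype=float)
    )
    p, L = compute_velocity_gauge_operators(scf_state.basis, origin)
    ops = {f"p{x}": p[x] for x in range(3)}
    ops.update({f"L{x}": L[x] for x in range(3)})
    pairs = [(f"p{a}", f"L{b}") for a in range(3) for b in range(3)]
    action = HessianAction(scf_state)
    sols = solve_cpp(action, ops, pairs, np.asarray(grid, dtype=float),
                     gamma, tol=tol)
    result = delta_epsilon_cpp(sols)
    result.meta = dict(
        origin=list(map(float, origin)),
        gamma_ev=gamma * HARTREE_EV,
        route="cpp",
        fock_builds=action.counters["fock_builds"],
    )
    return result


# --- I/O -----------------------------------------------------------------


def write_spectrum(
    path_prefix,
    grid,
    delta_epsilon,
    sticks=None,
    meta: dict | None = None,
) -> list[str]:
    """Write ``<prefix>.spectrum.tsv`` (wavelength_nm, energy_ev,
    delta_epsilon), ``<prefix>.sticks.tsv`` (energy_ev, rotatory_strength_au)
    and ``<prefix>.meta.json``."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    grid = np.asarray(grid, dtype=float)
    deps = np.asarray(delta_epsilon, dtype=float)
    written = []

    spath = prefix.with_suffix(".spectrum.tsv")
    with open(spath, "w") as fh:
        fh.write("wavelength_nm\tenergy_ev\tdelta_epsilon\n")
        for om, de in zip(grid, deps):
            ev = om * HARTREE_EV
            fh.write(f"{HC_EV_NM / ev:.6f}\t{ev:.8f}\t{de:.10e}\n")
    written.append(str(spath))

    kpath = prefix.with_suffix(".sticks.tsv")
    with open(kpath, "w") as fh:
        fh.write("energy_ev\trotatory_strength_au\n")
        if sticks is not None:
            for om, r in zip(*sticks):
                fh.write(f"{om * HARTREE_EV:.8f}\t{r:.10e}\n")
    written.append(str(kpath))

    mpath = prefix.with_suffix(".meta.json")
    with open(mpath, "w") as fh:
        json.dump(meta or {}, fh, indent=1, sort_keys=True)
    written.append(str(mpath))
    return written


def read_spectrum(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``.spectrum.tsv`` back: (energy grid in Hartree, Δε)."""
    rows = np.loadtxt(path, skiprows=1)
    rows = np.atleast_2d(rows)
    return rows[:, 1] * EV_TO_HARTREE, rows[:, 2]


__all__ = [
    "rotatory_strength",
    "cauchy_profile",
    "delta_epsilon_sticks",
    "delta_epsilon_cpp",
    "ecd_eigen",
    "ecd_cpp",
    "write_spectrum",
    "read_spectrum",
    "convert_damping",
    "RotatorySpectrum",
    "GTensorResult",
    "DELTA_EPS_AU",
]
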