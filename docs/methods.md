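# Methods

This note records the models, conventions and numerical choices behind
`chirospec`, and what the synthetic fixtures do and do not probe.

## Electronic-structure model

Closed-shell restricted SCF only: the electron count must be positive and
even, the density is D = C<sub>occ</sub>C<sub>occ</sub>ᵀ with
tr(DS) = N/2, and the Fock matrix is

    F = h + 2J − c_x·K − c_lr·K_ω + V_xc

The factor convention (2J − c_x K on a half-normalized density) is stated
explicitly because different codes absorb the closed-shell factor of two
in different places. Total energy: E = tr(D(2h + 2J − c_x K − c_lr K_ω)) +
E_xc + E_nuc, with E_nuc including nucleus–nucleus and nucleus–point-charge
terms; the MM–MM self-energy is a constant of the embedding and excluded.

Methods: `hf` (c_x = 1), `lda-demo` (pure Slater+VWN Kohn–Sham), and
`cam-lda-demo` — CAM-style exact exchange (global α = 0.19 plus
erf-attenuated long-range β = 0.46 at ω = 0.33 a.u.) with Slater exchange
scaled by 1 − α − β and VWN correlation. The range-separated *exact*
exchange is handled exactly through attenuated integrals; the
complementary short-range *DFT* exchange is only approximated at LDA level
with a global scale, which is why the functional carries a `-demo` suffix:
it demonstrates the range-separation machinery, it is not a production
functional.

## Integrals

* **Units.** Bohr/Hartree internally; XYZ and MM-charge files are Å
  (1 Å = 1/0.52917721 Bohr). Cartesian AOs in lexicographic component
  order (s; x,y,z; xx,xy,xz,yy,yz,zz); d shells stay Cartesian (6
  components, no solid-harmonic transformation), so AO counts differ from
  spherical-basis codes (water/def2-SVP is 25 Cartesian AOs here). Every
  contracted Cartesian AO is normalized to unit self-overlap; primitive
  norms separate into an exponent part and a component part, which the
  engine exploits to keep contraction weights separable.
* **One-electron integrals** use the McMurchie–Davidson Hermite expansion
  (E-coefficients; Hermite–Coulomb recursion for nuclear/point-charge
  attraction). They are validated against kernel-transform quadrature
  oracles in the tests. The momentum and angular-momentum matrices are
  returned as their *real* antisymmetric parts (the physical operators are
  −i times these); the angular momentum is taken about a configurable
  origin, defaulting to the center of nuclear charge. Origin independence
  is guaranteed for the final rotatory strengths, not for m̂ itself.
* **Two-electron integrals**: Obara–Saika with all recurrences unrolled at
  first use into straight-line plans per angular class (one output per
  Cartesian component quadruple; self-contained statement lists compiled
  to vectorized NumPy functions and cached in-process). The repository
  commits the generator, not generated code. A plain memoized recursion
  (`eri_reference`) provides the in-package reference; an independent
  quadrature oracle lives in the tests. The Boys function uses three
  regimes (Taylor below 1e-12; series-seeded downward recursion to x = 35;
  erf closed form with upward recursion beyond), accurate to ~1e-14
  relative against mpmath. Attenuated (erf(ωr)/r) integrals rescale the
  Boys sequence by s^{m+1/2} with s = ω²/(ω²+ρ), which follows from
  truncating the Gaussian transform of 1/r at t = ω.

## Screened Fock builds

Primitive pairs are enumerated once per basis, grouped by angular class,
each pair carrying the weighted Schwarz factor
Q = |κκ′|·max<sub>comp</sub>√[μν|μν]. The J build screens quartets with
Q<sub>μν</sub>·Q<sub>λσ</sub>|D<sub>λσ</sub>| against the threshold over
presorted ket lists; for antisymmetric densities J is skipped (it vanishes
identically because [μν|λσ] = [μν|σλ]). The K build scans ordered pairs
with the bound Q<sub>μλ</sub>Q<sub>νσ</sub>·min(D̂<sub>λ</sub>,D̂<sub>σ</sub>)
(D̂ = row maximum of |D|) plus the preLinK elementwise output bound
(Q̃|D|Q̃)<sub>μν</sub>; K elements under the preLinK threshold are left
exactly zero. Both builds exploit bra↔ket quartet symmetry (half the
evaluations, dual accumulation) and the within-pair symmetry via an
M + (±)Mᵀ assembly with half-weighted diagonal pairs.

**Threshold semantics.** The user-facing ERI threshold is an *accuracy
target for the matrices*: because many sub-threshold quartets contribute
additively and each Schwarz product bounds a whole component block, the
internal per-quartet cutoff is threshold/64. With that margin the measured
screened-vs-unscreened error stays within a small single-digit multiple of
the nominal threshold over the 1e-6…1e-12 ladder at desk scale. Defaults:
ERI 1e-12, preLinK 1e-10 — small enough that screening noise stays below
SCF convergence tolerances.

The brute-force O(N⁴) contracted tensor (`contracted_eri_tensor`) is kept
as the oracle; it is practical to ~25 AOs routinely and ~75 AOs once per
session.

## XC integration

Becke fuzzy-cell partition (three smoothing iterations, no atomic-size
adjustment) over atom-centered grids: Gauss–Chebyshev radial points with
the Becke [−1,1]→[0,∞) map and Bragg–Slater-like map radii, and a
Gauss–Legendre(cosθ) × uniform(φ) angular product shell. Levels: coarse
(40, 8), medium (60, 14), fine (80, 16) — medium integrates an off-center
unit Gaussian on a molecular grid to ~1e-6 and the water electron count to
~1e-5. Grid batches come from recursive median bisection of the bounding
box along its longest axis until each batch is below the box threshold
(default 256 points, exposed in config); batches partition the grid
exactly, and E_xc/V_xc are invariant to the box size at 1e-10. Per-batch
AO screening uses conservative shell radial extents against the batch
bounding box. Functionals are local only (Slater exchange; VWN form-V
correlation); no gradient corrections, consistent with the demo scope.

## SCF

Core-Hamiltonian initial guess; DIIS on FDS − SDF with a window of 8;
generalized eigensolver `scipy.linalg.eigh(F, S)` with an overlap
condition-number guard at 1e10. Convergence: |ΔE| < 1e-8 Hartree and
‖ΔD‖_F < 1e-6 within 100 iterations, else an explicit failure with the
last diagnostics. Each iteration logs energy change, density change and
per-stage wall times (ERI, XC, diagonalization); the Fock-build counter
feeds the builds-per-hour performance indicator
(KPI = 3600 × builds / build-seconds).

## Response

Paired RPA structure E[2] = [[A,B],[B,A]], S[2] = diag(1,−1) over
occupied–virtual pairs; all solvers work on the symmetric/antisymmetric
combinations g = X+Y, u = X−Y, whose Hessian actions are auxiliary Fock
builds: symmetric transition densities need J, K and the XC kernel;
antisymmetric ones are exchange-only. The XC kernel is applied by central
finite differences of V_xc along the transition density (step 1e-5 scaled
by the density norm) rather than analytic second derivatives. Property
gradients of the real antisymmetric velocity-gauge operators are u-type
(paired form (v, −v)) and carry the closed-shell √2.

* Eigensolver: Davidson-type subspace iteration; the reduced paired
  problem is solved via the (A−B)^{1/2}(A+B)(A−B)^{1/2} symmetrization;
  preconditioning by orbital-energy differences; modified Gram–Schmidt
  with re-orthogonalization (loss threshold 1e-10); defaults: residual
  1e-5 per root, subspace cap 50× roots. Eigenvectors normalized to
  gᵀu = 1 (X²−Y² = 1).
* CPP: the complex system (A+B)g = z·u, (A−B)u − z·g = −2v at z = ω + iγ
  is projected onto a growing *real* subspace shared across right-hand
  sides and frequencies; new directions are the real and imaginary parts
  of the shifted-preconditioned residuals. The contraction g_A·u_B then
  equals the spectral sum Σ_n t_A t_B [1/(ω_n−z) + 1/(ω_n+z)]·(−1), which
  the tests verify against explicit dense solutions.

## ECD conventions

With tp = ⟨0|∇|n⟩ and tL = ⟨0|(r−O)×∇|n⟩ (real numbers in this code):

* R_n = −(1/2c·ω_n)·tp·tL (a.u., velocity gauge). Origin shifts change tL
  by −d×tp, whose dot product with tp vanishes — origin independence is
  exact, and it is the tested contract. The *global* sign convention of
  Δε (which enantiomer is "positive") cannot be pinned by the internal
  contracts (mirror antisymmetry fixes only the relative sign) and is
  documented here as implemented.
* Cauchy profile normalized on the angular-frequency axis with γ = HWHM
  (default 0.1240 eV ≡ 1000 cm⁻¹; conversions are exact CODATA-based and
  round-trip to 1e-12). The alternative "γ = FWHM" convention was
  rejected to keep the half-maximum test literal.
* Δε(ω) = C₀·ω·Σ_n R_n f(ω−ω_n) in L mol⁻¹ cm⁻¹, with C₀ assembled at
  runtime from CODATA constants as
  (32π³N_A/(3000·ln10·hc)) × (e·a₀·2μ_B in cgs) ≈ 20.5 for ω in Hartree —
  no literature factor is copied; a test checks the assembled magnitude
  and dimensional identities instead.
* CPP route: G̃_ab(ω) = −(1/2cω)⟨⟨p_a;L_b⟩⟩_{ω+iγ},
  β(ω) = −(1/3π)·Tr Im G̃, Δε = 3C₀·ω·β. Near a resonance this reduces to
  the broadened-stick expression with R_n weighted by ω_n rather than ω
  and with antiresonance terms retained — the source of the ~1% residual
  between the two routes that the equivalence test bounds at 2% of the
  peak.

## Synthetic fixtures — what they emulate

* **Water droplets**: rigid TIP3P-geometry monomers (O–H 0.9572 Å,
  ∠104.52°), uniformly random positions/orientations inside the smallest
  sphere at liquid number density 0.0334 Å⁻³ with O–O ≥ 2.5 Å, rejection
  sampling with a bounded retry budget, deterministic per seed. They
  reproduce the 1:2 heavy:hydrogen composition and the pair-distance
  statistics that drive integral screening — which is all the scaling
  experiment measures. They are *not* equilibrated liquid structure: no
  hydrogen-bond network, so absolute energies and spectra of droplets are
  not physical, and passing scaling tests says nothing about the accuracy
  of condensed-phase CD.
* **Chiral fixtures**: H₂O₂ at ±112.5° H–O–O–H dihedral (O–O 1.475 Å,
  O–H 0.9572 Å, ∠OOH 94.8°); the two enantiomers are exact coordinatewise
  mirror images through the xz plane, making the spectrum-negation test an
  exact symmetry check rather than a tolerance comparison. Planar water is
  the achiral control. These are electronic-structure test substrates, not
  spectroscopic benchmarks — STO-3G excitation energies are far too high
  and no vibronic or solvent effects are included.
* The **scaling screening density** is the converged monomer density
  replicated block-diagonally (a superposition-of-monomers proxy, not
  rotated with the molecules); it sets realistic density magnitudes for
  the Q·Q·|D| counting without requiring droplet SCF convergence.

## Problem sizes and solver settings used in the shipped tests

Chosen so the whole suite runs in minutes on one core: STO-3G for all
SCF/response oracles (water: 7 AOs/10 ov-pairs; H₂O₂: 12 AOs/27
ov-pairs), 3-water/def2-SVP (75 Cartesian AOs) for the screening ladder,
droplets of 8–32 waters for scaling counts, 100 quartets per angular
class for integral agreement, and ~30-point frequency grids for spectra.
All are configuration parameters, not limits of the implementation.

## Known limitations

Cartesian-only d functions (no f or higher); no open-shell or
unrestricted reference; LDA-level kernels only (adiabatic, local); no
Tamm–Dancoff mode, quadratic response, gradients, or vibronic structure;
single-process execution (the GPU thread-block design that inspired the
pair-list organization is mirrored only in its screening semantics);
basis-set files ship only H, He, C, N, O.
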