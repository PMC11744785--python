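"""Coulomb (J) and exchange (K) matrix builds in the primitive basis with
Schwarz / density-weighted presorting for J and preLinK elementwise bounds
for K, contracted to the AO basis.

The build is organized exactly as the screening semantics demand — and as a
batched, dense-linear-algebra analogue of a thread-block design:

* primitive-function pairs are expanded once per basis, grouped by
  angular-momentum class, each pair carrying its Schwarz factor
  ``Q = max_comp √[μν|μν]`` (with contraction weights folded in);
* for J, bra pairs are screened against ket pairs presorted by
  ``Q_λσ·|D_λσ|`` and only quartets with ``Q_μν Q_λσ |D|  ≥ τ`` are
  evaluated; antisymmetric densities skip the J build entirely (the J of an
  antisymmetric density vanishes identically by [μν|λσ] = [μν|σλ]);
* for K, ordered pairs [μλ| scan ordered pairs |νσ], with a quartet bound
  ``Q_μλ Q_νσ min(D̂_λ, D̂_σ)`` (D̂ = density row maximum) and the preLinK
  elementwise output bound ``(Q̃ |D| Q̃)_μν`` deciding which K elements are
  formed at all — elements below the preLinK threshold are left exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import AOBasis, cartesian_components, double_factorial, n_cartesian
from .eri import eri_class_batch

_CHUNK = 1 << 21  # max quartets masked per rectangle chunk

# The ERI screening threshold is an accuracy target for the resulting J/K
# matrices.  Since many skipped quartets contribute additively (and each
# Schwarz product bounds a whole component block), the internal per-quartet
# cutoff carries a fixed safety margin so that the matrix error stays within
# a small multiple of the nominal threshold at desk scale.
_SCREEN_MARGIN = 64.0


def component_norms(l: int) -> np.ndarray:
    """Angular part of the primitive normalization, per Cartesian component."""
    return np.array(
        [
            1.0
            / np.sqrt(
                double_factorial(2 * lx - 1)
                * double_factorial(2 * ly - 1)
                * double_factorial(2 * lz - 1)
            )
            for lx, ly, lz in cartesian_components(l)
        ]
    )


def radial_norm(alpha: np.ndarray, l: int) -> np.ndarray:
    """Exponent-dependent part of the primitive normalization."""
    return (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)


@dataclass
class DensityMatrix:
    """An AO density with its symmetry tag ('symmetric' | 'antisymmetric')."""

    matrix: np.ndarray
    tag: str

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if self.tag == "symmetric":
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError("density tagged symmetric is not symmetric")
            m = 0.5 * (m + m.T)
        elif self.tag == "antisymmetric":
            if not np.allclose(m, -m.T, atol=1e-10):
                raise ValueError("density tagged antisymmetric is not")
            m = 0.5 * (m - m.T)
        else:
            raise ValueError(f"unknown symmetry tag {self.tag!r}")
        self.matrix = m

    @property
    def sign(self) -> float:
        return 1.0 if self.tag == "symmetric" else -1.0


@dataclass
class ScreeningConfig:
    eri_threshold: float = 1e-12
    prelink_threshold: float = 1e-10
    enabled: bool = True

    def __post_init__(self):
        if self.eri_threshold < 0 or self.prelink_threshold < 0:
            raise ValueError("screening thresholds must be >= 0")


@dataclass
class PairBlock:
    """All primitive pairs of one angular class, flattened into arrays."""

    l1: int
    l2: int
    A: np.ndarray  # (n, 3) center of first member
    B: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    kappa: np.ndarray  # product of contracted-basis radial coefficients
    deg: np.ndarray  # 2 for distinct unordered pairs, 1 for identical
    ao1: np.ndarray  # base AO index of first member's shell
    ao2: np.ndarray
    Q: np.ndarray = field(default=None)  # weighted Schwarz factor, filled later

    @property
    def n(self) -> int:
        return self.alpha.size


def _shell_kappas(basis: AOBasis):
    """Per-shell arrays of radial contraction coefficients c_k·f(α_k, L)
    (contracted normalization folded in; component norms handled separately)."""
    from .basis import contracted_self_overlap, primitive_norm

    out = []
    for sh in basis.shells:
        comp0 = cartesian_components(sh.l)[0]
        c_eff = sh.coefficients * np.array(
            [primitive_norm(a, *comp0) for a in sh.exponents]
        )
        so = contracted_self_overlap(sh.exponents, c_eff, comp0)
        g0 = component_norms(sh.l)[0]
        # raw-primitive coefficient = c·f·g/√so; store the g-independent part
        out.append(sh.coefficients * radial_norm(sh.exponents, sh.l) / np.sqrt(so))
    return out


class TwoElectronEngine:
    """Precomputed pair lists, Schwarz factors and sweep machinery for one
    AO basis.  Coulomb/exchange builds for any number of densities reuse the
    same pair data."""

    def __init__(self, basis: AOBasis):
        self.basis = basis
        self.nao = basis.n_ao
        coords = basis.molecule.coordinates
        kappas = _shell_kappas(basis)
        self._kappas = kappas

        shell_ao0 = []
        ao = 0
        for sh in basis.shells:
            shell_ao0.append(ao)
            ao += n_cartesian(sh.l)
        self.shell_ao0 = shell_ao0

        # unordered shell/primitive pair lists grouped by (l1, l2)
        raw: dict[tuple, list] = {}
        nsh = len(basis.shells)
        self.shell_pairs = []
        for s1 in range(nsh):
            for s2 in range(s1, nsh):
                sh1, sh2 = basis.shells[s1], basis.shells[s2]
                self.shell_pairs.append((s1, s2))
                A = coords[sh1.center]
                B = coords[sh2.center]
                for k in range(sh1.n_primitives):
                    lstart = k if s1 == s2 else 0
                    for l in range(lstart, sh2.n_primitives):
                        deg = 1.0 if (s1 == s2 and k == l) else 2.0
                        raw.setdefault((sh1.l, sh2.l), []).append(
                            (
                                A, B,
                                sh1.exponents[k], sh2.exponents[l],
                                kappas[s1][k] * kappas[s2][l],
                                deg, shell_ao0[s1], shell_ao0[s2],
                            )
                        )
        self.blocks: dict[tuple, PairBlock] = {}
        for key, rows in raw.items():
            self.blocks[key] = PairBlock(
                l1=key[0],
                l2=key[1],
                A=np.array([r[0] for r in rows]),
                B=np.array([r[1] for r in rows]),
                alpha=np.array([r[2] for r in rows]),
                beta=np.array([r[3] for r in rows]),
                kappa=np.array([r[4] for r in rows]),
                deg=np.array([r[5] for r in rows]),
                ao1=np.array([r[6] for r in rows], dtype=int),
                ao2=np.array([r[7] for r in rows], dtype=int),
            )
        self._compute_schwarz()
        self._ordered = None
        self._contracted_schwarz = None

    # -- Schwarz factors --------------------------------------------------

    def _compute_schwarz(self):
        for key, blk in self.blocks.items():
            l1, l2 = key
            g1, g2 = component_norms(l1), component_norms(l2)
            n1, n2 = g1.size, g2.size
            # diagonal component quadruples (ca, cb, ca, cb)
            idx = [
                ((ca * n2 + cb) * n1 + ca) * n2 + cb
                for ca in range(n1)
                for cb in range(n2)
            ]
            gg = np.outer(g1, g2).ravel()[:, None]
            Q = np.empty(blk.n)
            step = max(1, _CHUNK // (n1 * n2 * n1 * n2))
            for st in range(0, blk.n, step):
                sl = slice(st, min(st + step, blk.n))
                vals = eri_class_batch(
                    l1, l2, l1, l2,
                    blk.A[sl], blk.B[sl], blk.A[sl], blk.B[sl],
                    blk.alpha[sl], blk.beta[sl], blk.alpha[sl], blk.beta[sl],
                )
                diag = np.clip(vals[idx], 0.0, None)
                Q[sl] = np.max(gg * np.sqrt(diag), axis=0)
            blk.Q = np.abs(blk.kappa) * Q

    def contracted_schwarz(self) -> np.ndarray:
        """N×N matrix of contracted-pair Schwarz factors √[μν|μν]."""
        if self._contracted_schwarz is not None:
            return self._contracted_schwarz
        basis = self.basis
        Qc = np.zeros((self.nao, self.nao))
        for s1, s2 in self.shell_pairs:
            blk = self._pair_slice(s1, s2)
            l1 = basis.shells[s1].l
            l2 = basis.shells[s2].l
            g1, g2 = component_norms(l1), component_norms(l2)
            n1, n2 = g1.size, g2.size
            npair = blk["alpha"].size
            i1, i2 = np.meshgrid(np.arange(npair), np.arange(npair), indexing="ij")
            i1, i2 = i1.ravel(), i2.ravel()
            vals = eri_class_batch(
                l1, l2, l1, l2,
                blk["A"][i1], blk["B"][i1], blk["A"][i2], blk["B"][i2],
                blk["alpha"][i1], blk["beta"][i1],
                blk["alpha"][i2], blk["beta"][i2],
            )
            w = blk["kappa"][i1] * blk["kappa"][i2]
            contr = vals @ w  # (ncomp_quad,)
            contr = contr.reshape(n1, n2, n1, n2)
            a0, b0 = self.shell_ao0[s1], self.shell_ao0[s2]
            for ca in range(n1):
                for cb in range(n2):
                    v = contr[ca, cb, ca, cb] * (g1[ca] * g2[cb]) ** 2
                    q = np.sqrt(max(v, 0.0))
                    Qc[a0 + ca, b0 + cb] = max(Qc[a0 + ca, b0 + cb], q)
                    Qc[b0 + cb, a0 + ca] = Qc[a0 + ca, b0 + cb]
        self._contracted_schwarz = Qc
        return Qc

    def _pair_slice(self, s1, s2):
        """All primitive pairs (both exponent orders collapsed to k<=l only
        when s1==s2) of one shell pair, as plain arrays."""
        sh1, sh2 = self.basis.shells[s1], self.basis.shells[s2]
        kappas = self._kappas
        coords = self.basis.molecule.coordinates
        rows = {"A": [], "B": [], "alpha": [], "beta": [], "kappa": []}
        for k in range(sh1.n_primitives):
            for l in range(sh2.n_primitives):
                rows["A"].append(coords[sh1.center])
                rows["B"].append(coords[sh2.center])
                rows["alpha"].append(sh1.exponents[k])
                rows["beta"].append(sh2.exponents[l])
                rows["kappa"].append(kappas[s1][k] * kappas[s2][l])
        return {k: np.array(v) for k, v in rows.items()}

    # -- ordered pair lists for K -----------------------------------------

    def _ordered_blocks(self) -> dict[tuple, PairBlock]:
        """Ordered primitive pair lists (both orientations of every pair),
        grouped by (l_row, l_sum); used by the exchange build."""
        if self._ordered is not None:
            return self._ordered
        out: dict[tuple, dict] = {}

        def push(key, A, B, al, be, ka, q, ao1, ao2):
            d = out.setdefault(
                key,
                {"A": [], "B": [], "alpha": [], "beta": [], "kappa": [],
                 "Q": [], "ao1": [], "ao2": []},
            )
            d["A"].append(A)
            d["B"].append(B)
            d["alpha"].append(al)
            d["beta"].append(be)
            d["kappa"].append(ka)
            d["Q"].append(q)
            d["ao1"].append(ao1)
            d["ao2"].append(ao2)

        for key, blk in self.blocks.items():
            for i in range(blk.n):
                args = (
                    blk.A[i], blk.B[i], blk.alpha[i], blk.beta[i],
                    blk.kappa[i], blk.Q[i], blk.ao1[i], blk.ao2[i],
                )
                push((blk.l1, blk.l2), *args)
                if blk.deg[i] > 1.5:
                    push(
                        (blk.l2, blk.l1),
                        blk.B[i], blk.A[i], blk.beta[i], blk.alpha[i],
                        blk.kappa[i], blk.Q[i], blk.ao2[i], blk.ao1[i],
                    )
        blocks = {}
        for key, d in out.items():
            blocks[key] = PairBlock(
                l1=key[0], l2=key[1],
                A=np.array(d["A"]), B=np.array(d["B"]),
                alpha=np.array(d["alpha"]), beta=np.array(d["beta"]),
                kappa=np.array(d["kappa"]),
                deg=np.ones(len(d["A"])),
                ao1=np.array(d["ao1"], dtype=int),
                ao2=np.array(d["ao2"], dtype=int),
                Q=np.array(d["Q"]),
            )
        self._ordered = blocks
        return blocks

    # -- J build -----------------------------------------------------------

    def build_J(self, density: DensityMatrix,
                screening: ScreeningConfig | None = None,
                omega: float | None = None,
                counters: dict | None = None) -> np.ndarray:
        """Coulomb matrix J_μν = Σ_λσ [μν|λσ] D_λσ with Schwarz/presort
        screening; returns the zero matrix for antisymmetric densities."""
        screening = screening or ScreeningConfig()
        D = density.matrix
        if density.tag == "antisymmetric":
            return np.zeros((self.nao, self.nao))
        tau = screening.eri_threshold / _SCREEN_MARGIN if screening.enabled else 0.0

        classes = sorted(self.blocks)
        # per-block ket data: density patches and screening keys
        patch, dmax, gouter = {}, {}, {}
        for key in classes:
            blk = self.blocks[key]
            g1, g2 = component_norms(blk.l1), component_norms(blk.l2)
            gg = np.outer(g1, g2).ravel()
            comps = [
                (i, j) for i in range(g1.size) for j in range(g2.size)
            ]
            dpatch = np.empty((blk.n, len(comps)))
            for m, (i, j) in enumerate(comps):
                dpatch[:, m] = D[blk.ao1 + i, blk.ao2 + j]
            dmax[key] = np.max(np.abs(dpatch), axis=1)
            patch[key] = dpatch * gg[None, :] * (blk.deg * blk.kappa)[:, None]
            gouter[key] = gg

        M = np.zeros((self.nao, self.nao))
        for i1, c1 in enumerate(classes):
            for c2 in classes[i1:]:
                self._sweep_J(
                    c1, c2, patch, dmax, gouter, tau, M, omega, counters
                )
        J = M + M.T
        return J

    def _sweep_J(self, c1, c2, patch, dmax, gouter, tau, M, omega, counters):
        b1, b2 = self.blocks[c1], self.blocks[c2]
        # presort ket side by Q·|D| (descending) for reproducible pair lists
        ord2 = np.argsort(-(b2.Q * dmax[c2]), kind="stable")
        key2 = (b2.Q * dmax[c2])[ord2]
        key2b = b2.Q[ord2]
        chunk = max(1, _CHUNK // max(b2.n, 1))
        for st in range(0, b1.n, chunk):
            sl = slice(st, min(st + chunk, b1.n))
            q1 = b1.Q[sl][:, None]
            qd1 = (b1.Q[sl] * dmax[c1][sl])[:, None]
            # quartet needed for either the bra-output or ket-output update
            keep = (q1 * key2[None, :] >= tau) | (qd1 * key2b[None, :] >= tau)
            if c1 == c2:
                gidx1 = np.arange(sl.start, sl.stop)
                keep &= gidx1[:, None] <= ord2[None, :]
            ii, jj = np.nonzero(keep)
            if ii.size == 0:
                continue
            if counters is not None:
                counters["quartets"] = counters.get("quartets", 0) + ii.size
            i1 = ii + sl.start
            i2 = ord2[jj]
            vals = eri_class_batch(
                b1.l1, b1.l2, b2.l1, b2.l2,
                b1.A[i1], b1.B[i1], b2.A[i2], b2.B[i2],
                b1.alpha[i1], b1.beta[i1], b2.alpha[i2], b2.beta[i2],
                omega=omega,
            )
            n1c = n_cartesian(b1.l1) * n_cartesian(b1.l2)
            n2c = n_cartesian(b2.l1) * n_cartesian(b2.l2)
            V = vals.reshape(n1c, n2c, -1)
            diag = i1 * 0
            if c1 == c2:
                diag = (i1 == i2).astype(float)
            half = 1.0 - 0.5 * diag
            # contribution to bra outputs: Σ_ket V·patch2
            contr1 = np.einsum("mkq,qk->mq", V, patch[c2][i2]) * (
                half * 0.5 * b1.deg[i1] * b1.kappa[i1]
            )
            contr1 *= gouter[c1][:, None]
            self._scatter(M, b1, i1, contr1)
            # contribution to ket outputs: Σ_bra V·patch1
            contr2 = np.einsum("mkq,qm->kq", V, patch[c1][i1]) * (
                half * 0.5 * b2.deg[i2] * b2.kappa[i2]
            )
            contr2 *= gouter[c2][:, None]
            self._scatter(M, b2, i2, contr2)

    @staticmethod
    def _scatter(M, blk, idx, contrib):
        n1 = n_cartesian(blk.l1)
        n2 = n_cartesian(blk.l2)
        m = 0
        for i in range(n1):
            rows = blk.ao1[idx] + i
            for j in range(n2):
                np.add.at(M, (rows, blk.ao2[idx] + j), contrib[m])
                m += 1

    # -- preLinK bound and K build ----------------------------------------

    def prelink_bound(self, density: DensityMatrix) -> np.ndarray:
        """Elementwise upper bound on |K(D)| via the matrix product
        Q̃ |D| Q̃ of the contracted Schwarz matrix and the density magnitude."""
        Qc = self.contracted_schwarz()
        return Qc @ np.abs(density.matrix) @ Qc

    def build_K(self, density: DensityMatrix,
                screening: ScreeningConfig | None = None,
                omega: float | None = None,
                counters: dict | None = None) -> np.ndarray:
        """Exchange matrix K_μν = Σ_λσ [μλ|νσ] D_λσ.  Inherits the density's
        symmetry; elements whose preLinK bound is below threshold stay 0."""
        screening = screening or ScreeningConfig()
        D = density.matrix
        sign = density.sign
        tau = screening.eri_threshold / _SCREEN_MARGIN if screening.enabled else 0.0
        tau_plk = screening.prelink_threshold if screening.enabled else 0.0

        bound = self.prelink_bound(density) if tau_plk > 0 else None
        blocks = self._ordered_blocks()
        classes = sorted(blocks)

        # density row maxima per ordered pair (over the summed function)
        rowmax = np.max(np.abs(D), axis=1)
        dmax, keepmask = {}, {}
        for key in classes:
            blk = blocks[key]
            n2 = n_cartesian(blk.l2)
            dm = np.zeros(blk.n)
            for j in range(n2):
                dm = np.maximum(dm, rowmax[blk.ao2 + j])
            dmax[key] = dm
            if bound is not None:
                n1 = n_cartesian(blk.l1)
                bm = np.max(bound, axis=1)
                km = np.zeros(blk.n, dtype=bool)
                for i in range(n1):
                    km |= bm[blk.ao1 + i] >= tau_plk
                keepmask[key] = km
            else:
                keepmask[key] = np.ones(blk.n, dtype=bool)

        self._D_current = D
        M = np.zeros((self.nao, self.nao))
        for i1, c1 in enumerate(classes):
            for c2 in classes[i1:]:
                self._sweep_K(
                    blocks, c1, c2, dmax, keepmask, tau, M, omega, counters
                )
        self._D_current = None
        K = M + sign * M.T
        if bound is not None:
            K[bound < tau_plk] = 0.0
        return K

    def _sweep_K(self, blocks, c1, c2, dmax, keepmask, tau, M, omega,
                 counters):
        b1, b2 = blocks[c1], blocks[c2]
        g1a, g1b = component_norms(b1.l1), component_norms(b1.l2)
        g2a, g2b = component_norms(b2.l1), component_norms(b2.l2)
        k1 = np.nonzero(keepmask[c1])[0]
        k2 = np.nonzero(keepmask[c2])[0]
        if k1.size == 0 or k2.size == 0:
            return
        q1 = b1.Q[k1]
        q2 = b2.Q[k2]
        d1 = dmax[c1][k1]
        d2 = dmax[c2][k2]
        chunk = max(1, _CHUNK // max(k2.size, 1))
        D = None  # filled per survivors
        for st in range(0, k1.size, chunk):
            sl = slice(st, min(st + chunk, k1.size))
            keep = (
                q1[sl][:, None] * q2[None, :]
                * np.minimum(d1[sl][:, None], d2[None, :])
                >= tau
            )
            if c1 == c2:
                keep &= k1[sl][:, None] <= k2[None, :]
            ii, jj = np.nonzero(keep)
            if ii.size == 0:
                continue
            if counters is not None:
                counters["quartets"] = counters.get("quartets", 0) + ii.size
            i1 = k1[ii + sl.start]
            i2 = k2[jj]
            vals = eri_class_batch(
                b1.l1, b1.l2, b2.l1, b2.l2,
                b1.A[i1], b1.B[i1], b2.A[i2], b2.B[i2],
                b1.alpha[i1], b1.beta[i1], b2.alpha[i2], b2.beta[i2],
                omega=omega,
            )
            n1a, n1b = g1a.size, g1b.size
            n2a, n2b = g2a.size, g2b.size
            V = vals.reshape(n1a, n1b, n2a, n2b, -1)
            half = np.ones(i1.size)
            if c1 == c2:
                half[i1 == i2] = 0.5
            w = half * b1.kappa[i1] * b2.kappa[i2]
            # density patch over the summed functions: D[ao_λ + cb, ao_σ + cd]
            Dmat = _gather_patch(
                self._D_current, b1.ao2[i1], b2.ao2[i2], n1b, n2b
            )
            gbd = np.outer(g1b, g2b)
            contrib = np.einsum(
                "abcdq,bdq->acq", V, Dmat * gbd[:, :, None]
            ) * w[None, None, :]
            contrib *= np.outer(g1a, g2a)[:, :, None]
            for a in range(n1a):
                rows = b1.ao1[i1] + a
                for cidx in range(n2a):
                    np.add.at(
                        M, (rows, b2.ao1[i2] + cidx), contrib[a, cidx]
                    )

    # build_K stashes the density for its sweeps
    _D_current: np.ndarray = None


def _gather_patch(D, rows0, cols0, n1, n2):
    """(n1, n2, nq) patch of D at per-quartet base offsets."""
    out = np.empty((n1, n2, rows0.size))
    for a in range(n1):
        for b in range(n2):
            out[a, b] = D[rows0 + a, cols0 + b]
    return out


def contracted_eri_tensor(basis: AOBasis) -> np.ndarray:
    """Full contracted-basis ERI tensor (μν|λσ) — the O(N⁴) unscreened
    oracle for the screened builds.  Only practical for small systems."""
    engine = TwoElectronEngine(basis)
    nao = basis.n_ao
    shells = basis.shells
    ao0 = engine.shell_ao0
    T = np.zeros((nao, nao, nao, nao))
    sp = engine.shell_pairs
    cached = {
        (s1, s2): engine._pair_slice(s1, s2) for s1, s2 in sp
    }
    for u, (s1, s2) in enumerate(sp):
        p1 = cached[(s1, s2)]
        l1, l2 = shells[s1].l, shells[s2].l
        g1, g2 = component_norms(l1), component_norms(l2)
        for (s3, s4) in sp[u:]:
            p2 = cached[(s3, s4)]
            l3, l4 = shells[s3].l, shells[s4].l
            g3, g4 = component_norms(l3), component_norms(l4)
            n1, n2v = p1["alpha"].size, p2["alpha"].size
            i1, i2 = np.meshgrid(np.arange(n1), np.arange(n2v), indexing="ij")
            i1, i2 = i1.ravel(), i2.ravel()
            vals = eri_class_batch(
                l1, l2, l3, l4,
                p1["A"][i1], p1["B"][i1], p2["A"][i2], p2["B"][i2],
                p1["alpha"][i1], p1["beta"][i1],
                p2["alpha"][i2], p2["beta"][i2],
            )
            w = p1["kappa"][i1] * p2["kappa"][i2]
            block = (vals @ w).reshape(
                g1.size, g2.size, g3.size, g4.size
            )
            block = block * np.einsum("a,b,c,d->abcd", g1, g2, g3, g4)
            ra = slice(ao0[s1], ao0[s1] + g1.size)
            rb = slice(ao0[s2], ao0[s2] + g2.size)
            rc = slice(ao0[s3], ao0[s3] + g3.size)
            rd = slice(ao0[s4], ao0[s4] + g4.size)
            T[ra, rb, rc, rd] = block
            T[rb, ra, rc, rd] = block.transpose(1, 0, 2, 3)
            T[ra, rb, rd, rc] = block.transpose(0, 1, 3, 2)
            T[rb, ra, rd, rc] = block.transpose(1, 0, 3, 2)
            T[rc, rd, ra, rb] = block.transpose(2, 3, 0, 1)
            T[rd, rc, ra, rb] = block.transpose(3, 2, 0, 1)
            T[rc, rd, rb, ra] = block.transpose(2, 3, 1, 0)
            T[rd, rc, rb, ra] = block.transpose(3, 2, 1, 0)
    return T


def brute_force_J(T: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.einsum("mnls,ls->mn", T, D)


def brute_force_K(T: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.einsum("mlns,ls->mn", T, D)


@dataclass
class FockWeights:
    """Assembly coefficients for the two-electron Fock contribution.

    ``F_2e = 2 J − c_x K − c_lr K_ω`` for symmetric densities (closed-shell
    convention; the J term is absent for antisymmetric densities). CAM-type
    range separation: short-range exchange fraction α at r₁₂ → 0, total
    long-range fraction α + β.
    """

    coulomb: float = 1.0
    exchange: float = 1.0  # c_x (global HF-type exchange)
    lr_exchange: float = 0.0  # c_lr (erf-attenuated exchange)
    omega: float | None = None

    def __post_init__(self):
        if self.exchange + self.lr_exchange < 0:
            raise ValueError("total exchange weight must be non-negative")
        if self.lr_exchange != 0.0 and not (self.omega and self.omega > 0):
            raise ValueError("attenuated exchange requires omega > 0")


def assemble_two_electron_fock(
    engine: TwoElectronEngine,
    density: DensityMatrix,
    weights: FockWeights,
    screening: ScreeningConfig | None = None,
    counters: dict | None = None,
) -> np.ndarray:
    """Two-electron Fock contribution 2J − c_x·K − c_lr·K_ω."""
    F = np.zeros((engine.nao, engine.nao))
    if weights.coulomb != 0.0:
        F += 2.0 * weights.coulomb * engine.build_J(
            density, screening, counters=counters
        )
    if weights.exchange != 0.0:
        F -= weights.exchange * engine.build_K(
            density, screening, counters=counters
        )
    if weights.lr_exchange != 0.0:
        F -= weights.lr_exchange * engine.build_K(
            density, screening, omega=weights.omega, counters=counters
        )
    if counters is not None:
        counters["fock_builds"] = counters.get("fock_builds", 0) + 1
    return F

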