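"""Two-electron repulsion integrals over primitive Cartesian Gaussians.

The engine follows the Obara–Saika scheme with all vertical and horizontal
recurrences explicitly unrolled: for each angular-momentum class
``[La Lb | Lc Ld]`` a straight-line *plan* is auto-generated once (and
cached) that evaluates every Cartesian component quadruple of the class from
Boys-function values and geometric factors, with no reference to quantities
outside the plan.  The same recurrences are also available as a plain
memoized recursion (`eri_reference`) which serves as the in-package
reference evaluator for the generated plans.

Integrals are over *unnormalized* Cartesian primitives
``(x−Ax)^lx (y−Ay)^ly (z−Az)^lz exp(−α r_A²)``; normalization is applied by
callers (see `basis.primitive_norm`).

Range separation: the long-range kernel erf(ω r₁₂)/r₁₂ is obtained from the
same plans by rescaling the Boys sequence,
``F_m(T) → s^{m+1/2} F_m(sT)`` with ``s = ω²/(ω² + ρ)``, which follows from
truncating the Gaussian-transform integration of 1/r₁₂ at t = ω.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .basis import cartesian_components, n_cartesian
from .boys import boys

MAX_L = 2


# --- kernel-class enumeration -------------------------------------------


@dataclass(frozen=True)
class KernelClass:
    """An angular-momentum class of the J or K contraction kernels.

    For ``mode="coulomb"`` both the bra and ket pair classes are unordered
    (La ≤ Lb, Lc ≤ Ld).  For ``mode="exchange"`` the output-index pair
    (first members of bra and ket) is unordered while the summed pair runs
    over all ordered combinations, mirroring the distinct contraction
    pattern of the exchange matrix.
    """

    bra: tuple[int, int]
    ket: tuple[int, int]
    mode: str


def enumerate_kernel_classes(l_max: int, mode: str) -> list[KernelClass]:
    """All distinct J or K kernel classes up to ``l_max``.

    Coulomb: ((l_max+1)(l_max+2)/2)² classes — 9 up to p, 36 up to d.
    Exchange: ((l_max+1)(l_max+2)/2)·(l_max+1)² classes — 12 up to p, 54 up
    to d.
    """
    if l_max not in (0, 1, 2):
        raise ValueError(f"unsupported l_max {l_max}")
    if mode not in ("coulomb", "exchange"):
        raise ValueError(f"unknown mode {mode!r}")
    unordered = [
        (la, lb) for la in range(l_max + 1) for lb in range(la, l_max + 1)
    ]
    out = []
    if mode == "coulomb":
        for bra in unordered:
            for ket in unordered:
                out.append(KernelClass(bra, ket, mode))
    else:
        ordered = list(product(range(l_max + 1), repeat=2))
        for bra in unordered:
            for ket in ordered:
                out.append(KernelClass(bra, ket, mode))
    return out


# --- recursive reference evaluator --------------------------------------


def _dec(t: tuple[int, int, int], i: int) -> tuple[int, int, int]:
    out = list(t)
    out[i] -= 1
    return tuple(out)


def _first_axis(t) -> int:
    for i in range(3):
        if t[i] > 0:
            return i
    raise ValueError("zero tuple")


class _QuartetGeometry:
    """Scalar geometric factors shared by all components of one quartet."""

    def __init__(self, A, B, C, D, a, b, c, d, omega=None, m_max=12):
        A, B, C, D = (np.asarray(v, dtype=float) for v in (A, B, C, D))
        p, q = a + b, c + d
        P = (a * A + b * B) / p
        Q = (c * C + d * D) / q
        W = (p * P + q * Q) / (p + q)
        rho = p * q / (p + q)
        T = rho * np.dot(P - Q, P - Q)
        kab = np.exp(-a * b / p * np.dot(A - B, A - B))
        kcd = np.exp(-c * d / q * np.dot(C - D, C - D))
        self.pref = 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q)) * kab * kcd
        if omega is None:
            self.F = boys(m_max, T)
        else:
            s = omega**2 / (omega**2 + rho)
            self.F = s ** (np.arange(m_max + 1) + 0.5) * boys(m_max, s * T)
        self.PA = P - A
        self.WP = W - P
        self.QC = Q - C
        self.WQ = W - Q
        self.AB = A - B
        self.CD = C - D
        self.i2p = 0.5 / p
        self.i2q = 0.5 / q
        self.i2pq = 0.5 / (p + q)
        self.rop = rho / p
        self.roq = rho / q


def _eri_recursive(g: _QuartetGeometry, a, b, c, d, m, memo) -> float:
    key = (a, b, c, d, m)
    if key in memo:
        return memo[key]
    if any(v > 0 for v in d):
        i = _first_axis(d)
        val = _eri_recursive(
            g, a, b, tuple(np.add(c, np.eye(3, dtype=int)[i])), _dec(d, i), m, memo
        ) + g.CD[i] * _eri_recursive(g, a, b, c, _dec(d, i), m, memo)
    elif any(v > 0 for v in b):
        i = _first_axis(b)
        val = _eri_recursive(
            g, tuple(np.add(a, np.eye(3, dtype=int)[i])), _dec(b, i), c, d, m, memo
        ) + g.AB[i] * _eri_recursive(g, a, _dec(b, i), c, d, m, memo)
    elif any(v > 0 for v in c):
        i = _first_axis(c)
        cm = _dec(c, i)
        val = g.QC[i] * _eri_recursive(g, a, b, cm, d, m, memo)
        val += g.WQ[i] * _eri_recursive(g, a, b, cm, d, m + 1, memo)
        if cm[i] > 0:
            cmm = _dec(cm, i)
            val += (
                cm[i]
                * g.i2q
                * (
                    _eri_recursive(g, a, b, cmm, d, m, memo)
                    - g.roq * _eri_recursive(g, a, b, cmm, d, m + 1, memo)
                )
            )
        if a[i] > 0:
            val += (
                a[i]
                * g.i2pq
                * _eri_recursive(g, _dec(a, i), b, cm, d, m + 1, memo)
            )
    elif any(v > 0 for v in a):
        i = _first_axis(a)
        am = _dec(a, i)
        val = g.PA[i] * _eri_recursive(g, am, b, c, d, m, memo)
        val += g.WP[i] * _eri_recursive(g, am, b, c, d, m + 1, memo)
        if am[i] > 0:
            amm = _dec(am, i)
            val += (
                am[i]
                * g.i2p
                * (
                    _eri_recursive(g, amm, b, c, d, m, memo)
                    - g.rop * _eri_recursive(g, amm, b, c, d, m + 1, memo)
                )
            )
    else:
        val = g.pref * g.F[m]
    memo[key] = val
    return val


def eri_reference(comp_a, comp_b, comp_c, comp_d, A, B, C, D, a, b, c, d,
                  omega: float | None = None) -> float:
    """One primitive ERI component by plain memoized Obara–Saika recursion.

    This is the reference path the unrolled plans are validated against.
    Components are Cartesian exponent tuples; centers in Bohr; integrals
    over unnormalized primitives.
    """
    m_max = sum(comp_a) + sum(comp_b) + sum(comp_c) + sum(comp_d)
    g = _QuartetGeometry(A, B, C, D, a, b, c, d, omega=omega, m_max=m_max)
    return float(
        _eri_recursive(
            g, tuple(comp_a), tuple(comp_b), tuple(comp_c), tuple(comp_d), 0, {}
        )
    )


# --- unrolled plans ------------------------------------------------------

_ZERO = (0, 0, 0)
_INPUT_NAMES = (
    "PA0,PA1,PA2,WP0,WP1,WP2,QC0,QC1,QC2,WQ0,WQ1,WQ2,"
    "AB0,AB1,AB2,CD0,CD1,CD2,i2p,i2q,i2pq,rop,roq,pref,F"
)


@dataclass
class UnrolledPlan:
    """A straight-line evaluation plan for one angular-momentum class.

    ``statements`` is an ordered list of ``(name, expression)`` pairs over
    the geometric inputs and Boys values; ``outputs`` maps each Cartesian
    component quadruple of the class to the variable holding its value. The
    plan is self-contained: expressions reference only plan inputs and
    earlier plan statements.
    """

    key: tuple[int, int, int, int]
    statements: list[tuple[str, str]]
    outputs: list[tuple[tuple, str]]
    m_max: int

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    def to_source(self) -> str:
        name = "plan_{}{}{}{}".format(*self.key)
        lines = [f"def {name}({_INPUT_NAMES}):"]
        for var, expr in self.statements:
            lines.append(f"    {var} = {expr}")
        out = ", ".join(var for _, var in self.outputs)
        lines.append(f"    return ({out},)")
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "class": list(self.key),
            "m_max": self.m_max,
            "statements": [list(s) for s in self.statements],
            "outputs": [[list(map(list, comp)), var] for comp, var in self.outputs],
        }


class _Tracer:
    """Runs the Obara–Saika recursion symbolically to build a plan."""

    def __init__(self):
        self.memo: dict[tuple, str] = {}
        self.statements: list[tuple[str, str]] = []
        self.m_max = 0

    def _new(self, expr: str) -> str:
        var = f"v{len(self.statements)}"
        self.statements.append((var, expr))
        return var

    def get(self, a, b, c, d, m) -> str:
        key = (a, b, c, d, m)
        if key in self.memo:
            return self.memo[key]
        if any(v > 0 for v in d):
            i = _first_axis(d)
            cp = tuple(np.add(c, np.eye(3, dtype=int)[i]))
            dm = _dec(d, i)
            expr = (
                f"{self.get(a, b, cp, dm, m)}"
                f" + CD{i}*{self.get(a, b, c, dm, m)}"
            )
        elif any(v > 0 for v in b):
            i = _first_axis(b)
            ap = tuple(np.add(a, np.eye(3, dtype=int)[i]))
            bm = _dec(b, i)
            expr = (
                f"{self.get(ap, bm, c, d, m)}"
                f" + AB{i}*{self.get(a, bm, c, d, m)}"
            )
        elif any(v > 0 for v in c):
            i = _first_axis(c)
            cm = _dec(c, i)
            expr = (
                f"QC{i}*{self.get(a, b, cm, d, m)}"
                f" + WQ{i}*{self.get(a, b, cm, d, m + 1)}"
            )
            if cm[i] > 0:
                cmm = _dec(cm, i)
                expr += (
                    f" + {float(cm[i])}*i2q*({self.get(a, b, cmm, d, m)}"
                    f" - roq*{self.get(a, b, cmm, d, m + 1)})"
                )
            if a[i] > 0:
                am = _dec(a, i)
                expr += f" + {float(a[i])}*i2pq*{self.get(am, b, cm, d, m + 1)}"
        elif any(v > 0 for v in a):
            i = _first_axis(a)
            am = _dec(a, i)
            expr = (
                f"PA{i}*{self.get(am, b, c, d, m)}"
                f" + WP{i}*{self.get(am, b, c, d, m + 1)}"
            )
            if am[i] > 0:
                amm = _dec(am, i)
                expr += (
                    f" + {float(am[i])}*i2p*({self.get(amm, b, c, d, m)}"
                    f" - rop*{self.get(amm, b, c, d, m + 1)})"
                )
        else:
            self.m_max = max(self.m_max, m)
            expr = f"pref*F[{m}]"
        var = self._new(expr)
        self.memo[key] = var
        return var


def generate_unrolled_plan(La: int, Lb: int, Lc: int, Ld: int) -> UnrolledPlan:
    """Unroll all vertical and horizontal recurrences for one class."""
    for L in (La, Lb, Lc, Ld):
        if not 0 <= L <= MAX_L:
            raise ValueError(f"angular momentum {L} out of range")
    tracer = _Tracer()
    outputs = []
    for ca in cartesian_components(La):
        for cb in cartesian_components(Lb):
            for cc in cartesian_components(Lc):
                for cd in cartesian_components(Ld):
                    var = tracer.get(ca, cb, cc, cd, 0)
                    outputs.append(((ca, cb, cc, cd), var))
    return UnrolledPlan(
        key=(La, Lb, Lc, Ld),
        statements=tracer.statements,
        outputs=outputs,
        m_max=tracer.m_max,
    )


_PLAN_CACHE: dict[tuple, UnrolledPlan] = {}
_FN_CACHE: dict[tuple, callable] = {}


def get_plan(La, Lb, Lc, Ld) -> UnrolledPlan:
    key = (La, Lb, Lc, Ld)
    if key not in _PLAN_CACHE:
        _PLAN_CACHE[key] = generate_unrolled_plan(*key)
    return _PLAN_CACHE[key]


def get_plan_function(La, Lb, Lc, Ld):
    """Compile (and cache) the straight-line plan of a class into a callable
    operating elementwise on numpy arrays."""
    key = (La, Lb, Lc, Ld)
    if key not in _FN_CACHE:
        plan = get_plan(*key)
        ns: dict = {}
        exec(compile(plan.to_source(), f"<plan {key}>", "exec"), ns)
        _FN_CACHE[key] = ns[f"plan_{La}{Lb}{Lc}{Ld}"]
    return _FN_CACHE[key]


def total_m(La, Lb, Lc, Ld) -> int:
    return La + Lb + Lc + Ld


def eri_class_batch(La, Lb, Lc, Ld, A, B, C, D, a, b, c, d,
                    omega: float | None = None) -> np.ndarray:
    """Evaluate all component quadruples of a class for a batch of primitive
    quartets.

    Centers are (n, 3) (or broadcastable), exponents (n,). Returns an array
    of shape (n_comp_a·n_comp_b·n_comp_c·n_comp_d, n) over unnormalized
    primitives, component quadruples in lexicographic order.
    """
    A, B, C, D = (np.atleast_2d(np.asarray(v, dtype=float)) for v in (A, B, C, D))
    a, b, c, d = (np.atleast_1d(np.asarray(v, dtype=float)) for v in (a, b, c, d))
    p, q = a + b, c + d
    P = (a[:, None] * A + b[:, None] * B) / p[:, None]
    Q = (c[:, None] * C + d[:, None] * D) / q[:, None]
    W = (p[:, None] * P + q[:, None] * Q) / (p + q)[:, None]
    rho = p * q / (p + q)
    T = rho * np.einsum("ij,ij->i", P - Q, P - Q)
    kab = np.exp(-a * b / p * np.einsum("ij,ij->i", A - B, A - B))
    kcd = np.exp(-c * d / q * np.einsum("ij,ij->i", C - D, C - D))
    pref = 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q)) * kab * kcd
    m_max = total_m(La, Lb, Lc, Ld)
    if omega is None:
        F = boys(m_max, T)
    else:
        s = omega**2 / (omega**2 + rho)
        F = s[None, :] ** (np.arange(m_max + 1)[:, None] + 0.5) * boys(
            m_max, s * T
        )
    PA, WP = P - A, W - P
    QC, WQ = Q - C, W - Q
    AB, CD = A - B, C - D
    AB = np.broadcast_to(AB, P.shape)
    CD = np.broadcast_to(CD, P.shape)
    fn = get_plan_function(La, Lb, Lc, Ld)
    args = (
        PA[:, 0], PA[:, 1], PA[:, 2],
        WP[:, 0], WP[:, 1], WP[:, 2],
        QC[:, 0], QC[:, 1], QC[:, 2],
        WQ[:, 0], WQ[:, 1], WQ[:, 2],
        AB[:, 0], AB[:, 1], AB[:, 2],
        CD[:, 0], CD[:, 1], CD[:, 2],
        0.5 / p, 0.5 / q, 0.5 / (p + q), rho / p, rho / q, pref, F,
    )
    return np.stack(fn(*args))


def primitive_eri(comp_a, comp_b, comp_c, comp_d, A, B, C, D, a, b, c, d,
                  omega: float | None = None) -> float:
    """One primitive ERI component via the unrolled plan of its class."""
    La, Lb, Lc, Ld = (sum(t) for t in (comp_a, comp_b, comp_c, comp_d))
    vals = eri_class_batch(La, Lb, Lc, Ld, A, B, C, D, a, b, c, d, omega=omega)
    idx = 0
    found = None
    for i, ca in enumerate(cartesian_components(La)):
        for j, cb in enumerate(cartesian_components(Lb)):
            for k, cc in enumerate(cartesian_components(Lc)):
                for l, cd in enumerate(cartesian_components(Ld)):
                    if (ca, cb, cc, cd) == (
                        tuple(comp_a), tuple(comp_b), tuple(comp_c), tuple(comp_d)
                    ):
                        found = idx
                    idx += 1
    return float(vals[found, 0])
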