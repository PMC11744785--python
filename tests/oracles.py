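"""Independent numerical oracles used by the test suite only.

These deliberately avoid the Obara–Saika / McMurchie–Davidson machinery of
the package: electron repulsion and nuclear attraction are reduced to an
outer 1D quadrature over the Gaussian-transform variable of the Coulomb
kernel (1/r = 2/√π ∫ e^{−t²r²} dt), with the inner Cartesian integrals —
polynomials times Gaussians — evaluated *exactly* per t by Gauss–Hermite
quadrature after diagonalizing the coupled quadratic form.  Overlap-type
integrals use plain Gauss–Hermite.  Boys values come from high-precision
adaptive quadrature (mpmath).
"""

from __future__ import annotations

import numpy as np

_GH_NODES = 10
_GL_NODES = 96


def _gh(n=_GH_NODES):
    return np.polynomial.hermite.hermgauss(n)


def _pair_1d(i1, i2, A, B, a, b):
    """Closure evaluating (x−A)^i1 (x−B)^i2 exp(−a(x−A)²−b(x−B)²)."""

    def f(x):
        return (x - A) ** i1 * (x - B) ** i2 * np.exp(
            -a * (x - A) ** 2 - b * (x - B) ** 2
        )

    return f


def overlap_like_1d(i1, i2, A, B, a, b, extra_power=0, origin=0.0,
                    derivative=False):
    """∫ (x−A)^i1 (x−B)^i2 (x−O)^k [d/dx]? e^{−a(x−A)²−b(x−B)²} dx by
    Gauss–Hermite (exact for polynomial degree ≤ 2·nodes−1)."""
    p = a + b
    P = (a * A + b * B) / p
    x0, w = _gh()
    x = x0 / np.sqrt(p) + P
    ww = w / np.sqrt(p)
    ket = (x - B) ** i2
    if derivative:
        ket = i2 * (x - B) ** max(i2 - 1, 0) * (i2 > 0) - 2.0 * b * (
            x - B
        ) ** (i2 + 1)
    val = (
        (x - A) ** i1
        * ket
        * (x - origin) ** extra_power
        * np.exp(-a * (x - A) ** 2 - b * (x - B) ** 2 + p * (x - P) ** 2)
    )
    return float((val * ww).sum())


def _coupled_2d(i1, i2, i3, i4, A, B, C, D, a, b, c, d, t2):
    """Exact (Gauss–Hermite) value of the coupled two-electron 1D factor
    ∫∫ (x1−A)^i1 (x1−B)^i2 (x2−C)^i3 (x2−D)^i4
       e^{−a(x1−A)²−b(x1−B)²−c(x2−C)²−d(x2−D)²−t²(x1−x2)²} dx1 dx2."""
    p, q = a + b, c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    kab = np.exp(-a * b / p * (A - B) ** 2)
    kcd = np.exp(-c * d / q * (C - D) ** 2)
    delta = P - Q
    M = np.array([[p + t2, -t2], [-t2, q + t2]])
    l = np.array([2.0 * t2 * delta, -2.0 * t2 * delta])
    Minv = np.linalg.inv(M)
    shift = -0.5 * Minv @ l
    const = np.exp(0.25 * l @ Minv @ l - t2 * delta**2)
    w_eig, R = np.linalg.eigh(M)
    x0, wq = _gh()
    z1 = x0 / np.sqrt(w_eig[0])
    z2 = x0 / np.sqrt(w_eig[1])
    Z1, Z2 = np.meshgrid(z1, z2, indexing="ij")
    U = R[0, 0] * Z1 + R[0, 1] * Z2 + shift[0]
    V = R[1, 0] * Z1 + R[1, 1] * Z2 + shift[1]
    W = np.outer(wq / np.sqrt(w_eig[0]), wq / np.sqrt(w_eig[1]))
    poly = (
        (U + (P - A)) ** i1
        * (U + (P - B)) ** i2
        * (V + (Q - C)) ** i3
        * (V + (Q - D)) ** i4
    )
    return kab * kcd * const * float((poly * W).sum())


def eri_quadrature(comp_a, comp_b, comp_c, comp_d, A, B, C, D, a, b, c, d,
                   omega: float | None = None) -> float:
    """Primitive ERI by outer Gauss–Legendre over the kernel transform
    variable (t = s·tanθ) and exact inner Gauss–Hermite factors."""
    A, B, C, D = (np.asarray(v, float) for v in (A, B, C, D))
    p, q = a + b, c + d
    rho = p * q / (p + q)
    s = np.sqrt(rho)
    theta_max = np.pi / 2 if omega is None else np.arctan(omega / s)
    x0, w0 = np.polynomial.legendre.leggauss(_GL_NODES)
    theta = 0.5 * theta_max * (x0 + 1.0)
    wt = 0.5 * theta_max * w0
    total = 0.0
    for th, wq in zip(theta, wt):
        t = s * np.tan(th)
        dt = s / np.cos(th) ** 2
        t2 = t * t
        val = 1.0
        for x in range(3):
            val *= _coupled_2d(
                comp_a[x], comp_b[x], comp_c[x], comp_d[x],
                A[x], B[x], C[x], D[x], a, b, c, d, t2,
            )
        total += wq * dt * val
    return 2.0 / np.sqrt(np.pi) * total


def attraction_quadrature(comp_a, comp_b, A, B, a, b, C) -> float:
    """⟨μ| 1/|r−C| |ν⟩ by the same kernel-transform quadrature."""
    A, B, C = (np.asarray(v, float) for v in (A, B, C))
    p = a + b
    s = np.sqrt(p)
    x0, w0 = np.polynomial.legendre.leggauss(_GL_NODES)
    theta = 0.25 * np.pi * (x0 + 1.0)
    wt = 0.25 * np.pi * w0
    total = 0.0
    for th, wq in zip(theta, wt):
        t = s * np.tan(th)
        dt = s / np.cos(th) ** 2
        t2 = t * t
        val = 1.0
        for x in range(3):
            # 1D: ∫ (x−A)^i (x−B)^j e^{−a(..)²−b(..)²−t²(x−C)²} dx
            pp = p + t2
            P2 = (a * A[x] + b * B[x] + t2 * C[x]) / pp
            kexp = np.exp(
                -(a * A[x] ** 2 + b * B[x] ** 2 + t2 * C[x] ** 2)
                + pp * P2**2
            )
            y0, yw = _gh()
            xx = y0 / np.sqrt(pp) + P2
            ww = yw / np.sqrt(pp)
            poly = (xx - A[x]) ** comp_a[x] * (xx - B[x]) ** comp_b[x]
            val *= kexp * float((poly * ww).sum())
        total += wq * dt * val
    return 2.0 / np.sqrt(np.pi) * total


def overlap_quadrature(comp_a, comp_b, A, B, a, b) -> float:
    out = 1.0
    for x in range(3):
        out *= overlap_like_1d(comp_a[x], comp_b[x], A[x], B[x], a, b)
    return out


def boys_mpmath(m: int, x: float) -> float:
    """High-precision Boys value via adaptive quadrature."""
    import mpmath as mp

    mp.mp.dps = 40
    f = mp.quad(lambda t: t ** (2 * m) * mp.e ** (-x * t * t), [0, 1])
    return float(f)
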