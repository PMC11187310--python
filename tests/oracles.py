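"""Independent oracles used only by the test suite.

``burau_determinants`` computes |Δ(-1)| and |Δ(-2)| of a braid closure
algebraically via the reduced Burau representation — no 3D geometry, no
diagrams — so it is a fully independent cross-check of the geometric
knot engine.  ``two_sphere_sasa`` is the closed-form spherical-cap
solution for a pair of overlapping spheres.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache


def _reduced_burau(i: int, n: int, t: Fraction) -> list[list[Fraction]]:
    """Reduced Burau matrix of σ_i for an n-strand braid, evaluated at t."""
    m = [[Fraction(int(r == c)) for c in range(n - 1)] for r in range(n - 1)]
    j = i - 1
    m[j][j] = -t
    if j > 0:
        m[j][j - 1] = t
    if j < n - 2:
        m[j][j + 1] = Fraction(1)
    return m


def _mat_mul(a, b):
    n = len(a)
    return [
        [sum(a[r][k] * b[k][c] for k in range(n)) for c in range(n)]
        for r in range(n)
    ]


def _mat_inv(m):
    """Exact Gauss-Jordan inverse over Fractions."""
    n = len(m)
    aug = [row[:] + [Fraction(int(r == c)) for c in range(n)]
           for r, row in enumerate(m)]
    for col in range(n):
        piv = next(r for r in range(col, n) if aug[r][col] != 0)
        aug[col], aug[piv] = aug[piv], aug[col]
        f = aug[col][col]
        aug[col] = [x / f for x in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0:
                g = aug[r][col]
                aug[r] = [x - g * y for x, y in zip(aug[r], aug[col])]
    return [row[n:] for row in aug]


def _det(m):
    n = len(m)
    a = [row[:] for row in m]
    det = Fraction(1)
    for col in range(n):
        piv = next((r for r in range(col, n) if a[r][col] != 0), None)
        if piv is None:
            return Fraction(0)
        if piv != col:
            a[col], a[piv] = a[piv], a[col]
            det = -det
        det *= a[col][col]
        inv = 1 / a[col][col]
        for r in range(col + 1, n):
            if a[r][col] != 0:
                f = a[r][col] * inv
                a[r] = [x - f * y for x, y in zip(a[r], a[col])]
    return det


def _alexander_at(word: tuple[int, ...], n: int, t: Fraction) -> Fraction:
    """±t^k Δ(t) of the braid closure, evaluated exactly at rational t."""
    size = n - 1
    b = [[Fraction(int(r == c)) for c in range(size)] for r in range(size)]
    for w in word:
        m = _reduced_burau(abs(w), n, t)
        if w < 0:
            m = _mat_inv(m)
        b = _mat_mul(b, m)
    for r in range(size):
        b[r][r] -= 1
    det = _det(b)
    return det * (1 - t) / (1 - t**n)


@lru_cache(maxsize=None)
def burau_determinants(word: tuple[int, ...]) -> tuple[int, int]:
    """(|Δ(-1)|, |Δ(-2)|) of a braid-word closure, exactly.

    The Burau evaluation gives the Laurent polynomial f(t) = ±t^a Δ(t).
    t^M f(t) (M large enough to clear negative powers) is an ordinary
    polynomial, recovered exactly by Newton interpolation on rational
    nodes off the unit circle; stripping the monomial t-power and the
    sign then yields Δ up to mirror, which |·| removes.
    """
    n = max(abs(w) for w in word) + 1
    m_shift = len(word) + n
    deg_bound = 2 * m_shift + 2
    nodes = [Fraction(p) for p in range(2, deg_bound + 3)]
    values = [_alexander_at(word, n, x) * x**m_shift for x in nodes]
    # Newton divided differences -> monomial coefficients
    coef = values[:]
    for j in range(1, len(nodes)):
        for i in range(len(nodes) - 1, j - 1, -1):
            coef[i] = (coef[i] - coef[i - 1]) / (nodes[i] - nodes[i - j])
    poly = [Fraction(0)] * len(nodes)
    for i in range(len(nodes) - 1, -1, -1):
        new = [Fraction(0)] * len(nodes)
        new[0] = coef[i]
        for d in range(len(nodes) - 1):
            new[d] += poly[d] * (-nodes[i])
            new[d + 1] += poly[d]
        poly = new
    # strip trailing high-order zeros and the leading t^k unit
    while poly and poly[-1] == 0:
        poly.pop()
    k = 0
    while poly[k] == 0:
        k += 1
    coeffs = poly[k:]
    assert all(c.denominator == 1 for c in coeffs), "non-integer Δ coefficients"
    d1 = abs(sum(int(c) * (-1) ** i for i, c in enumerate(coeffs)))
    d2 = abs(sum(int(c) * (-2) ** i for i, c in enumerate(coeffs)))
    return d1, d2


def isolated_sphere_area(radius: float, probe: float) -> float:
    """SASA of a single atom: the full expanded sphere."""
    r = radius + probe
    return 4.0 * math.pi * r * r


def two_sphere_sasa(r1: float, r2: float, d: float, probe: float) -> tuple[float, float]:
    """Exact SASA of two overlapping atoms (expanded radii, cap formula).

    Returns (area1, area2).  For center distance d with expanded radii
    R1, R2, the buried cap on sphere 1 has height h1 = R1 - x1 with
    x1 = (d² + R1² - R2²) / 2d, and cap area 2π R1 h1.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return isolated_sphere_area(r1, probe), isolated_sphere_area(r2, probe)
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    x2 = d - x1
    h1 = R1 - x1
    h2 = R2 - x2
    a1 = 4 * math.pi * R1 * R1 - 2 * math.pi * R1 * h1
    a2 = 4 * math.pi * R2 * R2 - 2 * math.pi * R2 * h2
    return a1, a2
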