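"""Exact linear algebra over ``fractions.Fraction``.

The elementary-mode enumeration works on the rational kernel of the
stoichiometric matrix and calls rank tests inside its inner loop, so these
routines are written directly over Fractions rather than going through a
symbolic matrix library.  Matrices are plain lists of lists of Fraction.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd

Row = list[Fraction]
Matrix = list[Row]

ZERO = Fraction(0)
ONE = Fraction(1)


def rank(mat: Matrix) -> int:
    """Rank of a rational matrix by fraction-free-ish Gaussian elimination."""
    if not mat:
        return 0
    m = [row[:] for row in mat]
    ncols = len(m[0])
    r = 0
    for col in range(ncols):
        piv = None
        for i in range(r, len(m)):
            if m[i][col] != 0:
                piv = i
                break
        if piv is None:
            continue
        m[r], m[piv] = m[piv], m[r]
        prow = m[r]
        pval = prow[col]
        for i in range(r + 1, len(m)):
            f = m[i][col]
            if f != 0:
                f = f / pval
                m[i] = [a - f * b for a, b in zip(m[i], prow)]
        r += 1
        if r == len(m):
            break
    return r


def nullspace(mat: Matrix, ncols: int) -> list[Row]:
    """Basis of the right nullspace of ``mat`` (``ncols`` columns).

    Returns a list of Fraction vectors; empty list means the kernel is {0}.
    An empty matrix has the full space as kernel (standard basis returned).
    """
    if not mat:
        return [[ONE if j == i else ZERO for j in range(ncols)] for i in range(ncols)]
    m = [row[:] for row in mat]
    # reduced row echelon form
    pivots: list[int] = []
    r = 0
    for col in range(ncols):
        piv = None
        for i in range(r, len(m)):
            if m[i][col] != 0:
                piv = i
                break
        if piv is None:
            continue
        m[r], m[piv] = m[piv], m[r]
        pval = m[r][col]
        m[r] = [a / pval for a in m[r]]
        for i in range(len(m)):
            if i != r and m[i][col] != 0:
                f = m[i][col]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(col)
        r += 1
        if r == len(m):
            break
    free = [c for c in range(ncols) if c not in pivots]
    basis: list[Row] = []
    for fc in free:
        v = [ZERO] * ncols
        v[fc] = ONE
        for i, pc in enumerate(pivots):
            v[pc] = -m[i][fc]
        basis.append(v)
    return basis


def matvec(mat: Matrix, v: Row) -> Row:
    return [sum((a * b for a, b in zip(row, v)), ZERO) for row in mat]


def is_zero(v: Row) -> bool:
    return all(a == 0 for a in v)


def primitive(v: Row) -> Row:
    """Scale a rational vector by a positive constant to coprime integers."""
    denom_lcm = 1
    for a in v:
        if a != 0:
            d = a.denominator
            denom_lcm = denom_lcm * d // gcd(denom_lcm, d)
    ints = [int(a * denom_lcm) for a in v]
    g = 0
    for a in ints:
        g = gcd(g, abs(a))
    if g > 1:
        ints = [a // g for a in ints]
    return [Fraction(a) for a in ints]
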