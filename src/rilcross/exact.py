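"""Exact rational linear algebra on small matrices of Fractions.

Used for the variance algebra of linear estimators and for inverting the
normal-equations matrix of the joint scaling design exactly, so that
variance comparisons reproduce printed values with no floating-point
tolerance.  Matrices are lists of lists of :class:`fractions.Fraction`.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

F = Fraction

Matrix = list[list[Fraction]]


def transpose(m: Sequence[Sequence[Fraction]]) -> Matrix:
    return [list(row) for row in zip(*m)]


def matmul(a: Sequence[Sequence[Fraction]],
           b: Sequence[Sequence[Fraction]]) -> Matrix:
    bt = transpose(b)
    return [[sum((x * y for x, y in zip(row, col)), F(0)) for col in bt]
            for row in a]


def identity(n: int) -> Matrix:
    return [[F(1) if i == j else F(0) for j in range(n)] for i in range(n)]


def inverse(m: Sequence[Sequence[Fraction]]) -> Matrix:
    """Gauss-Jordan inverse with exact rational pivoting.

    Raises ``ValueError`` if the matrix is singular.
    """
    n = len(m)
    if any(len(row) != n for row in m):
        raise ValueError("matrix must be square")
    aug = [[F(x) for x in row] + ident_row
           for row, ident_row in zip(m, identity(n))]
    for col in range(n):
        pivot = next((r for r in range(col, n) if aug[r][col] != 0), None)
        if pivot is None:
            raise ValueError("matrix is singular")
        aug[col], aug[pivot] = aug[pivot], aug[col]
        pv = aug[col][col]
        aug[col] = [x / pv for x in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0:
                factor = aug[r][col]
                aug[r] = [x - factor * y for x, y in zip(aug[r], aug[col])]
    return [row[n:] for row in aug]


def normal_matrix_inverse(X: Sequence[Sequence[Fraction]]) -> Matrix:
    """Exact ``(X^T X)^{-1}`` for a design matrix of rationals."""
    Xt = transpose(X)
    return inverse(matmul(Xt, X))
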