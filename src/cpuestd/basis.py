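"""Penalized cubic regression spline basis.

The basis is parametrized by the spline's values at k knots placed at
evenly spaced quantiles of the covariate.  A natural cubic spline
interpolating those values is fully determined by them, which yields a
model matrix mapping knot values to fitted values and a penalty matrix
equal to the integrated squared second derivative of the interpolant
(rank k-2: straight lines are unpenalized).  Evaluation outside the knot
range extrapolates linearly, matching the natural boundary conditions.
"""

from __future__ import annotations

import numpy as np


def crs_knots(x: np.ndarray, k: int, name: str = "x") -> np.ndarray:
    """k knots at evenly spaced quantiles of the distinct values of x."""
    if k < 3:
        raise ValueError("basis dimension k must be >= 3")
    xu = np.unique(np.asarray(x, dtype=float))
    if xu.size < k:
        raise ValueError(
            f"covariate {name!r} has {xu.size} distinct values, fewer than "
            f"the basis dimension k={k}")
    knots = np.quantile(xu, np.linspace(0.0, 1.0, k))
    # quantiles of a sparse covariate can coincide; spread ties minimally
    for i in range(1, k):
        if knots[i] <= knots[i - 1]:
            knots[i] = np.nextafter(knots[i - 1], np.inf)
    return knots


def _bd_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Banded matrices relating knot values to knot second derivatives."""
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    return B, D


def crs_penalty(knots: np.ndarray) -> np.ndarray:
    """Integrated squared second derivative penalty, S = D' B^{-1} D."""
    B, D = _bd_matrices(knots)
    return D.T @ np.linalg.solve(B, D)


def crs_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Model matrix of the cubic regression spline at points x.

    Row i maps the k knot values to the natural-cubic-spline interpolant
    evaluated at x[i]; linear extrapolation beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    k = knots.size
    h = np.diff(knots)
    B, D = _bd_matrices(knots)
    # second derivatives at interior knots: delta = F @ beta; boundary rows 0
    F = np.zeros((k, k))
    F[1:-1] = np.linalg.solve(B, D)

    X = np.zeros((x.size, k))
    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hj = h[j]
    am = (knots[j + 1] - xc) / hj
    ap = (xc - knots[j]) / hj
    cm = ((knots[j + 1] - xc) ** 3 / hj - hj * (knots[j + 1] - xc)) / 6.0
    cp = ((xc - knots[j]) ** 3 / hj - hj * (xc - knots[j])) / 6.0
    rows = np.arange(x.size)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]

    # linear extrapolation using the boundary derivative rows
    left = x < knots[0]
    right = x > knots[-1]
    if left.any():
        d_row = np.zeros(k)
        d_row[0] = -1.0 / h[0]
        d_row[1] = 1.0 / h[0]
        d_row -= h[0] / 6.0 * F[1]
        X[left] += np.outer(x[left] - knots[0], d_row)
    if right.any():
        d_row = np.zeros(k)
        d_row[-2] = -1.0 / h[-1]
        d_row[-1] = 1.0 / h[-1]
        d_row += h[-1] / 6.0 * F[-2]
        X[right] += np.outer(x[right] - knots[-1], d_row)
    return X


def build_basis(x: np.ndarray, k: int, name: str = "x"
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convenience wrapper: (model matrix, penalty matrix, knots) for x."""
    knots = crs_knots(x, k, name=name)
    return crs_design(x, knots), crs_penalty(knots), knots
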