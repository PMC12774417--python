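"""Cubic smoothing splines with the MATLAB-``csaps`` smoothing convention.

The smoother minimizes::

    p * sum_i w_i * (y_i - f(x_i))**2  +  (1 - p) * integral f''(t)**2 dt

over natural cubic splines ``f`` with knots at the data sites.  ``p = 1``
interpolates the data; ``p = 0`` degenerates to the weighted least-squares
line.  This is the same functional as
:func:`scipy.interpolate.make_smoothing_spline` with ``lam = (1 - p) / p``,
but works for as few as three sites and exposes the linear-smoother matrix,
which the decoder exploits.

Implementation follows the Reinsch scheme (Green & Silverman, 1994): solve

    (alpha * Q' W^-1 Q + R) gamma = Q' y,     alpha = (1 - p) / p
    g = y - alpha * W^-1 Q gamma

for the fitted values ``g`` and return the natural cubic interpolant of
``(x, g)``, which is the unique minimizer.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def _second_difference_ops(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (Q^T, R) for knot sites ``x`` (n >= 3).

    Q^T is (n-2, n); R is (n-2, n-2) symmetric tridiagonal.
    """
    h = np.diff(x)
    n = x.size
    m = n - 2
    qt = np.zeros((m, n))
    idx = np.arange(m)
    qt[idx, idx] = 1.0 / h[:-1]
    qt[idx, idx + 1] = -1.0 / h[:-1] - 1.0 / h[1:]
    qt[idx, idx + 2] = 1.0 / h[1:]
    r = np.zeros((m, m))
    r[idx, idx] = (h[:-1] + h[1:]) / 3.0
    off = h[1:-1] / 6.0
    r[idx[:-1], idx[:-1] + 1] = off
    r[idx[:-1] + 1, idx[:-1]] = off
    return qt, r


def smoothing_spline(
    x: np.ndarray,
    y: np.ndarray,
    p: float = 0.93,
    weights: np.ndarray | None = None,
):
    """Fit a cubic smoothing spline to ``(x, y)`` and return a callable.

    Parameters
    ----------
    x : strictly increasing sample sites.
    y : sample values, same length as ``x``.
    p : smoothing parameter in [0, 1]; fidelity weight (1 = interpolation,
        0 = least-squares line).
    weights : optional positive fidelity weights per site (e.g. counts when
        duplicate sites were averaged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("smoothing spline needs at least 3 sites")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if not 0.0 <= p <= 1.0:
        raise ValueError("smoothing parameter p must lie in [0, 1]")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w <= 0):
            raise ValueError("weights must be positive, one per site")

    if p == 0.0:
        coeff = np.polyfit(x, y, 1, w=np.sqrt(w))
        return np.poly1d(coeff)

    g = _fitted_values(x, y, p, w)
    return CubicSpline(x, g, bc_type="natural")


def _fitted_values(x: np.ndarray, y: np.ndarray, p: float, w: np.ndarray) -> np.ndarray:
    if p == 1.0:
        return y.copy()
    alpha = (1.0 - p) / p
    qt, r = _second_difference_ops(x)
    a = alpha * (qt * (1.0 / w)) @ qt.T + r
    gamma = np.linalg.solve(a, qt @ y)
    return y - alpha * (qt.T @ gamma) / w


def smoother_matrix(x: np.ndarray, p: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Return the hat matrix H with fitted values ``g = H @ y`` at the sites.

    The smoothing spline is linear in the data for fixed sites, weights and
    ``p``; downstream code uses this to evaluate many fits cheaply.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if p == 1.0:
        return np.eye(n)
    alpha = (1.0 - p) / p
    qt, r = _second_difference_ops(x)
    a = alpha * (qt * (1.0 / w)) @ qt.T + r
    gamma = np.linalg.solve(a, qt)  # (n-2, n), gamma for each unit response
    return np.eye(n) - alpha * (qt.T @ gamma) / w[:, None]


def aggregate_duplicate_sites(
    x: np.ndarray, y: np.ndarray, tol: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average values sharing a site; return (unique x, mean y, counts).

    The counts serve as fidelity weights so the aggregated fit equals the
    fit that would weight every original observation once.  ``x`` must be
    sorted ascending.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")
    if x.size == 0:
        raise ValueError("empty input")
    # group boundaries where consecutive sites differ by more than tol
    new_group = np.concatenate(([True], np.diff(x) > tol))
    group = np.cumsum(new_group) - 1
    n_groups = group[-1] + 1
    counts = np.bincount(group, minlength=n_groups).astype(float)
    xu = np.bincount(group, weights=x, minlength=n_groups) / counts
    yu = np.bincount(group, weights=y, minlength=n_groups) / counts
    return xu, yu, counts
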