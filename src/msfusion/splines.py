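"""Spherical-spline scalp field interpolation and surface Laplacian.

Implements the classic spherical-spline approach: a scalp potential field
sampled at electrode positions on the unit sphere is modelled as

    v(x) = c0 + sum_i c_i g(cos(x, x_i))

with g a Legendre series whose coefficients decay as 1/(n(n+1))^m. The same
expansion yields the surface Laplacian through the companion series h.
Order m=4 and a small ridge term on the diagonal are the conventional
choices for EEG work.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as npleg

from .containers import MsfusionError

_N_TERMS = 60


def _legendre_series(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    c = np.zeros(len(coeffs) + 1)
    c[1:] = coeffs
    return npleg.legval(x, c)


def g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = _N_TERMS) -> np.ndarray:
    """Spline kernel g(cos) = (1/4pi) sum (2n+1)/(n(n+1))^m P_n(cos)."""
    n = np.arange(1, n_terms + 1, dtype=float)
    coeffs = (2 * n + 1) / (n * (n + 1)) ** m / (4 * np.pi)
    return _legendre_series(np.clip(cosang, -1.0, 1.0), coeffs)


def h_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = _N_TERMS) -> np.ndarray:
    """Laplacian kernel h(cos) = -(1/4pi) sum (2n+1)/(n(n+1))^(m-1) P_n(cos).

    Sign convention: the surface Laplacian of the interpolated field is
    L v = sum_i c_i h(cos(x, x_i)) / r^2 with h as above, so a focal
    positive potential yields a negative Laplacian at its centre
    (current source density positive there with the usual -L convention).
    """
    n = np.arange(1, n_terms + 1, dtype=float)
    coeffs = -(2 * n + 1) / (n * (n + 1)) ** (m - 1) / (4 * np.pi)
    return _legendre_series(np.clip(cosang, -1.0, 1.0), coeffs)


def _check_positions(pos: np.ndarray) -> np.ndarray:
    pos = np.asarray(pos, float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise MsfusionError("positions must be (n, 3)")
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise MsfusionError("zero-length position vector")
    return pos / norms[:, None]


def _solve_spline(pos_from: np.ndarray, data: np.ndarray, m: int, lam: float):
    """Fit spline coefficients (c, c0) for each column of ``data``.

    data is (n_from, n_samples). Returns (C, c0) with C (n_from, n_samples).
    """
    n = pos_from.shape[0]
    G = g_matrix(pos_from @ pos_from.T, m=m) + lam * np.eye(n)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.zeros((n + 1, data.shape[1]))
    rhs[:n] = data
    sol = np.linalg.solve(A, rhs)
    return sol[:n], sol[n]


def interpolate_field(pos_from: np.ndarray, pos_to: np.ndarray,
                      data: np.ndarray, m: int = 4, lam: float = 1e-5) -> np.ndarray:
    """Interpolate a field sampled at ``pos_from`` onto ``pos_to``.

    Parameters
    ----------
    data : ndarray, shape (n_from, n_samples)

    Returns
    -------
    ndarray, shape (n_to, n_samples)
    """
    pos_from = _check_positions(pos_from)
    pos_to = _check_positions(pos_to)
    data = np.atleast_2d(np.asarray(data, float))
    if pos_from.shape[0] < 4:
        raise MsfusionError("need at least 4 source positions for spline fit")
    C, c0 = _solve_spline(pos_from, data, m, lam)
    Gt = g_matrix(pos_to @ pos_from.T, m=m)
    return Gt @ C + c0


def interpolation_operator(pos_from: np.ndarray, pos_to: np.ndarray,
                           m: int = 4, lam: float = 1e-5) -> np.ndarray:
    """Linear operator P with interp(data) = P @ data (data: n_from x T)."""
    return interpolate_field(pos_from, pos_to, np.eye(pos_from.shape[0]), m, lam)


def surface_laplacian_operator(pos: np.ndarray, m: int = 4, lam: float = 1e-5,
                               head_radius_m: float = 0.085) -> np.ndarray:
    """Linear operator mapping scalp potentials (uV) to Laplacian (uV/m^2)."""
    pos = _check_positions(pos)
    n = pos.shape[0]
    cos = pos @ pos.T
    G = g_matrix(cos, m=m) + lam * np.eye(n)
    H = h_matrix(cos, m=m)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    # coefficient solve as linear map of the data, then apply H
    Ainv = np.linalg.inv(A)
    coef_op = Ainv[:n, :n]  # maps data -> spline coefficients c
    return (H @ coef_op) / head_radius_m**2
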