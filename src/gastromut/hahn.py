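"""Discrete orthogonal Hahn polynomials and Hahn moments.

The order-n Hahn polynomial on the integer lattice r = 0..P-1 with shape
parameters u, v > -1 is the terminating hypergeometric sum

    h_n(r, P) = 3F2(-n, n+u+v+1, -r; u+1, 1-P; 1)
              = sum_{k=0}^{n} (-n)_k (n+u+v+1)_k (-r)_k
                            / [ (u+1)_k (1-P)_k k! ]

with (a)_k the Pochhammer rising factorial (the classical discrete Hahn
family of Koekoek & Swarttouw, orthogonal under the hypergeometric weight
rho(r)).  Weighted by sqrt(rho) and divided by the square norm d_n, the
polynomials become an orthonormal family; projecting a square matrix onto
the tensor basis yields Hahn moments, and because the (full) basis is
complete the projection is invertible — the moments retain all the
information of the matrix.

Pochhammer factors for small k are formed by iterative products; the weight
function uses log-Gamma so that lattice sizes up to ~10^3 stay finite.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .errors import ConfigurationError, ValidationError

#: (i, j) exponent pairs of the ten moments up to combined order three.
MOMENT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (0, 2),
    (2, 0), (1, 2), (2, 1), (3, 0), (0, 3),
)


def _pochhammer(a: float, k: int) -> float:
    """Rising factorial a(a+1)...(a+k-1) by iterative product (k small)."""
    out = 1.0
    for i in range(k):
        out *= a + i
    return out


def hahn_polynomial(n: int, r: float, P: int, u: float = 0.0, v: float = 0.0) -> float:
    """Evaluate the order-``n`` Hahn polynomial at lattice point ``r``."""
    if P < 1:
        raise ConfigurationError(f"lattice size P must be >= 1, got {P}")
    if u <= -1 or v <= -1:
        raise ConfigurationError("shape parameters must satisfy u > -1, v > -1")
    if n > P - 1:
        raise ConfigurationError(f"order n={n} exceeds lattice degree limit P-1={P - 1}")
    total = 0.0
    for k in range(n + 1):
        num = _pochhammer(-n, k) * _pochhammer(n + u + v + 1, k) * _pochhammer(-r, k)
        den = _pochhammer(u + 1, k) * _pochhammer(1 - P, k) * float(math.factorial(k))
        total += num / den
    return total


def hahn_weight(r: np.ndarray, P: int, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """Hypergeometric weight rho(r) on r = 0..P-1 (uniform when u = v = 0)."""
    r = np.asarray(r, dtype=float)
    log_rho = (
        gammaln(u + r + 1)
        + gammaln(v + P - r)
        - gammaln(r + 1)
        - gammaln(P - r)
        - gammaln(u + 1)
        - gammaln(v + 1)
    )
    return np.exp(log_rho)


@lru_cache(maxsize=64)
def weighted_hahn_basis(P: int, u: float = 0.0, v: float = 0.0, max_order: int = 3) -> np.ndarray:
    """Orthonormal weighted Hahn functions h~_n(r) as an array (max_order+1, P).

    h~_n(r) = h_n(r) * sqrt(rho(r)) / d_n with the square norm
    d_n^2 = sum_r rho(r) h_n(r)^2 evaluated by direct summation — exact for
    the discrete lattice and independent of any closed-form norm expression.
    """
    if max_order > P - 1:
        raise ConfigurationError(
            f"lattice size P={P} supports polynomial orders up to {P - 1}"
        )
    r = np.arange(P, dtype=float)
    rho = hahn_weight(r, P, u, v)
    basis = np.empty((max_order + 1, P))
    for n in range(max_order + 1):
        h = np.array([hahn_polynomial(n, ri, P, u, v) for ri in r])
        d2 = float(np.sum(rho * h * h))
        basis[n] = h * np.sqrt(rho) / np.sqrt(d2)
    return basis


def hahn_moments(matrix: np.ndarray, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """Ten Hahn moments (orders of :data:`MOMENT_ORDERS`) of a square matrix.

    Matrices smaller than 4x4 are zero-padded to 4x4 so third-order
    polynomials exist on the lattice.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"Hahn moments need a square matrix, got shape {m.shape}")
    P = m.shape[0]
    if P < 4:
        padded = np.zeros((4, 4))
        padded[:P, :P] = m
        m, P = padded, 4
    basis = weighted_hahn_basis(P, u, v)
    # H_xy = sum_{i,j} m[i, j] * h~_x(j) * h~_y(i)
    proj = basis @ m @ basis.T  # proj[y, x] = h~_y(rows) m h~_x(cols)
    return np.array([proj[y, x] for (x, y) in MOMENT_ORDERS])


def reconstruct_from_full_basis(matrix: np.ndarray, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """Project a square matrix onto the complete P^2 weighted basis and invert.

    Demonstrates reversibility: with all P orders retained the round trip
    reproduces the matrix (up to floating error).
    """
    m = np.asarray(matrix, dtype=float)
    P = m.shape[0]
    basis = weighted_hahn_basis(P, u, v, max_order=P - 1)
    coeffs = basis @ m @ basis.T
    return basis.T @ coeffs @ basis
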