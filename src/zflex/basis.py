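"""Zernike3D basis: generalized Zernike radial polynomials times real
spherical harmonics, orthonormal on the unit ball.

The basis expands a smooth 3D deformation field with a small coefficient
vector.  A truncation ``(N, L)`` keeps angular degrees ``l <= L`` and radial
degrees satisfying ``2n + l <= N``; for the default ``N=3, L=2`` this yields
13 scalar basis functions, i.e. 39 components for a vector-valued field.

Conventions
-----------
* Radial part: ``Rbar^p_{l,n}(x) = sqrt(2) * sqrt(2n + l + p/2 + 1) *
  x**l * P_n^(0, l + p/2)(2 x**2 - 1)`` with ``P`` the Jacobi polynomial.
  For ``p = 1`` (3D volumes) this is orthonormal in L2([0,1], x^2 dx).
* Angular part: real spherical harmonics ``y_l^m`` with the cosine branch
  for ``m > 0``, sine for ``m < 0``, orthonormal on the sphere.
* theta is the polar angle from +Z, phi the azimuth from +X.
* All basis functions evaluate to 0 outside the closed unit ball.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import eval_jacobi, lpmv

__all__ = [
    "BasisSpec",
    "ZernikeIndex",
    "enumerate_indices",
    "radial",
    "spherical_harmonic",
    "basis_function",
    "cartesian_to_spherical",
]


class ZernikeIndex(NamedTuple):
    """Index triple (l, n, m) of one basis function."""

    l: int
    n: int
    m: int


@dataclass(frozen=True)
class BasisSpec:
    """Truncation of the basis.

    Parameters
    ----------
    N : int
        Maximum combined radial degree; an index (l, n, m) is admissible
        only when ``2n + l <= N``.
    L : int
        Maximum angular degree ``l``.
    p : float
        Inner-product/dimensionality parameter; 1 for 3D volumes.
    """

    N: int = 3
    L: int = 2
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 0 or self.L < 0 or self.p < 0:
            raise ValueError(f"BasisSpec requires N, L, p >= 0, got {self}")

    @property
    def size(self) -> int:
        """Number of admissible (l, n, m) triples."""
        return len(enumerate_indices(self))

    @property
    def n_components(self) -> int:
        """Number of scalar coefficient components (3 directions per index)."""
        return 3 * self.size


def enumerate_indices(spec: BasisSpec) -> list[ZernikeIndex]:
    """All admissible (l, n, m) triples, lexicographic in (l, n, m).

    Admissibility: ``l <= L``, ``n >= 0`` with ``2n + l <= N`` and
    ``-l <= m <= l``.  The joint degree bound ``2n + l <= N`` is what makes
    the default truncation N=3, L=2 contain exactly 13 triples
    (39 vector components).
    """
    out: list[ZernikeIndex] = []
    for l in range(spec.L + 1):
        n_max = (spec.N - l) // 2
        for n in range(max(n_max, 0) + 1):
            if 2 * n + l > spec.N:
                continue
            for m in range(-l, l + 1):
                out.append(ZernikeIndex(l, n, m))
    return out


def radial(l: int, n: int, p: float, x):
    """Normalized generalized Zernike radial polynomial Rbar^p_{l,n}(x).

    ``x`` may be a scalar or array with values in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("radial argument must lie in [0, 1]")
    if l < 0 or n < 0:
        raise ValueError("l and n must be non-negative")
    norm = np.sqrt(2.0) * np.sqrt(2 * n + l + p / 2.0 + 1.0)
    val = norm * x**l * eval_jacobi(n, 0.0, l + p / 2.0, 2.0 * x**2 - 1.0)
    return val if val.shape else float(val)


def spherical_harmonic(l: int, m: int, theta, phi):
    """Real spherical harmonic y_l^m(theta, phi).

    Orthonormal on the unit sphere.  The associated Legendre function is
    taken without the Condon-Shortley phase and the conventional (-1)^m
    factor is applied, which together reduce to scipy's ``lpmv`` directly.
    """
    if abs(m) > l:
        raise IndexError(f"|m| = {abs(m)} exceeds l = {l}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    am = abs(m)
    norm = np.sqrt(
        (2 * l + 1) / (4.0 * np.pi)
        * math.factorial(l - am) / math.factorial(l + am)
    )
    leg = lpmv(am, l, np.cos(theta))
    if m == 0:
        val = norm * leg
    elif m > 0:
        val = np.sqrt(2.0) * norm * leg * np.cos(m * phi)
    else:
        val = np.sqrt(2.0) * norm * leg * np.sin(am * phi)
    return val if np.shape(val) else float(val)


def cartesian_to_spherical(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x, y, z) -> (rho, theta, phi) with theta polar from +Z, phi from +X.

    ``r`` has shape (..., 3).  At the origin theta and phi are set to 0.
    """
    r = np.asarray(r, dtype=float)
    x, y, z = r[..., 0], r[..., 1], r[..., 2]
    rho = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(rho > 0, np.arccos(np.clip(np.divide(z, np.where(rho > 0, rho, 1.0)), -1, 1)), 0.0)
    phi = np.mod(np.arctan2(y, x), 2 * np.pi)
    return rho, theta, phi


def basis_function(idx: ZernikeIndex, r, p: float = 1.0):
    """Z_{l,n,m}(r) = Rbar^p_{l,n}(|r|) * y_l^m(theta, phi); 0 outside the ball.

    ``r`` has shape (..., 3) in unit-ball coordinates.
    """
    l, n, m = idx
    rho, theta, phi = cartesian_to_spherical(r)
    inside = rho <= 1.0
    rho_c = np.where(inside, rho, 0.0)
    val = radial(l, n, p, rho_c) * spherical_harmonic(l, m, theta, phi)
    val = np.where(inside, val, 0.0)
    return val if np.shape(val) else float(val)


def evaluate_basis_matrix(spec: BasisSpec, points: np.ndarray) -> np.ndarray:
    """Evaluate every basis function of ``spec`` at unit-ball ``points``.

    Returns an array of shape (npoints, K) with K = spec.size.  Points with
    ``|r| > 1`` get a zero row.  This is the workhorse used by field
    evaluation and the estimation objective, so radial/angular parts are
    computed once per (l, n) / (l, m) rather than per triple.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rho, theta, phi = cartesian_to_spherical(points)
    inside = rho <= 1.0
    rho_c = np.where(inside, rho, 0.0)
    indices = enumerate_indices(spec)
    cols = np.empty((points.shape[0], len(indices)))
    rad_cache: dict[tuple[int, int], np.ndarray] = {}
    ang_cache: dict[tuple[int, int], np.ndarray] = {}
    for j, (l, n, m) in enumerate(indices):
        if (l, n) not in rad_cache:
            rad_cache[(l, n)] = radial(l, n, spec.p, rho_c)
        if (l, m) not in ang_cache:
            ang_cache[(l, m)] = spherical_harmonic(l, m, theta, phi)
        cols[:, j] = rad_cache[(l, n)] * ang_cache[(l, m)]
    cols[~inside] = 0.0
    return cols
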