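"""Deformation fields expanded in the Zernike3D basis.

A conformational change is represented by one 3-vector coefficient per
basis index: ``g(r) = sum_{lnm} (ax, ay, az)_{lnm} Z_{lnm}(r)`` on the unit
ball.  The coefficients are dimensionless; ``scale_radius`` (Angstrom) maps
the unit ball onto the physical box, so the physical displacement at a
point ``x`` is ``scale_radius * g(x / scale_radius)``.

Sign convention (fixed package-wide): coefficients are the displacement
*added to the sampling point* when warping a volume (a gather,
``out(r) = in(r + g(r))``).  Under this convention the density content
moves by approximately ``-g``; use :func:`negate` when a coefficient set
estimated against volumes must displace atoms the way the density moved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .basis import (
    BasisSpec,
    ZernikeIndex,
    enumerate_indices,
    evaluate_basis_matrix,
)

__all__ = [
    "CoefficientSet",
    "VolumeGrid",
    "AtomicModel",
    "evaluate_field",
    "warp_volume",
    "warp_model",
    "rotate_coefficients",
    "cancel_projection_component",
    "rescale_coefficients",
    "deformation_magnitude",
    "negate",
    "sh_rotation_matrix",
    "unit_ball_points",
    "molecular_mask",
]


@dataclass
class CoefficientSet:
    """Per-index 3-vector expansion weights of a deformation field.

    ``alphas`` has shape (K, 3) with K = ``spec.size`` and columns
    (x, y, z), rows in :func:`zflex.basis.enumerate_indices` order.
    """

    spec: BasisSpec
    alphas: np.ndarray
    scale_radius: float

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        K = self.spec.size
        if self.alphas.shape != (K, 3):
            raise ValueError(
                f"alphas shape {self.alphas.shape} != ({K}, 3) for spec {self.spec}"
            )
        if not np.all(np.isfinite(self.alphas)):
            raise ValueError("coefficients must be finite")
        if not (self.scale_radius > 0):
            raise ValueError("scale_radius must be positive")

    @classmethod
    def zeros(cls, spec: BasisSpec, scale_radius: float) -> "CoefficientSet":
        return cls(spec, np.zeros((spec.size, 3)), scale_radius)

    def __getitem__(self, idx: ZernikeIndex) -> np.ndarray:
        return self.alphas[enumerate_indices(self.spec).index(ZernikeIndex(*idx))]

    def flatten(self) -> np.ndarray:
        """Direction-major flat vector (all x, then all y, then all z)."""
        return self.alphas.T.ravel().copy()

    @classmethod
    def from_flat(cls, spec: BasisSpec, flat: np.ndarray, scale_radius: float) -> "CoefficientSet":
        flat = np.asarray(flat, dtype=float)
        K = spec.size
        return cls(spec, flat.reshape(3, K).T, scale_radius)

    def copy(self) -> "CoefficientSet":
        return replace(self, alphas=self.alphas.copy())

    def __add__(self, other: "CoefficientSet") -> "CoefficientSet":
        if other.spec != self.spec:
            raise ValueError("cannot add coefficient sets with different specs")
        return replace(self, alphas=self.alphas + other.alphas)

    def __mul__(self, s: float) -> "CoefficientSet":
        return replace(self, alphas=self.alphas * float(s))

    __rmul__ = __mul__

    def __neg__(self) -> "CoefficientSet":
        return replace(self, alphas=-self.alphas)


def negate(c: CoefficientSet) -> CoefficientSet:
    """The coefficient set describing the opposite displacement."""
    return -c


@dataclass
class VolumeGrid:
    """Cubic voxel density.  The box centre (voxel ``box // 2``) is r = 0."""

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.values.shape}")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be positive")

    @property
    def box(self) -> int:
        return self.values.shape[0]

    @property
    def default_scale_radius(self) -> float:
        """Radius of the unit ball inscribed in the box, in Angstrom."""
        return (self.box / 2.0) * self.voxel_size

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.voxel_size)


@dataclass
class AtomicModel:
    """Minimal atomic model: parallel arrays of atom records.

    positions are in Angstrom in the same frame as the reference volume
    (box centre at the origin).
    """

    elements: list
    chains: list
    residue_ids: list
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (natoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            list(self.elements), list(self.chains), list(self.residue_ids),
            self.positions.copy(),
        )


# ---------------------------------------------------------------------------
# field evaluation

def evaluate_field(c: CoefficientSet, r) -> np.ndarray:
    """Deformation field g(r) at unit-ball coordinates ``r`` (shape (..., 3)).

    Zero outside the unit ball.  Linear in the coefficients.
    """
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    pts = np.atleast_2d(r)
    B = evaluate_basis_matrix(c.spec, pts)      # (n, K)
    g = B @ c.alphas                             # (n, 3)
    return g[0] if single else g.reshape(r.shape)


def unit_ball_points(n_per_axis: int = 24) -> np.ndarray:
    """Deterministic grid of points strictly inside the unit ball."""
    ax = (np.arange(n_per_axis) + 0.5) / n_per_axis * 2.0 - 1.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    return pts[np.linalg.norm(pts, axis=1) < 1.0]


# ---------------------------------------------------------------------------
# warping

def _unit_coords(box: int, voxel_size: float, scale_radius: float) -> np.ndarray:
    """Unit-ball coordinates of every voxel centre, shape (box^3, 3)."""
    idx = np.arange(box, dtype=float) - box // 2
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    return pts * (voxel_size / scale_radius)


def _warp_samples(box: int, voxel_size: float, c: CoefficientSet):
    """Inside-ball voxel indices and their displaced sampling coordinates."""
    u = _unit_coords(box, voxel_size, c.scale_radius)
    inside = np.flatnonzero(np.linalg.norm(u, axis=1) <= 1.0)
    g = evaluate_field(c, u[inside])
    sample = (u[inside] + g) * (c.scale_radius / voxel_size) + box // 2
    return inside, sample


def warp_volume(v: VolumeGrid, c: CoefficientSet) -> VolumeGrid:
    """Gather-warp: output value at voxel r is the trilinear sample of the
    input at ``r + g(r)``; reads outside the box are 0.  Voxels outside
    the unit ball (where the field vanishes) pass through unchanged.
    """
    from ._fastops import warp_flat

    if not np.any(c.alphas):
        return v.copy()
    box = v.box
    inside, sample = _warp_samples(box, v.voxel_size, c)
    flat = np.ascontiguousarray(v.values.reshape(-1), dtype=float)
    out = warp_flat(flat, inside, sample, box)
    return VolumeGrid(out.reshape(box, box, box), v.voxel_size)


def warp_volume_adjoint(v: VolumeGrid, c: CoefficientSet) -> VolumeGrid:
    """Exact adjoint of :func:`warp_volume` with the same coefficients.

    The gather-warp is a sparse linear operator (trilinear weights); this
    applies its transpose — a scatter with identical weights.  To first
    order in the field it agrees with ``warp_volume(v, negate(c))``, but
    unlike that approximation it satisfies the dot-product identity
    ``<warp(x), y> = <x, warp_adjoint(y)>`` to machine precision, which is
    what a residual-backprojection update needs.
    """
    from ._fastops import warp_flat_adjoint

    if not np.any(c.alphas):
        return v.copy()
    box = v.box
    inside, sample = _warp_samples(box, v.voxel_size, c)
    flat = np.ascontiguousarray(v.values.reshape(-1), dtype=float)
    out = warp_flat_adjoint(flat, inside, sample, box)
    return VolumeGrid(out.reshape(box, box, box), v.voxel_size)


def warp_model(mdl: AtomicModel, c: CoefficientSet) -> AtomicModel:
    """Move each atom from x to ``scale_radius * (u + g(u))``, u = x/scale_radius.

    Atoms outside the unit ball are left unmoved (a warning reports how many).
    """
    u = mdl.positions / c.scale_radius
    rho = np.linalg.norm(u, axis=1)
    outside = rho > 1.0
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} atom(s) outside the unit ball left unmoved",
            stacklevel=2,
        )
    g = evaluate_field(c, u)
    newpos = c.scale_radius * (u + g)
    newpos[outside] = mdl.positions[outside]
    out = mdl.copy()
    out.positions = newpos
    return out


# ---------------------------------------------------------------------------
# rotation of coefficient sets

def _check_rotation(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3) or not np.allclose(A @ A.T, np.eye(3), atol=1e-8) \
            or not np.isclose(np.linalg.det(A), 1.0, atol=1e-8):
        raise ValueError("A must be a proper rotation matrix (orthogonal, det +1)")
    return A


def sh_rotation_matrix(l: int, A: np.ndarray, _rng_cache={}) -> np.ndarray:
    """Matrix M with ``y_l^m(A^-1 rhat) = sum_m' M[m, m'] y_l^m'(rhat)``.

    Computed numerically: the relation is exactly linear, so sampling the
    harmonics at a fixed well-conditioned set of directions and solving a
    least-squares system recovers M to machine precision for the small l
    used here.  Rows/columns are ordered m = -l..l.
    """
    from .basis import spherical_harmonic

    if l == 0:
        return np.ones((1, 1))
    key = l
    if key not in _rng_cache:
        rng = np.random.default_rng(20230111 + l)
        dirs = rng.normal(size=(max(4 * (2 * l + 1), 32), 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        from .basis import cartesian_to_spherical

        _, th, ph = cartesian_to_spherical(dirs)
        Y = np.column_stack(
            [spherical_harmonic(l, m, th, ph) for m in range(-l, l + 1)]
        )
        _rng_cache[key] = (dirs, Y, np.linalg.pinv(Y))
    dirs, Y, Ypinv = _rng_cache[key]
    rot_dirs = dirs @ A  # rows: A^-1 @ dir  (A orthogonal)
    from .basis import cartesian_to_spherical

    _, th, ph = cartesian_to_spherical(rot_dirs)
    Yrot = np.column_stack(
        [spherical_harmonic(l, m, th, ph) for m in range(-l, l + 1)]
    )
    # Yrot = M @ Y^T per point  ->  solve Y M^T = Yrot
    return (Ypinv @ Yrot).T


def rotate_coefficients(c: CoefficientSet, A: np.ndarray) -> CoefficientSet:
    """Coefficients of the rotated field: evaluate_field(c', r) =
    A @ evaluate_field(c, A^-1 r).

    The 3-vector parts rotate by A; within each (l, n) block the m
    components mix by the real-spherical-harmonic rotation matrix.
    """
    A = _check_rotation(A)
    indices = enumerate_indices(c.spec)
    new = np.empty_like(c.alphas)
    vec_rot = c.alphas @ A.T                     # rotate vector parts
    # group rows by (l, n)
    blocks: dict[tuple[int, int], list[int]] = {}
    for i, (l, n, m) in enumerate(indices):
        blocks.setdefault((l, n), []).append(i)
    for (l, n), rows in blocks.items():
        M = sh_rotation_matrix(l, A)
        # alpha'_{m'} = sum_m M[m, m'] * (A alpha_m)
        new[rows] = M.T @ vec_rot[rows]
    return replace(c, alphas=new)


def _rotation_taking_to_z(d: np.ndarray) -> np.ndarray:
    """A proper rotation A with A @ d = +Z (shortest arc)."""
    d = np.asarray(d, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("projection direction must be non-zero")
    d = d / nd
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(d, z)
    s = np.linalg.norm(v)
    cth = float(np.dot(d, z))
    if s < 1e-12:
        if cth > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - cth) / s**2)


def cancel_projection_component(c: CoefficientSet, d: np.ndarray) -> CoefficientSet:
    """Remove the field component along the viewing direction ``d``.

    Deformation along a particle's projection direction is unobservable
    from that image; rotating the coefficients so d maps to +Z, zeroing the
    z coefficient column, and rotating back yields a field with
    ``g(r) . d = 0`` everywhere while preserving the orthogonal components.
    """
    A = _rotation_taking_to_z(d)
    rot = rotate_coefficients(c, A)
    rot.alphas[:, 2] = 0.0
    return rotate_coefficients(rot, A.T)


def inplane_subspace(spec: BasisSpec, d: np.ndarray) -> np.ndarray:
    """Orthonormal basis (columns) of the flat-coefficient subspace whose
    fields have no component along ``d``.

    The viewing-direction cancellation is a linear projection of the
    coefficient vector; its range is spanned by these columns, so an
    optimizer restricted to them satisfies ``g(r) . d = 0`` exactly at
    every iterate.
    """
    n = 3 * spec.size
    P = np.empty((n, n))
    dummy_radius = 1.0
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        c = CoefficientSet.from_flat(spec, e, dummy_radius)
        P[:, i] = cancel_projection_component(c, d).flatten()
    w, V = np.linalg.eigh((P + P.T) / 2.0)
    return V[:, w > 0.5]


def rescale_coefficients(c: CoefficientSet, k: float) -> CoefficientSet:
    """Move coefficients between sampling scales: every component and the
    scale_radius are multiplied by k (k = box_target / box_source).
    """
    if not (k > 0):
        raise ValueError("scale factor k must be positive")
    return CoefficientSet(c.spec, c.alphas * k, c.scale_radius * k)


# ---------------------------------------------------------------------------
# deformation magnitude

def deformation_magnitude(c: CoefficientSet, mask: VolumeGrid | None = None) -> float:
    """Mean physical displacement |scale_radius * g| in Angstrom.

    With ``mask`` (same frame as the reference), the mean runs over voxels
    where ``mask.values > 0`` that lie inside the unit ball; without a mask
    it runs over a fixed grid of unit-ball points.  Positively homogeneous
    of degree 1 in the coefficients.
    """
    if mask is None:
        pts = unit_ball_points(24)
    else:
        box = mask.box
        u = _unit_coords(box, mask.voxel_size, c.scale_radius)
        sel = (mask.values.reshape(-1) > 0) & (np.linalg.norm(u, axis=1) <= 1.0)
        if not np.any(sel):
            raise ValueError("mask selects no voxels inside the unit ball")
        pts = u[sel]
    g = evaluate_field(c, pts)
    return float(c.scale_radius * np.mean(np.linalg.norm(g, axis=1)))


def molecular_mask(v: VolumeGrid, threshold: float = 0.01) -> VolumeGrid:
    """Binary mask of voxels above ``threshold`` times the map maximum."""
    thr = threshold * float(v.values.max())
    return VolumeGrid((v.values > thr).astype(float), v.voxel_size)
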