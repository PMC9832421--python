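"""Projection geometry, CTF and image comparison.

The projector is real-space: the sampling grid is rotated by the particle
pose and summed along the viewing axis with trilinear interpolation.  The
backprojector is the exact transpose of the same interpolation weights, so
the adjoint identity <P v, i> = <v, P* i> holds to machine precision --
the property the algebraic reconstruction in :mod:`zflex.zart` relies on.

Euler convention: ZYZ intrinsic (rot, tilt, psi) in degrees, the
RELION/Xmipp convention.  The pose matrix is
``A = Rz(psi) @ Ry(tilt) @ Rz(rot)`` and maps reference-frame coordinates
to the projection frame; the viewing direction in the reference frame is
the third row of ``A``.  In-plane shifts are applied in the image plane by
a Fourier phase ramp (sub-pixel exact, unitary, hence with an exact
adjoint as well).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import VolumeGrid

__all__ = [
    "Pose",
    "CTFParams",
    "ParticleImage",
    "pose_matrix",
    "viewing_direction",
    "project",
    "backproject",
    "apply_ctf",
    "ctf_array",
    "pearson",
    "shift_image",
    "Projector",
]


@dataclass
class Pose:
    """Orientation (ZYZ intrinsic Euler angles, degrees) and shifts (Angstrom)."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    sx: float = 0.0
    sy: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt <= 180.0):
            raise ValueError(f"tilt must be in [0, 180] degrees, got {self.tilt}")


@dataclass
class CTFParams:
    """Contrast transfer function parameters."""

    defocus_u: float = 15000.0   # Angstrom; positive = underfocus
    defocus_v: float = 15000.0
    defocus_angle: float = 0.0   # degrees
    voltage: float = 300.0       # kV
    cs: float = 2.7              # spherical aberration, mm
    amplitude_contrast: float = 0.1

    def __post_init__(self) -> None:
        if not (self.voltage > 0):
            raise ValueError("voltage must be positive")
        if not np.isfinite(self.defocus_u) or not np.isfinite(self.defocus_v):
            raise ValueError("defocus must be finite")
        if not (0.0 <= self.amplitude_contrast <= 1.0):
            raise ValueError("amplitude contrast must be in [0, 1]")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        v = self.voltage * 1e3
        return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


@dataclass
class ParticleImage:
    """One experimental (or synthetic) particle: pixels + pose + CTF."""

    pixels: np.ndarray
    pixel_size: float
    pose: Pose
    ctf: CTFParams
    id: str = ""
    truth_coefficients: object = None  # CoefficientSet for synthetic data

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"particle image must be square, got {self.pixels.shape}")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    @property
    def box(self) -> int:
        return self.pixels.shape[0]


# ---------------------------------------------------------------------------
# geometry

def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def pose_matrix(pose: Pose) -> np.ndarray:
    """Rotation taking reference-frame coordinates to the projection frame."""
    return _rz(pose.psi) @ _ry(pose.tilt) @ _rz(pose.rot)


def viewing_direction(pose: Pose) -> np.ndarray:
    """Unit viewing axis of the particle, in the reference frame."""
    return pose_matrix(pose)[2, :].copy()


# ---------------------------------------------------------------------------
# trilinear gather/scatter sharing one set of weights

def _trilinear(coords: np.ndarray, box: int):
    """8-corner flat indices and weights for each coordinate (voxel units).

    Out-of-box corners get weight 0 (reads 0 / scatters nothing).
    """
    f = np.floor(coords).astype(np.int64)
    t = coords - f
    idx8 = np.empty((coords.shape[0], 8), dtype=np.int64)
    w8 = np.empty((coords.shape[0], 8))
    k = 0
    for dx in (0, 1):
        wx = (1.0 - t[:, 0]) if dx == 0 else t[:, 0]
        for dy in (0, 1):
            wy = (1.0 - t[:, 1]) if dy == 0 else t[:, 1]
            for dz in (0, 1):
                wz = (1.0 - t[:, 2]) if dz == 0 else t[:, 2]
                ix, iy, iz = f[:, 0] + dx, f[:, 1] + dy, f[:, 2] + dz
                ok = (ix >= 0) & (ix < box) & (iy >= 0) & (iy < box) & (iz >= 0) & (iz < box)
                w8[:, k] = np.where(ok, wx * wy * wz, 0.0)
                idx8[:, k] = np.where(ok, (ix * box + iy) * box + iz, 0)
                k += 1
    return idx8, w8


class Projector:
    """Line-integral projector for one pose, with precomputed weights.

    ``forward`` sums trilinear samples of the volume along the viewing axis
    (times voxel_size) and applies the in-plane shift; ``adjoint`` is the
    exact transpose.  Precomputing the interpolation table makes repeated
    application to the same pose (the inner loop of the coefficient search
    and of ART) cheap.
    """

    def __init__(self, pose: Pose, box: int, voxel_size: float):
        self.pose = pose
        self.box = box
        self.voxel_size = voxel_size
        A = pose_matrix(pose)
        c = box // 2
        ax = np.arange(box, dtype=float) - c
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")  # x, y, depth
        s = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        p = s @ A + c  # rows: A.T @ s + c
        self.idx8, self.w8 = _trilinear(p, box)
        self.shift_px = (pose.sx / voxel_size, pose.sy / voxel_size)

    def forward(self, values: np.ndarray) -> np.ndarray:
        from ._fastops import raysum

        flat = np.ascontiguousarray(values.reshape(-1), dtype=float)
        img_x = raysum(flat, self.idx8, self.w8, self.box, self.voxel_size)
        img = img_x.reshape(self.box, self.box).T  # index as [y, x]
        if self.shift_px != (0.0, 0.0):
            img = shift_image(img, *self.shift_px)
        return img

    def adjoint(self, img: np.ndarray) -> np.ndarray:
        from ._fastops import rayscatter

        if self.shift_px != (0.0, 0.0):
            img = shift_image(img, -self.shift_px[0], -self.shift_px[1])
        img_x = np.ascontiguousarray(img.T.reshape(-1), dtype=float)
        vol = rayscatter(img_x, self.idx8, self.w8, self.box, self.voxel_size)
        return vol.reshape(self.box, self.box, self.box)


def project(v: VolumeGrid, pose: Pose) -> np.ndarray:
    """Project a cubic volume along the pose's viewing axis.

    Returns an image indexed ``[y, x]`` with the volume's box and sampling.
    """
    return Projector(pose, v.box, v.voxel_size).forward(v.values)


def backproject(img: np.ndarray, pose: Pose, box: int, voxel_size: float = 1.0) -> VolumeGrid:
    """Exact adjoint of :func:`project` (Euclidean inner products)."""
    img = np.asarray(img, dtype=float)
    if img.shape != (box, box):
        raise ValueError(f"image shape {img.shape} does not match box {box}")
    vol = Projector(pose, box, voxel_size).adjoint(img)
    return VolumeGrid(vol, voxel_size)


# ---------------------------------------------------------------------------
# in-plane shift, CTF, correlation

def shift_ramp(n: int, dx_px: float, dy_px: float) -> np.ndarray:
    """Fourier multiplier translating an n x n image by (dx, dy) pixels.

    The unpaired Nyquist row/column of an even-sized grid is replaced by
    its real part so the operator maps real images to real images without
    discarding energy.
    """
    f = np.fft.fftfreq(n)
    rx = np.exp(-2j * np.pi * f * dx_px)
    ry = np.exp(-2j * np.pi * f * dy_px)
    if n % 2 == 0:
        # each separable factor must be real at its own Nyquist frequency
        # for the 2D multiplier to keep Hermitian symmetry
        rx[n // 2] = rx[n // 2].real
        ry[n // 2] = ry[n // 2].real
    return ry[:, None] * rx[None, :]


def shift_image(img: np.ndarray, dx_px: float, dy_px: float) -> np.ndarray:
    """Translate image content by (dx, dy) pixels via Fourier phase ramp
    (sub-pixel exact below Nyquist)."""
    ny, nx = img.shape
    if ny != nx:
        raise ValueError("shift_image expects a square image")
    ramp = shift_ramp(nx, dx_px, dy_px)
    return np.real(np.fft.ifft2(np.fft.fft2(img) * ramp))


def ctf_array(ctf: CTFParams, box: int, pixel_size: float) -> np.ndarray:
    """Signed CTF sampled on the FFT frequency grid of a box^2 image.

    ``CTF(f) = -sqrt(1 - A^2) sin(chi) - A cos(chi)`` with
    ``chi = pi lambda df(psi) |f|^2 - (pi/2) Cs lambda^3 |f|^4`` and the
    astigmatic defocus ``df(psi) = (dU + dV)/2 + (dU - dV)/2 cos 2(psi - psi_a)``.
    Underfocus is positive.
    """
    fy = np.fft.fftfreq(box, d=pixel_size)[:, None]
    fx = np.fft.fftfreq(box, d=pixel_size)[None, :]
    f2 = fx * fx + fy * fy
    ang = np.arctan2(fy, fx)
    lam = ctf.wavelength
    df = 0.5 * (ctf.defocus_u + ctf.defocus_v) + 0.5 * (
        ctf.defocus_u - ctf.defocus_v
    ) * np.cos(2.0 * (ang - np.deg2rad(ctf.defocus_angle)))
    chi = np.pi * lam * df * f2 - 0.5 * np.pi * ctf.cs * 1e7 * lam**3 * f2 * f2
    A = ctf.amplitude_contrast
    H = -np.sqrt(1.0 - A * A) * np.sin(chi) - A * np.cos(chi)
    # symmetrize the unpaired Nyquist row/column (where the astigmatic
    # angle is ambiguous) so the multiplier is exactly even and the
    # operator exactly self-adjoint
    H_flip = np.roll(H[::-1, ::-1], (1, 1), axis=(0, 1))
    return 0.5 * (H + H_flip)


def apply_ctf(img: np.ndarray, ctf: CTFParams, pixel_size: float) -> np.ndarray:
    """Multiply the image's Fourier transform by the signed CTF."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("apply_ctf expects a square image")
    H = ctf_array(ctf, img.shape[0], pixel_size)
    return np.real(np.fft.ifft2(np.fft.fft2(img) * H))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over all pixels; errors on constant input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))
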