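"""Synthetic cryo-EM data with known ground truth.

Gaussian-blob phantoms stand in for a reference density; particles are
generated through the same forward model the estimator inverts:
``I = C P_theta( V(r + g(r)) ) + noise`` with per-particle coefficient
draws, random poses and CTFs, and white Gaussian noise scaled to a
requested SNR.  Every truth (pose, CTF, coefficients, clean image, cluster
label) is recorded so recovery can be measured exactly.

SNR convention: variance of the clean signal over its support (pixels with
|clean| above 1% of the maximum) divided by the noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .basis import BasisSpec, ZernikeIndex, enumerate_indices
from .field import AtomicModel, CoefficientSet, VolumeGrid, warp_volume
from .imaging import CTFParams, ParticleImage, Pose, apply_ctf, project

__all__ = [
    "PhantomSpec",
    "HeterogeneitySpec",
    "SyntheticDataset",
    "make_phantom",
    "make_dataset",
    "default_phantom_spec",
    "bending_mode",
]


@dataclass
class PhantomSpec:
    """Sum-of-Gaussians phantom.

    blobs: list of (center_xyz_Angstrom, sigma_Angstrom, amplitude); centers
    must lie inside the ball inscribed in the box.
    """

    box: int = 48
    voxel_size: float = 2.0
    blobs: list = dfield(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box < 16:
            raise ValueError("box must be >= 16")
        radius = self.box / 2 * self.voxel_size
        for center, sigma, _amp in self.blobs:
            if np.linalg.norm(center) + 2 * sigma > radius:
                raise ValueError(
                    f"blob at {center} (sigma {sigma}) extends outside the "
                    f"inscribed ball of radius {radius:g} A"
                )


def default_phantom_spec(box: int = 48, voxel_size: float = 2.0) -> PhantomSpec:
    """The default test scene: an asymmetric 3-blob molecule.

    Blob centres/sigmas scale with the box so the phantom looks the same
    at any size.  Two of the blobs sit at high |z| where the default
    bending mode displaces them strongly, so deformations of a few percent
    of the box radius visibly move density.
    """
    r = box / 2 * voxel_size
    return PhantomSpec(
        box=box,
        voxel_size=voxel_size,
        blobs=[
            (np.array([0.25 * r, 0.10 * r, -0.45 * r]), 0.06 * r, 1.0),
            (np.array([-0.28 * r, -0.12 * r, 0.45 * r]), 0.07 * r, 0.8),
            (np.array([0.02 * r, 0.30 * r, 0.05 * r]), 0.055 * r, 0.9),
        ],
    )


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, AtomicModel]:
    """Render the phantom and a pseudo-atomic model (one atom per blob)."""
    box, vs = spec.box, spec.voxel_size
    ax = (np.arange(box) - box // 2) * vs
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.zeros((box, box, box))
    centers = []
    for center, sigma, amp in spec.blobs:
        c = np.asarray(center, dtype=float)
        centers.append(c)
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        vol += amp * np.exp(-r2 / (2.0 * sigma**2))
    model = AtomicModel(
        elements=["C"] * len(centers),
        chains=["A"] * len(centers),
        residue_ids=list(range(1, len(centers) + 1)),
        positions=np.array(centers) if centers else np.zeros((0, 3)),
    )
    return VolumeGrid(vol, vs), model


def bending_mode(spec: BasisSpec, scale_radius: float,
                 direction: int = 0) -> CoefficientSet:
    """A bending-like unit mode built from (l=1, n=0) and (l=2, n=0) terms.

    The displacement points along ``direction`` (0=x, 1=y, 2=z) and varies
    along z through the m=0 harmonics, i.e. a shear/bend of the top of the
    molecule against the bottom.  Normalized so the maximum field magnitude
    over the unit ball is 1; scale with an amplitude before use.
    """
    c = CoefficientSet.zeros(spec, scale_radius)
    indices = enumerate_indices(spec)
    want = [ZernikeIndex(1, 0, 0), ZernikeIndex(2, 0, 0)]
    weights = [1.0, 0.6]
    for idx, w in zip(want, weights):
        if idx in indices:
            c.alphas[indices.index(idx), direction] = w
    if not np.any(c.alphas):
        raise ValueError(f"spec {spec} admits none of the bending terms")
    # normalize to unit max displacement over a dense ball grid
    from .field import evaluate_field, unit_ball_points

    g = evaluate_field(c, unit_ball_points(24))
    c.alphas /= np.linalg.norm(g, axis=1).max()
    return c


@dataclass
class HeterogeneitySpec:
    """Per-particle conformational variability.

    modes : list of CoefficientSet sharing one BasisSpec; each particle's
        field is ``sum_i a_i * mode_i`` with amplitudes drawn per ``law``.
    law : 'uniform'  -> a_i ~ U(amp_range);
          'clusters' -> particle joins one cluster (equal odds) and
          a_i ~ N(centers[k][i], spread).
    Amplitudes are in units of the unit-ball radius (a max-normalized mode
    scaled by 0.05 displaces at most 5% of the box radius).
    """

    modes: list
    law: str = "uniform"
    amp_range: tuple = (-0.05, 0.05)
    centers: tuple = ((-0.04,), (0.04,))
    spread: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        specs = {m.spec for m in self.modes}
        if len(specs) > 1:
            raise ValueError("heterogeneity modes must share one BasisSpec")
        if self.law not in ("uniform", "clusters"):
            raise ValueError(f"unknown amplitude law {self.law!r}")
        if self.law == "uniform":
            bound = max(abs(self.amp_range[0]),
                        abs(self.amp_range[1])) * len(self.modes)
        else:
            bound = max(sum(abs(c) for c in ctr) for ctr in self.centers) \
                + 4 * self.spread * len(self.modes)
        if bound > 0.10 + 1e-9:
            raise ValueError("amplitudes allow displacements above 10% of the box radius")

    def draw(self, rng: np.random.Generator):
        """One (amplitudes, label) draw."""
        k = len(self.modes)
        if self.law == "uniform":
            return rng.uniform(*self.amp_range, size=k), -1
        label = int(rng.integers(len(self.centers)))
        mu = np.asarray(self.centers[label], dtype=float)
        if mu.size != k:
            raise ValueError("each cluster center needs one amplitude per mode")
        return mu + rng.normal(0.0, self.spread, size=k), label

    def compose(self, amplitudes) -> CoefficientSet:
        c = self.modes[0] * float(amplitudes[0])
        for a, m in zip(amplitudes[1:], self.modes[1:]):
            c = c + m * float(a)
        return c


@dataclass
class SyntheticDataset:
    """Particles plus every ground truth used to generate them."""

    particles: list
    clean_images: list
    truths: list          # CoefficientSet per particle
    labels: np.ndarray    # cluster label per particle (-1 when law=uniform)
    phantom: VolumeGrid
    model: AtomicModel
    snr: float


def _random_pose(rng: np.random.Generator, shift_range: float) -> Pose:
    return Pose(
        rot=rng.uniform(0.0, 360.0),
        tilt=np.rad2deg(np.arccos(rng.uniform(-1.0, 1.0))),
        psi=rng.uniform(0.0, 360.0),
        sx=rng.uniform(-shift_range, shift_range),
        sy=rng.uniform(-shift_range, shift_range),
    )


def _random_ctf(rng: np.random.Generator) -> CTFParams:
    d = rng.uniform(10000.0, 20000.0)
    return CTFParams(
        defocus_u=d,
        defocus_v=d * rng.uniform(0.95, 1.05),
        defocus_angle=rng.uniform(0.0, 180.0),
        voltage=300.0,
        cs=2.7,
        amplitude_contrast=0.1,
    )


def make_dataset(phantom: VolumeGrid, model: AtomicModel,
                 het: HeterogeneitySpec | None, n: int, *,
                 snr: float = np.inf, with_ctf: bool = True,
                 shift_range: float = 2.0, seed: int = 0) -> SyntheticDataset:
    """Generate ``n`` particles through the package's own forward model.

    ``het=None`` produces a homogeneous dataset (zero deformation).
    ``snr=np.inf`` disables noise.  Reuses the same warp/project/CTF
    operators the estimator applies, so recovery experiments probe
    inversion rather than operator mismatch.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (snr > 0):
        raise ValueError("snr must be positive (np.inf for noiseless)")
    rng = np.random.default_rng(seed)
    scale_radius = phantom.default_scale_radius
    spec = het.modes[0].spec if het is not None else BasisSpec(3, 2)

    particles, cleans, truths, labels = [], [], [], []
    for i in range(n):
        if het is not None:
            amps, label = het.draw(rng)
            c = het.compose(amps)
        else:
            c, label = CoefficientSet.zeros(spec, scale_radius), -1
        pose = _random_pose(rng, shift_range)
        ctf = _random_ctf(rng) if with_ctf else None
        vol = warp_volume(phantom, c) if np.any(c.alphas) else phantom
        clean = project(vol, pose)
        if ctf is not None:
            clean = apply_ctf(clean, ctf, phantom.voxel_size)
        img = clean
        if np.isfinite(snr):
            support = np.abs(clean) > 0.01 * np.abs(clean).max()
            sig_var = clean[support].var() if support.any() else clean.var()
            sigma = np.sqrt(sig_var / snr)
            img = clean + rng.normal(0.0, sigma, size=clean.shape)
        particles.append(ParticleImage(
            pixels=img, pixel_size=phantom.voxel_size, pose=pose, ctf=ctf,
            id=f"ptcl{i:05d}", truth_coefficients=c,
        ))
        cleans.append(clean)
        truths.append(c)
        labels.append(label)
    return SyntheticDataset(particles, cleans, truths, np.asarray(labels),
                            phantom, model, snr)
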