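"""Algebraic reconstruction (ART) and its deformation-aware variant (ZART).

Classic ART sweeps the particle set, correcting the running volume with
the backprojected residual of one image at a time:

    V <- V + lambda * P* ( C ( I_k - C P V ) )

The forward model includes the particle's CTF; the backprojected residual
is CTF-modulated again because the CTF (a real, even Fourier multiplier)
is self-adjoint, making the update the exact adjoint of the forward model.

ZART inserts each particle's estimated deformation field into the loop:
the forward model warps the volume with that particle's field before
projecting, and the correction is mapped back through the exact transpose
of that warp (a scatter with the same trilinear weights, equal to the
inverse warp to first order in the field) before being applied.  A
particle therefore only corrects the reference where its own conformation
says the density currently is, which undoes motion-induced blurring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import VolumeGrid
from .imaging import Projector, apply_ctf

__all__ = ["ReconOptions", "art_reconstruct", "zart_reconstruct"]


@dataclass
class ReconOptions:
    """ART/ZART iteration parameters.

    relaxation : per-image update weight lambda (default 1e-3).
    epochs : full passes over the shuffled particle set.
    decay : relaxation multiplier applied after each epoch.
    seed : shuffle seed (fixed seed => bitwise deterministic result).
    positivity : clamp the volume at 0 after every update.
    """

    relaxation: float = 1e-3
    epochs: int = 10
    decay: float = 0.9
    seed: int = 0
    positivity: bool = False

    def __post_init__(self) -> None:
        if not (self.relaxation > 0):
            raise ValueError("relaxation must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _check_particles(particles) -> tuple[int, float]:
    if len(particles) == 0:
        raise ValueError("cannot reconstruct from an empty particle list")
    box = particles[0].box
    px = particles[0].pixel_size
    for p in particles:
        if p.box != box or p.pixel_size != px:
            raise ValueError("all particles must share box and pixel size")
    return box, px


class _WarpCache:
    """Per-grid basis table so the loop warps volumes without re-evaluating
    the Zernike3D basis for every particle and epoch."""

    def __init__(self, box: int, voxel_size: float, spec, scale_radius: float):
        from .basis import evaluate_basis_matrix
        from .field import _unit_coords

        u = _unit_coords(box, voxel_size, scale_radius)
        rho = np.linalg.norm(u, axis=1)
        self.inside = np.flatnonzero(rho <= 1.0)
        self.B = evaluate_basis_matrix(spec, u[self.inside])
        self.to_vox = scale_radius / voxel_size
        self.base_vox = u[self.inside] * self.to_vox + box // 2
        self.box = box

    def _sample(self, alphas: np.ndarray) -> np.ndarray:
        return self.base_vox + (self.B @ alphas) * self.to_vox

    def warp(self, values: np.ndarray, alphas: np.ndarray) -> np.ndarray:
        from ._fastops import warp_flat

        flat = np.ascontiguousarray(values.reshape(-1), dtype=float)
        return warp_flat(flat, self.inside, self._sample(alphas),
                         self.box).reshape(values.shape)

    def warp_adjoint(self, values: np.ndarray, alphas: np.ndarray) -> np.ndarray:
        from ._fastops import warp_flat_adjoint

        flat = np.ascontiguousarray(values.reshape(-1), dtype=float)
        return warp_flat_adjoint(flat, self.inside, self._sample(alphas),
                                 self.box).reshape(values.shape)


def _recon(particles, coeffs, box: int, opt: ReconOptions,
           epoch_callback=None) -> VolumeGrid:
    _, px = _check_particles(particles)
    rng = np.random.default_rng(opt.seed)
    V = np.zeros((box, box, box))
    lam = opt.relaxation
    n = len(particles)
    cache: dict[tuple, _WarpCache] = {}
    for epoch in range(opt.epochs):
        order = rng.permutation(n)
        for j in order:
            p = particles[j]
            c = coeffs[j] if coeffs is not None else None
            deformed = c is not None and np.any(c.alphas)
            proj = Projector(p.pose, box, px)
            if deformed:
                key = (c.spec, c.scale_radius)
                if key not in cache:
                    cache[key] = _WarpCache(box, px, c.spec, c.scale_radius)
                wc = cache[key]
                vol_in = wc.warp(V, c.alphas)
            else:
                vol_in = V
            model = proj.forward(vol_in)
            if p.ctf is not None:
                model = apply_ctf(model, p.ctf, px)
            resid = p.pixels - model
            if p.ctf is not None:
                resid = apply_ctf(resid, p.ctf, px)
            corr = proj.adjoint(resid)
            if deformed:
                corr = wc.warp_adjoint(corr, c.alphas)
            V = V + lam * corr
            if opt.positivity:
                np.maximum(V, 0.0, out=V)
        lam *= opt.decay
        if epoch_callback is not None:
            epoch_callback(epoch, VolumeGrid(V.copy(), px))
    return VolumeGrid(V, px)


def art_reconstruct(particles: list, box: int,
                    opt: ReconOptions | None = None,
                    epoch_callback=None) -> VolumeGrid:
    """Classic per-image ART from posed, CTF-modulated particles.

    ``epoch_callback(epoch, volume)``, if given, receives a snapshot after
    every epoch (used e.g. to monitor convergence).
    """
    return _recon(particles, None, box, opt or ReconOptions(),
                  epoch_callback=epoch_callback)


def zart_reconstruct(pairs: list, box: int,
                     opt: ReconOptions | None = None,
                     epoch_callback=None) -> VolumeGrid:
    """Deformation-aware ART from (particle, coefficient set) pairs.

    With all coefficient sets zero this reproduces :func:`art_reconstruct`
    bit for bit (same shuffle order for the same seed).
    """
    particles = [p for p, _ in pairs]
    coeffs = []
    for p, c in pairs:
        if c is None:
            raise ValueError(f"particle {p.id!r} has no coefficient set")
        coeffs.append(c)
    return _recon(particles, coeffs, box, opt or ReconOptions(),
                  epoch_callback=epoch_callback)
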