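"""Per-particle and volume-to-volume estimation of deformation coefficients.

For a particle image I with known pose and CTF, the coefficients are found
by maximizing the regularized Pearson correlation

    rho(I, C P_theta( V(r + g(r)) ))  -  lambda1 * integral |g(r)|^2 dV

over the coefficient vector with Powell's conjugate-direction method,
starting from zero deformation.  The quadratic penalty discourages large
fields the data cannot justify.  Deformation along the particle's viewing
axis is unobservable from that image, so (by default) the current iterate
is projected onto the in-plane subspace after every Powell sweep and at
the end (see :func:`zflex.field.cancel_projection_component`).

Particles are band-limited and downsampled before the search by cropping
the Fourier transform to a working box; this preserves the physical frame,
so the returned coefficients apply to the full-size reference unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .basis import BasisSpec, evaluate_basis_matrix
from .field import (
    CoefficientSet,
    VolumeGrid,
    cancel_projection_component,
    inplane_subspace,
    _unit_coords,
)
from .imaging import (
    ParticleImage,
    Pose,
    Projector,
    ctf_array,
    pearson,
    viewing_direction,
)

__all__ = [
    "EstimationOptions",
    "estimate_particle",
    "estimate_volume",
    "regularized_objective",
    "fourier_crop_image",
    "fourier_crop_volume",
]


@dataclass
class EstimationOptions:
    """Knobs of the coefficient search.

    lambda1 : weight of the quadratic field penalty (recommended range
        0.001-0.01; default 0.005).
    max_sweeps : maximum full Powell sweeps over the coefficient vector.
    ftol : absolute objective tolerance to declare convergence.
    cancel_projection : restrict the result (and each sweep's iterate) to
        the subspace with no deformation along the viewing axis.
    box_work : working box for the search; particle and reference are
        Fourier-cropped to this size (None = no downsampling).
    lowpass_factor : additional soft low-pass at ``factor`` times the
        working Nyquist wavelength (None disables).
    step : half-width of each coordinate line search, in coefficient units.
    line_maxiter : budget of the bounded scalar line search per direction.
    seed : seed for the fixed quasi-random penalty quadrature points.
    """

    lambda1: float = 0.005
    max_sweeps: int = 4
    ftol: float = 1e-6
    cancel_projection: bool = True
    box_work: int | None = None
    lowpass_factor: float | None = 2.5
    step: float = 0.06
    step_decay: float = 0.5
    line_maxiter: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        if not (self.ftol > 0):
            raise ValueError("ftol must be positive")


# ---------------------------------------------------------------------------
# Fourier cropping (band limit + downsample in one step)

def _crop_slices(n_full: int, n_work: int):
    c = n_full // 2
    h = n_work // 2
    return slice(c - h, c - h + n_work)


def fourier_crop_image(img: np.ndarray, box_work: int) -> np.ndarray:
    """Downsample a square image by cropping its centred Fourier transform.

    Preserves the physical field of view; the mean value is preserved.
    """
    box = img.shape[0]
    if box_work >= box:
        return np.asarray(img, dtype=float).copy()
    F = np.fft.fftshift(np.fft.fft2(img))
    s = _crop_slices(box, box_work)
    out = np.fft.ifft2(np.fft.ifftshift(F[s, s])).real
    return out * (box_work**2 / box**2)


def fourier_crop_volume(v: VolumeGrid, box_work: int) -> VolumeGrid:
    """Volume counterpart of :func:`fourier_crop_image`."""
    box = v.box
    if box_work >= box:
        return v.copy()
    F = np.fft.fftshift(np.fft.fftn(v.values))
    s = _crop_slices(box, box_work)
    out = np.fft.ifftn(np.fft.ifftshift(F[s, s, s])).real
    out *= box_work**3 / box**3
    return VolumeGrid(out, v.voxel_size * box / box_work)


def _soft_lowpass(img: np.ndarray, pixel_size: float, cutoff_res: float) -> np.ndarray:
    """Gaussian low-pass with half-amplitude at resolution ``cutoff_res`` (A)."""
    n = img.shape[0]
    f = np.fft.fftfreq(n, d=pixel_size)
    if img.ndim == 2:
        f2 = f[:, None] ** 2 + f[None, :] ** 2
    else:
        f2 = f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2
    H = np.exp(-np.log(2.0) * f2 * cutoff_res**2)
    return np.fft.ifftn(np.fft.fftn(img) * H).real


# ---------------------------------------------------------------------------
# objective machinery

def _penalty_gram(spec: BasisSpec, box: int, seed: int) -> np.ndarray:
    """Quadrature Gram matrix of the field penalty.

    Monte-Carlo over 10^4 fixed quasi-random unit-ball points (seeded, so
    the optimizer sees one deterministic function).  The penalty measures
    |g| in working-box pixels (displacement in voxels of the grid the
    correlation is computed on), which puts lambda1 in the recommended
    [0.001, 0.01] range on a meaningful scale: a field moving density by a
    few pixels costs a few correlation points.
    """
    qr = np.random.default_rng(seed if seed is not None else 0)
    pts = qr.uniform(-1.0, 1.0, size=(30000, 3))
    pts = pts[np.linalg.norm(pts, axis=1) <= 1.0][:10000]
    Bq = evaluate_basis_matrix(spec, pts)
    ball_vol = 4.0 / 3.0 * np.pi
    return (Bq.T @ Bq) * (ball_vol / len(pts)) * (box / 2.0) ** 2


class _ParticleObjective:
    """Callable mapping a flat coefficient vector to the value to MINIMIZE
    (negative regularized correlation), with everything pose/CTF-dependent
    precomputed once per particle."""

    def __init__(self, particle_img: np.ndarray, pose: Pose, ctf, ref: VolumeGrid,
                 spec: BasisSpec, scale_radius: float, lambda1: float, seed: int):
        box = ref.box
        self.ref = np.ascontiguousarray(ref.values.reshape(-1), dtype=float)
        self.box = box
        u = _unit_coords(box, ref.voxel_size, scale_radius)
        rho = np.linalg.norm(u, axis=1)
        self.inside = np.flatnonzero(rho <= 1.0)
        self.u_in = u[self.inside]
        self.B = evaluate_basis_matrix(spec, self.u_in)          # (n_in, K)
        self.to_vox = scale_radius / ref.voxel_size
        self.base_vox = self.u_in * self.to_vox + box // 2
        self.projector = Projector(pose, box, ref.voxel_size)
        # shift and CTF combine into one Fourier-domain filter
        filt = None
        if ctf is not None:
            filt = ctf_array(ctf, box, ref.voxel_size).astype(complex)
        sx, sy = self.projector.shift_px
        if (sx, sy) != (0.0, 0.0):
            from .imaging import shift_ramp

            ramp = shift_ramp(box, sx, sy)
            filt = ramp if filt is None else filt * ramp
        self.filter = filt
        self.img = particle_img
        self.spec = spec
        self.K = spec.size
        self.gram = _penalty_gram(spec, box, seed)
        self.lambda1 = lambda1

    def render(self, alphas: np.ndarray) -> np.ndarray:
        """Forward model: warp reference, project, shift, CTF."""
        from ._fastops import raysum, warp_project

        P = self.projector
        if np.any(alphas):
            disp = self.B @ alphas                                # (n_in, 3)
            sample = self.base_vox + disp * self.to_vox
            img_x = warp_project(self.ref, self.inside, sample,
                                 P.idx8, P.w8, self.box, P.voxel_size)
        else:
            img_x = raysum(self.ref, P.idx8, P.w8, self.box, P.voxel_size)
        proj = img_x.reshape(self.box, self.box).T
        if self.filter is not None:
            proj = np.fft.ifft2(np.fft.fft2(proj) * self.filter).real
        return proj

    def penalty(self, alphas: np.ndarray) -> float:
        return float(np.einsum("kd,kj,jd->", alphas, self.gram, alphas))

    def value(self, flat: np.ndarray) -> float:
        alphas = flat.reshape(3, self.K).T
        proj = self.render(alphas)
        rho = pearson(self.img, proj)
        return -(rho - self.lambda1 * self.penalty(alphas))

    __call__ = value

    def score(self, flat: np.ndarray) -> float:
        alphas = flat.reshape(3, self.K).T
        return pearson(self.img, self.render(alphas))


class _VolumeObjective:
    """3D analogue: correlation between target and warped reference."""

    def __init__(self, target: VolumeGrid, ref: VolumeGrid, spec: BasisSpec,
                 scale_radius: float, lambda1: float, seed: int):
        if target.box != ref.box:
            raise ValueError("target and reference must share the same box")
        box = ref.box
        self.box = box
        self.ref = np.ascontiguousarray(ref.values.reshape(-1), dtype=float)
        u = _unit_coords(box, ref.voxel_size, scale_radius)
        rho = np.linalg.norm(u, axis=1)
        self.inside = np.flatnonzero(rho <= 1.0)
        self.u_in = u[self.inside]
        self.B = evaluate_basis_matrix(spec, self.u_in)
        self.to_vox = scale_radius / ref.voxel_size
        self.base_vox = self.u_in * self.to_vox + box // 2
        self.target = target.values.reshape(-1)
        self.spec = spec
        self.K = spec.size
        self.gram = _penalty_gram(spec, box, seed)
        self.lambda1 = lambda1

    def render(self, alphas: np.ndarray) -> np.ndarray:
        from ._fastops import warp_flat

        if np.any(alphas):
            disp = self.B @ alphas
            sample = self.base_vox + disp * self.to_vox
            return warp_flat(self.ref, self.inside, sample, self.box)
        return self.ref

    def penalty(self, alphas: np.ndarray) -> float:
        return float(np.einsum("kd,kj,jd->", alphas, self.gram, alphas))

    def value(self, flat: np.ndarray) -> float:
        alphas = flat.reshape(3, self.K).T
        rho = pearson(self.target, self.render(alphas))
        return -(rho - self.lambda1 * self.penalty(alphas))

    __call__ = value

    def score(self, flat: np.ndarray) -> float:
        alphas = flat.reshape(3, self.K).T
        return pearson(self.target, self.render(alphas))


# ---------------------------------------------------------------------------
# Powell conjugate-direction search with a fixed line-search budget

def _line_search(f, x, direction, fx, step, maxiter):
    def g(t):
        return f(x + t * direction)

    res = minimize_scalar(g, bounds=(-step, step), method="bounded",
                          options={"maxiter": maxiter, "xatol": step * 5e-3})
    if res.fun < fx:
        return x + res.x * direction, float(res.fun), float(res.x)
    return x, fx, 0.0


def powell_search(f, x0, *, step=0.3, max_sweeps=5, ftol=1e-4,
                  line_maxiter=8, step_decay=0.5, after_sweep=None):
    """Powell's conjugate-direction minimization with bounded line searches.

    The line-search half-width shrinks by ``step_decay`` after every sweep,
    which lets late sweeps refine sub-voxel optima that the coarse first
    sweeps cannot resolve.  ``after_sweep(x)``, if given, may project the
    iterate (used for the in-plane restriction); the objective is
    re-evaluated afterwards.  Never returns a point worse than ``x0``
    under the final constraint set.
    """
    x = np.asarray(x0, dtype=float).copy()
    n = len(x)
    dirs = [np.eye(n)[i] for i in range(n)]
    fx = f(x)
    h = step
    for _ in range(max_sweeps):
        f_start, x_start = fx, x.copy()
        biggest_drop, biggest_i = 0.0, 0
        for i, d in enumerate(dirs):
            f_before = fx
            x, fx, _ = _line_search(f, x, d, fx, h, line_maxiter)
            if f_before - fx > biggest_drop:
                biggest_drop, biggest_i = f_before - fx, i
        # Powell's direction replacement along the net sweep displacement
        net = x - x_start
        if np.linalg.norm(net) > 0:
            x_try, f_try, t = _line_search(f, x, net / np.linalg.norm(net),
                                           fx, h, line_maxiter)
            if f_try < fx:
                x, fx = x_try, f_try
                dirs[biggest_i] = net / np.linalg.norm(net)
        if after_sweep is not None:
            x = after_sweep(x)
            fx = f(x)
        h *= step_decay
        if f_start - fx < ftol:
            break
    return x, fx


# ---------------------------------------------------------------------------
# public API

def regularized_objective(c: CoefficientSet, p: ParticleImage, v: VolumeGrid,
                          lambda1: float, seed: int = 0) -> float:
    """rho(I, C P_theta(V warped by c)) - lambda1 * integral |g|^2 dV.

    The same definition the optimizer maximizes (no downsampling applied).
    """
    obj = _ParticleObjective(p.pixels, p.pose, p.ctf, v, c.spec,
                             c.scale_radius, lambda1, seed)
    return -obj.value(c.flatten())


def _prepare_particle(p: ParticleImage, v: VolumeGrid, opt: EstimationOptions):
    """Fourier-crop particle and reference to the working box; soft low-pass."""
    img, ref = p.pixels, v
    if opt.box_work is not None and opt.box_work < p.box:
        img = fourier_crop_image(img, opt.box_work)
        ref = fourier_crop_volume(v, opt.box_work)
    px = ref.voxel_size
    if opt.lowpass_factor is not None:
        cutoff = opt.lowpass_factor * 2.0 * px   # in Angstrom
        img = _soft_lowpass(img, px, cutoff)
        ref = VolumeGrid(_soft_lowpass(ref.values, px, cutoff), px)
    return img, ref


def estimate_particle(p: ParticleImage, v: VolumeGrid, spec: BasisSpec,
                      opt: EstimationOptions | None = None
                      ) -> tuple[CoefficientSet, float]:
    """Estimate the deformation coefficients of one particle.

    Returns the coefficient set (in the full-size physical frame) and the
    final Pearson correlation.  Raises on blank (constant) particles.
    """
    opt = opt or EstimationOptions()
    if p.pose is None:
        raise ValueError("particle pose is required")
    if p.pixels.std() == 0:
        raise ValueError("blank particle: correlation undefined")
    scale_radius = v.default_scale_radius
    img, ref = _prepare_particle(p, v, opt)
    obj = _ParticleObjective(img, p.pose, p.ctf, ref, spec, scale_radius,
                             opt.lambda1, opt.seed)
    d = viewing_direction(p.pose)

    if opt.cancel_projection:
        # optimize inside the in-plane subspace, so every iterate (not just
        # the final result) has no field component along the viewing axis
        U = inplane_subspace(spec, d)
        y, _ = powell_search(lambda y: obj(U @ y), np.zeros(U.shape[1]),
                             step=opt.step, max_sweeps=opt.max_sweeps,
                             ftol=opt.ftol, line_maxiter=opt.line_maxiter,
                             step_decay=opt.step_decay)
        c = CoefficientSet.from_flat(spec, U @ y, scale_radius)
        c = cancel_projection_component(c, d)  # numerical belt-and-braces
    else:
        x0 = np.zeros(3 * spec.size)
        x, _ = powell_search(obj, x0, step=opt.step, max_sweeps=opt.max_sweeps,
                             ftol=opt.ftol, line_maxiter=opt.line_maxiter,
                             step_decay=opt.step_decay)
        c = CoefficientSet.from_flat(spec, x, scale_radius)
    return c, obj.score(c.flatten())


def estimate_volume(target: VolumeGrid, reference: VolumeGrid, spec: BasisSpec,
                    opt: EstimationOptions | None = None
                    ) -> tuple[CoefficientSet, float]:
    """Estimate coefficients deforming ``reference`` into ``target`` (3D mode).

    No CTF, no projection, no viewing-direction cancellation; used for
    placing maps (e.g. discrete class averages) into the same coefficient
    space as particles.
    """
    opt = opt or EstimationOptions()
    if target.box != reference.box:
        raise ValueError("target and reference must share box and sampling")
    scale_radius = reference.default_scale_radius
    tgt, ref = target, reference
    if opt.box_work is not None and opt.box_work < reference.box:
        tgt = fourier_crop_volume(target, opt.box_work)
        ref = fourier_crop_volume(reference, opt.box_work)
    obj = _VolumeObjective(tgt, ref, spec, scale_radius, opt.lambda1, opt.seed)
    x0 = np.zeros(3 * spec.size)
    x, _ = powell_search(obj, x0, step=opt.step, max_sweeps=opt.max_sweeps,
                         ftol=opt.ftol, line_maxiter=opt.line_maxiter,
                         step_decay=opt.step_decay)
    c = CoefficientSet.from_flat(spec, x, scale_radius)
    return c, obj.score(x)


def estimate_particles(particles, v: VolumeGrid, spec: BasisSpec,
                       opt: EstimationOptions | None = None,
                       threads: int = 1):
    """Estimate every particle; deterministic for a fixed option set and
    particle order (results are returned in input order regardless of
    ``threads``).

    Returns a list of (CoefficientSet, score).
    """
    if threads == 1:
        return [estimate_particle(p, v, spec, opt) for p in particles]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=threads)(
        delayed(estimate_particle)(p, v, spec, opt) for p in particles
    )
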