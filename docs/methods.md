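# Methods

## The model

A flexible macromolecule imaged by cryo-EM single-particle analysis
produces projections of many slightly different conformations.  zflex
represents the conformational change of each particle as a smooth 3D
displacement field `g(r)` applied to a reference density `V`:

    I ≈ C · P_θ( V(r + g(r)) ) + noise

where `P_θ` projects along the particle's viewing axis (with in-plane
shift), `C` is the particle's contrast transfer function, and the deformed
map is sampled by a gather: the output voxel at `r` reads the reference at
`r + g(r)`.  The field is expanded on the unit ball in products of
generalized Zernike radial polynomials and real spherical harmonics,

    g(r) = Σ_{l,n,m} (α^x, α^y, α^z)_{l,n,m} · Z_{l,n,m}(r),
    Z_{l,n,m}(r) = Rbar¹_{l,n}(|r|) · y_l^m(θ, φ),

with `Rbar^p_{l,n}(x) = √2·√(2n+l+p/2+1) · x^l · P_n^(0, l+p/2)(2x²−1)`
(Jacobi polynomial `P`), `p = 1` for volumes.  The basis is orthonormal on
the unit ball (verified by quadrature in the test suite to 1e-14).  A
truncation keeps `l ≤ L` and `2n + l ≤ N`; the default `N = 3, L = 2`
admits 13 index triples, i.e. a 39-component vector per conformation.
The joint bound `2n + l ≤ N` is the admissibility rule that produces this
count; enumeration order is lexicographic in `(l, n, m)`.

Assumptions inherited from the model: poses and CTFs are known and fixed
(no pose refinement); heterogeneity is conformational, not compositional;
deformations are smooth at the scale of the basis truncation and small
enough that a first-order treatment of the warp is meaningful (defaults
cap synthetic displacements at 10% of the box radius).

### Conventions

* The box centre (`voxel box//2`) is the origin; the unit ball is scaled
  by `scale_radius` (default: the inscribed radius, `box/2 ·
  voxel_size`).  Coefficients are dimensionless; physical displacement is
  `scale_radius · g(r/scale_radius)`.
* One sign convention package-wide: coefficients are the displacement
  *added to the sampling point* of a gather-warp.  Density content
  therefore moves by ≈ `−g`; atoms of a model follow the density, so
  `warp_model` with the *negated* coefficients matches a `warp_volume`
  with the coefficients themselves (`negate()` is provided, and
  `synthesize_state` handles the pairing internally).
* Euler angles are ZYZ intrinsic (rot, tilt, psi; degrees), the
  RELION/Xmipp convention; the pose matrix is `Rz(psi)·Ry(tilt)·Rz(rot)`
  and the viewing direction is its third row.  Shifts are in Å, applied
  in the image plane by a Fourier phase ramp.
* θ is the polar angle from +Z and φ the azimuth from +X everywhere.

## Rotation closure and viewing-direction consistency

The basis is closed under rotations: within each `(l, n)` shell the `m`
components mix by the real-spherical-harmonic rotation matrix, and the
3-vector coefficient parts rotate by the spatial rotation.  The per-`l`
rotation matrices are obtained numerically by sampling the harmonics at a
fixed, well-conditioned set of directions and solving the (exactly
linear) relation in the least-squares sense; for `l ≤ 4` this is accurate
to machine precision and is validated against the continuous-space
closure identity rather than trusted a priori.  On a voxel grid the same
identity holds only up to interpolation error — the package's tests
assert that the grid error exceeds the continuous error, which is why
coefficients are always un-rotated back to the map frame before use.

A single projection carries no information about deformation along its
viewing axis.  `cancel_projection_component` rotates coefficients so the
axis maps to +Z, zeroes the z column, and rotates back; the result
satisfies `g(r)·d = 0` identically, is idempotent, and never increases
the deformation magnitude.  Because this cancellation is a linear
projection of the coefficient vector, the per-particle optimizer works
directly inside its range (an orthonormal basis of the in-plane subspace,
26 of 39 dimensions at the default truncation), so every iterate — not
just the final result — is consistent with the particle's geometry.

## Per-particle estimation

For each particle the coefficients maximize

    ρ( I, C·P_θ( V(r + g(r)) ) )  −  λ₁ ∫_ball ‖g_pix(r)‖² dV

by Powell's conjugate-direction method from the all-zeros start, where ρ
is Pearson correlation over pixels and `g_pix` is the field expressed in
*working-box pixels*.  The penalty units matter: measured in pixels, a
field that moves density by a few voxels costs a few correlation points,
which is the scale at which the recommended `λ₁ ∈ [0.001, 0.01]`
(default 0.005) meaningfully trades deformation against correlation.
The penalty integral is evaluated as a quadratic form whose Gram matrix
is precomputed from 10⁴ fixed, seeded quasi-random unit-ball points, so
the optimizer sees a deterministic objective.

Optimizer details: bounded per-direction line searches (Brent-style,
budget 8 evaluations, half-width 0.06 in coefficient units) whose window
halves after each sweep — the coarse early sweeps find the basin and the
shrinking window resolves the sub-voxel optimum; Powell's direction
replacement along the net sweep displacement; absolute objective
tolerance 1e-6; at most 4 sweeps.  The objective is monotone by
construction and never ends below its zero-deformation start.  Estimation
is invariant to positive rescaling of the particle (Pearson correlation).

Particles may be band-limited and downsampled before the search by
cropping the Fourier transform to a working box (`box_work`); a soft
Gaussian low-pass at 2.5× the working Nyquist wavelength is applied by
default.  Cropping preserves the physical field of view, so the returned
coefficients apply to the full-size reference without rescaling.  For the
small boxes used here the default is the native box: at 48³ the
deformation signal is sub-voxel, and the interpolation mismatch
introduced by a 48→32 crop is larger than that signal.  For realistic box
sizes (≳128) a working box of ~96–128 is the intended regime, and
`rescale_coefficients` implements the general `α → k·α` scale conversion
between representations whose unit balls map to different physical radii.

`estimate_volume` is the same objective in 3D — correlation between a
target map and the warped reference, no CTF, no projection, no
cancellation — which places maps (e.g. discrete 3D-classification
averages) in the same coefficient space as particles.

## Conformational landscapes

Each estimated conformation is one row: a flattened 39-vector, its
provenance (particle / map / model), its deformation magnitude (mean of
`scale_radius·‖g‖` over the molecular mask, Å) and its correlation score.
Distances are Euclidean on the flattened vector — by orthonormality this
is an L² distance between fields up to the vector mixing.  KMeans runs on
the raw vectors (not the 2D embedding); each cluster is represented by
its *medoid*, the realized conformation nearest the centroid, so a
synthesized state always corresponds to something observed.
`synthesize_state` warps the reference map (and optionally an atomic
model, with the internal sign pairing) with a representative's
coefficients; the output keeps the reference's grid and sampling.  PCA is
the deterministic, tested embedding; UMAP is available pass-through.

## Reconstruction: ART and ZART

Classic ART sweeps shuffled particles, correcting the volume per image:

    V ← V + λ · P*( C( I_k − C·P·V ) )

The projector is real-space (rotate the sampling grid, trilinear
interpolation, sum along depth × voxel size); the backprojector is the
exact transpose of the same interpolation table, so the adjoint identity
holds to 1e-15 and the iteration is a true (relaxed) Kaczmarz step.  The
CTF enters the forward model and — being a real, even, symmetrized
Fourier multiplier, hence self-adjoint — also modulates the backprojected
residual.  Relaxation defaults: λ = 1e-3 with ×0.9 decay per epoch;
optional positivity clamp; fixed shuffle seed ⇒ bitwise-reproducible
output.

ZART threads each particle's deformation through the same loop: the
forward model is `C·P·W_g` (warp with the particle's field, then project)
and the correction is mapped back through the *exact adjoint* of the warp
— the transpose of the gather's trilinear weights, a scatter.  The
scatter equals the first-order inverse warp `W_{−g}` up to interpolation
error, but unlike it satisfies the dot-product identity to machine
precision; an approximate inverse-warp adjoint was measured to carry an
irreducible ~1.4e-2 interpolation floor at box 24, which motivated the
exact form.  With all-zero coefficient sets ZART reproduces ART bit for
bit.  On heterogeneous data, correcting each image's conformation before
comparing concentrates density that plain ART smears — the
motion-blur-reduction property asserted in the tests with both true and
estimated fields.

## Synthetic data

The generator emulates the forward model only — Gaussian-blob phantoms, a
bending-like ground-truth mode built from the `(l=1, n=0)` and `(l=2,
n=0)` terms (max-normalized over the ball), uniform random poses, random
astigmatic CTFs (10–20 kÅ defocus, 300 kV, Cs 2.7 mm, 10% amplitude
contrast), and white Gaussian noise scaled so that (in-support signal
variance)/(noise variance) equals the requested SNR.  The default scene
is a 48³ box at 2 Å/voxel with three asymmetric blobs, two of which sit
at high |z| where the bending mode displaces them strongly — deformation
of a few percent of the box radius then visibly moves density, which is
what makes recovery experiments informative at this scale.  Amplitude
laws: uniform (continuum) or a two-cluster Gaussian mixture (discrete
states); the generator records every truth (pose, CTF, coefficients,
clean image, cluster label).

The generator deliberately reuses the package's own warp/project/CTF
operators, so estimation tests probe inversion of the model rather than
operator mismatch; an independent brute-force ray-sum oracle guards the
projector itself.  It does *not* emulate structured ice/solvent noise,
amplitude falloff, dose or motion within a movie, pose/CTF estimation
error, or compositional heterogeneity — so passing tests demonstrate
correctness of the machinery and the qualitative claims (landscape
separation, blur reduction), not performance on real micrographs.

### What per-particle accuracy is attainable at desk scale

A single noisy projection carries limited information about a small
deformation.  Writing `ΔM` for the change the true field causes in the
clean image and σ² for the per-pixel noise variance, any unbiased
estimate of the ~26 in-plane coefficients has relative field error of at
least about `√(26σ²/‖ΔM‖²)`.  In the default scene at SNR 0.5 with ~3%
displacements this floor is well above 1 — per-particle fields at this
noise level are dominated by noise no matter the estimator, and the
regularizer's shrinkage (which is what keeps estimates bounded) caps the
error near 1 rather than below 0.3.  The same experiment without noise
recovers fields to ~20–30%.  This is why the landscape-level results are
the meaningful ones: clustering and state synthesis aggregate over many
particles.  The two-state separation experiment uses clearly distinct
states (amplitudes ±5% of the box radius) at SNR 2; at harsher noise the
label accuracy degrades first for particles whose viewing axis is nearly
parallel to the motion, because those views carry no in-plane signal
about it.

## Numerical choices

* Trilinear interpolation everywhere, with a single hand-rolled kernel
  (numba) shared by warp, projector and their transposes; out-of-box
  reads are 0; voxels outside the unit ball pass through warps unchanged.
* Basis evaluation caches radial/angular factors per `(l,n)` / `(l,m)`;
  points with |r| > 1 get zero rows; the origin's angles are defined as 0.
* Real spherical harmonics use scipy's `lpmv`; the Condon–Shortley phase
  of `lpmv` and the conventional `(−1)^m` factor cancel.  Orthonormality
  tests are convention-independent.
* CTF: `CTF(f) = −√(1−A²)·sin χ − A·cos χ`, `χ = πλΔf(ψ)|f|² −
  (π/2)Cs λ³|f|⁴`, underfocus positive, astigmatic `Δf(ψ)`, relativistic
  electron wavelength; the sampled multiplier is symmetrized across the
  unpaired Nyquist entries so the operator is exactly self-adjoint.
  The full signed CTF is used during estimation (no phase flipping).
* Fourier shift ramps are made real at each 1-D factor's Nyquist
  frequency, keeping the operator real-to-real with an exact transpose;
  fractional shifts are exact below Nyquist.
* Degenerate inputs raise: blank (constant) images for correlation,
  empty particle lists, empty masks, non-cubic volumes, zero directions,
  non-rotation matrices, k ≤ 0 rescales.
* Problem sizes used by the test suite: 48³ scenes for estimation
  experiments (100 particles for recovery, 40 for the two-state
  landscape), 32³ scenes with 120–300 particles for reconstruction
  comparisons, box 24 for adjoint identities.  These sizes make the full
  suite run in tens of minutes on one CPU while keeping every effect
  being tested (sub-voxel warps, CTF zeros, noise levels) within the
  regime the method targets.

## Known limitations

* Poses and CTFs are taken as given; errors in them alias into the
  estimated fields.
* The gather-warp is not volume-preserving (no Jacobian correction), and
  warped atomic models receive no stereochemical regularization — bond
  lengths and clashes are not restored.
* The basis spans smooth global motions; `N = 3, L = 2` cannot express
  sharp domain boundaries or localized loops, and large rotations are
  outside the small-deformation regime even though the optimizer will
  still improve the fit.
* Per-particle estimates at realistic SNR are noisy (see above); use them
  in aggregate.
* The ART family here is real-space and per-image; no Fourier gridding
  reconstruction, no gold-standard half-sets or FSC machinery, and no
  local-resolution estimation.
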