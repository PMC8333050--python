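# Methods

## Model

A volumetric view acquired at rotation angle φ is modelled as

    o_µ^φ = shift_m( R_φ(o) * h ) + ε

where `o` is the object, `R_φ` the rotation about the transverse (y)
axis, `h` the instrument PSF — an anisotropic Gaussian elongated along
the scan (z) axis — `m` a small rigid misalignment of the rotation
stage, and `ε` additive noise.  The default regime sets ε = 0 (high
SNR); Gaussian, Poisson and mixed noise models exist for stress tests.
Axis order is (z scan, y transverse, x lateral) throughout; positive
rotation angles move content from +x toward +z.

After rotating each view back to the reference orientation, the
equivalent description is `o * h^φ` with `h^φ` the PSF rotated by −φ,
which the renderer evaluates analytically (rotated covariance on the
voxel grid, no interpolation).  The two paths agree to interpolation
accuracy and exactly at multiples of 90°; the simulator uses
rotate-then-blur, the analytic path serves as its oracle.

## Correlation algebra

All convolutions and correlations are FFT-based with the zero lag at
`floor(shape/2)` and the convention `(a ⋆ b)(ξ) = Σ_y a(y) b(y+ξ)`.
Two modes exist: *circular* (cyclic on the input grid) and *linear*
(zero-padded to ≥ 2n−1 per axis, rounded to fast FFT lengths — the
auto-correlation of an n-signal lives on a 2n−1 translation space).
Everything runs in 64-bit floats; round-off negatives are clamped only
where a contract requires non-negativity (solver ratios, noise rates),
never elsewhere.

In circular mode `autocorrelate` first rolls the input's argmax voxel
to the grid origin.  This is mathematically a no-op (the
auto-correlation is shift-invariant) but makes the invariance *exact in
floating point*: two inputs differing by an integer circular shift
produce bit-identical outputs, which is the property the multi-view
fusion rests on.  The canonical anchor is the argmax; for inputs with
exactly tied maxima the tie is broken by C-order scan, which is
deterministic but can differ between a volume and its shifted copy —
irrelevant in practice for measured or simulated data.

## Inversion

Both solvers are multiplicative fixed-point schemes of the
Richardson–Lucy family, minimizing the Csiszár I-divergence
`Σ[χ log(χ/m) − χ + m]` of the model m against the target χ.

**Schulz–Snyder** (de-autocorrelation, model m = o ⋆ o):

    o ← o/(2Σo) · [ (χ/(o⋆o)) * o + (χ/(o⋆o)) ⋆ o ]

The bracket is the majorization-minimization pairing
Σ_ξ r(ξ)[o(x−ξ) + o(x+ξ)]; its two terms coincide when the target is
exactly centro-symmetric (which sanitized auto-correlations are up to
round-off), and this pairing is what guarantees the non-increasing
divergence trace asserted after every checkpoint.  Under the opposite
lag-sign convention the convolution term is written with the reflected
iterate õ; with our convention that variant is a symmetrization whose
trace is *not* monotone, so it is not used.

**Anchor-Update** (simultaneous de-autocorrelation and deconvolution,
model m = o * 𝒦 with 𝒦 = o ⋆ 𝓗 re-derived each step):

    o ← o/Σ𝒦 · [ (χ/(o*𝒦)) * 𝒦̃ ]

With 𝓗 = δ this collapses to the SS model (o ⋆ δ = õ), and the two
schemes agree to solver precision — a reduction the suite asserts.

Normalization: the leading 1/(2Σo) and 1/Σ𝒦 make an exact solution a
true fixed point.  Both updates map the total mass Σo to Σχ/Σo exactly
(derivable in closed form), so any mass other than √Σχ oscillates with
period 2 instead of damping.  `solve` therefore rescales the initial
guess once to the data-dictated mass √Σχ; afterwards the mass is pinned
and `(Σo)² = Σχ` holds along the whole run.

Further numerical choices:

* denominator floor `1e-12 × max(model)` guards the multiplicative
  ratio against empty model voxels; zero target voxels contribute 0 to
  the divergence (0·log 0 = 0);
* multiplicative updates preserve non-negativity and support (a zero
  voxel stays zero), so a support-restricted init keeps cyclic algebra
  exactly linear on padded grids.  The default init is a flat positive
  volume on the central half-grid window — a flat guess over the
  *whole* cyclic grid is itself a fixed point of the update and never
  moves;
* the iteration budget is the method's only essential parameter.  The
  desk-scale default is 5 000 iterations (checkpoint every 100); a
  convergence tolerance on the divergence drop per checkpoint window is
  available but off by default;
* padding: the pipeline defaults to the linear (2n−1) geometry for
  volumes up to 128³.  Circular (unpadded) inversion is allowed with a
  warning; it is sound when started from a close guess — the reference
  view or the registered mean — and is what the bundled study uses.

## Synthetic study conditions

The headline experiment (`phantom_experiment`, also behind
`scripts/acceptance.py` and the recovery tests) is fixed at:

* 48³ voxel grid at 1 µm pitch, margin of 14 zero voxels on every face
  (≥ 3σ_scan + the largest misalignment);
* phantom: 6 pointlike beads (amplitude ≈ 2, min. separation 5 voxels)
  plus a branching random-walk vessel tree with hollow lumina (walls at
  1.0) — beads read out the effective PSF, vessel walls probe paired
  fine structure;
* PSF: Gaussian with σ_lat = σ_transverse = 1 µm, σ_scan = 3 µm (3:1
  axial elongation typical of LSFM detection);
* acquisition: a full turn in 30° steps (12 views), cubic-spline
  rotations, per-view uniform integer shifts in [−4, 4] voxels
  (reference view pinned at zero), no noise;
* inversion: 5 000 SS/AU iterations, circular mode, reference-view
  init; the AU anchor is the true 𝓗̄ rendered from the PSF model.

These sizes keep the full study at a few minutes on one CPU while
leaving the orderings it demonstrates (unregistered < SS < AU recovery;
AU beads at least as narrow as SS beads) stable across seeds.  The PSF
analysis uses two orthogonal views (0°, 90°) of the same PSF; the
effective PSF 𝒜⁻¹{𝓗̄} is computed by SS from a centered isotropic
Gaussian (σ = 2 voxels), re-centered on its centroid, and compared to
h̄ by FWHM along the former scan axis.

## What the generator does and does not emulate

The simulator reproduces the geometry and statistics that matter for
alignment-free fusion: anisotropic blur rotating with the view, rigid
per-view misalignment, rotation interpolation error, optional counting
noise.  It does not model scattering, absorption, stripe artifacts,
rotation-stage tilt (non-rigid errors), depth-dependent PSF variation
or camera fixed-pattern noise.  Passing tests therefore demonstrate the
algebraic and statistical machinery, not robustness to those
instrument-specific effects.

## Measurement conventions

* FWHM: 1D profile through the global argmax, cubic-resampled at 1/64
  voxel, linear interpolation at the half-maximum crossings; spike-like
  peaks (both neighbours already below half maximum) fall back to
  linear resampling to avoid cubic overshoot.  Reported in µm via the
  voxel pitch.
* Recovery score: Pearson correlation maximized over all global
  circular shifts and the flip, i.e. over the exact ambiguity group of
  de-autocorrelation.  Unrelated 48³ volumes score ≈ 0.014, so the
  scores above 0.5 in the study are far outside the null.
* Bead widths are measured at the most isolated bead (largest distance
  to any other structure) after aligning the reconstruction to the
  truth; beads shouldered by vessels have no clean half-maximum
  crossing and are skipped.

## Known limitations

* De-autocorrelation is recovered only up to global shift and flip; all
  comparisons must (and here do) quotient that group out.
* Integer-pixel registration only in the direct-fusion baseline;
  sub-pixel upsampled registration is out of scope by design.
* Circular-mode inversion without a close guess can stall in symmetric
  fixed points; use the padded geometry or a structured init.
* Convergence of both solvers is slow (each update is close to the
  previous); the iteration budgets here are desk-scale, and long runs
  simply continue the same monotone descent.
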