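# Methods

This note records the model implemented by `fptycho`, the conventions and
defaults it commits to, and the reasoning behind the design choices that
were genuinely open.

## Forward model

A thin sample is described by its complex transmission o(r) on a
high-resolution grid of side N·f (N = raw image side, f = upsampling
factor).  Illumination by the n'th LED is a tilted plane wave whose
directional sines are computed with the exact sine (not the paraxial
tangent): an LED at physical offset (dx, dy) mm and distance h mm
contributes (−dx, −dy)/√(dx²+dy²+h²).  The outer LEDs of the reference
bench sit at 28 mm on a 90 mm throw — well outside the paraxial regime, so
the tangent approximation would misplace the outer apertures by several
Fourier pixels.

In Fourier space the measurement is the shifted sub-aperture

    φ_n(k) = O(k + k_n) ⊙ C(k),    I_n(r) = |F⁻¹{φ_n}|² / f²,

where C is the pupil (binary CTF of radius NA/λ times any aberration
phase).  Conventions:

* All spectra are DC-centered (zero frequency at index n//2); all FFTs are
  unitary (`norm="ortho"`), so Parseval holds without factors and the
  adjoint of the inverse transform is the forward transform.
* The frequency step is 1/(N·Δx) with Δx the object-plane pixel pitch
  (camera pixel / magnification); it is the same on the low- and high-res
  grids (same field of view), which is what makes aperture extraction a
  plain crop.
* Wave vectors are converted to *integer* high-res Fourier-pixel shifts
  (nearest-integer rounding); spectra are shifted by whole pixels.
  Sub-pixel shifts are out of scope.
* The 1/f² intensity scale fixes the flat-field: a unit-amplitude object
  under the ideal on-axis pupil yields an image of exactly 1.  No other
  radiometric scale is modelled.
* Downsampling is realized purely by the Fourier crop.  There is no
  separate detector-binning model; the factor-f crop *is* the camera.

The sign convention (LED at +offset → spectrum sampled at +pixel-shift
via O(k + k_n)) is fixed once in `led_wave_vectors` and shared by the
simulator and both reconstructors through a single `IlluminationSet`; only
this consistency, not the sign itself, is physically meaningful.

## Zernike pupil model

The pupil phase is ∠C(k) = Σ c_l Z_l(k) with OSA/ANSI single-index
ordering and **unnormalized** radial polynomials (peak 1 at the disc edge;
defocus is 2ρ²−1, not √3(2ρ²−1)).  ρ is the radial frequency divided by
the objective cutoff NA/λ, so the basis lives exactly on the CTF support.
With this convention, 50 µm of defocus behind a 0.1 NA objective at 532 nm
projects to a defocus coefficient of −1.48 rad (the small-NA closed form
−(2π/λ)·z·NA²/4 gives −1.477; the exact-sine projection −1.480).  The
orthonormal convention would give −0.85 for the same field, which is
inconsistent with the ≈ −1.44 figure commonly quoted for this bench; the
residual −1.44 vs −1.48 discrepancy (≈ 3%) is attributed to disc-sampling
or rounding in the quoted figure and is within the 5% tolerance used
throughout.

Decomposition of a phase map onto the basis solves ridge-stabilized
normal equations (ridge 10⁻¹² of the mean Gram diagonal) over the disc
pixels.  Piston is carried in every coefficient vector for bookkeeping but
never trained: it is a global phase with no effect on intensities.

Default mode count L = 9 (the modes after piston through trefoil/coma
order): these dominate common microscope aberrations.  L is configurable
(tested up to 50) at unchanged per-iteration cost — mode evaluation is a
precomputed tensor contraction.

## Gradient reconstruction

The reconstructor minimizes, per varying-angle illumination unit (VAIU —
one image paired with its wave vector),

    loss_n = ‖φ_h − φ_l‖² + α₁·TV(amplitude) + α₂·TV(phase),

where φ_l is the model sub-aperture and φ_h = F{√I_n ⊙ phasor(F⁻¹{φ_l})}
is its alternating-projection (AP) update.  Trainable leaves: the
two-channel (real, imaginary) object *spectrum*, the Zernike coefficient
vector, and (optionally, default on) the pupil amplitude map, clamped to
[0, 1] and masked to the NA disc after every step.

**Exact explicit gradients.**  The backward pass is derived by Wirtinger
calculus through the crop (adjoint: scatter), the complex product
(adjoint: conjugate multiply), the unitary FFTs (adjoint: inverse), the
amplitude/phase extractions, and the TV stencil, and is validated against
central finite differences in the unit tests.  Two conventions matter:

* φ_h is the *projection target*: no gradient flows through the modulus
  replacement.  This is the classical alternating-projection reading of
  the update and keeps gradients bounded at vanishing moduli; at the AP
  fixed point the data gradient vanishes either way.
* Pixels of exactly zero modulus use phasor 1 in the AP step, and the
  phase-extraction gradient (which carries a 1/a factor) is masked where
  the modulus is negligible — phase is undefined there.

**Alternate updating (AU).**  Training is divided into stages (default 10)
of a few epochs (default 5); odd stages update only the sample, even
stages only the pupil parameters, starting with the sample.  The sample
and pupil have very different gradient sensitivities; with simultaneous
updates the pupil chases the under-converged sample and the coefficient
estimate degrades (the ablation test measures exactly this ordering).
Each epoch takes one adaptive-moment (Adam) step per VAIU in a fixed
center-outward spiral (optionally a seeded shuffle, or one accumulated
step per epoch).  Optimizer state persists across stages.

**Learning rates.**  Defaults: sample 10⁻², pupil phase 10⁻² rad, pupil
amplitude 10⁻³ (Adam, β = 0.9/0.999).  No published values exist for this
schedule; these were fixed by synthetic benchmark sweeps with known ground
truth.  Raising the sample rate to 2×10⁻² speeds data-loss convergence
but lets the object absorb part of the aberration before the pupil stages
can fit it, degrading coefficient recovery from ~3% to ~7% error — hence
the slower default.

**Initialization.**  The object starts as the square root of the on-axis
image, *sinc-upsampled* (Fourier zero-padding) to the high-res grid with
zero phase; the pupil starts as the ideal binary CTF with zero
coefficients.  Sinc upsampling is alignment-exact with respect to the
Fourier-crop decimation of the forward model.  A real-space interpolator
on pixel cells (e.g. bilinear) offsets the grids by (f−1)/2 high-res
pixels; because an object shift and a compensating pupil tilt are a gauge
freedom of intensity data, the optimization then parks ~0.35 rad in the
tilt coefficients and the aberration estimate is polluted.

**Divergence guard.**  A run aborts (`ReconstructionDiverged`) if the
epoch-mean total loss exceeds 10³ × its value at initialization.

## Total-variation regularization

TV is the isotropic forward-difference form, per-pixel (dx²+dy²)^(η/2)
with η = 1 by default and differences zero at the last row/column.  Its
gradient uses a Charbonnier floor (ε = 10⁻⁸) at the non-differentiable
point; the floor never affects reported values.

Where TV acts was a genuinely open design point, resolved empirically:

* `tv_target="object"` (default): TV is applied to the amplitude and the
  wrapped phase of the *current high-resolution object estimate* F⁻¹{O}.
  Both terms then carry gradients into the object and smooth the actual
  deliverable of the method.
* `tv_target="ap_field"`: TV applied to the spatial transform of φ_h, the
  literal reading of the loss above.  Note that |F⁻¹{φ_h}| = √I_n exactly
  — the amplitude term is then *constant* (it is measurement data) and
  only the phase term regularizes.  The variant is kept for comparison;
  it cannot reproduce an amplitude-denoising effect by construction.

Two further choices matter in practice:

* **Decoupled (proximal-style) application.**  Feeding a small persistent
  TV gradient through Adam moves weakly-data-constrained spectrum pixels
  at full sign-speed regardless of the weight — the well-known pathology
  of coupled regularizers under adaptive normalization — and over-smooths
  at any nominal α.  The TV step is therefore applied *outside* the Adam
  update, as `lr_sample · α · ∇TV`, so its strength scales with α.
* **Auto-balancing.**  `alpha1=None`/`alpha2=None` set the weights to
  10⁻² (amplitude) and 10⁻³ (phase) times the ratio of the data loss to
  the amplitude-TV of the initialization.  The initialization's *phase*
  TV is not a meaningful scale (the starting phase is identically zero up
  to sinc-ringing sign flips), so both terms balance against the
  amplitude scale.  The two multipliers were chosen by sweeps on noisy
  synthetic benchmarks: the amplitude term carries the denoising and
  tolerates a ~10× larger weight than the phase term before
  over-smoothing sets in.  Explicit weights remain fully exposed; as with
  any TV method, strength ultimately needs manual adjustment per noise
  regime.

## ePIE baseline

The comparison engine is plain AP with the standard conjugate-weighted
ePIE update pair (object patch += α·conj(P)/max|P|²·Δ, pupil +=
β·conj(O)/max|O|²·Δ, defaults α = β = 1, 50 sweeps), pupil masked to the
NA disc, same initialization and LED ordering as the gradient engine.  The
recovered pupil is free-form; for coefficient comparisons its phase is
decomposed onto the Zernike basis afterwards.  Step-size formulas follow
the standard ePIE literature; baseline comparisons are qualitative
(structure and sign of the recovered aberration), not number-matched.

## Simulator and phantom

The simulator emulates a defocus- (or arbitrarily Zernike-) aberrated
acquisition: one image per LED through the aberrated pupil, noiseless by
default.  Optional noise: additive Gaussian with σ a fraction of the
*stack peak* intensity (a fixed-exposure model — dark-field images then
carry much lower SNR than bright-field, which is the hard, realistic
regime), or Poisson with a photon budget at peak, both seeded and clipped
at zero.

The phantom is a synthetic complex object (smooth seeded blobs plus sharp
bars and a step edge; amplitude in [0.1, 1], independent phase pattern in
[−π/2, π/2]) standing in for natural-image test targets.  What the
simulator does **not** model: LED position miscalibration, intensity
falloff across the matrix, partial coherence, sample thickness
(multi-slice), sensor saturation/quantization.  Passing tests therefore
demonstrate correctness of the inverse computation under the stated
forward model, not robustness to these real-bench effects.

## Evaluation metrics

Reconstructions are compared after removing the global-phase gauge
(closed-form alignment maximizing Re⟨recon, truth⟩).  By default the
truth is low-passed to the synthetic-NA disc first: content beyond NA_syn
is physically unrecoverable, and including it would penalize every engine
by the same irrelevant constant.  Reported: relative L2 amplitude error,
RMSE of the wrapped phase difference, and per-mode absolute coefficient
errors (piston excluded).  The object-shift/pupil-tilt gauge is *not*
removed by the metrics; keeping the initialization alignment-exact (above)
is what pins it.

## Problem sizes used in validation

The end-to-end suite runs the reference bench at full scale: 225 images of
32×32 from 128×128 phantoms, 10 stages × 5 epochs, defocus −1.48 rad,
three phantom seeds for the recovery experiment, one seed for each
ablation.  Unit tests use a reduced bench (7×7 LEDs, 16×16 images, 2×
upsampling) with identical optics, where a full reconstruction takes well
under a second.  A full-scale reconstruction takes roughly 10–30 s on one
CPU core depending on the options.

## Known limitations

* Whole-pixel spectrum shifts bound the aberration model: tilt-like
  residuals below half a Fourier pixel are absorbed into the object.
* TV on the phase operates on the wrapped principal value; samples whose
  true phase spans close to ±π will see spurious TV penalty at wraps.
* Under heavy noise the AP modulus replacement re-injects the (rectified)
  noise floor every epoch; TV mitigates but cannot remove the resulting
  amplitude bias in dark-field-dominated frequencies.
* The divergence guard is a blunt instrument; pathological-but-bounded
  trajectories are not detected.
* No GPU path; the implementation is vectorized numpy throughout.
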