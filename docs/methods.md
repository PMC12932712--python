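# Methods

This note records the model conventions, parameter choices and numerical
decisions behind `pwftomo`, in the spirit of a methods section: enough
detail that every number the package produces can be traced to a stated
assumption.

## Physical model

A thin sample with complex refractive index `n = 1 − δ + iβ` multiplies
the incident plane wave by the exit field `x = e^ψ`, where the complex
phase of a projected thickness `T(x, y)` is

```
ψ = −(2π/λ) (β + iδ) T        (Re ψ ≤ 0: attenuation; Im ψ: phase)
```

Working with `ψ = log x` rather than `x` makes the phase unwrapped by
construction, which matters because projected phases of tens of radians
are routine at 10 keV.

The field propagates `L₁` to the diffuser (transmission `t`), then `L₂`
to the detector, by the exact scalar angular-spectrum method:
multiplication in the Fourier domain by
`H(u,v) = exp(i 2π (d/λ) √(1 − (λu)² − (λv)²))`, with evanescent
components (`(λu)² + (λv)² > 1`) set to zero. Hard clipping (rather than
exponential decay) keeps the adjoint of the propagator exact, and at
millimetre-to-centimetre distances evanescent terms are numerically zero
anyway. No zero padding is applied by default, matching single-FFT
processing of full detector frames; wrap-around is negligible for the
diffuse fields used here. A sampling check warns when the kernel phase
would alias at the band edge.

Partial coherence enters as a convolution of the *intensity* with a
separable Gaussian IPSF of widths `x_coh, y_coh` (the spatial coherence
lengths at the detector), implemented as multiplication by the IOTF
`exp(−(π/2)(u²x_coh² + v²y_coh²))` — exactly equivalent on the periodic
grid. The full forward model is therefore

```
f(ψ) = |P₂{t · P₁{e^ψ}}|² ⊛ IPSF .
```

## Coherence calibration

For fully developed speckle, the Siegert relation `g⁽²⁾ = 1 + |g⁽¹⁾|²`
ties the intensity autocorrelation to the field coherence. The
calibration computes a 1D circular autocorrelation per axis via FFT
(averaged over the orthogonal axis, lags restricted to a quarter of the
axis to avoid wrap bias) and fits `1 + c·exp(−πΔ²/ℓ²)` with the
contrast `c` free — detector binning and finite coherent-grain size push
`g⁽²⁾(0)` below 2, so pinning `c = 1` would bias `ℓ`. The recovered
length is the width of the *blurred* intensity correlation; it equals
the configured coherence length only when the underlying coherent
speckle grain is much finer than the blur (true for the default
simulated diffuser; the deviation grows as grain/blur approaches 1).

The expected spatial resolution, assuming the sample spectrum is
retrievable out to the `STF = 0.1` boundary, is the closed form
`√π·x_coh/(2 ln 10) ≈ 0.385 x_coh` per axis (natural logarithm — the
only reading consistent with the 0.385 value), with the root mean square
of the two axes as a scalar summary. The algebraic route from the STF
boundary to this exact prefactor is not reconstructable from the
Gaussian STF alone; the closed form is implemented as printed and used
as-is.

## Diffuser transmission and its limits

The diffuser transmission is estimated from the reference speckle alone:
Wiener-deconvolve the coherence blur with the calibrated IOTF (default
noise-to-signal 1e−2, configurable; smaller for noiseless data), take
the square root of the (clipped-nonnegative) intensity — the square root
because `t` multiplies a *field* — assign zero phase at the detector,
and back-propagate by `−L₂`. The zero-phase convention is exact for
nothing but guarantees one property, which the package tests: the
estimated `t`, propagated forward and re-blurred, reproduces the
reference speckle.

Its validity for *sample* retrieval rests on a ray-optics separation of
scales: the sample's phase must vary slowly over one speckle grain, so
that the intensity response is dominated by speckle displacement (which
is insensitive to the diffuser's phase) rather than by interference
terms (which are not). In the beamline geometry the sample features are
tens to hundreds of grains wide and the convention holds; on a
128-pixel simulation the ratio is only a few, and quantitative phase
amplitudes retrieved through the zero-phase estimate are systematically
low (measured forward-response correlations of 0.65–0.95 against the
true screen, depending on screen depth). The pipeline therefore
supports `diffuser="known"` for synthetic data — using the simulator's
actual phase screen — to validate the solver and tomography stages under
zero model mismatch, which is also what the quantitative end-to-end
tests use. Experimental data necessarily use `diffuser="estimated"`.

## The PWF iteration

The loss is the squared intensity misfit plus a Tikhonov term weighted
by `Γ² = 1 − STF`, with `Re α` on the attenuation channel and `Im α` on
the phase channel. The data-term gradient is the exact Wirtinger
adjoint chain through the forward model (residual → IOTF window → `|·|²`
→ `P₂†` → `conj(t)` → `P₁†` → `conj(e^ψ)`), verified against central
finite differences to better than 1e−5 relative error.

Numerical conventions that make the fixed step `η = 1` meaningful:

* the gradient is normalized by `8·max(y)²`, the scale of the largest
  Gauss–Newton curvature of an intensity least-squares fit — without
  this, a unit step diverges immediately for any realistic intensity
  normalization;
* the preconditioner `P⁻¹ = 1/(u² + v²)` uses frequencies in cycles per
  pixel with the DC term set to zero; the DC phase is re-anchored every
  iteration by zeroing the mean phase over a border mask (default: a 5 %
  frame border assumed sample-free). Measured curvature spectra of the
  data term confirm `λ(q) ∝ q²` for the phase channel at low frequency,
  which is exactly what the inverse-quadratic filter equalizes. Beyond
  equalizing convergence rates, the preconditioner biases the iteration
  toward explaining the data with smooth phase — the physically correct
  channel — rather than with fine attenuation structure.

Two further choices:

* **Non-positive attenuation projection** (`Re ψ ≤ 0`, default on): a
  passive sample cannot amplify the beam. On small noiseless frames
  this physical constraint also suppresses spurious sign-alternating
  attenuation structure that can mimic phase-displacement signatures.
* **Nesterov momentum** with the standard `t` sequence and a restart
  whenever the loss jumps by more than an order of magnitude.

The iteration starts from `ψ = 0` (the empty-beam field) and stops when
the normalized correlation between successive retrieved fields `e^ψ`
exceeds `10^(−0.00001)`, evaluated after a configurable minimum
iteration count (with the normalized step the correlation can cross the
threshold spuriously early); the desk-scale pipeline preset instead
runs a fixed budget of 1400 iterations for bit-reproducibility, in line
with the 700–1300 iterations typical of converged runs at full frame
size. Divergence (non-finite loss) raises an error naming the last
finite iteration.

`α` is a signal-to-noise-dependent heuristic. The shipped defaults are
`γ = 1`, `α = 0.1 + 0.01i`, `η = 1` (the full-frame beamline values);
the noiseless desk-scale pipeline preset reduces it to `α = 0.01 + 0i`
— noiseless data need no phase-channel damping, and the phase shrinkage
`α` causes grows as the measured curvatures shrink with frame size.

## Tomography

Per-angle phase maps are assembled into per-slice sinograms (one slice
per vertical detector row — the rotation axis is vertical and assumed
centred) and inverted with `skimage`'s parallel-beam `iradon` (Ram–Lak
filter, no apodization, linear interpolation). The phase sinogram is
`−Im ψ` and the attenuation sinogram `−Re ψ`, so both volumes are
non-negative for physical samples (`n = 1 − δ + iβ` fixes both signs).
The unit-spacing FBP output is converted to δ or β by the single
constant `λ/p/(2π)` with `p` the reconstruction pixel pitch. Residual
low-frequency background (the known weakness of phase-gradient sensing)
is removed by a per-slice least-squares quadratic fit over a background
mask — default: voxels outside a cylinder of 90 % of the slice width.
The Crowther bound `round(πD/(2d))` reports the minimum number of
projections for a diameter-`D` object at resolution `d`.

## Fourier shell correlation

FSC uses one-voxel-wide shells on the unshifted DFT radius and the real
part of the cross term (standard practice). Decomposing two
reconstructions into shared signal and independent noise gives
`FSC = S/(S+N)` per shell, and requiring the signal correlation
`√(S/(S+N))` to exceed a floor `c` yields the threshold `c²`; the 1/2
floor gives the 1/4 criterion appropriate for a single-shot method
(no half-set averaging, hence no 1/7 extrapolation). The resolution is
the inverse of the first threshold crossing, linearly interpolated; a
curve that never crosses returns the Nyquist bound with a flag.
Anisotropic voxels are not supported.

## Synthetic-data generator

The generator is the package's study-condition definition, not a demo:

* **Geometry**: the beamline constants (λ = 0.124 nm, pitch = 650 nm,
  L₁ = 3 mm, L₂ = 20 mm) on a 128² frame (83 µm field of view).
* **Coherence**: x_coh = 1.3 µm, y_coh = 1.625 µm (2 / 2.5 pixels).
  The beamline's calibrated 3.47 / 4.31 µm spans ~5–7 pixels; on a
  128-pixel frame that blur would suppress the IOTF to ~1e−5 at the
  speckle-grain frequency and erase the information phase retrieval
  needs. The simulated source is proportionally more coherent so the
  observed speckle (contrast ≈ 0.5) retains retrievable bandwidth.
* **Diffuser**: a unit-amplitude Gaussian phase screen, correlation
  length 3.38 µm (5.2 px) and standard deviation 6 rad — a deep screen
  like stacked fine-grit sandpaper. The resulting coherent field
  decorrelates below one pixel, so the Siegert calibration of the
  blurred reference recovers the configured coherence lengths within a
  few percent.
* **Phantom**: three glass-like beads (δ = 6e−6, β = 4.5e−8 —
  representative of soda-lime glass at 10 keV), radii 6–8 µm. Peak
  projected phases are a few radians and refraction displacements stay
  well below one speckle grain: the small-displacement regime in which
  the speckle encodes the phase linearly. An optional cylinder
  component (axis along the rotation axis) emulates a support stick.
  Projected thicknesses are analytic sphere/cylinder chords, so the
  ground truth has no ray-marching error.
* **Noise**: Poisson at a configurable mean photon count (default
  noiseless), applied last; optional Gaussian read noise on the dark
  frame. A fixed seed reproduces every frame bit-exactly.
* Partial coherence is simulated exactly as the model assumes (IOTF
  windowing of the intensity), so the default datasets probe solver
  correctness with zero model mismatch — robustness to model violation
  is a separate question the generator does not answer.

What passing the synthetic tests does **not** show about real data:
detector MTF beyond the coherence blur, polychromaticity, rotation-axis
misalignment, sample-induced decoherence (dark-field beyond the IOTF
model), and the accuracy of the zero-phase diffuser estimate at
realistic feature-to-grain ratios are all outside the simulated
conditions.

## Reported problem sizes

The quantitative end-to-end reconstruction runs the default conditions
above — 128² frames, 60 angles over 0–180°, noiseless, known screen,
1400 iterations per angle — and evaluates bead interior means over
voxels within 60 % of each bead radius (excluding the partial-volume
and Ram–Lak-ringing shell). Unit and property tests use 8²–64² frames;
coherence statistics use 1024² frames. These sizes are chosen so the
full suite runs on a single CPU core in minutes while every stage still
operates in its intended physical regime.

## Known limitations

* The zero-phase diffuser estimate is quantitative only for samples
  whose features span many speckle grains (see above); the package
  reports what it can verify and exposes the known-screen path for
  simulation studies.
* `γ = 1` leaves the single-shot inverse problem marginally determined;
  identifiability in practice rests on the preconditioner's smooth-phase
  bias, the attenuation non-positivity constraint, and the Γ² window.
* The rotation axis is assumed vertical and centred (an integer-pixel
  offset can be corrected upstream of FBP); no ring-artifact removal or
  iterative tomography is provided.
* Single-measurement (K = 1) retrieval only; joint sample–diffuser
  retrieval is out of scope by design.
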