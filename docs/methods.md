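# Methods

## Problem and physical model

A thin transparent specimen (an unstained cell slice is the canonical
example) delays the optical wavefront without absorbing it.  Illuminated by
a coherent plane wave of wavelength λ, its transmission is the unit-modulus
field

    U0(x, y) = exp[i φ(x, y)],

where φ is the quantity of interest (radians).  A bare detector at distance
d records only the diffraction intensity

    I(x, y; d) = |U_d|²,   U_d = F⁻¹{ F{U0} · G },
    G(fx, fy) = exp[i k d √(1 − λ²fx² − λ²fy²)],   k = 2π/λ,

the exact scalar angular-spectrum propagator.  Recovering φ from the single
intensity I is the phase-retrieval problem this package solves.

Discretisation conventions (fixed, because the continuous model does not
pin them down): unshifted DFT layout with DC at index (0, 0); forward
transform with negative exponent; pixel-centred samples at the detector
pitch; SI units internally.  Spatial frequencies with λ²f² > 1 are
evanescent and their transfer-function entries are set to zero, so |G| ∈
{0, 1} and propagation is unitary on the propagating band — this is what
makes the round-trip, semigroup and energy-conservation test invariants
exact.  The default boundary model is periodic (`pad_factor=1`); optional
padding embeds the phase map in a transparent (unit-amplitude) surround,
which is the physically right continuation for a phase-only object, and
crops back to the sensor after propagation.

## The untrained-network reconstruction

A randomly initialised convolutional encoder–decoder R_θ maps the measured
intensity to a candidate phase.  Its parameters are fitted to the *single*
measurement through the physical model:

    θ* = argmin_θ ‖ H(R_θ(I)) − I ‖²,    φ̂ = R_θ*(I),

where H is the forward model above.  No ground truth and no training set
appear anywhere: the convolutional architecture itself supplies the implicit
smoothness/self-similarity prior (the deep-image-prior effect), and the
physics supplies the data constraint.  The package verifies the "no ground
truth" property literally: supplying a reference phase for diagnostics
changes no bit of the output.

Optimisation recipe (defaults):

| parameter        | default | notes                                          |
|------------------|---------|------------------------------------------------|
| optimiser        | Adam    | lr 0.01, β = (0.9, 0.999)                      |
| epochs           | 10 000  | fixed budget; optional plateau stop            |
| input noise      | U[0, 1/30] | fresh draw added to the fixed input each epoch |
| loss             | mean squared error on intensity                          |
| normalisation    | I divided by its mean before optimisation                |

The mean-normalisation puts the measurement on the same unit-mean scale as
the plane-wave forward model, so the 1/30 input-noise amplitude and the
fidelity are well-scaled regardless of detector gain.  The per-epoch input
noise is a stochastic regulariser; it is removed for the final read-out
pass.  Batch-normalisation layers always use the current image's statistics
(a batch of one has no meaningful population statistics, so the final clean
pass reuses training-mode behaviour).

### Network

U-Net with `n_scales` resolution levels (default 4), two 3×3
convolution + batch-norm + leaky-ReLU (slope 0.1) blocks per level,
2×2 max-pooling on the way down, 3×3 up-convolutions (zero-stuffed
stride-2 transposed convolutions) on the way up, and skip connections.
Channels double per level from `base_channels` (default 16).  He-normal
initialisation, fully seeded.

### Output activation: why softplus is the default

The output layer must produce a nonnegative phase (anchoring the piston
ambiguity at zero).  A hard ReLU output seems natural, but under the
default recipe it has an *absorbing failure state* that we characterised
carefully on weak-contrast near-field scenes (smooth 1-rad object,
d = 10 mm, 64-px grids): the randomly initialised output starts several
radians hot, the first Adam steps (which move every parameter by ≈ lr
regardless of gradient magnitude) overshoot the whole pre-activation map
below zero within ~10 epochs, and with every rectifier unit dead the
gradient is identically zero forever — the reconstruction freezes at the
flat phase.  Near-zero output initialisation and surrogate gradients do not
cure this.  A softplus output, log(1 + eˣ), is the smooth rectifier: it
preserves nonnegativity exactly, behaves like ReLU away from zero, but
keeps a gradient everywhere, so amplitude can regrow after an overshoot.
With it the same scenes converge reliably.  `relu` and `scaled_sigmoid`
(range [0, 2π]) remain selectable in `NetworkSpec`; far-field scenes
(d ≳ 95 mm here) also converge with plain `relu`.

### Multiple measurements

With intensities I_i recorded at several distances the objective becomes
Σ_i ‖H_i(R_θ(I_1)) − I_i‖², the first measurement serving as the fixed
network input.  A one-element list reduces exactly (bit-identically) to the
single-measurement method.

### Numerical framework

The network and its training loop are implemented directly on NumPy with
explicit backward passes (im2col-style convolutions reduced to single BLAS
GEMMs, a fused flat-buffer Adam), in float32.  The gradient of the fidelity
with respect to the phase goes through the complex forward model
analytically (Wirtinger calculus: the adjoint of angular-spectrum
propagation is back-propagation with the conjugate transfer function).
Every gradient path — layers, skips and physics head — is verified against
central finite differences in float64 in the test suite.  Determinism: one
master seed is split into independent streams for network initialisation
and input noise; two runs with equal seeds are bit-identical on the same
machine.

## Baselines

**Gerchberg–Saxton (multi-plane).**  Alternating projections with the
phase-only (unit-modulus) constraint at the object plane and modulus
replacement √I at each measurement plane, cycled in ascending distance
order, zeros initialisation by default.  The free piston is removed by
subtracting the mean phase.  On noise-free data the single-plane modulus
mismatch is non-increasing (classic error-reduction behaviour, asserted in
tests).

**Transport of intensity.**  −k ∂I/∂z = ∇·(I ∇φ), with the axial
derivative from the central difference of two planes ±Δz around the
measurement plane, inverted spectrally.  The default `uniform` mode uses
the weak-object simplification ∇²φ = −k (∂I/∂z)/Ī (phase-only objects
under near-unit illumination); a `full` mode implements the exact two-step
inversion.  The Poisson inverse is singular at DC; division is
Tikhonov-regularised by ε·max|q|² (ε = 1e−9) and the DC mode (the free
piston) is zeroed.  The recovered phase lives at the central plane, which
for smooth objects in the near field is an accurate surrogate for the
object-plane phase.

**Regularisation by denoising (RED).**  Adds the penalty
(λ/2) φᵀ(φ − D(φ)) to the fidelity, with φ the network output and D a
pluggable denoiser (built-ins: identity, circular Gaussian blur, one
total-variation proximal step).  The gradient used is λ(φ − D(φ)), exact
for a linear symmetric D (verified against finite differences) and the
standard fixed-point update otherwise.  λ defaults to 0.05; with λ = 0 the
method reduces bit-identically to the plain reconstruction.  Training a
learned denoiser is out of scope; the interface accepts any callable.

## Evaluation metric

Intensity-only data leave a piston/gain and a conjugate-twin (sign)
ambiguity.  The reported error is therefore the *range-rescaled MSE*: the
reconstruction is affinely mapped so its min/max match the reference, both
the map and its negation are tried, and the smaller pixelwise mean squared
error is reported (the negated branch is flagged).  The number carries the
conventional unit label "rad" although it is a mean of squared radians.
The metric is asymmetric (the first argument is rescaled onto the second)
and invariant to positive-gain affine transforms of the reconstruction;
both properties are tested.  Errors are computed over the full frame, no
border crop.

## Synthetic scenes

The default phantom emulates a smooth, weakly modulating specimen on the
simulated bench: 8 µm pitch, λ = 632.8 nm, peak phase 1 rad (safely inside
the < 2π regime where single-shot retrieval is well-behaved), grid 256 px
by default.  `gaussian_blobs` sums 5 periodised Gaussian bumps with widths
drawn from [size/16, size/4] pixels — built in the Fourier domain so the
spectrum is exactly a sampled Gaussian and energy above half-Nyquist is
negligible, keeping the brute-force propagation oracle valid.
`smooth_noise` low-pass-filters white noise with a hard cutoff below
half-Nyquist.  Both are rescaled to [0, peak].  `binary_shapes` (hard
discs) and `imported_image` exist for qualitative experiments and make no
band-limit promise.  Measurement noise is off by default; additive
Gaussian and Poisson (photons/pixel) models are available and clipped at
zero.

What the phantoms do *not* emulate: absorption (real specimens are never
perfectly phase-only), detector quantisation and fixed-pattern noise,
partial coherence, mechanical drift between multi-plane exposures, and
model mismatch in d, λ or pitch.  Passing tests therefore demonstrate the
correctness of the algorithms under their own forward model, not
end-to-end robustness on a physical bench.

## Problem sizes used by the automated runs

The test suite and the acceptance script run the study scene at 64 px with
3 000 epochs (and 2-scale networks at 16–32 px for unit tests) — grids and
budgets chosen so the full suite runs comfortably on one CPU core while
staying inside the regime the method is designed for; the reconstruction
quality at 64 px matches the 256-px behaviour of the method.  The
multi-plane baselines use five planes at 10–30 mm (GS) and ±0.5 mm (TIE)
around d = 10 mm.

## Known limitations

* Phase modulation ranges beyond 2π break single-shot retrieval (the
  intensity constrains the phase only modulo wrapping); the package
  characterises this failure rather than fixing it — the 4π phantom is
  reconstructed at least 3× worse than the 1-rad phantom under identical
  settings.
* The periodic boundary model wraps diffraction at large d; both simulation
  and inversion share the model, so the inverse problem stays consistent,
  but comparison with aperture-limited experimental data needs
  `pad_factor ≥ 2`.
* The hard evanescent cutoff discards sub-wavelength detail by design
  (none exists at 8 µm pitch).
* CPU-only: a 3 000-epoch, 64-px reconstruction takes minutes; scaling to
  256 px × 10 000 epochs is possible but slow without an accelerator.
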