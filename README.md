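# physennet

Quantitative phase retrieval from a **single lens-less diffraction
pattern**, using an **untrained** convolutional network constrained by the
physics of coherent diffraction — no training data, no pre-trained weights.
Classical baselines (multi-plane Gerchberg–Saxton, transport-of-intensity,
regularisation-by-denoising) and a synthetic test bed are included.

## The problem

Transparent specimens — unstained cells, tissue slices, micro-optics —
modulate the *phase* of a coherent wavefront, not its amplitude.  A camera
placed a distance *d* behind a phase object φ(x, y) illuminated by a plane
wave records only the diffraction intensity

```
I = |U_d|²,    U_d = F⁻¹{ F{e^{iφ}} · G },
G(f) = exp[i k d √(1 − λ²f²)],    k = 2π/λ,
```

(the exact angular-spectrum propagator).  Recovering φ from the single
intensity I is ill-posed; classical methods buy stability with extra
measurements (several planes for Gerchberg–Saxton or the
transport-of-intensity equation) or handcrafted priors.

## The method

A randomly initialised U-Net `R_θ` receives the measurement I and proposes
a phase.  The proposal is pushed through the *known* forward model `H`
(diffraction + detection) and θ is fitted **to that one image**:

```
θ* = argmin_θ ‖ H(R_θ(I)) − I ‖²,        φ̂ = R_θ*(I).
```

The ground truth never appears: the convolutional architecture acts as an
implicit image prior (the deep-image-prior effect) and the physics supplies
the data constraint.  Optimisation uses Adam (lr 0.01) with uniform noise
U[0, 1/30] freshly added to the network input at every step; the noise is
removed for the final read-out.  Everything — network layers, their
backward passes, and the analytic (Wirtinger) gradient through the complex
forward model — is implemented directly on NumPy and verified against
finite differences; see `docs/methods.md` for the full model description
and design rationale.

Reconstruction quality is reported as the **range-rescaled MSE** ("rad"):
the reconstruction is min–max matched to the reference (the sign-flipped
twin is also tried) before the pixelwise mean squared error.

## Worked example

Simulate a smooth phase object on the default bench (λ = 632.8 nm, 8 µm
pitch) and reconstruct it from one pattern at d = 10 mm:

```
physennet phantom --size 64 --seed 7 --out phantom.tiff
physennet simulate phantom.tiff --distance 10mm --out intensity.tiff
physennet reconstruct intensity.tiff --epochs 3000 --seed 7 --out recovered.tiff
physennet evaluate recovered.tiff phantom.tiff
```

which prints

```
{
  "mse": 1.778187502213568e-05,
  "rescale_gain": 1.0091038027125656,
  "rescale_offset": -4.514211482792816e-05,
  "negated": false
}
```

a rescaled MSE of ~2 × 10⁻⁵ rad: the 1-rad phase object is recovered
essentially exactly from a single intensity image.  The affine gain/offset
are the (physically unavoidable) piston/gain ambiguity removed before
scoring; `negated` reports whether the conjugate-twin branch won.

The same library calls in Python:

```python
import physennet as pn

spec   = pn.PropagationSpec(wavelength=632.8e-9, pitch=8e-6, distance=10e-3)
truth  = pn.generate_phantom(pn.PhantomSpec(size=64, seed=7))
I      = pn.forward_intensity(truth, spec)
result = pn.reconstruct(I, spec, oconfig=pn.OptimizationConfig(epochs=3000, seed=7))
print(pn.mse(result.phase, truth))        # rescaled MSE in rad
```

Baselines use the same vocabulary: `gs_retrieve` (multi-plane
Gerchberg–Saxton), `tie_solve` (transport of intensity),
`red_reconstruct` (RED with a pluggable denoiser), all exposed through
`physennet reconstruct --method gs|tie|red` and the YAML-driven
`physennet run` / `physennet compare` experiment commands.

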