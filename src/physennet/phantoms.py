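"""Synthetic phase objects and simulated diffraction measurements.

The default scene emulates a single-beam lens-less phase-imaging bench:
a smooth, nonnegative phase object with sub-2*pi modulation (peak 1 rad)
sampled on a square grid with 8 um pitch, illuminated at 632.8 nm and
recorded 10-180 mm downstream.  Real specimens (e.g. unstained cell slices)
are smooth phase-delay maps of this kind; the generators below reproduce
that statistical structure without any external image data.

Phantoms are built on the torus (wrapped coordinates), which keeps their
spectra band-limited and consistent with the periodic propagation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import PropagationSpec, forward_intensity

__all__ = ["PhantomSpec", "NoiseSpec", "generate_phantom", "simulate_measurement"]

_KINDS = ("gaussian_blobs", "smooth_noise", "binary_shapes", "imported_image")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic phase object.

    Parameters
    ----------
    kind : str
        One of ``gaussian_blobs`` (default; sum of wrapped Gaussian bumps),
        ``smooth_noise`` (low-pass-filtered white noise), ``binary_shapes``
        (union of discs at constant phase) or ``imported_image`` (a single
        user-supplied grayscale image rescaled to the phase range).
    size : int
        Grid side in pixels (>= 8).
    peak_phase : float
        Maximum phase delay in radians.  Values above 2*pi are permitted
        only to exercise the documented failure regime of intensity-only
        retrieval; the default 1 rad is a typical weak phase object.
    n_features : int
        Number of bumps/shapes for the feature-based kinds.
    seed : int
        Seed for the phantom's private random stream.
    path : str | None
        Image file for ``imported_image``.
    """

    kind: str = "gaussian_blobs"
    size: int = 256
    peak_phase: float = 1.0
    n_features: int = 5
    seed: int = 0
    path: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if self.size < 8:
            raise ValueError(f"size must be >= 8, got {self.size}")
        if not (self.peak_phase > 0):
            raise ValueError(f"peak_phase must be > 0, got {self.peak_phase}")
        if self.n_features < 0:
            raise ValueError("n_features must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model applied to a simulated intensity.

    ``gaussian`` adds zero-mean additive white Gaussian noise with standard
    deviation ``parameter`` (on the dimensionless intensity scale);
    ``poisson`` draws shot noise with ``parameter`` expected photons per
    pixel at unit intensity.  ``none`` (default) is the noise-free setting
    used by the simulation studies.
    """

    model: str = "none"
    parameter: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.parameter < 0:
            raise ValueError("noise parameter must be >= 0")


def _wrapped_delta2(n: int, c: float) -> np.ndarray:
    """Squared circular (toroidal) distance from coordinate ``c`` along one axis."""
    x = np.arange(n, dtype=np.float64)
    d = (x - c + n / 2.0) % n - n / 2.0
    return d * d


def _gaussian_blobs(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    # built in the Fourier domain: the spectrum of a periodized Gaussian is a
    # sampled Gaussian, so the phantom is smooth across the wrap seam and its
    # energy above half-Nyquist is negligible at the minimum width n/16
    n = spec.size
    f = np.fft.fftfreq(n)  # cycles per pixel
    r2 = f[:, None] ** 2 + f[None, :] ** 2
    spectrum = np.zeros((n, n), dtype=complex)
    for _ in range(spec.n_features):
        cy, cx = rng.uniform(0.0, n, size=2)
        sigma = rng.uniform(n / 16.0, n / 4.0)
        amp = rng.uniform(0.5, 1.0)
        shift = np.exp(-2j * np.pi * (f[:, None] * cy + f[None, :] * cx))
        spectrum += amp * np.exp(-2.0 * np.pi ** 2 * sigma ** 2 * r2) * shift
    return np.fft.ifft2(spectrum).real


def _smooth_noise(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size
    white = rng.standard_normal((n, n))
    f = np.fft.fftfreq(n)  # cycles per pixel
    r2 = f[:, None] ** 2 + f[None, :] ** 2
    # soft Gaussian low-pass plus a hard cutoff safely below Nyquist/2
    mask = np.exp(-r2 / (2.0 * 0.06 ** 2)) * (np.sqrt(r2) <= 0.22)
    return np.fft.ifft2(np.fft.fft2(white) * mask).real


def _binary_shapes(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size
    out = np.zeros((n, n), dtype=np.float64)
    for _ in range(spec.n_features):
        cy, cx = rng.uniform(0.0, n, size=2)
        radius = rng.uniform(n / 16.0, n / 6.0)
        d2 = _wrapped_delta2(n, cy)[:, None] + _wrapped_delta2(n, cx)[None, :]
        out = np.maximum(out, (d2 <= radius * radius).astype(np.float64))
    return out


def _imported_image(spec: PhantomSpec) -> np.ndarray:
    if spec.path is None:
        raise ValueError("imported_image phantom requires a path")
    import imageio.v3 as iio

    img = np.asarray(iio.imread(spec.path), dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.shape != (spec.size, spec.size):
        from skimage.transform import resize

        img = resize(img, (spec.size, spec.size), anti_aliasing=True)
    return img


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate a phase map in radians, deterministically from ``spec``.

    The result is rescaled so its minimum is 0 and its maximum is exactly
    ``spec.peak_phase`` (a flat zero map is returned when there is nothing
    to scale, e.g. ``n_features=0``).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian_blobs":
        raw = _gaussian_blobs(spec, rng)
    elif spec.kind == "smooth_noise":
        raw = _smooth_noise(spec, rng)
    elif spec.kind == "binary_shapes":
        raw = _binary_shapes(spec, rng)
    else:
        raw = _imported_image(spec)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    out = (raw - lo) * (spec.peak_phase / (hi - lo))
    # guarantee the exact contract despite rounding
    out[np.unravel_index(np.argmax(out), out.shape)] = spec.peak_phase
    return out


def simulate_measurement(phase: np.ndarray, pspec: PropagationSpec,
                         noise: NoiseSpec = NoiseSpec(),
                         seed: int = 0) -> np.ndarray:
    """Simulate the recorded diffraction intensity of a phase object.

    Propagates ``exp(i*phase)`` over ``pspec.distance``, takes the squared
    modulus and applies the measurement-noise model; the result is clipped
    at zero (a detector never reports negative counts).
    """
    I = forward_intensity(phase, pspec)
    if noise.model == "none":
        return I
    rng = np.random.default_rng(seed)
    if noise.model == "gaussian":
        I = I + rng.normal(0.0, noise.parameter, size=I.shape)
    elif noise.model == "poisson":
        if noise.parameter > 0:
            I = rng.poisson(I * noise.parameter).astype(np.float64) / noise.parameter
    return np.clip(I, 0.0, None)
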