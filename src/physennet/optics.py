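"""Scalar free-space diffraction with the angular-spectrum method.

A thin phase-only object illuminated by a unit-amplitude coherent plane wave
transmits the field ``U0 = exp(i*phi)``.  Free-space propagation over a signed
distance ``d`` multiplies the spatial-frequency spectrum of the field by the
exact transfer function

    G(fx, fy) = exp[i * k * d * sqrt(1 - lambda^2 fx^2 - lambda^2 fy^2)],

with ``k = 2*pi/lambda``.  Spatial frequencies with negative radicand are
evanescent; their transfer-function entries are set to zero, so ``|G|`` is
either 0 or 1 and propagation is unitary on the propagating band.

Conventions (fixed throughout the package):

* unshifted DFT layout — the DC sample sits at array index ``(0, 0)``; the
  forward transform uses the negative-exponent convention of ``numpy.fft``;
* pixel-centred samples, sample spacing equal to the detector pitch;
* SI units (meters) everywhere in the library;
* periodic (circular) boundary model by default (``pad_factor=1``); optional
  zero-padding of the surrounding plane wave suppresses wraparound for large
  propagation distances.

All arrays are plain ``numpy`` arrays: phase maps are real (radians), fields
complex, intensities real nonnegative (dimensionless, detector-normalised).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PropagationSpec",
    "phase_to_field",
    "make_frequency_grid",
    "transfer_function",
    "propagate",
    "forward_intensity",
]


@dataclass(frozen=True)
class PropagationSpec:
    """Physical parameters of the free-space propagation kernel.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in meters (e.g. 632.8e-9 for a He-Ne laser).
    pitch : float
        Sample spacing (detector pixel pitch) in meters.
    distance : float
        Signed propagation distance in meters; negative values back-propagate.
    pad_factor : int
        Zero-padding factor applied around the field before the FFT
        (1 = none, the periodic model).  The output is cropped back.
    """

    wavelength: float
    pitch: float
    distance: float = 0.0
    pad_factor: int = 1

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if not (self.pitch > 0):
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if not np.isfinite(self.distance):
            raise ValueError("distance must be finite")
        if int(self.pad_factor) != self.pad_factor or self.pad_factor < 1:
            raise ValueError(f"pad_factor must be an integer >= 1, got {self.pad_factor}")

    @property
    def wavenumber(self) -> float:
        """k = 2*pi/lambda in rad/m (derived, never stored)."""
        return 2.0 * np.pi / self.wavelength

    def with_distance(self, distance: float) -> "PropagationSpec":
        return PropagationSpec(self.wavelength, self.pitch, distance, self.pad_factor)


def _as_2d(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2D array, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def phase_to_field(phase: np.ndarray) -> np.ndarray:
    """Complex transmission of a phase-only object: ``exp(i*phase)``.

    The modulus is exactly 1 everywhere — the object delays the wavefront but
    does not absorb.
    """
    phase = _as_2d(phase, "phase")
    if np.iscomplexobj(phase):
        raise ValueError("phase must be real-valued (radians)")
    return np.exp(1j * phase.astype(np.float64))


def make_frequency_grid(n: int, pitch: float):
    """DFT spatial-frequency grids ``(fx, fy)`` in cycles per meter.

    Unshifted layout: DC at index 0, spacing ``1/(n*pitch)``, extreme value
    at the Nyquist frequency ``1/(2*pitch)``.  ``fx`` varies along axis 1
    (columns), ``fy`` along axis 0 (rows); both are broadcastable to (n, n).
    """
    if int(n) != n or n < 1:
        raise ValueError(f"grid size must be an integer >= 1, got {n}")
    if not (pitch > 0):
        raise ValueError(f"pitch must be > 0, got {pitch}")
    f = np.fft.fftfreq(int(n), d=pitch)
    fy = f[:, None]
    fx = f[None, :]
    return fx, fy


def transfer_function(fx: np.ndarray, fy: np.ndarray, spec: PropagationSpec,
                      distance: float | None = None) -> np.ndarray:
    """Angular-spectrum transfer function on the given frequency grid.

    ``G = exp[i k d sqrt(1 - lambda^2 (fx^2 + fy^2))]`` on the propagating
    band; zero on the evanescent band (radicand < 0), where waves decay
    rather than propagate.
    """
    d = spec.distance if distance is None else float(distance)
    lam = spec.wavelength
    radicand = 1.0 - (lam * fx) ** 2 - (lam * fy) ** 2
    propagating = radicand >= 0.0
    kz = np.sqrt(np.where(propagating, radicand, 0.0))
    G = np.exp(1j * spec.wavenumber * d * kz)
    return np.where(propagating, G, 0.0 + 0.0j)


def _pad_field(field: np.ndarray, pad_factor: int) -> np.ndarray:
    """Embed the field centrally in a ``pad_factor``-times larger zero grid."""
    if pad_factor == 1:
        return field
    n0, n1 = field.shape
    m0, m1 = n0 * pad_factor, n1 * pad_factor
    out = np.zeros((m0, m1), dtype=complex)
    o0, o1 = (m0 - n0) // 2, (m1 - n1) // 2
    out[o0:o0 + n0, o1:o1 + n1] = field
    return out


def _crop_field(field: np.ndarray, shape) -> np.ndarray:
    n0, n1 = shape
    m0, m1 = field.shape
    o0, o1 = (m0 - n0) // 2, (m1 - n1) // 2
    return field[o0:o0 + n0, o1:o1 + n1]


def propagate(field: np.ndarray, spec: PropagationSpec,
              distance: float | None = None) -> np.ndarray:
    """Propagate a complex field over a signed distance.

    Computes ``IFFT2( FFT2(field) * G )`` with optional zero-padding
    (``spec.pad_factor``) to suppress periodic wraparound; the result is
    cropped back to the input shape.  Negative distance back-propagates.
    """
    field = _as_2d(field, "field").astype(complex)
    if field.shape[0] != field.shape[1]:
        raise ValueError(f"square grids expected, got shape {field.shape}")
    if spec.pitch < spec.wavelength / 2.0:
        warnings.warn(
            "pitch < lambda/2: the grid resolves evanescent frequencies, "
            "which are zeroed by the transfer-function cutoff",
            RuntimeWarning,
        )
    d = spec.distance if distance is None else float(distance)
    work = _pad_field(field, spec.pad_factor)
    fx, fy = make_frequency_grid(work.shape[0], spec.pitch)
    G = transfer_function(fx, fy, spec, distance=d)
    out = np.fft.ifft2(np.fft.fft2(work) * G)
    return _crop_field(out, field.shape)


def forward_intensity(phase: np.ndarray, spec: PropagationSpec) -> np.ndarray:
    """Diffraction-pattern intensity of a phase-only object: ``|U_d|^2``.

    This is the physical forward map ``H(phi)`` inverted by the
    reconstruction methods; the differentiable copy used inside the
    optimisation loop lives in :mod:`physennet.core` and is tested to agree
    with this one.

    With ``pad_factor > 1`` the *phase* is zero-padded (the object sits in a
    transparent surround of unit amplitude, i.e. the undisturbed plane wave),
    which is the physically appropriate continuation for a phase-only object;
    the intensity is cropped back to the sensor region.
    """
    phase = _as_2d(phase, "phase")
    if spec.pad_factor > 1:
        n0, n1 = phase.shape
        m0, m1 = n0 * spec.pad_factor, n1 * spec.pad_factor
        big = np.zeros((m0, m1), dtype=np.float64)
        o0, o1 = (m0 - n0) // 2, (m1 - n1) // 2
        big[o0:o0 + n0, o1:o1 + n1] = phase
        inner = PropagationSpec(spec.wavelength, spec.pitch, spec.distance, 1)
        Ud = propagate(phase_to_field(big), inner)
        Ud = Ud[o0:o0 + n0, o1:o1 + n1]
    else:
        Ud = propagate(phase_to_field(phase), spec)
    return (Ud.real ** 2 + Ud.imag ** 2)
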