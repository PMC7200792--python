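"""Classical phase-retrieval baselines: Gerchberg-Saxton, TIE and RED.

* Gerchberg-Saxton (:func:`gs_retrieve`) — alternating projections between
  the object plane, where the phase-only constraint (unit modulus) is
  enforced, and one or more measurement planes, where the modulus is
  replaced by the square root of the recorded intensity.
* Transport of intensity (:func:`tie_solve`) — solves
  ``-k dI/dz = div(I grad(phi))`` from a central-difference axial intensity
  derivative with a spectral Poisson inverse, Tikhonov-regularised at DC.
* Regularisation by denoising (:func:`red_reconstruct`) — augments the
  untrained-network objective with the RED penalty
  ``(lambda/2) * phi^T (phi - D(phi))`` built from a pluggable denoiser
  ``D``; for a linear symmetric ``D`` the penalty gradient is exactly
  ``lambda * (phi - D(phi))``, which is the update used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Callable, Sequence

import numpy as np

from .core import NetworkSpec, OptimizationConfig, ReconstructionResult, _optimize
from .optics import PropagationSpec, make_frequency_grid, propagate

__all__ = [
    "GSConfig", "TIEInput", "REDConfig",
    "gs_retrieve", "tie_solve", "red_reconstruct", "make_denoiser",
]


# ---------------------------------------------------------------- Gerchberg-Saxton

@dataclass
class GSConfig:
    """Multi-plane Gerchberg-Saxton settings.

    ``planes`` is a list of ``(intensity, distance_m)`` pairs; they are
    cycled in ascending distance order, one full cycle per iteration.
    ``init_phase`` is ``"zeros"`` (deterministic default) or ``"random"``
    with ``seed``.
    """

    planes: list
    n_iterations: int = 200
    init_phase: str = "zeros"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if len(self.planes) < 1:
            raise ValueError("at least one measurement plane is required")
        if self.init_phase not in ("zeros", "random"):
            raise ValueError("init_phase must be 'zeros' or 'random'")


def gs_retrieve(config: GSConfig, spec: PropagationSpec,
                return_errors: bool = False):
    """Phase-only Gerchberg-Saxton retrieval at the object plane.

    Each iteration cycles through the measurement planes in ascending
    distance order: enforce unit modulus at the object plane (keep phase),
    propagate to the plane, replace the modulus with ``sqrt(I)`` (keep
    phase), back-propagate.  The returned object-plane phase has its mean
    (the free piston) subtracted.

    With ``return_errors=True`` also returns the per-iteration modulus
    mismatch ``||sqrt(I_tilde) - sqrt(I)||`` at the first plane (the
    classic error-reduction diagnostic, non-increasing on noise-free data).
    """
    planes = sorted(((np.asarray(I, dtype=np.float64), float(d))
                     for I, d in config.planes), key=lambda p: p[1])
    dists = [d for _, d in planes]
    if len(set(dists)) != len(dists):
        raise ValueError("measurement-plane distances must be distinct")
    shape = planes[0][0].shape
    for I, _ in planes:
        if I.shape != shape:
            raise ValueError("all measurement planes must share one shape")
        if np.any(I < 0):
            raise ValueError("intensities must be nonnegative")
    roots = [(np.sqrt(I), d) for I, d in planes]

    if config.init_phase == "zeros":
        phi = np.zeros(shape, dtype=np.float64)
    else:
        phi = np.random.default_rng(config.seed).uniform(-np.pi, np.pi, size=shape)
    obj = np.exp(1j * phi)
    errors = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        for j, (rI, d) in enumerate(roots):
            obj = np.exp(1j * np.angle(obj))      # phase-only object constraint
            P = propagate(obj, spec, distance=d)
            mod = np.abs(P)
            if j == 0:
                errors[it] = np.linalg.norm(mod - rI)
            P = rI * np.where(mod > 0, P / np.where(mod > 0, mod, 1.0),
                              1.0 + 0.0j)          # modulus replacement
            obj = propagate(P, spec, distance=-d)
    phase = np.angle(obj)
    phase = phase - phase.mean()
    return (phase, errors) if return_errors else phase


# ------------------------------------------------------------- transport of intensity

@dataclass(frozen=True)
class TIEInput:
    """Three-plane intensity stack for the transport-of-intensity equation.

    ``I_minus``, ``I_0``, ``I_plus`` are recorded at distances
    ``d - delta_z``, ``d``, ``d + delta_z``; the recovered phase lives at
    the central plane.
    """

    I_minus: np.ndarray
    I_0: np.ndarray
    I_plus: np.ndarray
    delta_z: float
    regularization_eps: float = 1e-9

    def __post_init__(self) -> None:
        if not (self.delta_z > 0):
            raise ValueError("delta_z must be > 0")
        if not (self.regularization_eps > 0):
            raise ValueError("regularization_eps must be > 0")


def _inverse_laplacian(g: np.ndarray, pitch: float, eps_rel: float) -> np.ndarray:
    """Solve ``lap(phi) = g`` spectrally with Tikhonov-regularised division.

    The Laplacian symbol is ``-4*pi^2*(fx^2+fy^2)``; the singular DC mode
    (the free piston) is set to zero.
    """
    n = g.shape[0]
    fx, fy = make_frequency_grid(n, pitch)
    q2 = 4.0 * np.pi ** 2 * (fx * fx + fy * fy)
    denom = q2 + eps_rel * q2.max()
    phi_hat = -np.fft.fft2(g) / denom
    phi_hat[0, 0] = 0.0
    return np.fft.ifft2(phi_hat).real


def tie_solve(tin: TIEInput, spec: PropagationSpec, mode: str = "uniform") -> np.ndarray:
    """Recover the phase at the central plane from the axial intensity derivative.

    Solves ``-k * dI/dz = div(I * grad(phi))`` with the central difference
    ``(I_plus - I_minus) / (2*delta_z)``.  The default ``uniform`` mode uses
    the weak-object simplification ``lap(phi) = -k*(dI/dz)/I0`` with ``I0``
    the mean of the central intensity (appropriate for phase-only objects
    under near-unit illumination); ``full`` applies the exact two-step
    inversion with the pointwise intensity.
    """
    Im = np.asarray(tin.I_minus, dtype=np.float64)
    I0 = np.asarray(tin.I_0, dtype=np.float64)
    Ip = np.asarray(tin.I_plus, dtype=np.float64)
    if not (Im.shape == I0.shape == Ip.shape):
        raise ValueError("the three intensity planes must share one shape")
    if mode not in ("uniform", "full"):
        raise ValueError("mode must be 'uniform' or 'full'")
    k = spec.wavenumber
    dIdz = (Ip - Im) / (2.0 * tin.delta_z)
    rhs = -k * dIdz
    eps = tin.regularization_eps
    if mode == "uniform":
        return _inverse_laplacian(rhs / I0.mean(), spec.pitch, eps)
    # full mode: lap(psi) = rhs; grad(phi) = grad(psi)/I; phi = invlap(div(grad(phi)))
    psi = _inverse_laplacian(rhs, spec.pitch, eps)
    n = psi.shape[0]
    fx, fy = make_frequency_grid(n, spec.pitch)
    psi_hat = np.fft.fft2(psi)
    gx = np.fft.ifft2(2j * np.pi * fx * psi_hat).real
    gy = np.fft.ifft2(2j * np.pi * fy * psi_hat).real
    I_safe = np.maximum(I0, 1e-12 * I0.max())
    gx, gy = gx / I_safe, gy / I_safe
    div = (np.fft.ifft2(2j * np.pi * fx * np.fft.fft2(gx)).real
           + np.fft.ifft2(2j * np.pi * fy * np.fft.fft2(gy)).real)
    return _inverse_laplacian(div, spec.pitch, eps)


# ---------------------------------------------------------- regularisation by denoising

def make_denoiser(name: str, **kwargs) -> Callable[[np.ndarray], np.ndarray]:
    """Built-in denoisers for the RED penalty.

    ``identity`` — no-op (zero penalty for every phase);
    ``gaussian`` — circular (FFT) Gaussian blur, a linear *symmetric*
    operator (``sigma`` in pixels, default 2.0);
    ``tv`` — one total-variation proximal step
    (:func:`skimage.restoration.denoise_tv_chambolle`, ``weight`` default 0.1).
    """
    if name == "identity":
        return lambda x: x
    if name == "gaussian":
        sigma = float(kwargs.get("sigma", 2.0))

        def blur(x: np.ndarray) -> np.ndarray:
            n0, n1 = x.shape
            f0 = np.fft.fftfreq(n0)[:, None]
            f1 = np.fft.fftfreq(n1)[None, :]
            kernel = np.exp(-2.0 * np.pi ** 2 * sigma ** 2 * (f0 ** 2 + f1 ** 2))
            return np.fft.ifft2(np.fft.fft2(x) * kernel).real

        return blur
    if name == "tv":
        weight = float(kwargs.get("weight", 0.1))

        def tv(x: np.ndarray) -> np.ndarray:
            from skimage.restoration import denoise_tv_chambolle

            return denoise_tv_chambolle(x, weight=weight)

        return tv
    raise ValueError(f"unknown denoiser {name!r}; choose identity, gaussian or tv")


@dataclass
class REDConfig:
    """Regularisation-by-denoising settings.

    ``lambda_red`` is the regularisation strength; ``denoiser`` is either a
    name understood by :func:`make_denoiser` or any callable mapping a phase
    map to a denoised phase map.
    """

    lambda_red: float = 0.05
    denoiser: str | Callable[[np.ndarray], np.ndarray] = "gaussian"
    denoiser_params: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lambda_red < 0:
            raise ValueError("lambda_red must be >= 0")

    def get_denoiser(self) -> Callable[[np.ndarray], np.ndarray]:
        if callable(self.denoiser):
            return self.denoiser
        return make_denoiser(self.denoiser, **self.denoiser_params)


def red_penalty(phi: np.ndarray, D: Callable[[np.ndarray], np.ndarray],
                lambda_red: float) -> tuple[float, np.ndarray]:
    """RED penalty value ``(lambda/2) phi^T (phi - D(phi))`` and its gradient.

    The gradient ``lambda * (phi - D(phi))`` is exact for a linear symmetric
    denoiser and is the standard fixed-point update for the general case
    (local homogeneity + symmetric-Jacobian assumptions).
    """
    r = phi - D(phi)
    return 0.5 * lambda_red * float(np.sum(phi * r)), lambda_red * r


def red_reconstruct(I: np.ndarray,
                    pspec: PropagationSpec,
                    nspec: NetworkSpec = NetworkSpec(),
                    config: REDConfig = REDConfig(),
                    oconfig: OptimizationConfig = OptimizationConfig(),
                    ground_truth: np.ndarray | None = None) -> np.ndarray:
    """Untrained-network reconstruction with an added RED penalty.

    Minimises ``||H(R_theta(I)) - I||^2 + (lambda/2) phi^T (phi - D(phi))``
    with ``phi = R_theta(I)``, using the same Adam loop as the pure method.
    With ``lambda_red = 0`` the objective, code path and result coincide
    exactly with :func:`physennet.reconstruct` under equal seeds.
    """
    if config.lambda_red == 0:
        penalty = None
    else:
        D = config.get_denoiser()
        lam = config.lambda_red

        def penalty(phi: np.ndarray):
            return red_penalty(phi, D, lam)

    result: ReconstructionResult = _optimize(
        [I], [pspec], nspec, oconfig, ground_truth=ground_truth, penalty=penalty,
    )
    return result.phase
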