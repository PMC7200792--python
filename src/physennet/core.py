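"""Untrained-network phase retrieval (deep-image-prior with a physics head).

A randomly initialised U-Net ``R_theta`` maps the measured diffraction
intensity ``I`` to a candidate phase ``phi = R_theta(I)``.  The candidate is
pushed through the known physical forward model ``H`` (angular-spectrum
propagation + squared modulus, :mod:`physennet.optics`) and the parameters
are optimised to minimise the data fidelity

    theta* = argmin_theta || H(R_theta(I)) - I ||^2 ,

which never references the ground-truth phase: the structure of the
convolutional network is the only prior.  After the final step the phase is
read out with one clean forward pass, ``phi_tilde = R_theta*(I)``.

Optimisation follows the standard recipe for this method: Adam with learning
rate 0.01, i.i.d. uniform noise on ``[0, 1/30]`` added to the fixed network
input at every step (a stochastic regulariser that improves convergence), a
fixed epoch budget, and the noise removed for the final read-out.

The measured intensity is divided by its mean before optimisation, so the
unit-mean scale of the plane-wave forward model, the input-noise amplitude
1/30 and the fidelity loss are all mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from . import nn
from .optics import PropagationSpec, make_frequency_grid, transfer_function

__all__ = [
    "NetworkSpec", "OptimizationConfig", "ReconstructionResult",
    "build_network", "perturb_input", "reconstruct", "reconstruct_multi", "UNet",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the encoder-decoder prior network.

    The network is a U-Net built from 3x3 convolution + batch normalisation +
    leaky ReLU blocks, 2x2 max pooling on the encoder path, 3x3
    up-convolution (zero-stuffed transposed convolution) blocks on the
    decoder path, optional skip connections, and a nonnegative output layer
    that anchors the free piston of the recovered phase at zero.  Channel
    count at scale ``l`` is ``base_channels * channel_growth**l``.

    ``output_activation`` is ``softplus`` (default; a smooth rectifier that
    keeps gradients alive everywhere), ``relu`` (hard rectifier; prone to an
    absorbing all-zero collapse on weak-contrast near-field scenes, see the
    methods note) or ``scaled_sigmoid`` (range ``[0, sigmoid_scale]``).
    """

    n_scales: int = 4
    base_channels: int = 16
    channel_growth: int = 2
    kernel: int = 3
    leaky_slope: float = 0.1
    skip_connections: bool = True
    output_activation: str = "softplus"  # or "relu", "scaled_sigmoid"
    sigmoid_scale: float = 2.0 * np.pi

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.kernel != 3:
            raise ValueError("kernel is fixed at 3")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must be in (0, 1)")
        if self.output_activation not in ("softplus", "relu", "scaled_sigmoid"):
            raise ValueError(f"unknown output_activation {self.output_activation!r}")

    def channels(self, level: int) -> int:
        return int(self.base_channels * self.channel_growth ** level)


@dataclass(frozen=True)
class OptimizationConfig:
    """Settings of the Adam optimisation loop."""

    learning_rate: float = 0.01
    epochs: int = 10_000
    noise_amplitude: float = 1.0 / 30.0
    optimizer: str = "adam"
    seed: int = 0
    record_every: int = 50
    loss_reduction: str = "mean"  # or "sum"
    plateau_patience: int | None = None  # epochs; None = fixed budget
    plateau_rtol: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.learning_rate > 0):
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.optimizer != "adam":
            raise ValueError("adam is the only supported optimizer")
        if self.loss_reduction not in ("mean", "sum"):
            raise ValueError("loss_reduction must be 'mean' or 'sum'")


@dataclass
class ReconstructionResult:
    """Recovered phase plus the optimisation record.

    ``loss_trace`` is an ``(epochs, 2)`` array of (epoch, data-fidelity);
    ``mse_trace`` (present only when a ground truth was supplied) holds
    (epoch, range-rescaled MSE in rad) sampled every ``record_every`` epochs.
    """

    phase: np.ndarray
    loss_trace: np.ndarray
    mse_trace: np.ndarray | None
    config: dict
    seed: int


class _ConvBlock:
    """conv 3x3 -> batchnorm -> leaky ReLU."""

    def __init__(self, c_in: int, c_out: int, slope: float, rng: np.random.Generator):
        self.conv = nn.Conv2d(c_in, c_out, rng)
        self.bn = nn.BatchNorm2d(c_out)
        self.act = nn.LeakyReLU(slope)

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()

    def forward(self, x):
        return self.act.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))


class UNet:
    """Encoder-decoder with skip connections, one input and one output channel."""

    def __init__(self, spec: NetworkSpec, input_shape, rng: np.random.Generator):
        H, W = input_shape
        div = 2 ** spec.n_scales
        if H % div or W % div:
            raise ValueError(
                f"input shape {input_shape} must be divisible by 2^n_scales = {div}"
            )
        self.spec = spec
        s = spec.leaky_slope
        self.enc: list[tuple[_ConvBlock, _ConvBlock]] = []
        self.pools: list[nn.MaxPool2x2] = []
        c_prev = 1
        for l in range(spec.n_scales):
            c = spec.channels(l)
            self.enc.append((_ConvBlock(c_prev, c, s, rng), _ConvBlock(c, c, s, rng)))
            self.pools.append(nn.MaxPool2x2())
            c_prev = c
        c_mid = spec.channels(spec.n_scales)
        self.bott = (_ConvBlock(c_prev, c_mid, s, rng), _ConvBlock(c_mid, c_mid, s, rng))
        self.ups: list[tuple[nn.ZeroUpsample2x, _ConvBlock]] = []
        self.dec: list[tuple[_ConvBlock, _ConvBlock]] = []
        c_prev = c_mid
        for l in reversed(range(spec.n_scales)):
            c = spec.channels(l)
            self.ups.append((nn.ZeroUpsample2x(), _ConvBlock(c_prev, c, s, rng)))
            c_cat = 2 * c if spec.skip_connections else c
            self.dec.append((_ConvBlock(c_cat, c, s, rng), _ConvBlock(c, c, s, rng)))
            c_prev = c
        self.out_conv = nn.Conv2d(c_prev, 1, rng)
        if spec.output_activation == "relu":
            self.out_act: object = nn.ReLU()
        elif spec.output_activation == "softplus":
            self.out_act = nn.Softplus()
        else:
            self.out_act = nn.ScaledSigmoid(spec.sigmoid_scale)

    def parameters(self) -> list[nn.Parameter]:
        ps: list[nn.Parameter] = []
        for b1, b2 in self.enc:
            ps += b1.parameters() + b2.parameters()
        ps += self.bott[0].parameters() + self.bott[1].parameters()
        for _, ub in self.ups:
            ps += ub.parameters()
        for b1, b2 in self.dec:
            ps += b1.parameters() + b2.parameters()
        ps += self.out_conv.parameters()
        return ps

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a (H, W) image to a (H, W) image (channel axes handled internally)."""
        h = np.ascontiguousarray(x, dtype=nn.DTYPE)[None]
        skips = []
        for (b1, b2), pool in zip(self.enc, self.pools):
            h = b2.forward(b1.forward(h))
            skips.append(h)
            h = pool.forward(h)
        h = self.bott[1].forward(self.bott[0].forward(h))
        for i, l in enumerate(reversed(range(self.spec.n_scales))):
            up, ub = self.ups[i]
            h = ub.forward(up.forward(h))
            if self.spec.skip_connections:
                h = np.concatenate([h, skips[l]], axis=0)
            b1, b2 = self.dec[i]
            h = b2.forward(b1.forward(h))
        y = self.out_act.forward(self.out_conv.forward(h))
        return y[0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients for ``dL/d(output)``; returns dL/d(input)."""
        dh = self.out_conv.backward(self.out_act.backward(dy[None].astype(nn.DTYPE)))
        dskips: list[np.ndarray | None] = [None] * self.spec.n_scales
        for i in reversed(range(self.spec.n_scales)):  # reverse of forward order
            l = self.spec.n_scales - 1 - i
            b1, b2 = self.dec[i]
            dh = b1.backward(b2.backward(dh))
            if self.spec.skip_connections:
                c = self.spec.channels(l)
                dskips[l] = dh[c:]
                dh = np.ascontiguousarray(dh[:c])
            up, ub = self.ups[i]
            dh = up.backward(ub.backward(dh))
        dh = self.bott[0].backward(self.bott[1].backward(dh))
        for l in reversed(range(self.spec.n_scales)):
            dh = self.pools[l].backward(dh)
            if dskips[l] is not None:
                dh = dh + dskips[l]
            b1, b2 = self.enc[l]
            dh = b1.backward(b2.backward(dh))
        return dh[0]


def build_network(spec: NetworkSpec, input_shape, rng=None) -> UNet:
    """Construct a randomly initialised network for a given image shape.

    ``rng`` may be a seeded :class:`numpy.random.Generator` or an integer
    seed (default 0); initialisation is fully reproducible from it.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    return UNet(spec, input_shape, rng)


def perturb_input(I: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. uniform noise on ``[0, amplitude]`` to the fixed network input.

    A fresh draw is taken at every call; with ``amplitude = 0`` the output
    equals ``I`` exactly (the generator is still advanced, so seed streams
    stay aligned across configurations).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    u = rng.uniform(0.0, amplitude, size=I.shape) if amplitude > 0 else 0.0
    return I + u


class PhysicsHead:
    """Differentiable angular-spectrum intensity model with analytic gradient.

    Forward: ``I_hat = crop(|IFFT(FFT(exp(i*phi_pad)) * G)|^2)`` with the
    phase zero-padded into a transparent (unit-amplitude) surround when
    ``spec.pad_factor > 1``.  The gradient of the squared-error fidelity with
    respect to the phase follows from Wirtinger calculus: the adjoint of the
    propagation operator is back-propagation with the conjugate transfer
    function, and ``d exp(i*phi)/d phi = i * exp(i*phi)``.
    """

    def __init__(self, shape, spec: PropagationSpec):
        self.shape = tuple(shape)
        self.spec = spec
        n = self.shape[0]
        if self.shape[0] != self.shape[1]:
            raise ValueError("square grids expected")
        m = n * spec.pad_factor
        fx, fy = make_frequency_grid(m, spec.pitch)
        self.G = transfer_function(fx, fy, spec)
        self.m = m
        self.off = (m - n) // 2

    def _embed(self, phi: np.ndarray) -> np.ndarray:
        if self.spec.pad_factor == 1:
            return phi
        big = np.zeros((self.m, self.m), dtype=np.float64)
        big[self.off:self.off + self.shape[0], self.off:self.off + self.shape[1]] = phi
        return big

    def intensity(self, phi: np.ndarray) -> np.ndarray:
        U0 = np.exp(1j * self._embed(np.asarray(phi, dtype=np.float64)))
        Ud = np.fft.ifft2(np.fft.fft2(U0) * self.G)
        I = Ud.real ** 2 + Ud.imag ** 2
        o, (h, w) = self.off, self.shape
        return I[o:o + h, o:o + w] if self.spec.pad_factor > 1 else I

    def fidelity_and_grad(self, phi: np.ndarray, I: np.ndarray, reduction: str = "mean"):
        """Squared-error fidelity ``||H(phi) - I||^2`` and its phase gradient."""
        U0 = np.exp(1j * self._embed(np.asarray(phi, dtype=np.float64)))
        Ud = np.fft.ifft2(np.fft.fft2(U0) * self.G)
        Ihat = Ud.real ** 2 + Ud.imag ** 2
        o, (h, w) = self.off, self.shape
        if self.spec.pad_factor > 1:
            r_full = np.zeros_like(Ihat)
            r = Ihat[o:o + h, o:o + w] - I
            r_full[o:o + h, o:o + w] = r
        else:
            r = Ihat - I
            r_full = r
        if reduction == "mean":
            loss = float(np.mean(r * r))
            dI = (2.0 / r.size) * r_full
        else:
            loss = float(np.sum(r * r))
            dI = 2.0 * r_full
        gUd = dI * Ud                                   # dL/d(conj Ud)
        gU0 = np.fft.ifft2(np.fft.fft2(gUd) * np.conj(self.G))  # adjoint propagation
        dphi_full = 2.0 * np.imag(gU0 * np.conj(U0))
        dphi = dphi_full[o:o + h, o:o + w] if self.spec.pad_factor > 1 else dphi_full
        return loss, dphi


def _check_intensity(I: np.ndarray) -> np.ndarray:
    I = np.asarray(I, dtype=np.float64)
    if I.ndim != 2:
        raise ValueError(f"intensity must be 2D, got shape {I.shape}")
    if not np.all(np.isfinite(I)):
        raise ValueError("intensity contains non-finite values")
    if np.any(I < 0):
        raise ValueError("intensity must be nonnegative")
    if I.mean() == 0:
        raise ValueError("intensity is identically zero")
    return I


def _optimize(I_list: Sequence[np.ndarray],
              pspecs: Sequence[PropagationSpec],
              nspec: NetworkSpec,
              oconfig: OptimizationConfig,
              ground_truth: np.ndarray | None = None,
              penalty: Callable[[np.ndarray], tuple[float, np.ndarray]] | None = None,
              ) -> ReconstructionResult:
    """Shared optimisation loop for single-, multi-measurement and RED variants.

    ``penalty`` (used by regularisation-by-denoising) maps the current phase
    to an additional objective value and phase gradient; when ``None`` the
    loop is the pure data-fidelity method and follows a bit-identical code
    path regardless of whether ``ground_truth`` is supplied (the ground truth
    feeds only the diagnostic MSE trace).
    """
    if len(I_list) == 0:
        raise ValueError("at least one measurement is required")
    if len(I_list) != len(pspecs):
        raise ValueError(
            f"got {len(I_list)} measurements but {len(pspecs)} propagation specs"
        )
    Is = [_check_intensity(I) for I in I_list]
    shape = Is[0].shape
    for I in Is[1:]:
        if I.shape != shape:
            raise ValueError("all measurements must share one shape")
    Is = [I / I.mean() for I in Is]
    heads = [PhysicsHead(shape, ps) for ps in pspecs]

    init_ss, noise_ss = np.random.SeedSequence(oconfig.seed).spawn(2)
    net = build_network(nspec, shape, np.random.default_rng(init_ss))
    rng_noise = np.random.default_rng(noise_ss)
    opt = nn.Adam(net.parameters(), lr=oconfig.learning_rate)

    x0 = Is[0]
    loss_trace = np.empty((oconfig.epochs, 2), dtype=np.float64)
    mse_rec: list[tuple[int, float]] = []
    n_done = 0
    for epoch in range(1, oconfig.epochs + 1):
        x = perturb_input(x0, oconfig.noise_amplitude, rng_noise)
        phi = net.forward(x)
        phi64 = phi.astype(np.float64)
        loss = 0.0
        dphi = np.zeros(shape, dtype=np.float64)
        for head, I in zip(heads, Is):
            l_i, g_i = head.fidelity_and_grad(phi64, I, oconfig.loss_reduction)
            loss += l_i
            dphi += g_i
        if penalty is not None:
            p_val, p_grad = penalty(phi64)
            loss += p_val
            dphi += p_grad
        if not np.isfinite(loss):
            raise RuntimeError(
                f"optimization diverged (non-finite loss) at epoch {epoch} "
                f"with learning rate {oconfig.learning_rate}"
            )
        loss_trace[epoch - 1] = (epoch, loss)
        n_done = epoch
        opt.zero_grad()
        net.backward(dphi.astype(nn.DTYPE))
        opt.step()
        if ground_truth is not None and (
            epoch % oconfig.record_every == 0 or epoch == oconfig.epochs
        ):
            from .metrics import mse as _mse
            snap = net.forward(x0).astype(np.float64)
            mse_rec.append((epoch, _mse(snap, ground_truth, rescale=True)))
        if (
            oconfig.plateau_patience is not None
            and epoch > oconfig.plateau_patience
        ):
            prev = loss_trace[epoch - 1 - oconfig.plateau_patience, 1]
            if prev > 0 and abs(prev - loss) / prev < oconfig.plateau_rtol:
                break

    phase = net.forward(x0).astype(np.float64)  # clean pass: noise removed
    cfg = {
        "network": asdict(nspec),
        "optimization": asdict(oconfig),
        "distances_m": [ps.distance for ps in pspecs],
        "wavelength_m": pspecs[0].wavelength,
        "pitch_m": pspecs[0].pitch,
    }
    return ReconstructionResult(
        phase=phase,
        loss_trace=loss_trace[:n_done],
        mse_trace=np.asarray(mse_rec) if mse_rec else None,
        config=cfg,
        seed=oconfig.seed,
    )


def reconstruct(I: np.ndarray,
                pspec: PropagationSpec,
                nspec: NetworkSpec = NetworkSpec(),
                oconfig: OptimizationConfig = OptimizationConfig(),
                ground_truth: np.ndarray | None = None) -> ReconstructionResult:
    """Recover a phase map from a single diffraction intensity.

    Runs the untrained-network loop: at every epoch the fixed (mean-
    normalised) input is perturbed with fresh uniform noise, the network
    proposes a phase, the physical model simulates its diffraction pattern,
    and the mean squared error against the measurement is back-propagated
    into the network parameters.  The objective never sees ``ground_truth``,
    which only adds a diagnostic rescaled-MSE trace to the result.
    """
    return _optimize([I], [pspec], nspec, oconfig, ground_truth=ground_truth)


def reconstruct_multi(I_list: Sequence[np.ndarray],
                      pspecs: Sequence[PropagationSpec],
                      nspec: NetworkSpec = NetworkSpec(),
                      oconfig: OptimizationConfig = OptimizationConfig(),
                      ground_truth: np.ndarray | None = None) -> ReconstructionResult:
    """Joint reconstruction from measurements at several distances.

    Minimises the summed fidelity ``sum_i ||H_i(R_theta(I_1)) - I_i||^2``
    with the first measurement as the (fixed) network input; with a single
    measurement this reduces exactly to :func:`reconstruct`.
    """
    return _optimize(list(I_list), list(pspecs), nspec, oconfig,
                     ground_truth=ground_truth)
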