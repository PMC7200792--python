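"""Evaluation of reconstructed phases against a known ground truth.

Intensity-only measurements leave two ambiguities in a recovered phase: a
free piston/gain (the detector never sees a global offset, and methods
differ in their output scaling) and, for symmetric configurations, the
conjugate twin (a sign flip).  The quality metric used throughout the
package therefore min-max rescales the reconstruction to the range of the
ground truth — trying both the map and its negation and keeping the better
branch — before taking the pixelwise mean squared error.  The number is
reported in "rad", the conventional unit label for this quantity even
though it is a mean of squared radians.

Note that the rescaled MSE is *not* symmetric in its arguments: the first
argument is rescaled onto the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EvaluationReport", "rescale_to_reference", "mse", "evaluate"]


@dataclass(frozen=True)
class EvaluationReport:
    """Rescaled-MSE evaluation of a reconstruction.

    ``negated`` flags that the conjugate-twin branch (sign-flipped
    reconstruction) gave the smaller error; ``degenerate`` flags a constant
    reconstruction compared against a non-constant reference, for which no
    affine rescue exists.
    """

    mse: float
    rescale_gain: float
    rescale_offset: float
    negated: bool = False
    degenerate: bool = False
    method: str = ""
    scene: str = ""


def _check_pair(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rescale_to_reference(x: np.ndarray, ref: np.ndarray):
    """Affinely map ``x`` so its min/max equal those of ``ref``.

    Returns ``(rescaled, gain, offset)`` with ``rescaled = gain*x + offset``.
    Degenerate cases: a constant ``x`` against a non-constant ``ref`` cannot
    be rescued — a map filled with ``ref.min()`` is returned with a warning
    (gain 0); a constant ``ref`` is matched by offset only (gain 1).
    """
    x, ref = _check_pair(x, ref)
    rmin, rmax = float(ref.min()), float(ref.max())
    xmin, xmax = float(x.min()), float(x.max())
    if xmax == xmin:
        if rmax == rmin:
            offset = rmin - xmin
            return x + offset, 1.0, offset
        warnings.warn(
            "constant reconstruction against a non-constant reference: "
            "range matching is impossible", RuntimeWarning,
        )
        return np.full_like(x, rmin), 0.0, rmin
    if rmax == rmin:
        offset = rmin - float(x.mean())
        return x + offset, 1.0, offset
    gain = (rmax - rmin) / (xmax - xmin)
    offset = rmin - gain * xmin
    return gain * x + offset, gain, offset


def mse(a: np.ndarray, b: np.ndarray, rescale: bool = True) -> float:
    """Mean squared error of ``a`` against reference ``b``.

    With ``rescale=True`` (the reporting convention of this package), ``a``
    is first min-max matched to ``b``; both the reconstruction and its
    negation are tried and the smaller error is returned, removing the
    piston/gain and conjugate-twin ambiguities.
    """
    return evaluate(a, b, rescale=rescale).mse


def evaluate(a: np.ndarray, b: np.ndarray, rescale: bool = True,
             method: str = "", scene: str = "") -> EvaluationReport:
    """Full evaluation record (error, rescale parameters, twin flag)."""
    a, b = _check_pair(a, b)
    if not rescale:
        return EvaluationReport(
            mse=float(np.mean((a - b) ** 2)),
            rescale_gain=1.0, rescale_offset=0.0,
            method=method, scene=scene,
        )
    best = None
    for sign, neg in ((1.0, False), (-1.0, True)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y, gain, offset = rescale_to_reference(sign * a, b)
        err = float(np.mean((y - b) ** 2))
        if best is None or err < best[0]:
            best = (err, gain, offset, neg)
    err, gain, offset, neg = best
    degenerate = gain == 0.0
    return EvaluationReport(
        mse=err, rescale_gain=gain, rescale_offset=offset,
        negated=neg, degenerate=degenerate, method=method, scene=scene,
    )
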