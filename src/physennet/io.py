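"""Image and metadata serialization.

Images (phase maps in radians, intensities dimensionless) travel as 32-bit
float TIFF; 8/16-bit PNG input is accepted and rescaled to [0, 1].  The
physical metadata of a measurement lives in a sidecar JSON next to the image
(same stem, ``.json`` suffix) with the fixed keys ``wavelength_m``,
``pitch_m`` and ``distance_m``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .optics import PropagationSpec

__all__ = [
    "read_intensity", "read_phase", "write_image", "write_metadata",
    "sidecar_path", "parse_length",
]

_UNITS = {"nm": 1e-9, "um": 1e-6, "µm": 1e-6, "mm": 1e-3, "cm": 1e-2, "m": 1.0}
_META_KEYS = ("wavelength_m", "pitch_m", "distance_m")


def parse_length(text: str | float) -> float:
    """Parse a length with an explicit unit suffix into meters.

    Accepts e.g. ``"632.8nm"``, ``"8um"``, ``"10mm"``, ``"0.01"`` (plain
    numbers are meters).
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    for suffix in sorted(_UNITS, key=len, reverse=True):
        if s.endswith(suffix):
            return float(s[: -len(suffix)]) * _UNITS[suffix]
    return float(s)


def sidecar_path(image_path: str | Path) -> Path:
    return Path(image_path).with_suffix(".json")


def write_image(path: str | Path, values: np.ndarray) -> Path:
    """Write a 2D array as 32-bit float TIFF (lossless for float32 data)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    return path


def write_metadata(image_path: str | Path, spec: PropagationSpec) -> Path:
    meta = {
        "wavelength_m": spec.wavelength,
        "pitch_m": spec.pitch,
        "distance_m": spec.distance,
    }
    p = sidecar_path(image_path)
    p.write_text(json.dumps(meta, indent=2))
    return p


def _read_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path), dtype=np.float64)
    elif suffix == ".png":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path))
        if raw.ndim == 3:
            raw = raw.mean(axis=2)
        full = 65535.0 if raw.dtype == np.uint16 else 255.0
        arr = raw.astype(np.float64) / full
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    if arr.ndim != 2:
        raise ValueError(f"expected a single 2D image, got shape {arr.shape}")
    return arr


def read_phase(path: str | Path) -> np.ndarray:
    """Read a phase map (radians) from float TIFF."""
    return _read_image(Path(path))


def read_intensity(path: str | Path,
                   wavelength: float | str | None = None,
                   pitch: float | str | None = None,
                   distance: float | str | None = None,
                   ) -> tuple[np.ndarray, PropagationSpec]:
    """Read a measured intensity plus its propagation metadata.

    Metadata comes from the sidecar JSON; explicit keyword arguments
    override it (and may carry unit suffixes, e.g. ``"10mm"``).  Missing
    required keys raise an error that names them.
    """
    path = Path(path)
    arr = _read_image(path)
    if np.any(arr < 0):
        warnings.warn("negative intensity values clipped to zero", RuntimeWarning)
        arr = np.clip(arr, 0.0, None)

    meta: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    overrides = {
        "wavelength_m": wavelength, "pitch_m": pitch, "distance_m": distance,
    }
    for key, val in overrides.items():
        if val is not None:
            meta[key] = parse_length(val)
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValueError(
            f"missing physical metadata {missing} for {path.name}: provide a "
            f"sidecar JSON ({sp.name}) or explicit overrides"
        )
    spec = PropagationSpec(
        wavelength=float(meta["wavelength_m"]),
        pitch=float(meta["pitch_m"]),
        distance=float(meta["distance_m"]),
    )
    return arr, spec
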