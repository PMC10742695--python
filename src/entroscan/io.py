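"""RF frame I/O, Hilbert envelope detection and B-mode rendering.

An RF frame is the raw backscattered radiofrequency signal of one ultrasound
image: a 2-D real array with the axial (fast-time) axis first and one column
per scanline, plus acquisition metadata.  Frames are stored as a portable
container: a NumPy ``.npy`` array (or raw little-endian float32 with the shape
recorded in the sidecar) next to a JSON sidecar holding the acquisition
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .errors import ConfigurationError, FormatError

__all__ = [
    "AcquisitionMeta",
    "RFFrame",
    "EnvelopeFrame",
    "BModeImage",
    "read_rf_frame",
    "write_rf_frame",
    "detect_envelope",
    "render_bmode",
    "save_bmode_png",
]

# JSON sidecar keys <-> AcquisitionMeta fields
_META_KEYS = {
    "sampling_frequency_hz": "sampling_frequency",
    "center_frequency_hz": "center_frequency",
    "pulse_length_mm": "pulse_length",
    "sound_speed_mps": "sound_speed",
    "geometry": "geometry",
    "scanline_pitch": "scanline_pitch",
    "convex_radius_mm": "convex_radius",
    "sector_angle_deg": "sector_angle",
}
_REQUIRED_KEYS = ("sampling_frequency_hz", "center_frequency_hz", "pulse_length_mm")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters of one RF frame.

    Parameters
    ----------
    sampling_frequency : float
        RF sampling rate in Hz.  Must exceed twice the center frequency.
    center_frequency : float
        Transducer center frequency in Hz.
    pulse_length : float
        Axial −6 dB extent of the transmitted pulse, in mm.  Sets the natural
        scale of the entropy gating window (1 PL × 1 PL by default).
    sound_speed : float
        Assumed speed of sound in tissue, m/s.
    scanline_pitch : float
        Lateral spacing between scanlines: mm for linear arrays, degrees for
        convex arrays.
    geometry : str
        ``"linear"`` or ``"convex"``.
    convex_radius, sector_angle : float, optional
        Convex-array probe radius (mm) and total sector angle (degrees);
        required iff geometry is convex.
    """

    sampling_frequency: float
    center_frequency: float
    pulse_length: float
    sound_speed: float = 1540.0
    scanline_pitch: float = 0.3
    geometry: str = "linear"
    convex_radius: float | None = None
    sector_angle: float | None = None

    def __post_init__(self) -> None:
        if self.sampling_frequency <= 2.0 * self.center_frequency:
            raise ConfigurationError(
                "sampling_frequency must exceed 2 x center_frequency "
                f"(got {self.sampling_frequency} <= 2 x {self.center_frequency})"
            )
        if self.pulse_length <= 0:
            raise ConfigurationError("pulse_length must be > 0")
        if self.sound_speed <= 0:
            raise ConfigurationError("sound_speed must be > 0")
        if self.geometry not in ("linear", "convex"):
            raise ConfigurationError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "convex" and (
            self.convex_radius is None or self.sector_angle is None
        ):
            raise ConfigurationError(
                "convex geometry requires convex_radius and sector_angle"
            )

    @property
    def depth_per_sample_mm(self) -> float:
        """Axial depth covered by one RF sample (pulse-echo), in mm."""
        return self.sound_speed / (2.0 * self.sampling_frequency) * 1e3

    @property
    def pulse_length_samples(self) -> float:
        """Pulse length expressed in axial samples."""
        return self.pulse_length / self.depth_per_sample_mm

    def lateral_pitch_mm(self) -> float:
        """Scanline pitch as arc length at the transducer face, in mm."""
        if self.geometry == "convex":
            return self.convex_radius * np.deg2rad(self.scanline_pitch)
        return self.scanline_pitch

    def to_json_dict(self) -> dict:
        d = asdict(self)
        return {k: d[v] for k, v in _META_KEYS.items() if d[v] is not None}


def _meta_from_json_dict(obj: dict) -> AcquisitionMeta:
    for key in _REQUIRED_KEYS:
        if key not in obj:
            raise ConfigurationError(f"missing required metadata field: {key!r}")
    kwargs = {
        field_name: obj[key] for key, field_name in _META_KEYS.items() if key in obj
    }
    return AcquisitionMeta(**kwargs)


@dataclass(frozen=True)
class RFFrame:
    """One frame of raw backscattered RF signals (axial × lateral)."""

    samples: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 2:
            raise FormatError(f"RF samples must be 2-D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise FormatError("RF samples contain non-finite values")
        object.__setattr__(self, "samples", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape


@dataclass(frozen=True)
class EnvelopeFrame:
    """Hilbert-detected amplitude image, same shape as the source RF frame."""

    amplitude: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        arr = np.asarray(self.amplitude, dtype=np.float64)
        if arr.ndim != 2:
            raise FormatError("envelope must be 2-D")
        if np.any(arr < 0):
            raise FormatError("envelope amplitude must be non-negative")
        object.__setattr__(self, "amplitude", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


@dataclass(frozen=True)
class BModeImage:
    """Log-compressed envelope mapped to [0, 255] (acquisition coordinates)."""

    pixels: np.ndarray
    dynamic_range: float
    meta: AcquisitionMeta


def read_rf_frame(path: str | Path, meta_path: str | Path) -> RFFrame:
    """Read an RF frame from an array file plus a JSON metadata sidecar.

    ``.npy`` files are loaded directly; any other extension is treated as raw
    little-endian float32 and reshaped from the sidecar's ``"shape"`` entry.
    """
    meta_path = Path(meta_path)
    with open(meta_path) as fh:
        obj = json.load(fh)
    meta = _meta_from_json_dict(obj)

    path = Path(path)
    if path.suffix == ".npy":
        samples = np.load(path)
    else:
        raw = np.fromfile(path, dtype="<f4")
        if "shape" not in obj:
            raise ConfigurationError(
                "raw binary RF input requires a 'shape' entry in the metadata sidecar"
            )
        samples = raw.reshape(tuple(obj["shape"]))
    if np.ndim(samples) != 2:
        raise FormatError(f"RF array must be 2-D, got ndim={np.ndim(samples)}")
    return RFFrame(samples=np.asarray(samples), meta=meta)


def write_rf_frame(frame: RFFrame, path: str | Path, meta_path: str | Path) -> None:
    """Write a frame as ``.npy`` (or raw float32) plus its JSON sidecar."""
    path = Path(path)
    obj = frame.meta.to_json_dict()
    if path.suffix == ".npy":
        np.save(path, frame.samples)
    else:
        frame.samples.astype("<f4").tofile(path)
        obj["shape"] = list(frame.shape)
    with open(meta_path, "w") as fh:
        json.dump(obj, fh, indent=2)


def detect_envelope(rf: RFFrame) -> EnvelopeFrame:
    """Detect the envelope of each scanline as |analytic signal|.

    The Hilbert transform is taken along the axial axis over the whole
    scanline (full-length FFT, no segmentation or windowing).
    """
    analytic = hilbert(rf.samples, axis=0)
    return EnvelopeFrame(amplitude=np.abs(analytic), meta=rf.meta)


def render_bmode(env: EnvelopeFrame, dynamic_range_db: float = 40.0) -> BModeImage:
    """Log-compress an envelope frame into an 8-bit-range B-mode image.

    Amplitudes are referenced to the frame maximum, compressed to
    ``20*log10(A/Amax)``, clipped to ``[-dynamic_range_db, 0]`` dB and mapped
    affinely onto ``[0, 255]``.  Geometry resampling (scan conversion) is a
    separate display step shared with the parametric image.
    """
    if dynamic_range_db <= 0:
        raise ConfigurationError("dynamic_range_db must be > 0")
    amax = float(np.max(env.amplitude))
    if amax <= 0:
        raise FormatError("empty envelope")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env.amplitude / amax)
    db = np.clip(db, -dynamic_range_db, 0.0)
    pixels = (db + dynamic_range_db) / dynamic_range_db * 255.0
    return BModeImage(pixels=pixels, dynamic_range=dynamic_range_db, meta=env.meta)


def save_bmode_png(image: np.ndarray, path: str | Path) -> None:
    """Save a [0, 255] grayscale image (NaN rendered black) as 8-bit PNG."""
    from PIL import Image

    arr = np.nan_to_num(np.asarray(image, dtype=np.float64), nan=0.0)
    Image.fromarray(np.clip(np.rint(arr), 0, 255).astype(np.uint8), mode="L").save(path)
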