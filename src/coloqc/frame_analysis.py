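"""Stateless per-frame image measurements.

Three primitives drive the withdrawal quality-control pipeline:

* **Sharpness** — the variance of the discrete Laplacian response
  (``Var_L``).  Defocused or motion-blurred endoscopy frames lose
  high-frequency content, so their second-derivative response collapses
  toward zero.  Frames with ``Var_L`` below a threshold (default 50,
  calibrated for 8-bit frames at roughly SD-video resolution) are treated
  as non-interpretable.
* **Perceptual hash** — a 64-bit DCT fingerprint of the frame.  The
  Hamming distance ``D`` between the hashes of consecutive frames is a
  sensor-free proxy for how fast the scope is moving: visually similar
  frames hash close together.
* **Speed zones** — ``D`` is bucketed into *normal* (``D <= 20``),
  *warning* (``21 <= D <= 30``) and *danger* (``D > 30``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.fftpack import dct

__all__ = [
    "BlurAssessment",
    "FrameHash",
    "SpeedSample",
    "SpeedZone",
    "DEFAULT_BLUR_THRESHOLD",
    "ZONE_NORMAL_MAX",
    "ZONE_WARNING_MAX",
    "to_grayscale",
    "laplacian_variance",
    "is_blurred",
    "assess_blur",
    "perceptual_hash",
    "hamming_distance",
    "speed_zone",
]

#: Default Var_L decision boundary below which a frame counts as blurred.
DEFAULT_BLUR_THRESHOLD = 50.0

#: Largest Hamming distance still considered normal withdrawal speed.
ZONE_NORMAL_MAX = 20
#: Largest Hamming distance still considered warning speed.
ZONE_WARNING_MAX = 30

HASH_BITS = 64

# ITU-R BT.601 luminance weights, the common default for RGB->gray.
_BT601 = np.array([0.299, 0.587, 0.114])

# 4-neighbour discrete Laplacian.
_LAPLACIAN_KERNEL = np.array(
    [[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]
)


class SpeedZone(str, Enum):
    """Color-coded withdrawal-speed category."""

    NORMAL = "normal"
    WARNING = "warning"
    DANGER = "danger"


@dataclass(frozen=True)
class BlurAssessment:
    """Outcome of the Laplacian-variance blur decision for one frame."""

    variance: float
    is_blurred: bool
    threshold_used: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("Laplacian variance cannot be negative")
        if self.is_blurred != (self.variance < self.threshold_used):
            raise ValueError("is_blurred inconsistent with variance/threshold")


@dataclass(frozen=True)
class FrameHash:
    """64-bit DCT perceptual hash of a frame."""

    bits: int

    def __post_init__(self) -> None:
        if not 0 <= self.bits < (1 << HASH_BITS):
            raise ValueError("hash must fit in 64 bits")

    @property
    def hex(self) -> str:
        return format(self.bits, "016x")

    @classmethod
    def from_hex(cls, hx: str) -> "FrameHash":
        if len(hx) != 16:
            raise ValueError("expected 16 hex characters")
        return cls(int(hx, 16))

    def __sub__(self, other: "FrameHash") -> int:
        return hamming_distance(self, other)


@dataclass(frozen=True)
class SpeedSample:
    """Hamming distance between consecutive frame hashes plus its zone."""

    distance: int
    zone: SpeedZone

    def __post_init__(self) -> None:
        if not 0 <= self.distance <= HASH_BITS:
            raise ValueError("distance out of [0, 64]")
        if self.zone is not speed_zone(self.distance):
            raise ValueError("zone inconsistent with distance")


def _validate_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim not in (2, 3) or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D or 3-plane array")
    if frame.ndim == 3 and frame.shape[2] not in (3, 4):
        raise ValueError("color frames must have 3 (RGB) or 4 (RGBA) planes")
    return frame


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to float64 grayscale using BT.601 luminance weights.

    Grayscale input passes through unchanged (as float64); an alpha plane,
    if present, is ignored.
    """
    frame = _validate_frame(frame)
    if frame.ndim == 2:
        return frame.astype(np.float64)
    return frame[..., :3].astype(np.float64) @ _BT601


def laplacian_variance(frame: np.ndarray) -> float:
    """Variance of the 3x3 discrete Laplacian response of ``frame``.

    The frame is converted to grayscale (BT.601), convolved with the
    4-neighbour Laplacian kernel with edge-replication border handling,
    and the population variance of the response over all pixels is
    returned.  A constant frame gives exactly 0.
    """
    gray = to_grayscale(frame)
    response = ndimage.convolve(gray, _LAPLACIAN_KERNEL, mode="nearest")
    return float(response.var())


def is_blurred(variance: float, threshold: float = DEFAULT_BLUR_THRESHOLD) -> bool:
    """True iff ``variance`` is strictly below ``threshold``."""
    if variance < 0:
        raise ValueError("variance cannot be negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return variance < threshold


def assess_blur(
    frame: np.ndarray, threshold: float = DEFAULT_BLUR_THRESHOLD
) -> BlurAssessment:
    """Compute Var_L for ``frame`` and apply the blur decision."""
    var = laplacian_variance(frame)
    return BlurAssessment(var, is_blurred(var, threshold), threshold)


def perceptual_hash(frame: np.ndarray) -> FrameHash:
    """Standard 64-bit DCT perceptual hash (pHash).

    The frame is converted to 8-bit grayscale, resized to 32x32 with
    Lanczos resampling, transformed with a 2-D DCT-II, and the top-left
    8x8 low-frequency block (DC term included) is thresholded against its
    median: coefficients strictly above the median map to 1, coefficients
    at or below it map to 0.  Bits are packed row-major, first bit most
    significant.
    """
    frame = _validate_frame(frame)
    if frame.dtype != np.uint8:
        frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    img = Image.fromarray(frame).convert("L")
    pixels = np.asarray(
        img.resize((32, 32), Image.Resampling.LANCZOS), dtype=np.float64
    )
    coeffs = dct(dct(pixels, axis=0), axis=1)
    block = coeffs[:8, :8]
    bits_arr = block > np.median(block)
    bits = 0
    for b in bits_arr.ravel():
        bits = (bits << 1) | int(b)
    return FrameHash(bits)


def hamming_distance(h1: FrameHash, h2: FrameHash) -> int:
    """Number of differing bits between two 64-bit hashes."""
    return int(h1.bits ^ h2.bits).bit_count()


def speed_zone(distance: int) -> SpeedZone:
    """Map a hash distance to its withdrawal-speed zone.

    The zones partition [0, 64]: normal for ``D <= 20``, warning for
    ``21 <= D <= 30``, danger for ``D > 30``.
    """
    distance = int(distance)
    if not 0 <= distance <= HASH_BITS:
        raise ValueError("distance must lie in [0, 64]")
    if distance <= ZONE_NORMAL_MAX:
        return SpeedZone.NORMAL
    if distance <= ZONE_WARNING_MAX:
        return SpeedZone.WARNING
    return SpeedZone.DANGER


def speed_sample(distance: int) -> SpeedSample:
    """Bundle a distance with its zone."""
    return SpeedSample(distance, speed_zone(distance))
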