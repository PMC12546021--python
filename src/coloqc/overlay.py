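"""Live quality-display overlay rendering.

Reproduces the on-screen feedback of the quality-control display: a
timer block in the upper-left corner with the running withdrawal time
and effective withdrawal time as ``mm:ss``, and a color-coded speed
scale bar (blue / yellow / red for the normal / warning / danger zones)
with a pointer at the current hash distance.  Rendering is fully
deterministic and touches only the declared overlay rectangles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image, ImageDraw

from .frame_analysis import ZONE_NORMAL_MAX, ZONE_WARNING_MAX, HASH_BITS

__all__ = ["OverlaySpec", "render_overlay", "overlay_regions", "format_mmss"]

#: Fixed zone colors (RGB): blue normal, yellow warning, red danger.
ZONE_COLORS = {
    "normal": (40, 90, 235),
    "warning": (240, 200, 30),
    "danger": (220, 40, 40),
}

_TEXT_BG = (20, 20, 20)
_TEXT_FG = (255, 255, 255)
_POINTER = (255, 255, 255)


@dataclass(frozen=True)
class OverlaySpec:
    """Geometry and colors of the overlay, in pixels at scale 1."""

    margin: int = 8
    timer_size: Tuple[int, int] = (118, 36)  # (w, h)
    bar_size: Tuple[int, int] = (130, 14)
    gap: int = 6

    def footprint(self) -> Tuple[int, int]:
        w = self.margin + max(self.timer_size[0], self.bar_size[0])
        h = self.margin + self.timer_size[1] + self.gap + self.bar_size[1]
        return w, h


def format_mmss(seconds: float) -> str:
    seconds = max(0, int(seconds))
    return f"{seconds // 60:02d}:{seconds % 60:02d}"


def _scaled(spec: OverlaySpec, frame_w: int, frame_h: int) -> Tuple[OverlaySpec, float]:
    need_w, need_h = spec.footprint()
    scale = min(1.0, frame_w / (need_w + spec.margin), frame_h / (need_h + spec.margin))
    if scale < 1.0:
        warnings.warn(
            f"frame {frame_w}x{frame_h} smaller than the overlay footprint; "
            f"scaling overlay by {scale:.2f}"
        )
        s = lambda v: max(1, int(round(v * scale)))
        spec = OverlaySpec(
            margin=s(spec.margin),
            timer_size=(s(spec.timer_size[0]), s(spec.timer_size[1])),
            bar_size=(s(spec.bar_size[0]), s(spec.bar_size[1])),
            gap=s(spec.gap),
        )
    return spec, scale


def overlay_regions(
    frame_shape: Tuple[int, ...], spec: OverlaySpec = OverlaySpec()
) -> List[Tuple[int, int, int, int]]:
    """Declared overlay rectangles as (x0, y0, x1, y1), exclusive ends.

    Pixels outside these rectangles are guaranteed untouched by
    :func:`render_overlay`.
    """
    h, w = frame_shape[:2]
    spec, _ = _scaled(spec, w, h)
    m = spec.margin
    tw, th = spec.timer_size
    bw, bh = spec.bar_size
    bar_y = m + th + spec.gap
    return [(m, m, m + tw, m + th), (m, bar_y, m + bw, bar_y + bh)]


def render_overlay(
    frame: np.ndarray,
    wt_s: float,
    ewt_s: float,
    distance: Optional[int],
    spec: OverlaySpec = OverlaySpec(),
) -> np.ndarray:
    """Return an RGB copy of ``frame`` with the quality display drawn in.

    ``distance`` is the current consecutive-frame hash distance (clamped
    to [0, 64]); None (first frame) leaves the pointer at the left edge.
    The pointer position is a monotone function of the distance: 0 maps
    to the left edge of the blue band, 64 to the right extreme of the
    red band.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        rgb = np.stack([frame] * 3, axis=-1)
    else:
        rgb = frame[..., :3].copy()
    rgb = rgb.astype(np.uint8)
    h, w = rgb.shape[:2]
    spec, _ = _scaled(spec, w, h)

    img = Image.fromarray(rgb)
    draw = ImageDraw.Draw(img)
    m = spec.margin
    tw, th = spec.timer_size
    bw, bh = spec.bar_size

    # timer block
    draw.rectangle([m, m, m + tw - 1, m + th - 1], fill=_TEXT_BG)
    draw.text((m + 4, m + 2), f"WT  {format_mmss(wt_s)}", fill=_TEXT_FG)
    draw.text((m + 4, m + th // 2 + 1), f"EWT {format_mmss(ewt_s)}", fill=_TEXT_FG)

    # speed scale bar: bands sized by their share of the [0, 64] range
    bar_y = m + th + spec.gap
    edges = [0, ZONE_NORMAL_MAX + 1, ZONE_WARNING_MAX + 1, HASH_BITS + 1]
    colors = [ZONE_COLORS["normal"], ZONE_COLORS["warning"], ZONE_COLORS["danger"]]
    for lo, hi, color in zip(edges[:-1], edges[1:], colors):
        x0 = m + int(round(bw * lo / (HASH_BITS + 1)))
        x1 = m + int(round(bw * hi / (HASH_BITS + 1)))
        draw.rectangle([x0, bar_y, x1 - 1, bar_y + bh - 1], fill=color)

    d = 0 if distance is None else int(np.clip(distance, 0, HASH_BITS))
    px = m + min(int(round((bw - 2) * d / HASH_BITS)), bw - 2)
    draw.rectangle([px, bar_y, px + 1, bar_y + bh - 1], fill=_POINTER)

    return np.asarray(img)
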