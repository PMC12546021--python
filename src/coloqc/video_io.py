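"""Frame sources and sinks.

The always-available interchange format is a directory of numbered
PNG/JPEG stills; MP4/AVI files are read and written through imageio when
an ffmpeg-capable plugin is installed, with a clear error otherwise.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, List

import numpy as np
from PIL import Image

__all__ = ["iter_frames", "read_frames", "write_frames_png", "write_video"]

_STILL_SUFFIXES = {".png", ".jpg", ".jpeg"}
_VIDEO_SUFFIXES = {".mp4", ".avi", ".mkv", ".mov"}


def iter_frames(source: str | Path) -> Iterator[np.ndarray]:
    """Yield frames (uint8 arrays) from a stills directory or a video file.

    A directory is read as its image files in lexicographic order, which
    matches the ``frame_%06d`` naming the generator and the annotated
    output use.
    """
    source = Path(source)
    if source.is_dir():
        stills = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _STILL_SUFFIXES
        )
        if not stills:
            raise FileNotFoundError(f"no PNG/JPEG stills found in {source}")
        for p in stills:
            yield np.asarray(Image.open(p))
        return
    if not source.exists():
        raise FileNotFoundError(source)
    if source.suffix.lower() in _VIDEO_SUFFIXES:
        import imageio.v3 as iio

        try:
            for frame in iio.imiter(source):
                yield np.asarray(frame)
        except Exception as exc:
            raise IOError(
                f"cannot decode {source}: no capable video plugin available "
                "(install imageio-ffmpeg) — or pass a PNG frame directory"
            ) from exc
        return
    raise ValueError(f"unsupported frame source: {source}")


def read_frames(source: str | Path) -> List[np.ndarray]:
    return list(iter_frames(source))


def write_frames_png(frames, outdir: str | Path, prefix: str = "frame") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        Image.fromarray(np.asarray(frame)).save(outdir / f"{prefix}_{i:06d}.png")
    return outdir


def write_video(frames, path: str | Path, fps: float) -> Path:
    """Encode frames to a video file; requires an ffmpeg-capable plugin."""
    import imageio.v3 as iio

    path = Path(path)
    try:
        iio.imwrite(path, np.stack([np.asarray(f) for f in frames]), fps=fps)
    except Exception as exc:
        raise IOError(
            f"cannot encode {path}: no capable video plugin available "
            "(install imageio-ffmpeg) — use --annotated with a directory path"
        ) from exc
    return path
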