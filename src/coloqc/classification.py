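"""Frame classification contract and non-learned reference classifiers.

Every frame of a withdrawal video is assigned one of three classes:

* ``ileocecal`` — the ileocecal valve region, the landmark that marks the
  start of withdrawal timing;
* ``instrument`` — biopsy forceps, snares, or other instruments in view
  (instrument time is excluded from effective withdrawal time);
* ``normal`` — ordinary mucosal observation.

The downstream engine only depends on the :class:`Classifier` protocol, so
any model can be plugged in through :class:`CallableClassifier`.  Two
non-learned implementations ship with the package: a sidecar stub that
replays labels from a CSV file (used to drive the engine with ground
truth), and a marker heuristic keyed to the synthetic generator's visual
signatures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterable, Protocol

import numpy as np
from PIL import Image

__all__ = [
    "LABELS",
    "FrameLabel",
    "LabelSidecar",
    "Classifier",
    "SidecarClassifier",
    "MarkerHeuristicClassifier",
    "CallableClassifier",
    "letterbox_resize",
    "LETTERBOX_PAD_VALUE",
]

#: Closed three-class vocabulary.
LABELS = ("ileocecal", "instrument", "normal")

#: Mid-gray letterbox padding constant (common detector-family convention).
LETTERBOX_PAD_VALUE = 114


@dataclass(frozen=True)
class FrameLabel:
    """A class label plus the classifier's confidence in it."""

    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


class LabelSidecar:
    """Ordered per-frame labels read from / written to a CSV sidecar.

    The CSV dialect is ``frame_index,label,confidence`` with a header row;
    frame indices must be contiguous from 0.
    """

    def __init__(self, entries: Dict[int, FrameLabel]):
        n = len(entries)
        if sorted(entries) != list(range(n)):
            raise ValueError("sidecar indices must be contiguous from 0")
        self.entries = dict(sorted(entries.items()))
        self.n_frames = n

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, index: int) -> FrameLabel:
        try:
            return self.entries[index]
        except KeyError:
            raise KeyError(f"frame index {index} not present in sidecar") from None

    @classmethod
    def from_labels(
        cls, labels: Iterable[str], confidences: Iterable[float] | None = None
    ) -> "LabelSidecar":
        labels = list(labels)
        confs = list(confidences) if confidences is not None else [1.0] * len(labels)
        return cls({i: FrameLabel(l, c) for i, (l, c) in enumerate(zip(labels, confs))})

    @classmethod
    def read_csv(cls, path: str | Path) -> "LabelSidecar":
        entries: Dict[int, FrameLabel] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"frame_index", "label", "confidence"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                missing = required - set(reader.fieldnames or [])
                raise ValueError(f"sidecar missing column(s): {sorted(missing)}")
            for row in reader:
                entries[int(row["frame_index"])] = FrameLabel(
                    row["label"], float(row["confidence"])
                )
        return cls(entries)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame_index", "label", "confidence"])
            for idx, fl in self.entries.items():
                writer.writerow([idx, fl.label, f"{fl.confidence:.6g}"])


class Classifier(Protocol):
    """Anything that labels one frame given its pixel array and index."""

    def classify(self, frame: np.ndarray, index: int) -> FrameLabel: ...


class SidecarClassifier:
    """Stub classifier replaying a ground-truth sidecar by frame index."""

    def __init__(self, sidecar: LabelSidecar):
        self.sidecar = sidecar

    def classify(self, frame: np.ndarray, index: int) -> FrameLabel:
        return self.sidecar[index]


class CallableClassifier:
    """Adapter wrapping any ``(frame, index) -> FrameLabel`` callable.

    This is the extension point for a trained model: export the network
    behind a plain callable and pass it here.  No model loading or
    training machinery lives in this package.
    """

    def __init__(self, fn: Callable[[np.ndarray, int], FrameLabel]):
        self.fn = fn

    def classify(self, frame: np.ndarray, index: int) -> FrameLabel:
        out = self.fn(frame, index)
        if not isinstance(out, FrameLabel):
            out = FrameLabel(*out) if isinstance(out, tuple) else FrameLabel(out)
        return out


class MarkerHeuristicClassifier:
    """Heuristic keyed to the synthetic generator's marker signatures.

    The generator stamps an ileocecal frame with a dark annulus around the
    frame centre and an instrument frame with a bright straight chord
    entering from the bottom edge (see :mod:`coloqc.synthetic`).  The
    heuristic probes the mean intensity along each signature's footprint
    against the frame mean; contrast beyond ``margin`` gray levels decides
    the class.  Ileocecal takes priority over instrument.
    """

    def __init__(self, margin: float = 40.0):
        self.margin = margin

    def classify(self, frame: np.ndarray, index: int) -> FrameLabel:
        from . import synthetic  # shared marker geometry constants

        from .frame_analysis import to_grayscale

        gray = to_grayscale(frame)
        h, w = gray.shape
        frame_mean = gray.mean()

        ring = synthetic.annulus_mask(h, w)
        ring_contrast = frame_mean - gray[ring].mean()

        chord = synthetic.chord_mask(h, w)
        chord_contrast = gray[chord].mean() - frame_mean

        def conf(contrast: float) -> float:
            return float(np.clip(0.5 + contrast / (2 * self.margin), 0.0, 1.0))

        if ring_contrast > self.margin:
            return FrameLabel("ileocecal", conf(ring_contrast))
        if chord_contrast > self.margin:
            return FrameLabel("instrument", conf(chord_contrast))
        best = max(ring_contrast, chord_contrast)
        return FrameLabel("normal", conf(self.margin - best))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def letterbox_resize(frame: np.ndarray, target: int = 640) -> np.ndarray:
    """Resize to ``target`` x ``target`` preserving aspect ratio.

    Content is scaled by ``min(target/w, target/h)`` (dimensions rounded
    half-up), centred, and padded with mid-gray ``LETTERBOX_PAD_VALUE``.
    A frame already at the target size is returned unchanged apart from
    dtype normalisation, which makes the operation idempotent.
    """
    frame = np.asarray(frame)
    if frame.ndim not in (2, 3) or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D or 3-plane array")
    if frame.dtype != np.uint8:
        frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    h, w = frame.shape[:2]
    scale = min(target / w, target / h)
    new_w = min(_round_half_up(w * scale), target)
    new_h = min(_round_half_up(h * scale), target)
    if (new_w, new_h) != (w, h):
        resample = Image.Resampling.BILINEAR
        content = np.asarray(Image.fromarray(frame).resize((new_w, new_h), resample))
    else:
        content = frame
    shape = (target, target) + frame.shape[2:]
    out = np.full(shape, LETTERBOX_PAD_VALUE, dtype=np.uint8)
    top = (target - new_h) // 2
    left = (target - new_w) // 2
    out[top : top + new_h, left : left + new_w] = content
    return out
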