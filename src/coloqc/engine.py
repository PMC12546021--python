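"""The withdrawal state machine: time-bucket accounting over a frame stream.

Withdrawal time (WT) runs from the first frame of the first sustained run
of ileocecal-classified frames to the end of the stream.  Every frame
after that start is assigned to exactly one bucket:

* ``time1`` — instrument operation frames (biopsy, polypectomy, ...);
* ``time2`` — non-interpretable frames: not instrument, but blurred
  (Laplacian variance below the threshold);
* ``effective`` — everything else, i.e. actual mucosal inspection.

Frames before the start are ``pre_withdrawal`` and count toward nothing.
The effective withdrawal time is then the exact identity
``EWT = WT - Time1 - Time2``, maintained at frame resolution and
converted to seconds by the frame rate.

Instrument takes priority over blur so the buckets are disjoint and the
identity holds by construction.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .classification import Classifier, FrameLabel
from .frame_analysis import (
    DEFAULT_BLUR_THRESHOLD,
    ZONE_NORMAL_MAX,
    ZONE_WARNING_MAX,
    FrameHash,
    SpeedZone,
    hamming_distance,
    is_blurred,
    laplacian_variance,
    perceptual_hash,
    speed_zone,
)

__all__ = [
    "BUCKETS",
    "EngineConfig",
    "FrameObservation",
    "WithdrawalSummary",
    "detect_withdrawal_start",
    "assign_bucket",
    "run_engine",
    "summarize_zones",
    "write_framelog_csv",
    "write_summary_json",
]

BUCKETS = ("pre_withdrawal", "effective", "time1", "time2")

#: Fallback frame rate when neither the source nor the config provides one.
DEFAULT_FPS = 25.0


@dataclass(frozen=True)
class EngineConfig:
    """Tunable thresholds and rates for the withdrawal engine.

    ``start_run_length`` debounces the withdrawal-start trigger: the run
    of consecutive ileocecal-classified processed frames required before
    the first frame of that run is declared the start of withdrawal.
    """

    fps: float = DEFAULT_FPS
    blur_threshold: float = DEFAULT_BLUR_THRESHOLD
    start_run_length: int = 5
    frame_stride: int = 1
    zone_normal_max: int = ZONE_NORMAL_MAX
    zone_warning_max: int = ZONE_WARNING_MAX

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.blur_threshold <= 0:
            raise ValueError("blur_threshold must be positive")
        if self.start_run_length < 1:
            raise ValueError("start_run_length must be >= 1")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")
        if not 0 <= self.zone_normal_max < self.zone_warning_max <= 64:
            raise ValueError("zone thresholds must be strictly increasing in [0, 64]")

    def zone_of(self, distance: int) -> SpeedZone:
        if distance <= self.zone_normal_max:
            return SpeedZone.NORMAL
        if distance <= self.zone_warning_max:
            return SpeedZone.WARNING
        return SpeedZone.DANGER


@dataclass
class FrameObservation:
    """Everything the engine measured about one processed frame."""

    index: int
    time_s: float
    label: FrameLabel
    variance: float
    blurred: bool
    hash: FrameHash
    hash_distance: Optional[int]  # None for the first processed frame
    zone: Optional[SpeedZone]
    bucket: str = "pre_withdrawal"


@dataclass
class WithdrawalSummary:
    """WT / Time 1 / Time 2 / EWT in frames and seconds, plus zone counts.

    Frame counts are in processed frames; seconds account for the stride
    (``seconds = frames * stride / fps``), so with the default stride of 1
    the two are related by the frame rate exactly.
    """

    start_frame: Optional[int]
    fps: float
    frame_stride: int
    frames_total: int
    wt_frames: int
    time1_frames: int
    time2_frames: int
    ewt_frames: int
    wt_s: float
    time1_s: float
    time2_s: float
    ewt_s: float
    zone_occupancy: Dict[str, int]

    def __post_init__(self) -> None:
        if self.ewt_frames != self.wt_frames - self.time1_frames - self.time2_frames:
            raise ValueError("bucket counts violate EWT = WT - Time1 - Time2")
        if self.ewt_frames < 0:
            raise ValueError("EWT cannot be negative")


def detect_withdrawal_start(
    labels: Iterable[FrameLabel | str], run_length: int = 5
) -> Optional[int]:
    """Index of the first frame of the first run of >= ``run_length``
    consecutive ileocecal labels; None if no such run exists."""
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    run_start, run_len = None, 0
    for i, lab in enumerate(labels):
        name = lab.label if isinstance(lab, FrameLabel) else lab
        if name == "ileocecal":
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= run_length:
                return run_start
        else:
            run_len = 0
    return None


def assign_bucket(label: FrameLabel | str, blurred: bool, started: bool) -> str:
    """Bucket for one frame given its label, blur state and whether the
    withdrawal has started.  Instrument takes priority over blur."""
    if not started:
        return "pre_withdrawal"
    name = label.label if isinstance(label, FrameLabel) else label
    if name == "instrument":
        return "time1"
    if blurred:
        return "time2"
    return "effective"


def run_engine(
    frames: Iterable[np.ndarray] | Sequence[np.ndarray],
    classifier: Classifier,
    config: EngineConfig = EngineConfig(),
) -> Tuple[List[FrameObservation], WithdrawalSummary]:
    """Process a frame stream and account every frame to a time bucket.

    Frames are consumed in order, honouring ``config.frame_stride``
    (indices are the original source indices).  Per-frame hash distances
    and speed zones are computed between consecutive *processed* frames;
    the first processed frame has neither.  WT covers every processed
    frame from the detected start to the end of the stream.  The run is
    deterministic for fixed inputs.
    """
    stride = config.frame_stride
    observations: List[FrameObservation] = []
    prev_hash: Optional[FrameHash] = None
    for source_index, frame in enumerate(frames):
        if source_index % stride:
            continue
        label = classifier.classify(frame, source_index)
        var = laplacian_variance(frame)
        blurred = is_blurred(var, config.blur_threshold)
        fhash = perceptual_hash(frame)
        if prev_hash is None:
            dist, zone = None, None
        else:
            dist = hamming_distance(prev_hash, fhash)
            zone = config.zone_of(dist)
        observations.append(
            FrameObservation(
                index=source_index,
                time_s=source_index / config.fps,
                label=label,
                variance=var,
                blurred=blurred,
                hash=fhash,
                hash_distance=dist,
                zone=zone,
            )
        )
        prev_hash = fhash

    start = detect_withdrawal_start(
        (o.label for o in observations), config.start_run_length
    )
    started = False
    start_source_index: Optional[int] = None
    for pos, obs in enumerate(observations):
        if start is not None and pos == start:
            started = True
            start_source_index = obs.index
        obs.bucket = assign_bucket(obs.label, obs.blurred, started)

    counts = {b: 0 for b in BUCKETS}
    for obs in observations:
        counts[obs.bucket] += 1
    t1, t2 = counts["time1"], counts["time2"]
    wt = counts["effective"] + t1 + t2
    to_s = stride / config.fps
    summary = WithdrawalSummary(
        start_frame=start_source_index,
        fps=config.fps,
        frame_stride=stride,
        frames_total=len(observations),
        wt_frames=wt,
        time1_frames=t1,
        time2_frames=t2,
        ewt_frames=wt - t1 - t2,
        wt_s=wt * to_s,
        time1_s=t1 * to_s,
        time2_s=t2 * to_s,
        ewt_s=(wt - t1 - t2) * to_s,
        zone_occupancy=summarize_zones(observations),
    )
    return observations, summary


def summarize_zones(observations: Sequence[FrameObservation]) -> Dict[str, int]:
    """Processed-frame counts per speed zone.

    The first processed frame has no predecessor, hence no zone, so the
    counts sum to ``len(observations) - 1`` (or 0 for an empty list).
    """
    counts = {z.value: 0 for z in SpeedZone}
    for obs in observations:
        if obs.zone is not None:
            counts[obs.zone.value] += 1
    return counts


# ---------------------------------------------------------------------------
# serialization

FRAMELOG_HEADER = [
    "frame_index", "time_s", "label", "confidence", "lap_var", "blurred",
    "phash_hex", "hash_dist", "speed_zone", "bucket",
]


def write_framelog_csv(
    observations: Sequence[FrameObservation], path: str | Path
) -> None:
    """Write the per-frame log in the documented CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FRAMELOG_HEADER)
        for o in observations:
            writer.writerow([
                o.index,
                f"{o.time_s:.6g}",
                o.label.label,
                f"{o.label.confidence:.6g}",
                f"{o.variance:.6g}",
                int(o.blurred),
                o.hash.hex,
                "" if o.hash_distance is None else o.hash_distance,
                "" if o.zone is None else o.zone.value,
                o.bucket,
            ])


def summary_dict(summary: WithdrawalSummary, config: EngineConfig) -> Dict:
    """JSON-ready summary report including a config echo."""
    return {
        "start_frame": summary.start_frame,
        "fps": summary.fps,
        "wt_s": summary.wt_s,
        "time1_s": summary.time1_s,
        "time2_s": summary.time2_s,
        "ewt_s": summary.ewt_s,
        "wt_frames": summary.wt_frames,
        "time1_frames": summary.time1_frames,
        "time2_frames": summary.time2_frames,
        "ewt_frames": summary.ewt_frames,
        "frames_total": summary.frames_total,
        "zone_occupancy": dict(summary.zone_occupancy),
        "config": {
            "fps": config.fps,
            "blur_threshold": config.blur_threshold,
            "start_run_length": config.start_run_length,
            "frame_stride": config.frame_stride,
            "zone_thresholds": [config.zone_normal_max, config.zone_warning_max],
        },
    }


def write_summary_json(
    summary: WithdrawalSummary, config: EngineConfig, path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps(summary_dict(summary, config), indent=1, sort_keys=True),
        encoding="utf-8",
    )
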