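"""Walking-bout detection and duration stratification.

Strides are detected inside wear time with the same zero-velocity
segmentation used in the clinic, on both feet; consecutive strides (either
foot) closer than the 3-s gap merge into one walking bout.  Bouts shorter
than 10 s are *subthreshold*: they contribute steps but are not counted as
walking bouts.  Duration classes: short [10, 30] s, medium (30, 60] s,
long > 60 s (half-open bins, exhaustive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..config import IgaConfig, PamConfig
from ..recording import ImuRecording
from ..iga.reconstruct import reconstruct_trajectory
from ..iga.segmentation import segment_strides
from .nonwear import WearInterval

log = logging.getLogger("mobgait.pam")


def classify_wb(duration: float, cfg: PamConfig | None = None) -> str:
    """Duration class of a walking bout (``subthreshold`` below 10 s)."""
    cfg = cfg or PamConfig()
    if duration < cfg.subthreshold_s:
        return "subthreshold"
    if duration <= cfg.wb_short_max_s:
        return "short"
    if duration <= cfg.wb_medium_max_s:
        return "medium"
    return "long"


@dataclass
class BoutStride:
    """Minimal per-stride info needed by the monitoring layer."""

    foot: str
    start: float
    end: float
    gait_velocity: float
    stride_length: float

    @property
    def stride_time(self) -> float:
        return self.end - self.start


@dataclass
class WalkingBout:
    """One daily-life walking episode."""

    start: float
    end: float
    wb_class: str
    strides: list[BoutStride] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_strides_left(self) -> int:
        return sum(s.foot == "left" for s in self.strides)

    @property
    def n_strides_right(self) -> int:
        return sum(s.foot == "right" for s in self.strides)

    @property
    def steps(self) -> int:
        return len(self.strides)

    @property
    def step_times(self) -> np.ndarray:
        """Initial-contact proxies: one event per stride per foot."""
        return np.sort(np.array([s.end for s in self.strides]))

    @property
    def cadence(self) -> float:
        return self.steps / self.duration * 60.0

    @property
    def gait_velocity(self) -> float:
        return float(np.median([s.gait_velocity for s in self.strides]))

    @property
    def stride_length(self) -> float:
        return float(np.median([s.stride_length for s in self.strides]))


def _strides_one_foot(imu: ImuRecording, cfg_iga: IgaConfig) -> list[BoutStride]:
    out = []
    for seg in segment_strides(imu, cfg_iga):
        traj = reconstruct_trajectory(imu, seg, cfg_iga)
        if traj is None:
            continue
        t0 = imu.start + seg.start / imu.fs
        t1 = imu.start + seg.end / imu.fs
        out.append(BoutStride(
            foot=imu.foot, start=t0, end=t1,
            gait_velocity=traj.stride_length / (t1 - t0),
            stride_length=traj.stride_length,
        ))
    return out


def detect_walking_bouts(
    left: ImuRecording,
    right: ImuRecording,
    wear: list[WearInterval],
    cfg: PamConfig | None = None,
    cfg_iga: IgaConfig | None = None,
) -> list[WalkingBout]:
    """Detect and stratify walking bouts within wear time."""
    cfg = cfg or PamConfig()
    cfg_iga = cfg_iga or IgaConfig()
    strides: list[BoutStride] = []
    for iv in wear:
        if not iv.is_wear:
            continue
        for rec in (left, right):
            i0 = int(round((iv.start - rec.start) * rec.fs))
            i1 = int(round((iv.end - rec.start) * rec.fs))
            strides.extend(_strides_one_foot(rec.slice(i0, i1), cfg_iga))
    strides.sort(key=lambda s: s.start)
    if not strides:
        return []

    bouts: list[WalkingBout] = []
    group: list[BoutStride] = [strides[0]]
    running_end = strides[0].end
    for s in strides[1:]:
        if s.start - running_end > cfg.bout_gap_s:
            bouts.append(_finish(group, cfg))
            group = []
        group.append(s)
        running_end = max(running_end, s.end) if group[:-1] else s.end
    bouts.append(_finish(group, cfg))
    log.info("detected %d bouts (%d subthreshold)", len(bouts),
             sum(b.wb_class == "subthreshold" for b in bouts))
    return bouts


def _finish(group: list[BoutStride], cfg: PamConfig) -> WalkingBout:
    start = group[0].start
    end = max(s.end for s in group)
    return WalkingBout(start=start, end=end,
                       wb_class=classify_wb(end - start, cfg), strides=group)
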