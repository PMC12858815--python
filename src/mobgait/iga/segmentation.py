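"""Stride segmentation by zero-velocity (mid-stance) detection.

Candidate stance phases are maximal runs where the smoothed gyroscope norm
and the smoothed deviation of the accelerometer norm from 1 g both stay
below thresholds.  The gap between two stance runs is accepted as a swing
when its duration and motion energy (gyroscope peak, accelerometer peak
deviation) are plausible for a stride; each accepted swing yields one stride
segment bounded by the mid-stance instants of the flanking runs.  Stance
runs much longer than the typical one (quiet standing before/after a walk,
or pauses inside a bout) contribute only half a typical stance to the
adjacent stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..config import IgaConfig
from ..recording import ImuRecording

log = logging.getLogger("mobgait.iga")


@dataclass(frozen=True)
class StrideSegment:
    """Half-open sample range [start, end) of one stride (mid-stance bounds)."""

    start: int
    end: int

    @property
    def n(self) -> int:
        return self.end - self.start


def moving_average(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return x
    kernel = np.full(win, 1.0 / win)
    return np.convolve(x, kernel, mode="same")


def still_mask(imu: ImuRecording, cfg: IgaConfig | None = None) -> np.ndarray:
    """Boolean mask of samples that look like flat-foot stance."""
    cfg = cfg or IgaConfig()
    win = max(1, int(round(cfg.smooth_window_s * imu.fs)))
    acc_dev = moving_average(np.abs(imu.acc_norm() - 1.0), win)
    gyro = moving_average(imu.gyr_norm(), win)
    return (gyro < cfg.still_gyro_dps) & (acc_dev < cfg.still_acc_dev_g)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    ends = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def segment_strides(imu: ImuRecording, cfg: IgaConfig | None = None) -> list[StrideSegment]:
    """Detect stride segments; returns an empty list when nothing walks."""
    cfg = cfg or IgaConfig()
    fs = imu.fs
    if imu.duration < 1.0:
        return []
    mask = still_mask(imu, cfg)
    min_still = max(1, int(round(cfg.min_still_s * fs)))
    runs = [r for r in _runs(mask) if r[1] - r[0] >= min_still]
    if len(runs) < 2:
        return []

    acc_dev = np.abs(imu.acc_norm() - 1.0)
    win = max(1, int(round(cfg.smooth_window_s * fs)))
    gyro_s = moving_average(imu.gyr_norm(), win)

    # validate the gaps between consecutive stance runs as swings
    valid_gap = []
    for (s0, e0), (s1, e1) in zip(runs, runs[1:]):
        dur = (s1 - e0) / fs
        ok = (
            cfg.swing_min_s <= dur <= cfg.swing_max_s
            and e0 < s1
            and gyro_s[e0:s1].max() >= cfg.swing_min_gyro_dps
            and acc_dev[e0:s1].max() >= cfg.swing_min_acc_dev_g
        )
        valid_gap.append(ok)
    if not any(valid_gap):
        return []

    lengths = np.array([e - s for s, e in runs], dtype=float)
    interior = [
        i
        for i in range(1, len(runs) - 1)
        if valid_gap[i - 1] and valid_gap[i]
    ]
    if interior:
        typical = float(np.median(lengths[interior]))
    else:
        adjacent = [i for i in range(len(runs))
                    if (i > 0 and valid_gap[i - 1]) or (i < len(runs) - 1 and valid_gap[i])]
        typical = float(np.min(lengths[adjacent]))

    def midstance(i: int, side: str) -> int:
        s, e = runs[i]
        if e - s > cfg.long_still_factor * typical:
            # standing or pause: only half a typical stance belongs to the stride
            return int(round(e - typical / 2.0)) if side == "left" else int(round(s + typical / 2.0))
        return int(round((s + e) / 2.0))

    segments = []
    for j, ok in enumerate(valid_gap):
        if not ok:
            continue
        b0 = midstance(j, "left")
        b1 = midstance(j + 1, "right")
        if b1 > b0:
            segments.append(StrideSegment(start=b0, end=b1))
    return segments
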