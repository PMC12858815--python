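"""Non-wear detection and wear-time rules for home monitoring.

A maximal span is non-wear iff the accelerometer norm stays within 0.05 g of
1 g AND the gyroscope norm stays below 2 deg/s throughout AND the span lasts
more than 90 min (triple threshold).  A day is valid with 8-12 h of wear
(bounds inclusive) and a subject is analysed only with at least 3 valid
days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..config import PamConfig
from ..recording import ImuRecording


@dataclass(frozen=True)
class WearInterval:
    """A wear or non-wear span, in absolute seconds; intervals partition the
    recording."""

    start: float
    end: float
    is_wear: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_nonwear(imu: ImuRecording, cfg: PamConfig | None = None) -> list[WearInterval]:
    """Partition the recording into wear / non-wear intervals."""
    cfg = cfg or PamConfig()
    below = (np.abs(imu.acc_norm() - 1.0) < cfg.nonwear_acc_dev_g) & (
        imu.gyr_norm() < cfg.nonwear_gyro_dps
    )
    n = below.size
    t0 = imu.start
    fs = imu.fs
    min_samples = cfg.nonwear_min_minutes * 60.0 * fs

    # maximal runs of below-threshold samples longer than the window
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = list(edges[~below[edges]] + 1)
    ends = list(edges[below[edges]] + 1)
    if below.size and below[0]:
        starts.insert(0, 0)
    if below.size and below[-1]:
        ends.append(n)

    intervals: list[WearInterval] = []
    cursor = 0
    for s, e in zip(starts, ends):
        if e - s > min_samples:
            if s > cursor:
                intervals.append(WearInterval(t0 + cursor / fs, t0 + s / fs, True))
            intervals.append(WearInterval(t0 + s / fs, t0 + e / fs, False))
            cursor = e
    if cursor < n:
        intervals.append(WearInterval(t0 + cursor / fs, t0 + n / fs, True))
    return intervals


def wear_seconds(intervals: list[WearInterval]) -> float:
    return sum(iv.duration for iv in intervals if iv.is_wear)


def select_valid_days(
    daily_wear_hours, cfg: PamConfig | None = None
) -> tuple[list[int], bool]:
    """Apply the valid-day and subject-inclusion rules.

    Returns (indices of valid days, subject included?).
    """
    cfg = cfg or PamConfig()
    valid = [
        i
        for i, h in enumerate(daily_wear_hours)
        if cfg.valid_day_min_hours <= h <= cfg.valid_day_max_hours
    ]
    return valid, len(valid) >= cfg.min_valid_days
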