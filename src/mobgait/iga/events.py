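"""Gait-event detection from the sagittal angular-velocity profile.

Within a mid-stance-to-mid-stance segment the dominant gyroscope axis shows
the classic foot signature: a negative (plantarflexion) peak at toe-off, a
broad positive peak at mid-swing, and a second negative peak at heel strike.
Toe-off is taken as the most negative sample before the swing maximum and
heel strike as the most negative sample after it.  Segments without a clear
swing maximum (or without negative peaks on both sides) are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..config import IgaConfig
from ..recording import ImuRecording
from .segmentation import StrideSegment, moving_average

log = logging.getLogger("mobgait.iga")


@dataclass(frozen=True)
class StrideEvents:
    """Gait events of one stride, as 0-based sample indices into the
    recording; the segment convention is stance -> swing -> stance, so
    ``midstance_start < toe_off < heel_strike < midstance_end``."""

    midstance_start: int
    toe_off: int
    heel_strike: int
    midstance_end: int

    def __post_init__(self) -> None:
        if not (self.midstance_start < self.toe_off < self.heel_strike < self.midstance_end):
            raise ValueError("gait events out of order")


def detect_gait_events(
    imu: ImuRecording, segment: StrideSegment, cfg: IgaConfig | None = None
) -> StrideEvents | None:
    """Locate toe-off and heel strike inside ``segment``; None = rejected."""
    cfg = cfg or IgaConfig()
    g = imu.gyr[segment.start:segment.end]
    n = g.shape[0]
    if n < 5:
        return None
    win = max(1, int(round(0.05 * imu.fs)))
    lo, hi = int(0.425 * n), max(int(0.575 * n), int(0.425 * n) + 1)

    # sagittal axis: the most energetic gyroscope axis showing the swing
    # signature (negative peaks flanking the swing maximum); during turning
    # the yaw axis can carry more energy but lacks the signature, so fall
    # back across axes in decreasing-variance order.  The sign making the
    # swing maximum positive is guessed from the mid-segment extreme and the
    # opposite orientation is tried when the guess fails validation.
    for axis in np.argsort(np.var(g, axis=0))[::-1]:
        v = g[:, int(axis)]
        vs = moving_average(v, win)
        centre = vs[lo:hi]
        guess = 1.0 if centre[np.argmax(np.abs(centre))] >= 0 else -1.0
        for sign in (guess, -guess):
            sv, svs = sign * v, sign * vs
            swing = int(np.argmax(svs))
            if svs[swing] < cfg.event_swing_min_dps or swing <= 0 or swing >= n - 1:
                continue
            to = int(np.argmin(sv[:swing]))
            hs = swing + 1 + int(np.argmin(sv[swing + 1:]))
            if (sv[to] > -cfg.event_neg_min_dps or sv[hs] > -cfg.event_neg_min_dps
                    or to == 0 or hs >= n - 1):
                continue
            return StrideEvents(
                midstance_start=segment.start,
                toe_off=segment.start + to,
                heel_strike=segment.start + hs,
                midstance_end=segment.end,
            )
    log.debug("segment [%d, %d) rejected: no axis with a swing signature",
              segment.start, segment.end)
    return None
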