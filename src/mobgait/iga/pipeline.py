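"""Full instrumented-gait-analysis pipeline for a supervised walk test.

segment -> events -> trajectory -> per-stride parameters -> turn filter ->
aggregates (mean, CV, asymmetry) for the five spatiotemporal features:
gait velocity, stride length, stride time, stance percentage and maximum
sensor lift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import IgaConfig
from ..recording import ImuRecording
from .aggregate import aggregate_mean_cv, asymmetry_index, pair_consecutive
from .events import StrideEvents, detect_gait_events
from .reconstruct import TrajectoryEstimate, reconstruct_trajectory
from .segmentation import StrideSegment, segment_strides

log = logging.getLogger("mobgait.iga")

#: the five spatiotemporal gait parameters, in reporting order
PARAMS = (
    "gait_velocity",
    "stride_length",
    "stride_time",
    "stance_percentage",
    "max_sensor_lift",
)


@dataclass
class StrideRecord:
    """One detected stride with its five spatiotemporal parameters."""

    foot: str
    events: StrideEvents
    start_s: float
    gait_velocity: float
    stride_length: float
    stride_time: float
    stance_percentage: float
    max_sensor_lift: float
    heading_change_deg: float = 0.0
    is_turn: bool = False

    def as_row(self) -> dict:
        return {
            "foot": self.foot,
            "start_s": self.start_s,
            "gait_velocity": self.gait_velocity,
            "stride_length": self.stride_length,
            "stride_time": self.stride_time,
            "stance_percentage": self.stance_percentage,
            "max_sensor_lift": self.max_sensor_lift,
            "heading_change_deg": self.heading_change_deg,
            "is_turn": self.is_turn,
        }


def compute_stride_params(
    imu: ImuRecording,
    segment: StrideSegment,
    events: StrideEvents,
    trajectory: TrajectoryEstimate,
) -> StrideRecord | None:
    """Combine events and trajectory into a stride record.

    Stride time spans mid-stance to mid-stance; swing is toe-off to heel
    strike, and stance time is stride time minus swing time (robust to the
    segment's phase convention).  Gait velocity is stride length over stride
    time by definition.
    """
    fs = imu.fs
    stride_time = (events.midstance_end - events.midstance_start) / fs
    swing_time = (events.heel_strike - events.toe_off) / fs
    stance_time = stride_time - swing_time
    stance_pct = stance_time / stride_time * 100.0
    if not 0.0 < stance_pct < 100.0:
        log.debug("stride at sample %d rejected: stance %.1f%% out of range",
                  segment.start, stance_pct)
        return None
    return StrideRecord(
        foot=imu.foot,
        events=events,
        start_s=imu.start + segment.start / fs,
        gait_velocity=trajectory.stride_length / stride_time,
        stride_length=trajectory.stride_length,
        stride_time=stride_time,
        stance_percentage=stance_pct,
        max_sensor_lift=trajectory.max_lift,
        heading_change_deg=trajectory.heading_change_deg,
    )


def flag_turn_strides(
    strides: list[StrideRecord], threshold_deg: float = 45.0
) -> list[StrideRecord]:
    """Flag strides whose heading change exceeds ``threshold_deg`` (in place)."""
    for s in strides:
        s.is_turn = abs(s.heading_change_deg) > threshold_deg
    return strides


def extract_strides(imu: ImuRecording, cfg: IgaConfig | None = None) -> list[StrideRecord]:
    """Run segmentation, event detection and reconstruction on one foot."""
    cfg = cfg or IgaConfig()
    records = []
    segments = segment_strides(imu, cfg)
    for seg in segments:
        events = detect_gait_events(imu, seg, cfg)
        if events is None:
            continue
        traj = reconstruct_trajectory(imu, seg, cfg)
        if traj is None:
            log.debug("segment [%d, %d) rejected: integration diverged",
                      seg.start, seg.end)
            continue
        rec = compute_stride_params(imu, seg, events, traj)
        if rec is not None:
            records.append(rec)
    log.info("%s foot: %d segments, %d valid strides", imu.foot, len(segments), len(records))
    return records


@dataclass
class GaitTestResult:
    """Stride table and aggregate statistics of one supervised gait test."""

    strides: pd.DataFrame
    aggregates: pd.DataFrame  # index: parameter; columns: mean, cv, asymmetry_pct
    n_left: int
    n_right: int
    insufficient: bool
    notes: list[str] = field(default_factory=list)

    def aggregate(self, param: str, stat: str) -> float:
        return float(self.aggregates.loc[param, stat])


def _empty_aggregates() -> pd.DataFrame:
    return pd.DataFrame(
        np.nan, index=list(PARAMS), columns=["mean", "cv", "asymmetry_pct"]
    )


def run_iga(
    left: ImuRecording,
    right: ImuRecording,
    cfg: IgaConfig | None = None,
) -> GaitTestResult:
    """Analyse a supervised gait test recorded on both feet."""
    cfg = cfg or IgaConfig()
    if left.fs != right.fs:
        raise ValueError("left and right recordings must share a sampling rate")
    strides = extract_strides(left, cfg) + extract_strides(right, cfg)
    strides.sort(key=lambda s: s.start_s)
    flag_turn_strides(strides, cfg.turn_threshold_deg)
    valid = [s for s in strides if not (cfg.exclude_turns and s.is_turn)]

    notes = []
    insufficient = len(valid) < cfg.min_valid_strides
    if insufficient:
        notes.append(
            f"insufficient strides: {len(valid)} valid < {cfg.min_valid_strides} required"
        )
        log.warning(notes[-1])

    columns = ["foot", "start_s", *PARAMS, "heading_change_deg", "is_turn"]
    table = pd.DataFrame([s.as_row() for s in strides], columns=columns)
    aggregates = _empty_aggregates()
    if not insufficient:
        feet = [s.foot for s in valid]
        starts = [s.start_s for s in valid]
        pairs = pair_consecutive(feet, starts)
        for param in PARAMS:
            vals = np.array([getattr(s, param) for s in valid])
            mean, cv = aggregate_mean_cv(vals)
            asym = np.nan
            if pairs:
                lv = np.array([getattr(valid[i], param) for i, _ in pairs])
                rv = np.array([getattr(valid[j], param) for _, j in pairs])
                asym = asymmetry_index(lv, rv)
            aggregates.loc[param] = [mean, cv, asym]

    return GaitTestResult(
        strides=table,
        aggregates=aggregates,
        n_left=sum(s.foot == "left" for s in valid),
        n_right=sum(s.foot == "right" for s in valid),
        insufficient=insufficient,
        notes=notes,
    )
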