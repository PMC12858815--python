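"""Ground-truth containers produced alongside every synthetic signal."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StrideTruth:
    """True timing and parameters of one generated stride (times in s)."""

    foot: str
    start: float
    toe_off: float
    heel_strike: float
    end: float
    gait_velocity: float
    stride_length: float
    stride_time: float
    stance_percentage: float
    max_sensor_lift: float
    heading: float
    turn_angle: float
    is_turn: bool


def strides_frame(strides: list[StrideTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in strides])


@dataclass
class GaitTestTruth:
    """Ground truth for a supervised gait test (both feet)."""

    fs: float
    strides: list[StrideTruth]

    def frame(self, include_turns: bool = True) -> pd.DataFrame:
        df = strides_frame(self.strides).sort_values("start", ignore_index=True)
        if not include_turns:
            df = df[~df.is_turn].reset_index(drop=True)
        return df

    def count(self, foot: str | None = None, turns: bool | None = None) -> int:
        n = 0
        for s in self.strides:
            if foot is not None and s.foot != foot:
                continue
            if turns is not None and s.is_turn != turns:
                continue
            n += 1
        return n


@dataclass
class BoutTruth:
    """One scheduled daily-life walking bout (after the 3-s merge rule)."""

    start: float
    end: float
    wb_class: str
    n_strides_left: int
    n_strides_right: int
    cadence: float
    gait_velocity: float
    stride_length: float
    step_times: np.ndarray

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def steps(self) -> int:
        return int(self.step_times.size)


@dataclass
class EpisodeTruth:
    """One wear-time activity episode for the mobility-state taxonomy."""

    kind: str  # "walking" | "active" | "rest"
    start: float
    duration: float
    value: float  # cadence (walking) or acc-norm SD (active); 0 for rest


@dataclass
class DayTruth:
    """Ground truth for one recorded day."""

    day_index: int
    span: tuple[float, float]  # recording start/end, s since midnight
    wear_intervals: list[tuple[float, float, bool]]  # (start, end, is_wear)
    bouts: list[BoutTruth] = field(default_factory=list)
    episodes: list[EpisodeTruth] = field(default_factory=list)
    scheduled_wear_s: float = 0.0
    step_count: int = 0

    @property
    def wear_hours(self) -> float:
        return self.scheduled_wear_s / 3600.0

    def bout_counts(self) -> dict[str, int]:
        counts = {"subthreshold": 0, "short": 0, "medium": 0, "long": 0}
        for b in self.bouts:
            counts[b.wb_class] += 1
        return counts


@dataclass
class WeekTruth:
    days: list[DayTruth]

    @property
    def wear_hours(self) -> list[float]:
        return [d.wear_hours for d in self.days]

    @property
    def step_counts(self) -> list[int]:
        return [d.step_count for d in self.days]
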