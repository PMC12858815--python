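"""Multi-day home-monitoring simulation with full ground truth.

Day signals are rendered lazily: :func:`generate_week_recording` first draws
a deterministic *day plan* (concrete stride templates for every scheduled
walking bout) from which the ground truth is computed eagerly, and
:meth:`WeekRecording.day` renders the corresponding signals on demand.  A
full week of two-foot signals would otherwise not fit in memory at the
native sampling rate.

Signal model per episode kind (accelerometer in g, gyroscope in deg/s):

* ``nonwear``  - device off body: tightly clipped noise guaranteed inside the
  non-wear triple threshold (|acc norm - 1| < 0.05 g, gyro norm < 2 deg/s).
* ``sedentary`` - worn but resting: quiet accelerometer (sd 0.004 g, below
  the 0.01 g active-minute criterion) with small gyroscope micro-movements
  (sd 3 deg/s) so no 90-min span ever satisfies the non-wear threshold.
* ``active``   - non-locomotion activity: accelerometer wiggle at the
  episode's intensity (sd 0.015/0.06/0.15 g) plus moderate gyroscope noise.
* ``walking``  - stride trains from the kinematic model plus sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..recording import ImuRecording
from .gait_test import render_stride_train
from .model import StrideTemplate
from .phenotypes import PhenotypeParams, phenotype_presets
from .schedule import ACTIVE_INTENSITY_SD, ActivitySchedule, Episode, schedule_for_group
from .truth import BoutTruth, DayTruth, EpisodeTruth, StrideTruth, WeekTruth

#: walking-bout duration class bins (shared with the monitoring rules):
#: subthreshold < 10 s, short [10, 30], medium (30, 60], long > 60 s
def _wb_class(duration: float) -> str:
    if duration < 10.0:
        return "subthreshold"
    if duration <= 30.0:
        return "short"
    if duration <= 60.0:
        return "medium"
    return "long"


@dataclass
class BoutPlan:
    start: float
    templates: dict[str, list[StrideTemplate]]  # per foot
    cadence: float
    right_offset: float


@dataclass
class DayPlan:
    schedule: ActivitySchedule
    bouts: list[BoutPlan] = field(default_factory=list)


def _plan_bout(
    episode: Episode, phenotype: PhenotypeParams, rng: np.random.Generator
) -> BoutPlan:
    cls = _wb_class(episode.duration)
    spec = phenotype.daily[cls if cls != "subthreshold" else "short"]
    cadence = episode.cadence
    if cadence is None:
        cadence = float(np.clip(rng.normal(spec.cadence, spec.cadence_sd), 70.0, 130.0))
    stride_time = 120.0 / cadence
    n = max(1, round(episode.duration * cadence / 120.0))
    v_bout = max(rng.normal(spec.gait_velocity, spec.velocity_cv * spec.gait_velocity), 0.15)
    stance = phenotype.iga["stance_percentage"].center
    lift = phenotype.iga["max_sensor_lift"].center
    heading = float(rng.uniform(0.0, 360.0))
    scales = phenotype.iga["gait_velocity"].side_scales
    templates: dict[str, list[StrideTemplate]] = {}
    for side, foot in enumerate(("left", "right")):
        v = np.maximum(rng.normal(v_bout, 0.05 * v_bout, n), 0.1) * scales[side]
        templates[foot] = [
            StrideTemplate(
                stride_length=float(vi) * stride_time,
                stride_time=stride_time,
                stance_percentage=stance,
                max_lift=lift,
                heading=heading,
            )
            for vi in v
        ]
    return BoutPlan(start=episode.start, templates=templates,
                    cadence=cadence, right_offset=stride_time / 2.0)


def _bout_truth(plan: BoutPlan) -> tuple[float, float, list[StrideTruth], np.ndarray]:
    """Exact stride timing of a planned bout (no rendering needed)."""
    strides: list[StrideTruth] = []
    step_times = []
    end = plan.start
    for foot, offset in (("left", 0.0), ("right", plan.right_offset)):
        cursor = plan.start + offset
        for tpl in plan.templates[foot]:
            half = tpl.stance_time / 2.0
            strides.append(StrideTruth(
                foot=foot, start=cursor, toe_off=cursor + half,
                heel_strike=cursor + half + tpl.swing_time, end=cursor + tpl.stride_time,
                gait_velocity=tpl.gait_velocity, stride_length=tpl.stride_length,
                stride_time=tpl.stride_time, stance_percentage=tpl.stance_percentage,
                max_sensor_lift=tpl.max_lift, heading=tpl.heading,
                turn_angle=0.0, is_turn=False,
            ))
            step_times.append(cursor + half + tpl.swing_time)
            cursor += tpl.stride_time
        end = max(end, cursor)
    return plan.start, end, strides, np.sort(np.asarray(step_times))


def plan_day(
    schedule: ActivitySchedule,
    phenotype: PhenotypeParams,
    rng: np.random.Generator,
    day_index: int = 0,
    bout_gap_s: float = 3.0,
) -> tuple[DayPlan, DayTruth]:
    plan = DayPlan(schedule=schedule)
    raw: list[tuple[float, float, list[StrideTruth], np.ndarray, float]] = []
    episodes: list[EpisodeTruth] = []
    for ep in schedule.episodes:
        if ep.kind == "walking":
            bp = _plan_bout(ep, phenotype, rng)
            plan.bouts.append(bp)
            b0, b1, strides, steps = _bout_truth(bp)
            raw.append((b0, b1, strides, steps, bp.cadence))
            episodes.append(EpisodeTruth("walking", b0, b1 - b0, bp.cadence))
        elif ep.kind == "active":
            episodes.append(EpisodeTruth("active", ep.start, ep.duration,
                                         ACTIVE_INTENSITY_SD[ep.intensity]))
        elif ep.kind == "sedentary":
            episodes.append(EpisodeTruth("rest", ep.start, ep.duration, 0.0))
        # nonwear episodes carry no wear-time state

    # merge scheduled bouts separated by gaps <= bout_gap_s (same rule the
    # detector applies), then classify by realized duration
    groups: list[list] = []
    for rec in sorted(raw, key=lambda r: r[0]):
        if groups and rec[0] - max(r[1] for r in groups[-1]) <= bout_gap_s:
            groups[-1].append(rec)
        else:
            groups.append([rec])
    bouts: list[BoutTruth] = []
    for grp in groups:
        strides = sorted((s for r in grp for s in r[2]), key=lambda s: s.start)
        steps = np.sort(np.concatenate([r[3] for r in grp]))
        bouts.append(_make_bout_truth(grp[0][0], max(r[1] for r in grp), strides, steps))

    s0, s1 = schedule.span
    wear: list[tuple[float, float, bool]] = []
    cursor = s0
    for ep in schedule.episodes:
        if ep.kind == "nonwear":
            if ep.start > cursor:
                wear.append((cursor, ep.start, True))
            wear.append((ep.start, ep.end, False))
            cursor = ep.end
    if s1 > cursor:
        wear.append((cursor, s1, True))

    truth = DayTruth(
        day_index=day_index,
        span=(s0, s1),
        wear_intervals=wear,
        bouts=bouts,
        episodes=episodes,
        scheduled_wear_s=schedule.wear_seconds,
        step_count=sum(b.steps for b in bouts),
    )
    return plan, truth


def _make_bout_truth(start, end, strides, step_times) -> BoutTruth:
    v = float(np.median([s.gait_velocity for s in strides]))
    length = float(np.median([s.stride_length for s in strides]))
    dur = end - start
    return BoutTruth(
        start=start, end=end, wb_class=_wb_class(dur),
        n_strides_left=sum(s.foot == "left" for s in strides),
        n_strides_right=sum(s.foot == "right" for s in strides),
        cadence=step_times.size / dur * 60.0,
        gait_velocity=v, stride_length=length, step_times=step_times,
    )


def render_day(
    plan: DayPlan,
    fs: float,
    seed,
    noise_sd: tuple[float, float] = (0.02, 0.5),
) -> tuple[ImuRecording, ImuRecording]:
    """Render both feet's signals for one planned day (deterministic)."""
    s0, s1 = plan.schedule.span
    n = int(round((s1 - s0) * fs))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seqs = ss.spawn(2)
    out = []
    for foot, child, offset_key in (("left", seqs[0], 0.0), ("right", seqs[1], None)):
        rng = np.random.default_rng(child)
        acc = np.empty((n, 3))
        gyr = np.empty((n, 3))
        for ep in plan.schedule.episodes:
            k0 = max(0, int(round((ep.start - s0) * fs)))
            k1 = min(n, int(round((ep.end - s0) * fs)))
            m = k1 - k0
            if m <= 0:
                continue
            if ep.kind == "nonwear":
                acc[k0:k1] = np.clip(rng.normal(0.0, 0.008, (m, 3)), -0.025, 0.025)
                acc[k0:k1, 2] += 1.0
                gyr[k0:k1] = np.clip(rng.normal(0.0, 0.3, (m, 3)), -1.0, 1.0)
            elif ep.kind == "sedentary":
                acc[k0:k1] = rng.normal(0.0, 0.004, (m, 3))
                acc[k0:k1, 2] += 1.0
                gyr[k0:k1] = rng.normal(0.0, 3.0, (m, 3))
            elif ep.kind == "active":
                sd = ACTIVE_INTENSITY_SD[ep.intensity]
                acc[k0:k1] = rng.normal(0.0, sd, (m, 3))
                acc[k0:k1, 2] += 1.0
                gyr[k0:k1] = rng.normal(0.0, 20.0, (m, 3))
            else:  # walking: flat-foot baseline, strides overwrite, noise on top
                acc[k0:k1] = 0.0
                acc[k0:k1, 2] = 1.0
                gyr[k0:k1] = 0.0
        for bp in plan.bouts:
            offset = 0.0 if foot == "left" else bp.right_offset
            render_stride_train(bp.templates[foot], fs, bp.start - s0 + offset,
                                acc, gyr, foot)
        # sensor noise over walking spans only (other kinds already include
        # their own noise model)
        sd_a, sd_g = noise_sd
        for ep in plan.schedule.episodes:
            if ep.kind != "walking" or not (sd_a or sd_g):
                continue
            k0 = max(0, int(round((ep.start - s0) * fs)))
            k1 = min(n, int(round((ep.end + 2.0 - s0) * fs)))
            m = k1 - k0
            if m > 0:
                acc[k0:k1] += rng.normal(0.0, sd_a, (m, 3))
                gyr[k0:k1] += rng.normal(0.0, sd_g, (m, 3))
        out.append(ImuRecording(acc=acc, gyr=gyr, fs=fs, foot=foot, start=s0))
    return out[0], out[1]


@dataclass
class WeekRecording:
    """Handle to a simulated monitoring week: eager truth, lazy signals."""

    fs: float
    noise_sd: tuple[float, float]
    plans: list[DayPlan]
    truth: WeekTruth
    day_seeds: list
    subject: str | None = None

    @property
    def n_days(self) -> int:
        return len(self.plans)

    def day(self, i: int) -> tuple[ImuRecording, ImuRecording]:
        left, right = render_day(self.plans[i], self.fs, self.day_seeds[i], self.noise_sd)
        left.subject = right.subject = self.subject
        return left, right

    def days(self):
        for i in range(self.n_days):
            yield self.day(i)


def generate_week_recording(
    schedules: list[ActivitySchedule],
    phenotype: PhenotypeParams,
    seed: int | None = None,
    fs: float = 102.4,
    noise_sd: tuple[float, float] = (0.02, 0.5),
    bout_gap_s: float = 3.0,
    subject: str | None = None,
) -> WeekRecording:
    """Plan and (lazily) render a multi-day recording from daily schedules."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    plan_seed, *day_children = ss.spawn(len(schedules) + 1)
    # plain integers so repeated rendering of the same day is bit-identical
    day_seeds = [int(c.generate_state(1)[0]) for c in day_children]
    rng = np.random.default_rng(plan_seed)
    plans, days = [], []
    for i, sched in enumerate(schedules):
        plan, truth = plan_day(sched, phenotype, rng, day_index=i, bout_gap_s=bout_gap_s)
        plans.append(plan)
        days.append(truth)
    return WeekRecording(
        fs=fs, noise_sd=noise_sd, plans=plans, truth=WeekTruth(days=days),
        day_seeds=day_seeds, subject=subject,
    )


def generate_week_for_group(
    group: str,
    seed: int | None = None,
    n_days: int = 7,
    fs: float = 102.4,
    noise_sd: tuple[float, float] = (0.02, 0.5),
    subject: str | None = None,
    **schedule_kwargs,
) -> WeekRecording:
    """Convenience wrapper: preset schedules + week generation in one call."""
    ph = phenotype_presets(group)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_seed, week_seed = ss.spawn(2)
    rng = np.random.default_rng(sched_seed)
    schedules = [schedule_for_group(ph, rng, **schedule_kwargs) for _ in range(n_days)]
    return generate_week_recording(
        schedules, ph, seed=week_seed, fs=fs, noise_sd=noise_sd, subject=subject
    )
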