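"""Daily activity schedules: the scripted structure behind a simulated day.

A schedule is an ordered, non-overlapping list of episodes (walking,
non-locomotion activity, sedentary wear, or non-wear) covering a contiguous
recording span within one 24-hour day.  Builders compose days whose
walking-bout counts, cadences and daily step volumes follow the group
presets, plus randomized days for exercising the wear-time rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phenotypes import PhenotypeParams, phenotype_presets

EPISODE_KINDS = ("walking", "active", "sedentary", "nonwear")

#: acc-norm SD (g) emulated for each non-locomotion activity intensity
ACTIVE_INTENSITY_SD = {"low": 0.015, "medium": 0.06, "high": 0.15}


@dataclass(frozen=True)
class Episode:
    kind: str
    start: float  # seconds since midnight
    duration: float  # seconds
    cadence: float | None = None  # steps/min, walking only
    intensity: str | None = None  # low|medium|high, active only

    def __post_init__(self) -> None:
        if self.kind not in EPISODE_KINDS:
            raise ValueError(f"unknown episode kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("episode duration must be positive")
        if self.kind == "active" and self.intensity not in ACTIVE_INTENSITY_SD:
            raise ValueError("active episodes need intensity low|medium|high")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class ActivitySchedule:
    """One day's episode list; validated to be sorted and non-overlapping."""

    episodes: list[Episode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.episodes:
            raise ValueError("schedule needs at least one episode")
        for a, b in zip(self.episodes, self.episodes[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError("episodes overlap or are unsorted")
        if self.episodes[0].start < 0 or self.episodes[-1].end > 86400.0:
            raise ValueError("schedule must fit within a 24 h day")

    @property
    def span(self) -> tuple[float, float]:
        return self.episodes[0].start, self.episodes[-1].end

    @property
    def duration(self) -> float:
        s, e = self.span
        return e - s

    @property
    def wear_seconds(self) -> float:
        return sum(e.duration for e in self.episodes if e.kind != "nonwear")

    @property
    def nonwear_episodes(self) -> list[Episode]:
        return [e for e in self.episodes if e.kind == "nonwear"]

    @property
    def walking_episodes(self) -> list[Episode]:
        return [e for e in self.episodes if e.kind == "walking"]


def _compose(
    items: list[Episode],
    rng: np.random.Generator,
    day_start: float,
    total_span: float,
    min_gap: float = 10.0,
) -> ActivitySchedule:
    """Place ``items`` (durations only matter) into a contiguous span starting
    at ``day_start``, separated by sedentary gaps of at least ``min_gap`` s."""
    items = list(items)
    rng.shuffle(items)
    busy = sum(e.duration for e in items)
    n_gaps = len(items) + 1
    free = total_span - busy
    if free < min_gap * n_gaps:
        raise ValueError("schedule items do not fit into the requested span")
    extra = rng.dirichlet(np.ones(n_gaps)) * (free - min_gap * n_gaps)
    gaps = min_gap + extra

    episodes: list[Episode] = []
    cursor = day_start
    for gap, item in zip(gaps, items + [None]):
        episodes.append(Episode("sedentary", cursor, gap))
        cursor += gap
        if item is not None:
            episodes.append(Episode(item.kind, cursor, item.duration,
                                    cadence=item.cadence, intensity=item.intensity))
            cursor += item.duration
    return ActivitySchedule(episodes)


def schedule_for_group(
    group: str | PhenotypeParams,
    rng: np.random.Generator,
    day_start: float = 7 * 3600.0,
    wear_hours: float | None = None,
    bout_counts: dict[str, int] | None = None,
    target_steps: float | None = None,
    n_active_episodes: int | None = None,
    nonwear_minutes: float | None = None,
) -> ActivitySchedule:
    """Build one day following a group preset.

    Walking-bout counts per duration class default to the preset medians
    (bouts per day); subthreshold (<10 s) ambulation is appended until the
    scheduled step total reaches the preset's daily step count.  Passing a
    scaled-down ``bout_counts``/``target_steps`` shrinks the day
    proportionally for cheap simulations.
    """
    ph = phenotype_presets(group) if isinstance(group, str) else group
    if bout_counts is None:
        bout_counts = {c: int(round(ph.daily[c].wb_per_day)) for c in ("short", "medium", "long")}
    if target_steps is None:
        scale = bout_counts.get("short", 0) / max(ph.daily["short"].wb_per_day, 1.0)
        target_steps = ph.macro["step_count"].center * min(scale, 1.0)
    duration_ranges = {
        "short": (12.0, 28.0),
        "medium": (33.0, 58.0),
        "long": (65.0, max(2.0 * (ph.daily["long"].duration_s or 95.0) - 65.0, 80.0)),
    }

    items: list[Episode] = []
    steps = 0.0
    for cls, count in bout_counts.items():
        lo, hi = duration_ranges[cls]
        spec = ph.daily[cls]
        for _ in range(count):
            dur = rng.uniform(lo, hi)
            cad = float(np.clip(rng.normal(spec.cadence, spec.cadence_sd), 70.0, 130.0))
            items.append(Episode("walking", 0.0, dur, cadence=cad))
            steps += 2 * max(1, round(dur * cad / 120.0))
    # fill the remaining daily volume with brief (<10 s) ambulation
    spec = ph.daily["short"]
    while steps < target_steps:
        dur = rng.uniform(4.0, 9.0)
        cad = float(np.clip(rng.normal(spec.cadence, spec.cadence_sd), 70.0, 130.0))
        items.append(Episode("walking", 0.0, dur, cadence=cad))
        steps += 2 * max(1, round(dur * cad / 120.0))

    if n_active_episodes is None:
        n_active_episodes = int(rng.integers(1, 4))
    for _ in range(n_active_episodes):
        items.append(Episode("active", 0.0, rng.uniform(120.0, 1200.0),
                             intensity=str(rng.choice(list(ACTIVE_INTENSITY_SD)))))
    if nonwear_minutes is None and rng.random() < 0.3:
        nonwear_minutes = float(rng.uniform(20.0, 140.0))
    if nonwear_minutes:
        items.append(Episode("nonwear", 0.0, nonwear_minutes * 60.0))

    wear = (wear_hours if wear_hours is not None else rng.uniform(9.0, 11.0)) * 3600.0
    nonwear_s = sum(e.duration for e in items if e.kind == "nonwear")
    return _compose(items, rng, day_start, wear + nonwear_s)


def random_wear_schedule(
    rng: np.random.Generator,
    day_start: float = 7 * 3600.0,
    wear_hours: float | None = None,
    still_minutes: list[float] | None = None,
) -> ActivitySchedule:
    """A randomized sedentary day with off-body still blocks of mixed length
    (some above, some below the 90-min non-wear window), for exercising the
    non-wear and valid-day rules without rendering gait."""
    if wear_hours is None:
        wear_hours = float(rng.uniform(6.0, 12.5))
    if still_minutes is None:
        still_minutes = [float(rng.uniform(30.0, 150.0)) for _ in range(int(rng.integers(1, 4)))]
    items = [Episode("nonwear", 0.0, m * 60.0) for m in still_minutes]
    n_act = int(rng.integers(0, 3))
    for _ in range(n_act):
        items.append(Episode("active", 0.0, rng.uniform(120.0, 600.0),
                             intensity=str(rng.choice(list(ACTIVE_INTENSITY_SD)))))
    total = wear_hours * 3600.0 + sum(m * 60.0 for m in still_minutes)
    day_start = min(day_start, max(86400.0 - total - 60.0, 0.0))
    return _compose(items, rng, day_start, total, min_gap=60.0)
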