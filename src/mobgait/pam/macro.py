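"""Daily macro physical-activity parameters and their subject aggregation.

Step counts include all detected initial contacts of both feet (also during
subthreshold ambulation).  Minute epochs over wear time are labelled MVPA
when their step count reaches 90 steps/min, active when they contain at
least one stride or their accelerometer-norm SD exceeds 0.01 g, else
sedentary.  Per-subject descriptors are the median over valid days (average
performance) and, for the long-bout count, also the maximum over days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..config import PamConfig
from ..recording import ImuRecording
from .bouts import WalkingBout
from .nonwear import WearInterval

log = logging.getLogger("mobgait.pam")


@dataclass
class DailyMacro:
    day_index: int
    wear_hours: float
    wb_short: int
    wb_medium: int
    wb_long: int
    long_wb_duration_median_s: float
    step_count: int
    active_minutes: int
    sedentary_minutes: int
    active_sedentary_ratio: float
    mvpa_minutes: int

    def as_row(self) -> dict:
        return dict(vars(self))


def _minute_stat(rec: ImuRecording, minutes: np.ndarray) -> np.ndarray:
    """Accelerometer-norm SD per minute epoch (indices into ``minutes``)."""
    norm = rec.acc_norm()
    idx = np.searchsorted(minutes, rec.t, side="right") - 1
    ok = (idx >= 0) & (idx < minutes.size)
    sums = np.bincount(idx[ok], weights=norm[ok], minlength=minutes.size)
    sq = np.bincount(idx[ok], weights=norm[ok] ** 2, minlength=minutes.size)
    counts = np.bincount(idx[ok], minlength=minutes.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = np.maximum(sq / counts - mean**2, 0.0)
    sd = np.sqrt(var)
    sd[counts == 0] = 0.0
    return sd


def compute_macro_day(
    bouts: list[WalkingBout],
    wear: list[WearInterval],
    left: ImuRecording,
    right: ImuRecording,
    cfg: PamConfig | None = None,
    day_index: int = 0,
) -> DailyMacro:
    """Macro parameters for one valid day."""
    cfg = cfg or PamConfig()
    t0 = min(iv.start for iv in wear)
    t1 = max(iv.end for iv in wear)
    minutes = np.arange(np.floor(t0 / 60.0) * 60.0, t1, 60.0)
    nm = minutes.size

    wear_s = np.zeros(nm)
    for iv in wear:
        if not iv.is_wear:
            continue
        lo = np.clip(iv.start - minutes, 0.0, 60.0)
        hi = np.clip(iv.end - minutes, 0.0, 60.0)
        wear_s += np.maximum(hi - lo, 0.0)
    wear_min = wear_s >= cfg.minute_min_wear_s

    step_times = (
        np.sort(np.concatenate([b.step_times for b in bouts])) if bouts else np.empty(0)
    )
    steps_per_min = np.histogram(step_times, bins=np.append(minutes, minutes[-1] + 60.0))[0]

    acc_sd = np.maximum(_minute_stat(left, minutes), _minute_stat(right, minutes))
    active = wear_min & ((steps_per_min >= 1) | (acc_sd > cfg.active_acc_sd_g))
    mvpa = wear_min & (steps_per_min >= cfg.mvpa_steps_per_min)
    sedentary = wear_min & ~active

    n_active = int(active.sum())
    n_sed = int(sedentary.sum())
    if n_sed == 0:
        ratio = 0.0 if n_active == 0 else float("inf")
        if n_active:
            log.warning("day %d: no sedentary minutes, active/sedentary ratio infinite",
                        day_index)
    else:
        ratio = n_active / n_sed

    long_durations = [b.duration for b in bouts if b.wb_class == "long"]
    counts = {"short": 0, "medium": 0, "long": 0}
    for b in bouts:
        if b.wb_class in counts:
            counts[b.wb_class] += 1

    return DailyMacro(
        day_index=day_index,
        wear_hours=float(sum(iv.duration for iv in wear if iv.is_wear) / 3600.0),
        wb_short=counts["short"],
        wb_medium=counts["medium"],
        wb_long=counts["long"],
        long_wb_duration_median_s=float(np.median(long_durations)) if long_durations else float("nan"),
        step_count=int(sum(b.steps for b in bouts)),
        active_minutes=n_active,
        sedentary_minutes=n_sed,
        active_sedentary_ratio=float(ratio),
        mvpa_minutes=int(mvpa.sum()),
    )


#: macro fields aggregated by median across days
_MEDIAN_FIELDS = (
    "wb_short", "wb_medium", "wb_long", "long_wb_duration_median_s",
    "step_count", "active_minutes", "sedentary_minutes",
    "active_sedentary_ratio", "mvpa_minutes", "wear_hours",
)


def aggregate_macro(days: list[DailyMacro]) -> dict[str, float]:
    """Median over days per macro parameter, plus the maximum long-bout count."""
    if not days:
        raise ValueError("no valid days to aggregate")
    out: dict[str, float] = {}
    for name in _MEDIAN_FIELDS:
        vals = np.array([getattr(d, name) for d in days], dtype=float)
        out[name] = float(np.nanmedian(vals)) if np.isfinite(vals).any() else float("nan")
    out["max_long_wb_per_day"] = float(max(d.wb_long for d in days))
    return out
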