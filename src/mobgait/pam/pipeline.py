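"""Subject-level physical-activity monitoring pipeline.

Per day: non-wear detection -> valid-day rule -> walking bouts -> macro
parameters and mobility-state entropy.  Per subject: median/maximum macro
aggregation over valid days, kernel-density micro parameters per bout class
(and over all bouts) with the minimum-bout availability rule, and the
median daily entropy.  Subjects failing the 3-valid-day rule are flagged
excluded and skipped by the downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import IgaConfig, PamConfig
from .bouts import WalkingBout, detect_walking_bouts
from .macro import DailyMacro, aggregate_macro, compute_macro_day
from .micro import MicroEstimate, estimate_micro
from .nonwear import detect_nonwear, select_valid_days, wear_seconds
from .states import extract_activity_episodes, information_entropy, probs_from_episodes

log = logging.getLogger("mobgait.pam")

MICRO_METRICS = ("gait_velocity", "stride_length", "cadence")
MICRO_CLASSES = ("short", "medium", "long", "all")


@dataclass
class DayResult:
    day_index: int
    wear_hours: float
    valid: bool
    macro: DailyMacro | None = None
    bouts: list[WalkingBout] = field(default_factory=list)
    entropy: float = float("nan")
    state_probs: pd.Series | None = None


@dataclass
class PamProfile:
    """Per-subject monitoring profile (macro, micro, entropy, exclusions)."""

    subject: str | None
    included: bool
    exclusion_reason: str | None
    days: list[DayResult]
    macro: dict[str, float] = field(default_factory=dict)
    micro: dict[tuple[str, str], MicroEstimate] = field(default_factory=dict)
    entropy_median: float = float("nan")

    def micro_table(self) -> pd.DataFrame:
        rows = []
        for (cls, metric), est in self.micro.items():
            rows.append({
                "wb_class": cls, "metric": metric, "mode": est.mode,
                "p95": est.p95, "available": est.available, "n": est.n,
            })
        return pd.DataFrame(rows, columns=["wb_class", "metric", "mode", "p95", "available", "n"])

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "included": self.included,
            "exclusion_reason": self.exclusion_reason,
            "n_valid_days": sum(d.valid for d in self.days),
            "wear_hours": [round(d.wear_hours, 4) for d in self.days],
            "macro": {k: self.macro.get(k) for k in sorted(self.macro)},
            "entropy_median": self.entropy_median,
            "micro": {
                f"{cls}.{metric}": {"mode": est.mode, "p95": est.p95,
                                    "available": est.available, "n": est.n}
                for (cls, metric), est in sorted(self.micro.items())
            },
        }


def run_pam(
    week,
    cfg: PamConfig | None = None,
    cfg_iga: IgaConfig | None = None,
    subject: str | None = None,
) -> PamProfile:
    """Process a week of recordings.

    ``week`` is anything with ``n_days`` and ``day(i) -> (left, right)``
    (e.g. a synthetic :class:`~mobgait.synth.WeekRecording`), or a plain
    sequence of (left, right) recording pairs.
    """
    cfg = cfg or PamConfig()
    cfg_iga = cfg_iga or IgaConfig()
    if not hasattr(week, "day"):
        pairs = list(week)
        week = _ListWeek(pairs)
    subject = subject or getattr(week, "subject", None)

    days: list[DayResult] = []
    wear_hours: list[float] = []
    for i in range(week.n_days):
        left, right = week.day(i)
        wear = detect_nonwear(left, cfg)
        hours = wear_seconds(wear) / 3600.0
        wear_hours.append(hours)
        days.append(DayResult(day_index=i, wear_hours=hours, valid=False))
        days[-1]._wear = wear  # cached for the second pass
    valid_idx, included = select_valid_days(wear_hours, cfg)
    for i in valid_idx:
        days[i].valid = True
    for i, d in enumerate(days):
        if not d.valid:
            log.info(
                "day %d excluded: wear %.2f h outside [%g, %g] h", i,
                d.wear_hours, cfg.valid_day_min_hours, cfg.valid_day_max_hours,
            )

    if not included:
        reason = (f"only {len(valid_idx)} valid day(s); "
                  f"at least {cfg.min_valid_days} days with "
                  f"{cfg.valid_day_min_hours:g}-{cfg.valid_day_max_hours:g} h wear required")
        log.warning("subject %s excluded: %s", subject, reason)
        return PamProfile(subject=subject, included=False,
                          exclusion_reason=reason, days=days)

    macros: list[DailyMacro] = []
    bout_values: dict[tuple[str, str], list[float]] = {
        (cls, m): [] for cls in MICRO_CLASSES for m in MICRO_METRICS
    }
    entropies: list[float] = []
    for i in valid_idx:
        left, right = week.day(i)
        wear = days[i]._wear
        bouts = detect_walking_bouts(left, right, wear, cfg, cfg_iga)
        macro = compute_macro_day(bouts, wear, left, right, cfg, day_index=i)
        episodes = extract_activity_episodes(left, right, bouts, wear, cfg)
        probs = probs_from_episodes(episodes, cfg)
        hn = information_entropy(probs.to_numpy()) if probs.sum() > 0 else float("nan")
        days[i].macro = macro
        days[i].bouts = bouts
        days[i].entropy = hn
        days[i].state_probs = probs
        macros.append(macro)
        entropies.append(hn)
        for b in bouts:
            if b.wb_class == "subthreshold":
                continue
            for metric in MICRO_METRICS:
                value = getattr(b, metric)
                bout_values[(b.wb_class, metric)].append(value)
                bout_values[("all", metric)].append(value)

    micro: dict[tuple[str, str], MicroEstimate] = {}
    for key, values in bout_values.items():
        micro[key] = estimate_micro(values, cfg)
        if not micro[key].available:
            log.info("micro %s unavailable: %d bouts < %d required",
                     key, micro[key].n, cfg.min_wb_for_micro)

    return PamProfile(
        subject=subject,
        included=True,
        exclusion_reason=None,
        days=days,
        macro=aggregate_macro(macros),
        micro=micro,
        entropy_median=float(np.nanmedian(entropies)) if entropies else float("nan"),
    )


class _ListWeek:
    def __init__(self, pairs):
        self._pairs = pairs
        self.subject = None

    @property
    def n_days(self) -> int:
        return len(self._pairs)

    def day(self, i):
        return self._pairs[i]
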