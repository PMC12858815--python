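"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults are the values used throughout the analysis (sampling rate 102.4 Hz,
non-wear triple threshold 0.05 g / 2 deg/s / 90 min, valid day 8-12 h with at
least 3 valid days, walking-bout gap 3 s, duration bins 10/30/60 s, MVPA
cut-off 90 steps/min, minimum 10 walking bouts for density estimates,
alpha = 0.05 with Benjamini-Hochberg control).  A config round-trips
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class IgaConfig:
    """Stride segmentation, event detection and aggregation settings."""

    #: moving-average window (s) for the stillness masks
    smooth_window_s: float = 0.12
    #: stance (zero-velocity) criteria on smoothed norms
    still_gyro_dps: float = 40.0
    still_acc_dev_g: float = 0.12
    #: minimum duration of a stance run (s)
    min_still_s: float = 0.08
    #: swing validation: gap duration bounds and energy criteria
    swing_min_s: float = 0.1
    swing_max_s: float = 1.5
    swing_min_gyro_dps: float = 80.0
    swing_min_acc_dev_g: float = 0.4
    #: stance runs longer than this multiple of the typical run are treated
    #: as standing and trimmed to half a typical stance at the walking side
    long_still_factor: float = 1.6
    #: minimum (signed) sagittal swing peak for event detection, deg/s
    event_swing_min_dps: float = 60.0
    #: minimum magnitude of the toe-off / heel-strike negative peaks, deg/s
    event_neg_min_dps: float = 20.0
    #: per-stride heading change beyond which a stride is a turn, degrees
    turn_threshold_deg: float = 45.0
    #: drop turn strides from the aggregate statistics
    exclude_turns: bool = True
    #: a gait test with fewer valid strides is flagged insufficient
    min_valid_strides: int = 4
    #: zero-velocity anchor window at the segment ends (s)
    anchor_window_s: float = 0.05


@dataclass
class PamConfig:
    """Daily-life monitoring rules."""

    # non-wear triple threshold
    nonwear_acc_dev_g: float = 0.05
    nonwear_gyro_dps: float = 2.0
    nonwear_min_minutes: float = 90.0
    # valid-day / subject-inclusion rule (bounds inclusive)
    valid_day_min_hours: float = 8.0
    valid_day_max_hours: float = 12.0
    min_valid_days: int = 3
    # walking bouts
    bout_gap_s: float = 3.0
    subthreshold_s: float = 10.0
    wb_short_max_s: float = 30.0
    wb_medium_max_s: float = 60.0
    # macro parameters
    mvpa_steps_per_min: float = 90.0
    active_acc_sd_g: float = 0.01
    minute_min_wear_s: float = 30.0
    # micro parameters (kernel density)
    min_wb_for_micro: int = 10
    kde_grid_points: int = 512
    kde_grid_pad_bw: float = 3.0
    # 25-state mobility taxonomy
    state_epoch_s: float = 5.0
    cadence_bins: tuple[float, float] = (60.0, 90.0)
    acc_sd_bins: tuple[float, float] = (0.02, 0.10)
    duration_bins: tuple[float, float, float] = (10.0, 30.0, 60.0)


@dataclass
class StatsConfig:
    """Group-comparison and correlation settings."""

    alpha: float = 0.05
    #: Shapiro-Wilk / Levene gate level for test selection
    assumption_alpha: float = 0.05
    #: BH family scope: "family" adjusts within each feature family
    #: (clinical / IGA / PAM, as the tables are reported); "global" pools all
    bh_scope: str = "family"
    min_group_n: int = 3
    min_pairs_corr: int = 5
    #: |rho| upper edges of the strength categories
    strength_bins: tuple[float, float, float] = (0.25, 0.50, 0.75)
    strength_labels: tuple[str, str, str, str] = (
        "weak",
        "moderate",
        "strong",
        "very strong",
    )


@dataclass
class SimConfig:
    """Synthetic-data generation settings."""

    fs: float = 102.4
    #: sampling rate used when rendering multi-day recordings (the native
    #: rate is expensive at week scale; a coarser rate is a valid problem size)
    pam_fs: float = 102.4
    noise_acc_g: float = 0.02
    noise_gyro_dps: float = 0.5
    n_strides_per_pass: int = 8
    n_passes: int = 2
    n_turn_strides: int = 3
    n_days: int = 7
    #: scales daily walking volume (bout counts, step target) for small runs
    volume_scale: float = 1.0
    # cohort size for the end-to-end demo run
    n_subjects_per_group: int = 1
    groups: tuple[str, ...] = ("MSA", "PSP", "PD")


@dataclass
class RunConfig:
    """Top-level configuration for a full simulate -> IGA -> PAM -> stats run."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    iga: IgaConfig = field(default_factory=IgaConfig)
    pam: PamConfig = field(default_factory=PamConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    # -- (de)serialisation -------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def clean(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        def build(tp: type, payload: dict[str, Any]) -> Any:
            kwargs = {}
            for f in dataclasses.fields(tp):
                if f.name not in payload:
                    continue
                value = payload[f.name]
                if dataclasses.is_dataclass(f.type) or f.name in ("sim", "iga", "pam", "stats"):
                    sub = {"sim": SimConfig, "iga": IgaConfig, "pam": PamConfig, "stats": StatsConfig}[f.name]
                    kwargs[f.name] = build(sub, value)
                elif isinstance(value, list):
                    kwargs[f.name] = tuple(value)
                else:
                    kwargs[f.name] = value
            return tp(**kwargs)

        return build(cls, data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
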