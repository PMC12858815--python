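"""Disease-phenotype presets (MSA, PSP, PD) for the synthetic generator.

The presets ship in a versioned data file (``mobgait/data/phenotypes.yaml``)
holding the published group medians: gait-test stride parameters with their
inter-stride coefficients of variation and left/right asymmetry, daily-life
walking-bout gait metrics per bout-duration class, and daily activity
volumes.  They define both the generator's target conditions and the feature
distributions used to draw synthetic cohorts for the statistics layer.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from importlib import resources

import yaml

#: canonical order of the five gait-test parameters
IGA_PARAMS = (
    "gait_velocity",
    "stride_length",
    "stride_time",
    "stance_percentage",
    "max_sensor_lift",
)

WB_CLASSES = ("short", "medium", "long")


@dataclass(frozen=True)
class ParamSpec:
    """Central value, spread and left/right asymmetry of one gait parameter."""

    center: float
    cv: float = 0.0
    asymmetry_pct: float = 0.0
    iqr: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not 0 <= self.asymmetry_pct < 100:
            raise ValueError("asymmetry_pct must be in [0, 100)")

    @property
    def asymmetry_ratio(self) -> float:
        """Left/right ratio r > 0 implied by the asymmetry index."""
        return (100.0 + self.asymmetry_pct) / (100.0 - self.asymmetry_pct)

    @property
    def side_scales(self) -> tuple[float, float]:
        """(left, right) multipliers with mean 1 and the preset ratio."""
        r = self.asymmetry_ratio
        return 2.0 * r / (1.0 + r), 2.0 / (1.0 + r)


@dataclass(frozen=True)
class DailyClassSpec:
    """Daily-life gait metrics for one walking-bout duration class."""

    gait_velocity: float
    stride_length: float
    cadence: float
    wb_per_day: float
    max_wb_per_day: float | None = None
    duration_s: float | None = None
    #: between-bout spread used by the generator
    cadence_sd: float = 6.0
    velocity_cv: float = 0.10


@dataclass(frozen=True)
class PhenotypeParams:
    """Complete generator preset for one patient group."""

    group: str
    iga: dict[str, ParamSpec]
    daily: dict[str, DailyClassSpec]
    macro: dict[str, ParamSpec]
    p95: dict[str, float]
    clinical: dict[str, ParamSpec]

    def without_variability(self) -> "PhenotypeParams":
        """Copy with zero CV and unit asymmetry (degenerate, for testing)."""
        return replace(
            self,
            iga={k: replace(v, cv=0.0, asymmetry_pct=0.0) for k, v in self.iga.items()},
        )


@functools.lru_cache(maxsize=1)
def _load_presets() -> dict[str, PhenotypeParams]:
    text = resources.files("mobgait.data").joinpath("phenotypes.yaml").read_text()
    raw = yaml.safe_load(text)
    presets: dict[str, PhenotypeParams] = {}
    for group, spec in raw["groups"].items():
        presets[group] = PhenotypeParams(
            group=group,
            iga={k: ParamSpec(**v) for k, v in spec["iga"].items()},
            daily={k: DailyClassSpec(**v) for k, v in spec["daily"].items()},
            macro={k: ParamSpec(**v) for k, v in spec["macro"].items()},
            p95=dict(spec["p95"]),
            clinical={k: ParamSpec(**v) for k, v in spec["clinical"].items()},
        )
    return presets


def phenotype_presets(group_label: str) -> PhenotypeParams:
    """Return the preset for ``group_label`` (one of MSA, PSP, PD)."""
    presets = _load_presets()
    if group_label not in presets:
        valid = ", ".join(sorted(presets))
        raise ValueError(f"unknown group label {group_label!r}; valid labels: {valid}")
    return presets[group_label]


def available_groups() -> tuple[str, ...]:
    return tuple(_load_presets())
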