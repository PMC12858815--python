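"""Synthetic per-subject feature tables for the statistics layer.

Features (gait-test aggregates, daily-activity volumes, clinical motor
scores) are drawn around the group medians with spread IQR/1.349 (the normal
IQR-to-sigma factor).  A shared latent severity factor per subject couples
the features with the sign structure expected clinically (worse severity:
slower gait, shorter strides, fewer steps, higher motor scores), so the
correlation layer of the analysis has non-trivial structure to recover.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotypes import phenotype_presets

#: feature -> (preset section, key, sign of loading on latent severity)
FEATURE_MAP = {
    "iga_gait_velocity_mean": ("iga", "gait_velocity", -1),
    "iga_stride_length_mean": ("iga", "stride_length", -1),
    "iga_stride_time_mean": ("iga", "stride_time", +1),
    "iga_stance_percentage_mean": ("iga", "stance_percentage", +1),
    "iga_max_sensor_lift_mean": ("iga", "max_sensor_lift", -1),
    "pam_step_count": ("macro", "step_count", -1),
    "pam_active_sedentary_ratio": ("macro", "active_sedentary_ratio", -1),
    "pam_mvpa_min": ("macro", "mvpa_min", -1),
    "pam_entropy": ("macro", "entropy", -1),
    "mds_updrs_iii": ("clinical", "mds_updrs_iii", +1),
    "pigd": ("clinical", "pigd", +1),
    "bbs": ("clinical", "bbs", -1),
    "ipaq_walking": ("clinical", "ipaq_walking", -1),
}

#: lower bounds: these quantities cannot be negative
NONNEGATIVE = {
    "iga_gait_velocity_mean", "iga_stride_length_mean", "iga_stride_time_mean",
    "iga_max_sensor_lift_mean", "pam_step_count", "pam_active_sedentary_ratio",
    "pam_mvpa_min", "pam_entropy", "pigd", "ipaq_walking", "bbs",
}

IQR_TO_SD = 1.349


def sample_cohort_features(
    n_per_group: int = 30,
    seed=None,
    groups: tuple[str, ...] = ("MSA", "PSP", "PD"),
    features: list[str] | None = None,
    severity_loading: float = 0.6,
) -> pd.DataFrame:
    """Draw a cohort feature table (one row per subject, ``group`` column)."""
    if features is None:
        features = list(FEATURE_MAP)
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        ph = phenotype_presets(group)
        for i in range(n_per_group):
            z_sev = rng.standard_normal()
            row: dict = {"subject": f"{group}{i:03d}", "group": group}
            for name in features:
                section, key, sign = FEATURE_MAP[name]
                spec = getattr(ph, section)[key]
                sd = spec.iqr / IQR_TO_SD
                z = (severity_loading * sign * z_sev
                     + np.sqrt(1.0 - severity_loading**2) * rng.standard_normal())
                value = spec.center + sd * z
                if name in NONNEGATIVE:
                    value = max(value, 0.0)
                row[name] = float(value)
            rows.append(row)
    return pd.DataFrame(rows)
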