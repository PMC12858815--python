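"""End-to-end cohort run: simulate -> IGA -> PAM -> group statistics.

Everything is driven by a :class:`~mobgait.config.RunConfig`; all randomness
derives from its single seed through ``numpy`` seed sequences, so a run is
bit-reproducible: the same config and seed give byte-identical output files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .groupstats import run_group_analysis
from .iga import PARAMS, run_iga
from .io import write_json
from .pam import run_pam
from .synth import generate_gait_test, generate_week_for_group, phenotype_presets
from .synth.cohort import FEATURE_MAP, IQR_TO_SD, NONNEGATIVE

log = logging.getLogger("mobgait.pipeline")

CLINICAL_FEATURES = ("mds_updrs_iii", "pigd", "bbs", "ipaq_walking")


def _draw_clinical(group: str, rng: np.random.Generator, severity_loading: float = 0.6) -> dict:
    """Clinical motor scores for one subject, coupled to a latent severity."""
    ph = phenotype_presets(group)
    z_sev = rng.standard_normal()
    out = {}
    for name in CLINICAL_FEATURES:
        _, key, sign = FEATURE_MAP[name]
        spec = ph.clinical[key]
        z = (severity_loading * sign * z_sev
             + np.sqrt(1.0 - severity_loading**2) * rng.standard_normal())
        value = spec.center + spec.iqr / IQR_TO_SD * z
        out[name] = float(max(value, 0.0)) if name in NONNEGATIVE else float(value)
    return out


def run_subject(group: str, subject: str, cfg: RunConfig, seed) -> dict:
    """Simulate and analyse one subject; returns the feature row."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gait_seed, week_seed, clin_seed = ss.spawn(3)
    sim = cfg.sim

    left, right, _truth = generate_gait_test(
        phenotype_presets(group),
        n_strides_per_pass=sim.n_strides_per_pass,
        n_passes=sim.n_passes,
        seed=gait_seed,
        fs=sim.fs,
        noise_sd=(sim.noise_acc_g, sim.noise_gyro_dps),
        n_turn_strides=sim.n_turn_strides,
    )
    gait = run_iga(left, right, cfg.iga)

    ph = phenotype_presets(group)
    scale = getattr(sim, "volume_scale", 1.0)
    counts = {c: int(round(ph.daily[c].wb_per_day * scale)) for c in ("short", "medium", "long")}
    week = generate_week_for_group(
        group,
        seed=week_seed,
        n_days=sim.n_days,
        fs=getattr(sim, "pam_fs", sim.fs),
        noise_sd=(sim.noise_acc_g, sim.noise_gyro_dps),
        subject=subject,
        bout_counts=counts,
        target_steps=ph.macro["step_count"].center * scale,
    )
    profile = run_pam(week, cfg.pam, cfg.iga, subject=subject)

    row: dict = {"subject": subject, "group": group}
    for param in PARAMS:
        row[f"iga_{param}_mean"] = gait.aggregate(param, "mean")
        row[f"iga_{param}_cv"] = gait.aggregate(param, "cv")
        row[f"iga_{param}_asym"] = gait.aggregate(param, "asymmetry_pct")
    row["iga_insufficient"] = gait.insufficient

    row["pam_included"] = profile.included
    if profile.included:
        row["pam_step_count"] = profile.macro["step_count"]
        row["pam_active_sedentary_ratio"] = profile.macro["active_sedentary_ratio"]
        row["pam_mvpa_min"] = profile.macro["mvpa_minutes"]
        row["pam_wb_short"] = profile.macro["wb_short"]
        row["pam_wb_medium"] = profile.macro["wb_medium"]
        row["pam_wb_long"] = profile.macro["wb_long"]
        row["pam_max_long_wb"] = profile.macro["max_long_wb_per_day"]
        row["pam_entropy"] = profile.entropy_median
        for metric in ("gait_velocity", "stride_length"):
            est = profile.micro[("all", metric)]
            row[f"pam_p95_{metric}"] = est.p95
            row[f"pam_mode_{metric}"] = est.mode
    row.update(_draw_clinical(group, np.random.default_rng(clin_seed)))
    row["_profile"] = profile
    return row


def feature_families(columns) -> dict[str, list[str]]:
    return {
        "clinical": [c for c in columns if c in CLINICAL_FEATURES],
        "iga": [c for c in columns if c.startswith("iga_") and not c.endswith("insufficient")],
        "pam": [c for c in columns if c.startswith("pam_") and c != "pam_included"],
    }


def run_all(cfg: RunConfig, outdir) -> dict:
    """Full pipeline over a simulated cohort; writes the report files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    n = cfg.sim.n_subjects_per_group
    subject_seeds = ss.spawn(len(cfg.sim.groups) * n)

    rows = []
    profiles = {}
    i = 0
    for group in cfg.sim.groups:
        for j in range(n):
            subject = f"{group}{j:03d}"
            log.info("subject %s: simulating and analysing", subject)
            row = run_subject(group, subject, cfg, subject_seeds[i])
            profiles[subject] = row.pop("_profile")
            rows.append(row)
            i += 1
    features = pd.DataFrame(rows)
    features_path = outdir / "features.csv"
    features.to_csv(features_path, index=False, float_format="%.10g")

    families = feature_families(features.columns)
    iga_corr = [f"iga_{p}_mean" for p in ("gait_velocity", "stride_length", "max_sensor_lift")]
    pam_corr = [c for c in ("pam_step_count", "pam_entropy", "pam_p95_gait_velocity",
                            "pam_max_long_wb") if c in features.columns]
    report = run_group_analysis(
        features, families,
        correlation_pairs=(iga_corr + pam_corr, list(CLINICAL_FEATURES)),
        cfg=cfg.stats,
    )
    report_path = outdir / "report.json"
    report.to_json(report_path)
    report.omnibus.to_csv(outdir / "omnibus.csv", index=False, float_format="%.10g")
    report.correlations.to_csv(outdir / "correlations.csv", index=False, float_format="%.10g")
    write_json({s: p.as_dict() for s, p in profiles.items()}, outdir / "profiles.json")
    write_json({"config": cfg.to_dict(), "n_subjects": len(rows)}, outdir / "run_summary.json")
    return {
        "features": features_path,
        "report": report_path,
        "profiles": outdir / "profiles.json",
    }
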