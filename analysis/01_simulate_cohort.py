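"""Simulate the demonstration cohort: gait tests and home-monitoring weeks.

Writes one supervised gait test per group (signals + ground truth) and a
summary of the scheduled home weeks to results/simulation/.  The daily
walking volume is scaled to 12% of the preset medians and weeks are rendered
at 25.6 Hz so the whole demonstration runs in minutes; see docs/methods.md.
"""

from pathlib import Path

import pandas as pd

from mobgait.io import write_imu
from mobgait.synth import generate_gait_test, generate_week_for_group, phenotype_presets

OUT = Path("results/simulation")
SCALE = 0.12
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for group in ("MSA", "PSP", "PD"):
        ph = phenotype_presets(group)
        left, right, truth = generate_gait_test(ph, n_strides_per_pass=8, seed=SEED)
        write_imu(left, OUT / f"{group}_gait_left.csv")
        write_imu(right, OUT / f"{group}_gait_right.csv")
        truth.frame().to_csv(OUT / f"{group}_gait_truth.csv", index=False,
                             float_format="%.10g")
        straight = truth.frame(include_turns=False)
        counts = {c: int(round(ph.daily[c].wb_per_day * SCALE))
                  for c in ("short", "medium", "long")}
        week = generate_week_for_group(
            group, seed=SEED, n_days=4, fs=25.6, bout_counts=counts,
            target_steps=ph.macro["step_count"].center * SCALE,
        )
        for day in week.truth.days:
            rows.append({"group": group, "day": day.day_index,
                         "wear_hours": round(day.wear_hours, 2),
                         "scheduled_steps": day.step_count,
                         **{f"wb_{k}": v for k, v in day.bout_counts().items()}})
        print(f"{group}: gait test with {truth.count()} strides "
              f"(true median velocity {straight.gait_velocity.median():.3f} m/s), "
              f"week of {week.n_days} days, "
              f"~{sum(week.truth.step_counts) // week.n_days} steps/day scheduled")
    pd.DataFrame(rows).to_csv(OUT / "week_schedules.csv", index=False)
    print(f"wrote signals and ground truth to {OUT}/")


if __name__ == "__main__":
    main()
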