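"""Synthetic supervised gait test: two straight passes joined by a turn.

Each foot walks ``n_strides_per_pass`` strides per pass at parameters drawn
from a disease-phenotype preset (central value, inter-stride CV, left/right
asymmetry ratio), with a 180-degree turn of a few short strides between
passes.  The two feet share a timeline (the right foot starts half a stride
later), so consecutive left/right stride pairing is well defined.
"""

from __future__ import annotations

import numpy as np

from ..recording import ImuRecording
from .model import DEFAULT_NOISE, StrideTemplate, imu_channels, stride_kinematics
from .phenotypes import PhenotypeParams
from .truth import GaitTestTruth, StrideTruth

#: lead-in / lead-out quiet standing around the test, seconds
LEAD_S = 2.0
#: turn stride geometry: short slow steps with reduced lift
TURN_STRIDE_LENGTH = 0.4
TURN_STRIDE_LIFT = 0.03


def _draw(rng: np.random.Generator, center: float, cv: float) -> float:
    """Normal draw around ``center`` with relative spread ``cv``, clipped to
    +-3 sigma so degenerate (cv=0) presets are reproduced exactly."""
    if cv == 0.0:
        return center
    z = np.clip(rng.standard_normal(), -3.0, 3.0)
    return center * (1.0 + cv * z)


def draw_stride_templates(
    phenotype: PhenotypeParams,
    n: int,
    foot: str,
    rng: np.random.Generator,
    heading: float = 0.0,
) -> list[StrideTemplate]:
    """Draw ``n`` straight-walking stride templates for one foot.

    Gait velocity and stride time are the primary draws; stride length is
    derived as their product so the preset's velocity median is matched in
    expectation (the printed medians of the three quantities are not mutually
    consistent, being independent cohort medians).
    """
    side = 0 if foot == "left" else 1
    spec = phenotype.iga
    out = []
    for _ in range(n):
        v = _draw(rng, spec["gait_velocity"].center * spec["gait_velocity"].side_scales[side],
                  spec["gait_velocity"].cv)
        t = _draw(rng, spec["stride_time"].center * spec["stride_time"].side_scales[side],
                  spec["stride_time"].cv)
        stance = _draw(rng, spec["stance_percentage"].center * spec["stance_percentage"].side_scales[side],
                       spec["stance_percentage"].cv)
        lift = _draw(rng, spec["max_sensor_lift"].center * spec["max_sensor_lift"].side_scales[side],
                     spec["max_sensor_lift"].cv)
        v = max(v, 0.05)
        t = max(t, 0.3)
        stance = float(np.clip(stance, 25.0, 90.0))
        lift = max(lift, 0.005)
        out.append(StrideTemplate(
            stride_length=v * t, stride_time=t, stance_percentage=stance,
            max_lift=lift, heading=heading,
        ))
    return out


def turn_stride_templates(
    phenotype: PhenotypeParams, n_turn: int, start_heading: float, total_turn: float = 180.0
) -> list[StrideTemplate]:
    t = phenotype.iga["stride_time"].center
    stance = phenotype.iga["stance_percentage"].center
    step = total_turn / n_turn
    return [
        StrideTemplate(
            stride_length=TURN_STRIDE_LENGTH,
            stride_time=t,
            stance_percentage=stance,
            max_lift=TURN_STRIDE_LIFT,
            heading=start_heading + i * step,
            turn_angle=step,
        )
        for i in range(n_turn)
    ]


def render_stride_train(
    templates: list[StrideTemplate],
    fs: float,
    t0: float,
    acc: np.ndarray,
    gyr: np.ndarray,
    foot: str,
    is_turn_flags: list[bool] | None = None,
) -> list[StrideTruth]:
    """Write consecutive noise-free strides into ``acc``/``gyr`` starting at
    time ``t0`` (seconds relative to the arrays' first sample).  Returns the
    per-stride ground truth with exact event times."""
    if is_turn_flags is None:
        is_turn_flags = [tpl.turn_angle != 0.0 for tpl in templates]
    truths = []
    cursor = t0
    n_total = acc.shape[0]
    for tpl, turn in zip(templates, is_turn_flags):
        k0 = int(round(cursor * fs))
        k1 = min(int(round((cursor + tpl.stride_time) * fs)), n_total)
        if k0 >= n_total:
            break
        t_local = np.arange(k0, k1) / fs - cursor
        kin = stride_kinematics(tpl, t_local)
        a, g = imu_channels(kin)
        acc[k0:k1] = a
        gyr[k0:k1] = g
        half = tpl.stance_time / 2.0
        truths.append(StrideTruth(
            foot=foot,
            start=cursor,
            toe_off=cursor + half,
            heel_strike=cursor + half + tpl.swing_time,
            end=cursor + tpl.stride_time,
            gait_velocity=tpl.gait_velocity,
            stride_length=tpl.stride_length,
            stride_time=tpl.stride_time,
            stance_percentage=tpl.stance_percentage,
            max_sensor_lift=tpl.max_lift,
            heading=tpl.heading,
            turn_angle=tpl.turn_angle,
            is_turn=turn,
        ))
        cursor += tpl.stride_time
    return truths


def generate_gait_test(
    phenotype: PhenotypeParams,
    n_strides_per_pass: int = 8,
    n_passes: int = 2,
    seed: int | None = None,
    fs: float = 102.4,
    noise_sd: tuple[float, float] = DEFAULT_NOISE,
    n_turn_strides: int = 3,
    include_turn: bool = True,
) -> tuple[ImuRecording, ImuRecording, GaitTestTruth]:
    """Simulate a two-pass walk test; returns (left, right, ground truth)."""
    if n_strides_per_pass < 3:
        raise ValueError("n_strides_per_pass must be >= 3")
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    rng = np.random.default_rng(seed)

    per_foot: dict[str, tuple[list[StrideTemplate], list[bool]]] = {}
    for foot in ("left", "right"):
        templates: list[StrideTemplate] = []
        flags: list[bool] = []
        for p in range(n_passes):
            heading = 180.0 * (p % 2)
            straight = draw_stride_templates(phenotype, n_strides_per_pass, foot, rng, heading)
            templates.extend(straight)
            flags.extend([False] * len(straight))
            if include_turn and p < n_passes - 1:
                turns = turn_stride_templates(phenotype, n_turn_strides, heading)
                templates.extend(turns)
                flags.extend([True] * len(turns))
        per_foot[foot] = (templates, flags)

    offset = per_foot["left"][0][0].stride_time / 2.0
    t0 = {"left": LEAD_S, "right": LEAD_S + offset}
    total = max(
        t0[foot] + sum(tpl.stride_time for tpl in per_foot[foot][0]) for foot in per_foot
    ) + LEAD_S
    n = int(round(total * fs))

    recordings = {}
    strides: list[StrideTruth] = []
    for foot in ("left", "right"):
        acc = np.zeros((n, 3))
        acc[:, 2] = 1.0
        gyr = np.zeros((n, 3))
        templates, flags = per_foot[foot]
        strides.extend(render_stride_train(templates, fs, t0[foot], acc, gyr, foot, flags))
        sd_a, sd_g = noise_sd
        if sd_a:
            acc += rng.normal(0.0, sd_a, acc.shape)
        if sd_g:
            gyr += rng.normal(0.0, sd_g, gyr.shape)
        recordings[foot] = ImuRecording(acc=acc, gyr=gyr, fs=fs, foot=foot)

    truth = GaitTestTruth(fs=fs, strides=sorted(strides, key=lambda s: s.start))
    return recordings["left"], recordings["right"], truth
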