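"""25-state mobility taxonomy and normalized information entropy.

Wear time is partitioned into episodes labelled by activity type
(locomotion / non-locomotion), duration (very short < 10 s, short 10-30 s,
medium 30-60 s, long > 60 s) and intensity (cadence bins < 60 / 60-90 /
> 90 steps/min for locomotion; accelerometer-norm SD bins for
non-locomotion): 2 x 4 x 3 = 24 states plus one rest state.  The
time-weighted state distribution feeds the normalized Shannon entropy
Hn = -sum(p ln p) / ln 25, a complexity measure in [0, 1]: 0 for a single
state, 1 for uniform use of all states.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import PamConfig
from ..recording import ImuRecording
from .bouts import WalkingBout
from .nonwear import WearInterval

DURATION_LABELS = ("very_short", "short", "medium", "long")
INTENSITY_LABELS = ("low", "medium", "high")

#: fixed order of the 25 mobility states
STATE_LABELS: tuple[str, ...] = ("rest",) + tuple(
    f"{kind}_{dur}_{inten}"
    for kind in ("locomotion", "non_locomotion")
    for dur in DURATION_LABELS
    for inten in INTENSITY_LABELS
)

N_STATES = len(STATE_LABELS)


def _duration_bin(duration: float, cfg: PamConfig) -> str:
    b0, b1, b2 = cfg.duration_bins
    if duration < b0:
        return "very_short"
    if duration <= b1:
        return "short"
    if duration <= b2:
        return "medium"
    return "long"


def _intensity_bin(value: float, edges: tuple[float, float]) -> str:
    if value < edges[0]:
        return "low"
    if value <= edges[1]:
        return "medium"
    return "high"


def state_label(kind: str, duration: float, value: float, cfg: PamConfig | None = None) -> str:
    """State of one episode; ``value`` is cadence (walking) or acc-norm SD."""
    cfg = cfg or PamConfig()
    if kind == "rest":
        return "rest"
    if kind == "walking":
        return f"locomotion_{_duration_bin(duration, cfg)}_{_intensity_bin(value, cfg.cadence_bins)}"
    if kind == "active":
        return f"non_locomotion_{_duration_bin(duration, cfg)}_{_intensity_bin(value, cfg.acc_sd_bins)}"
    raise ValueError(f"unknown episode kind {kind!r}")


def probs_from_episodes(episodes, cfg: PamConfig | None = None) -> pd.Series:
    """Time-weighted state probability vector from (kind, duration, value)
    episodes (``EpisodeTruth``-like objects also accepted)."""
    cfg = cfg or PamConfig()
    weights = np.zeros(N_STATES)
    index = {label: i for i, label in enumerate(STATE_LABELS)}
    for ep in episodes:
        if hasattr(ep, "kind"):
            kind, duration, value = ep.kind, ep.duration, ep.value
        else:
            kind, duration, value = ep
        weights[index[state_label(kind, duration, value, cfg)]] += duration
    total = weights.sum()
    probs = weights / total if total > 0 else weights
    return pd.Series(probs, index=list(STATE_LABELS))


def extract_activity_episodes(
    left: ImuRecording,
    right: ImuRecording,
    bouts: list[WalkingBout],
    wear: list[WearInterval],
    cfg: PamConfig | None = None,
) -> list[tuple[str, float, float]]:
    """Episode list (kind, duration, value) covering all wear time.

    Walking bouts become locomotion episodes with their cadence; the
    remaining wear time is split into short epochs whose accelerometer-norm
    SD separates non-locomotion activity from rest, and adjacent epochs of
    the same kind merge into one episode.
    """
    cfg = cfg or PamConfig()
    episodes: list[tuple[str, float, float]] = [
        ("walking", b.duration, b.cadence) for b in bouts
    ]
    bout_spans = [(b.start, b.end) for b in bouts]

    for iv in wear:
        if not iv.is_wear:
            continue
        # subtract bout spans from this wear interval
        free: list[tuple[float, float]] = []
        cursor = iv.start
        for b0, b1 in sorted(bout_spans):
            if b1 <= iv.start or b0 >= iv.end:
                continue
            if b0 > cursor:
                free.append((cursor, b0))
            cursor = max(cursor, b1)
        if cursor < iv.end:
            free.append((cursor, iv.end))

        for f0, f1 in free:
            if f1 - f0 < cfg.state_epoch_s:
                continue
            episodes.extend(_epoch_episodes(left, right, f0, f1, cfg))
    return episodes


def _epoch_episodes(left, right, t0, t1, cfg) -> list[tuple[str, float, float]]:
    n_ep = int((t1 - t0) // cfg.state_epoch_s)
    if n_ep == 0:
        return []
    sds = []
    for rec in (left, right):
        i0 = int(round((t0 - rec.start) * rec.fs))
        step = cfg.state_epoch_s * rec.fs
        norm = rec.acc_norm()
        ends = np.minimum(i0 + (np.arange(n_ep) + 1) * step, norm.size).astype(int)
        starts = np.maximum(i0 + np.arange(n_ep) * step, 0).astype(int)
        sd = np.array([
            norm[s:e].std() if e - s > 1 else 0.0 for s, e in zip(starts, ends)
        ])
        sds.append(sd)
    sd = np.maximum(*sds)
    active = sd > cfg.active_acc_sd_g

    out: list[tuple[str, float, float]] = []
    i = 0
    while i < n_ep:
        j = i
        while j + 1 < n_ep and active[j + 1] == active[i]:
            j += 1
        dur = (j - i + 1) * cfg.state_epoch_s
        if active[i]:
            out.append(("active", dur, float(sd[i:j + 1].mean())))
        else:
            out.append(("rest", dur, 0.0))
        i = j + 1
    return out


def information_entropy(probs, n_states: int = N_STATES) -> float:
    """Normalized Shannon entropy Hn = -sum(p ln p) / ln(n_states).

    ``probs`` must be non-negative and sum to 1 (within 1e-9); zero entries
    contribute nothing (0 ln 0 := 0).
    """
    p = np.asarray(probs, dtype=float)
    if (p < 0).any():
        raise ValueError("state probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("state probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(n_states))
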