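"""Per-test aggregation: mean, coefficient of variation, asymmetry index."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("mobgait.iga")


def aggregate_mean_cv(values) -> tuple[float, float]:
    """Mean and coefficient of variation (sample SD over mean) of a series.

    Needs at least two values; a zero mean leaves the CV undefined (NaN,
    with a logged warning) rather than raising.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for mean/CV")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        log.warning("CV undefined: series mean is zero")
        return mean, float("nan")
    return mean, sd / abs(mean)


def pair_consecutive(feet, starts) -> list[tuple[int, int]]:
    """Pair each left stride with the next right stride in time.

    Returns index pairs into the input arrays; strides left over on either
    side are dropped.
    """
    order = np.argsort(starts, kind="stable")
    pairs: list[tuple[int, int]] = []
    pending_left: int | None = None
    for idx in order:
        if feet[idx] == "left":
            pending_left = idx
        elif pending_left is not None:
            pairs.append((pending_left, idx))
            pending_left = None
    return pairs


def asymmetry_index(left_values, right_values) -> float:
    """Median normalized left/right difference in percent.

    For each consecutive pair i, ``a_i = |(P_Li - P_Ri) / (P_Li + P_Ri)| *
    100``; the result is the median of the ``a_i`` and lies in [0, 100] for
    same-sign pairs.  Pairs whose sum is zero are dropped with a warning.
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right series must have equal length")
    if left.size < 1:
        raise ValueError("need at least one left/right pair")
    denom = left + right
    keep = denom != 0.0
    if not keep.all():
        log.warning("dropping %d pair(s) with zero sum", int((~keep).sum()))
    if not keep.any():
        raise ValueError("no valid pairs (all sums zero)")
    a = np.abs((left[keep] - right[keep]) / denom[keep]) * 100.0
    return float(np.median(a))
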