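"""Artifact filtering of RR-interval series.

Two automatic filters are applied before any scaling analysis:

1. a physiological range filter discarding intervals outside 200-2000 ms
   (equivalently heart rates outside 30-300 BPM), and
2. a windowed median filter discarding beats that deviate by more than 10%
   from the median of a 7-beat window centred on the beat.

A third, optional stage removes an explicit user-supplied list of beat
indices, standing in for removals by visual inspection.  The range filter
runs first so that gross outliers cannot corrupt the medians of their
neighbours; the median filter is a single pass over the range-filtered
series (flags are computed simultaneously, not cascaded).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .series import FilterReport, RRISeries

__all__ = [
    "filter_range",
    "filter_median_deviation",
    "preprocess",
]


def filter_range(series: RRISeries, lo: float = 200.0, hi: float = 2000.0) -> RRISeries:
    """Flag beats with intervals outside ``[lo, hi]`` milliseconds as not retained.

    Already-removed beats stay removed. Returns a new series.
    """
    if series.n_beats == 0:
        raise ValueError("empty series")
    out = series.copy()
    bad = (out.intervals < lo) | (out.intervals > hi)
    out.retained &= ~bad
    return out


def _window_median(values: np.ndarray, i: int, half: int) -> float:
    """Median of the window centred on ``i``, shrunk symmetrically at the edges.

    Near the series ends the symmetric window would collapse below 3 beats;
    there the first/last 3 beats are used instead of fabricating data by
    reflection.
    """
    n = values.size
    h = min(half, i, n - 1 - i)
    if 2 * h + 1 >= 3:
        return float(np.median(values[i - h : i + h + 1]))
    if i < 1:
        return float(np.median(values[: min(3, n)]))
    return float(np.median(values[max(0, n - 3) :]))


def filter_median_deviation(
    series: RRISeries, kernel: int = 7, frac: float = 0.10
) -> RRISeries:
    """Flag beats deviating by more than ``frac`` from the windowed median.

    Only retained beats participate in the median windows; the deviation is
    measured relative to the median. Window size shrinks symmetrically at
    the series ends (minimum 3 beats).
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 3")
    out = series.copy()
    idx = np.flatnonzero(out.retained)
    if idx.size < kernel:
        raise ValueError(
            f"kernel ({kernel}) larger than number of retained beats ({idx.size})"
        )
    vals = out.intervals[idx]
    half = kernel // 2
    medians = np.empty(idx.size)
    for j in range(idx.size):
        medians[j] = _window_median(vals, j, half)
    deviant = np.abs(vals - medians) / medians > frac
    out.retained[idx[deviant]] = False
    return out


def preprocess(
    series: RRISeries,
    lo: float = 200.0,
    hi: float = 2000.0,
    kernel: int = 7,
    frac: float = 0.10,
    manual_exclude: Iterable[int] | None = None,
) -> tuple[RRISeries, FilterReport]:
    """Range filter, then median filter, then optional manual exclusions.

    Returns the flagged series together with a :class:`FilterReport`
    attributing every removal to the stage that caused it.  Downstream
    scaling analysis should consume ``result.compact()``.
    """
    # n_raw counts beats retained at entry so that the per-stage removal
    # counts always sum to n_raw - n_retained, even on re-runs.
    report = FilterReport(n_raw=int(np.count_nonzero(series.retained)))
    stage1 = filter_range(series, lo=lo, hi=hi)
    report.n_removed_range = int(
        np.count_nonzero(series.retained) - np.count_nonzero(stage1.retained)
    )
    stage2 = filter_median_deviation(stage1, kernel=kernel, frac=frac)
    report.n_removed_median = int(
        np.count_nonzero(stage1.retained) - np.count_nonzero(stage2.retained)
    )
    if manual_exclude is not None:
        manual_exclude = np.asarray(list(manual_exclude), dtype=int)
        if manual_exclude.size and (
            manual_exclude.min() < 0 or manual_exclude.max() >= series.n_beats
        ):
            raise IndexError("manual exclusion index out of range")
        before = np.count_nonzero(stage2.retained)
        stage2.retained[manual_exclude] = False
        report.n_removed_manual = int(before - np.count_nonzero(stage2.retained))
    return stage2, report
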