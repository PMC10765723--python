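"""Core containers for beat-to-beat interval recordings.

The fundamental object is :class:`RRISeries`: an ordered sequence of RR
intervals (milliseconds between successive heartbeats) together with the
cumulative occurrence time of each beat and a per-beat retention flag used
by the artifact filters.  Filters only ever clear flags; downstream scaling
analysis consumes the gap-closed sequence of retained intervals while
reported times refer to the retained beats' original cumulative times.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RRISeries", "FilterReport"]


@dataclass
class RRISeries:
    """An RR-interval recording.

    Parameters
    ----------
    intervals : ndarray of float
        RR intervals in milliseconds, one per beat. All strictly positive.
    t_cum : ndarray of float
        Cumulative time of each beat in seconds, strictly increasing.
        When constructed from raw intervals, ``t_cum[i] = sum(intervals[:i+1]) / 1000``.
    retained : ndarray of bool
        Retention flag per beat. Filters flip flags true -> false only.
    """

    intervals: np.ndarray
    t_cum: np.ndarray
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise ValueError("RRISeries requires a nonempty 1-D interval sequence")
        if np.any(~np.isfinite(self.intervals)) or np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be finite and strictly positive")
        self.t_cum = np.asarray(self.t_cum, dtype=float)
        if self.t_cum.shape != self.intervals.shape:
            raise ValueError("t_cum must have the same length as intervals")
        if np.any(np.diff(self.t_cum) <= 0):
            raise ValueError("t_cum must be strictly increasing")
        if self.retained is None:
            self.retained = np.ones(self.intervals.size, dtype=bool)
        else:
            self.retained = np.asarray(self.retained, dtype=bool)
            if self.retained.shape != self.intervals.shape:
                raise ValueError("retained must have the same length as intervals")

    @classmethod
    def from_intervals(cls, intervals_ms) -> "RRISeries":
        """Build a series from raw intervals; occurrence times are cumulative sums."""
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        t_cum = np.cumsum(intervals_ms) / 1000.0
        return cls(intervals=intervals_ms, t_cum=t_cum)

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(self.retained))

    @property
    def duration_s(self) -> float:
        """Span of the recording in seconds (first to last beat)."""
        return float(self.t_cum[-1] - self.t_cum[0])

    def copy(self) -> "RRISeries":
        return RRISeries(
            intervals=self.intervals.copy(),
            t_cum=self.t_cum.copy(),
            retained=self.retained.copy(),
        )

    def compact(self) -> "RRISeries":
        """Gap-closed series of retained beats.

        The returned series keeps the retained beats' original cumulative
        times, so reported times stay on the recording's clock even though
        the interval sequence is contiguous in beat index.
        """
        if self.n_retained == 0:
            raise ValueError("no retained beats")
        m = self.retained
        return RRISeries(
            intervals=self.intervals[m],
            t_cum=self.t_cum[m],
            retained=np.ones(self.n_retained, dtype=bool),
        )


@dataclass
class FilterReport:
    """Bookkeeping of how many beats each preprocessing stage removed."""

    n_raw: int = 0
    n_removed_range: int = 0
    n_removed_median: int = 0
    n_removed_manual: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_raw - self.n_removed_range - self.n_removed_median - self.n_removed_manual

    @property
    def removed_fraction(self) -> float:
        return (self.n_raw - self.n_retained) / self.n_raw if self.n_raw else 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_retained"] = self.n_retained
        d["removed_fraction"] = self.removed_fraction
        return d
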