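"""Aerobic (T1) and anaerobic (T2) threshold estimators.

Four routes to the two boundaries of the three-zone exercise model:

* ``ddfa_*`` — the DDFA route: scaling exponents are binned by integer
  heart rate, an individual baseline (the 25 lowest-HR bins per scale) is
  subtracted, the scale-averaged curve is mean-filtered, and the thresholds
  are the first stable drops of the smoothed curve below 0 and below -0.5.
* ``dfa_alpha1_thresholds`` — the conventional short-term DFA method:
  linear regression of alpha1 on HR inside its near-linear decline, with
  T1/T2 where the fitted line crosses 0.75 and 0.5.
* ``hrmax_thresholds`` — fixed percentages (70% / 85%) of maximal HR.
* ``lactate_thresholds`` — the two-slope blood-lactate protocol: LT1 at
  0.3 mmol/L above the minimum, LT2 at the crossing of a line through the
  LT1 point and the next sample with a line through the steep final rise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ddfa import DDFAField, DFAalpha1Track

__all__ = [
    "HRBinProfile",
    "BaselineProfile",
    "SmoothedAlphaCurve",
    "ThresholdResult",
    "LactateCurve",
    "bin_by_hr",
    "compute_baseline",
    "smoothed_alpha",
    "ddfa_thresholds",
    "hrmax_thresholds",
    "dfa_alpha1_thresholds",
    "lactate_thresholds",
    "hr_at_time",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class HRBinProfile:
    """Mean scaling exponent per (integer HR bin, scale).

    ``alpha_bin`` is (n_bins, n_scales), NaN where a bin is unoccupied at
    that scale; ``counts`` holds the number of contributing segments.
    """

    bins: np.ndarray
    scales: np.ndarray
    alpha_bin: np.ndarray
    counts: np.ndarray


@dataclass
class BaselineProfile:
    """Per-scale resting baseline exponent from the lowest-HR bins."""

    b: np.ndarray
    n_bins_used: np.ndarray  # per scale; < requested when few bins are occupied


@dataclass
class SmoothedAlphaCurve:
    """Baseline-subtracted, scale-averaged, mean-filtered exponent per HR bin."""

    bins: np.ndarray
    alpha_tilde: np.ndarray


@dataclass
class ThresholdResult:
    """One estimator's thresholds in BPM, with method-specific diagnostics.

    ``t1_bpm``/``t2_bpm`` are integers or None when no stable estimate
    exists; exact (unrounded) values live in ``diagnostics`` where the
    method produces them.
    """

    method: str
    t1_bpm: int | None
    t2_bpm: int | None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.t1_bpm is not None
            and self.t2_bpm is not None
            and self.t1_bpm > self.t2_bpm
        ):
            warnings.warn(
                f"{self.method}: T1 ({self.t1_bpm}) exceeds T2 ({self.t2_bpm})",
                stacklevel=2,
            )


@dataclass
class LactateCurve:
    """Incremental-test lactate samples: one per exercise step.

    ``step_t`` is the end time of each load (s, strictly increasing),
    ``lactate`` the blood concentration (mmol/L), ``hr`` the 30-s-averaged
    heart rate at the step end (BPM).
    """

    step_t: np.ndarray
    lactate: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.step_t = np.asarray(self.step_t, dtype=float)
        self.lactate = np.asarray(self.lactate, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if np.any(np.diff(self.step_t) <= 0):
            raise ValueError("step_t must be strictly increasing")
        if np.any(self.lactate <= 0):
            raise ValueError("lactate concentrations must be positive")


# ---------------------------------------------------------------------------
# DDFA route


def bin_by_hr(field: DDFAField) -> HRBinProfile:
    """Aggregate a DDFA field into integer-HR bins.

    Every defined (t, s) entry is assigned to ``round(seg_hr)`` (ties round
    half to even) and the per-bin, per-scale arithmetic mean is taken.
    """
    defined = np.isfinite(field.alpha) & np.isfinite(field.seg_hr)
    if not defined.any():
        raise ValueError("empty DDFA field: no defined entries")
    binned = np.full(field.seg_hr.shape, -1, dtype=int)
    binned[defined] = np.rint(field.seg_hr[defined]).astype(int)
    lo, hi = binned[defined].min(), binned[defined].max()
    nb = hi - lo + 1
    S = field.scales.size
    sums = np.zeros((nb, S))
    counts = np.zeros((nb, S), dtype=int)
    for j in range(S):
        m = defined[:, j]
        idx = binned[m, j] - lo
        np.add.at(sums[:, j], idx, field.alpha[m, j])
        np.add.at(counts[:, j], idx, 1)
    occupied = counts.sum(axis=1) > 0
    with np.errstate(invalid="ignore"):
        alpha_bin = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HRBinProfile(
        bins=np.arange(lo, hi + 1)[occupied],
        scales=field.scales.copy(),
        alpha_bin=alpha_bin[occupied],
        counts=counts[occupied],
    )


def compute_baseline(profile: HRBinProfile, n_bins: int = 25) -> BaselineProfile:
    """Resting baseline: per scale, mean alpha over the ``n_bins`` lowest occupied bins."""
    S = profile.scales.size
    b = np.full(S, np.nan)
    used = np.zeros(S, dtype=int)
    short = False
    for j in range(S):
        occ = np.flatnonzero(profile.counts[:, j] > 0)
        if occ.size == 0:
            continue
        take = occ[:n_bins]
        if take.size < n_bins:
            short = True
        b[j] = profile.alpha_bin[take, j].mean()
        used[j] = take.size
    if not np.isfinite(b).any():
        raise ValueError("no occupied bins at any scale")
    if short:
        warnings.warn(
            f"fewer than {n_bins} occupied bins at some scales; baseline uses all available",
            stacklevel=2,
        )
    return BaselineProfile(b=b, n_bins_used=used)


def smoothed_alpha(
    profile: HRBinProfile, base: BaselineProfile, kernel: int = 10
) -> SmoothedAlphaCurve:
    """Baseline-subtract, average over scales, mean-filter over occupied bins.

    The mean filter runs over the sequence of occupied bins (unoccupied
    interior bins are skipped, not zero-filled) with a centred window of
    ``kernel`` bins that shrinks at the ends; for even kernels the window
    extends ``kernel // 2`` bins to the left and ``kernel // 2 - 1`` to the
    right.
    """
    resid = profile.alpha_bin - base.b[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_bin = np.nanmean(resid, axis=1)
    occ = np.isfinite(per_bin)
    bins = profile.bins[occ]
    vals = per_bin[occ]
    left = kernel // 2
    right = kernel - left - 1
    sm = np.empty_like(vals)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    n = vals.size
    for i in range(n):
        a = max(0, i - left)
        b = min(n, i + right + 1)
        sm[i] = (csum[b] - csum[a]) / (b - a)
    return SmoothedAlphaCurve(bins=bins, alpha_tilde=sm)


def _first_stable_run(
    values: np.ndarray, level: float, run: int, start: int
) -> tuple[int | None, list[int]]:
    """Index of the first position >= start opening a run of ``run``
    consecutive values strictly below ``level``; also the unstable
    candidate positions encountered before it."""
    below = values < level
    candidates: list[int] = []
    for i in range(start, values.size - run + 1):
        if below[i : i + run].all():
            return i, candidates
        if below[i] and (i == start or not below[i - 1]):
            candidates.append(i)
    return None, candidates


def ddfa_thresholds(
    curve: SmoothedAlphaCurve,
    run: int = 10,
    level1: float = 0.0,
    level2: float = -0.5,
    search_start: int = 25,
) -> ThresholdResult:
    """Thresholds from the smoothed baseline-subtracted exponent curve.

    T1 is the lowest HR bin opening a run of at least ``run`` consecutive
    occupied bins with the curve strictly below the baseline (0); T2 the
    same for the level -0.5.  The scan starts above the baseline region
    (occupied bin index ``search_start``), where the curve is ~0 by
    construction and could dip negative spuriously.  Unstable crossings are
    reported in the diagnostics; a threshold with no stable run is None.
    """
    at = curve.alpha_tilde
    if at.size == 0:
        raise ValueError("empty curve")
    start = min(search_start, at.size)
    i1, c1 = _first_stable_run(at, level1, run, start)
    i2, c2 = _first_stable_run(at, level2, run, start)
    diag = {
        "unstable_candidates_t1": [int(curve.bins[i]) for i in c1],
        "unstable_candidates_t2": [int(curve.bins[i]) for i in c2],
        "run": run,
        "levels": (level1, level2),
    }
    return ThresholdResult(
        method="DDFAT",
        t1_bpm=int(curve.bins[i1]) if i1 is not None else None,
        t2_bpm=int(curve.bins[i2]) if i2 is not None else None,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# HRmax route


def hrmax_thresholds(
    hr_max: float, p1: float = 0.70, p2: float = 0.85
) -> ThresholdResult:
    """Thresholds at fixed fractions of maximal heart rate."""
    if not 30 < hr_max < 300:
        raise ValueError(f"hr_max {hr_max} outside the physiological range (30, 300)")
    if p1 > p2:
        raise ValueError("p1 must not exceed p2")
    t1, t2 = p1 * hr_max, p2 * hr_max
    return ThresholdResult(
        method="HRmaxT",
        t1_bpm=int(np.rint(t1)),
        t2_bpm=int(np.rint(t2)),
        diagnostics={"t1_bpm_exact": t1, "t2_bpm_exact": t2, "p1": p1, "p2": p2},
    )


# ---------------------------------------------------------------------------
# DFA alpha1 route


def _r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS fit y ~ x; returns (slope, intercept, R^2)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2)


def dfa_alpha1_thresholds(
    track: DFAalpha1Track,
    gap_n: int = 4,
    band: tuple[float, float] = (0.5, 0.75),
) -> ThresholdResult:
    """Regression-region method on the alpha1-versus-HR decline.

    1. Select points with ``band[0] <= alpha1 <= band[1]`` (in HR order).
    2. Bridge disjoint selections separated by at most ``gap_n`` intervening
       points, which join the region.
    3. Of the remaining regions keep the one with the most points and fit
       alpha1 ~ HR by least squares.
    4. Greedily grow the region one point at a time from either end while
       the fit's coefficient of determination strictly improves.

    T1/T2 are the HR where the fitted line crosses the band edges (0.75 and
    0.5).  A non-declining fit or an empty band yields undefined thresholds
    with the reason in the diagnostics.
    """
    ok = np.isfinite(track.alpha1) & np.isfinite(track.seg_hr)
    hr = track.seg_hr[ok]
    a1 = track.alpha1[ok]
    order = np.argsort(hr, kind="stable")
    hr, a1 = hr[order], a1[order]

    in_band = (a1 >= band[0]) & (a1 <= band[1])
    n_band = int(np.count_nonzero(in_band))
    if n_band < 3:
        return ThresholdResult(
            "DFAa1T", None, None, {"reason": f"only {n_band} points inside band {band}"}
        )
    idx = np.flatnonzero(in_band)
    # contiguous runs of band indices, then bridge small gaps
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i == runs[-1][1] + 1:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    merged = [runs[0]]
    for lo, hi in runs[1:]:
        if lo - merged[-1][1] - 1 <= gap_n:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    lo, hi = max(merged, key=lambda r: r[1] - r[0])  # most data points; tie -> lowest HR
    slope, intercept, r2 = _r2(hr[lo : hi + 1], a1[lo : hi + 1])
    while True:
        best = None
        if lo > 0:
            cand = _r2(hr[lo - 1 : hi + 1], a1[lo - 1 : hi + 1])
            if cand[2] > r2:
                best = ("L", cand)
        if hi < hr.size - 1:
            cand = _r2(hr[lo : hi + 2], a1[lo : hi + 2])
            if cand[2] > r2 and (best is None or cand[2] > best[1][2]):
                best = ("R", cand)
        if best is None:
            break
        if best[0] == "L":
            lo -= 1
        else:
            hi += 1
        slope, intercept, r2 = best[1]

    diag = {
        "region_hr": (float(hr[lo]), float(hr[hi])),
        "n_points": hi - lo + 1,
        "slope": slope,
        "intercept": intercept,
        "r2": r2,
    }
    if slope >= 0:
        diag["reason"] = "alpha1 does not decline with HR in the fitted region"
        return ThresholdResult("DFAa1T", None, None, diag)
    t1 = (band[1] - intercept) / slope
    t2 = (band[0] - intercept) / slope
    diag.update(t1_bpm_exact=t1, t2_bpm_exact=t2)
    return ThresholdResult("DFAa1T", int(np.rint(t1)), int(np.rint(t2)), diag)


# ---------------------------------------------------------------------------
# lactate route


def hr_at_time(t: float, trace_t, trace_hr) -> float:
    """Heart rate of a 30-s-averaged trace at time ``t`` (linear interpolation)."""
    trace_t = np.asarray(trace_t, dtype=float)
    trace_hr = np.asarray(trace_hr, dtype=float)
    if not trace_t[0] <= t <= trace_t[-1]:
        raise ValueError(
            f"t = {t} outside the trace span [{trace_t[0]}, {trace_t[-1]}]"
        )
    return float(np.interp(t, trace_t, trace_hr))


def lactate_thresholds(
    curve: LactateCurve,
    hr_trace: tuple[np.ndarray, np.ndarray] | None = None,
    lt1_offset: float = 0.3,
    step_rise: float = 0.8,
) -> ThresholdResult:
    """Two-slope lactate protocol.

    LT1 is where the concentration first reaches ``min + lt1_offset``
    mmol/L on the rising side (interpolating linearly between samples).
    A first line runs through the LT1 point and the following sample; a
    second is the least-squares line through the points of every step whose
    increment exceeds ``step_rise`` mmol/L (both endpoints, each point
    once).  LT2 is the crossing of the two lines.  Times convert to BPM via
    the 30-s-averaged HR trace (defaults to interpolating the curve's own
    per-step HR values).
    """
    t, lac = curve.step_t, curve.lactate
    if t.size < 4:
        raise ValueError("need at least 4 lactate measurements")
    if hr_trace is None:
        hr_trace = (t, curve.hr)
    diag: dict = {}

    imin = int(np.argmin(lac))
    target = lac[imin] + lt1_offset
    lt1_t = None
    for j in range(imin + 1, t.size):
        if lac[j] >= target:
            if lac[j] == lac[j - 1]:
                lt1_t = float(t[j])
            else:
                lt1_t = float(
                    t[j - 1] + (t[j] - t[j - 1]) * (target - lac[j - 1]) / (lac[j] - lac[j - 1])
                )
            next_idx = j
            break
    if lt1_t is None:
        diag["reason"] = f"lactate never rises {lt1_offset} mmol/L above its minimum"
        return ThresholdResult("LT", None, None, diag)
    diag["lt1_time_s"] = lt1_t

    # fit A: exact line through the LT1 point and the following sample
    slope_a = (lac[next_idx] - target) / (t[next_idx] - lt1_t)
    inter_a = target - slope_a * lt1_t
    diag["fit_a"] = (float(slope_a), float(inter_a))

    # fit B: least squares through the endpoints of steep steps
    steep = np.flatnonzero(np.diff(lac) > step_rise)
    pts = sorted({int(i) for s in steep for i in (s, s + 1)})
    diag["fit_b_points"] = pts
    lt2_t = None
    if len(pts) >= 2:
        slope_b, inter_b = np.polyfit(t[pts], lac[pts], 1)
        diag["fit_b"] = (float(slope_b), float(inter_b))
        if slope_b != slope_a:
            lt2_t = float((inter_a - inter_b) / (slope_b - slope_a))
            diag["lt2_time_s"] = lt2_t
        else:
            diag["reason"] = "parallel lactate fits"
    else:
        diag["reason"] = "fewer than 2 points in the steep-rise fit"

    def to_bpm(ts: float | None) -> int | None:
        if ts is None:
            return None
        try:
            return int(np.rint(hr_at_time(ts, *hr_trace)))
        except ValueError:
            return None

    t1_bpm, t2_bpm = to_bpm(lt1_t), to_bpm(lt2_t)
    if lt1_t is not None:
        diag["t1_bpm_exact"] = hr_at_time(lt1_t, *hr_trace) if t1_bpm is not None else None
    if lt2_t is not None and t2_bpm is not None:
        diag["t2_bpm_exact"] = hr_at_time(lt2_t, *hr_trace)
    return ThresholdResult("LT", t1_bpm, t2_bpm, diag)
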