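"""Dynamical detrended fluctuation analysis (DDFA) of RR-interval series.

Conventional DFA characterises beat-to-beat correlations by a single
scaling exponent: the cumulative profile of the mean-subtracted intervals
is detrended in windows of ``s`` beats with a polynomial fit and the root
mean square residual F(s) grows as s**alpha.  DDFA resolves the exponent
in both time and scale: for each scale ``s`` a segment of length ``l = 5 s``
slides along the series, the second-order fluctuation function is evaluated
at scales ``s - 1``, ``s`` and ``s + 1`` inside the segment, and the local
exponent ``alpha(t, s)`` is the finite-difference derivative of log F with
respect to log s on that non-uniform three-point stencil.

alpha ~ 1 indicates 1/f-like long-range correlation (healthy heart at
rest), alpha = 0.5 uncorrelated intervals, alpha < 0.5 anticorrelation —
the regime reached during high-intensity exercise.

Implementation note: inside a segment the locally integrated profile
differs from the globally integrated one only by an affine function of beat
index, which a second-order polynomial fit annihilates.  Window residuals
are therefore computed once per window size on the global profile, and
per-segment fluctuation functions are assembled from prefix sums, making
the sliding evaluation exact and O(n) per scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import solveh_banded

from .series import RRISeries

__all__ = [
    "ScaleGrid",
    "DDFAField",
    "DFAalpha1Track",
    "dfa2_fluctuation",
    "local_alpha",
    "ddfa",
    "smoothness_priors_detrend",
    "alpha1_track",
]


# ---------------------------------------------------------------------------
# scale grid


@dataclass
class ScaleGrid:
    """Ordered unique integer DFA scales with logarithmic spacings.

    ``h_minus(s) = log s - log(s-1)`` and ``h_plus(s) = log(s+1) - log s``
    are the backward/forward spacings used by the finite-difference stencil.
    """

    scales: np.ndarray

    def __post_init__(self) -> None:
        s = np.unique(np.asarray(self.scales, dtype=int))
        if s.size == 0 or s.min() < 5:
            raise ValueError("scales must be integers >= 5")
        self.scales = s

    @classmethod
    def log_spaced(cls, lo: int = 5, hi: int = 64, n: int = 20) -> "ScaleGrid":
        """Round ``n`` log-spaced reals on [lo, hi] to integers, de-duplicated."""
        raw = np.geomspace(lo, hi, n)
        return cls(scales=np.unique(np.rint(raw).astype(int)))

    @property
    def h_minus(self) -> np.ndarray:
        s = self.scales.astype(float)
        return np.log(s) - np.log(s - 1)

    @property
    def h_plus(self) -> np.ndarray:
        s = self.scales.astype(float)
        return np.log(s + 1) - np.log(s)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class DDFAField:
    """Time- and scale-resolved scaling exponents alpha(t, s).

    ``alpha`` and ``seg_hr`` are (n_beats, n_scales) arrays over the
    gap-closed retained-beat index; entries are NaN where a full centred
    segment of length ``seg_len[j] = 5 * scales[j]`` does not fit.
    ``time_s`` carries the retained beats' original cumulative times.
    """

    scales: np.ndarray
    seg_len: np.ndarray
    alpha: np.ndarray
    seg_hr: np.ndarray
    time_s: np.ndarray

    @property
    def n_beats(self) -> int:
        return self.alpha.shape[0]

    def mean_alpha(self, scale: int) -> float:
        """Mean exponent over time at one scale, ignoring undefined entries."""
        j = int(np.flatnonzero(self.scales == scale)[0])
        col = self.alpha[:, j]
        return float(np.nanmean(col))

    def to_dataframe(self):
        """Long-format table (t_index, time_s, scale, alpha, seg_hr)."""
        import pandas as pd

        t_idx, s_idx = np.nonzero(np.isfinite(self.alpha))
        return pd.DataFrame(
            {
                "t_index": t_idx,
                "time_s": self.time_s[t_idx],
                "scale": self.scales[s_idx],
                "alpha": self.alpha[t_idx, s_idx],
                "seg_hr": self.seg_hr[t_idx, s_idx],
            }
        )


@dataclass
class DFAalpha1Track:
    """Short-term DFA exponent evaluated on a regular time grid.

    One evaluation per ``step`` seconds, each using the beats inside a
    ``window``-second segment; ``alpha1`` is NaN where the window holds too
    few beats.
    """

    t_grid: np.ndarray
    alpha1: np.ndarray
    seg_hr: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.t_grid, "alpha1": self.alpha1, "seg_hr": self.seg_hr}
        )


# ---------------------------------------------------------------------------
# fluctuation functions


def _poly_basis(w: int, order: int) -> np.ndarray:
    """Orthonormal basis (w x (order+1)) of polynomials on indices 0..w-1."""
    v = np.vander(np.arange(w, dtype=float), order + 1, increasing=True)
    q, _ = np.linalg.qr(v)
    return q


def _window_rss(profile: np.ndarray, w: int, order: int = 2) -> np.ndarray:
    """Residual sum of squares of an order-``order`` polynomial fit in every
    maximally overlapping window of ``w`` consecutive profile points.

    Returned array has length ``len(profile) - w + 1``. Residuals are formed
    explicitly (not by norm subtraction) to avoid cancellation.
    """
    q = _poly_basis(w, order)
    wins = sliding_window_view(profile, w)
    coef = wins @ q
    resid = wins - coef @ q.T
    return np.einsum("ij,ij->i", resid, resid)


def dfa2_fluctuation(segment, scale: int, order: int = 2) -> float:
    """Second-order DFA fluctuation function F(s) of one interval segment.

    The profile is the cumulative sum of the mean-subtracted intervals; in
    every window of ``scale`` consecutive profile points (stride 1, i.e.
    maximally overlapping) an order-2 polynomial is fitted and
    ``F(s) = sqrt(mean over windows of mean squared residual)``.

    Returns NaN (not an exception) when the segment is too short or the
    scale too small for the fit, so time edges degrade gracefully.
    """
    x = np.asarray(segment, dtype=float)
    if scale < order + 2 or x.size < scale:
        return float("nan")
    profile = np.cumsum(x - x.mean())
    rss = _window_rss(profile, int(scale), order)
    return float(np.sqrt(np.mean(rss) / scale))


def local_alpha(logF_minus, logF_0, logF_plus, s):
    """Finite-difference scaling exponent at scale ``s``.

    First derivative of log F with respect to log s on the non-uniform
    three-point stencil (s-1, s, s+1)::

        alpha = [h-^2 F~(s+1) + (h+^2 - h-^2) F~(s) - h+^2 F~(s-1)]
                / [h- h+ (h+ + h-)]

    with ``F~ = log F``, ``h- = log s - log(s-1)``, ``h+ = log(s+1) - log s``.
    Non-finite inputs yield NaN. Accepts scalars or broadcastable arrays.
    """
    fm = np.asarray(logF_minus, dtype=float)
    f0 = np.asarray(logF_0, dtype=float)
    fp = np.asarray(logF_plus, dtype=float)
    s = np.asarray(s, dtype=float)
    hm = np.log(s) - np.log(s - 1)
    hp = np.log(s + 1) - np.log(s)
    with np.errstate(invalid="ignore"):
        a = (hm**2 * fp + (hp**2 - hm**2) * f0 - hp**2 * fm) / (hm * hp * (hp + hm))
    a = np.where(np.isfinite(fm) & np.isfinite(f0) & np.isfinite(fp), a, np.nan)
    return float(a) if a.ndim == 0 else a


# ---------------------------------------------------------------------------
# the DDFA field


def ddfa(
    series: RRISeries,
    grid: ScaleGrid | None = None,
    segment_factor: int = 5,
    hop: int = 1,
    centered: bool = True,
    order: int = 2,
) -> DDFAField:
    """Compute the DDFA field alpha(t, s) of a preprocessed series.

    For each scale ``s`` in the grid a segment of ``segment_factor * s``
    beats slides along the gap-closed retained sequence with stride ``hop``
    (centred on ``t`` by default, trailing with ``centered=False``);
    fluctuation functions at s-1, s, s+1 inside the segment give the local
    exponent via :func:`local_alpha`.  ``seg_hr`` is ``60000 / mean RR`` of
    the segment in BPM.
    """
    if grid is None:
        grid = ScaleGrid.log_spaced()
    work = series.compact()
    x = work.intervals
    n = x.size
    l_min = segment_factor * int(grid.scales.min())
    if n < l_min:
        raise ValueError(
            f"insufficient data: {n} retained beats < minimum segment {l_min}"
        )

    # per-window residuals on the global profile, one array per window size
    profile = np.cumsum(x - x.mean())
    sizes = sorted({int(w) for s in grid.scales for w in (s - 1, s, s + 1)})
    rss_cum: dict[int, np.ndarray] = {}
    for w in sizes:
        if n >= w:
            r = _window_rss(profile, w, order)
            rss_cum[w] = np.concatenate(([0.0], np.cumsum(r)))
    x_cum = np.concatenate(([0.0], np.cumsum(x)))

    S = grid.scales.size
    alpha = np.full((n, S), np.nan)
    seg_hr = np.full((n, S), np.nan)
    for j, s in enumerate(grid.scales):
        s = int(s)
        l = segment_factor * s
        if n < l:
            continue
        off = l // 2 if centered else l - 1
        t = np.arange(off, n - l + off + 1, hop)
        a = t - off  # segment start indices
        logF = np.empty((t.size, 3))
        ok = np.ones(t.size, dtype=bool)
        for k, w in enumerate((s - 1, s, s + 1)):
            cum = rss_cum[w]
            nwin = l - w + 1
            mean_rss = (cum[a + nwin] - cum[a]) / nwin
            F = np.sqrt(mean_rss / w)
            with np.errstate(divide="ignore"):
                logF[:, k] = np.log(F)
            ok &= F > 0
        vals = local_alpha(logF[:, 0], logF[:, 1], logF[:, 2], s)
        alpha[t, j] = np.where(ok, vals, np.nan)
        seg_hr[t, j] = 60000.0 / ((x_cum[a + l] - x_cum[a]) / l)
    return DDFAField(
        scales=grid.scales.copy(),
        seg_len=segment_factor * grid.scales,
        alpha=alpha,
        seg_hr=seg_hr,
        time_s=work.t_cum.copy(),
    )


# ---------------------------------------------------------------------------
# smoothness-priors detrending and the conventional alpha1 track


def smoothness_priors_detrend(values, lam: float = 500.0) -> np.ndarray:
    """Remove the smooth trend solving ``(I + lam^2 D2' D2) trend = z``.

    ``D2`` is the second-difference operator, so the trend is a discrete
    smoothing spline whose stiffness grows with ``lam``; ``lam = 0`` returns
    all zeros (the trend equals the signal).  Standard detrending step for
    RR series prior to short-term DFA.
    """
    z = np.asarray(values, dtype=float)
    if z.size < 3:
        raise ValueError("smoothness priors detrending needs >= 3 points")
    if lam == 0:
        return np.zeros_like(z)
    m = z.size
    lam2 = float(lam) ** 2
    # pentadiagonal symmetric banded matrix I + lam^2 D2'D2, upper form
    ab = np.zeros((3, m))
    ab[0, 2:] = lam2  # second superdiagonal
    diag = np.full(m, 6.0 * lam2)
    diag[[0, -1]] = lam2
    diag[[1, -2]] = 5.0 * lam2
    if m == 3:  # single interior point: D2'D2 central entry is 4
        diag[1] = 4.0 * lam2
    ab[2] = 1.0 + diag
    sup1 = np.full(m - 1, -4.0 * lam2)
    sup1[[0, -1]] = -2.0 * lam2
    ab[1, 1:] = sup1
    trend = solveh_banded(ab, z)
    return z - trend


def alpha1_track(
    series: RRISeries,
    step: float = 5.0,
    window: float = 120.0,
    lam: float = 500.0,
    scales=range(4, 17),
    order: int = 1,
) -> DFAalpha1Track:
    """Short-term DFA exponent every ``step`` seconds in ``window``-second segments.

    Each evaluation detrends the window's intervals with smoothness priors
    (``lam``), computes fluctuation functions over ``scales`` beats (4-16 by
    default) and takes alpha1 as the least-squares slope of log F versus
    log s.  ``seg_hr`` is the window's mean heart rate.  Windows holding
    fewer than ``max(scales) + 2`` beats yield NaN.
    """
    work = series.compact()
    t = work.t_cum
    if t[-1] - t[0] < window:
        raise ValueError(f"series spans {t[-1] - t[0]:.1f} s < window {window} s")
    scales = np.asarray(list(scales), dtype=int)
    half = window / 2.0
    t_grid = np.arange(t[0] + half, t[-1] - half + 1e-9, step)
    a1 = np.full(t_grid.size, np.nan)
    hr = np.full(t_grid.size, np.nan)
    log_s = np.log(scales.astype(float))
    for i, te in enumerate(t_grid):
        lo = np.searchsorted(t, te - half, side="left")
        hi = np.searchsorted(t, te + half, side="right")
        xw = work.intervals[lo:hi]
        if xw.size < scales.max() + 2:
            continue
        hr[i] = 60000.0 / xw.mean()
        detr = smoothness_priors_detrend(xw, lam)
        F = np.array([dfa2_fluctuation(detr, int(s), order) for s in scales])
        good = np.isfinite(F) & (F > 0)
        if np.count_nonzero(good) < 2:
            continue
        a1[i] = np.polyfit(log_s[good], np.log(F[good]), 1)[0]
    return DFAalpha1Track(t_grid=t_grid, alpha1=a1, seg_hr=hr)
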