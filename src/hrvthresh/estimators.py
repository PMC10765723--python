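"""Scikit-learn-style estimators over the threshold pipeline.

Each estimator follows the fit / fitted-attribute convention
(``get_params``/``set_params`` via :class:`sklearn.base.BaseEstimator`,
results in trailing-underscore attributes), so the classes compose with
sklearn tooling even though the sample objects are domain containers
(:class:`~hrvthresh.series.RRISeries`, :class:`~hrvthresh.thresholds.LactateCurve`)
rather than feature matrices.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from . import thresholds as _thr  # module import is safe: name not rebound
from .ddfa import ScaleGrid
from .ddfa import alpha1_track as _alpha1_track
from .ddfa import ddfa as _ddfa_field
from .preprocess import preprocess as _preprocess
from .series import RRISeries
from .thresholds import LactateCurve, ThresholdResult

__all__ = [
    "RRIPreprocessor",
    "DDFAThresholdEstimator",
    "DFAAlpha1ThresholdEstimator",
    "HRMaxThresholdEstimator",
    "LactateThresholdEstimator",
]


class RRIPreprocessor(BaseEstimator):
    """Range + windowed-median artifact filter as a transformer.

    Parameters mirror :func:`hrvthresh.preprocess.preprocess`. ``transform``
    returns the flagged series; ``report_`` holds the per-stage removal
    counts of the last transform.
    """

    def __init__(self, lo=200.0, hi=2000.0, kernel=7, frac=0.10, manual_exclude=None):
        self.lo = lo
        self.hi = hi
        self.kernel = kernel
        self.frac = frac
        self.manual_exclude = manual_exclude

    def fit(self, X: RRISeries, y=None):
        del y
        self.transform(X)
        return self

    def transform(self, X: RRISeries) -> RRISeries:
        out, report = _preprocess(
            X,
            lo=self.lo,
            hi=self.hi,
            kernel=self.kernel,
            frac=self.frac,
            manual_exclude=self.manual_exclude,
        )
        self.report_ = report
        return out

    def fit_transform(self, X: RRISeries, y=None) -> RRISeries:
        del y
        return self.transform(X)


class _ThresholdEstimatorBase(BaseEstimator):
    """Shared fitted-attribute plumbing for the four threshold methods."""

    result_: ThresholdResult

    def _finish(self, result: ThresholdResult):
        self.result_ = result
        self.t1_bpm_ = result.t1_bpm
        self.t2_bpm_ = result.t2_bpm
        self.diagnostics_ = result.diagnostics
        return self


class DDFAThresholdEstimator(_ThresholdEstimatorBase):
    """Thresholds from time- and scale-resolved DDFA scaling exponents.

    ``fit`` expects a *preprocessed* :class:`RRISeries` (pass it through
    :class:`RRIPreprocessor` first, or set ``preprocess=True`` to apply the
    default filters).  The pipeline is: DDFA field over the log-spaced
    scale grid, integer-HR binning, per-scale baseline from the lowest-HR
    bins, scale averaging, mean filtering, and the stable-run threshold
    scan.

    Attributes set by fit: ``field_``, ``profile_``, ``baseline_``,
    ``curve_``, ``t1_bpm_``, ``t2_bpm_``, ``result_``.
    """

    def __init__(
        self,
        scale_min=5,
        scale_max=64,
        n_scales=20,
        segment_factor=5,
        hop=1,
        centered=True,
        baseline_bins=25,
        smooth_kernel=10,
        run=10,
        level2=-0.5,
        preprocess=False,
    ):
        self.scale_min = scale_min
        self.scale_max = scale_max
        self.n_scales = n_scales
        self.segment_factor = segment_factor
        self.hop = hop
        self.centered = centered
        self.baseline_bins = baseline_bins
        self.smooth_kernel = smooth_kernel
        self.run = run
        self.level2 = level2
        self.preprocess = preprocess

    def fit(self, X: RRISeries, y=None):
        del y
        if self.preprocess:
            X, _ = _preprocess(X)
        grid = ScaleGrid.log_spaced(self.scale_min, self.scale_max, self.n_scales)
        self.field_ = _ddfa_field(
            X,
            grid,
            segment_factor=self.segment_factor,
            hop=self.hop,
            centered=self.centered,
        )
        self.profile_ = _thr.bin_by_hr(self.field_)
        self.baseline_ = _thr.compute_baseline(self.profile_, n_bins=self.baseline_bins)
        self.curve_ = _thr.smoothed_alpha(
            self.profile_, self.baseline_, kernel=self.smooth_kernel
        )
        return self._finish(
            _thr.ddfa_thresholds(
                self.curve_,
                run=self.run,
                level2=self.level2,
                search_start=self.baseline_bins,
            )
        )


class DFAAlpha1ThresholdEstimator(_ThresholdEstimatorBase):
    """Thresholds from the short-term DFA exponent's decline with HR.

    Computes the alpha1 track (one evaluation per ``step`` seconds in
    ``window``-second segments, smoothness-priors detrended with ``lam``)
    and applies the regression-region crossing rule at the ``band`` edges.
    """

    def __init__(self, step=5.0, window=120.0, lam=500.0, order=1,
                 band=(0.5, 0.75), gap_n=4):
        self.step = step
        self.window = window
        self.lam = lam
        self.order = order
        self.band = band
        self.gap_n = gap_n

    def fit(self, X: RRISeries, y=None):
        del y
        self.track_ = _alpha1_track(
            X, step=self.step, window=self.window, lam=self.lam, order=self.order
        )
        return self._finish(
            _thr.dfa_alpha1_thresholds(self.track_, gap_n=self.gap_n, band=self.band)
        )


class HRMaxThresholdEstimator(_ThresholdEstimatorBase):
    """Fixed-percentage-of-HRmax thresholds (defaults 70% and 85%)."""

    def __init__(self, p1=0.70, p2=0.85):
        self.p1 = p1
        self.p2 = p2

    def fit(self, X: float, y=None):
        del y
        return self._finish(_thr.hrmax_thresholds(float(X), p1=self.p1, p2=self.p2))


class LactateThresholdEstimator(_ThresholdEstimatorBase):
    """Two-slope lactate protocol on an incremental-test lactate curve."""

    def __init__(self, lt1_offset=0.3, step_rise=0.8, hr_trace=None):
        self.lt1_offset = lt1_offset
        self.step_rise = step_rise
        self.hr_trace = hr_trace

    def fit(self, X: LactateCurve, y=None):
        del y
        return self._finish(
            _thr.lactate_thresholds(
                X,
                hr_trace=self.hr_trace,
                lt1_offset=self.lt1_offset,
                step_rise=self.step_rise,
            )
        )
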