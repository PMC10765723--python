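"""Synthetic incremental-exercise data with planted statistical structure.

The generators emulate an incremental cyclo-ergometer test: a monotone
heart-rate ramp (by default 110 to 200 BPM over 25 minutes), beat-to-beat
fluctuations whose local scaling exponent follows a prescribed schedule
(1/f-like correlation at rest decaying to anticorrelation at high HR),
injected missed-/extra-beat artifacts, and step-wise lactate curves with
planted threshold times.  They target statistical structure only — there is
no cardiovascular modelling (baroreflex, respiratory coupling) — so passing
recovery tests demonstrates estimator correctness on series with the
prescribed correlation structure, not clinical validity.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import RRISeries
from .thresholds import LactateCurve

__all__ = [
    "SyntheticSpec",
    "LactateSpec",
    "gen_fgn",
    "gen_exercise_rri",
    "gen_lactate_curve",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def _fgn_circulant(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn by circulant embedding of the autocovariance (Davies-Harte)."""
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    if np.any(eig < -1e-9 * eig.max()):
        raise FloatingPointError("circulant embedding not nonnegative definite")
    eig = np.clip(eig, 0.0, None)
    m = row.size
    z = rng.normal(size=m // 2 + 1) + 1j * rng.normal(size=m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2)
    if m % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2)
    w = np.sqrt(eig / (2 * m)) * z
    return np.fft.irfft(w, n=m)[:n] * np.sqrt(m / 2.0) * np.sqrt(2)


def _spectral_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^beta noise by Fourier synthesis, unit variance."""
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-beta / 2.0)
    z = rng.normal(size=f.size) + 1j * rng.normal(size=f.size)
    x = np.fft.irfft(amp * z, n=n)
    return (x - x.mean()) / x.std()


def gen_fgn(n: int, hurst: float, seed=None) -> np.ndarray:
    """Stationary sequence with DFA exponent ``hurst`` over scales 5-64.

    For ``hurst`` in (0, 1) this is exact fractional Gaussian noise by
    circulant embedding; at and above 1 (up to 1.2) the autocovariance
    degenerates and the sequence is synthesised spectrally with power
    spectral density f**-(2H-1), which has the same scaling behaviour.
    """
    if not 0 < hurst <= 1.2:
        raise ValueError(f"hurst must lie in (0, 1.2], got {hurst}")
    if n < 64:
        raise ValueError("n must be >= 64")
    rng = np.random.default_rng(seed)
    if hurst < 0.995:
        try:
            x = _fgn_circulant(n, hurst, rng)
            return (x - x.mean()) / x.std()
        except FloatingPointError:
            pass
    return _spectral_noise(n, 2 * hurst - 1, rng)


# ---------------------------------------------------------------------------
# exercise RRI series


def _default_schedule() -> list:
    return [(145.0, 1.0), (195.0, 0.0)]


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic incremental exercise test.

    ``alpha_schedule`` maps HR to the target scaling exponent as a
    non-increasing piecewise-linear function given by (HR, alpha) knots;
    values are held constant outside the knot range.  The default plants a
    resting exponent of 1.0 up to 145 BPM decaying linearly to 0 at
    195 BPM, which puts the baseline-subtracted curve at -0.5 around
    170 BPM.  ``fluct_sd`` is the beat-to-beat fluctuation magnitude in ms;
    ``artifact_rates`` are per-beat probabilities of a missed beat (two
    intervals merged) and an extra beat (one interval split).
    """

    duration: float = 1500.0
    hr_start: float = 110.0
    hr_end: float = 200.0
    alpha_schedule: list = field(default_factory=_default_schedule)
    fluct_sd: float = 10.0
    artifact_rates: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (30 <= self.hr_start <= self.hr_end <= 300):
            raise ValueError("require 30 <= hr_start <= hr_end <= 300 BPM")
        if any(not 0 <= p <= 0.05 for p in self.artifact_rates):
            raise ValueError("artifact rates must lie in [0, 0.05]")
        knots = sorted(self.alpha_schedule)
        alphas = [a for _, a in knots]
        if any(a2 > a1 + 1e-12 for a1, a2 in zip(alphas, alphas[1:])):
            raise ValueError("alpha_schedule must be non-increasing in HR")
        self.alpha_schedule = knots

    def alpha_at(self, hr) -> np.ndarray:
        hs = np.array([h for h, _ in self.alpha_schedule])
        als = np.array([a for _, a in self.alpha_schedule])
        return np.interp(hr, hs, als)


def _expected_mean_alpha(beta: float, scales: tuple, n_psd: int = 32768) -> float:
    """Exact expected DDFA-2 exponent (mean over ``scales``) of a stationary
    Gaussian process with power spectrum f**-beta.

    The autocovariance is the inverse transform of the spectrum; the
    expected window residual of the order-2 fit is a quadratic form in the
    profile covariance, and the exponent follows from the same three-point
    log-derivative stencil the analysis uses.
    """
    f = np.fft.rfftfreq(n_psd)
    S = np.zeros_like(f)
    S[1:] = f[1:] ** (-beta)
    gamma = np.fft.irfft(S, n=n_psd)[: 2 * max(scales) + 4]
    gamma = gamma / gamma[0]
    logF: dict[int, float] = {}
    for w in sorted({int(w) for s in scales for w in (s - 1, s, s + 1)}):
        i = np.arange(w)
        V = np.vander(i.astype(float), 3, increasing=True)
        H = V @ np.linalg.solve(V.T @ V, V.T)
        Sig_inc = gamma[np.abs(np.subtract.outer(i, i))]
        A = np.tril(np.ones((w, w)))
        Sig_prof = A @ Sig_inc @ A.T
        rss = np.trace((np.eye(w) - H) @ Sig_prof)
        logF[w] = 0.5 * np.log(rss / w)
    alphas = []
    for s in scales:
        hm = np.log(s) - np.log(s - 1)
        hp = np.log(s + 1) - np.log(s)
        alphas.append(
            (
                hm**2 * logF[s + 1]
                + (hp**2 - hm**2) * logF[s]
                - hp**2 * logF[s - 1]
            )
            / (hm * hp * (hp + hm))
        )
    return float(np.mean(alphas))


_RESPONSE_CACHE: dict = {}


def _alpha_to_beta(target_alpha: np.ndarray) -> np.ndarray:
    """Invert the estimator's exponent response: spectrum slopes beta such
    that the expected measured DDFA exponent equals ``target_alpha``.

    The forward map (mean expected exponent over the standard 5-64 scale
    grid as a function of beta) is computed exactly once and inverted by
    monotone interpolation; targets outside the attainable range clip to
    the table ends.
    """
    scales = tuple(np.unique(np.rint(np.geomspace(5, 64, 20))).astype(int))
    if scales not in _RESPONSE_CACHE:
        betas = np.linspace(-1.3, 1.6, 59)
        g = np.array([_expected_mean_alpha(b, scales) for b in betas])
        _RESPONSE_CACHE[scales] = (g, betas)
    g, betas = _RESPONSE_CACHE[scales]
    return np.interp(target_alpha, g, betas)


def _tv_spectral_noise(
    target_alpha: np.ndarray,
    rng: np.random.Generator,
    alpha_step: float = 0.01,
) -> np.ndarray:
    """Unit-variance noise whose local scaling exponent tracks ``target_alpha``.

    One complex Gaussian spectrum is drawn once; for every (quantised)
    exponent value the same spectrum is shaped with power-law amplitude
    ``f**(-beta/2)``, ``beta = 2 alpha - 1``, transformed back and
    normalised, and beat ``k`` takes its value from the realisation shaped
    with its own target exponent.  Because all realisations share the
    Fourier phases, neighbouring beats with nearby targets are nearly
    identical and the local correlation structure varies smoothly with no
    seams, while any stretch of constant target is exactly a stationary
    power-law-spectrum Gaussian process.
    """
    n = target_alpha.size
    aq = np.round(np.clip(target_alpha, 0.0, 1.2) / alpha_step) * alpha_step
    uniq, inv = np.unique(aq, return_inverse=True)
    uniq_beta = _alpha_to_beta(uniq)
    f = np.fft.rfftfreq(n)
    z = rng.normal(size=f.size) + 1j * rng.normal(size=f.size)
    out = np.empty(n)
    for u, beta in enumerate(uniq_beta):
        amp = np.zeros_like(f)
        amp[1:] = f[1:] ** (-beta / 2.0)
        x = np.fft.irfft(amp * z, n=n)
        x = (x - x.mean()) / x.std()
        rows = inv == u
        out[rows] = x[rows]
    return out


def gen_exercise_rri(
    spec: SyntheticSpec, return_info: bool = False
) -> RRISeries | tuple[RRISeries, dict]:
    """Synthetic RR-interval series for an incremental test.

    The mean interval follows ``60000 / HR(t)`` along the linear ramp from
    ``hr_start`` to ``hr_end``; fluctuations are power-law-spectrum noise
    whose local exponent follows the schedule at the planned HR (shared-
    phase spectral synthesis, calibrated so the scheduled exponent is what
    the DDFA functional measures).
    Clean intervals are clipped to the physiological 200-2000 ms range
    before artifact injection, so every preprocessing removal is
    attributable to a planted artifact.  With ``return_info=True`` a dict
    with the planted per-beat HR/exponent and final-series artifact indices
    is returned alongside.
    """
    rng = np.random.default_rng(spec.seed)
    # plan the clean beat grid on the noise-free ramp
    hrs: list[float] = []
    t = 0.0
    while t < spec.duration:
        hr = spec.hr_start + (spec.hr_end - spec.hr_start) * t / spec.duration
        hrs.append(hr)
        t += 60.0 / hr
    hr_beat = np.asarray(hrs)
    n = hr_beat.size
    target_h = spec.alpha_at(hr_beat)
    fluct = _tv_spectral_noise(target_h, rng)
    rri = 60000.0 / hr_beat + spec.fluct_sd * fluct
    rri = np.clip(rri, 200.0, 2000.0)

    p_miss, p_extra = spec.artifact_rates
    intervals: list[float] = []
    artifact_idx: list[int] = []
    i = 0
    while i < n:
        u = rng.random()
        if u < p_miss and i + 1 < n:
            artifact_idx.append(len(intervals))
            intervals.append(rri[i] + rri[i + 1])
            i += 2
        elif u < p_miss + p_extra:
            split = rng.uniform(0.0, 1.0)
            artifact_idx.extend([len(intervals), len(intervals) + 1])
            intervals.extend([rri[i] * split, rri[i] * (1 - split)])
            i += 1
        else:
            intervals.append(rri[i])
            i += 1
    series = RRISeries.from_intervals(np.asarray(intervals))
    if not return_info:
        return series
    info = {
        "hr_clean": hr_beat,
        "target_alpha": target_h,
        "artifact_idx": np.asarray(artifact_idx, dtype=int),
        "n_clean": n,
    }
    return series, info


# ---------------------------------------------------------------------------
# lactate curves


@dataclass
class LactateSpec:
    """A step-test lactate curve with planted threshold times.

    The curve dips to its minimum at the second step, rises gently so the
    ``+0.3 mmol/L`` crossing lands exactly at ``lt1_time``, then breaks to
    a steep rise of ``rise_rate`` mmol/L per step at ``lt2_time`` (snapped
    to a step boundary), so that the two-slope protocol recovers both
    planted times exactly at zero noise.
    """

    n_steps: int = 9
    step_s: float = 180.0
    baseline: float = 1.2
    lt1_time: float = 810.0
    lt2_time: float = 1260.0
    rise_rate: float = 1.2
    noise_sd: float = 0.0
    hr_start: float = 115.0
    hr_end: float = 195.0
    dip: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        total = self.n_steps * self.step_s
        if not (2 * self.step_s < self.lt1_time < self.lt2_time < total):
            raise ValueError("need 2*step_s < lt1_time < lt2_time < n_steps*step_s")
        if self.rise_rate <= 0.8:
            raise ValueError("rise_rate must exceed 0.8 mmol/L per step")
        slope1 = 0.3 / (self.lt1_time - 2 * self.step_s)
        if slope1 * self.step_s >= 0.8:
            raise ValueError("gentle rise would itself qualify as a steep step")


def gen_lactate_curve(spec: LactateSpec) -> LactateCurve:
    """Build the lactate curve described by ``spec``.

    At ``noise_sd = 0`` the two-slope protocol applied to the result yields
    the planted ``lt1_time`` and ``lt2_time`` exactly (the breakpoint is
    snapped to the nearest step boundary).
    """
    rng = np.random.default_rng(spec.seed)
    step_t = spec.step_s * np.arange(1, spec.n_steps + 1)
    t_min = 2 * spec.step_s
    t_break = spec.step_s * round(spec.lt2_time / spec.step_s)
    slope1 = 0.3 / (spec.lt1_time - t_min)
    slope2 = spec.rise_rate / spec.step_s
    v_break = spec.baseline + slope1 * (t_break - t_min)
    lac = np.empty(spec.n_steps)
    for i, t in enumerate(step_t):
        if t < t_min:
            lac[i] = spec.baseline + spec.dip
        elif t <= t_break:
            lac[i] = spec.baseline + slope1 * (t - t_min)
        else:
            lac[i] = v_break + slope2 * (t - t_break)
    if spec.noise_sd > 0:
        lac = np.maximum(lac + rng.normal(0.0, spec.noise_sd, lac.size), 0.05)
    hr = spec.hr_start + (spec.hr_end - spec.hr_start) * (
        step_t - step_t[0]
    ) / (step_t[-1] - step_t[0])
    return LactateCurve(step_t=step_t, lactate=lac, hr=hr)
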