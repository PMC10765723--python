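"""Agreement and consistency statistics for paired threshold estimates.

For each estimator-versus-benchmark pairing the framework reports the
Pearson correlation with a one-sided permutation p-value and a BCa
bootstrap lower confidence bound, Bland-Altman limits of agreement
(mean difference +/- 1.96 sample standard deviations), a Monte-Carlo test
of proportional bias (the regression slope of the differences against HR
compared with slopes of uncorrelated normal differences of the observed
spread), and a Shapiro-Wilk normality check of the differences.

All resampling honours an explicit seed; permutation and Monte-Carlo
p-values use the add-one estimator ``(1 + #extreme) / (n + 1)`` and are
therefore never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, ndtri

__all__ = [
    "ComparisonStats",
    "pearson_permutation",
    "bland_altman",
    "slope_mc_test",
    "bca_ci",
    "compare_table",
]


@dataclass
class ComparisonStats:
    """One row of the method-versus-benchmark agreement table."""

    method: str
    threshold: int
    r: float
    r_lb95: float
    p_corr: float
    mu_diff: float
    loa_lo: float
    loa_hi: float
    p_slope: float
    p_norm: float


def _pearson(x: np.ndarray, y: np.ndarray):
    """Pearson r, reducing along the last axis (broadcasts over resamples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = np.sum(xc * yc, axis=-1)
    den = np.sqrt(np.sum(xc**2, axis=-1) * np.sum(yc**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return float(r) if np.ndim(r) == 0 else r


def pearson_permutation(
    x, y, n_perm: int = 10_000, seed=None
) -> tuple[float, float]:
    """Pearson r with a one-sided (positive association) permutation p-value.

    ``p = (1 + #{permutations with r* >= r}) / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r = _pearson(x, y)
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
    r_null = perms @ xc / denom
    p = (1 + int(np.count_nonzero(r_null >= r))) / (n_perm + 1)
    return r, p


def bland_altman(diff) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 sample sd)."""
    diff = np.asarray(diff, dtype=float)
    if diff.size < 2:
        raise ValueError("need at least 2 differences")
    mu = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return mu, mu - 1.96 * sd, mu + 1.96 * sd


def slope_mc_test(hr_mean, diff, n_mc: int = 10_000, seed=None) -> float:
    """Monte-Carlo p-value for proportional bias of the differences.

    The statistic is the absolute OLS slope of ``diff`` on ``hr_mean``; the
    null draws are iid normal differences with the observed sample standard
    deviation at the same abscissae.  A high p-value means the slope is
    consistent with uncorrelated differences (no trend across the HR range).
    """
    x = np.asarray(hr_mean, dtype=float)
    d = np.asarray(diff, dtype=float)
    if x.shape != d.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 points")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("degenerate abscissae: hr_mean has zero variance")
    obs = abs(xc @ (d - d.mean()) / sxx)
    sd = d.std(ddof=1)
    rng = np.random.default_rng(seed)
    sim = rng.normal(0.0, sd, size=(n_mc, d.size)) if sd > 0 else np.zeros((n_mc, d.size))
    sim = sim - sim.mean(axis=1, keepdims=True)
    slopes = np.abs(sim @ xc / sxx)
    return (1 + int(np.count_nonzero(slopes >= obs))) / (n_mc + 1)


def bca_ci(
    stat,
    sample,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed=None,
    vectorized: bool = False,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    ``sample`` is one array or a tuple of equal-length arrays resampled
    jointly (paired resampling); ``stat`` receives the resampled array(s).
    With ``vectorized=True`` the statistic must reduce along the last axis
    and is handed all resamples at once.  The bias correction ``z0`` comes
    from the bootstrap distribution's fraction below the point estimate,
    the acceleration ``a`` from the jackknife skewness.
    """
    arrays = sample if isinstance(sample, tuple) else (np.asarray(sample, dtype=float),)
    arrays = tuple(np.asarray(a, dtype=float) for a in arrays)
    n = arrays[0].size
    if n < 3:
        raise ValueError("sample size must be >= 3")

    def ev(idx):
        parts = tuple(a[idx] for a in arrays)
        return stat(*parts) if isinstance(sample, tuple) else stat(parts[0])

    theta = ev(np.arange(n))
    rng = np.random.default_rng(seed)
    if vectorized:
        boot = np.asarray(ev(rng.integers(0, n, size=(n_boot, n))))
    else:
        boot = np.empty(n_boot)
        for b in range(n_boot):
            boot[b] = ev(rng.integers(0, n, size=n))
    boot = boot[np.isfinite(boot)]  # degenerate resamples (zero variance) excluded
    if boot.size == 0 or np.ptp(boot) == 0:
        warnings.warn("statistic constant across resamples; degenerate interval",
                      stacklevel=2)
        v = float(boot[0]) if boot.size else float(theta)
        return v, v

    frac = np.mean(boot < theta)
    frac = min(max(frac, 1.0 / (n_boot + 1)), 1 - 1.0 / (n_boot + 1))
    z0 = ndtri(frac)
    jack = np.array([ev(np.delete(np.arange(n), i)) for i in range(n)])
    jm = jack.mean()
    denom = np.sum((jm - jack) ** 2) ** 1.5
    a = np.sum((jm - jack) ** 3) / (6 * denom) if denom > 0 else 0.0
    alpha = (1 - level) / 2
    out = []
    for q in (alpha, 1 - alpha):
        zq = ndtri(q)
        adj = ndtr(z0 + (z0 + zq) / (1 - a * (z0 + zq)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


def compare_table(
    estimates: pd.DataFrame,
    benchmark: str = "LT",
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    n_mc: int = 10_000,
    seed=None,
    abscissa: str = "mean",
) -> pd.DataFrame:
    """Agreement statistics of every method column against the benchmark.

    ``estimates`` holds one row per subject with columns ``{method}{k}``
    for k in {1, 2} (e.g. ``LT1, VT1, DDFAT1, LT2, ...``).  Each non-
    benchmark method yields one :class:`ComparisonStats` row per threshold.
    ``abscissa`` selects the Bland-Altman x-axis for the slope test:
    ``"mean"`` (pairwise mean of method and benchmark, the conventional
    choice) or ``"benchmark"``.  Rows with missing cells are skipped with a
    warning.  Child seeds are spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    methods = sorted(
        {c[:-1] for c in estimates.columns if c[-1] in "12" and c[:-1] != benchmark},
        key=lambda m: [c[:-1] for c in estimates.columns].index(m),
    )
    rows = []
    for k in (1, 2):
        bench_col = f"{benchmark}{k}"
        for m in methods:
            col = f"{m}{k}"
            if col not in estimates.columns or bench_col not in estimates.columns:
                continue
            x = estimates[col].to_numpy(dtype=float)
            y = estimates[bench_col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if not ok.all():
                warnings.warn(f"{col}: missing cells; row skipped", stacklevel=2)
                continue
            # canonical subject order: output does not depend on row order
            canon = np.lexsort((x, y))
            x, y = x[canon], y[canon]
            s_perm, s_boot, s_mc = ss.spawn(3)
            r, p_corr = pearson_permutation(x, y, n_perm=n_perm, seed=s_perm)
            r_lb, _ = bca_ci(
                _pearson, (x, y), n_boot=n_boot, seed=s_boot, vectorized=True
            )
            diff = x - y
            mu, lo, hi = bland_altman(diff)
            hx = (x + y) / 2.0 if abscissa == "mean" else y
            p_slope = slope_mc_test(hx, diff, n_mc=n_mc, seed=s_mc)
            p_norm = float(sps.shapiro(diff).pvalue)
            rows.append(
                ComparisonStats(
                    method=m, threshold=k, r=r, r_lb95=r_lb, p_corr=p_corr,
                    mu_diff=mu, loa_lo=lo, loa_hi=hi, p_slope=p_slope, p_norm=p_norm,
                )
            )
    return pd.DataFrame([asdict(r) for r in rows])
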