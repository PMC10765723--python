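# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Preprocessing

Raw RR series carry missed-beat and extra-beat artifacts. Two automatic
filters run in a fixed order: a physiological range gate (200–2000 ms,
i.e. 30–300 BPM) followed by a windowed median filter that drops beats
deviating by more than 10% from the median of a 7-beat window. Running the
range gate first matters: a 2500 ms outlier inside a median window would
otherwise distort its neighbours' medians. The median pass is a single
simultaneous sweep over the range-filtered sequence (flags computed, then
applied), not an iterative re-filtering; the deviation denominator is the
window median, not the beat. At the series ends the window shrinks
symmetrically, falling back to the first/last three beats rather than
reflecting data. Removals by visual inspection are modelled as an explicit
index list — they are not automatable.

Downstream analysis consumes the gap-closed sequence of retained intervals
(DFA operates on beat index), while reported times keep the retained
beats' original cumulative times.

## DDFA

Scale grid: 20 logarithmically spaced reals on [5, 64] rounded to integers
and de-duplicated (19 distinct scales with the defaults); fluctuation
functions at s−1 = 4 and s+1 = 65 are computed because the three-point
stencil needs them at the grid edges. Segments of length 5s slide with a
hop of one beat and are centred on the evaluation beat (a trailing
anchoring is available by flag). F̃ is the natural logarithm of F — the
only reading under which the stencil is the derivative of log F with
respect to log s. Window fits use ordinary least squares on index
coordinates 0..s−1. Masking is explicit: wherever a full segment does not
fit, or F = 0 makes the logarithm undefined, the field holds NaN — never a
silent zero.

Implementation: within a segment, the locally integrated profile differs
from the globally integrated one only by an affine function of beat index,
which the order-2 window fit annihilates. Window residuals are therefore
computed once per window size on the global profile (explicit residual
formation, no norm-difference cancellation) and per-segment fluctuation
functions are assembled from prefix sums. The tests pin this against a
brute-force per-segment oracle to ~1e-10 relative agreement.

Known estimator bias: at window size 4 an order-2 fit leaves a single
residual degree of freedom, so F(4) is strongly suppressed and the stencil
exponent at s = 5 is biased high (for white noise the exact expectation is
≈ 1.12 at s = 5 versus ≈ 0.5 at large scales; the exact-covariance oracle
in the test suite computes these numbers). Two consequences are handled
deliberately:

* The scale-smoothness property of pure fGn is asserted for s ≥ 10 only.
* The threshold pipeline is unaffected, because the bias is a per-scale
  quantity that cancels in the per-scale baseline subtraction to the
  extent that it varies slowly with the underlying exponent.

## Threshold rules

HR binning rounds half to even (deterministic, bias-free). The baseline
uses the 25 lowest occupied bins per scale; with fewer occupied bins all
are used and a warning is emitted. The 10-bin mean filter runs over the
sequence of occupied bins (unoccupied interior bins are skipped); for the
even kernel the window extends kernel//2 bins left and kernel//2 − 1
right, shrinking at the ends.

"Stable intersection" is operationalised as a run of ≥ 10 consecutive
occupied bins strictly below the level (0 for T₁, −0.5 for T₂), reported
at the run's first bin. Strict inequality follows the "drops below"
semantics; with ≤ the level itself would count as crossed. The scan starts
above the baseline region (occupied bin 26 onward), where the curve is ≈ 0
by construction and can dip negative spuriously. Unstable crossings are
surfaced in the diagnostics rather than discarded silently.

The DFA-α1 comparison method implements the regression-region algorithm:
band selection (0.5 ≤ α1 ≤ 0.75 in HR order), gap bridging (≤ 4
intervening out-of-band points join regions), largest region, then greedy
single-point expansion from either end while R² strictly improves.
Noise-free collinear data leave R² = 1 under expansion; ties do not expand,
so the analytic crossings are exact. The α1 track detrends each 2-minute
window with smoothness priors (λ = 500; the trend solves
(I + λ²D₂ᵀD₂)·trend = z, a pentadiagonal symmetric system solved in banded
form) and uses **order-1** window detrending by default: with order 2 the
scale-4 window again has one residual degree of freedom and the exact
expected log-log slope of white noise inflates to ≈ 0.73, while order 1
gives ≈ 0.58 — calibrated within the tolerances this track is used at.
Order 2 remains available (`order=2`) for consistency experiments with the
DDFA engine.

The lactate protocol takes fit A as the exact line through the
interpolated LT₁ point and the following sample (two points determine a
line), and fit B as the least-squares line through the endpoints of every
step whose increment exceeds 0.8 mmol/L, each point counted once. Times
convert to BPM through linear interpolation of a 30-s-averaged HR trace
(by default the curve's own per-step HR values).

The per-method estimators are packaged sklearn-style (`fit`,
`get_params`/`set_params`, trailing-underscore fitted attributes) so they
compose with sklearn tooling; the sample objects are domain containers
rather than feature matrices.

## Agreement statistics

* Pearson correlation with a one-sided permutation p-value, add-one
  estimator (1 + #{r* ≥ r})/(n_perm + 1) — conservative and never zero.
* Bland–Altman limits of agreement: mean difference ± 1.96 sample
  (n − 1) standard deviations. The n − 1 convention is used throughout;
  it is the convention consistent with the bundled table's summary row.
* Proportional-bias test: observed |OLS slope| of differences against HR,
  compared with slopes refitted on iid normal differences with the
  observed sd at the same abscissae. The abscissa is the pairwise mean of
  method and benchmark (the Bland–Altman convention); benchmark-only is
  available by flag since the choice is genuinely open.
* BCa bootstrap: bias correction z₀ from the bootstrap distribution's
  fraction below the point estimate, acceleration from jackknife skewness;
  resampling is by subject (paired rows), preserving pairing. The
  implementation is cross-checked against `scipy.stats.bootstrap
  (method="BCa")` in the tests; Shapiro–Wilk is delegated to scipy
  outright.
* `compare_table` canonicalises subject order (lexicographic in the value
  pairs) before resampling, making every output — including p-values —
  invariant to row permutations of the input table, and spawns per-row
  child seeds from one seed sequence so a single seed fixes the whole
  table.

## Synthetic data

The generator emulates an incremental cyclo-ergometer test: a linear HR
ramp (default 110 → 200 BPM over 1500 s, matching a typical ~25-minute
test), mean interval 60000/HR(t), plus unit-variance fluctuations of
amplitude `fluct_sd` (default 10 ms, a realistic beat-to-beat variability
during loaded exercise) whose *local scaling exponent* follows a
non-increasing schedule in HR. The default schedule holds α = 1.0 up to
145 BPM and declines linearly to 0 at 195 BPM, placing the −0.5
baseline-subtracted crossing at 170 BPM.

Fluctuations are synthesised by shared-phase spectral mixing: one complex
Gaussian spectrum is drawn, shaped with power-law amplitude per quantised
exponent value, and each beat takes its value from the realisation shaped
with its own target. Neighbouring beats with nearby targets are nearly
identical samples, so the correlation structure varies smoothly with no
block seams (an earlier block-crossfade design decorrelated fluctuations
across block boundaries and biased large-scale exponents low; a one-sided
truncated fractional-integration filter compressed exponents toward 0.5 —
both were discarded).

The spectrum-to-exponent map is *calibrated to the estimator*: the DFA-2
functional's expected exponent for a power-law spectrum is computed
exactly from the process autocovariance (quadratic forms over the window
projections, the same three-point stencil), and the generator inverts this
response so that the scheduled α is what the analysis measures. Without
this, the estimator's exponent-dependent small-scale bias (≈ +0.07 at
α = 0.5, ≈ 0 at α = 1) would not cancel in the baseline subtraction and
would shift the planted T₂ by several BPM. The calibration involves no
empirical fitting and no free parameters.

Artifacts are injected after clipping clean intervals to [200, 2000] ms,
so every preprocessing removal is attributable to a plant: a missed beat
merges two adjacent intervals; an extra beat splits one interval at a
uniform random point. `gen_fgn` (the stationary oracle used to calibrate
the estimators) uses Davies–Harte circulant embedding for H ∈ (0, 1) and
spectral synthesis with PSD exponent 2H − 1 at and above 1, where the fGn
autocovariance degenerates.

The lactate generator builds a piecewise-linear step curve: a small dip to
the minimum at the second step, a gentle rise whose +0.3 mmol/L crossing
lands exactly at the planted LT₁ time, and a steep rise (> 0.8 mmol/L per
step) breaking exactly at a step boundary, so the two-slope protocol
recovers both planted times to machine precision at zero noise.

What the generator does **not** emulate: baroreflex and respiratory
coupling, ectopic-beat morphology, HR-dependent variability amplitude,
recovery phases, or measurement quantisation. Passing recovery tests
therefore demonstrates correctness of the estimators on series with the
prescribed correlation structure — not clinical validity on real
recordings.

## Test and acceptance conditions

Calibration checks run on n = 10⁴ beats (sampling error of the mean
exponent well under the ±0.1 band); planted-threshold recovery uses ten
~3900-beat synthetic subjects and asserts the *mean* estimate across seeds
within ±5 BPM of each plant. The mean is the right level for that claim:
below the first plant the scheduled curve sits exactly at the baseline, so
the first-stable-crossing rule applied to any single noisy realisation is
noise-limited (the smoothed curve's sd there is ≈ 0.05 with ~10-bin
correlation), while the mean over seeds isolates systematic
miscalibration. Type-I-error calibration of the two resampling tests uses
500 replicates of n = 15 with 999 resamples each; the add-one estimator's
nominal size is unchanged by the resample count. BCa coverage is checked
over 1000 simulations, where the Monte-Carlo standard error (≈ 0.009) is
small against the asserted [0.90, 0.99] band.

## Known limitations

* Thresholds are reported as integer BPM; sub-BPM resolution is not
  meaningful given integer-HR binning.
* The stability rule cannot detect a threshold within the last 9 occupied
  bins of a recording ended exactly at exhaustion.
* The α1 regression method assumes a near-linear decline through the
  0.5–0.75 band; plateaus or rebounds leave it undefined (reported with a
  reason, never guessed).
* BCa intervals at n = 15 undercover slightly (true coverage ≈ 0.92 at
  nominal 0.95) — a property of the method at this sample size, shared by
  the scipy reference implementation.
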