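# Methods

## Model and fitting sequence

Each trial is a 26-bin dF/F trace on a 10 Hz grid over [-1, 1.5] s around
stimulus onset, modeled as `y(t) = sum_i w_i * x_i + eps` with binary event
trains for stimulus onset (always at t = 0), saccades, and body movements,
plus a second-order term `w_be * (x_b (x) x_e)` whose input is the outer
product of the two movement trains.  Kernels act causally and
anti-causally over fixed lag windows: [-1, 1.5] s for the stimulus (26
bins), [-0.3, 2] s for the movement kernels (24 bins), and [-0.3, 1.7] s per
axis for the interaction kernel (21 x 21 bins).  Lags falling outside the
trial window contribute nothing (finite-window convolution; no padding).

Traces are baseline-corrected to the mean dF/F in [-1, -0.8] s.  Trials
with any movement inside that baseline window are discarded.  Because the
stimulus co-occurs with movements, kernels are fitted in sequence:

1. stimulus kernel on trials without any movement;
2. saccade and body kernels on the residuals of trials holding exactly one
   event of that type with no other movement within the isolation window
   (default +/- 1 s; the window is a free parameter because "sufficiently
   isolated" has no canonical value — note the movement kernels extend 2 s,
   so residual cross-contamination is only strictly zero when the isolation
   window spans the whole trial);
3. the interaction kernel on the residuals of trials with co-occurring
   saccades and body movements, after removing all three first-order
   predictions.

Interaction-kernel bins supported by fewer than 10 trials are masked.
Estimators on the stacked 2D design: OLS via the normal equation (rank
deficiency raises an error naming the offending columns; an explicit
pseudoinverse fallback exists for under-determined exploratory fits), ridge
with evidence-optimized variances, or ALD.

## ALD

The prior covariance is diagonal in each domain.  Time domain:
`C_ii = exp(-1/2 (chi_i - nu)' Psi^{-1} (chi_i - nu) - rho)` with lag
coordinates `chi_i` in bin units on the 21 x 21 grid ((0, 0) at the
(-0.3 s, -0.3 s) corner).  Frequency domain:
`C_ii = exp(-1/2 (|M w_i| - nu)' (|M w_i| - nu) - rho)` with *integer*
frequency coordinates `w_i` in cycles per kernel window on the centered
grid (-10 .. 10).  Integer coordinates make `M` entries of order one
correspond to priors a few bins wide; with cycles-per-bin coordinates in
[-0.5, 0.5) the same prior would require `M` entries of order 20-60, which
is not the natural scale of the shape matrix.  The frequency-domain center
`nu` is constrained to the non-negative octant: `|M w|` is elementwise
non-negative, so negative centers are degenerate with the `rho` scale and
destabilize across-animal comparisons of `M`.

The real orthonormal 2D Fourier basis `B` holds one cosine and one sine
vector per +/- frequency pair (odd grid sizes only — even sizes would need
Nyquist special-casing that the 21-bin grids never exercise).  The combined
prior is `C = C_t^{1/2} (B' C_f B) C_t^{1/2}`, reading the printed "Cs2" as
the square root of the diagonal time prior, the only reading under which
`C_f = I` collapses the combination to the time prior; the alternative
(square) interpretation can be swapped in by squaring the diagonal before
the call.

All evidence and posterior computations go through a factor `F` with
`C = F F'`: with `G = X F` and `A = sigma^2 I + G'G`,
`log E = -1/2 [n log 2 pi + (n - d) log sigma^2 + log|A| + (Y'Y - (G'Y)' A^{-1} (G'Y)) / sigma^2]`,
`mu = F A^{-1} G'Y`, `Lambda = sigma^2 F A^{-1} F'`.  This never inverts the
prior, which underflows far from the elliptical region.  Coordinates whose
prior scale is below 1e-7 of the maximum enter only through their diagonal
terms (relative error ~1e-14), which keeps localized priors cheap.  The
implementation is validated against the direct density
`log N(Y; 0, sigma^2 I + X C X')` to 1e-8.

Optimization is staged: first the time-prior parameters (evidence with
`C = C_t`), then the frequency-prior parameters (`C = B' C_f B`), then the
combination and posterior.  Each stage runs Nelder-Mead (the evidence is
cheap but its gradient is not available analytically here) from a
data-driven initialization — prior center at the ridge-pilot kernel's peak,
`M` from the pilot spectrum's second moments — plus jittered restarts
(default 4); `Psi` is parameterized by log-diagonal SDs and a bounded
correlation, `sigma2/psi` on log scales.  Objective tolerance 1e-7
(absolute) for full fits.  The global sign of `M` is canonicalized to
`M11 + M22 >= 0` (the prior only sees `|M w|`).

Constraints: the `Psi` correlation is clamped to 0.5 by default (diagonal
orientation of the interaction region).  The noise variance `sigma^2` is
part of theta and *free* by default: it is fitted in stage 1 and carried
into stage 2.  A fixed `sigma^2 = 0.001` (appropriate when responses are
normalized so that value sits near the unconstrained optimum) is available
via `ConstraintSet.fixed_noise()`.  On the synthetic cohort the
unexplainable residual variance grows with the planted arousal variability
(the gain fluctuations of the first-order responses do not live in the 2D
design span), so clamping `sigma^2` far below it makes the prior absorb
noise and *widen* with variability — the opposite of the mechanism of
interest; with `sigma^2` free, the noise floor adapts per animal and the
prior narrows (M grows) with variability, which is the behavior the fitted
hyperparameters are meant to read out.

The M-only refit clamps every prior parameter to the across-animal
arithmetic mean of the full fits, keeps `sigma^2` at the animal's own
estimate (it is a noise parameter, not a prior-shape parameter, and varies
by more than an order of magnitude across the graded cohort), and
re-optimizes only `M11, M12, M22`, warm-started.  A stability screen flags a
fit when any M entry's across-resample SD exceeds its absolute mean
(multiplier configurable).

## Spectral and diagonal statistics

"Anti-diagonals" run bottom-left to top-right (constant row + col) and are
used for spectral profiles; "diagonals" run top-left to bottom-right
(constant relative lag) and are used for time-domain kernels.  The width of
a profile is the count of anti-diagonals at or above a fraction of the
maximum after subtracting the minimum — 0.02 for ALD frequency priors, 0.15
for kernel Fourier magnitudes; no sub-bin interpolation (<= 41 diagonals; it
would fabricate precision).  A profile that is flat after min-subtraction
has no scale to threshold against; its width defaults to the full support
with a warning.  Diagonal SDs are taken over each full diagonal with
relative lag within +/- 0.8 s, excluding masked bins.

The spectrum-broadening manipulation multiplies the DFT magnitude by a
point-symmetric profile — a lognormal (mu = 0, sigma = 1) in the distance
from the main anti-diagonal, shifted by 0.5 bins so the main anti-diagonal
is not zeroed, times `1/(1 + r)` in the radial distance — normalized to
unit mean so low frequencies are genuinely amplified rather than everything
attenuated, then recombines with the original phase and inverts the DFT
("recombined with the original phase" being the only reading under which the
inverse transform returns a kernel).  The result is real up to numerical
residue, which is checked and discarded.

## Hierarchical bootstrap

Each of `n_B` iterations draws `n_A = 5` animals with replacement, then
`n_T` trial resamples per sampled animal; the per-resample statistics (M
entries from the M-only refit, pCV, inverse ridge SNR) are averaged over
`n_T`, prior widths are computed from the n_T-averaged M, and the
across-animal Pearson correlations form the per-iteration values.
Reference dimensions are `n_B = 300`, `n_T = 20` (and `n_B = 1000` for the
group comparison); tests and the acceptance script run reduced sizes
(`n_B = 100, n_T = 8` and `n_B = 60, n_T = 4` respectively) to keep wall
time in minutes — the statistic is identical, only the Monte-Carlo
resolution changes.  Outlier iterations are removed per monitored quantity
(M11, M12, M22, pCV) by a median +/- 3 x scaled-MAD rule — the removal rule
itself is a documented stand-in, since only *that* outliers were removed is
specified, not how.  `p_boot` is the fraction of kept iterations on a given
side of zero; a positive correlation is significant when `p_boot(r < 0) <
0.05`, a negative one when `p_boot(r > 0) < 0.05`.  Iterations with zero
variance in either correlate yield NaN and drop out visibly.  Seeding uses
spawned substreams per iteration; the per-animal refits warm-start from the
animal's previous resample within a run (fixed processing order, so runs
are reproducible from the master seed).

Pupil CV is the sample SD (n-1 denominator) of the stimulus-evoked pupil
area increase divided by its mean.  The group comparison pools (sums) the
bootstrap-averaged OLS kernels of the two lowest-M and two highest-M
animals and compares per-diagonal SDs over +/- 0.8 s with a two-sample t
test.  The psychometric curve is
`psi = gamma + (1 - gamma - lambda) Phi((dtheta - alpha)/beta)`, fitted by
binomial maximum likelihood with box bounds (lapses in [0, 0.5]); a fit
pegged at a bound is flagged unconverged; bootstrap CIs (conventionally 999
resamples) are optional.

## Synthetic cohort

The generator plants: a unit-amplitude stimulus transient peaking 0.3 s
after onset (responses are therefore in units of the peak stimulus
response); saccade and body transients of amplitude 0.6 and 0.8; and a
suppressive interaction — a -0.4 peak 2D Gaussian centered at
(0.35 s, 0.35 s), SD 0.45 s along and 0.18 s across the main diagonal.
Body movements arrive as a Poisson process (1 per trial), each paired with
probability 0.75 with a saccade at lag N(0, 0.35 s) (both orders), plus
independent saccades (0.3 per trial); events snap to the grid.  The
per-trial gain is `exp(N(0, sigma_gain))` and multiplies all response
components; sensor noise is additive Gaussian with SD 0.03.  Pupil
increases are `N(mean, cv_link * sigma_gain * mean)` clipped at zero
(truncation by clipping; negligible mass at the defaults), so the
ground-truth pupil CV is `cv_link * sigma_gain`.  The reference cohort has
five animals with `sigma_gain` in {0.05, 0.1, 0.2, 0.3, 0.4} and 2000
trials each (the acceptance script uses 1200 for runtime).

What the generator does *not* emulate: pixel-level imaging, eye videos or
wheel traces, hemodynamic contamination, session structure, across-animal
differences in kernel shape, or temporally correlated (1/f) noise.  Passing
tests therefore show that the estimation and inference machinery recovers
the planted structure and effect directions under multiplicative gain
variability — not that real cortical data satisfy those assumptions.
A known consequence: in this synthetic world the pooled high-variability
kernels have *larger* diagonal SDs (estimator noise survives pooling),
whereas in real data the same comparison can be dominated by genuine
suppression-strength differences between animals.

## Numerical choices and degenerate inputs

Exact noiseless recovery of all planted kernels (< 1e-6, in practice
~1e-14) requires a configuration in which the sequential stages are exactly
identified: events restricted to t >= -0.5 s (so anti-causal kernel tails
cannot reach the baseline window) and a whole-trial isolation window.  The
default generator places events over the whole trial, which exercises the
baseline discard rule and reproduces the (small, documented) stage-2
contamination any finite isolation window admits.

Degenerate cases: zero event rates produce clean-only cohorts and the
movement stages report "insufficient trials" instead of failing; a zero
response vector makes the evidence flat in M up to the complexity term and
is returned flagged (`flat_objective`) without optimization; collinear
interaction designs fall back to the minimum-norm solution with a warning;
all-zero prior scales reduce the evidence to the pure-noise density.

Problem sizes used by the shipped checks: evidence oracle n <= 50, d <= 25
(50 instances); ridge recovery n = 2000, d = 20 averaged over 6 replicates
(a single draw of 20 weights has ~32% sampling spread in its realized
variance, so the estimator is assessed by its mean); ALD-vs-OLS recovery at
n_trials = 2000; direction-of-effect cohort n_B = 100, n_T = 8; null
calibration 200 cohorts at n_B = 100.
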