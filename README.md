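# kernelvar

Regularization hyperparameters of 2D neural interaction kernels as measures
of trial-to-trial variability and arousal.

## The problem

When a mouse makes a saccade and a body movement close together in time, the
cortical calcium (dF/F) response is not the sum of the two movement
responses: a second-order GLM term — a two-dimensional **interaction kernel**
`w_be(tau_b, tau_e)` over the lags from body-movement and saccade onset —
captures the deviation, typically a contiguous *suppressive* (negative)
region at small positive lags.  Estimating a 21 x 21 lag grid from limited,
collinear trial data needs regularization, and this package is built around
the observation that the regularization hyperparameters themselves are
biologically informative: animals whose responses fluctuate more from trial
to trial (higher arousal variability) need tighter priors, so the fitted
hyperparameters track independent arousal measures such as the pupil
coefficient of variation (pCV).

## The model

Per trial, on a 10 Hz grid over [-1, 1.5] s around stimulus onset,

```
y(t) = sum_i w_i * x_i  +  w_be * (x_b (x) x_e)  +  eps
```

with binary event trains `x_i` (stimulus, saccade, body movement), 1D
kernels `w_i` acting causally and anti-causally, and the 2D term built from
the outer product of the two movement trains.  Kernels are fitted
sequentially (stimulus kernel on movement-free trials, movement kernels on
isolated-event residuals, interaction kernel on the remaining residuals) by
OLS, evidence-optimized ridge, or **automatic locality determination (ALD)**:
an empirical-Bayes prior that confines kernel weights to an elliptical
region in the time domain,

```
C_ii = exp( -1/2 (chi_i - nu)' Psi^{-1} (chi_i - nu) - rho )
```

and its Fourier coefficients to an elliptical region in the frequency
domain,

```
C_ii = exp( -1/2 (|M w_i| - nu)' (|M w_i| - nu) - rho ),
```

with all hyperparameters found by maximizing the Gaussian marginal
likelihood.  The symmetric 2 x 2 matrix `M = [[M11, M12], [M12, M22]]` sets
the shape of the frequency prior — larger entries mean narrower priors, and
`M12 > 0` means elongation — and is the package's variability read-out: the
anti-diagonal threshold **width** `w` of the prior falls as `M` grows, and
across a cohort `M` rises with the pupil CV and with the inverse ridge SNR
`sigma_n^2 / sigma_p^2`.  Inference on these correlations uses a two-level
**hierarchical bootstrap** (animals, then trials, with replacement) with
directional `p_boot` probabilities compared to a 0.05 criterion.

Because no public dataset accompanies the analysis, the package ships a
synthetic-data generator (`kernelvar.synth`) that plants the assumed
structure: known 1D kernels, a suppressive 2D interaction, per-trial
multiplicative response gain `exp(N(0, sigma_gain^2))` driven by a latent
arousal parameter, and pupil increases whose spread tracks the same
parameter.  Every downstream stage is exercised and tested against this
ground truth.

## Worked example

```python
import numpy as np
import kernelvar as kv
from kernelvar import ald

grid = kv.DEFAULT_GRID
kernels = kv.default_kernels(grid)
spec = kv.AnimalSpec("demo", n_trials=2000, sigma_gain=0.25, sigma_noise=0.03)
trials = kv.synth.generate_animal(spec, kernels, grid, rng_seed=5)

sel = kv.select_trials(trials, grid)
fit = kv.sequential_fit(trials, sel, grid)
X, Y, counts, _ = kv.glm.stack_interaction_design(fit.residual_trials)
res = kv.fit_ald(X, Y, shape=(21, 21), seed=1)

K_ols = kv.fit_interaction_kernel(fit.residual_trials, method="ols")
sup = ~K_ols.mask.ravel()
truth = kernels.w_be.weights.ravel()
print("M entries:", np.round(res.theta.m_entries, 3))
print("ALD vs planted r:", round(np.corrcoef(res.posterior.mu[sup], truth[sup])[0, 1], 3))
print("OLS vs planted r:", round(np.corrcoef(K_ols.weights.ravel()[sup], truth[sup])[0, 1], 3))
width = kv.freq_prior_width(kv.freq_prior_matrix(res.theta.freq_prior, (21, 21)))
print("frequency-prior width:", width)
```

prints

```
M entries: [0.711 0.284 0.689]
ALD vs planted r: 0.991
OLS vs planted r: 0.921
frequency-prior width: 9
```

meaning: with moderate arousal variability the fitted frequency prior is
fairly narrow (`M` entries ~0.7, width 9 of 41 anti-diagonals at the 0.02
threshold), the localized prior recovers the planted suppressive kernel at
r = 0.99, and it clearly beats plain OLS on the same residuals.  On a
low-variability animal (`sigma_gain = 0.05`) the same code yields smaller
`M` and a width of ~13; on a high-variability one (`sigma_gain = 0.4`),
`M` entries around 1 and the minimal width of 5 — the inverse M-width
relationship that makes `M` a variability read-out.

The full experiment — a graded five-animal cohort through simulation,
sequential GLM, ALD, spectral widths, and the hierarchical bootstrap — runs
from the command line:

```bash
kernelvar run-all --outdir runs/demo --seed 0          # default cohort
kernelvar report --outdir runs/demo                    # re-assemble report.json
```

The run directory holds `data/` (HDF5 + CSV + YAML echo), per-stage HDF5/CSV
artifacts, `bootstrap_summary.json` with the `p_boot` values, and
`report.json`; identical config and seed reproduce it exactly.

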