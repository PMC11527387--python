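"""Hierarchical bootstrap, pupil statistics, group tests, psychometrics.

The hierarchical bootstrap respects the nested structure of multi-animal
datasets: every iteration resamples animals with replacement and, within
each sampled animal, resamples trials with replacement ``n_T`` times.  The
per-resample statistics are averaged across the ``n_T`` trial resamples,
giving one summary per sampled animal, from which an across-animal statistic
(typically a Pearson correlation) is computed.  The fraction of iterations
on a given side of zero (``p_boot``) is compared to the 0.05 criterion for
directional significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .spectral import diagonal_std

__all__ = [
    "BootstrapSpec",
    "BootstrapResult",
    "PupilStats",
    "PsychometricFit",
    "compute_pcv",
    "hierarchical_bootstrap",
    "pearson_across_animals",
    "p_boot",
    "group_compare_diagonal_std",
    "fit_psychometric",
]


def compute_pcv(pupil_increases: np.ndarray) -> float:
    """Pupil coefficient of variation: sample SD / mean of the increases."""
    x = np.asarray(pupil_increases, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean pupil increase must be positive")
    return float(x.std(ddof=1) / mean)


@dataclass
class PupilStats:
    pupil_increases: np.ndarray
    pcv: float

    @classmethod
    def from_increases(cls, increases: np.ndarray) -> "PupilStats":
        return cls(np.asarray(increases, dtype=float), compute_pcv(increases))


@dataclass
class BootstrapSpec:
    """Hierarchical bootstrap dimensions: defaults follow the correlation
    analyses (300 iterations, 5 animals, 20 trial resamples)."""

    n_b: int = 300
    n_a: int = 5
    n_t: int = 20
    seed: int = 0
    outlier_mad_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if min(self.n_b, self.n_a, self.n_t) < 1:
            raise ValueError("n_b, n_a, n_t must all be >= 1")


@dataclass
class BootstrapResult:
    """Per-iteration statistics after hierarchical resampling."""

    iterations: pd.DataFrame          # one row per iteration, kept or not
    kept_mask: np.ndarray
    n_failed: int
    spec: BootstrapSpec

    def values(self, column: str, kept_only: bool = True) -> np.ndarray:
        vals = self.iterations[column].to_numpy()
        return vals[self.kept_mask] if kept_only else vals

    def p_boot(self, column: str, direction: str) -> float:
        return p_boot(self.values(column), direction)


def p_boot(values: np.ndarray, direction: str) -> float:
    """Fraction of bootstrap values with the stated sign.

    ``direction`` is "gt0" or "lt0"; exact zeros count toward neither, so the
    two fractions sum to 1 in the absence of ties at 0.  Significance at the
    0.05 criterion means the probability of the *opposite* sign is below it.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan
    if direction == "gt0":
        return float(np.mean(v > 0))
    if direction == "lt0":
        return float(np.mean(v < 0))
    raise ValueError("direction must be 'gt0' or 'lt0'")


def _mad_outliers(values: np.ndarray, multiplier: float) -> np.ndarray:
    """True where a value lies outside median +/- multiplier * scaled MAD."""
    v = np.asarray(values, dtype=float)
    med = np.nanmedian(v)
    mad = scipy.stats.median_abs_deviation(v, scale="normal", nan_policy="omit")
    if not np.isfinite(mad) or mad == 0:
        return ~np.isfinite(v)
    out = np.abs(v - med) > multiplier * mad
    return out | ~np.isfinite(v)


def hierarchical_bootstrap(
    dataset: dict,
    statistic_fn,
    spec: BootstrapSpec,
    across_fn=None,
    monitor: list[str] | None = None,
) -> BootstrapResult:
    """Two-level bootstrap: animals with replacement, then trials within.

    ``dataset`` maps animal id to an animal payload; ``statistic_fn(payload,
    trial_indices, rng)`` returns a scalar or a mapping of named scalars for
    one trial resample (``trial_indices`` indexes the animal's trials, with
    replacement).  Per animal the statistics are averaged over ``spec.n_t``
    resamples.  ``across_fn(per_animal: pd.DataFrame)`` maps the ``n_a``
    per-animal summaries to the per-iteration statistics (default: the mean
    of each field).  Iterations where ``statistic_fn`` raises are excluded
    and counted in ``n_failed``.

    Outlier iterations are removed per monitored column (default: every
    across-statistic column) using a median +/- ``outlier_mad_multiplier`` x
    scaled-MAD rule.  Seeding uses spawned substreams, so results do not
    depend on evaluation order.
    """
    animal_ids = list(dataset.keys())
    n_trials = {a: _n_trials(dataset[a]) for a in animal_ids}
    root = np.random.SeedSequence(spec.seed)
    iter_seeds = root.spawn(spec.n_b)

    rows = []
    n_failed = 0
    for it, ss in enumerate(iter_seeds):
        rng = np.random.default_rng(ss)
        sampled = [animal_ids[k] for k in
                   rng.integers(0, len(animal_ids), size=spec.n_a)]
        per_animal = []
        try:
            for aid in sampled:
                stats_t = []
                for _ in range(spec.n_t):
                    idx = rng.integers(0, n_trials[aid], size=n_trials[aid])
                    st = statistic_fn(dataset[aid], idx, rng)
                    if not isinstance(st, dict):
                        st = {"stat": float(st)}
                    stats_t.append(st)
                avg = {k: float(np.mean([s[k] for s in stats_t]))
                       for k in stats_t[0]}
                avg["animal_id"] = aid
                per_animal.append(avg)
        except Exception:
            n_failed += 1
            continue
        df = pd.DataFrame(per_animal)
        if across_fn is None:
            row = {c: float(df[c].mean())
                   for c in df.columns if c != "animal_id"}
        else:
            row = dict(across_fn(df))
        row["iteration"] = it
        rows.append(row)

    iters = pd.DataFrame(rows)
    if iters.empty:
        raise RuntimeError("every bootstrap iteration failed")
    stat_cols = [c for c in iters.columns if c != "iteration"]
    monitored = monitor if monitor is not None else stat_cols
    kept = np.ones(len(iters), dtype=bool)
    for col in monitored:
        if col in iters:
            kept &= ~_mad_outliers(iters[col].to_numpy(),
                                   spec.outlier_mad_multiplier)
    return BootstrapResult(iterations=iters, kept_mask=kept,
                           n_failed=n_failed, spec=spec)


def _n_trials(payload) -> int:
    if hasattr(payload, "n_trials"):
        return int(payload.n_trials)
    return len(payload)


def pearson_across_animals(x_field: str, y_field: str, name: str | None = None):
    """An ``across_fn`` computing Pearson r between two per-animal fields.

    Iterations where either field has zero variance across the sampled
    animals yield NaN (excluded downstream and visible in the kept counts).
    """
    out_name = name or f"r_{x_field}_{y_field}"

    def across(df: pd.DataFrame) -> dict:
        x = df[x_field].to_numpy(dtype=float)
        y = df[y_field].to_numpy(dtype=float)
        row = {f"mean_{x_field}": float(x.mean()), f"mean_{y_field}": float(y.mean())}
        if np.std(x) == 0 or np.std(y) == 0:
            row[out_name] = np.nan
        else:
            row[out_name] = float(np.corrcoef(x, y)[0, 1])
        return row

    return across


def group_compare_diagonal_std(
    kernels_low, kernels_high,
    lag_range: tuple[float, float] = (-0.8, 0.8),
    dt: float | None = None,
) -> dict:
    """Compare diagonal variability between pooled kernels of two groups.

    Kernels within each group are pooled by summation; the SD along each
    diagonal with relative lag inside ``lag_range`` is computed for each
    pooled kernel, and the two sets of per-diagonal SDs are compared with a
    two-sample t test.
    """
    def _pool(kernels):
        arrs = [k.weights if hasattr(k, "weights") else np.asarray(k)
                for k in kernels]
        return np.sum(arrs, axis=0)

    pooled_low, pooled_high = _pool(kernels_low), _pool(kernels_high)
    if dt is None:
        k0 = kernels_low[0]
        if not hasattr(k0, "dt"):
            raise ValueError("dt required for raw arrays")
        dt = k0.dt
    _, sd_low = diagonal_std(pooled_low, lag_range, dt)
    _, sd_high = diagonal_std(pooled_high, lag_range, dt)
    if sd_low.size < 2 or sd_high.size < 2:
        raise ValueError("insufficient diagonals in the stated lag range")
    t, p = scipy.stats.ttest_ind(sd_low, sd_high)
    return {
        "t": float(t), "p": float(p),
        "mean_sd_low": float(sd_low.mean()), "mean_sd_high": float(sd_high.mean()),
        "sd_low": sd_low, "sd_high": sd_high,
    }


# ---------------------------------------------------------------------------
# psychometric curve
# ---------------------------------------------------------------------------

@dataclass
class PsychometricFit:
    """Lapse-limited cumulative-Gaussian psychometric function.

    ``psi(dtheta) = gamma + (1 - gamma - lambda) * Phi((dtheta - alpha) / beta)``
    with ``alpha``/``beta`` the mean and SD (degrees) and ``gamma``/
    ``lambda_`` the left and right lapse rates.
    """

    alpha: float
    beta: float
    gamma: float
    lambda_: float
    converged: bool = True
    log_likelihood: float = np.nan
    ci: dict = field(default_factory=dict)

    def curve(self, delta_theta: np.ndarray) -> np.ndarray:
        z = (np.asarray(delta_theta, dtype=float) - self.alpha) / self.beta
        return self.gamma + (1.0 - self.gamma - self.lambda_) * scipy.stats.norm.cdf(z)


_PSY_BOUNDS = [(-80.0, 80.0), (1e-2, 90.0), (0.0, 0.5), (0.0, 0.5)]


def _psy_nll(params: np.ndarray, x: np.ndarray, choices: np.ndarray) -> float:
    a, b, g, l = params
    p = g + (1.0 - g - l) * scipy.stats.norm.cdf((x - a) / b)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -float(np.sum(choices * np.log(p) + (1 - choices) * np.log(1 - p)))


def fit_psychometric(delta_theta: np.ndarray, choices: np.ndarray,
                     n_bootstrap: int = 0, seed: int = 0) -> PsychometricFit:
    """Maximum-likelihood psychometric fit under a binomial model.

    ``choices`` are 0/1 (right-side choices); ``delta_theta`` the signed task
    difficulty in degrees.  Optional percentile bootstrap confidence
    intervals (the convention is 999 resamples).  A fit pegged at a parameter
    boundary is reported with ``converged=False``.
    """
    x = np.asarray(delta_theta, dtype=float)
    c = np.asarray(choices, dtype=float)
    if x.shape != c.shape:
        raise ValueError("delta_theta and choices must match")

    spread = max(x.std(), 1.0)
    starts = [
        np.array([np.median(x), spread, 0.02, 0.02]),
        np.array([0.0, spread / 2, 0.05, 0.05]),
        np.array([x.mean(), spread * 2, 0.1, 0.1]),
    ]
    best = None
    for s0 in starts:
        res = scipy.optimize.minimize(_psy_nll, s0, args=(x, c),
                                      method="L-BFGS-B", bounds=_PSY_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
    a, b, g, l = best.x
    pegged = any(
        np.isclose(v, lo, atol=1e-8) or np.isclose(v, hi, atol=1e-8)
        for v, (lo, hi) in zip(best.x, _PSY_BOUNDS)
    )
    fit = PsychometricFit(alpha=float(a), beta=float(b), gamma=float(g),
                          lambda_=float(l), converged=bool(best.success and not pegged),
                          log_likelihood=float(-best.fun))
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, x.size, size=x.size)
            r = scipy.optimize.minimize(_psy_nll, best.x, args=(x[idx], c[idx]),
                                        method="L-BFGS-B", bounds=_PSY_BOUNDS)
            samples.append(r.x)
        samples = np.array(samples)
        names = ("alpha", "beta", "gamma", "lambda_")
        fit.ci = {n: (float(np.percentile(samples[:, i], 2.5)),
                      float(np.percentile(samples[:, i], 97.5)))
                  for i, n in enumerate(names)}
    return fit
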