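"""End-to-end experiment orchestration.

Runs the full synthetic experiment: simulate a multi-animal cohort with
graded arousal variability; fit first-order kernels sequentially; estimate
2D interaction kernels by OLS, evidence-optimized ridge and ALD; compute
spectral widths; and run the hierarchical bootstrap linking the ALD shape
hyperparameters (M11, M12, M22) to the frequency-prior width, the pupil
coefficient of variation, and the inverse ridge SNR.

Every stage writes its outputs under the run directory:

``manifest.json``           config echo, config hash, versions, seed
``data/``                   dataset.h5 + trials.csv + cohort.yaml
``first_order.h5``          per-animal stimulus/saccade/body kernels
``interaction.h5`` / ``interaction_<animal>.csv``  OLS interaction kernels
``ald_fits.json``           per-animal hyperparameters + population average
``spectra.csv``             per-animal prior and kernel-FFT widths
``bootstrap.csv`` / ``bootstrap_summary.json``     iteration table, p_boot
``report.json``             everything above, assembled from the files
``run.log``                 stage timings and seeds
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .ald import (
    ALDData,
    ALDHyperparams,
    ConstraintSet,
    fit_ald,
    freq_prior_matrix,
    population_average,
    refit_M_only,
    _params_to_theta,
    _theta_to_params,
)
from .core import INTERACTION_WINDOW, Kernel2D, TimeGrid, lag_grid
from .glm import (
    build_design_2d,
    fit_interaction_kernel,
    select_trials,
    sequential_fit,
)
from .ridge import RidgeHyperparams, _SVDCache, _evidence_from_cache
from .spectral import (
    FFT_WIDTH_THRESHOLD,
    PRIOR_WIDTH_THRESHOLD,
    diagonal_profile,
    freq_prior_width,
    power_spectrum_2d,
    profile_width,
)
from .stats import BootstrapSpec, compute_pcv, hierarchical_bootstrap
from .synth import AnimalSpec, Cohort, generate_cohort, load_cohort, save_cohort

logger = logging.getLogger("kernelvar")

__all__ = [
    "AnimalConfig",
    "RunConfig",
    "RunReport",
    "default_recovery_config",
    "run_experiment",
    "regenerate_report",
]


# ---------------------------------------------------------------------------
# configuration (schema-validated; unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AnimalConfig(_Strict):
    animal_id: str
    n_trials: int = Field(2000, ge=1)
    sigma_gain: float = Field(0.2, ge=0)
    sigma_noise: float = Field(0.03, ge=0)
    pupil_mean_increase: float = Field(0.1, gt=0)
    pupil_cv_link: float = Field(1.0, ge=0)
    event_rate_params: dict = Field(default_factory=dict)


class GridConfig(_Strict):
    dt: float = 0.1
    t_start: float = -1.0
    t_end: float = 1.5


class FitConfig(_Strict):
    first_order: str = "ols"
    min_trials: int = 10
    isolation_window: float = 1.0


class ALDConfig(_Strict):
    sigma2: float | None = None      # None leaves the noise variance free
    psi_corr: float | None = 0.5
    n_restarts: int = 4
    maxiter: int = 400
    refit_maxiter: int = 100
    refit_restarts: int = 1


class BootstrapConfig(_Strict):
    n_b: int = 300
    n_a: int = 5
    n_t: int = 20
    outlier_mad_multiplier: float = 3.0


class WidthConfig(_Strict):
    prior_threshold: float = PRIOR_WIDTH_THRESHOLD
    fft_threshold: float = FFT_WIDTH_THRESHOLD


class RunConfig(_Strict):
    animals: list[AnimalConfig]
    grid: GridConfig = GridConfig()
    fitting: FitConfig = FitConfig()
    ald: ALDConfig = ALDConfig()
    bootstrap: BootstrapConfig = BootstrapConfig()
    widths: WidthConfig = WidthConfig()
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_recovery_config(n_trials: int = 2000, n_b: int = 300,
                            n_t: int = 20, master_seed: int = 0) -> RunConfig:
    """The default 5-animal cohort with graded arousal variability."""
    gains = [0.05, 0.1, 0.2, 0.3, 0.4]
    animals = [AnimalConfig(animal_id=f"m{k+1}", n_trials=n_trials,
                            sigma_gain=g) for k, g in enumerate(gains)]
    return RunConfig(animals=animals,
                     bootstrap=BootstrapConfig(n_b=n_b, n_t=n_t),
                     master_seed=master_seed)


@dataclass
class RunReport:
    """Assembled results; every number is traceable to a run-directory file."""

    config: dict
    per_animal: dict
    population_theta: dict
    correlations: dict
    p_boot: dict
    seeds: dict
    version: str
    outdir: str


# ---------------------------------------------------------------------------
# per-animal analysis state
# ---------------------------------------------------------------------------

@dataclass
class AnimalAnalysis:
    """Everything the bootstrap needs for one animal."""

    animal_id: str
    trial_designs: list        # per interaction trial: sparse 2D design
    trial_ys: list             # matching residual traces
    pupil: np.ndarray          # per interaction trial
    amplitudes: np.ndarray     # per interaction trial peak responses
    theta: ALDHyperparams      # the animal's own full ALD fit
    shape: tuple[int, int]

    @property
    def n_trials(self) -> int:
        return len(self.trial_designs)


def _resampled_data(analysis: AnimalAnalysis, idx: np.ndarray) -> ALDData:
    X = scipy.sparse.vstack([analysis.trial_designs[i] for i in idx]).tocsr()
    Y = np.concatenate([analysis.trial_ys[i] for i in idx])
    return ALDData.from_xy(X, Y, analysis.shape)


def _constraints_from_config(cfg: ALDConfig) -> ConstraintSet:
    fixed = {}
    if cfg.sigma2 is not None:
        fixed["sigma2"] = cfg.sigma2
    if cfg.psi_corr is not None:
        fixed["psi_corr"] = cfg.psi_corr
    return ConstraintSet(fixed=fixed)


def _theta_to_json(theta: ALDHyperparams) -> dict:
    return {k: float(v) for k, v in _theta_to_params(theta).items()}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, outdir: Path) -> Cohort:
    data_dir = outdir / "data"
    if (data_dir / "dataset.h5").exists():
        logger.info("simulate: reusing %s", data_dir)
        return load_cohort(data_dir)
    grid = TimeGrid(**config.grid.model_dump())
    specs = [
        AnimalSpec(animal_id=a.animal_id, n_trials=a.n_trials,
                   sigma_gain=a.sigma_gain, sigma_noise=a.sigma_noise,
                   pupil_mean_increase=a.pupil_mean_increase,
                   pupil_cv_link=a.pupil_cv_link,
                   event_rate_params=dict(a.event_rate_params))
        for a in config.animals
    ]
    cohort = generate_cohort(specs, grid, master_seed=config.master_seed)
    save_cohort(cohort, data_dir)
    return cohort


def _stage_first_order(cohort: Cohort, config: RunConfig, outdir: Path) -> dict:
    results = {}
    path = outdir / "first_order.h5"
    with h5py.File(path, "w") as f:
        for aid, trials in cohort.animals.items():
            sel = select_trials(trials, cohort.grid,
                                config.fitting.isolation_window)
            fit = sequential_fit(trials, sel, cohort.grid,
                                 regularizer=config.fitting.first_order,
                                 allow_pinv=True)
            results[aid] = (sel, fit)
            g = f.create_group(aid)
            for name in ("w_stim", "w_e", "w_b"):
                k = getattr(fit, name)
                if k is not None:
                    gg = g.create_group(name)
                    gg.create_dataset("lags", data=k.lags)
                    gg.create_dataset("weights", data=k.weights)
            g.attrs["n_clean"] = len(sel.clean_ids)
            g.attrs["n_interaction"] = len(sel.interaction_ids)
            g.attrs["n_discarded"] = len(sel.discarded_ids)
    return results


def _export_kernel_csv(kernel: Kernel2D, path: Path) -> None:
    rows = []
    for i, tb in enumerate(kernel.body_lags):
        for j, te in enumerate(kernel.saccade_lags):
            rows.append({"body_lag": tb, "saccade_lag": te,
                         "weight": kernel.weights[i, j],
                         "count": int(kernel.trial_counts[i, j]),
                         "masked": bool(kernel.mask[i, j])})
    pd.DataFrame(rows).to_csv(path, index=False)


def _stage_interaction(cohort: Cohort, first_order: dict, config: RunConfig,
                       outdir: Path) -> dict:
    kernels = {}
    with h5py.File(outdir / "interaction.h5", "w") as f:
        for aid, (sel, fit) in first_order.items():
            K = fit_interaction_kernel(fit.residual_trials, method="ols",
                                       min_trials=config.fitting.min_trials,
                                       grid=cohort.grid)
            kernels[aid] = K
            g = f.create_group(aid)
            g.create_dataset("body_lags", data=K.body_lags)
            g.create_dataset("saccade_lags", data=K.saccade_lags)
            g.create_dataset("weights", data=K.weights)
            g.create_dataset("trial_counts", data=K.trial_counts)
            g.create_dataset("mask", data=K.mask)
            _export_kernel_csv(K, outdir / f"interaction_{aid}.csv")
    return kernels


def _build_analyses(cohort: Cohort, first_order: dict, config: RunConfig,
                    outdir: Path) -> dict:
    """Full ALD fit per animal plus per-trial designs for the bootstrap."""
    constraints = _constraints_from_config(config.ald)
    lags = lag_grid(INTERACTION_WINDOW, cohort.grid.dt)
    shape = (lags.size, lags.size)
    analyses = {}
    fits_json = {}
    (outdir / "ald_kernels.h5").unlink(missing_ok=True)
    for k_animal, (aid, (sel, fit)) in enumerate(first_order.items()):
        designs, ys = [], []
        for rt in fit.residual_trials:
            dm = build_design_2d(rt.x_b, rt.x_e, INTERACTION_WINDOW,
                                 cohort.grid, sparse=True)
            designs.append(dm.values)
            ys.append(rt.y)
        ids = [rt.trial_id for rt in fit.residual_trials]
        trials = cohort.animals[aid]
        pupil = np.array([trials[i].pupil_increase for i in ids])
        stim_peak_bin = cohort.grid.bin_of(0.3)
        amplitudes = np.array([trials[i].y[stim_peak_bin] for i in ids])

        X = scipy.sparse.vstack(designs).tocsr()
        Y = np.concatenate(ys)
        data = ALDData.from_xy(X, Y, shape)
        result = fit_ald(None, None, data=data, constraints=constraints,
                         seed=config.master_seed + 1000 + k_animal,
                         n_restarts=config.ald.n_restarts,
                         maxiter=config.ald.maxiter)
        analyses[aid] = AnimalAnalysis(
            animal_id=aid, trial_designs=designs, trial_ys=ys, pupil=pupil,
            amplitudes=amplitudes, theta=result.theta, shape=shape,
        )
        fits_json[aid] = {
            "theta": _theta_to_json(result.theta),
            "evidence": float(result.evidence),
            "flags": result.flags,
        }
        with h5py.File(outdir / "ald_kernels.h5", "a") as f:
            g = f.create_group(aid)
            g.create_dataset("posterior_mean",
                             data=result.posterior.mu.reshape(shape))
            g.create_dataset("lags", data=lags)
            g.attrs["evidence"] = float(result.evidence)
        logger.info("ald fit %s: M = %s", aid,
                    np.round(result.theta.m_entries, 3).tolist())

    thetas = [a.theta for a in analyses.values()]
    pop_theta = population_average(thetas)
    fits_json["population_average"] = _theta_to_json(pop_theta)
    with open(outdir / "ald_fits.json", "w") as fh:
        json.dump(fits_json, fh, indent=2)
    rows = [{"animal_id": aid, **v["theta"], "evidence": v["evidence"]}
            for aid, v in fits_json.items() if aid != "population_average"]
    pd.DataFrame(rows).to_csv(outdir / "ald_fits.csv", index=False)
    return analyses, pop_theta


def _stage_spectra(analyses: dict, ols_kernels: dict, pop_theta: ALDHyperparams,
                   config: RunConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    for aid, an in analyses.items():
        prior = freq_prior_matrix(an.theta.freq_prior, an.shape)
        w_prior = freq_prior_width(prior, config.widths.prior_threshold)
        spec = power_spectrum_2d(ols_kernels[aid].weights)
        w_fft = profile_width(diagonal_profile(spec, "mean"),
                              config.widths.fft_threshold).width
        m = an.theta.m_entries
        full = ALDData.from_xy(
            scipy.sparse.vstack(an.trial_designs).tocsr(),
            np.concatenate(an.trial_ys), an.shape)
        hyper = _ridge_opt(_ridge_cache_from_stats(full))
        rows.append({"animal_id": aid, "prior_width": w_prior,
                     "fft_width": w_fft, "M11": m[0], "M12": m[1], "M22": m[2],
                     "pcv": compute_pcv(an.pupil),
                     "ridge_sigma_p2": hyper.sigma_p2,
                     "ridge_sigma_n2": hyper.sigma_n2,
                     "inv_snr": hyper.sigma_n2 / hyper.sigma_p2})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "spectra.csv", index=False)
    return df


def _bootstrap_statistic(config: RunConfig, pop_theta: ALDHyperparams):
    """Per-(animal, trial-resample) statistic for the hierarchical bootstrap."""
    cfg = config.ald
    # warm-start cache: an animal's resampled optima cluster tightly, so the
    # previous resample's M is the best starting simplex.  Iterations are
    # processed in a fixed order, so results stay reproducible from the seed.
    last_m: dict[str, np.ndarray] = {}

    def statistic(an: AnimalAnalysis, idx: np.ndarray,
                  rng: np.random.Generator) -> dict:
        data = _resampled_data(an, idx)
        # prior parameters at population averages, but the noise variance and
        # the warm-start M stay the animal's own (sigma^2 is a per-dataset
        # noise parameter, not a prior-shape parameter)
        warm = dict(_theta_to_params(pop_theta))
        warm["sigma2"] = an.theta.sigma2
        warm.update(zip(("M11", "M12", "M22"),
                        last_m.get(an.animal_id, an.theta.m_entries)))
        res = refit_M_only(None, None, _params_to_theta(warm), data=data,
                           seed=int(rng.integers(2**31)),
                           n_restarts=cfg.refit_restarts,
                           maxiter=cfg.refit_maxiter,
                           xatol=5e-3, fatol=1e-2)
        last_m[an.animal_id] = res.theta.m_entries
        m = res.theta.m_entries

        cache = _ridge_cache_from_stats(data)
        hyper = _ridge_opt(cache)
        pupil = an.pupil[idx]
        return {
            "M11": float(m[0]), "M12": float(m[1]), "M22": float(m[2]),
            "pcv": compute_pcv(pupil),
            "inv_snr": float(hyper.sigma_n2 / hyper.sigma_p2),
            "resp_sd": float(np.std(an.amplitudes[idx], ddof=1)),
        }

    return statistic


def _ridge_cache_from_stats(data: ALDData) -> _SVDCache:
    """Ridge evidence cache from Gram-matrix statistics (no SVD of X)."""
    evals, V = np.linalg.eigh(data.XtX)
    keep = evals > max(evals.max(), 0) * 1e-12
    lam = evals[keep]
    p = (V.T @ data.XtY)[keep]
    c2 = p**2 / lam
    return _SVDCache(lam=lam, c2=c2, yty=data.YtY, n=data.n,
                     V=V[:, keep], Uty=p / np.sqrt(lam), s=np.sqrt(lam))


def _ridge_opt(cache: _SVDCache) -> RidgeHyperparams:
    import scipy.optimize

    def neg(logs):
        return -_evidence_from_cache(cache, np.exp(logs[0]), np.exp(logs[1]))

    var_y = max(cache.yty / max(cache.n, 1), 1e-7)
    best = None
    for f in (0.1, 10.0):
        res = scipy.optimize.minimize(
            neg, np.log([var_y * f, var_y / f]), method="L-BFGS-B",
            bounds=[(np.log(1e-8), np.log(1e4))] * 2,
            options={"ftol": 1e-8, "maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
    sp2, sn2 = np.exp(best.x)
    return RidgeHyperparams(sigma_p2=float(sp2), sigma_n2=float(sn2))


def _across_with_width(config: RunConfig, pop_theta: ALDHyperparams,
                       shape: tuple[int, int]):
    """Across-animal statistics: widths from n_T-averaged M, then Pearson r."""
    base = _theta_to_params(pop_theta)

    def across(df: pd.DataFrame) -> dict:
        widths = []
        for _, r in df.iterrows():
            p = dict(base)
            p.update({"M11": r["M11"], "M12": r["M12"], "M22": r["M22"]})
            prior = freq_prior_matrix(_params_to_theta(p).freq_prior, shape)
            widths.append(freq_prior_width(prior, config.widths.prior_threshold))
        df = df.assign(width=widths)
        row = {}
        for col in ("M11", "M12", "M22", "pcv", "inv_snr", "width"):
            row[f"mean_{col}"] = float(df[col].mean())
        for m in ("M11", "M12", "M22"):
            row[f"r_{m}_pcv"] = _pearson(df[m], df["pcv"])
            row[f"r_{m}_width"] = _pearson(df[m], df["width"])
        row["r_pcv_inv_snr"] = _pearson(df["pcv"], df["inv_snr"])
        row["r_pcv_resp_sd"] = _pearson(df["pcv"], df["resp_sd"])
        return row

    return across


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


#: correlation columns and the side of zero whose probability must be small
#: for the expected effect direction (positive M-pCV and pCV-1/SNR links,
#: negative M-width link)
EXPECTED_DIRECTIONS = {
    "r_M11_pcv": "lt0", "r_M12_pcv": "lt0", "r_M22_pcv": "lt0",
    "r_M11_width": "gt0", "r_M12_width": "gt0", "r_M22_width": "gt0",
    "r_pcv_inv_snr": "lt0",
}


def _stage_bootstrap(analyses: dict, pop_theta: ALDHyperparams,
                     config: RunConfig, outdir: Path) -> dict:
    shape = next(iter(analyses.values())).shape
    spec = BootstrapSpec(
        n_b=config.bootstrap.n_b, n_a=config.bootstrap.n_a,
        n_t=config.bootstrap.n_t,
        seed=config.master_seed + 77,
        outlier_mad_multiplier=config.bootstrap.outlier_mad_multiplier,
    )
    result = hierarchical_bootstrap(
        analyses, _bootstrap_statistic(config, pop_theta), spec,
        across_fn=_across_with_width(config, pop_theta, shape),
        monitor=["mean_M11", "mean_M12", "mean_M22", "mean_pcv"],
    )
    df = result.iterations.assign(kept=result.kept_mask)
    df.to_csv(outdir / "bootstrap.csv", index=False)

    summary = {"n_b": spec.n_b, "n_kept": int(result.kept_mask.sum()),
               "n_failed": result.n_failed, "p_boot": {}, "mean_r": {}}
    for col, direction in EXPECTED_DIRECTIONS.items():
        vals = result.values(col)
        summary["p_boot"][col] = result.p_boot(col, direction)
        summary["mean_r"][col] = float(np.nanmean(vals))
    with open(outdir / "bootstrap_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def regenerate_report(outdir: str | Path) -> RunReport:
    """Assemble ``report.json`` from the persisted stage outputs only."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    spectra = pd.read_csv(outdir / "spectra.csv")
    with open(outdir / "ald_fits.json") as fh:
        fits = json.load(fh)
    with open(outdir / "bootstrap_summary.json") as fh:
        summary = json.load(fh)

    report = RunReport(
        config=manifest["config"],
        per_animal=spectra.set_index("animal_id").to_dict(orient="index"),
        population_theta=fits["population_average"],
        correlations=summary["mean_r"],
        p_boot=summary["p_boot"],
        seeds={"master_seed": manifest["config"]["master_seed"]},
        version=manifest["version"],
        outdir=str(outdir),
    )
    payload = {
        "config": report.config, "per_animal": report.per_animal,
        "population_theta": report.population_theta,
        "correlations": report.correlations, "p_boot": report.p_boot,
        "seeds": report.seeds, "version": report.version,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return report


def run_experiment(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute every stage in order and write a reproducible report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        manifest = {
            "config": config.model_dump(),
            "config_hash": config.config_hash(),
            "version": __version__,
            "numpy": np.__version__,
        }
        existing = outdir / "manifest.json"
        if existing.exists():
            with open(existing) as fh:
                if json.load(fh).get("config_hash") != manifest["config_hash"]:
                    raise RuntimeError(
                        "run directory holds outputs of a different config; "
                        "refusing to mix stale stages"
                    )
        with open(existing, "w") as fh:
            json.dump(manifest, fh, indent=2)

        logger.info("config hash %s | kernelvar %s | numpy %s | seed %d",
                    manifest["config_hash"], __version__, np.__version__,
                    config.master_seed)
        t0 = time.time()
        cohort = _stage_simulate(config, outdir)
        logger.info("simulate done (%.1f s)", time.time() - t0)

        first_order = _stage_first_order(cohort, config, outdir)
        logger.info("first-order fits done (%.1f s)", time.time() - t0)

        ols_kernels = _stage_interaction(cohort, first_order, config, outdir)
        logger.info("interaction kernels done (%.1f s)", time.time() - t0)

        analyses, pop_theta = _build_analyses(cohort, first_order, config, outdir)
        logger.info("ALD fits done (%.1f s)", time.time() - t0)

        _stage_spectra(analyses, ols_kernels, pop_theta, config, outdir)
        _stage_bootstrap(analyses, pop_theta, config, outdir)
        logger.info("bootstrap done (%.1f s)", time.time() - t0)

        return regenerate_report(outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
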