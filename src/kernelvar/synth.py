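"""Synthetic multi-animal datasets with the structure the analysis assumes.

The generator emulates trial-structured widefield-imaging data from a single
region of interest: per-trial binary event trains (stimulus onset, saccades,
body movements) on a 10 Hz grid, a dF/F response trace built from planted
convolution kernels plus a localized suppressive 2D interaction, per-trial
multiplicative response gain controlled by a latent arousal parameter, and a
stimulus-evoked pupil-area increase whose across-trial variability tracks
that same parameter.

Every generator is a pure function of (spec, seed): the same inputs always
produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import (
    DEFAULT_GRID,
    EVENT_WINDOW,
    INTERACTION_WINDOW,
    STIM_WINDOW,
    Kernel1D,
    Kernel2D,
    TimeGrid,
    lag_grid,
)

__all__ = [
    "AnimalSpec",
    "TrialRecord",
    "GroundTruthKernels",
    "Cohort",
    "default_kernels",
    "generate_event_trains",
    "simulate_trial",
    "simulate_pupil",
    "generate_animal",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

#: Default event-rate parameters: body movements arrive as a Poisson process
#: over the trial; each is paired with a saccade (probability ``pair_prob``)
#: at a Gaussian lag whose sign allows both event orders; extra unpaired
#: saccades arrive independently.
DEFAULT_EVENT_RATES = {
    "body_rate": 1.0,        # expected body movements per trial
    "extra_saccade_rate": 0.3,  # expected unpaired saccades per trial
    "pair_prob": 0.75,       # probability a body movement is paired with a saccade
    "lag_mean": 0.0,         # s, mean saccade-minus-body lag
    "lag_sd": 0.35,          # s, SD of the lag (covers both orders)
    "t_min": None,           # s, earliest event time (None: trial start)
    "t_max": None,           # s, latest event time (None: trial end)
}


@dataclass
class AnimalSpec:
    """Generative parameters for one synthetic animal.

    ``sigma_gain`` is the SD of the log of the per-trial multiplicative
    response gain and embodies the latent arousal-variability construct:
    larger values produce more variable responses and, through
    ``pupil_cv_link``, more variable pupil increases.
    """

    animal_id: str
    n_trials: int = 500
    sigma_gain: float = 0.2
    sigma_noise: float = 0.03          # dF/F units (responses are ~1 at peak)
    pupil_mean_increase: float = 0.1   # mm^2
    pupil_cv_link: float = 1.0         # maps sigma_gain to pupil-increase CV
    event_rate_params: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_RATES))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sigma_gain < 0:
            raise ValueError("sigma_gain must be >= 0")
        if self.pupil_mean_increase <= 0:
            raise ValueError("pupil_mean_increase must be > 0")
        params = dict(DEFAULT_EVENT_RATES)
        params.update(self.event_rate_params)
        self.event_rate_params = params
        for key in ("body_rate", "extra_saccade_rate", "pair_prob", "lag_sd"):
            if params[key] < 0:
                raise ValueError(f"event rate parameter {key!r} must be >= 0")
        if params["t_min"] is not None and params["t_max"] is not None \
                and params["t_max"] < params["t_min"]:
            raise ValueError("t_max must be >= t_min")


@dataclass
class TrialRecord:
    """One trial: binary event trains, dF/F trace, pupil increase.

    ``gain`` is the hidden per-trial multiplicative gain, retained so tests
    can check recovery of the planted structure.
    """

    x_stim: np.ndarray
    x_e: np.ndarray
    x_b: np.ndarray
    y: np.ndarray
    pupil_increase: float
    gain: float


@dataclass
class GroundTruthKernels:
    """Planted kernels: three first-order and one suppressive 2D interaction."""

    w_stim: Kernel1D
    w_e: Kernel1D
    w_b: Kernel1D
    w_be: Kernel2D


def default_kernels(grid: TimeGrid = DEFAULT_GRID) -> GroundTruthKernels:
    """Planted ground truth for the default simulations.

    The stimulus kernel is a positive transient peaking ~0.3 s after onset
    with unit amplitude (responses are therefore expressed in units of the
    peak stimulus response).  Saccade and body kernels are smaller positive
    transients with a weak anticipatory component.  The interaction kernel is
    a negative 2D Gaussian bump centered at small positive lags and elongated
    along the main diagonal, i.e. suppression that depends mostly on the
    relative timing of the two movements.
    """
    dt = grid.dt

    stim_lags = lag_grid(STIM_WINDOW, dt)
    w_stim = np.where(
        stim_lags > 0.0,
        np.exp(-0.5 * ((stim_lags - 0.3) / 0.15) ** 2),
        0.0,
    )
    w_stim[[0, -1]] = 0.0

    ev_lags = lag_grid(EVENT_WINDOW, dt)

    def _event_bump(amp: float, center: float, width: float) -> np.ndarray:
        w = amp * np.exp(-0.5 * ((ev_lags - center) / width) ** 2)
        w[[0, -1]] = 0.0
        return w

    w_e = _event_bump(0.6, 0.25, 0.18)
    w_b = _event_bump(0.8, 0.30, 0.22)

    int_lags = lag_grid(INTERACTION_WINDOW, dt)
    tb, te = np.meshgrid(int_lags, int_lags, indexing="ij")
    # rotate into along/across main-diagonal coordinates
    u = (tb + te) / np.sqrt(2.0)  # along the diagonal
    v = (tb - te) / np.sqrt(2.0)  # across the diagonal (relative lag)
    u0 = 2 * 0.35 / np.sqrt(2.0)  # center at (0.35 s, 0.35 s)
    w_be = -0.4 * np.exp(-0.5 * ((u - u0) / 0.45) ** 2 - 0.5 * (v / 0.18) ** 2)
    w_be[0, :] = w_be[-1, :] = 0.0
    w_be[:, 0] = w_be[:, -1] = 0.0

    return GroundTruthKernels(
        w_stim=Kernel1D(stim_lags, w_stim),
        w_e=Kernel1D(ev_lags, w_e),
        w_b=Kernel1D(ev_lags, w_b),
        w_be=Kernel2D(int_lags, int_lags, w_be),
    )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_event_trains(
    spec: AnimalSpec, grid: TimeGrid = DEFAULT_GRID, rng_seed=0
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-trial binary event trains (x_stim, x_e, x_b) on ``grid``.

    Body-movement onsets arrive as a Poisson process thinned to the trial
    window; each is paired with a saccade at a Gaussian lag (both orders
    possible through the sign of the lag); independent extra saccades are
    superimposed.  Events are snapped to the nearest grid bin; events whose
    times fall outside the grid are dropped.
    """
    p = spec.event_rate_params
    rng = _rng(rng_seed)
    n = grid.n_bins
    t_min = grid.t_start if p["t_min"] is None else max(p["t_min"], grid.t_start)
    t_max = grid.t_end if p["t_max"] is None else min(p["t_max"], grid.t_end)

    trials = []
    for _ in range(spec.n_trials):
        x_stim = np.zeros(n)
        x_stim[grid.stim_bin] = 1.0
        x_e = np.zeros(n)
        x_b = np.zeros(n)

        n_body = rng.poisson(p["body_rate"])
        body_times = rng.uniform(t_min, t_max, size=n_body)
        for tb in body_times:
            x_b[grid.bin_of(tb)] = 1.0
            if rng.uniform() < p["pair_prob"]:
                ts = tb + rng.normal(p["lag_mean"], p["lag_sd"])
                if t_min <= ts <= t_max:
                    x_e[grid.bin_of(ts)] = 1.0
        n_sac = rng.poisson(p["extra_saccade_rate"])
        for ts in rng.uniform(t_min, t_max, size=n_sac):
            x_e[grid.bin_of(ts)] = 1.0

        trials.append((x_stim, x_e, x_b))
    return trials


def _convolve_events(x: np.ndarray, kernel: Kernel1D, grid: TimeGrid) -> np.ndarray:
    """Sum of kernel copies placed at each event time (finite-window conv)."""
    y = np.zeros(grid.n_bins)
    lag_bins = np.round(kernel.lags / grid.dt).astype(int)
    for t0 in np.flatnonzero(x):
        for lb, w in zip(lag_bins, kernel.weights):
            t = t0 + lb
            if 0 <= t < grid.n_bins:
                y[t] += w
    return y


def _interaction_response(
    x_b: np.ndarray, x_e: np.ndarray, w_be: Kernel2D, grid: TimeGrid
) -> np.ndarray:
    """2D term: y(t) += w_be[t - t_b, t - t_e] summed over event pairs."""
    y = np.zeros(grid.n_bins)
    b_bins = np.round(w_be.body_lags / grid.dt).astype(int)
    e_bins = np.round(w_be.saccade_lags / grid.dt).astype(int)
    body_times = np.flatnonzero(x_b)
    sac_times = np.flatnonzero(x_e)
    for tb in body_times:
        for te in sac_times:
            for i, lb in enumerate(b_bins):
                t = tb + lb
                if not (0 <= t < grid.n_bins):
                    continue
                j = t - te  # saccade lag in bins
                k = np.searchsorted(e_bins, j)
                if k < e_bins.size and e_bins[k] == j:
                    y[t] += w_be.weights[i, k]
    return y


def simulate_trial(
    kernels: GroundTruthKernels,
    events: tuple[np.ndarray, np.ndarray, np.ndarray],
    gain: float = 1.0,
    sigma_noise: float = 0.0,
    rng_seed=0,
    grid: TimeGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Simulate one dF/F trace from planted kernels and event trains.

    ``y = gain * (w_stim*x_stim + w_e*x_e + w_b*x_b + interaction) + noise``
    where each ``*`` is the finite-window convolution of :mod:`kernelvar.core`.
    """
    x_stim, x_e, x_b = events
    for x in (x_stim, x_e, x_b):
        if len(x) != grid.n_bins:
            raise ValueError("event train length does not match grid")
    signal = (
        _convolve_events(x_stim, kernels.w_stim, grid)
        + _convolve_events(x_e, kernels.w_e, grid)
        + _convolve_events(x_b, kernels.w_b, grid)
        + _interaction_response(x_b, x_e, kernels.w_be, grid)
    )
    y = gain * signal
    if sigma_noise > 0:
        y = y + _rng(rng_seed).normal(0.0, sigma_noise, size=grid.n_bins)
    return y


def simulate_pupil(spec: AnimalSpec, gains: np.ndarray, rng_seed=0) -> np.ndarray:
    """Per-trial stimulus-evoked pupil-area increases (mm^2).

    Increases are Normal(mean, cv_link * sigma_gain * mean) truncated at 0,
    so the ground-truth pupil CV equals ``pupil_cv_link * sigma_gain`` up to
    the (negligible at defaults) truncation.  ``gains`` fixes the number of
    trials; the draw is coupled to arousal only through ``sigma_gain``.
    """
    rng = _rng(rng_seed)
    n = len(gains)
    sd = spec.pupil_cv_link * spec.sigma_gain * spec.pupil_mean_increase
    if sd == 0:
        return np.full(n, spec.pupil_mean_increase)
    draws = rng.normal(spec.pupil_mean_increase, sd, size=n)
    return np.maximum(draws, 0.0)


def generate_animal(
    spec: AnimalSpec,
    kernels: GroundTruthKernels,
    grid: TimeGrid = DEFAULT_GRID,
    rng_seed=0,
) -> list[TrialRecord]:
    """All trials of one animal: events, gains, responses, pupil increases."""
    seed = rng_seed if spec.seed is None else spec.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_events, s_gain, s_noise, s_pupil = ss.spawn(4)
    events = generate_event_trains(spec, grid, s_events)
    gains = np.exp(_rng(s_gain).normal(0.0, spec.sigma_gain, size=spec.n_trials))
    pupil = simulate_pupil(spec, gains, s_pupil)
    noise_rng = _rng(s_noise)
    trials = []
    for i, ev in enumerate(events):
        y = simulate_trial(kernels, ev, gains[i], 0.0, 0, grid)
        if spec.sigma_noise > 0:
            y = y + noise_rng.normal(0.0, spec.sigma_noise, size=grid.n_bins)
        trials.append(
            TrialRecord(
                x_stim=ev[0], x_e=ev[1], x_b=ev[2],
                y=y, pupil_increase=float(pupil[i]), gain=float(gains[i]),
            )
        )
    return trials


@dataclass
class Cohort:
    """A multi-animal synthetic dataset plus the ground truth that made it."""

    grid: TimeGrid
    kernels: GroundTruthKernels
    specs: list[AnimalSpec]
    animals: dict[str, list[TrialRecord]]
    master_seed: int = 0

    @property
    def animal_ids(self) -> list[str]:
        return [s.animal_id for s in self.specs]


def generate_cohort(
    specs: list[AnimalSpec],
    grid: TimeGrid = DEFAULT_GRID,
    master_seed: int = 0,
    kernels: GroundTruthKernels | None = None,
) -> Cohort:
    """Generate a cohort; per-animal seeds derive deterministically from
    ``master_seed`` (independent of animal order in ``specs``... they follow
    the list position, so identical spec lists reproduce identically)."""
    if kernels is None:
        kernels = default_kernels(grid)
    animals = {}
    children = np.random.SeedSequence(master_seed).spawn(len(specs))
    for spec, child in zip(specs, children):
        animals[spec.animal_id] = generate_animal(spec, kernels, grid, child)
    return Cohort(grid=grid, kernels=kernels, specs=specs,
                  animals=animals, master_seed=master_seed)


# ---------------------------------------------------------------------------
# serialization: HDF5 arrays + CSV trial table + YAML spec echo
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write ``dataset.h5``, ``trials.csv`` and ``cohort.yaml`` to ``outdir``.

    HDF5 layout: one group per animal with datasets ``x_stim``, ``x_e``,
    ``x_b``, ``y`` (n_trials x n_bins), ``pupil_increase`` and ``gain``;
    root attributes hold the grid; group ``ground_truth`` holds the planted
    kernels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with h5py.File(outdir / "dataset.h5", "w") as f:
        f.attrs["dt"] = cohort.grid.dt
        f.attrs["t_start"] = cohort.grid.t_start
        f.attrs["t_end"] = cohort.grid.t_end
        f.attrs["master_seed"] = cohort.master_seed
        gt = f.create_group("ground_truth")
        for name in ("w_stim", "w_e", "w_b"):
            k: Kernel1D = getattr(cohort.kernels, name)
            g = gt.create_group(name)
            g.create_dataset("lags", data=k.lags)
            g.create_dataset("weights", data=k.weights)
        g = gt.create_group("w_be")
        g.create_dataset("body_lags", data=cohort.kernels.w_be.body_lags)
        g.create_dataset("saccade_lags", data=cohort.kernels.w_be.saccade_lags)
        g.create_dataset("weights", data=cohort.kernels.w_be.weights)
        for aid, trials in cohort.animals.items():
            g = f.create_group(f"animals/{aid}")
            for name in ("x_stim", "x_e", "x_b", "y"):
                g.create_dataset(
                    name, data=np.stack([getattr(t, name) for t in trials])
                )
            g.create_dataset("pupil_increase",
                             data=np.array([t.pupil_increase for t in trials]))
            g.create_dataset("gain", data=np.array([t.gain for t in trials]))

    rows = []
    for aid, trials in cohort.animals.items():
        for i, t in enumerate(trials):
            rows.append({"animal_id": aid, "trial_id": i,
                         "pupil_increase": t.pupil_increase, "gain": t.gain})
    pd.DataFrame(rows).to_csv(outdir / "trials.csv", index=False)

    echo = {
        "master_seed": int(cohort.master_seed),
        "grid": {"dt": cohort.grid.dt, "t_start": cohort.grid.t_start,
                 "t_end": cohort.grid.t_end},
        "animals": [
            {k: (v if not isinstance(v, dict) else dict(v))
             for k, v in asdict(s).items()}
            for s in cohort.specs
        ],
    }
    with open(outdir / "cohort.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(echo)), fh, sort_keys=False)


def load_cohort(outdir: str | Path) -> Cohort:
    """Reload a cohort written by :func:`save_cohort` (bit-identical)."""
    outdir = Path(outdir)
    with open(outdir / "cohort.yaml") as fh:
        echo = yaml.safe_load(fh)
    grid = TimeGrid(**echo["grid"])
    specs = [AnimalSpec(**a) for a in echo["animals"]]
    with h5py.File(outdir / "dataset.h5", "r") as f:
        gt = f["ground_truth"]
        kernels = GroundTruthKernels(
            w_stim=Kernel1D(gt["w_stim/lags"][()], gt["w_stim/weights"][()]),
            w_e=Kernel1D(gt["w_e/lags"][()], gt["w_e/weights"][()]),
            w_b=Kernel1D(gt["w_b/lags"][()], gt["w_b/weights"][()]),
            w_be=Kernel2D(gt["w_be/body_lags"][()], gt["w_be/saccade_lags"][()],
                          gt["w_be/weights"][()]),
        )
        animals: dict[str, list[TrialRecord]] = {}
        for spec in specs:
            g = f[f"animals/{spec.animal_id}"]
            x_stim, x_e, x_b, y = (g[n][()] for n in ("x_stim", "x_e", "x_b", "y"))
            pupil, gain = g["pupil_increase"][()], g["gain"][()]
            animals[spec.animal_id] = [
                TrialRecord(x_stim[i], x_e[i], x_b[i], y[i],
                            float(pupil[i]), float(gain[i]))
                for i in range(y.shape[0])
            ]
        master_seed = int(f.attrs["master_seed"])
    return Cohort(grid=grid, kernels=kernels, specs=specs,
                  animals=animals, master_seed=master_seed)
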