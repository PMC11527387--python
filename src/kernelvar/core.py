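"""Shared containers: the trial time grid and 1D/2D convolution kernels.

Conventions used throughout the package:

* Time is discretized at ``dt`` = 0.1 s (10 Hz).  A trial covers
  [-1.0, 1.5] s around stimulus onset, inclusive on both ends, which gives
  26 bins with the stimulus-onset bin at t = 0.
* Kernels act both causally and anti-causally: the response contribution of
  an event at time ``t0`` is ``w[tau]`` placed at ``t = t0 + tau`` for every
  lag ``tau`` in the kernel window.  Lags that fall outside the trial window
  simply contribute nothing (no wrap-around, no padding).
* 2D interaction kernels are indexed ``[body_lag, saccade_lag]``; a
  "diagonal" (top-left to bottom-right) holds a fixed relative lag between
  the two events, while "anti-diagonals" (bottom-left to top-right) are used
  for spectral profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "Kernel1D",
    "Kernel2D",
    "DEFAULT_GRID",
    "STIM_WINDOW",
    "EVENT_WINDOW",
    "INTERACTION_WINDOW",
    "lag_grid",
]

#: Lag window of the stimulus kernel (covers the whole trial).
STIM_WINDOW = (-1.0, 1.5)
#: Lag window of the saccade and body-movement kernels.
EVENT_WINDOW = (-0.3, 2.0)
#: Per-axis lag window of the 2D saccade-body interaction kernel.
INTERACTION_WINDOW = (-0.3, 1.7)


def lag_grid(window: tuple[float, float], dt: float = 0.1) -> np.ndarray:
    """Uniform lag grid over ``window`` (inclusive) at resolution ``dt``."""
    lo, hi = window
    n = int(round((hi - lo) / dt)) + 1
    return lo + dt * np.arange(n)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform trial time grid around stimulus onset."""

    dt: float = 0.1
    t_start: float = -1.0
    t_end: float = 1.5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        # stimulus onset (t = 0) must land on a bin
        k = -self.t_start / self.dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError("t = 0 must coincide with a grid bin")

    @property
    def n_bins(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_bins)

    @property
    def stim_bin(self) -> int:
        """Index of the bin containing t = 0 (stimulus onset)."""
        return int(round(-self.t_start / self.dt))

    def bin_of(self, t: float) -> int:
        """Nearest bin index for time ``t``; raises if outside the grid."""
        idx = int(round((t - self.t_start) / self.dt))
        if idx < 0 or idx >= self.n_bins:
            raise ValueError(f"time {t} outside grid [{self.t_start}, {self.t_end}]")
        return idx


DEFAULT_GRID = TimeGrid()


@dataclass
class Kernel1D:
    """A 1D convolution kernel on a uniform lag grid (dF/F per event)."""

    lags: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.lags.shape != self.weights.shape or self.lags.ndim != 1:
            raise ValueError("lags and weights must be matching 1D arrays")
        if self.lags.size > 1 and not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if self.lags.size > 1 else 0.0


@dataclass
class Kernel2D:
    """A 2D interaction kernel over (body-lag, saccade-lag) pairs.

    ``weights[i, j]`` is the deviation from additive summation when a body
    movement occurred ``body_lags[i]`` and a saccade ``saccade_lags[j]``
    seconds before the current time bin.  ``trial_counts`` records how many
    trials supported the estimate of each bin, and ``mask`` is True where the
    support fell below the minimum-trial threshold (those weights are not
    interpretable).
    """

    body_lags: np.ndarray
    saccade_lags: np.ndarray
    weights: np.ndarray
    trial_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.body_lags = np.asarray(self.body_lags, dtype=float)
        self.saccade_lags = np.asarray(self.saccade_lags, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        shape = (self.body_lags.size, self.saccade_lags.size)
        if self.weights.shape != shape:
            raise ValueError(f"weights shape {self.weights.shape} != {shape}")
        if self.trial_counts is None:
            self.trial_counts = np.zeros(shape, dtype=int)
        else:
            self.trial_counts = np.asarray(self.trial_counts, dtype=int)
        if self.mask is None:
            self.mask = np.zeros(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        for arr, name in ((self.trial_counts, "trial_counts"), (self.mask, "mask")):
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @property
    def dt(self) -> float:
        return float(self.body_lags[1] - self.body_lags[0])

    def masked_weights(self) -> np.ndarray:
        """Weights with masked (under-sampled) bins set to NaN."""
        out = self.weights.copy()
        out[self.mask] = np.nan
        return out
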