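"""Spectral and diagonal statistics of 2D kernels and priors.

Orientation conventions (stated once, used everywhere):

* "anti-diagonals" run bottom-left to top-right (entries with constant
  ``row + col``); they are used for spectral profiles and threshold widths;
* "diagonals" run top-left to bottom-right (entries with constant
  ``col - row``); in a time-domain interaction kernel a diagonal holds a
  fixed relative lag between the two events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Kernel2D

__all__ = [
    "DiagonalProfile",
    "WidthResult",
    "BroadenProfile",
    "power_spectrum_2d",
    "diagonal_profile",
    "profile_width",
    "freq_prior_width",
    "diagonal_std",
    "broaden_spectrum",
]

#: Threshold fractions of the profile maximum used for widths.
PRIOR_WIDTH_THRESHOLD = 0.02   # ALD frequency-domain priors
FFT_WIDTH_THRESHOLD = 0.15     # Fourier transforms of OLS kernels


def _weights(K) -> np.ndarray:
    return K.weights if isinstance(K, Kernel2D) else np.asarray(K, dtype=float)


@dataclass
class DiagonalProfile:
    """Per-anti-diagonal aggregate of a matrix."""

    offsets: np.ndarray     # row + col index, 0 .. n1 + n2 - 2
    values: np.ndarray
    aggregate_kind: str     # "sum" or "mean"


@dataclass
class WidthResult:
    """Number of anti-diagonals at or above a fraction of the profile max."""

    width: int
    threshold_fraction: float
    baseline_subtracted: bool


def power_spectrum_2d(K) -> np.ndarray:
    """Magnitude of the 2D DFT with zero frequency at the center."""
    W = _weights(K)
    return np.abs(np.fft.fftshift(np.fft.fft2(W)))


def diagonal_profile(A, aggregate_kind: str = "sum") -> DiagonalProfile:
    """Aggregate each anti-diagonal (constant ``row + col``) of a matrix."""
    W = _weights(A)
    n1, n2 = W.shape
    agg = {"sum": np.sum, "mean": np.mean}.get(aggregate_kind)
    if agg is None:
        raise ValueError(f"unknown aggregate_kind {aggregate_kind!r}")
    flipped = np.fliplr(W)  # anti-diagonals become diagonals
    values = np.array([
        agg(np.diagonal(flipped, offset=k)) for k in range(n2 - 1, -n1, -1)
    ])
    return DiagonalProfile(offsets=np.arange(n1 + n2 - 1), values=values,
                           aggregate_kind=aggregate_kind)


def profile_width(p: DiagonalProfile, threshold_fraction: float,
                  subtract_min: bool = True) -> WidthResult:
    """Width of a profile at ``threshold_fraction`` of its maximum.

    Counts every anti-diagonal at or above the threshold (no interpolation:
    with at most ~41 diagonals, sub-bin interpolation would fabricate
    precision).  A profile that is flat after min-subtraction has no scale to
    threshold against; the width then defaults to the full support, with a
    warning.
    """
    vals = p.values.astype(float)
    if subtract_min:
        vals = vals - vals.min()
    peak = vals.max()
    if peak <= 0:
        warnings.warn("flat profile: width defaults to the full support")
        return WidthResult(width=vals.size, threshold_fraction=threshold_fraction,
                           baseline_subtracted=subtract_min)
    width = int(np.sum(vals >= threshold_fraction * peak))
    return WidthResult(width=width, threshold_fraction=threshold_fraction,
                       baseline_subtracted=subtract_min)


def freq_prior_width(prior_matrix: np.ndarray,
                     threshold_fraction: float = PRIOR_WIDTH_THRESHOLD,
                     aggregate_kind: str = "sum") -> int:
    """Anti-diagonal threshold width of a frequency-domain prior magnitude."""
    return profile_width(diagonal_profile(prior_matrix, aggregate_kind),
                         threshold_fraction).width


def diagonal_std(K, lag_range: tuple[float, float] = (-0.8, 0.8),
                 dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Standard deviation along each kernel diagonal (fixed relative lag).

    Only diagonals whose relative lag falls inside ``lag_range`` (seconds)
    are included.  Masked (under-sampled) bins are excluded; diagonals with
    fewer than two valid entries are skipped.  Returns ``(offsets_seconds,
    sds)``.
    """
    if isinstance(K, Kernel2D):
        W = K.masked_weights()
        dt = K.dt if dt is None else dt
    else:
        W = np.asarray(K, dtype=float)
        if dt is None:
            raise ValueError("dt required for raw arrays")
    n1, n2 = W.shape
    offs, sds = [], []
    for k in range(-(n1 - 1), n2):
        lag = k * dt
        if lag < lag_range[0] - 1e-9 or lag > lag_range[1] + 1e-9:
            continue
        diag = np.diagonal(W, offset=k)
        diag = diag[np.isfinite(diag)]
        if diag.size < 2:
            continue
        offs.append(lag)
        sds.append(np.std(diag, ddof=1))
    return np.array(offs), np.array(sds)


@dataclass
class BroadenProfile:
    """Multiplicative modulation of a power spectrum's magnitude.

    The profile is a lognormal function of distance from the main
    anti-diagonal of the centered spectrum (shifted by ``offset_shift`` bins
    so the main anti-diagonal itself is not zeroed) times a ``1/(1 + r)``
    function of radial distance from the center; both factors are symmetric
    under point reflection so the modulated spectrum stays that of a real
    kernel.  The combination amplifies low frequencies around the origin,
    which broadens the power spectrum.
    """

    lognorm_mu: float = 0.0
    lognorm_sigma: float = 1.0
    offset_shift: float = 0.5

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        n1, n2 = shape
        u = np.arange(n1) - n1 // 2
        v = np.arange(n2) - n2 // 2
        gu, gv = np.meshgrid(u, v, indexing="ij")
        d = np.abs(gu + gv) + self.offset_shift   # distance from main anti-diagonal
        r = np.sqrt(gu.astype(float) ** 2 + gv.astype(float) ** 2)
        lognorm = np.exp(-0.5 * ((np.log(d) - self.lognorm_mu)
                                 / self.lognorm_sigma) ** 2) / d
        prof = lognorm / (1.0 + r)
        # unit mean: frequencies near the origin/main anti-diagonal are scaled
        # up, the rest down, so the low-frequency (broad, suppressive) content
        # genuinely gains amplitude
        return prof / prof.mean()


def broaden_spectrum(K, profile=None) -> np.ndarray | Kernel2D:
    """Rescale a kernel's DFT magnitude by a profile, keeping its phase.

    ``profile`` is a :class:`BroadenProfile`, a centered modulation matrix of
    the kernel's shape, or None for the default profile.  The output is the
    inverse DFT of (modulated magnitude x original phase); with a
    point-symmetric profile the result is real up to numerical residue,
    which is discarded after verification.
    """
    W = _weights(K)
    if profile is None:
        profile = BroadenProfile()
    P = profile.matrix(W.shape) if isinstance(profile, BroadenProfile) \
        else np.asarray(profile, dtype=float)
    if P.shape != W.shape:
        raise ValueError("modulation profile shape mismatch")
    if np.any(P < 0):
        raise ValueError("modulation profile must be non-negative")

    F = np.fft.fft2(W)
    mag = np.abs(F)
    phase = np.where(mag > 0, F / np.where(mag > 0, mag, 1.0), 1.0)
    new_mag = np.fft.ifftshift(P) * mag
    out = np.fft.ifft2(new_mag * phase)
    if np.max(np.abs(out.imag)) > 1e-9 * max(np.max(np.abs(out.real)), 1e-300):
        raise ValueError("modulated spectrum is not that of a real kernel")
    Wout = out.real
    if isinstance(K, Kernel2D):
        return Kernel2D(K.body_lags, K.saccade_lags, Wout,
                        K.trial_counts, K.mask)
    return Wout
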