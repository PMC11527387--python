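"""Design matrices, trial selection and sequential GLM kernel estimation.

The encoding model is ``y(t) = sum_i w_i * x_i + eps``: a linear model in
lagged copies of binary event trains, plus a second-order term whose input is
the outer product of the body-movement and saccade trains.  Because the
stimulus co-occurs with movements, kernels are fitted in a sequence — the
stimulus kernel on movement-free trials, the two movement kernels on the
residuals of temporally isolated single events, and the 2D interaction
kernel on the residuals of trials with co-occurring events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse

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
from .synth import TrialRecord

__all__ = [
    "DesignMatrix",
    "TrialSelection",
    "ResidualTrial",
    "SequentialFitResult",
    "baseline_correct",
    "select_trials",
    "build_design_1d",
    "build_design_2d",
    "ols_fit",
    "sequential_fit",
    "fit_interaction_kernel",
    "normalize_to_stimulus",
]

BASELINE_WINDOW = (-1.0, -0.8)  # s, pre-stimulus baseline
MIN_TRIALS_PER_BIN = 10         # interaction-kernel bins with fewer are masked


@dataclass
class DesignMatrix:
    """Lagged-event design; rows are time bins, columns kernel dimensions.

    ``column_index[j]`` is the lag (seconds) of column ``j`` for 1D designs,
    or the ``(body_lag, saccade_lag)`` pair for 2D designs.
    """

    values: np.ndarray | scipy.sparse.spmatrix
    column_index: list

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class TrialSelection:
    """Partition of trial ids by the roles they play in the fitting sequence."""

    clean_ids: list[int] = field(default_factory=list)
    isolated_saccade_ids: list[int] = field(default_factory=list)
    isolated_body_ids: list[int] = field(default_factory=list)
    interaction_ids: list[int] = field(default_factory=list)
    discarded_ids: list[int] = field(default_factory=list)


def baseline_correct(y: np.ndarray, grid: TimeGrid = DEFAULT_GRID,
                     window: tuple[float, float] = BASELINE_WINDOW) -> np.ndarray:
    """Subtract the mean dF/F over the pre-stimulus baseline window."""
    lo, hi = window
    if lo < grid.t_start - 1e-9 or hi > grid.t_end + 1e-9:
        raise ValueError("baseline window outside grid")
    times = grid.times
    sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    return y - y[sel].mean()


def _event_bins(trial: TrialRecord) -> tuple[np.ndarray, np.ndarray]:
    return np.flatnonzero(trial.x_e), np.flatnonzero(trial.x_b)


def select_trials(trials: list[TrialRecord], grid: TimeGrid = DEFAULT_GRID,
                  isolation_window: float = 1.0) -> TrialSelection:
    """Assign trials to the roles used by :func:`sequential_fit`.

    * discarded: any movement during the baseline window [-1, -0.8] s;
    * clean: no saccade and no body movement anywhere in the trial;
    * isolated saccade / body: exactly one event of that type and no other
      movement event within ``isolation_window`` seconds of it;
    * interaction: at least one saccade and one body movement (co-occurring
      pair) — these provide the 2D residuals.

    The isolated sets can overlap the interaction set when the events are
    farther apart than ``isolation_window``; all sets exclude discarded
    trials.
    """
    sel = TrialSelection()
    times = grid.times
    base = (times >= BASELINE_WINDOW[0] - 1e-9) & (times <= BASELINE_WINDOW[1] + 1e-9)
    iso_bins = int(round(isolation_window / grid.dt))

    for i, tr in enumerate(trials):
        e_bins, b_bins = _event_bins(tr)
        movement = tr.x_e.astype(bool) | tr.x_b.astype(bool)
        if movement[base].any():
            sel.discarded_ids.append(i)
            continue
        if e_bins.size == 0 and b_bins.size == 0:
            sel.clean_ids.append(i)
            continue
        if e_bins.size >= 1 and b_bins.size >= 1:
            sel.interaction_ids.append(i)
        if e_bins.size == 1:
            others = b_bins
            if not np.any(np.abs(others - e_bins[0]) <= iso_bins):
                sel.isolated_saccade_ids.append(i)
        if b_bins.size == 1:
            others = e_bins
            if not np.any(np.abs(others - b_bins[0]) <= iso_bins):
                sel.isolated_body_ids.append(i)
    return sel


def _lag_bins(lag_window: tuple[float, float], dt: float) -> np.ndarray:
    return np.round(lag_grid(lag_window, dt) / dt).astype(int)


def build_design_1d(events, lag_window: tuple[float, float],
                    grid: TimeGrid = DEFAULT_GRID) -> DesignMatrix:
    """Design with ``entry(t, tau) = x(t - tau)``.

    ``events`` is one binary train or a list of trains; trains are stacked
    row-wise (one block of ``grid.n_bins`` rows per trial).
    """
    if isinstance(events, np.ndarray) and events.ndim == 1:
        events = [events]
    lags = lag_grid(lag_window, grid.dt)
    lag_b = _lag_bins(lag_window, grid.dt)
    n = grid.n_bins
    blocks = []
    for x in events:
        X = np.zeros((n, lag_b.size))
        for j, lb in enumerate(lag_b):
            lo = max(0, lb)
            hi = min(n, n + lb)
            if lo < hi:
                X[lo:hi, j] = x[lo - lb:hi - lb]
        blocks.append(X)
    return DesignMatrix(values=np.vstack(blocks), column_index=list(lags))


def build_design_2d(x_b: np.ndarray, x_e: np.ndarray,
                    lag_window: tuple[float, float] = INTERACTION_WINDOW,
                    grid: TimeGrid = DEFAULT_GRID,
                    sparse: bool = False) -> DesignMatrix:
    """Outer-product design: ``entry(t, (tau_b, tau_e)) = x_b(t-tau_b) x_e(t-tau_e)``.

    Columns are ordered row-major over the (body-lag, saccade-lag) grid, the
    same order as ``Kernel2D.weights.ravel()``.
    """
    lags = lag_grid(lag_window, grid.dt)
    lag_b = _lag_bins(lag_window, grid.dt)
    n = grid.n_bins
    d = lag_b.size
    cols = [(tb, te) for tb in lags for te in lags]

    b_ev = np.flatnonzero(x_b)
    e_ev = np.flatnonzero(x_e)
    rows_idx, cols_idx, vals = [], [], []
    for t in range(n):
        tb_lags = t - b_ev   # body lags hit at this row
        te_lags = t - e_ev
        tb_ok = tb_lags[(tb_lags >= lag_b[0]) & (tb_lags <= lag_b[-1])]
        te_ok = te_lags[(te_lags >= lag_b[0]) & (te_lags <= lag_b[-1])]
        for lb in tb_ok:
            i = int(lb - lag_b[0])
            for le in te_ok:
                j = int(le - lag_b[0])
                rows_idx.append(t)
                cols_idx.append(i * d + j)
                vals.append(1.0)
    mat = scipy.sparse.coo_matrix(
        (vals, (rows_idx, cols_idx)), shape=(n, d * d)
    ).tocsr()
    # repeated event pairs hitting the same (row, col) must stay binary
    mat.data = np.minimum(mat.data, 1.0)
    values = mat if sparse else np.asarray(mat.todense())
    return DesignMatrix(values=values, column_index=cols)


def ols_fit(X, y: np.ndarray, allow_pinv: bool = False) -> np.ndarray:
    """Ordinary least squares via the normal equation.

    Raises a singularity error naming the offending columns on rank
    deficiency unless ``allow_pinv`` requests a minimum-norm solution.
    """
    Xv = X.values if isinstance(X, DesignMatrix) else X
    if scipy.sparse.issparse(Xv):
        Xv = np.asarray(Xv.todense())
    Xv = np.asarray(Xv, dtype=float)
    y = np.asarray(y, dtype=float)
    gram = Xv.T @ Xv
    xty = Xv.T @ y
    d = Xv.shape[1]
    rank = np.linalg.matrix_rank(Xv)
    if rank < d:
        if allow_pinv:
            return np.linalg.pinv(Xv) @ y
        _, _, piv = scipy.linalg.qr(Xv, pivoting=True, mode="economic")
        offending = sorted(piv[rank:].tolist())
        if isinstance(X, DesignMatrix):
            offending = [X.column_index[j] for j in offending]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {d}); "
            f"offending columns: {offending}"
        )
    return np.linalg.solve(gram, xty)


@dataclass
class ResidualTrial:
    """Events plus the dF/F residual after removing first-order predictions."""

    trial_id: int
    x_b: np.ndarray
    x_e: np.ndarray
    y: np.ndarray


@dataclass
class SequentialFitResult:
    w_stim: Kernel1D | None
    w_e: Kernel1D | None
    w_b: Kernel1D | None
    residual_trials: list[ResidualTrial]
    flags: dict


def _fit_stage(X: DesignMatrix, y: np.ndarray, regularizer: str,
               allow_pinv: bool = False) -> np.ndarray:
    if regularizer == "ols":
        return ols_fit(X, y, allow_pinv=allow_pinv)
    if regularizer == "ridge":
        from .ridge import ridge_evidence

        hyper, w, _ = ridge_evidence(np.asarray(X.values), y)
        return w
    raise ValueError(f"unknown regularizer {regularizer!r}")


def sequential_fit(trials: list[TrialRecord], selection: TrialSelection,
                   grid: TimeGrid = DEFAULT_GRID, regularizer: str = "ols",
                   min_stage_trials: int = 3,
                   allow_pinv: bool = False) -> SequentialFitResult:
    """Three-stage kernel estimation.

    1. Stimulus kernel on clean trials (full [-1, 1.5] s window).
    2. Saccade and body kernels on isolated-event residuals after removing
       the stimulus prediction.
    3. Residuals of interaction trials after removing all three first-order
       predictions; these feed :func:`fit_interaction_kernel`.

    Traces are baseline-corrected before any fitting.  With ``allow_pinv``
    an under-determined movement-kernel design (event lags no trial can
    support) yields the minimum-norm solution, flagged, instead of aborting
    the stage.
    """
    flags: dict = {"regularizer": regularizer}
    corrected = [baseline_correct(t.y, grid) for t in trials]

    # --- stage 1: stimulus kernel ------------------------------------------
    if len(selection.clean_ids) < min_stage_trials:
        flags["stimulus"] = "insufficient trials"
        return SequentialFitResult(None, None, None, [], flags)
    stim_lags = lag_grid(STIM_WINDOW, grid.dt)
    X = build_design_1d([trials[i].x_stim for i in selection.clean_ids],
                        STIM_WINDOW, grid)
    y = np.concatenate([corrected[i] for i in selection.clean_ids])
    w_stim = Kernel1D(stim_lags, _fit_stage(X, y, regularizer))

    stim_pred = build_design_1d(trials[0].x_stim, STIM_WINDOW, grid).values @ \
        w_stim.weights  # x_stim is identical across trials

    # --- stage 2: movement kernels on stimulus residuals -------------------
    ev_lags = lag_grid(EVENT_WINDOW, grid.dt)

    def _movement_kernel(ids: list[int], attr: str) -> Kernel1D | None:
        if len(ids) < min_stage_trials:
            flags[attr] = "insufficient trials"
            return None
        Xm = build_design_1d([getattr(trials[i], attr) for i in ids],
                             EVENT_WINDOW, grid)
        ym = np.concatenate([corrected[i] - stim_pred for i in ids])
        try:
            return Kernel1D(ev_lags, _fit_stage(Xm, ym, regularizer))
        except np.linalg.LinAlgError as err:
            if allow_pinv:
                flags[attr] = "singular design: minimum-norm solution used"
                return Kernel1D(ev_lags,
                                _fit_stage(Xm, ym, regularizer, allow_pinv=True))
            flags[attr] = f"singular design: {err}"
            return None

    w_e = _movement_kernel(selection.isolated_saccade_ids, "x_e")
    w_b = _movement_kernel(selection.isolated_body_ids, "x_b")

    # --- stage 3: interaction residuals ------------------------------------
    residual_trials: list[ResidualTrial] = []
    if w_e is not None and w_b is not None:
        for i in selection.interaction_ids:
            pred = stim_pred.copy()
            pred += build_design_1d(trials[i].x_e, EVENT_WINDOW, grid).values @ w_e.weights
            pred += build_design_1d(trials[i].x_b, EVENT_WINDOW, grid).values @ w_b.weights
            residual_trials.append(
                ResidualTrial(trial_id=i, x_b=trials[i].x_b, x_e=trials[i].x_e,
                              y=corrected[i] - pred)
            )
    else:
        flags["interaction"] = "skipped: missing first-order kernels"
    return SequentialFitResult(w_stim, w_e, w_b, residual_trials, flags)


def stack_interaction_design(
    residuals: list[ResidualTrial],
    lag_window: tuple[float, float] = INTERACTION_WINDOW,
    grid: TimeGrid = DEFAULT_GRID,
) -> tuple[scipy.sparse.csr_matrix, np.ndarray, np.ndarray, list]:
    """Stacked sparse 2D design, response vector and per-column trial counts."""
    designs, ys = [], []
    d2 = None
    counts = None
    col_index = None
    for rt in residuals:
        dm = build_design_2d(rt.x_b, rt.x_e, lag_window, grid, sparse=True)
        if d2 is None:
            d2 = dm.values.shape[1]
            counts = np.zeros(d2, dtype=int)
            col_index = dm.column_index
        counts += np.asarray((dm.values != 0).sum(axis=0)).ravel() > 0
        designs.append(dm.values)
        ys.append(rt.y)
    if not designs:
        raise ValueError("no residual trials to fit")
    X = scipy.sparse.vstack(designs).tocsr()
    return X, np.concatenate(ys), counts, col_index


def fit_interaction_kernel(
    residuals: list[ResidualTrial],
    method: str = "ols",
    min_trials: int = MIN_TRIALS_PER_BIN,
    lag_window: tuple[float, float] = INTERACTION_WINDOW,
    grid: TimeGrid = DEFAULT_GRID,
    **kwargs,
) -> Kernel2D:
    """Estimate the 2D interaction kernel from first-order residuals.

    ``method`` selects the estimator on the stacked 2D design: plain OLS,
    evidence-optimized ridge, or the locality prior ("ald").  Bins supported
    by fewer than ``min_trials`` trials are masked.
    """
    X, y, counts, _ = stack_interaction_design(residuals, lag_window, grid)
    lags = lag_grid(lag_window, grid.dt)
    d = lags.size
    supported = counts > 0

    weights = np.zeros(d * d)
    if method == "ols":
        Xs = np.asarray(X[:, supported].todense())
        try:
            weights[supported] = ols_fit(Xs, y,
                                         allow_pinv=kwargs.pop("allow_pinv", False))
        except np.linalg.LinAlgError:
            warnings.warn("collinear interaction design; using the "
                          "minimum-norm (pseudoinverse) solution")
            weights[supported] = np.linalg.pinv(Xs) @ y
    elif method == "ridge":
        from .ridge import ridge_evidence

        _, w, _ = ridge_evidence(np.asarray(X.todense()), y, **kwargs)
        weights = w
    elif method == "ald":
        from .ald import fit_ald

        result = fit_ald(X, y, shape=(d, d), **kwargs)
        weights = result.posterior.mu
    else:
        raise ValueError(f"unknown method {method!r}")

    count_mat = counts.reshape(d, d)
    mask = count_mat < min_trials
    if mask.all():
        warnings.warn("all interaction-kernel bins are under-sampled")
    return Kernel2D(body_lags=lags, saccade_lags=lags,
                    weights=weights.reshape(d, d),
                    trial_counts=count_mat, mask=mask)


def normalize_to_stimulus(kernel, w_stim: Kernel1D):
    """Express kernel weights in units of the peak stimulus response."""
    peak = float(np.max(np.abs(w_stim.weights)))
    if peak == 0:
        raise ValueError("stimulus kernel has zero peak")
    if isinstance(kernel, Kernel1D):
        return Kernel1D(kernel.lags, kernel.weights / peak)
    return Kernel2D(kernel.body_lags, kernel.saccade_lags,
                    kernel.weights / peak, kernel.trial_counts, kernel.mask)
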