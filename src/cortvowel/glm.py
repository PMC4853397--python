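"""Mass-univariate GLM on per-vertex BOLD series and the two t-contrast maps.

The first-level model regresses each vertex's volume series on HRF-convolved
task boxcars (one regressor per task) plus one intercept per run, then forms
Student-t statistics for the /a/ > /i/ contrast and its negation. These two
maps are the raw material for the area/activity priors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidConfigurationError, InvalidInputError
from .simulate import BoldSeries, TASKS, hrf_double_gamma

logger = logging.getLogger(__name__)

TASK_REGRESSORS = {"A": "task_a", "I": "task_i", "CTRL": "task_ctrl"}


@dataclass
class DesignMatrix:
    matrix: np.ndarray            # (n_volumes, n_regressors)
    names: list[str]
    df_residual: int
    rank: int

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class TMap:
    """Per-vertex t-statistics for one named contrast."""

    contrast: str
    t: np.ndarray
    df: int


def build_design(
    events: list,
    tr: float,
    n_volumes: int,
    run_index: np.ndarray | None = None,
    hrf_params: dict | None = None,
    oversample_dt: float = 0.1,
) -> DesignMatrix:
    """HRF-convolved boxcar regressors per task plus per-run intercepts.

    ``events`` is a list of ``(task, onset_s, duration_s)`` with onsets on the
    concatenated-run time axis; ``run_index`` assigns each volume to a run
    (one run assumed when omitted).
    """
    if not events:
        raise InvalidConfigurationError("empty event list")
    hrf_params = hrf_params or {}
    if run_index is None:
        run_index = np.zeros(n_volumes, dtype=int)
    run_index = np.asarray(run_index)
    vol_times = np.arange(n_volumes) * tr
    hrf = hrf_double_gamma(np.arange(0, 32 + oversample_dt, oversample_dt), **hrf_params)

    # convolve within each run separately: haemodynamic responses do not
    # carry over acquisition breaks
    runs = np.unique(run_index)
    run_start = {}
    offset = 0.0
    for run in runs:
        run_start[run] = offset
        offset += int(np.sum(run_index == run)) * tr
    cols, names = [], []
    for task in TASKS:
        col = np.zeros(n_volumes)
        for run in runs:
            sel = run_index == run
            t0 = run_start[run]
            dur_s = int(sel.sum()) * tr
            grid = np.arange(0, dur_s + oversample_dt, oversample_dt)
            box = np.zeros_like(grid)
            for ev_task, onset, dur in events:
                local = onset - t0
                if ev_task == task and 0 <= local < dur_s:
                    box[(grid >= local) & (grid < local + dur)] = 1.0
            conv = np.convolve(box, hrf)[: grid.size] * oversample_dt
            col[sel] = np.interp(vol_times[sel] - t0, grid, conv)
        cols.append(col)
        names.append(TASK_REGRESSORS[task])
    for run in np.unique(run_index):
        cols.append((run_index == run).astype(float))
        names.append(f"intercept_run{run}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)",
            RuntimeWarning,
            stacklevel=2,
        )
    return DesignMatrix(X, names, df_residual=n_volumes - rank, rank=rank)


def design_from_bold(bold: BoldSeries, **kwargs) -> DesignMatrix:
    """Build the design matrix matching a simulated BOLD series."""
    return build_design(bold.events, bold.tr, bold.n_volumes,
                        run_index=bold.run_index, **kwargs)


def contrast_a_gt_i(design: DesignMatrix) -> np.ndarray:
    """Contrast weights for task /a/ > task /i/ on the given design."""
    c = np.zeros(len(design.names))
    c[design.names.index("task_a")] = 1.0
    c[design.names.index("task_i")] = -1.0
    return c


def fit_glm_tmaps(
    bold: BoldSeries,
    design: DesignMatrix,
    contrasts: dict[str, np.ndarray] | None = None,
) -> dict[str, TMap]:
    """OLS per vertex and t = c'b / sqrt(s2 c'(X'X)^-1 c) for each contrast.

    Default contrasts are ``a_gt_i`` and its negation ``i_gt_a``. A singular
    normal matrix falls back to the pseudo-inverse with a logged warning.
    Vertices with zero residual variance get t = 0 for any contrast with
    nonzero estimated effect denominator guard.
    """
    Y = bold.data
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise InvalidInputError(
            f"bold has {Y.shape[0]} volumes but design has {X.shape[0]}"
        )
    if contrasts is None:
        c = contrast_a_gt_i(design)
        contrasts = {"a_gt_i": c, "i_gt_a": -c}
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        logger.warning("singular X'X; using pseudo-inverse")
        xtx_inv = np.linalg.pinv(xtx)
    beta = xtx_inv @ X.T @ Y                       # (p, n_vertices)
    resid = Y - X @ beta
    df = design.df_residual
    if df <= 0:
        raise InvalidInputError("no residual degrees of freedom")
    sigma2 = np.sum(resid**2, axis=0) / df         # (n_vertices,)
    out = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        num = c @ beta
        var = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, num / np.sqrt(var), 0.0)
        out[name] = TMap(contrast=name, t=t, df=df)
    return out


def tmap_to_frame(tmap: TMap):
    """TMap as a (vertex_id, t, df) DataFrame for CSV round trips."""
    import pandas as pd

    return pd.DataFrame(
        {"vertex_id": np.arange(tmap.t.size), "t": tmap.t, "df": tmap.df}
    )


def tmap_from_frame(frame, contrast: str) -> TMap:
    return TMap(contrast=contrast, t=frame["t"].to_numpy(),
                df=int(frame["df"].iloc[0]))


def null_t_ks_statistic(t_values: np.ndarray, df: int) -> float:
    """KS distance between observed t-values and the Student-t(df) null."""
    return float(stats.kstest(t_values, stats.t(df).cdf).statistic)
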