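"""Dual regression and block-design GLMs on component time series.

Stage 1 regresses each task volume on the retained component spatial maps
(after spatial demeaning) to extract one time series per component.
Stage 2 fits an ordinary-least-squares GLM with HRF-convolved regressors
for the three n-back load levels plus instruction and response nuisance
columns.  Task engagement is summarized by the contrast
``(beta_1back + beta_2back) / 2 - beta_0back``: working-memory load versus
the attention-only baseline.  Signal-detection scores (hit rate, false-alarm
rate, d-prime) summarize in-scanner behavior.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm as _norm

from .design import CONDITION_NAMES, TaskDesign, hrf_regressor
from .ecm import BoldRun, Mask
from .errors import CollinearityError, DataError, DesignError, DimensionError

logger = logging.getLogger(__name__)

NUISANCE_NAMES = ("instructions", "responses")
INTERCEPT = "intercept"


@dataclass
class DesignMatrix:
    """GLM design: HRF-convolved condition columns plus intercept."""

    matrix: np.ndarray  # (T, P)
    labels: list[str]
    tr_seconds: float

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


@dataclass
class ComponentBetas:
    """OLS estimates for one component's time series."""

    betas: dict[str, float]
    residual_variance: float
    dof: int


@dataclass
class BehaviorScores:
    """Signal-detection summary of in-scanner responses."""

    hits: int
    false_alarms: int
    n_targets: int
    n_nontargets: int
    hit_rate: float
    fp_rate: float
    dprime: float


def build_design_matrix(
    design: TaskDesign, n_timepoints: int, tr_seconds: float
) -> DesignMatrix:
    """Sample HRF-convolved indicator regressors at the TR.

    Condition boxcars are convolved with the double-gamma HRF and truncated
    to the run length; event types with no occurrences are dropped with a
    warning; an intercept column is appended.
    """
    run_seconds = n_timepoints * tr_seconds
    if design.total_seconds > run_seconds + 1e-9:
        raise DesignError(
            f"design spans {design.total_seconds:.0f}s but the run has only "
            f"{run_seconds:.0f}s"
        )
    columns, labels = [], []
    for name in list(CONDITION_NAMES) + list(NUISANCE_NAMES):
        events = design.condition_onsets.get(name, [])
        if not events:
            logger.warning("regressor %r has no events; dropped from the design", name)
            continue
        columns.append(hrf_regressor(events, n_timepoints, tr_seconds))
        labels.append(name)
    columns.append(np.ones(n_timepoints))
    labels.append(INTERCEPT)
    matrix = np.column_stack(columns)
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    return DesignMatrix(matrix=matrix, labels=labels, tr_seconds=tr_seconds)


def dual_regression_timeseries(
    run: BoldRun, spatial_maps: np.ndarray, mask: Mask
) -> np.ndarray:
    """Stage-1 dual regression: per-volume multiple spatial regression.

    Each volume and each map is spatially demeaned over the mask, then all
    maps are regressed on the volume simultaneously; the coefficients over
    time form the (T, K) component time-series matrix.  Demeaning makes the
    series invariant to global spatial offsets.
    """
    if spatial_maps.ndim != 2:
        raise DimensionError("spatial_maps must be (K, V)")
    K, V = spatial_maps.shape
    if V != mask.n_voxels:
        raise DimensionError(
            f"maps have {V} voxels but the mask has {mask.n_voxels}"
        )
    P = spatial_maps.T - spatial_maps.mean(axis=1)  # (V, K), demeaned columns
    if np.linalg.matrix_rank(P) < K:
        corr = np.corrcoef(spatial_maps)
        pairs = [
            (i, j)
            for i in range(K)
            for j in range(i + 1, K)
            if abs(corr[i, j]) > 0.99
        ]
        raise CollinearityError(
            f"spatial map set is rank deficient; near-duplicate pairs: {pairs}"
        )
    Y = mask.extract(run.data)  # (T, V)
    Yd = Y - Y.mean(axis=1, keepdims=True)
    series, *_ = np.linalg.lstsq(P, Yd.T, rcond=None)  # (K, T)
    return series.T


def fit_component_glm(series: np.ndarray, dm: DesignMatrix) -> ComponentBetas:
    """Ordinary least squares of one component time series on the design."""
    series = np.asarray(series, dtype=float)
    if series.shape != (dm.n_timepoints,):
        raise DimensionError(
            f"series has shape {series.shape}, design expects ({dm.n_timepoints},)"
        )
    X = dm.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("singular design matrix")
    dof = dm.n_timepoints - dm.n_regressors
    if dof <= 0:
        raise DimensionError("no residual degrees of freedom")
    beta, *_ = np.linalg.lstsq(X, series, rcond=None)
    resid = series - X @ beta
    return ComponentBetas(
        betas={label: float(b) for label, b in zip(dm.labels, beta)},
        residual_variance=float(resid @ resid / dof),
        dof=dof,
    )


def activation_contrast(betas: ComponentBetas) -> float:
    """Task-engagement contrast: mean of the 1- and 2-back betas minus 0-back."""
    for name in CONDITION_NAMES:
        if name not in betas.betas:
            raise DataError(f"betas are missing the {name!r} condition")
    b0 = betas.betas["0-back"]
    b1 = betas.betas["1-back"]
    b2 = betas.betas["2-back"]
    return (b1 + b2) / 2.0 - b0


def behavior_scores(
    hits: int, false_alarms: int, n_targets: int, n_nontargets: int
) -> BehaviorScores:
    """Hit rate, false-alarm rate, and d-prime from response counts.

    Rates are clamped to ``[1/(2n), 1 - 1/(2n)]`` before the z-transform so
    perfect scores yield finite d-prime.
    """
    if not (0 <= hits <= n_targets):
        raise DataError(f"hits={hits} outside [0, {n_targets}]")
    if not (0 <= false_alarms <= n_nontargets):
        raise DataError(f"false_alarms={false_alarms} outside [0, {n_nontargets}]")
    hit_rate = float(
        np.clip(hits / n_targets, 1 / (2 * n_targets), 1 - 1 / (2 * n_targets))
    )
    fp_rate = float(
        np.clip(
            false_alarms / n_nontargets,
            1 / (2 * n_nontargets),
            1 - 1 / (2 * n_nontargets),
        )
    )
    dprime = float(_norm.ppf(hit_rate) - _norm.ppf(fp_rate))
    return BehaviorScores(
        hits=hits,
        false_alarms=false_alarms,
        n_targets=n_targets,
        n_nontargets=n_nontargets,
        hit_rate=hit_rate,
        fp_rate=fp_rate,
        dprime=dprime,
    )
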