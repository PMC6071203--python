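"""Voxel-wise eigenvector centrality mapping (ECM).

Each fMRI run defines a weighted graph whose nodes are in-mask voxels and
whose edge weights are the absolute Pearson correlations between voxel
time series, so positive and negative correlations carry equal weight.
Eigenvector centrality is the Perron (leading) eigenvector of that
nonnegative matrix: a voxel is central when it is strongly connected to
other central voxels.  The voxel-by-voxel matrix is never materialized;
matrix-vector products are evaluated in row blocks so peak memory stays
O(block_rows x V).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.signal

from .errors import (
    ConfigError,
    ConvergenceError,
    DimensionError,
    EmptyDataError,
    GridMismatchError,
    ReducibleGraphError,
)

logger = logging.getLogger(__name__)

REST, TASK = "rest", "task"


@dataclass
class BoldRun:
    """One 4D time-series image for a single subject and condition."""

    data: np.ndarray  # (x, y, z, T)
    tr_seconds: float
    subject_id: str
    condition: str

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise DimensionError("BoldRun data must be 4D (x, y, z, T)")
        if self.data.shape[3] < 8:
            raise DimensionError("BoldRun needs at least 8 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise DimensionError("BoldRun data contains non-finite values")
        if self.condition not in (REST, TASK):
            raise ConfigError(f"condition must be 'rest' or 'task', got {self.condition!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class Mask:
    """3D boolean analysis mask with a fixed, C-ordered voxel index."""

    array: np.ndarray

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array).astype(bool)
        if self.array.ndim != 3:
            raise DimensionError("mask must be 3D")
        if self.n_voxels < 2:
            raise EmptyDataError("mask must contain at least 2 voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.array.sum())

    @property
    def indices(self) -> np.ndarray:
        """Flat (C-order) indices of in-mask voxels."""
        return np.flatnonzero(self.array.ravel())

    def extract(self, volume4d: np.ndarray) -> np.ndarray:
        """Return the (T, V) matrix of in-mask voxel time series."""
        return volume4d[self.array].T

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back into a 3D volume."""
        vol = np.full(self.array.shape, fill, dtype=float)
        vol[self.array] = values
        return vol


@dataclass
class ECMConfig:
    """Numerical settings for centrality estimation.

    ``highpass_hz`` applies a second-order zero-phase Butterworth high-pass
    after linear detrending; set to ``None`` to disable.  ``keep_diagonal``
    controls whether the unit diagonal of the |correlation| matrix enters
    the products; it shifts the eigenvalue by one but leaves the
    eigenvector unchanged.
    """

    tolerance: float = 1e-6
    max_iterations: int = 1000
    block_rows: int = 512
    highpass_hz: float | None = 0.01
    keep_diagonal: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.block_rows < 1:
            raise ConfigError("block_rows must be >= 1")


@dataclass
class ECMap:
    """Eigenvector centrality for one run: nonnegative, unit L2 norm."""

    values: np.ndarray  # per in-mask voxel, zero where flagged
    eigenvalue: float
    n_iterations: int
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    subject_id: str = ""
    condition: str = ""

    def to_volume(self, mask: Mask) -> np.ndarray:
        return mask.to_volume(self.values)


@dataclass
class PreprocessedRun:
    """Standardized in-mask time series with zero-variance voxels removed.

    ``data`` is (T, V_kept); ``kept`` and ``flagged`` index into the mask's
    voxel ordering.
    """

    data: np.ndarray
    kept: np.ndarray
    flagged: np.ndarray


def preprocess_timeseries(run: BoldRun, mask: Mask, config: ECMConfig | None = None) -> PreprocessedRun:
    """Detrend, high-pass filter, and standardize in-mask voxel series.

    Each voxel series is linearly detrended, optionally high-pass filtered
    at ``config.highpass_hz``, then standardized to zero mean and unit
    sample variance (denominator T-1, so a standardized column dotted with
    itself equals T-1).  Voxels with no residual variance are flagged,
    removed from the working index, and logged.
    """
    config = config or ECMConfig()
    if run.grid_dims != mask.array.shape:
        raise GridMismatchError(
            f"run grid {run.grid_dims} does not match mask grid {mask.array.shape}"
        )
    raw = mask.extract(run.data).astype(float)  # (T, V)
    T = raw.shape[0]
    X = scipy.signal.detrend(raw, axis=0, type="linear")
    if config.highpass_hz:
        fs = 1.0 / run.tr_seconds
        nyquist = fs / 2.0
        if config.highpass_hz >= nyquist:
            logger.warning(
                "high-pass cutoff %.4f Hz is at or above Nyquist (%.4f Hz); skipping filter",
                config.highpass_hz,
                nyquist,
            )
        else:
            sos = scipy.signal.butter(
                2, config.highpass_hz, btype="highpass", fs=fs, output="sos"
            )
            default_padlen = 3 * (2 * sos.shape[0] + 1)
            padlen = min(default_padlen, T - 2)
            X = scipy.signal.sosfiltfilt(sos, X, axis=0, padlen=padlen)
    sd = X.std(axis=0, ddof=1)
    scale = np.abs(raw).max(axis=0)
    flagged = np.flatnonzero(sd <= 1e-10 * np.maximum(scale, 1.0))
    kept = np.setdiff1d(np.arange(X.shape[1]), flagged)
    if kept.size == 0:
        raise EmptyDataError("all in-mask voxels have zero variance")
    if flagged.size:
        logger.warning(
            "flagged %d zero-variance voxel(s); removed from centrality estimation",
            flagged.size,
        )
    Xk = X[:, kept]
    Xk = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=1)
    return PreprocessedRun(data=Xk, kept=kept, flagged=flagged)


def abs_corr_matvec(
    X: np.ndarray,
    v: np.ndarray,
    block_rows: int = 512,
    keep_diagonal: bool = True,
) -> np.ndarray:
    """Product of the absolute correlation matrix with a vector.

    ``X`` must hold standardized columns (zero mean, unit sample variance)
    so that ``r_ij = (X_i . X_j) / (T - 1)``.  Returns ``y`` with
    ``y_i = sum_j |r_ij| v_j``, computed in blocks of ``block_rows`` rows;
    the result is independent of the block size.
    """
    T, V = X.shape
    v = np.asarray(v, dtype=float)
    if v.shape != (V,):
        raise DimensionError(f"vector has shape {v.shape}, expected ({V},)")
    denom = T - 1
    y = np.empty(V)
    for start in range(0, V, block_rows):
        stop = min(start + block_rows, V)
        block = X[:, start:stop].T @ X
        block /= denom
        np.abs(block, out=block)
        if not keep_diagonal:
            block[np.arange(stop - start), np.arange(start, stop)] = 0.0
        y[start:stop] = block @ v
    return y


def power_iteration(
    matvec: Callable[[np.ndarray], np.ndarray],
    n: int,
    tolerance: float = 1e-6,
    max_iterations: int = 1000,
) -> tuple[np.ndarray, float, int]:
    """Leading eigenpair of a nonnegative symmetric operator.

    Starts from the uniform positive vector and iterates
    ``v <- matvec(v) / ||matvec(v)||`` until the relative L2 change falls
    below ``tolerance``.  Returns the nonnegative unit eigenvector, the
    Rayleigh-quotient eigenvalue, and the iteration count.
    """
    v = np.full(n, 1.0 / np.sqrt(n))
    eigenvalue = 0.0
    for iteration in range(1, max_iterations + 1):
        w = matvec(v)
        eigenvalue = float(v @ w)  # Rayleigh quotient (||v|| = 1)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ReducibleGraphError("operator annihilated the iterate")
        v_new = w / norm
        residual = np.linalg.norm(v_new - v)
        v = v_new
        if residual < tolerance:
            return v, eigenvalue, iteration
    raise ConvergenceError(
        f"power iteration did not converge in {max_iterations} iterations "
        f"(last residual {residual:.3e})"
    )


def compute_ec_map(run: BoldRun, mask: Mask, config: ECMConfig | None = None) -> ECMap:
    """Eigenvector centrality of one run over the |correlation| graph.

    Zero-variance voxels receive centrality 0; the remaining values form a
    nonnegative unit-norm vector.  Raises :class:`ReducibleGraphError` if
    any voxel is exactly disconnected from the rest of the graph (the
    leading eigenvector would then not be unique).
    """
    config = config or ECMConfig()
    prep = preprocess_timeseries(run, mask, config)
    V = prep.data.shape[1]
    if V == 1:
        values = np.zeros(mask.n_voxels)
        values[prep.kept] = 1.0
        return ECMap(
            values=values,
            eigenvalue=1.0 if config.keep_diagonal else 0.0,
            n_iterations=0,
            flagged=prep.flagged,
            subject_id=run.subject_id,
            condition=run.condition,
        )

    def matvec(v: np.ndarray) -> np.ndarray:
        return abs_corr_matvec(
            prep.data, v, block_rows=config.block_rows, keep_diagonal=config.keep_diagonal
        )

    # connectivity diagnostic: off-diagonal row sums of |r| must be positive
    row_sums = abs_corr_matvec(
        prep.data, np.ones(V), block_rows=config.block_rows, keep_diagonal=False
    )
    if np.any(row_sums <= 1e-12):
        raise ReducibleGraphError(
            "voxel(s) with zero |correlation| to every other voxel; "
            "the correlation graph is reducible"
        )

    vec, eigenvalue, n_iter = power_iteration(
        matvec, V, tolerance=config.tolerance, max_iterations=config.max_iterations
    )
    values = np.zeros(mask.n_voxels)
    values[prep.kept] = vec
    return ECMap(
        values=values,
        eigenvalue=eigenvalue,
        n_iterations=n_iter,
        flagged=prep.flagged,
        subject_id=run.subject_id,
        condition=run.condition,
    )
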