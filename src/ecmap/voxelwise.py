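"""Voxel-wise group inference with TFCE and permutation FWE correction.

Paired task-minus-rest EC difference maps (or condition maps with
covariates) are tested voxel-wise; the resulting t-map is enhanced with
threshold-free cluster enhancement (TFCE), which integrates cluster
extent^E x height^H over all supra-threshold levels so spatially extended
signal is boosted without choosing a cluster-forming threshold.
Family-wise error is controlled by the permutation distribution of the
maximum TFCE statistic over both signs and all voxels (two-tailed).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage

from .ecm import Mask
from .errors import ConfigError, DataError, DimensionError

logger = logging.getLogger(__name__)

ONE_SAMPLE = "one_sample"
REGRESSION = "regression"


@dataclass
class TFCEParams:
    """TFCE integration settings: extent exponent E, height exponent H,
    number of threshold steps, and the 3D neighborhood (6, 18, or 26)."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ConfigError("TFCE exponents must be positive")
        if self.n_steps < 10:
            raise ConfigError("n_steps must be >= 10")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18, or 26")

    @property
    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return scipy.ndimage.generate_binary_structure(3, order)


@dataclass
class VoxelStatResult:
    """Observed statistics plus permutation-based FWE-corrected p-values."""

    t_map: np.ndarray  # (V,) over the mask
    tfce_pos: np.ndarray  # TFCE of the positive tail
    tfce_neg: np.ndarray  # TFCE of the negated map's positive tail
    p_map: np.ndarray  # FWE-corrected two-tailed p, in [1/(n_perm+1), 1]
    zero_variance: np.ndarray  # flags for voxels with no variance
    n_perm: int
    seed: int
    params: TFCEParams
    max_stats: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> np.ndarray:
        return self.p_map <= 0.05


def voxelwise_difference(
    ec_task: dict[str, np.ndarray], ec_rest: dict[str, np.ndarray]
) -> tuple[np.ndarray, list[str]]:
    """Per-subject task-minus-rest maps; unpaired subjects dropped with a warning."""
    paired = [s for s in ec_task if s in ec_rest]
    unpaired = sorted(set(ec_task) ^ set(ec_rest))
    if unpaired:
        logger.warning("dropping unpaired subject(s): %s", ", ".join(unpaired))
    if not paired:
        raise DataError("no paired subjects")
    diffs = np.array([ec_task[s] - ec_rest[s] for s in paired])
    return diffs, paired


def _one_sample_t(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    flags = sd == 0
    t = np.zeros(maps.shape[1])
    ok = ~flags
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return t, flags


def _regression_t(
    maps: np.ndarray, X: np.ndarray, coef_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """OLS t for one coefficient, vectorized over voxels (columns of maps)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ maps  # (p, V)
    resid = maps - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    flags = maps.std(axis=0) == 0
    se = np.sqrt(sigma2 * XtX_inv[coef_index, coef_index])
    t = np.zeros(maps.shape[1])
    ok = (se > 0) & ~flags
    t[ok] = beta[coef_index, ok] / se[ok]
    return t, flags


def voxelwise_glm(
    maps: np.ndarray,
    covariates: pd.DataFrame | None,
    test: str = ONE_SAMPLE,
    predictor: str = "age",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel group statistic: one-sample t, or the OLS t of ``predictor``
    (with intercept and the remaining covariate columns as nuisance).

    Zero-variance voxels get t = 0 and are flagged.  Returns (t, flags).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 3:
        raise DimensionError("need a (n >= 3, V) array of maps")
    if test == ONE_SAMPLE:
        return _one_sample_t(maps)
    if test != REGRESSION:
        raise ConfigError(f"unknown test {test!r}")
    if covariates is None or covariates.isna().any().any():
        raise DataError("regression requires complete covariates")
    cols = list(covariates.columns)
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    return _regression_t(maps, X, coef_index=1 + cols.index(predictor))


def tfce(
    stat_map: np.ndarray, mask: Mask, params: TFCEParams | None = None
) -> np.ndarray:
    """TFCE of the positive part of a statistic map.

    For each voxel, sums ``e(h)^E h^H dh`` over ``n_steps`` equal threshold
    steps from 0 to the map maximum, where ``e(h)`` is the size of the
    voxel's supra-threshold connected cluster.  Returns per-voxel values on
    the mask ordering.  Negative statistics are handled by the two-tailed
    wrapper, which enhances the negated map separately.
    """
    params = params or TFCEParams()
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise DataError("statistic map contains non-finite values")
    if stat_map.ndim == 1:
        volume = mask.to_volume(stat_map)
    else:
        volume = np.where(mask.array, stat_map, 0.0)
    pos = np.where(volume > 0, volume, 0.0)
    vmax = pos.max()
    out = np.zeros_like(pos)
    if vmax <= 0:
        return out[mask.array]
    dh = vmax / params.n_steps
    structure = params.structure
    # midpoint quadrature over the threshold integral: O(n_steps^-2) bias
    for i in range(1, params.n_steps + 1):
        h = (i - 0.5) * dh
        supra = pos >= h
        labels, n_labels = scipy.ndimage.label(supra, structure=structure)
        if n_labels == 0:
            break
        sizes = np.bincount(labels.ravel())
        extent = sizes[labels].astype(float)
        out[supra] += (extent[supra] ** params.E) * (h**params.H) * dh
    return out[mask.array]


def tfce_two_tailed(
    stat_map: np.ndarray, mask: Mask, params: TFCEParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Enhance both tails: returns (TFCE of map, TFCE of negated map)."""
    return tfce(stat_map, mask, params), tfce(-np.asarray(stat_map), mask, params)


def permutation_fwe(
    maps: np.ndarray,
    mask: Mask,
    covariates: pd.DataFrame | None = None,
    test: str = ONE_SAMPLE,
    predictor: str = "age",
    n_perm: int = 500,
    seed: int = 0,
    params: TFCEParams | None = None,
    alpha: float = 0.05,
) -> VoxelStatResult:
    """Permutation max-TFCE inference with two-tailed FWE correction.

    One-sample tests permute by random sign flips of the subject maps;
    regressions use the Freedman-Lane scheme (residualize on the nuisance
    model, permute residuals, refit).  Each permutation records the maximum
    TFCE over both signs and all voxels; the corrected p-value of a voxel
    is ``(1 + #{perm max >= observed TFCE}) / (n_perm + 1)``.
    """
    params = params or TFCEParams()
    maps = np.asarray(maps, dtype=float)
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    if 1.0 / (n_perm + 1) > alpha:
        logger.warning(
            "n_perm=%d cannot resolve alpha=%.3f (min p = %.4f)",
            n_perm, alpha, 1.0 / (n_perm + 1),
        )
    rng = np.random.default_rng(seed)
    n = maps.shape[0]

    if test == ONE_SAMPLE:
        t_obs, flags = _one_sample_t(maps)
        sumsq = (maps**2).sum(axis=0)  # invariant under sign flips

        def perm_t() -> np.ndarray:
            signs = rng.choice([-1.0, 1.0], size=n)
            mean = (signs @ maps) / n
            var = np.maximum(sumsq - n * mean**2, 0.0) / (n - 1)
            t = np.zeros_like(mean)
            ok = var > 0
            t[ok] = mean[ok] / np.sqrt(var[ok] / n)
            return t

    elif test == REGRESSION:
        if covariates is None:
            raise DataError("regression requires covariates")
        cols = list(covariates.columns)
        coef_index = 1 + cols.index(predictor)
        X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
        t_obs, flags = _regression_t(maps, X, coef_index)
        # Freedman-Lane: fit the nuisance-only model, permute its residuals
        Z = np.delete(X, coef_index, axis=1)
        Hz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        fitted = Hz @ maps
        resid = maps - fitted

        def perm_t() -> np.ndarray:
            order = rng.permutation(n)
            return _regression_t(fitted + resid[order], X, coef_index)[0]

    else:
        raise ConfigError(f"unknown test {test!r}")

    obs_pos, obs_neg = tfce_two_tailed(mask.to_volume(t_obs), mask, params)
    observed = np.maximum(obs_pos, obs_neg)

    max_stats = np.empty(n_perm)
    for b in range(n_perm):
        t_b = perm_t()
        e_pos, e_neg = tfce_two_tailed(mask.to_volume(t_b), mask, params)
        max_stats[b] = max(e_pos.max(), e_neg.max())

    exceed = (max_stats[None, :] >= observed[:, None]).sum(axis=1)
    p_map = (1.0 + exceed) / (n_perm + 1.0)
    return VoxelStatResult(
        t_map=t_obs,
        tfce_pos=obs_pos,
        tfce_neg=obs_neg,
        p_map=p_map,
        zero_variance=flags,
        n_perm=n_perm,
        seed=seed,
        params=params,
        max_stats=max_stats,
    )
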