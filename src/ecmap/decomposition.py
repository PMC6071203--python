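"""Spatial ICA of stacked eigenvector-centrality maps.

Per-run EC maps are stacked into a runs-by-voxels matrix, normalized, and
decomposed into K spatially independent source maps with one mixing
weight per run and component ("subject weights").  Because ICA is blind to
sign and order, components are canonicalized (positive spatial skewness,
descending explained variance) before any group statistic touches the
weights.  Components matching planted artifact references better than any
signal reference are excluded, and the retained components are clustered
by the correlation of their weights across runs.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .ecm import ECMap, Mask
from .errors import ConvergenceError, DimensionError, GridMismatchError, ZeroVarianceError

logger = logging.getLogger(__name__)


@dataclass
class ECMatrix:
    """Stacked EC maps: one row per subject-condition run."""

    matrix: np.ndarray  # (R, V), normalized
    meta: pd.DataFrame  # columns: subject_id, condition

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Decomposition:
    """Spatial component maps plus per-run mixing weights."""

    spatial_maps: np.ndarray  # (K, V)
    weights: np.ndarray  # (R, K)
    meta: pd.DataFrame
    row_means: np.ndarray  # (R,), removed before ICA; needed to reconstruct
    explained_variance_ratio: np.ndarray  # PCA spectrum of the retained subspace
    seed: int
    retained: np.ndarray = field(default=None)  # bool per component

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(self.k, dtype=bool)

    @property
    def k(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)

    def reconstruct(self) -> np.ndarray:
        """Model reconstruction of the normalized EC matrix."""
        return self.weights @ self.spatial_maps + self.row_means[:, None]


def stack_ec_maps(
    ec_maps: list[ECMap], mask: Mask, row_zscore: bool = False
) -> ECMatrix:
    """Stack per-run EC maps and normalize for group decomposition.

    Each voxel (column) is demeaned across runs, so the decomposition sees
    only between-run variation around the group-mean centrality pattern.
    EC maps are unit-norm by construction, so rows arrive on a common
    scale; with ``row_zscore=True`` each row is additionally z-scored
    across voxels first.  That variant is off by default because a map's
    spatial dispersion tracks how concentrated centrality is — exactly the
    hub-coupling signal the subject weights should retain — and dividing
    it out attenuates between-run effects.
    """
    V = mask.n_voxels
    rows, meta = [], []
    for m in ec_maps:
        if m.values.shape != (V,):
            raise GridMismatchError(
                f"EC map for {m.subject_id}/{m.condition} has {m.values.shape[0]} "
                f"voxels, mask has {V}"
            )
        rows.append(m.values)
        meta.append({"subject_id": m.subject_id, "condition": m.condition})
    X = np.asarray(rows, dtype=float)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ZeroVarianceError("an EC map is constant across voxels")
    if row_zscore:
        X = (X - X.mean(axis=1, keepdims=True)) / sd
    X = X - X.mean(axis=0, keepdims=True)
    return ECMatrix(matrix=X, meta=pd.DataFrame(meta))


def fit_spatial_ica(
    ecmat: ECMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
    n_restarts: int = 3,
) -> Decomposition:
    """Estimate K spatially independent components by fixed-point ICA.

    Rows are PCA-whitened to K dimensions, then FastICA with the logcosh
    contrast estimates spatially independent source maps; the mixing
    coefficients are the per-run subject weights.  Deterministic given
    ``seed``; retries with derived seeds before raising on non-convergence.
    """
    if isinstance(ecmat, np.ndarray):
        meta = pd.DataFrame(
            {"subject_id": [f"row-{i}" for i in range(ecmat.shape[0])],
             "condition": [""] * ecmat.shape[0]}
        )
        ecmat = ECMatrix(matrix=np.asarray(ecmat, dtype=float), meta=meta)
    R, V = ecmat.matrix.shape
    if k > min(R, V):
        raise DimensionError(
            f"K={k} exceeds min(runs, voxels) = {min(R, V)}"
        )
    data = ecmat.matrix.T  # (V, R): samples are voxels -> spatial independence
    last_n_iter = None
    for attempt in range(n_restarts):
        ica = FastICA(
            n_components=k,
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + 7919 * attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(data)  # (V, K)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        last_n_iter = ica.n_iter_
        if converged:
            break
        logger.warning(
            "FastICA did not converge (attempt %d, %d iterations); retrying",
            attempt + 1,
            ica.n_iter_,
        )
    else:
        raise ConvergenceError(
            f"FastICA failed to converge after {n_restarts} restarts "
            f"({last_n_iter} iterations each, tol={tol})"
        )
    pca = PCA(n_components=k, random_state=seed)
    pca.fit(data)
    return Decomposition(
        spatial_maps=sources.T,
        weights=ica.mixing_,
        meta=ecmat.meta.copy(),
        row_means=ica.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        seed=seed,
    )


def canonicalize_components(dec: Decomposition) -> Decomposition:
    """Resolve ICA sign and order ambiguity.

    Each component is flipped so its spatial map has positive skewness
    (ties broken by the sign of the largest-magnitude voxel), with the
    weights flipped to compensate; components are then ordered by
    descending contribution to the reconstruction.  Idempotent, and the
    reconstruction is unchanged.
    """
    maps = dec.spatial_maps.copy()
    weights = dec.weights.copy()
    for i in range(dec.k):
        skew = scipy.stats.skew(maps[i])
        if skew < 0 or (skew == 0 and maps[i][np.argmax(np.abs(maps[i]))] < 0):
            maps[i] = -maps[i]
            weights[:, i] = -weights[:, i]
    contribution = (weights**2).sum(axis=0) * (maps**2).sum(axis=1)
    order = np.argsort(-contribution, kind="stable")
    return replace(
        dec,
        spatial_maps=maps[order],
        weights=weights[:, order],
        retained=dec.retained[order],
    )


def classify_artifact_components(
    dec: Decomposition,
    signal_refs: np.ndarray | None,
    artifact_refs: np.ndarray | None,
) -> np.ndarray:
    """Flag components that match artifact references better than signal ones.

    A component is retained iff its best absolute spatial correlation with
    any signal reference exceeds its best against the artifact references.
    With no references everything is retained with a warning.  The flags
    are stored on the decomposition and returned.
    """
    if signal_refs is None or len(signal_refs) == 0:
        logger.warning("no reference maps supplied; retaining all components")
        dec.retained = np.ones(dec.k, dtype=bool)
        return dec.retained
    retained = np.ones(dec.k, dtype=bool)
    if artifact_refs is not None and len(artifact_refs) > 0:
        for i in range(dec.k):
            sig = max(abs(_safe_corr(dec.spatial_maps[i], r)) for r in signal_refs)
            art = max(abs(_safe_corr(dec.spatial_maps[i], r)) for r in artifact_refs)
            retained[i] = sig > art
    dec.retained = retained
    n_dropped = int((~retained).sum())
    if n_dropped:
        logger.info("excluded %d artifact-matched component(s)", n_dropped)
    return retained


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class WeightClustering:
    """Hierarchical clustering of retained components by weight correlation."""

    correlation: np.ndarray  # (K_ret, K_ret) Pearson correlation of weights
    linkage: np.ndarray  # scipy linkage matrix (distance 1 - r, average)
    labels: np.ndarray  # flat cluster labels at the requested cut
    component_indices: np.ndarray  # positions in the decomposition


def component_weight_clustering(
    dec: Decomposition, n_clusters: int = 2
) -> WeightClustering:
    """Cluster retained components by the similarity of their subject weights.

    Builds the component-by-component Pearson correlation of weight columns
    across all runs (both conditions), converts to distance ``1 - r``, and
    applies average-linkage agglomerative clustering.
    """
    idx = dec.retained_indices
    if idx.size < 2:
        raise DimensionError("need at least 2 retained components to cluster")
    W = dec.weights[:, idx]
    sd = W.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceError(
            f"component(s) {idx[dead].tolist()} have zero weight variance"
        )
    corr = np.corrcoef(W.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    labels = scipy.cluster.hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return WeightClustering(
        correlation=corr, linkage=Z, labels=labels, component_indices=idx
    )


def match_components(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one maximum-|correlation| assignment (Hungarian algorithm).

    Returns ``(ref_idx, est_idx)`` pairing each reference map with its best
    estimated component; used by recovery diagnostics and tests.
    """
    n_ref, n_est = len(reference), len(estimated)
    cost = np.zeros((n_ref, n_est))
    for i in range(n_ref):
        for j in range(n_est):
            cost[i, j] = -abs(_safe_corr(reference[i], estimated[j]))
    ref_idx, est_idx = linear_sum_assignment(cost)
    return ref_idx, est_idx
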