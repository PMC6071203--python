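"""Spatial ICA: stacking, source recovery, canonicalization, clustering."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from ecmap import (
    canonicalize_components,
    classify_artifact_components,
    component_weight_clustering,
    fit_spatial_ica,
    generate_network_maps,
    match_components,
    stack_ec_maps,
)
from ecmap.decomposition import ECMatrix
from ecmap.ecm import ECMap
from ecmap.errors import DimensionError, GridMismatchError, ZeroVarianceError
from ecmap.synthetic import default_mask


def _source_maps(k, seed, grid=(14, 14, 9)):
    """Planted super-Gaussian (sparse blob) spatial sources on a mask."""
    atlas = generate_network_maps(grid, k, seed=seed, sigma=1.5)
    mask = default_mask(grid)
    return atlas.maps[:, mask.array], mask


def _mixtures(k, n_runs, seed, snr=10.0):
    rng = np.random.default_rng(seed)
    S, mask = _source_maps(k, seed)
    A = rng.standard_normal((n_runs, k))
    X = A @ S
    noise = rng.standard_normal(X.shape)
    noise *= X.std() / (np.sqrt(snr) * noise.std())
    return X + noise, A, S, mask


class TestStack:
    def _maps(self, values, mask):
        return [
            ECMap(values=v, eigenvalue=1.0, n_iterations=1,
                  subject_id=f"sub-{i:03d}", condition="rest" if i % 2 else "task")
            for i, v in enumerate(values)
        ]

    def test_identical_maps_stack_to_zero(self, small_mask, rng):
        v = np.abs(rng.standard_normal(small_mask.n_voxels))
        ecmat = stack_ec_maps(self._maps([v] * 4, small_mask), small_mask)
        assert np.allclose(ecmat.matrix, 0.0)

    def test_columns_demeaned_rows_preserved(self, small_mask, rng):
        vals = [np.abs(rng.standard_normal(small_mask.n_voxels)) for _ in range(6)]
        ecmat = stack_ec_maps(self._maps(vals, small_mask), small_mask)
        assert np.allclose(ecmat.matrix.mean(axis=0), 0.0, atol=1e-12)
        # default keeps the between-run scale: rows = map - column mean
        X = np.asarray(vals)
        assert np.allclose(ecmat.matrix, X - X.mean(axis=0), atol=1e-12)

    def test_row_zscore_variant_contract(self, small_mask, rng):
        vals = [np.abs(rng.standard_normal(small_mask.n_voxels)) for _ in range(6)]
        ecmat = stack_ec_maps(self._maps(vals, small_mask), small_mask, row_zscore=True)
        X = np.asarray(vals)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        assert np.allclose(ecmat.matrix, Z - Z.mean(axis=0), atol=1e-9)

    def test_cohort_run_count(self, tiny_cohort, tiny_ec_maps):
        ecmat = stack_ec_maps(tiny_ec_maps, tiny_cohort.mask)
        assert ecmat.n_runs == 2 * len(tiny_cohort.subjects)
        assert set(ecmat.meta.condition) == {"rest", "task"}

    def test_mask_mismatch_raises(self, small_mask, rng):
        bad = ECMap(values=rng.random(3), eigenvalue=1.0, n_iterations=1,
                    subject_id="s", condition="rest")
        with pytest.raises(GridMismatchError):
            stack_ec_maps([bad], small_mask)


class TestFitSpatialICA:
    def test_planted_source_recovery(self):
        X, A, S, _ = _mixtures(k=3, n_runs=30, seed=4, snr=50.0)
        dec = fit_spatial_ica(X, k=3, seed=0)
        ref_idx, est_idx = match_components(dec.spatial_maps, S)
        corrs = [abs(np.corrcoef(S[i], dec.spatial_maps[j])[0, 1])
                 for i, j in zip(ref_idx, est_idx)]
        assert min(corrs) > 0.95

    def test_rank_one_identifiability(self):
        rng = np.random.default_rng(1)
        S, _ = _source_maps(1, seed=2)
        A = rng.standard_normal((10, 1))
        dec = fit_spatial_ica(A @ S, k=1, seed=0)
        assert abs(np.corrcoef(dec.spatial_maps[0], S[0])[0, 1]) > 0.999

    def test_reconstruction_matches_pca_bound(self):
        X, *_ = _mixtures(k=4, n_runs=24, seed=5, snr=5.0)
        dec = fit_spatial_ica(X, k=4, seed=0)
        resid_ica = np.linalg.norm(X - dec.reconstruct())
        from sklearn.decomposition import PCA

        pca = PCA(n_components=4).fit(X.T)
        resid_pca = np.linalg.norm(X.T - pca.inverse_transform(pca.transform(X.T)))
        assert resid_ica <= resid_pca + 1e-6

    def test_k_exceeding_runs_raises(self):
        X, *_ = _mixtures(k=2, n_runs=5, seed=6)
        with pytest.raises(DimensionError):
            fit_spatial_ica(X, k=6, seed=0)

    def test_deterministic_given_seed(self):
        X, *_ = _mixtures(k=3, n_runs=20, seed=7)
        a = fit_spatial_ica(X, k=3, seed=11)
        b = fit_spatial_ica(X, k=3, seed=11)
        assert np.array_equal(a.spatial_maps, b.spatial_maps)
        assert np.array_equal(a.weights, b.weights)


class TestCanonicalize:
    def test_positive_skewness_and_idempotence(self):
        X, *_ = _mixtures(k=3, n_runs=20, seed=8)
        dec = fit_spatial_ica(X, k=3, seed=0)
        canon = canonicalize_components(dec)
        from scipy.stats import skew

        assert (skew(canon.spatial_maps, axis=1) >= 0).all()
        again = canonicalize_components(canon)
        assert np.array_equal(again.spatial_maps, canon.spatial_maps)
        assert np.array_equal(again.weights, canon.weights)

    def test_reconstruction_invariant(self):
        X, *_ = _mixtures(k=3, n_runs=20, seed=9)
        dec = fit_spatial_ica(X, k=3, seed=0)
        canon = canonicalize_components(dec)
        assert np.allclose(canon.reconstruct(), dec.reconstruct(), atol=1e-10)

    def test_ordered_by_contribution(self):
        X, *_ = _mixtures(k=4, n_runs=24, seed=10)
        canon = canonicalize_components(fit_spatial_ica(X, k=4, seed=0))
        contrib = (canon.weights**2).sum(axis=0) * (canon.spatial_maps**2).sum(axis=1)
        assert (np.diff(contrib) <= 1e-9).all()


class TestArtifactClassification:
    def test_exact_matches(self):
        S, mask = _source_maps(4, seed=11)
        signal, artifact = S[:3], S[3:]
        dec = fit_spatial_ica(
            np.random.default_rng(0).standard_normal((12, 4)) @ S, k=4, seed=0
        )
        # overwrite with exact copies to pin the contract
        dec.spatial_maps = np.vstack([signal, artifact])
        retained = classify_artifact_components(dec, signal, artifact)
        assert retained.tolist() == [True, True, True, False]

    def test_no_references_retains_all_with_warning(self, caplog):
        X, *_ = _mixtures(k=2, n_runs=10, seed=12)
        dec = fit_spatial_ica(X, k=2, seed=0)
        with caplog.at_level("WARNING"):
            retained = classify_artifact_components(dec, None, None)
        assert retained.all()
        assert "retaining all components" in caplog.text

    def test_low_noise_cohort_excludes_planted_artifacts(self):
        """6 signal + 2 artifact sources, K=8: exactly the 6 survive."""
        rng = np.random.default_rng(13)
        S, mask = _source_maps(8, seed=13)
        signal, artifact = S[:6], S[6:]
        A = rng.standard_normal((40, 8))
        X = A @ S + 0.01 * rng.standard_normal((40, S.shape[1]))
        dec = canonicalize_components(fit_spatial_ica(X, k=8, seed=0))
        retained = classify_artifact_components(dec, signal, artifact)
        assert retained.sum() == 6
        ref_idx, est_idx = match_components(dec.spatial_maps, artifact)
        assert not retained[est_idx].any()


class TestWeightClustering:
    def _dec_with_weights(self, W):
        k = W.shape[1]
        from ecmap.decomposition import Decomposition

        return Decomposition(
            spatial_maps=np.random.default_rng(0).standard_normal((k, 50)),
            weights=W,
            meta=pd.DataFrame({"subject_id": [f"s{i}" for i in range(len(W))],
                               "condition": ["rest"] * len(W)}),
            row_means=np.zeros(len(W)),
            explained_variance_ratio=np.ones(k) / k,
            seed=0,
        )

    def test_perfectly_correlated_merge_first_at_zero(self, rng):
        base = rng.standard_normal(20)
        W = np.column_stack([base, 2 * base + 1, rng.standard_normal(20)])
        result = component_weight_clustering(self._dec_with_weights(W), n_clusters=2)
        first = result.linkage[0]
        assert sorted(first[:2]) == [0, 1]
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_two_group_structure_recovered(self, rng):
        g1 = rng.standard_normal(40)
        g2 = rng.standard_normal(40)
        W = np.column_stack([
            g1 + 0.3 * rng.standard_normal(40),
            g1 + 0.3 * rng.standard_normal(40),
            g2 + 0.3 * rng.standard_normal(40),
            g2 + 0.3 * rng.standard_normal(40),
        ])
        result = component_weight_clustering(self._dec_with_weights(W), n_clusters=2)
        labels = result.labels
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_correlation_matrix_symmetric_unit_diagonal(self, rng):
        W = rng.standard_normal((30, 5))
        result = component_weight_clustering(self._dec_with_weights(W), n_clusters=2)
        assert np.allclose(result.correlation, result.correlation.T)
        assert np.allclose(np.diag(result.correlation), 1.0)

    def test_zero_variance_component_raises(self, rng):
        W = np.column_stack([rng.standard_normal(20), np.full(20, 2.0)])
        with pytest.raises(ZeroVarianceError):
            component_weight_clustering(self._dec_with_weights(W))


def test_scale_ambiguity_absorbed_by_statistics(tiny_cohort, tiny_ec_maps):
    """Rescaling a (map, weight-column) pair by (c, 1/c) leaves downstream
    weight t-statistics unchanged once canonicalization is reapplied."""
    from ecmap import compute_difference_scores, task_effect_test

    ecmat = stack_ec_maps(tiny_ec_maps, tiny_cohort.mask)
    dec = canonicalize_components(fit_spatial_ica(ecmat, k=4, seed=0))
    t_ref = task_effect_test(compute_difference_scores(dec))["t"].to_numpy()

    scaled = fit_spatial_ica(ecmat, k=4, seed=0)
    c = 3.7
    scaled.spatial_maps[1] *= c
    scaled.weights[:, 1] /= c
    scaled = canonicalize_components(scaled)
    t_scaled = task_effect_test(compute_difference_scores(scaled))["t"].to_numpy()
    assert np.allclose(np.sort(np.abs(t_scaled)), np.sort(np.abs(t_ref)), atol=1e-6)
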