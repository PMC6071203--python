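"""Synthetic cohort generator: atlas, runs, behavior, determinism."""
import numpy as np
import pytest

from ecmap import (
    CohortConfig,
    generate_cohort,
    generate_network_maps,
    simulate_behavior,
    simulate_run,
)
from ecmap.errors import ConfigError, GridTooSmallError
from ecmap.synthetic import (
    SubjectRecord,
    _network_correlation,
    default_mask,
    make_nback_design,
)


class TestNetworkMaps:
    def test_single_blob_unit_peak(self):
        atlas = generate_network_maps((20, 20, 12), 1, seed=1)
        assert atlas.maps.shape == (1, 20, 20, 12)
        assert atlas.maps.max() == pytest.approx(1.0, abs=1e-6)
        assert (atlas.maps >= 0).all()

    def test_pairwise_correlations_low(self):
        atlas = generate_network_maps((20, 20, 12), 6, seed=1)
        mask = default_mask((20, 20, 12))
        flat = atlas.maps[:, mask.array]
        corr = np.corrcoef(flat)
        off = corr[~np.eye(6, dtype=bool)]
        assert (np.abs(off) < 0.5).all()

    def test_supra_half_maximum_extent(self):
        atlas = generate_network_maps((20, 20, 12), 4, seed=2)
        mask = default_mask((20, 20, 12))
        supra = (atlas.maps[:, mask.array] >= 0.5).sum(axis=1)
        assert (supra >= 8).all()

    def test_deterministic(self):
        a = generate_network_maps((20, 20, 12), 3, seed=7)
        b = generate_network_maps((20, 20, 12), 3, seed=7)
        assert np.array_equal(a.maps, b.maps)

    def test_grid_too_small(self):
        with pytest.raises(GridTooSmallError):
            generate_network_maps((6, 6, 4), 8, seed=1)

    def test_role_labels(self):
        atlas = generate_network_maps((20, 20, 12), 4, seed=1, n_artifacts=2)
        assert atlas.labels == ["hub", "sensory", "other", "other",
                                "artifact", "artifact"]


class TestSimulateRun:
    def test_design_condition_pairing_enforced(self, tiny_cohort, tiny_config):
        s = tiny_cohort.subjects[0]
        with pytest.raises(ConfigError):
            simulate_run(s, "task", tiny_cohort.atlas, None, tiny_config)
        with pytest.raises(ConfigError):
            simulate_run(s, "rest", tiny_cohort.atlas, tiny_cohort.design, tiny_config)

    def test_near_noiseless_blob_is_rank_one(self):
        """With one network and negligible noise, in-blob voxel series are
        proportional to each other (an outer product of map and course)."""
        cfg = CohortConfig(
            n_subjects=1, grid_dims=(12, 12, 8), k_networks=1, n_artifacts=0,
            noise_sd=1e-8, n_timepoints_rest=30, n_timepoints_task=60,
            blob_sigma=1.4, block_seconds=15.0, instruction_seconds=5.0,
            trial_seconds=0.7, seed=3,
        )
        cohort = generate_cohort(cfg)
        run = cohort.simulate("sub-001", "rest")
        flat = cohort.atlas.flat_maps(cohort.mask)[0]
        strong = np.argsort(flat)[-5:]
        series = run.data[cohort.mask.array][strong]
        ratios = series / flat[strong, None]
        assert np.allclose(ratios, ratios[0], rtol=1e-4)

    def test_task_coupling_raises_hub_voxel_correlation(self):
        """Mean |corr| of hub voxels to everything is larger in the task run,
        averaged over seeds (brute-force correlation on the generated data)."""
        gains = []
        for seed in range(8):
            cfg = CohortConfig(
                n_subjects=1, grid_dims=(12, 12, 8), k_networks=3, n_artifacts=0,
                n_timepoints_rest=80, n_timepoints_task=80, blob_sigma=1.4,
                block_seconds=15.0, instruction_seconds=5.0, trial_seconds=0.7,
                seed=seed,
            )
            cohort = generate_cohort(cfg)
            hub_vox = cohort.atlas.flat_maps(cohort.mask)[0] > 0.5
            vals = {}
            for cond in ("rest", "task"):
                data = cohort.simulate("sub-001", cond).data[cohort.mask.array]
                corr = np.corrcoef(data)
                vals[cond] = np.abs(corr[hub_vox]).mean()
            gains.append(vals["task"] - vals["rest"])
        assert np.mean(gains) > 0

    def test_age_raises_hub_cross_network_coupling(self):
        """Older subjects' planted hub coupling exceeds younger subjects'."""
        cfg = CohortConfig(n_subjects=2, grid_dims=(12, 12, 8), k_networks=3,
                           n_artifacts=0, blob_sigma=1.4, seed=0,
                           coupling_subject_sd=0.0, delta_subject_sd=0.0)
        atlas = generate_network_maps((12, 12, 8), 3, seed=0, sigma=1.4)
        young = SubjectRecord(id="a", age_years=9.0, sex=0, hub_coupling=0.0,
                              rest_coupling=cfg.hub_base_coupling
                              + cfg.age_slope * (9.0 - cfg.age_midpoint))
        old = SubjectRecord(id="b", age_years=21.0, sex=0, hub_coupling=0.0,
                            rest_coupling=cfg.hub_base_coupling
                            + cfg.age_slope * (21.0 - cfg.age_midpoint))
        Ry = _network_correlation(young, "rest", atlas, cfg)
        Ro = _network_correlation(old, "rest", atlas, cfg)
        assert Ro[0, 1] > Ry[0, 1]

    def test_sensory_suppression_under_task(self, tiny_cohort, tiny_config):
        # a subject with typical (positive) resting hub coupling
        s = SubjectRecord(id="s", age_years=18.0, sex=0,
                          hub_coupling=0.45, rest_coupling=0.25)
        R_rest = _network_correlation(s, "rest", tiny_cohort.atlas, tiny_config)
        R_task = _network_correlation(s, "task", tiny_cohort.atlas, tiny_config)
        sens = tiny_cohort.atlas.index_of("sensory")
        others = [i for i in range(tiny_cohort.atlas.k_total)
                  if i != sens and tiny_cohort.atlas.labels[i] != "artifact"]
        assert np.abs(R_task[sens, others]).mean() < np.abs(R_rest[sens, others]).mean()


class TestBehavior:
    def test_neutral_parameters_give_half_hit_rate(self):
        cfg = CohortConfig(n_subjects=1, hit_intercept=0.0, hit_age_slope=0.0,
                           behavior_link=0.0, seed=0)
        subj = SubjectRecord(id="s", age_years=15.0, sex=0, hub_coupling=0.5)
        hits = [simulate_behavior(
            SubjectRecord(id=f"s{i}", age_years=15.0, sex=0, hub_coupling=0.5),
            cfg).hits for i in range(300)]
        assert np.mean(hits) / 45 == pytest.approx(0.5, abs=0.05)

    def test_counts_within_trial_budget(self, tiny_cohort):
        t = tiny_cohort.subject_table
        assert ((t.hits >= 0) & (t.hits <= 45)).all()
        assert ((t.false_alarms >= 0) & (t.false_alarms <= 135)).all()

    def test_strong_link_couples_coupling_and_hits(self):
        cfg = CohortConfig(n_subjects=1, behavior_link=10.0, seed=0)
        rng = np.random.default_rng(0)
        mean_c = cfg.hub_base_coupling + cfg.task_coupling_delta
        couplings = mean_c + rng.normal(0, 0.2, 100)
        rates = [
            simulate_behavior(
                SubjectRecord(id=f"s{i}", age_years=15.0, sex=0, hub_coupling=c),
                cfg).hit_rate
            for i, c in enumerate(couplings)
        ]
        assert np.corrcoef(couplings, rates)[0, 1] > 0.5


class TestGenerateCohort:
    def test_two_runs_per_subject(self):
        cfg = CohortConfig(n_subjects=4, grid_dims=(12, 12, 8), k_networks=3,
                           n_artifacts=1, n_timepoints_rest=30,
                           n_timepoints_task=60, blob_sigma=1.4,
                           block_seconds=15.0, instruction_seconds=5.0,
                           trial_seconds=0.7, seed=9)
        cohort = generate_cohort(cfg)
        runs = list(cohort.iter_runs())
        assert len(runs) == 8
        assert {(r.subject_id, r.condition) for r in runs} == {
            (f"sub-{i:03d}", c) for i in range(1, 5) for c in ("rest", "task")
        }

    def test_ages_within_range(self, tiny_cohort, tiny_config):
        lo, hi = tiny_config.age_range_years
        assert ((tiny_cohort.subject_table.age >= lo)
                & (tiny_cohort.subject_table.age <= hi)).all()

    def test_regeneration_is_bit_identical(self, tiny_config):
        a = generate_cohort(tiny_config)
        b = generate_cohort(tiny_config)
        assert a.subject_table.equals(b.subject_table)
        ra = a.simulate("sub-003", "task")
        rb = b.simulate("sub-003", "task")
        assert np.array_equal(ra.data, rb.data)

    def test_ground_truth_reproduces_correlation(self, tiny_cohort):
        gt = tiny_cohort.ground_truth
        s = tiny_cohort.subjects[1]
        R = gt.expected_correlation(s, "task")
        assert R.shape == (tiny_cohort.atlas.k_total,) * 2
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert gt.task_effect_signs[tiny_cohort.atlas.index_of("hub")] > 0
        assert gt.task_effect_signs[tiny_cohort.atlas.index_of("sensory")] < 0

    def test_null_cohort_task_effects_centered_at_zero(self):
        """With no planted condition differences the downstream paired task
        statistics are null-distributed (realizability of the null)."""
        from ecmap import (canonicalize_components, compute_difference_scores,
                           compute_ec_map, fit_spatial_ica, stack_ec_maps,
                           task_effect_test)

        tvals = []
        for seed in range(3):
            cfg = CohortConfig(
                n_subjects=10, grid_dims=(12, 12, 8), k_networks=3,
                n_artifacts=0, blob_sigma=1.4, n_timepoints_rest=60,
                n_timepoints_task=60, block_seconds=15.0,
                instruction_seconds=5.0, trial_seconds=0.7, seed=seed,
                task_coupling_delta=0.0, delta_subject_sd=0.0,
                age_slope=0.0, activation_amplitude=0.0,
            )
            cohort = generate_cohort(cfg)
            ecs = [compute_ec_map(r, cohort.mask) for r in cohort.iter_runs()]
            dec = canonicalize_components(
                fit_spatial_ica(stack_ec_maps(ecs, cohort.mask), k=4, seed=seed)
            )
            tvals.extend(task_effect_test(compute_difference_scores(dec))["t"])
        tvals = np.asarray(tvals)
        assert abs(tvals.mean()) < 0.8  # ~3 MC standard errors for 12 t values
        assert np.abs(tvals).max() < 6.0

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_subjects=0)
        with pytest.raises(ConfigError):
            CohortConfig(noise_sd=0.0)
        with pytest.raises(ConfigError):
            CohortConfig(age_range_years=(22.0, 8.0))
        with pytest.raises(ConfigError):
            CohortConfig(grid_dims=(2, 2, 2), k_networks=10)
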