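"""Recovery and calibration checks against planted ground truth.

These routines exercise the full analysis chain on synthetic data where the
truth is known — dense-oracle equivalence for the centrality solver, source
recovery for the ICA, beta recovery for the GLM, type-I calibration for the
group tests, and sign recovery of the planted hub/sensory pattern — and
return the measured quantities.  They are used by the test suite and by the
reproduction script.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .component_stats import (
    build_stat_table,
    compute_difference_scores,
    ec_activation_correlation,
    task_effect_test,
    weight_regression,
)
from .decomposition import (
    canonicalize_components,
    classify_artifact_components,
    fit_spatial_ica,
    match_components,
    stack_ec_maps,
)
from .ecm import ECMConfig, Mask, abs_corr_matvec, compute_ec_map, power_iteration
from .synthetic import CohortConfig, default_mask, generate_cohort, generate_network_maps
from .task_glm import (
    activation_contrast,
    behavior_scores,
    build_design_matrix,
    dual_regression_timeseries,
    fit_component_glm,
)
from .voxelwise import TFCEParams, permutation_fwe, tfce

logger = logging.getLogger(__name__)


def _standardize(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def ecm_oracle_check(
    n_instances: int = 20, seed: int = 0, max_voxels: int = 50
) -> dict:
    """Blockwise power-iteration EC versus dense |corr| eigendecomposition.

    Returns the worst cosine similarity over random instances and the worst
    map discrepancy between keeping and zeroing the |corr| diagonal.
    """
    rng = np.random.default_rng(seed)
    cosines, diag_diffs = [], []
    for _ in range(n_instances):
        V = int(rng.integers(10, max_voxels + 1))
        T = int(rng.integers(20, 60))
        X = _standardize(rng.standard_normal((T, V)))
        block = int(rng.integers(1, V + 1))
        cfg = dict(tolerance=1e-12, max_iterations=5000)
        v_keep, _, _ = power_iteration(
            lambda w: abs_corr_matvec(X, w, block_rows=block, keep_diagonal=True),
            V, **cfg,
        )
        v_zero, _, _ = power_iteration(
            lambda w: abs_corr_matvec(X, w, block_rows=block, keep_diagonal=False),
            V, **cfg,
        )
        C = np.abs(np.corrcoef(X.T))
        w_dense = np.abs(np.linalg.eigh(C)[1][:, -1])
        cosines.append(float(v_keep @ w_dense))
        diag_diffs.append(float(np.abs(v_keep - v_zero).max()))
    return {"min_cosine": min(cosines), "max_diagonal_diff": max(diag_diffs)}


def ica_recovery(
    n_seeds: int = 10, n_runs: int = 30, snr: float = 10.0, seed: int = 0
) -> dict:
    """Planted super-Gaussian source recovery across seeds.

    Mixes 3-6 blob sources with Gaussian mixing at the given SNR, fits the
    spatial ICA, matches components one-to-one, and averages the matched
    absolute spatial correlations and mixing-column correlations.
    """
    spatial, weights = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * s)
        k = 3 + s % 4
        atlas = generate_network_maps((14, 14, 9), k, seed=seed + s, sigma=1.5)
        mask = default_mask((14, 14, 9))
        S = atlas.maps[:, mask.array]
        A = rng.standard_normal((n_runs, k))
        X = A @ S
        noise = rng.standard_normal(X.shape)
        X = X + noise * (X.std() / (np.sqrt(snr) * noise.std()))
        dec = fit_spatial_ica(X, k=k, seed=seed + s)
        ref_idx, est_idx = match_components(dec.spatial_maps, S)
        for i, j in zip(ref_idx, est_idx):
            spatial.append(abs(np.corrcoef(S[i], dec.spatial_maps[j])[0, 1]))
            weights.append(abs(np.corrcoef(A[:, i], dec.weights[:, j])[0, 1]))
    return {
        "mean_spatial_corr": float(np.mean(spatial)),
        "mean_weight_corr": float(np.mean(weights)),
    }


def glm_recovery(n_seeds: int = 50, noise_sd: float = 0.1, seed: int = 0) -> dict:
    """Recovery of planted condition betas (0.2, 0.5, 0.9) under noise."""
    from .design import make_nback_design

    design = make_nback_design(seed=1)
    T, tr = 120, 3.0
    dm = build_design_matrix(design, T, tr)
    planted = {"0-back": 0.2, "1-back": 0.5, "2-back": 0.9}
    rng = np.random.default_rng(seed)
    errors = {k: [] for k in planted}
    for _ in range(n_seeds):
        series = sum(planted[k] * dm.column(k) for k in planted)
        series = series + noise_sd * rng.standard_normal(T)
        betas = fit_component_glm(series, dm)
        for k in planted:
            errors[k].append(betas.betas[k] - planted[k])
    return {
        "max_abs_mean_beta_error": float(
            max(abs(np.mean(v)) for v in errors.values())
        )
    }


def null_calibration(
    n_reps: int = 1000, n: int = 20, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error of the paired task test and the age regression under the
    null (no planted effects)."""
    rng = np.random.default_rng(seed)
    diff = pd.DataFrame(
        rng.standard_normal((n, n_reps)),
        index=[f"s{i}" for i in range(n)],
        columns=range(n_reps),
    )
    task_rate = float((task_effect_test(diff)["p"] < alpha).mean())

    hits = 0
    age = rng.uniform(8, 22, n)
    sex = rng.integers(0, 2, n).astype(float)
    cov = pd.DataFrame({"age": age, "sex": sex}, index=range(n))
    for _ in range(n_reps):
        y = pd.Series(rng.standard_normal(n), index=range(n))
        if weight_regression(y, cov, "age")["p"] < alpha:
            hits += 1
    return {"task_type_i": task_rate, "age_type_i": hits / n_reps}


def fwe_calibration(
    n_reps: int = 100,
    n_subjects: int = 20,
    n_perm: int = 500,
    grid: tuple[int, int, int] = (8, 8, 5),
    n_steps: int = 32,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise false-positive rate of max-TFCE permutation inference on
    pure-noise difference maps."""
    mask = default_mask(grid)
    params = TFCEParams(n_steps=n_steps)
    rng = np.random.default_rng(seed)
    fp = 0
    for rep in range(n_reps):
        maps = rng.standard_normal((n_subjects, mask.n_voxels))
        res = permutation_fwe(
            maps, mask, n_perm=n_perm, seed=seed + 7000 + rep, params=params
        )
        fp += int((res.p_map <= alpha).any())
    return {"fwe_fpr": fp / n_reps}


def tfce_uniform_cluster_value(
    extent: int = 4, height: float = 1.0, E: float = 0.5, H: float = 2.0,
    n_steps: int = 100,
) -> float:
    """TFCE peak for a uniform face-connected cluster (closed form
    ``extent^E height^(H+1) / (H+1)``)."""
    mask = Mask(np.ones((6, 6, 4), bool))
    vol = np.zeros((6, 6, 4))
    vol[2, 2 : 2 + extent // 2, 1] = height
    vol[3, 2 : 2 + extent - extent // 2, 1] = height
    return float(tfce(vol, mask, TFCEParams(E=E, H=H, n_steps=n_steps)).max())


# study conditions for the planted-pattern recovery runs: n = 40 subjects,
# a 14 x 14 x 9 grid (~900 in-mask voxels), 5 signal + 2 artifact networks,
# and run lengths matching the emulated protocol at TR 3 s
PATTERN_CONFIG = dict(
    n_subjects=40,
    grid_dims=(14, 14, 9),
    blob_sigma=1.7,
    n_timepoints_rest=124,
    n_timepoints_task=120,
    k_networks=5,
    n_artifacts=2,
)
PATTERN_ICA_K = 9  # planted sources + 2: over-extraction absorbs noise


@dataclass
class PatternResult:
    """Signed hub/sensory statistics from one end-to-end replicate."""

    t_values: dict
    significant: dict
    ec_activation_r: float

    @property
    def all_signs_recovered(self) -> bool:
        return (
            self.t_values["hub_task"] > 0 and self.significant["hub_task"]
            and self.t_values["sens_task"] < 0 and self.significant["sens_task"]
            and self.t_values["hub_age"] > 0 and self.significant["hub_age"]
            and self.t_values["hub_dprime"] > 0 and self.significant["hub_dprime"]
        )


def planted_pattern_replicate(seed: int, **overrides) -> PatternResult:
    """One full pipeline pass on a cohort planted with the qualitative
    pattern: hub centrality rises with task, age, and predicts d-prime;
    sensory centrality falls with task.

    Returns hub/sensory statistics aligned to the planted maps' signs.
    """
    cfg = CohortConfig(seed=seed, **{**PATTERN_CONFIG, **overrides})
    cohort = generate_cohort(cfg)
    ec_maps = [compute_ec_map(run, cohort.mask) for run in cohort.iter_runs()]
    ecmat = stack_ec_maps(ec_maps, cohort.mask)
    dec = canonicalize_components(fit_spatial_ica(ecmat, k=PATTERN_ICA_K, seed=seed))
    refs = cohort.atlas.flat_maps(cohort.mask)
    classify_artifact_components(
        dec,
        refs[cohort.atlas.signal_indices],
        refs[cohort.atlas.artifact_indices],
    )
    dm = build_design_matrix(cohort.design, cfg.n_timepoints_task, cfg.tr_seconds)
    retained = dec.retained_indices
    act_rows = {}
    for s in cohort.subjects:
        run = cohort.simulate(s.id, "task")
        series = dual_regression_timeseries(
            run, dec.spatial_maps[retained], cohort.mask
        )
        act_rows[s.id] = [
            activation_contrast(fit_component_glm(series[:, j], dm))
            for j in range(len(retained))
        ]
    activation = pd.DataFrame.from_dict(act_rows, orient="index", columns=retained)
    activation.index.name = "subject_id"
    behavior = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                **vars(
                    behavior_scores(
                        int(r.hits), int(r.false_alarms),
                        cohort.design.n_targets, cohort.design.n_nontargets,
                    )
                ),
            }
            for r in cohort.subject_table.itertuples()
        ]
    )[["subject_id", "hit_rate", "fp_rate", "dprime"]]
    diff = compute_difference_scores(dec)
    table = build_stat_table(
        dec, diff, cohort.subject_table, activation=activation, behavior=behavior
    )

    ref_idx, est_idx = match_components(dec.spatial_maps, refs)
    pairing = dict(zip(ref_idx.tolist(), est_idx.tolist()))
    hub_ref = cohort.atlas.index_of("hub")
    sens_ref = cohort.atlas.index_of("sensory")
    hub_comp, sens_comp = pairing[hub_ref], pairing[sens_ref]
    hub_sign = np.sign(np.corrcoef(refs[hub_ref], dec.spatial_maps[hub_comp])[0, 1])
    sens_sign = np.sign(np.corrcoef(refs[sens_ref], dec.spatial_maps[sens_comp])[0, 1])

    def pull(family: str, comp: int, sign: float) -> tuple[float, bool]:
        sub = table[table.family == family].set_index("component")
        return float(sub.loc[comp, "t"] * sign), bool(sub.loc[comp, "significant"])

    t_values, significant = {}, {}
    t_values["hub_task"], significant["hub_task"] = pull("task_effect", hub_comp, hub_sign)
    t_values["sens_task"], significant["sens_task"] = pull("task_effect", sens_comp, sens_sign)
    t_values["hub_age"], significant["hub_age"] = pull("age_rest", hub_comp, hub_sign)
    t_values["hub_dprime"], significant["hub_dprime"] = pull("perf_dprime", hub_comp, hub_sign)
    r, _, _ = ec_activation_correlation(table)
    return PatternResult(t_values=t_values, significant=significant, ec_activation_r=r)
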