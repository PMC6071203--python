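"""End-to-end orchestration: synthetic cohort (or disk inputs) through
centrality mapping, ICA, dual regression, group statistics, and voxel-wise
permutation inference, with provenance and stage-level resume.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as ecio
from .component_stats import (
    build_stat_table,
    compute_difference_scores,
    ec_activation_correlation,
)
from .decomposition import (
    canonicalize_components,
    classify_artifact_components,
    component_weight_clustering,
    fit_spatial_ica,
    stack_ec_maps,
)
from .design import TaskDesign
from .ecm import ECMConfig, Mask, REST, TASK, compute_ec_map
from .errors import ConfigError
from .synthetic import Cohort, CohortConfig, generate_cohort
from .task_glm import (
    activation_contrast,
    behavior_scores,
    build_design_matrix,
    dual_regression_timeseries,
    fit_component_glm,
)
from .voxelwise import ONE_SAMPLE, REGRESSION, TFCEParams, permutation_fwe

logger = logging.getLogger(__name__)

VOXELWISE_TESTS = ("task_effect", "age_task", "age_rest", "age_diff")


@dataclass
class PipelineConfig:
    """One document configuring every stage.

    Exactly one of ``synthetic`` (a :class:`CohortConfig`) or ``paths``
    (runs_dir / mask / subject_table / design) must be provided.
    """

    out_dir: str
    synthetic: CohortConfig | None = None
    paths: dict | None = None
    ecm: ECMConfig = field(default_factory=ECMConfig)
    ica_k: int | None = None
    ica_seed: int = 0
    n_clusters: int = 2
    fdr_q: float = 0.05
    fdr_scope: str = "per_family"
    tfce: TFCEParams = field(default_factory=TFCEParams)
    n_perm: int = 500
    perm_seed: int = 0
    voxelwise_tests: tuple[str, ...] = VOXELWISE_TESTS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.paths is None):
            raise ConfigError("provide exactly one of synthetic/paths")
        for t in self.voxelwise_tests:
            if t not in VOXELWISE_TESTS:
                raise ConfigError(f"unknown voxelwise test {t!r}")
        if self.paths is not None:
            required = {"runs_dir", "mask", "subject_table", "design"}
            missing = required - set(self.paths)
            if missing:
                raise ConfigError(f"paths missing {sorted(missing)}")
            for key in required:
                if not Path(self.paths[key]).exists():
                    raise ConfigError(f"path for {key!r} does not exist: {self.paths[key]}")

    def to_dict(self) -> dict:
        payload = asdict(self)
        return payload

    def config_hash(self) -> str:
        """Content hash of the configuration, ignoring the output location."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if payload.get("synthetic") is not None:
            syn = dict(payload["synthetic"])
            for key in ("grid_dims", "age_range_years"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            payload["synthetic"] = CohortConfig(**syn)
        if payload.get("ecm") is not None and not isinstance(payload["ecm"], ECMConfig):
            payload["ecm"] = ECMConfig(**payload["ecm"])
        if payload.get("tfce") is not None and not isinstance(payload["tfce"], TFCEParams):
            payload["tfce"] = TFCEParams(**payload["tfce"])
        if "voxelwise_tests" in payload:
            payload["voxelwise_tests"] = tuple(payload["voxelwise_tests"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class ResultsBundle:
    """In-memory handles on everything the pipeline produced."""

    config: PipelineConfig
    mask: Mask
    ec_maps: list
    decomposition: object
    stat_table: pd.DataFrame
    ec_activation: tuple[float, float, int]
    clustering: object
    voxelwise: dict
    manifest: dict
    cohort: Cohort | None = None


def _stage_done(manifest: dict, stage: str, out_dir: Path, cfg_hash: str) -> bool:
    entry = manifest.get("stages", {}).get(stage)
    if not entry or manifest.get("config_hash") != cfg_hash:
        return False
    return all((out_dir / f).exists() for f in entry.get("outputs", []))


def run_pipeline(config: PipelineConfig, stages: set[str] | None = None) -> ResultsBundle:
    """Execute the full analysis and write a results bundle to ``out_dir``.

    Stage order: inputs -> ecm -> decompose -> task_glm -> stats ->
    clustering -> voxelwise.  Completed stages from a previous run with an
    identical configuration are resumed from disk (EC maps only; later
    stages are cheap and recomputed).  ``stages`` restricts execution to a
    subset (later stages are skipped, not resumed).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest_path = out_dir / "manifest.json"
    old_manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest: dict = {
        "config": {k: v for k, v in config.to_dict().items() if k != "out_dir"},
        "config_hash": cfg_hash,
        "versions": {"ecmap": __version__, "numpy": np.__version__},
        "stages": {},
    }

    def want(stage: str) -> bool:
        return stages is None or stage in stages

    # ---- inputs ----------------------------------------------------------
    cohort: Cohort | None = None
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        mask = cohort.mask
        subject_table = cohort.subject_table
        design = cohort.design
        run_specs = [
            (s.id, cond) for s in cohort.subjects for cond in (REST, TASK)
        ]

        def get_run(sid: str, cond: str):
            return cohort.simulate(sid, cond)

        ecio.save_mask(mask, out_dir / "mask.nii")
        ecio.save_subject_table(subject_table, out_dir / "participants.tsv")
        ecio.save_design(design, out_dir / "design.json")
        manifest["stages"]["inputs"] = {
            "outputs": ["mask.nii", "participants.tsv", "design.json"]
        }
    else:
        run_index, mask, subject_table, design = ecio.read_inputs(
            config.paths["runs_dir"],
            config.paths["mask"],
            config.paths["subject_table"],
            config.paths["design"],
        )
        run_specs = [(sid, cond) for sid, cond, _ in run_index]
        run_paths = {(sid, cond): path for sid, cond, path in run_index}

        def get_run(sid: str, cond: str):
            return ecio.load_run(run_paths[(sid, cond)], sid, cond)

        manifest["stages"]["inputs"] = {"outputs": []}

    tr_seconds = (
        config.synthetic.tr_seconds if config.synthetic is not None else None
    )

    # ---- stage: ecm ------------------------------------------------------
    ec_dir = out_dir / "ec"
    ec_dir.mkdir(exist_ok=True)
    ec_maps = []
    ec_files = []
    if want("ecm"):
        for sid, cond in run_specs:
            fname = f"{sid}_{cond}_ec.nii"
            ec_files.append(f"ec/{fname}")
            path = ec_dir / fname
            resumable = _stage_done(
                old_manifest, "ecm", out_dir, cfg_hash
            ) and path.exists()
            if resumable:
                ec_maps.append(ecio.load_ec_map(path, mask))
                continue
            run = get_run(sid, cond)
            if tr_seconds is None:
                tr_seconds = run.tr_seconds
            ec = compute_ec_map(run, mask, config.ecm)
            ecio.save_ec_map(ec, mask, path)
            ec_maps.append(ec)
        logger.info("ecm stage: %d maps", len(ec_maps))
        manifest["stages"]["ecm"] = {"outputs": ec_files}
    if stages is not None and not (stages - {"ecm"}):
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return ResultsBundle(
            config, mask, ec_maps, None, pd.DataFrame(), (np.nan,) * 3, None, {},
            manifest, cohort,
        )

    # ---- stage: decompose ------------------------------------------------
    ecmat = stack_ec_maps(ec_maps, mask)
    k = config.ica_k
    if k is None:
        if config.synthetic is not None:
            k = config.synthetic.k_networks + config.synthetic.n_artifacts
        else:
            k = min(40, ecmat.n_runs - 1)
    dec = fit_spatial_ica(ecmat, k=k, seed=config.ica_seed)
    dec = canonicalize_components(dec)
    if cohort is not None:
        refs = cohort.atlas.flat_maps(mask)
        signal_refs = refs[cohort.atlas.signal_indices]
        artifact_refs = (
            refs[cohort.atlas.artifact_indices]
            if cohort.atlas.artifact_indices.size
            else None
        )
    else:
        signal_refs = artifact_refs = None
    classify_artifact_components(dec, signal_refs, artifact_refs)
    ecio.save_component_maps(dec.spatial_maps, mask, out_dir / "ica_maps.nii")
    ecio.save_weights(dec.weights, dec.meta, dec.retained, out_dir / "ica_weights.tsv")
    manifest["stages"]["decompose"] = {
        "outputs": ["ica_maps.nii", "ica_weights.tsv", "retained_components.json"],
        "k": k,
        "n_retained": int(dec.retained.sum()),
    }

    # ---- stage: task_glm -------------------------------------------------
    retained_maps = dec.spatial_maps[dec.retained_indices]
    activation_rows = {}
    n_task_tp = None
    dm = None
    for sid, cond in run_specs:
        if cond != TASK:
            continue
        run = get_run(sid, cond)
        if dm is None:
            n_task_tp = run.n_timepoints
            dm = build_design_matrix(design, n_task_tp, run.tr_seconds)
        series = dual_regression_timeseries(run, retained_maps, mask)
        contrasts = []
        for kk in range(series.shape[1]):
            betas = fit_component_glm(series[:, kk], dm)
            contrasts.append(activation_contrast(betas))
        activation_rows[sid] = contrasts
    activation = pd.DataFrame.from_dict(
        activation_rows, orient="index", columns=dec.retained_indices
    )
    activation.index.name = "subject_id"
    activation.reset_index().to_csv(
        out_dir / "activation_contrasts.tsv", sep="\t", index=False
    )

    behavior = pd.DataFrame(
        [
            {
                "subject_id": row.subject_id,
                **vars(
                    behavior_scores(
                        int(row.hits), int(row.false_alarms),
                        design.n_targets, design.n_nontargets,
                    )
                ),
            }
            for row in subject_table.itertuples()
        ]
    )[["subject_id", "hit_rate", "fp_rate", "dprime"]]
    manifest["stages"]["task_glm"] = {"outputs": ["activation_contrasts.tsv"]}

    # ---- stage: stats ----------------------------------------------------
    diff = compute_difference_scores(dec)
    stat_table = build_stat_table(
        dec,
        diff,
        subject_table,
        activation=activation,
        behavior=behavior,
        q=config.fdr_q,
        fdr_scope=config.fdr_scope,
    )
    ecio.save_stat_table(stat_table, out_dir / "component_stats.tsv")
    r, p, n_comp = ec_activation_correlation(stat_table)
    ecio.save_json(
        {"r": r, "p": p, "n_components": n_comp},
        out_dir / "ec_activation_correlation.json",
    )
    manifest["stages"]["stats"] = {
        "outputs": ["component_stats.tsv", "ec_activation_correlation.json"]
    }

    # ---- stage: clustering -----------------------------------------------
    clustering = component_weight_clustering(dec, n_clusters=config.n_clusters)
    ecio.save_json(
        {
            "linkage": clustering.linkage.tolist(),
            "labels": clustering.labels.tolist(),
            "component_indices": clustering.component_indices.tolist(),
            "correlation": clustering.correlation.tolist(),
        },
        out_dir / "component_clustering.json",
    )
    manifest["stages"]["clustering"] = {"outputs": ["component_clustering.json"]}

    # ---- stage: voxelwise ------------------------------------------------
    ec_by = {(m.subject_id, m.condition): m.values for m in ec_maps}
    subjects = [s for s, c in run_specs if c == TASK]
    task_mat = np.array([ec_by[(s, TASK)] for s in subjects])
    rest_mat = np.array([ec_by[(s, REST)] for s in subjects])
    diff_mat = task_mat - rest_mat
    covars = subject_table.set_index("subject_id").loc[subjects, ["age", "sex"]]
    voxelwise_results = {}
    vox_files = []
    for test_name in config.voxelwise_tests:
        if test_name == "task_effect":
            result = permutation_fwe(
                diff_mat, mask, test=ONE_SAMPLE, n_perm=config.n_perm,
                seed=config.perm_seed, params=config.tfce,
            )
        else:
            target = {"age_task": task_mat, "age_rest": rest_mat, "age_diff": diff_mat}[
                test_name
            ]
            result = permutation_fwe(
                target, mask, covariates=covars, test=REGRESSION, predictor="age",
                n_perm=config.n_perm, seed=config.perm_seed, params=config.tfce,
            )
        voxelwise_results[test_name] = result
        prefix = f"voxelwise_{test_name}"
        ecio.save_volume(mask.to_volume(result.t_map), out_dir / f"{prefix}_t.nii")
        ecio.save_volume(
            mask.to_volume(np.maximum(result.tfce_pos, result.tfce_neg)),
            out_dir / f"{prefix}_tfce.nii",
        )
        ecio.save_volume(
            mask.to_volume(1.0 - result.p_map), out_dir / f"{prefix}_1minusp.nii"
        )
        ecio.save_json(
            {
                "test": test_name,
                "n_perm": result.n_perm,
                "seed": result.seed,
                "tfce": asdict(result.params),
                "n_significant": int(result.significant.sum()),
            },
            out_dir / f"{prefix}.json",
        )
        vox_files += [f"{prefix}_t.nii", f"{prefix}_tfce.nii", f"{prefix}_1minusp.nii"]
    manifest["stages"]["voxelwise"] = {"outputs": vox_files}

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ResultsBundle(
        config=config,
        mask=mask,
        ec_maps=ec_maps,
        decomposition=dec,
        stat_table=stat_table,
        ec_activation=(r, p, n_comp),
        clustering=clustering,
        voxelwise=voxelwise_results,
        manifest=manifest,
        cohort=cohort,
    )
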