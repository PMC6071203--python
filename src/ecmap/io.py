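"""Readers and writers for the pipeline's on-disk formats.

Images are NIfTI-1 (uncompressed ``.nii`` so outputs are byte-stable),
tables are TSV, and designs/manifests/sidecars are JSON.  All writers have
a matching reader and round-trip to value equality.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import TaskDesign
from .ecm import BoldRun, ECMap, Mask
from .errors import GridMismatchError, SchemaError

logger = logging.getLogger(__name__)

# synthetic grids are nominally 3 mm isotropic
DEFAULT_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])

SUBJECT_COLUMNS = ["subject_id", "age", "sex", "hits", "false_alarms"]


def save_run(run: BoldRun, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float32), DEFAULT_AFFINE)
    img.header.set_zooms((3.0, 3.0, 3.0, run.tr_seconds))
    nib.save(img, str(path))
    return path


def load_run(path: str | Path, subject_id: str, condition: str) -> BoldRun:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 3.0
    return BoldRun(data=data, tr_seconds=tr, subject_id=subject_id, condition=condition)


def save_mask(mask: Mask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.array.astype(np.uint8), DEFAULT_AFFINE)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    return Mask(np.asarray(img.dataobj) > 0)


def save_volume(values_3d: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(values_3d.astype(np.float32), DEFAULT_AFFINE)
    nib.save(img, str(path))
    return path


def save_ec_map(ec: ECMap, mask: Mask, path: str | Path) -> tuple[Path, Path]:
    """Write an EC map as a 3D NIfTI plus a JSON sidecar with diagnostics."""
    path = Path(path)
    save_volume(ec.to_volume(mask), path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "subject_id": ec.subject_id,
                "condition": ec.condition,
                "eigenvalue": ec.eigenvalue,
                "n_iterations": ec.n_iterations,
                "flagged_voxels": ec.flagged.tolist(),
            },
            indent=2,
        )
    )
    return path, sidecar


def load_ec_map(path: str | Path, mask: Mask) -> ECMap:
    path = Path(path)
    img = nib.load(str(path))
    volume = np.asarray(img.dataobj, dtype=np.float64)
    if volume.shape != mask.array.shape:
        raise GridMismatchError(f"{path.name}: grid {volume.shape} != mask {mask.array.shape}")
    meta = json.loads(path.with_suffix(".json").read_text())
    return ECMap(
        values=volume[mask.array],
        eigenvalue=float(meta["eigenvalue"]),
        n_iterations=int(meta["n_iterations"]),
        flagged=np.asarray(meta["flagged_voxels"], dtype=int),
        subject_id=meta["subject_id"],
        condition=meta["condition"],
    )


def save_subject_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[SUBJECT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def load_subject_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SUBJECT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing column(s) {missing}")
    if table.subject_id.duplicated().any():
        dupes = table.subject_id[table.subject_id.duplicated()].tolist()
        raise SchemaError(f"{Path(path).name}: duplicate subject id(s) {dupes}")
    return table


def save_design(design: TaskDesign, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(design.to_json())
    return path


def load_design(path: str | Path) -> TaskDesign:
    return TaskDesign.from_json(Path(path).read_text())


def save_component_maps(maps_2d: np.ndarray, mask: Mask, path: str | Path) -> Path:
    """Stack K spatial maps into a 4D NIfTI (component axis last)."""
    volumes = np.stack([mask.to_volume(m) for m in maps_2d], axis=-1)
    img = nib.Nifti1Image(volumes.astype(np.float32), DEFAULT_AFFINE)
    nib.save(img, str(path))
    return Path(path)


def save_weights(
    weights: np.ndarray, meta: pd.DataFrame, retained: np.ndarray, path: str | Path
) -> Path:
    """Weights TSV: run_id, subject_id, condition, comp_01 ... comp_K."""
    k = weights.shape[1]
    out = pd.DataFrame(
        {
            "run_id": [
                f"{s}_{c}" for s, c in zip(meta.subject_id, meta.condition)
            ],
            "subject_id": meta.subject_id,
            "condition": meta.condition,
        }
    )
    for j in range(k):
        out[f"comp_{j + 1:02d}"] = weights[:, j]
    out.to_csv(path, sep="\t", index=False)
    retained_path = Path(path).with_name("retained_components.json")
    retained_path.write_text(json.dumps({"retained": retained.astype(bool).tolist()}))
    return Path(path)


def save_stat_table(table: pd.DataFrame, path: str | Path) -> Path:
    cols = ["component", "family", "estimate", "t", "p", "q", "significant", "n"]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def save_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_inputs(
    runs_dir: str | Path,
    mask_path: str | Path,
    table_path: str | Path,
    design_path: str | Path,
) -> tuple[list[tuple[str, str, Path]], Mask, pd.DataFrame, TaskDesign]:
    """Validate and index a directory of per-subject runs.

    Run files are named ``<subject_id>_<condition>.nii``.  Grid consistency
    with the mask is enforced; malformed tables and duplicate ids raise
    distinct errors.  Returns (run index, mask, subject table, design); the
    run index carries paths so callers can stream runs one at a time.
    """
    runs_dir = Path(runs_dir)
    mask = load_mask(mask_path)
    table = load_subject_table(table_path)
    design = load_design(design_path)
    run_index = []
    for sid in table.subject_id:
        for condition in ("rest", "task"):
            path = runs_dir / f"{sid}_{condition}.nii"
            if not path.exists():
                raise SchemaError(f"missing run file {path.name}")
            img = nib.load(str(path))
            if img.shape[:3] != mask.array.shape:
                raise GridMismatchError(
                    f"{path.name}: grid {img.shape[:3]} != mask {mask.array.shape}"
                )
            run_index.append((str(sid), condition, path))
    return run_index, mask, table, design


def write_cohort(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort to disk in the package's input layout."""
    out_dir = Path(out_dir)
    runs_dir = out_dir / "runs"
    runs_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mask": save_mask(cohort.mask, out_dir / "mask.nii"),
        "subject_table": save_subject_table(
            cohort.subject_table, out_dir / "participants.tsv"
        ),
        "design": save_design(cohort.design, out_dir / "design.json"),
    }
    for run in cohort.iter_runs():
        save_run(run, runs_dir / f"{run.subject_id}_{run.condition}.nii")
    paths["runs_dir"] = runs_dir
    return paths
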