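"""NIfTI / TSV / JSON input-output for cohorts and derived maps."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .synthetic import CohortDataset, SimulationConfig, SubjectRecord

__all__ = [
    "read_volume",
    "write_volume",
    "write_cohort",
    "read_cohort",
]

_MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine).

    The affine maps 0-based voxel indices to world millimetres.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several format-specific types
        raise FormatError(f"not a readable NIfTI file: {path}") from exc
    return data, img.affine


def write_volume(path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return path


def write_cohort(dataset: CohortDataset, directory) -> dict:
    """Persist a cohort: per-subject NIfTI + motion TSV, masks, phenotype, manifest.

    Returns the manifest (also written as ``manifest.json``); the layout
    round-trips losslessly through :func:`read_cohort` up to the float32
    storage dtype of the BOLD volumes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = dataset.affine
    files = []
    pheno_rows = []
    for s in dataset.subjects:
        bold_path = directory / f"{s.subject_id}_bold.nii"
        write_volume(bold_path, s.bold.astype(np.float32), affine)
        motion_path = directory / f"{s.subject_id}_motion.tsv"
        pd.DataFrame(s.motion, columns=_MOTION_COLS).to_csv(
            motion_path, sep="\t", index=False
        )
        files.extend([bold_path.name, motion_path.name])
        pheno_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "ndi": s.ndi,
                "sds_raw": s.sds_raw,
                "sas_raw": s.sas_raw,
                "duration_months": s.duration_months,
            }
        )
    for name, mask in [
        ("gm_mask", dataset.gm_mask),
        ("wm_mask", dataset.wm_mask),
        ("csf_mask", dataset.csf_mask),
    ]:
        path = directory / f"{name}.nii"
        write_volume(path, mask.astype(np.uint8), affine)
        files.append(path.name)
    pheno_path = directory / "phenotype.tsv"
    pd.DataFrame(pheno_rows).to_csv(pheno_path, sep="\t", index=False)
    files.append(pheno_path.name)

    manifest = {
        "seed": dataset.config.seed,
        "config": dataclasses.asdict(dataset.config),
        "n_subjects": len(dataset.subjects),
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_cohort(directory) -> CohortDataset:
    """Load a cohort written by :func:`write_cohort`.

    Raises :class:`FormatError` naming the subject whose files are missing
    or malformed.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    cfg_dict["grid_shape"] = tuple(cfg_dict["grid_shape"])
    cfg_dict["effect_rois"] = tuple(
        (tuple(c), r) for c, r in cfg_dict["effect_rois"]
    )
    config = SimulationConfig(**cfg_dict)

    pheno = pd.read_csv(directory / "phenotype.tsv", sep="\t")
    masks = {}
    for name in ("gm_mask", "wm_mask", "csf_mask"):
        data, affine = read_volume(directory / f"{name}.nii")
        masks[name] = data.astype(bool)
    subjects = []
    for _, row in pheno.iterrows():
        sid = row["subject_id"]
        bold_path = directory / f"{sid}_bold.nii"
        motion_path = directory / f"{sid}_motion.tsv"
        if not bold_path.exists():
            raise FormatError(f"subject {sid}: missing BOLD file {bold_path}")
        if not motion_path.exists():
            raise FormatError(f"subject {sid}: missing motion file {motion_path}")
        bold, _ = read_volume(bold_path)
        motion = pd.read_csv(motion_path, sep="\t")[_MOTION_COLS].to_numpy()
        duration = row["duration_months"]
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=row["group"],
                bold=np.asarray(bold, dtype=np.float32),
                motion=motion,
                ndi=float(row["ndi"]),
                sds_raw=float(row["sds_raw"]),
                sas_raw=float(row["sas_raw"]),
                duration_months=None if pd.isna(duration) else float(duration),
            )
        )
    return CohortDataset(
        subjects=subjects,
        gm_mask=masks["gm_mask"],
        wm_mask=masks["wm_mask"],
        csf_mask=masks["csf_mask"],
        affine=affine,
        config=config,
        truth={},
    )
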