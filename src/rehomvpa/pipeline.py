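"""End-to-end orchestration: simulate/load -> preprocess -> ReHo -> MVPA
-> permutation inference -> ROI correlations, with a structured run report.

Every stage is logged with its parameters; reruns with the same
configuration and seed reproduce all outputs bit-identically (up to float
serialization of the persisted files).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import PATIENT, CONTROL, build_feature_matrix, loocv, metrics
from .discriminative import (
    PermutationConfig,
    cluster_pvalues,
    extract_clusters,
    observed_weight_map,
    permutation_null,
    voxel_pvalues,
)
from .errors import ConfigurationError
from .io import read_cohort, write_cohort, write_volume
from .preproc import MotionQCConfig, PreprocConfig, preprocess_subject, qc_motion
from .reho import ReHoConfig, reho_map
from .roi import correlate_rois, mean_reho_in_roi, peak_roi
from .synthetic import CohortDataset, SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage configurations plus paths and the master seed.

    Defaults are the reference analysis constants: 10 discarded volumes,
    0.01-0.08 Hz band, 27-voxel ReHo neighborhood, C = 1, 5000
    permutations at voxel alpha 0.02 / cluster size 10 / cluster alpha
    0.001, 6 mm ROI spheres, Bonferroni 0.01.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    motion_qc: MotionQCConfig = field(default_factory=MotionQCConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    reho: ReHoConfig = field(default_factory=ReHoConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    svm_c: float = 1.0
    roi_radius_mm: float = 6.0
    correlation_alpha: float = 0.01
    correlation_variables: tuple = ("ndi", "duration_months")
    input_dir: str | None = None  # load a cohort instead of simulating
    out_dir: str | None = None
    seed: int = 0
    persist: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation")
        sim["grid_shape"] = tuple(sim["grid_shape"])
        sim["effect_rois"] = tuple((tuple(c), r) for c, r in sim["effect_rois"])
        pre = raw.pop("preproc")
        pre["nuisance_set"] = frozenset(pre["nuisance_set"])
        return cls(
            simulation=SimulationConfig(**sim),
            motion_qc=MotionQCConfig(**raw.pop("motion_qc")),
            preproc=PreprocConfig(**pre),
            reho=ReHoConfig(**raw.pop("reho")),
            permutation=PermutationConfig(**raw.pop("permutation")),
            correlation_variables=tuple(raw.pop("correlation_variables")),
            **raw,
        )


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_plain(v) for v in sorted(obj) if True] if isinstance(
            obj, (set, frozenset)
        ) else [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class RunReport:
    """Stage log, classifier metrics, cluster table and correlations."""

    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)
    excluded_subjects: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    confusion: dict = field(default_factory=dict)
    clusters: list = field(default_factory=list)
    correlations: list = field(default_factory=list)

    def log(self, stage: str, **params) -> None:
        self.stages.append({"stage": stage, "t": time.time(), **params})

    def stage_names(self) -> list[str]:
        return [s["stage"] for s in self.stages]

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(
    config: PipelineConfig, cohort: CohortDataset | None = None
) -> RunReport:
    """Execute the full analysis stream and return its report.

    ``cohort`` may be supplied directly (already in memory); otherwise it
    is loaded from ``config.input_dir`` or simulated per
    ``config.simulation`` (seeded by ``config.seed``).
    """
    report = RunReport(seed=config.seed)
    out = Path(config.out_dir) if (config.out_dir and config.persist) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    if cohort is None:
        if config.input_dir is not None:
            cohort = read_cohort(config.input_dir)
            report.log("load", input_dir=str(config.input_dir))
        else:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim_cfg)
            report.log("simulate", **dataclasses.asdict(sim_cfg))
            if out is not None:
                write_cohort(cohort, out / "cohort")

    # --- motion QC ---------------------------------------------------------
    kept = []
    for s in cohort.subjects:
        qc = qc_motion(s.motion, config.motion_qc)
        if qc.passed:
            kept.append(s)
        else:
            report.excluded_subjects.append(
                {"subject_id": s.subject_id, "axis": qc.offending_axis,
                 "max_abs": qc.max_abs}
            )
    report.log(
        "motion_qc",
        n_in=len(cohort.subjects),
        n_excluded=len(report.excluded_subjects),
        max_translation_mm=config.motion_qc.max_translation_mm,
        max_rotation_deg=config.motion_qc.max_rotation_deg,
    )
    if len(kept) < 4:
        raise ConfigurationError("fewer than 4 subjects survive motion QC")

    # --- preprocessing and ReHo -------------------------------------------
    labels, maps = [], []
    for s in kept:
        try:
            clean = preprocess_subject(
                s.bold, s.motion, cohort.wm_mask, cohort.csf_mask, config.preproc
            )
            maps.append(reho_map(clean, cohort.gm_mask, config.reho))
        except Exception as exc:
            raise type(exc)(f"subject {s.subject_id}: {exc}") from exc
        labels.append(PATIENT if s.group == "patient" else CONTROL)
    report.log(
        "preproc",
        n_discard=config.preproc.n_discard,
        band_hz=[config.preproc.band_low_hz, config.preproc.band_high_hz],
        nuisance=sorted(config.preproc.nuisance_set),
    )
    report.log("reho", neighborhood=config.reho.neighborhood,
               edge_policy=config.reho.edge_policy)

    fm = build_feature_matrix(maps, labels)
    if out is not None:
        np.savez_compressed(
            out / "features.npz", X=fm.X, labels=fm.labels,
            voxel_index=fm.voxel_index,
        )

    # --- LOOCV classification ---------------------------------------------
    counts, preds, _ = loocv(fm, C=config.svm_c)
    report.confusion = dataclasses.asdict(counts)
    report.metrics = metrics(counts)
    report.log("classify", C=config.svm_c, cv="loo",
               n_folds=len(preds), **report.metrics)

    # --- discriminative map + permutation inference ------------------------
    perm_cfg = dataclasses.replace(config.permutation, seed=config.seed + 1)
    w_obs = observed_weight_map(fm, C=config.svm_c)
    null = permutation_null(fm, perm_cfg)
    p_map = voxel_pvalues(w_obs, null)
    clusters = extract_clusters(
        p_map, fm.mask, perm_cfg.voxel_alpha,
        perm_cfg.min_cluster_voxels, perm_cfg.connectivity,
    )
    table = cluster_pvalues(
        clusters, null, w_obs, p_map, cohort.affine, perm_cfg.cluster_alpha
    )
    report.clusters = table.rows
    report.log("permtest", n_perm=perm_cfg.n_perm,
               voxel_alpha=perm_cfg.voxel_alpha,
               min_cluster_voxels=perm_cfg.min_cluster_voxels,
               cluster_alpha=perm_cfg.cluster_alpha,
               connectivity=perm_cfg.connectivity,
               n_candidates=len(clusters),
               n_significant=len(table.significant()))
    if out is not None:
        write_volume(out / "weight_map.nii", np.nan_to_num(w_obs.map3d),
                     cohort.affine)
        write_volume(out / "p_map.nii", np.nan_to_num(p_map, nan=1.0),
                     cohort.affine)
        table.to_dataframe().to_csv(out / "clusters.tsv", sep="\t", index=False)

    # --- ROI extraction and symptom correlations ---------------------------
    patient_rows = [i for i, s in enumerate(kept) if s.group == "patient"]
    patient_maps = [maps[i] for i in patient_rows]
    behavior = {}
    for var in config.correlation_variables:
        vals = np.array([getattr(kept[i], var) for i in patient_rows], float)
        behavior[var] = vals
    roi_means = {}
    sig = table.significant()
    for row in sig:
        cl = clusters[row["cluster_id"]]
        roi = peak_roi(
            w_obs, cl.indices, cohort.affine, cohort.gm_mask,
            radius_mm=config.roi_radius_mm, source_cluster=row["cluster_id"],
        )
        roi_means[row["cluster_id"]] = np.array(
            [mean_reho_in_roi(m, roi) for m in patient_maps]
        )
    if roi_means:
        results = correlate_rois(roi_means, behavior,
                                 alpha=config.correlation_alpha)
        report.correlations = [dataclasses.asdict(r) for r in results]
    report.log("roicorr", radius_mm=config.roi_radius_mm,
               alpha=config.correlation_alpha, n_rois=len(roi_means),
               variables=list(config.correlation_variables))

    if out is not None:
        report.to_json(out / "report.json")
    return report
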