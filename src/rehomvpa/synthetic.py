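"""Synthetic resting-state BOLD cohorts with planted local synchrony.

The generator produces two groups of subjects on a common 3 mm grid:
"controls" whose voxel time series are independent Gaussian noise plus a
shared slow drift, and "patients" in whom configurable spherical regions
receive an extra shared regional signal.  Mixing a voxel series ``v(t)``
with the region's shared series ``s(t)`` as ``v' = (1 - lam) * v + lam * s``
raises local temporal synchrony — exactly the quantity regional homogeneity
(Kendall's W over a voxel neighborhood) measures — monotonically in ``lam``.
Behavioral scores (NDI symptom severity, Zung depression/anxiety raw scores,
disease duration) are drawn so that group means and spreads match a typical
dyspepsia case-control cohort, with the patient NDI linearly coupled to the
planted per-subject synchrony level.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "SubjectRecord",
    "CohortDataset",
    "simulate_cohort",
    "generate_behavior",
    "default_masks",
    "sphere_mask",
    "make_affine",
]

# Cohort-level behavioral targets (means / sds) used as realistic defaults.
# Zung scales are stored as raw sums (20-80); the index scale is raw * 1.25.
_PATIENT_NDI_MEAN = 48.73
_CONTROL_NDI = (1.37, 2.51)
_PATIENT_SDS_RAW = (43.04 / 1.25, 10.20 / 1.25)
_CONTROL_SDS_RAW = (33.38 / 1.25, 6.62 / 1.25)
_PATIENT_SAS_RAW = (41.79 / 1.25, 8.49 / 1.25)
_CONTROL_SAS_RAW = (33.83 / 1.25, 6.29 / 1.25)
_PATIENT_DURATION = (35.77, 22.44)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated two-group resting-state cohort.

    Parameters
    ----------
    n_per_group:
        Subjects per group (patients and controls each).
    grid_shape:
        Voxel grid, e.g. ``(16, 16, 16)``.
    voxel_size_mm:
        Isotropic voxel size in millimetres.
    n_volumes:
        Time points per subject (acquired volumes).
    tr_s:
        Repetition time in seconds.
    effect_rois:
        Spheres ``((cx, cy, cz), radius_voxels)`` receiving the planted
        patient effect.  Each sphere plus a one-voxel shell must lie inside
        the gray-matter mask.
    synchrony_lambda:
        Mean mixing weight ``lam`` of the shared regional signal in
        patients, in ``[0, 1)``.  ``0`` plants no effect.
    synchrony_sd:
        Between-patient spread of the per-subject mixing weight.
    noise_sd:
        Standard deviation of the white voxel noise (BOLD a.u.).
    drift_sd:
        Amplitude of the slow AR(1) drift shared by all voxels of a subject.
    ar_rho:
        AR(1) coefficient of the drift.
    behav_slope:
        NDI score units per unit of planted synchrony level.
    behav_noise_sd:
        Residual NDI noise (score units).
    motion_step_sd:
        Per-frame step of the random-walk motion parameters (mm / degrees).
    n_high_motion:
        Number of subjects given a large translation spike (for QC tests).
    seed:
        Master seed; all randomness derives from it.
    """

    n_per_group: int = 30
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_volumes: int = 150
    tr_s: float = 2.0
    effect_rois: tuple = (((8, 8, 8), 2),)
    synchrony_lambda: float = 0.9
    synchrony_sd: float = 0.1
    noise_sd: float = 1.0
    drift_sd: float = 0.3
    ar_rho: float = 0.3
    behav_slope: float = 100.0
    behav_noise_sd: float = 13.8
    motion_step_sd: float = 0.05
    n_high_motion: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.n_volumes <= 10:
            raise ConfigurationError(
                "n_volumes must exceed 10 (preprocessing discards 10 volumes)"
            )
        if not (0.0 <= self.synchrony_lambda < 1.0):
            raise ConfigurationError(
                f"synchrony_lambda must lie in [0, 1), got {self.synchrony_lambda}"
            )
        if min(self.grid_shape) < 8:
            raise ConfigurationError("each grid dimension must be >= 8 voxels")
        gm, _, _ = default_masks(self.grid_shape)
        for center, radius in self.effect_rois:
            shell = sphere_mask(self.grid_shape, center, radius + 1)
            if not shell[gm].sum() == shell.sum():
                raise ConfigurationError(
                    f"effect ROI at {center} (radius {radius}) plus its "
                    "one-voxel shell must lie inside the gray-matter mask"
                )


@dataclass
class SubjectRecord:
    """One subject: 4D BOLD, motion parameters, group and behavior."""

    subject_id: str
    group: str  # "patient" | "control"
    bold: np.ndarray  # (x, y, z, t), BOLD a.u.
    motion: np.ndarray  # (t, 6): 3 translations mm, 3 rotations deg
    ndi: float
    sds_raw: float
    sas_raw: float
    duration_months: float | None = None


@dataclass
class CohortDataset:
    """A simulated cohort plus its ground truth."""

    subjects: list[SubjectRecord]
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    affine: np.ndarray
    config: SimulationConfig
    truth: dict = field(default_factory=dict)

    @property
    def patients(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "patient"]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]


def make_affine(grid_shape: Sequence[int], voxel_size_mm: float) -> np.ndarray:
    """World-coordinate affine with the grid centered on the origin."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.asarray(grid_shape, float) - 1) / 2.0 * voxel_size_mm
    return affine


def sphere_mask(
    grid_shape: Sequence[int], center: Sequence[int], radius: float
) -> np.ndarray:
    """Boolean mask of voxels within ``radius`` (voxel units) of ``center``."""
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius**2


def default_masks(grid_shape):
    """Gray-matter cuboid with thin white-matter / CSF slabs at the faces.

    The three masks are mutually disjoint: gray matter fills the grid minus
    a two-voxel border, white matter and CSF occupy single-voxel slabs on
    opposite x-faces (stand-ins for the nuisance-signal compartments).
    """
    gm = np.zeros(grid_shape, dtype=bool)
    gm[2:-2, 2:-2, 2:-2] = True
    wm = np.zeros(grid_shape, dtype=bool)
    wm[0, 2:-2, 2:-2] = True
    csf = np.zeros(grid_shape, dtype=bool)
    csf[-1, 2:-2, 2:-2] = True
    return gm, wm, csf


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    e = rng.normal(0.0, 1.0, n)
    out = np.empty(n)
    out[0] = e[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + scale * e[t]
    return sd * out


def generate_behavior(
    effect: np.ndarray,
    slope: float,
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
) -> np.ndarray:
    """Linear symptom model ``score_i = intercept + slope * effect_i + eps_i``.

    With ``effect`` of standard deviation ``s_e`` the population Pearson
    correlation between effect and score is
    ``slope * s_e / sqrt(slope**2 * s_e**2 + noise_sd**2)``.
    """
    effect = np.asarray(effect, dtype=float)
    if not np.isfinite(slope):
        raise ConfigurationError("slope must be finite")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return intercept + slope * effect + rng.normal(0.0, noise_sd, effect.shape)


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Simulate a full two-group cohort per the configuration.

    Patients receive, inside each effect ROI, a mixture
    ``v' = (1 - lam_i) * v + lam_i * s`` of their baseline series with a
    shared regional Gaussian series ``s(t)`` (one per ROI per subject);
    ``lam_i`` is the subject's planted synchrony level, drawn around
    ``synchrony_lambda`` and recorded in ``truth``.  Controls have
    ``lam_i = 0``.  Deterministic given the seed.
    """
    config.validate()
    shape = tuple(config.grid_shape)
    T = config.n_volumes
    gm, wm, csf = default_masks(shape)
    affine = make_affine(shape, config.voxel_size_mm)
    roi_masks = [sphere_mask(shape, c, r) for c, r in config.effect_rois]

    ss = np.random.SeedSequence(config.seed)
    n_total = 2 * config.n_per_group
    child_seeds = ss.spawn(n_total + 1)
    behav_rng = np.random.default_rng(child_seeds[-1])

    ndi_intercept = _PATIENT_NDI_MEAN - config.behav_slope * config.synchrony_lambda

    subjects: list[SubjectRecord] = []
    effect_levels = np.zeros(n_total)
    for i in range(n_total):
        is_patient = i < config.n_per_group
        rng = np.random.default_rng(child_seeds[i])
        bold = rng.normal(0.0, config.noise_sd, shape + (T,))
        drift = _ar1(rng, T, config.ar_rho, config.drift_sd)
        bold += drift  # broadcast over the time axis

        lam = 0.0
        if is_patient and config.synchrony_lambda > 0:
            lam = float(
                np.clip(
                    rng.normal(config.synchrony_lambda, config.synchrony_sd),
                    0.0,
                    0.99,
                )
            )
        effect_levels[i] = lam
        if lam > 0:
            for roi in roi_masks:
                s = rng.normal(0.0, config.noise_sd, T) + drift
                bold[roi] = (1.0 - lam) * bold[roi] + lam * s

        motion = np.cumsum(
            rng.normal(0.0, config.motion_step_sd, (T, 6)), axis=0
        )
        if i < config.n_high_motion:
            motion[T // 2, 0] += 2.5  # translation spike well past QC gate

        if is_patient:
            ndi = max(
                0.0,
                ndi_intercept
                + config.behav_slope * lam
                + behav_rng.normal(0.0, config.behav_noise_sd),
            )
            sds = float(np.clip(behav_rng.normal(*_PATIENT_SDS_RAW), 20, 80))
            sas = float(np.clip(behav_rng.normal(*_PATIENT_SAS_RAW), 20, 80))
            duration = float(max(1.0, behav_rng.normal(*_PATIENT_DURATION)))
            sid = f"patient{i + 1:03d}"
            group = "patient"
        else:
            ndi = float(max(0.0, behav_rng.normal(*_CONTROL_NDI)))
            sds = float(np.clip(behav_rng.normal(*_CONTROL_SDS_RAW), 20, 80))
            sas = float(np.clip(behav_rng.normal(*_CONTROL_SAS_RAW), 20, 80))
            duration = None
            sid = f"control{i - config.n_per_group + 1:03d}"
            group = "control"

        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                bold=bold.astype(np.float32),
                motion=motion,
                ndi=ndi,
                sds_raw=sds,
                sas_raw=sas,
                duration_months=duration,
            )
        )

    truth = {
        "roi_masks": roi_masks,
        "effect_union": (
            np.logical_or.reduce(roi_masks)
            if roi_masks
            else np.zeros(shape, bool)
        ),
        "effect_levels": effect_levels,
        "config": asdict(config),
    }
    return CohortDataset(
        subjects=subjects,
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
        affine=affine,
        config=config,
        truth=truth,
    )
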