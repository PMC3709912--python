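"""Spherical ROIs at cluster peaks and brain-symptom correlations.

For each significant cluster a 6 mm sphere is centered on the voxel of
largest absolute classification weight; the mean normalized ReHo inside
the sphere is extracted per patient and correlated (Pearson) with symptom
severity (NDI) and disease duration, with Bonferroni adjustment over
ROIs x variables at the 0.01 level.  Also scores the Zung depression /
anxiety scales (index = raw sum x 1.25; normal below 53 / 50).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .discriminative import WeightMap
from .errors import ConfigurationError, DegenerateInputError
from .reho import ReHoMap

__all__ = [
    "ROISpec",
    "CorrelationResult",
    "zung_index",
    "peak_roi",
    "mean_reho_in_roi",
    "pearson_correlation",
    "bonferroni_adjust",
    "correlate_rois",
]

_ZUNG_NORMAL_CUTOFF = {"sds": 53.0, "sas": 50.0}


@dataclass
class ROISpec:
    """A sphere of gray-matter voxels around a cluster's peak weight."""

    center_mm: tuple
    radius_mm: float
    source_cluster: int
    voxel_set: np.ndarray  # (n, 3) grid coordinates


@dataclass
class CorrelationResult:
    roi_id: int
    variable: str
    r: float
    p_raw: float
    p_adjusted: float
    significant: bool


def zung_index(raw_score: float, scale: str = "sds") -> tuple[float, bool]:
    """Zung index = raw x 1.25; returns (index, in_normal_range).

    Raw scores are sums of 20 items scored 1-4, hence in [20, 80]; the
    normal range is an index below 53 (depression) or 50 (anxiety).
    """
    if not 20 <= raw_score <= 80:
        raise ConfigurationError(
            f"raw Zung score must lie in [20, 80], got {raw_score}"
        )
    if scale not in _ZUNG_NORMAL_CUTOFF:
        raise ConfigurationError("scale must be 'sds' or 'sas'")
    index = raw_score * 1.25
    return index, index < _ZUNG_NORMAL_CUTOFF[scale]


def peak_roi(
    weight_map: WeightMap,
    cluster_indices: np.ndarray,
    affine: np.ndarray,
    gm_mask: np.ndarray,
    radius_mm: float = 6.0,
    source_cluster: int = 0,
) -> ROISpec:
    """Sphere around the in-cluster voxel of maximal |weight|.

    Ties at the maximum resolve to the lowest linear voxel index.  The
    voxel set contains every gray-matter voxel whose center lies within
    ``radius_mm`` of the peak's world coordinate.
    """
    idx = np.asarray(cluster_indices)
    if idx.size == 0:
        raise ConfigurationError("cluster is empty")
    weights = np.abs(weight_map.map3d[tuple(idx.T)])
    order = np.argsort(-weights, kind="stable")  # argwhere order == linear index
    peak = idx[order[0]]
    center_mm = (affine @ np.append(peak, 1.0))[:3]

    gm_idx = np.argwhere(gm_mask)
    centers_mm = (affine[:3, :3] @ gm_idx.T).T + affine[:3, 3]
    dist = np.linalg.norm(centers_mm - center_mm, axis=1)
    voxel_set = gm_idx[dist <= radius_mm]
    if voxel_set.shape[0] == 0:
        raise ConfigurationError("resolved sphere contains no gray-matter voxels")
    return ROISpec(
        center_mm=tuple(float(v) for v in center_mm),
        radius_mm=radius_mm,
        source_cluster=source_cluster,
        voxel_set=voxel_set,
    )


def mean_reho_in_roi(reho: ReHoMap, roi: ROISpec) -> float:
    """Mean normalized ReHo over the ROI's computable voxels."""
    sel = reho.computable_mask[tuple(roi.voxel_set.T)]
    if not sel.any():
        raise DegenerateInputError("no computable voxels inside the ROI")
    vals = reho.normalized[tuple(roi.voxel_set[sel].T)]
    return float(vals.mean())


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment r with two-tailed p from the t distribution (df n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ConfigurationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(
    p_raw, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply-and-cap Bonferroni: p_adj = min(1, p * m); significant if < alpha."""
    p_raw = np.atleast_1d(np.asarray(p_raw, dtype=float))
    if p_raw.size == 0:
        raise ConfigurationError("need at least one p-value")
    _, p_adj, _, _ = multipletests(p_raw, method="bonferroni")
    return p_adj, p_adj < alpha


def correlate_rois(
    roi_means: dict[int, np.ndarray],
    behavior: dict[str, np.ndarray],
    alpha: float = 0.01,
    raw_threshold: bool = False,
) -> list[CorrelationResult]:
    """Pearson correlations of per-patient ROI means with symptom variables.

    ``roi_means`` maps ROI id -> per-patient mean ReHo; ``behavior`` maps
    variable name (e.g. "ndi", "duration_months") -> per-patient scores.
    Bonferroni m = (#ROIs) x (#variables).  With ``raw_threshold`` the
    per-test criterion p_raw < alpha / m is used instead of the adjusted-p
    reading (both are equivalent decisions; the reported p differs).
    """
    tests = [
        (roi_id, var, *pearson_correlation(means, behavior[var]))
        for roi_id, means in sorted(roi_means.items())
        for var in behavior
    ]
    if not tests:
        return []
    m = len(tests)
    p_adj, sig = bonferroni_adjust([t[3] for t in tests], alpha=alpha)
    results = []
    for (roi_id, var, r, p), pa, s in zip(tests, p_adj, sig):
        if raw_threshold:
            s = p < alpha / m
        results.append(
            CorrelationResult(
                roi_id=roi_id,
                variable=var,
                r=r,
                p_raw=p,
                p_adjusted=float(pa),
                significant=bool(s),
            )
        )
    return results
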