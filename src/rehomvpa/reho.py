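"""Regional homogeneity (ReHo): voxelwise Kendall's coefficient of concordance.

ReHo treats the time series of a voxel and its neighbors (26 nearest by
default) as K judges ranking the n time points, and summarizes their
agreement with Kendall's W in [0, 1].  Locally synchronized BOLD activity
yields W near 1; independent noise yields W near 1/K on average.  Maps are
computed within a gray-matter mask and normalized by the mean W over the
computable gray matter, so a value of 1 means "as homogeneous as the
gray-matter average".

With midrank tie handling the statistic is

    W = 12 S / (K^2 (n^3 - n) - K * sum_j T_j),

where S is the sum over time points of squared deviations of the rank sums
from their mean K (n + 1) / 2, and T_j = sum over tie groups of (t^3 - t)
within series j (zero without ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "ReHoConfig",
    "ReHoMap",
    "kendalls_w",
    "reho_map",
    "normalize_reho",
    "neighborhood_offsets",
]


@dataclass(frozen=True)
class ReHoConfig:
    """Neighborhood, edge and tie conventions for the ReHo map.

    neighborhood
        27 (center + 26 neighbors, default), 19 (center + face + edge), or
        7 (center + face neighbors).
    edge_policy
        ``"all_neighbors_required"`` (default): a voxel gets a W value only
        if every neighbor in the chosen cube lies inside the gray-matter
        mask; other mask voxels are excluded from both the map and the
        normalization mean.  ``"available_neighbors"``: use whatever
        in-mask members exist, requiring at least ``min_members``.
    tie_policy
        ``"midrank_corrected"`` (default) or ``"error_on_ties"``.
    """

    neighborhood: int = 27
    edge_policy: str = "all_neighbors_required"
    tie_policy: str = "midrank_corrected"
    min_members: int = 7

    def __post_init__(self):
        if self.neighborhood not in (7, 19, 27):
            raise ConfigurationError("neighborhood must be one of 7, 19, 27")
        if self.edge_policy not in ("all_neighbors_required", "available_neighbors"):
            raise ConfigurationError(f"unknown edge_policy {self.edge_policy!r}")
        if self.tie_policy not in ("midrank_corrected", "error_on_ties"):
            raise ConfigurationError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass
class ReHoMap:
    """Voxelwise Kendall's W and its gray-matter-normalized form."""

    kcc: np.ndarray  # 3D, NaN outside computable_mask
    computable_mask: np.ndarray  # 3D bool
    normalized: np.ndarray  # kcc / mean(kcc over computable_mask)


def neighborhood_offsets(neighborhood: int) -> np.ndarray:
    """Voxel offsets of the 7/19/27 cube including the center."""
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    if neighborhood == 27:
        keep = offsets
    elif neighborhood == 19:
        keep = [o for o in offsets if sum(abs(v) for v in o) <= 2]
    elif neighborhood == 7:
        keep = [o for o in offsets if sum(abs(v) for v in o) <= 1]
    else:
        raise ConfigurationError("neighborhood must be one of 7, 19, 27")
    return np.array(keep, dtype=int)


def _tie_term_1d(values: np.ndarray) -> float:
    """Sum of (t^3 - t) over groups of tied values in one series."""
    _, counts = np.unique(values, return_counts=True)
    counts = counts[counts > 1]
    return float((counts**3 - counts).sum())


def kendalls_w(
    series_set: np.ndarray, tie_policy: str = "midrank_corrected"
) -> float:
    """Kendall's coefficient of concordance of K time series of length n.

    Each series is ranked over time (midranks for ties); W in [0, 1]
    measures the agreement of the K rankings.  Raises
    ``DegenerateInputError`` when every series is constant (0/0).
    """
    series = np.asarray(series_set, dtype=float)
    if series.ndim != 2:
        raise ConfigurationError("series_set must be a K x n array")
    K, n = series.shape
    if K < 2 or n < 2:
        raise ConfigurationError(f"need K >= 2 and n >= 2, got K={K}, n={n}")
    tie_sum = sum(_tie_term_1d(row) for row in series)
    if tie_policy == "error_on_ties" and tie_sum > 0:
        raise DegenerateInputError("tied values present with tie_policy='error_on_ties'")
    denom = K**2 * (n**3 - n) - K * tie_sum
    if denom <= 0:
        raise DegenerateInputError(
            "Kendall's W undefined: all series constant (zero denominator)"
        )
    ranks = rankdata(series, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - K * (n + 1) / 2.0) ** 2).sum())
    return 12.0 * s / denom


def _shift_add(acc: np.ndarray, arr: np.ndarray, offset) -> None:
    """acc[v] += arr[v + offset] with zero padding at the grid boundary."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, d in enumerate(offset):
        n = arr.shape[axis]
        if d > 0:
            src[axis], dst[axis] = slice(d, n), slice(0, n - d)
        elif d < 0:
            src[axis], dst[axis] = slice(0, n + d), slice(-d, n)
    acc[tuple(dst)] += arr[tuple(src)]


def reho_map(
    bold: np.ndarray, gm_mask: np.ndarray, config: ReHoConfig | None = None
) -> ReHoMap:
    """Voxelwise Kendall's W over cubic neighborhoods inside a mask.

    Fully vectorized: series are rank-transformed once, then neighborhood
    rank sums and tie terms are accumulated by array shifting.
    """
    config = config or ReHoConfig()
    bold = np.asarray(bold, dtype=float)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if bold.ndim != 4:
        raise ConfigurationError("bold must be 4D (x, y, z, t)")
    if bold.shape[:3] != gm_mask.shape:
        raise ConfigurationError("bold and gray-matter mask grids differ")
    n = bold.shape[-1]
    if n < 2:
        raise ConfigurationError("need at least 2 time points")

    offsets = neighborhood_offsets(config.neighborhood)
    ranks = rankdata(bold, axis=-1)
    ranks[~gm_mask] = 0.0

    # per-voxel tie correction terms (zero for strictly untied series)
    tie_map = np.zeros(gm_mask.shape)
    sorted_vals = np.sort(bold, axis=-1)
    has_tie = (np.diff(sorted_vals, axis=-1) == 0).any(axis=-1) & gm_mask
    if has_tie.any():
        if config.tie_policy == "error_on_ties":
            raise DegenerateInputError(
                "tied values present with tie_policy='error_on_ties'"
            )
        for idx in np.argwhere(has_tie):
            tie_map[tuple(idx)] = _tie_term_1d(bold[tuple(idx)])

    gm_f = gm_mask.astype(float)
    count = np.zeros(gm_mask.shape)
    rank_sum = np.zeros(gm_mask.shape + (n,))
    tie_sum = np.zeros(gm_mask.shape)
    for off in offsets:
        _shift_add(count, gm_f, off)
        _shift_add(rank_sum, ranks, off)
        _shift_add(tie_sum, tie_map, off)

    if config.edge_policy == "all_neighbors_required":
        computable = gm_mask & (count == len(offsets))
    else:
        computable = gm_mask & (count >= config.min_members)
    if not computable.any():
        raise ConfigurationError("no computable voxels inside the mask")

    K = count
    s = ((rank_sum - K[..., None] * (n + 1) / 2.0) ** 2).sum(axis=-1)
    denom = K**2 * (n**3 - n) - K * tie_sum
    degenerate = computable & (denom <= 0)
    if degenerate.any():
        computable = computable & ~degenerate
        if not computable.any():
            raise DegenerateInputError("all computable voxels have constant series")

    kcc = np.full(gm_mask.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_all = 12.0 * s / denom
    kcc[computable] = w_all[computable]

    normalized = normalize_reho(kcc, computable)
    return ReHoMap(kcc=kcc, computable_mask=computable, normalized=normalized)


def normalize_reho(kcc_map: np.ndarray, computable_mask: np.ndarray) -> np.ndarray:
    """Divide W by its mean over the computable mask (mean of output = 1)."""
    mean_w = float(np.nanmean(kcc_map[computable_mask]))
    if not np.isfinite(mean_w) or mean_w <= 0:
        raise DegenerateInputError(
            f"cannot normalize: mean W over mask is {mean_w}"
        )
    out = np.full(kcc_map.shape, np.nan)
    out[computable_mask] = kcc_map[computable_mask] / mean_w
    return out
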