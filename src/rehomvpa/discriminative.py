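"""Discriminative weight maps and permutation-based cluster inference.

The linear SVM's reduced-space weight vector w is mapped back to voxel
space as U w (U the PCA eigenvector matrix), giving a discriminative map
whose large-|weight| voxels drive the patient/control separation.  A
label-permutation null — retraining the classifier under each of n_perm
random relabelings — yields (i) two-sided empirical voxel p-values on |w|
and (ii) a max-cluster-size null distribution for cluster-level inference:
each permuted map is thresholded at its own (1 - voxel_alpha) quantile of
|w| and the largest surviving connected component is recorded.

Empirical p-values use the add-one convention p = (1 + b) / (m + 1), so
they are never 0 and never exceed 1.

Weight maps are scaled to unit L2 norm before observed/null comparison
(``PermutationConfig.unit_norm``, on by default): a soft-margin SVM's
weight magnitude scales inversely with the achieved margin, so raw
weights of a well-separated observed fit are systematically smaller than
those of inseparable permuted fits.  The unit-norm statistic — each
voxel's relative contribution to the discriminating direction — is
exchangeable under the null, so the permutation p-values stay exact,
and it is insensitive to the global margin scale.

Note the PCA step depends only on the feature matrix, not the labels, so
it is fit once and shared across permutations; only the SVM is retrained,
which is mathematically identical to refitting both per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage

from .classify import FeatureMatrix, PCAModel, SVMModel, fit_pca, train_svm
from .errors import ConfigurationError

__all__ = [
    "PermutationConfig",
    "WeightMap",
    "PermutationNull",
    "Cluster",
    "ClusterTable",
    "observed_weight_map",
    "permutation_null",
    "voxel_pvalues",
    "extract_clusters",
    "cluster_pvalues",
    "connectivity_structure",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test parameters (defaults follow the reference analysis)."""

    n_perm: int = 5000
    voxel_alpha: float = 0.02
    min_cluster_voxels: int = 10
    cluster_alpha: float = 0.001
    connectivity: int = 26
    seed: int = 0
    threshold_mode: str = "own_quantile"  # or "pooled_quantile"
    unit_norm: bool = True  # compare weight maps after scaling to unit L2 norm

    def __post_init__(self):
        if not (0 < self.voxel_alpha < 1 and 0 < self.cluster_alpha < 1):
            raise ConfigurationError("alphas must lie in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError("connectivity must be 6, 18 or 26")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.n_perm < 1.0 / self.cluster_alpha:
            warnings.warn(
                f"n_perm={self.n_perm} cannot resolve cluster p-values below "
                f"1/{self.n_perm + 1}; cluster_alpha={self.cluster_alpha} is "
                "unreachable",
                stacklevel=2,
            )


@dataclass
class WeightMap:
    """SVM weights back-projected to voxel space (U w_reduced)."""

    w_flat: np.ndarray  # (D,) on the feature mask
    map3d: np.ndarray  # 3D, NaN off-mask
    mask: np.ndarray  # 3D bool feature mask
    pca: PCAModel
    svm: SVMModel
    meta: dict = field(default_factory=dict)


@dataclass
class PermutationNull:
    abs_null: np.ndarray  # (n_perm, D) |w| under permuted labels
    max_cluster_sizes: np.ndarray  # (n_perm,)
    config: PermutationConfig


@dataclass
class Cluster:
    indices: np.ndarray  # (size, 3) voxel coordinates
    size: int


@dataclass
class ClusterTable:
    """Per-cluster peaks, sizes and voxel-/cluster-level p-values."""

    rows: list[dict]

    def significant(self) -> list[dict]:
        return [r for r in self.rows if r["significant"]]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structure for 6-, 18- or 26-connected components."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ConfigurationError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def neighborhood_offsets_for_connectivity(connectivity: int) -> list[tuple]:
    """Neighbor offsets (center excluded) of the 6/18/26 connectivity."""
    struct = connectivity_structure(connectivity)
    return [tuple(o) for o in (np.argwhere(struct) - 1) if any(o)]


def observed_weight_map(fm: FeatureMatrix, C: float = 1.0) -> WeightMap:
    """Train PCA + SVM on all subjects with true labels; back-project w."""
    pca = fit_pca(fm.X)
    svm = train_svm(pca.project(fm.X), fm.labels, C=C)
    w_flat = pca.back_project(svm.w)
    return WeightMap(
        w_flat=w_flat,
        map3d=fm.to_map(w_flat),
        mask=fm.mask,
        pca=pca,
        svm=svm,
        meta={"label_convention": "patient=+1, control=-1", "C": C},
    )


def _max_cluster_size(
    binary_flat: np.ndarray, fm: FeatureMatrix, structure: np.ndarray
) -> int:
    vol = fm.to_map(binary_flat.astype(float), fill=0.0) > 0
    labeled, n = ndimage.label(vol, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


def permutation_null(
    fm: FeatureMatrix, config: PermutationConfig | None = None
) -> PermutationNull:
    """Null weight maps and max-cluster-size record under label permutation.

    Permutations are drawn uniformly (with replacement) from the group-size
    preserving permutation group, seeded by ``config.seed``.
    """
    config = config or PermutationConfig()
    if config.n_perm < 100:
        warnings.warn(
            f"n_perm={config.n_perm} < 100 gives coarse p-values", stacklevel=2
        )
    rng = np.random.default_rng(config.seed)
    structure = connectivity_structure(config.connectivity)
    pca = fit_pca(fm.X)
    Y = pca.project(fm.X)
    D = fm.X.shape[1]
    abs_null = np.empty((config.n_perm, D))
    max_sizes = np.empty(config.n_perm, dtype=int)
    for p in range(config.n_perm):
        perm_labels = rng.permutation(fm.labels)
        svm = train_svm(Y, perm_labels, C=1.0)
        w_vox = np.abs(pca.back_project(svm.w))
        if config.unit_norm:
            norm = np.linalg.norm(w_vox)
            if norm > 0:
                w_vox = w_vox / norm
        abs_null[p] = w_vox
        if config.threshold_mode == "own_quantile":
            thr = np.quantile(w_vox, 1.0 - config.voxel_alpha)
            supra = w_vox > thr
            max_sizes[p] = _max_cluster_size(supra, fm, structure)
        else:
            max_sizes[p] = -1  # filled in below for pooled mode
    if config.threshold_mode == "pooled_quantile":
        thr_map = np.quantile(abs_null, 1.0 - config.voxel_alpha, axis=0)
        for p in range(config.n_perm):
            supra = abs_null[p] > thr_map
            max_sizes[p] = _max_cluster_size(supra, fm, structure)
    return PermutationNull(
        abs_null=abs_null, max_cluster_sizes=max_sizes, config=config
    )


def voxel_pvalues(w_obs: WeightMap, null: PermutationNull) -> np.ndarray:
    """Two-sided empirical p per voxel: p = (1 + #{|w_perm| >= |w_obs|}) / (m + 1).

    Returns a 3D p-map, NaN outside the feature mask.
    """
    m = null.abs_null.shape[0]
    w = np.abs(w_obs.w_flat)
    if null.config.unit_norm:
        norm = np.linalg.norm(w)
        if norm > 0:
            w = w / norm
    exceed = (null.abs_null >= w).sum(axis=0)
    p_flat = (1.0 + exceed) / (m + 1.0)
    return _scatter(w_obs, p_flat)


def _scatter(w_obs: WeightMap, values: np.ndarray) -> np.ndarray:
    out = np.full(w_obs.mask.shape, np.nan)
    out[w_obs.mask] = values
    return out


def extract_clusters(
    p_map: np.ndarray,
    mask: np.ndarray,
    voxel_alpha: float = 0.02,
    min_cluster_voxels: int = 10,
    connectivity: int = 26,
) -> list[Cluster]:
    """Connected components of {p < voxel_alpha}, dropping small ones."""
    binary = np.zeros(mask.shape, dtype=bool)
    binary[mask] = p_map[mask] < voxel_alpha
    labeled, n = ndimage.label(binary, structure=connectivity_structure(connectivity))
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        if idx.shape[0] >= min_cluster_voxels:
            clusters.append(Cluster(indices=idx, size=idx.shape[0]))
    clusters.sort(key=lambda c: -c.size)
    return clusters


def cluster_pvalues(
    candidates: list[Cluster],
    null: PermutationNull,
    w_obs: WeightMap,
    p_map: np.ndarray,
    affine: np.ndarray,
    cluster_alpha: float = 0.001,
) -> ClusterTable:
    """Cluster-level p from the max-cluster-size null; flag significance.

    p_cluster = (1 + #{perm: max_size_perm >= observed_size}) / (n_perm + 1);
    a cluster is significant when p_cluster < cluster_alpha.  All candidate
    clusters are reported, significant or not.
    """
    m = null.max_cluster_sizes.shape[0]
    rows = []
    for k, cl in enumerate(candidates):
        weights = w_obs.map3d[tuple(cl.indices.T)]
        order = np.argsort(-np.abs(weights), kind="stable")
        peak = cl.indices[order[0]]  # ties: first in index order (stable sort)
        peak_mm = (affine @ np.append(peak, 1.0))[:3]
        p_cl = (1.0 + (null.max_cluster_sizes >= cl.size).sum()) / (m + 1.0)
        rows.append(
            {
                "cluster_id": k,
                "size": cl.size,
                "peak_ijk": tuple(int(v) for v in peak),
                "peak_mm": tuple(float(v) for v in peak_mm),
                "peak_weight": float(w_obs.map3d[tuple(peak)]),
                "p_voxel_peak": float(p_map[tuple(peak)]),
                "p_cluster": float(p_cl),
                "significant": bool(p_cl < cluster_alpha),
            }
        )
    return ClusterTable(rows=rows)
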