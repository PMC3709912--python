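"""Validation studies: oracles, null calibration and planted-effect recovery.

This module hosts (i) independent brute-force reference implementations
used to cross-check the production code (a Friedman-statistic route to
Kendall's W, a flood-fill connected-component labeller), and (ii) the
scaled-down simulation studies that characterize the pipeline: the null
expectation of ReHo on white noise, PCA/SVM equivalence and
back-projection identities, permutation-test calibration on effect-free
cohorts, planted-signal recovery, and symptom-correlation recovery.

The reference implementations are deliberately naive (explicit loops,
independent rank computation) so that agreement with the vectorized
production code is informative.
"""

from __future__ import annotations

import dataclasses
from collections import deque

import numpy as np
from sklearn.svm import SVC

from .classify import (
    CONTROL,
    PATIENT,
    ConfusionCounts,
    build_feature_matrix,
    fit_pca,
    loocv,
    metrics,
    train_svm,
)
from .discriminative import (
    PermutationConfig,
    cluster_pvalues,
    connectivity_structure,
    extract_clusters,
    neighborhood_offsets_for_connectivity,
    observed_weight_map,
    permutation_null,
    voxel_pvalues,
)
from .preproc import PreprocConfig, preprocess_subject
from .reho import ReHoConfig, kendalls_w, reho_map
from .roi import mean_reho_in_roi, peak_roi, pearson_correlation
from .synthetic import SimulationConfig, generate_behavior, simulate_cohort

__all__ = [
    "friedman_w_reference",
    "flood_fill_label",
    "metric_worked_example",
    "kcc_oracle_max_diff",
    "white_noise_mean_w",
    "pca_svm_equivalence_max_diff",
    "backprojection_identity_max_diff",
    "null_calibration",
    "signal_recovery",
    "correlation_recovery",
    "cluster_oracle_agreement",
]


# --------------------------------------------------------------------------
# independent reference implementations
# --------------------------------------------------------------------------

def _midranks(values) -> list[float]:
    """Midranks computed by explicit sorting and tie-group averaging."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def friedman_w_reference(series_set: np.ndarray) -> float:
    """Kendall's W via the tie-corrected Friedman statistic, brute force.

    chi2_F = 12 / (K n (n+1)) * sum_t R_t^2 - 3 K (n+1), divided by the
    tie correction c = 1 - sum T_j / (K (n^3 - n)); W = chi2_F / (K (n-1)).
    """
    series = [list(map(float, row)) for row in np.asarray(series_set)]
    K, n = len(series), len(series[0])
    ranks = [_midranks(row) for row in series]
    rank_sums = [sum(ranks[j][t] for j in range(K)) for t in range(n)]
    chi2 = 12.0 / (K * n * (n + 1)) * sum(r * r for r in rank_sums) - 3.0 * K * (
        n + 1
    )
    tie_sum = 0.0
    for row in series:
        seen = {}
        for v in row:
            seen[v] = seen.get(v, 0) + 1
        tie_sum += sum(c**3 - c for c in seen.values())
    c = 1.0 - tie_sum / (K * (n**3 - n))
    if c <= 0:
        raise ZeroDivisionError("all series constant")
    return chi2 / c / (K * (n - 1))


def flood_fill_label(binary: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a 3D binary map by breadth-first flood fill."""
    offsets = neighborhood_offsets_for_connectivity(connectivity)
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros(binary.shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                nb = tuple(v[a] + off[a] for a in range(3))
                if any(c < 0 or c >= binary.shape[a] for a, c in enumerate(nb)):
                    continue
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(comp)
    return components


# --------------------------------------------------------------------------
# acceptance-style studies
# --------------------------------------------------------------------------

def metric_worked_example() -> dict[str, float]:
    """Classifier metrics for 25/30 patients and 27/30 controls correct."""
    counts = ConfusionCounts(tp=25, fn=5, tn=27, fp=3)
    return metrics(counts)


def kcc_oracle_max_diff(
    n_instances: int = 200, seed: int = 20_001, max_k: int = 30, max_n: int = 20
) -> float:
    """Max |kendalls_w - Friedman reference| over random small instances.

    Half the instances are rounded to one decimal to force ties.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        K = int(rng.integers(2, max_k + 1))
        n = int(rng.integers(3, max_n + 1))
        series = rng.normal(size=(K, n))
        if i % 2 == 1:
            series = np.round(series, 1)  # introduces ties
        worst = max(worst, abs(kendalls_w(series) - friedman_w_reference(series)))
    return worst


def white_noise_mean_w(
    n_seeds: int = 10, grid: tuple = (12, 12, 12), n_time: int = 140,
    seed: int = 20_002,
) -> float:
    """Mean Kendall's W of 27-voxel ReHo on pure white noise (null ~ 1/27)."""
    rng = np.random.default_rng(seed)
    mask = np.ones(grid, dtype=bool)
    means = []
    for _ in range(n_seeds):
        bold = rng.normal(size=grid + (n_time,))
        rmap = reho_map(bold, mask, ReHoConfig())
        means.append(np.nanmean(rmap.kcc[rmap.computable_mask]))
    return float(np.mean(means))


def pca_svm_equivalence_max_diff(
    n: int = 12, d: int = 200, seed: int = 20_003
) -> float:
    """Reduced-space SVM vs voxel-space SVM on mean-centered features.

    With all N-1 principal components the projection preserves the linear
    kernel Gram matrix of the centered data, so both routes must give the
    same decision values.  Returns the max absolute difference.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X[: n // 2] += 0.5
    labels = np.array([PATIENT] * (n // 2) + [CONTROL] * (n - n // 2))
    pca = fit_pca(X)
    svm_reduced = train_svm(pca.project(X), labels, C=1.0)
    dec_reduced = svm_reduced.decision(pca.project(X))
    clf = SVC(kernel="linear", C=1.0, tol=1e-7)
    Xc = X - X.mean(axis=0)
    clf.fit(Xc, labels)
    dec_voxel = clf.decision_function(Xc)
    return float(np.max(np.abs(dec_reduced - dec_voxel)))


def backprojection_identity_max_diff(
    n: int = 16, d: int = 300, seed: int = 20_004
) -> float:
    """Max |<w_voxel, x_i - mean> - <w_reduced, y_i>| over training rows."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X[: n // 2, : d // 10] += 0.8
    labels = np.array([PATIENT] * (n // 2) + [CONTROL] * (n - n // 2))
    pca = fit_pca(X)
    Y = pca.project(X)
    svm = train_svm(Y, labels, C=1.0)
    w_voxel = pca.back_project(svm.w)
    lhs = (X - pca.mean) @ w_voxel
    rhs = Y @ svm.w
    return float(np.max(np.abs(lhs - rhs)))


def _cohort_features(config: SimulationConfig):
    """Simulate, preprocess and map a cohort; return (feature matrix, cohort, maps)."""
    cohort = simulate_cohort(config)
    pcfg = PreprocConfig(tr_s=config.tr_s)
    maps, labels = [], []
    for s in cohort.subjects:
        clean = preprocess_subject(
            s.bold, s.motion, cohort.wm_mask, cohort.csf_mask, pcfg
        )
        maps.append(reho_map(clean, cohort.gm_mask))
        labels.append(PATIENT if s.group == "patient" else CONTROL)
    return build_feature_matrix(maps, labels), cohort, maps


def null_calibration(
    n_runs: int = 40, n_per_group: int = 10, n_perm: int = 200,
    cluster_alpha: float = 0.05, seed: int = 20_005,
) -> dict[str, float]:
    """Permutation-test calibration on effect-free cohorts (lambda = 0).

    Returns the mean Kolmogorov-Smirnov distance of the pooled voxel
    p-values from uniform and the fraction of runs producing any cluster
    with cluster-level p below ``cluster_alpha``.
    """
    root = np.random.SeedSequence(seed)
    ks_stats, any_sig = [], 0
    for run_seed in root.generate_state(n_runs):
        run_seed = int(run_seed % (2**31 - 1))
        config = SimulationConfig(
            n_per_group=n_per_group, grid_shape=(16, 16, 16),
            n_volumes=150, synchrony_lambda=0.0, seed=run_seed,
        )
        fm, cohort, _ = _cohort_features(config)
        pcfg = PermutationConfig(
            n_perm=n_perm, cluster_alpha=cluster_alpha, seed=run_seed + 1
        )
        w_obs = observed_weight_map(fm)
        null = permutation_null(fm, pcfg)
        p_map = voxel_pvalues(w_obs, null)
        p_vals = np.sort(p_map[fm.mask])
        # KS distance to U(0,1) of the empirical CDF
        grid_hi = np.arange(1, p_vals.size + 1) / p_vals.size
        grid_lo = np.arange(0, p_vals.size) / p_vals.size
        ks = max(np.max(grid_hi - p_vals), np.max(p_vals - grid_lo))
        ks_stats.append(ks)
        clusters = extract_clusters(
            p_map, fm.mask, pcfg.voxel_alpha, pcfg.min_cluster_voxels,
            pcfg.connectivity,
        )
        table = cluster_pvalues(
            clusters, null, w_obs, p_map, cohort.affine, cluster_alpha
        )
        if table.significant():
            any_sig += 1
    return {
        "mean_ks": float(np.mean(ks_stats)),
        "any_significant_cluster_rate": any_sig / n_runs,
    }


def signal_recovery(
    n_seeds: int = 10, n_per_group: int = 15, n_perm: int = 500,
    synchrony_lambda: float = 0.9, cluster_alpha: float = 0.05,
    seed: int = 20_006,
) -> dict[str, float]:
    """Planted-effect recovery: LOOCV accuracy and cluster/ROI overlap.

    One spherical region of elevated synchrony is planted in patients; a
    run succeeds when LOOCV GR >= 90% and some significant cluster overlaps
    the planted region with Jaccard > 0.2.
    """
    root = np.random.SeedSequence(seed)
    grs, jaccards, successes = [], [], 0
    for run_seed in root.generate_state(n_seeds):
        run_seed = int(run_seed % (2**31 - 1))
        config = SimulationConfig(
            n_per_group=n_per_group, grid_shape=(16, 16, 16),
            synchrony_lambda=synchrony_lambda, seed=run_seed,
        )
        fm, cohort, _ = _cohort_features(config)
        counts, _, _ = loocv(fm)
        gr = metrics(counts)["GR"]
        grs.append(gr)
        pcfg = PermutationConfig(
            n_perm=n_perm, cluster_alpha=cluster_alpha, seed=run_seed + 1
        )
        w_obs = observed_weight_map(fm)
        null = permutation_null(fm, pcfg)
        p_map = voxel_pvalues(w_obs, null)
        clusters = extract_clusters(
            p_map, fm.mask, pcfg.voxel_alpha, pcfg.min_cluster_voxels,
            pcfg.connectivity,
        )
        table = cluster_pvalues(
            clusters, null, w_obs, p_map, cohort.affine, cluster_alpha
        )
        truth = cohort.truth["effect_union"]
        detected = np.zeros_like(truth)
        for row in table.significant():
            idx = clusters[row["cluster_id"]].indices
            detected[tuple(idx.T)] = True
        inter = (detected & truth).sum()
        union = (detected | truth).sum()
        jac = inter / union if union else 0.0
        jaccards.append(jac)
        if gr >= 90.0 and jac > 0.2:
            successes += 1
    return {
        "mean_gr": float(np.mean(grs)),
        "mean_jaccard": float(np.mean(jaccards)),
        "success_rate": successes / n_seeds,
    }


def correlation_recovery(
    n_seeds: int = 50, n_patients: int = 30, target_r: float = 0.6,
    seed: int = 20_007,
) -> dict[str, float]:
    """Recovery of a planted ReHo-symptom correlation across patients.

    Per seed: simulate a patient group with between-subject variation in
    the planted synchrony level, extract each patient's mean normalized
    ReHo inside the planted region, generate a symptom score linear in
    that ReHo with noise calibrated to a theoretical Pearson r of
    ``target_r``, and re-estimate r.  Reports the mean estimate and the
    fraction of seeds with |r_hat - target_r| <= 0.2.
    """
    root = np.random.SeedSequence(seed)
    estimates = []
    for run_seed in root.generate_state(n_seeds):
        run_seed = int(run_seed % (2**31 - 1))
        config = SimulationConfig(
            n_per_group=n_patients, grid_shape=(12, 12, 12),
            effect_rois=(((6, 6, 6), 2),), synchrony_lambda=0.6,
            synchrony_sd=0.25, n_volumes=100, seed=run_seed,
        )
        cohort = simulate_cohort(config)
        pcfg = PreprocConfig(tr_s=config.tr_s)
        roi = cohort.truth["roi_masks"][0]
        means = []
        for s in cohort.patients:
            clean = preprocess_subject(
                s.bold, s.motion, cohort.wm_mask, cohort.csf_mask, pcfg
            )
            rmap = reho_map(clean, cohort.gm_mask)
            sel = roi & rmap.computable_mask
            means.append(float(np.nanmean(rmap.normalized[sel])))
        means = np.asarray(means)
        sd = means.std(ddof=1)
        noise_sd = sd * np.sqrt(1.0 / target_r**2 - 1.0)
        scores = generate_behavior(
            means, slope=1.0, noise_sd=noise_sd, seed=run_seed + 1
        )
        r, _ = pearson_correlation(means, scores)
        estimates.append(r)
    estimates = np.asarray(estimates)
    return {
        "mean_r": float(estimates.mean()),
        "within_band_rate": float(
            (np.abs(estimates - target_r) <= 0.2).mean()
        ),
    }


def cluster_oracle_agreement(
    n_maps: int = 100, grid: tuple = (16, 16, 16), seed: int = 20_008
) -> float:
    """Fraction of random binary maps where clustering matches flood fill.

    Cycles over 6/18/26 connectivity; agreement requires identical
    component voxel sets.
    """
    rng = np.random.default_rng(seed)
    mask = np.ones(grid, dtype=bool)
    agree = 0
    for i in range(n_maps):
        connectivity = (6, 18, 26)[i % 3]
        density = rng.uniform(0.05, 0.4)
        binary = rng.random(grid) < density
        p_map = np.where(binary, 0.0, 1.0)
        clusters = extract_clusters(
            p_map, mask, voxel_alpha=0.5, min_cluster_voxels=1,
            connectivity=connectivity,
        )
        ours = {frozenset(map(tuple, c.indices)) for c in clusters}
        oracle = {frozenset(c) for c in flood_fill_label(binary, connectivity)}
        if ours == oracle:
            agree += 1
    return agree / n_maps
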