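"""Kendall's W and the ReHo map against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import friedmanchisquare

from rehomvpa.errors import ConfigurationError, DegenerateInputError
from rehomvpa.evaluation import friedman_w_reference
from rehomvpa.reho import (
    ReHoConfig,
    kendalls_w,
    neighborhood_offsets,
    normalize_reho,
    reho_map,
)


class TestKendallsW:
    def test_perfect_concordance(self, rng):
        base = np.sort(rng.normal(size=10))
        series = np.vstack([2.0 * base + c for c in range(5)])
        assert kendalls_w(series) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_discordance_two_series(self):
        series = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert kendalls_w(series) == pytest.approx(0.0, abs=1e-12)

    def test_hand_rank_table_matches_friedman_oracle(self):
        # K=3 judges ranking n=4 timepoints; moderate agreement
        series = np.array(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [1.0, 3.0, 2.0, 4.0]]
        )
        w = kendalls_w(series)
        assert w == pytest.approx(friedman_w_reference(series), abs=1e-12)
        # and against the closed form: rank sums (4,6,9,11), mean 7.5
        s = sum((r - 7.5) ** 2 for r in (4, 6, 9, 11))
        assert w == pytest.approx(12 * s / (9 * (64 - 4)), abs=1e-12)

    def test_tie_correction_matches_scipy_friedman(self, rng):
        for _ in range(20):
            K, n = int(rng.integers(3, 10)), int(rng.integers(4, 12))
            series = np.round(rng.normal(size=(K, n)), 1)  # forces ties
            if any(np.ptp(row) == 0 for row in series):
                continue
            chi2, _ = friedmanchisquare(*series.T)
            assert kendalls_w(series) == pytest.approx(
                chi2 / (K * (n - 1)), abs=1e-10
            )

    def test_all_constant_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            kendalls_w(np.ones((4, 6)))

    def test_error_on_ties_policy(self):
        series = np.array([[1.0, 1.0, 2.0], [0.0, 1.0, 2.0]])
        with pytest.raises(DegenerateInputError):
            kendalls_w(series, tie_policy="error_on_ties")
        assert 0.0 <= kendalls_w(series) <= 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_range_and_rank_invariance(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.normal(size=(int(rng.integers(2, 8)), int(rng.integers(3, 12))))
        w = kendalls_w(series)
        assert 0.0 <= w <= 1.0
        # strictly increasing monotone transform leaves W unchanged
        assert kendalls_w(np.exp(series)) == pytest.approx(w, abs=1e-12)
        assert kendalls_w(series**3) == pytest.approx(w, abs=1e-12)


def naive_reho(bold, mask, neighborhood=27):
    """Triple-loop reference: kendalls_w per voxel, strict edge rule."""
    offsets = neighborhood_offsets(neighborhood)
    shape = mask.shape
    out = np.full(shape, np.nan)
    computable = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                members = []
                ok = True
                for dx, dy, dz in offsets:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if not (
                        0 <= nx < shape[0]
                        and 0 <= ny < shape[1]
                        and 0 <= nz < shape[2]
                        and mask[nx, ny, nz]
                    ):
                        ok = False
                        break
                    members.append(bold[nx, ny, nz])
                if ok:
                    computable[x, y, z] = True
                    out[x, y, z] = kendalls_w(np.array(members))
    return out, computable


class TestReHoMap:
    def test_matches_naive_triple_loop(self, rng):
        bold = rng.normal(size=(5, 5, 5, 12))
        mask = np.ones((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = False  # irregular mask edge
        rmap = reho_map(bold, mask)
        ref, ref_mask = naive_reho(bold, mask)
        np.testing.assert_array_equal(rmap.computable_mask, ref_mask)
        np.testing.assert_allclose(
            rmap.kcc[ref_mask], ref[ref_mask], atol=1e-10
        )

    @pytest.mark.parametrize("neighborhood", [7, 19])
    def test_smaller_neighborhoods_match_oracle(self, rng, neighborhood):
        bold = rng.normal(size=(4, 4, 4, 10))
        mask = np.ones((4, 4, 4), dtype=bool)
        rmap = reho_map(bold, mask, ReHoConfig(neighborhood=neighborhood))
        ref, ref_mask = naive_reho(bold, mask, neighborhood)
        np.testing.assert_array_equal(rmap.computable_mask, ref_mask)
        np.testing.assert_allclose(rmap.kcc[ref_mask], ref[ref_mask], atol=1e-10)

    def test_identical_series_give_w_one(self):
        t = np.arange(16, dtype=float)
        bold = np.broadcast_to(t, (6, 6, 6, 16)).copy()
        bold *= np.arange(1, 217).reshape(6, 6, 6, 1)  # scaled copies, same ranks
        mask = np.ones((6, 6, 6), dtype=bool)
        rmap = reho_map(bold, mask)
        np.testing.assert_allclose(rmap.kcc[rmap.computable_mask], 1.0, atol=1e-12)
        np.testing.assert_allclose(
            rmap.normalized[rmap.computable_mask], 1.0, atol=1e-10
        )

    def test_strict_edge_rule_excludes_boundary(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        bold = np.random.default_rng(0).normal(size=(6, 6, 6, 10))
        rmap = reho_map(bold, mask)
        expected = np.zeros_like(mask)
        expected[2:4, 2:4, 2:4] = True
        np.testing.assert_array_equal(rmap.computable_mask, expected)

    def test_permissive_edge_policy_covers_more_voxels(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        bold = np.random.default_rng(1).normal(size=(6, 6, 6, 10))
        strict = reho_map(bold, mask)
        permissive = reho_map(
            bold, mask, ReHoConfig(edge_policy="available_neighbors")
        )
        assert permissive.computable_mask.sum() == mask.sum()
        assert (
            permissive.computable_mask & strict.computable_mask
        ).sum() == strict.computable_mask.sum()

    def test_null_mean_near_one_over_k(self, rng):
        bold = rng.normal(size=(10, 10, 10, 60))
        rmap = reho_map(bold, np.ones((10, 10, 10), dtype=bool))
        mean_w = np.nanmean(rmap.kcc[rmap.computable_mask])
        assert mean_w == pytest.approx(1.0 / 27.0, abs=0.01)

    def test_planted_synchrony_raises_in_roi_w(self, toy_cohort):
        roi = toy_cohort.truth["roi_masks"][0]
        patient = toy_cohort.patients[0]
        rmap = reho_map(
            np.asarray(patient.bold, float), toy_cohort.gm_mask
        )
        in_roi = roi & rmap.computable_mask
        out_roi = ~roi & rmap.computable_mask
        assert np.nanmean(rmap.kcc[in_roi]) > np.nanmean(rmap.kcc[out_roi])

    def test_empty_computable_mask_errors(self, rng):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True  # no full neighborhood
        with pytest.raises(ConfigurationError):
            reho_map(rng.normal(size=(5, 5, 5, 8)), mask)


class TestNormalize:
    def test_uniform_map_becomes_ones(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        out = normalize_reho(np.full((3, 3, 3), 0.42), mask)
        np.testing.assert_allclose(out[mask], 1.0)

    def test_two_voxel_arithmetic(self):
        kcc = np.array([[[1.0, 3.0]]])
        mask = np.ones_like(kcc, dtype=bool)
        np.testing.assert_allclose(
            normalize_reho(kcc, mask)[mask], [0.5, 1.5]
        )

    def test_mean_over_mask_is_one(self, rng):
        kcc = np.abs(rng.normal(size=(6, 6, 6))) + 0.01
        mask = rng.random((6, 6, 6)) < 0.5
        out = normalize_reho(kcc, mask)
        assert np.nanmean(out[mask]) == pytest.approx(1.0, abs=1e-10)

    def test_zero_mean_errors(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(DegenerateInputError):
            normalize_reho(np.zeros((2, 2, 2)), mask)
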