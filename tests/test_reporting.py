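"""Cluster tables, condition brain scores, contrasts, and summary t-tests."""

from collections import Counter, deque

import numpy as np
import pytest

from npairspls import (
    VoxelVolume,
    brain_scores,
    condition_brain_scores,
    contrast_tests,
    fit_pls,
    t_from_summary,
    threshold_clusters,
)
from npairspls.images import CohortDesign
from npairspls.phantom import default_design
from npairspls.pls import BrainScores


def flood_fill_sizes(exceed, connectivity):
    """Independent component labeling: BFS flood fill, returns size multiset."""
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= order
    ]
    visited = np.zeros_like(exceed, dtype=bool)
    sizes = []
    for start in map(tuple, np.argwhere(exceed)):
        if visited[start]:
            continue
        queue, size = deque([start]), 0
        visited[start] = True
        while queue:
            x, y, z = queue.popleft()
            size += 1
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < exceed.shape[i] for i in range(3)):
                    if exceed[p] and not visited[p]:
                        visited[p] = True
                        queue.append(p)
        sizes.append(size)
    return Counter(sizes)


class TestThresholdClusters:
    def test_subthreshold_map_gives_empty_table(self):
        z = VoxelVolume(np.full((6, 6, 6), 2.0), 1.0)
        table = threshold_clusters(z, 2.8, 640.0)
        assert len(table) == 0

    def test_extent_threshold_keeps_only_large_blob(self):
        # 1 mm voxels: a 700-voxel blob at z=3 survives the 640 mm^3 extent,
        # a 100-voxel blob at z=3.5 does not
        values = np.zeros((20, 20, 20))
        values[1:8, 1:11, 1:11] = 3.0  # 7*10*10 = 700 voxels
        values[12:16, 12:17, 12:17] = 3.5  # 4*5*5 = 100 voxels
        table = threshold_clusters(VoxelVolume(values, 1.0), 2.8, 640.0)
        assert len(table) == 1
        assert table.loc[0, "size_mm3"] == 700.0
        assert table.loc[0, "peak_z_score"] == 3.0

    def test_extent_unit_conversion_at_2mm(self):
        # 2 mm voxels: 640 mm^3 = 80 voxels minimum extent
        values = np.zeros((10, 10, 10))
        values[0:4, 0:4, 0:5] = 3.0  # 80 voxels -> 640 mm^3, survives
        values[6:9, 6:9, 6:9] = -3.0  # 27 voxels -> 216 mm^3, dropped
        table = threshold_clusters(VoxelVolume(values, 2.0), 2.8, 640.0)
        assert len(table) == 1
        assert table.loc[0, "size_mm3"] == pytest.approx(640.0)

    def test_opposite_signs_never_merge(self):
        values = np.zeros((8, 8, 8))
        values[0:4, :, :] = 3.0
        values[4:8, :, :] = -3.0  # face-adjacent to the positive slab
        table = threshold_clusters(VoxelVolume(values, 2.0), 2.8, 100.0)
        assert len(table) == 2
        assert set(table["sign"]) == {1, -1}

    def test_peak_tie_breaks_to_smallest_coordinate(self):
        values = np.zeros((6, 6, 6))
        values[1:5, 1:5, 1:5] = 3.0  # constant blob: every voxel ties
        table = threshold_clusters(VoxelVolume(values, 2.0), 2.8, 100.0)
        assert tuple(table.loc[0, ["peak_x", "peak_y", "peak_z"]]) == (1, 1, 1)

    def test_nan_voxels_are_subthreshold(self):
        values = np.full((6, 6, 6), np.nan)
        values[1:5, 1:5, 1:5] = 4.0
        table = threshold_clusters(_volume_with_nans(values), 2.8, 100.0)
        assert len(table) == 1
        assert table.loc[0, "size_mm3"] == 64 * 8  # 2 mm voxels

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_flood_fill_oracle(self, connectivity, rng):
        for trial in range(8):
            values = rng.choice([0.0, 3.0], size=(8, 8, 8), p=[0.7, 0.3])
            table = threshold_clusters(
                _volume_with_nans(values), 2.8, extent_mm3=1e-9,
                connectivity=connectivity,
            )
            expected = flood_fill_sizes(values > 2.8, connectivity)
            got = Counter(int(s / 8) for s in table["size_mm3"])  # 2 mm voxels
            assert got == expected


def _volume_with_nans(values):
    """Build a VoxelVolume bypassing the finite-values check (Z maps may
    carry NaN at zero-SE voxels)."""
    vol = VoxelVolume(np.zeros_like(np.nan_to_num(values)), 2.0)
    object.__setattr__(vol, "values", np.asarray(values, dtype=float))
    return vol


def _scores_from(values, design):
    return BrainScores(scores=np.asarray(values, float)[:, None], row_design=design)


class TestConditionScores:
    def test_equal_scores_center_to_zero_with_degenerate_cis(self):
        design = default_design((3, 2))
        cond = condition_brain_scores(_scores_from(np.full(10, 4.2), design),
                                      n_boot=200, seed=0)
        np.testing.assert_allclose(cond.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(cond.ci_low, cond.ci_high, atol=1e-12)

    def test_weighted_centering_identity(self, rng):
        design = default_design((5, 3))
        cond = condition_brain_scores(
            _scores_from(rng.normal(size=16), design), n_boot=50, seed=1
        )
        sizes = np.array([5, 5, 3, 3], dtype=float)
        assert float(sizes @ cond.mean) == pytest.approx(0.0, abs=1e-9)

    def test_cis_contain_their_means(self, rng):
        design = default_design((4, 2))
        cond = condition_brain_scores(
            _scores_from(rng.normal(size=12), design), n_boot=100, seed=2
        )
        assert np.all(cond.ci_low <= cond.mean) and np.all(cond.mean <= cond.ci_high)

    def test_ci_width_shrinks_with_condition_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (6, 24, 96):
            design = default_design((n, n))
            values = rng.normal(0.0, 1.0, size=4 * n)
            cond = condition_brain_scores(_scores_from(values, design),
                                          n_boot=400, seed=4)
            widths.append(float(np.mean(cond.ci_high - cond.ci_low)))
        assert widths[0] > widths[1] > widths[2]

    def test_missing_condition_errors(self):
        records = tuple(
            (f"s{i}", "nonSAD", season)
            for i in range(3) for season in ("summer", "winter")
        )
        design = CohortDesign(records)  # no SAD subjects at all
        with pytest.raises(ValueError, match="no scans"):
            condition_brain_scores(_scores_from(np.zeros(6), design), n_boot=10)

    def test_planted_cohort_winter_cis_disjoint(self, strong_cohort):
        model = fit_pls(strong_cohort["X"], strong_cohort["Y"])
        sc = brain_scores(strong_cohort["X"], model)
        cond = condition_brain_scores(sc, n_boot=500, seed=5)
        by_label = dict(zip(cond.labels, zip(cond.ci_low, cond.ci_high)))
        lo_ns, hi_ns = by_label["nonSAD-winter"]
        lo_sad, hi_sad = by_label["SAD-winter"]
        assert hi_sad < lo_ns or hi_ns < lo_sad


class TestContrastTests:
    def test_six_contrasts_with_correct_test_kinds(self, rng):
        design = default_design((5, 4))
        cond = condition_brain_scores(
            _scores_from(rng.normal(size=18), design), n_boot=20, seed=0
        )
        table = contrast_tests(cond)
        assert len(table) == 6
        assert list(table["test"][:2]) == ["paired", "paired"]
        assert list(table["test"][2:]) == ["two-sample"] * 4
        np.testing.assert_allclose(
            table["p_bonferroni"], table["p_uncorrected"] * 6, atol=1e-12
        )

    def test_bonferroni_not_capped_at_one(self, rng):
        design = default_design((6, 5))
        # near-identical conditions -> p near 1 -> corrected near 6
        values = rng.normal(0, 0.01, size=22)
        cond = condition_brain_scores(_scores_from(values, design), n_boot=20, seed=1)
        table = contrast_tests(cond)
        assert table["p_bonferroni"].max() > 1.0

    def test_group_exchange_negates_t_preserves_p(self, rng):
        n = 4
        design = default_design((n, n))
        values = rng.normal(size=4 * n)
        cond = condition_brain_scores(_scores_from(values, design), n_boot=20, seed=2)
        # exchange group labels: nonSAD subjects become SAD and vice versa,
        # keeping each subject's scores
        swapped_records = tuple(
            (sid, "SAD" if g == "nonSAD" else "nonSAD", s)
            for sid, g, s in design.records
        )
        swapped = CohortDesign(swapped_records)
        cond_sw = condition_brain_scores(_scores_from(values, swapped), n_boot=20, seed=2)
        t_a = contrast_tests(cond).set_index("contrast")
        t_b = contrast_tests(cond_sw).set_index("contrast")
        # the winter-winter between-group contrast flips sign exactly
        a = t_a.loc["nonSAD_winter vs SAD_winter"]
        b = t_b.loc["nonSAD_winter vs SAD_winter"]
        assert b["t"] == pytest.approx(-a["t"], abs=1e-9)
        assert b["p_uncorrected"] == pytest.approx(a["p_uncorrected"], abs=1e-12)

    def test_planted_cohort_winter_contrast_strongest(self, strong_cohort):
        model = fit_pls(strong_cohort["X"], strong_cohort["Y"])
        sc = brain_scores(strong_cohort["X"], model)
        cond = condition_brain_scores(sc, n_boot=50, seed=3)
        table = contrast_tests(cond).set_index("contrast")
        assert table.loc["nonSAD_winter vs SAD_winter", "p_bonferroni"] < 0.05


class TestTFromSummary:
    def test_pooled_recomputation_of_printed_rows(self):
        t, df, p = t_from_summary(22.8, 2.3, 13, 20.9, 1.7, 6)
        assert df == 17
        assert round(p, 2) == 0.09
        _, _, p = t_from_summary(4.3, 2.2, 13, 14.5, 2.1, 6)
        assert p < 0.0001

    def test_identical_summaries(self):
        t, df, p = t_from_summary(5.0, 1.0, 8, 5.0, 1.0, 8)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        assert t_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5) == (0.0, 8, 1.0)
        with pytest.raises(ValueError, match="zero variance"):
            t_from_summary(3.0, 0.0, 5, 4.0, 0.0, 5)
        with pytest.raises(ValueError):
            t_from_summary(3.0, 1.0, 1, 4.0, 1.0, 5)
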