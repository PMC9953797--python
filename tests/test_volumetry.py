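"""Volumetrics: ellipsoid TV, LD, ETV, FTV (single and grid), changes,
and histogram mask refinement."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftvmri import (
    DiameterTriplet,
    EnhancementMaps,
    MaskSource,
    ThresholdGrid,
    TumorMask,
    build_grid,
    ellipsoid_tv,
    etv,
    ftv,
    ftv_grid,
    longest_dimension,
    mask_to_diameters,
    refine_mask_histogram,
    relative_change,
)

SPACING = (1.0, 1.0, 1.5)


def random_maps(rng, shape, pe_hi=250.0, ser_hi=3.0, p_invalid=0.1):
    pe = rng.uniform(-20.0, pe_hi, size=shape)
    ser = rng.uniform(0.0, ser_hi, size=shape)
    valid = rng.random(shape) > p_invalid
    return EnhancementMaps(pe=pe, ser=ser, valid=valid, early_phase_label=1.0)


class TestEllipsoidTV:
    def test_sphere_of_radius_one(self):
        d = DiameterTriplet(2, 2, 2)
        assert ellipsoid_tv(d) == pytest.approx(4.18879, abs=1e-5)

    def test_one_two_three_gives_pi(self):
        assert ellipsoid_tv(DiameterTriplet(1, 2, 3)) == pytest.approx(math.pi)

    def test_zero_dimension_degenerates(self):
        assert ellipsoid_tv(DiameterTriplet(0, 5, 7)) == 0.0

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            DiameterTriplet(-1, 2, 3)


_dims = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


@settings(derandomize=True, max_examples=50)
@given(a=_dims, b=_dims, c=_dims)
def test_ellipsoid_tv_symmetric_under_axis_permutation(a, b, c):
    vols = [ellipsoid_tv(DiameterTriplet(*p))
            for p in itertools.permutations((a, b, c))]
    assert max(vols) - min(vols) <= 1e-9 * max(1.0, max(vols))


@settings(derandomize=True, max_examples=50)
@given(x=st.floats(min_value=1e-3, max_value=1e6))
def test_relative_change_identities(x):
    assert relative_change(x, x) == 0.0
    assert relative_change(x, 0.0) == -100.0


class TestLongestDimension:
    @pytest.mark.parametrize("dims,expected", [
        ((2.8, 1.2, 2.0), 2.8),
        ((1, 1, 1), 1),
        ((0, 0, 0), 0),
    ])
    def test_examples(self, dims, expected):
        assert longest_dimension(DiameterTriplet(*dims)) == expected


class TestETV:
    def test_thousand_two_mm_voxels(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.flat[:1000] = True
        assert etv(TumorMask(mask), (2.0, 2.0, 2.0)) == pytest.approx(8.0)

    def test_empty_mask(self):
        assert etv(TumorMask(np.zeros((4, 4, 4), bool)), SPACING) == 0.0

    def test_matches_loop_count_oracle(self, rng):
        mask = rng.random((6, 7, 5)) > 0.5
        count = sum(1 for idx in np.ndindex(*mask.shape) if mask[idx])
        expected = count * (1.0 * 1.0 * 1.5) / 1000.0
        assert etv(TumorMask(mask), SPACING) == pytest.approx(expected)


def brute_force_ftv(mask, maps, pe_thr, ser_thr, spacing):
    vv = spacing[0] * spacing[1] * spacing[2] / 1000.0
    n = 0
    for idx in np.ndindex(*mask.mask.shape):
        if (mask.mask[idx] and maps.valid[idx]
                and maps.pe[idx] > pe_thr and maps.ser[idx] > ser_thr):
            n += 1
    return vv * n


class TestFTV:
    def test_counted_voxels_times_voxel_volume(self):
        mask = np.zeros((1, 2, 5), bool)
        mask[0, 0, :] = True  # 5 voxels... plus 5 more below
        mask[0, 1, :] = True
        pe = np.zeros((1, 2, 5))
        ser = np.zeros((1, 2, 5))
        pe[0, 0, :4] = 100.0
        ser[0, 0, :4] = 1.0
        maps = EnhancementMaps(pe=pe, ser=ser,
                               valid=np.ones((1, 2, 5), bool),
                               early_phase_label=1.0)
        # voxel volume 0.01 cm^3 = 10x10x100 mm is unwieldy; use 0.01 via 10,10,100? keep literal
        out = ftv(TumorMask(mask), maps, 30.0, 0.40, (10.0, 10.0, 100.0))
        assert out == pytest.approx(4 * 10.0)

    def test_thresholds_above_all_values_give_zero(self, rng):
        mask = TumorMask(np.ones((4, 4, 4), bool))
        maps = random_maps(rng, (4, 4, 4))
        assert ftv(mask, maps, 1e6, 1e6, SPACING) == 0.0

    def test_matches_per_voxel_oracle_at_paper_pair(self, rng):
        """Threshold pair (30%, 0.40) against the brute-force voxel loop."""
        mask = TumorMask(rng.random((6, 6, 4)) > 0.3)
        maps = random_maps(rng, (6, 6, 4))
        got = ftv(mask, maps, 30.0, 0.40, SPACING)
        assert got == pytest.approx(
            brute_force_ftv(mask, maps, 30.0, 0.40, SPACING))

    def test_grid_mismatch_raises(self, rng):
        mask = TumorMask(np.ones((4, 4, 4), bool))
        maps = random_maps(rng, (5, 4, 4))
        with pytest.raises(ValueError, match="mismatch"):
            ftv(mask, maps, 0, 0, SPACING)


class TestFTVGrid:
    def test_single_voxel_strict_inequality(self):
        mask = TumorMask(np.ones((1, 1, 1), bool))
        maps = EnhancementMaps(pe=np.full((1, 1, 1), 50.0),
                               ser=np.full((1, 1, 1), 1.0),
                               valid=np.ones((1, 1, 1), bool),
                               early_phase_label=1.0)
        grid = build_grid()
        out = ftv_grid(mask, maps, grid, SPACING)
        for i, pe_t in enumerate(grid.pe_values):
            for j, ser_t in enumerate(grid.ser_values):
                assert (out[i, j] > 0) == (pe_t < 50.0 and ser_t < 1.0)

    def test_empty_mask_all_zero(self):
        mask = TumorMask(np.zeros((3, 3, 3), bool))
        maps = EnhancementMaps(pe=np.ones((3, 3, 3)), ser=np.ones((3, 3, 3)),
                               valid=np.ones((3, 3, 3), bool),
                               early_phase_label=1.0)
        assert not ftv_grid(mask, maps, build_grid(), SPACING).any()

    def test_equals_pairwise_ftv_over_all_1845_pairs(self, rng):
        mask = TumorMask(rng.random((12, 12, 3)) > 0.4)
        maps = random_maps(rng, (12, 12, 3))
        grid = build_grid()
        out = ftv_grid(mask, maps, grid, SPACING)
        assert out.shape == (45, 41)
        for i, pe_t in enumerate(grid.pe_values):
            for j, ser_t in enumerate(grid.ser_values):
                assert out[i, j] == pytest.approx(
                    ftv(mask, maps, pe_t, ser_t, SPACING))

    def test_monotone_nonincreasing_and_bounded_by_etv(self, rng):
        mask = TumorMask(rng.random((8, 8, 4)) > 0.4)
        maps = random_maps(rng, (8, 8, 4))
        out = ftv_grid(mask, maps, build_grid(), SPACING)
        assert np.all(np.diff(out, axis=0) <= 1e-12)
        assert np.all(np.diff(out, axis=1) <= 1e-12)
        assert np.all(out <= etv(mask, SPACING) + 1e-12)

    def test_invalid_voxels_never_counted(self, rng):
        """End-to-end: flipping valid off removes voxels from every count."""
        mask = TumorMask(np.ones((5, 5, 2), bool))
        maps = random_maps(rng, (5, 5, 2), p_invalid=0.0)
        all_valid = ftv_grid(mask, maps, build_grid(), SPACING)
        none_valid = ftv_grid(
            mask,
            EnhancementMaps(pe=maps.pe, ser=maps.ser,
                            valid=np.zeros((5, 5, 2), bool),
                            early_phase_label=1.0),
            build_grid(), SPACING)
        assert all_valid[0, 0] > 0
        assert not none_valid.any()


class TestRelativeChange:
    @pytest.mark.parametrize("bl,later,expected", [
        (10, 5, -50.0),
        (10, 0, -100.0),
        (10, 10, 0.0),
        (4, 6, 50.0),
    ])
    def test_examples(self, bl, later, expected):
        assert relative_change(bl, later) == pytest.approx(expected)

    def test_zero_baseline_propagates_as_missing(self):
        assert math.isnan(relative_change(0.0, 5.0))
        assert math.isnan(relative_change(-1.0, 5.0))


class TestRefineMaskHistogram:
    def test_bimodal_retains_high_mode(self):
        mask = np.zeros((2, 10, 10), bool)
        mask[0] = True
        mask[1] = True
        img = np.zeros((2, 10, 10))
        img[0] = 5.0    # 100 voxels at the low mode
        img[1] = 200.0  # 100 voxels at the high mode
        refined = refine_mask_histogram(TumorMask(mask), img)
        assert refined.source == MaskSource.REFINED
        assert np.array_equal(refined.mask, img > 100)

    def test_constant_intensities_unchanged(self):
        mask = np.ones((3, 3, 3), bool)
        refined = refine_mask_histogram(TumorMask(mask), np.full((3, 3, 3), 7.0))
        assert np.array_equal(refined.mask, mask)

    def test_result_is_subset_of_input(self, rng):
        mask = rng.random((6, 6, 3)) > 0.3
        img = rng.normal(50, 30, size=(6, 6, 3))
        refined = refine_mask_histogram(TumorMask(mask), img)
        assert not np.any(refined.mask & ~mask)

    def test_random_bimodal_matches_exhaustive_otsu(self, rng):
        """Retained set equals thresholding at the brute-force maximum of
        the between-class variance over all observed cut points."""
        mask = np.ones((1, 20, 20), bool)
        img = np.where(rng.random((1, 20, 20)) < 0.5,
                       rng.normal(5, 1.5, (1, 20, 20)),
                       rng.normal(200, 10, (1, 20, 20)))
        refined = refine_mask_histogram(TumorMask(mask), img)
        vals = img[mask]
        best_t, best_v = None, -1.0
        for t in np.sort(vals)[:-1]:
            hi = vals > t
            w1 = hi.mean()
            w0 = 1 - w1
            v = w0 * w1 * (vals[hi].mean() - vals[~hi].mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        assert np.array_equal(refined.mask, mask & (img > best_t))

    def test_idempotent_on_bimodal_input(self, rng):
        mask = np.ones((1, 16, 16), bool)
        img = np.where(rng.random((1, 16, 16)) < 0.4,
                       rng.normal(5, 1.0, (1, 16, 16)),
                       rng.normal(200, 8.0, (1, 16, 16)))
        once = refine_mask_histogram(TumorMask(mask), img)
        twice = refine_mask_histogram(once, img)
        assert np.array_equal(once.mask, twice.mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            refine_mask_histogram(TumorMask(np.zeros((2, 2, 2), bool)),
                                  np.zeros((2, 2, 2)))


class TestMaskToDiameters:
    def test_box_extents(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:6, 1:9, 3:5] = True  # 4 slices, 8 rows, 2 cols
        d = mask_to_diameters(TumorMask(mask), (1.0, 2.0, 1.5))
        assert d.anteroposterior_cm == pytest.approx(0.8)   # 8 rows x 1 mm
        assert d.transverse_cm == pytest.approx(0.4)        # 2 cols x 2 mm
        assert d.craniocaudal_cm == pytest.approx(0.6)      # 4 slices x 1.5 mm

    def test_empty_mask_zero_triplet(self):
        d = mask_to_diameters(TumorMask(np.zeros((4, 4, 4), bool)), SPACING)
        assert (d.anteroposterior_cm, d.craniocaudal_cm, d.transverse_cm) == (0, 0, 0)
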