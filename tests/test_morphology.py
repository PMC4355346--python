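import numpy as np
import pytest

from retveseg import (
    EmptyFovError,
    build_fov_mask,
    clear_border_structures,
    dilate,
    erode,
    make_disc,
    make_line,
    opening,
    remove_small_components,
)

from _oracles import (
    clear_border_reference,
    component_sizes_reference,
    dilate_reference,
    erode_reference,
)


def _random_masks(rng, n=30, max_side=16):
    for _ in range(n):
        h = int(rng.integers(5, max_side + 1))
        w = int(rng.integers(5, max_side + 1))
        yield rng.random((h, w)) < rng.uniform(0.2, 0.7)


class TestStructuringElements:
    def test_disc_radius_1_is_plus_shape(self):
        se = make_disc(1)
        np.testing.assert_array_equal(
            se.footprint, [[0, 1, 0], [1, 1, 1], [0, 1, 0]])

    def test_disc_radius_2_has_13_lattice_points(self):
        assert make_disc(2).footprint.sum() == 13

    def test_disc_radius_zero_rejected(self):
        with pytest.raises(ValueError):
            make_disc(0)

    @pytest.mark.parametrize("angle, check", [
        (180, lambda r, c: (r == 0).all()),              # horizontal row
        (90, lambda r, c: (c == 0).all()),               # vertical column
        (45, lambda r, c: (r == -c).all()),              # diagonal
    ])
    def test_line_10px_axis_and_diagonal(self, angle, check):
        se = make_line(10, angle)
        rows, cols = np.nonzero(se.footprint)
        oy, ox = se.origin
        assert len(rows) == 10
        assert check(rows - oy, cols - ox)

    def test_line_cell_count_is_exact_for_every_bank_angle(self):
        for angle in range(15, 181, 15):
            assert make_line(10, angle).footprint.sum() == 10

    def test_line_contains_origin(self):
        for angle in (15, 75, 120):
            se = make_line(9, angle)
            assert se.footprint[se.origin]


class TestPrimitivesAgainstBruteForce:
    def test_erode_trivial_cases(self):
        all_true = np.ones((8, 8), dtype=bool)
        assert erode(all_true, make_disc(1)).all()  # border counts as foreground
        single = np.zeros((8, 8), dtype=bool)
        single[4, 4] = True
        assert not erode(single, make_disc(1)).any()

    def test_dilate_trivial_cases(self):
        single = np.zeros((7, 7), dtype=bool)
        single[3, 3] = True
        assert dilate(single, make_disc(1)).sum() == 5
        assert not dilate(np.zeros((5, 5), dtype=bool), make_disc(2)).any()

    @pytest.mark.parametrize("se_factory", [
        lambda: make_disc(1), lambda: make_disc(2), lambda: make_line(5, 90),
        lambda: make_line(4, 30),
    ])
    def test_erode_dilate_match_set_definitions(self, rng, se_factory):
        se = se_factory()
        for mask in _random_masks(rng, n=15):
            np.testing.assert_array_equal(erode(mask, se), erode_reference(mask, se.footprint))
            np.testing.assert_array_equal(dilate(mask, se), dilate_reference(mask, se.footprint))

    def test_opening_is_idempotent_and_anti_extensive(self, rng):
        se = make_disc(1)
        for mask in _random_masks(rng, n=10):
            opened = opening(mask, se)
            assert not (opened & ~mask).any()
            np.testing.assert_array_equal(opening(opened, se), opened)

    def test_opening_removes_speckle_keeps_wide_stripe(self):
        img = np.zeros((12, 12), dtype=bool)
        img[1, 1] = True           # isolated pixel
        img[5:8, :] = True         # 3-px-wide stripe
        opened = opening(img, make_disc(1))
        assert not opened[1, 1]
        assert opened[5:8, 1:-1].all()

    def test_duality_of_erosion_and_dilation(self, rng):
        # dilate(~m, s) == ~erode(m, s-reflected), with matched border rules
        se = make_line(4, 60)
        reflected = se.footprint[::-1, ::-1]
        for mask in _random_masks(rng, n=10):
            lhs = dilate(~mask, se)
            rhs = ~erode_reference(mask, reflected)
            np.testing.assert_array_equal(lhs, rhs)

    def test_extensivity_ordering(self, rng):
        se = make_disc(2)
        for mask in _random_masks(rng, n=10):
            er, di = erode(mask, se), dilate(mask, se)
            assert not (er & ~mask).any()
            assert not (mask & ~di).any()

    def test_greyscale_erosion_dilation_are_min_max(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        se = make_disc(1)
        er = erode(img, se)
        di = dilate(img, se)
        offs = se.offsets
        for r in range(10):
            for c in range(10):
                vals = [img[r + dr, c + dc] for dr, dc in offs
                        if 0 <= r + dr < 10 and 0 <= c + dc < 10]
                assert er[r, c] == pytest.approx(min(vals))
                assert di[r, c] == pytest.approx(max(vals))


class TestClearBorderAndComponents:
    def test_border_blob_removed_interior_kept(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:2, 3:5] = True   # touches row 0
        mask[5:7, 5:7] = True   # interior
        out = clear_border_structures(mask)
        assert not out[0:2, 3:5].any()
        assert out[5:7, 5:7].all()

    def test_empty_mask_unchanged(self):
        assert not clear_border_structures(np.zeros((6, 6), dtype=bool)).any()

    def test_matches_flood_fill_oracle(self, rng):
        for mask in _random_masks(rng, n=20):
            np.testing.assert_array_equal(
                clear_border_structures(mask), clear_border_reference(mask))

    def test_size_50_boundary_is_kept_49_removed(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[1:8, 1:8] = True          # 49 px
        mask[10:15, 10:20] = True      # 50 px
        mask[20:23, 30:47] = True      # 51 px
        out = remove_small_components(mask, min_size=50)
        assert not out[1:8, 1:8].any()
        assert out[10:15, 10:20].all()
        assert out[20:23, 30:47].all()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_label_and_count_oracle(self, rng, connectivity):
        for mask in _random_masks(rng, n=15):
            min_size = int(rng.integers(1, 8))
            expected = component_sizes_reference(mask, connectivity) >= min_size
            np.testing.assert_array_equal(
                remove_small_components(mask, min_size, connectivity), expected & mask)

    def test_empty_mask_stays_empty(self):
        assert not remove_small_components(np.zeros((5, 5), dtype=bool), 50).any()


class TestFovMask:
    def test_bright_disc_recovered(self):
        h = w = 120
        yy, xx = np.mgrid[0:h, 0:w]
        disc = np.hypot(yy - 59.5, xx - 59.5) <= 40
        green = np.where(disc, 120.0, 3.0)
        fov = build_fov_mask(green)
        sym_diff = np.count_nonzero(fov.fov ^ disc)
        boundary = np.count_nonzero(disc) - np.count_nonzero(
            np.hypot(yy - 59.5, xx - 59.5) <= 39)
        assert sym_diff <= boundary  # agreement to within the 1-px rim

    def test_morphological_ordering(self, default_phantom):
        from retveseg import extract_channel

        green = extract_channel(default_phantom.image, "green")
        fov = build_fov_mask(green)
        assert not (fov.eroded & ~fov.fov).any()
        assert not (fov.fov & ~fov.dilated).any()

    def test_all_dark_image_raises_empty_fov(self):
        with pytest.raises(EmptyFovError):
            build_fov_mask(np.full((32, 32), 2.0))

    def test_holes_inside_fov_are_filled(self):
        h = w = 80
        yy, xx = np.mgrid[0:h, 0:w]
        disc = np.hypot(yy - 39.5, xx - 39.5) <= 30
        green = np.where(disc, 120.0, 3.0)
        green[35:42, 35:42] = 0.0  # dark vessel shadow inside the FOV
        fov = build_fov_mask(green)
        assert fov.fov[35:42, 35:42].all()
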