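"""Morphological primitives against brute-force oracles and their algebra."""

import bruteforce as bf
import numpy as np
import pytest
from scipy import ndimage as ndi

from mcseg import morphology as mm

S8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# erosion / dilation / opening / closing
# ---------------------------------------------------------------------------

def test_flat_image_invariant_under_all_filters():
    img = np.full((6, 7), 7, dtype=np.uint8)
    for op in (mm.erode, mm.dilate, mm.opening, mm.closing):
        assert np.array_equal(op(img, mm.square3()), img)
    assert np.array_equal(mm.co_filter(img), img)


def test_single_bright_pixel_erodes_away_and_dilates_to_block():
    img = np.zeros((7, 7), dtype=np.uint8)
    img[3, 3] = 50
    assert mm.erode(img, mm.square3()).max() == 0
    d = mm.dilate(img, mm.square3())
    assert (d == 50).sum() == 9
    assert d[2:5, 2:5].min() == 50


def test_opening_removes_spike_closing_keeps_it():
    img = np.full((7, 7), 10, dtype=np.uint8)
    img[3, 3] = 50
    assert mm.opening(img, mm.square3())[3, 3] == 10
    assert mm.closing(img, mm.square3())[3, 3] == 50


def test_co_filter_flattens_spike_and_pit():
    img = np.full((9, 9), 100, dtype=np.uint8)
    img[2, 2] = 180
    img[6, 6] = 20
    assert np.array_equal(mm.co_filter(img), np.full((9, 9), 100, dtype=np.uint8))


@pytest.mark.parametrize("se_name,se", [
    ("square3", np.ones((3, 3), dtype=bool)),
    ("hline5", np.ones((1, 5), dtype=bool)),
    ("vline5", np.ones((5, 1), dtype=bool)),
    ("diag5", np.eye(5, dtype=bool)),
])
def test_erode_dilate_match_bruteforce(se_name, se, random_images):
    for img in random_images[:10]:
        assert np.array_equal(mm.erode(img, se), bf.erode(img, se)), se_name
        assert np.array_equal(mm.dilate(img, se), bf.dilate(img, se)), se_name


def test_ordering_and_idempotence(random_images):
    se = mm.square3()
    for img in random_images[:10]:
        o = mm.opening(img, se)
        c = mm.closing(img, se)
        assert (o <= img).all() and (img <= c).all()
        assert np.array_equal(mm.opening(o, se), o)
        assert np.array_equal(mm.closing(c, se), c)
        co = mm.co_filter(img)
        assert np.array_equal(mm.co_filter(co), co)


def test_line_se_shapes_and_errors():
    assert mm.line_se("horizontal", 5).shape == (1, 5)
    assert mm.line_se("vertical", 5).shape == (5, 1)
    assert mm.line_se("diag_left", 3)[0, 0] and mm.line_se("diag_left", 3)[2, 2]
    assert mm.line_se("diag_right", 3)[0, 2] and mm.line_se("diag_right", 3)[2, 0]
    with pytest.raises(ValueError):
        mm.line_se("horizontal", 4)
    with pytest.raises(ValueError):
        mm.line_se("sideways", 5)
    with pytest.raises(ValueError):
        mm.erode(np.zeros((4, 4), dtype=np.uint8), np.zeros((3, 3), dtype=bool))


# ---------------------------------------------------------------------------
# reconstruction and h-convexity
# ---------------------------------------------------------------------------

def test_reconstruction_fixed_points():
    mask = np.random.default_rng(0).integers(0, 16, (8, 8)).astype(np.uint8)
    assert np.array_equal(mm.reconstruct_by_dilation(mask, mask), mask)
    zero = np.zeros_like(mask)
    assert np.array_equal(mm.reconstruct_by_dilation(zero, mask), zero)


def test_binary_reconstruction_recovers_touched_blob_only():
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[1:4, 1:4] = 1
    mask[6:9, 6:9] = 1
    marker = np.zeros_like(mask)
    marker[2, 2] = 1
    rec = mm.reconstruct_by_dilation(marker, mask)
    expected = np.zeros_like(mask)
    expected[1:4, 1:4] = 1
    assert np.array_equal(rec, expected)
    assert np.array_equal(mm.binary_reconstruct(marker.astype(bool), mask.astype(bool)),
                          expected.astype(bool))


def test_reconstruction_matches_bruteforce_and_bounds(random_images, rng):
    for img in random_images[:8]:
        marker = np.minimum(img, rng.integers(0, 16, img.shape).astype(np.uint8))
        rec = mm.reconstruct_by_dilation(marker, img)
        assert np.array_equal(rec, bf.reconstruct_by_dilation(marker, img))
        assert (marker <= rec).all() and (rec <= img).all()


def test_h_convexity_flat_and_peak():
    # a constant image is one global maximum plateau: residue = h everywhere
    flat = np.full((6, 6), 40, dtype=np.uint8)
    res_flat = mm.h_convexity(flat, 5)
    assert np.array_equal(res_flat, bf.h_convexity(flat, 5))
    assert (res_flat == 5).all()
    # a peak of height 3 < h yields residue 3 provided a brighter structure
    # elsewhere anchors the reconstruction (the global maximum itself always
    # carries residue h)
    img = np.full((9, 9), 30, dtype=np.uint8)
    img[2, 2] = 33   # low peak
    img[6:8, 6:8] = 45  # brighter anchor
    res = mm.h_convexity(img, 5)
    assert np.array_equal(res, bf.h_convexity(img, 5))
    assert res[2, 2] == 3
    assert res[6, 6] == 5
    assert res[4, 4] == 0
    with pytest.raises(ValueError):
        mm.h_convexity(img, 0)


def test_h_convexity_dome_cap_value():
    img = np.full((11, 11), 100, dtype=np.uint8)
    img[3:8, 3:8] = 110
    img[4:7, 4:7] = 115
    img[5, 5] = 120  # dome of height 20
    res = mm.h_convexity(img, 5)
    assert np.array_equal(res, bf.h_convexity(img, 5))
    assert res[5, 5] == 5  # cap clipped at h
    assert res.max() == 5


def test_threshold_boundary():
    img = np.array([[3, 4, 5]], dtype=np.uint8)
    assert mm.threshold(img, 4).tolist() == [[False, True, True]]
    assert mm.threshold(img, 0).all()


# ---------------------------------------------------------------------------
# regional minima / imposition / watershed
# ---------------------------------------------------------------------------

def test_regional_minima_constant_and_ramp():
    assert mm.regional_minima(np.full((4, 5), 9, dtype=np.uint8)).all()
    ramp = np.arange(12, dtype=np.uint8).reshape(3, 4)
    mins = mm.regional_minima(ramp, 8)
    assert mins[0, 0] and mins.sum() == 1


def test_regional_minima_matches_plateau_enumeration(random_images):
    for img in random_images[:12]:
        for conn in (4, 8):
            assert np.array_equal(mm.regional_minima(img, conn),
                                  bf.regional_minima(img, conn))


def test_minima_imposition_defining_property(random_images, rng):
    for img in random_images[:8]:
        marker = rng.random(img.shape) < 0.1
        if not marker.any():
            marker[0, 0] = True
        out = mm.minima_imposition(img, marker)
        assert np.array_equal(out, bf.minima_imposition(img, marker))
        mins = mm.regional_minima(out, 8)
        lbl_m, n_m = ndi.label(marker, structure=S8)
        lbl_o, n_o = ndi.label(mins, structure=S8)
        assert n_m == n_o
        assert np.array_equal(mins, marker)


def test_minima_imposition_ridge_profile():
    img = np.array([[5, 1, 5, 9, 5, 1, 5]], dtype=np.uint8)
    marker = np.zeros_like(img, dtype=bool)
    marker[0, 3] = True
    out = mm.minima_imposition(img, marker)
    mins = mm.regional_minima(out, 8)
    assert mins.tolist() == marker.tolist()
    with pytest.raises(ValueError):
        mm.minima_imposition(img, np.zeros_like(img, dtype=bool))


def test_minima_imposition_full_marker_zeroes_image():
    img = np.random.default_rng(1).integers(0, 16, (5, 6)).astype(np.uint8)
    out = mm.minima_imposition(img, np.ones_like(img, dtype=bool))
    assert out.max() == 0


def test_watershed_constant_and_1d_profile():
    assert np.array_equal(mm.watershed(np.full((3, 4), 5, dtype=np.uint8)),
                          np.ones((3, 4), dtype=np.int32))
    lab = mm.watershed(np.array([[0, 1, 2, 1, 0]], dtype=np.uint8), 8)
    assert lab.max() == 2
    assert (lab == 0).sum() == 1 and lab[0, 2] == 0


def test_watershed_partition_and_basin_count(random_images):
    for img in random_images[:10]:
        lab = mm.watershed(img, 8)
        mins = mm.regional_minima(img, 8)
        _, n = ndi.label(mins, structure=S8)
        assert lab.max() == n
        assert lab.min() >= 0
        for k in range(1, n + 1):
            basin = lab == k
            assert basin.any()
            _, parts = ndi.label(basin, structure=S8)
            assert parts == 1  # basins are connected
        # every minimum component lies inside a single basin
        lbl_m, nm = ndi.label(mins, structure=S8)
        for k in range(1, nm + 1):
            vals = np.unique(lab[lbl_m == k])
            assert len(vals) == 1 and vals[0] > 0


def test_watershed_agrees_with_skimage_on_basin_seeding(random_images):
    """Independent route: each basin must contain exactly the minima
    component that seeds the same region in skimage's line-free watershed."""
    from skimage.segmentation import watershed as skws
    for img in random_images[:6]:
        mins = mm.regional_minima(img, 8)
        markers, n = ndi.label(mins, structure=S8)
        sk = skws(img, markers=markers, connectivity=2, watershed_line=False)
        lab = mm.watershed(img, 8)
        for k in range(1, n + 1):
            seed_px = np.argwhere(markers == k)[0]
            assert lab[tuple(seed_px)] > 0
            assert sk[tuple(seed_px)] == k


# ---------------------------------------------------------------------------
# cleaning operations
# ---------------------------------------------------------------------------

def test_area_filter_boundary_sizes():
    mask = np.zeros((40, 40), dtype=bool)
    mask[1:2, 1:6] = True            # 5 px
    mask[5:7, 10:15] = True          # 10 px
    mask[12:19, 10:20] = True        # 70 px
    mask[25:32, 25:35] = True
    mask[32, 25] = True              # 71 px
    out = mm.area_filter(mask, 10, 70)
    assert out[5, 10] and out[12, 10]
    assert not out[1, 1] and not out[25, 25]
    with pytest.raises(ValueError):
        mm.area_filter(mask, 20, 10)


def test_area_filter_matches_bruteforce(rng):
    for _ in range(10):
        mask = rng.random((12, 12)) < 0.35
        assert np.array_equal(mm.area_filter(mask, 2, 6), bf.area_filter(mask, 2, 6))


def test_fill_holes_ring_and_idempotence():
    ring = np.zeros((9, 9), dtype=bool)
    ring[2:7, 2:7] = True
    ring[3:6, 3:6] = False
    filled = mm.fill_holes(ring)
    assert filled[4, 4]
    assert np.array_equal(mm.fill_holes(filled), filled)


def test_remove_border_objects_keeps_interior():
    mask = np.zeros((10, 10), dtype=bool)
    mask[4:7, 0:3] = True   # touches left edge
    mask[4:6, 6:8] = True   # interior
    out = mm.remove_border_objects(mask)
    assert not out[4, 0]
    assert out[4, 6]


def test_empty_masks_pass_through_cleaning():
    empty = np.zeros((8, 8), dtype=bool)
    assert not mm.area_filter(empty, 1, 5).any()
    assert not mm.fill_holes(empty).any()
    assert not mm.remove_border_objects(empty).any()
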