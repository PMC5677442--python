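import numpy as np
import pytest
from scipy import ndimage

from moundscan.material_classify import BinaryLayer
from moundscan.mound_detect import (
    Contour,
    DegenerateShapeError,
    DetectionParams,
    IncomparableShapesError,
    condition_soil,
    detect_mounds,
    filter_soil_contours,
    find_contours,
    log_hu,
    make_soil_halo,
    overlap_gate,
    pair_and_confirm,
    shape_ratio,
)

from conftest import disk_mask


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------


def oracle_hu(mask):
    """Raw -> central -> normalized -> Hu moments by literal summation."""
    pts = list(zip(*np.nonzero(mask)))
    m00 = float(len(pts))
    xb = sum(c for _, c in pts) / m00
    yb = sum(r for r, _ in pts) / m00

    def mu(p, q):
        return sum((c - xb) ** p * (r - yb) ** q for r, c in pts)

    def eta(p, q):
        return mu(p, q) / m00 ** (1 + (p + q) / 2)

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03, n21, n12 = eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2)
    h = [
        n20 + n02,
        (n20 - n02) ** 2 + 4 * n11**2,
        (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2,
        (n30 + n12) ** 2 + (n21 + n03) ** 2,
        (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
        (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
        + 4 * n11 * (n30 + n12) * (n21 + n03),
        (3 * n21 - n03) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
    ]
    return (yb, xb), np.array(h)


def oracle_signed_log(h, floor=1e-30):
    out = np.full(7, np.nan)
    for i, v in enumerate(h):
        if abs(v) >= floor:
            out[i] = np.sign(v) * np.log10(abs(v))
    return out


def oracle_shoelace(points):
    s = 0.0
    n = len(points)
    for i in range(n):
        y1, x1 = points[i]
        y2, x2 = points[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def oracle_perimeter(points):
    total = 0.0
    n = len(points)
    for i in range(n):
        y1, x1 = points[i]
        y2, x2 = points[(i + 1) % n]
        total += np.hypot(y2 - y1, x2 - x1)
    return total


def random_blob(rng, size=48):
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), 6)
    mask = field > np.quantile(field, 0.75)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return None
    sizes = ndimage.sum(mask, labels, range(1, n + 1))
    biggest = labels == (1 + int(np.argmax(sizes)))
    return biggest if biggest.sum() >= 20 else None


def rotate_mask(mask, deg):
    return ndimage.rotate(mask.astype(float), deg, order=1, reshape=True) > 0.5


# ---------------------------------------------------------------------------
# conditioning and gating
# ---------------------------------------------------------------------------


class TestConditioning:
    def test_zero_mask_stays_zero(self):
        out = condition_soil(BinaryLayer(np.zeros((10, 10), bool)))
        assert not out.mask.any()

    def test_isolated_pixel_removed_by_median(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        # oracle: 3x3 majority around the lone pixel is background
        assert not condition_soil(BinaryLayer(m)).mask.any()

    def test_solid_square_interior_stable(self):
        # the median rounds exactly the four corner pixels; everything else
        # of a solid square is a fixed point of the conditioning
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        out = condition_soil(BinaryLayer(m)).mask
        changed = {tuple(p) for p in np.argwhere(out != m)}
        assert changed <= {(2, 2), (2, 11), (11, 2), (11, 11)}
        assert np.array_equal(out[3:11, 3:11], m[3:11, 3:11])

    def test_output_is_binary_same_shape(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 30)) < 0.4
        out = condition_soil(BinaryLayer(m))
        assert out.mask.shape == m.shape and out.mask.dtype == bool


class TestHalo:
    def test_single_pixel_becomes_radius2_diamond(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        halo = make_soil_halo(BinaryLayer(m)).mask
        rr, cc = np.mgrid[0:9, 0:9]
        # oracle: two dilations with the cross element = L1 ball of radius 2
        np.testing.assert_array_equal(halo, np.abs(rr - 4) + np.abs(cc - 4) <= 2)

    def test_empty_and_full_absorbing(self):
        assert not make_soil_halo(BinaryLayer(np.zeros((5, 5), bool))).mask.any()
        assert make_soil_halo(BinaryLayer(np.ones((5, 5), bool))).mask.all()

    def test_halo_is_superset(self):
        rng = np.random.default_rng(1)
        m = rng.random((15, 15)) < 0.3
        assert np.all(make_soil_halo(BinaryLayer(m)).mask >= m)


class TestOverlapGate:
    def test_disjoint_masks_fail(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:3, :3] = True
        b[7:, 7:] = True
        passes, t2 = overlap_gate(BinaryLayer(a), BinaryLayer(b))
        assert not passes and not t2.mask.any()

    def test_identical_masks_mean_is_foreground_fraction(self):
        m = np.zeros((10, 10), bool)
        m[:5] = True
        passes, t2 = overlap_gate(BinaryLayer(m), BinaryLayer(m))
        assert passes
        assert t2.mask.sum() / t2.mask.size == pytest.approx(0.5)

    def test_single_overlap_pixel_passes(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[5, :6] = True
        b[5, 5:] = True
        passes, t2 = overlap_gate(BinaryLayer(a), BinaryLayer(b))
        assert passes and t2.mask.sum() == 1  # mean = 0.01 > 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            overlap_gate(BinaryLayer(np.zeros((4, 4), bool)), BinaryLayer(np.zeros((5, 4), bool)))


# ---------------------------------------------------------------------------
# contours and moments
# ---------------------------------------------------------------------------


class TestFindContours:
    def test_filled_rectangle_geometry(self):
        m = np.zeros((12, 14), bool)
        m[2:9, 3:12] = True  # h=7, w=9
        (c,) = find_contours(BinaryLayer(m))
        # polygon through pixel centres: area (h-1)(w-1), perimeter 2(h-1+w-1)
        assert c.area_px2 == pytest.approx(6 * 8)
        assert c.perimeter_px == pytest.approx(2 * (6 + 8))
        assert c.centroid == pytest.approx((5.0, 7.0))

    def test_two_blobs_two_contours(self):
        m = np.zeros((20, 20), bool)
        m[2:6, 2:6] = True
        m[12:18, 10:17] = True
        assert len(find_contours(BinaryLayer(m))) == 2

    def test_empty_mask_empty_list(self):
        assert find_contours(BinaryLayer(np.zeros((5, 5), bool))) == []

    def test_enclosing_circle_covers_all_points(self):
        rng = np.random.default_rng(2)
        blob = random_blob(rng)
        (c,) = find_contours(BinaryLayer(blob))
        d = np.hypot(*(c.points - np.mean(c.points, axis=0)).T)
        assert c.enclosing_radius_px >= d.max() / 2  # radius covers the spread
        center_dists = np.hypot(
            c.points[:, 0] - c.centroid[0], c.points[:, 1] - c.centroid[1]
        )
        assert np.all(center_dists <= 2 * c.enclosing_radius_px + 1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_geometry_matches_bruteforce_oracles(self, seed):
        rng = np.random.default_rng(100 + seed)
        blob = random_blob(rng)
        if blob is None:
            pytest.skip("degenerate draw")
        (c,) = find_contours(BinaryLayer(blob))
        assert c.area_px2 == pytest.approx(oracle_shoelace(c.points), rel=1e-9)
        assert c.perimeter_px == pytest.approx(oracle_perimeter(c.points), rel=1e-9)
        centroid, h = oracle_hu(blob)
        assert c.centroid == pytest.approx(centroid, rel=1e-9)
        np.testing.assert_allclose(
            c.log_hu, oracle_signed_log(h), rtol=1e-6, equal_nan=True
        )


class TestLogHu:
    def test_identical_masks_identical_vectors(self):
        m = disk_mask(10, 25)
        np.testing.assert_array_equal(log_hu(m), log_hu(m.copy()))

    def test_disks_of_different_radius_share_m1(self):
        h30 = log_hu(disk_mask(30, 70))
        h60 = log_hu(disk_mask(60, 140))
        # oracle agreement on both rasters, then scale invariance of m1
        np.testing.assert_allclose(h30, oracle_signed_log(oracle_hu(disk_mask(30, 70))[1]),
                                   rtol=1e-6, equal_nan=True)
        assert abs(h30[0] - h60[0]) < 1e-2

    def test_mirroring_flips_only_m7(self):
        rng = np.random.default_rng(5)
        tri = np.zeros((50, 50), bool)
        rr, cc = np.mgrid[0:50, 0:50]
        tri[(cc > 5) & (rr > 5) & (cc + 2 * rr < 80)] = True
        h = log_hu(tri)
        hm = log_hu(tri[:, ::-1])
        np.testing.assert_allclose(h[:6], hm[:6], atol=1e-9)
        assert h[6] == pytest.approx(-hm[6])

    def test_empty_mask_is_degenerate(self):
        with pytest.raises(DegenerateShapeError):
            log_hu(np.zeros((5, 5), bool))


class TestShapeRatio:
    def test_identical_vectors_give_zero_and_symmetry(self):
        a = log_hu(disk_mask(12, 30))
        b = log_hu(rotate_mask(disk_mask(12, 30), 30))
        assert shape_ratio(a, a) == 0.0
        assert shape_ratio(a, b) == pytest.approx(shape_ratio(b, a))
        assert shape_ratio(a, b) >= 0.0

    def test_rotation_and_scale_invariance(self, templates):
        oval = templates.templates[1].image
        big = np.kron(oval, np.ones((2, 2), dtype=bool))
        transformed = rotate_mask(big, 37.0)
        assert shape_ratio(log_hu(oval), log_hu(transformed)) <= 0.05

    def test_disk_vs_bar_orders_above_rotated_disk(self):
        d = log_hu(disk_mask(25, 60))
        rotated = log_hu(rotate_mask(disk_mask(25, 60), 45))
        bar = np.zeros((60, 60), bool)
        bar[27:33, 5:55] = True  # 10:1 thin rectangle
        assert shape_ratio(d, log_hu(bar)) > shape_ratio(d, rotated)

    def test_all_terms_excluded_is_incomparable(self):
        a = np.full(7, np.nan)
        with pytest.raises(IncomparableShapesError):
            shape_ratio(a, np.ones(7))


# ---------------------------------------------------------------------------
# filtering, pairing, detection
# ---------------------------------------------------------------------------


class TestFilterSoilContours:
    def test_template_own_contour_kept_with_zero_ratio(self, templates):
        t = templates.templates[0]
        (c,) = find_contours(BinaryLayer(t.image))
        kept = filter_soil_contours([c], templates)
        assert kept == [c]
        assert c.best_ratio == pytest.approx(0.0, abs=1e-12)
        assert c.best_template == t.name

    def test_small_perimeter_discarded(self, templates):
        tiny = np.zeros((8, 8), bool)
        tiny[3:5, 3:5] = True  # perimeter well under 10 px
        (c,) = find_contours(BinaryLayer(tiny))
        assert c.perimeter_px < 10
        assert filter_soil_contours([c], templates) == []

    def test_thin_rectangle_rejected_by_shape(self, templates):
        bar = np.zeros((60, 60), bool)
        bar[27:33, 3:57] = True
        (c,) = find_contours(BinaryLayer(bar))
        assert filter_soil_contours([c], templates) == []
        assert c.best_ratio > DetectionParams().ratio_max


class TestPairing:
    def concentric(self):
        size = 41
        soil = disk_mask(10, size)
        ring = disk_mask(12, size) & ~disk_mask(11, size)
        return find_contours(BinaryLayer(soil)), find_contours(BinaryLayer(ring))

    def test_concentric_disk_and_ring_pair(self):
        sc, gc = self.concentric()
        (det,) = pair_and_confirm(sc, gc)
        assert det.d_px == pytest.approx(0.0, abs=0.2)
        assert det.ild_px <= 2.5
        assert det.prop > 1.0

    def test_translated_ring_fails_distance_gate(self):
        size = 41
        soil = np.zeros((160, 160), bool)
        soil[:size, :size] = disk_mask(10, size)
        ring = np.zeros((160, 160), bool)
        ring[100:141, 100:141] = disk_mask(12, 41) & ~disk_mask(11, 41)
        assert pair_and_confirm(
            find_contours(BinaryLayer(soil)), find_contours(BinaryLayer(ring))
        ) == []

    def test_tiny_fleck_fails_perimeter_proportion(self):
        sc, _ = self.concentric()
        fleck = np.zeros((41, 41), bool)
        fleck[8, 31:34] = True  # adjacent but P_gc ~ 0.1 P_sc
        gc = find_contours(BinaryLayer(fleck))
        assert gc and pair_and_confirm(sc, gc) == []


class TestDetectMounds:
    def test_disjoint_layers_short_circuit(self, templates):
        soil = np.zeros((64, 64), bool)
        grass = np.zeros((64, 64), bool)
        soil[8:20, 8:20] = True
        grass[45:60, 45:60] = True
        dets, overlay = detect_mounds(
            BinaryLayer(soil), BinaryLayer(grass), templates
        )
        assert dets == []
        assert overlay.shape == (64, 64, 3)

    def test_three_planted_mounds_found_at_centroids(self, scene_runner):
        out = scene_runner(seed=21, n_mounds=3, noise=0.0, blur=0.0)
        assert out["counts"].tp == 3 and out["counts"].fp == 0
        truth_c = np.array([e.centroid for e in out["truth"].entries])
        det_c = np.array(
            [d.soil_contour.centroid for d in out["detections"]]
        )
        for tc in truth_c:
            assert np.min(np.hypot(*(det_c - tc).T)) <= 2.0

    def test_rotation_90_preserves_detections(self, scene_runner, templates):
        out = scene_runner(seed=22, n_mounds=3, want_layers=True)
        soil, grass = out["soil"], out["grass"]
        base, _ = detect_mounds(soil, grass, templates)
        rot, _ = detect_mounds(
            BinaryLayer(np.rot90(soil.mask)), BinaryLayer(np.rot90(grass.mask)), templates
        )
        assert len(rot) == len(base)
        H = soil.mask.shape[1]
        mapped = sorted(
            (round(H - 1 - c, 1), round(r, 1))
            for r, c in (d.soil_contour.centroid for d in base)
        )
        got = sorted(
            (round(r, 1), round(c, 1))
            for r, c in (d.soil_contour.centroid for d in rot)
        )
        np.testing.assert_allclose(np.array(got), np.array(mapped), atol=1.0)

    def test_integer_translation_equivariance(self, scene_runner, templates):
        out = scene_runner(seed=23, n_mounds=3, want_layers=True)
        soil, grass = out["soil"], out["grass"]
        base, _ = detect_mounds(soil, grass, templates)
        dy, dx = 7, -5
        soil2 = BinaryLayer(np.roll(soil.mask, (dy, dx), axis=(0, 1)))
        grass2 = BinaryLayer(np.roll(grass.mask, (dy, dx), axis=(0, 1)))
        moved, _ = detect_mounds(soil2, grass2, templates)
        assert len(moved) == len(base)
        base_c = sorted(
            (round(r + dy, 1), round(c + dx, 1))
            for r, c in (d.soil_contour.centroid for d in base)
        )
        moved_c = sorted(
            (round(r, 1), round(c, 1)) for r, c in (d.soil_contour.centroid for d in moved)
        )
        np.testing.assert_allclose(np.array(moved_c), np.array(base_c), atol=1.0)

    def test_gate_soundness(self, scene_runner, templates):
        from moundscan.mound_detect import condition_grass, make_soil_halo

        out = scene_runner(seed=24, n_mounds=4, want_layers=True)
        dets, _ = detect_mounds(out["soil"], out["grass"], templates)
        if dets:
            halo = make_soil_halo(condition_soil(out["soil"]))
            grass_m = condition_grass(out["grass"])
            assert (halo.mask & grass_m.mask).any()

    def test_enlarging_thresholds_never_shrinks_detections(self, scene_runner, templates):
        out = scene_runner(seed=25, n_mounds=4, want_layers=True)
        soil, grass = out["soil"], out["grass"]

        def centroid_set(params):
            dets, _ = detect_mounds(soil, grass, templates, params)
            return {
                (round(d.soil_contour.centroid[0], 2), round(d.soil_contour.centroid[1], 2))
                for d in dets
            }

        base = centroid_set(DetectionParams())
        for loose in (
            DetectionParams(ratio_max=0.30),
            DetectionParams(ild_max_px=6.0),
            DetectionParams(radius_factor=2.0),
            DetectionParams(ratio_max=0.5, ild_max_px=8.0, radius_factor=3.0),
        ):
            assert centroid_set(loose) >= base
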