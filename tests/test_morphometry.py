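"""Morphometry checked on analytic shapes and brute-force hull oracles."""

import math

import numpy as np
import pytest
from skimage.draw import polygon

from mitoqc import morphometry as M


def disc_mask(radius, pad=6):
    n = 2 * (radius + pad) + 1
    y, x = np.mgrid[0:n, 0:n]
    c = radius + pad
    return (y - c) ** 2 + (x - c) ** 2 <= radius**2


def gift_wrap_hull(points):
    """Brute-force convex hull (gift wrapping), independent of scipy."""
    pts = [tuple(p) for p in {tuple(q) for q in points}]
    start = min(pts)
    hull = [start]
    while True:
        cur = hull[-1]
        cand = pts[0] if pts[0] != cur else pts[1]
        for p in pts:
            if p == cur:
                continue
            cross = (cand[0] - cur[0]) * (p[1] - cur[1]) - (cand[1] - cur[1]) * (p[0] - cur[0])
            d_cand = (cand[0] - cur[0]) ** 2 + (cand[1] - cur[1]) ** 2
            d_p = (p[0] - cur[0]) ** 2 + (p[1] - cur[1]) ** 2
            if cross < 0 or (cross == 0 and d_p > d_cand):
                cand = p
        if cand == start:
            break
        hull.append(cand)
    return np.array(hull, float)


def shoelace(verts):
    y, x = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestLabelObjects:
    def test_two_blobs_counted(self):
        m = np.zeros((32, 32), bool)
        m[2:4, 2:4] = True  # 4 px
        m[10:11, 10:15] = True  # 5 px
        objs = M.label_objects(m, 9.7, 0.0)
        assert objs.n_objects == 2

    def test_small_blob_removed_by_area_filter(self):
        # 9 px at 9.7 px/µm is 9 / 9.7² ≈ 0.096 µm² < 0.3 µm²
        m = np.zeros((16, 16), bool)
        m[5:8, 5:8] = True
        assert 9 / 9.7**2 < 0.3
        assert M.label_objects(m, 9.7, 0.3).n_objects == 0

    def test_empty_mask(self):
        assert M.label_objects(np.zeros((8, 8), bool), 1.0).n_objects == 0

    def test_labels_follow_raster_order_of_first_pixel(self):
        m = np.zeros((16, 16), bool)
        m[10:12, 1:3] = True
        m[1:3, 10:12] = True
        objs = M.label_objects(m, 1.0)
        first = np.argwhere(objs.labels == 1)[0]
        assert first[0] < 5  # the top blob got label 1

    def test_diagonal_pixels_are_one_object(self):
        m = np.zeros((8, 8), bool)
        m[1, 1] = m[2, 2] = m[3, 3] = True
        assert M.label_objects(m, 1.0).n_objects == 1


class TestAnalyticShapes:
    def test_disc(self):
        objs = M.label_objects(disc_mask(20), 1.0)
        f = M.compute_features(objs, 1)
        assert f["circularity"] >= 0.95
        assert f["aspect_ratio"] == pytest.approx(1.0, abs=0.02)
        assert f["feret"] == pytest.approx(40.0, abs=1.0)
        assert f["solidity"] >= 0.98
        assert f["area"] == pytest.approx(math.pi * 400, rel=0.02)
        assert f["round"] == pytest.approx(1.0, abs=0.05)
        assert f["area_eq_diameter"] == pytest.approx(40.0, rel=0.02)

    def test_rectangle(self):
        m = np.zeros((60, 60), bool)
        m[10:20, 5:45] = True  # 10 x 40 px
        f = M.compute_features(M.label_objects(m, 1.0), 1)
        assert f["extent"] == pytest.approx(1.0, abs=0.01)
        assert f["ar_box"] == pytest.approx(4.0, abs=0.05)
        assert f["feret"] == pytest.approx(math.hypot(10, 40), abs=1.0)
        assert f["min_feret"] == pytest.approx(10.0, abs=0.5)

    def test_regular_hexagon(self):
        a = 15.0
        ang = np.arange(6) * np.pi / 3
        m = np.zeros((80, 80), bool)
        rr, cc = polygon(40 + a * np.sin(ang), 40 + a * np.cos(ang))
        m[rr, cc] = True
        f = M.compute_features(M.label_objects(m, 1.0), 1)
        assert f["hexagonality"] == pytest.approx(1.0, abs=0.03)
        assert f["hex_shape_factor"] == pytest.approx(1.0, abs=0.03)
        # analytic hexagon side recovered from the measured area
        assert f["hex_side"] == pytest.approx(a, rel=0.03)

    def test_polyomino_solidity_matches_hull_oracle(self, rng):
        m = np.zeros((12, 12), bool)
        m[2, 2:10] = True
        m[3:7, 2] = True
        f = M.compute_features(M.label_objects(m, 1.0), 1)
        hull = gift_wrap_hull(np.argwhere(m).astype(float))
        expected = min(m.sum() / shoelace(hull), 1.0)
        assert f["solidity"] == pytest.approx(expected, abs=1e-6)

    def test_random_blob_solidity_matches_hull_oracle(self, rng):
        m = np.zeros((24, 24), bool)
        m[12, 12] = True
        while m.sum() < 40:
            ys, xs = np.nonzero(m)
            k = rng.integers(len(ys))
            dy, dx = [(0, 1), (0, -1), (1, 0), (-1, 0)][rng.integers(4)]
            ny, nx = ys[k] + dy, xs[k] + dx
            if 0 < ny < 23 and 0 < nx < 23:
                m[ny, nx] = True
        f = M.compute_features(M.label_objects(m, 1.0), 1)
        hull = gift_wrap_hull(np.argwhere(m).astype(float))
        expected = min(m.sum() / shoelace(hull), 1.0)
        assert f["solidity"] == pytest.approx(expected, abs=1e-6)


@pytest.fixture(scope="module")
def disc_features():
    objs1 = M.label_objects(disc_mask(20), 1.0)
    objs2 = M.label_objects(disc_mask(20), 2.0)
    return M.compute_features(objs1, 1), M.compute_features(objs2, 1)


class TestInvariants:
    def test_scale_equivariance(self, disc_features):
        f1, f2 = disc_features
        dimensionless = {
            "circularity", "aspect_ratio", "round", "solidity", "feret_ar",
            "compactness", "extent", "ar_box", "ar_feret", "round_feret",
            "compact_feret", "elongation", "thinness_ratio", "convexity",
            "roundness_corr_ar", "hex_shape_factor", "hex_shape_factor_ratio",
            "hexagonality",
        }
        lengths = {
            "perimeter", "feret", "min_feret", "area_eq_diameter",
            "perimeter_eq_diameter", "spherical_eq_diameter", "hex_side",
            "hex_perimeter",
        }
        assert f1["area"] == pytest.approx(4 * f2["area"], rel=1e-9)
        assert f1["interfacial_density"] == pytest.approx(
            f2["interfacial_density"] / 2, rel=1e-9
        )
        for k in lengths:
            assert f1[k] == pytest.approx(2 * f2[k], rel=1e-9), k
        for k in dimensionless:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k

    def test_descriptor_count_and_order(self):
        assert len(M.FEATURE_NAMES) == 32
        f = M.compute_features(M.label_objects(disc_mask(5), 1.0), 1)
        assert list(f.keys()) == list(M.FEATURE_NAMES)

    @pytest.mark.parametrize("shape", ["disc", "tube", "pixel", "L"])
    def test_descriptor_ranges(self, shape):
        m = np.zeros((40, 40), bool)
        if shape == "disc":
            m = disc_mask(8)
        elif shape == "tube":
            m[20:22, 5:35] = True
        elif shape == "pixel":
            m[20, 20] = True
        else:
            m[5:7, 5:25] = True
            m[5:25, 5:7] = True
        f = M.compute_features(M.label_objects(m, 9.7), 1)
        assert all(np.isfinite(v) for v in f.values())
        assert 0 < f["circularity"] <= 1
        assert 0 < f["solidity"] <= 1
        assert f["aspect_ratio"] >= 1
        assert f["feret"] >= f["min_feret"]
        assert 0 <= f["angle_0_90"] <= 90
        assert 0 <= f["feret_angle_0_90"] <= 90
        assert 0 <= f["feret_angle"] < 180
        assert f["circularity"] == min(f["thinness_ratio"], 1.0)
        assert f["hex_shape_factor"] * f["hex_shape_factor_ratio"] == pytest.approx(
            1.0, abs=1e-9
        )

    def test_corner_hull_area_at_least_pixel_area(self, rng):
        # geometric hull of the pixel squares always contains the object
        m = rng.random((20, 20)) < 0.3
        m[10, 10] = True
        objs = M.label_objects(m, 1.0)
        for lbl in range(1, objs.n_objects + 1):
            coords = np.argwhere(objs.labels == lbl).astype(float)
            if len(coords) < 3:
                continue
            corners = M._corner_points(coords)
            hull = gift_wrap_hull(corners)
            assert shoelace(hull) + 1e-9 >= len(coords)


class TestFeatureTable:
    def test_empty_mask_gives_header_only(self):
        objs = M.label_objects(np.zeros((8, 8), bool), 1.0)
        t = M.feature_table(objs)
        assert len(t) == 0
        assert list(t.columns[-32:]) == list(M.FEATURE_NAMES)

    def test_row_count_and_determinism(self, rng):
        m = np.zeros((64, 64), bool)
        for k in range(7):
            y, x = 5 + 8 * (k // 3), 5 + 20 * (k % 3)
            m[y : y + 4, x : x + 4] = True
        objs = M.label_objects(m, 1.0)
        t1 = M.feature_table(objs, "img0")
        t2 = M.feature_table(objs, "img0")
        assert len(t1) == 7
        assert t1.equals(t2)

    def test_invalid_label_rejected(self):
        objs = M.label_objects(np.ones((4, 4), bool), 1.0)
        with pytest.raises(ValueError):
            M.compute_features(objs, 2)
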