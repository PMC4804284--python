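"""Per-pixel feature families and per-nucleus descriptor summaries."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

import nucliq as nq
from nucliq.features import (
    PixelFeatureMaps,
    feature_names,
    haralick_from_glcm,
    local_entropy,
    nucleus_regions,
    quantize,
    ridge_filter,
    scale_per_image,
    summarize_nucleus,
    windowed_glcm,
)
from nucliq.preprocess import NucleusRecord

from oracles import (
    component_areas,
    entropy_at_pixel,
    fourier_hog_at_center,
    glcm_at_pixel,
    haralick_stats_direct,
)


def smooth_random_grid(shape=(33, 33), seed=0, sigma=2.0):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.random(shape), sigma) * 10.0


class TestFourierHog:
    def test_constant_grid_gives_zero_for_all_orders(self):
        maps = nq.fourier_hog(np.full((33, 33), 3.0))
        for name, grid in maps.items():
            np.testing.assert_allclose(grid, 0.0, atol=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_quarter_rotation_equivariance(self, k):
        """90-degree rotations are interpolation-free: each invariant map of
        the rotated image is the rotation of the original map."""
        grid = smooth_random_grid(seed=1)
        base = nq.fourier_hog(grid)
        rotated = nq.fourier_hog(np.rot90(grid, k))
        for name in base:
            np.testing.assert_allclose(
                rotated[name], np.rot90(base[name], k), atol=1e-6
            )

    def test_center_values_match_numeric_integration_oracle(self):
        """Moment magnitudes at the center equal a brute-force windowed sum
        over an explicitly built Gaussian kernel, for a ramp and for a
        smooth random field."""
        cfg = nq.FeatureConfig(hog_radial_sigmas=(2.0,), hog_max_order=3)
        ramp = np.tile(np.arange(33, dtype=float), (33, 1))
        for grid in (ramp, smooth_random_grid(seed=2)):
            maps = nq.fourier_hog(grid, cfg)
            for m in range(4):
                expected = fourier_hog_at_center(grid, m, 2.0)
                got = maps[f"fhog_m{m}_s2"][16, 16]
                assert got == pytest.approx(expected, rel=1e-3, abs=1e-9)

    def test_ramp_moment_magnitudes_are_unit_gradient(self):
        ramp = np.tile(np.arange(33, dtype=float), (33, 1))
        maps = nq.fourier_hog(ramp)
        for name, grid in maps.items():
            assert grid[16, 16] == pytest.approx(1.0, rel=1e-6)


class TestHaralick:
    def test_constant_window_limits(self):
        maps = nq.haralick_maps(np.full((9, 9), 7.0))
        assert maps["haralick_energy"][4, 4] == pytest.approx(1.0)
        assert maps["haralick_entropy"][4, 4] == pytest.approx(0.0)
        assert maps["haralick_contrast"][4, 4] == pytest.approx(0.0)

    def test_checkerboard_single_offset_contrast_is_one(self):
        """Perfectly alternating two-level pattern: every horizontal pair is
        (0,1) or (1,0), so the symmetric GLCM is anti-diagonal and the
        contrast equals 1 exactly."""
        board = np.indices((4, 4)).sum(axis=0) % 2
        glcm = windowed_glcm(board, levels=2, window=3, offsets=[(0, 1)])
        center = glcm[2, 2]
        oracle = glcm_at_pixel(board, 2, 2, 2, 3, [(0, 1)])
        np.testing.assert_allclose(center, oracle, atol=1e-12)
        stats = haralick_from_glcm(glcm)
        assert stats["haralick_contrast"][2, 2] == pytest.approx(1.0)

    def test_glcm_normalized_and_symmetric(self):
        rng = np.random.default_rng(5)
        q = quantize(rng.random((12, 12)), 4)
        glcm = windowed_glcm(q, 4, 5, [(0, 1), (1, 0)])
        sums = glcm.sum(axis=(2, 3))
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        np.testing.assert_allclose(glcm, glcm.transpose(0, 1, 3, 2), atol=1e-7)

    def test_stat_maps_match_pair_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        cfg = nq.FeatureConfig(
            haralick_window=5, haralick_levels=4, haralick_offsets=((0, 1), (1, -1))
        )
        grid = rng.random((12, 12))
        maps = nq.haralick_maps(grid, cfg)
        q = quantize(grid, 4)
        for r in range(12):
            for c in range(12):
                oracle = haralick_stats_direct(
                    glcm_at_pixel(q, r, c, 4, 5, [(0, 1), (1, -1)])
                )
                for name, val in oracle.items():
                    assert maps[name][r, c] == pytest.approx(val, abs=1e-5), (
                        name,
                        r,
                        c,
                    )


class TestLocalEntropy:
    def test_constant_window_is_zero_bits(self):
        np.testing.assert_allclose(local_entropy(np.full((9, 9), 2.5)), 0.0)

    def test_exact_one_bit_for_even_split(self):
        """A window with exactly half its pixels in each of 2 bins -> 1 bit."""
        cfg = nq.FeatureConfig(entropy_window=3, entropy_bins=2)
        grid = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        out = local_entropy(grid, cfg)
        assert out[0, 1] == pytest.approx(1.0)  # clipped 6-px window, 3 per bin

    def test_matches_direct_histogram_oracle(self):
        rng = np.random.default_rng(7)
        cfg = nq.FeatureConfig(entropy_window=5, entropy_bins=8)
        grid = rng.random((15, 15))
        out = local_entropy(grid, cfg)
        q = quantize(grid, 8)
        for r in range(15):
            for c in range(15):
                assert out[r, c] == pytest.approx(
                    entropy_at_pixel(q, r, c, 8, 5), abs=1e-9
                )


def _line_image(h=64, w=64, row=32):
    img = np.zeros((h, w))
    img[row, :] = 1.0
    return img


class TestMembraneDetector:
    def test_line_outscores_isotropic_blob(self):
        """Curvilinear saliency prefers a 1-px line over an isotropic blob
        of the same peak intensity."""
        line = _line_image()
        blob = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        blob = np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 2.0**2))
        blob *= 1.0 / blob.max()
        cfg = nq.FeatureConfig(voting_sigma=5.0)
        sal_line = nq.cmd_map(line, cfg)
        sal_blob = nq.cmd_map(blob, cfg)
        assert sal_line[32, 32] > sal_blob[32, 32]

    def test_orientation_matches_discretized_angle_oracle(self):
        """Closed-form ridge orientation equals brute-force steering of the
        second-derivative filter over 360 discrete angles."""
        img = ndimage.gaussian_filter(_line_image(), 1.0)
        sigma = 2.0
        strength, orientation = ridge_filter(img, sigma)
        rcc = ndimage.gaussian_filter(img, sigma, order=(0, 2), mode="reflect")
        rrr = ndimage.gaussian_filter(img, sigma, order=(2, 0), mode="reflect")
        rrc = ndimage.gaussian_filter(img, sigma, order=(1, 1), mode="reflect")
        angles = np.linspace(0, np.pi, 360, endpoint=False)
        r, c = 32, 32
        responses = [
            np.cos(t) ** 2 * rcc[r, c]
            + np.sin(t) ** 2 * rrr[r, c]
            + 2 * np.sin(t) * np.cos(t) * rrc[r, c]
            for t in angles
        ]
        ridge_dir = (angles[int(np.argmin(responses))] + np.pi / 2) % np.pi
        got = orientation[r, c]
        delta = min(abs(got - ridge_dir), np.pi - abs(got - ridge_dir))
        assert np.degrees(delta) <= 2.0
        assert np.degrees(min(got, np.pi - got)) <= 2.0  # horizontal line -> 0 deg

    def test_quarter_rotation_equivariance(self):
        img = ndimage.gaussian_filter(_line_image(), 1.0)
        cfg = nq.FeatureConfig(voting_sigma=5.0)
        _, orient = ridge_filter(img, cfg.ridge_sigma)
        _, orient_rot = ridge_filter(np.rot90(img), cfg.ridge_sigma)
        mid = orient[32, 32]
        mid_rot = orient_rot[32, 32]
        delta = abs((mid_rot - mid) % np.pi - np.pi / 2)
        assert min(delta, np.pi - delta) < np.radians(0.1)
        sal = nq.cmd_map(img, cfg)
        sal_rot = nq.cmd_map(np.rot90(img), cfg)
        np.testing.assert_allclose(sal_rot, np.rot90(sal), atol=1e-6)


class TestEcs:
    def _stack(self, structural):
        return nq.ChannelStack(
            "x", np.zeros_like(structural, dtype=float), structural.astype(float),
            corrected=True,
        )

    def test_all_tissue_gives_zero(self):
        out = nq.ecs_map(self._stack(np.full((16, 16), 5.0)))
        np.testing.assert_array_equal(out, 0.0)

    def test_single_hole_gets_its_area(self):
        structural = np.full((20, 20), 10.0)
        structural[5:9, 5:12] = 0.0  # 4x7 hole, area 28
        out = nq.ecs_map(self._stack(structural))
        assert np.all(out[5:9, 5:12] == 28.0)
        assert out[0, 0] == 0.0

    def test_matches_flood_fill_component_areas(self):
        rng = np.random.default_rng(8)
        structural = (rng.random((32, 32)) < 0.5).astype(float) * 10.0
        out = nq.ecs_map(self._stack(structural))
        extracellular = structural < 5.0
        from oracles import flood_fill_labels

        labels = flood_fill_labels(extracellular, 8)
        for lab in range(1, labels.max() + 1):
            area = np.sum(labels == lab)
            assert np.all(out[labels == lab] == area)
        assert np.all(out[~extracellular] == 0)


def _make_maps(grid, image_id="img"):
    return PixelFeatureMaps(
        image_id=image_id,
        per_channel={"nuclear": {"m": grid}, "structural": {"m": grid}},
    )


def _nucleus(pixels, image_id="img", nucleus_id=1):
    pts = sorted(pixels)
    rows = [p[0] for p in pts]
    cols = [p[1] for p in pts]
    return NucleusRecord(
        nucleus_id=nucleus_id,
        image_id=image_id,
        pixels=frozenset(pts),
        area=len(pts),
        centroid=(float(np.mean(rows)), float(np.mean(cols))),
    )


class TestSummarizeNucleus:
    def test_constant_map_statistics(self):
        grid = np.full((40, 40), 4.5)
        nucleus = _nucleus({(20, 20), (20, 21), (21, 20)})
        vec = summarize_nucleus(_make_maps(grid), nucleus, nq.FeatureConfig(ring_radius=3))
        for region in ("nucleus", "ring"):
            assert vec.values[f"nuclear.m.{region}.mean"] == pytest.approx(4.5)
            assert vec.values[f"nuclear.m.{region}.median"] == pytest.approx(4.5)
            assert vec.values[f"nuclear.m.{region}.std"] == 0.0
            assert vec.values[f"nuclear.m.{region}.mad"] == 0.0

    def test_outlier_region_statistics(self):
        """Values {1,2,3,4,100}: mean 22, median 3, mad 1."""
        grid = np.zeros((40, 40))
        pix = [(10, 10), (10, 11), (10, 12), (10, 13), (10, 14)]
        for p, v in zip(pix, [1, 2, 3, 4, 100]):
            grid[p] = v
        vec = summarize_nucleus(
            _make_maps(grid), _nucleus(pix), nq.FeatureConfig(ring_radius=2)
        )
        assert vec.values["nuclear.m.nucleus.mean"] == pytest.approx(22.0)
        assert vec.values["nuclear.m.nucleus.median"] == pytest.approx(3.0)
        assert vec.values["nuclear.m.nucleus.mad"] == pytest.approx(1.0)

    def test_regions_are_disjoint(self):
        grid = np.full((40, 40), 7.0)
        pix = {(20, 20), (20, 21), (21, 20), (21, 21)}
        nucleus = _nucleus(pix)
        for p in pix:
            grid[p] = 5.0
        vec = summarize_nucleus(_make_maps(grid), nucleus, nq.FeatureConfig(ring_radius=4))
        assert vec.values["nuclear.m.nucleus.mean"] == pytest.approx(5.0)
        assert vec.values["nuclear.m.ring.mean"] == pytest.approx(7.0)

    def test_ring_clipped_to_image_bounds(self):
        (nr, nc), (gr, gc) = nucleus_regions(
            _nucleus({(0, 0), (0, 1)}), shape=(30, 30), ring_radius=3
        )
        assert gr.min() >= 0 and gc.min() >= 0
        assert len(gr) > 0

    def test_empty_ring_warns_and_zeroes(self):
        pix = {(r, c) for r in range(3) for c in range(3)}
        with pytest.warns(UserWarning, match="empty ring"):
            vec = summarize_nucleus(
                _make_maps(np.ones((3, 3))), _nucleus(pix), nq.FeatureConfig(ring_radius=2)
            )
        assert vec.values["nuclear.m.ring.mean"] == 0.0


class TestScalePerImage:
    def _vectors(self, mat, image_id="img"):
        return [
            nq.NucleusFeatureVector(
                nucleus_id=i + 1,
                image_id=image_id,
                values={f"f{j}": float(v) for j, v in enumerate(row)},
            )
            for i, row in enumerate(mat)
        ]

    def test_standardization_identity(self):
        rng = np.random.default_rng(9)
        scaled = scale_per_image(self._vectors(rng.random((10, 4))))
        mat = np.array([[v.values[f"f{j}"] for j in range(4)] for v in scaled])
        np.testing.assert_allclose(mat.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(mat.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        mat = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        scaled = scale_per_image(self._vectors(mat))
        assert all(v.values["f1"] == 0.0 for v in scaled)

    def test_images_scaled_independently(self):
        rng = np.random.default_rng(10)
        a = scale_per_image(self._vectors(rng.random((6, 2)) + 5.0, "a"))
        b = scale_per_image(self._vectors(rng.random((6, 2)) - 5.0, "b"))
        col_a = np.array([v.values["f0"] for v in a])
        col_b = np.array([v.values["f0"] for v in b])
        assert col_a.mean() == pytest.approx(0.0, abs=1e-9)
        assert col_b.mean() == pytest.approx(0.0, abs=1e-9)
        # pooled mean of the raw columns would not be 0; scaling is per image
        raw_pooled = np.concatenate(
            [rng.random(6) + 5.0, rng.random(6) - 5.0]
        )
        assert abs(raw_pooled.mean()) > 0.1

    def test_single_nucleus_warns(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = scale_per_image(self._vectors(np.array([[1.0, 2.0]])))
        assert all(v == 0.0 for v in out[0].values.values())

    def test_mixed_images_rejected(self):
        vecs = self._vectors(np.ones((2, 2)), "a") + self._vectors(np.ones((2, 2)), "b")
        with pytest.raises(ValueError):
            scale_per_image(vecs)


class TestDescriptorNaming:
    def test_descriptor_size_in_expected_range(self):
        names = feature_names()
        assert 100 <= len(names) <= 1000

    def test_naming_is_deterministic(self):
        assert feature_names() == feature_names()
        cfg = nq.FeatureConfig(hog_max_order=2)
        assert feature_names(cfg) == feature_names(cfg)
        assert feature_names(cfg) != feature_names()

    def test_summaries_follow_canonical_order(self, small_corrected):
        stack, nuclei = small_corrected
        maps = nq.compute_feature_maps(stack)
        vec = summarize_nucleus(maps, nuclei[0])
        assert list(vec.values.keys()) == feature_names()
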