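"""Texture features against independent oracles and closed forms."""

import numpy as np
import pytest

from saffronvision.colorfeat import color_feature_block
from saffronvision.texturefeat import (
    Glcm,
    TextureParams,
    glcm,
    glcm_stats,
    histogram25,
    lbp,
    lbp_riu2_histogram,
    local_entropy,
    local_std,
    table1_stats,
    texture_feature_block,
    texture_feature_names,
    to_gray,
)

ALL_OFFSETS = [(0, 1), (0, 2), (-1, 1), (-2, 2), (-1, 0), (-2, 0), (-1, -1), (-2, -2)]


def naive_glcm(gray, offset, levels, mask=None):
    """Pair-enumeration oracle: walk every pixel, count both directions."""
    gray = np.asarray(gray)
    h, w = gray.shape
    if mask is None:
        mask = np.ones((h, w), bool)
    q = (gray.astype(int) * levels) // 256
    counts = np.zeros((levels, levels))
    dr, dc = offset
    for i in range(h):
        for j in range(w):
            ii, jj = i + dr, j + dc
            if 0 <= ii < h and 0 <= jj < w and mask[i, j] and mask[ii, jj]:
                counts[q[i, j], q[ii, jj]] += 1
                counts[q[ii, jj], q[i, j]] += 1
    return counts / counts.sum()


def naive_stats(p):
    """Brute-force double sums for the four co-occurrence statistics."""
    L = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(L) for j in range(L))
    mu_j = sum(j * p[i, j] for i in range(L) for j in range(L))
    si = np.sqrt(sum((i - mu_i) ** 2 * p[i, j] for i in range(L) for j in range(L)))
    sj = np.sqrt(sum((j - mu_j) ** 2 * p[i, j] for i in range(L) for j in range(L)))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    energy = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    homog = sum(p[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L))
    corr = (
        sum((i - mu_i) * (j - mu_j) * p[i, j] for i in range(L) for j in range(L)) / (si * sj)
        if si > 0 and sj > 0
        else 0.0
    )
    return contrast, corr, energy, homog


class TestGlcm:
    def test_two_row_image_horizontal_offset(self):
        gray = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        g = glcm(gray, (0, 1), levels=2)
        assert np.allclose(g.p, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_cell(self):
        g = glcm(np.full((5, 5), 200, np.uint8), (0, 1), levels=8)
        q = (200 * 8) // 256
        assert g.p[q, q] == pytest.approx(1.0)
        assert g.p.sum() == pytest.approx(1.0)

    def test_normalization(self, rng):
        gray = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        for off in ALL_OFFSETS:
            assert glcm(gray, off, 8).p.sum() == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            gray = rng.integers(0, 256, (8, 8), dtype=np.uint8)
            for off in ALL_OFFSETS:
                g = glcm(gray, off, 8)
                assert np.abs(g.p - naive_glcm(gray, off, 8)).max() < 1e-10

    def test_masked_matches_oracle(self, rng):
        gray = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        mask = rng.random((10, 10)) < 0.6
        for off in [(0, 1), (-1, 1)]:
            g = glcm(gray, off, 4, mask)
            assert np.abs(g.p - naive_glcm(gray, off, 4, mask)).max() < 1e-10

    def test_no_valid_pair_raises(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            glcm(np.zeros((4, 4), np.uint8), (0, 1), 2, mask)


class TestGlcmStats:
    def test_diagonal_matrix(self):
        g = Glcm(p=np.array([[0.5, 0.0], [0.0, 0.5]]), levels=2, offset=(0, 1))
        s = glcm_stats(g)
        assert s["contrast"] == pytest.approx(0.0)
        assert s["energy"] == pytest.approx(0.5)
        assert s["homogeneity"] == pytest.approx(1.0)
        assert s["correlation"] == pytest.approx(1.0)

    def test_uniform_matrix(self):
        g = Glcm(p=np.full((2, 2), 0.25), levels=2, offset=(0, 1))
        s = glcm_stats(g)
        assert s["contrast"] == pytest.approx(0.5)
        assert s["energy"] == pytest.approx(0.25)
        assert s["homogeneity"] == pytest.approx(0.75)
        assert s["correlation"] == pytest.approx(0.0)

    def test_constant_image_contrast_zero_and_degenerate_correlation(self):
        g = glcm(np.full((6, 6), 99, np.uint8), (0, 1), 8)
        with pytest.warns(UserWarning):
            s = glcm_stats(g)
        assert s["contrast"] == 0.0
        assert s["correlation"] == 0.0

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(20):
            gray = rng.integers(0, 256, (8, 8), dtype=np.uint8)
            for off in ALL_OFFSETS:
                g = glcm(gray, off, 8)
                s = glcm_stats(g)
                c, r, e, h = naive_stats(g.p)
                assert abs(s["contrast"] - c) < 1e-10
                assert abs(s["correlation"] - r) < 1e-10
                assert abs(s["energy"] - e) < 1e-10
                assert abs(s["homogeneity"] - h) < 1e-10

    def test_statistic_bounds_on_random_input(self, rng):
        for _ in range(30):
            gray = rng.integers(0, 256, (10, 10), dtype=np.uint8)
            s = glcm_stats(glcm(gray, (0, 1), 8))
            assert 0 < s["energy"] <= 1
            assert 0 < s["homogeneity"] <= 1
            assert abs(s["correlation"]) <= 1 + 1e-12
            assert s["contrast"] >= 0


class TestLocalMaps:
    def test_entropy_constant_image_zero(self):
        assert np.all(local_entropy(np.full((20, 20), 50, np.uint8)) == 0)

    def test_entropy_checkerboard_near_one_bit(self):
        cb = ((np.indices((31, 31)).sum(axis=0) % 2) * 255).astype(np.uint8)
        e = local_entropy(cb, window=9)
        # 9x9 window holds a 41/40 split of the two levels: H = 0.99991 bits
        assert abs(e[15, 15] - 1.0) < 1e-3

    def test_entropy_bounded_by_log2_levels(self, rng):
        g = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        assert local_entropy(g, 9, 32).max() <= np.log2(32) + 1e-9

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            local_entropy(np.zeros((5, 5), np.uint8), window=4)
        with pytest.raises(ValueError):
            local_std(np.zeros((5, 5), np.uint8), window=2)

    def test_std_constant_zero(self):
        assert np.all(local_std(np.full((10, 10), 9, np.uint8)) == 0)

    def test_std_matches_window_oracle(self, rng):
        g = rng.integers(0, 256, (15, 15)).astype(np.float64)
        out = local_std(g, 3)
        for i, j in [(5, 5), (7, 2), (10, 12)]:
            window = g[i - 1 : i + 2, j - 1 : j + 2]
            assert out[i, j] == pytest.approx(window.std(), abs=1e-9)

    def test_std_scale_equivariance(self, rng):
        g = rng.integers(0, 100, (12, 12)).astype(np.float64)
        assert np.allclose(local_std(2 * g, 3), 2 * local_std(g, 3))

    def test_std_half_half_window_reaches_two_point_sd(self):
        # a window split evenly between 0 and 255 has population SD 127.5;
        # no odd window is exactly even, so check the bound and the nearest case
        stripe = np.where(np.arange(20)[None, :] < 10, 0.0, 255.0) * np.ones((9, 1))
        out = local_std(stripe, 3)
        assert out.max() <= 127.5 + 1e-9
        # at the edge column the 3x3 window splits 3/6: SD = 255*sqrt(2)/3
        assert out[4, 9] == pytest.approx(255.0 * np.sqrt(2) / 3.0)


class TestLbp:
    def test_bright_center_codes_zero(self):
        g = np.zeros((3, 3), np.uint8)
        g[1, 1] = 255
        assert lbp(g)[0, 0] == 0

    def test_constant_image_ties_give_255(self):
        assert np.all(lbp(np.full((6, 6), 42, np.uint8)) == 255)

    def test_gray_shift_invariance(self, rng):
        g = rng.integers(0, 240, (10, 10), dtype=np.uint8)
        assert np.array_equal(lbp(g), lbp(g + 10))

    def test_matches_bitwise_oracle(self, rng):
        g = rng.integers(0, 256, (6, 6), dtype=np.uint8)
        codes = lbp(g)
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
        for i in range(1, 5):
            for j in range(1, 5):
                expected = sum(
                    (1 << k) for k, (dr, dc) in enumerate(offs)
                    if g[i + dr, j + dc] >= g[i, j]
                )
                assert codes[i - 1, j - 1] == expected

    def test_riu2_histogram_normalized(self, rng):
        codes = rng.integers(0, 256, 500)
        h = lbp_riu2_histogram(codes)
        assert h.shape == (10,)
        assert h.sum() == pytest.approx(1.0)


class TestTable1Stats:
    def test_point_mass(self):
        s = table1_stats(np.full(50, 100.0))
        assert s["std"] == 0
        assert s["smoothness"] == 0
        assert s["uniformity"] == pytest.approx(1.0)
        assert s["entropy"] == 0
        assert s["range"] == 0

    def test_uniform_over_levels(self):
        L = 16
        values = np.repeat(np.arange(L), 10)
        s = table1_stats(values, levels=L, value_range=(0, L))
        assert s["uniformity"] == pytest.approx(1 / L)
        assert s["entropy"] == pytest.approx(np.log2(L))

    def test_symmetric_histogram_zero_third_moment(self):
        values = np.concatenate([np.full(40, 50.0), np.full(40, 150.0)])
        assert table1_stats(values)["third_moment"] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_direct_moments_within_binning_error(self, rng):
        values = rng.uniform(0, 255, 1000)
        s = table1_stats(values, levels=256, value_range=(0, 255))
        # one bin is ~0.996 gray levels wide; allow one bin of slack
        assert abs(s["mean"] - values.mean()) < 1.0
        assert abs(s["std"] - values.std()) < 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            table1_stats(np.array([]))


class TestHistogram25:
    def test_constant_single_bin(self):
        h = histogram25(np.full(100, 30.0))
        assert h[2] == pytest.approx(1.0)  # 30 falls in bin [20.4, 30.6)
        assert h.sum() == pytest.approx(1.0)

    def test_normalized_on_random_input(self, rng):
        assert histogram25(rng.integers(0, 256, 1000)).sum() == pytest.approx(1.0)

    def test_linear_ramp_is_nearly_flat(self):
        h = histogram25(np.arange(256, dtype=np.float64))
        assert np.all(np.abs(h - 0.04) <= 0.005)


class TestTextureBlock:
    def test_99_unique_names(self):
        names = texture_feature_names()
        assert len(names) == 99
        assert len(set(names)) == 99

    def test_block_matches_registry(self, rng):
        gray = rng.integers(0, 256, (40, 40), dtype=np.uint8)
        mask = np.ones((40, 40), bool)
        block = texture_feature_block(gray, mask)
        assert list(block) == texture_feature_names()

    def test_combined_with_color_block_gives_120(self, rng):
        img = rng.integers(30, 256, (40, 40, 3), dtype=np.uint8)
        mask = np.ones((40, 40), bool)
        combined = {**color_feature_block(img, mask),
                    **texture_feature_block(to_gray(img), mask)}
        assert len(combined) == 120

    def test_deterministic(self, rng):
        gray = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        mask = rng.random((32, 32)) < 0.9
        b1 = texture_feature_block(gray, mask)
        b2 = texture_feature_block(gray, mask)
        assert b1 == b2

    def test_per_angle_stats_invariant_under_90_degree_rotation(self, rng):
        """Rotating the image by 90 degrees permutes the GLCM angles
        (0<->90, 45<->135), so the per-angle statistic multiset is unchanged."""
        gray = rng.integers(0, 256, (24, 24), dtype=np.uint8)
        mask = np.ones((24, 24), bool)
        params = TextureParams()
        b1 = texture_feature_block(gray, mask, params)
        b2 = texture_feature_block(np.rot90(gray).copy(), mask, params)
        for stat in ("contrast", "correlation", "energy", "homogeneity"):
            for d in params.glcm_distances:
                s1 = sorted(b1[f"tex.glcm_{stat}_d{d}_a{a}"] for a in params.glcm_angles)
                s2 = sorted(b2[f"tex.glcm_{stat}_d{d}_a{a}"] for a in params.glcm_angles)
                assert np.allclose(s1, s2)

    def test_to_gray_green_brighter_than_blue(self):
        green = np.zeros((4, 4, 3), np.uint8)
        green[..., 1] = 200
        blue = np.zeros((4, 4, 3), np.uint8)
        blue[..., 2] = 200
        assert to_gray(green).mean() > to_gray(blue).mean()
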