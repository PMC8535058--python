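"""Masked GLCM accumulation and Haralick feature formulas."""

import numpy as np
import pytest

from pclt2.io import T2Map
from pclt2.texture import (
    GlcmAccumulator,
    GlcmConfig,
    accumulate_glcm,
    texture_features,
)

SPACING = (3.2, 0.4, 0.4)


def map_from_image(img, valid=None):
    """Wrap a 2D integer image as a single-slice T2Map (values in ms)."""
    img = np.asarray(img, float)[None]
    v = np.ones_like(img, bool) if valid is None else np.asarray(valid, bool)[None]
    t2 = np.where(v, img, np.nan)
    return T2Map(t2=t2, s0=np.ones_like(img), r2_adj=np.ones_like(img),
                 valid=v, voxel_spacing=SPACING)


def brute_force_glcm(img, valid, symmetric=True, levels=81):
    """Oracle: loop over every ordered pixel pair explicitly."""
    img = np.asarray(img, int)
    valid = np.asarray(valid, bool)
    counts = np.zeros((levels, levels), dtype=np.int64)
    offs = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
    H, W = img.shape
    for y in range(H):
        for x in range(W):
            if not valid[y, x]:
                continue
            for dy, dx in offs:
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < H and 0 <= x2 < W and valid[y2, x2]:
                    counts[img[y, x], img[y2, x2]] += 1
                    if symmetric:
                        counts[img[y2, x2], img[y, x]] += 1
    return counts


def brute_force_features(counts):
    p = counts / counts.sum()
    L = counts.shape[0]
    ent = con = hom = 0.0
    for i in range(L):
        for j in range(L):
            if p[i, j] > 0:
                ent -= p[i, j] * np.log2(p[i, j])
            con += (i - j) ** 2 * p[i, j]
            hom += p[i, j] / (1 + abs(i - j))
    px = p.sum(axis=1)
    mu = sum(i * px[i] for i in range(L))
    var = sum((i - mu) ** 2 * px[i] for i in range(L))
    return ent, con, hom, var


def test_two_by_two_constant_image_pair_count():
    m = map_from_image([[1, 1], [1, 1]])
    acc = accumulate_glcm(m, np.ones((1, 2, 2), bool))
    assert acc.n_pairs == 12  # 2H + 2V + 2D adjacent pairs, doubled
    assert acc.counts[1, 1] == 12
    assert acc.counts.sum() == acc.counts[1, 1]


def test_isolated_pixel_mask_yields_empty_accumulator():
    img = np.arange(16).reshape(4, 4) % 5
    yy, xx = np.indices((4, 4))
    valid = (yy % 2 == 0) & (xx % 2 == 0)  # no two valid pixels adjacent
    m = map_from_image(img, valid)
    with pytest.warns(UserWarning, match="empty"):
        acc = accumulate_glcm(m, np.ones((1, 4, 4), bool))
    assert acc.empty
    with pytest.raises(ValueError):
        texture_features(acc)


def test_probabilities_normalize():
    rng = np.random.default_rng(0)
    m = map_from_image(rng.integers(0, 60, (6, 6)))
    acc = accumulate_glcm(m, np.ones((1, 6, 6), bool))
    assert acc.probabilities().sum() == pytest.approx(1.0)


def test_constant_image_feature_limits_exact():
    m = map_from_image(np.full((4, 4), 37))
    f = texture_features(accumulate_glcm(m, np.ones((1, 4, 4), bool)))
    assert f.entropy == 0.0
    assert f.contrast == 0.0
    assert f.homogeneity == 1.0
    assert f.variance == 0.0


def test_two_diagonal_cells_closed_form():
    a, b = 10, 24
    counts = np.zeros((81, 81), dtype=np.int64)
    counts[a, a] = counts[b, b] = 8
    f = texture_features(GlcmAccumulator(counts=counts, levels=np.arange(81.0)))
    assert f.entropy == pytest.approx(1.0)          # one bit
    assert f.contrast == pytest.approx(0.0)
    assert f.homogeneity == pytest.approx(1.0)
    assert f.variance == pytest.approx((b - a) ** 2 / 4)


def test_matches_brute_force_oracle_on_random_images():
    rng = np.random.default_rng(123)
    for _ in range(20):
        img = rng.integers(0, 80, (8, 8))
        valid = rng.random((8, 8)) > 0.2
        if not valid.any():
            continue
        m = map_from_image(img, valid)
        oracle_counts = brute_force_glcm(img, valid)
        if oracle_counts.sum() == 0:
            continue
        acc = accumulate_glcm(m, np.ones((1, 8, 8), bool))
        np.testing.assert_array_equal(acc.counts, oracle_counts)
        f = texture_features(acc)
        oe, oc, oh, ov = brute_force_features(oracle_counts)
        assert f.entropy == pytest.approx(oe, rel=1e-10, abs=1e-12)
        assert f.contrast == pytest.approx(oc, rel=1e-10, abs=1e-12)
        assert f.homogeneity == pytest.approx(oh, rel=1e-10, abs=1e-12)
        assert f.variance == pytest.approx(ov, rel=1e-10, abs=1e-12)


def test_agrees_with_skimage_on_full_rectangle():
    skimage = pytest.importorskip("skimage.feature")
    rng = np.random.default_rng(5)
    img = rng.integers(0, 40, (12, 12))
    m = map_from_image(img)
    acc = accumulate_glcm(m, np.ones((1, 12, 12), bool),
                          GlcmConfig(t2_range=(0.0, 40.0)))
    g = skimage.graycomatrix(img.astype(np.uint8), [1],
                             [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                             levels=41, symmetric=True)
    pooled = g[:, :, 0, :].sum(axis=2)
    np.testing.assert_array_equal(acc.counts, pooled)


def test_gray_level_shift_invariance():
    rng = np.random.default_rng(9)
    img = rng.integers(5, 40, (7, 7))
    m1 = map_from_image(img)
    m2 = map_from_image(img + 11)
    roi = np.ones((1, 7, 7), bool)
    f1 = texture_features(accumulate_glcm(m1, roi))
    f2 = texture_features(accumulate_glcm(m2, roi))
    assert f2.entropy == pytest.approx(f1.entropy, rel=1e-12)
    assert f2.contrast == pytest.approx(f1.contrast, rel=1e-12)
    assert f2.homogeneity == pytest.approx(f1.homogeneity, rel=1e-12)
    assert f2.variance == pytest.approx(f1.variance, rel=1e-9)


def test_entropy_increases_when_a_cell_is_split():
    merged = np.zeros((81, 81), np.int64)
    merged[10, 10] = 16
    merged[20, 20] = 16
    split = merged.copy()
    split[20, 20] = 8
    split[21, 21] = 8
    e_merged = texture_features(GlcmAccumulator(merged, np.arange(81.0))).entropy
    e_split = texture_features(GlcmAccumulator(split, np.arange(81.0))).entropy
    assert e_split > e_merged


def test_glcm_variance_tracks_roi_sd_squared(fitted_noisy_d0):
    """With integer-ms quantization the GLCM marginal variance sits close
    to the squared pixel SD of the ROI (slightly below, via saturation)."""
    from pclt2.relaxometry import summarize_roi

    t2map, mask, _ = fitted_noisy_d0
    pcl = mask.mask_for("PCL")
    s = summarize_roi(t2map, pcl)
    f = texture_features(accumulate_glcm(t2map, pcl))
    assert f.variance == pytest.approx(s.sd**2, rel=0.15)
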