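"""Lung-extraction pipeline stages against hand-computed oracles."""

import numpy as np
import pytest

from noduleseg.preprocessing import (DegenerateInputError, DiffusionParams,
                                     PreprocessConfig, PreprocessingError,
                                     RegionCriteria, StructuringElement,
                                     anisotropic_diffusion, apply_lung_mask,
                                     dilate, erode, kmeans_threshold,
                                     median_filter, morphological_open,
                                     preprocess_slice, rasterize_annotations,
                                     select_lung_regions, standardize)
from noduleseg.io import AnnotationSet, Contour, ReaderAnnotation


# -- standardize -----------------------------------------------------------
def test_standardize_zero_mean_unit_std(rng):
    out = standardize(rng.random((20, 20)))
    assert abs(out.mean()) < 1e-6
    assert abs(out.std() - 1.0) < 1e-6


def test_standardize_affine_invariance(rng):
    x = rng.random((10, 10))
    np.testing.assert_allclose(standardize(3.0 * x + 7.0), standardize(x),
                               atol=1e-9)


def test_standardize_hand_example():
    np.testing.assert_allclose(
        standardize(np.array([[0.0, 0.0], [2.0, 2.0]])),
        [[-1.0, -1.0], [1.0, 1.0]])


def test_standardize_constant_raises():
    with pytest.raises(DegenerateInputError):
        standardize(np.full((5, 5), 3.0))


# -- median filter ---------------------------------------------------------
def test_median_filter_examples(rng):
    const = np.full((8, 8), 2.0)
    np.testing.assert_array_equal(median_filter(const, 3), const)
    img = np.zeros((7, 7))
    img[3, 3] = 100.0  # single outlier
    np.testing.assert_array_equal(median_filter(img, 3), np.zeros((7, 7)))
    x = rng.random((6, 6))
    np.testing.assert_array_equal(median_filter(x, 1), x)
    with pytest.raises(ValueError):
        median_filter(x, 4)


# -- anisotropic diffusion -------------------------------------------------
def test_diffusion_fixes_constants_and_identity():
    const = np.full((10, 10), 5.0)
    np.testing.assert_allclose(
        anisotropic_diffusion(const, DiffusionParams(n_iterations=25)), const)
    x = np.random.default_rng(0).random((10, 10))
    np.testing.assert_array_equal(
        anisotropic_diffusion(x, DiffusionParams(n_iterations=0)), x)


@pytest.mark.parametrize("conduction", ["exponential", "rational"])
def test_diffusion_never_increases_variance(conduction):
    for seed in range(10):
        x = np.random.default_rng(seed).standard_normal((24, 24))
        prev = x.var()
        img = x
        params = DiffusionParams(n_iterations=1, conduction=conduction)
        for _ in range(5):
            img = anisotropic_diffusion(img, params)
            assert img.var() <= prev + 1e-12
            prev = img.var()


def test_diffusion_gamma_stability_bound():
    with pytest.raises(ValueError, match="gamma"):
        DiffusionParams(gamma=0.3)


# -- k-means thresholding --------------------------------------------------
def test_kmeans_two_level_image_oracle():
    img = np.where(np.random.default_rng(1).random((16, 16)) < 0.4, 10.0, 200.0)
    mask = kmeans_threshold(img, k=2, seed=0)
    np.testing.assert_array_equal(mask, (img == 10.0).astype(np.uint8))
    assert mask.shape == img.shape
    assert set(np.unique(mask)) <= {0, 1}
    # seed/relabeling invariance on a two-level image
    for seed in (1, 2, 3):
        np.testing.assert_array_equal(kmeans_threshold(img, 2, seed), mask)


def test_kmeans_too_few_distinct_values():
    with pytest.raises(DegenerateInputError):
        kmeans_threshold(np.full((5, 5), 1.0), k=2, seed=0)


# -- morphology ------------------------------------------------------------
def brute_force_erode(mask, fp):
    h, w = mask.shape
    r = fp.shape[0] // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if fp[di + r, dj + r]:
                        ii, jj = i + di, j + dj
                        val = mask[ii, jj] if 0 <= ii < h and 0 <= jj < w else 0
                        if not val:
                            ok = False
            out[i, j] = 1 if ok else 0
    return out


def brute_force_dilate(mask, fp):
    h, w = mask.shape
    r = fp.shape[0] // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            hit = False
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if fp[di + r, dj + r]:
                        ii, jj = i - di, j - dj
                        if 0 <= ii < h and 0 <= jj < w and mask[ii, jj]:
                            hit = True
            out[i, j] = 1 if hit else 0
    return out


def test_morphology_against_pixel_enumeration_oracle(rng):
    selem = StructuringElement("square", 1)
    fp = selem.footprint()
    mask = np.zeros((5, 5), dtype=np.uint8)
    mask[0, 4] = 1            # isolated pixel
    mask[2:5, 0:3] = 1        # 3x3 solid block
    opened = morphological_open(mask, selem)
    expected = brute_force_dilate(brute_force_erode(mask, fp), fp)
    np.testing.assert_array_equal(opened, expected)
    assert opened[0, 4] == 0          # isolated pixel removed
    assert opened[2:5, 0:3].all()     # block preserved
    for seed in range(5):
        m = (np.random.default_rng(seed).random((12, 12)) < 0.5).astype(np.uint8)
        np.testing.assert_array_equal(erode(m, selem), brute_force_erode(m, fp))
        np.testing.assert_array_equal(dilate(m, selem), brute_force_dilate(m, fp))


def test_opening_idempotent_and_anti_extensive(rng):
    selem = StructuringElement("disk", 1)
    zero = np.zeros((6, 6), dtype=np.uint8)
    np.testing.assert_array_equal(morphological_open(zero, selem), zero)
    for seed in range(8):
        m = (np.random.default_rng(seed).random((16, 16)) < 0.55).astype(np.uint8)
        o1 = morphological_open(m, selem)
        assert not (o1 & ~m).any()                       # anti-extensive
        np.testing.assert_array_equal(morphological_open(o1, selem), o1)
        d = dilate(m, selem)
        assert not (m & ~d).any()                        # dilation extensive


# -- region selection ------------------------------------------------------
def test_select_lung_regions_keeps_interior_blobs():
    mask = np.zeros((40, 40), dtype=np.uint8)
    mask[0, :] = 1
    mask[-1, :] = 1
    mask[:, 0] = 1
    mask[:, -1] = 1                    # border frame
    mask[8:18, 8:16] = 1               # blob A
    mask[22:34, 20:30] = 1             # blob B
    out = select_lung_regions(mask, RegionCriteria(closing_radius=0))
    assert out[10, 10] and out[25, 25]
    assert not out[0].any() and not out[:, 0].any()
    assert out.sum() == 10 * 8 + 12 * 10


def test_select_lung_regions_trivial_cases():
    empty = np.zeros((20, 20), dtype=np.uint8)
    with pytest.warns(UserWarning, match="no lung region"):
        out = select_lung_regions(empty)
    assert out.sum() == 0
    single = np.zeros((30, 30), dtype=np.uint8)
    single[10:20, 10:20] = 1
    np.testing.assert_array_equal(
        select_lung_regions(single, RegionCriteria(closing_radius=0)), single)


# -- masking ---------------------------------------------------------------
def test_apply_lung_mask_examples(rng):
    img = rng.random((12, 12))
    ones = np.ones((12, 12), dtype=np.uint8)
    np.testing.assert_allclose(
        apply_lung_mask(img, ones, StructuringElement("disk", 2)), img)
    zeros = np.zeros_like(ones)
    np.testing.assert_allclose(
        apply_lung_mask(img, zeros, StructuringElement("disk", 1)), 0.0)
    half = np.zeros_like(ones)
    half[:, :6] = 1
    out = apply_lung_mask(img, half, None)  # no dilation: exact complement
    np.testing.assert_allclose(out[:, :6], img[:, :6])
    np.testing.assert_allclose(out[:, 6:], 0.0)
    with pytest.raises(ValueError, match="shapes differ"):
        apply_lung_mask(img, np.ones((5, 5), dtype=np.uint8))


# -- annotation rasterization ----------------------------------------------
def _square(r0, c0, side):
    return [(r0, c0), (r0, c0 + side), (r0 + side, c0 + side), (r0 + side, c0)]


def test_rasterize_single_reader_square():
    ann = AnnotationSet([ReaderAnnotation("R1", [Contour(0, _square(5, 5, 10))])])
    mask = rasterize_annotations(ann, (32, 32))
    assert mask[10, 10] == 1
    assert mask[4, 4] == 0 and mask[20, 20] == 0
    assert mask.sum() > 80  # ~10x10 filled interior


def test_rasterize_consensus_voting():
    big = _square(2, 2, 12)
    readers = [ReaderAnnotation(f"R{i}", [Contour(0, big)]) for i in range(4)]
    full = rasterize_annotations(AnnotationSet(readers), (24, 24), 1.0)
    assert full[8, 8] == 1  # identical contours pass any consensus
    # 2 of 4 readers mark the square
    two = AnnotationSet(readers[:2] + [ReaderAnnotation("R2", []),
                                       ReaderAnnotation("R3", [])])
    assert rasterize_annotations(two, (24, 24), 0.5)[8, 8] == 1
    assert rasterize_annotations(two, (24, 24), 0.75)[8, 8] == 0


def test_rasterize_small_nodule_filtered():
    tiny = [(5.0, 5.0), (5.0, 7.0), (7.0, 7.0), (7.0, 5.0)]  # d ~ 2.26 mm
    ann = AnnotationSet([ReaderAnnotation("R1", [Contour(0, tiny)])])
    assert rasterize_annotations(ann, (16, 16), min_diameter_mm=3.0).sum() == 0
    assert rasterize_annotations(ann, (16, 16), min_diameter_mm=1.0).sum() > 0


# -- full pipeline ---------------------------------------------------------
def test_preprocess_slice_recovers_phantom_lung(default_phantom):
    roi, lung = preprocess_slice(default_phantom.image)
    true = default_phantom.lung_mask.astype(bool)
    got = lung.astype(bool)
    iou = (true & got).sum() / (true | got).sum()
    assert iou >= 0.7
    assert lung.shape == default_phantom.image.shape
    assert set(np.unique(lung)) <= {0, 1}
    assert roi.shape == default_phantom.image.shape
    # ROI vanishes outside the dilated lung mask
    outside = ~dilate(lung, PreprocessConfig().dilation_selem).astype(bool)
    np.testing.assert_allclose(roi[outside], 0.0)


def test_preprocess_slice_constant_image_error():
    with pytest.raises(PreprocessingError, match="standardize"):
        preprocess_slice(np.full((64, 64), 7.0))
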