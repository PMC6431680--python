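"""Segmentation workflow: oracles and invariants for every step."""

import numpy as np
import pytest
from scipy import ndimage

from famet import (
    Maturity,
    SegmentationParams,
    conditional_erosion,
    fill_holes,
    max_projection,
    otsu_binarize,
    preprocess,
    segment_cell,
    segment_focal_adhesions,
    segment_nucleus,
    segment_scene,
)
from famet.segmentation import label_focal_adhesions

from conftest import rect_mask


# ---------------------------------------------------------------------- otsu

def brute_force_otsu(img: np.ndarray) -> int:
    """Exhaustive between-class-variance maximizer over all 8-bit thresholds.

    Candidate threshold t assigns gray levels <= t to the background class;
    the first t maximizing w0*w1*(mu0-mu1)^2 wins.
    """
    assert img.dtype == np.uint8
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    levels = np.arange(256, dtype=float)
    best_var, best_thr = -1.0, 0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, t
    return best_thr


def test_otsu_separates_two_level_image():
    img = np.full((20, 20), 10, dtype=np.uint8)
    img[:, 10:] = 200
    mask = otsu_binarize(img)
    assert mask[:, 10:].all() and not mask[:, :10].any()


def test_otsu_equals_exhaustive_scan_on_bimodal_images():
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(42)
    for _ in range(10):
        img = np.concatenate(
            [rng.normal(60, 12, 2000), rng.normal(190, 20, 1500)]
        )
        img = np.clip(img, 0, 255).astype(np.uint8).reshape(50, 70)
        assert threshold_otsu(img) == brute_force_otsu(img)


def test_otsu_inversion_swaps_labels():
    img = np.full((20, 20), 10, dtype=np.uint8)
    img[:5] = 200
    mask = otsu_binarize(img)
    inv_mask = otsu_binarize(255 - img)
    assert np.array_equal(inv_mask, ~mask)


def test_otsu_constant_image_raises():
    with pytest.raises(ValueError):
        otsu_binarize(np.full((8, 8), 3.0))


# ------------------------------------------------------- conditional erosion

def brute_force_conditional_erosion(mask, threshold):
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            bg = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                        bg += 1
            if bg >= threshold:
                out[i, j] = False
    return out


def test_erosion_removes_isolated_pixel():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 2] = True
    assert not conditional_erosion(mask, 5).any()


def test_erosion_keeps_interior_of_solid_square():
    mask = rect_mask(10, 10, pad=3)
    out = conditional_erosion(mask, 5)
    assert out[6:10, 6:10].all()


def test_erosion_rectangle_corner_removed_edge_kept():
    # corner of a solid rectangle has 5 background neighbors; an
    # edge-midpoint pixel has 3
    mask = rect_mask(10, 10, pad=3)
    out = conditional_erosion(mask, 5)
    assert not out[3, 3]  # corner
    assert out[3, 8]  # edge midpoint


def test_erosion_matches_brute_force_on_random_masks():
    rng = np.random.default_rng(7)
    for threshold in (1, 3, 5, 8):
        mask = rng.random((24, 31)) > 0.45
        assert np.array_equal(
            conditional_erosion(mask, threshold),
            brute_force_conditional_erosion(mask, threshold),
        )


def test_erosion_is_synchronous_single_pass():
    # a 2-px-wide bar: every pixel has 5 bg neighbors counted on the INPUT,
    # so the whole bar disappears in one pass (an iterative/asynchronous
    # scheme could behave differently on the second sweep)
    mask = np.zeros((6, 10), dtype=bool)
    mask[2:4, 1:9] = True
    out = conditional_erosion(mask, 5)
    expected = brute_force_conditional_erosion(mask, 5)
    assert np.array_equal(out, expected)


# ----------------------------------------------------------------- max proj

def test_max_projection_pixelwise_max():
    stack = np.zeros((3, 2, 2))
    stack[:, 0, 0] = [1, 5, 3]
    assert max_projection(stack)[0, 0] == 5


def test_max_projection_single_plane_identity():
    stack = np.random.default_rng(0).random((1, 7, 9))
    assert np.array_equal(max_projection(stack), stack[0])


def test_max_projection_plane_permutation_invariant():
    rng = np.random.default_rng(1)
    stack = rng.random((4, 6, 6))
    perm = stack[[2, 0, 3, 1]]
    assert np.array_equal(max_projection(stack), max_projection(perm))


def test_max_projection_empty_raises():
    with pytest.raises(ValueError):
        max_projection(np.zeros((0, 4, 4)))


# --------------------------------------------------------------- fill holes

def test_fill_holes_annulus_to_disk():
    from conftest import disk_mask

    outer = disk_mask(20)
    inner = disk_mask(10, pad=20)
    annulus = outer & ~inner
    assert np.array_equal(fill_holes(annulus), outer)


def test_fill_holes_idempotent_on_solid():
    from conftest import disk_mask

    solid = disk_mask(15)
    assert np.array_equal(fill_holes(solid), solid)


def test_fill_holes_conserves_area_plus_holes():
    rng = np.random.default_rng(3)
    mask = rect_mask(30, 40, pad=5)
    # punch k interior holes
    hole_area = 0
    for _ in range(4):
        r, c = rng.integers(10, 30), rng.integers(10, 40)
        mask[r : r + 3, c : c + 3] = False
    # measure holes with an independent flood fill from the border
    outside = np.zeros_like(mask)
    outside[0, 0] = True
    outside = ndimage.binary_propagation(outside, mask=~mask)
    hole_area = (~mask & ~outside).sum()
    assert fill_holes(mask).sum() == mask.sum() + hole_area


# --------------------------------------------------------------- preprocess

def test_preprocess_constant_image_unchanged():
    img = np.full((64, 64), 0.4)
    out = preprocess(img)
    assert np.allclose(out, img, atol=1e-6)


def test_preprocess_denoising_reduces_noise():
    # the NLM stage must bring the noisy image strictly closer to the
    # clean one than contrast equalization alone leaves it
    rng = np.random.default_rng(5)
    clean = np.zeros((96, 96))
    clean[30:70, 30:70] = 0.8
    noisy = clean + rng.normal(0, 0.08, clean.shape)
    no_nlm = SegmentationParams(nlm_strength=0.0)
    mse_before = np.mean(
        (preprocess(noisy, no_nlm) - preprocess(clean, no_nlm)) ** 2
    )
    mse_after = np.mean((preprocess(noisy) - preprocess(clean, no_nlm)) ** 2)
    assert mse_after < mse_before


def test_preprocess_deterministic():
    rng = np.random.default_rng(9)
    img = rng.random((80, 80))
    assert np.array_equal(preprocess(img), preprocess(img))


# ---------------------------------------------------------------- FA triage

def _component_mask(px_counts, width=200):
    """Disjoint roughly square components with exact pixel counts."""
    mask = np.zeros((60, width), dtype=bool)
    col = 5
    for n in px_counts:
        h = int(np.floor(np.sqrt(n)))
        w, extra = divmod(n, h)
        mask[5 : 5 + h, col : col + w] = True
        if extra:
            mask[5 : 5 + extra, col + w] = True
        col += w + 10
    return mask


def test_triage_bins_at_005_um_per_px():
    # pixel area 0.0025 µm²: 30 px -> 0.075 (background), 60 px -> 0.15
    # (nascent), 100 px -> 0.25 (mature)
    mask = _component_mask([30, 60, 100])
    fas = label_focal_adhesions(mask, pixel_size=0.05)
    fas = sorted(fas, key=lambda f: f.pixel_count)
    assert [f.maturity for f in fas] == [
        Maturity.BACKGROUND, Maturity.NASCENT, Maturity.MATURE,
    ]
    assert [f.area for f in fas] == pytest.approx([0.075, 0.15, 0.25])


def test_triage_boundary_exactly_02_is_mature():
    mask = _component_mask([80])  # 80 px * 0.0025 = 0.2 µm² exactly
    (fa,) = label_focal_adhesions(mask, pixel_size=0.05)
    assert fa.area == pytest.approx(0.2)
    assert fa.maturity is Maturity.MATURE


def test_triage_counts_conserved_and_cutoff_monotone():
    rng = np.random.default_rng(11)
    sizes = rng.integers(10, 200, size=12).tolist()
    mask = _component_mask(sizes, width=1400)
    fas = label_focal_adhesions(mask, pixel_size=0.05)
    assert len(fas) == len(sizes)
    prev_mature = None
    for cutoff in (0.15, 0.2, 0.3, 0.4):
        params = SegmentationParams(mature_area_cutoff=cutoff)
        n_mature = sum(
            1 for f in label_focal_adhesions(mask, 0.05, params)
            if f.maturity is Maturity.MATURE
        )
        if prev_mature is not None:
            assert n_mature <= prev_mature
        prev_mature = n_mature


def test_area_scales_with_pixel_size_squared():
    mask = _component_mask([100])
    (fa1,) = label_focal_adhesions(mask, pixel_size=0.05)
    (fa2,) = label_focal_adhesions(mask, pixel_size=0.10)
    assert fa2.area == pytest.approx(4 * fa1.area)


# ------------------------------------------------------------- whole scenes

def test_polarity_double_inversion_is_identity():
    rng = np.random.default_rng(2)
    mask = rng.random((16, 16)) > 0.5
    assert np.array_equal(~~mask, mask)


def test_segment_cell_matches_ground_truth(scene_a_clean):
    seg = segment_cell(scene_a_clean.channels["red"])
    truth = scene_a_clean.ground_truth.cell_mask
    jaccard = (seg & truth).sum() / (seg | truth).sum()
    assert jaccard >= 0.95


def test_nucleus_inside_dilated_cell(scene_a_clean):
    cell = segment_cell(scene_a_clean.channels["red"])
    nucleus = segment_nucleus(scene_a_clean.channels["blue"])
    grown = ndimage.binary_dilation(cell, iterations=2)
    assert (nucleus & ~grown).sum() == 0


def test_segment_cell_blank_image_raises():
    with pytest.raises(ValueError):
        segment_cell(np.zeros((64, 64)))


def test_noise_free_scene_recovers_mature_count():
    from famet import SceneConfig, generate_scene

    cfg = SceneConfig(noise_sd=0.0)
    scene = generate_scene("B", cfg, rng_seed=21)
    seg = segment_scene(
        scene.channels["red"], scene.channels["green"],
        scene.channels["blue"], scene.pixel_size,
    )
    truth_mature = scene.ground_truth.fa_maturity.count("mature")
    assert truth_mature > 0
    assert abs(len(seg.mature) - truth_mature) <= max(2, 0.25 * truth_mature)


def test_params_validation():
    with pytest.raises(ValueError):
        SegmentationParams(background_area_cutoff=0.3)
    with pytest.raises(ValueError):
        SegmentationParams(erosion_neighbor_threshold=9)
    with pytest.raises(ValueError):
        SegmentationParams(connectivity=6)
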