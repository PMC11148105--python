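"""Tests of the seeded synthetic dataset generator and preprocessing."""

import numpy as np
import pytest
from scipy import ndimage

from madrnet import (SyntheticSpec, augment, generate, generate_binary,
                     generate_multiclass3, masks_to_targets,
                     normalize_and_resize, split_dataset)
from madrnet.synthetic import (IDENTITY_AUGMENT, apply_augment, load_dataset,
                               save_dataset)


# -------------------------------------------------------------------- binary
def test_binary_determinism_byte_identical():
    spec = SyntheticSpec(n_images=8, image_size=64, seed=7)
    a_img, a_msk = generate_binary(spec)
    b_img, b_msk = generate_binary(spec)
    assert a_img.tobytes() == b_img.tobytes()
    assert a_msk.tobytes() == b_msk.tobytes()


def test_binary_masks_binary_and_nonempty():
    imgs, masks = generate_binary(SyntheticSpec(n_images=8, image_size=64, seed=0))
    assert imgs.shape == (8, 1, 64, 64)
    assert masks.shape == (8, 64, 64)
    assert imgs.dtype == np.float32 and masks.dtype == np.uint8
    assert np.all((imgs >= 0) & (imgs <= 1))
    for m in masks:
        assert set(np.unique(m)) <= {0, 1}
        assert m.any()


def test_binary_foreground_fraction_in_band():
    spec = SyntheticSpec(n_images=100, image_size=64, seed=3)
    _, masks = generate_binary(spec)
    fracs = masks.reshape(100, -1).mean(axis=1)
    assert np.all(fracs >= spec.fg_band[0])
    assert np.all(fracs <= spec.fg_band[1])


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(image_size=16)
    with pytest.raises(ValueError):
        SyntheticSpec(task="nope")
    with pytest.raises(ValueError):
        SyntheticSpec(channels=2)


# ---------------------------------------------------------------- multiclass
def test_multiclass_labels_and_nesting():
    spec = SyntheticSpec(n_images=4, image_size=64, task="multiclass3", seed=1)
    imgs, masks = generate_multiclass3(spec)
    assert imgs.shape == (4, 1, 64, 64)
    for m in masks:
        assert np.array_equal(np.unique(m), [0, 1, 2, 3])
        # nesting: dilating label 1 never escapes the {1, 2} region
        inner = m == 1
        grown = ndimage.binary_dilation(inner)
        assert np.all(np.isin(m[grown], (1, 2)))
        # label 3 is disjoint from the nested pair
        assert not np.any(ndimage.binary_dilation(inner) & (m == 3))


def test_multiclass_geometric_invariants_over_many_seeds():
    for seed in range(200):
        spec = SyntheticSpec(n_images=1, image_size=48, task="multiclass3",
                             seed=seed)
        _, masks = generate_multiclass3(spec)
        m = masks[0]
        assert np.array_equal(np.unique(m), [0, 1, 2, 3])
        grown = ndimage.binary_dilation(m == 1)
        assert np.all(np.isin(m[grown], (1, 2)))


def test_generate_dispatches_on_task():
    b = generate(SyntheticSpec(n_images=2, image_size=32, seed=0))
    m = generate(SyntheticSpec(n_images=2, image_size=32, task="multiclass3", seed=0))
    assert b[1].max() == 1
    assert m[1].max() == 3


# ------------------------------------------------------------- preprocessing
def test_normalize_constant_image_is_zero():
    out = normalize_and_resize(np.full((1, 64, 64), 3.0), 64)
    assert np.all(out == 0)


def test_normalize_idempotent_on_unit_range_image():
    rng = np.random.default_rng(0)
    img = rng.uniform(size=(1, 128, 128)).astype(np.float32)
    img[0, 0, 0], img[0, 0, 1] = 0.0, 1.0  # pin the range
    out = normalize_and_resize(img, 128)
    np.testing.assert_allclose(out, img, atol=1e-6)


def test_downsample_checkerboard_matches_block_average():
    # 16-pixel checkerboard: 2x block averaging preserves the pattern
    tile = np.kron(np.indices((16, 16)).sum(axis=0) % 2,
                   np.ones((16, 16))).astype(np.float64)
    out = normalize_and_resize(tile[None], 128)[0]
    blocks = tile.reshape(128, 2, 128, 2).mean(axis=(1, 3))
    # anti-aliasing smooths ~2 output pixels around each tile edge; compare
    # on tile interiors (output tiles are 8 pixels wide)
    pos = np.arange(128) % 8
    inner = (pos >= 2) & (pos <= 5)
    interior = inner[:, None] & inner[None, :]
    np.testing.assert_allclose(out[interior], blocks[interior], atol=0.02)
    assert abs(out.mean() - blocks.mean()) < 0.01


def test_mask_resize_preserves_labels():
    mask = np.random.default_rng(0).integers(0, 4, size=(64, 64)).astype(np.uint8)
    out = normalize_and_resize(mask, 32, is_mask=True)
    assert out.dtype == mask.dtype
    assert set(np.unique(out)) <= set(np.unique(mask))


# ---------------------------------------------------------------- augmentation
def test_identity_augment_is_noop():
    rng = np.random.default_rng(0)
    img = rng.uniform(size=(1, 16, 16)).astype(np.float32)
    msk = (rng.uniform(size=(16, 16)) < 0.3).astype(np.uint8)
    img2, msk2 = apply_augment(img, msk, IDENTITY_AUGMENT)
    np.testing.assert_array_equal(img, img2)
    np.testing.assert_array_equal(msk, msk2)


def test_augment_preserves_label_set_and_pairing():
    rng = np.random.default_rng(1)
    img = rng.uniform(size=(1, 16, 16)).astype(np.float32)
    msk = rng.integers(0, 4, size=(16, 16)).astype(np.uint8)
    for seed in range(10):
        img2, msk2 = augment(img, msk, seed)
        assert set(np.unique(msk2)) == set(np.unique(msk))
        assert img2.shape == img.shape and msk2.shape == msk.shape
        # geometric transform applied identically: label histogram preserved
        assert np.array_equal(np.bincount(msk2.ravel(), minlength=4),
                              np.bincount(msk.ravel(), minlength=4))


def test_double_horizontal_flip_is_identity():
    rng = np.random.default_rng(2)
    img = rng.uniform(size=(1, 8, 8)).astype(np.float32)
    msk = (rng.uniform(size=(8, 8)) < 0.5).astype(np.uint8)
    params = dict(IDENTITY_AUGMENT, flip_h=True)
    once = apply_augment(img, msk, params)
    twice = apply_augment(once[0], once[1], params)
    np.testing.assert_array_equal(twice[0], img)
    np.testing.assert_array_equal(twice[1], msk)


# ----------------------------------------------------------------------- split
def test_split_2000_gives_1600_200_200():
    tr, va, te = split_dataset(2000, seed=0)
    assert (len(tr), len(va), len(te)) == (1600, 200, 200)


def test_split_disjoint_exhaustive_and_seeded():
    for n in (10, 37, 101):
        tr, va, te = split_dataset(n, seed=5)
        union = np.concatenate([tr, va, te])
        assert len(union) == n
        assert np.array_equal(np.sort(union), np.arange(n))
    a = split_dataset(50, seed=9)
    b = split_dataset(50, seed=9)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_split_rejects_small_n():
    with pytest.raises(ValueError):
        split_dataset(9, seed=0)


# -------------------------------------------------------------------- targets
def test_masks_to_targets_binary_and_onehot():
    masks = np.array([[[0, 1], [1, 0]]], dtype=np.uint8)
    t1 = masks_to_targets(masks, 1)
    assert t1.shape == (1, 1, 2, 2) and t1.dtype == np.float32
    t3 = masks_to_targets(np.array([[[0, 2], [1, 0]]]), 3)
    assert t3.shape == (1, 3, 2, 2)
    np.testing.assert_array_equal(t3.sum(axis=1), 1.0)


# ---------------------------------------------------------------------- disk
def test_dataset_roundtrip(tmp_path):
    spec = SyntheticSpec(n_images=12, image_size=32, seed=4)
    images, masks = generate_binary(spec)
    save_dataset(tmp_path / "ds", images, masks, spec, split_seed=4)
    images2, masks2, manifest = load_dataset(tmp_path / "ds")
    np.testing.assert_array_equal(masks, masks2)
    assert np.abs(images - images2).max() <= 1 / 255 + 1e-6  # 8-bit quantization
    assert manifest["n_images"] == 12
    assert sorted(manifest["split"]) == ["seed", "test", "train", "val"]
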