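"""Scene generator statistics, degradations and dataset round-trips."""

import numpy as np
import pytest

from seanet.boxes import BoxSet
from seanet.synthetic import (BLUR_KERNEL_LADDER, NOISE_STD_LADDER,
                              DegradationSpec, SceneSpec, apply_gaussian_noise,
                              apply_motion_blur, generate_scene,
                              motion_blur_kernel, read_dataset, write_dataset)


def test_same_spec_and_seed_is_bit_identical():
    spec = SceneSpec(image_size=96, seed=5)
    img1, bs1 = generate_scene(spec, seed=11)
    img2, bs2 = generate_scene(spec, seed=11)
    assert np.array_equal(img1, img2)
    assert np.array_equal(bs1.boxes, bs2.boxes)
    assert np.array_equal(bs1.classes, bs2.classes)
    img3, _ = generate_scene(spec, seed=12)
    assert not np.array_equal(img1, img3)


def test_annotation_box_is_tight_around_owned_pixels():
    spec = SceneSpec(image_size=128, contrast_delta=0.4, seed=0)
    img, bs, owner = generate_scene(spec, seed=3, return_masks=True)
    for i, box in enumerate(bs.boxes):
        ys, xs = np.nonzero(owner == i)
        assert [xs.min(), ys.min(), xs.max() + 1, ys.max() + 1] == box.tolist()


def test_contrast_delta_controls_foreground_shift():
    """Paired renders with the same seed differ only inside objects, by
    exactly the requested contrast shift; at delta = 0 objects carry the
    background texture unchanged (gap below quantisation)."""
    for s in range(3):
        img0, _, owner = generate_scene(
            SceneSpec(image_size=128, contrast_delta=0.0, seed=0),
            seed=s, return_masks=True)
        imgd, _, _ = generate_scene(
            SceneSpec(image_size=128, contrast_delta=0.2, seed=0),
            seed=s, return_masks=True)
        g0 = img0.mean(axis=2) / 255.0
        gd = imgd.mean(axis=2) / 255.0
        fg = owner >= 0
        assert np.abs(g0 - gd)[~fg].max() == 0.0          # background untouched
        gap0 = np.abs(g0[fg] - g0[fg]).mean()             # delta = 0: no shift
        assert gap0 < 2 / 255
        # the delta = 0.2 render shifts interiors by ~0.2 of the tint mean
        shift = np.abs(gd[fg] - g0[fg]).mean()
        assert shift == pytest.approx(0.2 * np.mean([0.62, 0.93, 1.0]),
                                      abs=0.04)


def test_crowding_statistics_match_survey_profile():
    """Counts stay in [1, 15] with a long-run mean near 9.57."""
    spec = SceneSpec(image_size=64, seed=0)
    counts = [len(generate_scene(spec, seed=s)[1]) for s in range(500)]
    assert min(counts) >= 1 and max(counts) <= 15
    assert abs(np.mean(counts) - 9.57) < 0.5


def test_area_fractions_respect_configured_range():
    spec = SceneSpec(image_size=160, contrast_delta=0.5, seed=0)
    fracs = []
    for s in range(20):
        img, bs = generate_scene(spec, seed=s)
        areas = (bs.boxes[:, 2] - bs.boxes[:, 0]) * \
            (bs.boxes[:, 3] - bs.boxes[:, 1])
        fracs.extend(areas / 160 ** 2)
    # occlusion can shrink boxes below the nominal floor; the ceiling holds
    # with slack for the square bbox of non-square shapes
    assert max(fracs) < 0.5
    assert np.median(fracs) > 0.005


def test_classes_are_shape_coded_within_range():
    spec = SceneSpec(image_size=96, n_classes=3, seed=0)
    for s in range(10):
        _, bs = generate_scene(spec, seed=s)
        assert set(np.unique(bs.classes)) <= {0, 1, 2}


def test_invalid_scene_specs_rejected():
    with pytest.raises(ValueError):
        SceneSpec(bbox_area_fraction_range=(0.0, 0.2))
    with pytest.raises(ValueError):
        SceneSpec(contrast_delta=1.5)


# ---------------------------------------------------------------------------
# degradations
# ---------------------------------------------------------------------------

def test_severity_ladders_are_exact():
    assert NOISE_STD_LADDER == {1: 10.0, 2: 20.0, 3: 30.0, 4: 40.0, 5: 50.0}
    assert BLUR_KERNEL_LADDER == {1: 5, 2: 9, 3: 13, 4: 17, 5: 21}
    for s in range(1, 6):
        assert DegradationSpec.from_severity("gaussian_noise", s).noise_std \
            == NOISE_STD_LADDER[s]
        assert DegradationSpec.from_severity("motion_blur", s).blur_kernel \
            == BLUR_KERNEL_LADDER[s]
    with pytest.raises(ValueError):
        DegradationSpec.from_severity("gaussian_noise", 6)
    with pytest.raises(ValueError):
        DegradationSpec.from_severity("fog", 1)


def test_zero_noise_is_identity_and_seeded_noise_reproducible():
    img = np.full((32, 32, 3), 128, dtype=np.uint8)
    assert np.array_equal(apply_gaussian_noise(img, 0, seed=1), img)
    a = apply_gaussian_noise(img, 30, seed=7)
    b = apply_gaussian_noise(img, 30, seed=7)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, apply_gaussian_noise(img, 30, seed=8))


def test_noise_standard_deviation_on_midgray():
    img = np.full((128, 128, 3), 128, dtype=np.uint8)
    noisy = apply_gaussian_noise(img, 30, seed=0).astype(np.float64)
    assert abs(noisy.std() - 30) < 1.0   # far from clipping at mid-gray


def test_motion_blur_kernel_normalised_and_constant_preserving():
    for k in (5, 9, 13, 17, 21):
        kern = motion_blur_kernel(k, 0.0)
        assert kern.sum() == pytest.approx(1.0)
    img = np.full((24, 24, 3), 77, dtype=np.uint8)
    assert np.array_equal(apply_motion_blur(img, 9, 0.0), img)


def test_motion_blur_matches_sliding_window_oracle():
    """Horizontal kernel 5 on a vertical step edge, interior pixels."""
    img = np.zeros((16, 16), dtype=np.float64)
    img[:, 8:] = 200.0
    out = apply_motion_blur(img, 5, 0.0)
    kern = motion_blur_kernel(5, 0.0)
    for i in range(4, 12):
        for j in range(4, 12):
            ref = (img[i - 2:i + 3, j - 2:j + 3] * kern).sum()
            assert out[i, j] == pytest.approx(ref, abs=1e-9)


def test_even_blur_kernel_rejected():
    with pytest.raises(ValueError):
        apply_motion_blur(np.zeros((8, 8)), 4)


def test_larger_blur_kernels_reduce_gradient_energy():
    spec = SceneSpec(image_size=96, contrast_delta=0.6, seed=0)
    img, _ = generate_scene(spec, seed=2)

    def energy(im):
        g = im.astype(np.float64).mean(axis=2)
        gx = np.diff(g, axis=1)
        gy = np.diff(g, axis=0)
        return (gx ** 2).sum() + (gy ** 2).sum()

    energies = [energy(apply_motion_blur(img, k, 0.0))
                for k in (5, 9, 13, 17, 21)]
    assert all(a >= b for a, b in zip(energies, energies[1:]))


# ---------------------------------------------------------------------------
# dataset round-trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["yolo", "coco"])
def test_write_read_round_trip(tmp_path, fmt):
    spec = SceneSpec(image_size=96, contrast_delta=0.5, seed=0)
    scenes = [generate_scene(spec, seed=s) for s in range(3)]
    write_dataset(scenes, tmp_path / fmt, fmt)
    back = read_dataset(tmp_path / fmt, fmt)
    assert len(back) == 3
    for (img, bs), (img2, bs2) in zip(scenes, back):
        assert np.array_equal(img, img2)
        assert np.array_equal(bs.classes, bs2.classes)
        assert np.abs(bs.boxes - bs2.boxes).max() / 96 < 1e-6


def test_empty_scene_writes_valid_empty_label(tmp_path):
    img = np.zeros((32, 32, 3), dtype=np.uint8)
    write_dataset([(img, BoxSet.empty())], tmp_path, "yolo")
    back = read_dataset(tmp_path, "yolo")
    assert len(back) == 1 and len(back[0][1]) == 0
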