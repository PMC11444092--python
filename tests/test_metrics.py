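import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from panelpet.grid import VoxelGrid, ImageVolume
from panelpet.phantoms import (
    CylinderPhantomSpec,
    LesionFieldSpec,
    SphereLesion,
    rasterize_phantom,
    sample_lesion_field,
)
from panelpet.metrics import (
    VOIMask,
    background_mask,
    bias_percent,
    crc,
    image_roughness,
    lesion_masks,
    pvm,
    report,
    sphere_voi_mask,
)

# ---------------------------------------------------------------------------
# closed-form arithmetic oracles
# ---------------------------------------------------------------------------


def test_bias_hand_computed_example():
    image = np.array([8.0, 9.0, 10.0])
    truth = np.array([10.0, 10.0, 10.0])
    mask = np.ones(3, bool)
    assert bias_percent(image, truth, mask) == pytest.approx(-10.0)


def test_bias_identity_and_linearity(rng):
    truth = rng.random((8, 8)) + 1.0
    mask = np.zeros((8, 8), bool)
    mask[2:5, 2:5] = True
    assert bias_percent(truth, truth, mask) == pytest.approx(0.0)
    assert bias_percent(0.5 * truth, truth, mask) == pytest.approx(-50.0)


def test_crc_hand_computed_example():
    img = np.array([5.0, 5.0, 1.0, 1.0])
    lm = np.array([True, True, False, False])
    bm = ~lm
    # lesion mean 5, background 1, truth contrast (9-1)/1 = 8
    assert crc(img, lm, bm, 8.0) == pytest.approx(0.5)


def test_crc_identity_and_zero_contrast():
    truth = np.array([9.0, 9.0, 1.0, 1.0])
    lm = np.array([True, True, False, False])
    assert crc(truth, lm, ~lm, 8.0) == pytest.approx(1.0)
    flat = np.ones(4)
    assert crc(flat, lm, ~lm, 8.0) == pytest.approx(0.0)


def test_crc_requires_disjoint_masks():
    img = np.ones(4)
    m = np.array([True, True, False, False])
    with pytest.raises(ValueError, match="disjoint"):
        crc(img, m, m, 1.0)


def test_image_roughness_closed_forms():
    assert image_roughness(np.full(100, 3.3), np.ones(100, bool)) == 0.0
    # two voxels (1, 3): population sigma 1, mean 2 -> 50%
    assert image_roughness(np.array([1.0, 3.0]), np.ones(2, bool)) == pytest.approx(50.0)


def test_metrics_invariant_under_joint_rescale(rng):
    g = VoxelGrid((48, 48))
    spec, label = sample_lesion_field(rng, 1, g, size_range=(8, 10))
    img = ImageVolume(gaussian_filter(label.data, 2.0), g)
    voi = lesion_masks(spec, g)[0]
    bkg = background_mask(spec, g, margin_mm=6.0, wall_margin_mm=3.0)
    contrast = spec.lesions[0].contrast - 1.0
    for s in (10.0, 0.25):
        i2 = ImageVolume(img.data * s, g)
        t2 = ImageVolume(label.data * s, g)
        assert bias_percent(i2, t2, voi) == pytest.approx(bias_percent(img, label, voi))
        assert crc(i2, voi, bkg, contrast) == pytest.approx(crc(img, voi, bkg, contrast))
        assert image_roughness(i2, bkg) == pytest.approx(image_roughness(img, bkg))


# ---------------------------------------------------------------------------
# VOI masks
# ---------------------------------------------------------------------------


def _sphere_spec(d_mm=8.0):
    return CylinderPhantomSpec(
        diameter_cm=4.0,
        height_cm=5.0,
        lesions=[SphereLesion((0.0, 0.0, 0.0), d_mm, 9.0)],
    )


def test_full_mask_equals_rasterized_lesion_set():
    g = VoxelGrid((48, 48, 56))
    spec = _sphere_spec()
    label = rasterize_phantom(spec, g)
    m = lesion_masks(spec, g, erode_voxels=0)[0].mask
    assert np.array_equal(m, label.data == 9.0)


def test_eroded_sphere_mask_approximates_smaller_sphere():
    g = VoxelGrid((48, 48, 56))
    full = lesion_masks(_sphere_spec(8.0), g, 0)[0]
    eroded = lesion_masks(_sphere_spec(8.0), g, 1)[0]
    six = lesion_masks(_sphere_spec(6.0), g, 0)[0]
    assert eroded.mask.sum() < full.mask.sum()
    assert np.all(full.mask[eroded.mask])
    # one-voxel erosion of an 8 mm sphere is close to a 6 mm sphere
    assert abs(eroded.n_voxels - six.n_voxels) / six.n_voxels < 0.25


def test_erosion_emptying_mask_raises():
    g = VoxelGrid((48, 48, 56))
    with pytest.raises(ValueError, match="lesion 0"):
        lesion_masks(_sphere_spec(2.0), g, 1)


def test_disjoint_lesions_give_disjoint_masks():
    g = VoxelGrid((48, 48, 56))
    spec = CylinderPhantomSpec(
        diameter_cm=4.0,
        lesions=[
            SphereLesion((-7.0, 0.0, 0.0), 6.0, 9.0),
            SphereLesion((7.0, 0.0, 0.0), 6.0, 9.0),
        ],
    )
    m1, m2 = (v.mask for v in lesion_masks(spec, g))
    assert not np.logical_and(m1, m2).any()


def test_background_mask_geometry_and_errors():
    g = VoxelGrid((48, 48))
    spec = LesionFieldSpec(background_diameter_mm=40.0)
    m = background_mask(spec, g, margin_mm=5.0, wall_margin_mm=2.0).mask
    r = np.hypot(*np.meshgrid(g.axis_coords(0), g.axis_coords(1), indexing="ij"))
    assert np.array_equal(m, r <= 18.0)
    spec2 = LesionFieldSpec(
        background_diameter_mm=40.0, lesions=[SphereLesion((0.0, 0.0), 10.0, 5.0)]
    )
    m2 = background_mask(spec2, g, margin_mm=5.0, wall_margin_mm=2.0)
    lm = lesion_masks(spec2, g)[0]
    assert not np.logical_and(m2.mask, lm.mask).any()
    with pytest.raises(ValueError, match="empty"):
        background_mask(spec2, g, margin_mm=100.0)
    with pytest.raises(ValueError, match="warm"):
        background_mask(LesionFieldSpec(background_level=0.0), g)


def test_voi_mask_rejects_empty():
    with pytest.raises(ValueError):
        VOIMask(np.zeros((4, 4), bool), 0, False)


# ---------------------------------------------------------------------------
# peak-to-valley measure
# ---------------------------------------------------------------------------


def _two_lesion_truth(gap_mm=8.0, d=8.0):
    g = VoxelGrid((48, 48))
    half = (d + gap_mm) / 2.0
    centers = [(0.0, -half), (0.0, +half)]
    spec = CylinderPhantomSpec(
        diameter_cm=4.0, lesions=[SphereLesion(c, d, 9.0) for c in centers]
    )
    return g, spec, rasterize_phantom(spec, g), centers


def test_pvm_identity_is_100_percent():
    g, spec, truth, centers = _two_lesion_truth()
    assert pvm(truth, truth, centers, g) == pytest.approx(100.0)


def test_pvm_flat_profile_is_zero():
    g, spec, truth, centers = _two_lesion_truth()
    flat = ImageVolume(np.full(g.shape, 2.0), g)
    assert pvm(flat, truth, centers, g) == pytest.approx(0.0)


def test_pvm_decreases_with_blur():
    g, spec, truth, centers = _two_lesion_truth(gap_mm=5.0)
    mild = ImageVolume(gaussian_filter(truth.data, 1.0), g)
    strong = ImageVolume(gaussian_filter(truth.data, 3.0), g)
    assert pvm(mild, truth, centers, g) > pvm(strong, truth, centers, g)


def test_pvm_requires_y_separation():
    g, spec, truth, _ = _two_lesion_truth()
    with pytest.raises(ValueError, match="separated along y"):
        pvm(truth, truth, [(-5.0, 0.0), (5.0, 0.0)], g)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def test_report_truth_against_itself(rng):
    g = VoxelGrid((48, 48))
    spec, label = sample_lesion_field(rng, 2, g, size_range=(6, 9))
    rep = report(
        {"truth": label}, label, spec, background_margin_mm=6.0, wall_margin_mm=3.0
    )
    row = rep.table.iloc[0]
    assert row.avg_abs_bias_percent == pytest.approx(0.0)
    assert row.avg_crc == pytest.approx(1.0)
    assert row.ir_percent == pytest.approx(0.0)


def test_report_is_pure_function(rng):
    g = VoxelGrid((48, 48))
    spec, label = sample_lesion_field(rng, 1, g, size_range=(6, 9))
    img = ImageVolume(gaussian_filter(label.data, 1.5), g)
    r1 = report({"a": img}, label, spec, background_margin_mm=6.0, wall_margin_mm=3.0)
    r2 = report({"a": img}, label, spec, background_margin_mm=6.0, wall_margin_mm=3.0)
    assert r1.table.equals(r2.table)


def test_small_voi_crc_beats_full_mask_on_blurred_image():
    # the lesion center is least blurred, so a 6 mm VOI on an 8 mm lesion
    # recovers more contrast than the full mask
    g = VoxelGrid((48, 48, 56))
    spec = _sphere_spec(8.0)
    truth = rasterize_phantom(spec, g)
    blurred = ImageVolume(gaussian_filter(truth.data, 2.0), g)
    bkg = background_mask(spec, g, margin_mm=10.0, wall_margin_mm=2.0)
    full = lesion_masks(spec, g)[0]
    small = sphere_voi_mask((0.0, 0.0, 0.0), 6.0, g)
    # exclude lesion region from background explicitly
    contrast = 8.0
    c_small = crc(blurred, small, bkg, contrast)
    c_full = crc(blurred, full, bkg, contrast)
    assert c_small >= c_full
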