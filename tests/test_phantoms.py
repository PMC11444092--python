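import numpy as np
import pytest

from panelpet.grid import VoxelGrid
from panelpet.phantoms import (
    CylinderPhantomSpec,
    LesionFieldSpec,
    PhantomError,
    SphereLesion,
    load_spec,
    rasterize_phantom,
    sample_bpet_phantom,
    sample_lesion_field,
    sample_triple_ellipsoid,
    save_spec,
)
from panelpet.metrics import lesion_masks


def test_empty_cylinder_volume_matches_analytic():
    # d = 4 cm, h = 5 cm, background 1.0 on a 1 mm grid: the voxel sum
    # approximates pi * 20^2 * 50 within the voxelization tolerance
    g = VoxelGrid((48, 48, 56))
    spec = CylinderPhantomSpec(diameter_cm=4.0, height_cm=5.0, background_level=1.0)
    vol = rasterize_phantom(spec, g)
    analytic = np.pi * 20.0**2 * 50.0
    assert abs(vol.total() - analytic) / analytic < 0.01


def test_point_source_is_single_voxel():
    g = VoxelGrid((21, 21, 21))
    spec = LesionFieldSpec(
        background_level=0.0,
        background_diameter_mm=18.0,
        background_height_mm=18.0,
        lesions=[SphereLesion((0.0, 0.0, 0.0), 0.9, 7.0)],
    )
    vol = rasterize_phantom(spec, g)
    nz = np.nonzero(vol.data)
    assert len(nz[0]) == 1
    assert vol.data[10, 10, 10] == 7.0


def test_sphere_contrast_levels():
    g = VoxelGrid((48, 48, 56))
    spec = CylinderPhantomSpec(
        diameter_cm=4.0,
        height_cm=5.0,
        lesions=[SphereLesion((0.0, 5.0, 0.0), 8.0, 9.0)],
    )
    vol = rasterize_phantom(spec, g)
    inside = spec.cylinder_indicator(
        spec.to_phantom_frame(
            np.stack(np.meshgrid(*[g.axis_coords(a) for a in range(3)], indexing="ij"), -1)
        )
    )
    assert vol.data.max() == 9.0
    assert vol.data[inside].min() == 1.0


def test_rasterization_monotone_in_contrast():
    g = VoxelGrid((32, 32))
    les_lo = SphereLesion((0.0, 3.0), 6.0, 4.0)
    les_hi = SphereLesion((0.0, 3.0), 6.0, 5.5)
    lo = rasterize_phantom(LesionFieldSpec(background_diameter_mm=26, lesions=[les_lo]), g)
    hi = rasterize_phantom(LesionFieldSpec(background_diameter_mm=26, lesions=[les_hi]), g)
    assert np.all(hi.data >= lo.data)


def test_sphere_volume_converges_with_voxel_size():
    analytic = np.pi * 8.0**3 / 6.0
    errs = []
    for vs in (1.0, 0.5):
        n = int(24 / vs)
        g = VoxelGrid((n, n, n), vs)
        spec = LesionFieldSpec(
            background_level=0.0,
            background_diameter_mm=20.0,
            background_height_mm=20.0,
            lesions=[SphereLesion((0, 0, 0), 8.0, 1.0)],
        )
        vol = rasterize_phantom(spec, g)
        errs.append(abs(np.count_nonzero(vol.data) * vs**3 - analytic) / analytic)
    assert errs[1] < errs[0]
    assert errs[1] < 0.02


def test_lesion_outside_cylinder_rejected():
    g = VoxelGrid((48, 48, 56))
    spec = CylinderPhantomSpec(
        diameter_cm=4.0, lesions=[SphereLesion((18.0, 0.0, 0.0), 8.0, 9.0)]
    )
    with pytest.raises(PhantomError, match="wall clearance"):
        rasterize_phantom(spec, g)


def test_cylinder_exceeding_grid_rejected():
    g = VoxelGrid((30, 30, 30))
    spec = CylinderPhantomSpec(diameter_cm=6.0)
    with pytest.raises(PhantomError, match="exceeds"):
        rasterize_phantom(spec, g)


def test_lesion_field_deterministic_given_seed():
    g = VoxelGrid((64, 64))
    spec1, lab1 = sample_lesion_field(np.random.default_rng(7), 3, g, size_range=(5, 10))
    spec2, lab2 = sample_lesion_field(np.random.default_rng(7), 3, g, size_range=(5, 10))
    assert np.array_equal(lab1.data, lab2.data)
    assert spec1.lesions[0].effective_diameter == spec2.lesions[0].effective_diameter


def test_effective_diameter_matches_voxel_count_oracle():
    # requesting a fixed 10 mm effective diameter: count rasterized
    # lesion voxels and invert the 3D sphere volume formula
    rng = np.random.default_rng(3)
    for _ in range(3):
        les = sample_triple_ellipsoid(rng, 10.0, 5.0, (0, 0, 0), ndim=3)
        g = VoxelGrid((61, 61, 61), 0.5)
        spec = LesionFieldSpec(
            background_level=0.0,
            background_diameter_mm=27.0,
            background_height_mm=27.0,
            lesions=[les],
        )
        vol = rasterize_phantom(spec, g)
        v = np.count_nonzero(vol.data) * 0.5**3
        d_eff = (6 * v / np.pi) ** (1 / 3)
        assert abs(d_eff - 10.0) < 0.5
        assert abs(les.effective_diameter - 10.0) < 0.3


def test_lesion_field_contrasts_stay_in_range():
    g = VoxelGrid((96, 96))
    rng = np.random.default_rng(11)
    contrasts = []
    for _ in range(25):
        spec, _ = sample_lesion_field(rng, 2, g, size_range=(6, 12))
        contrasts.extend(l.contrast for l in spec.lesions)
    assert len(contrasts) == 50
    assert all(2.0 <= c <= 10.0 for c in contrasts)


def test_bpet_sampler_respects_invariants():
    rng = np.random.default_rng(5)
    specs = [sample_bpet_phantom(rng) for _ in range(30)]
    for s in specs:
        assert 4.0 <= s.diameter_cm <= 6.0
        assert 4.5 <= s.height_cm <= 5.5
        assert 1 <= len(s.lesions) <= 10
        assert abs(s.rot_x_deg) <= 6.0 and abs(s.rot_z_deg) <= 6.0
        for les in s.lesions:
            assert 2.0 <= les.diameter <= 10.0
            assert 6.0 <= les.contrast <= 10.0
    # distinct draws
    assert len({s.diameter_cm for s in specs}) > 25


def test_bpet_sampler_deterministic():
    s1 = sample_bpet_phantom(np.random.default_rng(9))
    s2 = sample_bpet_phantom(np.random.default_rng(9))
    assert s1 == s2


def test_mask_builder_agrees_with_rasterizer_exactly():
    g = VoxelGrid((64, 64))
    spec, label = sample_lesion_field(
        np.random.default_rng(21), 1, g, size_range=(8, 12), contrast_range=(4, 4)
    )
    mask = lesion_masks(spec, g, erode_voxels=0)[0].mask
    assert np.array_equal(mask, label.data == 4.0)


def test_spec_json_round_trip(tmp_path):
    g = VoxelGrid((64, 64))
    spec, label = sample_lesion_field(np.random.default_rng(2), 2, g, size_range=(6, 10))
    p = tmp_path / "spec.json"
    save_spec(spec, p)
    back = load_spec(p)
    relabel = rasterize_phantom(back, g)
    assert np.array_equal(relabel.data, label.data)
    s2 = sample_bpet_phantom(np.random.default_rng(4), ndim=3)
    save_spec(s2, p)
    b2 = load_spec(p)
    assert b2.lesions == s2.lesions and b2.rot_x_deg == s2.rot_x_deg
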