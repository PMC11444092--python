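import numpy as np
import pytest

from panelpet.grid import VoxelGrid, ImageVolume
from panelpet.phantoms import LesionFieldSpec, SphereLesion, rasterize_phantom
from panelpet.psf import (
    GaussianComponent,
    KernelGrid,
    PSFKernelParams,
    add_poisson_noise,
    default_fig1_grid,
    deform_image,
    identity_kernel_grid,
    kernel_at,
    load_kernel_grid,
    render_kernel,
    save_kernel_grid,
)
from panelpet.metrics import image_roughness


def _fwhm_of_profile(prof, step=1.0):
    prof = np.asarray(prof, float)
    m = prof.max()
    above = np.where(prof >= m / 2)[0]
    return (above[-1] - above[0] + 1) * step


# ---------------------------------------------------------------------------
# default kernel table (Fig-1-like structure)
# ---------------------------------------------------------------------------


def test_center_kernel_is_near_symmetric(kgrid2d):
    p = kernel_at(kgrid2d, (0.0, 0.0))
    assert np.linalg.norm(p.mean_shift()) < 0.5


def test_panel_kernels_mirror_in_y(grid2d, kgrid2d):
    ymax = grid2d.half_extent_mm[1] - 1.0
    top = kernel_at(kgrid2d, (0.0, +ymax))
    bot = kernel_at(kgrid2d, (0.0, -ymax))
    for ct, cb in zip(top.components, bot.components):
        assert ct.weight == cb.weight
        assert ct.sigma == cb.sigma
        assert ct.shift[1] == -cb.shift[1]
    # near-panel kernels are genuinely asymmetric (secondary component active)
    assert top.components[1].weight > 0.1
    assert abs(top.mean_shift()[1]) > 0.5


def test_elongation_normal_to_panels(grid2d, kgrid2d):
    # y-profile FWHM exceeds x-profile FWHM at every anchor
    for y in np.linspace(0, grid2d.half_extent_mm[1], 7):
        params = kernel_at(kgrid2d, (0.0, float(y)))
        kern, hw = render_kernel(params, grid2d.voxel_size)
        fx = _fwhm_of_profile(kern[:, hw[1]])
        fy = _fwhm_of_profile(kern[hw[0], :])
        assert fy > fx


# ---------------------------------------------------------------------------
# parameter interpolation
# ---------------------------------------------------------------------------


def _two_anchor_grid(shift_a, shift_b):
    """1-axis-varying 2D kernel grid with two y anchors differing only
    in the secondary component's y-shift."""
    coords = (np.array([0.0, 15.0]), np.array([0.0, 15.0]))
    vecs = []
    for s in (shift_a, shift_b):
        vecs.append([0.5, 2.0, 2.0, 0.0, 0.0, 0.5, 2.0, 2.0, 0.0, s])
    params = np.zeros((2, 2, 10))
    params[:, 0] = vecs[0]
    params[:, 1] = vecs[1]
    return KernelGrid(coords, params, (True, True), (15.0, 15.0))


def test_anchor_position_returns_anchor_params():
    kg = _two_anchor_grid(2.0, 6.0)
    p = kernel_at(kg, (0.0, 15.0))
    assert p.components[1].shift[1] == 6.0


def test_midpoint_interpolates_linearly():
    kg = _two_anchor_grid(2.0, 6.0)
    p = kernel_at(kg, (0.0, 7.5))
    assert p.components[1].shift[1] == pytest.approx(4.0)


def test_mirrored_position_negates_axis_shift():
    # a table with an x-shift: mirror in x must flip its sign
    coords = (np.array([0.0, 15.0]), np.array([0.0, 15.0]))
    vec = [0.5, 2.0, 2.0, 3.0, 0.0, 0.5, 2.0, 2.0, 1.0, 0.0]
    params = np.tile(np.asarray(vec), (2, 2, 1))
    kg = KernelGrid(coords, params, (True, True), (15.0, 15.0))
    p_pos = kernel_at(kg, (10.0, 5.0))
    p_neg = kernel_at(kg, (-10.0, 5.0))
    assert p_neg.components[0].shift[0] == -p_pos.components[0].shift[0]
    assert p_neg.components[1].shift[0] == -p_pos.components[1].shift[0]


# ---------------------------------------------------------------------------
# kernel rendering
# ---------------------------------------------------------------------------


def _single_component(sigma, shift, ndim=2):
    c1 = GaussianComponent(1.0, (sigma,) * ndim, shift)
    c2 = GaussianComponent(0.0, (sigma,) * ndim, (0.0,) * ndim)
    return PSFKernelParams((c1, c2))


def test_rendered_kernel_is_normalized_and_symmetric():
    kern, hw = render_kernel(_single_component(2.0, (0.0, 0.0)))
    assert kern.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(kern, kern[::-1, :])
    assert np.allclose(kern, kern[:, ::-1])


def test_rendered_shift_moves_center_of_mass():
    kern, hw = render_kernel(_single_component(2.0, (0.0, 5.0)))
    ys = np.arange(-hw[1], hw[1] + 1)
    com = float((kern.sum(axis=0) * ys).sum())
    assert com == pytest.approx(5.0, abs=0.1)


def test_opposed_shifts_cancel_center_of_mass():
    c1 = GaussianComponent(0.5, (2.0, 2.0), (0.0, +4.0))
    c2 = GaussianComponent(0.5, (2.0, 2.0), (0.0, -4.0))
    kern, hw = render_kernel(PSFKernelParams((c1, c2)))
    ys = np.arange(-hw[1], hw[1] + 1)
    assert abs((kern.sum(axis=0) * ys).sum()) < 1e-10


def test_degenerate_sigma_rejected():
    with pytest.raises(ValueError, match="unresolvable"):
        render_kernel(_single_component(0.1, (0.0, 0.0)))


# ---------------------------------------------------------------------------
# deformation engine
# ---------------------------------------------------------------------------


def test_identity_kernel_grid_is_exact_identity(grid2d, rng):
    img = ImageVolume(rng.random(grid2d.shape), grid2d)
    out = deform_image(img, identity_kernel_grid(grid2d))
    assert np.array_equal(out.data, img.data)


def test_point_source_reproduces_rendered_kernel(grid2d_odd):
    kg = default_fig1_grid(grid2d_odd)
    img = ImageVolume.zeros(grid2d_odd)
    img.data[32, 32] = 7.0
    out = deform_image(img, kg)
    kern, hw = render_kernel(kernel_at(kg, (0.0, 0.0)), grid2d_odd.voxel_size)
    window = out.data[32 - hw[0] : 33 + hw[0], 32 - hw[1] : 33 + hw[1]]
    assert np.allclose(window, 7.0 * kern, atol=1e-12)


def test_deform_matches_bruteforce_scatter_oracle_2d(rng):
    # the full 3D oracle-equivalence check lives in the acceptance suite;
    # this is a fast 2D version of the same comparison
    from conftest import oracle_deform, random_smooth_kernel_grid

    g = VoxelGrid((20, 18))
    img = ImageVolume(rng.random(g.shape), g)
    kg = random_smooth_kernel_grid(g, rng)
    fast = deform_image(img, kg)
    slow = oracle_deform(img, kg)
    assert np.max(np.abs(fast.data - slow.data)) <= 1e-10


def test_total_intensity_conserved_for_interior_support(grid2d, kgrid2d, rng):
    img = ImageVolume.zeros(grid2d)
    img.data[28:36, 28:36] = rng.random((8, 8)) + 0.5
    out = deform_image(img, kgrid2d)
    assert abs(out.total() - img.total()) / img.total() < 1e-6


def test_mirror_equivariance(grid2d, kgrid2d, rng):
    img = ImageVolume.zeros(grid2d)
    img.data[20:44, 12:52] = rng.random((24, 40))
    a = deform_image(ImageVolume(img.data[:, ::-1].copy(), grid2d), kgrid2d).data
    b = deform_image(img, kgrid2d).data[:, ::-1]
    assert np.max(np.abs(a - b)) < 1e-9


def test_uniform_region_stays_uniform():
    # warm disk entirely inside the constant-kernel core: no noise and no
    # spatial variation reach the interior, so the background is exactly flat
    g = VoxelGrid((160, 160))
    spec = LesionFieldSpec(background_diameter_mm=88.0, background_level=2.0)
    label = rasterize_phantom(spec, g)
    out = deform_image(label, default_fig1_grid(g))
    r = np.hypot(*np.meshgrid(g.axis_coords(0), g.axis_coords(1), indexing="ij"))
    interior = r < 20.0
    vals = out.data[interior]
    assert vals.std() / vals.mean() < 1e-9


# ---------------------------------------------------------------------------
# Poisson noise
# ---------------------------------------------------------------------------


def test_poisson_high_count_limit(grid2d, rng):
    img = ImageVolume.full(grid2d, 3.0)
    noisy = add_poisson_noise(img, 1e6, rng)
    assert np.max(np.abs(noisy.data - img.data) / img.data) < 0.01


def test_poisson_zeros_stay_zero(grid2d, rng):
    img = ImageVolume.zeros(grid2d)
    img.data[10, 10] = 5.0
    noisy = add_poisson_noise(img, 2.0, rng)
    assert np.all(noisy.data[img.data == 0] == 0)


def test_poisson_negative_input_rejected(grid2d, rng):
    img = ImageVolume.zeros(grid2d)
    img.data[0, 0] = -1.0
    with pytest.raises(ValueError):
        add_poisson_noise(img, 1.0, rng)


def test_poisson_noise_matches_cv_closed_form(rng):
    # IR% of a uniform background b at counts_scale s is 100/sqrt(b*s)
    g = VoxelGrid((128, 128))
    b, s = 2.0, 8.0
    noisy = add_poisson_noise(ImageVolume.full(g, b), s, rng)
    ir = 100.0 * noisy.data.std() / noisy.data.mean()
    expected = 100.0 / np.sqrt(b * s)
    assert g.shape[0] * g.shape[1] >= 10_000
    assert abs(ir - expected) / expected < 0.10


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_kernel_grid_yaml_round_trip(tmp_path, grid2d, kgrid2d, rng):
    p = tmp_path / "kernels.yaml"
    save_kernel_grid(kgrid2d, p)
    back = load_kernel_grid(p)
    img = ImageVolume(rng.random(grid2d.shape), grid2d)
    assert np.array_equal(deform_image(img, back).data, deform_image(img, kgrid2d).data)
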