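import numpy as np
import pytest

from panelpet.grid import VoxelGrid, ImageVolume
from panelpet.psf import KernelGrid, default_fig1_grid, kernel_at


def random_smooth_kernel_grid(grid, rng):
    """Random but smooth spatially-variant kernel table covering ``grid``."""
    nd = grid.ndim
    half = grid.half_extent_mm
    coords = tuple(np.arange(int(np.ceil(h / 15.0)) + 1) * 15.0 for h in half)
    shape = tuple(len(c) for c in coords)
    n_par = 2 * (1 + 2 * nd)
    params = np.zeros(shape + (n_par,))
    it = np.nditer(np.zeros(shape), flags=["multi_index"])
    for _ in it:
        w2 = rng.uniform(0.0, 0.5)
        s1 = rng.uniform(1.0, 2.5, nd)
        s2 = rng.uniform(1.0, 2.5, nd)
        sh1 = rng.uniform(-1.5, 1.5, nd)
        sh2 = rng.uniform(-2.0, 2.0, nd)
        params[it.multi_index] = [1 - w2, *s1, *sh1, w2, *s2, *sh2]
    return KernelGrid(coords, params, (True,) * nd, tuple(half))


def oracle_deform(image, kgrid, support_radius_sigmas=4.0):
    """Independent oracle: naive per-voxel scatter loop that renders
    each source voxel's Gaussian mixture from scratch."""
    grid = image.grid
    nd = grid.ndim
    out = np.zeros(grid.shape)
    vs = grid.voxel_size
    for idx in np.ndindex(grid.shape):
        val = image.data[idx]
        if val == 0:
            continue
        params = kernel_at(kgrid, grid.index_to_world(idx))
        comps = [c for c in params.components if c.weight > 0]
        hw = [
            max(
                1,
                max(
                    int(np.ceil((support_radius_sigmas * c.sigma[a] + abs(c.shift[a])) / vs[a]))
                    for c in comps
                ),
            )
            for a in range(nd)
        ]
        axes = [np.arange(-hw[a], hw[a] + 1) * vs[a] for a in range(nd)]
        mesh = np.meshgrid(*axes, indexing="ij", sparse=True)
        kern = np.zeros(tuple(2 * h + 1 for h in hw))
        for c in comps:
            g = np.ones_like(kern)
            for a in range(nd):
                g = g * np.exp(-0.5 * ((mesh[a] - c.shift[a]) / c.sigma[a]) ** 2)
            kern += c.weight * g
        kern /= kern.sum()
        sl_out, sl_k = [], []
        for a in range(nd):
            lo, hi = idx[a] - hw[a], idx[a] + hw[a] + 1
            sl_out.append(slice(max(lo, 0), min(hi, grid.shape[a])))
            sl_k.append(slice(max(0, -lo), kern.shape[a] - max(0, hi - grid.shape[a])))
        out[tuple(sl_out)] += val * kern[tuple(sl_k)]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid2d():
    return VoxelGrid((64, 64))


@pytest.fixture
def grid2d_odd():
    """Odd-sized grid: the central voxel sits exactly at world (0,0)."""
    return VoxelGrid((65, 65))


@pytest.fixture
def grid3d_small():
    return VoxelGrid((25, 25, 17))


@pytest.fixture
def kgrid2d(grid2d):
    return default_fig1_grid(grid2d)


@pytest.fixture
def point_image(grid2d_odd):
    img = ImageVolume.zeros(grid2d_odd)
    img.data[32, 32] = 100.0
    return img
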