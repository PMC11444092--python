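"""Spatially-variant, asymmetric point-spread-function deformation.

A dual-panel scanner's reconstructed point response is strongly
anisotropic (elongated along ``y``, the axis normal to the panels),
asymmetric, and shifted toward the nearer panel, with all of these
effects growing from the FOV center outward.  The deformation is
modeled as a Gaussian mixture of two weighted 3D (or 2D) Gaussians per
anchor point on a regular 15 mm lattice stored over the non-negative
half/quadrant/octant of the FOV and mirrored to the rest; parameters
are interpolated multilinearly between anchors.

Deformation uses the *scatter* convention: every source voxel's
activity is distributed according to the unit-sum kernel rendered at
that voxel's own world position.  This conserves total activity exactly
(up to boundary truncation) and keeps a uniform region uniform wherever
the kernel parameters are locally constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import fftconvolve

from .grid import VoxelGrid, ImageVolume

__all__ = [
    "GaussianComponent",
    "PSFKernelParams",
    "KernelGrid",
    "default_fig1_grid",
    "identity_kernel_grid",
    "kernel_at",
    "render_kernel",
    "deform_image",
    "add_poisson_noise",
    "save_kernel_grid",
    "load_kernel_grid",
]

#: anchor lattice spacing in mm
DEFAULT_ANCHOR_SPACING_MM = 15.0
#: fraction of the half-FOV (along y) over which the kernel stays constant
CORE_FRACTION = 0.6
#: default parameters of the central (near-symmetric) kernel, mm
CENTER_SIGMA = (2.0, 5.0, 2.0)
#: near-panel extremes: secondary component weight, y-shift (mm), extra y-width (mm)
PANEL_W2 = 0.45
PANEL_SHIFT_Y = 6.0
PANEL_EXTRA_SIGMA_Y = 2.0


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian of a mixture kernel: ``weight``, per-axis ``sigma``
    (mm, all > 0, or all exactly 0 for a delta component) and per-axis
    ``shift`` (mm, displacement of the component mean from the source
    voxel)."""

    weight: float
    sigma: tuple
    shift: tuple

    def __post_init__(self):
        object.__setattr__(self, "weight", float(self.weight))
        object.__setattr__(self, "sigma", tuple(float(s) for s in self.sigma))
        object.__setattr__(self, "shift", tuple(float(s) for s in self.shift))
        if self.weight < 0:
            raise ValueError(f"component weight must be >= 0, got {self.weight}")
        if any(s < 0 for s in self.sigma):
            raise ValueError(f"sigma must be >= 0 componentwise, got {self.sigma}")

    @property
    def is_delta(self) -> bool:
        return all(s == 0.0 for s in self.sigma)


@dataclass(frozen=True)
class PSFKernelParams:
    """A two-component Gaussian mixture kernel; weights sum to 1."""

    components: tuple

    def __post_init__(self):
        comps = tuple(self.components)
        if len(comps) != 2:
            raise ValueError("a PSF kernel has exactly two Gaussian components")
        wsum = comps[0].weight + comps[1].weight
        if not np.isclose(wsum, 1.0, atol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {wsum}")
        object.__setattr__(self, "components", comps)

    @property
    def ndim(self) -> int:
        return len(self.components[0].sigma)

    def mean_shift(self) -> np.ndarray:
        """Center of mass displacement of the mixture, mm."""
        return sum(
            c.weight * np.asarray(c.shift) for c in self.components
        )


# parameter vector layout per anchor: for each of the two components,
# [weight, sigma_0..sigma_{d-1}, shift_0..shift_{d-1}]
def _params_to_vector(params: PSFKernelParams) -> np.ndarray:
    out = []
    for c in params.components:
        out.extend([c.weight, *c.sigma, *c.shift])
    return np.asarray(out, dtype=np.float64)


def _vector_to_params(vec: np.ndarray, ndim: int) -> PSFKernelParams:
    stride = 1 + 2 * ndim
    comps = []
    for k in range(2):
        seg = vec[k * stride : (k + 1) * stride]
        comps.append(
            GaussianComponent(seg[0], tuple(seg[1 : 1 + ndim]), tuple(seg[1 + ndim :]))
        )
    return PSFKernelParams(tuple(comps))


@dataclass
class KernelGrid:
    """Anchor lattice of kernel parameters with mirror symmetry.

    ``anchor_coords`` holds, per axis, the non-negative anchor
    positions (mm); ``params`` is an array of shape
    ``(*n_anchors, 2*(1+2*ndim))`` holding the per-anchor parameter
    vectors; ``mirror`` flags axes whose negative side is obtained by
    mirroring (negating that axis' shift component).
    """

    anchor_coords: tuple
    params: np.ndarray
    mirror: tuple
    fov_half_mm: tuple

    def __post_init__(self):
        self.anchor_coords = tuple(np.asarray(a, dtype=float) for a in self.anchor_coords)
        self.params = np.asarray(self.params, dtype=np.float64)
        self.mirror = tuple(bool(m) for m in self.mirror)
        self.fov_half_mm = tuple(float(f) for f in self.fov_half_mm)
        nd = len(self.anchor_coords)
        if self.params.shape[:nd] != tuple(len(a) for a in self.anchor_coords):
            raise ValueError("params array does not match the anchor lattice")
        for a, half in zip(self.anchor_coords, self.fov_half_mm):
            if a[-1] < half - 1e-9:
                raise ValueError("anchor lattice does not cover the FOV after mirroring")

    @property
    def ndim(self) -> int:
        return len(self.anchor_coords)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _fig1_param_vector(y_abs: float, y_half: float, ndim: int) -> np.ndarray:
    """Parameter vector at distance ``y_abs`` from the center plane for
    a half-FOV ``y_half``: constant near-symmetric kernel within the
    core, secondary shifted component ramping up toward the panel."""
    sig = CENTER_SIGMA[:ndim] if ndim == 3 else (CENTER_SIGMA[0], CENTER_SIGMA[1])
    u = y_abs / y_half if y_half > 0 else 0.0
    t = float(_smoothstep((u - CORE_FRACTION) / (1.0 - CORE_FRACTION)))
    w2 = PANEL_W2 * t
    sigma2 = list(sig)
    sigma2[1] += PANEL_EXTRA_SIGMA_Y * t
    shift1 = [0.0] * ndim
    shift2 = [0.0] * ndim
    shift2[1] = PANEL_SHIFT_Y * t  # toward the nearer (+y) panel on the stored side
    vec = [1.0 - w2, *sig, *shift1, w2, *sigma2, *shift2]
    return np.asarray(vec, dtype=np.float64)


def default_fig1_grid(
    grid: VoxelGrid, spacing_mm: float = DEFAULT_ANCHOR_SPACING_MM
) -> KernelGrid:
    """Built-in kernel table for a generic dual-panel system.

    Near the FOV center the kernel is a single near-symmetric Gaussian
    elongated along ``y`` (normal to the panels); toward either panel a
    second component with growing weight and a growing shift toward the
    nearer panel produces strong asymmetry, while x/z widths stay
    mutually similar and symmetric.  All values are configuration
    defaults, overridable by editing or serializing the returned table.
    """
    ndim = grid.ndim
    half = grid.half_extent_mm
    coords = []
    for a in range(ndim):
        n = int(np.ceil(half[a] / spacing_mm)) + 1
        coords.append(np.arange(n) * spacing_mm)
    n_par = 2 * (1 + 2 * ndim)
    shape = tuple(len(c) for c in coords)
    params = np.zeros(shape + (n_par,))
    y_half = half[1]
    for iy, y in enumerate(coords[1]):
        vec = _fig1_param_vector(float(y), y_half, ndim)
        sl = [slice(None)] * ndim
        sl[1] = iy
        params[tuple(sl)] = vec
    return KernelGrid(tuple(coords), params, (True,) * ndim, tuple(half))


def identity_kernel_grid(grid: VoxelGrid, spacing_mm: float = DEFAULT_ANCHOR_SPACING_MM) -> KernelGrid:
    """Kernel grid of exact delta kernels (sigma = 0): deformation with
    it is the identity map."""
    ndim = grid.ndim
    half = grid.half_extent_mm
    coords = []
    for a in range(ndim):
        n = int(np.ceil(half[a] / spacing_mm)) + 1
        coords.append(np.arange(n) * spacing_mm)
    vec = np.asarray([1.0] + [0.0] * (2 * ndim) + [0.0] * (1 + 2 * ndim))
    shape = tuple(len(c) for c in coords)
    params = np.tile(vec, shape + (1,))
    return KernelGrid(tuple(coords), params, (True,) * ndim, tuple(half))


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


def _interp_vectors(kgrid: KernelGrid, positions: np.ndarray) -> np.ndarray:
    """Multilinear interpolation of anchor parameter vectors at world
    positions (N, ndim), with mirror handling and clamping.

    Uses nested lerps, so positions surrounded by identical anchors
    return bit-identical vectors (this exactness is what lets the
    deformation engine batch constant-kernel regions).
    """
    nd = kgrid.ndim
    pos = np.asarray(positions, dtype=float)
    signs = np.ones_like(pos)
    for a in range(nd):
        if kgrid.mirror[a]:
            signs[:, a] = np.where(pos[:, a] < 0, -1.0, 1.0)
    p = np.abs(pos) if all(kgrid.mirror) else np.where(signs < 0, -pos, pos)

    idx0 = []
    frac = []
    for a in range(nd):
        c = kgrid.anchor_coords[a]
        x = np.clip(p[:, a], c[0], c[-1])
        i = np.clip(np.searchsorted(c, x, side="right") - 1, 0, len(c) - 2)
        idx0.append(i)
        frac.append((x - c[i]) / (c[i + 1] - c[i]))

    # gather the 2^nd corner vectors and lerp axis by axis
    def gather(offsets):
        ind = tuple(
            np.clip(idx0[a] + offsets[a], 0, len(kgrid.anchor_coords[a]) - 1)
            for a in range(nd)
        )
        return kgrid.params[ind]

    corners = {}
    for code in range(2**nd):
        offs = [(code >> a) & 1 for a in range(nd)]
        corners[tuple(offs)] = gather(offs)
    # reduce one axis at a time
    for a in reversed(range(nd)):
        t = frac[a][:, None]
        new = {}
        for code, vec in corners.items():
            if code[a] == 1:
                continue
            hi = list(code)
            hi[a] = 1
            v0, v1 = vec, corners[tuple(hi)]
            # nested lerp: exact when v0 == v1
            new[tuple(code[:a] + code[a + 1 :])] = v0 + t * (v1 - v0)
        corners = new
    out = corners[()]

    # mirror: negate the shift components of mirrored axes
    stride = 1 + 2 * nd
    for a in range(nd):
        if kgrid.mirror[a]:
            for k in range(2):
                col = k * stride + 1 + nd + a
                out[:, col] = out[:, col] * signs[:, a]
    return out


def kernel_at(kgrid: KernelGrid, position) -> PSFKernelParams:
    """Kernel parameters at a world position (clamped to the FOV box):
    componentwise multilinear interpolation among the surrounding
    anchors after symmetry mirroring."""
    vec = _interp_vectors(kgrid, np.asarray(position, dtype=float)[None, :])[0]
    return _vector_to_params(vec, kgrid.ndim)


# ---------------------------------------------------------------------------
# kernel rendering
# ---------------------------------------------------------------------------

MIN_SIGMA_VOXELS = 0.25


def _halfwidths(vec: np.ndarray, voxel_size, support_radius_sigmas: float, ndim: int):
    stride = 1 + 2 * ndim
    hw = np.zeros(ndim, dtype=int)
    for k in range(2):
        w = vec[k * stride]
        if w <= 0:
            continue
        sig = vec[k * stride + 1 : k * stride + 1 + ndim]
        shf = vec[k * stride + 1 + ndim : (k + 1) * stride]
        for a in range(ndim):
            reach = support_radius_sigmas * sig[a] + abs(shf[a])
            hw[a] = max(hw[a], int(np.ceil(reach / voxel_size[a])))
    return np.maximum(hw, 1)


def _render_vector(vec, voxel_size, support_radius_sigmas, ndim):
    """Render a parameter vector to a discrete kernel; returns
    ``(kernel, halfwidths)`` with the kernel centered at index
    ``halfwidths`` and renormalized to sum exactly 1."""
    stride = 1 + 2 * ndim
    sig_all = np.concatenate(
        [vec[k * stride + 1 : k * stride + 1 + ndim] for k in range(2) if vec[k * stride] > 0]
    )
    if np.all(sig_all == 0.0):  # exact delta (identity deformation)
        hw = np.ones(ndim, dtype=int)
        kern = np.zeros(tuple(2 * hw + 1))
        kern[tuple(hw)] = 1.0
        return kern, hw
    for a in range(ndim):
        active = [
            vec[k * stride + 1 + a]
            for k in range(2)
            if vec[k * stride] > 0
        ]
        if any(0 < s < MIN_SIGMA_VOXELS * voxel_size[a] for s in active):
            raise ValueError(
                f"kernel sigma {min(active):.3g} mm is unresolvable on a "
                f"{voxel_size[a]} mm grid (needs >= {MIN_SIGMA_VOXELS} voxels)"
            )
    hw = _halfwidths(vec, voxel_size, support_radius_sigmas, ndim)
    axes = [np.arange(-hw[a], hw[a] + 1) * voxel_size[a] for a in range(ndim)]
    mesh = np.meshgrid(*axes, indexing="ij", sparse=True)
    kern = np.zeros(tuple(2 * hw + 1))
    for k in range(2):
        w = vec[k * stride]
        if w <= 0:
            continue
        sig = vec[k * stride + 1 : k * stride + 1 + ndim]
        shf = vec[k * stride + 1 + ndim : (k + 1) * stride]
        g = np.ones_like(kern)
        for a in range(ndim):
            g = g * np.exp(-0.5 * ((mesh[a] - shf[a]) / sig[a]) ** 2)
        kern += w * g
    total = kern.sum()
    if total <= 0:
        raise ValueError("rendered kernel has no mass inside its support")
    return kern / total, hw


def render_kernel(
    params: PSFKernelParams, voxel_size=1.0, support_radius_sigmas: float = 4.0
):
    """Discrete non-negative kernel sampled at voxel centers,
    renormalized to sum exactly 1.  Returns ``(kernel, halfwidths)``."""
    if support_radius_sigmas < 3:
        raise ValueError("support_radius_sigmas must be >= 3")
    ndim = params.ndim
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * ndim
    return _render_vector(
        _params_to_vector(params), voxel_size, support_radius_sigmas, ndim
    )


# ---------------------------------------------------------------------------
# deformation engine
# ---------------------------------------------------------------------------

#: groups at least this large are applied as a single convolution
_CONV_GROUP_MIN = 64


def deform_image(
    image: ImageVolume, kgrid: KernelGrid, support_radius_sigmas: float = 4.0
) -> ImageVolume:
    """Apply the spatially-variant PSF deformation (scatter convention).

    Each source voxel's value is distributed according to the unit-sum
    kernel at that voxel's world position; kernel mass falling outside
    the grid is truncated (not renormalized).  Regions of constant
    kernel parameters are dispatched as a single convolution, the rest
    voxel by voxel; both paths compute the identical scatter sum.
    """
    grid = image.grid
    if grid.ndim != kgrid.ndim or tuple(grid.half_extent_mm) != tuple(kgrid.fov_half_mm):
        raise ValueError("image grid does not match the kernel grid FOV")
    nz = np.nonzero(image.data)
    if len(nz[0]) == 0:
        return ImageVolume.zeros(grid)
    positions = np.stack(
        [grid.axis_coords(a)[nz[a]] for a in range(grid.ndim)], axis=-1
    )
    vecs = _interp_vectors(kgrid, positions)
    out = np.zeros(grid.shape)
    uniq, inverse = np.unique(vecs, axis=0, return_inverse=True)
    vs = grid.voxel_size
    values = image.data[nz]
    idx_arr = np.stack(nz, axis=-1)
    for g in range(len(uniq)):
        members = np.nonzero(inverse == g)[0]
        kern, hw = _render_vector(uniq[g], vs, support_radius_sigmas, grid.ndim)
        nz_k = np.nonzero(kern)
        if len(nz_k[0]) == 1 and kern[nz_k][0] == 1.0:
            # exact delta (possibly shifted by whole voxels): direct placement
            off = [int(nz_k[a][0]) - hw[a] for a in range(grid.ndim)]
            for m in members:
                tgt = idx_arr[m] + off
                if np.all(tgt >= 0) and np.all(tgt < grid.shape):
                    out[tuple(tgt)] += values[m]
        elif len(members) >= _CONV_GROUP_MIN:
            src = np.zeros(grid.shape)
            src[tuple(idx_arr[members].T)] = values[members]
            out += _convolve_same(src, kern)
        else:
            for m in members:
                _scatter_one(out, idx_arr[m], values[m], kern, hw)
    return ImageVolume(out, grid)


def _convolve_same(src: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Linear convolution cropped to the source extent: equals the
    per-voxel scatter sum with boundary truncation."""
    full = fftconvolve(src, kern, mode="full")
    hw = [(k - 1) // 2 for k in kern.shape]
    sl = tuple(slice(h, h + n) for h, n in zip(hw, src.shape))
    # FFT round-off can leave ~ -1e-17 where the result is exactly 0
    return np.maximum(full[sl], 0.0)


def _scatter_one(out, index, value, kern, hw):
    sl_out = []
    sl_k = []
    for a in range(out.ndim):
        lo = index[a] - hw[a]
        hi = index[a] + hw[a] + 1
        klo = max(0, -lo)
        khi = kern.shape[a] - max(0, hi - out.shape[a])
        sl_out.append(slice(max(lo, 0), min(hi, out.shape[a])))
        sl_k.append(slice(klo, khi))
    out[tuple(sl_out)] += value * kern[tuple(sl_k)]


def add_poisson_noise(
    image: ImageVolume, counts_scale: float, rng: np.random.Generator
) -> ImageVolume:
    """Image-domain Poisson noise: ``y = Poisson(x * s) / s`` per voxel.

    ``counts_scale`` (counts per activity unit) sets the noise level;
    the expectation is preserved and zero voxels stay exactly zero.
    """
    if counts_scale <= 0:
        raise ValueError("counts_scale must be > 0")
    if np.any(image.data < 0):
        raise ValueError("Poisson noise requires a non-negative image")
    noisy = rng.poisson(image.data * counts_scale).astype(np.float64) / counts_scale
    return ImageVolume(noisy, image.grid)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_kernel_grid(kgrid: KernelGrid, path) -> None:
    doc = {
        "anchor_coords": [list(map(float, a)) for a in kgrid.anchor_coords],
        "mirror": list(kgrid.mirror),
        "fov_half_mm": list(kgrid.fov_half_mm),
        "params": kgrid.params.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_kernel_grid(path) -> KernelGrid:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return KernelGrid(
        tuple(np.asarray(a) for a in doc["anchor_coords"]),
        np.asarray(doc["params"]),
        tuple(doc["mirror"]),
        tuple(doc["fov_half_mm"]),
    )
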