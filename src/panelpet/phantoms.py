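"""Synthetic phantom specification and rasterization.

Phantoms are declarative: a warm (or cold) cylindrical background plus a
list of hot lesions, with an optional rigid pose.  The same spec object
is consumed by the rasterizer here and by the VOI-mask builder in
:mod:`panelpet.metrics`, which guarantees that metric masks agree with
the rasterized lesion voxel sets exactly.

Two lesion families are provided:

* :class:`SphereLesion` — spherical hot spots (2–10 mm) used for the
  dual-panel breast-scanner training phantoms;
* :class:`TripleEllipsoidLesion` — irregular lesions built as the union
  of three overlapping random ellipsoids, 6–30 mm effective diameter,
  used for the generic warm-background studies.

Rasterization is binary by voxel-center (no anti-aliasing): a voxel
takes ``background_level`` inside the cylinder, ``background_level *
contrast`` inside a lesion, and 0 outside.  All geometry is specified in
mm in the phantom frame; the pose maps the phantom frame to world.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .grid import VoxelGrid, ImageVolume

__all__ = [
    "SphereLesion",
    "EllipsoidComponent",
    "TripleEllipsoidLesion",
    "CylinderPhantomSpec",
    "LesionFieldSpec",
    "LabeledPair",
    "PhantomError",
    "rasterize_phantom",
    "lesion_indicator",
    "sample_lesion_field",
    "sample_bpet_phantom",
    "save_spec",
    "load_spec",
]

#: minimum clearance (mm) between a lesion surface and the cylinder wall
WALL_CLEARANCE_MM = 2.0


@dataclass
class LabeledPair:
    """A training/test pair: ground-truth ``label`` and the deformed or
    reconstructed ``input`` on the same grid, with the originating spec
    and RNG seed for provenance."""

    label: ImageVolume
    input: ImageVolume
    spec: object = None
    seed: int | None = None

    def __post_init__(self):
        if self.label.grid != self.input.grid:
            raise ValueError("label and input must share one voxel grid")


class PhantomError(ValueError):
    """Raised when a phantom spec is geometrically infeasible."""


# ---------------------------------------------------------------------------
# lesion types
# ---------------------------------------------------------------------------


@dataclass
class SphereLesion:
    """A spherical (circular in 2D) hot lesion.

    ``center`` is in phantom-frame mm; ``diameter`` in mm; ``contrast``
    is the lesion:background activity ratio (> 1 for hot lesions).
    """

    center: tuple
    diameter: float
    contrast: float

    def __post_init__(self):
        self.center = tuple(float(c) for c in self.center)
        self.diameter = float(self.diameter)
        self.contrast = float(self.contrast)
        if self.diameter <= 0:
            raise PhantomError(f"lesion diameter must be > 0, got {self.diameter}")
        if self.contrast <= 0:
            raise PhantomError(f"lesion contrast must be > 0, got {self.contrast}")

    @property
    def bounding_radius(self) -> float:
        return self.diameter / 2.0

    def indicator(self, pts: np.ndarray) -> np.ndarray:
        """Boolean membership for points (..., ndim) in phantom-frame mm."""
        c = np.asarray(self.center[: pts.shape[-1]])
        d2 = ((pts - c) ** 2).sum(axis=-1)
        return d2 <= (self.diameter / 2.0) ** 2


def _rotmat_euler(angles_deg, ndim: int) -> np.ndarray:
    """Rotation matrix from Euler angles (z in 2D; z-y-x intrinsic in 3D)."""
    if ndim == 2:
        (az,) = angles_deg if np.iterable(angles_deg) else (angles_deg,)
        a = np.deg2rad(az)
        return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    ax, ay, az = angles_deg
    ax, ay, az = np.deg2rad([ax, ay, az])
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class EllipsoidComponent:
    """One ellipsoid of a composite lesion (offsets relative to the
    lesion center, semi-axes in mm, Euler rotation in degrees)."""

    offset: tuple
    semi_axes: tuple
    angles_deg: tuple

    def __post_init__(self):
        self.offset = tuple(float(o) for o in self.offset)
        self.semi_axes = tuple(float(s) for s in self.semi_axes)
        self.angles_deg = tuple(float(a) for a in self.angles_deg)
        if any(s <= 0 for s in self.semi_axes):
            raise PhantomError(f"semi-axes must be > 0, got {self.semi_axes}")

    @property
    def ndim(self) -> int:
        return len(self.semi_axes)

    def indicator(self, pts: np.ndarray) -> np.ndarray:
        r = _rotmat_euler(self.angles_deg, self.ndim)
        local = (pts - np.asarray(self.offset)) @ r  # r^T applied from the right
        q = (local / np.asarray(self.semi_axes)) ** 2
        return q.sum(axis=-1) <= 1.0


@dataclass
class TripleEllipsoidLesion:
    """An irregular lesion formed by the union of three overlapping
    ellipsoids sharing one contrast value.

    ``effective_diameter`` is the diameter of the sphere (circle in 2D)
    whose volume (area) equals the union volume, measured once at
    construction by fine-grid voxel counting.
    """

    center: tuple
    components: list
    contrast: float
    effective_diameter: float

    def __post_init__(self):
        self.center = tuple(float(c) for c in self.center)
        self.contrast = float(self.contrast)
        self.effective_diameter = float(self.effective_diameter)
        if len(self.components) != 3:
            raise PhantomError("a composite lesion needs exactly 3 components")

    @property
    def ndim(self) -> int:
        return self.components[0].ndim

    @property
    def bounding_radius(self) -> float:
        return max(
            float(np.linalg.norm(c.offset)) + max(c.semi_axes) for c in self.components
        )

    def indicator(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center[: pts.shape[-1]])
        local = pts - c
        out = np.zeros(pts.shape[:-1], dtype=bool)
        for comp in self.components:
            out |= comp.indicator(local)
        return out


def lesion_indicator(lesion, pts: np.ndarray) -> np.ndarray:
    """Membership of world-independent (phantom-frame) points in a lesion."""
    return lesion.indicator(pts)


# ---------------------------------------------------------------------------
# phantom specs
# ---------------------------------------------------------------------------


@dataclass
class _CylinderBase:
    """Shared geometry: a cylinder of activity with posed lesions."""

    background_level: float = 1.0
    lesions: list = field(default_factory=list)
    rot_x_deg: float = 0.0
    rot_z_deg: float = 0.0
    offset_mm: tuple = (0.0, 0.0, 0.0)

    # subclasses define radius_mm / half_height_mm properties

    def pose_matrix(self, ndim: int) -> np.ndarray:
        if ndim == 2:
            if abs(self.rot_x_deg) > 1e-12:
                raise PhantomError("x-rotation is undefined for a 2D (single-slice) grid")
            a = np.deg2rad(self.rot_z_deg)
            return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        rx = _rotmat_euler((self.rot_x_deg, 0.0, 0.0), 3)
        rz = _rotmat_euler((0.0, 0.0, self.rot_z_deg), 3)
        return rx @ rz

    def to_phantom_frame(self, world_pts: np.ndarray) -> np.ndarray:
        ndim = world_pts.shape[-1]
        r = self.pose_matrix(ndim)
        off = np.asarray(self.offset_mm[:ndim])
        return (world_pts - off) @ r  # == r^T @ (x - off)

    def cylinder_indicator(self, pts: np.ndarray) -> np.ndarray:
        ndim = pts.shape[-1]
        r2 = pts[..., 0] ** 2 + pts[..., 1] ** 2
        inside = r2 <= self.radius_mm**2
        if ndim == 3:
            inside &= np.abs(pts[..., 2]) <= self.half_height_mm
        return inside

    def validate(self, grid: VoxelGrid) -> None:
        ndim = grid.ndim
        # cylinder must fit inside the grid (conservative bounding check)
        bound = self.radius_mm + float(np.linalg.norm(self.offset_mm[:2]))
        tilt = abs(np.sin(np.deg2rad(self.rot_x_deg))) * self.half_height_mm
        half = grid.half_extent_mm
        if bound + tilt > min(half[0], half[1]) + 1e-9:
            raise PhantomError(
                f"cylinder (radius {self.radius_mm} mm) exceeds the grid extent"
            )
        if ndim == 3:
            zmax = self.half_height_mm + abs(self.offset_mm[2]) + abs(
                np.sin(np.deg2rad(self.rot_x_deg))
            ) * self.radius_mm
            if zmax > half[2] + 1e-9:
                raise PhantomError("cylinder height exceeds the axial grid extent")
        for i, les in enumerate(self.lesions):
            c = np.asarray(les.center)
            radial = float(np.hypot(c[0], c[1])) + les.bounding_radius
            if radial > self.radius_mm - WALL_CLEARANCE_MM + 1e-9:
                raise PhantomError(
                    f"lesion {i} is not strictly inside the cylinder "
                    f"(needs {WALL_CLEARANCE_MM} mm wall clearance)"
                )
            if ndim == 3 or len(c) == 3:
                if len(c) == 3 and abs(c[2]) + les.bounding_radius > (
                    self.half_height_mm - WALL_CLEARANCE_MM + 1e-9
                ):
                    raise PhantomError(f"lesion {i} exceeds the cylinder height")


@dataclass
class CylinderPhantomSpec(_CylinderBase):
    """A breast-scanner style cylindrical phantom: diameter 4–6 cm,
    height 4.5–5.5 cm, 1–10 spherical lesions of 2–10 mm at 6:1–10:1
    contrast, posed with up to ±6° rotations about x and z."""

    diameter_cm: float = 5.0
    height_cm: float = 5.0

    @property
    def radius_mm(self) -> float:
        return self.diameter_cm * 10.0 / 2.0

    @property
    def half_height_mm(self) -> float:
        return self.height_cm * 10.0 / 2.0


@dataclass
class LesionFieldSpec(_CylinderBase):
    """Generic warm-background phantom: a large cylinder of uniform
    activity holding irregular (triple-ellipsoid) lesions."""

    background_diameter_mm: float = 120.0
    background_height_mm: float = 80.0

    @property
    def radius_mm(self) -> float:
        return self.background_diameter_mm / 2.0

    @property
    def half_height_mm(self) -> float:
        return self.background_height_mm / 2.0


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _world_points(grid: VoxelGrid) -> np.ndarray:
    axes = [grid.axis_coords(a) for a in range(grid.ndim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack(mesh, axis=-1)


def rasterize_phantom(spec, grid: VoxelGrid) -> ImageVolume:
    """Rasterize a phantom spec onto ``grid`` by voxel-center membership.

    Voxels inside the cylinder get ``background_level``; voxels inside a
    lesion get ``background_level * contrast`` (for a cold background of
    0, lesion voxels get the contrast value itself); outside is 0.
    """
    spec.validate(grid)
    pts = spec.to_phantom_frame(_world_points(grid))
    out = np.zeros(grid.shape)
    bg = float(spec.background_level)
    out[spec.cylinder_indicator(pts)] = bg
    level = bg if bg > 0 else 1.0
    for les in spec.lesions:
        mask = les.indicator(pts)
        out[mask] = np.maximum(out[mask], level * les.contrast)
    return ImageVolume(out, grid)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _measure_union_size(components, ndim: int, res: float = 0.25) -> float:
    """Union volume (mm^3) / area (mm^2) of ellipsoid components by fine
    sub-grid counting — the oracle behind ``effective_diameter``."""
    r = max(float(np.linalg.norm(c.offset)) + max(c.semi_axes) for c in components)
    n = int(np.ceil(2 * r / res)) + 3
    ax = (np.arange(n) - (n - 1) / 2.0) * res
    mesh = np.meshgrid(*([ax] * ndim), indexing="ij")
    pts = np.stack(mesh, axis=-1)
    inside = np.zeros(pts.shape[:-1], dtype=bool)
    for c in components:
        inside |= c.indicator(pts)
    return float(inside.sum()) * res**ndim


def _effective_diameter(volume: float, ndim: int) -> float:
    if ndim == 2:
        return float(2.0 * np.sqrt(volume / np.pi))
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))


def sample_triple_ellipsoid(
    rng: np.random.Generator,
    effective_diameter: float,
    contrast: float,
    center,
    ndim: int = 3,
    max_tries: int = 200,
) -> TripleEllipsoidLesion:
    """Draw three random overlapping ellipsoids and rescale them so the
    union matches the requested effective diameter.

    Pairwise overlap of the components is enforced (each component
    contains a ball of its smallest semi-axis around its offset), which
    guarantees the union is connected.
    """
    target = effective_diameter / 2.0
    for _ in range(max_tries):
        comps = []
        for _k in range(3):
            semi = rng.uniform(0.5, 1.0, size=ndim) * target
            off = rng.uniform(-0.5, 0.5, size=ndim) * target
            ang = rng.uniform(0, 180, size=(1 if ndim == 2 else 3))
            comps.append(EllipsoidComponent(tuple(off), tuple(semi), tuple(ang)))
        ok = True
        for i in range(3):
            for j in range(i + 1, 3):
                di = np.linalg.norm(np.asarray(comps[i].offset) - np.asarray(comps[j].offset))
                if di >= min(comps[i].semi_axes) + min(comps[j].semi_axes):
                    ok = False
        if not ok:
            continue
        vol = _measure_union_size(comps, ndim)
        want = np.pi * target**2 if ndim == 2 else np.pi / 6.0 * effective_diameter**3
        s = (want / vol) ** (1.0 / ndim)
        scaled = [
            EllipsoidComponent(
                tuple(np.asarray(c.offset) * s),
                tuple(np.asarray(c.semi_axes) * s),
                c.angles_deg,
            )
            for c in comps
        ]
        d_eff = _effective_diameter(_measure_union_size(scaled, ndim), ndim)
        return TripleEllipsoidLesion(tuple(center), scaled, contrast, d_eff)
    raise PhantomError("failed to draw overlapping ellipsoid components")


def sample_lesion_field(
    rng: np.random.Generator,
    n_lesions: int,
    grid: VoxelGrid,
    contrast_range=(2.0, 10.0),
    size_range=(6.0, 30.0),
    background_level: float = 1.0,
    background_diameter_mm: float | None = None,
    background_height_mm: float | None = None,
    placement_radius_mm: float | None = None,
    max_tries: int = 500,
):
    """Sample a warm-background phantom with ``n_lesions`` irregular
    lesions at uniform-random in-FOV locations.

    Returns ``(spec, label)`` where ``label = rasterize_phantom(spec,
    grid)``; the spec is kept so metric masks can be rebuilt exactly.
    Lesion contrasts are drawn uniformly from ``contrast_range`` and
    effective diameters from ``size_range``.
    """
    ndim = grid.ndim
    half = grid.half_extent_mm
    if background_diameter_mm is None:
        background_diameter_mm = 2.0 * 0.92 * min(half[0], half[1])
    if background_height_mm is None:
        background_height_mm = 2.0 * 0.92 * half[2] if ndim == 3 else 2.0
    radius = background_diameter_mm / 2.0
    lesions = []
    for _ in range(n_lesions):
        d_eff = float(rng.uniform(*size_range))
        contrast = float(rng.uniform(*contrast_range))
        placed = False
        for _try in range(max_tries):
            # draw a center, then check wall clearance and lesion overlap
            rmax = placement_radius_mm if placement_radius_mm is not None else radius
            center = rng.uniform(-rmax, rmax, size=ndim)
            les = sample_triple_ellipsoid(rng, d_eff, contrast, tuple(center), ndim)
            radial = float(np.hypot(center[0], center[1])) + les.bounding_radius
            if radial > radius - WALL_CLEARANCE_MM:
                continue
            if ndim == 3 and abs(center[2]) + les.bounding_radius > (
                background_height_mm / 2.0 - WALL_CLEARANCE_MM
            ):
                continue
            clash = False
            for other in lesions:
                gap = np.linalg.norm(np.asarray(other.center) - center)
                if gap < other.bounding_radius + les.bounding_radius + 2.0:
                    clash = True
                    break
            if not clash:
                lesions.append(les)
                placed = True
                break
        if not placed:
            raise PhantomError(
                f"could not place a {d_eff:.1f} mm lesion inside the "
                f"{background_diameter_mm:.0f} mm background after {max_tries} tries"
            )
    spec = LesionFieldSpec(
        background_level=background_level,
        lesions=lesions,
        background_diameter_mm=background_diameter_mm,
        background_height_mm=background_height_mm,
    )
    return spec, rasterize_phantom(spec, grid)


def sample_bpet_phantom(
    rng: np.random.Generator,
    ndim: int = 3,
    diameter_range_cm=(4.0, 6.0),
    height_range_cm=(4.5, 5.5),
    n_lesion_range=(1, 10),
    lesion_diameter_range_mm=(2.0, 10.0),
    contrast_range=(6.0, 10.0),
    max_rotation_deg: float = 6.0,
    max_offset_mm: float = 2.0,
    max_tries: int = 500,
) -> CylinderPhantomSpec:
    """Draw a random breast-scanner training phantom: a 4–6 cm cylinder
    with 1–10 spherical lesions (2–10 mm, 6:1–10:1 contrast), rotated by
    up to ±6° about x and z and slightly offset in the FOV."""
    diam = float(rng.uniform(*diameter_range_cm))
    height = float(rng.uniform(*height_range_cm))
    radius_mm = diam * 10 / 2
    n = int(rng.integers(n_lesion_range[0], n_lesion_range[1] + 1))
    lesions = []
    for _ in range(n):
        d = float(rng.uniform(*lesion_diameter_range_mm))
        c = float(rng.uniform(*contrast_range))
        for _try in range(max_tries):
            rmax = radius_mm - WALL_CLEARANCE_MM - d / 2
            center = rng.uniform(-rmax, rmax, size=ndim)
            if np.hypot(center[0], center[1]) > rmax:
                continue
            if ndim == 3:
                zmax = height * 10 / 2 - WALL_CLEARANCE_MM - d / 2
                if abs(center[2]) > zmax:
                    continue
            les = SphereLesion(tuple(center), d, c)
            clash = any(
                np.linalg.norm(np.asarray(o.center) - center)
                < o.diameter / 2 + d / 2 + 1.0
                for o in lesions
            )
            if not clash:
                lesions.append(les)
                break
        else:
            raise PhantomError(f"could not place a {d:.1f} mm lesion after retries")
    rot_x = float(rng.uniform(-max_rotation_deg, max_rotation_deg)) if ndim == 3 else 0.0
    rot_z = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
    off = rng.uniform(-max_offset_mm, max_offset_mm, size=3)
    if ndim == 2:
        off[2] = 0.0
    return CylinderPhantomSpec(
        background_level=1.0,
        lesions=lesions,
        rot_x_deg=rot_x,
        rot_z_deg=rot_z,
        offset_mm=tuple(off),
        diameter_cm=diam,
        height_cm=height,
    )


# ---------------------------------------------------------------------------
# JSON side-car serialization
# ---------------------------------------------------------------------------

_SPEC_CLASSES = {"CylinderPhantomSpec": CylinderPhantomSpec, "LesionFieldSpec": LesionFieldSpec}


def _lesion_to_dict(les) -> dict:
    d = asdict(les)
    d["__type__"] = type(les).__name__
    return d


def _lesion_from_dict(d: dict):
    kind = d.pop("__type__")
    if kind == "SphereLesion":
        return SphereLesion(**d)
    comps = [EllipsoidComponent(**c) for c in d.pop("components")]
    return TripleEllipsoidLesion(components=comps, **d)


def save_spec(spec, path) -> None:
    d = asdict(spec)
    d["lesions"] = [_lesion_to_dict(l) for l in spec.lesions]
    d["__type__"] = type(spec).__name__
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def load_spec(path):
    with open(path) as fh:
        d = json.load(fh)
    cls = _SPEC_CLASSES[d.pop("__type__")]
    lesions = [_lesion_from_dict(l) for l in d.pop("lesions")]
    for key in ("offset_mm",):
        if key in d:
            d[key] = tuple(d[key])
    return cls(lesions=lesions, **d)
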