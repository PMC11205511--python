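"""Digitized test shapes with closed-form descriptor oracles.

Spheres, ellipsoids and boxes have analytic surface area, volume and axis
lengths, so every descriptor value is known in closed form; dumbbells (two
overlapping spheres) provide a concave shape with no simple closed form,
standing in for the constricted membrane geometry of a dividing cell.
Voxelization is by center inclusion: a voxel is occupied iff its center
lies inside the continuous shape, matching the binary-mask semantics of
segmented microscopy data.

Shapes are centered on a lattice corner so that integer-sized axis-aligned
shapes digitize to their exact physical extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .descriptors import (
    DEFAULT_ROUNDNESS_CONSTANT,
    DescriptorSet,
    compute_descriptors,
)
from .geometry import AxisFrame, BasicParams, CellShapeError, VoxelRegion

__all__ = [
    "OracleUnavailableError",
    "ShapeSpec",
    "sphere",
    "ellipsoid",
    "box",
    "dumbbell",
    "voxelize",
    "analytic_descriptors",
    "division_sequence",
    "sphere_sequence",
]

THOMSEN_P = 1.6075  # ellipsoid surface-area approximation exponent, error < 1.1%


class OracleUnavailableError(CellShapeError):
    """No closed-form descriptor oracle exists for this shape kind."""


@dataclass
class ShapeSpec:
    """A continuous 3D shape to digitize.

    ``kind`` is one of ``sphere`` (radius), ``ellipsoid`` (semiaxes
    A >= B >= C), ``box`` (edge lengths) or ``dumbbell`` (two sphere radii
    plus center separation; connected iff separation < r1 + r2).
    ``euler_deg`` rotates the shape (xyz intrinsic angles, degrees).
    ``noise`` jitters the metric parameters by a relative Gaussian factor
    drawn from ``seed`` — a crude stand-in for biological variability;
    the analytic oracle always refers to the nominal (un-jittered) shape.
    """

    kind: str
    radius: Optional[float] = None
    semiaxes: Optional[Tuple[float, float, float]] = None
    edges: Optional[Tuple[float, float, float]] = None
    radii: Optional[Tuple[float, float]] = None
    separation: Optional[float] = None
    euler_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "ellipsoid", "box", "dumbbell"):
            raise CellShapeError(f"unknown shape kind {self.kind!r}")
        if isinstance(self.spacing, (int, float)):
            self.spacing = (float(self.spacing),) * 3
        params = {
            "sphere": (self.radius,),
            "ellipsoid": self.semiaxes or (None,),
            "box": self.edges or (None,),
            "dumbbell": tuple(self.radii or (None,)) + (self.separation,),
        }[self.kind]
        if any(p is None or p <= 0 for p in params if p != 0) or any(
            p is None for p in params
        ):
            raise CellShapeError(f"invalid parameters for kind {self.kind!r}")
        if self.kind == "dumbbell" and self.separation >= sum(self.radii):
            raise CellShapeError(
                "dumbbell separation must be < r1 + r2 for a connected shape"
            )


def sphere(radius: float, **kw) -> ShapeSpec:
    return ShapeSpec(kind="sphere", radius=radius, **kw)


def ellipsoid(a: float, b: float, c: float, **kw) -> ShapeSpec:
    """Semiaxes in descending order (a >= b >= c)."""
    return ShapeSpec(kind="ellipsoid", semiaxes=(a, b, c), **kw)


def box(lx: float, ly: float, lz: float, **kw) -> ShapeSpec:
    return ShapeSpec(kind="box", edges=(lx, ly, lz), **kw)


def dumbbell(r1: float, r2: float, separation: float, **kw) -> ShapeSpec:
    return ShapeSpec(kind="dumbbell", radii=(r1, r2), separation=separation, **kw)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _effective_params(spec: ShapeSpec) -> dict:
    """Nominal parameters, jittered when noise is requested."""
    p = {
        "radius": spec.radius,
        "semiaxes": spec.semiaxes,
        "edges": spec.edges,
        "radii": spec.radii,
        "separation": spec.separation,
    }
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)

        def jit(x):
            return x * float(
                np.clip(1.0 + rng.normal(0.0, spec.noise), 0.5, 1.5)
            )

        if spec.kind == "sphere":
            # noisy spheres become mildly anisotropic ellipsoids
            r = p["radius"]
            p["semiaxes"] = tuple(jit(r) for _ in range(3))
        elif spec.kind == "ellipsoid":
            p["semiaxes"] = tuple(jit(x) for x in p["semiaxes"])
        elif spec.kind == "box":
            p["edges"] = tuple(jit(x) for x in p["edges"])
        elif spec.kind == "dumbbell":
            p["radii"] = tuple(jit(x) for x in p["radii"])
            p["separation"] = min(jit(p["separation"]), 0.95 * sum(p["radii"]))
    return p


def _bounding_radius(spec: ShapeSpec, p: dict) -> float:
    if spec.kind == "sphere":
        return max(p["semiaxes"]) if p.get("semiaxes") and spec.noise > 0 else p["radius"]
    if spec.kind == "ellipsoid":
        return max(p["semiaxes"])
    if spec.kind == "box":
        return 0.5 * math.sqrt(sum(e**2 for e in p["edges"]))
    return p["separation"] / 2.0 + max(p["radii"])


def _axis_extents(spec: ShapeSpec, p: dict) -> Tuple[float, float, float]:
    """Nominal extents along the shape's local axes."""
    if spec.kind == "sphere" and not (spec.noise > 0):
        return (2 * p["radius"],) * 3
    if spec.kind in ("sphere", "ellipsoid"):
        return tuple(2 * x for x in p["semiaxes"])
    if spec.kind == "box":
        return tuple(p["edges"])
    r1, r2 = p["radii"]
    w = 2 * max(r1, r2)
    return (p["separation"] + r1 + r2, w, w)


def _inside(spec: ShapeSpec, p: dict, local: np.ndarray) -> np.ndarray:
    if spec.kind == "sphere" and not (spec.noise > 0):
        return (local**2).sum(axis=1) <= p["radius"] ** 2
    if spec.kind == "sphere" or spec.kind == "ellipsoid":
        ax = np.asarray(p["semiaxes"], dtype=float)
        return ((local / ax) ** 2).sum(axis=1) <= 1.0
    if spec.kind == "box":
        half = 0.5 * np.asarray(p["edges"], dtype=float)
        return np.all(np.abs(local) <= half, axis=1)
    # dumbbell: union of two spheres with centers on the first axis
    r1, r2 = p["radii"]
    half_sep = p["separation"] / 2.0
    c1 = np.array([-half_sep, 0.0, 0.0])
    c2 = np.array([half_sep, 0.0, 0.0])
    in1 = ((local - c1) ** 2).sum(axis=1) <= r1**2
    in2 = ((local - c2) ** 2).sum(axis=1) <= r2**2
    return in1 | in2


def voxelize(
    spec: ShapeSpec,
    margin: int = 2,
    grid_shape: Optional[Tuple[int, int, int]] = None,
    label: int = 1,
    time_index: Optional[int] = None,
) -> VoxelRegion:
    """Digitize a shape spec onto a voxel grid (center-inclusion rule).

    The grid is sized automatically to contain the rotated shape plus
    ``margin`` voxels per face, with the shape centered on a lattice
    corner; an explicit ``grid_shape`` that cannot contain the shape
    raises a size error.  Deterministic for a fixed spec (and seed).
    """
    p = _effective_params(spec)
    spacing = np.asarray(spec.spacing, dtype=float)
    bound = _bounding_radius(spec, p)
    rot = Rotation.from_euler("xyz", spec.euler_deg, degrees=True).as_matrix()

    if grid_shape is None:
        # per-axis grid parity follows the nominal extent so integer-sized
        # axis-aligned shapes digitize to their exact voxel counts: an even
        # extent centers the shape on a lattice corner, an odd one on a
        # voxel center
        ext_world = np.abs(rot) @ np.asarray(_axis_extents(spec, p))
        half_n = np.ceil(bound / spacing).astype(int) + margin
        shape = 2 * half_n + (np.rint(ext_world / spacing).astype(int) % 2)
    else:
        shape = np.asarray(grid_shape, dtype=int)
        if np.any(shape * spacing < 2 * bound):
            raise CellShapeError(
                f"shape of extent {2 * bound:.3f} exceeds grid {tuple(shape)}"
            )
    origin = -0.5 * shape * spacing  # shape centered at the grid midpoint

    axes = [
        origin[k] + (np.arange(shape[k]) + 0.5) * spacing[k] for k in range(3)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1)
    rot = Rotation.from_euler("xyz", spec.euler_deg, degrees=True).as_matrix()
    local = centers @ rot  # world -> shape frame (rot is orthogonal)
    mask = _inside(spec, p, local).reshape(tuple(shape))
    if not mask.any():
        raise CellShapeError("shape digitized to an empty mask (too small for grid)")

    # crop tight, preserving physical placement
    occ = np.argwhere(mask)
    lo = occ.min(axis=0)
    hi = occ.max(axis=0) + 1
    mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return VoxelRegion(
        mask=mask,
        spacing=spacing,
        origin=origin + lo * spacing,
        label=label,
        time_index=time_index,
    )


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------


def _thomsen_area(a: float, b: float, c: float) -> float:
    p = THOMSEN_P
    return 4.0 * math.pi * (
        ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    ) ** (1.0 / p)


def analytic_descriptors(
    spec: ShapeSpec,
    roundness_constant: float = DEFAULT_ROUNDNESS_CONSTANT,
) -> DescriptorSet:
    """Closed-form descriptor values for the continuous (nominal) shape.

    Exact for spheres and boxes; the ellipsoid surface area uses the
    Thomsen approximation (relative error below 1.1%).  Dumbbells have no
    simple closed form and raise :class:`OracleUnavailableError`.
    """
    if spec.kind == "sphere":
        r = spec.radius
        S = 4.0 * math.pi * r**2
        V = 4.0 / 3.0 * math.pi * r**3
        abc = (2.0 * r,) * 3
    elif spec.kind == "ellipsoid":
        A, B, C = sorted(spec.semiaxes, reverse=True)
        S = _thomsen_area(A, B, C)
        V = 4.0 / 3.0 * math.pi * A * B * C
        abc = (2.0 * A, 2.0 * B, 2.0 * C)
    elif spec.kind == "box":
        l1, l2, l3 = sorted(spec.edges, reverse=True)
        S = 2.0 * (l1 * l2 + l1 * l3 + l2 * l3)
        V = l1 * l2 * l3
        abc = (l1, l2, l3)
    else:
        raise OracleUnavailableError(
            f"no closed-form oracle for kind {spec.kind!r}"
        )
    params = BasicParams(
        S=S,
        V=V,
        S_convex=S,  # these shapes are convex
        V_convex=V,
        axes=AxisFrame(directions=np.eye(3), lengths=np.asarray(abc)),
        centroid=np.zeros(3),
    )
    return compute_descriptors(params, roundness_constant)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------


def random_shape(rng: np.random.Generator) -> ShapeSpec:
    """One randomly parameterized, randomly oriented shape spec.

    Kinds are drawn uniformly from sphere/ellipsoid/box/dumbbell with
    metric parameters in the 4–12 voxel range, the scale regime of early
    embryonic cells at typical confocal sampling.
    """
    kind = rng.choice(["sphere", "ellipsoid", "box", "dumbbell"])
    euler = tuple(rng.uniform(0, 90, size=3))
    if kind == "sphere":
        return sphere(rng.uniform(4, 9), euler_deg=euler)
    if kind == "ellipsoid":
        semi = np.sort(rng.uniform(4, 10, size=3))[::-1]
        return ellipsoid(*semi, euler_deg=euler)
    if kind == "box":
        edges = rng.uniform(4, 12, size=3)
        return box(*edges, euler_deg=euler)
    r1, r2 = rng.uniform(4, 7, size=2)
    sep = rng.uniform(0.4, 0.9) * (r1 + r2)
    return dumbbell(r1, r2, sep, euler_deg=euler)


def division_sequence(
    n_frames: int = 5,
    radius: float = 10.0,
    spacing: float = 1.0,
    seed: Optional[int] = None,
    noise: float = 0.0,
    euler_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> list:
    """Frames of a sphere deforming into a thinning-necked dumbbell.

    Emulates cytokinesis geometry: the cell body elongates while a
    contractile neck forms at the equator.  Frame ``t`` in [0, 1]
    interpolates lobe radius from the initial sphere radius toward the
    volume-conserving two-daughter radius (2^(-1/3) of it) and grows the
    lobe separation, so the elongation ratio increases monotonically.
    ``noise`` applies one random scale factor per sequence to the lobe
    separation (seeded), leaving within-sequence monotonicity intact.
    """
    if n_frames < 3:
        raise CellShapeError("a division sequence needs at least 3 frames")
    rng = np.random.default_rng(seed)
    sep_scale = 1.0
    rad_scale = 1.0
    if noise > 0:
        sep_scale = float(np.clip(1.0 + rng.normal(0.0, noise), 0.7, 1.3))
        rad_scale = float(np.clip(1.0 + rng.normal(0.0, noise), 0.7, 1.3))
    frames = []
    for k in range(n_frames):
        t = k / (n_frames - 1)
        r_t = radius * rad_scale * (1.0 - (1.0 - 2.0 ** (-1.0 / 3.0)) * t)
        sep_t = 1.7 * t * r_t * sep_scale
        if sep_t <= 0:
            spec = sphere(r_t, spacing=spacing, euler_deg=euler_deg)
        else:
            spec = dumbbell(
                r_t, r_t, min(sep_t, 1.95 * r_t), spacing=spacing,
                euler_deg=euler_deg,
            )
        frames.append(voxelize(spec, time_index=k))
    return frames


def sphere_sequence(
    n_frames: int = 5,
    radius: float = 10.0,
    spacing: float = 1.0,
    seed: Optional[int] = None,
    noise: float = 0.0,
) -> list:
    """A non-dividing control: the same (optionally jittered) round cell
    repeated over time.

    The jitter is drawn once per sequence, so all frames of one track are
    identical digitizations — a resting cell whose shape does not change —
    while different seeds give different cells.
    """
    rng = np.random.default_rng(seed)
    semi = np.full(3, float(radius))
    if noise > 0:
        semi = semi * np.clip(1.0 + rng.normal(0.0, noise, size=3), 0.8, 1.2)
    semi = np.sort(semi)[::-1]
    spec = ellipsoid(*semi, spacing=spacing)
    region = voxelize(spec)
    return [
        VoxelRegion(
            mask=region.mask,
            spacing=region.spacing,
            origin=region.origin,
            label=region.label,
            time_index=k,
        )
        for k in range(n_frames)
    ]
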