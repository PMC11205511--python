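"""Voxel-region geometry: meshing, convex hull, principal axes.

This module turns one segmented cell (a binary voxel occupancy grid with
physical spacing) into the four groups of basic geometric parameters that
every dimensionless shape descriptor consumes:

1. surface area ``S`` — sum of triangle areas of the marching-cubes
   boundary mesh;
2. volume ``V`` — space enclosed by that mesh (divergence theorem);
3. convex-hull surface area and volume ``S_convex``, ``V_convex`` —
   the same two measurements applied to the convex hull of the mesh;
4. triaxial lengths ``a >= b >= c`` — extents of the region along the
   principal directions of the voxel-center point cloud (PCA), i.e. the
   edge lengths of the oriented bounding box.

Conventions used throughout the package:

* masks are indexed in array order (axis 0, 1, 2); when a volume comes
  from a multi-page TIFF this order is (z, y, x);
* voxel index ``i`` occupies the half-open physical interval
  ``[i*s, (i+1)*s)``; its center is at ``origin + (i + 0.5) * spacing``;
* all physical quantities are in micrometres (lengths), μm² (areas) and
  μm³ (volumes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

logger = logging.getLogger("cellshape3d")

__all__ = [
    "CellShapeError",
    "EmptyRegionError",
    "OpenMeshError",
    "DegenerateHullError",
    "VoxelRegion",
    "SurfaceMesh",
    "AxisFrame",
    "BasicParams",
    "extract_regions",
    "triangulate_surface",
    "surface_area",
    "enclosed_volume",
    "convex_hull_of_points",
    "convex_hull_mesh",
    "principal_axes",
    "centroid",
    "basic_params",
]


class CellShapeError(ValueError):
    """Base class for all domain errors raised by this package."""


class EmptyRegionError(CellShapeError):
    """A region with no occupied voxel (or a volume with no labels)."""


class OpenMeshError(CellShapeError):
    """A mesh with boundary edges where a closed surface is required."""


class DegenerateHullError(CellShapeError):
    """Point set is coplanar/collinear; a 3D convex hull does not exist."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VoxelRegion:
    """One cell's binary occupancy grid with physical placement.

    Parameters
    ----------
    mask
        3D boolean array, ``True`` where the cell occupies a voxel.  Stored
        tight (cropped to the occupied bounding box); a one-voxel zero
        margin is added internally before meshing so the surface is closed.
    spacing
        Voxel edge lengths per mask axis, in μm; strictly positive.
    origin
        Physical coordinate of grid index (0, 0, 0), in μm.
    label
        Integer identifier of the cell in the source label volume.
    time_index
        Optional frame number for time-lapse data.
    """

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    label: int = 1
    time_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise CellShapeError(f"mask must be 3D, got ndim={self.mask.ndim}")
        if not self.mask.any():
            raise EmptyRegionError("region has no occupied voxel")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise CellShapeError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        """Physical volume of a single voxel, μm³."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """(n, 3) physical coordinates of occupied voxel centers."""
        idx = np.argwhere(self.mask)
        return (idx + 0.5) * self.spacing + self.origin

    def translated(self, offset: Sequence[float]) -> "VoxelRegion":
        """Same region rigidly shifted by ``offset`` μm."""
        return VoxelRegion(
            mask=self.mask,
            spacing=self.spacing,
            origin=self.origin + np.asarray(offset, dtype=float),
            label=self.label,
            time_index=self.time_index,
        )


@dataclass
class SurfaceMesh:
    """Closed triangulated boundary: vertices in μm, triangle index triples."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise CellShapeError("triangle indices out of range")
            if np.any(
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            ):
                raise CellShapeError("triangle with repeated vertex index")

    def edge_counts(self) -> dict:
        """Undirected edge -> number of incident triangles."""
        counts: dict = {}
        for tri in self.triangles:
            for k in range(3):
                e = (int(tri[k]), int(tri[(k + 1) % 3]))
                e = (min(e), max(e))
                counts[e] = counts.get(e, 0) + 1
        return counts

    def is_closed(self) -> bool:
        return all(c == 2 for c in self.edge_counts().values())

    def euler_characteristic(self) -> int:
        n_v = len(np.unique(self.triangles))
        n_e = len(self.edge_counts())
        n_f = len(self.triangles)
        return n_v - n_e + n_f


@dataclass
class AxisFrame:
    """Orthonormal principal directions with sorted extents a >= b >= c."""

    directions: np.ndarray  # rows are unit vectors
    lengths: np.ndarray  # (a, b, c), μm

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float).reshape(3, 3)
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        gram = self.directions @ self.directions.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise CellShapeError("axis directions are not orthonormal")
        if not (self.lengths[0] >= self.lengths[1] >= self.lengths[2] > 0):
            raise CellShapeError(
                f"axis lengths must satisfy a >= b >= c > 0, got {self.lengths}"
            )

    @property
    def a(self) -> float:
        return float(self.lengths[0])

    @property
    def b(self) -> float:
        return float(self.lengths[1])

    @property
    def c(self) -> float:
        return float(self.lengths[2])


@dataclass
class BasicParams:
    """The four basic parameter groups plus the centroid, for one region."""

    S: float
    V: float
    S_convex: float
    V_convex: float
    axes: AxisFrame
    centroid: np.ndarray
    label: int = 1
    time_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)
        if self.V <= 0:
            raise CellShapeError(f"volume must be positive, got {self.V}")
        if self.S <= 0:
            raise CellShapeError(f"surface area must be positive, got {self.S}")
        # hull encloses the region; small fp slack only
        if self.V > self.V_convex * (1 + 1e-9):
            raise CellShapeError(
                f"V={self.V} exceeds V_convex={self.V_convex}"
            )


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------


def extract_regions(
    volume: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> list:
    """Split a labelled integer volume into per-cell :class:`VoxelRegion`.

    Label 0 is background.  Each region's mask is cropped to its bounding
    box, with the origin shifted so physical coordinates are preserved.
    Labels are taken as given: disconnected voxels sharing a label stay one
    region (a warning is logged).
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise CellShapeError(f"label volume must be 3D, got ndim={volume.ndim}")
    if not np.issubdtype(volume.dtype, np.integer) and volume.dtype != bool:
        raise CellShapeError(f"label volume must be integer, got {volume.dtype}")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)

    labels = np.unique(volume)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise EmptyRegionError("no regions: volume contains no nonzero label")

    regions = []
    for lab in labels:
        mask = volume == lab
        slc = ndimage.find_objects(mask.astype(np.int8))[0]
        cropped = mask[slc]
        start = np.array([s.start for s in slc], dtype=float)
        n_comp = ndimage.label(cropped)[1]
        if n_comp > 1:
            logger.warning(
                "label %d has %d disconnected components; kept as one region",
                int(lab),
                n_comp,
            )
        regions.append(
            VoxelRegion(
                mask=cropped,
                spacing=spacing,
                origin=origin + start * spacing,
                label=int(lab),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# surface mesh, area, volume
# ---------------------------------------------------------------------------


def _fairing_iterations(mask_shape: Sequence[int]) -> int:
    """Taubin iteration count scaled with region size.

    Marching cubes on a binary mask produces a staircase surface whose
    area overestimates the true boundary by a resolution-independent ~9%,
    so the raw mesh is faired with the volume-preserving Taubin filter.
    The staircase wavelength is fixed at one voxel while the shape scale
    grows, so the iteration budget scales with the mean bounding-box
    extent (clipped to [10, 60]); regions under 4 voxels across are left
    unsmoothed — fairing would collapse them.
    """
    mean_ext = float(np.mean(mask_shape))
    if mean_ext < 4:
        return 0
    return int(np.clip(round(mean_ext), 10, 60))


def triangulate_surface(
    region: VoxelRegion,
    smooth: bool = True,
    iterations: Optional[int] = None,
) -> SurfaceMesh:
    """Closed, outward-oriented mesh of the occupancy iso-surface.

    The binary mask is zero-padded by one voxel on every face so the 0.5
    iso-surface is closed, then meshed with marching cubes at iso-level
    0.5 using the region's physical spacing, and faired with a Taubin
    (shrink-free Laplacian) filter to remove the voxel staircase
    (``smooth=False`` returns the raw marching-cubes mesh).  Vertices are
    in physical coordinates.
    """
    padded = np.pad(region.mask, 1).astype(np.float32)
    verts, faces, _normals, _values = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(region.spacing)
    )
    # padded index j samples the center of original voxel j - 1, which sits
    # at origin + (j - 0.5) * spacing
    verts = verts + region.origin - 0.5 * region.spacing
    if smooth:
        n_iter = (
            _fairing_iterations(region.mask.shape)
            if iterations is None
            else iterations
        )
        if n_iter > 0:
            tm = trimesh.Trimesh(verts, faces, process=False)
            trimesh.smoothing.filter_taubin(
                tm, lamb=0.5, nu=0.53, iterations=n_iter
            )
            verts = np.asarray(tm.vertices)
    mesh = SurfaceMesh(vertices=verts, triangles=faces)
    if _signed_volume(mesh) < 0:
        mesh.triangles = mesh.triangles[:, [0, 2, 1]]
    return mesh


def _signed_volume(mesh: SurfaceMesh) -> float:
    v = mesh.vertices[mesh.triangles]
    return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0)


def surface_area(mesh: SurfaceMesh) -> float:
    """Sum of triangle areas, μm².  Degenerate triangles contribute zero."""
    v = mesh.vertices[mesh.triangles]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    area = float(0.5 * np.linalg.norm(cross, axis=1).sum())
    if area <= 0:
        raise CellShapeError("mesh has zero total area (all triangles degenerate)")
    return area


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Volume enclosed by a closed oriented mesh (divergence theorem), μm³."""
    if not mesh.is_closed():
        raise OpenMeshError("mesh has boundary edges; enclosed volume undefined")
    vol = abs(_signed_volume(mesh))
    if vol <= 0:
        raise CellShapeError("mesh encloses zero volume")
    return vol


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------


def convex_hull_of_points(points: np.ndarray) -> SurfaceMesh:
    """Triangulated, outward-oriented convex hull of a 3D point cloud."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateHullError(
            f"degenerate hull (coplanar or collinear points): {exc}"
        ) from exc
    used = np.unique(hull.simplices)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = points[used]
    tris = remap[hull.simplices]
    # orient every face outward (away from the hull centroid)
    center = verts.mean(axis=0)
    v = verts[tris]
    normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    inward = np.einsum("ij,ij->i", normals, v.mean(axis=1) - center) < 0
    tris[inward] = tris[inward][:, [0, 2, 1]]
    return SurfaceMesh(vertices=verts, triangles=tris)


def convex_hull_mesh(region: VoxelRegion, mesh: Optional[SurfaceMesh] = None) -> SurfaceMesh:
    """Convex hull of the region's surface-mesh vertices.

    Passing the already-computed boundary ``mesh`` avoids re-meshing.
    The hull's enclosed volume is >= the region mesh volume by construction.
    """
    if mesh is None:
        mesh = triangulate_surface(region)
    return convex_hull_of_points(mesh.vertices)


# ---------------------------------------------------------------------------
# principal axes and centroid
# ---------------------------------------------------------------------------

_TIE_REL_TOL = 1e-9


def _grid_aligned_basis(eigvals: np.ndarray, eigvecs: np.ndarray) -> np.ndarray:
    """Resolve degenerate eigenvalue subspaces toward the grid axes.

    For exactly repeated eigenvalues (spheres, cubes) any orthonormal basis
    of the degenerate subspace is a valid eigenbasis; for determinism we
    pick the one closest to the grid axes.
    """
    scale = max(float(eigvals.sum()), np.finfo(float).tiny)
    groups = []
    start = 0
    for i in range(1, 3):
        if abs(eigvals[i] - eigvals[i - 1]) > _TIE_REL_TOL * scale:
            groups.append(list(range(start, i)))
            start = i
    groups.append(list(range(start, 3)))

    out = eigvecs.copy()
    for g in groups:
        if len(g) == 1:
            continue
        if len(g) == 3:
            return np.eye(3)
        # 2D degenerate subspace: project grid axes into it, keep the best
        sub = eigvecs[:, g]  # 3x2 basis
        proj = sub @ (sub.T @ np.eye(3))  # projections of e_k, columns
        norms = np.linalg.norm(proj, axis=0)
        u1 = proj[:, int(np.argmax(norms))]
        u1 = u1 / np.linalg.norm(u1)
        other = [i for i in range(3) if i not in g][0]
        u2 = np.cross(eigvecs[:, other], u1)
        u2 = u2 / np.linalg.norm(u2)
        out[:, g[0]] = u1
        out[:, g[1]] = u2
    return out


def principal_axes(
    region: VoxelRegion, mesh: Optional[SurfaceMesh] = None
) -> AxisFrame:
    """PCA axis frame: covariance directions, oriented-bounding-box extents.

    The covariance matrix of the physical voxel-center coordinates (with
    the unbiased 1/(n-1) normalization) is diagonalized; eigenvectors
    sorted by descending eigenvalue give the directions.  The length along
    each direction is the extent (max - min) of the boundary-mesh vertices
    projected onto it — the edge lengths of the oriented bounding box of
    the region's surface.  The raw (unfaired) marching-cubes mesh is used
    here: its faces lie exactly on the physical boundary planes, so an
    axis-aligned W x H x D box of unit voxels measures exactly (W, H, D)
    and one-voxel-thick slabs keep a positive short axis.  Passing a
    precomputed raw boundary ``mesh`` avoids re-meshing.

    A single-voxel region has no sample covariance; by convention it gets
    grid-aligned directions with lengths equal to the (sorted) spacing.
    """
    coords = region.voxel_centers()
    n = len(coords)
    if n == 1:
        order = np.argsort(region.spacing)[::-1]
        return AxisFrame(directions=np.eye(3)[order], lengths=region.spacing[order])

    cov = np.cov(coords.T, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    eigvals = eigvals[::-1]
    eigvecs = eigvecs[:, ::-1]
    eigvecs = _grid_aligned_basis(eigvals, eigvecs)

    if mesh is None:
        mesh = triangulate_surface(region, smooth=False)

    directions = []
    lengths = []
    for k in range(3):
        d = eigvecs[:, k]
        if d[np.argmax(np.abs(d))] < 0:  # deterministic sign
            d = -d
        proj = mesh.vertices @ d
        directions.append(d)
        lengths.append(float(proj.max() - proj.min()))

    order = np.argsort(lengths)[::-1]  # guarantee a >= b >= c
    directions = np.array(directions)[order]
    lengths = np.array(lengths)[order]
    return AxisFrame(directions=directions, lengths=lengths)


def centroid(region: VoxelRegion) -> np.ndarray:
    """Mass center: unweighted mean of occupied voxel-center coordinates, μm."""
    return region.voxel_centers().mean(axis=0)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


def basic_params(region: VoxelRegion) -> BasicParams:
    """Compute all basic geometric parameters for one region.

    S, V and the convex hull are measured on the faired boundary mesh;
    the axis extents use the raw marching-cubes mesh, whose faces lie
    exactly on the physical boundary planes.
    """
    mesh = triangulate_surface(region)
    raw_mesh = triangulate_surface(region, smooth=False)
    hull = convex_hull_mesh(region, mesh=mesh)
    return BasicParams(
        S=surface_area(mesh),
        V=enclosed_volume(mesh),
        S_convex=surface_area(hull),
        V_convex=enclosed_volume(hull),
        axes=principal_axes(region, mesh=raw_mesh),
        centroid=centroid(region),
        label=region.label,
        time_index=region.time_index,
    )
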