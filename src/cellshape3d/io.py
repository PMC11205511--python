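"""File I/O and run configuration.

Label volumes travel as multi-page TIFF stacks of unsigned integers, one
page per z-slice, stacked in (z, y, x) axis order.  Descriptor tables go
out as CSV (6 significant digits, locale-independent) or JSON (full
precision); meshes can be exported as ASCII PLY.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .descriptors import DEFAULT_ROUNDNESS_CONSTANT
from .geometry import CellShapeError, SurfaceMesh
from .tracking import DEFAULT_FRAME_INTERVAL_MIN

logger = logging.getLogger("cellshape3d")

__all__ = [
    "RunConfig",
    "read_label_volume",
    "write_label_volume",
    "write_table",
    "write_mesh_ply",
]


@dataclass
class RunConfig:
    """Reproducible-run settings shared by the CLI subcommands.

    spacing
        Voxel edge lengths (sx, sy, sz) in μm; the source dataset is
        isotropic at 0.25 μm.
    frame_interval_min
        Time between consecutive frames, minutes (dataset cadence 1.39).
    connectivity
        Voxel adjacency used as "direct contact" in the perturbation
        protocol: 6 (faces), 18 or 26.
    roundness_constant
        Normalization constant of the Hayakawa roundness (6 calibrates a
        perfect sphere to 1).
    """

    spacing: Tuple[float, float, float] = (0.25, 0.25, 0.25)
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    connectivity: int = 6
    roundness_constant: float = DEFAULT_ROUNDNESS_CONSTANT
    output_format: str = "csv"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.spacing, (int, float)):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise CellShapeError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.frame_interval_min <= 0:
            raise CellShapeError("frame_interval_min must be positive")
        if self.connectivity not in (6, 18, 26):
            raise CellShapeError(
                f"connectivity must be 6, 18 or 26, got {self.connectivity}"
            )
        if self.output_format not in ("csv", "json"):
            raise CellShapeError(f"output_format must be csv or json")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CellShapeError(f"unknown config keys: {sorted(unknown)}")
        if "spacing" in data:
            data["spacing"] = tuple(data["spacing"])
        return cls(**data)


def read_label_volume(path: Union[str, Path]) -> np.ndarray:
    """Read a multi-page TIFF of integer labels as a (z, y, x) grid."""
    grid = tifffile.imread(str(path))
    if grid.ndim == 2:
        grid = grid[np.newaxis]
    if grid.ndim != 3:
        raise CellShapeError(
            f"label volume must stack to 3D, got ndim={grid.ndim}"
        )
    if not np.issubdtype(grid.dtype, np.integer):
        raise CellShapeError(
            f"label volume must have an integer pixel type, got {grid.dtype}"
        )
    return grid


def write_label_volume(path: Union[str, Path], grid: np.ndarray) -> None:
    """Write a (z, y, x) integer grid as a multi-page TIFF."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise CellShapeError(f"grid must be 3D, got ndim={grid.ndim}")
    if not np.issubdtype(grid.dtype, np.integer):
        raise CellShapeError(f"grid must be integer, got {grid.dtype}")
    tifffile.imwrite(str(path), grid, photometric="minisblack")


def write_table(
    df: pd.DataFrame, path: Union[str, Path], fmt: Optional[str] = None
) -> None:
    """Write a results table as CSV (6 significant digits) or JSON (full)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.6g")
    elif fmt == "json":
        df.to_json(path, orient="records", indent=2)
    else:
        raise CellShapeError(f"unknown table format {fmt!r}")


def write_mesh_ply(mesh: SurfaceMesh, path: Union[str, Path]) -> None:
    """Export a triangle mesh as ASCII PLY."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
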