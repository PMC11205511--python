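"""The 12 dimensionless shape descriptors for a 3D cell region.

Every descriptor is a ratio of the basic geometric parameters
(S, V, S_convex, V_convex, a, b, c), so all are invariant under isotropic
rescaling.  Grouped by what they measure:

sphericity (gross closeness to a ball)
    general sphericity      (36 π V²)^(1/3) / S
    diameter sphericity     (6 V / π)^(1/3) / a
    intercept sphericity    (b c / a²)^(1/3)
    max-projection sphericity  (c² / (a b))^(1/3)
roundness (edge/corner sharpness, not elongation)
    Hayakawa roundness      C · (V/S) / (a b c)^(1/3)
convex hull (protrusions / concavities)
    spreading index         (36 π V_convex²)^(1/3) / S_convex
shape factors (axis-ratio anisotropy)
    elongation ratio        a / b
    pivotability index      c / b        (a.k.a. rollability)
    Wilson flatness         c / a
    Hayakawa flatness ratio (a + b) / (2 c)
    Huang shape factor      (b + c) / (2 a)
    Corey shape factor      c / sqrt(a b)

The Hayakawa roundness normalization constant ``C`` is configurable and
defaults to 6, which calibrates a perfect sphere (V/S = R/3,
(abc)^(1/3) = 2R) to score exactly 1; the raw un-normalized ratio
(V/S)/(abc)^(1/3) is recorded alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .geometry import BasicParams, CellShapeError, VoxelRegion, basic_params

logger = logging.getLogger("cellshape3d")

__all__ = [
    "DEFAULT_ROUNDNESS_CONSTANT",
    "DESCRIPTOR_NAMES",
    "DescriptorSet",
    "compute_descriptors",
    "descriptor_table",
]

DEFAULT_ROUNDNESS_CONSTANT = 6.0

#: Stable column order of the 12 descriptors in every tabular output.
DESCRIPTOR_NAMES = (
    "general_sphericity",
    "diameter_sphericity",
    "intercept_sphericity",
    "max_projection_sphericity",
    "hayakawa_roundness",
    "spreading_index",
    "elongation_ratio",
    "pivotability_index",
    "wilson_flatness",
    "hayakawa_flatness_ratio",
    "huang_shape_factor",
    "corey_shape_factor",
)


@dataclass
class DescriptorSet:
    """The 12 named descriptor values plus the basic parameters they use."""

    general_sphericity: float
    diameter_sphericity: float
    intercept_sphericity: float
    max_projection_sphericity: float
    hayakawa_roundness: float
    spreading_index: float
    elongation_ratio: float
    pivotability_index: float
    wilson_flatness: float
    hayakawa_flatness_ratio: float
    huang_shape_factor: float
    corey_shape_factor: float
    hayakawa_roundness_raw: float
    roundness_constant: float
    params: Optional[BasicParams] = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}

    def __getitem__(self, name: str) -> float:
        if name not in DESCRIPTOR_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _require_positive(value: float, name: str) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise CellShapeError(f"descriptor domain error: {name}={value} must be > 0")


def compute_descriptors(
    params: BasicParams,
    roundness_constant: float = DEFAULT_ROUNDNESS_CONSTANT,
) -> DescriptorSet:
    """Evaluate all 12 descriptors from one region's basic parameters.

    Sphericities may exceed 1 by a small mesh-discretization margin; values
    above 1.001 trigger a warning but are reported as-is.
    """
    S, V = params.S, params.V
    Sc, Vc = params.S_convex, params.V_convex
    a, b, c = params.axes.a, params.axes.b, params.axes.c
    for value, name in ((S, "S"), (V, "V"), (Sc, "S_convex"), (Vc, "V_convex"),
                        (a, "a"), (b, "b"), (c, "c")):
        _require_positive(value, name)

    raw_roundness = (V / S) / (a * b * c) ** (1.0 / 3.0)
    ds = DescriptorSet(
        general_sphericity=(36.0 * math.pi * V**2) ** (1.0 / 3.0) / S,
        diameter_sphericity=(6.0 * V / math.pi) ** (1.0 / 3.0) / a,
        intercept_sphericity=(b * c / a**2) ** (1.0 / 3.0),
        max_projection_sphericity=(c**2 / (a * b)) ** (1.0 / 3.0),
        hayakawa_roundness=roundness_constant * raw_roundness,
        spreading_index=(36.0 * math.pi * Vc**2) ** (1.0 / 3.0) / Sc,
        elongation_ratio=a / b,
        pivotability_index=c / b,
        wilson_flatness=c / a,
        hayakawa_flatness_ratio=(a + b) / (2.0 * c),
        huang_shape_factor=(b + c) / (2.0 * a),
        corey_shape_factor=c / math.sqrt(a * b),
        hayakawa_roundness_raw=raw_roundness,
        roundness_constant=roundness_constant,
        params=params,
    )
    for name in ("general_sphericity", "spreading_index"):
        val = getattr(ds, name)
        if val > 1.001:
            logger.warning(
                "%s = %.6f exceeds 1.001 (mesh discretization); reported as-is",
                name,
                val,
            )
    return ds


def descriptor_table(
    regions: Iterable[VoxelRegion],
    roundness_constant: float = DEFAULT_ROUNDNESS_CONSTANT,
) -> pd.DataFrame:
    """Batch-evaluate descriptors: one row per region, input order preserved.

    A failing region produces a row with its label and the error message;
    the batch continues.
    """
    basic_cols = ("S", "V", "S_convex", "V_convex", "a", "b", "c",
                  "cx", "cy", "cz")
    rows = []
    for region in regions:
        row: dict = {"label": region.label, "time_index": region.time_index,
                     "error": None}
        try:
            params = basic_params(region)
            ds = compute_descriptors(params, roundness_constant)
        except CellShapeError as exc:
            row["error"] = str(exc)
            logger.warning("region label=%s failed: %s", region.label, exc)
            rows.append(row)
            continue
        # centroid is stored in mask-axis order (z, y, x) for TIFF input
        cz, cy, cx = params.centroid
        row.update(
            S=params.S, V=params.V,
            S_convex=params.S_convex, V_convex=params.V_convex,
            a=params.axes.a, b=params.axes.b, c=params.axes.c,
            cx=cx, cy=cy, cz=cz,
        )
        row.update(ds.as_dict())
        rows.append(row)
    columns = (["label", "time_index"] + list(basic_cols)
               + list(DESCRIPTOR_NAMES) + ["error"])
    return pd.DataFrame(rows, columns=columns)
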