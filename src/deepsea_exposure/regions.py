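"""Geospatial support: geodesic buffers, depth-band masks, percent overlap.

These are the operations behind statistics such as "what fraction of a ridge
region lies inside a fisheries-management area" or "what fraction of a depth
band is trawlable": boolean cell masks on the analysis grid, combined and
compared by cell count or by spherical cell area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shapely_transform

from ._geo import aeqd_forward, aeqd_inverse, distance_to_meters
from .grid import Grid, RegionSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CellMask:
    """Boolean membership per grid cell, with provenance."""

    grid: Grid
    member: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValidationError("mask shape must match grid shape")

    def count(self) -> int:
        return int(self.member.sum())

    def __or__(self, other: "CellMask") -> "CellMask":
        if self.grid != other.grid:
            raise ValidationError("masks on different grids")
        return CellMask(grid=self.grid, member=self.member | other.member,
                        provenance=f"({self.provenance})|({other.provenance})")

    def __and__(self, other: "CellMask") -> "CellMask":
        if self.grid != other.grid:
            raise ValidationError("masks on different grids")
        return CellMask(grid=self.grid, member=self.member & other.member,
                        provenance=f"({self.provenance})&({other.provenance})")


def buffer_region(geometry: BaseGeometry, distance: float,
                  unit: str = "nautical_mile",
                  quad_segs: int = 64) -> BaseGeometry:
    """Geodesic buffer of a point/line/polygon by ``distance`` in ``unit``.

    The geometry is projected into a spherical azimuthal-equidistant frame
    centred on its representative point — distances from the centre are exact
    there — buffered in metres, and projected back. Boundary points lie at
    the requested distance to well within 0.5% for regional-scale geometries.

    ``unit`` is one of nautical_mile (default, the standard in maritime
    delimitation), statute_mile, km, m; record the unit you used.
    """
    if distance < 0:
        raise ValidationError("buffer distance must be >= 0")
    if distance == 0:
        return geometry
    meters = distance_to_meters(distance, unit)
    centre = geometry.centroid
    lon0, lat0 = float(centre.x), float(centre.y)

    def fwd(x, y, z=None):
        return aeqd_forward(np.asarray(x), np.asarray(y), lon0, lat0)

    def inv(x, y, z=None):
        return aeqd_inverse(np.asarray(x), np.asarray(y), lon0, lat0)

    projected = shapely_transform(fwd, geometry)
    buffered = projected.buffer(meters, quad_segs=quad_segs)
    return shapely_transform(inv, buffered)


def depth_band_mask(bathymetry: np.ndarray, grid: Grid,
                    band: tuple[float, float]) -> CellMask:
    """Cells whose depth (metres, positive down) lies in [min_m, max_m]."""
    lo, hi = band
    if not lo < hi:
        raise ValidationError("depth band min must be < max")
    bathymetry = np.asarray(bathymetry, dtype=float)
    if bathymetry.shape != grid.shape:
        raise ValidationError("bathymetry shape must match grid")
    member = np.isfinite(bathymetry) & (bathymetry >= lo) & (bathymetry <= hi)
    if not np.any(np.isfinite(bathymetry)):
        logger.warning("bathymetry entirely masked; empty depth-band mask")
    return CellMask(grid=grid, member=member,
                    provenance=f"depth_band({lo},{hi})")


def overlap_percent(mask_a: CellMask, mask_b: CellMask,
                    weighting: str = "cells") -> float:
    """Directional overlap: 100 * |A ∩ B| / |A|, the fraction of A inside B.

    ``weighting="cells"`` counts member cells; ``weighting="area"`` weights
    each cell by its spherical area. Raises if A is empty (undefined).
    """
    if mask_a.grid != mask_b.grid:
        raise ValidationError("masks on different grids")
    if weighting not in ("cells", "area"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    a, b = mask_a.member, mask_b.member
    if weighting == "cells":
        denom = float(a.sum())
        num = float((a & b).sum())
    else:
        areas = mask_a.grid.cell_areas_km2()
        denom = float(areas[a].sum())
        num = float(areas[a & b].sum())
    if denom == 0:
        raise ValidationError("overlap_percent undefined: first mask is empty")
    return 100.0 * num / denom


def mask_from_regions(regions: RegionSet, grid: Grid,
                      category: str | None = None,
                      name: str | None = None) -> CellMask:
    """Cell-centre membership mask for regions selected by category or name.

    Multiple matching regions are unioned (element-wise OR).
    """
    if category is None and name is None:
        raise ValidationError("select regions by category or by name")
    selected = [r for r in regions
                if (name is not None and r.name == name)
                or (category is not None and r.category == category)]
    if not selected:
        raise ValidationError(
            f"no region matches selector (category={category!r}, name={name!r})")
    lon2d, lat2d = grid.mesh()
    member = np.zeros(grid.shape, dtype=bool)
    for r in selected:
        member |= shapely.contains_xy(r.geometry, lon2d.ravel(), lat2d.ravel()
                                      ).reshape(grid.shape)
    prov = "|".join(r.name for r in selected)
    return CellMask(grid=grid, member=member, provenance=prov)
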