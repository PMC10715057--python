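"""Gap-centre-aligned kernel density rasters of stem locations.

Each stem contributes a quartic (biweight) bump of compact support equal to
the search radius (default 1 m). The kernel is normalised in two dimensions,

    K(u) = (3 / pi) (1 - u**2)**2   for u <= 1,

so each point's bump integrates to one stem over the plane and cell values
are summed intensity in stems per m². A probability-density mode (divide by
the point count) and a literal 1/(p r) mode are available for comparison;
the latter reproduces the dimensionally one-dimensional normaliser sometimes
printed alongside this estimator and is not recommended for density maps.

Replicate gaps are compared by aligning their rasters on the shared
gap-centre origin and averaging cellwise over the rasters that cover each
cell.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ConfigurationError, Layer, ShadeTolerance, StemMap


@dataclass
class KdeRaster:
    """Regular density raster. ``values[row, col]`` with row 0 the
    northernmost row (ESRI ASCII convention); ``origin`` is the lower-left
    corner of the grid."""

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols), stems m^-2
    search_radius: float
    coverage: np.ndarray | None = None  # rasters covering each cell (averages)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (west->east) and y (north->south, row order)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return xs, ys

    def integral(self) -> float:
        """Total mass: sum of cell values times cell area (stems)."""
        return float(self.values.sum() * self.cell_size**2)

    def max(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0

    def to_long_dataframe(self) -> pd.DataFrame:
        xs, ys = self.cell_centers()
        xx, yy = np.meshgrid(xs, ys)
        return pd.DataFrame({
            "x": xx.ravel(), "y": yy.ravel(), "density": self.values.ravel(),
        })

    def write_asc(self, path, nodata: float = -9999.0) -> None:
        """ESRI ASCII grid (.asc)."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.origin[0]:.6f}\n")
            fh.write(f"yllcorner {self.origin[1]:.6f}\n")
            fh.write(f"cellsize {self.cell_size:.6f}\n")
            fh.write(f"NODATA_value {nodata:.1f}\n")
            for row in self.values:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _quartic_profile(u: np.ndarray) -> np.ndarray:
    """2-D quartic kernel profile (3/pi)(1-u^2)^2 on u <= 1, else 0."""
    out = np.zeros_like(u)
    inside = u <= 1.0
    out[inside] = (3.0 / math.pi) * (1.0 - u[inside] ** 2) ** 2
    return out


Extent = tuple[float, float, float, float]  # xmin, xmax, ymin, ymax


def _snap_extent(extent: Extent, cell_size: float) -> Extent:
    """Expand the extent outward onto the cell lattice anchored at 0."""
    xmin, xmax, ymin, ymax = extent
    f = lambda v, up: (math.ceil(v / cell_size) if up
                       else math.floor(v / cell_size)) * cell_size
    return (f(xmin, False), f(xmax, True), f(ymin, False), f(ymax, True))


def kde_raster(points, search_radius: float = 1.0, cell_size: float = 0.25,
               extent: Extent | None = None,
               mode: Literal["stems", "probability", "literal"] = "stems"
               ) -> KdeRaster:
    """Kernel density raster of a point set.

    ``extent`` is (xmin, xmax, ymin, ymax); by default the points' bounding
    box padded by the search radius, snapped outward to the cell lattice so
    that rasters from replicate gaps align. ``cell_size`` must not exceed
    half the search radius (resolution guard). With ``mode='stems'`` the
    raster integral equals the number of contributing points (to midpoint-
    rule accuracy).
    """
    if search_radius <= 0:
        raise ConfigurationError("search radius must be positive")
    if cell_size <= 0 or cell_size > search_radius / 2 + 1e-12:
        raise ConfigurationError(
            f"cell size {cell_size} m too coarse for search radius "
            f"{search_radius} m (must be <= radius/2)"
        )
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if extent is None:
        if len(pts) == 0:
            extent = (-1.0, 1.0, -1.0, 1.0)
        else:
            extent = (pts[:, 0].min() - search_radius, pts[:, 0].max() + search_radius,
                      pts[:, 1].min() - search_radius, pts[:, 1].max() + search_radius)
    xmin, xmax, ymin, ymax = _snap_extent(extent, cell_size)
    n_cols = max(1, int(round((xmax - xmin) / cell_size)))
    n_rows = max(1, int(round((ymax - ymin) / cell_size)))
    values = np.zeros((n_rows, n_cols))
    xs = xmin + (np.arange(n_cols) + 0.5) * cell_size
    ys = ymin + (n_rows - np.arange(n_rows) - 0.5) * cell_size

    r = search_radius
    reach = int(math.ceil(r / cell_size)) + 1
    for px, py in pts:
        ci = int((px - xmin) / cell_size)
        rj = int(n_rows - 1 - (py - ymin) / cell_size)
        c0, c1 = max(0, ci - reach), min(n_cols, ci + reach + 1)
        r0, r1 = max(0, rj - reach), min(n_rows, rj + reach + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xs[c0:c1] - px
        dy = ys[r0:r1] - py
        u = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2) / r
        values[r0:r1, c0:c1] += _quartic_profile(u)

    if mode == "stems":
        values /= r**2
    elif mode == "probability":
        values /= r**2 * max(1, len(pts))
    elif mode == "literal":
        # the 1/(p r) normaliser printed with the 1-D form of this estimator
        values /= r * max(1, len(pts))
    else:
        raise ConfigurationError(f"unknown KDE mode {mode!r}")
    return KdeRaster(origin=(xmin, ymin), cell_size=cell_size, values=values,
                     search_radius=search_radius)


def align_and_average(rasters: Sequence[KdeRaster]) -> KdeRaster:
    """Cellwise mean of gap-centred rasters from replicate gaps.

    Rasters must share the cell size and sit on the same lattice. The output
    covers the union extent; each cell is averaged over the rasters whose
    extent covers it (coverage counts are reported in ``coverage``), so a
    small gap does not dilute the mean outside its own footprint.
    """
    rasters = list(rasters)
    if not rasters:
        raise ConfigurationError("no rasters to average")
    cs = rasters[0].cell_size
    for r in rasters[1:]:
        if abs(r.cell_size - cs) > 1e-12:
            raise ConfigurationError("rasters have mismatched cell sizes")
    for r in rasters:
        for v in r.origin:
            if abs(v / cs - round(v / cs)) > 1e-6:
                raise ConfigurationError("raster origins not on a shared lattice")

    xmin = min(r.origin[0] for r in rasters)
    ymin = min(r.origin[1] for r in rasters)
    xmax = max(r.origin[0] + r.n_cols * cs for r in rasters)
    ymax = max(r.origin[1] + r.n_rows * cs for r in rasters)
    n_cols = int(round((xmax - xmin) / cs))
    n_rows = int(round((ymax - ymin) / cs))
    total = np.zeros((n_rows, n_cols))
    cover = np.zeros((n_rows, n_cols), dtype=int)
    for r in rasters:
        c0 = int(round((r.origin[0] - xmin) / cs))
        r1 = n_rows - int(round((r.origin[1] - ymin) / cs))  # bottom row + 1
        r0 = r1 - r.n_rows
        total[r0:r1, c0:c0 + r.n_cols] += r.values
        cover[r0:r1, c0:c0 + r.n_cols] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cover > 0, total / np.maximum(cover, 1), 0.0)
    return KdeRaster(origin=(xmin, ymin), cell_size=cs, values=mean,
                     search_radius=rasters[0].search_radius, coverage=cover)


GroupKey = tuple[ShadeTolerance, Layer]


def density_by_group(stem_map: StemMap, search_radius: float = 1.0,
                     cell_size: float = 0.25,
                     extent: Extent | None = None
                     ) -> dict[GroupKey, KdeRaster]:
    """One density raster per non-empty (shade tolerance x layer) group.

    The shared extent defaults to the plot window's bounding box padded by
    the search radius, so group rasters partition the stems and their
    integrals sum to the plot total.
    """
    if extent is None:
        xmin, ymin, xmax, ymax = stem_map.window.bbox
        extent = (xmin - search_radius, xmax + search_radius,
                  ymin - search_radius, ymax + search_radius)
    groups: dict[GroupKey, list[tuple[float, float]]] = {}
    for s in stem_map.stems:
        groups.setdefault((s.shade_tolerance, s.layer), []).append((s.x, s.y))
    return {
        key: kde_raster(np.array(pts), search_radius, cell_size, extent)
        for key, pts in sorted(groups.items(),
                               key=lambda kv: (kv[0][0].value, kv[0][1].value))
    }
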