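"""Domain types and stem-map I/O for gap-regeneration analysis.

Conventions used throughout the package:

* Coordinates are local metres in a gap-centred Cartesian system:
  origin at the gap (or plot) centre, +X east, +Y north.
* Every censused stem is taller than the 0.1 m cutoff; shorter recruits
  are outside the census definition and rejected at read time.
* Three vertical layers partition the censused height range with
  half-open bounds: lower [0.1, 5) m, medium [5, 10) m, upper [10, inf).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HEIGHT_CUTOFF = 0.1
"""Census height cutoff in metres: only stems strictly taller are recorded."""

BREAST_HEIGHT = 1.3
"""Height (m) above which stems carry a DBH rather than a root-collar diameter."""


class GrowthForm(str, Enum):
    tree = "tree"
    shrub = "shrub"


class ShadeTolerance(str, Enum):
    light_demanding = "light_demanding"
    intermediate = "intermediate"
    shade_tolerant = "shade_tolerant"


class Layer(str, Enum):
    """Vertical layer: lower [0.1, 5) m, medium [5, 10) m, upper [10, inf) m."""

    lower = "lower"
    medium = "medium"
    upper = "upper"


class DiameterKind(str, Enum):
    dbh = "dbh"
    rcd = "rcd"


class Treatment(str, Enum):
    """Six study treatments: young/old gaps and closed-canopy controls in
    primary (P) and secondary (S) forest."""

    PYG = "PYG"
    POG = "POG"
    PCK = "PCK"
    SYG = "SYG"
    SOG = "SOG"
    SCK = "SCK"

    @property
    def is_control(self) -> bool:
        return self in (Treatment.PCK, Treatment.SCK)


LAYER_BOUNDS: dict[Layer, tuple[float, float]] = {
    Layer.lower: (HEIGHT_CUTOFF, 5.0),
    Layer.medium: (5.0, 10.0),
    Layer.upper: (10.0, math.inf),
}


class StemMapFormatError(ValueError):
    """Malformed stem-map file: missing/unknown columns."""


class StemMapParseError(ValueError):
    """Unparseable value in a stem-map row."""


class GeometryError(ValueError):
    """Stems outside the observation window, or inconsistent geometry."""


class ConfigurationError(ValueError):
    """Invalid parameter combination."""


def assign_layer(height: float) -> Layer:
    """Vertical layer of a stem of the given height (m).

    Bounds are half-open so that every censused height belongs to exactly
    one layer: lower [0.1, 5), medium [5, 10), upper [10, inf).
    """
    if not np.isfinite(height) or height <= HEIGHT_CUTOFF:
        raise ValueError(
            f"height {height!r} is at or below the census cutoff of {HEIGHT_CUTOFF} m"
        )
    if height < 5.0:
        return Layer.lower
    if height < 10.0:
        return Layer.medium
    return Layer.upper


@dataclass(frozen=True)
class Stem:
    """One censused woody individual.

    Coordinates ``x``/``y`` are metres east/north of the gap centre,
    ``height`` in metres, ``diameter`` in cm (DBH for stems at or above
    breast height, root-collar diameter otherwise).
    """

    stem_id: str
    species: str
    growth_form: GrowthForm
    shade_tolerance: ShadeTolerance
    x: float
    y: float
    height: float
    diameter: float
    diameter_kind: DiameterKind

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"stem {self.stem_id}: non-finite coordinates")
        if not np.isfinite(self.height) or self.height <= HEIGHT_CUTOFF:
            raise ValueError(
                f"stem {self.stem_id}: height {self.height} at or below the "
                f"{HEIGHT_CUTOFF} m census cutoff"
            )
        if not np.isfinite(self.diameter) or self.diameter < 0:
            raise ValueError(f"stem {self.stem_id}: negative diameter")

    @property
    def layer(self) -> Layer:
        return assign_layer(self.height)

    @property
    def basal_area_m2(self) -> float:
        """Cross-sectional area in m² from the diameter in cm."""
        return math.pi * (self.diameter / 200.0) ** 2


class WindowShape(str, Enum):
    rectangle = "rectangle"
    ellipse = "ellipse"


@dataclass(frozen=True)
class Window:
    """Observation window: an axis-aligned rectangle or ellipse.

    ``half_extents`` are (half-width, half-height) for a rectangle and the
    semi-axes (a, b) for an ellipse.
    """

    shape: WindowShape
    center: tuple[float, float]
    half_extents: tuple[float, float]

    def __post_init__(self) -> None:
        a, b = self.half_extents
        if a <= 0 or b <= 0:
            raise ValueError("window half-extents must be positive")

    @classmethod
    def rectangle(cls, width: float, height: float,
                  center: tuple[float, float] = (0.0, 0.0)) -> "Window":
        return cls(WindowShape.rectangle, center, (width / 2.0, height / 2.0))

    @classmethod
    def ellipse(cls, a: float, b: float,
                center: tuple[float, float] = (0.0, 0.0)) -> "Window":
        return cls(WindowShape.ellipse, center, (a, b))

    @classmethod
    def ellipse_from_area(cls, area: float, aspect: float = 1.0,
                          center: tuple[float, float] = (0.0, 0.0)) -> "Window":
        """Ellipse of the given area (m²) with semi-axis ratio b/a = aspect."""
        if area <= 0 or aspect <= 0:
            raise ValueError("area and aspect must be positive")
        a = math.sqrt(area / (math.pi * aspect))
        return cls(WindowShape.ellipse, center, (a, a * aspect))

    @property
    def area(self) -> float:
        a, b = self.half_extents
        if self.shape is WindowShape.rectangle:
            return 4.0 * a * b
        return math.pi * a * b

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        cx, cy = self.center
        a, b = self.half_extents
        return (cx - a, cy - b, cx + a, cy + b)

    def contains(self, x, y) -> np.ndarray:
        """Vectorised point-in-window test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cx, cy = self.center
        a, b = self.half_extents
        dx, dy = x - cx, y - cy
        if self.shape is WindowShape.rectangle:
            tol = 1e-9
            return (np.abs(dx) <= a + tol) & (np.abs(dy) <= b + tol)
        return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0 + 1e-9

    def boundary_distance(self, x, y) -> np.ndarray:
        """Distance from interior points to the window boundary.

        Exact for rectangles. For ellipses the boundary is sampled densely
        (1024 vertices) and the minimum vertex distance returned; the chord
        error is far below the distance-grid resolution used downstream.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        cx, cy = self.center
        a, b = self.half_extents
        if self.shape is WindowShape.rectangle:
            return np.minimum(a - np.abs(x - cx), b - np.abs(y - cy))
        theta = np.linspace(0.0, 2.0 * math.pi, 1024, endpoint=False)
        bx = cx + a * np.cos(theta)
        by = cy + b * np.sin(theta)
        d2 = (x[:, None] - bx[None, :]) ** 2 + (y[:, None] - by[None, :]) ** 2
        return np.sqrt(d2.min(axis=1))

    def translate(self, dx: float, dy: float) -> "Window":
        cx, cy = self.center
        return replace(self, center=(cx + dx, cy + dy))

    def to_shapely(self):
        """Shapely polygon for geometric set operations (quadrat clipping)."""
        from shapely.geometry import Point, box

        cx, cy = self.center
        a, b = self.half_extents
        if self.shape is WindowShape.rectangle:
            return box(cx - a, cy - b, cx + a, cy + b)
        from shapely import affinity

        circle = Point(cx, cy).buffer(1.0, quad_segs=256)
        return affinity.scale(circle, a, b, origin=(cx, cy))


@dataclass(frozen=True)
class StemMap:
    """A fully mapped plot: stems plus observation window and treatment metadata."""

    plot_id: str
    treatment: Treatment
    window: Window
    stems: tuple[Stem, ...]
    gap_age: float | None = None  # years; None for closed-canopy controls
    gap_area: float | None = None  # m²; None -> window.area

    def __post_init__(self) -> None:
        if self.stems:
            x = np.array([s.x for s in self.stems])
            y = np.array([s.y for s in self.stems])
            inside = self.window.contains(x, y)
            if not inside.all():
                bad = [self.stems[i].stem_id for i in np.flatnonzero(~inside)]
                raise GeometryError(
                    f"plot {self.plot_id}: stems outside the window: {bad[:20]}"
                    + (" ..." if len(bad) > 20 else "")
                )

    def __len__(self) -> int:
        return len(self.stems)

    @property
    def area(self) -> float:
        return self.gap_area if self.gap_area is not None else self.window.area

    def coords(self) -> np.ndarray:
        """(n, 2) array of stem coordinates."""
        return np.array([(s.x, s.y) for s in self.stems], dtype=float).reshape(-1, 2)

    def subset(self, predicate: Callable[[Stem], bool],
               plot_id: str | None = None) -> "StemMap":
        return replace(
            self,
            plot_id=plot_id if plot_id is not None else self.plot_id,
            stems=tuple(s for s in self.stems if predicate(s)),
        )

    def by_layer(self, layer: Layer) -> "StemMap":
        return self.subset(lambda s: s.layer is layer)

    def by_growth_form(self, form: GrowthForm) -> "StemMap":
        return self.subset(lambda s: s.growth_form is form)

    def recenter(self, new_origin: tuple[float, float]) -> "StemMap":
        """Translate coordinates so ``new_origin`` maps to (0, 0).

        A rigid translation: all inter-stem distances are preserved.
        """
        ox, oy = new_origin
        stems = tuple(replace(s, x=s.x - ox, y=s.y - oy) for s in self.stems)
        return replace(self, stems=stems, window=self.window.translate(-ox, -oy))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "plot_id": self.plot_id,
                "treatment": self.treatment.value,
                "gap_age_yr": "" if self.gap_age is None else self.gap_age,
                "gap_area_m2": "" if self.gap_area is None else self.gap_area,
                "stem_id": s.stem_id,
                "species": s.species,
                "growth_form": s.growth_form.value,
                "shade_tolerance": s.shade_tolerance.value,
                "x_m": s.x,
                "y_m": s.y,
                "height_m": s.height,
                "diameter_cm": s.diameter,
                "diameter_kind": s.diameter_kind.value,
            }
            for s in self.stems
        ]
        return pd.DataFrame(rows, columns=STEM_MAP_COLUMNS)


STEM_MAP_COLUMNS = [
    "plot_id", "treatment", "gap_age_yr", "gap_area_m2", "stem_id", "species",
    "growth_form", "shade_tolerance", "x_m", "y_m", "height_m", "diameter_cm",
    "diameter_kind",
]

_NUMERIC_COLUMNS = ["x_m", "y_m", "height_m", "diameter_cm"]


def recenter(stem_map: StemMap, new_origin: tuple[float, float]) -> StemMap:
    """Functional alias for :meth:`StemMap.recenter`."""
    return stem_map.recenter(new_origin)


def read_stem_map(path, window: Window, *,
                  plot_id: str | None = None,
                  treatment: Treatment | str | None = None,
                  gap_age: float | None = None,
                  gap_area: float | None = None,
                  permissive: bool = False) -> StemMap:
    """Read a delimited stem-map file into a :class:`StemMap`.

    The file is comma-delimited UTF-8 with a header row naming the columns in
    :data:`STEM_MAP_COLUMNS`. Plot metadata is taken from the first data row
    unless overridden by keyword. Rows with height at or below the 0.1 m
    census cutoff raise :class:`StemMapParseError` unless ``permissive`` is
    set, in which case they are dropped and the count logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in STEM_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise StemMapFormatError(f"missing required column(s): {', '.join(missing)}")

    for col in _NUMERIC_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise StemMapParseError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = vals

    below = df["height_m"] <= HEIGHT_CUTOFF
    if below.any():
        if not permissive:
            lines = (below[below].index + 2).tolist()
            raise StemMapParseError(
                f"{int(below.sum())} row(s) at or below the {HEIGHT_CUTOFF} m "
                f"census cutoff (lines {lines[:10]}); pass permissive=True to drop"
            )
        log.warning("dropping %d stem(s) at or below the %.1f m census cutoff",
                    int(below.sum()), HEIGHT_CUTOFF)
        df = df[~below].reset_index(drop=True)

    if len(df) and plot_id is None:
        plot_id = str(df["plot_id"].iloc[0])
    if len(df) and treatment is None:
        treatment = df["treatment"].iloc[0]
    if isinstance(treatment, str):
        treatment = Treatment(treatment)
    if len(df) and gap_age is None:
        raw = str(df["gap_age_yr"].iloc[0]).strip()
        gap_age = float(raw) if raw else None
    if len(df) and gap_area is None:
        raw = str(df["gap_area_m2"].iloc[0]).strip()
        gap_area = float(raw) if raw else None

    stems = tuple(
        Stem(
            stem_id=str(r.stem_id),
            species=str(r.species),
            growth_form=GrowthForm(r.growth_form),
            shade_tolerance=ShadeTolerance(r.shade_tolerance),
            x=float(r.x_m),
            y=float(r.y_m),
            height=float(r.height_m),
            diameter=float(r.diameter_cm),
            diameter_kind=DiameterKind(r.diameter_kind),
        )
        for r in df.itertuples(index=False)
    )
    return StemMap(
        plot_id=plot_id or "plot",
        treatment=treatment or Treatment.PCK,
        window=window,
        stems=stems,
        gap_age=gap_age,
        gap_area=gap_area,
    )


def write_stem_map(stem_map: StemMap, path) -> None:
    """Write a stem map as comma-delimited UTF-8 text, re-readable by
    :func:`read_stem_map` into an equal map."""
    stem_map.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class GapCandidate:
    """A pre-selected canopy gap awaiting the selection filter."""

    gap_id: str
    diameter: float  # m, gap diameter
    canopy_height: float  # m, surrounding canopy height
    disturbance_flag: bool  # signs of human/animal disturbance
    age_determinable: bool  # tree cores show clear release, age datable

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.canopy_height <= 0:
            raise ValueError("gap diameter and canopy height must be positive")


GAP_RATIO_THRESHOLD = 0.73
"""Minimum gap diameter : canopy height ratio (strict) for medium/large gaps."""


def filter_gap_candidates(candidates: Iterable[GapCandidate]) -> list[GapCandidate]:
    """Retain gaps suitable for the census, preserving input order.

    A candidate passes when its diameter-to-canopy-height ratio strictly
    exceeds 0.73, it shows no disturbance, and its age is determinable from
    tree-ring release patterns.
    """
    return [
        c for c in candidates
        if c.diameter / c.canopy_height > GAP_RATIO_THRESHOLD
        and not c.disturbance_flag
        and c.age_determinable
    ]


@dataclass(frozen=True)
class QuadratGrid:
    """Regular quadrat grid over a window's bounding box.

    Cells are indexed row-major from the lower-left corner. ``active`` marks
    cells that intersect the window (all cells, for a rectangle the grid
    divides exactly).
    """

    origin: tuple[float, float]
    side: float
    nx: int
    ny: int
    active: np.ndarray = field(repr=False)  # shape (ny*nx,), bool

    @property
    def n_cells(self) -> int:
        return int(self.active.sum())

    def index(self, x, y) -> np.ndarray:
        """Row-major cell index of in-grid points (boundary snaps inward)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ox, oy = self.origin
        ix = np.clip(np.floor((x - ox) / self.side).astype(int), 0, self.nx - 1)
        iy = np.clip(np.floor((y - oy) / self.side).astype(int), 0, self.ny - 1)
        out = (x < ox - 1e-9) | (x > ox + self.nx * self.side + 1e-9) \
            | (y < oy - 1e-9) | (y > oy + self.ny * self.side + 1e-9)
        if np.any(out):
            raise GeometryError("point outside the quadrat grid")
        return iy * self.nx + ix


def count_quadrats(window: Window, quadrat_side: float) -> QuadratGrid:
    """Divide a rectangular window into square quadrats.

    The side must divide both extents exactly (a 30 m × 30 m plot at 3 m
    yields 100 subplots); otherwise a :class:`ConfigurationError` is raised.
    """
    if window.shape is not WindowShape.rectangle:
        raise ConfigurationError("count_quadrats requires a rectangular window")
    if quadrat_side <= 0:
        raise ConfigurationError("quadrat side must be positive")
    a, b = window.half_extents
    w, h = 2 * a, 2 * b
    nx, ny = w / quadrat_side, h / quadrat_side
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ConfigurationError(
            f"quadrat side {quadrat_side} m does not divide the "
            f"{w} m × {h} m window"
        )
    nx, ny = int(round(nx)), int(round(ny))
    xmin, ymin, _, _ = window.bbox
    return QuadratGrid(origin=(xmin, ymin), side=quadrat_side, nx=nx, ny=ny,
                       active=np.ones(nx * ny, dtype=bool))


def quadrats_for_window(window: Window, quadrat_side: float) -> QuadratGrid:
    """Quadrat grid for any window.

    Rectangles use :func:`count_quadrats`. For ellipses the 3 m grid is laid
    over the bounding box and cells that intersect the ellipse are active;
    frequency counts downstream use only active cells.
    """
    if window.shape is WindowShape.rectangle:
        return count_quadrats(window, quadrat_side)
    xmin, ymin, xmax, ymax = window.bbox
    nx = int(math.ceil((xmax - xmin) / quadrat_side - 1e-9))
    ny = int(math.ceil((ymax - ymin) / quadrat_side - 1e-9))
    from shapely.geometry import box

    poly = window.to_shapely()
    active = np.zeros(nx * ny, dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            cell = box(xmin + ix * quadrat_side, ymin + iy * quadrat_side,
                       xmin + (ix + 1) * quadrat_side, ymin + (iy + 1) * quadrat_side)
            active[iy * nx + ix] = poly.intersects(cell)
    return QuadratGrid(origin=(xmin, ymin), side=quadrat_side, nx=nx, ny=ny,
                       active=active)
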