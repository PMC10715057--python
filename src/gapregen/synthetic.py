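"""Seeded generators of synthetic stem maps.

Field stem maps of this kind are rarely deposited, so the package ships a
generator that reproduces the *statistical structure* the analysis assumes:
clustered lower-layer regeneration (Poisson cluster / Thomas processes),
spatially random upper-layer canopy trees, hard-core "regular" patterns,
and bivariate shrub-tree structure (shared-parent attraction or mutual
inhibition). Treatment presets echo the printed gap-area and gap-age summary
statistics of the six study treatments; see :mod:`gapregen.presets`.

All generators are pure functions of (parameters, seed): a root seed is
expanded into independent substreams, so identical inputs give identical
output regardless of evaluation order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .model import (
    BREAST_HEIGHT,
    ConfigurationError,
    DiameterKind,
    GrowthForm,
    Layer,
    LAYER_BOUNDS,
    ShadeTolerance,
    Stem,
    StemMap,
    Treatment,
    Window,
    WindowShape,
)
from .pointpattern import _sample_csr


class ProcessKind(str, Enum):
    poisson = "poisson"
    thomas = "thomas"
    inhibition = "inhibition"


class Interaction(str, Enum):
    independent = "independent"
    shared_parents = "shared_parents"
    mutual_inhibition = "mutual_inhibition"


@dataclass(frozen=True)
class ProcessSpec:
    """Parameters of one point process.

    ``intensity`` is the target mean density (stems m^-2). For a Thomas
    process the mean offspring per parent is intensity / parents_per_m2.
    """

    kind: ProcessKind
    intensity: float
    parents_per_m2: float | None = None  # thomas only
    cluster_sd: float | None = None  # thomas dispersal sigma, m
    min_dist: float = 0.0  # inhibition only, m

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ConfigurationError("intensity must be non-negative")
        if self.kind is ProcessKind.thomas:
            if not self.parents_per_m2 or self.parents_per_m2 <= 0:
                raise ConfigurationError("thomas process needs parents_per_m2 > 0")
            if not self.cluster_sd or self.cluster_sd <= 0:
                raise ConfigurationError("thomas process needs cluster_sd > 0")
        if self.kind is ProcessKind.inhibition and self.min_dist < 0:
            raise ConfigurationError("min_dist must be non-negative")

    @property
    def mean_offspring(self) -> float:
        if self.kind is not ProcessKind.thomas:
            raise AttributeError("mean_offspring is defined for thomas processes")
        return self.intensity / self.parents_per_m2


def simulate_poisson(window: Window, intensity: float, seed) -> np.ndarray:
    """Homogeneous Poisson pattern: count ~ Poisson(intensity * area),
    positions i.i.d. uniform in the window."""
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * window.area)
    return _sample_csr(window, n, rng)


def _dilate(window: Window, pad: float) -> Window:
    a, b = window.half_extents
    return Window(window.shape, window.center, (a + pad, b + pad))


def simulate_thomas(window: Window, parents_per_m2: float, mean_offspring: float,
                    cluster_sd: float, seed) -> np.ndarray:
    """Thomas cluster process.

    Poisson parents are simulated on the window dilated by 4*cluster_sd (so
    clusters straddling the boundary are not truncated), each parent gets a
    Poisson(mean_offspring) brood displaced by an isotropic Gaussian of
    standard deviation cluster_sd, and offspring falling outside the target
    window are clipped. Only offspring are returned.
    """
    if parents_per_m2 <= 0 or cluster_sd <= 0 or mean_offspring < 0:
        raise ValueError("thomas parameters must be positive")
    rng = np.random.default_rng(seed)
    parent_win = _dilate(window, 4.0 * cluster_sd)
    n_par = rng.poisson(parents_per_m2 * parent_win.area)
    parents = _sample_csr(parent_win, n_par, rng)
    broods = rng.poisson(mean_offspring, size=n_par)
    total = int(broods.sum())
    if total == 0:
        return np.empty((0, 2))
    centers = np.repeat(parents, broods, axis=0)
    pts = centers + rng.normal(scale=cluster_sd, size=(total, 2))
    keep = window.contains(pts[:, 0], pts[:, 1])
    return pts[keep]


def simulate_inhibition(window: Window, intensity: float, min_dist: float,
                        seed) -> np.ndarray:
    """Hard-core pattern by dart throwing with rejection.

    All pairwise distances of the output are >= min_dist. Feasibility guard:
    intensity * pi * min_dist**2 must be < 0.5, else packing is refused.
    """
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    if min_dist > 0 and intensity * math.pi * min_dist**2 >= 0.5:
        raise ConfigurationError(
            f"infeasible packing: intensity {intensity} m^-2 at hard core "
            f"{min_dist} m exceeds the dart-throwing limit"
        )
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * window.area)
    if n == 0:
        return np.empty((0, 2))
    pts: list[np.ndarray] = []
    attempts, max_attempts = 0, 2000 * n
    while len(pts) < n and attempts < max_attempts:
        cand = _sample_csr(window, 1, rng)[0]
        attempts += 1
        if min_dist > 0 and pts:
            arr = np.array(pts)
            if np.min(np.hypot(arr[:, 0] - cand[0], arr[:, 1] - cand[1])) < min_dist:
                continue
        pts.append(cand)
    if len(pts) < n:
        raise ConfigurationError(
            f"dart throwing placed only {len(pts)} of {n} points at hard core "
            f"{min_dist} m"
        )
    return np.array(pts)


def simulate_process(window: Window, spec: ProcessSpec, seed) -> np.ndarray:
    if spec.kind is ProcessKind.poisson:
        return simulate_poisson(window, spec.intensity, seed)
    if spec.kind is ProcessKind.thomas:
        return simulate_thomas(window, spec.parents_per_m2, spec.mean_offspring,
                               spec.cluster_sd, seed)
    return simulate_inhibition(window, spec.intensity, spec.min_dist, seed)


def make_bivariate(window: Window, spec1: ProcessSpec, spec2: ProcessSpec,
                   interaction: Interaction | str, param: float,
                   seed) -> tuple[np.ndarray, np.ndarray]:
    """Two point patterns with a controlled cross-type relationship.

    * ``independent``: two independent draws.
    * ``shared_parents``: both types are Thomas broods around one common
      parent set (small-scale attraction); ``param`` is unused.
    * ``mutual_inhibition``: type-2 candidates within ``param`` metres of any
      type-1 point are rejected (repulsion; type-2 intensity is thinned).
    """
    interaction = Interaction(interaction)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s1, s2 = ss.spawn(2)
    if interaction is Interaction.independent:
        return simulate_process(window, spec1, s1), simulate_process(window, spec2, s2)
    if interaction is Interaction.shared_parents:
        if spec1.kind is not ProcessKind.thomas or spec2.kind is not ProcessKind.thomas:
            raise ConfigurationError("shared_parents requires two thomas specs")
        rng = np.random.default_rng(s1)
        pad = 4.0 * max(spec1.cluster_sd, spec2.cluster_sd)
        parent_win = _dilate(window, pad)
        kappa = spec1.parents_per_m2
        if abs(spec2.parents_per_m2 - kappa) > 1e-12:
            raise ConfigurationError("shared_parents requires equal parents_per_m2")
        parents = _sample_csr(parent_win, rng.poisson(kappa * parent_win.area), rng)
        out = []
        for spec in (spec1, spec2):
            broods = rng.poisson(spec.intensity / kappa, size=len(parents))
            total = int(broods.sum())
            if total == 0:
                out.append(np.empty((0, 2)))
                continue
            pts = np.repeat(parents, broods, axis=0) + rng.normal(
                scale=spec.cluster_sd, size=(total, 2))
            keep = window.contains(pts[:, 0], pts[:, 1])
            out.append(pts[keep])
        return out[0], out[1]
    # mutual inhibition
    p1 = simulate_process(window, spec1, s1)
    p2 = simulate_process(window, spec2, s2)
    if len(p1) and len(p2) and param > 0:
        d = np.hypot(p2[:, 0][:, None] - p1[:, 0][None, :],
                     p2[:, 1][:, None] - p1[:, 1][None, :])
        p2 = p2[d.min(axis=1) >= param]
    return p1, p2


@dataclass(frozen=True)
class SpeciesEntry:
    species: str
    growth_form: GrowthForm
    shade_tolerance: ShadeTolerance
    weight: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """One demographic cohort of a treatment preset.

    Heights are drawn from a Beta(2, 2) rescaled to ``height_range`` (which
    must lie within the cohort layer's bounds); diameters follow the
    allometry d = allom_a * h**allom_b cm with lognormal noise.
    """

    name: str
    layer: Layer
    pool: tuple[SpeciesEntry, ...]
    process: ProcessSpec
    height_range: tuple[float, float] | None = None
    allom_a: float = 1.0  # cm * m^-b
    allom_b: float = 1.1
    allom_sd: float = 0.15  # lognormal sigma of diameter noise

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        blo, bhi = LAYER_BOUNDS[self.layer]
        if lo < blo - 1e-12 or hi > bhi + 1e-12 or lo >= hi:
            raise ConfigurationError(
                f"cohort {self.name}: height range {(lo, hi)} outside the "
                f"{self.layer.value} layer bounds {LAYER_BOUNDS[self.layer]}"
            )
        if not self.pool:
            raise ConfigurationError(f"cohort {self.name}: empty species pool")

    @property
    def bounds(self) -> tuple[float, float]:
        if self.height_range is not None:
            return self.height_range
        lo, hi = LAYER_BOUNDS[self.layer]
        return (lo, 25.0 if math.isinf(hi) else hi)


@dataclass(frozen=True)
class InteractionSpec:
    """Cross-cohort spatial interaction within a preset."""

    kind: Interaction
    cohort_a: str
    cohort_b: str
    param: float = 0.0


@dataclass(frozen=True)
class TreatmentPreset:
    """Generator parameters of one study treatment.

    ``gap_area`` is (mean, sd) m² for gap treatments; closed-canopy controls
    (area None) use a 30 m x 30 m rectangular plot. ``gap_age`` is (mean, sd)
    years, absent for controls. ``aspect`` is the semi-axis ratio b/a of the
    elliptical gap window.
    """

    treatment: Treatment
    cohorts: tuple[CohortSpec, ...]
    gap_area: tuple[float, float] | None = None
    gap_age: tuple[float, float] | None = None
    aspect: float = 1.0
    interaction: InteractionSpec | None = None
    control_side: float = 30.0

    def __post_init__(self) -> None:
        if self.gap_area is not None and self.gap_area[0] <= 0:
            raise ConfigurationError("gap area mean must be positive")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ConfigurationError("cohort names must be unique")
        if self.interaction is not None:
            for key in (self.interaction.cohort_a, self.interaction.cohort_b):
                if key not in names:
                    raise ConfigurationError(f"interaction names unknown cohort {key!r}")


MIN_GAP_AREA = 100.0  # m²; truncation floor for drawn gap areas


def _draw_window(preset: TreatmentPreset, rng: np.random.Generator
                 ) -> tuple[Window, float | None, float | None]:
    if preset.gap_area is None:
        side = preset.control_side
        return Window.rectangle(side, side), None, None
    mean, sd = preset.gap_area
    area = -math.inf
    while area < MIN_GAP_AREA:
        area = rng.normal(mean, sd)
    window = Window.ellipse_from_area(area, preset.aspect)
    age = None
    if preset.gap_age is not None:
        age = max(1.0, rng.normal(*preset.gap_age))
    return window, float(area), age


def _stems_from_points(points: np.ndarray, cohort: CohortSpec,
                       rng: np.random.Generator, prefix: str) -> list[Stem]:
    n = len(points)
    if n == 0:
        return []
    weights = np.array([e.weight for e in cohort.pool], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(cohort.pool), size=n, p=weights)
    lo, hi = cohort.bounds
    heights = lo + (hi - lo) * rng.beta(2.0, 2.0, size=n)
    heights = np.maximum(heights, lo + 1e-6)
    diam = cohort.allom_a * heights**cohort.allom_b * np.exp(
        rng.normal(scale=cohort.allom_sd, size=n))
    stems = []
    for i in range(n):
        entry = cohort.pool[picks[i]]
        stems.append(Stem(
            stem_id=f"{prefix}-{cohort.name}-{i:05d}",
            species=entry.species,
            growth_form=entry.growth_form,
            shade_tolerance=entry.shade_tolerance,
            x=float(points[i, 0]),
            y=float(points[i, 1]),
            height=float(heights[i]),
            diameter=float(diam[i]),
            diameter_kind=(DiameterKind.dbh if heights[i] >= BREAST_HEIGHT
                           else DiameterKind.rcd),
        ))
    return stems


def generate_stem_map(preset: TreatmentPreset, seed,
                      plot_id: str | None = None) -> StemMap:
    """One synthetic plot drawn from a treatment preset.

    Deterministic under (preset, seed): the seed is expanded into one
    substream per cohort plus one for the window, so adding a cohort does
    not perturb the others.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(len(preset.cohorts) + 2)
    win_rng = np.random.default_rng(children[0])
    window, area, age = _draw_window(preset, win_rng)
    pid = plot_id or f"{preset.treatment.value}-{ss.entropy}"

    interacting: dict[str, np.ndarray] = {}
    if preset.interaction is not None:
        ia = preset.interaction
        ca = next(c for c in preset.cohorts if c.name == ia.cohort_a)
        cb = next(c for c in preset.cohorts if c.name == ia.cohort_b)
        pa, pb = make_bivariate(window, ca.process, cb.process, ia.kind,
                                ia.param, children[1])
        interacting = {ia.cohort_a: pa, ia.cohort_b: pb}

    stems: list[Stem] = []
    for cohort, child in zip(preset.cohorts, children[2:]):
        proc_seed, attr_seed = child.spawn(2)
        if cohort.name in interacting:
            points = interacting[cohort.name]
        else:
            points = simulate_process(window, cohort.process, proc_seed)
        stems.extend(_stems_from_points(points, cohort,
                                        np.random.default_rng(attr_seed), pid))
    return StemMap(plot_id=pid, treatment=preset.treatment, window=window,
                   stems=tuple(stems), gap_age=age, gap_area=area)
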