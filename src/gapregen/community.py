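"""Community metrics: importance values, richness, Shannon diversity,
upper-layer attainment, and height comparisons across gap ages.

The importance value (IV) of species i averages three relative components,
each expressed in percent:

    IV_i = (RD_i + RF_i + RC_i) / 3

with RD_i = 100 n_i / sum(n) (relative dominance, from stem counts),
RC_i = 100 a_i / sum(a) (relative coverage, from basal area a_i computed
from the recorded diameters), and RF_i = 100 f_i / sum(f) (relative
frequency, from the number of 3 m quadrats the species occupies). The
three components and hence the IVs each sum to 100 over species.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import (
    GrowthForm,
    Layer,
    QuadratGrid,
    StemMap,
    quadrats_for_window,
)


@dataclass(frozen=True)
class IvTable:
    """Per-species IV components. ``table`` columns: species, n, basal_area_m2,
    quadrats, RD, RF, RC, IV — sorted by IV descending, ties alphabetical."""

    table: pd.DataFrame
    n_quadrats: int

    @property
    def S(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_iv(stem_map: StemMap, quadrat_side: float = 3.0,
               stratum: Layer | None = None,
               include: str = "trees") -> IvTable:
    """Importance-value table for a plot.

    ``include`` selects growth forms: ``"trees"`` (default), ``"shrubs"`` or
    ``"all"``. ``stratum`` restricts to one vertical layer. For elliptical
    gap windows the quadrats are the 3 m grid cells of the bounding box that
    intersect the window. An empty stratum yields an empty table (S = 0).
    """
    if include not in ("trees", "shrubs", "all"):
        raise ValueError("include must be 'trees', 'shrubs' or 'all'")
    grid = quadrats_for_window(stem_map.window, quadrat_side)
    stems = [
        s for s in stem_map.stems
        if (stratum is None or s.layer is stratum)
        and (include == "all"
             or (include == "trees" and s.growth_form is GrowthForm.tree)
             or (include == "shrubs" and s.growth_form is GrowthForm.shrub))
    ]
    cols = ["species", "n", "basal_area_m2", "quadrats", "RD", "RF", "RC", "IV"]
    if not stems:
        return IvTable(pd.DataFrame(columns=cols), grid.n_cells)

    by_species: dict[str, dict] = {}
    for s in stems:
        rec = by_species.setdefault(s.species, {"n": 0, "a": 0.0, "cells": set()})
        rec["n"] += 1
        rec["a"] += s.basal_area_m2
        rec["cells"].add(int(grid.index(s.x, s.y)))

    species = sorted(by_species)
    n = np.array([by_species[sp]["n"] for sp in species], dtype=float)
    a = np.array([by_species[sp]["a"] for sp in species], dtype=float)
    f = np.array([len(by_species[sp]["cells"]) for sp in species], dtype=float)
    rd = 100.0 * n / n.sum()
    rc = 100.0 * a / a.sum()
    rf = 100.0 * f / f.sum()
    iv = (rd + rf + rc) / 3.0
    df = pd.DataFrame({
        "species": species, "n": n.astype(int), "basal_area_m2": a,
        "quadrats": f.astype(int), "RD": rd, "RF": rf, "RC": rc, "IV": iv,
    })
    df = df.sort_values(["IV", "species"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return IvTable(df[cols], grid.n_cells)


def species_richness(stem_map: StemMap, stratum: Layer | None = None,
                     include: str = "all") -> int:
    """Number of distinct species in the plot (optionally one layer)."""
    return len({
        s.species for s in stem_map.stems
        if (stratum is None or s.layer is stratum)
        and (include == "all"
             or (include == "trees" and s.growth_form is GrowthForm.tree)
             or (include == "shrubs" and s.growth_form is GrowthForm.shrub))
    })


def pooled_richness(stem_maps: Iterable[StemMap],
                    stratum: Layer | None = None,
                    include: str = "all") -> int:
    """Richness of the union of several plots (e.g. a treatment's replicates)."""
    species: set[str] = set()
    for m in stem_maps:
        species |= {
            s.species for s in m.stems
            if (stratum is None or s.layer is stratum)
            and (include == "all"
                 or (include == "trees" and s.growth_form is GrowthForm.tree)
                 or (include == "shrubs" and s.growth_form is GrowthForm.shrub))
        }
    return len(species)


@dataclass(frozen=True)
class DiversityResult:
    richness: int
    shannon: float  # nats
    proportions: tuple[float, ...]


def shannon_index(abundances: Sequence[float] | Mapping[str, float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats).

    Zero abundances are excluded; an all-zero vector is a domain error.
    H is 0 for a monoculture and ln S for S equally abundant species.
    """
    if isinstance(abundances, Mapping):
        abundances = list(abundances.values())
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("at least one abundance must be positive")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def diversity(stem_map: StemMap, include: str = "all") -> DiversityResult:
    """Richness and Shannon H of a plot from its species abundances."""
    counts: dict[str, int] = {}
    for s in stem_map.stems:
        if (include == "all"
                or (include == "trees" and s.growth_form is GrowthForm.tree)
                or (include == "shrubs" and s.growth_form is GrowthForm.shrub)):
            counts[s.species] = counts.get(s.species, 0) + 1
    if not counts:
        return DiversityResult(0, 0.0, ())
    total = sum(counts.values())
    props = tuple(counts[k] / total for k in sorted(counts))
    return DiversityResult(len(counts), shannon_index(counts), props)


def upper_layer_fraction(stem_maps: StemMap | Iterable[StemMap],
                         include: str = "all") -> float:
    """Percentage of species that reach the upper layer (>10 m), to 1 decimal.

    100 * (richness of the upper layer) / (total richness), pooled over the
    given plots.
    """
    maps = [stem_maps] if isinstance(stem_maps, StemMap) else list(stem_maps)
    total = pooled_richness(maps, include=include)
    if total == 0:
        raise ValueError("no species present: upper-layer fraction undefined")
    upper = pooled_richness(maps, stratum=Layer.upper, include=include)
    return round(100.0 * upper / total, 1)


@dataclass(frozen=True)
class HeightComparison:
    """One-way ANOVA of heights across gap-age classes with Tukey HSD
    post-hoc pairs and a compact letter display.

    Groups that share no letter differ at the chosen alpha. ``degenerate``
    flags the zero-within-variance/unequal-means case (F reported as inf).
    """

    groups: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    tukey_p: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float

    def to_json(self) -> str:
        return json.dumps({
            "groups": list(self.groups),
            "means": self.means,
            "sds": self.sds,
            "ns": self.ns,
            "F": self.f_statistic,
            "p": self.p_value,
            "df": [self.df_between, self.df_within],
            "tukey_p": {f"{a}|{b}": p for (a, b), p in self.tukey_p.items()},
            "letters": self.letters,
            "alpha": self.alpha,
        }, indent=2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": list(self.groups),
            "n": [self.ns[g] for g in self.groups],
            "mean": [self.means[g] for g in self.groups],
            "sd": [self.sds[g] for g in self.groups],
            "letters": [self.letters[g] for g in self.groups],
        })


def _compact_letters(groups: Sequence[str], means: Mapping[str, float],
                     significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one letter covering all groups; for every significant pair,
    split each letter containing both; absorb letters that became subsets.
    Letters are ordered by the largest member mean, ties by label, so the
    assignment is deterministic.
    """
    letters: list[set[str]] = [set(groups)]
    for pair in sorted(significant):
        i, j = pair
        new: list[set[str]] = []
        for letter in letters:
            if i in letter and j in letter:
                new.append(letter - {i})
                new.append(letter - {j})
            else:
                new.append(letter)
        # absorb duplicates/subsets
        new.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for cand in new:
            if cand and not any(cand <= k for k in kept):
                kept.append(cand)
        letters = kept
    letters.sort(key=lambda L: (-max(means[g] for g in L), min(sorted(L))))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, list[str]] = {g: [] for g in groups}
    for ch, letter in zip(alphabet, letters):
        for g in letter:
            assigned[g].append(ch)
    return {g: "".join(sorted(v)) for g, v in assigned.items()}


def height_anova_tukey(heights: Mapping[str, Sequence[float]],
                       alpha: float = 0.05) -> HeightComparison:
    """Classical one-way ANOVA with Tukey HSD (Tukey-Kramer for unbalanced
    groups) on heights grouped by gap-age class.

    Each group needs at least two observations. If every group has zero
    within-group variance but means differ, F is reported as +inf with
    p = 0 and all pairs with unequal means treated as significant.
    """
    groups = tuple(heights.keys())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(heights[g], dtype=float) for g in groups}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than two observations")
    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    sds = {g: float(arr.std(ddof=1)) for g, arr in arrays.items()}
    ns = {g: int(arr.size) for g, arr in arrays.items()}
    n_total = sum(ns.values())
    dfb, dfw = len(groups) - 1, n_total - len(groups)

    ssw = sum(((arr - arr.mean()) ** 2).sum() for arr in arrays.values())
    grand = sum(arr.sum() for arr in arrays.values()) / n_total
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in groups)

    degenerate = ssw <= 1e-300 * max(1.0, ssb)
    if degenerate and ssb > 0:
        f_stat, p_val = math.inf, 0.0
        tukey_p = {
            (a, b): (0.0 if means[a] != means[b] else 1.0)
            for i, a in enumerate(groups) for b in groups[i + 1:]
        }
    else:
        f_stat = (ssb / dfb) / (ssw / dfw) if ssw > 0 else 0.0
        p_val = float(stats.f.sf(f_stat, dfb, dfw)) if ssw > 0 else 1.0
        data = np.concatenate([arrays[g] for g in groups])
        labels = np.concatenate([[g] * ns[g] for g in groups])
        res = pairwise_tukeyhsd(data, labels, alpha=alpha)
        gu = [str(g) for g in res.groupsunique]
        raw = {
            (gu[i], gu[j]): float(p)
            for (i, j), p in zip(combinations(range(len(gu)), 2), res.pvalues)
        }
        # canonical key order matching the input group order
        tukey_p = {
            (a, b): raw.get((a, b), raw.get((b, a)))
            for i, a in enumerate(groups) for b in groups[i + 1:]
        }
    significant = {(a, b) for (a, b), p in tukey_p.items() if p < alpha}
    letters = _compact_letters(groups, means, significant)
    return HeightComparison(
        groups=groups, means=means, sds=sds, ns=ns,
        f_statistic=f_stat, p_value=p_val, df_between=dfb, df_within=dfw,
        tukey_p=tukey_p, letters=letters, alpha=alpha,
    )
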