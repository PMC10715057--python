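"""Second-order point-pattern analysis with Monte Carlo envelopes.

Implements Ripley's K and the pair correlation function g(r) for univariate
patterns, the bivariate cross pair correlation g12(r), and rank-based
pointwise simulation envelopes (default: 199 simulations, 2nd-extreme ranks,
i.e. a pointwise two-sided level of 2*2/200 = 0.02, a 98% envelope).

Estimator conventions
---------------------
K follows the ordered-pair sum

    K(r) = s / (n (n - 1)) * sum_{m != n} I(d_mn <= r) e_mn

with s the window area and e an edge-correction weight. g(r) is estimated
directly from annulus counts (box kernel of half-width h) rather than by
differentiating K:

    g(r) = s / (n (n - 1)) * sum_{pairs, d in (r-h, r+h]} e / (2 pi r * 2 h)

Edge corrections: the translation correction (exact for rectangles) and the
border (minus-sampling) correction (any convex window). Under complete
spatial randomness (CSR) both estimators are unbiased: E K(r) = pi r**2 and
E g(r) = 1.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import ConfigurationError, Window, WindowShape

Correction = Literal["translation", "border", "none"]

UNIVARIATE_CLASSES = ("clustered", "random", "regular")
BIVARIATE_CLASSES = ("attraction", "independent", "repulsion")


@dataclass(frozen=True)
class DistanceGrid:
    """Regular grid of annulus centre distances r (m) with half-width h.

    The default grid r = 0.5, 1.0, ..., 10 m with h = 0.25 m gives
    contiguous non-overlapping annuli (r - h, r + h].
    """

    r: tuple[float, ...]
    half_width: float = 0.25

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 1 or len(r) == 0:
            raise ConfigurationError("distance grid must be a non-empty 1-D sequence")
        if r[0] <= 0 or np.any(np.diff(r) <= 0):
            raise ConfigurationError("distances must be positive and strictly increasing")
        if self.half_width <= 0:
            raise ConfigurationError("annulus half-width must be positive")

    @classmethod
    def default(cls, r_max: float = 10.0, step: float = 0.5,
                half_width: float = 0.25) -> "DistanceGrid":
        n = int(round(r_max / step))
        return cls(tuple(step * (i + 1) for i in range(n)), half_width)

    @property
    def r_array(self) -> np.ndarray:
        return np.asarray(self.r, dtype=float)

    def validate_for(self, window: Window) -> None:
        """Cap r at half the window's shorter extent (estimator stability)."""
        if max(self.r) > min(window.half_extents) + 1e-9:
            raise ConfigurationError(
                f"r_max = {max(self.r)} m exceeds half the window's shorter "
                f"extent ({min(window.half_extents)} m)"
            )

    def clipped_to(self, window: Window) -> "DistanceGrid":
        """Copy of the grid with bins above half the shorter extent dropped."""
        lim = min(window.half_extents)
        keep = tuple(r for r in self.r if r <= lim + 1e-9)
        if not keep:
            raise ConfigurationError("window too small for any distance bin")
        return DistanceGrid(keep, self.half_width)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    return pts


def _pair_data(p1: np.ndarray, p2: np.ndarray | None, window: Window,
               correction: Correction):
    """Distances and edge weights for ordered pairs (cross pairs if p2 given).

    Returns (d, w) flat arrays. For the univariate case, self-pairs are
    excluded and each unordered pair appears twice, matching the n(n-1)
    normalisation.
    """
    cross = p2 is not None
    q = p2 if cross else p1
    dx = p1[:, 0][:, None] - q[:, 0][None, :]
    dy = p1[:, 1][:, None] - q[:, 1][None, :]
    d = np.hypot(dx, dy)
    if correction == "translation":
        if window.shape is not WindowShape.rectangle:
            raise ConfigurationError(
                "translation correction is defined for rectangular windows; "
                "use the border correction for ellipses"
            )
        a, b = window.half_extents
        w_, h_ = 2 * a, 2 * b
        gamma = (w_ - np.abs(dx)) * (h_ - np.abs(dy))
        with np.errstate(divide="ignore"):
            w = np.where(gamma > 0, (w_ * h_) / np.where(gamma > 0, gamma, 1.0), 0.0)
    else:
        w = np.ones_like(d)
    if not cross:
        np.fill_diagonal(d, -1.0)  # sentinel: excluded below
    return d.ravel(), w.ravel()


def k_function(points, window: Window, grid: DistanceGrid,
               correction: Correction = "translation") -> np.ndarray:
    """Ripley's K at each grid distance (translation or no correction).

    For the border correction use :func:`_k_border`-style minus sampling via
    ``correction='border'``.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError("K requires at least two points")
    grid.validate_for(window)
    r = grid.r_array
    s = window.area
    if correction == "border":
        bd = window.boundary_distance(pts[:, 0], pts[:, 1])
        dx = pts[:, 0][:, None] - pts[:, 0][None, :]
        dy = pts[:, 1][:, None] - pts[:, 1][None, :]
        d = np.hypot(dx, dy)
        np.fill_diagonal(d, np.inf)
        out = np.empty(len(r))
        for k, rk in enumerate(r):
            ref = bd >= rk
            n_ref = int(ref.sum())
            if n_ref == 0:
                out[k] = np.nan
                continue
            counts = (d[ref] <= rk).sum()
            out[k] = s * counts / (n_ref * (n - 1))
        return out
    d, w = _pair_data(pts, None, window, correction)
    valid = d >= 0
    d, w = d[valid], w[valid]
    out = np.array([(w[d <= rk]).sum() for rk in r])
    return s / (n * (n - 1)) * out


def _annulus_sums(d: np.ndarray, w: np.ndarray, grid: DistanceGrid) -> np.ndarray:
    """Sum of weights per annulus (r-h, r+h]."""
    r = grid.r_array
    h = grid.half_width
    steps = np.diff(r)
    if len(r) > 1 and np.allclose(steps, 2 * h, atol=1e-12):
        # contiguous annuli: one histogram pass
        edges = np.concatenate(([r[0] - h], r + h))
        idx = np.searchsorted(edges, d, side="left")
        sums = np.zeros(len(r))
        inb = (idx >= 1) & (idx <= len(r))
        np.add.at(sums, idx[inb] - 1, w[inb])
        return sums
    return np.array([w[(d > rk - h) & (d <= rk + h)].sum() for rk in r])


def pcf(points, window: Window, grid: DistanceGrid,
        correction: Correction = "translation") -> np.ndarray:
    """Pair correlation function g(r) from annulus pair counts."""
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError("g(r) requires at least two points")
    grid.validate_for(window)
    r = grid.r_array
    h = grid.half_width
    s = window.area
    if correction == "border":
        return _pcf_border(pts, None, window, grid)[0]
    d, w = _pair_data(pts, None, window, correction)
    valid = d >= 0
    sums = _annulus_sums(d[valid], w[valid], grid)
    return s / (n * (n - 1)) * sums / (2 * math.pi * r * 2 * h)


def _pcf_border(p1: np.ndarray, p2: np.ndarray | None, window: Window,
                grid: DistanceGrid):
    """Border (minus-sampling) g or g12: reference points are those of
    pattern 1 whose full annulus lies inside the window.

    Returns (g, n_ref per r).
    """
    cross = p2 is not None
    q = p2 if cross else p1
    n1, n2 = len(p1), len(q)
    r = grid.r_array
    h = grid.half_width
    s = window.area
    bd = window.boundary_distance(p1[:, 0], p1[:, 1])
    dx = p1[:, 0][:, None] - q[:, 0][None, :]
    dy = p1[:, 1][:, None] - q[:, 1][None, :]
    d = np.hypot(dx, dy)
    if not cross:
        np.fill_diagonal(d, np.inf)
    denom_pts = n2 if cross else (n1 - 1)
    nb = len(r)
    steps = np.diff(r)
    if nb > 1 and np.allclose(steps, 2 * h, atol=1e-12):
        # contiguous annuli: per-row bin counts in one pass, then prefix sums
        # over rows ordered by decreasing boundary distance
        edges = np.concatenate(([r[0] - h], r + h))
        order = np.argsort(-bd)
        idx = np.searchsorted(edges, d[order].ravel(), side="left")
        # map out-of-range distances to a spill bin
        idx = np.where((idx >= 1) & (idx <= nb), idx - 1, nb)
        flat = np.arange(n1).repeat(d.shape[1]) * (nb + 1) + idx
        counts = np.bincount(flat, minlength=n1 * (nb + 1)).reshape(n1, nb + 1)
        csum = counts[:, :nb].cumsum(axis=0)
        bd_sorted = bd[order]
        # rows usable at bin k: bd >= r_k + h (prefix of the sorted order)
        n_ref = np.searchsorted(-bd_sorted, -(r + h), side="right")
        g = np.full(nb, np.nan)
        for k in range(nb):
            m = int(n_ref[k])
            if m == 0 or denom_pts == 0:
                continue
            g[k] = s * csum[m - 1, k] / (m * denom_pts * 2 * math.pi * r[k] * 2 * h)
        return g, n_ref.astype(int)
    g = np.empty(nb)
    n_ref = np.empty(nb, dtype=int)
    for k, rk in enumerate(r):
        ref = bd >= rk + h
        m = int(ref.sum())
        n_ref[k] = m
        if m == 0 or denom_pts == 0:
            g[k] = np.nan
            continue
        dk = d[ref]
        cnt = ((dk > rk - h) & (dk <= rk + h)).sum()
        g[k] = s * cnt / (m * denom_pts * 2 * math.pi * rk * 2 * h)
    return g, n_ref


def cross_pcf(points1, points2, window: Window, grid: DistanceGrid,
              correction: Correction = "translation") -> np.ndarray:
    """Bivariate cross pair correlation g12(r) from cross-pair annulus counts."""
    p1, p2 = _as_points(points1), _as_points(points2)
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("g12(r) requires both patterns to be non-empty")
    grid.validate_for(window)
    r = grid.r_array
    h = grid.half_width
    s = window.area
    if correction == "border":
        return _pcf_border(p1, p2, window, grid)[0]
    d, w = _pair_data(p1, p2, window, correction)
    sums = _annulus_sums(d, w, grid)
    return s / (len(p1) * len(p2)) * sums / (2 * math.pi * r * 2 * h)


@dataclass
class PcfResult:
    """Observed summary function with rank-based Monte Carlo envelopes.

    ``classification`` per distance bin: above the upper envelope ->
    clustered (univariate) / attraction (bivariate); below the lower ->
    regular / repulsion; inside -> random / independent. ``unstable`` flags
    bins whose border-corrected reference count fell below 10 (kept, not
    dropped).
    """

    grid: DistanceGrid
    g_obs: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    classification: list[str]
    n_sims: int
    rank: int
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    unstable: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def nominal_level(self) -> float:
        """Pointwise two-sided significance of the envelope test."""
        return 2.0 * self.rank / (self.n_sims + 1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "r": self.grid.r_array,
                "g_obs": self.g_obs,
                "lo": self.envelope_lo,
                "hi": self.envelope_hi,
                "class": self.classification,
            }
        )
        if self.unstable is not None:
            df["unstable"] = self.unstable
        return df

    def write(self, path, sidecar_path=None) -> None:
        """Delimited-text result plus a JSON sidecar of run metadata."""
        self.to_dataframe().to_csv(path, index=False)
        if sidecar_path is not None:
            meta = dict(self.metadata)
            meta.update(n_sims=self.n_sims, rank=self.rank,
                        nominal_level=self.nominal_level,
                        half_width=self.grid.half_width)
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2, default=str)


def _classify(g_obs, lo, hi, classes) -> list[str]:
    above, inside, below = classes
    out = []
    for g, l, h in zip(g_obs, lo, hi):
        if np.isnan(g) or np.isnan(l) or np.isnan(h):
            out.append(inside)
        elif g > h:
            out.append(above)
        elif g < l:
            out.append(below)
        else:
            out.append(inside)
    return out


def _sample_csr(window: Window, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. uniform points in the window."""
    cx, cy = window.center
    a, b = window.half_extents
    if window.shape is WindowShape.rectangle:
        xy = rng.uniform(-1.0, 1.0, size=(n, 2))
        return np.column_stack((cx + a * xy[:, 0], cy + b * xy[:, 1]))
    u = np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack((cx + a * u * np.cos(th), cy + b * u * np.sin(th)))


def _check_rank(n_sims: int, rank: int) -> None:
    if n_sims < 1:
        raise ConfigurationError("need at least one simulation")
    if rank < 1 or rank >= (n_sims + 1) / 2:
        raise ConfigurationError(
            f"rank {rank} invalid for {n_sims} simulations "
            f"(must satisfy 1 <= rank < (n_sims+1)/2)"
        )


def csr_envelope(points, window: Window, grid: DistanceGrid, *,
                 n_sims: int = 199, rank: int = 2,
                 correction: Correction = "translation",
                 seed=None) -> PcfResult:
    """g(r) with a pointwise CSR envelope test.

    Envelopes are the rank-th smallest/largest of ``n_sims`` simulated g
    curves, each from a CSR pattern conditioned on the observed point count.
    Defaults (199 simulations, rank 2) give the conventional 98% envelope,
    a pointwise two-sided significance level of 0.02.
    """
    pts = _as_points(points)
    n = len(pts)
    _check_rank(n_sims, rank)
    g_obs = pcf(pts, window, grid, correction)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, len(grid.r)))
    for i in range(n_sims):
        sims[i] = pcf(_sample_csr(window, n, rng), window, grid, correction)
    sims_sorted = np.sort(sims, axis=0)
    lo, hi = sims_sorted[rank - 1], sims_sorted[-rank]
    unstable = None
    if correction == "border":
        _, n_ref = _pcf_border(pts, None, window, grid)
        unstable = n_ref < 10
    return PcfResult(
        grid=grid, g_obs=g_obs, envelope_lo=lo, envelope_hi=hi,
        classification=_classify(g_obs, lo, hi, UNIVARIATE_CLASSES),
        n_sims=n_sims, rank=rank, n=n, unstable=unstable,
        metadata={"null": "csr", "correction": correction, "seed": seed},
    )


def _toroidal_shift(points: np.ndarray, window: Window,
                    rng: np.random.Generator) -> np.ndarray:
    if window.shape is not WindowShape.rectangle:
        raise ConfigurationError(
            "the toroidal-shift null requires a rectangular window; "
            "use null='csr2' for elliptical gaps"
        )
    xmin, ymin, xmax, ymax = window.bbox
    w_, h_ = xmax - xmin, ymax - ymin
    shift = rng.uniform(size=2) * np.array([w_, h_])
    out = points - np.array([xmin, ymin]) + shift
    out[:, 0] %= w_
    out[:, 1] %= h_
    return out + np.array([xmin, ymin])


def independence_envelope(points1, points2, window: Window, grid: DistanceGrid, *,
                          n_sims: int = 199, rank: int = 2,
                          null: Literal["toroidal", "csr2"] = "toroidal",
                          correction: Correction = "translation",
                          seed=None) -> PcfResult:
    """g12(r) with a pointwise bivariate independence envelope test.

    Pattern 1 is held fixed; each simulation perturbs pattern 2 under the
    chosen null: ``toroidal`` shifts it rigidly on the torus (preserving its
    internal structure — the independence null proper), ``csr2``
    re-randomises it as CSR with the same count. Exceedance above the upper
    envelope is classified attraction, below the lower repulsion.
    """
    p1, p2 = _as_points(points1), _as_points(points2)
    _check_rank(n_sims, rank)
    g_obs = cross_pcf(p1, p2, window, grid, correction)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, len(grid.r)))
    for i in range(n_sims):
        if null == "toroidal":
            q = _toroidal_shift(p2, window, rng)
        elif null == "csr2":
            q = _sample_csr(window, len(p2), rng)
        else:
            raise ConfigurationError(f"unknown bivariate null {null!r}")
        sims[i] = cross_pcf(p1, q, window, grid, correction)
    sims_sorted = np.sort(sims, axis=0)
    lo, hi = sims_sorted[rank - 1], sims_sorted[-rank]
    unstable = None
    if correction == "border":
        _, n_ref = _pcf_border(p1, p2, window, grid)
        unstable = n_ref < 10
    return PcfResult(
        grid=grid, g_obs=g_obs, envelope_lo=lo, envelope_hi=hi,
        classification=_classify(g_obs, lo, hi, BIVARIATE_CLASSES),
        n_sims=n_sims, rank=rank, n1=len(p1), n2=len(p2), unstable=unstable,
        metadata={"null": null, "correction": correction, "seed": seed},
    )


@dataclass(frozen=True)
class ScaleSummary:
    """Percentage of distance bins falling in each pattern class."""

    fractions: dict[str, float]  # percent, sums to 100
    n_bins: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.n_bins and abs(total - 100.0) > 1e-6:
            raise ValueError("class percentages must sum to 100")


def summarize_scales(result: PcfResult) -> ScaleSummary:
    """Fraction of examined distances in each class, as percentages.

    Mirrors statements of the form "clustered at 100% of scales examined".
    """
    classes = (UNIVARIATE_CLASSES
               if result.classification[0] in UNIVARIATE_CLASSES
               else BIVARIATE_CLASSES)
    n = len(result.classification)
    fractions = {
        c: 100.0 * result.classification.count(c) / n for c in classes
    }
    return ScaleSummary(fractions=fractions, n_bins=n)


def csr_rejection_rate(*, n_points: int, window: Window, grid: DistanceGrid,
                       r_eval: float, n_reps: int = 500, n_sims: int = 199,
                       rank: int = 2, correction: Correction = "translation",
                       seed=None) -> float:
    """Empirical pointwise rejection rate of the CSR envelope test at one
    distance, for patterns that are themselves CSR.

    Generates ``n_reps`` CSR patterns, builds a rank-based envelope from
    ``n_sims`` conditional CSR simulations for each, and returns the fraction
    whose observed g at ``r_eval`` falls outside the envelope. Calibration
    check: the result should match the nominal level 2*rank/(n_sims+1).
    """
    r = grid.r_array
    k = int(np.argmin(np.abs(r - r_eval)))
    if abs(r[k] - r_eval) > 1e-9:
        raise ConfigurationError(f"r_eval = {r_eval} is not on the distance grid")
    root = np.random.SeedSequence(seed)
    rejections = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        pts = _sample_csr(window, n_points, rng)
        g_obs = pcf(pts, window, grid, correction)[k]
        sims = np.empty(n_sims)
        for i in range(n_sims):
            sims[i] = pcf(_sample_csr(window, n_points, rng), window, grid,
                          correction)[k]
        sims.sort()
        if g_obs < sims[rank - 1] or g_obs > sims[-rank]:
            rejections += 1
    return rejections / n_reps
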