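"""Orchestration of the full gap-regeneration analysis.

A run takes either a directory of stem-map files or a list of synthetic
treatment presets, and produces a machine-readable results bundle:
importance-value tables (overall and per layer), richness and Shannon
diversity, upper-layer attainment fractions, height ANOVA/Tukey comparisons,
univariate pair-correlation envelope tests per layer, the bivariate
shrub-tree test in the lower layer, scale summaries, and mean kernel-density
rasters per shade-tolerance x layer group — written to an output directory
with a JSON manifest of content hashes.

Every default echoes the study's fixed constants: 3 m quadrats, three
height layers, 199 envelope simulations at rank 2 (pointwise level 0.02),
1 m KDE search radius, alpha 0.05.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import community, kde, pointpattern as pp
from .model import (
    GrowthForm,
    Layer,
    StemMap,
    Treatment,
    Window,
    WindowShape,
    read_stem_map,
    write_stem_map,
)
from .presets import PRESETS
from .synthetic import generate_stem_map

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run. Defaults are the study constants."""

    mode: str = "synthetic"  # "synthetic" | "files"
    treatments: tuple[str, ...] = ("PYG", "POG", "PCK", "SYG", "SOG", "SCK")
    n_replicates: int = 3
    seed: int = 0
    input_files: tuple[str, ...] = ()  # mode="files": stem-map CSV paths
    window_spec: dict = field(default_factory=dict)  # mode="files" geometry
    quadrat_side: float = 3.0
    r_max: float = 10.0
    r_step: float = 0.5
    half_width: float = 0.25
    n_sims: int = 199
    rank: int = 2
    bivariate_null: str = "toroidal"  # falls back to csr2 on elliptical gaps
    kde_radius: float = 1.0
    kde_cell: float = 0.25
    alpha: float = 0.05
    stages: tuple[str, ...] = ("metrics", "ppa", "kde")
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for t in self.treatments:
            Treatment(t)
        for s in self.stages:
            if s not in ("metrics", "ppa", "kde"):
                raise ValueError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("treatments", "stages", "input_files"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("treatments", "stages", "input_files"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def grid(self) -> pp.DistanceGrid:
        return pp.DistanceGrid.default(self.r_max, self.r_step, self.half_width)


@dataclass
class ResultsBundle:
    """In-memory results of a run; the on-disk layout mirrors this."""

    config: RunConfig
    stem_maps: dict[str, list[StemMap]]  # treatment -> replicate plots
    iv_tables: dict = field(default_factory=dict)
    richness: dict = field(default_factory=dict)
    shannon: dict = field(default_factory=dict)
    upper_fraction: dict = field(default_factory=dict)
    height_comparisons: dict = field(default_factory=dict)
    pcf_results: dict = field(default_factory=dict)
    bivariate_results: dict = field(default_factory=dict)
    scale_summaries: dict = field(default_factory=dict)
    mean_rasters: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _load_maps(config: RunConfig) -> dict[str, list[StemMap]]:
    maps: dict[str, list[StemMap]] = {t: [] for t in config.treatments}
    if config.mode == "synthetic":
        root = np.random.SeedSequence(config.seed)
        streams = root.spawn(len(config.treatments) * config.n_replicates)
        k = 0
        for t in config.treatments:
            preset = PRESETS[t]
            for rep in range(config.n_replicates):
                maps[t].append(generate_stem_map(
                    preset, streams[k], plot_id=f"{t}-{rep + 1}"))
                k += 1
    elif config.mode == "files":
        spec = config.window_spec
        shape = spec.get("shape", "rectangle")
        he = tuple(spec.get("half_extents", (15.0, 15.0)))
        window = Window(WindowShape(shape), (0.0, 0.0), he)
        for path in config.input_files:
            m = read_stem_map(path, window)
            maps.setdefault(m.treatment.value, []).append(m)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    return maps


def _grid_for(window: Window, config: RunConfig) -> pp.DistanceGrid:
    return config.grid().clipped_to(window)


def _age_class(treatment: str) -> str:
    return {"Y": "young", "O": "old", "C": "closed"}[treatment[1]]


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Run every enabled stage over all plots; write results and a manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps = _load_maps(config)
    bundle = ResultsBundle(config=config, stem_maps=maps)
    outputs: list[Path] = []

    for t, plots in maps.items():
        for m in plots:
            p = out / f"stemmap_{m.plot_id}.csv"
            write_stem_map(m, p)
            outputs.append(p)
            log.info("plot %s: %d stems, window area %.1f m^2",
                     m.plot_id, len(m), m.window.area)

    if "metrics" in config.stages:
        _stage_metrics(config, maps, bundle, out, outputs)
    if "ppa" in config.stages:
        _stage_ppa(config, maps, bundle, out, outputs)
    if "kde" in config.stages:
        _stage_kde(config, maps, bundle, out, outputs)

    cfg_path = out / "config.yaml"
    config.to_yaml(cfg_path)
    outputs.append(cfg_path)
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "elapsed_s": round(time.time() - t0, 2),
        "disabled_stages": [s for s in ("metrics", "ppa", "kde")
                            if s not in config.stages],
        "outputs": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outputs)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle.manifest = manifest
    return bundle


def _stage_metrics(config, maps, bundle, out: Path, outputs: list[Path]) -> None:
    for t, plots in maps.items():
        for m in plots:
            for stratum in (None, Layer.lower, Layer.medium, Layer.upper):
                for include in ("trees", "all"):
                    key = (m.plot_id, stratum.value if stratum else "overall",
                           include)
                    iv = community.compute_iv(m, config.quadrat_side,
                                              stratum=stratum, include=include)
                    bundle.iv_tables[key] = iv
                    p = out / f"iv_{m.plot_id}_{key[1]}_{include}.csv"
                    iv.write(p)
                    outputs.append(p)
            bundle.richness[m.plot_id] = {
                layer.value: community.species_richness(m, layer)
                for layer in Layer
            } | {"overall": community.species_richness(m)}
            bundle.shannon[m.plot_id] = {
                "all": community.diversity(m, "all").shannon,
                "trees": community.diversity(m, "trees").shannon,
            }
        try:
            bundle.upper_fraction[t] = community.upper_layer_fraction(plots)
        except ValueError:
            bundle.upper_fraction[t] = None

    # heights across gap-age classes, per forest type x shade tolerance
    for forest, codes in (("primary", ("PYG", "POG", "PCK")),
                          ("secondary", ("SYG", "SOG", "SCK"))):
        present = [c for c in codes if maps.get(c)]
        if len(present) < 2:
            continue
        for tol in ("light_demanding", "intermediate", "shade_tolerant"):
            heights = {}
            for c in present:
                h = [s.height for m in maps[c] for s in m.stems
                     if s.shade_tolerance.value == tol
                     and s.growth_form is GrowthForm.tree]
                if len(h) >= 2:
                    heights[_age_class(c)] = h
            if len(heights) >= 2:
                cmp_res = community.height_anova_tukey(heights, config.alpha)
                bundle.height_comparisons[(forest, tol)] = cmp_res
                p = out / f"heights_{forest}_{tol}.json"
                p.write_text(cmp_res.to_json())
                outputs.append(p)


def _stage_ppa(config, maps, bundle, out: Path, outputs: list[Path]) -> None:
    root = np.random.SeedSequence((config.seed, 1))
    for t, plots in maps.items():
        for m in plots:
            grid = _grid_for(m.window, config)
            correction = ("translation"
                          if m.window.shape is WindowShape.rectangle
                          else "border")
            for layer in Layer:
                pts = m.by_layer(layer).by_growth_form(GrowthForm.tree).coords()
                key = (m.plot_id, layer.value)
                if len(pts) < 2:
                    log.info("ppa: %s %s skipped (%d trees)",
                             m.plot_id, layer.value, len(pts))
                    continue
                res = pp.csr_envelope(
                    pts, m.window, grid, n_sims=config.n_sims,
                    rank=config.rank, correction=correction,
                    seed=root.spawn(1)[0])
                bundle.pcf_results[key] = res
                bundle.scale_summaries[key] = pp.summarize_scales(res)
                p = out / f"pcf_{m.plot_id}_{layer.value}.csv"
                res.write(p, out / f"pcf_{m.plot_id}_{layer.value}.json")
                outputs.extend([p, out / f"pcf_{m.plot_id}_{layer.value}.json"])
            # bivariate shrub-tree test, lower layer
            lower = m.by_layer(Layer.lower)
            shrubs = lower.by_growth_form(GrowthForm.shrub).coords()
            trees = lower.by_growth_form(GrowthForm.tree).coords()
            if len(shrubs) >= 1 and len(trees) >= 1:
                null = config.bivariate_null
                if (null == "toroidal"
                        and m.window.shape is not WindowShape.rectangle):
                    null = "csr2"
                res = pp.independence_envelope(
                    shrubs, trees, m.window, grid, n_sims=config.n_sims,
                    rank=config.rank, null=null, correction=correction,
                    seed=root.spawn(1)[0])
                bundle.bivariate_results[m.plot_id] = res
                bundle.scale_summaries[(m.plot_id, "shrub_tree")] = \
                    pp.summarize_scales(res)
                p = out / f"g12_{m.plot_id}_lower.csv"
                res.write(p, out / f"g12_{m.plot_id}_lower.json")
                outputs.extend([p, out / f"g12_{m.plot_id}_lower.json"])


def _stage_kde(config, maps, bundle, out: Path, outputs: list[Path]) -> None:
    for t, plots in maps.items():
        per_group: dict[tuple, list[kde.KdeRaster]] = {}
        # shared extent across replicates so rasters align on the gap centre
        pad = config.kde_radius
        xmin = min(m.window.bbox[0] for m in plots) - pad
        ymin = min(m.window.bbox[1] for m in plots) - pad
        xmax = max(m.window.bbox[2] for m in plots) + pad
        ymax = max(m.window.bbox[3] for m in plots) + pad
        for m in plots:
            rasters = kde.density_by_group(
                m, config.kde_radius, config.kde_cell,
                extent=(xmin, xmax, ymin, ymax))
            for key, raster in rasters.items():
                per_group.setdefault(key, []).append(raster)
        for (tol, layer), rasters in per_group.items():
            mean = kde.align_and_average(rasters)
            bundle.mean_rasters[(t, tol.value, layer.value)] = mean
            p = out / f"kde_{t}_{tol.value}_{layer.value}.asc"
            mean.write_asc(p)
            outputs.append(p)


def report(bundle: ResultsBundle) -> str:
    """Human-readable markdown summary of a results bundle."""
    lines = ["# Gap-regeneration analysis report", ""]
    any_stage = False
    if bundle.richness:
        any_stage = True
        lines.append("## Community metrics")
        for pid, r in sorted(bundle.richness.items()):
            sh = bundle.shannon.get(pid, {})
            lines.append(
                f"- {pid}: richness overall {r['overall']} "
                f"(lower {r['lower']}, medium {r['medium']}, upper {r['upper']}); "
                f"Shannon H = {sh.get('all', float('nan')):.2f} (all stems), "
                f"{sh.get('trees', float('nan')):.2f} (trees)"
            )
        for t, frac in sorted(bundle.upper_fraction.items()):
            if frac is not None:
                lines.append(f"- {t}: {frac}% of species reach the upper layer")
        lines.append("")
        lines.append("### Top-5 species by importance value (trees, overall)")
        for (pid, stratum, include), iv in sorted(bundle.iv_tables.items()):
            if stratum == "overall" and include == "trees" and iv.S:
                top = ", ".join(
                    f"{row.species} ({row.IV:.1f})"
                    for row in iv.table.head(5).itertuples())
                lines.append(f"- {pid}: {top}")
        lines.append("")
    if bundle.height_comparisons:
        any_stage = True
        lines.append("## Height ANOVA across gap ages")
        for (forest, tol), hc in sorted(bundle.height_comparisons.items()):
            letters = ", ".join(f"{g}={hc.letters[g]}" for g in hc.groups)
            f_txt = "inf" if hc.f_statistic == float("inf") else f"{hc.f_statistic:.2f}"
            lines.append(f"- {forest}/{tol}: F = {f_txt}, p = {hc.p_value:.3g}; "
                         f"letters: {letters}")
        lines.append("")
    if bundle.scale_summaries:
        any_stage = True
        lines.append("## Spatial pattern by scale")
        for key, summ in sorted(bundle.scale_summaries.items()):
            label = " ".join(key) if isinstance(key, tuple) else key
            parts = ", ".join(f"{c} at {p:.0f}% of scales"
                              for c, p in summ.fractions.items() if p > 0)
            lines.append(f"- {label}: {parts}")
        lines.append("")
    if bundle.mean_rasters:
        any_stage = True
        lines.append("## Mean kernel stem density (stems per m², raster maxima)")
        for (t, tol, layer), raster in sorted(bundle.mean_rasters.items()):
            lines.append(f"- {t} {tol} {layer}: max {raster.max():.2f}")
        lines.append("")
    if not any_stage:
        lines.append("No analysis stages were run.")
    return "\n".join(lines)
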