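"""Shipped treatment presets: PYG, POG, PCK, SYG, SOG, SCK.

Six treatments span young gaps (<10 yr), old gaps (10-20 yr) and
closed-canopy controls in primary broadleaved Korean pine forest (P*) and
in secondary birch-dominated forest (S*). Gap-area and gap-age parameters
are the printed field summaries: PYG 440.7 ± 153.7 m² at 6.3 ± 1.7 yr,
POG 612.7 ± 115.2 m² at 15 ± 1.6 yr, SYG 395.6 ± 80.7 m² at 6 ± 1.4 yr,
SOG 417.6 ± 78.6 m² at 14 ± 2.2 yr; controls are 30 m × 30 m plots.

Demographic structure encodes the qualitative findings the analysis is
built to detect:

* lower-layer regeneration is clustered (Thomas processes), densest for
  light-demanding species in young gaps and shifting toward intermediate /
  shade-tolerant species as gaps age;
* medium-layer trees are clustered at small scales in primary stands but
  spatially random in older secondary stands;
* upper-layer canopy trees are sparse and spatially random everywhere;
* lower-layer shrubs share cluster parents with lower-layer trees in young
  gaps (small-scale attraction).

Densities are plausible for temperate gap regeneration (plot means of a few
stems per m² in the lower layer of young gaps, dropping with gap age) and
are not fitted to any census.
"""
from __future__ import annotations

from .model import GrowthForm, Layer, ShadeTolerance, Treatment
from .synthetic import (
    CohortSpec,
    Interaction,
    InteractionSpec,
    ProcessKind,
    ProcessSpec,
    SpeciesEntry,
    TreatmentPreset,
)

_T = GrowthForm.tree
_S = GrowthForm.shrub
_LD = ShadeTolerance.light_demanding
_IM = ShadeTolerance.intermediate
_ST = ShadeTolerance.shade_tolerant


def _sp(name: str, form: GrowthForm, tol: ShadeTolerance, w: float) -> SpeciesEntry:
    return SpeciesEntry(name, form, tol, w)


# Species of the mixed broadleaved Korean pine forests of the Changbai
# region; shade-tolerance classes follow common silvicultural usage.
LD_TREES = (
    _sp("Betula platyphylla", _T, _LD, 3.0),
    _sp("Populus davidiana", _T, _LD, 1.5),
    _sp("Phellodendron amurense", _T, _LD, 0.6),
    _sp("Salix caprea", _T, _LD, 0.4),
)
IM_TREES = (
    _sp("Pinus koraiensis", _T, _IM, 1.0),
    _sp("Fraxinus mandshurica", _T, _IM, 1.2),
    _sp("Juglans mandshurica", _T, _IM, 0.8),
    _sp("Quercus mongolica", _T, _IM, 1.0),
    _sp("Ulmus japonica", _T, _IM, 0.6),
)
ST_TREES = (
    _sp("Acer mono", _T, _ST, 2.0),
    _sp("Tilia amurensis", _T, _ST, 1.4),
    _sp("Acer pseudosieboldianum", _T, _ST, 1.0),
    _sp("Abies holophylla", _T, _ST, 0.5),
    _sp("Carpinus cordata", _T, _ST, 0.4),
)
SHRUBS = (
    _sp("Corylus mandshurica", _S, _IM, 2.0),
    _sp("Lonicera praeflorens", _S, _ST, 1.0),
    _sp("Philadelphus schrenkii", _S, _ST, 0.8),
    _sp("Eleutherococcus senticosus", _S, _ST, 0.6),
    _sp("Syringa reticulata", _S, _LD, 0.5),
)

ALL_TREES = LD_TREES + IM_TREES + ST_TREES


def _thomas(intensity: float, parents: float = 0.05, sd: float = 1.0) -> ProcessSpec:
    return ProcessSpec(ProcessKind.thomas, intensity, parents_per_m2=parents,
                       cluster_sd=sd)


def _poisson(intensity: float) -> ProcessSpec:
    return ProcessSpec(ProcessKind.poisson, intensity)


def _lower(name: str, pool, proc: ProcessSpec, hmax: float = 5.0) -> CohortSpec:
    return CohortSpec(name=name, layer=Layer.lower, pool=pool, process=proc,
                      height_range=(0.1, hmax))


def _medium(pool, proc: ProcessSpec) -> CohortSpec:
    return CohortSpec(name="medium_trees", layer=Layer.medium, pool=pool,
                      process=proc, height_range=(5.0, 10.0),
                      allom_a=1.4, allom_b=1.2)


def _upper(pool, intensity: float) -> CohortSpec:
    return CohortSpec(name="upper_trees", layer=Layer.upper, pool=pool,
                      process=_poisson(intensity), height_range=(10.0, 25.0),
                      allom_a=1.8, allom_b=1.2)


def _shrub_cohort(intensity: float, sd: float = 1.0) -> CohortSpec:
    return _lower("lower_shrubs", SHRUBS, _thomas(intensity, sd=sd), hmax=4.0)


_SHARED = lambda: InteractionSpec(Interaction.shared_parents,
                                  "lower_ld_trees", "lower_shrubs")


def _gap_preset(treatment: Treatment, area, age, ld: float, im: float,
                st: float, shrub: float, medium_proc: ProcessSpec,
                upper: float, interaction: InteractionSpec | None
                ) -> TreatmentPreset:
    cohorts = (
        _lower("lower_ld_trees", LD_TREES, _thomas(ld)),
        _lower("lower_im_trees", IM_TREES, _thomas(im, parents=0.04, sd=1.2)),
        _lower("lower_st_trees", ST_TREES, _thomas(st, parents=0.04, sd=1.5)),
        _shrub_cohort(shrub),
        _medium(ALL_TREES, medium_proc),
        _upper(ALL_TREES, upper),
    )
    return TreatmentPreset(treatment=treatment, cohorts=cohorts, gap_area=area,
                           gap_age=age, aspect=0.8, interaction=interaction)


PYG = _gap_preset(Treatment.PYG, (440.7, 153.7), (6.3, 1.7),
                  ld=2.2, im=0.9, st=0.5, shrub=0.9,
                  medium_proc=_thomas(0.08, parents=0.02, sd=1.5), upper=0.03,
                  interaction=_SHARED())
POG = _gap_preset(Treatment.POG, (612.7, 115.2), (15.0, 1.6),
                  ld=0.8, im=1.4, st=0.8, shrub=0.7,
                  medium_proc=_thomas(0.15, parents=0.03, sd=2.0), upper=0.04,
                  interaction=_SHARED())
SYG = _gap_preset(Treatment.SYG, (395.6, 80.7), (6.0, 1.4),
                  ld=2.6, im=1.1, st=0.4, shrub=1.0,
                  medium_proc=_thomas(0.08, parents=0.02, sd=1.5), upper=0.03,
                  interaction=_SHARED())
SOG = _gap_preset(Treatment.SOG, (417.6, 78.6), (14.0, 2.2),
                  ld=1.0, im=1.6, st=0.6, shrub=0.8,
                  medium_proc=_poisson(0.15), upper=0.04,
                  interaction=_SHARED())

PCK = TreatmentPreset(
    treatment=Treatment.PCK,
    cohorts=(
        _lower("lower_ld_trees", LD_TREES, _thomas(0.35)),
        _lower("lower_im_trees", IM_TREES, _thomas(0.8, parents=0.04, sd=1.2)),
        _lower("lower_st_trees", ST_TREES, _thomas(0.7, parents=0.04, sd=1.5)),
        _shrub_cohort(0.5),
        _medium(ALL_TREES, _thomas(0.12, parents=0.03, sd=1.2)),
        _upper(ALL_TREES, 0.05),
    ),
    interaction=InteractionSpec(Interaction.mutual_inhibition,
                                "lower_st_trees", "lower_shrubs", param=0.5),
)
SCK = TreatmentPreset(
    treatment=Treatment.SCK,
    cohorts=(
        _lower("lower_ld_trees", LD_TREES, _thomas(0.3)),
        _lower("lower_im_trees", IM_TREES, _thomas(0.9, parents=0.04, sd=1.2)),
        _lower("lower_st_trees", ST_TREES, _thomas(0.6, parents=0.04, sd=1.5)),
        _shrub_cohort(0.5),
        _medium(ALL_TREES, _poisson(0.15)),
        _upper(ALL_TREES, 0.05),
    ),
    interaction=None,
)

PRESETS: dict[str, TreatmentPreset] = {
    "PYG": PYG, "POG": POG, "PCK": PCK, "SYG": SYG, "SOG": SOG, "SCK": SCK,
}


def get_preset(name: str) -> TreatmentPreset:
    try:
        return PRESETS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
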