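import numpy as np
import pytest

from gapregen.model import (
    DiameterKind,
    GrowthForm,
    ShadeTolerance,
    Stem,
    StemMap,
    Treatment,
    Window,
)


@pytest.fixture
def rect30() -> Window:
    return Window.rectangle(30.0, 30.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_stem(i: int, x: float, y: float, *, species: str = "Acer mono",
              height: float = 2.0, diameter: float = 2.0,
              form: GrowthForm = GrowthForm.tree,
              tol: ShadeTolerance = ShadeTolerance.shade_tolerant) -> Stem:
    return Stem(
        stem_id=f"s{i:04d}", species=species, growth_form=form,
        shade_tolerance=tol, x=x, y=y, height=height, diameter=diameter,
        diameter_kind=DiameterKind.dbh if height >= 1.3 else DiameterKind.rcd,
    )


def make_map(stems, window: Window | None = None,
             treatment: Treatment = Treatment.PCK,
             plot_id: str = "test") -> StemMap:
    return StemMap(
        plot_id=plot_id, treatment=treatment,
        window=window or Window.rectangle(30.0, 30.0),
        stems=tuple(stems),
    )


@pytest.fixture
def toy_map(rect30) -> StemMap:
    """4-quadrat toy plot (12 m x 12 m at 6 m quadrats).

    Species A: 6 stems in 3 quadrats, total basal area 0.06 m²;
    B: 3 stems, 2 quadrats, 0.03 m²; C: 1 stem, 1 quadrat, 0.01 m².
    Diameters chosen so pi*(d/200)^2 sums per species hit those areas.
    """
    import math

    def dia(area_each: float) -> float:
        return 200.0 * math.sqrt(area_each / math.pi)

    win = Window.rectangle(12.0, 12.0)
    stems = []
    # A: quadrats (-,-), (+,-), (-,+); 6 stems, 0.01 m² each
    pos_a = [(-3, -3), (-4, -4), (3, -3), (4, -4), (-3, 3), (-4, 4)]
    for i, (x, y) in enumerate(pos_a):
        stems.append(make_stem(i, x, y, species="A", diameter=dia(0.01)))
    pos_b = [(3, 3), (4, 4), (3, -4)]
    for i, (x, y) in enumerate(pos_b, start=10):
        stems.append(make_stem(i, x, y, species="B", diameter=dia(0.01)))
    stems.append(make_stem(20, -5, -5, species="C", diameter=dia(0.01)))
    return make_map(stems, win)
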