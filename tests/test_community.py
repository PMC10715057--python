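import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gapregen.community import (
    _compact_letters,
    compute_iv,
    diversity,
    height_anova_tukey,
    pooled_richness,
    shannon_index,
    species_richness,
    upper_layer_fraction,
)
from gapregen.model import Layer, Window
from gapregen.presets import PRESETS
from gapregen.synthetic import generate_stem_map

from .conftest import make_map, make_stem


class TestImportanceValue:
    def test_toy_plot_hand_computed(self, toy_map):
        """A 6/3/1-stem, 3/2/1-quadrat, 0.06/0.03/0.01 m² toy plot:
        RD = RC = (60, 30, 10), RF = (50, 33.33, 16.67)."""
        iv = compute_iv(toy_map, quadrat_side=6.0)
        t = iv.table.set_index("species")
        assert t.loc["A", "IV"] == pytest.approx(56.6667, abs=1e-2)
        assert t.loc["B", "IV"] == pytest.approx(31.1111, abs=1e-2)
        assert t.loc["C", "IV"] == pytest.approx(12.2222, abs=1e-2)
        assert t.loc["A", "RF"] == pytest.approx(50.0, abs=1e-9)

    def test_monoculture_iv_100(self, rect30):
        m = make_map([make_stem(i, x, 0.0) for i, x in enumerate([-5, 0, 5])],
                     rect30)
        iv = compute_iv(m)
        assert iv.S == 1
        assert iv.table.IV.iloc[0] == pytest.approx(100.0)

    def test_symmetric_species_split_evenly(self, rect30):
        stems = [make_stem(0, -5, -5, species="X"),
                 make_stem(1, 5, 5, species="Y")]
        iv = compute_iv(make_map(stems, rect30))
        assert iv.table.IV.tolist() == pytest.approx([50.0, 50.0])

    def test_empty_stratum_empty_table(self, rect30):
        m = make_map([make_stem(0, 0, 0, height=2.0)], rect30)
        iv = compute_iv(m, stratum=Layer.upper)
        assert iv.S == 0

    @pytest.mark.parametrize("preset", ["PYG", "SCK"])
    def test_components_sum_to_100_on_synthetic_maps(self, preset):
        m = generate_stem_map(PRESETS[preset], 17)
        for include in ("trees", "all"):
            iv = compute_iv(m, include=include)
            for col in ("RD", "RF", "RC", "IV"):
                assert iv.table[col].sum() == pytest.approx(100.0, abs=1e-9)
            assert ((iv.table.IV >= 0) & (iv.table.IV <= 100)).all()
            assert (iv.table.IV.diff().dropna() <= 1e-12).all()  # sorted desc


class TestRichnessAndShannon:
    def test_richness_counts_distinct_species(self, rect30):
        stems = [make_stem(i, i - 5.0, 0.0, species=sp)
                 for i, sp in enumerate("AABBBCCCCC")]
        m = make_map(stems, rect30)
        assert species_richness(m) == 3
        assert species_richness(make_map([], rect30)) == 0

    def test_pooled_richness_is_union(self, rect30):
        m1 = make_map([make_stem(0, 0, 0, species="A")], rect30)
        m2 = make_map([make_stem(0, 1, 1, species="B"),
                       make_stem(1, 2, 2, species="A")], rect30)
        pooled = pooled_richness([m1, m2])
        assert pooled == 2
        assert pooled >= max(species_richness(m1), species_richness(m2))

    def test_shannon_known_values(self):
        assert shannon_index([7]) == pytest.approx(0.0)
        assert shannon_index([5, 5, 5, 5]) == pytest.approx(math.log(4), abs=1e-12)
        assert shannon_index([0.5, 0.3, 0.2]) == pytest.approx(1.0297, abs=1e-4)

    def test_shannon_excludes_zeros_and_rejects_all_zero(self):
        assert shannon_index([3, 0, 3]) == pytest.approx(math.log(2))
        with pytest.raises(ValueError):
            shannon_index([0, 0])

    @given(st.lists(st.integers(1, 50), min_size=2, max_size=8))
    @settings(derandomize=True, max_examples=100)
    def test_shannon_permutation_invariant_and_bounded(self, abund):
        h = shannon_index(abund)
        assert h == pytest.approx(shannon_index(list(reversed(abund))))
        assert -1e-12 <= h <= math.log(len(abund)) + 1e-12

    def test_evening_an_abundance_vector_raises_shannon(self):
        # transfer from the most to the least abundant species
        assert shannon_index([5, 5]) > shannon_index([8, 2])
        assert shannon_index([4, 3, 3]) > shannon_index([6, 3, 1])


class TestUpperLayerFraction:
    def test_half_reach_upper(self, rect30):
        stems = []
        for i in range(10):
            stems.append(make_stem(i, i - 5.0, 0.0, species=f"sp{i}",
                                   height=2.0))
        for i in range(5):  # 5 of the 10 species also in the upper layer
            stems.append(make_stem(100 + i, i - 5.0, 3.0, species=f"sp{i}",
                                   height=12.0, diameter=20.0))
        assert upper_layer_fraction(make_map(stems, rect30)) == 50.0

    def test_rounding_to_one_decimal(self, rect30):
        stems = [make_stem(i, (i % 25) - 12.0, i // 25 - 10.0,
                           species=f"sp{i}", height=2.0) for i in range(39)]
        stems += [make_stem(100 + i, (i % 25) - 12.0, 12.0, species=f"sp{i}",
                            height=12.0, diameter=20.0) for i in range(14)]
        assert upper_layer_fraction(make_map(stems, rect30)) == 35.9

    def test_no_upper_layer_stems(self, rect30):
        m = make_map([make_stem(0, 0, 0, height=2.0)], rect30)
        assert upper_layer_fraction(m) == 0.0

    def test_empty_plot_is_domain_error(self, rect30):
        with pytest.raises(ValueError):
            upper_layer_fraction(make_map([], rect30))


def brute_force_anova_f(groups: dict) -> float:
    """Independent sums-of-squares oracle."""
    allv = [v for arr in groups.values() for v in arr]
    grand = sum(allv) / len(allv)
    ssb = sum(len(arr) * (sum(arr) / len(arr) - grand) ** 2
              for arr in groups.values())
    ssw = sum((v - sum(arr) / len(arr)) ** 2
              for arr in groups.values() for v in arr)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestHeightAnova:
    def test_printed_toy_f_73(self):
        groups = {"A": [1, 2, 3], "B": [2, 3, 4], "C": [10, 11, 12]}
        res = height_anova_tukey(groups)
        assert res.f_statistic == pytest.approx(73.0, abs=1e-10)
        assert res.f_statistic == pytest.approx(brute_force_anova_f(groups))
        assert (res.df_between, res.df_within) == (2, 6)
        # C differs from both A and B; A and B share a letter
        assert set(res.letters["A"]) & set(res.letters["B"])
        assert not set(res.letters["C"]) & set(res.letters["A"])
        assert not set(res.letters["C"]) & set(res.letters["B"])

    def test_identical_groups_share_one_letter(self):
        res = height_anova_tukey({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0)
        assert res.letters["A"] == res.letters["B"]

    @given(st.lists(st.lists(st.floats(0.2, 20.0), min_size=3, max_size=9),
                    min_size=2, max_size=4))
    @settings(derandomize=True, max_examples=50)
    def test_f_matches_brute_force(self, data):
        groups = {f"g{i}": arr for i, arr in enumerate(data)}
        if any(max(arr) - min(arr) < 1e-3 for arr in data):
            return  # (near-)degenerate within-group variance covered separately
        res = height_anova_tukey(groups)
        assert res.f_statistic == pytest.approx(
            brute_force_anova_f(groups), abs=1e-10, rel=1e-10)

    def test_letter_semantics_match_tukey_alpha(self, rng):
        heights = {g: rng.normal(mu, 1.0, size=30)
                   for g, mu in [("young", 1.5), ("old", 2.2), ("closed", 4.0)]}
        res = height_anova_tukey(heights, alpha=0.05)
        for (a, b), p in res.tukey_p.items():
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            assert share == (p >= 0.05)

    def test_zero_variance_unequal_means_flagged(self):
        res = height_anova_tukey({"A": [1.0, 1.0], "B": [2.0, 2.0]})
        assert math.isinf(res.f_statistic) and res.p_value == 0.0
        assert not set(res.letters["A"]) & set(res.letters["B"])

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            height_anova_tukey({"A": [1.0], "B": [1.0, 2.0]})


class TestCompactLetters:
    def test_chain_structure(self):
        # A > B > C with only A-C significant: A=a, B=ab, C=b
        letters = _compact_letters(
            ["A", "B", "C"], {"A": 3.0, "B": 2.0, "C": 1.0}, {("A", "C")})
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_all_different(self):
        letters = _compact_letters(
            ["A", "B", "C"], {"A": 3.0, "B": 2.0, "C": 1.0},
            {("A", "B"), ("A", "C"), ("B", "C")})
        assert len({letters[g] for g in "ABC"}) == 3
        for g in "ABC":
            assert len(letters[g]) == 1


class TestDiversityOnSyntheticMaps:
    def test_tree_only_and_all_modes_reported(self):
        m = generate_stem_map(PRESETS["POG"], 23)
        d_all = diversity(m, "all")
        d_tree = diversity(m, "trees")
        assert d_all.richness >= d_tree.richness
        assert 0 <= d_tree.shannon <= math.log(max(2, d_tree.richness))
        assert sum(d_all.proportions) == pytest.approx(1.0)
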