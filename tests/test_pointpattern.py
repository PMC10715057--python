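import math

import numpy as np
import pytest

from gapregen.model import ConfigurationError, Window
from gapregen.pointpattern import (
    DistanceGrid,
    _sample_csr,
    cross_pcf,
    csr_envelope,
    independence_envelope,
    k_function,
    pcf,
    summarize_scales,
)

W30 = Window.rectangle(30, 30)


def naive_pair_sums(points, window, grid, correction):
    """O(n²) enumeration oracle with explicit Python loops.

    Returns (g, K, annulus weight multisets, cumulative weight multisets);
    the multisets (sorted per-bin weight tuples) identify exactly which
    weighted pairs each bin received.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    a, b = window.half_extents
    W, H = 2 * a, 2 * b
    r = grid.r_array
    h = grid.half_width
    ann = [[] for _ in r]
    cum = [[] for _ in r]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = pts[i, 0] - pts[j, 0]
            dy = pts[i, 1] - pts[j, 1]
            d = math.hypot(dx, dy)
            if correction == "translation":
                w = (W * H) / ((W - abs(dx)) * (H - abs(dy)))
            else:
                w = 1.0
            for k, rk in enumerate(r):
                if rk - h < d <= rk + h:
                    ann[k].append(w)
                if d <= rk:
                    cum[k].append(w)
    s = window.area
    ann_sums = np.array([math.fsum(ws) for ws in ann])
    cum_sums = np.array([math.fsum(ws) for ws in cum])
    g = s / (n * (n - 1)) * ann_sums / (2 * math.pi * r * 2 * h)
    kf = s / (n * (n - 1)) * cum_sums
    ann_sets = [tuple(sorted(ws)) for ws in ann]
    cum_sets = [tuple(sorted(ws)) for ws in cum]
    return g, kf, ann_sets, cum_sets


def impl_pair_multisets(points, window, grid, correction):
    """Per-bin weight multisets as the package's vectorised pair machinery
    assigns them (same code path the estimators use)."""
    from gapregen.pointpattern import _pair_data

    pts = np.asarray(points, float)
    d, w = _pair_data(pts, None, window, correction)
    valid = d >= 0
    d, w = d[valid], w[valid]
    r = grid.r_array
    h = grid.half_width
    ann = [tuple(sorted(w[(d > rk - h) & (d <= rk + h)])) for rk in r]
    cum = [tuple(sorted(w[d <= rk])) for rk in r]
    return ann, cum


class TestKFunction:
    def test_three_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        w = Window.rectangle(10, 10)
        grid = DistanceGrid((1.5,), 0.25)
        k = k_function(pts, w, grid, correction="none")
        # 4 of 6 ordered pairs within 1.5 m, s = 100 m²
        assert k[0] == pytest.approx(100.0 * 4 / 6)

    def test_zero_below_min_pair_distance(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        grid = DistanceGrid((1.0, 2.0), 0.25)
        assert k_function(pts, W30, grid).tolist() == [0.0, 0.0]

    def test_monotone_nondecreasing(self):
        pts = _sample_csr(W30, 300, np.random.default_rng(3))
        k = k_function(pts, W30, DistanceGrid.default())
        assert (np.diff(k) >= -1e-12).all()

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            k_function(np.array([[0.0, 0.0]]), W30, DistanceGrid.default())


class TestPcf:
    def test_nonnegative(self):
        pts = _sample_csr(W30, 200, np.random.default_rng(0))
        assert (pcf(pts, W30, DistanceGrid.default()) >= 0).all()

    def test_hard_core_zero_below_core(self):
        from gapregen.synthetic import simulate_inhibition

        pts = simulate_inhibition(Window.rectangle(60, 60), 0.03, 2.0, 2)
        grid = DistanceGrid.default()
        g = grid.r_array + grid.half_width < 2.0
        assert (pcf(pts, Window.rectangle(60, 60), grid)[g] == 0.0).all()

    def test_r_max_beyond_window_rejected(self):
        with pytest.raises(ConfigurationError):
            pcf(np.zeros((5, 2)), Window.rectangle(10, 10),
                DistanceGrid.default(r_max=10.0))

    def test_translation_invariance(self):
        """Shifting points and window together leaves estimates unchanged."""
        rng = np.random.default_rng(8)
        pts = _sample_csr(W30, 150, rng)
        grid = DistanceGrid.default(r_max=5.0)
        g0 = pcf(pts, W30, grid)
        shift = np.array([112.5, -47.25])
        w2 = Window.rectangle(30, 30, center=tuple(shift))
        g1 = pcf(pts + shift, w2, grid)
        np.testing.assert_allclose(g0, g1, atol=1e-9)

    def test_rotation_invariance_square_window(self):
        """A 90-degree rotation maps the square window onto itself; the
        estimate is unchanged (isotropy of the mathematics)."""
        rng = np.random.default_rng(9)
        pts = _sample_csr(W30, 150, rng)
        grid = DistanceGrid.default(r_max=5.0)
        rot = np.column_stack((-pts[:, 1], pts[:, 0]))
        np.testing.assert_allclose(pcf(pts, W30, grid), pcf(rot, W30, grid),
                                   atol=1e-9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("correction", ["translation", "none"])
    def test_matches_naive_enumeration(self, correction):
        rng = np.random.default_rng(123)
        grid = DistanceGrid.default(r_max=5.0)
        for _ in range(20):
            n = int(rng.integers(3, 51))
            pts = _sample_csr(W30, n, rng)
            g_naive, k_naive, ann, cum = naive_pair_sums(
                pts, W30, grid, correction)
            # identical bin membership and edge weights, pair for pair
            ann_impl, cum_impl = impl_pair_multisets(pts, W30, grid, correction)
            assert ann_impl == ann
            assert cum_impl == cum
            # estimates agree to summation-order precision
            np.testing.assert_allclose(
                pcf(pts, W30, grid, correction), g_naive, rtol=1e-12)
            np.testing.assert_allclose(
                k_function(pts, W30, grid, correction), k_naive, rtol=1e-12)


class TestCrossPcf:
    def test_shifted_copy_peaks_at_shift_distance(self):
        rng = np.random.default_rng(5)
        p1 = _sample_csr(Window.rectangle(28, 28), 150, rng)
        delta = np.array([1.95, 0.0])
        p2 = p1 + delta
        grid = DistanceGrid.default(r_max=5.0)
        g12 = cross_pcf(p1, p2, W30, grid, correction="none")
        peak_bin = int(np.argmax(g12))
        expect_bin = int(np.argmin(np.abs(grid.r_array - np.hypot(*delta))))
        assert peak_bin == expect_bin

    def test_independent_csr_near_one(self):
        rng = np.random.default_rng(6)
        grid = DistanceGrid.default(r_max=5.0)
        acc = np.zeros(len(grid.r))
        n_sims = 200
        for _ in range(n_sims):
            p1 = _sample_csr(W30, 150, rng)
            p2 = _sample_csr(W30, 150, rng)
            acc += cross_pcf(p1, p2, W30, grid)
        mean = acc / n_sims
        sel = (grid.r_array >= 1.0) & (grid.r_array <= 5.0)
        assert np.abs(mean[sel] - 1.0).max() < 0.05

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            cross_pcf(np.zeros((0, 2)), np.zeros((3, 2)), W30,
                      DistanceGrid.default())


class TestEnvelopes:
    def test_nominal_level_and_rank_validation(self):
        pts = _sample_csr(W30, 80, np.random.default_rng(1))
        res = csr_envelope(pts, W30, DistanceGrid.default(r_max=5.0),
                           n_sims=199, rank=2, seed=0)
        assert res.nominal_level == pytest.approx(0.02)
        with pytest.raises(ConfigurationError):
            csr_envelope(pts, W30, DistanceGrid.default(), n_sims=9, rank=5)

    def test_envelope_ordering_and_determinism(self):
        pts = _sample_csr(W30, 80, np.random.default_rng(2))
        grid = DistanceGrid.default(r_max=5.0)
        a = csr_envelope(pts, W30, grid, n_sims=39, seed=7)
        b = csr_envelope(pts, W30, grid, n_sims=39, seed=7)
        assert (a.envelope_lo <= a.envelope_hi).all()
        np.testing.assert_array_equal(a.envelope_lo, b.envelope_lo)
        np.testing.assert_array_equal(a.envelope_hi, b.envelope_hi)
        assert a.classification == b.classification

    def test_classification_consistent_with_envelopes(self):
        pts = _sample_csr(W30, 120, np.random.default_rng(3))
        res = csr_envelope(pts, W30, DistanceGrid.default(r_max=5.0),
                           n_sims=99, seed=1)
        for g, lo, hi, cls in zip(res.g_obs, res.envelope_lo,
                                  res.envelope_hi, res.classification):
            expected = ("clustered" if g > hi
                        else "regular" if g < lo else "random")
            assert cls == expected

    def test_independence_envelope_tags_bivariate_classes(self):
        rng = np.random.default_rng(4)
        p1 = _sample_csr(W30, 90, rng)
        p2 = _sample_csr(W30, 90, rng)
        res = independence_envelope(p1, p2, W30,
                                    DistanceGrid.default(r_max=5.0),
                                    n_sims=39, seed=2)
        assert set(res.classification) <= {"attraction", "independent",
                                           "repulsion"}
        assert res.n1 == 90 and res.n2 == 90

    def test_toroidal_requires_rectangle(self):
        w = Window.ellipse(10, 8)
        rng = np.random.default_rng(5)
        p1, p2 = _sample_csr(w, 50, rng), _sample_csr(w, 50, rng)
        with pytest.raises(ConfigurationError):
            independence_envelope(p1, p2, w, DistanceGrid.default(r_max=5.0),
                                  n_sims=19, null="toroidal", seed=0)
        res = independence_envelope(p1, p2, w, DistanceGrid.default(r_max=5.0),
                                    n_sims=19, null="csr2",
                                    correction="border", seed=0)
        assert len(res.classification) == 10


class TestScaleSummary:
    def test_counting(self):
        pts = _sample_csr(W30, 100, np.random.default_rng(6))
        res = csr_envelope(pts, W30, DistanceGrid.default(), n_sims=19, seed=3)
        res.classification = ["clustered"] * 5 + ["random"] * 15
        summ = summarize_scales(res)
        assert summ.fractions == {"clustered": 25.0, "random": 75.0,
                                  "regular": 0.0}
        assert sum(summ.fractions.values()) == pytest.approx(100.0)
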