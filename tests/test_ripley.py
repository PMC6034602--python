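import numpy as np
import pytest

from cytospat.errors import (
    GridAlignmentError,
    InsufficientDataError,
    InvalidParameterError,
)
from cytospat.ripley import (
    EnvelopeResult,
    KFunctionResult,
    classify_pattern,
    csr_envelope,
    default_r_grid,
    k_function,
)
from cytospat.geometry import MarkedPointPattern, PlotWindow
from cytospat.simulate import simulate_csr, simulate_thomas

from conftest import make_pattern


def brute_force_k(coords: np.ndarray, r: np.ndarray, area: float) -> np.ndarray:
    """Naive O(n^2) double-loop estimator, no edge correction."""
    n = len(coords)
    k = np.zeros_like(r, dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.hypot(*(coords[i] - coords[j])))
            k += d <= r
    return area / (n * (n - 1)) * k


class TestKFunction:
    def test_two_point_closed_form(self, unit_window):
        pat = make_pattern(unit_window, [(0.2, 0.5), (0.7, 0.5)])
        r = np.array([0.1, 0.3, 0.49, 0.5, 0.8])
        res = k_function(pat, r, edge_correction="none")
        np.testing.assert_allclose(res.k_hat, [0, 0, 0, 1, 1])
        np.testing.assert_allclose(res.k_theo, np.pi * r**2)

    def test_matches_brute_force_small(self, square100):
        rng = np.random.default_rng(0)
        r = np.linspace(0, 25, 40)
        for trial in range(10):
            n = rng.integers(5, 31)
            coords = rng.uniform(0, 100, (n, 2))
            pat = make_pattern(square100, coords)
            res = k_function(pat, r, edge_correction="none")
            np.testing.assert_array_equal(
                res.k_hat, brute_force_k(coords, r, 1e4)
            )

    def test_nondecreasing_in_r(self, square100):
        for seed, gen in ((1, "csr"), (2, "thomas")):
            pat = (
                simulate_csr(square100, 150, seed)
                if gen == "csr"
                else simulate_thomas(square100, 0.005, 10, 2.0, seed)
            )
            for corr in ("none", "translation"):
                res = k_function(pat, edge_correction=corr)
                assert np.all(np.diff(res.k_hat) >= -1e-12)
                assert np.all(res.k_hat >= 0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 100, (80, 2))
        r = np.linspace(0, 20, 50)
        w0 = PlotWindow("a", ((0, 0), (100, 0), (100, 100), (0, 100)))
        base = k_function(make_pattern(w0, coords), r).k_hat
        for dx, dy in [(57.0, -12.0), (-3.5, 1e4)]:
            w1 = PlotWindow(
                "b", tuple((x + dx, y + dy) for x, y in w0.vertices)
            )
            shifted = k_function(make_pattern(w1, coords + [dx, dy]), r).k_hat
            np.testing.assert_allclose(shifted, base, rtol=1e-9)

    def test_translation_weights_at_least_one(self, square100):
        from cytospat.ripley import _translation_weights

        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 100, (50, 2))
        assert np.all(_translation_weights(coords, square100) >= 1.0)

    def test_translation_on_general_polygon_matches_rectangle(self):
        # same rectangle entered with vertices rotated so the fast path
        # is bypassed and the shapely intersection path is exercised
        w_fast = PlotWindow("r", ((0, 0), (50, 0), (50, 30), (0, 30)))
        w_slow = PlotWindow("r2", ((25, 0), (50, 0), (50, 30), (0, 30), (0, 0)))
        assert w_slow.as_rectangle() is None
        rng = np.random.default_rng(5)
        coords = rng.uniform((0, 0), (50, 30), (25, 2))
        r = np.linspace(0, 10, 20)
        k1 = k_function(make_pattern(w_fast, coords), r).k_hat
        k2 = k_function(make_pattern(w_slow, coords), r).k_hat
        np.testing.assert_allclose(k1, k2, rtol=1e-9)

    def test_csr_mean_matches_theory(self, square100):
        """Mean K-hat over 200 CSR simulations tracks pi r^2 within 5 %
        for r in [2, 15] m (translation correction, n=500)."""
        r = np.linspace(2, 15, 14)
        acc = np.zeros_like(r)
        for s in range(200):
            pat = simulate_csr(square100, 500, seed=5000 + s)
            acc += k_function(pat, r).k_hat
        np.testing.assert_allclose(acc / 200, np.pi * r**2, rtol=0.05)

    def test_errors(self, square100):
        pat = simulate_csr(square100, 1, seed=1)
        with pytest.raises(InsufficientDataError):
            k_function(pat)
        pat = simulate_csr(square100, 10, seed=1)
        with pytest.raises(InvalidParameterError):
            k_function(pat, np.linspace(0, 80, 10))  # beyond admissible range
        with pytest.raises(InvalidParameterError):
            k_function(pat, np.array([0.0, 0.0, 1.0]))  # not increasing
        with pytest.raises(InvalidParameterError):
            k_function(pat, np.linspace(0, 10, 5), edge_correction="isotropic")

    def test_default_grid(self, square100):
        r = default_r_grid(square100)
        assert r.size == 512 and r[0] == 0.0 and r[-1] == pytest.approx(25.0)


def _fake_env(r, lo, hi, k_hat):
    k = KFunctionResult(r=r, k_hat=k_hat, edge_correction="none",
                        n_used=10, window_area=1.0)
    return k, (r, lo, hi)


class TestClassification:
    def test_midline_is_random(self):
        r = np.linspace(0, 10, 20)
        lo, hi = np.pi * r**2 * 0.8, np.pi * r**2 * 1.2 + 1
        k, env = _fake_env(r, lo, hi, (lo + hi) / 2)
        labels, intervals = classify_pattern(k, env)
        assert np.all(labels == "random")
        assert intervals["random"] == [(0.0, 10.0)]
        assert intervals["clumped"] == []

    def test_above_is_clumped_below_is_regular(self):
        r = np.linspace(0, 10, 20)
        lo, hi = np.pi * r**2 * 0.8, np.pi * r**2 * 1.2 + 1
        k, env = _fake_env(r, lo, hi, hi + 1)
        assert np.all(classify_pattern(k, env)[0] == "clumped")
        k, env = _fake_env(r, lo, hi, lo - 1)
        assert np.all(classify_pattern(k, env)[0] == "regular")

    def test_grid_mismatch(self):
        r = np.linspace(0, 10, 20)
        k, _ = _fake_env(r, r, r, r)
        with pytest.raises(GridAlignmentError):
            classify_pattern(k, (r[:-1], r[:-1], r[:-1]))


class TestEnvelope:
    def test_bounds_order_and_reproducibility(self, square100):
        pat = simulate_csr(square100, 100, seed=9)
        r = np.linspace(0, 12, 25)
        env1 = csr_envelope(pat, r, n_sim=39, seed=10)
        env2 = csr_envelope(pat, r, n_sim=39, seed=10)
        assert np.all(env1.lo <= env1.hi)
        np.testing.assert_array_equal(env1.lo, env2.lo)
        np.testing.assert_array_equal(env1.hi, env2.hi)
        np.testing.assert_array_equal(env1.classification, env2.classification)

    def test_invalid_n_sim(self, square100):
        pat = simulate_csr(square100, 50, seed=1)
        with pytest.raises(InvalidParameterError):
            csr_envelope(pat, n_sim=1, seed=2)
        with pytest.raises(InvalidParameterError):
            csr_envelope(pat, n_sim=10, rank=6, seed=2)

    def test_near_regular_pattern_detected(self, square100):
        """A jittered grid is classified regular at small r in >=90 %
        of 100 trials."""
        side = np.arange(15) * (100 / 15) + 100 / 30
        gx, gy = np.meshgrid(side, side)
        base = np.column_stack([gx.ravel(), gy.ravel()])
        r = np.linspace(0.5, 5, 10)
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(600 + s)
            coords = np.clip(base + rng.uniform(-0.5, 0.5, base.shape), 0, 100)
            env = csr_envelope(
                make_pattern(square100, coords), r, n_sim=99, seed=700 + s
            )
            hits += np.any(env.classification == "regular")
        assert hits >= 90
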