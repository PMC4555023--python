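"""The piecewise-linear nonlinear regression estimator and its delay scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from h2sync import (
    DEFAULT_CONFIG,
    AnalysisConfig,
    Direction,
    directed_pair_estimate,
    fit_piecewise_curve,
    h2_coefficient,
    h2_delay_scan,
)
from h2sync.h2core import DegenerateSignalError


def brute_force_bin_means(x, y, n_bins):
    """Independent oracle: per-bin conditional means by explicit grouping."""
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    ax, ay = [], []
    for b in range(n_bins):
        if b < n_bins - 1:
            mask = (x >= edges[b]) & (x < edges[b + 1])
        else:
            mask = (x >= edges[b]) & (x <= edges[b + 1])
        if mask.any():
            ax.append(x[mask].mean())
            ay.append(y[mask].mean())
    return np.array(ax), np.array(ay)


class TestPiecewiseCurve:
    def test_linear_data_reproduced_exactly(self):
        x = np.linspace(-1, 1, 512)
        curve = fit_piecewise_curve(x, x, n_bins=10)
        assert np.allclose(curve(x), x, atol=1e-12)

    @pytest.mark.parametrize("n_bins", [4, 10, 16])
    def test_anchors_match_brute_force_bin_means(self, n_bins, rng):
        x = rng.uniform(-1, 1, 2048)
        y = x**2
        curve = fit_piecewise_curve(x, y, n_bins=n_bins)
        ax, ay = brute_force_bin_means(x, y, n_bins)
        assert np.allclose(curve.anchor_x, ax, atol=1e-12)
        assert np.allclose(curve.anchor_y, ay, atol=1e-12)

    def test_empty_interior_bin_merges_away(self):
        # a gap in x leaves one bin of 4 empty -> 3 anchors
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(3, 4, 50)])
        y = x.copy()
        curve = fit_piecewise_curve(x, y, n_bins=4)
        assert curve.n_anchors == 3

    def test_constant_predictor_raises(self):
        with pytest.raises(DegenerateSignalError):
            fit_piecewise_curve(np.ones(100), np.arange(100.0))


class TestH2Coefficient:
    def test_identity_and_affine_are_exact(self):
        x = np.linspace(-1, 1, 512)
        assert h2_coefficient(x, x) == 1.0
        assert h2_coefficient(x, 2 * x + 3) == 1.0

    def test_quadratic_dependence_seen_by_h2_not_pearson(self, rng):
        x = rng.uniform(-1, 1, 512)
        y = x**2
        assert h2_coefficient(x, y) >= 0.9
        assert np.corrcoef(x, y)[0, 1] ** 2 <= 0.05

    def test_independent_noise_gives_small_h2(self):
        vals = []
        for s in range(200):
            r = np.random.default_rng(s)
            vals.append(h2_coefficient(r.standard_normal(512), r.standard_normal(512)))
        assert np.median(vals) <= 0.15

    def test_degenerate_inputs_return_zero(self):
        x = np.linspace(0, 1, 100)
        assert h2_coefficient(np.ones(100), x) == 0.0
        assert h2_coefficient(x, np.ones(100)) == 0.0

    def test_asymmetric_on_two_valued_inverse(self, rng):
        # y = x^2 with symmetric x: the forward map is a function, the
        # inverse is two-valued, so h2 must be strongly asymmetric
        x = rng.uniform(-1, 1, 1024)
        y = x**2
        assert h2_coefficient(x, y) - h2_coefficient(y, x) >= 0.2

    def test_matches_squared_correlation_on_gaussian_pairs(self):
        for rho in (0.0, 0.5, 0.9):
            errs = []
            for s in range(200):
                r = np.random.default_rng(s)
                x = r.standard_normal(512)
                y = rho * x + np.sqrt(1 - rho**2) * r.standard_normal(512)
                errs.append(h2_coefficient(x, y))
            assert abs(np.mean(errs) - rho**2) <= 0.05

    def test_monotone_in_coupling_strength(self):
        cs = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        means = []
        for c in cs:
            vals = []
            for s in range(30):
                r = np.random.default_rng(s)
                x = r.standard_normal(512)
                xi = r.standard_normal(512)
                y = (1 - c) * xi + c * np.tanh(3 * x)
                vals.append(h2_coefficient(x, y))
            means.append(np.mean(vals))
        assert np.all(np.diff(means) >= 0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_range_invariant_on_random_signals(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(256)
        y = r.standard_normal(256) + r.uniform(-1, 1) * x
        assert 0.0 <= h2_coefficient(x, y) <= 1.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        a=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-5, 5),
        c=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
        d=st.floats(-5, 5),
    )
    def test_affine_invariance(self, a, b, c, d):
        r = np.random.default_rng(7)
        x = r.standard_normal(400)
        y = np.tanh(2 * x) + 0.3 * r.standard_normal(400)
        assert h2_coefficient(a * x + b, c * y + d) == pytest.approx(
            h2_coefficient(x, y), abs=1e-9
        )


class TestDelayScan:
    def test_pure_lag_recovered(self):
        r = np.random.default_rng(0)
        x = r.standard_normal(512)
        y = np.concatenate([np.full(5, x[0]), x[:-5]])
        h2, tau = h2_delay_scan(x, y)
        assert tau == 5
        assert h2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_lag_tie_breaks_to_smallest_tau(self):
        x = np.random.default_rng(1).standard_normal(512)
        _, tau = h2_delay_scan(x, x)
        assert tau == 0

    def test_noisy_nonlinear_lag_recovered_within_one_sample(self):
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            x = r.standard_normal(600)
            y = np.tanh(3 * np.concatenate([np.full(10, x[0]), x[:-10]]))
            y = y + 0.1 * r.standard_normal(600)
            _, tau = h2_delay_scan(x, y)
            hits += abs(tau - 10) <= 1
        assert hits >= 90

    def test_empty_scan_range_rejected(self):
        cfg = AnalysisConfig(n_bins=10)
        with pytest.raises(ValueError):
            h2_delay_scan(np.arange(30.0), np.arange(30.0), cfg)


class TestDirectedEstimate:
    def test_forward_nonlinear_lag_gives_x_to_y(self):
        r = np.random.default_rng(3)
        x = r.standard_normal(512)
        y = np.tanh(3 * np.concatenate([np.full(8, x[0]), x[:-8]]))
        est = directed_pair_estimate(x, y)
        assert est.direction is Direction.X_TO_Y
        assert est.delay_s == pytest.approx(8 / 256)

    def test_swapped_arguments_give_y_to_x(self):
        r = np.random.default_rng(3)
        x = r.standard_normal(512)
        y = np.tanh(3 * np.concatenate([np.full(8, x[0]), x[:-8]]))
        est = directed_pair_estimate(y, x)
        assert est.direction is Direction.Y_TO_X
        assert est.delay_s == pytest.approx(-8 / 256)

    def test_identical_signals_are_undirected(self):
        x = np.random.default_rng(4).standard_normal(512)
        est = directed_pair_estimate(x, x)
        assert est.direction is Direction.UNDIRECTED
        assert est.delay_s == 0.0
        assert est.h2 == pytest.approx(1.0)
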