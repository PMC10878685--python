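"""Bootstrap bands, prediction ellipses and the geometric decision rules."""

import numpy as np
import pytest

from agreekit import (BootstrapBand, band_admits_line, bootstrap_lines,
                      build_ellipse, point_in_ellipse)
from agreekit.errors import DegenerateDataError
from agreekit.simulate import SimulationSpec, generate
from conftest import make_set


def _ols_fitter(ms):
    x, y = ms.x, ms.y
    xc = x - x.mean()
    sxx = float(np.sum(xc * xc))
    if sxx == 0.0:
        raise DegenerateDataError("constant x in resample")
    slope = float(np.sum(xc * (y - y.mean())) / sxx)
    return slope, float(y.mean() - slope * x.mean())


class TestBootstrapLines:
    def test_same_seed_same_band(self):
        ms, _ = generate(SimulationSpec(n=30, seed=2))
        b1, p1 = bootstrap_lines(ms, _ols_fitter, n_boot=250, seed=9)
        b2, p2 = bootstrap_lines(ms, _ols_fitter, n_boot=250, seed=9)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)
        np.testing.assert_array_equal(p1, p2)

    def test_exact_line_collapses_band(self):
        x = np.arange(1.0, 13.0)
        ms = make_set(x, 2.0 * x + 1.0)
        band, pairs = bootstrap_lines(ms, _ols_fitter, n_boot=200, seed=0)
        np.testing.assert_allclose(band.lower, band.upper, atol=1e-10)
        np.testing.assert_allclose(band.lower, 2.0 * band.grid + 1.0,
                                   atol=1e-10)
        np.testing.assert_allclose(pairs[:, 0], 2.0, atol=1e-10)

    def test_grid_spans_observed_range(self):
        ms, _ = generate(SimulationSpec(n=30, seed=2))
        band, _ = bootstrap_lines(ms, _ols_fitter, n_boot=200, seed=1,
                                  grid_size=50)
        assert band.grid[0] == pytest.approx(ms.x.min())
        assert band.grid[-1] == pytest.approx(ms.x.max())
        assert len(band.grid) == 50

    def test_rejects_too_few_resamples(self):
        ms, _ = generate(SimulationSpec(n=30, seed=2))
        with pytest.raises(ValueError):
            bootstrap_lines(ms, _ols_fitter, n_boot=50, seed=1)

    def test_band_narrows_with_sample_size(self):
        widths = {}
        for n in (50, 200):
            per_run = []
            for seed in range(8):
                ms, _ = generate(SimulationSpec(n=n, seed=seed))
                band, _ = bootstrap_lines(ms, _ols_fitter, n_boot=200,
                                          seed=seed)
                per_run.append(float(np.median(band.upper - band.lower)))
            widths[n] = np.median(per_run)
        assert widths[200] < widths[50]

    def test_pointwise_coverage_near_nominal(self):
        """Null draws: the band covers the true line value at the center
        abscissa at roughly the nominal rate."""
        hits = 0
        reps = 150
        spec = SimulationSpec(n=100, seed=0)
        # population regression of y on x under the structural null:
        # slope attenuated by the reference error, line through (μ, μ)
        slope = spec.true_sd ** 2 / (spec.true_sd ** 2 + spec.sd_eps ** 2)
        intercept = spec.true_mean * (1.0 - slope)
        for seed in range(reps):
            ms, _ = generate(SimulationSpec(n=100, seed=seed))
            band, _ = bootstrap_lines(ms, _ols_fitter, n_boot=200, seed=seed)
            mid = np.argmin(np.abs(band.grid - spec.true_mean))
            truth = intercept + slope * band.grid[mid]
            hits += band.lower[mid] <= truth <= band.upper[mid]
        rate = hits / reps
        se = np.sqrt(0.95 * 0.05 / reps)
        assert abs(rate - 0.95) <= 3 * se


class TestBandGeometry:
    def _flat_band(self, lower, upper, g0=0.0, g1=10.0, m=21):
        g = np.linspace(g0, g1, m)
        return BootstrapBand(grid=g, lower=np.full(m, lower),
                             upper=np.full(m, upper), n_boot=1000,
                             level=0.95, seed=0)

    def test_symmetric_band_admits_zero(self):
        feasible, witness = band_admits_line(self._flat_band(-1.0, 1.0), 0.0)
        assert feasible and witness == pytest.approx(0.0)

    def test_tilted_band_excludes_horizontal_lines(self):
        g = np.linspace(0.0, 10.0, 50)
        band = BootstrapBand(grid=g, lower=g - 0.1, upper=g + 0.1,
                             n_boot=1000, level=0.95, seed=0)
        feasible, witness = band_admits_line(band, 0.0)
        assert not feasible and witness is None

    def test_intercept_range_restriction(self):
        band = self._flat_band(-1.0, 1.0)
        assert band_admits_line(band, 0.0, (0.5, 2.0))[0]
        assert not band_admits_line(band, 0.0, (1.5, 2.0))[0]

    def test_agrees_with_exhaustive_intercept_scan(self, rng):
        """Random bands: the analytic feasibility rule matches a dense scan
        over 10⁴ candidate intercepts."""
        for _ in range(40):
            m = 30
            g = np.sort(rng.uniform(0, 10, m))
            g += np.arange(m) * 1e-6          # ensure strictly increasing
            center = rng.normal(0, 1, m)
            half = rng.uniform(0.05, 1.0, m)
            band = BootstrapBand(grid=g, lower=center - half,
                                 upper=center + half, n_boot=1000,
                                 level=0.95, seed=0)
            slope = rng.normal(0, 0.3)
            feasible, witness = band_admits_line(band, slope)
            cands = np.linspace(band.lower.min() - slope * g.max() - 1,
                                band.upper.max() + abs(slope) * g.max() + 1,
                                10_000)
            lines = cands[:, None] + slope * g[None, :]
            ok = np.any(np.all((lines >= band.lower) & (lines <= band.upper),
                               axis=1))
            assert feasible == ok
            if feasible:
                line = witness + slope * g
                assert np.all(line >= band.lower - 1e-9)
                assert np.all(line <= band.upper + 1e-9)


class TestEllipse:
    @pytest.fixture(scope="class")
    def pairs(self):
        rng = np.random.default_rng(5)
        cov = np.array([[0.04, -0.03], [-0.03, 0.09]])
        return rng.multivariate_normal([1.0, 0.0], cov, size=2000)

    def test_center_is_inside(self, pairs):
        e = build_ellipse(pairs)
        assert point_in_ellipse(e, tuple(e.center))

    def test_boundary_is_closed_and_just_outside_excluded(self, pairs):
        # exact-boundary membership on an analytically constructed ellipse
        from agreekit import PredictionEllipse
        e0 = PredictionEllipse(center=np.array([0.0, 0.0]),
                               shape=np.eye(2), radius2=4.0)
        assert point_in_ellipse(e0, (2.0, 0.0))       # on the boundary
        assert not point_in_ellipse(e0, (2.0 + 1e-9, 0.0))
        # near-boundary behaviour on an empirical ellipse
        e = build_ellipse(pairs)
        vals, vecs = np.linalg.eigh(e.shape)
        direction = vecs[:, 0] * np.sqrt(vals[0] * e.radius2)
        assert point_in_ellipse(e, tuple(e.center + 0.999 * direction))
        assert not point_in_ellipse(e, tuple(e.center + 1.01 * direction))

    def test_classification_matches_quadratic_form(self, pairs, rng):
        e = build_ellipse(pairs)
        inv = np.linalg.inv(e.shape)
        pts = rng.normal([1.0, 0.0], [0.5, 0.8], size=(10_000, 2))
        dev = pts - e.center
        d2 = np.einsum("ij,jk,ik->i", dev, inv, dev)
        expected = d2 <= e.radius2
        got = np.array([point_in_ellipse(e, tuple(p)) for p in pts])
        np.testing.assert_array_equal(got, expected)

    def test_covers_95pct_of_generating_pairs(self, pairs):
        e = build_ellipse(pairs)
        inv = np.linalg.inv(e.shape)
        dev = pairs - e.center
        d2 = np.einsum("ij,jk,ik->i", dev, inv, dev)
        frac = np.mean(d2 <= e.radius2)
        se = np.sqrt(0.95 * 0.05 / len(pairs))
        assert abs(frac - 0.95) <= 2 * se

    def test_degenerate_scatter_raises(self):
        line = np.column_stack([np.linspace(0, 1, 500),
                                np.linspace(0, 2, 500)])
        with pytest.raises(DegenerateDataError):
            build_ellipse(line)
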