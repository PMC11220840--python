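"""Linear fitting, hydration-contrast optimization and the landscape scan."""

import numpy as np
import pytest
from scipy.optimize import minimize

from emsaxs import (
    NoiseModel,
    PhantomSpec,
    SAXSData,
    ScanConfig,
    ScatteringCurve,
    fit_model,
    linear_fit,
    make_phantom_map,
    phantom_structure,
    report,
    scan_landscape,
    simulate_saxs,
)
from emsaxs.fitting import (
    RankDeficiencyError,
    find_local_minima,
    moving_average,
)


def _data(q, intensity, sigma):
    return SAXSData(np.asarray(q, float), np.asarray(intensity, float),
                    np.asarray(sigma, float))


class TestLinearFit:
    def test_exact_recovery(self, rng):
        q = np.linspace(0.01, 0.5, 30)
        model = np.exp(-q * 5) * 100
        data = _data(q, 2.0 * model + 3.0, rng.uniform(0.1, 1.0, 30))
        a, b, chi2 = linear_fit(model, data)
        assert a == pytest.approx(2.0)
        assert b == pytest.approx(3.0)
        assert chi2 == pytest.approx(0.0, abs=1e-18)

    def test_sigma_scaling(self, rng):
        q = np.linspace(0.01, 0.5, 30)
        model = np.exp(-q * 5) * 100
        y = 2.0 * model + 3.0 + rng.normal(0, 1, 30)
        sigma = rng.uniform(0.5, 1.5, 30)
        a1, b1, chi1 = linear_fit(model, _data(q, y, sigma))
        a2, b2, chi2 = linear_fit(model, _data(q, y, 2 * sigma))
        assert (a1, b1) == pytest.approx((a2, b2))
        assert chi2 == pytest.approx(chi1 / 4)

    def test_matches_numeric_minimizer(self, rng):
        q = np.linspace(0.01, 0.5, 40)
        model = np.exp(-q * 4) * 50 + q
        y = 1.7 * model - 2.0 + rng.normal(0, 0.5, 40)
        sigma = rng.uniform(0.2, 0.8, 40)
        data = _data(q, y, sigma)
        a, b, chi2 = linear_fit(model, data)

        def objective(p):
            return float(np.sum(((y - p[0] * model - p[1]) / sigma) ** 2))

        res = minimize(objective, [1.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert a == pytest.approx(res.x[0], abs=1e-6)
        assert b == pytest.approx(res.x[1], abs=1e-6)
        assert chi2 == pytest.approx(res.fun, rel=1e-9)

    def test_constant_model_degenerate(self):
        q = np.linspace(0.01, 0.5, 10)
        with pytest.raises(RankDeficiencyError):
            linear_fit(np.full(10, 3.0), _data(q, q, np.ones(10)))

    def test_chi2_invariant_under_common_scaling(self, rng):
        q = np.linspace(0.01, 0.5, 30)
        model = np.exp(-q * 5) * 100
        y = 2.0 * model + 3.0 + rng.normal(0, 1, 30)
        sigma = rng.uniform(0.5, 1.5, 30)
        a1, _, chi1 = linear_fit(model, _data(q, y, sigma))
        a2, _, chi2 = linear_fit(model, _data(q, 10 * y, 10 * sigma))
        assert chi2 == pytest.approx(chi1, rel=1e-12)
        assert a2 == pytest.approx(10 * a1, rel=1e-12)


class TestFitModel:
    def _curve(self, rng, n=40):
        q = np.linspace(0.01, 0.5, n)
        return ScatteringCurve(
            q=q,
            I_pp=np.exp(-q * 5) * 100,
            I_pw=np.exp(-q * 4) * 20,
            I_ww=np.exp(-q * 3) * 4,
        )

    def test_recovers_known_cw(self, rng):
        curve = self._curve(rng)
        truth = 2.0 * curve.intensity(1.5) + 3.0
        data = _data(curve.q, truth, np.full(len(curve.q), 0.1))
        fit = fit_model(curve, data)
        assert fit.c_w == pytest.approx(1.5)
        assert fit.a == pytest.approx(2.0, rel=1e-9)
        assert fit.b == pytest.approx(3.0, rel=1e-6)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_no_water_components_reduces_to_linear(self, rng):
        curve = self._curve(rng)
        curve.I_pw = np.zeros_like(curve.q)
        curve.I_ww = np.zeros_like(curve.q)
        y = 1.2 * curve.I_pp + 0.5 + rng.normal(0, 0.1, len(curve.q))
        data = _data(curve.q, y, np.full(len(curve.q), 0.1))
        fit = fit_model(curve, data)
        a, b, chi2 = linear_fit(curve.I_pp, data)
        assert (fit.a, fit.b) == pytest.approx((a, b))
        assert fit.chi2 == pytest.approx(chi2)

    def test_hydration_free_truth_selects_zero(self, rng):
        curve = self._curve(rng)
        truth = 2.0 * curve.intensity(0.0) + 1.0
        data = _data(curve.q, truth, np.full(len(curve.q), 0.05))
        assert fit_model(curve, data).c_w == 0.0

    def test_extra_freedom_never_hurts(self, rng):
        curve = self._curve(rng)
        y = 2.0 * curve.I_pp + rng.normal(0, 5, len(curve.q))
        data = _data(curve.q, y, np.full(len(curve.q), 5.0))
        fit = fit_model(curve, data)
        _, _, chi2_plain = linear_fit(curve.I_pp, data)
        assert fit.chi2 <= chi2_plain + 1e-9

    def test_empty_grid_rejected(self, rng):
        curve = self._curve(rng)
        data = _data(curve.q, curve.I_pp, np.ones(len(curve.q)))
        with pytest.raises(ValueError):
            fit_model(curve, data, c_w_grid=np.array([]))


class TestSmoothing:
    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_centered_average(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = moving_average(x, 3)
        np.testing.assert_allclose(out, [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_nan_passthrough_and_skip(self):
        x = np.array([1.0, np.nan, 3.0])
        out = moving_average(x, 3)
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(1.0)
        assert out[2] == pytest.approx(3.0)

    def test_single_dip_single_minimum(self):
        x = np.concatenate([np.linspace(5, 1, 10), np.linspace(1.2, 8, 10)])
        assert len(find_local_minima(x)) == 1

    def test_endpoints_can_be_minima(self):
        assert find_local_minima(np.array([1.0, 2.0, 3.0])) == [0]
        assert find_local_minima(np.array([3.0, 2.0, 1.0])) == [2]

    def test_plateau_reports_last_index(self):
        x = np.array([5.0, 1.0, 1.0, 1.0, 4.0])
        assert find_local_minima(x) == [3]


@pytest.fixture(scope="module")
def small_roundtrip():
    """A small matched phantom map + simulated curve, scanned end to end."""
    spec = PhantomSpec(kind="ball", radius=16, voxel_size=2.0,
                       shape=(32, 32, 32), smear_sigma=2.0)
    dmap = make_phantom_map(spec)
    structure = phantom_structure(spec)
    q = np.linspace(0.02, 0.3, 80)
    data = simulate_saxs(structure, q, NoiseModel(seed=11))
    config = ScanConfig(n_levels=15, tmin=0.02, seed=5, window=3)
    landscape = scan_landscape(dmap, data, config)
    return spec, dmap, structure, data, config, landscape


class TestScanLandscape:
    def test_roundtrip_recovers_threshold(self, small_roundtrip):
        spec, dmap, structure, data, config, landscape = small_roundtrip
        step = landscape.thresholds[0] - landscape.thresholds[1]
        best = landscape.best_fit
        assert abs(best.threshold - 0.5) <= 2 * step
        assert best.chi2_reduced < 5.0
        truth_mass = len(structure) * dmap.voxel_volume * 0.813 / 1000
        assert best.mass_kda == pytest.approx(truth_mass, rel=0.25)

    def test_landscape_shapes(self, small_roundtrip):
        *_, landscape = small_roundtrip
        n = len(landscape.thresholds)
        assert len(landscape.chi2_reduced) == n
        assert len(landscape.chi2_smoothed) == n
        assert len(landscape.masses) == n
        assert landscape.best_index in landscape.minima
        assert np.all(np.diff(landscape.thresholds) < 0)

    def test_empty_levels_recorded_as_nan(self, small_roundtrip):
        spec, dmap, _, data, config, _ = small_roundtrip
        import dataclasses

        cfg = dataclasses.replace(config, tmax=2.0, n_levels=10, tmin=0.02)
        landscape = scan_landscape(dmap, data, cfg)
        assert np.isnan(landscape.chi2_reduced[0])  # nothing above density 2
        assert 0 not in landscape.minima

    def test_all_levels_empty_raises(self, small_roundtrip):
        spec, dmap, _, data, config, _ = small_roundtrip
        import dataclasses

        cfg = dataclasses.replace(config, tmin=5.0, tmax=9.0)
        with pytest.raises(ValueError):
            scan_landscape(dmap, data, cfg)


class TestReport:
    def test_report_files_and_values(self, small_roundtrip, tmp_path):
        spec, dmap, _, data, config, landscape = small_roundtrip
        summary = report(landscape, dmap, data, config, tmp_path)
        for name in ("landscape.tsv", "fit.tsv", "summary.json", "summary.txt",
                     "config.json", "best_model.pdb"):
            assert (tmp_path / name).exists()
        # one model per landscape minimum
        pdbs = list(tmp_path.glob("*.pdb"))
        assert len(pdbs) == len(landscape.minima)
        best = landscape.best_fit
        assert summary["threshold_rms"] == pytest.approx(
            best.threshold / dmap.density_rms
        )
        half = landscape.window // 2
        lo = max(0, landscape.best_index - half)
        hi = landscape.best_index + half + 1
        assert summary["chi2_reduced_avg"] == pytest.approx(
            float(np.nanmean(landscape.chi2_reduced[lo:hi]))
        )
        # fit table residuals consistent with chi2
        table = np.loadtxt(tmp_path / "fit.tsv")
        chi2 = float(np.sum(table[:, 4] ** 2))
        assert chi2 == pytest.approx(best.chi2, rel=1e-6)
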