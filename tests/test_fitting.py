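import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstkin.fitting import (
    FitError,
    NoDetectableProductError,
    ProgressCurve,
    TitrationSeries,
    bootstrap_cis,
    fit_burst,
    fit_titration,
    fold_stimulation,
    grid_oracle_fit,
)
from burstkin.models import (
    BurstParams,
    HyperbolaParams,
    RateConstants,
    burst_product,
    derived_rates,
    hyperbolic_rate,
)

from conftest import biphasic_grid, noiseless_curve


class TestProgressCurveValidation:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 4"):
            ProgressCurve([0, 1, 2], [0, 1, 2], 5, 5)

    def test_nonmonotone_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ProgressCurve([0, 2, 1, 3], [0, 1, 2, 3], 5, 100)

    def test_negative_product(self):
        with pytest.raises(ValueError, match=">= 0"):
            ProgressCurve([0, 1, 2, 3], [0, -1, 2, 3], 5, 100)

    def test_product_above_substrate(self):
        with pytest.raises(ValueError, match="exceeds total substrate"):
            ProgressCurve([0, 1, 2, 3], [0, 1, 2, 8], 5, 5)


class TestFitBurst:
    def test_noiseless_recovery(self):
        truth = BurstParams(5.0, RateConstants(1.0, 0.004))
        t = np.unique(np.concatenate([[0.0], np.geomspace(0.1, 6, 10), np.linspace(10, 60, 6)]))
        curve = ProgressCurve(t, burst_product(t, truth), 5.0, 1e9)
        fit = fit_burst(curve)
        assert fit.converged
        assert fit.params.e_active == pytest.approx(5.0, rel=1e-6)
        assert fit.params.rates.k2 == pytest.approx(1.0, rel=1e-6)
        assert fit.params.rates.k3 == pytest.approx(0.004, rel=1e-6)

    def test_flat_signal_raises(self):
        with pytest.raises(NoDetectableProductError):
            fit_burst(ProgressCurve([0, 1, 2, 3, 4], np.zeros(5), 5, 5))

    def test_printed_pi6_rate_reproduced(self):
        # potentiated pi6 condition: k_burst = 0.32 min^-1
        k_burst, k_ss = 0.32, 0.003
        disc = np.sqrt(k_burst**2 - 4 * k_burst * k_ss)
        k2, k3 = (k_burst + disc) / 2, (k_burst - disc) / 2
        curve = noiseless_curve(2.0, k2, k3)
        fit = fit_burst(curve)
        assert fit.k_burst == pytest.approx(0.32, rel=0.01)

    def test_derived_rates_consistent(self):
        curve = noiseless_curve(3.0, 0.5, 0.01)
        fit = fit_burst(curve)
        kb, ks = derived_rates(fit.params.rates)
        assert fit.k_burst == pytest.approx(kb, rel=1e-12)
        assert fit.k_ss == pytest.approx(ks, rel=1e-12)
        assert fit.k_ss <= fit.k_burst / 4 + 1e-15

    def test_fix_e_active(self):
        truth = BurstParams(5.0, RateConstants(1.0, 0.004))
        t = biphasic_grid(1.004)
        curve = ProgressCurve(t, burst_product(t, truth), 5.0, 1e9)
        fit = fit_burst(curve, fix_e_active=5.0)
        assert fit.params.e_active == 5.0
        assert fit.params.rates.k2 == pytest.approx(1.0, rel=1e-6)

    @given(
        st.floats(0.5, 8.0),
        st.floats(-2.0, 0.5),
        st.floats(np.log10(5.0), np.log10(500.0)),
    )
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_random_draws(self, e, log_k2, log_ratio):
        k2 = 10.0**log_k2
        k3 = k2 / 10.0**log_ratio
        curve = noiseless_curve(e, k2, k3)
        fit = fit_burst(curve)
        assert fit.params.e_active == pytest.approx(e, rel=1e-6)
        assert fit.params.rates.k2 == pytest.approx(k2, rel=1e-6)
        assert fit.params.rates.k3 == pytest.approx(k3, rel=1e-6)


class TestGridOracle:
    def test_grid_optimum_near_fit(self):
        truth = BurstParams(5.0, RateConstants(1.0, 0.004))
        t = biphasic_grid(1.004)
        curve = ProgressCurve(t, burst_product(t, truth), 5.0, 1e9)
        # 21-point grids bracketing (and containing) the truth
        e_grid = np.linspace(4.0, 6.0, 21)
        k2_grid = np.linspace(0.8, 1.2, 21)
        k3_grid = np.linspace(0.002, 0.006, 21)
        best, ssr = grid_oracle_fit(curve, e_grid, k2_grid, k3_grid)
        fit = fit_burst(curve)
        assert abs(best.e_active - fit.params.e_active) <= np.diff(e_grid)[0] + 1e-12
        assert abs(best.rates.k2 - fit.params.rates.k2) <= np.diff(k2_grid)[0] + 1e-12
        assert abs(best.rates.k3 - fit.params.rates.k3) <= np.diff(k3_grid)[0] + 1e-12
        assert fit.ssr <= ssr + 1e-12

    def test_fit_never_beaten_by_grid(self, rng):
        for _ in range(5):
            e = rng.uniform(1, 6)
            k2 = 10 ** rng.uniform(-1.5, 0.3)
            k3 = k2 / rng.uniform(5, 300)
            curve = noiseless_curve(e, k2, k3)
            fit = fit_burst(curve)
            _, grid_ssr = grid_oracle_fit(
                curve,
                np.linspace(0.5 * e, 1.5 * e, 8),
                np.geomspace(0.5 * k2, 2 * k2, 8),
                np.geomspace(0.5 * k3, 2 * k3, 8),
            )
            assert fit.ssr <= grid_ssr + 1e-12

    def test_excluding_truth_region_is_worse(self):
        curve = noiseless_curve(5.0, 1.0, 0.004)
        fit = fit_burst(curve)
        _, ssr = grid_oracle_fit(curve, [50.0], [10.0], [1.0])
        assert ssr > fit.ssr

    def test_single_cell_grid(self):
        curve = noiseless_curve(5.0, 1.0, 0.004)
        best, _ = grid_oracle_fit(curve, [2.0], [0.5], [0.01])
        assert best.e_active == 2.0
        assert best.rates.k2 == 0.5
        assert best.rates.k3 == 0.01

    def test_empty_grid(self):
        curve = noiseless_curve(5.0, 1.0, 0.004)
        with pytest.raises(ValueError, match="empty"):
            grid_oracle_fit(curve, [], [1.0], [0.01])


class TestFitTitration:
    wt_concs = np.array([1.0, 3.0, 8.0, 30.0, 100.0, 500.0, 5000.0])

    def test_wildtype_parameters_recovered(self):
        truth = HyperbolaParams(1.1, 8.0)
        series = TitrationSeries(self.wt_concs, hyperbolic_rate(self.wt_concs, truth))
        fit = fit_titration(series)
        assert fit.params.kd == pytest.approx(8.0, rel=1e-6)
        assert fit.params.k_pot == pytest.approx(1.1, rel=1e-6)

    def test_mutant_parameters_recovered(self):
        truth = HyperbolaParams(0.8, 500.0)
        concs = np.geomspace(1, 10000, 9)
        series = TitrationSeries(concs, hyperbolic_rate(concs, truth))
        fit = fit_titration(series)
        assert fit.params.kd == pytest.approx(500.0, rel=1e-6)

    def test_two_point_series_rejected(self):
        with pytest.raises(ValueError, match="distinct concentrations"):
            TitrationSeries([1.0, 10.0], [0.1, 0.5])

    def test_flat_series_rejected(self):
        with pytest.raises(FitError, match="saturated or flat"):
            fit_titration(TitrationSeries([1, 10, 100], [0.5, 0.5, 0.5]))

    def test_basal_offset_mode(self):
        truth = HyperbolaParams(1.0, 10.0)
        y = hyperbolic_rate(self.wt_concs, truth) + 0.05
        fit = fit_titration(TitrationSeries(self.wt_concs, y), basal_offset=True)
        assert fit.params.kd == pytest.approx(10.0, rel=1e-4)
        assert fit.params.k_pot == pytest.approx(1.0, rel=1e-4)


class TestBootstrap:
    def test_noiseless_zero_width(self):
        curve = noiseless_curve(5.0, 1.0, 0.004)
        fit = fit_burst(curve)
        ci = bootstrap_cis("burst", curve, fit, n_boot=100, seed=1)
        for lo, hi in ci.values():
            assert hi - lo < 1e-6 * max(abs(hi), 1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        concs = np.geomspace(1, 5000, 7)
        y = hyperbolic_rate(concs, HyperbolaParams(1.1, 8.0)) * (1 + 0.05 * rng.normal(size=7))
        series = TitrationSeries(concs, np.clip(y, 0, None))
        fit = fit_titration(series)
        ci1 = bootstrap_cis("titration", series, fit, n_boot=150, seed=42)
        ci2 = bootstrap_cis("titration", series, fit, n_boot=150, seed=42)
        assert ci1 == ci2
        ci3 = bootstrap_cis("titration", series, fit, n_boot=150, seed=43)
        assert ci1 != ci3

    def test_n_boot_floor(self):
        curve = noiseless_curve(5.0, 1.0, 0.004)
        fit = fit_burst(curve)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_cis("burst", curve, fit, n_boot=50, seed=1)


class TestFoldStimulation:
    def test_identical_fits_give_one(self):
        curve = noiseless_curve(5.0, 1.0, 0.004)
        fit = fit_burst(curve)
        assert fold_stimulation(fit, fit) == pytest.approx(1.0)

    def test_pi9_fold(self):
        # printed pi9 rates: 0.033 min^-1 alone, 0.62 min^-1 with activator
        fits = []
        for kb in (0.033, 0.62):
            k3 = 0.003
            disc = np.sqrt(kb**2 - 4 * kb * k3)
            curve = noiseless_curve(2.0, (kb + disc) / 2, (kb - disc) / 2)
            fits.append(fit_burst(curve))
        fold = fold_stimulation(fits[0], fits[1])
        assert fold == pytest.approx(0.62 / 0.033, rel=0.01)
        assert round(fold) == 19

    def test_pi6_fold(self):
        # printed pi6 rates: 0.0040 min^-1 alone, 0.32 min^-1 with activator
        fits = []
        for kb, k3 in ((0.0040, 0.0008), (0.32, 0.003)):
            disc = np.sqrt(kb**2 - 4 * kb * k3)
            curve = noiseless_curve(2.0, (kb + disc) / 2, (kb - disc) / 2)
            fits.append(fit_burst(curve))
        assert fold_stimulation(fits[0], fits[1]) == pytest.approx(80.0, rel=0.01)
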