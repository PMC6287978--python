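import numpy as np
import pytest
from scipy import stats

from mitoswitch import (
    DoseResponseCurve,
    NoCrossingError,
    PopulationSpec,
    cycb_quantile_grid,
    fold_points,
    hysteresis_ratio,
    ic50,
    lognormal_from_median_sd,
    population_dose_response,
)
from mitoswitch.population import classify_cells


class TestLognormal:
    def test_degenerate_sd_zero(self):
        mu, sigma = lognormal_from_median_sd(8.18, 0.0)
        assert mu == pytest.approx(np.log(8.18))
        assert sigma == 0.0

    def test_fitted_population_sigma(self):
        """The assay population (median 8.18, SD 4.31 AU) has log-scale
        sigma ≈ 0.4518; cross-check the moment equation by Monte Carlo."""
        mu, sigma = lognormal_from_median_sd(8.18, 4.31)
        assert sigma == pytest.approx(0.4518, abs=5e-4)
        rng = np.random.default_rng(42)
        draws = np.exp(mu + sigma * rng.standard_normal(1_000_000))
        assert np.median(draws) == pytest.approx(8.18, rel=0.01)
        assert draws.std() == pytest.approx(4.31, rel=0.01)

    @pytest.mark.parametrize("sd,tol", [(0.1, 0.01), (1.0, 0.01), (3.0, 0.03)])
    def test_moment_inversion_matches_sampling(self, sd, tol):
        # sd = 3 on median 1 is a very heavy tail (sigma ≈ 1.12): the
        # sample SD itself has ~1% standard error at 1e6 draws, so the
        # tolerance there is widened to 3 standard errors
        mu, sigma = lognormal_from_median_sd(1.0, sd)
        rng = np.random.default_rng(7)
        draws = np.exp(mu + sigma * rng.standard_normal(1_000_000))
        assert np.median(draws) == pytest.approx(1.0, rel=0.01)
        assert draws.std() == pytest.approx(sd, rel=tol)

    def test_quantile_grid_is_sorted_and_median_centred(self, population):
        cells = cycb_quantile_grid(population)
        assert np.all(np.diff(cells) > 0)
        assert np.median(cells) == pytest.approx(8.18, rel=0.01)


class TestIC50:
    def test_linear_interpolation(self):
        c = DoseResponseCurve(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert ic50(c) == pytest.approx(0.5)

    def test_exact_grid_hit(self):
        c = DoseResponseCurve(np.array([0.0, 0.2, 0.4]), np.array([1.0, 0.5, 0.0]))
        assert ic50(c) == pytest.approx(0.2)

    def test_no_crossing_is_an_explicit_error(self):
        c = DoseResponseCurve(np.array([0.0, 1.0]), np.array([0.8, 0.8]))
        with pytest.raises(NoCrossingError):
            ic50(c)

    def test_first_crossing_wins(self):
        c = DoseResponseCurve(np.array([0.0, 1.0, 2.0, 3.0]),
                              np.array([1.0, 0.4, 0.6, 0.0]))
        assert ic50(c) < 1.0


class TestDoseResponse:
    def test_homogeneous_population_gives_step_curve(self, params):
        spec = PopulationSpec(median=8.18, sd=0.0, n_quantiles=16)
        curve = population_dose_response(
            params, "control", "entry", spec, np.array([0.0, 0.05, 0.5, 2.0]))
        assert set(curve.fraction_mitotic.tolist()) <= {0.0, 1.0}
        assert curve.fraction_mitotic[0] == 1.0
        assert curve.fraction_mitotic[-1] == 0.0

    def test_monotone_bisection_equals_exhaustive_evaluation(self, params):
        cells = np.array([2.0, 5.0, 8.18, 12.0, 20.0, 3.5, 9.0, 6.5])
        for dose in (0.05, 0.2, 0.8):
            fast = classify_cells(params, "control", "entry", dose, cells,
                                  assume_monotone=True)
            slow = classify_cells(params, "control", "entry", dose, cells,
                                  assume_monotone=False)
            assert np.array_equal(fast, slow)

    def test_everyone_enters_without_inhibitor(self, params, population):
        curve = population_dose_response(params, "control", "entry",
                                         population, np.array([0.0]))
        assert curve.fraction_mitotic[0] == pytest.approx(1.0, abs=0.02)

    def test_nobody_enters_at_saturating_dose(self, params, population):
        curve = population_dose_response(params, "control", "entry",
                                         population, np.array([2.0]))
        assert curve.fraction_mitotic[0] == pytest.approx(0.0, abs=0.02)

    def test_quantile_resolution_converged(self, params, dose_grid):
        lo = PopulationSpec(median=8.18, sd=4.31, n_quantiles=64)
        hi = PopulationSpec(median=8.18, sd=4.31, n_quantiles=128)
        v_lo = ic50(population_dose_response(params, "control", "entry", lo, dose_grid))
        v_hi = ic50(population_dose_response(params, "control", "entry", hi, dose_grid))
        assert v_hi == pytest.approx(v_lo, rel=0.02)

    def test_sampling_mode_brackets_deterministic_curve(self, params):
        doses = np.array([0.05, 0.10, 0.15])
        det = population_dose_response(
            params, "control", "entry",
            PopulationSpec(median=8.18, sd=4.31, n_quantiles=64), doses)
        n = 300
        # binomial 99% band around the infinite-N fraction, padded by the
        # 1/64 quantile-discretisation step of the deterministic curve
        for seed in (1, 2, 3):
            spec = PopulationSpec(median=8.18, sd=4.31, n_cells=n, seed=seed)
            smp = population_dose_response(params, "control", "entry", spec,
                                           doses, mode="sample")
            for p_det, p_smp in zip(det.fraction_mitotic, smp.fraction_mitotic):
                p = min(max(p_det, 1e-6), 1 - 1e-6)
                lo, hi = stats.binom.interval(0.99, n, p)
                assert lo / n - 1 / 64 <= p_smp <= hi / n + 1 / 64


class TestHysteresis:
    @pytest.mark.parametrize("condition", ["control", "wee1i", "gwl_depleted"])
    def test_exit_needs_more_inhibitor_than_entry(self, params, condition,
                                                  population, refined_dose_grid):
        r = hysteresis_ratio(params, condition, population, refined_dose_grid)
        assert r > 1.0

    def test_double_perturbation_collapses_hysteresis(self, params, population,
                                                      refined_dose_grid):
        r = hysteresis_ratio(params, "wee1i_gwl_depleted", population,
                             refined_dose_grid)
        assert abs(r - 1.0) < 0.15

    def test_entry_ic50_ordering_across_conditions(self, params, population,
                                                   refined_dose_grid):
        values = {
            cond: ic50(population_dose_response(params, cond, "entry",
                                                population, refined_dose_grid))
            for cond in ("gwl_depleted", "control", "wee1i")
        }
        assert values["gwl_depleted"] < values["control"] < values["wee1i"]

    def test_homogeneous_ratio_matches_single_cell_folds(self, params):
        """With SD = 0 the population collapses onto the median cell, so
        the IC50 ratio equals the fold-dose ratio from the bifurcation
        analysis (up to dose-grid resolution and the finite endpoint)."""
        spec = PopulationSpec(median=8.1808, sd=0.0, n_quantiles=16)
        grid = np.unique(np.concatenate([
            np.linspace(0.05, 0.7, 66), np.array([0.0, 1.0, 2.0])]))
        r = hysteresis_ratio(params, "control", spec, grid)
        fp = fold_points(params, "control")
        assert r == pytest.approx(fp.exit / fp.entry, rel=0.10)
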