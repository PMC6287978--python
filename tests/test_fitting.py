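import numpy as np
import pytest

from mitoswitch import (
    DoseResponseDataset,
    FitSpec,
    GeneratorConfig,
    PopulationSpec,
    default_dose_grid,
    fit_rate_constants,
    fit_stage1_median,
    fit_stage2_variance,
    generate_dataset,
    generate_noise_free_curves,
    objective,
)

SMALL_DOSES = tuple(default_dose_grid(13))


def noise_free_datasets(params, median, sd, conditions=("control",),
                        protocols=("entry",), doses=SMALL_DOSES, n_quantiles=32):
    """Datasets whose mean fractions equal the quantile-mode curves
    exactly (n_cells = n_quantiles makes every fraction k/n exact)."""
    cfg = GeneratorConfig(
        true_params=params, conditions=conditions, protocols=protocols,
        dose_grid=doses,
        population=PopulationSpec(median=median, sd=sd, n_quantiles=n_quantiles),
        seed=0,
    )
    curves = generate_noise_free_curves(cfg)
    out = []
    for curve in curves:
        counts = np.round(curve.fraction_mitotic * n_quantiles).astype(int)[:, None]
        out.append(DoseResponseDataset(
            condition=curve.condition, protocol=curve.protocol,
            doses=np.asarray(doses), counts=counts, n_cells=n_quantiles,
        ))
    return out


class TestObjective:
    def test_zero_at_the_generating_parameters(self, params):
        datasets = noise_free_datasets(params, 8.18, 4.31)
        spec = FitSpec(free_parameters=("kB55Sub",),
                       bounds={"kB55Sub": (0.01, 0.3)}, n_quantiles=32)
        pop = PopulationSpec(median=8.18, sd=4.31, n_quantiles=32)
        loss = objective(np.array([params.kB55Sub]), datasets, spec, params, pop)
        assert loss < 1e-12

    def test_empty_dataset_list_gives_zero(self, params):
        spec = FitSpec(free_parameters=("kB55Sub",),
                       bounds={"kB55Sub": (0.01, 0.3)})
        assert objective(np.array([0.06]), [], spec, params,
                         PopulationSpec()) == 0.0

    def test_perturbed_parameter_is_identifiable(self, params):
        # kB55Sub positions the dose threshold only where no saddle-node
        # masks it: with both feedback loops cut (wee1i + Gwl depletion)
        # the endpoint is a pure kinase/phosphatase substrate balance.
        # In the feedback-intact conditions the substrate is a passive
        # reporter of the switch and kB55Sub barely moves the fractions.
        datasets = noise_free_datasets(params, 8.18, 4.31,
                                       conditions=("wee1i_gwl_depleted",))
        spec = FitSpec(free_parameters=("kB55Sub",),
                       bounds={"kB55Sub": (0.01, 0.3)}, n_quantiles=32)
        pop = PopulationSpec(median=8.18, sd=4.31, n_quantiles=32)
        loss = objective(np.array([params.kB55Sub * 1.5]), datasets, spec,
                         params, pop)
        assert loss > 1e-3

    def test_perturbed_cyclin_median_raises_the_stage2_loss(self, params):
        datasets = noise_free_datasets(params, 8.18, 4.31)
        r_true = fit_stage2_variance(datasets, 8.18, FitSpec(n_quantiles=32),
                                     params)
        r_wrong = fit_stage2_variance(datasets, 8.18 * 1.5, FitSpec(n_quantiles=32),
                                      params)
        assert r_wrong.loss > r_true.loss + 1e-3


class TestStage1:
    @pytest.mark.parametrize("true_median", [8.18, 4.0])
    def test_recovers_the_generating_median(self, params, true_median):
        datasets = noise_free_datasets(
            params, true_median, 4.31 * true_median / 8.18,
            conditions=("control", "gwl_depleted"), protocols=("entry", "exit"))
        result = fit_stage1_median(datasets, base_params=params)
        assert result.values["median"] == pytest.approx(true_median, rel=0.05)

    def test_all_flat_datasets_is_an_error(self, params):
        flat = DoseResponseDataset(
            condition="control", protocol="entry",
            doses=np.array([0.0, 1.0, 2.0]),
            counts=np.full((3, 2), 80), n_cells=100,
        )
        with pytest.raises(ValueError, match="no dataset crosses"):
            fit_stage1_median([flat], base_params=params)


class TestStage2:
    def test_recovers_the_generating_sd(self, params):
        datasets = noise_free_datasets(params, 8.18, 4.31,
                                       protocols=("entry", "exit"))
        result = fit_stage2_variance(datasets, 8.18, FitSpec(n_quantiles=32),
                                     params)
        assert result.values["sd"] == pytest.approx(4.31, rel=0.10)

    def test_step_data_recovers_near_zero_sd(self, params):
        # resolving a near-degenerate population requires doses packed
        # around the single-cell threshold (~0.113 μM): the entry fold
        # moves by only ~0.015 μM per AU of cyclin, so the default
        # log-spaced grid cannot distinguish sd below ~0.5 AU
        doses = tuple(np.concatenate([
            [0.0, 0.05], np.linspace(0.09, 0.14, 26), [0.2, 0.5, 2.0]]))
        datasets = noise_free_datasets(params, 8.18, 0.0, doses=doses)
        result = fit_stage2_variance(datasets, 8.18, FitSpec(n_quantiles=32),
                                     params)
        assert result.values["sd"] < 0.2

    def test_recovery_under_binomial_counting_noise(self, params):
        cfg = GeneratorConfig(
            true_params=params, conditions=("control",),
            protocols=("entry", "exit"), dose_grid=SMALL_DOSES,
            n_cells=100, n_repeats=3,
            population=PopulationSpec(median=8.18, sd=4.31), seed=5,
        )
        datasets = generate_dataset(cfg)
        result = fit_stage2_variance(datasets, 8.18, FitSpec(n_quantiles=32),
                                     params)
        assert result.values["sd"] == pytest.approx(4.31, rel=0.25)


class TestRateConstantFit:
    def test_single_constant_recovery(self, params):
        # fit under the double perturbation, where kB55Sub directly
        # positions the dose threshold (pure substrate balance, no fold)
        datasets = noise_free_datasets(params, 8.18, 4.31, doses=SMALL_DOSES,
                                       n_quantiles=16,
                                       conditions=("wee1i_gwl_depleted",))
        spec = FitSpec(free_parameters=("kB55Sub",),
                       bounds={"kB55Sub": (0.02, 0.2)}, budget=40, seed=3,
                       n_quantiles=16)
        result = fit_rate_constants(datasets, spec, params,
                                    PopulationSpec(median=8.18, sd=4.31,
                                                   n_quantiles=16))
        assert result.values["kB55Sub"] == pytest.approx(params.kB55Sub, rel=0.20)

    def test_zero_budget_returns_initial_guess_unconverged(self, params):
        datasets = noise_free_datasets(params, 8.18, 4.31, doses=SMALL_DOSES[:5])
        spec = FitSpec(free_parameters=("kB55Sub",),
                       bounds={"kB55Sub": (0.02, 0.2)}, budget=0)
        result = fit_rate_constants(datasets, spec, params)
        assert result.values["kB55Sub"] == pytest.approx(0.11)
        assert not result.converged

    def test_identifiability_guard(self, params):
        with pytest.raises(ValueError, match="at most 6"):
            FitSpec(free_parameters=tuple(
                ["kB55Sub", "kCdk1Sub", "kWee1F", "kCdc25F", "kB55Wee1",
                 "kB55Cdc25", "kass"]))
            fit_rate_constants([], FitSpec(
                free_parameters=("kB55Sub", "kCdk1Sub", "kWee1F", "kCdc25F",
                                 "kB55Wee1", "kB55Cdc25", "kass"),
                bounds={}), params)
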