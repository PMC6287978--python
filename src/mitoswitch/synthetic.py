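"""Synthetic endpoint-assay datasets with the experiment's statistical
structure.

Each simulated biological repeat draws ``n_cells`` (default 100) total
cyclin B values from the log-normal population, runs the per-cell entry
or exit protocol at each dose, and counts mitotic cells — so per-dose
counts are exactly binomial around the noise-free population fraction.
No dose-measurement error and no repeat-level random effects are added:
in this model all variability between cells comes from cyclin B.

Seeding: one master seed; the stream for each (condition, protocol,
dose-index, repeat) is ``SeedSequence([master, condition_index,
protocol_index, dose_index, repeat])``, so any subset of the design can
be regenerated in isolation, bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import DoseResponseDataset
from .params import Condition, ParameterSet
from .population import (
    DoseResponseCurve,
    PopulationSpec,
    classify_cells,
    default_dose_grid,
    population_dose_response,
)
from .simulate import ClassificationConfig

__all__ = ["GeneratorConfig", "generate_dataset", "generate_noise_free_curves"]

_PROTOCOLS = ("entry", "exit")


@dataclass(frozen=True)
class GeneratorConfig:
    true_params: ParameterSet
    conditions: tuple[Condition, ...] = tuple(Condition)
    protocols: tuple[str, ...] = _PROTOCOLS
    dose_grid: tuple[float, ...] = tuple(default_dose_grid())
    n_cells: int = 100
    n_repeats: int = 3
    population: PopulationSpec = field(default_factory=PopulationSpec)
    seed: int = 0
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        object.__setattr__(self, "conditions",
                           tuple(Condition(c) for c in self.conditions))
        for prot in self.protocols:
            if prot not in _PROTOCOLS:
                raise ValueError(f"unknown protocol {prot!r}")


def _repeat_rng(cfg: GeneratorConfig, ci: int, pi: int, di: int, rep: int):
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), ci, pi, di, rep])
    )


def generate_dataset(cfg: GeneratorConfig) -> list[DoseResponseDataset]:
    """One dataset per (condition, protocol); counts out of ``n_cells``
    per dose and repeat, with full provenance recorded."""
    mu, sigma = cfg.population.mu_sigma()
    datasets = []
    for ci, cond in enumerate(cfg.conditions):
        for pi, prot in enumerate(cfg.protocols):
            counts = np.zeros((len(cfg.dose_grid), cfg.n_repeats), dtype=int)
            for di, dose in enumerate(cfg.dose_grid):
                for rep in range(cfg.n_repeats):
                    rng = _repeat_rng(cfg, ci, pi, di, rep)
                    cells = np.exp(mu + sigma * rng.standard_normal(cfg.n_cells))
                    mitotic = classify_cells(
                        cfg.true_params, cond, prot, float(dose), cells,
                        cfg.classification,
                    )
                    counts[di, rep] = int(mitotic.sum())
            datasets.append(DoseResponseDataset(
                condition=cond.value,
                protocol=prot,
                doses=np.asarray(cfg.dose_grid, dtype=float),
                counts=counts,
                n_cells=cfg.n_cells,
                provenance={
                    "seed": int(cfg.seed),
                    "true_params": cfg.true_params.digest(),
                    "median": cfg.population.median,
                    "sd": cfg.population.sd,
                },
            ))
    return datasets


def generate_noise_free_curves(cfg: GeneratorConfig) -> list[DoseResponseCurve]:
    """Deterministic quantile-mode curves on the same grid — the
    infinite-N limit the stochastic datasets converge to."""
    return [
        population_dose_response(
            cfg.true_params, cond, prot, cfg.population,
            np.asarray(cfg.dose_grid, dtype=float), cfg.classification,
        )
        for cond in cfg.conditions
        for prot in cfg.protocols
    ]
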