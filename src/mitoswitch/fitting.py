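"""Two-stage estimation of the cyclin B population from endpoint data.

The canonical procedure mirrors how the model was parameterised:

* Stage 1 uses only the 50 % crossings (IC50s) of each condition's
  dose-response curve.  With a homogeneous population (SD = 0) the
  population IC50 equals the single-cell threshold dose of the median
  cell, so the stage reduces to a one-dimensional fit of the cyclin B
  *median*.
* Stage 2 holds the median fixed and fits the *spread* (arithmetic SD of
  the log-normal) to the full curves by least squares on fractions.

Rate-constant fitting ships as an opt-in utility (global differential
evolution followed by local refinement) restricted to a handful of free
constants at a time; the canonical pipeline fits only the cyclin B
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize, minimize_scalar

from .params import Condition, ParameterSet, PARAM_NAMES
from .population import (
    DoseResponseCurve,
    NoCrossingError,
    PopulationSpec,
    classify_cells,
    ic50,
    population_dose_response,
)
from .simulate import ClassificationConfig

__all__ = [
    "DoseResponseDataset",
    "FitSpec",
    "FitResult",
    "objective",
    "fit_stage1_median",
    "fit_stage2_variance",
    "fit_rate_constants",
    "read_dataset_csv",
    "write_dataset_csv",
]

log = logging.getLogger(__name__)

#: loss assigned when a simulation fails at a trial parameter vector
PENALTY = 1e6


@dataclass(frozen=True)
class DoseResponseDataset:
    """Per-dose mitotic counts for one condition and protocol."""

    condition: str
    protocol: str
    doses: np.ndarray                 # μM
    counts: np.ndarray                # (n_doses, n_repeats) mitotic counts
    n_cells: int = 100
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape[0] != doses.size:
            raise ValueError("counts must have one row per dose")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any(counts < 0) or np.any(counts > self.n_cells):
            raise ValueError(f"counts must lie in [0, {self.n_cells}]")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "counts", counts)

    @property
    def n_repeats(self) -> int:
        return self.counts.shape[1]

    def mean_fractions(self) -> np.ndarray:
        return self.counts.mean(axis=1) / self.n_cells

    def empirical_ic50(self) -> float:
        """50 % crossing of the mean curve (raises NoCrossingError)."""
        return ic50(DoseResponseCurve(
            self.doses, np.clip(self.mean_fractions(), 0, 1),
            condition=self.condition, protocol=self.protocol,
        ))


@dataclass(frozen=True)
class FitSpec:
    """What is free, within which bounds, and how hard to search."""

    free_parameters: tuple[str, ...] = ()
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    budget: int = 60                 # objective evaluations for global search
    seed: int = 0
    median_bounds: tuple[float, float] = (1.0, 30.0)
    sd_bounds: tuple[float, float] = (0.0, 15.0)
    n_quantiles: int = 32            # quadrature resolution during fitting

    def __post_init__(self) -> None:
        for name in self.free_parameters:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown free parameter {name!r}")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or hi <= lo:
                raise ValueError(f"bad bounds for {name!r}: ({lo}, {hi})")


@dataclass(frozen=True)
class FitResult:
    values: dict[str, float]
    loss: float
    n_evaluations: int
    converged: bool
    seed: int


def _sim_fractions(
    params: ParameterSet,
    dataset: DoseResponseDataset,
    spec_pop: PopulationSpec,
    cfg: ClassificationConfig,
) -> np.ndarray:
    curve = population_dose_response(
        params, dataset.condition, dataset.protocol, spec_pop,
        dataset.doses, cfg,
    )
    return curve.fraction_mitotic


def objective(
    theta: np.ndarray,
    datasets: list[DoseResponseDataset],
    spec: FitSpec,
    base_params: ParameterSet,
    population: PopulationSpec,
    cfg: ClassificationConfig | None = None,
) -> float:
    """Sum of squared differences between simulated (deterministic
    quantile mode) and observed mean mitotic fractions, over all datasets
    and doses.  Simulation failures yield a large finite penalty so
    optimizers can continue."""
    cfg = cfg or ClassificationConfig()
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.size != len(spec.free_parameters):
        raise ValueError("theta length must match spec.free_parameters")
    try:
        params = base_params.with_(**dict(zip(spec.free_parameters, map(float, theta))))
    except ValueError:
        return PENALTY
    loss = 0.0
    for ds in datasets:
        try:
            sim = _sim_fractions(params, ds, population, cfg)
        except Exception:  # noqa: BLE001 — any solver failure is penalised
            return PENALTY
        loss += float(np.sum((sim - ds.mean_fractions()) ** 2))
    return loss


def _single_cell_threshold(
    params: ParameterSet,
    condition: str,
    protocol: str,
    median: float,
    dose_lo: float,
    dose_hi: float,
    cfg: ClassificationConfig,
    tol: float = 2e-4,
) -> float | None:
    """Threshold dose at which the median cell's endpoint classification
    flips, by bisection; None if it does not flip inside the range."""
    def mitotic(d: float) -> bool:
        return bool(classify_cells(params, condition, protocol, d,
                                   np.array([median]), cfg)[0])

    lo_m, hi_m = mitotic(dose_lo), mitotic(dose_hi)
    if lo_m == hi_m:
        return None
    lo, hi = dose_lo, dose_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mitotic(mid) == lo_m:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_stage1_median(
    datasets: list[DoseResponseDataset],
    spec: FitSpec | None = None,
    base_params: ParameterSet | None = None,
    cfg: ClassificationConfig | None = None,
) -> FitResult:
    """Fit the cyclin B median to the empirical IC50s.

    For each dataset whose mean curve crosses 50 %, the simulated
    homogeneous-population IC50 (the median cell's threshold dose) is
    matched to the empirical crossing in least squares.  Datasets with no
    crossing are excluded with a warning; if all are excluded the fit is
    impossible and raises.
    """
    from .params import default_parameters

    spec = spec or FitSpec()
    base_params = base_params or default_parameters()
    cfg = cfg or ClassificationConfig()

    targets = []
    for ds in datasets:
        try:
            targets.append((ds, ds.empirical_ic50()))
        except NoCrossingError:
            log.warning("dataset %s/%s has no 50%% crossing; excluded from stage 1",
                        ds.condition, ds.protocol)
    if not targets:
        raise ValueError("no dataset crosses 50%; stage-1 fit impossible")

    d_hi = max(float(ds.doses.max()) for ds, _ in targets) * 1.5
    evals = 0

    def loss(median: float) -> float:
        nonlocal evals
        evals += 1
        total = 0.0
        for ds, emp in targets:
            thr = _single_cell_threshold(
                base_params, ds.condition, ds.protocol, median, 0.0, d_hi, cfg)
            total += (thr - emp) ** 2 if thr is not None else 1.0
        return total

    res = minimize_scalar(loss, bounds=spec.median_bounds, method="bounded",
                          options={"xatol": 1e-3})
    return FitResult(values={"median": float(res.x)}, loss=float(res.fun),
                     n_evaluations=evals, converged=bool(res.success),
                     seed=spec.seed)


def fit_stage2_variance(
    datasets: list[DoseResponseDataset],
    median: float,
    spec: FitSpec | None = None,
    base_params: ParameterSet | None = None,
    cfg: ClassificationConfig | None = None,
) -> FitResult:
    """Fit the arithmetic SD of the cyclin B distribution to the full
    curves, with the median fixed from stage 1."""
    from .params import default_parameters

    spec = spec or FitSpec()
    base_params = base_params or default_parameters()
    cfg = cfg or ClassificationConfig()
    evals = 0

    def loss(sd: float) -> float:
        nonlocal evals
        evals += 1
        pop = PopulationSpec(median=median, sd=max(float(sd), 0.0),
                             n_quantiles=spec.n_quantiles)
        total = 0.0
        for ds in datasets:
            try:
                sim = _sim_fractions(base_params, ds, pop, cfg)
            except Exception:  # noqa: BLE001
                return PENALTY
            total += float(np.sum((sim - ds.mean_fractions()) ** 2))
        return total

    # the loss is piecewise constant in sd (fractions are quantised to
    # 1/n_quantiles), so a plain 1-D minimiser stalls on plateaus: scan a
    # coarse grid first, then golden-section inside the best bracket
    lo, hi = spec.sd_bounds
    grid = np.linspace(lo, hi, 13)
    values = [loss(s) for s in grid]
    i = int(np.argmin(values))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(loss, bounds=(b_lo, b_hi), method="bounded",
                          options={"xatol": 1e-3})
    best_x, best_f = (float(res.x), float(res.fun))
    if values[i] < best_f:
        best_x, best_f = float(grid[i]), float(values[i])
    return FitResult(values={"sd": best_x}, loss=best_f,
                     n_evaluations=evals, converged=bool(res.success),
                     seed=spec.seed)


def fit_rate_constants(
    datasets: list[DoseResponseDataset],
    spec: FitSpec,
    base_params: ParameterSet | None = None,
    population: PopulationSpec | None = None,
    cfg: ClassificationConfig | None = None,
) -> FitResult:
    """Bounded global-then-local least squares over ≤ 6 rate constants.

    Differential evolution (seeded) explores the box, Nelder-Mead
    polishes the best point.  A zero budget returns the mid-box initial
    guess flagged non-converged.
    """
    from .params import default_parameters

    base_params = base_params or default_parameters()
    population = population or PopulationSpec(n_quantiles=spec.n_quantiles)
    cfg = cfg or ClassificationConfig()
    if not spec.free_parameters:
        raise ValueError("fit_rate_constants needs at least one free parameter")
    if len(spec.free_parameters) > 6:
        raise ValueError("at most 6 free rate constants (identifiability guard)")
    missing = [n for n in spec.free_parameters if n not in spec.bounds]
    if missing:
        raise ValueError(f"bounds missing for: {', '.join(missing)}")

    bounds = [spec.bounds[n] for n in spec.free_parameters]
    x0 = np.array([0.5 * (lo + hi) for lo, hi in bounds])
    evals = 0

    def f(theta: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        return objective(theta, datasets, spec, base_params, population, cfg)

    if spec.budget <= 0:
        return FitResult(
            values=dict(zip(spec.free_parameters, map(float, x0))),
            loss=f(x0), n_evaluations=evals, converged=False, seed=spec.seed,
        )

    n_free = len(bounds)
    popsize = max(5, min(8, spec.budget // max(n_free, 1)))
    maxiter = max(1, spec.budget // (popsize * n_free))
    de = differential_evolution(
        f, bounds, seed=spec.seed, popsize=popsize, maxiter=maxiter,
        tol=1e-8, polish=False, init="sobol", updating="deferred",
    )
    local = minimize(f, de.x, method="Nelder-Mead",
                     options={"maxfev": max(20 * n_free, 40), "xatol": 1e-4,
                              "fatol": 1e-10})
    best = local if local.fun <= de.fun else de
    converged = bool(de.success or local.fun < 1e-8)
    x = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return FitResult(
        values=dict(zip(spec.free_parameters, map(float, np.atleast_1d(x)))),
        loss=float(best.fun), n_evaluations=evals, converged=converged,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# dataset CSV I/O (schema: condition, protocol, dose_uM, repeat_id,
# n_mitotic, n_total)

def write_dataset_csv(datasets: list[DoseResponseDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for di, dose in enumerate(ds.doses):
            for rep in range(ds.n_repeats):
                rows.append({
                    "condition": ds.condition,
                    "protocol": ds.protocol,
                    "dose_uM": float(dose),
                    "repeat_id": rep,
                    "n_mitotic": int(ds.counts[di, rep]),
                    "n_total": ds.n_cells,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset_csv(path: str | Path) -> list[DoseResponseDataset]:
    df = pd.read_csv(path)
    required = {"condition", "protocol", "dose_uM", "repeat_id", "n_mitotic", "n_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing column(s): {', '.join(sorted(missing))}")
    datasets = []
    for (cond, prot), grp in df.groupby(["condition", "protocol"], sort=False):
        Condition(cond)  # validates the label
        n_cells = int(grp["n_total"].iloc[0])
        if not (grp["n_total"] == n_cells).all():
            raise ValueError("n_total must be constant within a dataset")
        pivot = grp.pivot_table(index="dose_uM", columns="repeat_id",
                                values="n_mitotic", aggfunc="first").sort_index()
        datasets.append(DoseResponseDataset(
            condition=str(cond), protocol=str(prot),
            doses=pivot.index.to_numpy(dtype=float),
            counts=pivot.to_numpy(dtype=int),
            n_cells=n_cells,
        ))
    return datasets
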