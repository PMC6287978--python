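"""Parameter sets and experimental-condition perturbations.

The model describes the mutual antagonism between Cdk1:CycB and its
counteracting phosphatase PP2A:B55 with mass-action kinetics.  All rate
constants are per minute (second-order constants per AU per minute);
total protein pools are in arbitrary concentration units (AU) with most
totals normalised to 1, ``B55Tot = 0.25`` and a median ``CycBTot`` of
8.1808.  The ATP-analog inhibitor dose and its dissociation constant
``Kd`` are in micromolar.

Two named parameter sets ship with the package:

``xpp``
    The high-precision values of the published XPPAUT listing; this is
    the canonical set used everywhere by default.
``table``
    The rounded values of the published prose table.  The two differ
    only in rounding (e.g. ``kass`` 617.2807 vs 617).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields, replace
from enum import Enum
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ParameterSet",
    "Condition",
    "apply_condition",
    "default_parameters",
    "table_parameters",
    "load_parameters",
    "save_parameters",
    "PARAM_NAMES",
]

# Wee1 and Cdc25 total pools are the literal 1 of the model equations and
# are deliberately not exposed as parameters.
WEE1_TOT = 1.0
CDC25_TOT = 1.0


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants, total pools and the inhibitor Kd of the model.

    The inhibitor dose itself is *not* a parameter; it is part of the
    experimental protocol (see :class:`mitoswitch.simulate.InhibitorSchedule`).
    """

    # PP1 regulation
    kaPP1: float      # constitutive PP1 activation, /min
    kaPP1a: float     # PP1 self-activation in trans, /AU/min
    kiPP1: float      # constitutive PP1 inactivation, /min
    kCdk1PP1: float   # PP1 inactivation by Cdk1:CycB, /AU/min
    kPP1Gwl: float    # Gwl dephosphorylation by PP1, /AU/min
    # ENSA / PP2A:B55 core
    kass: float       # pENSA + PP2A:B55 association, /AU/min
    kdis: float       # complex dissociation, /min
    kcatB55: float    # pENSA dephosphorylation in the complex, /min
    kGwlENSA: float   # ENSA phosphorylation by active Gwl, /AU/min
    kPPXGwl: float    # basal Gwl dephosphorylation, /min
    # substrate
    kCdk1Sub: float   # substrate phosphorylation by Cdk1:CycB, /AU/min
    kB55Sub: float    # substrate dephosphorylation by PP2A:B55, /AU/min
    # Gwl regulation
    kCdk1Gwl: float
    kB55Gwl: float
    kCdk2Gwl: float
    # Cdk1 Y15 regulation (Wee1 / Cdc25)
    kCdc25S: float    # Y15 dephosphorylation by less-active Cdc25, /min
    kCdc25F: float    # Y15 dephosphorylation by phosphorylated Cdc25, /min
    kWee1S: float     # Y15 phosphorylation by phosphorylated (slow) Wee1, /min
    kWee1F: float     # Y15 phosphorylation by unphosphorylated (fast) Wee1, /min
    kCdk1Wee1: float
    kCdk1Cdc25: float
    kPPXY15: float    # constitutive Wee1/Cdc25 dephosphorylation, /min
    kCdk2Wee1: float
    kCdk2Cdc25: float
    kB55Wee1: float
    kB55Cdc25: float
    # total pools (AU)
    CycBTot: float
    Cdk2Tot: float
    PP1Tot: float
    ENSATot: float
    B55Tot: float
    GwlTot: float
    SubTot: float
    # inhibitor dissociation constant (μM)
    Kd: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise TypeError(f"{f.name} must be a number, got {type(v).__name__}")
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
        if self.Kd <= 0:
            raise ValueError(f"Kd must be positive, got {self.Kd}")

    def with_(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def as_tuple(self) -> tuple[float, ...]:
        """Field values in declaration order (hot-path representation)."""
        return tuple(float(getattr(self, n)) for n in PARAM_NAMES)

    def digest(self) -> str:
        """Stable hash of the parameter values, for run manifests."""
        payload = ",".join(f"{n}={getattr(self, n)!r}" for n in PARAM_NAMES)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ParameterSet))

# Canonical values: the XPPAUT listing (executable source of the published
# bifurcation diagrams).
_XPP_VALUES: dict[str, float] = {
    "kaPP1": 0.0115, "kaPP1a": 0.7054, "kiPP1": 0.0018, "kCdk1PP1": 0.7549,
    "kPP1Gwl": 18.4724,
    "kass": 617.2807, "kdis": 0.0088, "kcatB55": 1.0338,
    "kGwlENSA": 20.8811, "kPPXGwl": 0.1560,
    "kCdk1Sub": 0.0080, "kB55Sub": 0.0593,
    "kCdk1Gwl": 0.2393, "kB55Gwl": 496.5636, "kCdk2Gwl": 0.1916,
    "kCdc25S": 0.0050, "kCdc25F": 0.9411, "kWee1S": 0.0050, "kWee1F": 47.2937,
    "kCdk1Wee1": 1.3132, "kCdk1Cdc25": 1.3132, "kPPXY15": 0.0050,
    "kCdk2Wee1": 0.1096, "kCdk2Cdc25": 0.1096,
    "kB55Wee1": 0.5511, "kB55Cdc25": 0.5511,
    "CycBTot": 8.1808, "Cdk2Tot": 1.0, "PP1Tot": 1.0, "ENSATot": 1.0,
    "B55Tot": 0.25, "GwlTot": 1.0, "SubTot": 1.0,
    "Kd": 0.025,
}

# The rounded published table (identical model, lower precision).
_TABLE_VALUES: dict[str, float] = dict(
    _XPP_VALUES,
    kaPP1=0.01, kaPP1a=0.70, kiPP1=0.002, kCdk1PP1=0.75, kPP1Gwl=18.47,
    kass=617.0, kdis=0.009, kcatB55=1.0, kGwlENSA=21.0, kPPXGwl=0.16,
    kCdk1Sub=0.008, kB55Sub=0.06, kCdk1Gwl=0.24, kB55Gwl=496.0,
    kCdk2Gwl=0.19, kCdc25S=0.005, kCdc25F=0.94, kWee1S=0.005, kWee1F=47.0,
    kCdk1Wee1=1.31, kCdk1Cdc25=1.31, kPPXY15=0.005, kCdk2Wee1=0.11,
    kCdk2Cdc25=0.11, kB55Wee1=0.55, kB55Cdc25=0.55,
    CycBTot=8.18,
)


def default_parameters() -> ParameterSet:
    """The canonical (XPPAUT-precision) parameter set."""
    return ParameterSet(**_XPP_VALUES)


def table_parameters() -> ParameterSet:
    """The rounded prose-table parameter set."""
    return ParameterSet(**_TABLE_VALUES)


class Condition(str, Enum):
    """The four experimental conditions of the endpoint hysteresis assay."""

    CONTROL = "control"
    WEE1I = "wee1i"                      # Wee1 inhibition
    GWL_DEPLETED = "gwl_depleted"        # Greatwall siRNA
    WEE1I_GWL_DEPLETED = "wee1i_gwl_depleted"


def apply_condition(params: ParameterSet, condition: Condition | str) -> ParameterSet:
    """Return a copy of *params* with the condition's perturbation applied.

    Wee1 inhibition zeroes both Y15-kinase rate constants (``kWee1S``,
    ``kWee1F``); Greatwall depletion zeroes the total Gwl pool.  The
    combined condition applies both.  The input is never modified.
    """
    condition = Condition(condition)
    updates: dict[str, float] = {}
    if condition in (Condition.WEE1I, Condition.WEE1I_GWL_DEPLETED):
        updates.update(kWee1S=0.0, kWee1F=0.0)
    if condition in (Condition.GWL_DEPLETED, Condition.WEE1I_GWL_DEPLETED):
        updates.update(GwlTot=0.0)
    return params.with_(**updates) if updates else params


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a flat key-value YAML parameter file.

    Missing keys fall back to the canonical defaults; unknown keys are an
    error (they are usually typos of rate-constant names).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must be a flat mapping")
    unknown = set(raw) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter key(s): {', '.join(sorted(unknown))}")
    values = dict(_XPP_VALUES)
    values.update({k: float(v) for k, v in raw.items()})
    return ParameterSet(**values)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in PARAM_NAMES:
            fh.write(f"{name}: {getattr(params, name)!r}\n")


def packaged_parameters(name: str) -> ParameterSet:
    """Load one of the shipped parameter files (``'xpp'`` or ``'table'``)."""
    ref = resources.files("mitoswitch.data").joinpath(f"params_{name}.yaml")
    with resources.as_file(ref) as p:
        return load_parameters(p)
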