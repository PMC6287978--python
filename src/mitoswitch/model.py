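"""State representation, rate functions and the mass-action right-hand side.

The dynamical system has ten state variables, ordered as in the published
initial-condition listing::

    (Subp, CycBCdk1, PP1, pENSATot, Gwlp, PP2AB55, Wee1, Wee1pp, Cdc25, Cdc25pp)

Three pools are eliminated algebraically by conservation:

* ``pENSA:B55`` complex = ``B55Tot - PP2AB55``
* ``Wee1p``  = ``1 - Wee1 - Wee1pp``
* ``Cdc25p`` = ``1 - Cdc25 - Cdc25pp``

Conventions worth remembering: the ``Wee1`` variable is the
*unphosphorylated, fast (active)* kinase form, so the interphase state has
``Wee1 = 1``; ``Cdc25pp`` is the doubly phosphorylated *active* phosphatase
form.  The ATP-analog inhibitor acts by rapid-equilibrium binding, which
divides every Cdk1:CycB-driven term by ``1 + dose/Kd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CDC25_TOT, WEE1_TOT, ParameterSet

__all__ = [
    "STATE_VARS",
    "ModelState",
    "RateValues",
    "interphase_state",
    "rate_functions",
    "rhs",
    "rhs_array",
    "derived_pools",
    "validate_state",
    "clamp_state",
    "jacobian_fd",
    "jacobian_cs",
]

STATE_VARS: tuple[str, ...] = (
    "Subp", "CycBCdk1", "PP1", "pENSATot", "Gwlp",
    "PP2AB55", "Wee1", "Wee1pp", "Cdc25", "Cdc25pp",
)

#: tolerance for small negative solver drift that is clamped rather than raised
CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class ModelState:
    """The ten dynamic concentrations (AU)."""

    Subp: float
    CycBCdk1: float
    PP1: float
    pENSATot: float
    Gwlp: float
    PP2AB55: float
    Wee1: float
    Wee1pp: float
    Cdc25: float
    Cdc25pp: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_VARS),):
            raise ValueError(f"expected a 10-vector, got shape {y.shape}")
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class RateValues:
    """Effective activities of the four regulated enzymes."""

    VCdk1: float
    VWee1: float
    VCdc25: float
    VGwl: float


def interphase_state(params: ParameterSet | None = None) -> ModelState:
    """The published interphase-arrest initial conditions.

    PP1 fully active, PP2A:B55 fully free, Wee1 active, Cdc25 inactive,
    no active Cdk1:CycB and no substrate phosphorylation.
    """
    b55 = params.B55Tot if params is not None else 0.25
    return ModelState(
        Subp=0.0, CycBCdk1=0.0, PP1=1.0, pENSATot=0.0, Gwlp=0.0,
        PP2AB55=b55, Wee1=1.0, Wee1pp=0.0, Cdc25=1.0, Cdc25pp=0.0,
    )


def validate_state(state: ModelState, params: ParameterSet, tol: float = 1e-6) -> None:
    """Raise ``ValueError`` if *state* violates the invariant box."""
    y = state.as_array()
    tots = _pool_bounds(params)
    for name, v, hi in zip(STATE_VARS, y, tots):
        if v < -tol or v > hi + tol:
            raise ValueError(f"{name}={v} outside [0, {hi}]")
    if state.Wee1 + state.Wee1pp > WEE1_TOT + tol:
        raise ValueError("Wee1 + Wee1pp exceeds the total Wee1 pool")
    if state.Cdc25 + state.Cdc25pp > CDC25_TOT + tol:
        raise ValueError("Cdc25 + Cdc25pp exceeds the total Cdc25 pool")
    cplx = params.B55Tot - state.PP2AB55
    if cplx < -tol or cplx > state.pENSATot + tol:
        raise ValueError("pENSA:B55 complex outside [0, pENSATot]")


def _pool_bounds(params: ParameterSet) -> np.ndarray:
    return np.array([
        params.SubTot, params.CycBTot, params.PP1Tot, params.ENSATot,
        params.GwlTot, params.B55Tot, WEE1_TOT, WEE1_TOT, CDC25_TOT, CDC25_TOT,
    ])


def clamp_state(y: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Clamp tiny negative integrator drift to zero; larger violations raise.

    Mass-action positivity is exact, so components in ``(-1e-9, 0)`` are
    solver noise; anything more negative signals an integration failure.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < -CLAMP_TOL * 100):
        worst = STATE_VARS[int(np.argmin(y))]
        raise ValueError(f"state component {worst} is negative beyond tolerance: {y.min()}")
    return np.maximum(y, 0.0)


def rate_functions(
    state: ModelState, params: ParameterSet, inhibitor: float = 0.0
) -> RateValues:
    """Evaluate the four rate functions at *state* under the given dose (μM).

    ``VCdk1 = CycBCdk1 / (1 + dose/Kd)`` is the rapid-equilibrium residual
    kinase activity; Wee1 and Cdc25 activities are the weighted sums of
    their less- and more-active forms; ``VGwl`` is proportional to
    phosphorylated Greatwall.
    """
    if inhibitor < 0:
        raise ValueError(f"inhibitor dose must be non-negative, got {inhibitor}")
    validate_state(state, params)
    vcdk1 = state.CycBCdk1 / (1.0 + inhibitor / params.Kd)
    vwee = params.kWee1S * (WEE1_TOT - state.Wee1) + params.kWee1F * state.Wee1
    v25 = params.kCdc25S * (CDC25_TOT - state.Cdc25pp) + params.kCdc25F * state.Cdc25pp
    vgwl = params.kGwlENSA * state.Gwlp
    return RateValues(VCdk1=vcdk1, VWee1=vwee, VCdc25=v25, VGwl=vgwl)


def derived_pools(
    state: ModelState, params: ParameterSet, tol: float = 1e-6
) -> dict[str, float]:
    """Return the conserved pools eliminated from the dynamic state.

    A violation beyond *tol* means the state did not come from a valid
    integration and is reported as an error.
    """
    cplx = params.B55Tot - state.PP2AB55
    wee1p = WEE1_TOT - state.Wee1 - state.Wee1pp
    cdc25p = CDC25_TOT - state.Cdc25 - state.Cdc25pp
    if cplx < -tol or cplx > state.pENSATot + tol:
        raise ValueError(f"conservation violated: pENSA:B55 complex = {cplx}")
    if wee1p < -tol or cdc25p < -tol:
        raise ValueError("conservation violated: negative monophosphorylated pool")
    return {"complex": cplx, "Wee1p": wee1p, "Cdc25p": cdc25p}


def rhs_array(y, params: ParameterSet, inhibitor: float):
    """Time derivative of the 10-vector *y*.

    Elementwise arithmetic only, so *y* may be a plain sequence of floats,
    a 1-D array, a ``(10, n)`` array (vectorised over columns), or complex
    (for complex-step differentiation).  Returns a list of 10 components.
    """
    p = params
    Subp, CycBCdk1, PP1, pENSAt, Gwlp, PP2AB55, Wee1, Wee1pp, Cdc25, Cdc25pp = y
    vcdk1 = CycBCdk1 / (1.0 + inhibitor / p.Kd)
    cplx = p.B55Tot - PP2AB55
    wee1p = WEE1_TOT - Wee1 - Wee1pp
    cdc25p = CDC25_TOT - Cdc25 - Cdc25pp
    vwee = p.kWee1S * (WEE1_TOT - Wee1) + p.kWee1F * Wee1
    v25 = p.kCdc25S * (CDC25_TOT - Cdc25pp) + p.kCdc25F * Cdc25pp
    vgwl = p.kGwlENSA * Gwlp
    kin_w = p.kCdk1Wee1 * vcdk1 + p.kCdk2Wee1 * p.Cdk2Tot
    kin_c = p.kCdk1Cdc25 * vcdk1 + p.kCdk2Cdc25 * p.Cdk2Tot
    deph_w = p.kPPXY15 + p.kB55Wee1 * PP2AB55
    deph_c = p.kPPXY15 + p.kB55Cdc25 * PP2AB55
    return [
        p.kCdk1Sub * vcdk1 * (p.SubTot - Subp) - p.kB55Sub * PP2AB55 * Subp,
        v25 * (p.CycBTot - CycBCdk1) - vwee * CycBCdk1,
        (p.kaPP1 + p.kaPP1a * PP1) * (p.PP1Tot - PP1)
        - (p.kiPP1 + p.kCdk1PP1 * vcdk1) * PP1,
        vgwl * (p.ENSATot - pENSAt) - p.kcatB55 * cplx,
        (p.kCdk1Gwl * vcdk1 + p.kCdk2Gwl * p.Cdk2Tot) * (p.GwlTot - Gwlp)
        - (p.kB55Gwl * PP2AB55 + p.kPPXGwl + p.kPP1Gwl * PP1) * Gwlp,
        (p.kdis + p.kcatB55) * cplx - p.kass * PP2AB55 * (pENSAt - cplx),
        deph_w * wee1p - kin_w * Wee1,
        kin_w * wee1p - deph_w * Wee1pp,
        deph_c * cdc25p - kin_c * Cdc25,
        kin_c * cdc25p - deph_c * Cdc25pp,
    ]


def rhs(state: ModelState, params: ParameterSet, inhibitor: float = 0.0) -> ModelState:
    """Validated right-hand side; returns the derivative as a ModelState."""
    if inhibitor < 0:
        raise ValueError(f"inhibitor dose must be non-negative, got {inhibitor}")
    validate_state(state, params)
    return ModelState(*rhs_array(state.as_array(), params, inhibitor))


def jacobian_fd(y: np.ndarray, params: ParameterSet, inhibitor: float) -> np.ndarray:
    """Jacobian of the right-hand side by central finite differences.

    Relative step 1e-7, floored for components near zero.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-7 * max(abs(y[j]), 1e-3)
        yp = y.copy(); yp[j] += h
        ym = y.copy(); ym[j] -= h
        fp = np.asarray(rhs_array(yp, params, inhibitor))
        fm = np.asarray(rhs_array(ym, params, inhibitor))
        J[:, j] = (fp - fm) / (2.0 * h)
    return J


def jacobian_cs(y: np.ndarray, params: ParameterSet, inhibitor: float) -> np.ndarray:
    """Jacobian by complex-step differentiation (machine-precision check)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    h = 1e-20
    for j in range(n):
        yc = y.astype(complex)
        yc[j] += 1j * h
        J[:, j] = np.imag(np.asarray(rhs_array(yc, params, inhibitor))) / h
    return J
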