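"""Time integration, steady states, mitotic classification and the three
in-silico protocols of the endpoint hysteresis assay.

All protocols start from the published interphase-arrest initial
conditions (the state after a long G2 arrest at a saturating inhibitor
dose).  A cell is scored *mitotic* when its generic Cdk1/PP2A:B55
substrate is at least 30 % phosphorylated, matching the fixed-endpoint
microscopy assay.

* entry protocol: constant dose from release; classify at 240 min.
* exit protocol:  90 min inhibitor-free (cell enters mitosis), then the
  dose; classify 240 min after dose addition.
* prophase protocol: inhibitor-free release, dose re-added at
  ``readd_time`` (default 25 min); the cell is integrated to steady state
  and labelled by the stable attractor it converges to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import warnings

import numpy as np
from scipy.integrate import ODEintWarning, odeint

from .model import (
    ModelState,
    clamp_state,
    interphase_state,
    rhs_array,
)
from .params import Condition, ParameterSet, apply_condition

__all__ = [
    "InhibitorSchedule",
    "Trajectory",
    "ClassificationConfig",
    "IntegrationError",
    "integrate",
    "rk4_integrate",
    "steady_state",
    "classify",
    "run_entry_protocol",
    "run_exit_protocol",
    "run_prophase_protocol",
    "refine_interphase_state",
]

RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time that integrated cleanly."""

    def __init__(self, message: str, last_good_time: float):
        super().__init__(message)
        self.last_good_time = last_good_time


@dataclass(frozen=True)
class InhibitorSchedule:
    """Piecewise-constant 1NM-PP1 dose: ordered ``(start_time_min, dose_uM)``."""

    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bps = tuple((float(t), float(d)) for t, d in self.breakpoints)
        object.__setattr__(self, "breakpoints", bps)
        if not bps:
            raise ValueError("schedule needs at least one segment")
        if bps[0][0] != 0.0:
            raise ValueError("first segment must start at t = 0")
        times = [t for t, _ in bps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(d < 0 for _, d in bps):
            raise ValueError("doses must be non-negative")

    @classmethod
    def constant(cls, dose: float) -> "InhibitorSchedule":
        return cls(breakpoints=((0.0, dose),))

    @classmethod
    def step(cls, t_switch: float, dose_before: float, dose_after: float) -> "InhibitorSchedule":
        return cls(breakpoints=((0.0, dose_before), (t_switch, dose_after)))

    def dose_at(self, t: float) -> float:
        dose = self.breakpoints[0][1]
        for start, d in self.breakpoints:
            if t >= start:
                dose = d
        return dose

    def segments(self, t_end: float):
        """Yield ``(t0, t1, dose)`` covering [0, t_end]."""
        starts = [t for t, _ in self.breakpoints if t < t_end] + [t_end]
        for (t0, dose), t1 in zip(self.breakpoints, starts[1:]):
            yield t0, t1, dose


@dataclass(frozen=True)
class Trajectory:
    """Integration result on caller-requested output times."""

    times: np.ndarray
    states: np.ndarray          # shape (n_times, 10)
    schedule: InhibitorSchedule

    def state_at_end(self) -> ModelState:
        return ModelState.from_array(self.states[-1])


@dataclass(frozen=True)
class ClassificationConfig:
    """Mitotic scoring: threshold on Subp/SubTot and the assay endpoint."""

    mitotic_threshold: float = 0.30
    endpoint_time: float = 240.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mitotic_threshold < 1.0:
            raise ValueError("mitotic_threshold must be in (0, 1)")
        if self.endpoint_time <= 0:
            raise ValueError("endpoint_time must be positive")


def _make_segment_rhs(p: ParameterSet, dose: float):
    """Bind all rate constants into locals: odeint calls this millions of
    times, and attribute lookups on the dataclass dominate otherwise."""
    finh = 1.0 / (1.0 + dose / p.Kd)
    (kaPP1, kaPP1a, kiPP1, kCdk1PP1, kPP1Gwl, kass, kdis, kcatB55, kGwlENSA,
     kPPXGwl, kCdk1Sub, kB55Sub, kCdk1Gwl, kB55Gwl, kCdk2Gwl, kCdc25S,
     kCdc25F, kWee1S, kWee1F, kCdk1Wee1, kCdk1Cdc25, kPPXY15, kCdk2Wee1,
     kCdk2Cdc25, kB55Wee1, kB55Cdc25, CycBTot, Cdk2Tot, PP1Tot, ENSATot,
     B55Tot, GwlTot, SubTot, _Kd) = p.as_tuple()
    kw2 = kCdk2Wee1 * Cdk2Tot
    kc2 = kCdk2Cdc25 * Cdk2Tot
    kg2 = kCdk2Gwl * Cdk2Tot

    def f(y, t):
        Subp, CycBCdk1, PP1, pENSAt, Gwlp, PP2AB55, Wee1, Wee1pp, Cdc25, Cdc25pp = y
        vcdk1 = CycBCdk1 * finh
        cplx = B55Tot - PP2AB55
        wee1p = 1.0 - Wee1 - Wee1pp
        cdc25p = 1.0 - Cdc25 - Cdc25pp
        kin_w = kCdk1Wee1 * vcdk1 + kw2
        kin_c = kCdk1Cdc25 * vcdk1 + kc2
        deph_w = kPPXY15 + kB55Wee1 * PP2AB55
        deph_c = kPPXY15 + kB55Cdc25 * PP2AB55
        return (
            kCdk1Sub * vcdk1 * (SubTot - Subp) - kB55Sub * PP2AB55 * Subp,
            (kCdc25S * (1.0 - Cdc25pp) + kCdc25F * Cdc25pp) * (CycBTot - CycBCdk1)
            - (kWee1S * (1.0 - Wee1) + kWee1F * Wee1) * CycBCdk1,
            (kaPP1 + kaPP1a * PP1) * (PP1Tot - PP1)
            - (kiPP1 + kCdk1PP1 * vcdk1) * PP1,
            kGwlENSA * Gwlp * (ENSATot - pENSAt) - kcatB55 * cplx,
            (kCdk1Gwl * vcdk1 + kg2) * (GwlTot - Gwlp)
            - (kB55Gwl * PP2AB55 + kPPXGwl + kPP1Gwl * PP1) * Gwlp,
            (kdis + kcatB55) * cplx - kass * PP2AB55 * (pENSAt - cplx),
            deph_w * wee1p - kin_w * Wee1,
            kin_w * wee1p - deph_w * Wee1pp,
            deph_c * cdc25p - kin_c * Cdc25,
            kin_c * cdc25p - deph_c * Cdc25pp,
        )

    return f


def _odeint_segment(y0, params, dose, t_eval):
    """LSODA over one constant-dose segment; full-output error check."""
    with warnings.catch_warnings():
        # failures are detected from the info dict and handled by callers
        warnings.simplefilter("ignore", ODEintWarning)
        y, info = odeint(
            _make_segment_rhs(params, dose),
            y0, t_eval, rtol=RTOL, atol=ATOL, mxstep=100_000, full_output=True,
        )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"LSODA failed at dose {dose}: {info['message']}",
            last_good_time=float(info["tcur"][-1]) if len(info["tcur"]) else float(t_eval[0]),
        )
    return y


def integrate(
    state0: ModelState,
    params: ParameterSet,
    schedule: InhibitorSchedule,
    t_end: float,
    t_eval: Sequence[float] | None = None,
) -> Trajectory:
    """Stiff-capable integration under a piecewise-constant dose schedule.

    The integrator is restarted exactly at every schedule breakpoint so
    the dose discontinuity is never interpolated across.  ``t_end = 0``
    returns a trajectory holding only *state0*.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    y0 = state0.as_array()
    if t_end == 0:
        return Trajectory(np.array([0.0]), y0[None, :], schedule)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, max(int(t_end) + 1, 2))
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] != 0.0 or np.any(np.diff(t_eval) <= 0) or t_eval[-1] > t_end:
        raise ValueError("t_eval must be increasing, start at 0 and end within t_end")

    out_t: list[float] = [0.0]
    out_y: list[np.ndarray] = [y0]
    y = y0
    for t0, t1, dose in schedule.segments(t_end):
        inner = t_eval[(t_eval > t0) & (t_eval < t1)]
        ts = np.concatenate([[t0], inner, [t1]])
        ys = _odeint_segment(y, params, dose, ts)
        y = clamp_state(ys[-1], params)
        keep = np.isin(ts[1:], t_eval)
        for tv, yv in zip(ts[1:][keep], ys[1:][keep]):
            out_t.append(float(tv))
            out_y.append(clamp_state(yv, params))
    # segment ends coincide with breakpoints which may not be in t_eval;
    # guarantee the final state is reported
    if out_t[-1] != t_end:
        out_t.append(t_end)
        out_y.append(y)
    return Trajectory(np.array(out_t), np.vstack(out_y), schedule)


def rk4_integrate(
    y0: np.ndarray, params: ParameterSet, dose, t_end: float, dt: float = 1e-3
) -> np.ndarray:
    """Independent fixed-step classical Runge-Kutta integrator.

    Serves as the cross-check oracle for the adaptive stiff solver.
    *y0* may be ``(10,)`` or ``(10, n)`` (vectorised over instances, with
    *dose* scalar or length-n).
    """
    y = np.array(y0, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    dose = np.asarray(dose, dtype=float)
    n_steps = int(round(t_end / dt))
    h = t_end / n_steps if n_steps else 0.0
    for _ in range(n_steps):
        k1 = np.stack(rhs_array(y, params, dose))
        k2 = np.stack(rhs_array(y + 0.5 * h * k1, params, dose))
        k3 = np.stack(rhs_array(y + 0.5 * h * k2, params, dose))
        k4 = np.stack(rhs_array(y + h * k3, params, dose))
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y[:, 0] if squeeze else y


def steady_state(
    state0: ModelState,
    params: ParameterSet,
    dose: float,
    rhs_tol: float = 1e-10,
    t_max: float = 10_000.0,
) -> tuple[ModelState, bool]:
    """Integrate at constant dose until the flow stalls.

    Convergence: max-norm of the right-hand side below *rhs_tol* (AU/min).
    Non-convergence by *t_max* is reported through the flag, never raised.
    """
    from scipy.optimize import root

    def polish(y: np.ndarray) -> np.ndarray | None:
        """Newton-land on the fixed point once the flow is nearly flat;
        LSODA crawls near equilibria at these tolerances."""
        sol = root(lambda z: rhs_array(z, params, dose), y, method="hybr", tol=1e-13)
        if not sol.success:
            return None
        if np.max(np.abs(rhs_array(sol.x, params, dose))) >= rhs_tol:
            return None
        scale = np.maximum(np.abs(y), 1e-3)
        if np.max(np.abs(sol.x - y) / scale) > 0.05:
            return None   # jumped somewhere else; keep integrating
        return sol.x

    y = state0.as_array()
    t = 0.0
    chunk = 250.0
    while t < t_max:
        step = min(chunk, t_max - t)
        try:
            ys = _odeint_segment(y, params, dose, np.array([0.0, step]))
        except IntegrationError:
            if chunk <= 2.0:
                raise
            chunk /= 4.0
            continue
        y = clamp_state(ys[-1], params)
        t += step
        resid = np.max(np.abs(rhs_array(y, params, dose)))
        if resid < rhs_tol:
            return ModelState.from_array(y), True
        if resid < 1e-6:
            polished = polish(y)
            if polished is not None:
                return ModelState.from_array(np.maximum(polished, 0.0)), True
        chunk = min(chunk * 2.0, 2_000.0)
    converged = bool(np.max(np.abs(rhs_array(y, params, dose))) < rhs_tol)
    return ModelState.from_array(y), converged


def classify(
    state: ModelState, params: ParameterSet, cfg: ClassificationConfig | None = None
) -> str:
    """Score a state as ``'mitotic'`` or ``'interphase'``.

    Mitotic iff ``Subp/SubTot >= threshold`` (boundary inclusive).
    """
    cfg = cfg or ClassificationConfig()
    frac = state.Subp / params.SubTot
    return "mitotic" if frac >= cfg.mitotic_threshold else "interphase"


def _protocol_params(
    params: ParameterSet, condition: Condition | str, cycb_tot: float | None
) -> ParameterSet:
    p = apply_condition(params, condition)
    if cycb_tot is not None:
        if cycb_tot < 0:
            raise ValueError("cycb_tot must be non-negative")
        p = p.with_(CycBTot=float(cycb_tot))
    return p


def run_entry_protocol(
    params: ParameterSet,
    condition: Condition | str = Condition.CONTROL,
    dose: float = 0.0,
    cycb_tot: float | None = None,
    cfg: ClassificationConfig | None = None,
) -> str:
    """Mitotic-entry assay: release into a constant dose, classify at endpoint."""
    cfg = cfg or ClassificationConfig()
    p = _protocol_params(params, condition, cycb_tot)
    traj = integrate(
        interphase_state(p), p, InhibitorSchedule.constant(dose),
        cfg.endpoint_time, t_eval=np.array([0.0, cfg.endpoint_time]),
    )
    return classify(traj.state_at_end(), p, cfg)


def run_exit_protocol(
    params: ParameterSet,
    condition: Condition | str = Condition.CONTROL,
    dose: float = 0.0,
    cycb_tot: float | None = None,
    cfg: ClassificationConfig | None = None,
    release_time: float = 90.0,
) -> str:
    """Mitotic-exit assay: 90 min inhibitor-free, then the dose; classify
    one endpoint interval after dose addition."""
    cfg = cfg or ClassificationConfig()
    p = _protocol_params(params, condition, cycb_tot)
    t_end = release_time + cfg.endpoint_time
    traj = integrate(
        interphase_state(p), p, InhibitorSchedule.step(release_time, 0.0, dose),
        t_end, t_eval=np.array([0.0, t_end]),
    )
    return classify(traj.state_at_end(), p, cfg)


def run_prophase_protocol(
    params: ParameterSet,
    dose: float,
    readd_time: float = 25.0,
    cycb_tot: float | None = None,
    cfg: ClassificationConfig | None = None,
    condition: Condition | str = Condition.CONTROL,
) -> str:
    """Partial-inhibition capture assay.

    Inhibitor-free release from the G2 arrest, dose re-added at
    *readd_time*, then integration to steady state.  The endpoint is
    labelled by the nearest stable attractor at that dose (in state space
    normalised by the pool totals): lowest-Subp attractor →
    ``'back_to_interphase'``, highest → ``'mitotic'``, any middle branch →
    ``'intermediate'``.  With only two attractors the intermediate label
    is unreachable.
    """
    from .bifurcation import find_fixed_points  # deferred: avoids cycle

    if readd_time <= 0:
        raise ValueError("readd_time must be positive")
    cfg = cfg or ClassificationConfig()
    p = _protocol_params(params, condition, cycb_tot)
    traj = integrate(
        interphase_state(p), p, InhibitorSchedule.constant(0.0),
        readd_time, t_eval=np.array([0.0, readd_time]),
    )
    final, _ = steady_state(traj.state_at_end(), p, dose)

    attractors = [s for s, stable in find_fixed_points(p, dose) if stable]
    attractors.sort(key=lambda s: s.Subp)
    scale = np.array([
        p.SubTot, p.CycBTot, p.PP1Tot, p.ENSATot, max(p.GwlTot, 1.0),
        p.B55Tot, 1.0, 1.0, 1.0, 1.0,
    ])
    yf = final.as_array() / scale
    dists = [np.max(np.abs(yf - a.as_array() / scale)) for a in attractors]
    idx = int(np.argmin(dists))
    if len(attractors) == 1:
        return "mitotic" if classify(attractors[0], p, cfg) == "mitotic" else "back_to_interphase"
    if idx == 0:
        return "back_to_interphase"
    if idx == len(attractors) - 1:
        return "mitotic"
    return "intermediate"


def refine_interphase_state(
    params: ParameterSet, arrest_dose: float = 2.0
) -> ModelState:
    """Relax the printed interphase initial conditions to the exact fixed
    point at the arrest dose (optional utility; protocols use the printed
    table directly)."""
    state, _ = steady_state(interphase_state(params), params, arrest_dose)
    return state
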