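"""Steady-state structure of the switch: fixed points, stability,
signal-response branches and saddle-node (fold) thresholds.

The approach is deliberately brute-force rather than AUTO-style
pseudo-arclength continuation: the system is 10-dimensional but cheap to
evaluate, and only the stable-branch structure and fold locations are
needed.  Fixed points come from multi-start damped-Newton root finding
(a Latin-hypercube of the invariant box plus three structured seeds:
interphase-like, mitotic-like, and a partial-switch configuration with
the Cdk1 loop on but the phosphatase loop still active — the region
where the intermediate "prophase" branch lives).  Stability is read from
the eigenvalues of a central-finite-difference Jacobian.  Unstable
branches are reported only where the multi-start search finds them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root
from scipy.stats import qmc

from .model import ModelState, interphase_state, jacobian_fd, rhs_array
from .params import Condition, ParameterSet, apply_condition

__all__ = [
    "SignalResponseBranch",
    "FoldPoints",
    "find_fixed_points",
    "sweep_signal_response",
    "fold_points",
    "count_stable_states_over_grid",
]

#: a fixed point must satisfy max-norm rhs below this (AU/min)
ROOT_TOL = 1e-9
#: eigenvalue real parts must be below -STAB_TOL for "stable"
STAB_TOL = 1e-9
#: de-duplication tolerance in pool-normalised state space
DEDUP_TOL = 1e-6
#: tolerance for membership of the invariant box
BOX_TOL = 1e-6


@dataclass(frozen=True)
class SignalResponseBranch:
    """One traced branch of steady states along a swept parameter."""

    parameter: str                    # "dose" or "CycBTot"
    values: np.ndarray
    states: np.ndarray                # (n, 10)
    stable: np.ndarray                # bool per point
    branch_id: str = ""

    def subp(self) -> np.ndarray:
        return self.states[:, 0]


@dataclass(frozen=True)
class FoldPoints:
    """Entry/exit saddle-node doses (μM); ``None`` where the branch never
    disappears inside the scanned range (monostable conditions)."""

    entry: float | None
    exit: float | None


def _scale(params: ParameterSet) -> np.ndarray:
    return np.array([
        params.SubTot, params.CycBTot, params.PP1Tot, params.ENSATot,
        max(params.GwlTot, 1e-12), params.B55Tot, 1.0, 1.0, 1.0, 1.0,
    ])


def _norm_scale(params: ParameterSet) -> np.ndarray:
    """De-duplication scale: unit for pools whose total is zero."""
    s = _scale(params)
    return np.where(s > 1e-8, s, 1.0)


def _in_box(y: np.ndarray, params: ParameterSet) -> bool:
    s = _scale(params)
    z = y / np.where(s > 1e-12, s, 1.0)
    if np.any(z < -BOX_TOL) or np.any(z > 1 + BOX_TOL):
        return False
    if y[6] + y[7] > 1 + BOX_TOL or y[8] + y[9] > 1 + BOX_TOL:
        return False
    cplx = params.B55Tot - y[5]
    return -BOX_TOL <= cplx <= y[3] + BOX_TOL


def _structured_seeds(params: ParameterSet) -> list[np.ndarray]:
    p = params
    interphase = interphase_state(p).as_array()
    mitotic = np.array([
        0.95 * p.SubTot, 0.99 * p.CycBTot, 0.02 * p.PP1Tot, 0.9 * p.ENSATot,
        0.02 * p.GwlTot, 0.002 * p.B55Tot, 0.0, 0.95, 0.0, 0.95,
    ])
    # Cdk1 loop flipped, phosphatase loop still active
    partial = np.array([
        0.4 * p.SubTot, 0.9 * p.CycBTot, 0.5 * p.PP1Tot, 0.1 * p.ENSATot,
        0.004 * p.GwlTot, 0.7 * p.B55Tot, 0.01, 0.95, 0.01, 0.95,
    ])
    return [interphase, mitotic, partial]


def _is_stable(y: np.ndarray, params: ParameterSet, dose: float) -> bool:
    eig = np.linalg.eigvals(jacobian_fd(y, params, dose))
    return bool(np.all(eig.real < -STAB_TOL))


def find_fixed_points(
    params: ParameterSet,
    dose: float,
    n_starts: int = 32,
    seed: int = 0,
    extra_seeds: list[np.ndarray] | None = None,
) -> list[tuple[ModelState, bool]]:
    """All distinct fixed points found at *dose*, with stability flags.

    Multi-start Newton (``scipy.optimize.root``, hybrid Powell) from a
    Latin-hypercube of the invariant box plus structured seeds.  Roots
    outside the invariant box (beyond 1e-6 normalised) are discarded;
    duplicates are merged at max-norm 1e-6 in pool-normalised space.
    Raises if nothing is found — the system always has at least one
    fixed point, so an empty result means the search failed.
    """
    if n_starts < 8:
        raise ValueError("n_starts must be at least 8")
    p = params
    scale = _scale(p)
    nscale = _norm_scale(p)
    sampler = qmc.LatinHypercube(d=10, seed=seed)
    lhs = sampler.random(n_starts) * scale
    # respect the two-site conservation constraints in the samples
    lhs[:, 7] *= 1.0 - lhs[:, 6]
    lhs[:, 9] *= 1.0 - lhs[:, 8]
    # keep the complex inside [0, pENSATot]
    lhs[:, 5] = np.maximum(lhs[:, 5], p.B55Tot - lhs[:, 3])

    starts = _structured_seeds(p) + list(extra_seeds or []) + list(lhs)
    roots: list[tuple[np.ndarray, bool]] = []
    for s in starts:
        sol = root(lambda y: rhs_array(y, p, dose), s, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        y = sol.x
        if np.max(np.abs(rhs_array(y, p, dose))) > ROOT_TOL:
            continue
        if not _in_box(y, p):
            continue
        if any(np.max(np.abs((y - r) / nscale)) < DEDUP_TOL for r, _ in roots):
            continue
        roots.append((y, _is_stable(y, p, dose)))
    if not roots:
        raise RuntimeError(f"no fixed points found at dose {dose}; search failed")
    roots.sort(key=lambda r: r[0][0])
    return [(ModelState.from_array(np.maximum(y, 0.0)), st) for y, st in roots]


def sweep_signal_response(
    params: ParameterSet,
    condition: Condition | str,
    dose_grid,
    direction: str = "up",
) -> SignalResponseBranch:
    """Quasi-static continuation of a stable branch along the dose axis.

    ``direction='up'`` starts from the mitotic steady state at the lowest
    grid dose; ``'down'`` starts from the interphase state at the highest.
    At each grid dose the steady state is re-relaxed from the previous
    endpoint, so the trace jumps branches exactly where the occupied
    branch folds — the up/down pair reconstructs the hysteresis loop.
    """
    from .simulate import steady_state

    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    dose_grid = np.asarray(dose_grid, dtype=float)
    p = apply_condition(params, condition)
    if dose_grid.size == 0:
        return SignalResponseBranch(
            "dose", dose_grid, np.empty((0, 10)), np.empty(0, dtype=bool),
            branch_id=direction,
        )
    if np.any(np.diff(dose_grid) <= 0):
        raise ValueError("dose_grid must be sorted strictly increasing")

    order = dose_grid if direction == "up" else dose_grid[::-1]
    if direction == "up":
        state, _ = steady_state(interphase_state(p), p, order[0])
    else:
        state = interphase_state(p)
    states, stable = [], []
    for d in order:
        state, _ = steady_state(state, p, float(d))
        y = state.as_array()
        states.append(y)
        stable.append(_is_stable(y, p, float(d)))
    states = np.array(states)
    stab = np.array(stable)
    if direction == "down":
        states, stab = states[::-1], stab[::-1]
    return SignalResponseBranch("dose", dose_grid, states, stab, branch_id=direction)


def _newton_from(y_seed: np.ndarray, params: ParameterSet, dose: float):
    sol = root(lambda y: rhs_array(y, params, dose), y_seed, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(rhs_array(sol.x, params, dose))) > ROOT_TOL:
        return None
    if not _in_box(sol.x, params):
        return None
    return sol.x


def _follow_branch(
    y0: np.ndarray,
    params: ParameterSet,
    d0: float,
    d_target: float,
    refine_tol: float,
    step0: float = 0.05,
) -> float | None:
    """March a stable branch from *d0* toward *d_target*; return the fold
    dose (where the branch disappears) refined to *refine_tol*, or None
    if the branch survives all the way to *d_target*."""
    nscale = _norm_scale(params)

    def exists_from(seed: np.ndarray, d: float):
        y = _newton_from(seed, params, d)
        if y is None:
            return None
        if np.max(np.abs((y - seed) / nscale)) > 0.25:   # jumped to another branch
            return None
        if not _is_stable(y, params, d):
            return None
        return y

    sign = 1.0 if d_target > d0 else -1.0
    d, y = d0, y0
    step = step0
    while sign * (d_target - d) > 0:
        d_next = d + sign * min(step, abs(d_target - d))
        y_next = exists_from(y, d_next)
        if y_next is not None:
            d, y = d_next, y_next
            continue
        if step <= refine_tol:
            # bracket [d, d_next] is tight: fold at its midpoint
            return 0.5 * (d + d_next)
        step /= 2.0
    return None


def fold_points(
    params: ParameterSet,
    condition: Condition | str = Condition.CONTROL,
    dose_range: tuple[float, float] = (0.0, 2.0),
    refine_tol: float = 1e-4,
) -> FoldPoints:
    """Locate the saddle-node doses bounding the hysteresis loop.

    * ``entry``: dose below which the interphase-like branch no longer
      exists (continuation of the high-dose arrested state down-dose).
      Entry into mitosis is blocked above this threshold.
    * ``exit``: dose above which the mitotic branch no longer exists
      (continuation of the inhibitor-free mitotic state up-dose).  Exit
      is forced above it.

    A branch that never disappears inside *dose_range* yields ``None``
    (absent fold), as for the monostable double perturbation.
    """
    from .simulate import steady_state

    if refine_tol <= 0:
        raise ValueError("refine_tol must be positive")
    lo, hi = dose_range
    p = apply_condition(params, condition)

    inter, _ = steady_state(interphase_state(p), p, hi)
    entry = _follow_branch(inter.as_array(), p, hi, lo, refine_tol)

    mitotic, _ = steady_state(interphase_state(p), p, lo)
    exit_ = _follow_branch(mitotic.as_array(), p, lo, hi, refine_tol)
    return FoldPoints(entry=entry, exit=exit_)


def count_stable_states_over_grid(
    params: ParameterSet,
    condition: Condition | str,
    dose_grid,
    n_starts: int = 32,
    seed: int = 0,
) -> dict[float, int]:
    """Number of coexisting stable steady states at each grid dose.

    Fixed points found at one dose are recycled as warm-start seeds at
    the next, so narrow branches are followed once discovered.
    """
    p = apply_condition(params, condition)
    counts: dict[float, int] = {}
    carry: list[np.ndarray] = []
    for d in np.asarray(dose_grid, dtype=float):
        fps = find_fixed_points(p, float(d), n_starts=n_starts, seed=seed,
                                extra_seeds=carry)
        counts[float(d)] = sum(1 for _, s in fps if s)
        carry = [s.as_array() for s, _ in fps]
    return counts
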