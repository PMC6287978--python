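# Methods

## The model

Ten ordinary differential equations describe the mutual antagonism
between the mitotic kinase Cdk1:CycB and its counteracting phosphatase
PP2A:B55 in a somatic mammalian cell held at constant protein levels
(the experimental assay uses proteasome inhibition, so no synthesis or
degradation terms appear). All kinetics are mass action; enzyme–substrate
complexes are eliminated except the stoichiometric pENSA·PP2A:B55
complex, which is the phosphatase-sequestration mechanism itself.

State vector (fixed order, used for serialisation and trajectories):
`(Subp, CycBCdk1, PP1, pENSATot, Gwlp, PP2AB55, Wee1, Wee1pp, Cdc25,
Cdc25pp)`. Three pools are eliminated algebraically:
`[pENSA:B55] = B55Tot − PP2AB55`, `Wee1p = 1 − Wee1 − Wee1pp`,
`Cdc25p = 1 − Cdc25 − Cdc25pp`. Two conventions are easy to get wrong
and are therefore locked in by unit tests:

* `Wee1` is the *unphosphorylated, fast (active)* kinase form — the
  interphase state has `Wee1 = 1` and `VWee1 = kWee1F = 47.2937/min`;
* `Cdc25pp` is the doubly phosphorylated *active* phosphatase form —
  interphase has `Cdc25pp = 0` and only the basal `kCdc25S = 0.005/min`.

Wee1 and Cdc25 each carry two regulatory phosphosites with identical
per-site rate constants. The ATP-analog inhibitor binds Cdk1 in rapid
equilibrium, dividing every Cdk1:CycB-driven term by `1 + dose/Kd`; the
division is applied inside each term (substrate, PP1, Gwl, Wee1, Cdc25
phosphorylation), not to the CycB:Cdk1 balance itself, because Wee1 and
Cdc25 act on the complex regardless of whether its active site is
occupied by the analog.

### Parameters and units

Two named parameter sets ship with the package and differ only in
rounding: the canonical high-precision set (the executable source of the
published analysis; e.g. `kass = 617.2807`, `kiPP1 = 0.0018`) and the
rounded prose-table set (`kass = 617`, `kiPP1 = 0.002`). Concentrations
are in arbitrary units with most totals normalised to 1, `B55Tot =
0.25` and `CycBTot = 8.1808` for the median cell; time in minutes; dose
and `Kd` in μM. `Kd` is a dissociation constant and therefore carries a
concentration unit — the published table's `min^-1` entry for it is a
typographic slip (the expression `1 + dose/Kd` is dimensionless).
`Wee1Tot = Cdc25Tot = 1` are literals of the equations, not parameters.

The interphase initial condition is the published arrested-G2 state
(`PP1 = 1`, `PP2AB55 = 0.25`, `Wee1 = 1`, everything else at its
interphase pole). The 20-h arrest itself is not simulated; a utility
(`refine_interphase_state`) can relax the printed state onto the exact
fixed point at the arrest dose, which moves nothing by more than ~1e-3.

## Numerics

* **Integration.** LSODA (stiff-capable; the pENSA·B55 binding at
  `kass ≈ 617` gives relaxation rates of ~150/min against protocol
  horizons of hours) at `rtol 1e-8`, `atol 1e-10`, restarted exactly at
  every dose breakpoint so discontinuities are never interpolated
  across. Components in `(−1e-9, 0)` after a step are clamped to zero
  (solver drift around an exact positivity invariant); anything more
  negative raises. An independent fixed-step classical RK4 integrator
  (`dt = 0.001` min, stability limit ≈ 0.018 min) is kept in the package
  purely as a cross-check oracle; the test suite demands max-norm
  agreement of 1e-5 over 240 min on random states and doses.
* **Steady states.** Chunked integration (250 → 2000 min chunks, cap
  10 000 min) until the right-hand side max-norm falls below 1e-10
  AU/min. Near equilibria LSODA crawls at these tolerances, so once the
  flow is below 1e-6 a Newton polish lands on the fixed point and is
  accepted only if it stays within 5 % (relative) of the integrated
  state; a solver failure inside a chunk retries with a quarter-length
  chunk. Oscillatory non-convergence is reported through a flag, never
  an exception.
* **Fixed points and stability.** Multi-start damped Newton
  (`scipy.optimize.root`, hybrid Powell) from a seeded Latin hypercube
  of the invariant box plus three structured seeds: interphase-like,
  mitotic-like, and a partial-switch configuration (Cdk1 loop on,
  phosphatase loop active) targeting the narrow intermediate branch.
  Roots are kept if the residual max-norm is below 1e-9 and the root
  lies inside the invariant box (1e-6 normalised tolerance); duplicates
  merge at max-norm 1e-6 in pool-normalised coordinates. Stability is
  read from eigenvalues of a central finite-difference Jacobian
  (relative step 1e-7, floored at 1e-10 absolute), validated against a
  complex-step Jacobian in the tests; "stable" means every real part
  below −1e-9. Unstable branches are reported only where the search
  finds them — completeness is guaranteed only for stable branches,
  which is what the census and fold logic consume.
* **Folds.** Brute-force continuation instead of pseudo-arclength: a
  stable branch is marched along the dose axis with adaptive steps
  (start 0.05 μM), re-Newtoning from the previous root; the branch is
  declared gone when Newton fails, leaves the box, loses stability or
  jumps by more than 0.25 (normalised) — and the disappearance dose is
  bisected to `refine_tol` (default 1e-4 μM). The entry fold is where
  the interphase branch vanishes going down-dose; the exit fold where
  the mitotic branch vanishes going up-dose. A branch that survives the
  whole scanned range yields an *absent* fold (monostable double
  perturbation), reported as `None`, never zero.
* **Classification.** Mitotic iff `Subp/SubTot ≥ 0.30`, boundary
  inclusive (arbitrary but fixed). Entry/exit protocols classify the
  state at the fixed assay endpoint (240 min after dose addition),
  matching the fixed-cell readout; the prophase protocol classifies by
  converged attractor identity (nearest stable fixed point in
  pool-normalised coordinates, labelled by its Subp rank) because its
  claim is about steady states.
* **IC50.** First 50 % crossing from low dose by piecewise-linear
  interpolation on the dose grid; a curve that never crosses raises an
  explicit error rather than returning NaN. Default dose grid: zero
  plus 25 log-spaced points in [0.01, 2] μM, which resolves both the
  tens-of-nM (Gwl-depleted) and hundreds-of-nM (exit) regimes.

## Population layer

Cell-to-cell variability enters through `CycBTot` only, as a log-normal
with median 8.18 AU and *arithmetic* standard deviation 4.31 AU on the
natural scale (log-scale sigma ≈ 0.4518 by exact moment inversion; the
SD is read on the natural scale because cyclin abundance distributions
are reported that way). The default evaluation is deterministic
mid-point quantile quadrature (64 equal-probability strata), which makes
every curve and IC50 a reproducible float; a seeded sampling mode exists
for noise studies. Because the endpoint outcome of the entry and exit
protocols is monotone in `CycBTot` (more cyclin never demotes a cell
from mitosis at fixed dose), per-dose fractions over the sorted quantile
grid are located by bisection, and whole ascending-dose curves by a
staircase walk over the (dose × cell) grid — both produce outputs
identical to exhaustive per-cell evaluation (asserted in tests) at a
fraction of the simulations. The non-monotone prophase protocol always
evaluates every cell.

## Synthetic data and fitting

The generator emulates the endpoint assay's statistical structure: per
(condition, protocol, dose, repeat), draw `n_cells = 100` cyclin values
from the population, run the per-cell protocol, count mitotic cells.
Counts are therefore exactly binomial around the infinite-N fraction
(verified by a chi-square goodness-of-fit against the analytic
log-normal tail probability). No dose error and no repeat-level random
effects are modelled — in this model all between-cell variability is
cyclin B. Seeds derive from a documented counter scheme
(`SeedSequence([master, condition, protocol, dose, repeat])`), so any
subset regenerates bit-identically in isolation. What passing recovery
tests on these data do *not* show: robustness to the noise sources the
generator omits (dose pipetting error, scoring error, day effects,
per-cell variability in anything but cyclin B).

The two-stage fit mirrors how the model was parameterised. Stage 1 uses
only the 50 % crossings: with a homogeneous population the simulated
IC50 equals the median cell's threshold dose (computed by bisection to
2e-4 μM), and the median minimises the squared distance to the
empirical crossings; datasets without a crossing are excluded with a
warning. Stage 2 fixes the median and fits the SD to the full curves by
least squares on fractions (counts are not Poisson/binomial-weighted;
a likelihood-based loss would be a straightforward extension but the
canonical procedure is least squares). The stage-2 loss is piecewise
constant in the SD — fractions are quantised to `1/n_quantiles` — so a
13-point grid scan brackets the optimum before golden-section
refinement; plain Brent stalls on the plateaus. Identifiability is
resolution-limited: near the entry fold the threshold dose moves by only
~0.015 μM per AU of cyclin, so distinguishing SD below ~0.5 AU requires
doses packed around the fold (the near-degenerate recovery test uses a
0.002-μM spacing there).

Rate-constant fitting (differential evolution with a seeded budget, then
Nelder–Mead polish, at most six free constants) ships as an opt-in
utility: the canonical pipeline fits only the cyclin distribution. A
caution from the model's own structure: the generic substrate is a
passive reporter wherever a saddle-node sets the threshold, so its rate
constants (`kCdk1Sub`, `kB55Sub`) are identifiable from endpoint
fractions only in the double-perturbation condition, where the threshold
is a pure kinase/phosphatase balance.

## Steady-state geography (what the analysis finds)

At the canonical parameters the control cell has entry/exit folds at
≈0.118 and ≈0.587 μM. A third, intermediate stable state — Cdk1 switch
on, phosphatase switch still active, `Subp ≈ 0.46` — exists in a narrow
island: at the median cyclin level it spans doses ≈0.115–0.17 μM, and
the window scales with cyclin (≈22–26 AU at 0.5 μM, i.e. the top ~1 %
of the population). Capture on this branch by inhibitor re-addition
requires hitting the interval after the Cdk1 loop flips but before the
phosphatase loop does: for a 24-AU cell at 0.5 μM that is re-addition
≈7.6–8.4 min after release. Re-addition at 25 min captures nothing at
any dose, because every cell whose cyclin supports the intermediate
branch has already flipped both switches by then; the corresponding
acceptance check is left failing with this analysis rather than tuned
around. The same applies to the double-perturbation midpoints: with
both loops cut, PP2A:B55 is pinned at `B55Tot` and the 30 % threshold
sits analytically at `Kd·(CycBTot·kCdk1Sub·(7/3)/(kB55Sub·B55Tot) − 1)`
≈ 232 nM, a number the printed parameter set cannot move to the
experimentally measured 147/150 nM; the hysteresis-collapse claim
(entry ≈ exit) does hold, at ≈230 vs 240 nM.

## Problem sizes

Defaults used throughout the package's own analyses: 64 quantile nodes,
26-dose grids (refined below 200 nM where the low thresholds live),
21–47-dose census grids, 32 Newton starts per census dose, fit
resolution 32 nodes. These were chosen as the coarsest settings whose
halving-refinement checks (quantile doubling, fold-tolerance halving,
grid refinement) move no reported quantity by more than ~2 %.

## Known limitations

* Heterogeneity only in total cyclin B; no stochastic single-cell
  kinetics (Langevin/Gillespie) and no inhibitor photo-instability.
* No cyclin synthesis/degradation — valid only for the
  proteasome-inhibited assay window.
* Unstable-branch inventories are best-effort (multi-start), not
  exhaustive; no Hopf/oscillation analysis and no two-parameter
  bifurcation surfaces.
* No uncertainty quantification on fits (no profile likelihood or
  bootstrap); the recovery tests bound bias under the generator's own
  assumptions only.
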