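# Methods

## Model

The bivalent-analyte scheme treats the analyte (an IgG-class molecule
with two equivalent binding arms) as binding immobilised ligand in two
sequential steps: A + L ⇌ AL1 (ka1, kd1), then AL1 + L ⇌ AL2
(ka2, kd2). The second step can only happen after the first, and AL2
can only dissociate back through AL1. Ligand-side species (L, AL1,
AL2) are carried in response units; the analyte concentration [A] is
molar and assumed constant during an injection (continuous flow).
With this bookkeeping ka1 has units M⁻¹s⁻¹ and ka2 RU⁻¹s⁻¹, and the
association ODEs close dimensionally. Statistical factors of two enter
where either of the two arms can act.

Both phase models conserve the ligand-site total L + AL1 + 2·AL2. The
measured response is AL1 + AL2: each bound analyte contributes its
mass once regardless of whether it is held by one arm or two.

**Association phase.** Nonlinear 3-state system (see README for the
equations). The implementation integrates the conservation-reduced
2-state system (AL1, AL2) and recovers L algebraically, so the
conservation invariant holds to machine precision by construction; a
full 3-state `solve_ivp` (LSODA) route is retained as an independent
cross-check and is the one used when `method="scipy"` is requested.

**Dissociation phase.** Rebinding is neglected (ka1 = ka2 = 0),
leaving a linear constant-coefficient system solved in closed form:
AL2(t) = AL2₀·e^(−2·kd2·t) and
AL1(t) = AL1₀·e^(−kd1·t) + 2·kd2·AL2₀·(e^(−2·kd2·t) − e^(−kd1·t))/(kd1 − 2·kd2),
with the confluent limit branch (t·e^(−kd1·t)) taken when
|kd1 − 2·kd2| < 1e−12 s⁻¹. Tests verify the closed form against
independent numeric integration to ≤1e−6 relative over 1800 s for
rates spanning 1e−6–1e−1 s⁻¹.

**Non-regenerative titration.** Analyte left bound from earlier
cycles makes the initial amounts of AL1/AL2 unknown. Each cycle is
therefore integrated from an adjusted start t₀ = t₀* − t* with a bare
surface (L = Rmaxⱼ, no complexes), where t*ⱼ ≥ 0 is fitted per cycle;
only [t₀*, t₀* + t_assoc] is observed. Cycles are simulated on their
own clocks (association starts at 0); baseline segments are not
modelled. In regenerative mode t* is fixed at 0 and dropped from the
parameter vector. How residual analyte actually partitions between AL1
and AL2 at a cycle start is not modelled beyond this back-extrapolation
device; it is taken as the model, not approximated further.

## Integration

Default path: an adaptive Dormand–Prince RK45 (numba-compiled) on the
reduced association system, relative tolerance 1e−8, absolute 1e−10
(both configurable), output samples landed on exactly (no dense-output
interpolation), plus the exact dissociation solution. A step budget of
4000 steps per cycle bounds worst-case cost: physically plausible
parameter regions need at most ~1000 adaptive steps (measured across
the whole default grid-start space, including large t*), while
degenerate compensation regimes (Rmax inflated by orders of magnitude
together with a fast cross-arm rate) are stiff for an explicit method
and would otherwise cost minutes inside the optimiser. Exceeding the
budget signals numerical failure; inside a fit this surfaces as a
large constant residual vector that steers the optimiser back out.

## Estimation

Unweighted least squares over all fitted concentrations jointly
(global fit): SSE(p) = Σⱼ Σᵢ (RÛ(p, tᵢ, [A]ⱼ) − RUᵒᵢⱼ)², evaluated at
the observed timepoints only. Observed cycle times are normalised
shift-invariantly (association offsets relative to the first
association timestamp, dissociation offsets relative to the last).

The minimiser is `scipy.optimize.least_squares` (method `trf`, a
damped trust-region least-squares of the Levenberg–Marquardt family)
with every parameter bounded below by zero and MINPACK-style adaptive
column scaling (`x_scale="jac"`). On interior solutions this agrees
with plain LM. Finite-difference Jacobian steps are 1e−5 relative —
large enough to stay above the ODE-solver error floor (~rtol × signal),
small enough for truncation not to matter at these curvatures.
Convergence: relative SSE change below 1e−10 or projected gradient
below 1e−10, at most 1000 objective evaluations.

Because the SSE surface is multimodal, fitting starts from a Cartesian
grid over the four rate constants — by default three decade-spaced
values per axis (ka1 ∈ {1e2, 1e3, 1e4} M⁻¹s⁻¹, kd1 ∈ {1e−4, 1e−3,
1e−2} s⁻¹, ka2 ∈ {1e−5, 1e−4, 1e−3} RU⁻¹s⁻¹, kd2 ∈ {1e−5, 1e−4,
1e−3} s⁻¹), 3⁴ = 81 starts — with shared local-parameter starting
values: Rmaxⱼ = 2 × the cycle's maximum observed response (surface
assumed at most half-saturated) and t*ⱼ = 60 s (0 when regenerative).
Exploratory per-start fits are capped at 150 objective evaluations and
the winning start is re-polished under the full budget; starts ending
within 1e−4 relative SSE of the best are labelled "global", the rest
"local". A bracketing 2⁴ = 16-start subset (`QUICK_GRID`, the outer
two decade values per axis) is provided for replicated scans and is
what the replication studies below use. Per-start fits are independent
and deterministic, so results do not depend on execution order or
worker count.

Standard errors come from the Jacobian-based covariance approximation
s²(JᵀJ)⁻¹ with s² = SSE/(N − #p). With strongly correlated parameters
this local-curvature measure can be optimistic relative to
replicate-to-replicate spread — one more reason the identifiability
analysis, not the standard errors, carries the reliability verdict.
The residual SD √(SSE/(N − #p)) doubles as the measurement-error
estimate when σ is not configured.

## Identifiability

With i.i.d. Gaussian error of known SD σ the negative log-likelihood
is NLL(p) = N/2·ln(2π) + SSE(p)/(2σ²) (constant kept for
reproducibility; the minimiser is independent of σ and of the
constant). The profile likelihood of parameter pⱼ clamps pⱼ = c on a
log-spaced grid — by default 21 points spanning 3 decades below to 2
above the unconstrained estimate; an estimate at the zero bound
carries no scale, so the grid is instead anchored with its lower edge
at a floor (default 1e−8 in the parameter's units) spanning the same
total width — and re-fits all remaining parameters at each point,
warm-starting from the neighbouring point's constrained optimum and
sweeping outward from the point nearest the estimate. Constrained
re-fits reuse the estimation machinery with one coordinate fixed,
under looser controls (ftol 1e−8, ≤300 evaluations): the profile only
needs NLL resolved well below the χ² threshold step. A failed
constrained fit flags its point and the sweep continues.

The confidence threshold is min NLL + χ²(α, df)/2 with α = 0.95 and
df = #p by default (the joint threshold; df = 1 gives per-parameter
intervals). Classification replaces visual judgment with a rule: a
parameter is practically identifiable iff its profile rises above the
threshold on **both** sides of its minimum; a side that never crosses
before the grid boundary is flat (the L-shape), and the verdict
records which side. A profile lying entirely above the threshold means
the optimum was not bracketed and raises an error rather than a
verdict. During replicated design scans the outward sweep may stop
once a side has risen a full χ² step above the threshold — the verdict
is provably unchanged, only the reported curve is truncated; full
curves remain the default elsewhere.

σ for the likelihood is taken from the configuration when numeric,
otherwise from the best fit's residual SD.

## Synthetic data and design evaluation

The generator emulates the simulation-study conditions: five doubling
analyte concentrations 6.25e−8…1e−6 M, 300 s association, 2 s sampling
(~0.5 Hz), dissociation 600 s (standard) or 1780 s (extended),
generating parameters ka1 = 2.00e3 M⁻¹s⁻¹, kd1 = 4.00e−3 s⁻¹,
ka2 = 5.00e−5 RU⁻¹s⁻¹, kd2 = 1.00e−5 s⁻¹, Rmaxⱼ = 600 RU and
t*ⱼ = (283, 300, 282, 222, 145) s, with i.i.d. Gaussian noise of SD
σ = 6 RU added to association and dissociation observations
(baseline is not modelled). Replicates are reproducible from
(seed, replicate index) via independent `SeedSequence` spawns. The
generator does not emulate drift, mass-transport limitation, surface
heterogeneity, or correlated instrument noise — passing tests
demonstrate estimator correctness under the stated noise model, not
robustness to those real-data artefacts.

`evaluate_design` runs the full loop per replicate — generate, grid
fit, profile all four rate constants, classify — aggregates verdicts
by majority, and summarises dispersion by the coefficient of variation
(sample SD with n−1 denominator divided by the mean). Estimates at the
zero lower bound (≤1e−12 in the parameter's units) are excluded from
CV summaries and counted, mirroring the exclusion of collapsed kd2
estimates from log-scale summaries; a parameter with fewer than two
usable values reports an undefined (NaN) CV. Replicate-level failures
are recorded in the report, never abort the sweep.

Replicated checks in the test suite use 10 seeded replicates per
design, the 16-start quick grid and 11-point profile grids; at those
sizes the full two-design study runs in a few minutes on one CPU.
Expected outcomes: standard design — kd2 practically non-identifiable
(flat left branch), frequent kd2 collapse to the bound; extended
design — all four rate constants identifiable, kd1/kd2 CVs strictly
smaller than under the standard design. The kd2 = 1e−5 s⁻¹ versus
kd2 = 0 model curves differ by less than the noise SD within 600 s of
dissociation and separate clearly by 1780 s, which is the mechanism
behind the contrast.

## Known limitations

- Mass-transport limitation, heterogeneous-ligand and
  conformational-change models are out of scope, as is any baseline or
  buffer-cycle modelling and vendor-format parsing.
- The dissociation model forbids rebinding; at high surface densities
  this is an idealisation.
- Local-curvature standard errors understate uncertainty for
  near-non-identifiable parameters (see above).
- The grid search guards against, but cannot guarantee escape from,
  local minima; no global optimiser is included.
- An explicit integrator with a step budget deliberately fails fast in
  extreme compensation regimes rather than resolving them.
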