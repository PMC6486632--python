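# Methods

## Models

**Binding isotherm.** EMSA titrations are quantified as percent RNA bound
versus protein concentration and fitted to the one-site isotherm
%bound = B_max·[P]/(K_d^app + [P]). B_max is fixed at 100% by default —
densitometry is normalised so complete binding is 100 — and the only free
parameter is K_d^app (μM). Fitting B_max is opt-in (`fit_bmax=True`);
doing so needs a titration that visibly saturates. The constant is
*apparent*: free protein is identified with total protein, valid when the
labelled RNA is well below K_d.

**Dose-response.** Residual activity at fixed substrates follows
%activity = 100·(1 − [I]/([I] + IC₅₀)), a one-site hyperbolic decline from
100% to 0%. IC₅₀ is condition-specific (it moves with the fixed substrate
concentrations), unlike the mechanistic constants below.

**Substrate inhibition.** The folate substrate inhibits at high
concentration through a dead-end second-binding event:
v = V_max·S/(K_m + S(1 + S/K_i,THF)). The velocity has a unique interior
maximum at S\* = √(K_m·K_i,THF).

**Hyperbolic (partial) competitive inhibition.** RNA (R) and the folate
substrate (S) bind with mutually reduced — but nonzero — affinity; the
ternary E·R·S complex still turns over with the same k_cat. The apparent
K_m is multiplied by f(I) = (1 + I/K_i)/(1 + I/(αK_i)), which saturates at
α, so the rate law

v = V_max·S / (K_m·f(I) + S(1 + S/K_i,THF))

tends to the nonzero floor V_max·S/(αK_m + S(1 + S/K_i,THF)) as I → ∞ —
the operational fingerprint that separates partial from pure competitive
inhibition (where the floor is zero). α = 1 removes the inhibitor from the
rate law entirely; α → ∞ is the pure-competitive limit, represented by an
explicit model variant rather than a numeric infinity to avoid overflow
and to make model comparison explicit.

**Units.** Concentrations are μM throughout; inputs quoted in mM (serine)
are converted at the I/O boundary. Velocities carry arbitrary
absorbance-based units, so only ratios and concentration-valued constants
are meaningful.

## Equilibrium scheme and the oracle

The rate law above is the rapid-equilibrium consequence of the binding
cycle E + S ⇌ E·S (K_s ≡ K_m), E + R ⇌ E·R (K_i), E·S + R ⇌ E·R·S (αK_i),
E·R + S ⇌ E·R·S (αK_s — thermodynamic closure: the same α scales both
cross-affinities), plus the dead-end second-folate site. The second folate
must bind *both* productive complexes (E·S + S and E·R·S + S, same
K_i,THF) for the substrate-inhibition term S(1 + S/K_i,THF) to be
independent of R — with the dead-end on E·S only, the algebra produces an
extra (1 + I/(αK_i))⁻¹ factor on the S²-term and the closed form would not
be recovered.

`solve_equilibrium` finds free S and R by damped root-finding
(`scipy.optimize.root`, hybr) on log-transformed free concentrations —
positivity is automatic — with deterministic initialisation at the totals,
and demands every mass balance to 1e-9 relative. The oracle velocity is
k_cat([E·S] + [E·R·S]). Because the rapid-equilibrium rate law is exactly
a function of *free* concentrations, the oracle matches the closed form at
the solved free concentrations to solver precision (~1e-15); evaluated at
*totals* the agreement is limited by ligand depletion, of order
e_total/r_total (≈3e-5 at trace enzyme on the standard grid, and a large,
directional positive bias when enzyme is comparable to K_i).

## Estimation

All fits minimise unweighted ordinary least squares on the measured
response, the convention of the graphical-analysis tradition these assays
come from (no weighting scheme is implied by the data; replicate scatter
is roughly proportional to signal, and OLS matches common practice in
curve-fitting software). The optimiser (`scipy.optimize.least_squares`,
Levenberg–Marquardt) runs in log-parameter space: positivity is built in
and estimates are equivariant under concentration-unit rescaling.
Exploratory steps are clipped to |log θ| ≤ 230 so underflow cannot produce
an exact zero parameter.

Initialisation is deterministic: V_max from the maximum observed velocity;
K_m from the half-max point *on the rising limb* (with substrate
inhibition the half-max velocity recurs on the falling limb, which would
poison the start); K_i,THF from the largest substrate concentration; K_i
from a 13-point logarithmic grid search over 1e-3–10 μM at the other
starts; α = 10. An optional deterministic 3×3 multistart over (K_i, α)
verifies the optimum is start-independent. Standard errors come from the
Gauss–Newton covariance mapped from log space by the delta method; a free
parameter whose Jacobian column vanishes is flagged unidentifiable (e.g.
K_i when α is fixed at 1). Non-convergence is recorded on the result
object, never raised, so batch simulations can tally failures.

**Bootstrap.** Percentile intervals by case resampling, stratified by
inhibitor series for global fits (each series keeps its size), refits
warm-started at the full-data estimates, mandatory seed, default 1000
resamples (fewer than 100 is flagged). On the standard noisy design
(5% CV, 3 replicates), 95% intervals for K_i cover the generating value in
96/100 simulated datasets at 200 resamples.

**Model comparison.** AICc (error variance counted as a parameter) ranks
all candidate fits of the same data; the winner must clear a margin of 2,
otherwise a tie is reported. Pairs with different parameter counts get an
extra-sum-of-squares F-test, treating the smaller model as nested — for
pure competitive inside the hyperbolic law this is a boundary (α → ∞)
rather than interior nesting, the usual curve-fitting convention. When the
data are generated at that boundary, a tie is the designed and common
verdict; the full model was wrongly preferred 0/100 times in simulation.

## Replot diagnostics

The inference chain mirrors classical graphical analysis, made
quantitative: (1) drop points beyond S\* = √(K_m·K_i,THF) — the optimum is
the natural changepoint of the substrate-inhibited curve; (2) average
replicates per cell and fit 1/v vs 1/S lines per inhibitor level
(unweighted OLS, as in the visual procedure); (3) replot slopes and
intercepts against I; (4) test slope linear-vs-hyperbolic and intercept
flat-vs-linear, and map the shape pair to a mechanism (hyperbolic+flat →
hyperbolic competitive; linear+flat → pure competitive; linear+linear →
pure mixed; else indeterminate).

Numerical choices that matter, each adopted after simulation at the
standard operating point (5% CV, 3 replicates, 100 seeds per mechanism):

- **One exclusion cutoff for all series**, taken from the
  lowest-inhibitor series. Per-series cutoffs drift upward with inhibitor
  (the apparent K_m rises), leaving different substrate grids per series;
  the grid-dependent curvature bias then imprints a spurious trend on the
  intercept replot and mis-calls mixed inhibition.
- **Weighted shape tests.** Reciprocal-space noise is strongly
  heteroscedastic — Var(1/v) scales with (1/v)², so high-inhibitor lines
  have slope/intercept estimates an order of magnitude noisier. The
  replot shape fits weight by the propagated standard errors of each
  line's slope and intercept (uniform weights when SEs are zero or
  missing, e.g. noiseless input). The reciprocal lines themselves stay
  unweighted.
- **Dual statistical rule with an effect-size gate.** A richer shape is
  called only when AICc (margin > 2) *and* the extra-sum-of-squares F-test
  (p < 0.05) agree; an intercept trend must additionally amount to >20% of
  the mean intercept across the observed inhibitor range (real mixed
  inhibition moves 1/V_max several-fold; noise trends stay at the
  few-percent level). Replot AICc counts regression parameters only: with
  as few as 6 replot points, also counting the error variance makes the
  small-sample correction degenerate (n − k − 1 ≤ 1) and the hyperbola
  could never be selected on any evidence.
- **Limiting velocity.** Reported as the I → ∞ velocity at S equal to the
  uninhibited apparent K_m, computed from the hyperbolic slope-replot
  asymptote with a delta-method SE; "excludes zero" means the estimate
  exceeds twice its SE. In simulation it excludes zero in 100/100
  hyperbolic datasets and 0/100 pure-competitive ones.

Resulting operating characteristics: hyperbolic truth recovered 94/100,
pure competitive 92/100, pure mixed (on the serine-varied design) 96/100.

Note the residual curvature retained after exclusion biases each
reciprocal line's intercept above 1/V_max (by up to S\*/K_i,THF, ~37% on
the standard design); the bias is identical across series — same substrate
grid, same curvature term — which is exactly why the intercept *replot*
remains flat and the classification is unaffected.

## Synthetic data

The generator emulates the statistical structure of the assays: a model
value per cell times (1 + CV·z), z standard normal, independent per
replicate — constant coefficient of variation, the typical error structure
of coupled spectrophotometric assays — with defaults of 5% CV and 3
replicates. Negative draws are truncated at zero (logged); percent-scale
outputs are clipped to their physical ranges. All randomness flows from a
single user seed through named substreams per stage
(`SeedSequence([seed, crc32(stage)])`), so identical (design, truth, seed)
triples give byte-identical output files.

Built-in designs: THF 10–488 μM × tRNA {0, 0.11, 0.22, 0.44, 0.88, 1.77} μM
at 10 mM serine (the 8 log-spaced substrate levels are a design choice,
recorded in the design's notes — only the range is prescribed); serine
0.156–10 mM in two-fold steps at 80 μM THF (a source table quotes
"80 mM", an evident unit slip for μM, resolved here and noted); protein
0.3–9.6 μM in six two-fold steps; RNA 1 nM–10 μM, 10 log-spaced points.

What the generator does *not* emulate: systematic (non-multiplicative)
error, instrument drift, enzyme inactivation over time, pipetting
correlation across a titration, or gel-quantification artefacts. Passing
recovery tests on these simulations therefore demonstrates correctness of
the estimation machinery under the stated error model, not robustness to
every failure mode of real data.

## Score combination

Predictor outputs (an interaction-propensity score and a [0,1] affinity
score) are inputs, never computed or fetched. The affinity threshold call
is ≥ 0.25 (inclusive boundary, documented choice). The combined
interaction score min-max-normalises each score over background ∪ target
and averages with equal weights (configurable) — equal weighting is the
minimal assumption for a linear combination. The reported percentile is
the target's rank, (1 + #{background ≥ target})/(n + 1): exactly invariant
under positive affine rescaling of either score (min-max removes it); not
invariant under arbitrary monotone transforms, which can genuinely reorder
a linear combination.

## Problem sizes and determinism

Simulation-based checks use 100 seeds per condition for classification
power and bootstrap coverage (200 resamples per dataset), and 30 seeds in
the per-module tests; all are seeded and reproducible. The full test
suite runs in about two minutes on one core.

## Known limitations

- Rapid-equilibrium treatment only: K_s is identified with K_m, and no
  steady-state or time-course (progress-curve) analysis is offered.
- The K_d^app fit ignores ligand depletion in the titration itself.
- OLS assumes homoscedastic velocity errors; under the constant-CV error
  model this mildly over-weights high velocities (no robust or weighted
  regression options).
- Whether reported ± uncertainties from other software are asymptotic SEs
  or across-experiment SDs is often unstated; this package reports both
  asymptotic SEs and bootstrap percentiles and claims comparability for
  neither.
- The mechanism decision table covers competitive/mixed/hyperbolic only;
  uncompetitive patterns return `indeterminate`.
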