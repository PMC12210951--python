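# Methods

This note documents the models implemented in `fermkin`, the numerical
and design choices made where the problem left room, and what the
synthetic-data generators do and do not establish.

## Kinetic models and fitting

**Model structure.** The viable count is modelled on the lg CFU/mL scale.
A logistic law is applied to the *increment* X̃(t) of the count above a
baseline load `d`, giving the four-coefficient closed form
X(t) = a·e^{ct}/D(t) + d with D(t) = 1 − (a/b)(1 − e^{ct}). Fitting a
logistic model to log-transformed counts is unconventional (the logistic
law is usually posed on linear biomass); it is reproduced here as the
study's operational model without biological reinterpretation. Product
and substrate follow the Luedeking–Piret form applied to the same
increment, integrated analytically: P(t) = P₀ + m·g(t) + (n·b/c)·ln D(t),
and S(t) with signs flipped and coefficients (M, N). The differential
forms are also exposed (`ode_rhs`) and property tests verify closed form
and numeric integration agree to 1e-6 over 0–14 h.

**Solver.** Bound-constrained trust-region least squares
(`scipy.optimize.least_squares`, method `trf`), started from the tabulated
initialization values, tolerances `xtol=ftol=1e-14`, `gtol=1e-10`, at most
1000 function evaluations. Deterministic; no random restarts. Coefficients
whose lower and upper bounds coincide are substituted, not optimized, and
excluded from both the error degrees of freedom and the covariance.

**Goodness of fit.** R² = 1 − SSE/SST with SST about the observed mean;
RMSE = √(SSE/(n − p)) with p the number of *free* coefficients. On the
built-in growth data (n = 8, p = 4) this convention reproduces the pair
R² = 0.9998, RMSE = 0.0156 exactly; the residual-df convention n − p is
therefore fixed by that reproduction. Confidence intervals are Wald
intervals from the linearized-Jacobian covariance, estimate ±
t(level, n−p)·SE; a singular normal matrix yields explicitly unbounded
intervals rather than a silent failure.

**Substrate offset.** The built-in series tabulates cumulative glucose
*consumed* (it rises from 0), while the substrate model describes residual
glucose (S₀ ≈ 30 g/L, decreasing). Residual glucose is reconstructed as
K − consumed for a caller-chosen constant K (default 30.44 g/L, the
fitted initial level of the study culture). Internally the fit runs on the
offset-centred scale, so every output except the reported S₀ is *exactly*
invariant to K, and S₀ shifts by exactly the offset difference — a unit
test asserts both to 1e-8.

**Known reproduction limits.** The product-fit objective is nearly flat in
(b, m, n): the study's reported intervals span ±1e5–1e7. Coefficient
point values for that fit are solver-dependent and only R²/RMSE are
checked. For the substrate fit, the metrics printed in the study
(R² 0.9992, RMSE 0.1545) are not attainable from the printed table means:
evaluating the study's own printed coefficients on those means gives
R² 0.9989 / RMSE 0.1771, and the fit here finds a strictly better optimum
(R² 0.9990, RMSE 0.1665, all coefficients inside the printed confidence
intervals). The original fit evidently used unrounded raw data.

## Orthogonal-design ANOVA

The L9(3³) array assigns three 3-level factors in nine runs with every
factor-pair level combination occurring once. Sums of squares use the
balanced-design shortcut Σ(level-sum²/3) − grand²/9, identical (to 1e-10,
property-tested against a definitional oracle and against a categorical
OLS decomposition from statsmodels) to the deviation-based definition.
Each factor has 2 df and is tested against the 2-df residual with an exact
F(2,2) p-value; no multiplicity correction is applied across the three
factors. Effect size is classical η² = SS_factor/SS_total (not partial
η²), so the three values sum to the model R². An intercept row
(SS = 9·grand-mean²) is included for completeness. Tukey HSD uses the
studentized range with the residual mean square (df 2) and n = 3 per level
mean. `best_levels` reports the per-factor argmax of level means with ties
to the lowest level; it makes no attempt to reproduce selections made on
other grounds.

## Neural-network surrogate

**Topology.** Default 3-3-1: three inputs (glucose, peptone, sweet corn
juice concentrations), one hidden layer of three tanh units, one linear
output (the viable count). The hidden-layer count and width are
configurable; the source description of the topology ("three hidden
layers, resulting in a 3-3-1 topology") is self-contradictory, and the
3-3-1 reading is the default.

**Scaling.** Inputs and target are min-max scaled to [−1, 1] on the
training set; predictions are unscaled for reporting, and all reported
metrics are in original target units unless stated otherwise.

**Training.** Levenberg–Marquardt on the regularized objective
F = β·SSE + α·SSW with MacKay evidence re-estimation after accepted steps:
γ = k − 2α·tr(H⁻¹), α = γ/(2·SSW), β = (n−γ)/(2·SSE), H = 2β·JᵀJ + 2α·I.
Two numerical safeguards matter in practice:

1. *Warmup.* Starting the evidence updates from an unconverged small-weight
   state locks the fixed-point iteration into an over-regularized
   equilibrium (training R² ≈ 0.57 on a representable surface). Training
   therefore begins with α ≈ 0 and runs plain LM to gradient convergence
   before the updates start.
2. *Multistart.* The weight landscape has genuine local minima; 3 seeded
   restarts are run and the lowest-SSE result kept. Training is bitwise
   reproducible for a fixed seed.

α and β are clamped to [1e-12, 1e6] and [1e-12, 1e12]; μ (LM damping)
starts at 0.005 with ×10 / ×0.1 adjustment and aborts above 1e10.
Weight init is seeded uniform on [−0.5, 0.5].

**Committee.** A single near-interpolating network fitted to a 15-run
Box–Behnken design is unreliable *between and beyond* the design points:
a sum of three monotone tanh ridges cannot represent a three-dimensional
interior maximum, and optimizing such a surrogate drives the search to the
box faces. `train_committee` trains 12 independently initialized members
(6 hidden units by default for surrogate-optimization work), discards
those whose final SSE exceeds twice the best, and averages the rest. The
committee is what the optimum-recovery harness optimizes.

**Cross-validation.** Seeded shuffle into k near-equal folds; scaling
re-fitted per fold on the training portion; a 15% slice of each fold's
training portion is reported as a validation partition. Fold-wise R² is
near-meaningless for 3-point folds (their SST is tiny), so the report also
carries pooled metrics over concatenated held-out predictions (a Q²-style
summary). An important negative result, verified by simulation: for a
response surface with an *interior* maximum, held-out Box–Behnken edge
runs are out-of-hull extrapolations and the surrogate does not
cross-validate (pooled Q² ≈ −0.9). For a surface whose maximum lies
outside the design box — the geometry of a screen that has not bracketed
its optimum — pooled Q² ≈ 0.84. Cross-validated metrics on such designs
measure interpolation only where the design has support.

## Genetic algorithm

Real-coded minimizer over a finite box. Population 50, up to 300
generations, crossover probability 0.8, elite fraction 0.05 (elite count
= ceil(0.05·50) = 3), stall stop when the best fitness improves by less
than 1e-6 over 20 consecutive generations. Selection is stochastic
universal sampling on inverse-rank weights; crossover is per-pair
arithmetic blend with mixing ratio ~U(0,1); mutation is Gaussian with
scale 0.1·range decaying as 1/(1 + g/50) and shrinking near the bounds;
children are clipped into the box. The stall metric tracks the incumbent
best (not the population mean). Maximization is expressed by negating the
objective. With elitism, the best-so-far fitness is non-increasing — an
asserted invariant. All randomness flows from the config seed.

## Assays

Closed-form and pure: titratable acidity P = c·(V1−V0)·k/V·1000 with
k = 0.090 g/mmol for lactic acid; DNS standard curve by ordinary least
squares of absorbance on concentration with inverse prediction
(A − intercept)/slope and flagged extrapolation; apparent adsorption
q = (C0−C)/dose, in grams of lactic acid per gram of resin (dimensionless
as a ratio of g/L quantities; reported unrounded with a 1-decimal display
helper); fold change between lg counts as 10^(Δlg).

## Synthetic data

`simulate_fermentation` draws batch series from the closed-form kinetics
with additive homoscedastic Gaussian noise per channel (defaults: 0.02 lg
for counts, 0.15 g/L for lactate and glucose — the order of the replicate
scatter in the study tables; ground-truth parameters default to the fitted
study coefficients on the 0–14 h two-hour grid). It does not emulate
heteroscedastic error growth, autocorrelated sampling error, or plate-count
quantization. `simulate_bbd` evaluates a concave quadratic
y = peak + (x−x*)ᵀQ(x−x*) (Q negative definite) on a Box–Behnken design
plus noise; the default places the optimum at coded (0.3, −0.2, 0.4) with
peak 9.6 lg CFU/mL and curvature spanning ≈1.3 lg units across the design
— strictly inside the box, so that recovery can be scored, although the
real study's optimum lay outside its design box. A real medium-response
surface need not be quadratic; passing recovery tests therefore show the
pipeline can locate a smooth interior optimum, not that it would match any
particular wet-lab outcome.

`recovery_experiment` quantifies end-to-end accuracy. Kinetics: at noise
0.02 lg over 100 seeded replicates, the median relative error of the
recovered growth rate c is ≈3.7% (asserted ≤5%). ANN–GA: committee
surrogate plus GA over 5 seeded replicates at surface noise 0.01 recovers
the optimum with a median per-variable error of ≈4.6% of each variable's
range (asserted ≤5%, pooled over seeds × variables); the per-replicate
worst-variable error is larger, typically 6–9% — optimum localization from
15 design points is the pipeline's weakest link, and single-network
surrogates are far worse (30–40%).

## Problem sizes

All analyses are desk-scale: 8-point time series, 9-run and 15-run
designs, networks with ≤ 60 weights, GA populations of 50 for ≤ 300
generations. The full test suite runs in well under five minutes on one
CPU; the recovery experiments use 100 replicates (kinetics) and 5 seeds
(ANN–GA), sizes at which the reported medians are stable.

## Limitations

- Point estimates from the product fit are not identifiable in practice
  (flat objective); only its fit quality is meaningful.
- The surrogate committee localizes an interior optimum to roughly 5% of
  each variable's range on a 15-run design; applications needing sharper
  localization should augment the design near the provisional optimum.
- No pH dynamics, no resin-coupled simulation, no adsorption isotherms,
  no multi-substrate kinetics; the GA handles box bounds only.
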