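# Methods

## Model

Two coupled ODEs describe a subcutaneously implanted tumor: volume
T(t) in mm³ and the well-vascularized fraction V(t) ∈ [0, 1], the
complement of the hypoxic fraction. Growth is exponential (rate k_T,
per day); immune kill acts through the product T·V because immune
effectors reach well-perfused tissue, at baseline rate μ_T plus a
transient increment γ_i per immunotherapy dose that washes out at rate
r_i. The vascularized fraction relaxes toward 1 at rate k_V, boosted
transiently by γ_e per evofosfamide dose (washout r_e), and is eroded
by tumor growth at rate μ_V·(T/T_c)·V. Doses act from their
administration instant (Heaviside ℋ(0) = 1). Evofosfamide has no
direct cytotoxic term; its entire effect is re-oxygenation, which
amplifies immune kill.

### Units and the volume scale T_c

All rates are per day. The μ_V coupling measures tumor volume in units
of T_c = 1000 mm³ (cm³). This convention is forced by internal
consistency of the calibrated rate magnitudes: with T in raw mm³ and
μ_V ≈ 0.08, the erosion term would be ~8/day already at the 100 mm³
inoculation size — V would collapse to ~0.01 within a day, every
treatment term (all proportional to V) would be inert, and no
between-arm contrast of the observed size could arise. With T in cm³
the erosion and replenishment terms are commensurate and the model
produces realistic multi-week murine dynamics.

### Default initial conditions

T0 = 100 mm³ (tumors are enrolled at that size). The initial vascular
fraction is arm-specific and not published; the defaults are V0 = 0.2
for hypoxic arms (SUV-ratio-stratified hypoxic tumors are predominantly
hypoxic) and V0 = 0.6 for normoxic arms (imaging shows clearly higher
initial vascularization there). These are package conventions,
config-overridable everywhere.

## Numerics

The solver is classical fixed-step RK4 (default dt = 0.01 day for
single trajectories, 0.05–0.1 in the batched calibration/sensitivity
paths; accuracy at these steps is far below the data noise). The grid
is refined so every dose day and requested output day falls on a step
boundary, and dose activity within a step is decided at the step's
start; each step therefore integrates a smooth field and the scheme
retains clean fourth-order convergence despite the C⁰ kinks at dose
onsets (verified against an adaptive high-accuracy reference to 1e−5
relative).

The V equation becomes stiff when μ_V·T/T_c is large (fast-growing
corners of the prior box). Steps whose size exceeds a row's local
stability limit are subdivided for that row only; wherever the grid is
already stable — everywhere near calibrated parameters — the scheme is
exactly fixed-grid RK4. Rows needing more than 128 subdivisions are
reported as integration failures: they contribute −∞ likelihood in
calibration and are rejected and resampled in Sobol designs. The batch
kernel is numba-compiled with a bitwise-equivalent numpy fallback.
Tumor volume is never clamped; V is clamped to [0, 1] only beyond a
1e−9 solver tolerance.

## Synthetic cohorts

The generator emulates the experimental protocol: six arms (control;
hypoxic/normoxic + immunotherapy; evofosfamide; hypoxic/normoxic +
combination), caliper measurements every 2–3 days over days 6–39,
vascular-fraction observations at days 12 and 17, evofosfamide daily on
days 13–17 and immunotherapy on days 7/10/13 by default. The
immunotherapy days are only depicted graphically in the source
protocol; 7/10/13 is consistent with enrollment at ~day 7 and with the
sensitivity analysis showing the γ_i importance window opening near
day 7.6, and is config-overridable.

Measurements are group means of `n_replicates = 8` simulated mice per
arm (a typical murine arm size — the calibration targets group-mean
curves with confidence intervals, which presuppose several animals)
with i.i.d. additive Gaussian noise per mouse, σ_T = 25 mm³ and
σ_V = 0.05, truncated to the physical domain. With a single mouse per
arm the per-dose kill increment γ_i is not identifiable at this noise
level — its trajectory effect is within noise — so single-series
cohorts are supported but not the default. The generator captures the
noise structure the likelihood assumes; it does not emulate inter-mouse
parameter heterogeneity, measurement-day jitter, dropout, or PET
physics, so passing recovery tests demonstrate correctness of the
inference machinery under the assumed error model, not robustness to
real-data misspecification.

## Calibration

The likelihood is weighted Gaussian: tumor residuals weighted α = 2,
vascular residuals β = 1 (two imaging days only). Priors are
independent uniform boxes: U(0, 0.4) for k_T, U(0, 0.5) for k_V, μ_V,
μ_T, U(0, 3.5) for γ_i and γ_e, U(0, 0.2) for r_i and r_e, U(0, 1) for
each arm's V0. The noise scales are calibrated as hyperparameters with
U(0, 200 mm³) and U(0, 0.5) hyperpriors.

Sampling uses an affine-invariant ensemble (emcee) with differential-
evolution and snooker moves, which mix far better than stretch moves on
the narrow curved ridges this posterior develops. Walkers start in a
small ball around a MAP estimate found in two phases: differential
evolution on a scale-free surrogate (log-volume least squares plus
vascular residuals — the raw Gaussian objective is dominated by the
largest volumes and lets optimizers trade misfit against inflated σ),
then bounded Levenberg–Marquardt on the true weighted residuals,
iterating the analytic conditional update σ² = SSR/N of any free noise
scale. Every stochastic step derives from one integer seed; identical
settings give bitwise-identical chains. Split-R̂ and effective sample
size are reported per parameter, warning beyond 1.05 / below 200.

Because α = 2 double-counts the tumor block, the posterior is tempered
— deliberately overconfident by ~√2 in tumor-dominated directions. Its
percentile width therefore understates the repeat-cohort spread of the
posterior mean, and the package's repeated-cohort test asserts recovery
accuracy (k_T, μ_T within 3 %) rather than nominal interval coverage.

The staged workflow: stage 1 calibrates {k_T, k_V, μ_V, μ_T, γ_i, r_i,
V0 of arms I–III, σ_T, σ_V} to the three evofosfamide-free arms; stage
2 fixes those at their posterior means (single-value hand-off, matching
the workflow's "use the values obtained previously"; σ reuse is
config-exposed) and calibrates {γ_e, r_e, V0_IV, V0_V} to arms IV–V;
stage 3 fits only V0_VI — by deterministic bounded least squares on arm
VI's two vascular observations, keeping its tumor series strictly out
of sample — and scores the tumor prediction by CCC against a 0.8
threshold (configurable). On failure, stage 4 re-calibrates one
parameter at a time in descending Sobol total-effect rank until the
threshold is met, reporting the minimal re-calibrated set and its fold
change; exhausting all parameters yields a "model-inadequate" status.

Stage 4's ranking uses log-volume output for the indices: the ranking
should reflect trajectory-wide multiplicative misfit, and the raw-
volume estimator is too heavy-tailed over the prior box for a stable
integrated ranking (see below). On the combination protocol this puts
γ_i first, consistently across seeds.

## Sensitivity analysis

Saltelli design: two independent N×K uniform matrices A and B plus K
hybrids AB(k) (A with column k from B), N(K+1) model evaluations in
total; K covers the eight rates plus V0. The total effect at each
output time is the Jansen paired-difference estimator
ST_k ≈ (1/2N)·Σ_j (Y_A,j − Y_AB(k),j)², by default normalized by the
empirical variance of Y_A so indices live on the standard [0, 1] scale
and are comparable across time; the raw unnormalized mode is also
available. Ties in rankings break alphabetically; the "importance
interval" of a parameter is the longest contiguous span on which its
index strictly exceeds every other's, with endpoints linearly
interpolated between grid days.

Default sampling ranges are the prior boxes with V0 ~ U(0, 1); a
posterior-percentile mode is available. On the raw volume scale the
output is approximately lognormal with a log-sd that reaches ~3 late in
the window, so the estimator's late-time values converge slowly: at
N = 4096 the qualitative orderings (k_T top without immunotherapy with
μ_T second; γ_i top throughout the dosing period when immunotherapy is
given) are stable across seeds, but fine interval endpoints — in
particular whether evofosfamide strictly prolongs γ_i's dominance
window — are not resolved at this sample size, and with these ranges
the model tends to the opposite ordering: boosting V late amplifies
the variance of every V-multiplied term, ending γ_i's dominance no
later than without evofosfamide.

## Metrics

CCC uses Lin's original population-moment (1/n) estimator — sample-
variance variants differ noticeably at the ~14-point series length
here; identical constant series score 1, degenerate zero-variance pairs
otherwise 0. MAPE excludes observations at or below a 1 mm³ floor
(measured zeros are a caliper floor) and reports the exclusion count.
Burden reduction between arms is evaluated at the final simulated day
by default (the evaluation day is config-exposed). Uncertainty on the
headline reduction uses independent normal approximations of the
published percentile intervals; this ignores posterior correlations and
therefore overstates the spread relative to joint-posterior draws.

## Known limitations

* Spatial structure, direct evofosfamide cytotoxicity and per-mouse
  random effects are out of scope by design.
* Initial vascular fractions and the immunotherapy dose days are
  conventions (config), not published values.
* The evidence/normalizing constant is never computed; only the
  unnormalized posterior is sampled.
* Raw-scale Sobol indices over the full prior box are heavy-tailed;
  treat fine time-interval comparisons at N ≲ 10⁴ as qualitative.
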