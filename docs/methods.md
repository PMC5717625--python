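# Methods

`desertsem` implements a piecewise structural equation model (SEM) of a
central-Australian sand-dune food web, together with a negative-binomial
climate/wildfire scenario simulator and a 100-year projection of the
vegetation–rodent–predator cascade under three predator-removal regimes.
This note records the model, its assumptions, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## The piecewise SEM

The system is represented as a directed graph of nine locally estimated
submodels — insectivorous dasyurids, spinifex cover, spinifex seed,
rodents, mulgara, feral cat, red fox, dingo and reptiles — totalling 26
directed effects. No global covariance model is fitted: the submodels
differ in dataset length (17–22 years of trapping versus 2 years of
camera monitoring) and each carries a random effect, so the SEM is the
collection of local generalized linear mixed models (GLMMs), and model
fit is summarised per node rather than globally.

Each node is either

* **Poisson with log link** for pooled minimum-known-alive capture counts
  (or predator photograph counts), with `log(effort)` as offset — trap
  nights for pitfall captures, camera nights for photographs; or
* **binomial with logit link** for grid-averaged scores: percentage
  spinifex cover as "successes" out of 100, and the 0–5 seed index out
  of 5. Because the scores are averages, non-integer successes are
  accepted (a quasi-likelihood reading; the kernel and deviance formulas
  are unchanged). The denominators 100 and 5 are the only ranges the
  score definitions admit.

All nodes include a normal random intercept for trapping trip (sampling
occasion) to absorb repeated-measures correlation; for the camera models
the month is the sampling occasion. Count covariates enter as
effort-standardised rates exactly as the formulas write them (captures
per 100 trap-nights; photographs per camera-night). The red-fox model
z-transforms its predictors (needed for convergence on the original
data); slopes are converted back to raw units with the recorded scale
factors when compared against generative values.

### Estimation

The random intercept is integrated out by a Laplace approximation. For
each occasion *j* the scalar conditional mode `b_j` is found by a
vectorised Newton iteration, and the marginal log-likelihood is

    l(beta, sigma) = sum_j [ l_j(b_j) - b_j^2/(2 sigma^2) ]
                     - (1/2) sum_j log(1 + sigma^2 W_j),

with `W_j` the summed GLM working weight at the mode. The `log1p` form
is exact at the `sigma = 0` boundary, where the model collapses to an
ordinary GLM; that limit is solved by the package's own IRLS routine
(quadratically convergent for the canonical links), which also provides
starting values for the mixed optimisation (L-BFGS-B over fixed effects
and `sigma >= 0`, relative tolerance 1e-12, up to 500 iterations).
Laplace (rather than adaptive quadrature) matches standard practice for
a single scalar random effect and keeps the fitter self-contained.

Wald standard errors come from the central-difference Hessian of the
marginal log-likelihood over the fixed effects at the optimum (sigma
held at its estimate, as mixed-model software conventionally reports);
p-values are two-sided normal, `p = 2*Phi(-|z|)`, with significance at
0.05. Fits that drive sigma below 1e-4 are reported as singular
(SD = 0, with a warning) and the fixed effects are re-solved by IRLS.
Rows with missing covariates are dropped listwise with a logged count.

### Deviance explained

Per-node fit is the percentage of null-model deviance removed by the
fixed predictors, `(D_null - D_fit) / D_null`, where deviance is −2 ×
the maximised marginal (Laplace) log-likelihood including its
normalising constants — the quantity mixed-model software reports — and
the null model retains the intercept, offset and random intercept on the
identical rows. Nesting of the null guarantees a value in [0, 1] up to
optimiser tolerance (tiny negative noise, |v| < 1e-6, is clipped to 0).
A conditional (unit-deviance) definition was considered and rejected:
with the random-intercept SD re-estimated separately in null and fitted
models it can violate the nesting bound.

### Standardized path coefficients

Effect sizes are range-normalised: predict the response on its natural
scale (random effect at zero; rate per effort unit for Poisson nodes) at
the predictor's observed minimum and maximum with all other predictors
held at their observed means, difference the two predictions, and divide
by the observed range of the response. The divisor uses the observed
range (not the theoretical one) by default. Because the links are
monotone, the sign always matches the raw coefficient, and the value is
invariant to affine rescaling of the predictor. Two conventions were
genuinely open and are resolved as follows: the categorical site term is
swept across its levels and reported as the spread between the extreme
level predictions (non-negative by construction, joint Wald chi-square
p-value across the dummy block); the phase × dingo interaction is swept
over the observed range of the product column with the main effects at
their means — a single-column sweep that satisfies the sign-consistency
invariant and the two-point oracle exactly.

## The causal graph and its apparent cycles

The 26-effect network contains nominal feedback (rodents → predators
and predators → rodents). Two kinds of edges are distinguished:
*direct-dependency* edges, where one node's response column feeds
another's linear predictor (cover → seed → rodents; cover → mulgara,
reptiles), and *observed-rate* edges, where a field-measured
effort-standardised rate enters as a covariate. Local estimation treats
the latter as observed data, so only the direct-dependency subgraph must
be acyclic — it is, and its topological order (cover before seed before
rodents) is the propagation order of the projection.

## Scenario simulation

Exogenous drivers are drawn from negative binomials in mean/dispersion
form (variance = µ + µ²/size), preferred over the Poisson because
arid-zone rainfall is over-dispersed by the many nil or small events.
Eight-month cumulative rainfall drifts from µ = 152 mm (current,
size 1.57) to µ = 419 mm at 100 years; years-since-wildfire from µ = 21
to µ = 10 (size 3.34). The drift is linear over 12 steps (only the
endpoints and the step count are specified; the per-step mean vector is
overridable), the dispersion is held constant (it is stated identically
at both endpoints), and draws are kept as the integers the distribution
produces while entering the downstream equations as continuous
covariates. 2000 draws per step.

## Projection

Per run and step, a rainfall and a fire-age draw enter the fitted cover
equation; each run's predicted cover (not the cross-run mean) feeds the
seed equation with the same rainfall draw; predicted seed feeds the
rodent equation with that run's predator rates — so uncertainty
compounds across nodes. Predictions are population-level (random effect
zero) on the natural response scale; the logit keeps cover in [0, 100] %
and seed in [0, 5], the log keeps rodent rates positive. Predator rates
per run are resampled with replacement from the observed camera-rate
table and held constant across steps (no predator-dynamics model is
specified); the three scenarios are all predators present, introduced
cat + fox zeroed, and all three zeroed. The rodent node is summarised
over a 342-run subsample of the 2000 runs, mirroring the smaller
predator dataset. Reported per step: mean and s.e. (SD across runs /
sqrt(n)). Scenario contrasts are pooled over steps:
`100 × (mean_b − mean_a)/mean_a` on the rodent rate.

One wording ambiguity deserves note: the projection description says
simulated data were entered "using the standardized path coefficients",
but standardized coefficients are range-normalised summaries that cannot
be combined dimensionally with mm or years. The default propagates the
raw link-scale coefficients; a `standardized` mode (an affine
range-normalised approximation, clipped to the response bounds) is
selectable for comparison. Scenario draws routinely exceed the fitted
covariate range (the NB right tail); a warning is emitted rather than an
error, since extrapolation is the point of the exercise.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design — 9 sites, 2–12 grids each
(drawn uniformly), 36 pitfall traps × 2–6 nights per grid-trip, daily
two-part rainfall per site (Bernoulli wet day at 0.12; gamma event sizes,
mean 6 mm, shape 0.75, giving heavy-tailed over-dispersed totals),
continuous per-grid fire ages with occasional resets, binomial-logit
cover/seed, and a 24-month camera window (3 cameras/site) with monthly
pooled photo counts and a boom(1)/decline(2)/bust(3) phase sequence
triggered by rainfall pulses. A pulse is guaranteed early in the camera
window, as the emulated deployment was timed to span a boom and the
subsequent bust (this also guarantees phase variation for the fox
z-transform). The default of 20 quarterly trips is deliberate: it gives
pooled per-node sample sizes (~1200 grid-trips for the long-term nodes,
~500 rodent-node rows, 216 camera site-months) on the order of the
original pooled analysis datasets, at a cost of a few seconds per
replicate.

The rodent ↔ predator feedback is broken causally in time: predator
counts in month *m* are generated from the most recent trapping-derived
site rodent rate before *m* (exactly the merge rule the reader-side
frame assembly applies — tested for equality), while rodent counts at a
trip respond to that month's realised predator rates. Every node is
therefore correctly specified given the covariates in its analysis
frame, which is what makes simulate-and-refit parameter recovery
well-posed. Trip random intercepts are drawn independently per node; no
field estimate of the trip-level variance is available, so the defaults
(SD 0.25–0.3 on the link scale) are configuration, not assertions. Default ground-truth slopes reproduce the qualitative sign
structure of the fitted field model (rainfall and fire age raise cover,
cover raises seed, seed and dingo raise rodents, cat and fox suppress
them, the dingo × phase interaction suppresses the mesopredators) with
magnitudes that keep all covariates and counts in realistic field
ranges.

What passing tests show: the fitter recovers known coefficients from
data generated under its own model class at realistic size and design
(all 25 slopes within 2 SE in ≥ 92% of 100 replicates); the assembled
network, standardized coefficients, scenario draws and projection agree
with independent closed-form oracles; and the qualitative cascade
conclusions (cover decline under the drift; larger rodent gains from
removing introduced predators than from removing all predators) follow
from the sign structure. What they do not show: robustness to real-data
features the generator omits — spatial rainfall correlation, animal
movement, detection error in photo counts, model misspecification, or
the irregular field trip calendar.

## Numerical conventions and degenerate inputs

Seeded `numpy` Generators everywhere; identical seeds give byte-identical
tables, fits and projection artifacts. Zero or negative effort is a
validation error, never silently rescaled. A dry month's mean event size
is missing, not zero; covariates with insufficient 12-month lookback are
missing, not zero. Z-transforming a constant column raises. A zero
observed response range makes the standardized coefficient undefined
(error); a constant predictor yields 0 with a warning. Tables are
CSV/UTF-8 with a leading `# units:` comment line; readers check declared
units of known columns and the range invariants (cover in [0, 100], seed
in [0, 5], phase in {1, 2, 3}, positive effort, unique keys).

## Known limitations

* Laplace accuracy for the seed node (binomial denominator 5) is the
  weakest link; an adaptive-quadrature escape hatch is noted but not
  implemented.
* p-values are Wald; likelihood-ratio tests would be a natural
  extension and may differ for the small camera datasets.
* No feedbacks in projection (e.g. rodents → vegetation), no predator
  population dynamics, and no projection of dasyurids, mulgara or
  reptiles — only cover, seed and rodents are projected.
* The standardized-mode propagation is a linear approximation intended
  for sensitivity comparison, not inference.
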