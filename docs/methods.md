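# Methods

`phenodyn` infers *phenomenological* dynamical models: given sparse, noisy
measurements of a few variables of an unknown system, it searches an ordered
hierarchy of nested ODE models — adding nonlinear interaction terms and
hidden variables one step at a time — and selects the single model whose
complexity the data can support. This note records the model classes, the
estimators, the numerical choices, and what the built-in benchmark
generators do and do not emulate.

## Model classes

Two nested-complete families are implemented; each can approximate any
smooth dynamics given enough hidden variables, and each encodes a different
structural prior about the system.

**S-systems (power-law networks).** Each of the J dynamical variables obeys

    dx_i/dt = alpha_i * prod_j x_j^g_ij  -  beta_i * prod_j x_j^h_ij,

a difference of one production and one degradation term, each a product of
powers of all variables; the K inputs enter as constant pseudo-variables
x_{J+k} = I_k. Prefactors are non-negative; exponents are unrestricted in
sign and need not be integers, which is why the dynamics are ill-defined at
non-positive states — candidate parameters that drive any state to zero or
below are simply discarded as infinitely bad fits rather than patched.

**Sigmoidal (CTRNN-style) networks.** Each variable relaxes with a time
constant and is driven by a weighted sum of saturating functions:

    dx_i/dt = -x_i/tau_i + sum_j W_ij * xi(theta_j - x_j),
    xi(y) = 1/(1 + exp(y)).

We use one offset theta_j per *source* variable, with the sigmoid applied
per source before the linear combination. The alternative convention —
a sigmoid of a linear combination, as in classical neural networks — is a
known variation of this class and is deliberately not implemented; the
convention in force is written into every serialized model
(`sigmoid_convention` tag) so exported models are unambiguous.

Hidden variables are ordinary dynamical variables that never appear in the
data; their initial values are fit parameters shared across experimental
conditions (the benchmarks are designed so this is the right structure: in
each protocol the unobserved degrees of freedom start from a
condition-independent state, e.g. radial velocity zero at release).

## The hierarchy

A single a-priori ordering interleaves nonlinearity and hidden-variable
growth. The first model is minimal (independent production/decay per
observed variable: `alpha_i, beta_i, h_i_i` for S-systems, `tau_i, theta_i,
w_i_i` for sigmoidal nets). Each later model activates the next interaction
parameter in a fixed row-major sweep over (target, source) pairs; when the
network at the current hidden count is fully connected, the next model
instead adds a hidden variable (its own decay/production parameters,
self-term, initial value, and coupling to the most recently added variable),
then the sweep resumes. Parameters are only appended, so every model is an
exact restriction of all later ones. The exact insertion order is a design
choice; experience with these hierarchies is that results depend on the
model *class* far more than on the order in which parameters are added
within it, and our recovery tests are insensitive to it.

Newly activated parameters start at *neutral* values (exponents, weights,
offsets 0; time constants 1; hidden initial values 1 for S-systems, 0 for
sigmoidal nets), so a warm-started richer model begins with exactly the
trajectories — and exactly the chi-squared — of its predecessor's optimum.

## Fitting

The cost is weighted least squares over measurement records plus
weakly-informative priors:

    cost = chi2/2 - log_prior,
    chi2 = sum_records ((prediction - value)/sigma)^2.

Priors are zero-mean Gaussians with scale 10 on exponents, weights and
offsets, and log-normal with scale ln 10 on positivity-constrained
parameters (alpha, beta, tau, S-system hidden initial values); sigmoidal
hidden initial values are real-valued and get the Gaussian prior. Positive
parameters are optimized on log scale, where their priors are Gaussian and
positivity is automatic. Reported measurement sigmas are taken at face
value; no error-model re-estimation is attempted.

Each model is fit in two phases from its warm start:

1. **Annealed exploration.** A random walk over the transformed parameters
   under a geometric temperature ladder (default 10 → 1 over 20 stages, 50
   proposals per stage; scaled down in the test suite). The kernel mixes
   local Gaussian steps with occasional *global* moves that resample one
   coordinate from its prior — without these, a parameter sitting at a
   switched-off neutral value (e.g. a new hidden variable's production
   rate, optimized in log space) sits on a gradient plateau that local
   steps cannot leave. Proposals whose trajectories fail to integrate are
   rejected outright.
2. **Least-squares refinement.** Trust-region least squares on the stacked
   residual vector (data residuals plus prior residuals), finite-difference
   Jacobians. Failed integrations contribute large constant residuals, so
   the trust region backs away from infeasible regions.

The returned optimum never has a higher cost than the warm start, which
makes chi-squared non-increasing along the hierarchy by construction.

For speed, all constant-input conditions are integrated simultaneously as
one block-diagonal ODE system (LSODA, told the Jacobian bandwidth so stiff
steps stay cheap); the right-hand side is vectorized over conditions.
Solvers probe infeasible trial states as part of normal step control, so
the integrated right-hand sides are made finite everywhere (states clipped
into the computable domain, non-finite derivatives saturated) and genuine
pathologies — positivity violations, blow-ups past |x| = 1e10, solver
failures — are detected from the *returned* trajectory and charged to the
candidate as an infinite cost. Default tolerances: rtol 1e-6, atol 1e-8,
at most 2000 internal steps per cost evaluation (all configurable).

## Scoring and selection

A fitted model is scored by a generalized-BIC estimate of its Bayesian
log-likelihood. With lam_i the eigenvalues of the data-only cost (chi2/2)
curvature at the optimum, in the basis whitened by the prior scales (so
every prior precision is 1):

    Lhat = -chi2/2 + log_prior - (1/2) sum_i ln(1 + lam_i).

The penalty charges each parameter direction by how strongly the data
constrain it relative to the prior: sloppy directions (lam << 1) cost
essentially nothing, and when all k directions are data-dominated with
curvature growing like N the penalty approaches the familiar (k/2) ln N of
BIC up to an N-independent constant (asserted by the test suite on a
linear-Gaussian toy). We sum over all directions rather than only the
constrained ones — the difference is at most (ln 2)/2 per sloppy direction
and the smooth form behaves better under the one-peak stopping rule. The
**effective parameter count** is the number of directions with lam_i > 1;
it is at most the nominal count (active parameters plus hidden initial
values) and is the quantity that saturates when a model stops extracting
structure from the data.

Curvature is a Gauss-Newton estimate J^T J from a central finite-difference
Jacobian of the data residuals at the optimum; negative eigenvalues beyond
numerical tolerance trigger a degenerate-optimum warning and are clamped
to zero.

Selection walks the hierarchy in order with warm starts, tracking the
running maximum of Lhat. Because the hierarchy is nested, Lhat rises while
added complexity pays for itself and falls once it overfits; statistical
fluctuations aside there is a single peak, so the search stops once Lhat
has stayed more than `margin` (default 2 log-units) below the maximum for
`patience` (default 3) consecutive models, or when the hierarchy or the
model-evaluation budget is exhausted. The argmax model is selected, ties
within 1e-6 broken toward the simpler model. One *model evaluation* is one
trajectory integration over one experimental condition; right-hand-side
call counts are logged separately.

Posterior uncertainty uses the Laplace approximation at the optimum
(covariance = pseudo-inverse of data curvature plus unit prior precision in
the whitened basis); predictive medians and 90% bands integrate each
posterior sample.

## Benchmark generators

All three generators are seed-deterministic, corrupt measurements with
multiplicative Gaussian noise, and report sigma = max(noise_frac * |value|,
1% of the observable's dynamic range) so zero-valued observations keep a
positive uncertainty. Each returns its noiseless truth oracle alongside the
data, so evaluation never re-implements the truth.

**Radial gravity.** A particle is released with speed v0 perpendicular to
the sun line at distance r0; only the distance r is observed, once per
condition at a random time. Reduced dynamics: dr/dt = v, dv/dt =
ell^2/r^3 - mu/r^2 with ell = r0*v0 and v(0) = 0. Units and ranges (chosen
once; the study conditions are not dictated by the protocol itself): mu = 1,
v0 = 1, r0 ~ U[0.5, 3], observation time ~ U[0, 5], 5% noise. The circular
radius mu/v0^2 = 1 lies inside the range and the bound/unbound boundary
sits at r0 = 2, so the data mix elliptical (oscillatory) and hyperbolic
(monotonic) trajectories. The release distance is exposed as a constant
input: it is experimentally controlled, and with it the radial Kepler
dynamics are *exactly* representable in the 1-hidden S-system (hidden
variable z = v + b with shared initial value b: dr/dt = z - b, dz/dt =
v0^2 I^2 r^-3 - mu r^-2) — the hidden variable is defined only up to such
shifts/powers, so the test asserts the hidden-variable count and the
qualitative phase-space surface, not particular parameter values.

**Multisite phosphorylation.** A receptor with 5 modification sites in a
linear chain; each site (de)phosphorylates with Michaelis-Menten kinetics
whose (V, K) depend on the site, direction, and the occupancy of its
nearest neighbours — 2^5 = 32 microstate ODEs, total concentration
conserved. The 32 neighbour-dependent (V, K) pairs (64 constants) are drawn
log-uniformly from [0.1, 10] under a fixed seed and frozen, so the truth is
exactly known to the tests; the published variant of this construction
counts 52 parameters, a decomposition (likely sharing Michaelis constants
across neighbour configurations) that is not fully specified, so the count
is recorded but not asserted. The controllable input V is the maximum rate
of cooperative phosphorylation of site 2 when site 3 is occupied. The
observable is total phosphorylation from the unphosphorylated state,
measured at several random times per input level, 10% noise; time-varying
(piecewise-constant) inputs are supported for extrapolation tests. A
hand-built 5-parameter model — exponential saturation in time with a
sigmoidal dependence of the asymptote on V:
x(t; V) = A * xi((V0-V)/w) * (1 - exp(-t/tau)) + c — serves as the simple
competitor in error-versus-N comparisons.

**Yeast glycolysis.** The 7-species oscillator whose equations and 16
parameters are transcribed in `phenodyn/glycolysis_constants.py` (14
kinetic/saturation/conservation constants plus two stoichiometric yield
coefficients; this accounting matches the conventional statement that the
model has 16 free parameters). At the recorded constants the limit cycle
has a period of about 1.17 min. Three species (S1-S3) are observed; per
condition all 7 initial concentrations are drawn uniformly from ranges
centred on the limit cycle with half-width equal to the cycle amplitude
(scaled by 2 for the hard out-of-sample test, clipped to positive), and
the 3 observables are recorded at one uniform random time in [0, 1] min,
10% noise.

### What the generators do not emulate

Measurement noise is exactly the Gaussian the fitter assumes, sigmas are
honestly reported, initial conditions of observed variables are known
exactly, and the dynamics are deterministic (no intrinsic stochasticity).
Passing the recovery tests therefore demonstrates the statistical and
algorithmic machinery — complexity control, hidden-variable discovery,
out-of-sample generalization — under a correctly-specified observation
model; it does not demonstrate robustness to misspecified noise,
systematic errors, or unknown initial conditions, which real data have.

## Evaluation protocols

Out-of-sample quality is Pearson correlation between predicted and true
time courses on fresh initial conditions: per observed species over a
100-point uniform grid (5 min for glycolysis), averaged over species within
a condition, then over conditions (the pooled-over-everything correlation
is also reported in the metadata). Failed out-of-sample integrations score
0 rather than being dropped — excluding them would inflate the mean by
survivorship. Error-versus-N tables report the mean and the standard
deviation of the mean over replicate data sets.

## Problem sizes in the shipped test suite

The test suite runs every protocol end to end at sizes chosen to keep the
whole suite in the tens of minutes on one core: the gravity study at its
full N = 150 with a reduced annealing budget (8 stages x 12 proposals),
in-hierarchy recovery at N in {50, ..., 800} with 3 replicate seeds, and a
scaled-down glycolysis search (N = 10, 3 hierarchy steps). The full-scale
glycolysis study (N = 40, deep hierarchy, up to 5e8 model evaluations) is a
long-running computation exposed as `phenodyn reproduce-glycolysis`; its
defaults are the full-study settings.

## Known limitations

* The hierarchy's insertion order is one principled choice among several;
  models selected under a different interleaving can differ in detail
  (though not, in our tests, in hidden-variable count or predictive
  quality).
* The annealing schedule is modest by default; for hard landscapes
  (S-systems near positivity boundaries) the search can settle above the
  global optimum. All budgets are configuration, not architecture.
* Hidden initial values are shared across conditions; protocols where the
  hidden state genuinely differs per condition would need per-condition
  initial-value parameters, which are not implemented.
* The Laplace posterior underestimates uncertainty in strongly non-Gaussian
  directions; bands are approximate.
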