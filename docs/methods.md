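# Methods

## Model

`agingnet` implements a network model of aging and mortality. An
individual's health is a graph `G` of `n` binary nodes (health
indicators): state 0 is healthy, 1 is damaged. Node `i` flips at rates
driven by the fraction `f_i` of its damaged neighbours,

    damage:    A+(f) = Γ0 · exp(r+ · f)        [1/year]
    recovery:  A−(f) = (Γ0/R) · exp(−r− · f)   [1/year]

Two designated *mortality nodes* — the two most highly connected hubs —
define death: the lifetime τ is the first time both are damaged,
starting from the all-healthy state. The exponential rate form is not ad
hoc: each indicator aggregates many slowly varying background processes,
and superpositions of many sparse point processes are asymptotically
Poisson regardless of the constituents' law (demonstrated empirically in
`poissonisation`).

All rates depend only on the current network state, so the process is a
continuous-time Markov jump process on {0,1}^n and the classical
Gillespie stochastic simulation algorithm is exact. The implementation
(`dynamics`, kernel in `_gillespie`) keeps per-node rates in a Fenwick
tree: event selection and the post-flip rate update (flipped node plus
its neighbours) both cost O(log n). Event-count guard: 10^8 events per
lifetime (death is reached almost surely, the cap protects against
pathological parameter choices).

## Mean-field reduction

Replacing each node's neighbour fraction by the population damage
fraction `p(t)` (a law-of-large-numbers step justified by the large,
overlapping neighbourhoods of a scale-free graph), and aggregating
states by the mortality-node pair into other / pre-death / death
classes, gives on the scaled time `s = Γ0·t`:

    dp*/ds  = (1 − p*)·A+*(p*) − p*·A−*(p*),       p*(0) = 0
    dχ*/ds  = (1 − χ*)·2A+*(p*) − χ*·A−*(p*),      χ*(0) = 0

with `A+*(p) = e^{r+·p}`, `A−*(p) = e^{−r−·p}/R`; `χ*` is the pre-death
occupancy conditional on survival. The approximate mortality rate is

    m(t) = m*(Γ0·t),   m*(s) = Γ0 · A+*(p*(s)) · χ*(s).

Both curves rise strictly to fixed points `p† = 1/(1 + e^{−(r++r−)p†}/R)`
(bisection on [0,1], tolerance 1e−12) and `χ† = 2p†/(1+p†)`, and satisfy
`p* < χ* < 2p*` for all `s > 0` — verified numerically on every solved
grid.

Numerical choices:

- **ODE solver.** `scipy.integrate.solve_ivp` RK45, rtol 1e−9,
  atol 1e−12, dense output resampled to a uniform grid (default
  s ∈ [0, 0.15], 3001 points ≈ ages 0–133 y at the reference Γ0). The
  system is smooth and non-stiff, but the log-hazard window regression is
  sensitive to solution accuracy, hence the tight tolerances. A third
  integrated component accumulates the cumulative hazard
  H(s) = ∫ A+*·χ* ds.
- **χ\* closed form.** The occupancy ODE is linear given `p*`, so `χ*`
  also has an integral representation. It is evaluated with a stepwise
  exponential-integrator (integrating-factor) rule with trapezoidal
  coefficients, which stays accurate and overflow-free where the rates
  saturate (the naive double integral would exponentiate the cumulative
  rate, ~10^3 at the grid end).
- **Damage fraction at death.** E[p̂(τ)] ≈ ∫ p·m·exp(−∫m) dt, evaluated
  by composite trapezoidal quadrature on the macroscopic scale (Γ0
  cancels). Requires H(s_max) > 23 (survival mass < 1e−10 beyond the
  grid); the leftover mass is returned as an explicit truncation bound.
  Deterministic quadrature is used instead of Monte-Carlo integration to
  remove sampling noise from a deterministic quantity; a sampling
  cross-check (death times drawn via H(τ) ~ Exp(1)) agrees to < 0.005.
  For the reference parameters the integral evaluates to 0.648 — the
  model predicts that roughly two thirds of the nodes are damaged at
  death.
- **Fixed-point bracket.** Bisection on [1e−15, 1−1e−15] to avoid
  evaluating the boundary.

## Gompertz fitting

Hazards are estimated from lifetimes by occurrence/exposure: deaths per
person-year at risk in age bins (default width 1 year), ages reported at
bin midpoints. This estimator is robust in sparse bins and shares its
limit with −Δln S. The Gompertz law `m(t) = α·e^{βt}` is fitted by OLS
of `ln m` against age at the curve's sample points inside a closed
window — integer years for mean-field curves, bin midpoints for
simulated cohorts. Zero or missing hazard points are *excluded* (with a
warning) rather than floored: flooring biases the intercept. The implied
survival is normalised at birth, `s(t) = exp[(α/β)(1 − e^{βt})]`, with
the β→0 limit `exp(−αt)`; the normalisation `s(0)=1` is an
interpretation, as the integration constant is otherwise free.

## Analytic bounds

Integrating the damage ODE between crude rate envelopes yields explicit
bounds (valid sandwiches around the mean-field `m(t)`, checked on every
grid):

- lower: `m(t) ≳ (Γ0²t/D)·exp(r+Γ0t/D)` with `D = 1 + ((R+1)/R)Γ0t`;
- upper: `m(t) ≲ (2Γ0/r+)·L·e^L` with `L = −ln(1 − r+Γ0t)`, valid only
  for `r+Γ0t < 1` (series radius). The printed-series form
  Σ(r+Γ0t)^k/k is kept as a test oracle; values above 10^10/yr are
  reported as +inf with a validity flag.

In the small-`t` regime both bounds reduce to (1 resp. 2)·Γ0²t·e^{r+Γ0t},
giving the explicit approximations `β ≈ r+Γ0` and
`t_lo·Γ0² ≲ α ≲ 2·t_hi·Γ0²` on a window [t_lo, t_hi] (the canonical
[40, 80]-year window gives the factor-4-wide sandwich 40Γ0²..160Γ0²).
Windows other than [40, 80] recompute these constants by the same
small-`t` argument.

## Network generator

No explicit wiring for the reference health network is available, only
its two structural properties: scale-free and disassortative. The
generator therefore uses the simplest construction with both: a
Barabási–Albert graph (preferential attachment, `attachment` edges per
new node) followed by degree-preserving double-edge swaps accepted iff
they strictly decrease the degree-assortativity coefficient. With the
degree sequence fixed, assortativity is monotone in Σ d_u·d_v over
edges, so acceptance is the O(1) test `(d_a − d_c)(d_b − d_d) > 0`;
rewiring runs for 10×|E| proposals by default and is reproducible by
seed. Mortality nodes are the two highest-degree nodes, ties broken by
lowest id. The two hubs may be adjacent (nothing forbids it). At
n = 10^4, attachment 2, the result has assortativity ≈ −0.12 and a
power-law degree survival over more than a decade of degrees.

## Synthetic data and what the tests show

All test inputs are generated in code: networks from the generator,
lifetimes from the simulator or from inverse-CDF Gompertz sampling,
renewal superpositions from the poissonisation module. These emulate the
*model's* world — homogeneous rate parameters, a single connected
network per cohort, no secular trends, no measurement error, no
censoring. Passing tests therefore validate internal consistency
(simulator vs matrix-exponential oracle on tiny networks, ODE vs closed
forms, estimator vs known-hazard cohorts), not agreement with empirical
mortality tables; an external age/rate CSV can be fitted through the CLI
for that purpose.

Problem sizes were chosen to keep the full suite in the tens of seconds
on one CPU: the matrix-exponential cross-check uses the 2-node network
with 10^4 lifetimes (KS < 0.02); the cohort-level checks use an
n = 2000 network with 5×10^3 lifetimes, which suffices to pin the
log-hazard slope to a few percent.

## Known limitations

- The mean-field rate step replaces E[e^{r+·p̂}] by e^{r+·E p̂}; by
  Jensen's inequality this *undershoots* the true rates, so simulated
  hazards rise faster with age than the mean-field curve (simulated
  log-hazard slope ≈ 0.12 on the generated networks vs 0.059 mean-field
  over [40, 80] years, reference parameters). The gap size depends on
  the network topology, which the generator fixes only up to its two
  structural properties.
- The [40, 100]-year Gompertz window reaches into the regime where the
  mean-field damage fraction saturates and the hazard blows up
  (m(100) ≈ 33/yr); fits including those ages are dominated by the
  upturn and are reported for diagnosis, not as a mortality model.
- Frailty nodes (highly connected aging nodes) and the frailty index are
  out of scope: the mean-field step treats all nodes identically.
- No error bounds on the mean-field and homogeneity approximations are
  computed; the bounds module sandwiches the *approximate* rate, not the
  exact network hazard.
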