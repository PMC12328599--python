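# agingnet

Why does the mortality rate of adult humans grow exponentially with age
— Gompertz's law, `m(t) ≈ α·e^{βt}` — while damage at the molecular
level accumulates only linearly? `agingnet` implements a network answer
to that question, for researchers in biodemography and the mathematics
of aging.

Health is modelled as a graph of `n` binary indicators (healthy/damaged).
A node with a fraction `f` of damaged neighbours gets damaged at rate
`Γ0·e^{r+f}` and recovers at rate `(Γ0/R)·e^{−r−f}`; death is the first
time the two most connected hubs (the *mortality nodes*) are both
damaged. The package provides:

- **`network`** — scale-free, disassortative health-network generation
  (preferential attachment + assortativity-decreasing rewiring);
- **`dynamics`** — exact Gillespie simulation of lifetimes and
  damage-fraction trajectories (numba Fenwick-tree kernel, ~10^3
  lifetimes/s at n = 2000);
- **`meanfield`** — the two-ODE mean-field reduction for the damage
  fraction `p*(s)` and pre-death occupancy `χ*(s)` on the scaled time
  `s = Γ0·t`, the approximate mortality rate
  `m(t) = Γ0·e^{r+·p}·χ`, its fixed points, and the expected damage
  fraction at death;
- **`gompertz`** — occurrence/exposure hazard estimation from lifetimes
  and log-linear (α, β, R², MSE) window fits;
- **`bounds`** — closed-form lower/upper envelopes of the hazard and the
  explicit approximations `β ≈ r+Γ0`, `40Γ0² ≲ α ≲ 160Γ0²`;
- **`poissonisation`** — an empirical demonstration that merging many
  sparse renewal processes yields a Poisson process, the rationale for
  the exponential-clock node dynamics.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

The reference calibration (`mitnitski2017` preset) is n = 10^4,
r+ = 10.27, r− = 6.5, R = 1.5, Γ0 = 0.00113/year — one unit of scaled
time is 1/Γ0 ≈ 885 years, so ages 40–100 map to s ∈ [0.045, 0.113].

```python
import agingnet as ag

params = ag.preset_rate_parameters("mitnitski2017")
sol = ag.solve_meanfield(params)
fit = ag.fit_gompertz(ag.meanfield_hazard_curve(sol), (40, 80))
print(f"alpha={fit.alpha:.3g} beta={fit.beta:.4f} R2={fit.r_squared:.2f}")
# alpha=1.97e-05 beta=0.0593 R2=0.99

print(ag.damage_fraction_at_death(params, sol).value)
# 0.6484022362701894
```

The fit says the mean-field model follows Gompertz's law over ages
40–80 with baseline mortality α ≈ 2×10⁻⁵/yr and rate of aging
β ≈ 0.059/yr (ln m(t) ≈ −10.83 + 0.059·t); the second number says that
at death roughly two thirds of the health indicators are damaged. The
same table over widening windows, from the CLI:

```
$ agingnet gompertz-table
t-interval             alpha      beta   R-squared     MSE
[40, 80] years      1.97e-05    0.0593        0.99    0.00
[40, 85] years      1.61e-05    0.0631        0.99    0.01
[40, 90] years      1.18e-05    0.0687        0.97    0.03
[40, 95] years      6.68e-06    0.0785        0.93    0.11
[40, 100] years     6.21e-07    0.1187        0.66    2.23
```

Widening the window trades α down for β up while the fit quality decays:
the log-hazard is genuinely linear only away from the high-age upturn,
so the Gompertz law emerges as a good mid-life approximation rather than
an exact consequence of the model.

Full stochastic pipeline (generate a network, simulate a cohort, fit its
empirical hazard):

```sh
agingnet network --n 2000 --attachment 2 --seed 1 --out net.edges
agingnet simulate --network net.edges --samples 5000 --seed 1 --out cohort.csv
```

Simulated cohorts show a *steeper* log-hazard slope (≈ 0.12 over
[40, 80] at these sizes) than the mean-field curve — the mean-field rate
approximation undershoots by Jensen's inequality; see
`docs/methods.md`.

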