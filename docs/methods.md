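# Methods

## Model

`agepop` simulates a population as a dynamic collection of strata
(age-development groups). A stratum is the set of individuals sharing the
integer counters `(age, devcycle, development)`; its size is an integer in
stochastic mode and a non-negative real in deterministic mode. Two
processes act each step: survival, evaluated at the age counter, and
development, evaluated at the development counter. The working assumptions
are (i) event probabilities are constant within one step, and (ii)
individuals with identical counters are exchangeable, so the number of
events per stratum is binomial.

For a stratum of `n` individuals with death hazard `q` and development
hazard `g`:

* stochastic: `dead ~ Binom(n, q)`, then `completing ~ Binom(n − dead, g)`;
* deterministic: `dead = n·q`, `completing = (n − dead)·g`.

Death is applied before development, so an individual cannot both die and
complete development within a step; the survivor fraction is the base for
development. The original formulation only states that an individual
remains when neither event occurs, without fixing the order; our choice is
asserted explicitly by the unit tests (`dead = n·q`, `developed =
n·(1−q)·g`) so the convention is visible rather than implicit. Survivors
advance `age` and `development` by one; completing strata are removed to
the devtable with `devcycle + 1` and `development = 0`. Under
`pause = True` (the `perturb` operation) all counters of both survivors
and devtable entries are frozen — the semantics used for instantaneous
interventions and migration. Because hazards never depend on stratum
*sizes*, expectations propagate exactly through the linear recursion: the
deterministic run equals the pointwise mean of the stochastic process.

Completion timing convention: a fresh stratum has counter 0 and
experiences `h(0) = (F(1) − F(0)) / (1 − F(0))` in its first step;
counters advance afterwards. Consequently a fixed duration `d` fires with
certainty during the step in which the counter is `d − 1` (post-step sizes
of a `d = 3` cohort read `n, n, 0`), and the implied step-event
distribution `pmf(τ) = Π_{s<τ}(1 − h(s))·h(τ)` has mean `d − 1` for fixed
durations and `≈ μ − ½` for gamma lifetimes. Cohort statistics in the
tests therefore assign lifetime `τ + ½` to individuals dying during
iteration `τ` (mid-interval convention).

## Lifetime families

| family | parameters | F(τ) |
|---|---|---|
| fixed probability | `p` per step | `1 − (1−p)^τ` (geometric; hazard is `p` itself) |
| fixed duration | `d` steps | step function at `d` |
| gamma | `μ, σ` | regularized lower incomplete gamma `P(k, τ/θ)`, `k = μ²/σ²`, `θ = σ²/μ` |
| negative binomial | `μ, σ` (σ² > μ) | regularized incomplete beta `I_p(r, τ+1)`, `p = μ/σ²`, `r = μ²/(σ²−μ)` |

Gamma with `σ = 0` degrades to a fixed duration of `round(μ)` steps (the
limit distribution is a point mass; special-casing avoids evaluating the
incomplete gamma at unbounded shape). The negative-binomial `r` may be
non-integer (Polya case); `σ² ≤ μ` is a hard error, never clamped. The
negative-binomial CDF has mass at 0 (`p^r`), so the implied step-event
distribution is normalised by `1 − F(0)`; the hazard-product definition
telescopes to exactly this, keeping `Σ pmf = 1` for every valid family.

Numerical guards: when the survival mass `1 − F(τ)` falls below `1e−12`
the hazard is pinned to 1, avoiding catastrophic cancellation deep in the
tail (strata then terminate cleanly instead of lingering at denormal
sizes). Hazards are clipped to `[0, 1]`. A memoization cache
(`HazardCache`) is available for scalar hazard lookups; it is transparent
(bit-identical values) and bounded, resetting wholesale on overflow. The
engine's own vectorised path groups strata by distinct `(mean, sd)` pairs
per step instead, which achieves the same economy without a persistent
table.

## Engine internals

Strata are stored as sorted arrays with the three counters packed into one
int64 (21 bits each), so merging after a step is a 1-D `np.unique` and a
scatter-add. Binomial draws are taken in key-sorted stratum order from a
single per-population generator, so a seed fully determines a trajectory.
Deterministic fractional strata are kept until they reach exactly zero; no
threshold pruning is applied by default, because silent pruning changes
totals and the long tails matter for the periodic-development scenario.
Conservation (`size_before = size_after + dead + developed`) is asserted
inside every step, exactly for integers and to 1e−9 relative for reals.

Process specifications resolve with fixed probability taking priority over
`(mean, sd)`; `sd = 0` with a mean selects a fixed duration. Per-stratum
callables are evaluated once per stratum per step; callables flagged
`vectorized` receive the whole key array, which is how the cycle-dependent
survival rule of the worked example is implemented efficiently.

## Scenarios and time-step scaling

A `Scenario` is day-denominated: lifetime means/SDs are multiplied by the
scaling factor `α` (steps per day) at run time, per-day probabilities are
converted via `1 − (1−p)^(1/α)`, and a day-denominated horizon runs
`round(horizon·α)` steps. `α = 1` gives daily and `α = 24` hourly
iterations. Because the discretisation is first-order, the total number of
completions over a fixed horizon deviates from a fine-grid reference
approximately linearly in the step size; the acceptance suite measures
this on a scenario with development 10 ± 2 d and lifetime 50 ± 10 d over
50 days across `α ∈ {1, 2, 4, 24}` (slope positive, R² ≈ 1).

## Case studies and what they do (not) show

All case-study inputs are synthetic, generated by the builders at run
time; parameter defaults live in `data/case_params.yaml`.

**Worked example** — 1000 individuals, hourly steps, development gamma
50 ± 10 h repeated via devtable reintroduction, survival gamma with mean
`max(240, 480 − 48·t_π)` h and SD = mean/10. The deterministic run
completes ≥ 5 development cycles within 20 days and crosses below one
individual on day 14.

**Blowflies** — five stages (egg 0.6 d, larva 5.0 d, pupa 5.9 d, immature
adult 4.1 d, mature adult) with strict durations, adult mortality
0.27 /d, and per-capita fecundity `8.5·exp(−A/600)` eggs/adult/d; 2.4-hour
steps (α = 10, the coarsest grid on which all stage durations are integer
step counts). This is the published parameterisation of the classic
delayed-recruitment blowfly model; the simulation-script fixture it was
meant to be copied from was not obtainable, so the file is a labelled
synthetic reconstruction. The model produces sustained quasi-cycles of
period ≈ 37 d whose major peaks carry a secondary sub-peak; note that a
raw local-maximum count therefore roughly doubles a visual count of the
major oscillation humps. Stochastic replicates conserve the peak count
while amplitudes fluctuate.

**Nicholson–Bailey / Hastings** — discrete generations; parasitoids attack
juveniles with escape probability `exp(−aP)`; parasitised juveniles become
next generation's parasitoids. Without age structure (all hosts juvenile
and semelparous) the loop collapses to the classical map
`H' = RH·e^{−aP}`, `P' = H(1 − e^{−aP})`, verified against the algebraic
oracle to machine precision; its oscillations diverge. With an adult class
surviving at 0.8 per generation the dynamics stabilise; replacing fixed
survival by a gamma lifetime of mean 10 generations destabilises them
again as the SD shrinks toward a strict age limit (SD 5 → 2.5 → 1.25).
These defaults were chosen to sit inside the qualitative regimes the
source models establish, not fitted to any data.

**SIR** — susceptible depletion by `S·(1 − e^{−βI/α})` per step with
`β = 5.85e−4` per infectious individual per day and an Eyam-plague-scale
population (S₀ = 254, I₀ = 7); the infectious pool is an engine population
whose "development" is removal. With `σ = μ` the gamma exit hazard is
constant and the trajectory reproduces the classical difference-equation
SIR to < 1e−9 absolute; with `σ = 0` the outbreak resolves roughly twice
as fast. Fitting the historical outbreak data is out of scope.

Passing these tests shows the engine reproduces the structural behaviour
of well-understood models under synthetic conditions; it says nothing
about the fidelity of any particular field parameterisation, nor about
processes the generator omits (environmental forcing, density dependence
inside the engine, individual covariates beyond the three counters).

## Statistical test design

Monte-Carlo comparisons use fixed seeds and pre-registered bands:
deterministic vs stochastic-mean on the worked example uses 500 replicates
and a pointwise 3 SE band with a `sqrt(det/n_rep)` floor for steps where
every replicate is extinct (the sample SE is degenerate there); the
blowfly and SIR mean-level comparisons add a 5% / 2% allowance because
those dynamics are nonlinear and the deterministic model is only the
large-population limit. The binomial sampling check uses 10⁴ single-step
replicates against a decile chi-square at p > 1e−4. Cohort lifetime
recovery uses 10⁴ individuals (μ within 2%, σ within 5%).

## Known limitations

* Hazards are first-order within a step; accuracy at coarse steps degrades
  linearly (use α to refine).
* One development process per population; multi-process life cycles are
  composed from several populations, as in the blowfly builder.
* Counters are capped at 2²¹ − 1 steps by the packed key layout.
* Deterministic long runs accumulate strata with denormal-scale sizes
  (no default pruning); extremely long horizons may want the prune
  threshold raised.
* The accumulative degree-day development variant and continuous-time
  limits are not implemented.
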