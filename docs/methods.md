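# Methods

## Model

The process is a decomposable continuous-time multi-type branching
process on a consecutive mutation chain `1 → 2 → … → n`.  A type-`i`
cell divides at rate `α_i`, dies at rate `β_i`, and mutates into type
`i+1` at rate `ν_i` (the last type cannot mutate, `ν_n = 0`); cells act
independently and waiting times are exponential.  The *critical* family,
`α_i = β_i + ν_i` for every `i`, models populations at a limiting
mutation rate: each type's appearance and disappearance rates balance,
so every sub-population — and hence the whole system — dies out with
probability one, even though the mean total size never decreases.

Two named parameterisations recur.  The **simple chain** sets
`α_i = ν_i = 1, β_i = 0` for `i < n` and `α_n = β_n = 1`: pure
birth-mutation until the lethal (`n`-th) mutation.  The **constant-ν
family** keeps `α_i = 1` and gives every type the same mutation rate
`ν ∈ (0, 1]` and death rate `1 − ν`; it is the setting for the arrival
results.  With division rate 1, one time unit is one expected cell
division and is read as a *generation*; this is a documented convention,
not an enforced one.  Non-critical rate vectors are accepted with a
validation warning — the simulator runs any rates, but every closed
form and asymptotic in the package assumes criticality.

Types are labelled `1..n` in all public interfaces and reports; the
internal arrays are 0-based.

## Exact solutions

The chain is decomposable: the sub-process started from a type-`i+1`
cell is the `(n−1)`-type chain with labels shifted.  This index-shift
identity closes the backward Kolmogorov equations from the last type
downwards and is exploited everywhere (it is also asserted structurally
in the tests).

For one type the generating function is rational in `t`, giving
`P_0(t) = t/(1+t)`, a geometric law conditioned on survival, survival
`1/(1+t)`, and conserved mean 1.  With unbounded types the total
population is a rate-one Yule process (`E Z(t) = e^t`).  For two types
the backward equation for `1 − Z` is a Riccati equation in the variable
`τ = sqrt(t + (1−x₂)^{-1})`; linearising yields the modified Bessel
equation, so

    Z_{1,2} = 1 − (1/τ) · (I₀(2τ) − c K₀(2τ)) / (I₁(2τ) + c K₁(2τ)),

with the amplitude `c` fixed by the `t = 0` condition.  At
`x₁ = x₂ = 0` this gives the survival probability with
`c = (I₀(2) − I₁(2)) / (K₀(2) + K₁(2))`; the constant is evaluated once
in 40-digit arithmetic and cached, never hard-coded.

**Numerical evaluation.**  Naive Bessel evaluation overflows near
`t ≈ 700`.  All ratios are computed with exponentially scaled `I` and
`K` (`scipy.special.ive/kve`); the scalings cancel algebraically, and
the combined factor multiplying the `K` branch,
`exp(2τ₀ + 2 Re τ₀ − 2τ − 2 Re τ)`, has modulus ≤ 1 for every `t ≥ 0`
and `x₂` in the unit disk, so the formula is stable from `t = 0` to at
least `10^8` and arbitrarily close to the singular point `x₂ = 1`
(`x₂ = 1` itself raises).  The principal branch of the complex square
root is used; for `|x₂| ≤ r < 1` the argument stays off the branch cut.
An arbitrary-precision path (`precision=<digits>`, via mpmath) is
available for coefficient-extraction contexts where the cancellation
between the `I` and `K` branches matters.

## ODE systems

Three quadratically coupled families are integrated for arbitrary `n`:

* survival `dS_i/dt = S_{i+1} − S_i²`, `S_n' = −S_n²`, `S_i(0) = 1`;
* last-type presence: same right-hand side, `Q_i(0) = 0` for `i < n`,
  `Q_n(0) = 1` (the zero initial condition for *all* `i < n` is forced
  by the absence of type-`n` cells at `t = 0`);
* arrival `dg_i/dt = −g_i² + ν g_{i+1}`, `g_i(0) = 0`, `g_n ≡ 1`.  The
  system is integrated in `g` rather than its complement `h = 1 − g`
  because the `g` form is autonomous-quadratic and better conditioned
  near the defective limit `g(∞) = ν^{1−χ_n} < 1`; `h` is returned as
  `1 − g`.

The integrator is LSODA with defaults `rtol = 1e-10`, `atol = 1e-12`.
Direct integration in `t` was measured against the Bessel solution:
maximum absolute error 7e-12 over `[0, 10^4]` and stable exponent
recovery to `t = 10^7`, so no change of time variable is needed at the
horizons the package targets.  The state is never clipped; values are
clipped to `[0, 1]` only in the reporting accessor, so convergence
diagnostics stay honest.

Quantities with astronomically remote horizons (e.g. the 10% survival
crossing for `n = 8` sits near `10^{128}` generations) are outside any
ODE solve; the inverse problem offers an explicit expansion-based route
(below) for that regime.

## Generating-function inversion

Mass functions are extracted from generating functions by Cauchy's
formula discretised on a circle of radius `r < 1` (the two-type
generating function is singular at `x₂ = 1`), i.e. an FFT of contour
samples; the joint two-variable case nests the construction per axis.
Two error sources are controlled explicitly and drive the defaults
(`r = 0.99`, `N = 8·s_max`):

* **aliasing** adds `Σ_m P_{s+mN} r^{mN}`; `N` is kept a multiple of
  the truncation so `r^N` times the unresolved tail mass is negligible
  (heavy-tailed cases at large `t` need larger `N`, as the tests note);
* **amplification** multiplies contour round-off by `r^{-s}`, bounding
  the usable truncation at about `15.65/|log10 r|`; requests beyond the
  bound raise, and an arbitrary-precision contour mode lifts it for
  deep-tail work.

Negative extracted values larger than `−1e-12` are zeroed as round-off;
anything worse raises a quality error rather than being clipped
silently, as does an imaginary residue above tolerance or total mass
exceeding 1 by more than `1e-6`.  The reported normalization deficit is
exactly `1 − Σ values` (the unresolved tail mass).

## Asymptotics

The exponent family `χ_n = 2^{1−n}` governs every large-time law (the
survival-tail exponent sometimes written with a separate symbol is the
same family; one function is exported).  Matched-asymptotics expansions
are provided with the printed coefficients: two terms
`(1+t)^{-χ_n} + (χ_n/2)(1+t)^{-1/2-χ_n}` for any `n ≥ 2`, three terms
(`+ (3/32)(1+t)^{-3/2}`) for the next-to-last starter, and the
gap-`j` form `(1+t)^{-χ_{j+1}} + 2^{-j-1}(1+t)^{-1/2-χ_{j+1}}`.

The conditioned last-type scaling density is
`f(y) = χ_n F(1+χ_n; 2; −y)` with Laplace transform
`1 − (p/(p+1))^{χ_n}`.  Evaluation switches to the algebraic
large-argument branch of the Kummer function at `|y| = 50` (18 series
terms, truncation below `1e-13` at the switch; both sides verified
against arbitrary-precision evaluation).

The mass-function tail `χ_n/Γ(1−χ_n) s^{−1−χ_n}` is stationary inside
the window `t ≪ s ≪ s_*` with cutoff `s_* ∝ t^{(n−1)/(1−χ_n)}` (the
cutoff restores the finite mean `t^{n−1}`; only the proportionality is
defined, and the package reports it as such).  The "much less than"
margins are operationalised as factors of 5 on both sides, exposed as
flags — the theory fixes no constants.  The window is genuinely narrow
at small `t`: for `n = 2` it is empty below `t = 125` under the default
margins, and fits of the tail exponent are meaningful only inside it;
the package's own validity window is what the tail-facing tests use.
Measured at `t = 50..400`, the fitted slope inside the window converges
to `−3/2` from below (−1.55 at `t = 50`) and the pmf sits ~10% above
the stationary prefactor at `s = 10t`.

The arrival scaling `g_{1,n}(t) ≈ ν^{1−χ_n} tanh(ν^{1−χ_n} t)` is exact
for `n = 2` and the `ν → 0` limit otherwise; the sup-distance to the
solved system decreases monotonically with `ν` (measured 0.18 → 0.11 →
0.066 for `ν = 10^{-2..-4}`, `n = 3`).

## Simulator

Exact SSA (direct method) only — no tau-leaping: criticality keeps
populations desk-scale over the horizons of interest and exactness is
the point.  The RNG is numpy's PCG64; replicate `r` of an ensemble
draws its own `SeedSequence((seed, r))` substream, so ensembles are
reproducible, order-independent and parallelizable, and a fixed seed
yields an identical trajectory on any platform.  Uniforms are consumed
from a buffered stream (4096 per draw call) purely for speed; the draw
sequence is part of the pinned behaviour.

Grid recording stores the state *left-continuous* at each grid time
(the state just before any event falling exactly on a grid point).
Arrival times `T_k` are recorded exactly at the generating mutation
event; extinction times `E_k` are the last transition of `Z_k` to zero,
reported as censored when the run ends at `t_max` with the type — or
any earlier type that could reseed it — still alive.  Censored values
are excluded from extinction-time means and included in survival
curves.  Safety caps (default `10^8` events, `10^7` cells) raise a
distinguishable error carrying the partial trajectory rather than
truncating silently; they exist because critical processes have
infinite-mean extinction times.  A run can also stop at the arrival of
a chosen type, which makes arrival-time sampling O(arrival) instead of
O(whole excursion).

Ensemble estimators: survival curves carry 95% Wilson half-widths
(computed in closed form); mean counts average over all replicates,
extinct ones contributing zeros, so the conserved type-1 mean is
estimated without conditioning bias.

## Diversity applications

Shannon diversity `H'(t) = −Σ p_i log p_i` uses natural log by default
(base is a flag), `0·log 0 = 0`, and is recorded as missing when the
population is extinct.  Ensemble curves report the mean over surviving
replicates — a conditioning choice, documented here, matching the
per-run character of diversity traces.  The expected number of types
`K_n(t) = Σ_{i≤n} Q_{1,i}(t)` uses decomposability (the presence
probability of type `i` in the `n`-chain equals the last-type presence
probability of the `i`-chain) with `Q_{1,1} = 1/(1+t)`.

`generations_to_survival` returns the root of the exact (`n ≤ 2`) or
ODE (`n ≥ 3`) survival; the expansion value is available as a labelled
alternative, and is the only route when the crossing lies beyond any
integrable horizon (small `χ_n`, small target probability), where its
error is negligible anyway.  `expected_colony_size` evaluates
`Σ_{i≤n} t^{i−1}/(i−1)!` as `e^t Γ(n, t)/Γ(n)` (regularised incomplete
gamma) for stability at large `n` and `t`.

## What the synthetic ensembles do and do not show

There is no external data: the stochastic ensembles generated by the
simulator *are* the study system, and the simple-chain defaults (unit
rates, one initial type-1 cell) are the study conditions.  Monte-Carlo
checks are run at desk scale — `10^5` replicates for the single-type
conservation and arrival-time checks, `10^3`–`10^4` elsewhere, horizons
`t ≤ 50` for multi-type ensembles because SSA cost grows with the
time-integrated population (`∝ t^n`).  Deterministic routes (Bessel,
ODE, FFT) are tested to `10^{-8}`–`10^{-12}`; stochastic routes to 3–4
standard errors or Wilson half-widths.  Passing tests therefore
validate the mathematical machinery and its internal consistency; they
say nothing about whether a real population's division/death/mutation
rates are balanced, independent, or constant in time — the model's
substantive assumptions.

## Known limitations

* No closed forms exist for `n ≥ 3`; those chains rely on the ODE and
  simulation routes (cross-checked against each other and against the
  asymptotics).
* The arrival ODE family assumes the constant-ν critical
  parameterisation; fully heterogeneous per-type rates are supported by
  the simulator only.
* Mutation graphs other than the consecutive chain, spatial structure,
  carrying capacity, and selection between co-resident types are out of
  scope.
* The exact solver for the third-type arrival law (a hypergeometric
  combination) is not implemented; the ODE route covers it.
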