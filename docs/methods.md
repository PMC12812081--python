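# Methods

This note records the model as implemented, the tunable parameters, the
numerical choices, and what the test battery does and does not establish.

## Model and assumptions

The state `N(t)` counts naïve T cell *clones* (distinct receptor
specificities) in the periphery, not cells; peripheral proliferation changes
cell numbers but not diversity, so it is absent from the model. Clones decay
at rate `u` and are replenished by thymic production `h(t)`:
`dN/dt = h − uN`. Pathogen strain `i` is met as a Poisson process with rate
`f_i`, independently across strains and hosts; memory is perfect and
lifelong, so only the first encounter with a strain requires a naïve
response, at cost `K/N` (the simplest form in which repertoire diversity
speeds detection). Maintenance of thymic output costs `m·h`. The fitness of a
production schedule over a life span `T` is
`phi = C − ∫₀ᵀ (K n g(t)/N + m h) dt` with `g(t) = E[f e^{-f t}]`.

Assumptions worth keeping in mind: encounter processes are stationary (no
epidemics, no age-dependent exposure), the fighting cost ignores
within-infection dynamics, `u` is constant (no density-dependent decay), and
fitness is additive in cost with no discounting.

## Parameters

| symbol | meaning | units | typical value here |
|---|---|---|---|
| `n` | strains met over a lifetime | count | 1000 |
| `f̄` | mean encounter rate per strain | 1/age | 0.05–0.5 |
| `a`, `b` | Gamma shape and rate of the rate distribution (`f̄ = a/b`, `var/mean² = 1/a`) | — , age | (100, 1000), (10, 100), (1, 10) |
| `K` | fighting-cost magnitude | cost | 0.001–10 |
| `m` | maintenance cost per unit production | cost·age | 1 |
| `u` | peripheral clone decay rate | 1/age | user-supplied; demos pin 1 |
| `h_max` | production cap | clones/age | 3 (three-phase demo), 0.1 (two-phase demo) |
| `T` | life span | age | 10 |
| `C` | baseline fitness | cost | 0 |

The quasi-static schedule depends on `K`, `m`, `u`, `n` only through
`K·u·n/m`; the quasi-static presets realize the demonstration value `1e4` as
`K=10, m=1, u=1, n=1000` and record that choice in their manifests. The
dynamic presets deliberately have **no default `u`**: the phase structure
depends qualitatively on it (see below), and no principled default exists, so
it must be supplied. The demonstration problems and regression fixtures pin
`u = 1`, an implementation choice recorded in the manifests; conclusions that
depend on `u` should be treated as qualitative.

The Gamma law is parametrized shape–rate (density ∝ `f^{a−1} e^{−bf}`), so
`f̄ = a/b`; the three Gamma presets named `fig3a/b/c` share `f̄ = 0.1` and
differ tenfold in `var/mean² = 1/a`. (One scenario table elsewhere renders the
mean as `b/a`; with `a = 100, b = 1000` only `a/b` gives 0.1, and the package
uses `a/b` throughout.)

## Initial-state regularization

The prescribed initial condition `N(0) = 0` makes `∫ K n g/N dt` diverge for
every schedule with finite production near birth, so fitness comparisons are
made from a small regularizing clone count `N0`, identical for every compared
schedule; the default is `1e-6 ×` the singular-arc clone count at birth.
Rankings of schedules are insensitive to `N0` in this regime, but absolute
fitness values contain an `N0`-dependent (logarithmic) offset and should not
be interpreted on their own.

One consequence matters for Monte Carlo work: with a vanishing `N0` the
realized fighting cost is heavy-tailed — a host unlucky enough to meet a
strain just after birth pays `K/N0` — and the sample mean over hosts
under-covers the deterministic integral at any practical sample size, with an
unusable standard-error estimate. Monte Carlo validation therefore uses a
mild explicit `N0 = 0.05` (about 10% of the arc value at birth for the
demonstration parameters), again identically for every compared schedule.
This changes what is being validated only in that the comparison targets a
problem whose estimator has finite variance.

## Constructing the candidate schedule

* **Singular arc.** Stationarity of the costate (`λ ≡ m`) gives
  `K n g(t)/N² = u m`, i.e. `N*(t) = sqrt(K n g(t)/(u m))` — the quasi-static
  optimum — for *any* rate distribution; the sustaining control is
  `h* = dN*/dt + u N*`, closed-form for degenerate/Gamma models and via the
  derivative of `log g` (exact for those kinds, central differences at step
  `1e-6·(1+t)` otherwise). The arc is admissible only where `0 ≤ h* ≤ h_max`;
  for a common rate this is `u > f̄/2`, below which all production is
  concentrated at the start of life.
* **t1** solves `N_bang(t) = N*(t)` with `N_bang` the exact max-rate
  trajectory from `N0`, bracketed on a 1000-point scan and refined by Brent's
  method (`xtol 1e-14`).
* **t2**: integrating the costate backward from `λ(T) = 0` through a final
  phase with `h = 0` gives, for a common rate, the closed form
  `T − t2 = log(2 − f̄/u)/(u − f̄)` (computed via `log1p` with the removable
  limit `1/u` at `u = f̄`); for other models the same construction is solved
  numerically: the linear costate equation reduces `λ(t2)` to the quadrature
  `(u m/g(t2)) ∫_{t2}^{T} g(s) e^{u(s−t2)} ds`, and `λ(t2) = m` is root-found.
* **Two-phase fallback.** If `t1 ≥ t2`, the arc is inadmissible, or the
  max-rate trajectory never reaches it, the candidate is bang-bang with `t3`
  the root of the self-consistent switching condition `λ(t3) = m` (same
  quadrature form with the bang-bang state), cross-checkable against a 1-D
  fitness scan. Degenerate horizons produce single-phase schedules with a
  warning.
* **Trajectories.** State closed forms are used segment-wise; on singular
  segments the singular *rule* is applied from the actual entry state (the
  arc plus an `e^{-u(t−a)}` deviation term), so perturbed switch times remain
  well-defined. The costate is reconstructed backward with exact per-panel
  integrating factors and 5-point Gauss–Legendre panel integrals, stable for
  any `u·T`. Output grids contain every phase boundary exactly and refine
  geometrically (240 points over 12 decades) toward `t = 0`, where the
  regularized `1/N` spike lives.

## Certificate

`pmp_certificate` checks: `λ > m ⟺ h = h_max` and `λ < m ⟺ h = 0` (slack
`1e-6·m`), `|λ − m|/m < 1e-4` on singular segments, `λ(T) = 0`, and the
generalized Legendre–Clebsch sign condition, evaluated numerically as the
finite-difference sensitivity `∂/∂h [d²(λ − m)/dt²] ≥ 0` along the arc (for
this model it equals `2Kng/N³ > 0`). It reports violation magnitudes rather
than raising, so deliberately wrong schedules can be inspected.

## Direct optimizer

Fitness over piecewise-constant controls is evaluated on a fixed quadrature:
each of the (default 200) intervals is split into 24 geometric sub-pieces
refined toward its left edge with a 4-point Gauss–Legendre rule per piece, so
post-jump `1/N` transients are resolved; node ages and `g` values are
precomputed once per breakpoint set. The gradient uses the adjoint identity
`∂phi/∂h_k = ∫_{I_k} (λ − m) dt`, with `λ` at interval edges from exact
integrating factors and the interval integral reduced analytically to
`(λ(B_k) − λ(A_k) + ∫_{I_k} Q dt)/u − m·L_k` (where `Q = K n g/N²`); adjoint
and finite-difference gradients agree to ~1e-8 relative. Ascent is
bound-constrained L-BFGS-B from one warm start (the clipped quasi-static
schedule) plus 7 random level vectors by default; per-iteration fitness is
recorded and is monotone. On the demonstration problems the optimum matches
the analytic candidate's fitness to ~1e-6 relative — far inside the 1e-3
agreement the tests require.

## Monte Carlo simulator

Per host, first-encounter ages are `Exp(f_i)` draws (one per strain);
fighting costs `K/N(age)` accrue at first encounters inside `[0, T]`, with
the deterministic production cost added. For Gamma/lognormal models rates are
resampled per host by default; a `freeze_rates` flag fixes one rate vector
across hosts, matching the fixed-list reading of the strain sum — both
estimate the same expectation. The novel-fraction curve from simulated
histories estimates `E[e^{-f t}]` directly. Standard problem sizes in tests:
`1e4` hosts × `1000` strains, agreeing with deterministic integrals within
3 SE and shrinking as `hosts^{-1/2}`.

What the simulator does *not* emulate: within-infection dynamics, waning or
imperfect memory, correlated exposure across strains, and host heterogeneity
in parameters. Passing tests therefore validate the expectation structure of
the cost model, not its biological realism.

## Other numerical choices

* Lognormal `g(t)` uses 64-node Gauss–Hermite quadrature in `z = log f` with
  a node-doubling convergence check (relative tolerance `1e-8`); the
  integrand is smooth, so the rule converges spectrally.
* The continuous-distribution approximation of the finite strain sum is the
  default for `n ≥ 100`; constructing a Gamma model with fewer strains logs a
  warning recommending an explicit empirical rate list.
* Infinite-horizon lifetime production truncates where the integrand falls
  below `1e-12` of its peak (analytically located) and integrates adaptively;
  heavy-tailed cases (Gamma `a ≤ 1`) are reported as divergent rather than
  truncated, since `h ~ t^{-(a+1)/2}` is not integrable.
* Log-convexity diagnostics use second differences with a `1e-10` tolerance
  on log values to absorb floating-point noise.
* Grid-search oracles use geometric grids (`h` spans orders of magnitude).

## Known limitations

* Fitness values depend logarithmically on `N0`; only differences and
  rankings are meaningful.
* The two-phase switch for multi-root costate crossings picks the
  best-fitness root; pathological parameter sets with many crossings have not
  been characterized.
* The maximum-principle conditions checked are necessary, not sufficient; the
  direct-optimizer agreement and random-schedule dominance checks are the
  practical substitute for a proof of global optimality.
* `λ` reconstruction assumes `u·ΔT` per panel is moderate; extremely large
  `u·T` (≫ 10³) has not been exercised.
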