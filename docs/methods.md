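# Methods

## Model structure and assumptions

The model couples continuous within-season transmission dynamics to
discrete between-season maps (a semi-discrete or "hybrid" formulation).
Hosts are univoltine: each season's cohort emerges over a window `[0, tl]`,
lives at most one season, and reproduces only through the end-of-season
recruitment map.  Parasites are free-living between transmission events,
decay in the environment at rate `δ`, and are absorbed by the hosts they
infect (`−β s v` in the parasite equation).  Infection makes a host
permanently unavailable for reinfection.

The latency period τ enters as a literal time delay: the flux of new
recoveries/infectious hosts/released parasites at time `t` is proportional
to the infection flux `β s(t−τ) v(t−τ)`, discounted by the probability of
surviving latency.  Hosts that die of background mortality during latency
release nothing.  Because hosts do not exist before the season starts, the
pre-season history is identically zero and delayed terms vanish for
`t < τ`; nothing released after `t = T` counts.

Two release modes share this skeleton:

* **semelparous** — all `α(τ)` progeny appear at a single delay τ after
  infection; the host then moves to the recovered class.  The survival
  discount on the release term is `e^(−μs τ)` and on the recovered-class
  recruitment `e^(−μi τ)`, exactly as the within-season systems are
  defined; both exponents can be overridden independently
  (`latency_survival_rate`, `recovery_survival_rate`) for sensitivity
  analyses.
* **iteroparous** — the host enters an infectious class at delay τ
  (survival `e^(−μs τ)`) and releases at rate `α(τ)` until recovery at
  rate `γ`.

Between seasons, recruitment is Beverton–Holt:
`ŝ(n+1) = σ (s(T) + ϕ i(T) + ϕ r(T)) / (1 + ρ (s(T) + i(T) + r(T)))`, with
the `i` terms present only in the iteroparous model (the semelparous model
tracks no infectious class, and hosts still latent at `t = T` appear in
neither the fecundity nor the crowding term).  A fixed-cohort mode
(`ŝ = 10^7` every season) is available for decoupling parasite dynamics
from host demography.

## Parameter defaults

| parameter | meaning | default |
|---|---|---|
| `T` | season length | 4 |
| `tl` | host emergence window | 1 |
| `beta` | transmission rate | 1e-7 |
| `delta` | environmental decay of free parasites | 1 |
| `mu_s`, `mu_i`, `mu_r` | host death rates | 0.25 |
| `gamma` | recovery rate (iteroparous) | 3 |
| `sigma` | host fecundity | 200 |
| `rho` | density dependence | 1e-4 |
| `phi` | fecundity retention of ever-infected hosts | 0.5 |
| `b` | trade-off scale | 75 (semel) / 200 (itero) |
| `alpha_const` | progeny number, trade-off disabled | 200 (semel) / 400 (itero) |

Time units are unspecified by design (weeks or months depending on the
system); densities are absolute counts.

Two defaults deserve comment because the source parameterization admits
either of two values and the package had to commit:

* **ϕ = 0.5.**  With ϕ = 1 (no fecundity cost) the selection gradient of
  the baseline semelparous model has a near-zero local maximum around
  τ ≈ 1.2–1.3 but never crosses zero — the system sits just below the fold
  at which the shorter ESS/repellor pair is born, so only the longer ESS
  exists.  With ϕ = 0.5 the full bistable structure (ESS 1.314, repellor
  1.914, ESS 2.802) is present.  This is step-size-converged, not a
  numerical artifact (identical gradients at h = 1e-3, 5e-4 and 2.5e-4).
* **Beverton–Holt demography.**  With a fixed cohort ŝ = 10^7 the
  structure is qualitatively different (single interior ESS ≈ 2.97,
  repellor ≈ 1.21, lower boundary attractor); the coupled-demography model
  is the default and is what all scenario presets use.

## Numerical integration

The within-season systems are delay differential equations whose only
delayed quantity is the infection flux `P(t) = s(t) v(t)`.  Because the
history is zero before the season, the method of steps collapses to one
forward sweep: a fixed-step classical RK4 pass in which delayed fluxes are
read back from the already-computed solution grid.  Each strain's delay is
snapped to the nearest whole number of steps (default step 1e-3 time
units, so the effective latency is within 5e-4 of the requested value);
half-step stage lookups interpolate the stored flux linearly.  The
emergence density's discontinuity at `t = tl` is sampled with half weight
exactly on the edge, which keeps the disease-free season solution accurate
to ~1e-13 relative against its closed form.

Accuracy checks (all in the test suite): halving the step changes `v(T)`
by far less than 0.1%; an independent explicit-Euler re-integration at
step 1e-4 agrees to 0.5%; an external DDE solver (R deSolve's `dede`)
agrees to ~1e-4 relative on an iteroparous season.  States dipping below
−1e-9 (relative) abort with a diagnostic error; smaller dips are clamped
to zero as solver noise.

Ecological equilibration iterates seasons until the relative change of the
host cohort and every surviving strain density stays below 1e-8 for 10
consecutive seasons (cap 2,000 seasons; baseline residents converge in
tens of seasons).  Strains below density 1 at a season boundary are
extinct and removed.

## Invasion analysis

Invasion fitness is the raw end-of-season mutant density from a unit
introduction against the frozen resident attractor — not a log growth
rate — and the invasion threshold is 1.  A mutant at density 1 against a
resident at ~10^7 is dynamically negligible, so no explicit linearization
is needed; the diagonal of every pairwise invasibility plot is neutral to
~1e-8, a direct readout of the equilibration residual.

The selection gradient at `τ_r` is the sign of
`f(τ_r, τ_r+ε) − f(τ_r, τ_r−ε)` with ε = 0.01.  Selection near the
singular points of this model is weak (|f−1| ~ 1e-4), so the neutrality
band that maps gradient values to "zero" is set at 1e-6 — two orders
above the numerical noise floor, three below the genuine signal.  Singular
strategies are located by bisecting coarse-grid sign changes to 5e-3 in τ
(the reported values carry 3 significant figures) and classified from the
local geometry: a +→− crossing that is locally uninvasible (mutants at
τ* ± {0.02, 0.05, 0.1} all have fitness < 1) is an ESS attractor; a −→+
crossing is a repellor.  A negative gradient at the lowest viable grid
point is reported as a lower-boundary attractor (this is how the
trade-off-free model's shorter optimum appears).  Residents whose
attractor is a cycle rather than a fixed point make the invasion analysis
refuse; evolutionary questions in cycling regimes belong to the
simulation.

## Evolutionary simulation

The trait-substitution protocol: burn in a monomorphic resident for 100
seasons; introduce a single mutant at density 1 at a season start, its τ
drawn from a normal kernel (sd 0.1, truncated to `(0, T]` by redrawing)
centred on the currently densest strain (ties break toward the newest
strain — a probability-zero event handled only for determinism); repeat
every 1,000 seasons (optional uniform jitter, off by default); remove
strains below density 1 at season boundaries.  Mutants may arrive before
earlier ones have fixed, so the community is transiently polymorphic.  The
kernel sd of 0.1 is small relative to the ≈1.5 gap between the two ESS, so
basins of attraction are respected.  With 25 introductions, seeded runs
from either basin finish within 0.1 of the ESS the invasion analysis
predicts for that basin — the two routes cross-validate.

## Competition and attractor classification

"Which ESS outcompetes the other" is decided dynamically: both strains
start at equal density (10^3) with the host at its disease-free attractor
and seasons are iterated.  The semelparous ESS pair resolves by genuine
competitive exclusion (the longer-latency strain survives, ~550 seasons).
The iteroparous pair instead converges to a stable two-strain fixed point
(the two strategies are mutually invasible); the run detects the interior
equilibrium, stops, and reports the strain holding the higher equilibrium
density as dominant — the shorter-latency strain.  Exclusion and
density-dominance are distinguished in the returned `outcome` field.

Long-run ecological attractors are classified from the post-burn-in
start-of-season parasite series (seasons 400–500 in the presets): relative
fluctuation below 1e-3 is a fixed point; otherwise the dominant
autocorrelation lag ≥ 2 gives a candidate period, accepted as a cycle only
if shifting by that period reproduces the series to 20%; anything else is
non-converged (quasiperiodic regimes exist at high virulence).  Cycling is
latency-dependent, so the cycling preset pins each stressor to the ESS of
the basin where the contrast occurs: semelparous τ = 2.8 under high
mortality (μi = μr = 5), τ = 1.31 under strong fecundity loss (ϕ = 0.1),
with the analogous iteroparous ESS values (2.43, 0.96).  Under both
stressors the semelparous system cycles and the iteroparous one does not.

## Generation counting

An infection "generation" is a wave of new infections whose progeny are
released within the season.  The instantaneous new-infection rate is
`β s v`, but its raw local maxima overcount at long latency: at the
monocyclic ESS the final release burst triggers a late wave of infections
that can never release progeny.  Counting is therefore restricted to
infection times `t ≤ T − τ`; peaks are local maxima at least 0.1 time
units apart and above 1e-3 of the window maximum, with maxima on the
window edges counted.  At the baseline ESS pair this yields 2 generations
at τ = 1.31 and 1 at τ = 2.8.

## What the simulations do and do not show

All experiments are self-contained simulations of the model; there is no
external data.  Conclusions are statements about the model family at the
stated parameters, at the documented numerical tolerances, over the
latency range `[0.5, 3.8]` scanned by default.  Scenario sweeps run at
reduced grid resolution (6–10 points per axis) chosen to keep desk-scale
runtimes; a `full_resolution` flag densifies them.  Known limitations:
within-season host reproduction is absent; emergence is uniform only;
no analytic invasion fitness (the polycyclic case is intractable, hence
the fully numerical pipeline); no formal bifurcation or
Lyapunov analysis of the non-fixed-point regimes; coexistence/dimorphism
beyond the two-strain competition runs is out of scope.
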