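# Methods

## The model

The package models the co-evolution of the PRDM9 locus and its genomic
binding targets in a panmictic diploid Wright–Fisher population of constant
size `Ne`, non-overlapping generations. Only PRDM9 is explicit; the targets
enter through one summary per allele, the activity `θ` (fraction of targets
not yet fixed inactive). This rests on a mutation–fixation approximation at
the targets: with target mutation rate `v ~ 1e-7` and `4·Ne·v ≪ 1`, targets
are almost never polymorphic, and the genome-wide decay of activity equals
the substitution rate of inactivating mutations, `2·Ne·v` per target times
the dBGC fixation probability `2·g·x` — hence `dθ/dt = −ρ·x·θ` with
`ρ = 4·Ne·v·g`. The discrete-generation update uses the exact one-step
solution `θ ← θ·exp(−ρx)` rather than the first-order `θ·(1−ρx)`; the two
agree to `O((ρx)²)` and the exponential stays positive in extreme parameter
scans.

Genotype fitness is `f((θ_i + θ_j)/2)` (additive activities, valid for
homozygotes too), with `f(R) = R^α` or `f(R) = exp(β(R−1))`. The marginal
fitness of allele *i* is `f̄_i = Σ_j x_j f((θ_i+θ_j)/2)` (random mating,
homozygote term included at weight `x_i`), the selection coefficient is the
ratio form `s_i = f̄_i/f̄ − 1`, and `s₀` is the same quantity for a `θ = 1`
invader at vanishing frequency.

### Parameters

| parameter | meaning | default / central value |
|---|---|---|
| `Ne` | diploid effective size | 1e5 (phase scans), 1e5 (mouse) |
| `u` | functional PRDM9 mutation rate /copy/gen | 1e-6 (scans), 3e-6 (mouse fit) |
| `v` | inactivating mutation rate /target/gen | 1e-7 |
| `g` | dBGC conversion rate /het target/gen | such that `vg` = 1e-9 (scans), 3e-3 (mouse fit) |
| `α`, `β` | fitness-curvature parameter | 0.01 (scans), 1e-4 (mouse fit) |
| `a` | gamma shape of hot-spot strengths | None (uniform); 1 (mouse) |

Everything macroscopic depends on these through `ρ = 4Ne·vg`, `μ = 4Ne·u`
and `ε = ρ/μ = vg/u`.

## Simulation protocol

Each generation applies mutation → erosion → selection/drift in that order
(the stated cycle order; whether erosion precedes or follows donor removal
within a generation is immaterial at `O(u·ρ)`). Runs start monomorphic with
a fresh allele; the burn-in ends when every starting allele is extinct, and
the stationary phase then runs for `burnin_multiplier` (default 50) times
the burn-in length. Mutation donors are uniformly chosen haploid *copies*
(standard Wright–Fisher mutation semantics), so common alleles donate more
often; allele ids are never recycled. A single seeded NumPy generator drives
Poisson draw → donor choices → multinomial resampling, in that fixed order,
making every output a pure function of (config, seed).

## Mean-field solvers

Both solvers assume strong selection (deterministic trajectories) and a
stationary mean field. The **linearized** solver replaces `f` by its
log-slope `γ(R) = f′(R)/f(R)` at the mean activity `R` (evaluating γ at the
mean field rather than at `θ = 1` is the choice that reproduces the exact
invader coefficient to first order in `1 − R`; the alternative is exposed as
an option). It gives `s₀ = γ(R)(1−R)/2`, `τ = 1/(μs₀)`, and the
self-consistency `R = (1−e^{−L})/L`, `L = ρτ = ε/s₀(R)`, solved by Brent's
method on a bracket `(1e-9, 1−1e-9)` with `xtol = 1e-14` (residual at the
root `< 1e-10`; no sign change raises). The typical-allele path has the
closed form `x(θ) = x₀ + (γ/2ρ)[(1−θ) + R·ln θ]`, from which
`∫x dt = L/ρ = τ` (tiling identity) and
`∫x² dt = (γ/2ρ²)[L − (1−R∞) − L(1−R∞)/2]`, verified against adaptive
quadrature to 1e-8 relative. Diversity follows from the tiling/ergodicity
argument, `1/D = (1/τ)∫x² dt`.

The **generalized** solver closes on `s₀` with the exact fitness and
arbitrary hot-spot model. Changing variables from time to erosion dose
`y = ρ∫x dt` makes the stationary dose distribution exactly uniform on
`[0, L]` and reduces self-consistency to the scalar root problem
`L·s₀(L) = ε`, where `s₀(L)` is the exact invader coefficient against a
dose-uniform population (double Gauss–Legendre averages, 300 nodes — the
integrands are smooth, so this is effectively exact). The scaled frequency
along the trajectory is `w(y) = ∫₀^y s(y′)dy′`, which vanishes at `y = L`
automatically (`∫₀^L s dy = 0` is an identity of the closure); diversity is
`D = ρL/∫₀^L w dy` on a 4001-point dose grid. Because the fixed point
depends on parameters only through `(ε, fitness, a)`, the Ne-scaling laws
(`R, s₀, T` invariant, `τ ∝ 1/Ne`, `D ∝ Ne`) hold exactly by construction,
not just approximately.

Under gamma-distributed hot-spot strengths (mean 1, shape `a`), a strength-c
hot spot survives a dose `y` with probability `e^{−cy}`, so the active
fraction is the gamma Laplace transform `θ(y) = (1+y/a)^{−a}` and the mean
recombination rate is the strength-weighted survival
`r(y) = (1+y/a)^{−(a+1)} ≤ θ(y)`: strong hot spots die first, which is why
`H > R` for finite `a` and why the two statistics must be distinguished.
`a → ∞` recovers the uniform model (verified to 0.1% at `a = 1e6`).

### Turnover-time convention

Two renewal measures coexist. Full renewal of the allele pool takes `D`
successive invasions, `T_renew = D·τ`. The operational turnover time —
the lag at which the cross-homozygosity `CH(T)` falls to half the instant
homozygosity — is `D·τ/2` under the mean field (in the succession limit
`CH` decays linearly over one invasion interval, halving at `τ/2`; the
calibration scenarios confirm the same factor in the polymorphic regime).
Solutions report the half-decorrelation time as `T` and expose `T_renew`
alongside. The simulator-side `turnover_time` measures `CH` directly from
recorded samples and interpolates the half-crossing, returning an explicit
"undetermined" (None) when the half-point is never reached.

### Weak-erosion expansion

For `ε ≪ 1`, expanding the linearized fixed point to first order gives
`1−R = √(ε/α)`, `s₀ = √(αε)/2`, `L = 2√(ε/α)`, and — from
`∫x²dt = γL³/24ρ² + O(L⁴)` — the polymorphic diversity `D = 6μ`. These
match the full solvers to better than 1% at `ε/α = 1e-6` and break down
(>10% error) once the predicted gap `1−R` exceeds ~0.2, where an advisory
diagnostic is set.

### Known limitations

* The deterministic closure needs strong selection; a `WeakSelectionWarning`
  is emitted whenever the self-consistent `4·Ne·s₀ < 10`. Near that
  threshold the predicted `D` can be off by tens of percent.
* The mean field ignores the frequency loss of resident alleles to mutation,
  biasing predictions once `u` is not small against `s₀` (relevant when
  rescaling to small `Ne` at fixed `μ`).
* Mean-field `1/D` is a *time average* of `Σx²`; the per-sample average of
  `1/Σx²` in a stochastic trajectory sits above it by Jensen's inequality
  (~10–15% at `μ ≈ 0.4`). Comparisons between simulation and theory should
  therefore use the inverse of the time-averaged homozygosity, which is what
  the acceptance tests do.

## What the simulator runs in the test suite emulate — and what they do not

Tests run the model itself, not a surrogate of data: there is no external
data in this problem. Desk-scale runs rescale the central parameter values
to `Ne = 1e4` (simulator–theory comparison; `u = 1e-5`, `vg = 1e-8`,
`α = 0.01`, preserving `ε = 1e-3`, `μ = 0.4`, with a stationary span of 30
burn-in lengths sampled every 100 generations) and to `Ne = 200–500` for
invariant and protocol tests. What passing shows: the engine conserves
copy number, erodes monotonically, reproduces bit-exactly from seed, and
agrees with the mean-field equilibria where the theory says it should.
What it does not show: behaviour at biological `Ne = 1e5` with `2·Ne·u`
mutants per generation over millions of generations (the scaling laws
solved exactly by the mean field are the substitute for brute force there),
nor anything about real PRDM9 sequence evolution, which the model abstracts
into a single functional mutation rate.

## Numerical choices

Bisection/Brent tolerances 1e-13–1e-14 on the self-consistent roots;
Gauss–Legendre order 300 and dose-grid 4001 for the generalized solver
(increasing either changes the calibration outputs by < 1e-6 relative);
trajectory time grids cut the deterministic path where the frequency
returns to `x₀ = 1/(2Ne)` (one copy), avoiding the infinite deterministic
tail; `D` is clamped at its definitional floor of 1, with the raw
deterministic value kept in diagnostics; degenerate inputs (empty
populations, non-normalised frequencies, negative doses, `R ∉ (0,1]`)
raise `ValueError` rather than being silently corrected.
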