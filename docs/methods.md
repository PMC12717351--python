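# Methods

## The model

`soceeo` implements a minimal microbial-explicit soil-organic-carbon
(SOC) model in which the decomposer community's per-biomass
extracellular enzyme production rate `m_e` [1/d] is an adaptable
functional trait, and several eco-evolutionary optimality schemes that
predict its value under given environmental conditions.

Three carbon pools are tracked, all in mg C per g soil: SOC `x_s`,
microbial biomass `x_b` and extracellular enzymes `x_e`. SOC receives
an external input `I` [mg C g⁻¹ d⁻¹], is lost abiotically at rate
`ℓ_s` [1/d] and is depolymerized with flux

    ρ = v_u · α x_s · x_e / (α k_u + α x_s + x_e)

an equilibrium-chemistry-approximation (ECA) rate law in which
substrate and enzyme compete for binding: ρ saturates in whichever of
the two is not limiting and is bounded by `v_u·min(α x_s, x_e)`. `α`
is the fraction of SOC with accessible reactive sites.

Microbes assimilate `y·ρ` (yield `y`), spend `ε_e·m_e·x_b` on enzyme
production — of which `m_e·x_b` becomes enzyme carbon and the overhead
`(ε_e−1)·m_e·x_b` is respired, hence the invariant `ε_e > 1` — and die
at rate `d`. Enzymes decay at rate `d_e`.

Two operating modes:

* **full** — the three-pool ODE system with a constant mortality
  coefficient `d_fixed`;
* **qss** — enzymes and biomass are slaved to SOC
  (`x_e = (m_e/d_e)·x_b`, `x_b = β·x_s`), leaving SOC as the only
  dynamic state and making mortality emergent: at the resident's
  ecological equilibrium growth balances death, so
  `d* = G − ε_e·m_e` where `G = y·ρ/x_b` is the per-biomass uptake.

Under the QSS closure the net specific growth rate is

    μ(x_s, m_e) = y v_u α x_s (m_e/d_e) / (α k_u + α x_s + (m_e/d_e) β x_s) − ε_e m_e

a saturating benefit minus a linear cost. Its maximizer in `m_e` has
the closed form (re-derived from the first-order condition and checked
against a brute-force oracle in the test suite)

    m_e*(x_s) = d_e/(β x_s) · ( sqrt( y v_u α x_s A / (ε_e d_e) ) − A ),   A = α(k_u + x_s)

which is positive exactly above the feasibility threshold
`x_s > ε_e d_e k_u / (y v_u − ε_e d_e)`. Below it the optimum is
clamped to zero and flagged infeasible — never returned negative.

## Optimization schemes

All schemes maximize a fitness proxy built from `μ`, and differ in the
assumed timescale of trait adaptation relative to the ecological
feedback, and in whether competition among strains is represented:

* **instantaneous** (`inst`): the trait adapts faster than SOC
  changes; `m_e*` maximizes `μ(x_s, ·)` at frozen SOC and is a direct
  function of the state.
* **equilibrium** (`eq`): the trait adapts more slowly than the
  ecological feedback; `m_e*` maximizes `μ̃(m_e) = μ(X_s(m_e), m_e)`
  where `X_s(m_e)` is the steady-state SOC the strategy itself
  creates. The optimum depends on parameters only (including `I` and
  `ℓ_s`). The emergent mortality of the QSS closure is what keeps this
  objective non-degenerate at steady state: with a constant mortality,
  growth would equal death identically and no optimum would exist.
* **adaptive dynamics** (`ad`): fitness is the invasion growth rate of
  a rare mutant with trait `m_em` in the environment fixed by a
  resident `m_er` at its ecological equilibrium,

      s(m_er, m_em) = c(m_er, m_em)·G − ε_e·m_em − d*,

  which vanishes on the diagonal by construction. The competition
  kernel `c` grants over-producers preferential access to
  depolymerization products; the default is the power law
  `c = (m_em/m_er)^c0` with `c0 = 0.5`, chosen because it satisfies
  `c(m,m) = 1`, is monotone in both arguments, gives the analytic
  selection gradient `G·c0/m_er − ε_e`, and yields evolutionarily
  stable singular points exactly when `c0 < 1` (diagonal curvature
  `G·c0(c0−1)/m²`). Singular strategies are located by bracketing the
  selection gradient and classified by central differences:
  evolutionary stability from the invasion-fitness curvature in the
  mutant trait, convergence stability from the slope of the selection
  gradient in the resident; both together make a continuously stable
  strategy (CSS). A two-strain simulator (shared enzyme pool, uptake
  shares weighted by the kernel against the biomass-weighted mean
  trait, mortality frozen at `d*`) verifies invasion outcomes
  dynamically.
* **time-integrated** (optimal control): the trait trajectory
  `m_e(t)` maximizes `J = ∫₀ᵀ μ dt` on the QSS model over a finite
  horizon. See below.
* **marginal-gradient adaptation**: instead of solving the optimality
  condition, the trait climbs the fitness gradient,
  `dm_e/dt = κ_u·∂μ/∂m_e`, coupled to the SOC dynamics. For
  `κ_u` large against the SOC relaxation rate this tracks the
  instantaneous optimum; for `κ_u → 0` the fixed-parameter model is
  recovered.

### Trait search bounds

Under the QSS closure the per-biomass uptake is bounded by
`y v_u α/β` (the ECA denominator is at least the enzyme term), so `μ`
is strictly negative for `m_e > y v_u α/(ε_e β)` at every SOC level.
All searches (1-D maximizations, singular-strategy scans, control
bounds) use `[0, y v_u α/(ε_e β)]`. Note the `α/β` factor: a bound of
`y v_u/ε_e` — which ignores that an enzyme pool may exceed the biomass
pool — would truncate genuine optima whenever `β < α`.

## Parameters

| name | meaning | unit | baseline | why |
|---|---|---|---|---|
| `alpha` | reactive fraction of SOC | – | 0.5 | half of SOC accessible to enzymes |
| `beta` | microbial fraction of SOC | – | 0.02 | microbial quotient ~2% |
| `eps_e` | enzyme production cost factor | – | 1.5 | 0.5 units respired per unit enzyme C |
| `d_e` | enzyme decay rate | 1/d | 0.0015 | slow turnover of stabilized enzymes |
| `input_rate` | SOC input `I` | mg C g⁻¹ d⁻¹ | 0.1 | mid-range of the sweep grid |
| `k_u` | ECA half-saturation | mg C g⁻¹ | 15 | decomposition unsaturated at low SOC |
| `ell_s` | abiotic SOC loss | 1/d | 0.01 | leaching/erosion, ~100 d residence |
| `v_u` | max decomposition rate | 1/d | 0.05 | slow, SOC spans ~2–370 mg/g over the sweep |
| `y` | microbial yield | – | 0.45 | typical growth efficiency |
| `c0` | competitive advantage exponent | – | 0.5 | sub-linear ⇒ ESS possible |
| `d_fixed` | mortality (full mode) | 1/d | 0 | full-ODE experiments set it per run |
| `m_e_fixed` | fixed-parametrization trait | 1/d | 0.08 | near the high-input optimum |

The packaged baseline (`data/baseline_synthetic.params`) is a
*synthetic* parameter set: the values are representative of
microbial-explicit SOC modelling literature and were fixed once so that
the model operates in the regime the comparative experiments probe —
benefit/cost ratio `R = y v_u/(ε_e d_e) = 10`, growth-maximisation
feasibility threshold ≈ 1.7 mg C/g, trait–SOC curves that rise, peak
below 50 mg C/g and decay toward the common asymptote
`(d_e α/β)(√R − 1)`, and an input grid (60 log-spaced points over
10⁻³…10 mg C g⁻¹ d⁻¹) whose upper decade brings the instantaneous and
equilibrium optima within a few percent of each other. It is a
mathematically coherent study condition, not a calibration to any
site: real soils add nutrient co-limitation, temperature/moisture
response, multiple substrate qualities and spatial structure, none of
which are represented, so tests passing here demonstrate properties of
the model family, not predictions for field data.

Random fixture sets for property tests are sampled log-uniformly
within one decade of the baseline (fractions capped at their admissible
bounds), rejecting draws with `y v_u ≤ ε_e d_e`; a fixed seed makes
them reproducible.

## Steady states and bookkeeping

Setting `dx_s/dt = 0` under the QSS closure and clearing the ECA
denominator leaves a quadratic in `X_s` whose root product is
non-positive, so exactly one root is non-negative; that root (the
stable branch reached by forward integration from any positive SOC, as
one test verifies) is returned, with all roots and the implicit-equation
residual available as diagnostics. With `m_e = 0` this reduces to
`I/ℓ_s` exactly; `m_e = 0` together with `ℓ_s = 0` and positive input
has no steady state and raises.

Integrations (LSODA, rtol 1e-9, atol 1e-12) carry cumulative fluxes as
extra states, so the carbon budget closes to integrator tolerance by
construction and is asserted to 1e-8 relative in the tests. No clipping
is applied: the flux laws vanish at zero pools, which keeps the exact
dynamics non-negative. Carbon fates: decayed enzymes and dead biomass
leave the system (the SOC equation contains no recycling term);
respiration collects the uptake inefficiency `(1−y)ρ` plus the enzyme
overhead `(ε_e−1)m_e x_b`. In QSS mode the closure identity is tracked
on the substrate pool, with depolymerization counted as the outflow
into the diagnostic microbial loop.

## Optimal control

The finite-horizon problem is solved by direct transcription: the
control is piecewise-constant on `n` intervals, the SOC state and the
running objective are integrated per interval, and the resulting
`n`-dimensional problem is maximized with bounded L-BFGS-B from
multiple starts (an optional warm start, the instantaneous optimum at
the initial state, a mid-bound constant, and seeded random constants).
Gradients come from the adjoint equation
`dλ/dt = −∂H/∂x_s`, `λ(T) = 0` (free terminal state), with
`H = μ + λ·(I − ρ − ℓ_s x_s)`; the exact identity
`dJ/dm_j = ∫_j ∂H/∂m_e dt` makes the optimizer's projected gradient
coincide with the interval-averaged Pontryagin stationarity residual,
which is reported per interval along with the peak-to-peak Hamiltonian
drift (the problem is autonomous, so `H` is constant along an optimum
up to discretization error). The default objective is cumulative
*specific* growth `∫μ dt`, matching the per-biomass fitness measure of
the other schemes; cumulative absolute growth (`∫μ·β x_s dt`) is
available as an alternative. Horizon and terminal condition are user
choices; no free-terminal-time problems are posed. The shipped
experiments use horizons up to 60 d and grids up to 32 intervals, at
which the objective changes by less than 1e-4 relative under further
grid doubling.

## Numerical choices

* Trait derivatives: central finite differences, relative step 1e-6;
  analytic forms, where derived, are cross-checked against them rather
  than trusted alone. Curvatures use a wider step (1e-4 relative).
* Scalar maximization oracle: coarse grid scan (linear or log) plus
  bounded golden-section/parabolic refinement; every closed form in
  the package is tested against it to 1e-6 relative.
* Singular strategies: log-grid scan for a sign change of the
  selection gradient, then Brent's method to near machine precision;
  absence of a sign change is a result ("no singular strategy"), not
  an error.
* The self-consistent instantaneous fixed point (`m = m*(X_s(m))`,
  needed to place the instantaneous scheme on steady-state axes) is
  solved by damped fixed-point iteration with a bracketing fallback.
* Infeasible optima are clamped to zero and flagged; sweep outputs
  record them as zero-trait rows with `feasible = False`.
* Invasion simulations require a rare mutant (inoculum ≤ 1e-3 of
  biomass) and small mutation steps (|Δm|/m ≤ 0.2), and call outcomes
  only beyond a 1e-8 neutrality band on the initial per-capita growth.

## Known limitations

* **Adaptive dynamics and SOC cannot trade off in this closure.** For
  any competition kernel of the form `c(m_er, m_em)` — smooth, equal
  to one on the diagonal, environment-independent — a singular
  strategy that is convergence stable must shift *upward* as the input
  rate rises: writing the singular condition as
  `F(m, I) = σ(m)·G(X(m,I), m) − ε_e = 0` with `σ` the diagonal kernel
  derivative, `G` increases in `X` and `X` increases in `I`, so
  `∂F/∂I > 0`, while convergence stability is `∂F/∂m < 0`; hence
  `dm*/dI > 0`, and the resident's equilibrium SOC rises along with
  it. The emergent adaptive-dynamics trait–SOC relation in this model
  is therefore increasing wherever the strategy is an attractor, and
  with the power-law kernel the scheme also loses viability below
  `X_s = k_u/(c0·R − 1)`, which for `c0 < 1` lies *above* the
  growth-maximisation threshold `k_u/(R − 1)`. Reversing either
  behaviour would require a kernel whose competitive advantage itself
  strengthens as resources become scarce — an environment-dependent
  mechanism outside the present kernel interface. The corresponding
  comparative expectations (an AD curve that decreases at high SOC and
  stays high at low SOC) are left as failing checks in the acceptance
  suite rather than satisfied by changing the kernel contract.
* The QSS biomass closure `x_b = β·x_s` fixes the microbial quotient;
  regimes where biomass decouples from SOC (flushes, dormancy) are
  outside the model.
* Single substrate pool, single lumped community, no stoichiometry,
  no abiotic response functions, no space.
* The two literature worked examples encode printed growth-rate and
  closed-form expressions only; the original studies' full dynamical
  systems are not reproduced.
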