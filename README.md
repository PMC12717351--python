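# soceeo

Eco-evolutionary optimization of microbial traits in a minimal soil
organic carbon (SOC) model.

Soil microbes decompose organic matter with extracellular enzymes they
must pay to produce. How much enzyme a community "should" produce is
not a fixed parameter but the outcome of eco-evolutionary dynamics —
and different optimality assumptions (how fitness is measured, and on
what timescale the trait adapts) give systematically different answers.
`soceeo` is a laboratory for comparing those assumptions on one shared
model. It is aimed at soil biogeochemical modellers and theoretical
ecologists who want to see how the choice of optimization scheme
propagates into predicted enzyme investment and carbon stocks.

## The model and the schemes

Pools (mg C g⁻¹ soil): SOC *x*ₛ, microbial biomass *x*_b, enzymes
*x*_e. SOC gains input *I*, loses carbon abiotically (rate ℓₛ) and by
depolymerization with ECA kinetics

ρ = v_u α xₛ x_e / (α k_u + α xₛ + x_e).

Microbes assimilate *y*ρ and spend ε_e·m_e·x_b on enzyme production,
where the per-biomass production rate **m_e [d⁻¹] is the adaptable
trait**. With the quasi-steady-state closure x_e = (m_e/d_e)x_b,
x_b = β xₛ, the net specific growth rate is

μ(xₛ, m_e) = y v_u α xₛ (m_e/d_e) / (α k_u + α xₛ + (m_e/d_e) β xₛ) − ε_e m_e.

Implemented predictions for m_e:

| scheme | fitness proxy | optimum depends on |
|---|---|---|
| instantaneous | μ at frozen SOC | state xₛ and parameters |
| equilibrium | μ at the steady state the trait creates | parameters only |
| adaptive dynamics | invasion fitness s(m_er, m_em) = c·G − ε_e m_em − d* | parameters incl. competition c0 |
| time-integrated | J = ∫₀ᵀ μ dt (optimal control) | trajectory (x₀, T) |
| gradient adaptation | dm_e/dt = κ_u ∂μ/∂m_e | dynamic, tracks inst. for large κ_u |

Adaptive dynamics uses a pluggable competition kernel (default
c = (m_em/m_er)^c0) granting enzyme over-producers preferential access
to depolymerization products, and classifies singular strategies as
ESS / convergence stable / CSS. A two-strain simulator verifies
invasion outcomes dynamically. The optimal-control module solves the
finite-horizon problem by direct transcription with adjoint gradients
and reports Pontryagin stationarity and Hamiltonian-drift residuals.

See `docs/methods.md` for assumptions, parameter meanings, numerics
and known limitations.

## Worked example

```python
from soceeo import (baseline_params, maximize_instantaneous,
                    maximize_equilibrium, find_singular_strategy,
                    invasion_fitness)

p = baseline_params()                      # packaged synthetic baseline
inst = maximize_instantaneous(30.0, p)     # trait optimal at SOC = 30 mg/g
eq = maximize_equilibrium(p)               # trait shaping its own steady state
ss = find_singular_strategy(p)             # adaptive-dynamics CSS
s = invasion_fitness(ss.value, 1.1 * ss.value, p)
```

prints (via the obvious f-strings):

```
instantaneous optimum at SOC=30 mg/g : m_e* = 0.0890 /d, mu* = 0.2112 /d
equilibrium optimum (I=0.1)          : m_e* = 0.0674 /d at X_s = 5.51 mg/g
adaptive dynamics CSS (c0=0.5)       : m_e* = 0.0536 /d, ESS=True, convergence stable=True
invasion fitness of a 10% over-producer: s = -1.914e-04 /d
```

Reading: at 30 mg C/g of SOC a growth-maximising community would put
8.9% of its biomass per day into enzymes and grow at 0.21 d⁻¹. If the
trait instead equilibrates with the SOC stock it creates (input 0.1
mg C g⁻¹ d⁻¹), investment drops to 0.067 d⁻¹ — consuming the resource
more slowly pays off once the feedback on the resource is accounted
for. Under competition for depolymerization products the continuously
stable strategy is 0.054 d⁻¹; a mutant over-producing by 10% has
negative invasion fitness, so the strategy resists invasion.

The same is available from the shell:

```sh
soceeo optimize --scheme eq
soceeo sweep --out sweep.csv --plot sweep.png   # scheme comparison across inputs
soceeo invade --resident 0.05 --mutant 0.052
soceeo control --x0 30 --horizon 60 --n-intervals 16 --out traj.csv
```

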