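"""Eco-evolutionary optimization schemes for the SOC toy model.

Three ways of predicting the community-aggregated enzyme-production
trait ``m_e``:

* **instantaneous maximisation** -- maximise the net specific growth
  rate ``mu(x_s, m_e)`` at the current, frozen SOC level (trait adapts
  faster than the ecological feedback);
* **equilibrium maximisation** -- maximise ``mu`` after substituting
  the steady-state SOC ``X_s(m_e)`` the trait itself creates (trait
  adapts slower than the ecological feedback);
* **adaptive dynamics** -- locate the singular strategy of the invasion
  fitness of a rare mutant in the environment set by a resident at its
  ecological equilibrium, with a competition kernel granting enzyme
  over-producers preferential access to depolymerization products, and
  classify it as ESS / convergence-stable / CSS.

A brute-force numeric oracle, a two-strain invasion simulator and a
marginal-gradient trait-adaptation ODE are provided to cross-check the
closed forms and the adaptive-dynamics predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from . import model
from .params import ToyModelParams

#: relative step for central finite differences on trait derivatives
FD_REL_STEP = 1e-6


class InfeasibleTraitError(ValueError):
    """No positive trait optimum exists at the requested SOC level."""


class ResidentEquilibriumError(ValueError):
    """The resident strategy has no positive ecological equilibrium."""


class CompetitionKernel(Protocol):
    """Multiplier on a rare mutant's resource access, ``c(m_er, m_em)``.

    Must satisfy ``c(m, m) = 1``, increase in the mutant trait, decrease
    in the resident trait, and be smooth near the diagonal.
    """

    def __call__(self, m_er: float, m_em: float) -> float: ...


@dataclass(frozen=True)
class PowerLawKernel:
    """``c(m_er, m_em) = (m_em/m_er)**c0``.

    The ratio form makes the diagonal exactly one for every trait value,
    and its diagonal curvature ``c0*(c0-1)/m**2`` is negative exactly
    when ``c0 < 1``, which is what makes interior singular strategies
    evolutionarily stable for sub-linear competitive advantage.
    """

    c0: float = 0.5

    def __call__(self, m_er: float, m_em: float) -> float:
        if m_er <= 0.0:
            raise ValueError("resident trait must be positive")
        return (m_em / m_er) ** self.c0

    def dc_dmm_diag(self, m: float) -> float:
        """d c / d m_em on the diagonal."""
        return self.c0 / m

    def d2c_dmm2_diag(self, m: float) -> float:
        """d^2 c / d m_em^2 on the diagonal."""
        return self.c0 * (self.c0 - 1.0) / m**2


def kernel_for(params: ToyModelParams) -> PowerLawKernel:
    """Default competition kernel built from the parameter set's c0."""
    return PowerLawKernel(c0=params.c0)


@dataclass(frozen=True)
class OptimalTrait:
    """An optimized enzyme-production rate with diagnostics.

    ``feasible`` is False when the unconstrained optimum is non-positive
    and the trait was clamped to zero (the model predicts no viable
    enzyme investment under those conditions).  ``context`` records the
    SOC level at which the optimum holds: the frozen ``x_s`` for the
    instantaneous scheme, the self-created steady state ``X_s`` for the
    equilibrium scheme.
    """

    value: float
    scheme: str
    feasible: bool
    gradient_residual: float
    second_derivative: float
    context: float
    objective_value: float


@dataclass(frozen=True)
class SingularStrategy:
    """A singular point of the adaptive dynamics with its classification."""

    value: float
    is_ess: bool
    is_convergence_stable: bool
    is_css: bool
    ess_curvature: float
    convergence_derivative: float
    gradient_residual: float
    context: float  # resident steady-state SOC


@dataclass(frozen=True)
class OracleResult:
    argmax: float
    value: float
    at_boundary: bool


def numeric_oracle_maximize(
    objective: Callable[[float], float],
    bounds: tuple[float, float],
    grid_size: int = 200,
    spacing: str = "linear",
    xatol: float = 1e-10,
) -> OracleResult:
    """Derivative-free scalar maximization: grid scan + golden-section.

    Deliberately simple so it can serve as an independent check on every
    closed-form optimum; a coarse scan brackets the global maximum on
    the grid resolution and bounded golden-section/parabolic refinement
    (:func:`scipy.optimize.minimize_scalar`) polishes it to ``xatol``.
    """
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("bounds must satisfy hi > lo")
    if spacing == "log":
        if lo <= 0.0:
            grid = np.concatenate(
                [[lo], np.geomspace(max(hi * 1e-12, 1e-300), hi, grid_size - 1)]
            )
        else:
            grid = np.geomspace(lo, hi, grid_size)
    else:
        grid = np.linspace(lo, hi, grid_size)
    vals = np.array([objective(g) for g in grid])
    k = int(np.argmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    if a == b:
        return OracleResult(argmax=float(grid[k]), value=float(vals[k]), at_boundary=True)
    res = minimize_scalar(
        lambda u: -objective(u), bounds=(a, b), method="bounded",
        options={"xatol": xatol},
    )
    cand = [(float(res.x), float(-res.fun)), (float(grid[k]), float(vals[k]))]
    x_best, f_best = max(cand, key=lambda t: t[1])
    at_boundary = min(x_best - lo, hi - x_best) <= 10.0 * xatol
    return OracleResult(argmax=x_best, value=f_best, at_boundary=at_boundary)


def _mu_derivatives(x_s: float, m_e: float, params: ToyModelParams) -> tuple[float, float]:
    """Central-difference (d mu/d m_e, d^2 mu/d m_e^2) at (x_s, m_e)."""
    h = FD_REL_STEP * max(abs(m_e), 1.0)
    f = lambda m: model.net_specific_growth(x_s, m, params)  # noqa: E731
    g = (f(m_e + h) - f(m_e - h)) / (2.0 * h)
    h2 = 1e-4 * max(abs(m_e), 1.0)
    d2 = (f(m_e + h2) - 2.0 * f(m_e) + f(m_e - h2)) / h2**2
    return g, d2


def instantaneous_closed_form(x_s: float, params: ToyModelParams) -> float:
    """Closed-form instantaneous optimum ``m_e*(x_s)`` [1/d].

    From the first-order condition of ``mu`` in the trait: with
    ``A = alpha*(k_u + x_s)`` and ``z = m_e/d_e``, ``(A + beta*x_s*z)^2
    = y*v_u*alpha*x_s*A/(eps_e*d_e)``, giving

        m_e* = d_e/(beta*x_s) * (sqrt(y*v_u*alpha*x_s*A/(eps_e*d_e)) - A)

    Positive exactly when ``x_s`` exceeds the feasibility threshold;
    below it this raises :class:`InfeasibleTraitError` (callers clamp).
    """
    p = params
    if x_s <= 0.0:
        raise InfeasibleTraitError("x_s must be positive")
    A = p.alpha * (p.k_u + x_s)
    root = math.sqrt(p.y * p.v_u * p.alpha * x_s * A / (p.eps_e * p.d_e))
    m_star = (p.d_e / (p.beta * x_s)) * (root - A)
    if m_star <= 0.0:
        raise InfeasibleTraitError(
            f"x_s={x_s:g} is at or below the feasibility threshold "
            f"{model.feasibility_threshold(p):g}"
        )
    return m_star


def maximize_instantaneous(x_s: float, params: ToyModelParams) -> OptimalTrait:
    """Instantaneous growth maximisation at frozen SOC ``x_s``."""
    if x_s <= 0.0:
        raise ValueError("x_s must be positive")
    try:
        m_star = instantaneous_closed_form(x_s, params)
        feasible = True
    except InfeasibleTraitError:
        m_star, feasible = 0.0, False
    if feasible:
        grad, d2 = _mu_derivatives(x_s, m_star, params)
    else:
        grad, d2 = 0.0, 0.0
    return OptimalTrait(
        value=m_star,
        scheme="instantaneous",
        feasible=feasible,
        gradient_residual=abs(grad),
        second_derivative=d2,
        context=x_s,
        objective_value=model.net_specific_growth(x_s, m_star, params),
    )


def equilibrium_objective(m_e: float, params: ToyModelParams) -> float:
    """``mu`` evaluated at the steady-state SOC the trait itself creates."""
    x_eq = model.steady_state_soc(m_e, params)
    return model.net_specific_growth(x_eq, m_e, params)


def maximize_equilibrium(
    params: ToyModelParams, grid_size: int = 200
) -> OptimalTrait:
    """Equilibrium growth maximisation: trait shapes its own environment.

    Mortality is emergent under the QSS biomass closure (growth balances
    death through ``x_b = beta*x_s``), which is what leaves a
    non-degenerate objective at steady state.  Solved by a safeguarded
    1-D search (log-grid scan + bounded refinement) over
    ``[0, m_e_max]`` with a nested steady-state solve per evaluation.
    """
    if params.input_rate <= 0.0:
        raise ValueError("equilibrium maximisation requires input_rate > 0")
    m_max = params.m_e_max
    obj = lambda m: equilibrium_objective(m, params)  # noqa: E731
    res = numeric_oracle_maximize(
        obj, (0.0, m_max), grid_size=grid_size, spacing="log", xatol=1e-12
    )
    m_star, mu_star = res.argmax, res.value
    if mu_star <= 0.0 or m_star <= 0.0:
        return OptimalTrait(
            value=0.0,
            scheme="equilibrium",
            feasible=False,
            gradient_residual=0.0,
            second_derivative=0.0,
            context=model.steady_state_soc(0.0, params),
            objective_value=obj(0.0),
        )
    h = FD_REL_STEP * m_star
    grad = (obj(m_star + h) - obj(m_star - h)) / (2.0 * h)
    h2 = 1e-4 * m_star
    d2 = (obj(m_star + h2) - 2.0 * mu_star + obj(m_star - h2)) / h2**2
    return OptimalTrait(
        value=m_star,
        scheme="equilibrium",
        feasible=True,
        gradient_residual=abs(grad),
        second_derivative=d2,
        context=model.steady_state_soc(m_star, params),
        objective_value=mu_star,
    )


def resident_environment(
    m_er: float, params: ToyModelParams
) -> tuple[float, float, float]:
    """Equilibrium environment set by a resident: ``(X_s, G, d_star)``.

    ``G = y*rho*/X_b`` is the resident's per-biomass uptake at its
    ecological equilibrium and ``d_star = G - eps_e*m_er`` the emergent
    mortality coefficient that balances its growth there.
    """
    if m_er <= 0.0:
        raise ValueError("resident trait must be positive")
    x_eq = model.steady_state_soc(m_er, params)
    if x_eq <= 0.0:
        raise ResidentEquilibriumError(
            f"resident m_er={m_er:g} has no positive equilibrium (I={params.input_rate:g})"
        )
    G = model.growth_benefit(x_eq, m_er, params)
    d_star = G - params.eps_e * m_er
    return x_eq, G, d_star


def invasion_fitness(
    m_er: float,
    m_em: float,
    params: ToyModelParams,
    kernel: CompetitionKernel | None = None,
) -> float:
    """Invasion fitness ``s(m_er, m_em)`` [1/d] of a rare mutant.

    Initial per-capita growth of a mutant with trait ``m_em`` in the
    environment fixed by the resident at its ecological equilibrium:
    ``s = c(m_er, m_em)*G - eps_e*m_em - d_star``, which vanishes on the
    diagonal by construction (the resident is neutral against itself).
    """
    if kernel is None:
        kernel = kernel_for(params)
    _, G, d_star = resident_environment(m_er, params)
    return kernel(m_er, m_em) * G - params.eps_e * m_em - d_star


def selection_gradient(
    m_er: float,
    params: ToyModelParams,
    kernel: CompetitionKernel | None = None,
    method: str = "fd",
) -> float:
    """Derivative of invasion fitness in the mutant trait, on the diagonal.

    ``method="fd"`` uses a central difference with relative step
    ``1e-6``; ``method="analytic"`` uses ``G*dc/dm_em|diag - eps_e`` for
    kernels exposing a diagonal derivative.
    """
    if kernel is None:
        kernel = kernel_for(params)
    if method == "analytic":
        if not hasattr(kernel, "dc_dmm_diag"):
            raise ValueError("kernel does not expose an analytic diagonal derivative")
        _, G, _ = resident_environment(m_er, params)
        return G * kernel.dc_dmm_diag(m_er) - params.eps_e
    h = FD_REL_STEP * m_er
    s_plus = invasion_fitness(m_er, m_er + h, params, kernel)
    s_minus = invasion_fitness(m_er, m_er - h, params, kernel)
    return (s_plus - s_minus) / (2.0 * h)


def find_singular_strategy(
    params: ToyModelParams,
    kernel: CompetitionKernel | None = None,
    bracket: tuple[float, float] | None = None,
    n_scan: int = 120,
) -> SingularStrategy | None:
    """Locate and classify a singular strategy of the adaptive dynamics.

    Scans a log grid over the admissible trait range for a sign change
    of the selection gradient, polishes the root by safeguarded
    bracketing, and classifies it via central differences: ESS when the
    invasion-fitness curvature in the mutant trait is negative at the
    diagonal, convergence-stable when the selection gradient decreases
    through the root.  Returns ``None`` when no sign change exists in
    the search interval (e.g. ``c0 = 0``: enzyme production is a pure
    cost for a rare mutant and selection points monotonically to zero).
    """
    if kernel is None:
        kernel = kernel_for(params)
    use_analytic = hasattr(kernel, "dc_dmm_diag")
    grad = lambda m: selection_gradient(  # noqa: E731
        m, params, kernel, method="analytic" if use_analytic else "fd"
    )
    if bracket is None:
        lo, hi = 1e-8 * params.m_e_max, params.m_e_max
    else:
        lo, hi = bracket
    ms = np.geomspace(lo, hi, n_scan)
    gs = np.array([grad(m) for m in ms])
    idx = np.nonzero(np.signbit(gs[:-1]) != np.signbit(gs[1:]))[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    m_star = brentq(grad, ms[i], ms[i + 1], xtol=1e-14, rtol=8.9e-16)
    residual = abs(grad(m_star))

    x_eq, G, _ = resident_environment(m_star, params)
    # ESS: curvature of s in the mutant trait at the diagonal.
    h2 = 1e-4 * m_star
    s0 = invasion_fitness(m_star, m_star, params, kernel)
    curv = (
        invasion_fitness(m_star, m_star + h2, params, kernel)
        - 2.0 * s0
        + invasion_fitness(m_star, m_star - h2, params, kernel)
    ) / h2**2
    # Convergence stability: slope of the selection gradient in the resident.
    hc = 1e-5 * m_star
    conv = (grad(m_star + hc) - grad(m_star - hc)) / (2.0 * hc)
    is_ess = curv < 0.0
    is_conv = conv < 0.0
    return SingularStrategy(
        value=float(m_star),
        is_ess=is_ess,
        is_convergence_stable=is_conv,
        is_css=is_ess and is_conv,
        ess_curvature=float(curv),
        convergence_derivative=float(conv),
        gradient_residual=float(residual),
        context=float(x_eq),
    )


@dataclass
class InvasionOutcome:
    """Result of a two-strain invasion experiment."""

    outcome: str  # "invades" | "repelled" | "neutral"
    per_capita_growth: float
    frame: pd.DataFrame


def simulate_invasion(
    m_er: float,
    m_em: float,
    mutant_fraction: float,
    params: ToyModelParams,
    kernel: CompetitionKernel | None = None,
    t_span: tuple[float, float] = (0.0, 50.0),
    neutral_tol: float = 1e-8,
) -> InvasionOutcome:
    """Dynamic verification of the invasion criterion.

    Integrates a two-strain system started at the resident's ecological
    equilibrium with a tiny mutant inoculum: the enzyme pool is shared
    (QSS over both producers), each strain's share of the uptake flux is
    proportional to its biomass weighted by the competition kernel
    evaluated against the biomass-weighted mean trait, and mortality is
    frozen at the resident-equilibrium value ``d_star``.  The outcome is
    the sign of the mutant's per-capita growth averaged over the initial
    tenth of the horizon, which must agree with the sign of the
    invasion fitness.
    """
    if kernel is None:
        kernel = kernel_for(params)
    if mutant_fraction > 1e-3:
        raise ValueError("mutant_fraction must be <= 1e-3 (rare-mutant limit)")
    if abs(m_em - m_er) / m_er > 0.2:
        raise ValueError("|m_em - m_er|/m_er must be <= 0.2 (small mutation steps)")
    x_eq, _, d_star = resident_environment(m_er, params)
    x_b_tot = params.beta * x_eq
    y0 = [x_eq, (1.0 - mutant_fraction) * x_b_tot, mutant_fraction * x_b_tot]

    def rhs(t, yv):
        x_s, b_r, b_m = yv
        b_r = max(b_r, 0.0)
        b_m = max(b_m, 0.0)
        b_tot = b_r + b_m
        if b_tot <= 0.0:
            return [params.input_rate - params.ell_s * x_s, 0.0, 0.0]
        m_bar = (m_er * b_r + m_em * b_m) / b_tot
        x_e = (m_er * b_r + m_em * b_m) / params.d_e
        rho = model.eca_flux(x_s, x_e, params)
        w_r = b_r * kernel(m_bar, m_er)
        w_m = b_m * kernel(m_bar, m_em)
        w_tot = w_r + w_m
        up_r = params.y * rho * w_r / w_tot
        up_m = params.y * rho * w_m / w_tot
        return [
            params.input_rate - rho - params.ell_s * x_s,
            up_r - (params.eps_e * m_er + d_star) * b_r,
            up_m - (params.eps_e * m_em + d_star) * b_m,
        ]

    t_window = t_span[0] + 0.1 * (t_span[1] - t_span[0])
    t_eval = np.linspace(*t_span, 201)
    sol = solve_ivp(rhs, t_span, y0, method="LSODA", rtol=1e-10, atol=1e-14,
                    t_eval=t_eval)
    if not sol.success:
        raise model.IntegrationError(f"invasion simulation failed: {sol.message}")
    frame = pd.DataFrame(
        {"t": sol.t, "x_s": sol.y[0], "x_b_resident": sol.y[1], "x_b_mutant": sol.y[2]}
    )
    bm = np.interp(t_window, sol.t, sol.y[2])
    growth = math.log(bm / y0[2]) / (t_window - t_span[0])
    if growth > neutral_tol:
        outcome = "invades"
    elif growth < -neutral_tol:
        outcome = "repelled"
    else:
        outcome = "neutral"
    return InvasionOutcome(outcome=outcome, per_capita_growth=growth, frame=frame)


def gradient_adaptation(
    state0: model.SystemState,
    m_e0: float,
    kappa_u: float,
    params: ToyModelParams,
    t_span: tuple[float, float],
    n_eval: int = 201,
) -> pd.DataFrame:
    """Marginal-gradient trait adaptation coupled to the SOC dynamics.

    Instead of solving the optimality condition, the trait climbs the
    marginal fitness gradient, ``dm_e/dt = kappa_u * d mu/d m_e``
    (finite-difference gradient), coupled to the QSS SOC dynamics;
    ``kappa_u`` [1/d] sets the adaptation speed relative to the
    ecological feedback.  The trait is constrained to stay non-negative
    by switching off downhill motion at zero.  For ``kappa_u`` much
    larger than the state dynamics the trait tracks the instantaneous
    optimum; for ``kappa_u -> 0`` the fixed-parameter model is
    recovered.
    """
    if kappa_u <= 0.0:
        raise ValueError("kappa_u must be positive")

    def rhs(t, yv):
        x_s, m_e = yv
        x_e, _ = model.qss_reduce(x_s, max(m_e, 0.0), params)
        rho = model.eca_flux(x_s, x_e, params)
        dxs = params.input_rate - rho - params.ell_s * x_s
        g, _ = _mu_derivatives(x_s, max(m_e, 0.0), params)
        dme = kappa_u * g
        if m_e <= 0.0 and dme < 0.0:
            dme = 0.0
        return [dxs, dme]

    t_eval = np.linspace(*t_span, n_eval)
    sol = solve_ivp(rhs, t_span, [state0.x_s, m_e0], method="LSODA",
                    rtol=1e-9, atol=1e-12, t_eval=t_eval)
    if not sol.success:
        raise model.IntegrationError(f"gradient adaptation failed: {sol.message}")
    mu = np.array(
        [model.net_specific_growth(x, max(m, 0.0), params)
         for x, m in zip(sol.y[0], sol.y[1])]
    )
    return pd.DataFrame({"t": sol.t, "x_s": sol.y[0], "m_e": sol.y[1], "mu": mu})
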