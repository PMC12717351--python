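"""Minimal microbial-explicit SOC model: kinetics, ODEs, steady states.

Three carbon pools (all mg C per g soil): SOC ``x_s``, microbial biomass
``x_b`` and extracellular enzymes ``x_e``.  SOC receives an external
input ``I``, loses carbon abiotically at rate ``ell_s`` and through
enzymatic depolymerization with flux ``rho`` described by
equilibrium-chemistry-approximation (ECA) kinetics::

    rho = v_u * alpha*x_s * x_e / (alpha*k_u + alpha*x_s + x_e)

Microbes assimilate ``y*rho``, spend ``eps_e*m_e*x_b`` on producing
enzymes (of which ``m_e*x_b`` becomes enzyme carbon and the overhead
``(eps_e-1)*m_e*x_b`` is respired) and die at rate ``d``.  Enzymes decay
at rate ``d_e``.  The per-biomass enzyme production rate ``m_e`` [1/d]
is the adaptable trait.

Two operating modes are provided:

* ``full`` -- the three-pool ODE system with a fixed mortality
  coefficient ``d_fixed``;
* ``qss`` -- the reduced model in which enzymes and biomass are slaved
  to SOC (``x_e = (m_e/d_e)*x_b``, ``x_b = beta*x_s``), mortality is
  emergent (growth balances death at equilibrium) and SOC is the only
  dynamic state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ToyModelParams


class IntegrationError(RuntimeError):
    """Numerical integration failed; carries solver diagnostics."""


@dataclass(frozen=True)
class SystemState:
    """Carbon pools [mg C g^-1 soil]; all non-negative."""

    x_s: float
    x_b: float
    x_e: float

    def __post_init__(self) -> None:
        if min(self.x_s, self.x_b, self.x_e) < 0.0:
            raise ValueError(f"carbon pools must be non-negative, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_s, self.x_b, self.x_e], dtype=float)


@dataclass(frozen=True)
class CarbonBudget:
    """Cumulative carbon fates of an integration [mg C g^-1].

    In ``full`` mode the closure identity is

        delta(x_s + x_b + x_e) = input - abiotic - respiration
                                 - mortality - enzyme_decay.

    In ``qss`` mode only SOC is dynamic and the identity is tracked on
    the substrate pool, with the depolymerization flux counted as the
    outflow into the (diagnostic) microbial loop:

        delta(x_s) = input - abiotic - decomposition.

    ``residual`` is the closure defect; ``relative_residual`` scales it
    by the cumulative input (or the pool change when input is zero).
    """

    mode: str
    delta_pools: float
    cumulative_input: float
    cumulative_abiotic_loss: float
    cumulative_respiration: float
    cumulative_mortality_loss: float
    cumulative_enzyme_decay: float
    cumulative_decomposition: float

    @property
    def residual(self) -> float:
        if self.mode == "full":
            out = (
                self.cumulative_abiotic_loss
                + self.cumulative_respiration
                + self.cumulative_mortality_loss
                + self.cumulative_enzyme_decay
            )
        else:
            out = self.cumulative_abiotic_loss + self.cumulative_decomposition
        return self.delta_pools - (self.cumulative_input - out)

    @property
    def relative_residual(self) -> float:
        scale = max(self.cumulative_input, abs(self.delta_pools), 1e-30)
        return abs(self.residual) / scale


def eca_flux(x_s: float, x_e: float, params: ToyModelParams) -> float:
    """ECA depolymerization flux for scalar pools (no state object)."""
    num = params.v_u * params.alpha * x_s * x_e
    den = params.alpha * params.k_u + params.alpha * x_s + x_e
    if den <= 0.0:
        return 0.0
    return num / den


def depolymerization_flux(state: SystemState, params: ToyModelParams) -> float:
    """Depolymerization flux rho [mg C g^-1 d^-1] at the given state.

    Bounded by ``v_u*min(alpha*x_s, x_e)``; zero whenever substrate or
    enzymes are absent.  The degenerate all-zero denominator is defined
    as zero flux.
    """
    return eca_flux(state.x_s, state.x_e, params)


def qss_reduce(x_s: float, m_e: float, params: ToyModelParams) -> tuple[float, float]:
    """Quasi-steady-state enzyme and biomass pools ``(X_e, X_b)``.

    Biomass is slaved to SOC through the microbial quotient
    (``X_b = beta*x_s``) and enzymes balance production against decay
    (``X_e = (m_e/d_e)*X_b``).
    """
    x_b = params.beta * x_s
    x_e = (m_e / params.d_e) * x_b
    return x_e, x_b


def net_specific_growth(x_s: float, m_e: float, params: ToyModelParams) -> float:
    """Net specific growth rate mu [1/d] under the QSS reduction.

    Per-biomass uptake benefit minus the adaptable enzyme-production
    cost ``eps_e*m_e``; mortality is not included (it is non-adaptable).
    """
    x_s = np.asarray(x_s, dtype=float)
    m_e = np.asarray(m_e, dtype=float)
    z = m_e / params.d_e
    den = params.alpha * params.k_u + params.alpha * x_s + z * params.beta * x_s
    benefit = np.where(
        den > 0.0,
        params.y * params.v_u * params.alpha * x_s * z / np.where(den > 0.0, den, 1.0),
        0.0,
    )
    out = benefit - params.eps_e * m_e
    return float(out) if out.ndim == 0 else out


def growth_benefit(x_s: float, m_e: float, params: ToyModelParams) -> float:
    """Per-biomass uptake ``y*rho/x_b`` under the QSS closure [1/d]."""
    return net_specific_growth(x_s, m_e, params) + params.eps_e * m_e


def rhs_full(
    state: SystemState, m_e: float, params: ToyModelParams, d: float | None = None
) -> np.ndarray:
    """Right-hand side of the three-pool ODE system.

    Mortality uses ``d`` when given, else ``params.d_fixed``.
    Returns ``[dx_s/dt, dx_b/dt, dx_e/dt]``.
    """
    if d is None:
        d = params.d_fixed
    rho = eca_flux(state.x_s, state.x_e, params)
    dxs = params.input_rate - rho - params.ell_s * state.x_s
    dxb = params.y * rho - params.eps_e * m_e * state.x_b - d * state.x_b
    dxe = m_e * state.x_b - params.d_e * state.x_e
    return np.array([dxs, dxb, dxe])


@dataclass
class TrajectoryResult:
    """Time series and carbon bookkeeping from :func:`integrate_trajectory`."""

    frame: pd.DataFrame
    budget: CarbonBudget
    mode: str


def integrate_trajectory(
    state0: SystemState,
    params: ToyModelParams,
    trait_policy: Callable[[float, np.ndarray], float] | float,
    t_span: tuple[float, float],
    mode: str = "full",
    n_eval: int = 201,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    d: float | None = None,
) -> TrajectoryResult:
    """Integrate the model forward with a (possibly time-varying) trait.

    Parameters
    ----------
    trait_policy
        Either a constant ``m_e`` or a callable ``(t, pools) -> m_e``
        where ``pools`` is the array ``[x_s, x_b, x_e]``; must be
        non-negative.
    mode
        ``"full"`` integrates all three pools with fixed mortality;
        ``"qss"`` integrates SOC only under the QSS closure.

    Cumulative fluxes are integrated as additional states, so the carbon
    budget closes to integrator tolerance by construction (no clipping
    is applied; the flux laws vanish at zero pools, which keeps the
    exact dynamics non-negative).
    """
    if callable(trait_policy):
        policy = trait_policy
    else:
        m_const = float(trait_policy)
        policy = lambda t, pools: m_const  # noqa: E731

    if mode == "full":
        d_use = params.d_fixed if d is None else d

        def rhs(t, yv):
            x_s, x_b, x_e = yv[0], yv[1], yv[2]
            m_e = policy(t, yv[:3])
            rho = eca_flux(x_s, x_e, params)
            dxs = params.input_rate - rho - params.ell_s * x_s
            dxb = params.y * rho - params.eps_e * m_e * x_b - d_use * x_b
            dxe = m_e * x_b - params.d_e * x_e
            resp = (1.0 - params.y) * rho + (params.eps_e - 1.0) * m_e * x_b
            return [
                dxs,
                dxb,
                dxe,
                params.input_rate,
                params.ell_s * x_s,
                resp,
                d_use * x_b,
                params.d_e * x_e,
                rho,
            ]

        y0 = list(state0.as_array()) + [0.0] * 6
    elif mode == "qss":

        def rhs(t, yv):
            x_s = yv[0]
            x_e, x_b = None, None
            m_e = policy(t, np.array([x_s, params.beta * x_s, 0.0]))
            x_e, x_b = qss_reduce(x_s, m_e, params)
            rho = eca_flux(x_s, x_e, params)
            dxs = params.input_rate - rho - params.ell_s * x_s
            resp = (1.0 - params.y) * rho + (params.eps_e - 1.0) * m_e * x_b
            return [
                dxs,
                params.input_rate,
                params.ell_s * x_s,
                resp,
                0.0,
                params.d_e * x_e,
                rho,
            ]

        y0 = [state0.x_s] + [0.0] * 6
    else:
        raise ValueError(f"mode must be 'full' or 'qss', got {mode!r}")

    t_eval = np.linspace(t_span[0], t_span[1], n_eval)
    sol = solve_ivp(
        rhs, t_span, y0, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed in mode={mode!r}: {sol.message} "
            f"(reached t={sol.t[-1] if len(sol.t) else t_span[0]})"
        )

    t = sol.t
    if mode == "full":
        x_s, x_b, x_e = sol.y[0], sol.y[1], sol.y[2]
        cum_in, cum_ab, cum_resp, cum_mort, cum_enz, cum_dec = sol.y[3:9]
        delta = (x_s[-1] + x_b[-1] + x_e[-1]) - (x_s[0] + x_b[0] + x_e[0])
    else:
        x_s = sol.y[0]
        cum_in, cum_ab, cum_resp, cum_mort, cum_enz, cum_dec = sol.y[1:7]
        m_tmp = np.array([policy(ti, np.array([xi, params.beta * xi, 0.0]))
                          for ti, xi in zip(t, x_s)])
        x_b = params.beta * x_s
        x_e = (m_tmp / params.d_e) * x_b
        delta = x_s[-1] - x_s[0]

    if min(x_s.min(), x_b.min(), x_e.min()) < -10.0 * atol:
        raise IntegrationError(
            f"negative pool encountered (min {min(x_s.min(), x_b.min(), x_e.min()):.3e}); "
            "tighten tolerances"
        )

    m_e_path = np.array(
        [policy(ti, np.array([a, b, c])) for ti, a, b, c in zip(t, x_s, x_b, x_e)]
    )
    rho_path = np.array([eca_flux(a, c, params) for a, c in zip(x_s, x_e)])
    mu_path = np.array(
        [net_specific_growth(a, m, params) for a, m in zip(x_s, m_e_path)]
    )

    budget = CarbonBudget(
        mode=mode,
        delta_pools=float(delta),
        cumulative_input=float(cum_in[-1]),
        cumulative_abiotic_loss=float(cum_ab[-1]),
        cumulative_respiration=float(cum_resp[-1]),
        cumulative_mortality_loss=float(cum_mort[-1]),
        cumulative_enzyme_decay=float(cum_enz[-1]),
        cumulative_decomposition=float(cum_dec[-1]),
    )
    frame = pd.DataFrame(
        {
            "t": t,
            "x_s": x_s,
            "x_b": x_b,
            "x_e": x_e,
            "m_e": m_e_path,
            "mu": mu_path,
            "rho": rho_path,
            "cum_input": cum_in,
            "cum_abiotic": cum_ab,
            "cum_respiration": cum_resp,
            "cum_mortality": cum_mort,
            "cum_enzyme_decay": cum_enz,
            "cum_decomposition": cum_dec,
        }
    )
    return TrajectoryResult(frame=frame, budget=budget, mode=mode)


def steady_state_soc(
    m_e: float, params: ToyModelParams, full_output: bool = False
):
    """Steady-state SOC ``X_s`` under the QSS closure for a given trait.

    Setting ``dx_s/dt = 0`` with ``x_e = (m_e/d_e)*beta*x_s`` and
    clearing the ECA denominator leaves a quadratic in ``X_s`` whose
    root product is non-positive, so exactly one root is non-negative;
    that root is the stable branch reached by forward integration from
    any positive SOC.  With ``m_e = 0`` this reduces to ``I/ell_s``.

    Returns the non-negative root (float), or ``(root, diagnostics)``
    with all roots and the implicit-equation residual when
    ``full_output`` is set.
    """
    if m_e < 0:
        raise ValueError("m_e must be non-negative")
    p = params
    z = m_e / p.d_e
    A = p.alpha * p.k_u
    B = p.alpha + z * p.beta
    a2 = p.ell_s * B + p.v_u * p.alpha * z * p.beta
    a1 = p.ell_s * A - p.input_rate * B
    a0 = -p.input_rate * A

    if a2 == 0.0:
        # m_e = 0 and ell_s = 0: no loss process at all.
        if p.input_rate == 0.0:
            roots = (0.0,)
            x = 0.0
        else:
            raise ValueError(
                "no steady state: input without any loss process "
                "(m_e = 0 and ell_s = 0)"
            )
    else:
        disc = a1 * a1 - 4.0 * a2 * a0
        assert disc >= 0.0, "root product <= 0 guarantees real roots"
        sq = math.sqrt(disc)
        # Numerically stable quadratic roots.
        q = -0.5 * (a1 + math.copysign(sq, a1) if a1 != 0.0 else -sq)
        r1 = q / a2
        r2 = a0 / q if q != 0.0 else 0.0
        roots = (r1, r2)
        nonneg = [r for r in roots if r >= -1e-14]
        assert nonneg, "a non-negative root must exist for I >= 0"
        x = max(0.0, max(nonneg))

    x_e, _ = qss_reduce(x, m_e, params)
    residual = p.input_rate - eca_flux(x, x_e, p) - p.ell_s * x
    if full_output:
        return x, {"roots": roots, "residual": residual}
    return x


def feasibility_threshold(params: ToyModelParams) -> float:
    """SOC level below which the instantaneous optimum is non-positive.

    ``eps_e*d_e*k_u / (y*v_u - eps_e*d_e)`` [mg C g^-1] when a positive
    optimum is attainable at all (``y*v_u > eps_e*d_e``), else ``+inf``.
    Independent of ``alpha``: site accessibility scales benefit and
    saturation alike.
    """
    margin = params.y * params.v_u - params.eps_e * params.d_e
    if margin <= 0.0:
        return math.inf
    return params.eps_e * params.d_e * params.k_u / margin
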