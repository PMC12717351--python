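"""Two literature-style optimal-enzyme-production models.

Both describe microbes that must release extracellular enzymes to turn
SOC into an assimilable substrate, but they sit in different corners of
the scheme classification:

* an instantaneous growth-maximisation model with a Hill-type benefit
  in ``m_e * x_s**2`` and linear enzyme plus maintenance costs, whose
  optimum is a direct, decreasing function of SOC; and
* an adaptive-dynamics model whose continuously stable strategy for the
  enzyme allocation fraction ``phi`` has the closed form
  ``phi* = 1 - (d/(y*v_u))**(1/c0)``.

Only the printed closed forms and growth-rate definitions are encoded;
the surrounding dynamical systems of the original studies are not
re-implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class CalabreseParams:
    """Parameters of the instantaneous-maximisation example.

    ``q`` groups kinetic constants (units consistent with
    ``m_e * x_s**2``), ``r_b`` is maintenance respiration [1/d], ``r_e``
    the dimensionless enzyme-production respiration overhead, ``v_u``
    the maximum growth-rate coefficient [1/d] and ``y`` the yield.
    """

    q: float
    r_b: float
    r_e: float
    v_u: float
    y: float

    def __post_init__(self) -> None:
        if min(self.q, self.v_u, self.y) <= 0 or min(self.r_b, self.r_e) < 0:
            raise ValueError(f"parameters must be positive (costs >= 0), got {self}")
        if self.y > 1.0:
            raise ValueError("yield must be <= 1")


@dataclass(frozen=True)
class AbsParams:
    """Parameters of the adaptive-dynamics allocation example."""

    d: float
    y: float
    v_u: float
    c0: float

    def __post_init__(self) -> None:
        if min(self.d, self.y, self.v_u, self.c0) <= 0:
            raise ValueError(f"all parameters must be positive, got {self}")
        if self.y > 1.0:
            raise ValueError("yield must be <= 1")


def calabrese_growth_rate(x_s: float, m_e: float, params: CalabreseParams) -> float:
    """Net specific growth rate: Hill-type uptake minus enzyme and maintenance costs.

    ``mu = y*v_u*m_e*x_s^2/(m_e*x_s^2 + q) - m_e*(1 + r_e) - r_b``
    """
    p = params
    num = m_e * x_s * x_s
    benefit = p.y * p.v_u * num / (num + p.q) if (num + p.q) > 0 else 0.0
    return benefit - m_e * (1.0 + p.r_e) - p.r_b


def calabrese_optimal_enzyme(
    x_s: float, params: CalabreseParams, approximate: bool = False
) -> float:
    """Optimal enzyme production for the Hill-benefit model.

    Exact first-order-condition solution, re-derived from
    ``d mu/d m_e = 0``::

        m_e* = sqrt(y*v_u*q/(1 + r_e))/x_s - q/x_s**2

    i.e. ``A/x_s - B/x_s**2`` with A, B positive and independent of
    SOC, so the optimum decays with SOC and turns non-positive below
    ``x_s = sqrt(q*(1 + r_e)/(y*v_u))``, where it is clamped to zero.
    With ``approximate=True`` the leading-order ``~ 1/x_s`` term is
    returned instead (no clamping), which overestimates the exact
    optimum at low SOC and converges to it as SOC grows.
    """
    p = params
    if x_s <= 0.0:
        raise ValueError("x_s must be positive")
    lead = math.sqrt(p.y * p.v_u * p.q / (1.0 + p.r_e)) / x_s
    if approximate:
        return lead
    return max(lead - p.q / (x_s * x_s), 0.0)


def calabrese_feasibility_threshold(params: CalabreseParams) -> float:
    """SOC below which the exact optimum is non-positive."""
    p = params
    return math.sqrt(p.q * (1.0 + p.r_e) / (p.y * p.v_u))


def abs_css(params: AbsParams) -> float:
    """Continuously stable enzyme-allocation fraction ``phi*``.

    ``phi* = 1 - (d/(y*v_u))**(1/c0)``; requires ``d < y*v_u`` (an
    interior strategy exists only when baseline mortality is smaller
    than the maximal assimilation rate).  Lies in (0, 1) whenever
    defined, approaches 0 as ``d -> y*v_u`` and 1 as the competitive
    advantage of producers grows or mortality vanishes.
    """
    p = params
    ratio = p.d / (p.y * p.v_u)
    if ratio >= 1.0:
        raise ValueError(
            f"no interior strategy: mortality d={p.d:g} >= y*v_u={p.y * p.v_u:g}"
        )
    phi = 1.0 - ratio ** (1.0 / p.c0)
    assert 0.0 < phi < 1.0
    return phi
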