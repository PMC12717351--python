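"""Parameter container for the minimal microbial-explicit SOC model.

The model tracks soil organic carbon (SOC), microbial biomass and
extracellular enzymes in units of mg C per g soil, with first-order rate
coefficients per day.  The nine environmental/physiological parameters,
the competition parameter ``c0`` of the adaptive-dynamics extension, and
two optional bookkeeping values (a fixed mortality for full-ODE runs and
a conventional fixed enzyme-production rate for scheme comparisons) are
collected in :class:`ToyModelParams`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass


class ParameterError(ValueError):
    """Raised when a parameter set violates a hard invariant.

    ``problems`` lists every violated constraint by field name, so a bad
    config file is diagnosed in one pass.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid parameters: " + "; ".join(self.problems))


class FeasibilityWarning(UserWarning):
    """A parameter set admits no positive trait optimum (y*v_u <= eps_e*d_e)."""


@dataclass(frozen=True)
class ToyModelParams:
    """Environmental and physiological parameters of the SOC toy model.

    Attributes
    ----------
    alpha : float
        Fraction of SOC with accessible reactive sites, dimensionless, 0 < alpha <= 1.
    beta : float
        Fraction of SOC that is microbial biomass C (QSS closure x_b = beta*x_s),
        dimensionless, 0 < beta < 1.
    eps_e : float
        Cost factor of enzyme production (respiration overhead included),
        dimensionless, > 1.
    d_e : float
        Enzyme decay rate coefficient [1/d], > 0.
    input_rate : float
        External SOC input I [mg C g^-1 d^-1], >= 0.
    k_u : float
        Half-saturation constant of the decomposition kinetics [mg C g^-1], > 0.
    ell_s : float
        Abiotic SOC loss rate coefficient (leaching, erosion) [1/d], >= 0.
    v_u : float
        Maximum decomposition rate coefficient [1/d], > 0.
    y : float
        Microbial yield, fraction of decomposition flux not respired,
        0 < y <= 1.
    c0 : float
        Competitive-advantage exponent of the adaptive-dynamics competition
        kernel, dimensionless, >= 0.
    d_fixed : float
        Mortality rate coefficient used in full-ODE mode [1/d], >= 0.
    m_e_fixed : float or None
        Conventional fixed enzyme-production rate [1/d] used by the "fixed"
        parametrization in scheme-comparison sweeps; optional.
    """

    alpha: float
    beta: float
    eps_e: float
    d_e: float
    input_rate: float
    k_u: float
    ell_s: float
    v_u: float
    y: float
    c0: float = 0.5
    d_fixed: float = 0.0
    m_e_fixed: float | None = None

    def __post_init__(self) -> None:
        problems = []
        if not (0.0 < self.alpha <= 1.0):
            problems.append(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 < self.beta < 1.0):
            problems.append(f"beta must be in (0, 1), got {self.beta}")
        if not self.eps_e > 1.0:
            problems.append(
                f"eps_e must exceed 1 (enzyme production carries a respiration "
                f"overhead), got {self.eps_e}"
            )
        if not self.d_e > 0.0:
            problems.append(f"d_e must be > 0, got {self.d_e}")
        if not self.input_rate >= 0.0:
            problems.append(f"input_rate must be >= 0, got {self.input_rate}")
        if not self.k_u > 0.0:
            problems.append(f"k_u must be > 0, got {self.k_u}")
        if not self.ell_s >= 0.0:
            problems.append(f"ell_s must be >= 0, got {self.ell_s}")
        if not self.v_u > 0.0:
            problems.append(f"v_u must be > 0, got {self.v_u}")
        if not (0.0 < self.y <= 1.0):
            problems.append(f"y must be in (0, 1], got {self.y}")
        if not self.c0 >= 0.0:
            problems.append(f"c0 must be >= 0, got {self.c0}")
        if not self.d_fixed >= 0.0:
            problems.append(f"d_fixed must be >= 0, got {self.d_fixed}")
        if self.m_e_fixed is not None and not self.m_e_fixed >= 0.0:
            problems.append(f"m_e_fixed must be >= 0, got {self.m_e_fixed}")
        if problems:
            raise ParameterError(problems)
        if not self.y * self.v_u > self.eps_e * self.d_e:
            # Soft invariant: without it no SOC level supports a positive
            # instantaneous optimum. Valid parameters, degenerate optimum.
            warnings.warn(
                "y*v_u <= eps_e*d_e: enzyme production can never pay off, "
                "all trait optima will be clamped to zero",
                FeasibilityWarning,
                stacklevel=2,
            )

    @property
    def m_e_max(self) -> float:
        """Upper trait bound [1/d].

        Under the QSS closure the per-biomass uptake is bounded by
        ``y*v_u*alpha/beta`` (the ECA denominator is at least the
        enzyme term ``z*beta*x_s``), so beyond
        ``y*v_u*alpha/(eps_e*beta)`` the linear enzyme cost exceeds any
        possible benefit and the net specific growth rate is negative
        at every SOC level; all trait searches are bracketed by this
        bound.
        """
        return self.y * self.v_u * self.alpha / (self.eps_e * self.beta)

    def replace(self, **changes) -> "ToyModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
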