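"""Scheme-comparison experiments: input-rate sweeps and emergent curves.

The central comparison runs every optimization scheme across a grid of
SOC input rates and records, for each, the predicted trait and the
steady-state SOC it produces.  Because the input rate moves the
equilibrium SOC, each scheme traces an *emergent* trait-SOC relation
even when its optimum is formally a function of parameters only; the
instantaneous scheme's curve is instead the direct function
``m_e*(X_s)`` evaluated along its self-consistent equilibria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import engine, model
from .params import ToyModelParams

SCHEMES = ("inst", "eq", "ad", "fixed")


@dataclass
class SweepResult:
    """Rows of (input rate, scheme, trait, steady-state SOC, diagnostics)."""

    frame: pd.DataFrame
    params: ToyModelParams
    m_e_fixed: float | None
    i_grid: np.ndarray = field(default=None)


def default_input_grid(n: int = 60, lo: float = 1e-3, hi: float = 1e1) -> np.ndarray:
    """Log-spaced input-rate grid [mg C g^-1 d^-1] spanning four decades."""
    return np.geomspace(lo, hi, n)


def self_consistent_instantaneous(
    params: ToyModelParams, tol: float = 1e-12, max_iter: int = 200
) -> tuple[float, float]:
    """Fixed point where the trait is instantaneously optimal at the SOC it creates.

    At steady state the instantaneous scheme must satisfy
    ``m = m_inst*(X_s(m))``; solved by damped fixed-point iteration with
    a bracketing (brentq) fallback on the composite map.  Returns
    ``(m_e, X_s)``; ``m_e = 0`` when no positive self-consistent
    optimum exists (SOC stays below the feasibility threshold).
    """
    thr = model.feasibility_threshold(params)

    def inst_at(m):
        x = model.steady_state_soc(m, params)
        if x <= thr:
            return 0.0
        return engine.instantaneous_closed_form(x, params)

    # The no-enzyme equilibrium is the largest attainable SOC; if even it
    # is below threshold there is no positive fixed point.
    if model.steady_state_soc(0.0, params) <= thr:
        return 0.0, model.steady_state_soc(0.0, params)

    m = inst_at(0.0)
    for _ in range(max_iter):
        m_new = 0.5 * m + 0.5 * inst_at(m)
        if abs(m_new - m) <= tol * max(m_new, 1e-12):
            m = m_new
            break
        m = m_new
    else:
        # Damped iteration stalled: bracket the root of m - inst_at(m).
        g = lambda mm: mm - inst_at(mm)  # noqa: E731
        hi = params.m_e_max
        lo = 1e-12 * hi
        if g(lo) * g(hi) > 0:
            return 0.0, model.steady_state_soc(0.0, params)
        m = brentq(g, lo, hi, xtol=1e-14)
    if m <= 0.0:
        return 0.0, model.steady_state_soc(0.0, params)
    return m, model.steady_state_soc(m, params)


def sweep_input_rate(
    params: ToyModelParams,
    i_grid: np.ndarray | None = None,
    schemes: tuple[str, ...] = SCHEMES,
    m_e_fixed: float | None = None,
    include_reference: bool = True,
) -> SweepResult:
    """Per-scheme optima and steady states across SOC input rates.

    For each input rate ``I`` and scheme the predicted trait, the
    resulting steady-state SOC, the net specific growth rate there and
    a feasibility flag are recorded.  Infeasible cases (clamped optima,
    or a fixed parametrization whose growth rate is negative at its own
    equilibrium, or an adaptive-dynamics resident whose emergent
    mortality would be negative) keep ``m_e_star = 0`` or the computed
    trait with ``feasible = False`` -- never a negative rate.  With
    ``include_reference`` a microbe-free row (``m_e = 0``,
    ``X_s = I/ell_s``) is added per input rate under scheme ``"none"``.
    """
    if i_grid is None:
        i_grid = default_input_grid()
    i_grid = np.asarray(i_grid, dtype=float)
    if np.any(i_grid <= 0) or np.any(np.diff(i_grid) <= 0):
        raise ValueError("i_grid must be positive and strictly increasing")
    unknown = set(schemes) - set(SCHEMES)
    if unknown:
        raise ValueError(f"unknown schemes: {sorted(unknown)}")
    if "fixed" in schemes:
        if m_e_fixed is None:
            m_e_fixed = params.m_e_fixed
        if m_e_fixed is None:
            raise ValueError("scheme 'fixed' needs m_e_fixed (argument or params)")

    kernel = engine.kernel_for(params)
    rows = []
    for I in i_grid:
        p = params.replace(input_rate=float(I))
        if include_reference:
            x_ref = model.steady_state_soc(0.0, p)
            rows.append((I, "none", 0.0, x_ref, 0.0, True))
        for scheme in schemes:
            if scheme == "inst":
                m, x = self_consistent_instantaneous(p)
                mu = model.net_specific_growth(x, m, p)
                ok = m > 0.0 and mu > 0.0
            elif scheme == "eq":
                opt = engine.maximize_equilibrium(p)
                m, x, mu, ok = opt.value, opt.context, opt.objective_value, opt.feasible
            elif scheme == "ad":
                ss = engine.find_singular_strategy(p, kernel)
                if ss is None:
                    m, x, mu, ok = 0.0, model.steady_state_soc(0.0, p), 0.0, False
                else:
                    m, x = ss.value, ss.context
                    mu = model.net_specific_growth(x, m, p)
                    # viable resident: non-negative emergent mortality
                    _, _, d_star = engine.resident_environment(m, p)
                    ok = ss.is_css and d_star >= 0.0
            else:  # fixed
                m = float(m_e_fixed)
                x = model.steady_state_soc(m, p)
                mu = model.net_specific_growth(x, m, p)
                ok = mu > 0.0
            rows.append((I, scheme, m, x, mu, ok))
    frame = pd.DataFrame(
        rows, columns=["input_rate", "scheme", "m_e_star", "X_s", "mu_star", "feasible"]
    )
    return SweepResult(frame=frame, params=params, m_e_fixed=m_e_fixed, i_grid=i_grid)


def emergent_trait_soc_curve(sweep: SweepResult, scheme: str) -> pd.DataFrame:
    """The (X_s, m_e*) relation a scheme traces across input rates.

    Feasible rows sorted by SOC with finite-difference slope
    diagnostics (``dm_dX`` on each segment, attached to the segment's
    right endpoint).  Emits a warning-laden partial result when fewer
    than two feasible rows exist.
    """
    sub = sweep.frame[(sweep.frame["scheme"] == scheme) & sweep.frame["feasible"]]
    sub = sub.sort_values("X_s").reset_index(drop=True)
    if len(sub) < 2:
        import warnings

        warnings.warn(
            f"scheme {scheme!r}: fewer than 2 feasible rows; no slopes computed",
            stacklevel=2,
        )
        sub["dm_dX"] = np.nan
        return sub
    dm = np.diff(sub["m_e_star"].to_numpy())
    dx = np.diff(sub["X_s"].to_numpy())
    slope = np.full(len(sub), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope[1:] = np.where(dx != 0, dm / dx, np.nan)
    sub["dm_dX"] = slope
    return sub


def monotone_decrease_onset(sweep: SweepResult, scheme: str) -> float:
    """Smallest SOC beyond which the trait-SOC curve only decreases.

    Returns the ``X_s`` of the last local rise in the scheme's emergent
    curve (0 when the curve decreases everywhere, ``inf`` when it never
    settles into a decrease).
    """
    curve = emergent_trait_soc_curve(sweep, scheme)
    slopes = curve["dm_dX"].to_numpy()[1:]
    xs = curve["X_s"].to_numpy()[1:]
    rising = xs[slopes >= 0.0]
    if len(rising) == 0:
        return 0.0
    if rising[-1] == xs[-1]:
        return float("inf")
    return float(rising[-1])


def feasible_input_range(
    params: ToyModelParams,
    scheme: str,
    i_grid: np.ndarray | None = None,
    m_e_fixed: float | None = None,
) -> tuple[float, float]:
    """Smallest feasible input rate and feasible fraction for one scheme.

    Feasibility means a positive trait with a positive growth rate at
    the resulting equilibrium (see :func:`sweep_input_rate`); the
    returned tuple is ``(I_min_feasible, fraction_feasible)`` with
    ``I_min = inf`` when no grid point is feasible.
    """
    if i_grid is None:
        i_grid = default_input_grid()
    res = sweep_input_rate(
        params, i_grid, schemes=(scheme,), m_e_fixed=m_e_fixed,
        include_reference=False,
    )
    sub = res.frame
    feas = sub[sub["feasible"]]
    frac = len(feas) / len(sub)
    i_min = float(feas["input_rate"].min()) if len(feas) else float("inf")
    return i_min, frac


def low_soc_comparison(sweep: SweepResult) -> dict[str, float]:
    """Trait values of the three adaptive schemes at the low-SOC end.

    Evaluated at the smallest SOC where the adaptive-dynamics curve is
    feasible: the AD value there, the instantaneous optimum as a direct
    function of that SOC, and the equilibrium curve interpolated to it
    (0 when the equilibrium scheme is infeasible that low).  At low SOC
    the competition for scarce depolymerization products keeps the AD
    enzyme investment high while both growth-maximisation schemes
    collapse toward zero.
    """
    ad = emergent_trait_soc_curve(sweep, "ad")
    if len(ad) == 0:
        raise ValueError("adaptive-dynamics curve has no feasible rows")
    x_low = float(ad["X_s"].iloc[0])
    out = {"X_s": x_low, "ad": float(ad["m_e_star"].iloc[0])}
    thr = model.feasibility_threshold(sweep.params)
    if x_low > thr:
        out["inst"] = engine.instantaneous_closed_form(x_low, sweep.params)
    else:
        out["inst"] = 0.0
    eq = emergent_trait_soc_curve(sweep, "eq")
    if len(eq) and eq["X_s"].iloc[0] <= x_low:
        out["eq"] = float(
            np.interp(x_low, eq["X_s"].to_numpy(), eq["m_e_star"].to_numpy())
        )
    else:
        out["eq"] = 0.0
    return out
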