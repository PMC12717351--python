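"""Time-integrated trait optimization by direct transcription.

Finite-horizon problem on the QSS-reduced model: choose the enzyme
production trajectory ``m_e(t)`` to maximise cumulative net specific
growth ``J = int_0^T mu(x_s(t), m_e(t)) dt``, with SOC evolving as
``dx_s/dt = I - rho - ell_s*x_s`` under the enzyme/biomass closure.
The control is discretized as piecewise-constant on ``n_intervals``
segments and the finite-dimensional problem is solved with a bounded
quasi-Newton method from several starts; gradients come from the
adjoint (costate) equation, whose terminal condition is free
(``lambda(T) = 0``).

First-order necessary conditions are checked a posteriori through
:func:`pontryagin_residuals`: stationarity of the Hamiltonian
``H = mu + lambda*(I - rho - ell_s*x_s)`` in the control on interior
segments, and constancy of ``H`` along the optimum (first integral of
the autonomous problem).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from . import model
from .params import ToyModelParams

_FD_X = 1e-7  # relative step for state derivatives in the adjoint


class ControlSolverError(RuntimeError):
    """Optimizer failed to converge; the best trajectory found is attached."""

    def __init__(self, message: str, best: "ControlTrajectory | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class OCProblem:
    """A finite-horizon trait-trajectory optimization problem.

    ``objective="specific"`` integrates the per-biomass growth rate mu
    (the fitness measure of the growth-maximisation schemes);
    ``objective="absolute"`` weights it by biomass, integrating
    ``mu * beta * x_s``.
    """

    params: ToyModelParams
    x_s0: float
    horizon: float
    n_intervals: int
    objective: str = "specific"

    def __post_init__(self) -> None:
        if self.horizon <= 0.0:
            raise ValueError("horizon must be positive")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.x_s0 < 0.0:
            raise ValueError("x_s0 must be non-negative")
        if self.objective not in ("specific", "absolute"):
            raise ValueError("objective must be 'specific' or 'absolute'")

    def running_cost(self, x_s: float, m_e: float) -> float:
        mu = model.net_specific_growth(x_s, m_e, self.params)
        if self.objective == "absolute":
            return mu * self.params.beta * x_s
        return mu


@dataclass
class ControlTrajectory:
    """Solution of a direct-transcription run with necessary-condition data."""

    t_grid: np.ndarray            # interval edges, length n_intervals+1
    controls: np.ndarray          # piecewise-constant m_e, length n_intervals
    objective: float              # J
    frame: pd.DataFrame           # dense t, x_s, m_e, mu, lambda, H, dH/dm_e
    stationarity_residuals: np.ndarray = field(default=None)  # per interval
    hamiltonian_drift: float = float("nan")
    n_starts_converged: int = 0


def _soc_rhs(x_s: float, m_e: float, p: ToyModelParams) -> float:
    x_e, _ = model.qss_reduce(x_s, m_e, p)
    return p.input_rate - model.eca_flux(x_s, x_e, p) - p.ell_s * x_s


def _forward(problem: OCProblem, controls: np.ndarray, rtol: float = 1e-10):
    """Integrate state and running objective; returns (J, per-interval sols)."""
    p = problem.params
    edges = np.linspace(0.0, problem.horizon, problem.n_intervals + 1)
    sols = []
    x, J = problem.x_s0, 0.0
    for j, m in enumerate(controls):
        def rhs(t, yv, m=m):
            return [_soc_rhs(yv[0], m, p), problem.running_cost(yv[0], m)]

        sol = solve_ivp(rhs, (edges[j], edges[j + 1]), [x, J], method="LSODA",
                        rtol=rtol, atol=1e-12, dense_output=True)
        if not sol.success:
            raise model.IntegrationError(f"forward pass failed: {sol.message}")
        sols.append(sol)
        x, J = sol.y[0, -1], sol.y[1, -1]
    return J, edges, sols


def _dmu_dm(x_s: float, m_e: float, problem: OCProblem) -> float:
    h = 1e-6 * max(m_e, 1.0)
    lo = max(m_e - h, 0.0)
    return (problem.running_cost(x_s, m_e + h) - problem.running_cost(x_s, lo)) / (
        m_e + h - lo
    )


def _df_dx(x_s: float, m_e: float, p: ToyModelParams) -> float:
    h = _FD_X * max(abs(x_s), 1.0)
    return (_soc_rhs(x_s + h, m_e, p) - _soc_rhs(x_s - h, m_e, p)) / (2.0 * h)


def _dmu_dx(x_s: float, m_e: float, problem: OCProblem) -> float:
    h = _FD_X * max(abs(x_s), 1.0)
    return (
        problem.running_cost(x_s + h, m_e) - problem.running_cost(x_s - h, m_e)
    ) / (2.0 * h)


def _backward(problem: OCProblem, edges, sols, controls):
    """Adjoint sweep; returns (lambda at edges, gradient dJ/dm_j)."""
    p = problem.params
    lam = 0.0  # free terminal state
    lam_edges = [lam]
    grad = np.zeros_like(controls)
    for j in range(problem.n_intervals - 1, -1, -1):
        m = controls[j]
        fwd = sols[j]

        def rhs(t, yv, m=m, fwd=fwd):
            x = fwd.sol(t)[0]
            dlam = -(_dmu_dx(x, m, problem) + yv[0] * _df_dx(x, m, p))
            # quadrature of dH/dm along the interval (integrated backward)
            dq = _dmu_dm(x, m, problem) + yv[0] * _df_dm(x, m, p)
            return [dlam, dq]

        sol = solve_ivp(rhs, (edges[j + 1], edges[j]), [lam, 0.0],
                        method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise model.IntegrationError(f"adjoint pass failed: {sol.message}")
        lam = sol.y[0, -1]
        grad[j] = -sol.y[1, -1]  # backward integration flips the sign
        lam_edges.append(lam)
    return np.array(lam_edges[::-1]), grad


def _df_dm(x_s: float, m_e: float, p: ToyModelParams) -> float:
    h = 1e-6 * max(m_e, 1.0)
    lo = max(m_e - h, 0.0)
    return (_soc_rhs(x_s, m_e + h, p) - _soc_rhs(x_s, lo, p)) / (m_e + h - lo)


def solve_time_integrated(
    problem: OCProblem,
    n_starts: int = 5,
    seed: int = 0,
    pgtol: float = 1e-6,
    x0: np.ndarray | None = None,
) -> ControlTrajectory:
    """Maximise the time-integrated objective by direct transcription.

    Multi-start bounded L-BFGS-B on the piecewise-constant control
    vector, with adjoint gradients (``dJ/dm_j`` equals the integral of
    ``dH/dm_e`` over interval ``j``).  Starts: an optional warm start
    ``x0`` (e.g. a coarser solution, repeated), the instantaneous
    optimum at the initial SOC held constant, a mid-bound constant, and
    seeded random constants.  A start counts as converged when the
    optimizer reports success or its projected gradient is within 10x
    of ``pgtol``; raises :class:`ControlSolverError` with the best
    trajectory attached if no start converges.
    """
    p = problem.params
    m_max = p.m_e_max
    rng = np.random.default_rng(seed)
    from . import engine

    starts = []
    if x0 is not None:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (problem.n_intervals,):
            raise ValueError("x0 must have length n_intervals")
        starts.append(np.clip(x0, 0.0, m_max))
    inst = engine.maximize_instantaneous(max(problem.x_s0, 1e-12), p) \
        if problem.x_s0 > 0 else None
    if inst is not None and inst.feasible:
        starts.append(np.full(problem.n_intervals, inst.value))
    starts.append(np.full(problem.n_intervals, 0.5 * m_max))
    while len(starts) < n_starts:
        starts.append(np.full(problem.n_intervals, rng.uniform(0.02, 0.98) * m_max))

    def neg_J_and_grad(mvec):
        J, edges, sols = _forward(problem, mvec)
        _, grad = _backward(problem, edges, sols, mvec)
        return -J, -grad

    def projected_grad(x, jac):
        g = np.where((x <= 1e-12) & (jac > 0), 0.0, jac)
        g = np.where((x >= m_max - 1e-12) & (g < 0), 0.0, g)
        return float(np.max(np.abs(g)))

    best = None
    n_ok = 0
    for s0 in starts:
        res = minimize(
            neg_J_and_grad, s0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, m_max)] * problem.n_intervals,
            options={"gtol": pgtol, "ftol": 1e-13, "maxiter": 300},
        )
        if res.success or projected_grad(res.x, res.jac) <= 10.0 * pgtol:
            n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    controls = np.clip(best.x, 0.0, m_max)
    traj = _assemble(problem, controls, n_ok)
    if n_ok == 0:
        raise ControlSolverError(
            f"no optimizer start converged ({best.message})", best=traj
        )
    return traj


def _assemble(problem: OCProblem, controls: np.ndarray, n_ok: int) -> ControlTrajectory:
    p = problem.params
    J, edges, sols = _forward(problem, controls)
    lam_edges, grad = _backward(problem, edges, sols, controls)

    # Dense diagnostics: state, adjoint, Hamiltonian along the path.
    rows = []
    for j, sol in enumerate(sols):
        ts = np.linspace(edges[j], edges[j + 1], 21)
        m = controls[j]

        # re-integrate adjoint densely on this interval
        def rhs(t, yv, m=m, sol=sol):
            x = sol.sol(t)[0]
            return [-(_dmu_dx(x, m, problem) + yv[0] * _df_dx(x, m, p))]

        lam_sol = solve_ivp(rhs, (edges[j + 1], edges[j]), [lam_edges[j + 1]],
                            method="LSODA", rtol=1e-11, atol=1e-13,
                            dense_output=True)
        for t in ts:
            x = sol.sol(t)[0]
            lam = lam_sol.sol(t)[0]
            H = problem.running_cost(x, m) + lam * _soc_rhs(x, m, p)
            dHdm = _dmu_dm(x, m, problem) + lam * _df_dm(x, m, p)
            rows.append((t, x, m, model.net_specific_growth(x, m, p), lam, H, dHdm))
    frame = pd.DataFrame(
        rows, columns=["t", "x_s", "m_e", "mu", "lambda", "H", "dH_dm"]
    ).drop_duplicates(subset="t").reset_index(drop=True)

    lengths = np.diff(edges)
    avg_resid = np.abs(grad) / lengths  # interval-averaged dH/dm
    H_vals = frame["H"].to_numpy()
    drift = float(np.max(H_vals) - np.min(H_vals))
    return ControlTrajectory(
        t_grid=edges,
        controls=controls,
        objective=float(J),
        frame=frame,
        stationarity_residuals=avg_resid,
        hamiltonian_drift=drift,
        n_starts_converged=n_ok,
    )


def evaluate_controls(problem: OCProblem, controls) -> ControlTrajectory:
    """Diagnostics for an arbitrary (not necessarily optimal) control path."""
    controls = np.asarray(controls, dtype=float)
    if controls.shape != (problem.n_intervals,):
        raise ValueError("controls must have length n_intervals")
    return _assemble(problem, controls, n_ok=0)


@dataclass(frozen=True)
class ResidualSummary:
    """Necessary-condition residuals of a control trajectory."""

    max_interior_stationarity: float
    hamiltonian_drift: float
    terminal_adjoint: float
    interior_mask: np.ndarray


def pontryagin_residuals(
    traj: ControlTrajectory, problem: OCProblem, bound_tol: float = 1e-9
) -> ResidualSummary:
    """First-order optimality diagnostics for a returned trajectory.

    Interval-averaged ``|dH/dm_e|`` over segments whose control is
    strictly inside the bounds (at active bounds the stationarity
    condition is an inequality and is skipped), plus the peak-to-peak
    Hamiltonian drift: for a time-invariant input the Hamiltonian is a
    first integral and should be constant along an optimum up to
    discretization error.
    """
    m_max = problem.params.m_e_max
    interior = (traj.controls > bound_tol) & (traj.controls < m_max - bound_tol)
    resid = traj.stationarity_residuals
    max_int = float(np.max(resid[interior])) if interior.any() else 0.0
    lam_T = float(traj.frame["lambda"].iloc[-1])
    return ResidualSummary(
        max_interior_stationarity=max_int,
        hamiltonian_drift=traj.hamiltonian_drift,
        terminal_adjoint=lam_T,
        interior_mask=interior,
    )
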