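"""Forward integration of the two-pool reaction-advection-diffusion system.

The governing equations on the cross-section ``Omega = [-L, L]`` are

    dS/dt = -d/dx J_S - R(S, I, x),      J_S = -D_S dS/dx,
    dI/dt = -d/dx J_I + R(S, I, x),      J_I = -D_I dI/dx - sgn(x) c(x) I,

where ``R`` is the net assembly rate (module :mod:`keradyn.scenarios`),
``c(x)`` is the scenario's drift speed (zero, ``v(x)`` or ``u(x)``) and
``sgn`` is realized by the smooth logistic sign with smoothing length
1 um.  Both fluxes vanish at ``x = +/-L`` (impermeable plasma membrane),
so total keratin mass is conserved exactly by the spatial scheme.

Discretization: node-centred finite volumes on the uniform 200-point
grid.  Diffusive interface fluxes are central; the advective flux is
first-order upwinded in the local drift direction, which keeps the scheme
monotone across the sign change of the drift at the cell centre.  The
advection term is discretized in conservative (flux-difference) form:
together with the zero boundary fluxes this makes mass conservation a
structural property rather than an accuracy statement.  Time integration
uses a stiff implicit method (BDF) since the reaction timescale (~60 s)
is far shorter than the transport timescales (hours to weeks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .profiles import (
    FixedParameters,
    SpatialGrid,
    eval_drift_speed_const,
    eval_drift_speed_var,
    eval_f0,
    smooth_sgn,
)
from .scenarios import (
    ScenarioSpec,
    TurnoverParameters,
    assembly_rate_profile,
    disassembly_rate_profile,
)

__all__ = [
    "T0_SECONDS",
    "T_FINAL_SECONDS",
    "SOLUBLE_FRACTION_T0",
    "KeratinState",
    "Trajectory",
    "IntegrationError",
    "initial_state",
    "drift_speed",
    "flux_I",
    "integrate",
    "pool_fractions",
    "export_trajectory_csv",
]

HOUR = 3600.0
T0_SECONDS = 24.0 * HOUR       # start of the observation window
T_FINAL_SECONDS = 48.0 * HOUR  # time of the target profile

# The soluble pool holds 5% of the keratin material at 24 h, the insoluble
# pool 95%; S0 = (0.05/0.95) * I0 pointwise.
SOLUBLE_FRACTION_T0 = 0.05 / 0.95

RTOL_DEFAULT = 1e-6
ATOL_DEFAULT = 1e-6  # uM


class IntegrationError(RuntimeError):
    """Raised when the time integrator fails (e.g. step-size collapse)."""


@dataclass(frozen=True)
class KeratinState:
    """Paired soluble/insoluble concentration profiles at one time."""

    S: NDArray[np.float64]
    I: NDArray[np.float64]
    t: float

    def __post_init__(self) -> None:
        if self.S.shape != self.I.shape:
            raise ValueError("S and I must have the same shape")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered sequence of states for one scenario integration."""

    states: tuple[KeratinState, ...]
    scenario: ScenarioSpec
    params: TurnoverParameters
    grid: SpatialGrid = field(repr=False, default_factory=SpatialGrid)

    def __post_init__(self) -> None:
        times = [s.t for s in self.states]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("state times must be strictly increasing")

    @property
    def times(self) -> NDArray[np.float64]:
        return np.array([s.t for s in self.states])

    def state_at(self, t: float) -> KeratinState:
        for state in self.states:
            if np.isclose(state.t, t, rtol=0, atol=1e-6):
                return state
        raise KeyError(f"no state stored at t = {t} s")

    @property
    def final(self) -> KeratinState:
        return self.states[-1]


def initial_state(grid: SpatialGrid) -> KeratinState:
    """Shared initial condition at 24 h: ``I = f0(x)`` and
    ``S = (0.05/0.95) f0(x)``, i.e. a 5%/95% soluble/insoluble split."""
    I0 = eval_f0(grid.x)
    return KeratinState(S=SOLUBLE_FRACTION_T0 * I0, I=I0, t=T0_SECONDS)


def drift_speed(spec: ScenarioSpec, x: ArrayLike,
                fixed: FixedParameters) -> NDArray[np.float64]:
    """Magnitude of the scenario's active-transport speed at ``x``."""
    x = np.asarray(x, dtype=float)
    if spec.drift == "none":
        return np.zeros_like(x)
    if spec.drift == "const_speed":
        return eval_drift_speed_const(x, fixed)
    return eval_drift_speed_var(x)


def _interface_positions(grid: SpatialGrid) -> NDArray[np.float64]:
    """All n+1 finite-volume interfaces: the two membrane boundaries plus
    the midpoints between adjacent nodes."""
    mid = 0.5 * (grid.x[:-1] + grid.x[1:])
    return np.concatenate(([-grid.L], mid, [grid.L]))


def _cell_widths(grid: SpatialGrid) -> NDArray[np.float64]:
    w = np.full(grid.n_points, grid.dx)
    w[0] = w[-1] = 0.5 * grid.dx
    return w


def flux_I(spec: ScenarioSpec, I: ArrayLike, grid: SpatialGrid,
           fixed: FixedParameters | None = None) -> NDArray[np.float64]:
    """Insoluble-pool flux at every finite-volume interface (uM um/s).

    ``J_I = -D_I dI/dx - sgn(x) c(x) I`` with the diffusive part central
    and the advective part upwinded; the boundary entries are exactly
    zero.  Returned array has length ``n_points + 1`` and is aligned with
    the interfaces of :func:`_interface_positions`.
    """
    fixed = fixed or FixedParameters()
    I = np.asarray(I, dtype=float)
    x_if = _interface_positions(grid)[1:-1]
    # advective velocity of the insoluble pool at interior interfaces;
    # negative for x > 0 (inward drift)
    vel = -smooth_sgn(x_if) * drift_speed(spec, x_if, fixed)
    diff = -fixed.D_I * (I[1:] - I[:-1]) / grid.dx
    upwind = np.where(vel > 0, I[:-1], I[1:])
    interior = diff + vel * upwind
    return np.concatenate(([0.0], interior, [0.0]))


def _rhs_factory(spec: ScenarioSpec, params: TurnoverParameters,
                 grid: SpatialGrid, fixed: FixedParameters):
    """Build the semi-discrete right-hand side ``dy/dt = f(t, y)`` with
    ``y = [S; I]`` and all spatial fields precomputed."""
    n = grid.n_points
    dx = grid.dx
    widths = _cell_widths(grid)
    x_if = _interface_positions(grid)[1:-1]
    vel = -smooth_sgn(x_if) * drift_speed(spec, x_if, fixed)
    vel_pos = np.maximum(vel, 0.0)
    vel_neg = np.minimum(vel, 0.0)
    D_S, D_I = fixed.D_S, fixed.D_I

    # rate profiles scale linearly with their level, but precomputing at
    # the actual level keeps the reaction evaluation a pure array product
    kass_x = assembly_rate_profile(spec, params.k_ass, grid.x, L=grid.L)
    kdis_x = disassembly_rate_profile(spec, params.k_dis, grid.x, L=grid.L)
    nonlinear = spec.turnover == "nonlinear"
    k_S = params.k_S
    k_I = params.k_I

    def rhs(t: float, y: NDArray[np.float64]) -> NDArray[np.float64]:
        S = y[:n]
        I = y[n:]
        # reaction, evaluated on clipped concentrations for robustness
        # against tiny negative undershoots within solver tolerance
        Sc = np.maximum(S, 0.0)
        Ic = np.maximum(I, 0.0)
        if nonlinear:
            R = kass_x * Sc / (k_S + Sc) - kdis_x * Ic / (k_I + Ic)
        else:
            R = kass_x * Sc - kdis_x * Ic

        # interior interface fluxes (boundary fluxes are identically 0)
        flux_S = -D_S * (S[1:] - S[:-1]) / dx
        flux_Ii = (-D_I * (I[1:] - I[:-1]) / dx
                   + vel_pos * I[:-1] + vel_neg * I[1:])

        dS = np.empty(n)
        dI = np.empty(n)
        dS[0] = -flux_S[0] / widths[0]
        dS[1:-1] = -(flux_S[1:] - flux_S[:-1]) / widths[1:-1]
        dS[-1] = flux_S[-1] / widths[-1]
        dI[0] = -flux_Ii[0] / widths[0]
        dI[1:-1] = -(flux_Ii[1:] - flux_Ii[:-1]) / widths[1:-1]
        dI[-1] = flux_Ii[-1] / widths[-1]
        dS -= R
        dI += R
        return np.concatenate((dS, dI))

    return rhs


def _jacobian_sparsity(n: int) -> lil_matrix:
    """Sparsity pattern of the semi-discrete system: tridiagonal coupling
    within each pool plus diagonal reaction coupling between pools."""
    pattern = lil_matrix((2 * n, 2 * n), dtype=np.int8)
    idx = np.arange(n)
    for block in (0, n):
        pattern[block + idx, block + idx] = 1
        pattern[block + idx[:-1], block + idx[1:]] = 1
        pattern[block + idx[1:], block + idx[:-1]] = 1
    pattern[idx, n + idx] = 1
    pattern[n + idx, idx] = 1
    return pattern


def integrate(spec: ScenarioSpec, params: TurnoverParameters,
              grid: SpatialGrid | None = None,
              fixed: FixedParameters | None = None,
              t_end: float = T_FINAL_SECONDS,
              rtol: float = RTOL_DEFAULT, atol: float = ATOL_DEFAULT,
              output_times: ArrayLike | None = None,
              y0: KeratinState | None = None) -> Trajectory:
    """Integrate a scenario from 24 h to ``t_end`` (default 48 h).

    Returns a :class:`Trajectory` with states at ``output_times``
    (which always include the start and ``t_end``).  Invalid inputs raise
    ``ValueError``; a failure of the time stepper raises
    :class:`IntegrationError`.
    """
    params.require_for(spec)
    grid = grid or SpatialGrid()
    fixed = fixed or FixedParameters()
    if t_end <= T0_SECONDS:
        raise ValueError("t_end must exceed the 24 h initial time")

    state0 = y0 if y0 is not None else initial_state(grid)
    if state0.S.shape[0] != grid.n_points:
        raise ValueError("initial state does not match the grid")

    if output_times is None:
        t_eval = np.array([T0_SECONDS, t_end])
    else:
        t_eval = np.unique(np.concatenate(
            (np.atleast_1d(np.asarray(output_times, dtype=float)),
             [T0_SECONDS, t_end])))
        if t_eval[0] < T0_SECONDS or t_eval[-1] > t_end:
            raise ValueError("output times must lie in [24 h, t_end]")

    rhs = _rhs_factory(spec, params, grid, fixed)
    sol = solve_ivp(
        rhs, (T0_SECONDS, t_end),
        np.concatenate((state0.S, state0.I)),
        method="BDF", t_eval=t_eval, rtol=rtol, atol=atol,
        jac_sparsity=_jacobian_sparsity(grid.n_points),
    )
    if not sol.success:
        raise IntegrationError(
            f"scenario {spec.index} integration failed: {sol.message}")

    n = grid.n_points
    states = tuple(
        KeratinState(S=sol.y[:n, j].copy(), I=sol.y[n:, j].copy(),
                     t=float(sol.t[j]))
        for j in range(sol.t.size))
    return Trajectory(states=states, scenario=spec, params=params, grid=grid)


def pool_fractions(state: KeratinState,
                   grid: SpatialGrid) -> tuple[float, float]:
    """Percentage of the total keratin material in the soluble and
    insoluble pools, from trapezoidal integrals over the domain."""
    mass_S = float(np.trapezoid(state.S, grid.x))
    mass_I = float(np.trapezoid(state.I, grid.x))
    total = mass_S + mass_I
    if total <= 0:
        raise ValueError("total keratin mass is zero")
    return 100.0 * mass_S / total, 100.0 * mass_I / total


def total_mass(state: KeratinState, grid: SpatialGrid) -> float:
    """Total keratin material (uM um) — conserved by every scenario."""
    return float(np.trapezoid(state.S + state.I, grid.x))


def export_trajectory_csv(path, traj: Trajectory) -> None:
    """Write a trajectory as long-format CSV (t_s, x_um, S_uM, I_uM)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "x_um", "S_uM", "I_uM"])
        for state in traj.states:
            for x, s, i in zip(traj.grid.x, state.S, state.I):
                writer.writerow([state.t, x, s, i])
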