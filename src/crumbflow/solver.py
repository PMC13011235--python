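"""Steady-state Stokes-flow solver: boundary tables, time stepping with
L2 convergence monitoring, Darcy permeability extraction.

The flow is driven by a uniform body force F along one axis, equivalent to
an imposed pressure gradient dP/dx = -F under periodic boundaries.  The
update iterates collide -> force -> stream -> bounce-back on fluid nodes
until the relative L2 change of the velocity field (or of the superficial
velocity, criterion ``"flux"``) per iteration drops below ``epsilon``.
Checks happen every ``check_interval`` iterations; the change measured
between checks is compared against ``epsilon * check_interval``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import DomainGeometry
from .moments import RelaxationVector, relaxation_frequencies, viscosity
from .stencil import D2Q9, D3Q27, StencilSpec
from .units import DARCY_M2, convert_units

__all__ = [
    "SimulationConfig",
    "FlowSolution",
    "PermeabilityResult",
    "DivergenceError",
    "run_to_steady_state",
    "l2_error",
    "darcy_permeability",
    "reynolds",
]

_AXIS_NAMES = "xyz"


class DivergenceError(RuntimeError):
    """The simulation produced non-finite fields or left the low-Mach regime."""


@dataclass(frozen=True)
class SimulationConfig:
    """Solver parameters (lattice units).

    Attributes
    ----------
    tau : relaxation time (> 0.5); nu = cs^2 (tau - 1/2).
    force : body-force density magnitude along the flow axis.
    flow_axis, flow_sign : driving direction (axis index, +1 or -1).
    epsilon : per-iteration convergence threshold (paper default 1e-10).
    check_interval : iterations between convergence checks; the measured
        between-check change is compared to ``epsilon * check_interval``.
    criterion : ``"el2"`` (relative L2 change of the full velocity field)
        or ``"flux"`` (relative change of the superficial velocity, the
        cheaper monitor used for porous-sample runs).
    boundaries : per-axis ``"periodic"`` or ``"wall"``; a wall face behaves
        as a solid half-way bounce-back plane beyond the boundary nodes.
    mach_limit : divergence guard on max |u| in lattice units.
    """

    tau: float = 1.0
    force: float = 1e-5
    flow_axis: int = 0
    flow_sign: int = 1
    epsilon: float = 1e-10
    check_interval: int = 100
    max_iterations: int = 1_000_000
    criterion: str = "el2"
    boundaries: tuple = ()
    mach_limit: float = 0.3

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.tau <= 0.5:
            raise ValueError("tau must exceed 0.5")
        if self.flow_sign not in (-1, 1):
            raise ValueError("flow_sign must be +1 or -1")
        if self.criterion not in ("el2", "flux"):
            raise ValueError("criterion must be 'el2' or 'flux'")

    def force_vector(self, dimension: int) -> np.ndarray:
        if not 0 <= self.flow_axis < dimension:
            raise ValueError("flow_axis outside geometry dimension")
        F = np.zeros(dimension)
        F[self.flow_axis] = self.flow_sign * self.force
        return F

    @property
    def direction_label(self) -> str:
        return f"F{_AXIS_NAMES[self.flow_axis].upper()}{'+' if self.flow_sign > 0 else '-'}"


@dataclass
class FlowSolution:
    """Converged (or terminal) state of a steady-state run."""

    rho: np.ndarray            # full grid, zero on solid
    u: np.ndarray              # full grid + axis, zero on solid
    P: np.ndarray              # cs^2 rho
    solid: np.ndarray
    iterations: int
    history: list              # (iteration, el2_per_iter, Ud)
    converged: bool
    config: SimulationConfig
    geometry: DomainGeometry

    @property
    def superficial_velocity(self) -> float:
        """Darcy velocity: force-directed mean of u over the *total* volume."""
        cfg = self.config
        return float(
            cfg.flow_sign * self.u[..., cfg.flow_axis].sum() / self.solid.size
        )


def _gather_table(solid: np.ndarray, stencil: StencilSpec, boundaries) -> tuple:
    """Pull-stream gather table over fluid nodes (see _kernels docstring)."""
    Q = stencil.Q
    fluid = ~solid
    n_fluid = int(fluid.sum())
    ids = np.full(solid.shape, -1, dtype=np.int64)
    ids[fluid] = np.arange(n_fluid)
    own = ids[fluid]
    nbr = np.empty((n_fluid, Q), dtype=np.int64)
    if not boundaries:
        boundaries = ("periodic",) * solid.ndim
    for i, c in enumerate(stencil.velocities):
        src = np.roll(ids, shift=tuple(c), axis=tuple(range(len(c))))
        # wall faces: upwind outside the domain acts as solid
        for ax, b in enumerate(boundaries):
            if b == "wall" and c[ax] != 0:
                sl = [slice(None)] * solid.ndim
                sl[ax] = 0 if c[ax] > 0 else -1
                src[tuple(sl)] = -1
        s = src[fluid]
        blocked = s < 0
        nbr[:, i] = np.where(blocked, own * Q + stencil.opposite[i], s * Q + i)
    return nbr.reshape(-1), ids, n_fluid


def run_to_steady_state(
    geom: DomainGeometry,
    cfg: SimulationConfig,
    rv: RelaxationVector | None = None,
) -> FlowSolution:
    """Iterate the central-moment LBM to steady state on ``geom``.

    Deterministic given inputs.  Raises :class:`DivergenceError` on
    non-finite fields or Mach-guard violation; returns with
    ``converged=False`` if ``max_iterations`` is reached first.
    """
    dim = geom.dimension
    stencil = D2Q9 if dim == 2 else D3Q27
    if rv is None:
        rv = relaxation_frequencies(cfg.tau, stencil)
    F = cfg.force_vector(dim)
    solid = geom.solid
    nbr, ids, n_fluid = _gather_table(solid, stencil, cfg.boundaries)

    Q = stencil.Q
    f = np.tile(stencil.weights, n_fluid).astype(np.float64)
    ftmp = np.empty_like(f)
    rho_n = np.empty(n_fluid)
    u_n = [np.empty(n_fluid) for _ in range(dim)]
    omega = np.ascontiguousarray(rv.omega, dtype=np.float64)

    u_prev = None
    ud_prev = None
    history: list = []
    it = 0
    converged = False
    thresh = cfg.epsilon * cfg.check_interval
    while it < cfg.max_iterations:
        n_steps = min(cfg.check_interval, cfg.max_iterations - it)
        try:
            if dim == 2:
                parity = _kernels.d2q9_chunk(
                    f, ftmp, nbr, omega, F[0], F[1], n_steps, rho_n, *u_n
                )
            else:
                parity = _kernels.d3q27_chunk(
                    f, ftmp, nbr, omega, F[0], F[1], F[2], n_steps, rho_n, *u_n
                )
        except ZeroDivisionError as exc:  # vanished density during blow-up
            raise DivergenceError(
                f"density reached zero near iteration {it}"
            ) from exc
        if parity:
            f, ftmp = ftmp, f
        it += n_steps
        uvec = np.stack(u_n, axis=-1)
        if not np.isfinite(uvec).all():
            raise DivergenceError(f"non-finite velocity field at iteration {it}")
        umax = float(np.abs(uvec).max())
        if umax > cfg.mach_limit:
            raise DivergenceError(
                f"|u|max = {umax:.3g} exceeded the Mach guard "
                f"{cfg.mach_limit} at iteration {it}"
            )
        ud = float(cfg.flow_sign * u_n[cfg.flow_axis].sum() / solid.size)
        if cfg.criterion == "el2":
            if u_prev is not None:
                num = float(((uvec - u_prev) ** 2).sum())
                den = float((uvec ** 2).sum())
                el2 = np.sqrt(num / den) if den > 0 else 0.0
                history.append((it, el2 / n_steps, ud))
                if el2 < thresh:
                    converged = True
            u_prev = uvec
        else:  # flux criterion on the superficial velocity
            if ud_prev is not None:
                rel = abs(ud - ud_prev) / max(abs(ud), 1e-300)
                history.append((it, rel / n_steps, ud))
                if rel < thresh:
                    converged = True
            ud_prev = ud
        if converged:
            break

    grid = solid.shape
    rho = np.zeros(grid)
    rho[~solid] = rho_n
    u = np.zeros(grid + (dim,))
    for a in range(dim):
        u[..., a][~solid] = u_n[a]
    return FlowSolution(
        rho=rho, u=u, P=stencil.cs2 * rho, solid=solid, iterations=it,
        history=history, converged=converged, config=cfg, geometry=geom,
    )


def l2_error(numeric, reference) -> float:
    """Relative L2-norm error sqrt(sum (num - ref)^2 / sum ref^2)."""
    numeric = np.asarray(numeric, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if numeric.shape != reference.shape:
        raise ValueError("fields must have the same shape")
    den = float((reference ** 2).sum())
    if den == 0.0:
        raise ZeroDivisionError("reference field has zero norm")
    return float(np.sqrt(((numeric - reference) ** 2).sum() / den))


@dataclass
class PermeabilityResult:
    """Darcy permeability extracted from a converged creeping flow.

    ``k_lattice`` is in lattice units (dx = dt = 1); ``k_si = k_lattice *
    voxel_size^2``; ``k_darcy = k_si / 9.869233e-13``.  ``reynolds`` uses
    the recorded characteristic length (``reynolds_length``, lattice
    units); flows with Re >= 1 are outside the Darcy regime and are
    flagged by ``darcy_valid``.
    """

    Ud: float
    k_lattice: float
    k_si: float
    k_darcy: float
    direction: str
    reynolds: float
    reynolds_length: float
    reynolds_length_label: str
    darcy_valid: bool


def reynolds(
    sol: FlowSolution,
    characteristic_length: float | None = None,
    label: str | None = None,
) -> tuple:
    """Reynolds number Re = rho u L / mu from the mean interstitial speed.

    ``characteristic_length`` defaults to the domain extent along the flow
    axis (lattice units); the choice is returned alongside Re.
    """
    cfg = sol.config
    nu = viscosity(cfg.tau)
    fluid = ~sol.solid
    speed = float(np.sqrt((sol.u[fluid] ** 2).sum(axis=-1)).mean()) if fluid.any() else 0.0
    if characteristic_length is None:
        characteristic_length = float(sol.solid.shape[cfg.flow_axis])
        label = label or "domain_extent"
    label = label or "user"
    re = speed * characteristic_length / nu
    return re, characteristic_length, label


def darcy_permeability(
    sol: FlowSolution,
    characteristic_length: float | None = None,
) -> PermeabilityResult:
    """Permeability from Darcy's law, k = rho Ud nu / F.

    The superficial velocity Ud averages the force-directed velocity over
    the *total* volume (solid nodes count as zero flux); the driving
    pressure gradient equals the body-force density.
    """
    cfg = sol.config
    if cfg.force == 0:
        raise ValueError("permeability undefined for zero driving force")
    nu = viscosity(cfg.tau)
    fluid = ~sol.solid
    rho_mean = float(sol.rho[fluid].mean()) if fluid.any() else 1.0
    ud = sol.superficial_velocity
    k_l = rho_mean * ud * nu / cfg.force
    dx = sol.geometry.voxel_size
    k_si = convert_units(k_l, "permeability", dx)
    re, L, label = reynolds(sol, characteristic_length)
    return PermeabilityResult(
        Ud=ud,
        k_lattice=k_l,
        k_si=k_si,
        k_darcy=k_si / DARCY_M2,
        direction=cfg.direction_label,
        reynolds=re,
        reynolds_length=L,
        reynolds_length_label=label,
        darcy_valid=bool(re < 1.0),
    )


def with_direction(cfg: SimulationConfig, axis: int, sign: int) -> SimulationConfig:
    """Copy of ``cfg`` driving along a different axis/sign."""
    return replace(cfg, flow_axis=axis, flow_sign=sign)
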