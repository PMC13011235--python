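"""Model/Results interface to the Stokes-flow permeability solver.

`StokesFlowModel` wraps a binary pore geometry plus solver configuration;
``fit()`` runs the central-moment LBM to steady state and returns a
:class:`FlowResults` carrying the converged fields, the permeability
estimate in lattice units / m^2 / darcy, convergence diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import numpy as np

from .geometry import DomainGeometry
from .moments import viscosity
from .solver import (
    PermeabilityResult,
    SimulationConfig,
    darcy_permeability,
    run_to_steady_state,
)

__all__ = ["StokesFlowModel", "FlowResults"]


class StokesFlowModel:
    """Creeping (Darcy-regime) flow through a binary pore-space image.

    Parameters
    ----------
    geometry : DomainGeometry (or bool solid mask), True = solid.
    tau : relaxation time; the magic relaxation set makes the computed
        permeability independent of this choice.
    force : body-force density driving the flow (lattice units); must be
        small enough that Re < 1.
    axis, sign : flow direction.
    **config : further :class:`SimulationConfig` fields (epsilon,
        criterion, check_interval, max_iterations, boundaries, ...).

    Examples
    --------
    >>> geom = make_channel(8, 34)
    >>> res = StokesFlowModel(geom, tau=0.8, force=1e-6).fit()
    >>> res.permeability.k_lattice  # doctest: +SKIP
    """

    def __init__(self, geometry, tau: float = 1.0, force: float = 1e-5,
                 axis: int = 0, sign: int = 1, **config):
        if not isinstance(geometry, DomainGeometry):
            geometry = DomainGeometry(np.asarray(geometry, bool))
        self.geometry = geometry
        self.config = SimulationConfig(
            tau=tau, force=force, flow_axis=axis, flow_sign=sign, **config
        )

    @classmethod
    def from_image(cls, path, voxel_size=None, **kwargs):
        """Build from a TIFF/PNG image (white = pore)."""
        from .geometry import load_geometry

        return cls(load_geometry(path, voxel_size=voxel_size), **kwargs)

    def fit(self) -> "FlowResults":
        """Run to steady state and extract the Darcy permeability."""
        sol = run_to_steady_state(self.geometry, self.config)
        perm = darcy_permeability(sol)
        return FlowResults(self, sol, perm)


class FlowResults:
    """Converged flow fields plus the permeability estimate."""

    def __init__(self, model: StokesFlowModel, solution, permeability: PermeabilityResult):
        self.model = model
        self.solution = solution
        self.permeability = permeability

    # ----- convenience accessors
    @property
    def k_lattice(self) -> float:
        return self.permeability.k_lattice

    @property
    def k_si(self) -> float:
        return self.permeability.k_si

    @property
    def k_darcy(self) -> float:
        return self.permeability.k_darcy

    @property
    def converged(self) -> bool:
        return self.solution.converged

    @property
    def convergence(self):
        """History DataFrame: iteration, per-iteration residual, Ud."""
        import pandas as pd

        return pd.DataFrame(
            self.solution.history, columns=["iteration", "residual", "Ud"]
        )

    def pressure_profile(self, axis: int | None = None,
                         include_force_potential: bool = True):
        """Mean effective pressure over transverse planes along ``axis``.

        In a body-force-driven periodic run the lattice pressure cs^2 rho
        is itself periodic; the force potential rho0 * F * x carries the
        imposed mean gradient.  Including it (default) recovers the
        physically decreasing pressure a true inlet/outlet pair would
        show, falling monotonically downstream.
        """
        cfg = self.model.config
        axis = cfg.flow_axis if axis is None else axis
        P = self.solution.P
        fluid = ~self.solution.solid
        axes = tuple(a for a in range(P.ndim) if a != axis)
        with np.errstate(invalid="ignore"):
            prof = np.nanmean(np.where(fluid, P, np.nan), axis=axes)
        if include_force_potential and axis == cfg.flow_axis:
            x = np.arange(prof.shape[0]) + 0.5
            prof = prof - cfg.flow_sign * cfg.force * x
        return prof

    def save_vtk(self, path) -> None:
        """Write velocity and pressure as a legacy-ASCII VTK file."""
        from .io import write_vtk_structured_points

        sol = self.solution
        fields = {
            "pressure": sol.P,
            "velocity_magnitude": np.sqrt((sol.u ** 2).sum(axis=-1)),
            "velocity": sol.u,
            "solid": sol.solid.astype(np.float64),
        }
        write_vtk_structured_points(
            path, fields, spacing=self.model.geometry.voxel_size
        )

    def save_convergence_csv(self, path) -> None:
        from .io import write_convergence_csv

        write_convergence_csv(path, self.solution.history,
                              nu=viscosity(self.model.config.tau),
                              force=self.model.config.force)

    def summary(self) -> str:
        """Human-readable run summary."""
        cfg = self.model.config
        geom = self.model.geometry
        p = self.permeability
        sol = self.solution
        lines = [
            "Stokes flow permeability (central-moment LBM)",
            "=" * 52,
            f"{'grid':<28}{' x '.join(str(s) for s in geom.shape)}",
            f"{'voxel size [um]':<28}{geom.voxel_size * 1e6:.4g}",
            f"{'porosity':<28}{geom.porosity:.4f}",
            f"{'direction':<28}{p.direction}",
            f"{'tau / nu [lu]':<28}{cfg.tau:g} / {viscosity(cfg.tau):.6g}",
            f"{'body force [lu]':<28}{cfg.force:g}",
            f"{'iterations':<28}{sol.iterations}",
            f"{'converged':<28}{sol.converged}",
            f"{'criterion':<28}{cfg.criterion} (eps={cfg.epsilon:g})",
            "-" * 52,
            f"{'superficial velocity [lu]':<28}{p.Ud:.6g}",
            f"{'k [lu^2]':<28}{p.k_lattice:.6g}",
            f"{'k [m^2]':<28}{p.k_si:.6g}",
            f"{'k [darcy]':<28}{p.k_darcy:.6g}",
            f"{'Re (L=' + p.reynolds_length_label + ')':<28}{p.reynolds:.3g}",
            f"{'Darcy regime (Re<1)':<28}{p.darcy_valid}",
            "=" * 52,
        ]
        return "\n".join(lines)
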