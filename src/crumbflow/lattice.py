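"""Grid-level lattice operations: the pure-numpy reference path.

These functions operate on full grids of populations with trailing velocity
axis ``(..., Q)`` and are the readable counterpart of the compiled kernels
in :mod:`crumbflow._kernels`; the two paths are cross-checked to round-off
in the test-suite.  Use this path for small domains and debugging; the
solver uses the compiled path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moments import RelaxationVector, collide, equilibrium
from .stencil import StencilSpec

__all__ = [
    "DistributionField",
    "MacroFields",
    "stream",
    "halfway_bounce_back",
    "periodic_exchange",
    "macroscopics",
    "reference_step",
]


@dataclass
class DistributionField:
    """Populations on a full grid plus the solid mask they live on."""

    f: np.ndarray          # (*grid, Q)
    solid: np.ndarray      # (*grid,) bool
    stencil: StencilSpec

    def __post_init__(self):
        if self.f.shape[:-1] != self.solid.shape:
            raise ValueError("population grid does not match the solid mask")
        if self.f.shape[-1] != self.stencil.Q:
            raise ValueError("population count does not match the stencil")


@dataclass
class MacroFields:
    """Macroscopic fields on the grid; defined on fluid nodes (zero in solid)."""

    rho: np.ndarray
    u: np.ndarray
    P: np.ndarray


def stream(f: np.ndarray, stencil: StencilSpec) -> np.ndarray:
    """Periodic streaming: f_i(x + c_i) <- f_i(x) for every direction."""
    out = np.empty_like(f)
    for i, c in enumerate(stencil.velocities):
        out[..., i] = np.roll(f[..., i], shift=tuple(c), axis=tuple(range(len(c))))
    return out


def periodic_exchange(f_ghost: np.ndarray, axes=None) -> np.ndarray:
    """Fill one-node ghost layers from the geometrically opposite boundary.

    ``f_ghost`` has one ghost layer on each side of every axis in ``axes``
    (default: all grid axes).  The ghost layer on the low side receives a
    copy of the last physical layer from the high side and vice versa —
    a plain copy of populations, no geometry mirroring.
    """
    f_ghost = f_ghost.copy()
    grid_ndim = f_ghost.ndim - 1
    axes = range(grid_ndim) if axes is None else axes
    for ax in axes:
        lo = [slice(None)] * f_ghost.ndim
        hi = [slice(None)] * f_ghost.ndim
        src_hi = [slice(None)] * f_ghost.ndim
        src_lo = [slice(None)] * f_ghost.ndim
        lo[ax], src_hi[ax] = 0, -2
        hi[ax], src_lo[ax] = -1, 1
        f_ghost[tuple(lo)] = f_ghost[tuple(src_hi)]
        f_ghost[tuple(hi)] = f_ghost[tuple(src_lo)]
    return f_ghost


def macroscopics(f: np.ndarray, stencil: StencilSpec, F=None) -> MacroFields:
    """Density, half-force-corrected velocity and pressure P = cs^2 rho."""
    rho = f.sum(axis=-1)
    mom = f @ stencil.velocities.astype(np.float64)
    if F is not None:
        mom = mom + 0.5 * np.asarray(F, dtype=np.float64)
    u = mom / rho[..., None]
    return MacroFields(rho=rho, u=u, P=stencil.cs2 * rho)


def halfway_bounce_back(f_streamed: np.ndarray, f_star: np.ndarray,
                        solid: np.ndarray, stencil: StencilSpec) -> np.ndarray:
    """Apply the half-way bounce-back rule after periodic streaming.

    For every fluid node whose upwind neighbour along direction ``i`` is
    solid, the streamed-in population is replaced by the node's own
    post-collision population in the opposite direction — placing the
    no-slip wall half-way along the cut link.  A no-op on solid-free
    domains.
    """
    f_new = f_streamed.copy()
    for i, c in enumerate(stencil.velocities):
        upwind_solid = np.roll(solid, shift=tuple(c), axis=tuple(range(len(c))))
        fix = upwind_solid & ~solid
        f_new[fix, i] = f_star[fix, stencil.opposite[i]]
    f_new[solid] = 0.0
    return f_new


def reference_step(field: DistributionField, rv: RelaxationVector, F=None):
    """One full update (collide -> stream -> half-way bounce-back).

    Populations on solid nodes are kept at zero.  Returns a new
    :class:`DistributionField`.
    """
    st = field.stencil
    solid = field.solid
    f_star, _, _ = collide(field.f, rv, st, F=F)
    f_star[solid] = 0.0
    f_new = halfway_bounce_back(stream(f_star, st), f_star, solid, st)
    return DistributionField(f=f_new, solid=solid, stencil=st)


def init_equilibrium(solid: np.ndarray, stencil: StencilSpec, rho0: float = 1.0):
    """Rest-state field: f = w_i rho0 on fluid nodes, zero on solid."""
    grid = solid.shape
    f = np.zeros(grid + (stencil.Q,))
    u0 = np.zeros(grid + (stencil.dimension,))
    f[...] = equilibrium(np.full(grid, rho0), u0, stencil)
    f[solid] = 0.0
    return DistributionField(f=f, solid=np.asarray(solid, bool), stencil=stencil)
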