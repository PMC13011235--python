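"""Lattice stencils for the D2Q9 and D3Q27 velocity sets.

Both stencils are full tensor products of the one-dimensional three-velocity
set {-1, 0, +1} with weights (1/6, 2/3, 1/6).  Velocity ``i`` decomposes as

    D2Q9 :  i = 3*(cx+1) + (cy+1)
    D3Q27:  i = 9*(cx+1) + 3*(cy+1) + (cz+1)

This ordering is load-bearing: the central-moment transform is applied as a
sequence of per-axis 3x3 contractions (see :mod:`crumbflow.moments`), which is
only possible because the population index factorises over the axes.

Moment ordering
---------------
Relaxation frequencies address *moments*, not velocities.  The documented
moment ordering (used by :func:`crumbflow.moments.relaxation_frequencies` and
by the collision kernels) is, with k_mn / k_mnp the central moment of
(cx-ux)^m (cy-uy)^n [(cz-uz)^p]:

D2Q9 (9 moments)::

    0: k00 (density)        3: k20 + k02 (trace)     6: k21
    1: k10 (x momentum)     4: k20 - k02 (shear)     7: k12
    2: k01 (y momentum)     5: k11       (shear)     8: k22

D3Q27 (27 moments)::

    0      : k000
    1-3    : k100, k010, k001
    4-8    : k110, k101, k011, k200 - k020, k020 - k002   (shear group)
    9      : k200 + k020 + k002                           (trace)
    10-16  : k111, k210, k201, k120, k021, k102, k012     (third order)
    17-26  : k220, k202, k022, k211, k121, k112,
             k221, k212, k122, k222

Indices 4-5 (2D) / 4-8 (3D) carry the shear ("viscous") frequency 1/tau;
indices 6-7 (2D) / 10-16 (3D) carry the magic frequency 8(2-1/tau)/(8-1/tau)
that pins the bounce-back wall half-way along cut links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StencilSpec", "build_stencil", "D2Q9", "D3Q27"]

# 1D building blocks: velocities -1, 0, +1 with weights 1/6, 2/3, 1/6.
_C1 = np.array([-1, 0, 1], dtype=np.int64)
_W1 = np.array([1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0])

# A[k, j] = c_j^k for the 1D set: rows are moment order 0, 1, 2.
_A = np.array([[1.0, 1.0, 1.0], [-1.0, 0.0, 1.0], [1.0, 0.0, 1.0]])
_AINV = np.linalg.inv(_A)


@dataclass(frozen=True)
class StencilSpec:
    """Constants of a tensor-product lattice stencil.

    Attributes
    ----------
    dimension : 2 or 3.
    Q : number of discrete velocities (9 or 27).
    velocities : (Q, dimension) int array, components in {-1, 0, +1}.
    weights : (Q,) lattice weights, summing to 1.
    cs2 : squared lattice sound speed, 1/3 with dx = dt = 1.
    opposite : (Q,) index of the reversed velocity (for bounce-back).
    exponents : (Q, dimension) moment exponents (m, n[, p]) of the *natural*
        (pre-combination) moment with the same tensor-product index.
    moment_names : names of the Q moments in the documented combined ordering.
    """

    dimension: int
    Q: int
    velocities: np.ndarray
    weights: np.ndarray
    cs2: float
    opposite: np.ndarray
    exponents: np.ndarray
    moment_names: tuple = field(default_factory=tuple)

    def __post_init__(self):  # freeze the arrays against accidents
        for name in ("velocities", "weights", "opposite", "exponents"):
            getattr(self, name).setflags(write=False)


def _tensor_indices(dim: int) -> np.ndarray:
    """All (dim,)-tuples over {0,1,2} in tensor-product order."""
    grids = np.meshgrid(*([np.arange(3)] * dim), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


_MOMENT_NAMES_2D = (
    "k00", "k10", "k01", "k20+k02", "k20-k02", "k11", "k21", "k12", "k22",
)
_MOMENT_NAMES_3D = (
    "k000", "k100", "k010", "k001",
    "k110", "k101", "k011", "k200-k020", "k020-k002",
    "k200+k020+k002",
    "k111", "k210", "k201", "k120", "k021", "k102", "k012",
    "k220", "k202", "k022", "k211", "k121", "k112",
    "k221", "k212", "k122", "k222",
)


def build_stencil(dimension: int) -> StencilSpec:
    """Return the D2Q9 (``dimension=2``) or D3Q27 (``dimension=3``) stencil.

    Raises
    ------
    ValueError
        If ``dimension`` is not 2 or 3.
    """
    if dimension not in (2, 3):
        raise ValueError(f"unsupported dimension {dimension!r}; must be 2 or 3")
    idx = _tensor_indices(dimension)
    velocities = _C1[idx]
    weights = np.prod(_W1[idx], axis=1)
    Q = 3 ** dimension
    # opposite velocity: component-wise negation
    key = {tuple(v): i for i, v in enumerate(velocities)}
    opposite = np.array([key[tuple(-v)] for v in velocities], dtype=np.int64)
    names = _MOMENT_NAMES_2D if dimension == 2 else _MOMENT_NAMES_3D
    return StencilSpec(
        dimension=dimension,
        Q=Q,
        velocities=velocities,
        weights=weights,
        cs2=1.0 / 3.0,
        opposite=opposite,
        exponents=idx.astype(np.int64),
        moment_names=names,
    )


D2Q9 = build_stencil(2)
D3Q27 = build_stencil(3)
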