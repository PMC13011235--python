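"""Equilibria, central-moment transforms and the non-orthogonal
central-moment collision operator.

Central moments are moments of the populations taken about the local fluid
velocity,

    k_{mnp} = sum_i f_i (c_xi - u_x)^m (c_yi - u_y)^n (c_zi - u_z)^p ,

so the transform population -> central moments factorises into a constant
per-axis Vandermonde contraction (raw moments) followed by a per-axis
binomial shift by -u.  Both pieces are 3x3 per axis, which keeps the
operator cheap and exactly invertible.

Collision relaxes each central moment towards its equilibrium with its own
frequency, ``k* = k + omega (k_eq - k)``, where the equilibria are obtained
by transforming the third-order polynomial equilibrium populations.  The
body force enters twice: as a half-force shift of the velocity used for the
equilibria and the moment shift, and as a per-moment source term
``(1 - omega/2) R`` whose central moments are velocity-independent
(R = F on the first-order moments, cs^2 F / cs^4 F on the sparse higher
ones).  This is the standard second-order (Guo-consistent) forcing written
in central-moment space.

All functions accept populations of shape (..., Q); leading axes are node
axes and broadcast freely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stencil import _A, _AINV, StencilSpec

__all__ = [
    "RelaxationVector",
    "relaxation_frequencies",
    "magic_frequency",
    "viscosity",
    "equilibrium",
    "to_central_moments",
    "from_central_moments",
    "force_source_moments",
    "collide",
    "apply_force",
]


# ----------------------------------------------------------------- viscosity

def viscosity(tau: float, cs2: float = 1.0 / 3.0) -> float:
    """Kinematic viscosity nu = cs^2 (tau - dt/2) in lattice units (dt = 1)."""
    if tau <= 0.5:
        raise ValueError(f"tau must exceed 0.5 (got {tau}): viscosity would be <= 0")
    return cs2 * (tau - 0.5)


def magic_frequency(tau: float) -> float:
    """Higher-order frequency 8(2 - 1/tau)/(8 - 1/tau).

    Together with the shear frequency 1/tau this realises the "magic"
    two-relaxation-time combination Lambda = 3/16, which pins the
    half-way bounce-back wall exactly mid-link and makes permeability
    independent of tau.
    """
    if tau <= 0.5:
        raise ValueError(f"tau must exceed 0.5 (got {tau})")
    return 8.0 * (2.0 - 1.0 / tau) / (8.0 - 1.0 / tau)


# ------------------------------------------------------- relaxation vectors

@dataclass(frozen=True)
class RelaxationVector:
    """Per-moment relaxation frequencies in the documented moment ordering.

    ``viscous_idx`` entries carry 1/tau (shear moments); ``magic_idx``
    entries carry the magic frequency (third-order moments).
    """

    tau: float
    omega: np.ndarray
    viscous_idx: tuple
    magic_idx: tuple

    def __post_init__(self):
        self.omega.setflags(write=False)


def relaxation_frequencies(tau: float, stencil: StencilSpec) -> RelaxationVector:
    """Relaxation-frequency set for the central-moment operator.

    D2Q9:  omega = (1, 1, 1, 1.6, 1/tau, 1/tau, magic, magic, 1.8)
    D3Q27: 1/tau on moments 4-8, magic on 10-16, 1 elsewhere.
    """
    om_nu = 1.0 / tau  # raises implicitly? no: validate via viscosity()
    viscosity(tau)  # validates tau > 0.5
    om_magic = magic_frequency(tau)
    if stencil.dimension == 2:
        omega = np.array(
            [1.0, 1.0, 1.0, 1.6, om_nu, om_nu, om_magic, om_magic, 1.8]
        )
        viscous, magic = (4, 5), (6, 7)
    else:
        omega = np.ones(27)
        omega[4:9] = om_nu
        omega[10:17] = om_magic
        viscous, magic = tuple(range(4, 9)), tuple(range(10, 17))
    return RelaxationVector(tau=tau, omega=omega, viscous_idx=viscous, magic_idx=magic)


# ------------------------------------------------ combination matrix C (Q,Q)
# combined moment vector = C @ natural tensor-order moment vector, where the
# natural index of k_{mnp} is 9m + 3n + p (3m + n in 2D).

def _combination_matrix(stencil: StencilSpec) -> np.ndarray:
    d = stencil.dimension
    Q = stencil.Q

    def nat(*exp):
        return sum(e * 3 ** (d - 1 - a) for a, e in enumerate(exp))

    C = np.zeros((Q, Q))
    if d == 2:
        rows = [
            [(1, 0, 0)], [(1, 1, 0)], [(1, 0, 1)],
            [(1, 2, 0), (1, 0, 2)],            # trace
            [(1, 2, 0), (-1, 0, 2)],           # shear difference
            [(1, 1, 1)],
            [(1, 2, 1)], [(1, 1, 2)],
            [(1, 2, 2)],
        ]
    else:
        rows = [
            [(1, 0, 0, 0)],
            [(1, 1, 0, 0)], [(1, 0, 1, 0)], [(1, 0, 0, 1)],
            [(1, 1, 1, 0)], [(1, 1, 0, 1)], [(1, 0, 1, 1)],
            [(1, 2, 0, 0), (-1, 0, 2, 0)],
            [(1, 0, 2, 0), (-1, 0, 0, 2)],
            [(1, 2, 0, 0), (1, 0, 2, 0), (1, 0, 0, 2)],
            [(1, 1, 1, 1)],
            [(1, 2, 1, 0)], [(1, 2, 0, 1)], [(1, 1, 2, 0)],
            [(1, 0, 2, 1)], [(1, 1, 0, 2)], [(1, 0, 1, 2)],
            [(1, 2, 2, 0)], [(1, 2, 0, 2)], [(1, 0, 2, 2)],
            [(1, 2, 1, 1)], [(1, 1, 2, 1)], [(1, 1, 1, 2)],
            [(1, 2, 2, 1)], [(1, 2, 1, 2)], [(1, 1, 2, 2)],
            [(1, 2, 2, 2)],
        ]
    for r, terms in enumerate(rows):
        for coeff, *exp in terms:
            C[r, nat(*exp)] += coeff
    return C


_C_CACHE: dict = {}


def _comb(stencil: StencilSpec):
    key = stencil.dimension
    if key not in _C_CACHE:
        C = _combination_matrix(stencil)
        _C_CACHE[key] = (C, np.linalg.inv(C))
    return _C_CACHE[key]


# ------------------------------------------------------------- equilibrium

def equilibrium(rho, u, stencil: StencilSpec) -> np.ndarray:
    """Third-order polynomial equilibrium populations.

    f_i^eq = w_i rho [1 + cu/cs2 + cu^2/(2 cs4) - u^2/(2 cs2)
                        + cu^3/(6 cs6) - cu u^2/(2 cs4)]

    with cu = c_i . u.  The third-order terms do not alter the conserved
    moments: sum f_eq = rho and sum c f_eq = rho u exactly.
    """
    rho = np.asarray(rho, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    cs2 = stencil.cs2
    cu = u @ stencil.velocities.T.astype(np.float64)  # (..., Q)
    u2 = np.sum(u * u, axis=-1)[..., None]
    one = 1.0 + cu / cs2 + cu * cu / (2 * cs2 * cs2) - u2 / (2 * cs2)
    third = cu ** 3 / (6 * cs2 ** 3) - cu * u2 / (2 * cs2 * cs2)
    return stencil.weights * rho[..., None] * (one + third)


# ------------------------------------------------------ moment transforms

def _shift_matrices(u, sign: float):
    """Per-axis 3x3 binomial shift matrices S(sign*u) for each node.

    Row m of S maps raw-moment orders 0..m to the central moment of order m:
    S = [[1,0,0], [s, 1, 0], [s^2, 2s, 1]] with s = sign * (-u_axis).
    """
    s = -sign * np.asarray(u, dtype=np.float64)  # (..., d)
    shp = s.shape[:-1]
    d = s.shape[-1]
    S = np.zeros(shp + (d, 3, 3))
    S[..., 0, 0] = 1.0
    S[..., 1, 1] = 1.0
    S[..., 2, 2] = 1.0
    S[..., 1, 0] = s
    S[..., 2, 0] = s * s
    S[..., 2, 1] = 2.0 * s
    return S


def _apply_axis(t, mat, axis_from_end, ntensor):
    """Contract 3x3 ``mat`` ((nodes...,3,3) or (3,3)) along one tensor axis.

    ``t`` has ``ntensor`` trailing tensor axes of length 3 over node axes.
    """
    t = np.moveaxis(t, -1 - axis_from_end, -1)
    if mat.ndim == 2:
        t = t @ mat.T
    else:
        # align per-node matrices across the remaining tensor axes
        mat = mat.reshape(mat.shape[:-2] + (1,) * (ntensor - 1) + (3, 3))
        t = np.einsum("...ij,...j->...i", mat, t)
    return np.moveaxis(t, -1, -1 - axis_from_end)


def _natural_moments(f, u, stencil: StencilSpec) -> np.ndarray:
    d = stencil.dimension
    t = np.asarray(f, dtype=np.float64).reshape(f.shape[:-1] + (3,) * d)
    for ax in range(d):
        t = _apply_axis(t, _A, d - 1 - ax, d)
    S = _shift_matrices(u, +1.0)
    for ax in range(d):
        t = _apply_axis(t, S[..., ax, :, :], d - 1 - ax, d)
    return t.reshape(f.shape[:-1] + (stencil.Q,))


def to_central_moments(f, u, stencil: StencilSpec) -> np.ndarray:
    """Central moments of populations ``f`` about velocity ``u``.

    Returned in the documented combined moment ordering (see
    :mod:`crumbflow.stencil`); entry 0 is the density.
    """
    C, _ = _comb(stencil)
    return _natural_moments(f, u, stencil) @ C.T


def from_central_moments(k, u, stencil: StencilSpec) -> np.ndarray:
    """Inverse of :func:`to_central_moments` (exact linear bijection)."""
    _, Cinv = _comb(stencil)
    d = stencil.dimension
    t = (np.asarray(k, dtype=np.float64) @ Cinv.T).reshape(
        k.shape[:-1] + (3,) * d
    )
    S = _shift_matrices(u, -1.0)  # inverse shift: shift back by +u
    for ax in range(d):
        t = _apply_axis(t, S[..., ax, :, :], d - 1 - ax, d)
    for ax in range(d):
        t = _apply_axis(t, _AINV, d - 1 - ax, d)
    return t.reshape(k.shape[:-1] + (stencil.Q,))


# ------------------------------------------------------------ force source

def force_source_moments(F, stencil: StencilSpec) -> np.ndarray:
    """Central moments R of the forcing term (velocity-independent).

    Derived from the Maxwellian central moments M = (1, 0, cs^2, 0):
    R_{mnp} = [Fx M_{m+1} M_n M_p + Fy M_m M_{n+1} M_p + ...] / cs^2,
    returned in the combined moment ordering.
    """
    F = np.asarray(F, dtype=np.float64)
    cs2 = stencil.cs2
    M = np.array([1.0, 0.0, cs2, 0.0])
    d = stencil.dimension
    Q = stencil.Q
    Rnat = np.zeros(F.shape[:-1] + (Q,))
    for t in range(Q):
        exp = stencil.exponents[t]  # natural exponents in tensor order
        for axis in range(d):
            e = exp.copy()
            e[axis] += 1
            coeff = np.prod(M[e]) / cs2
            if coeff != 0.0:
                Rnat[..., t] += coeff * F[..., axis]
    C, _ = _comb(stencil)
    return Rnat @ C.T


# ---------------------------------------------------------------- collision

def collide(f, rv: RelaxationVector, stencil: StencilSpec, F=None):
    """One central-moment collision (plus forcing) on populations ``f``.

    Computes rho = sum f, the half-force-corrected velocity
    u = (sum c f + F/2)/rho, relaxes each central moment towards the
    transformed equilibrium with its own frequency, adds the
    (1 - omega/2) R force source, and maps back to population space.

    Returns ``(f_star, rho, u)``.
    """
    f = np.asarray(f, dtype=np.float64)
    rho = f.sum(axis=-1)
    mom = f @ stencil.velocities.astype(np.float64)
    if F is not None:
        F = np.broadcast_to(np.asarray(F, dtype=np.float64), mom.shape)
        mom = mom + 0.5 * F
    u = mom / rho[..., None]
    feq = equilibrium(rho, u, stencil)
    dk = to_central_moments(feq - f, u, stencil)
    upd = rv.omega * dk
    if F is not None:
        R = force_source_moments(F, stencil)
        upd = upd + (1.0 - 0.5 * rv.omega) * R
    f_star = f + from_central_moments(upd, u, stencil)
    return f_star, rho, u


def apply_force(f, F, rv: RelaxationVector, stencil: StencilSpec):
    """Add the discrete force source to post-relaxation populations.

    Returns ``(f_forced, u_corrected)`` where ``u_corrected`` includes the
    half-force shift; over a full step the fluid gains momentum F*dt per
    node.  :func:`collide` already folds this in; this entry point exists
    for budget checks and for composing custom update loops.
    """
    f = np.asarray(f, dtype=np.float64)
    rho = f.sum(axis=-1)
    mom = f @ stencil.velocities.astype(np.float64)
    F = np.broadcast_to(np.asarray(F, dtype=np.float64), mom.shape)
    u = (mom + 0.5 * F) / rho[..., None]
    R = force_source_moments(F, stencil)
    f_forced = f + from_central_moments((1.0 - 0.5 * rv.omega) * R, u, stencil)
    return f_forced, u
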