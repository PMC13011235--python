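"""Compiled single-core update kernels for the central-moment LBM.

The solver state lives on *fluid nodes only*: populations are stored as a
flat float64 array ``f[n*Q + i]`` over the fluid-node list.  Streaming is a
precomputed gather (pull scheme): ``nbr[n*Q + i]`` is the flat index of the
post-collision population that arrives at node ``n`` in direction ``i`` —
either ``id(x - c_i)*Q + i`` for a fluid upwind neighbour (periodic wrap
folded into the table) or ``n*Q + opp(i)`` when the link is cut by a solid
(half-way bounce-back).

Collision uses the separable structure of the tensor-product stencils: the
raw-moment transform and the binomial velocity shift are per-axis 3x3
passes over a local flat tensor, so a full D3Q27 central-moment collision
costs a few hundred flops per node.  The per-moment relaxation applies the
``omega`` vector (documented combined ordering) with the trace/deviatoric
recombination of the diagonal second-order block, and adds the
velocity-independent central-moment force sources with (1 - omega/2)
prefactors; this is bit-identical to the pure-numpy reference path in
:mod:`crumbflow.moments` (cross-checked in the test-suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit

CS2 = 1.0 / 3.0


# base offsets of the 1D sub-arrays for each axis pass, tensor-flat layout
_STARTS_2D_X = np.array([0, 1, 2], dtype=np.int64)          # stride 3
_STARTS_2D_Y = np.array([0, 3, 6], dtype=np.int64)          # stride 1
_STARTS_3D_X = np.arange(9, dtype=np.int64)                 # stride 9
_STARTS_3D_Y = np.array([b + c for b in (0, 9, 18) for c in (0, 1, 2)],
                        dtype=np.int64)                     # stride 3
_STARTS_3D_Z = np.arange(0, 27, 3, dtype=np.int64)          # stride 1


@njit(cache=True, inline="always")
def _pass_forward(k, stride, starts):
    for j in range(starts.shape[0]):
        b = starts[j]
        x0 = k[b]
        x1 = k[b + stride]
        x2 = k[b + 2 * stride]
        k[b] = x0 + x1 + x2
        k[b + stride] = x2 - x0
        k[b + 2 * stride] = x0 + x2


@njit(cache=True, inline="always")
def _pass_inverse(k, stride, starts):
    for j in range(starts.shape[0]):
        b = starts[j]
        t0 = k[b]
        t1 = k[b + stride]
        t2 = k[b + 2 * stride]
        k[b] = 0.5 * (t2 - t1)
        k[b + stride] = t0 - t2
        k[b + 2 * stride] = 0.5 * (t1 + t2)


@njit(cache=True, inline="always")
def _pass_shift(k, stride, starts, v):
    # binomial shift: k1 += v*k0 ; k2 += 2v*k1_old + v^2*k0
    for j in range(starts.shape[0]):
        b = starts[j]
        x0 = k[b]
        x1 = k[b + stride]
        k[b + 2 * stride] += 2.0 * v * x1 + v * v * x0
        k[b + stride] += v * x0


@njit(cache=True)
def d2q9_chunk(f, fout, nbr, omega, Fx, Fy, nsteps,
               rho_out, ux_out, uy_out):
    """Advance the D2Q9 state ``nsteps`` steps; returns buffer parity.

    On exit the newest state is in ``f`` if the return value is 0, else in
    ``fout``; macroscopic fields are filled from the final step.
    """
    n_nodes = rho_out.shape[0]
    s0 = _STARTS_2D_X
    s1 = _STARTS_2D_Y
    w1 = np.array([1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0])
    fin = np.empty(9)
    k = np.empty(9)
    for s in range(nsteps):
        last = s == nsteps - 1
        for n in range(n_nodes):
            base = 9 * n
            rho = 0.0
            mx = 0.0
            my = 0.0
            for a in range(3):
                for b in range(3):
                    i = 3 * a + b
                    v = f[nbr[base + i]]
                    fin[i] = v
                    rho += v
                    mx += (a - 1) * v
                    my += (b - 1) * v
            ux = (mx + 0.5 * Fx) / rho
            uy = (my + 0.5 * Fy) / rho
            u2 = ux * ux + uy * uy
            for a in range(3):
                cxu = (a - 1) * ux
                for b in range(3):
                    i = 3 * a + b
                    cu = cxu + (b - 1) * uy
                    feq = w1[a] * w1[b] * rho * (
                        1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * u2
                        + 4.5 * cu * cu * cu - 4.5 * cu * u2
                    )
                    k[i] = feq - fin[i]
            _pass_forward(k, 3, s0)
            _pass_forward(k, 1, s1)
            _pass_shift(k, 3, s0, -ux)
            _pass_shift(k, 1, s1, -uy)
            # per-moment relaxation + force sources (natural index 3m+n)
            k[0] *= omega[0]
            k[3] = omega[1] * k[3] + (1.0 - 0.5 * omega[1]) * Fx
            k[1] = omega[2] * k[1] + (1.0 - 0.5 * omega[2]) * Fy
            k[4] *= omega[5]
            tr = omega[3] * (k[6] + k[2])
            dv = omega[4] * (k[6] - k[2])
            k[6] = 0.5 * (tr + dv)
            k[2] = 0.5 * (tr - dv)
            k[7] = omega[6] * k[7] + (1.0 - 0.5 * omega[6]) * CS2 * Fy
            k[5] = omega[7] * k[5] + (1.0 - 0.5 * omega[7]) * CS2 * Fx
            k[8] *= omega[8]
            _pass_shift(k, 3, s0, ux)
            _pass_shift(k, 1, s1, uy)
            _pass_inverse(k, 3, s0)
            _pass_inverse(k, 1, s1)
            for i in range(9):
                fout[base + i] = fin[i] + k[i]
            if last:
                rho_out[n] = rho
                ux_out[n] = ux
                uy_out[n] = uy
        tmp = f
        f = fout
        fout = tmp
    return nsteps % 2


@njit(cache=True)
def d3q27_chunk(f, fout, nbr, omega, Fx, Fy, Fz, nsteps,
                rho_out, ux_out, uy_out, uz_out):
    """Advance the D3Q27 state ``nsteps`` steps; returns buffer parity."""
    n_nodes = rho_out.shape[0]
    s0 = _STARTS_3D_X
    s1 = _STARTS_3D_Y
    s2 = _STARTS_3D_Z
    w1 = np.array([1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0])
    fin = np.empty(27)
    k = np.empty(27)
    for s in range(nsteps):
        last = s == nsteps - 1
        for n in range(n_nodes):
            base = 27 * n
            rho = 0.0
            mx = 0.0
            my = 0.0
            mz = 0.0
            for a in range(3):
                for b in range(3):
                    for c in range(3):
                        i = 9 * a + 3 * b + c
                        v = f[nbr[base + i]]
                        fin[i] = v
                        rho += v
                        mx += (a - 1) * v
                        my += (b - 1) * v
                        mz += (c - 1) * v
            ux = (mx + 0.5 * Fx) / rho
            uy = (my + 0.5 * Fy) / rho
            uz = (mz + 0.5 * Fz) / rho
            u2 = ux * ux + uy * uy + uz * uz
            for a in range(3):
                cxu = (a - 1) * ux
                for b in range(3):
                    cxyu = cxu + (b - 1) * uy
                    wab = w1[a] * w1[b]
                    for c in range(3):
                        i = 9 * a + 3 * b + c
                        cu = cxyu + (c - 1) * uz
                        feq = wab * w1[c] * rho * (
                            1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * u2
                            + 4.5 * cu * cu * cu - 4.5 * cu * u2
                        )
                        k[i] = feq - fin[i]
            _pass_forward(k, 9, s0)
            _pass_forward(k, 3, s1)
            _pass_forward(k, 1, s2)
            _pass_shift(k, 9, s0, -ux)
            _pass_shift(k, 3, s1, -uy)
            _pass_shift(k, 1, s2, -uz)
            # natural flat index 9m+3n+p; omega in combined ordering
            k[0] *= omega[0]
            k[9] = omega[1] * k[9] + (1.0 - 0.5 * omega[1]) * Fx
            k[3] = omega[2] * k[3] + (1.0 - 0.5 * omega[2]) * Fy
            k[1] = omega[3] * k[1] + (1.0 - 0.5 * omega[3]) * Fz
            k[12] *= omega[4]
            k[10] *= omega[5]
            k[4] *= omega[6]
            tr = omega[9] * (k[18] + k[6] + k[2])
            v1 = omega[7] * (k[18] - k[6])
            v2 = omega[8] * (k[6] - k[2])
            third = 1.0 / 3.0
            k[18] = third * (tr + 2.0 * v1 + v2)
            k[6] = third * (tr - v1 + v2)
            k[2] = third * (tr - v1 - 2.0 * v2)
            k[13] *= omega[10]
            k[21] = omega[11] * k[21] + (1.0 - 0.5 * omega[11]) * CS2 * Fy
            k[19] = omega[12] * k[19] + (1.0 - 0.5 * omega[12]) * CS2 * Fz
            k[15] = omega[13] * k[15] + (1.0 - 0.5 * omega[13]) * CS2 * Fx
            k[7] = omega[14] * k[7] + (1.0 - 0.5 * omega[14]) * CS2 * Fz
            k[11] = omega[15] * k[11] + (1.0 - 0.5 * omega[15]) * CS2 * Fx
            k[5] = omega[16] * k[5] + (1.0 - 0.5 * omega[16]) * CS2 * Fy
            k[24] *= omega[17]
            k[20] *= omega[18]
            k[8] *= omega[19]
            k[22] *= omega[20]
            k[16] *= omega[21]
            k[14] *= omega[22]
            cs4 = CS2 * CS2
            k[25] = omega[23] * k[25] + (1.0 - 0.5 * omega[23]) * cs4 * Fz
            k[23] = omega[24] * k[23] + (1.0 - 0.5 * omega[24]) * cs4 * Fy
            k[17] = omega[25] * k[17] + (1.0 - 0.5 * omega[25]) * cs4 * Fx
            k[26] *= omega[26]
            _pass_shift(k, 9, s0, ux)
            _pass_shift(k, 3, s1, uy)
            _pass_shift(k, 1, s2, uz)
            _pass_inverse(k, 9, s0)
            _pass_inverse(k, 3, s1)
            _pass_inverse(k, 1, s2)
            for i in range(27):
                fout[base + i] = fin[i] + k[i]
            if last:
                rho_out[n] = rho
                ux_out[n] = ux
                uy_out[n] = uy
                uz_out[n] = uz
        tmp = f
        f = fout
        fout = tmp
    return nsteps % 2
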