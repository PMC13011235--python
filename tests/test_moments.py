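import dataclasses

import numpy as np
import pytest

from crumbflow.moments import (
    apply_force,
    collide,
    equilibrium,
    force_source_moments,
    from_central_moments,
    magic_frequency,
    relaxation_frequencies,
    to_central_moments,
    viscosity,
)


def random_state(stencil, rng, n=7):
    f = rng.random((n, stencil.Q)) + 0.5
    u = rng.normal(0.0, 0.05, (n, stencil.dimension))
    return f, u


# ----------------------------------------------------------- viscosity

@pytest.mark.parametrize("tau,nu", [(1.0, 1 / 6), (2.0, 0.5), (0.6, 1 / 30)])
def test_viscosity_values(tau, nu):
    assert viscosity(tau) == pytest.approx(nu, rel=1e-14)


@pytest.mark.parametrize("tau", [0.5, 0.2, -1.0])
def test_viscosity_invalid_tau(tau):
    with pytest.raises(ValueError):
        viscosity(tau)
    with pytest.raises(ValueError):
        magic_frequency(tau)


# --------------------------------------------------- relaxation vector

def test_relaxation_frequencies_tau1(stencil):
    """At tau = 1 the shear entries are 1 and the magic entries 8/7."""
    rv = relaxation_frequencies(1.0, stencil)
    assert rv.omega.shape == (stencil.Q,)
    for i in rv.viscous_idx:
        assert rv.omega[i] == pytest.approx(1.0)
    for i in rv.magic_idx:
        assert rv.omega[i] == pytest.approx(8.0 / 7.0)
    assert np.all((rv.omega > 0) & (rv.omega < 2))


def test_relaxation_frequencies_tau06(stencil):
    rv = relaxation_frequencies(0.6, stencil)
    for i in rv.viscous_idx:
        assert rv.omega[i] == pytest.approx(1 / 0.6)
    magic = 8 * (2 - 1 / 0.6) / (8 - 1 / 0.6)
    for i in rv.magic_idx:
        assert rv.omega[i] == pytest.approx(magic)


def test_relaxation_frequencies_fixed_entries():
    from crumbflow.stencil import D2Q9, D3Q27

    rv2 = relaxation_frequencies(0.8, D2Q9)
    assert rv2.omega[3] == pytest.approx(1.6)
    assert rv2.omega[8] == pytest.approx(1.8)
    assert np.allclose(rv2.omega[:3], 1.0)
    rv3 = relaxation_frequencies(0.8, D3Q27)
    assert np.allclose(rv3.omega[[0, 1, 2, 3, 9]], 1.0)
    assert np.allclose(rv3.omega[17:], 1.0)


def test_relaxation_requires_positive_viscosity(stencil):
    with pytest.raises(ValueError):
        relaxation_frequencies(0.5, stencil)


# --------------------------------------------------------- equilibrium

def test_equilibrium_at_rest_is_weights(stencil):
    feq = equilibrium(np.array(2.5), np.zeros(stencil.dimension), stencil)
    assert np.allclose(feq, 2.5 * stencil.weights, atol=1e-15)


def test_equilibrium_conserved_moments(stencil, rng):
    """Zeroth/first moments equal (rho, rho u) despite third-order terms."""
    rho = rng.random(5) + 0.5
    u = rng.normal(0, 0.08, (5, stencil.dimension))
    feq = equilibrium(rho, u, stencil)
    assert np.allclose(feq.sum(-1), rho, atol=1e-14)
    mom = feq @ stencil.velocities.astype(float)
    assert np.allclose(mom, rho[:, None] * u, atol=1e-14)


# ----------------------------------------------------- moment transform

def test_central_moment_roundtrip(stencil, rng):
    f, u = random_state(stencil, rng)
    k = to_central_moments(f, u, stencil)
    assert np.allclose(from_central_moments(k, u, stencil), f, atol=1e-12)


def test_zeroth_moment_is_density(stencil, rng):
    f, u = random_state(stencil, rng)
    k = to_central_moments(f, u, stencil)
    assert np.allclose(k[..., 0], f.sum(-1), atol=1e-12)


def test_zero_velocity_gives_raw_moments(stencil, rng):
    f, _ = random_state(stencil, rng)
    u0 = np.zeros((f.shape[0], stencil.dimension))
    k = to_central_moments(f, u0, stencil)
    c = stencil.velocities.astype(float)
    # first-order central moments at u=0 are the raw momenta
    for axis in range(stencil.dimension):
        assert np.allclose(k[..., 1 + axis], f @ c[:, axis], atol=1e-12)


# ------------------------------------------------------------ collision

def test_equilibrium_is_collision_fixed_point(stencil, rng):
    rho = np.full(4, 1.1)
    u = rng.normal(0, 0.05, (4, stencil.dimension))
    feq = equilibrium(rho, u, stencil)
    rv = relaxation_frequencies(0.8, stencil)
    out, _, _ = collide(feq, rv, stencil)
    assert np.allclose(out, feq, atol=1e-13)


def test_unit_frequencies_project_to_equilibrium(stencil, rng):
    f, _ = random_state(stencil, rng)
    rv = relaxation_frequencies(0.8, stencil)
    rv1 = dataclasses.replace(rv, omega=np.ones(stencil.Q))
    out, rho, u = collide(f, rv1, stencil)
    assert np.allclose(out, equilibrium(rho, u, stencil), atol=1e-13)


def test_collision_reduces_to_bgk_when_all_equal(stencil, rng):
    """With every frequency 1/tau the operator is exactly BGK."""
    tau = 0.8
    f, _ = random_state(stencil, rng)
    rv = dataclasses.replace(
        relaxation_frequencies(tau, stencil), omega=np.full(stencil.Q, 1 / tau)
    )
    out, _, _ = collide(f, rv, stencil)
    rho = f.sum(-1)
    u = (f @ stencil.velocities.astype(float)) / rho[:, None]
    bgk = f + (equilibrium(rho, u, stencil) - f) / tau
    assert np.allclose(out, bgk, atol=1e-12)


def test_collision_conservation(stencil, rng):
    f, _ = random_state(stencil, rng)
    rv = relaxation_frequencies(0.8, stencil)
    out, _, _ = collide(f, rv, stencil)
    assert np.allclose(out.sum(-1), f.sum(-1), atol=1e-12)
    c = stencil.velocities.astype(float)
    assert np.allclose(out @ c, f @ c, atol=1e-12)


def test_forced_collision_momentum_budget(stencil, rng):
    """Each forced step adds exactly F per node; mass unchanged."""
    f, _ = random_state(stencil, rng)
    F = np.zeros(stencil.dimension)
    F[0] = 2e-4
    rv = relaxation_frequencies(0.7, stencil)
    c = stencil.velocities.astype(float)
    cur = f
    for _ in range(5):
        cur, _, _ = collide(cur, rv, stencil, F=F)
    assert np.allclose(cur.sum(-1), f.sum(-1), atol=1e-12)
    assert np.allclose(cur @ c - f @ c, 5 * F, atol=1e-12)


def test_apply_force_zero_is_identity(stencil, rng):
    f, _ = random_state(stencil, rng)
    rv = relaxation_frequencies(0.9, stencil)
    out, u = apply_force(f, np.zeros(stencil.dimension), rv, stencil)
    assert np.allclose(out, f, atol=1e-15)
    assert np.allclose(u, (f @ stencil.velocities.astype(float)) / f.sum(-1)[:, None])


def test_force_source_moments_structure(stencil):
    """The central-moment force source is F on the first-order moments
    and zero on all conserved/second-order ones."""
    F = np.zeros(stencil.dimension)
    F[0] = 1.0
    R = force_source_moments(F, stencil)
    assert R[0] == pytest.approx(0.0)
    assert R[1] == pytest.approx(1.0)  # x momentum source
    for i in range(2, 1 + stencil.dimension):
        assert R[i] == pytest.approx(0.0)
    # second-order block carries no source
    if stencil.dimension == 2:
        assert np.allclose(R[[3, 4, 5]], 0.0)
    else:
        assert np.allclose(R[4:10], 0.0)
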