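"""Deterministic study systems and test fixtures.

The package's worked examples are Laplace (Gaussian steady-state)
approximations of the stochastic Lorenz system and of two Lorenz systems
coupled through their first states.  All rates are expressed per
integration bin of 1/64 s -- i.e. the flows are the classical equations
scaled by 1/64 and one time unit equals one bin -- so that the stated
noise variances 2*Gamma = [1/8, 1/16, 1/32] balance the drift.  Reported
times in seconds correspond to 64 bins per second.

The Laplace exemplars are constructed by a fixed, fully deterministic
pipeline:

1. moments of the stochastic steady state are estimated from seeded
   Euler-Maruyama ensembles, restricted to the region where the flow is
   subsequently sampled (the quadratic expansion only has to describe the
   density there);
2. moment entries that vanish under the flow's detected sign symmetries
   are set exactly to zero;
3. the covariance is information-projected onto the Gaussian graphical
   model whose missing edges are the structurally uncoupled state pairs
   (the sparse-coupling rule: if one state nowhere influences another,
   the corresponding precision entry vanishes);
4. the solenoidal operator and housekeeping term are obtained by exact
   least squares against the target flow on a sampling hypergrid, with
   the potential held fixed.

Fixture regeneration from (name, seed) is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .helmholtz import (
    HelmholtzParams,
    detect_sign_symmetries,
    exact_lorenz_decomposition,
    fit_operator,
    params_from_gaussian,
    solve_solenoidal_linear,
)
from .polybasis import enumerate_monomials
from .systems import FlowSpec, coupled_lorenz, lorenz
from . import ness as _ness

__all__ = [
    "FixtureSet",
    "make_fixture",
    "FIXTURE_NAMES",
    "TIME_SCALE",
    "scaled_flow",
]

#: rate scaling: flows are expressed per 1/64 s integration bin
TIME_SCALE = 1.0 / 64.0

#: noise variances 2*Gamma per three-state block
NOISE_VARIANCE_3 = np.array([1.0 / 8.0, 1.0 / 16.0, 1.0 / 32.0])

FIXTURE_NAMES = (
    "lorenz-exact",
    "lorenz-laplace",
    "coupled-laplace",
    "ou-linear",
    "white-noise",
)


@dataclass
class FixtureSet:
    """A named study system with cached reference outputs."""

    name: str
    seed: int
    params: HelmholtzParams
    target: FlowSpec | None
    Gamma: np.ndarray
    reference: dict = field(default_factory=dict)


def scaled_flow(spec: FlowSpec, scale: float = TIME_SCALE):
    """The flow (and Jacobian) of ``spec`` expressed per integration bin."""
    return (lambda x: spec.flow(x) * scale), (lambda x: spec.jacobian(x) * scale)


def _hypergrid(centre, span, points):
    centre = np.asarray(centre, dtype=float)
    axes = [c + np.linspace(-span, span, points) for c in centre]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def _box_moments(
    flow, n, Gamma, seed, x0, centre, halfwidth,
    T=40000.0, dt=0.25, realisations=16, burn=2000.0, thin=2,
):
    """Seeded Euler-Maruyama moment estimate restricted to a box."""
    rng = np.random.default_rng(seed)
    steps = int(T / dt)
    nburn = int(burn / dt)
    x = np.tile(np.asarray(x0, dtype=float), (realisations, 1))
    amp = np.sqrt(2.0 * Gamma * dt)
    s1 = np.zeros(n)
    s2 = np.zeros((n, n))
    count = 0
    centre = np.asarray(centre, dtype=float)
    for s in range(steps):
        x = x + flow(x) * dt + amp * rng.standard_normal((realisations, n))
        if s >= nburn and s % thin == 0:
            inbox = np.all(np.abs(x - centre) <= halfwidth, axis=1)
            xs = x[inbox]
            if len(xs):
                s1 += xs.sum(axis=0)
                s2 += xs.T @ xs
                count += len(xs)
    if count < 100 * n:
        raise RuntimeError(f"too few in-box samples ({count}) for moment estimation")
    mu = s1 / count
    C = s2 / count - np.outer(mu, mu)
    return mu, C, count


def _apply_symmetry_zeros(mu, C, symmetries):
    """Zero the moment entries that are odd under any sign symmetry."""
    mu = mu.copy()
    C = C.copy()
    n = len(mu)
    for S in symmetries:
        for i in range(n):
            if S[i] < 0:
                mu[i] = 0.0
            for j in range(n):
                if S[i] * S[j] < 0:
                    C[i, j] = 0.0
    return mu, C


def _laplace_exemplar(spec: FlowSpec, Gamma, seed, x0, centre,
                      grid_points=4, span=8.0):
    """Run the moment -> symmetry -> projection -> operator pipeline."""
    n = spec.n
    flow, jac = scaled_flow(spec)
    mu, C, count = _box_moments(flow, n, Gamma, seed, x0, centre, span)
    syms = detect_sign_symmetries(flow, n)
    mu, C = _apply_symmetry_zeros(mu, C, syms)
    zeros = _ness.structural_zero_pairs(jac, n)
    Sigma, H = _ness.project_precision_zeros(C, zeros)
    basis = enumerate_monomials(n, 2)
    h = params_from_gaussian(basis, mu, H)
    grid = _hypergrid(centre, span, grid_points)
    params = fit_operator(flow, grid, basis, h, Gamma, symmetries=syms)
    return params, {
        "mean": mu,
        "H": H,
        "Sigma": Sigma,
        "structural_zeros": zeros,
        "n_moment_samples": count,
        "sample_grid": {"centre": list(map(float, centre)), "span": span,
                        "points_per_axis": grid_points},
    }


def make_fixture(name: str, seed: int = 1) -> FixtureSet:
    """Build one of the named study systems.

    Known names: lorenz-exact, lorenz-laplace, coupled-laplace, ou-linear,
    white-noise.  The same (name, seed) always regenerates an identical
    fixture.
    """
    if name == "lorenz-exact":
        params = exact_lorenz_decomposition(10.0, 32.0, 8.0 / 3.0)
        return FixtureSet(
            name=name, seed=seed, params=params, target=lorenz(),
            Gamma=params.Gamma,
            reference={"gauge": params.gauge},
        )

    if name == "lorenz-laplace":
        spec = lorenz()
        Gamma = NOISE_VARIANCE_3 / 2.0
        params, ref = _laplace_exemplar(
            spec, Gamma, seed, x0=[1.0, 1.0, 20.0], centre=[0.0, 0.0, 28.0],
        )
        return FixtureSet(
            name=name, seed=seed, params=params, target=spec, Gamma=Gamma,
            reference=ref,
        )

    if name == "coupled-laplace":
        spec = coupled_lorenz()
        Gamma = np.concatenate([NOISE_VARIANCE_3, NOISE_VARIANCE_3]) / 2.0
        params, ref = _laplace_exemplar(
            spec, Gamma, seed,
            x0=[1.0, 1.0, 20.0, 1.2, 0.9, 21.0],
            centre=[0.0, 0.0, 28.0, 0.0, 0.0, 28.0],
            grid_points=3,
        )
        g = _ness.gaussian_from_potential(params)
        part = _ness.particular_partition(g, internal=(4, 5))
        ref["partition"] = {
            "eta": part.eta, "s": part.s, "a": part.a, "mu": part.mu,
        }
        return FixtureSet(
            name=name, seed=seed, params=params, target=spec, Gamma=Gamma,
            reference=ref,
        )

    if name == "ou-linear":
        # planar linear flow with rotation: f = J x, J = [[-1,-4],[4,-1]]
        J = np.array([[-1.0, -4.0], [4.0, -1.0]])
        Gamma = np.ones(2)
        Q = solve_solenoidal_linear(J, Gamma)
        Omega = Q - np.diag(Gamma)
        H = np.linalg.solve(Omega, J)
        H = 0.5 * (H + H.T)
        basis = enumerate_monomials(2, 2)
        h = params_from_gaussian(basis, np.zeros(2), H)
        q = {(0, 1): np.zeros(basis.size)}
        q[(0, 1)][basis.index_of((0, 0))] = Q[0, 1]
        params = HelmholtzParams(
            basis=basis, h=h, q=q, Gamma=Gamma, diagonal_free=False,
        )
        return FixtureSet(
            name=name, seed=seed, params=params, target=None, Gamma=Gamma,
            reference={"J": J, "Q": Q, "H": H},
        )

    if name == "white-noise":
        # three uncoupled unit-variance Ornstein-Uhlenbeck states
        n = 3
        basis = enumerate_monomials(n, 2)
        h = params_from_gaussian(basis, np.zeros(n), np.eye(n))
        params = HelmholtzParams(
            basis=basis, h=h, q={}, Gamma=np.ones(n), diagonal_free=False,
        )
        return FixtureSet(
            name=name, seed=seed, params=params, target=None,
            Gamma=np.ones(n), reference={"Sigma": np.eye(n)},
        )

    raise ValueError(
        f"unknown fixture {name!r}; known names: {', '.join(FIXTURE_NAMES)}"
    )
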