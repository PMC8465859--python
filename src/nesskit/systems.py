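"""Built-in flow fields and trajectory integrators.

The Lorenz system (and a symmetric pair of Lorenz systems coupled through
their first states) serve both as fitting targets for the Helmholtz
decomposition and as the package's fixture generators.  Flows are plain
callables accepting a single state vector or an (N, n) batch; Jacobians
are analytic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "FlowSpec",
    "Trajectory",
    "lorenz",
    "coupled_lorenz",
    "integrate_deterministic",
    "integrate_stochastic",
]

DEFAULT_DT = 1.0 / 64.0  # integration step, seconds


@dataclass(frozen=True)
class FlowSpec:
    """An evaluable flow field with its exact Jacobian."""

    name: str
    parameters: dict
    flow: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    n: int

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.flow(x)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled solution of a (stochastic) flow."""

    times: np.ndarray       # (T,)
    states: np.ndarray      # (T, n)
    dt: float
    scheme: str             # "deterministic" | "stochastic"
    seed: int | None = None
    noise_variance: np.ndarray | None = None  # 2*Gamma, per state

    @property
    def n(self) -> int:
        return self.states.shape[1]


def _batched(fn):
    def wrapped(x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return fn(x[None, :])[0]
        return fn(x)
    return wrapped


def lorenz(sigma: float = 10.0, rho: float = 32.0, beta: float = 8.0 / 3.0) -> FlowSpec:
    """The Lorenz convection flow and its Jacobian.

    f = (sigma (x2 - x1), rho x1 - x2 - x1 x3, x1 x2 - beta x3).
    The defaults are the chaotic parameter set used throughout the package.
    """

    def flow(x):
        x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
        return np.stack(
            [sigma * (x2 - x1), rho * x1 - x2 - x1 * x3, x1 * x2 - beta * x3],
            axis=1,
        )

    def jac(x):
        N = x.shape[0]
        J = np.zeros((N, 3, 3))
        x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
        J[:, 0, 0] = -sigma
        J[:, 0, 1] = sigma
        J[:, 1, 0] = rho - x3
        J[:, 1, 1] = -1.0
        J[:, 1, 2] = -x1
        J[:, 2, 0] = x2
        J[:, 2, 1] = x1
        J[:, 2, 2] = -beta
        return J

    return FlowSpec(
        name="lorenz",
        parameters={"sigma": sigma, "rho": rho, "beta": beta},
        flow=_batched(flow),
        jacobian=_batched(jac),
        n=3,
    )


def coupled_lorenz(
    sigma: float = 10.0,
    rho: float = 32.0,
    beta: float = 8.0 / 3.0,
    chi: float = -0.5,
) -> FlowSpec:
    """Two Lorenz systems coupled symmetrically through their first states.

    The motion of each first state blends the first states of both systems:
    f1 = sigma x2 - sigma (chi x4 - x1 (chi - 1)), and symmetrically under
    the swap (x1,x2,x3) <-> (x4,x5,x6).  Equivalently the usual Lorenz
    drive is supplemented with a prediction error eps = x4 - x1 scaled by
    the coupling chi, so identical synchronisation (eps = 0) solves the
    expected flow.  chi = 0 decouples the pair exactly.
    """

    def flow(x):
        x1, x2, x3, x4, x5, x6 = (x[:, i] for i in range(6))
        return np.stack(
            [
                sigma * x2 - sigma * (chi * x4 - x1 * (chi - 1.0)),
                rho * x1 - x2 - x1 * x3,
                x1 * x2 - beta * x3,
                sigma * x5 - sigma * (chi * x1 - x4 * (chi - 1.0)),
                rho * x4 - x5 - x4 * x6,
                x4 * x5 - beta * x6,
            ],
            axis=1,
        )

    def jac(x):
        N = x.shape[0]
        J = np.zeros((N, 6, 6))
        x1, x2, x3, x4, x5, x6 = (x[:, i] for i in range(6))
        for off, (a1, a3) in ((0, (x1, x3)), (3, (x4, x6))):
            other = 3 - off
            J[:, off + 0, off + 0] = sigma * (chi - 1.0)
            J[:, off + 0, off + 1] = sigma
            J[:, off + 0, other + 0] = -sigma * chi
            J[:, off + 1, off + 0] = rho - a3
            J[:, off + 1, off + 1] = -1.0
            J[:, off + 1, off + 2] = -a1
            J[:, off + 2, off + 0] = (x2 if off == 0 else x5)
            J[:, off + 2, off + 1] = a1
            J[:, off + 2, off + 2] = -beta
        return J

    return FlowSpec(
        name="coupled_lorenz",
        parameters={"sigma": sigma, "rho": rho, "beta": beta, "chi": chi},
        flow=_batched(flow),
        jacobian=_batched(jac),
        n=6,
    )


def _flow_callable(flow):
    """Accept a FlowSpec, HelmholtzParams or bare callable."""
    if isinstance(flow, FlowSpec):
        return flow.flow, flow.n
    if hasattr(flow, "basis"):  # HelmholtzParams
        from .helmholtz import model_flow

        return (lambda x: model_flow(flow, x, jacobian=False)), flow.basis.n
    return flow, None


def _check_finite(x, t):
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            f"trajectory diverged (non-finite state) at t = {t:.6g} s"
        )


def integrate_deterministic(
    flow, x0: np.ndarray, dt: float = DEFAULT_DT, T: float = 64.0
) -> Trajectory:
    """Fixed-step classical Runge-Kutta (order 4) integration of the flow."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    f, _ = _flow_callable(flow)
    x = np.asarray(x0, dtype=float).copy()
    steps = int(round(T / dt))
    out = np.empty((steps + 1, x.size))
    out[0] = x
    for s in range(steps):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        _check_finite(x, (s + 1) * dt)
        out[s + 1] = x
    times = np.arange(steps + 1) * dt
    return Trajectory(times=times, states=out, dt=dt, scheme="deterministic")


def integrate_stochastic(
    flow,
    Gamma: np.ndarray,
    x0: np.ndarray,
    dt: float = DEFAULT_DT,
    T: float = 64.0,
    seed: int = 0,
    n_realisations: int = 1,
) -> Trajectory | list:
    """Euler-Maruyama integration: x += f dt + sqrt(2 Gamma dt) * N(0, 1).

    ``Gamma`` holds per-state half-amplitudes (the increment variance per
    unit time is 2 Gamma).  A single numpy Generator seeded with ``seed``
    drives all states and realisations; the same seed reproduces the same
    trajectories exactly.  With ``n_realisations > 1`` a list of
    trajectories sharing one noise stream is returned.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    Gamma = np.asarray(Gamma, dtype=float)
    if np.any(Gamma < 0):
        raise ValueError("noise half-amplitudes Gamma must be nonnegative")
    f, _ = _flow_callable(flow)
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    R = n_realisations
    x = np.tile(x0, (R, 1))
    steps = int(round(T / dt))
    out = np.empty((steps + 1, R, n))
    out[0] = x
    rng = np.random.default_rng(seed)
    amp = np.sqrt(2.0 * Gamma * dt)
    for s in range(steps):
        x = x + f(x) * dt + amp * rng.standard_normal((R, n))
        _check_finite(x, (s + 1) * dt)
        out[s + 1] = x
    times = np.arange(steps + 1) * dt
    trajs = [
        Trajectory(
            times=times,
            states=out[:, r, :],
            dt=dt,
            scheme="stochastic",
            seed=seed,
            noise_variance=2.0 * Gamma,
        )
        for r in range(R)
    ]
    return trajs[0] if n_realisations == 1 else trajs
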