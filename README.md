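# nesskit

Turn stochastic equations of motion into an explicit nonequilibrium
steady-state (NESS) density — and read Markov blankets, particular
partitions, synchronisation maps and variational-free-energy gradient
flows off the result.

Given a Langevin system `dx/dt = f(x) + omega` with noise covariance
`2 Gamma`, the expected flow of any system with a steady-state density
`p = exp(-I)` decomposes as

    f(x) = Q(x) grad I(x) - Gamma grad I(x) - Lambda(x),
    Q = -Q^T,   Lambda_i = sum_j dOmega_ij/dx_j,   Omega = Q - Gamma,

a solenoidal circulation on the isocontours of `p`, a dissipative descent
of the surprisal `I = -log p`, and a housekeeping correction.  `nesskit`
parameterises `I` and every entry of `Omega` on a canonical polynomial
basis, fits or constructs decompositions for target flows, and — in the
quadratic (Laplace) regime where `p` is Gaussian with precision
`H = grad^2 I` — reads conditional independence off zero entries of `H`:
Markov boundaries, particular partitions into external / sensory / active
/ internal states, linear synchronisation maps between conditional
expectations, and free-energy gradient flows.  A grid Fokker-Planck
solver evolves time-dependent densities in surprisal form and scores
their path with the information length.  The worked examples are the
stochastic Lorenz system and two Lorenz systems coupled through their
first states, with all rates per 1/64 s integration bin (see
`docs/methods.md`).

Audience: researchers in stochastic thermodynamics, nonlinear dynamics
and theoretical neurobiology who want executable Helmholtz
decompositions, blanket discovery on Gaussian steady states, and the
Bayesian-mechanics bookkeeping that follows from them.

## Worked example

```python
import numpy as np
from nesskit import ness, bayesmech
from nesskit.fixtures import make_fixture

# Laplace exemplar of two coupled stochastic Lorenz systems
fx = make_fixture("coupled-laplace", seed=1)
g = ness.gaussian_from_potential(fx.params)
part = ness.particular_partition(g, internal=(4, 5))
print("sensory", part.s, "active", part.a, "external", part.eta)

m = bayesmech.synchronisation_map(g, part)
print("eta_bar coefficient", round(float(m.coef_eta[0, 0]), 3))
print("mu_bar coefficient ", round(float(m.coef_mu[0, 0]), 3))

lor = make_fixture("lorenz-laplace", seed=1)
lam = ness.expected_jacobian_eigenvalues(
    lor.params, grid_points=16, span=32.0, centre=np.array([0.0, 0.0, 28.0]))
print("expected exponents", np.round(lam, 4),
      "KY dimension", round(ness.kaplan_yorke_dimension(lam), 3))
```

prints (seed 1)

```
sensory (0,) active (3,) external (1, 2)
eta_bar coefficient 0.701
mu_bar coefficient  0.538
expected exponents [ 0.0103 -0.0015 -0.0191] KY dimension 2.458
```

i.e. around the internal pair (states 5, 6 of the second system) the
blanket comprises state 4 (active) and state 1 (sensory); the expected
external and internal states are linear in the sensory state with the
printed slopes (the synchronisation map is their quotient); and the
density-weighted Jacobian spectrum of the three-state exemplar gives a
fractional attractor dimension just under 2.5 — stochastic chaos on a
Gaussian steady state.

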