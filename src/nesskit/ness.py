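"""Gaussian nonequilibrium steady-state analysis.

Under a quadratic (Laplace) potential the steady-state density is Gaussian
with precision H equal to the constant Hessian of the surprisal.  Zero
entries of H encode conditional independence between pairs of states given
all the others; Markov boundaries, particular partitions (external /
sensory / active / internal states) and synchronisation structure are all
read off this matrix.  The module also provides the spectral side of the
analysis: density-weighted expected Jacobian eigenvalues and the
Kaplan-Yorke dimension of the implied attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq as _lstsq

from .helmholtz import HelmholtzParams, model_flow
from .systems import Trajectory

__all__ = [
    "GaussianNESS",
    "ParticularPartition",
    "gaussian_from_potential",
    "gaussian_from_samples",
    "conditional_gaussian",
    "is_conditionally_independent",
    "markov_boundary",
    "particular_partition",
    "sparse_coupling_audit",
    "expected_jacobian_eigenvalues",
    "kaplan_yorke_dimension",
    "lorenz_analytic_dimension",
    "empirical_partial_correlation",
    "partial_correlation_matrix",
    "structural_zero_pairs",
    "project_precision_zeros",
]

#: default normalised tolerance for treating an analytic precision entry as zero
ANALYTIC_ZERO_TOL = 1e-6


@dataclass
class GaussianNESS:
    """Gaussian steady state: precision H, linear term b, moments.

    ``proper`` is True iff H is positive definite; improper densities (as
    produced by exact decompositions of deterministic flows) are flagged
    but kept, since their Hessian still encodes conditional structure.
    """

    H: np.ndarray
    b: np.ndarray
    mean: np.ndarray | None
    Sigma: np.ndarray | None
    proper: bool
    source: str = "potential"

    @property
    def n(self) -> int:
        return self.H.shape[0]

    def normalised_precision(self) -> np.ndarray:
        d = np.sqrt(np.abs(np.diag(self.H)))
        d[d == 0] = 1.0
        return self.H / np.outer(d, d)


@dataclass
class ParticularPartition:
    """Disjoint index sets (0-based) covering all states.

    eta: external, s: sensory, a: active, mu: internal; derived unions
    b = s+a (blanket), alpha = a+mu (autonomous), pi = s+a+mu (particular).
    """

    eta: tuple
    s: tuple
    a: tuple
    mu: tuple

    def __post_init__(self):
        sets = [set(self.eta), set(self.s), set(self.a), set(self.mu)]
        total = set().union(*sets)
        if sum(len(x) for x in sets) != len(total):
            raise ValueError("partition sets must be disjoint")
        self.eta, self.s = tuple(sorted(self.eta)), tuple(sorted(self.s))
        self.a, self.mu = tuple(sorted(self.a)), tuple(sorted(self.mu))

    @property
    def blanket(self) -> tuple:
        return tuple(sorted(set(self.s) | set(self.a)))

    @property
    def autonomous(self) -> tuple:
        return tuple(sorted(set(self.a) | set(self.mu)))

    @property
    def particular(self) -> tuple:
        return tuple(sorted(set(self.s) | set(self.a) | set(self.mu)))


def gaussian_from_potential(params: HelmholtzParams) -> GaussianNESS:
    """Read (H, b, mean, Sigma) off a quadratic potential's coefficients."""
    basis = params.basis
    if basis.m != 2:
        raise ValueError("Gaussian form requires a quadratic potential (m = 2)")
    n = basis.n
    origin = np.zeros(n)
    H = params.potential_hessian(origin)
    b = np.zeros(n)
    for i in range(n):
        e = [0] * n
        e[i] = 1
        b[i] = params.h[basis.index_of(tuple(e))]
    eig = np.linalg.eigvalsh(H)
    proper = bool(np.all(eig > 0))
    mean = Sigma = None
    if proper:
        mean = np.linalg.solve(H, -b)
        Sigma = np.linalg.inv(H)
    else:
        # a singular H may still admit a mean if b lies in its range
        sol, res, rank, _ = _lstsq(H, -b, lapack_driver="gelsd")
        if rank == n:
            mean = sol
    return GaussianNESS(H=H, b=b, mean=mean, Sigma=Sigma, proper=proper)


def gaussian_from_samples(
    trajectory: Trajectory | list, burn_in: float = 0.0
) -> GaussianNESS:
    """Moment-matched Gaussian from one or more sampled trajectories.

    The inverse sample covariance serves as the empirical precision; a
    rank-deficient covariance (too short or degenerate series) raises.
    """
    trajs = trajectory if isinstance(trajectory, (list, tuple)) else [trajectory]
    chunks = []
    for tr in trajs:
        keep = tr.times >= burn_in
        chunks.append(tr.states[keep])
    X = np.concatenate(chunks, axis=0)
    n = X.shape[1]
    if X.shape[0] < 10 * n:
        raise ValueError(
            f"need at least {10 * n} post-burn-in samples for a stable "
            f"covariance, got {X.shape[0]}; use a longer series"
        )
    mean = X.mean(axis=0)
    Sigma = np.cov(X.T)
    eig = np.linalg.eigvalsh(Sigma)
    if eig.min() <= 1e-12 * max(eig.max(), 1.0):
        raise np.linalg.LinAlgError(
            "sample covariance is rank deficient; the series does not "
            "explore all state dimensions - use a longer series"
        )
    H = np.linalg.inv(Sigma)
    return GaussianNESS(
        H=H, b=-H @ mean, mean=mean, Sigma=Sigma, proper=True, source="samples"
    )


def conditional_gaussian(
    ness: GaussianNESS, given: list, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the retained states given fixed values.

    Conditioning on the empty set returns the marginal.  Uses precision
    blocks: H_uu^-1 and mean_u - H_uu^-1 H_uv (v - mean_v).
    """
    given = sorted(given)
    n = ness.n
    keep = [i for i in range(n) if i not in given]
    if ness.mean is None:
        raise ValueError("conditional moments undefined: no mean (improper density)")
    values = np.asarray(values, dtype=float)
    Huu = ness.H[np.ix_(keep, keep)]
    eig = np.linalg.eigvalsh(Huu)
    if eig.min() <= 0:
        raise ValueError(
            "retained-block precision is not positive definite; conditional "
            "density improper"
        )
    cov = np.linalg.inv(Huu)
    if not given:
        if ness.Sigma is None:
            raise ValueError("marginal covariance undefined for improper density")
        return ness.mean.copy(), ness.Sigma.copy()
    Huv = ness.H[np.ix_(keep, given)]
    mean = ness.mean[keep] - cov @ Huv @ (values - ness.mean[given])
    return mean, cov


def is_conditionally_independent(
    ness: GaussianNESS, u: int, v: int, tol: float = ANALYTIC_ZERO_TOL
) -> bool:
    """True iff states u and v are independent given all remaining states.

    Criterion: |H_uv| / sqrt(|H_uu H_vv|) < tol (zero Hessian entry).
    """
    if u == v:
        raise ValueError("u and v must differ")
    P = ness.normalised_precision()
    return bool(abs(P[u, v]) < tol)


def markov_boundary(
    ness: GaussianNESS, subset, tol: float = ANALYTIC_ZERO_TOL
) -> set:
    """Minimal set of states coupling to ``subset`` through the precision.

    Under the Gaussian criterion this is exactly the set of states outside
    ``subset`` with a nonzero (normalised) precision entry to some member.
    """
    subset = set(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    P = ness.normalised_precision()
    out = set()
    for v in range(ness.n):
        if v in subset:
            continue
        if any(abs(P[u, v]) >= tol for u in subset):
            out.add(v)
    return out


def particular_partition(
    ness: GaussianNESS, internal, tol: float = ANALYTIC_ZERO_TOL
) -> ParticularPartition:
    """Partition states around a chosen internal set.

    Active states are the Markov boundary of the internal set; sensory
    states the boundary of the autonomous (internal + active) set; the
    rest is external.  The construction is validated by checking the three
    zero blocks H[mu,eta], H[a,eta], H[s,mu]; violation means the internal
    set does not admit a particular partition.
    """
    mu = set(internal)
    a = markov_boundary(ness, mu, tol)
    s = markov_boundary(ness, mu | a, tol) - a
    eta = set(range(ness.n)) - mu - a - s
    part = ParticularPartition(eta=tuple(eta), s=tuple(s), a=tuple(a), mu=tuple(mu))
    P = ness.normalised_precision()
    for uset, vset, name in (
        (mu, eta, "internal-external"),
        (a, eta, "active-external"),
        (s, mu, "sensory-internal"),
    ):
        if uset and vset:
            block = P[np.ix_(sorted(uset), sorted(vset))]
            if np.max(np.abs(block)) >= tol:
                raise ValueError(
                    f"inadmissible internal set: nonzero {name} precision "
                    f"block (max {np.max(np.abs(block)):.2e})"
                )
    return part


def sparse_coupling_audit(
    params: HelmholtzParams, points: np.ndarray, tol: float = ANALYTIC_ZERO_TOL
) -> dict:
    """Audit the sparse-coupling conjecture pair by pair.

    For every unordered state pair the report records whether the flow
    Jacobian entries J_uv, J_vu vanish at every audit point, whether the
    solenoidal entry Q_uv vanishes, and whether the Hessian entry is zero,
    and classifies the pair:

    - "conjecture-consistent": no dynamical coupling and H_uv = 0;
    - "edge-case": no coupling in at least one direction but H_uv != 0
      (terms must cancel) -- or coupled yet conditionally independent;
    - "coupled": reciprocal coupling with H_uv != 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    _, J = model_flow(params, pts)
    ness = gaussian_from_potential(params)
    P = ness.normalised_precision()
    from .helmholtz import flow_operator

    Om = flow_operator(params, pts)
    n = params.n
    scale = max(np.max(np.abs(J)), 1.0)
    report = {}
    for u in range(n):
        for v in range(u + 1, n):
            Juv0 = np.max(np.abs(J[:, u, v])) < tol * scale
            Jvu0 = np.max(np.abs(J[:, v, u])) < tol * scale
            Quv0 = np.max(np.abs(Om[:, u, v])) < tol * max(np.max(np.abs(Om)), 1.0)
            Huv0 = abs(P[u, v]) < tol
            if (Juv0 or Jvu0) and Huv0:
                cls = "conjecture-consistent"
            elif (Juv0 or Jvu0) and not Huv0:
                cls = "edge-case"
            elif Huv0:
                # reciprocally coupled yet conditionally independent
                cls = "edge-case"
            else:
                cls = "coupled"
            report[(u, v)] = {
                "J_uv_zero": Juv0,
                "J_vu_zero": Jvu0,
                "Q_uv_zero": Quv0,
                "H_uv_zero": Huv0,
                "class": cls,
            }
    return report


# --------------------------------------------------------------------------
# spectra and dimensions
# --------------------------------------------------------------------------

def expected_jacobian_eigenvalues(
    params: HelmholtzParams,
    grid_points: int = 16,
    span: float = 32.0,
    centre: np.ndarray | None = None,
) -> np.ndarray:
    """Expected (density-weighted) sorted real parts of the flow Jacobian.

    The flow Jacobian is evaluated on a rectangular hypergrid, its
    eigenvalue real parts sorted descending at each node, and averaged
    under the steady-state density renormalised over the grid.  Requires a
    proper Gaussian steady state.
    """
    ness = gaussian_from_potential(params)
    if not ness.proper:
        raise ValueError(
            "expected eigenvalues require a proper (positive definite) "
            "steady-state density"
        )
    n = params.n
    if centre is None:
        centre = ness.mean
    axes = [centre[i] + np.linspace(-span, span, grid_points) for i in range(n)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    d = pts - ness.mean
    logw = -0.5 * np.einsum("pi,ij,pj->p", d, ness.H, d)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    _, J = model_flow(params, pts)
    ev = np.sort(np.linalg.eigvals(J).real, axis=1)[:, ::-1]
    return w @ ev


def kaplan_yorke_dimension(lams: np.ndarray) -> float:
    """Kaplan-Yorke (Lyapunov) dimension j + sum_{i<=j} lam_i / |lam_{j+1}|.

    ``lams`` must be sorted descending; j is the largest index with a
    nonnegative partial sum.  Returns 0 when the leading exponent is
    negative and n when every partial sum is nonnegative.
    """
    lams = np.asarray(lams, dtype=float)
    if np.any(np.diff(lams) > 1e-12):
        raise ValueError("exponents must be sorted in descending order")
    if lams[0] < 0:
        return 0.0
    c = np.cumsum(lams)
    j = int(np.max(np.nonzero(c >= 0)[0]) + 1)
    if j >= len(lams):
        return float(len(lams))
    return float(j + c[j - 1] / abs(lams[j]))


def lorenz_analytic_dimension(sigma: float, rho: float, beta: float) -> float:
    """Closed-form Lyapunov dimension of the Lorenz attractor.

    d = 3 - 2 (sigma + beta + 1) / (sigma + 1 + sqrt((sigma-1)^2 + 4 sigma rho)).
    """
    disc = (sigma - 1.0) ** 2 + 4.0 * sigma * rho
    if disc < 0:
        raise ValueError("complex square root: no real Lyapunov dimension")
    return 3.0 - 2.0 * (sigma + beta + 1.0) / (sigma + 1.0 + np.sqrt(disc))


# --------------------------------------------------------------------------
# empirical partial correlations
# --------------------------------------------------------------------------

def partial_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Partial correlations from the sample precision of rows-of-samples X.

    P_uv = -Theta_uv / sqrt(Theta_uu Theta_vv) with Theta the inverse
    sample covariance; diagonal set to 1.
    """
    Sigma = np.cov(X.T)
    eig = np.linalg.eigvalsh(Sigma)
    if eig.min() <= 1e-12 * max(eig.max(), 1.0):
        raise np.linalg.LinAlgError("singular sample covariance")
    Theta = np.linalg.inv(Sigma)
    d = np.sqrt(np.diag(Theta))
    P = -Theta / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def empirical_partial_correlation(
    trajectories: list, window_lengths: list
) -> dict:
    """Window-resolved partial correlations averaged over realisations.

    For each window length T, each trajectory is truncated to its first T
    seconds, the partial-correlation matrix computed from that window's
    sample precision, and matrices averaged across realisations.  Returns
    ``{"windows": ..., "matrices": [...], "per_pair": {(u,v): curve}}``
    where curves give the convergence of each pair with window length.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n = trajectories[0].n
    mats = []
    for T in window_lengths:
        acc = np.zeros((n, n))
        for tr in trajectories:
            keep = tr.times <= T
            if keep.sum() < 10 * n:
                raise ValueError(f"window {T} too short for {n} states")
            acc += partial_correlation_matrix(tr.states[keep])
        mats.append(acc / len(trajectories))
    per_pair = {
        (u, v): np.array([m[u, v] for m in mats])
        for u in range(n)
        for v in range(u + 1, n)
    }
    return {
        "windows": np.asarray(window_lengths, dtype=float),
        "matrices": mats,
        "per_pair": per_pair,
    }


# --------------------------------------------------------------------------
# structural zeros and graphical projection
# --------------------------------------------------------------------------

def structural_zero_pairs(jacobian, n: int, span: float = 8.0) -> list:
    """State pairs forced conditionally independent by absent coupling.

    A pair (u, v) qualifies when the flow Jacobian entry J_uv (or J_vu)
    vanishes at every probe point -- one state does not influence the
    other anywhere in state space.  Under the sparse-coupling conjecture
    the corresponding precision entries are zero.
    """
    rng = np.random.default_rng(7654321)
    pts = rng.uniform(-span, span, size=(32, n))
    J = jacobian(pts)
    zero = np.max(np.abs(J), axis=0) < 1e-10 * max(np.max(np.abs(J)), 1.0)
    pairs = []
    for u in range(n):
        for v in range(u + 1, n):
            if zero[u, v] or zero[v, u]:
                pairs.append((u, v))
    return pairs


def project_precision_zeros(Sigma: np.ndarray, zero_pairs: list) -> np.ndarray:
    """Project a covariance onto the Gaussian graphical model with given zeros.

    Iterative proportional scaling over the maximal cliques of the allowed
    graph: the result matches Sigma on all free entries while the
    precision vanishes exactly on the forced pairs (the information
    projection onto the model).  Returns (projected covariance, precision).
    """
    import networkx as nx

    n = Sigma.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    forbidden = {tuple(sorted(p)) for p in zero_pairs}
    for u in range(n):
        for v in range(u + 1, n):
            if (u, v) not in forbidden:
                G.add_edge(u, v)
    cliques = [sorted(c) for c in nx.find_cliques(G)]
    K = np.diag(1.0 / np.diag(Sigma))
    for _ in range(500):
        delta = 0.0
        for C in cliques:
            Sig = np.linalg.inv(K)
            upd = np.linalg.inv(Sigma[np.ix_(C, C)]) - np.linalg.inv(Sig[np.ix_(C, C)])
            K[np.ix_(C, C)] += upd
            delta = max(delta, float(np.max(np.abs(upd))))
        if delta < 1e-13:
            break
    # exact zeros by construction up to round-off; snap them
    for (u, v) in forbidden:
        K[u, v] = K[v, u] = 0.0
    return np.linalg.inv(K), K
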