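"""Bayesian mechanics on a particular partition.

Given a Gaussian steady state with a particular partition (external eta,
sensory s, active a, internal mu), the conditional expectations of
internal and external states given sensory states are linear maps, and
the invertible map between them -- the synchronisation map -- lets the
expected internal state parameterise a density over external states.
The autonomous (active + internal) flow can then be written as a gradient
flow on a variational free energy whose gradients coincide with those of
the surprisal of particular states.

All quantities are computed from precision/covariance blocks for general
partitions; the six-state worked system additionally admits closed forms
in individual potential coefficients, exposed for verification in
:func:`worked_example_coefficients`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .helmholtz import HelmholtzParams, correction_term, flow_operator, model_flow
from .ness import GaussianNESS, ParticularPartition, gaussian_from_potential

__all__ = [
    "SynchronisationMap",
    "FreeEnergyReport",
    "synchronisation_map",
    "conditional_expectations",
    "variational_free_energy",
    "free_energy_gradients",
    "autonomous_flow",
    "worked_example_coefficients",
]


@dataclass
class SynchronisationMap:
    """Linear conditional-expectation structure around the blanket.

    ``coef_eta``, ``coef_a``, ``coef_mu`` map centred sensory states to
    centred conditional expectations; ``sigma`` maps expected internal to
    expected external states, with composition consistency
    sigma(mu_bar(s)) = eta_bar(s).  ``H_eta_cond`` is the conditional
    precision of external states given particular states.
    """

    partition: ParticularPartition
    coef_eta: np.ndarray
    coef_a: np.ndarray
    coef_mu: np.ndarray
    sigma: np.ndarray
    H_eta_cond: np.ndarray
    means: dict

    def eta_bar(self, s_value: np.ndarray) -> np.ndarray:
        s_value = np.atleast_1d(np.asarray(s_value, dtype=float))
        return self.means["eta"] + self.coef_eta @ (s_value - self.means["s"])

    def a_bar(self, s_value: np.ndarray) -> np.ndarray:
        s_value = np.atleast_1d(np.asarray(s_value, dtype=float))
        return self.means["a"] + self.coef_a @ (s_value - self.means["s"])

    def mu_bar(self, s_value: np.ndarray) -> np.ndarray:
        s_value = np.atleast_1d(np.asarray(s_value, dtype=float))
        return self.means["mu"] + self.coef_mu @ (s_value - self.means["s"])

    def predict_eta(self, mu_value: np.ndarray) -> np.ndarray:
        """sigma(mu): expected external state encoded by an internal state."""
        mu_value = np.atleast_1d(np.asarray(mu_value, dtype=float))
        return self.means["eta"] + self.sigma @ (mu_value - self.means["mu"])


@dataclass
class FreeEnergyReport:
    """Variational free energy of a particular state, with decompositions."""

    F: float
    accuracy: float
    complexity: float
    surprisal: float
    constant_offset: float
    gradient_a: np.ndarray
    gradient_mu: np.ndarray


def _blocks(ness: GaussianNESS, part: ParticularPartition):
    if ness.Sigma is None or ness.mean is None:
        raise ValueError("Bayesian mechanics require a proper Gaussian steady state")
    idx = {
        "eta": list(part.eta), "s": list(part.s), "a": list(part.a),
        "mu": list(part.mu), "pi": list(part.particular),
    }
    means = {k: ness.mean[v] for k, v in idx.items()}
    return idx, means


def synchronisation_map(
    ness: GaussianNESS, partition: ParticularPartition
) -> SynchronisationMap:
    """Conditional-expectation maps given sensory states, and sigma.

    Coefficients are covariance regressions Sigma_{x,s} Sigma_ss^{-1};
    sigma = coef_eta pinv(coef_mu) requires the internal coefficient to
    have full column rank (an invertible synchronisation), otherwise an
    error names the degenerate block.
    """
    idx, means = _blocks(ness, partition)
    S = ness.Sigma
    Sss = S[np.ix_(idx["s"], idx["s"])]
    if np.linalg.matrix_rank(Sss) < len(idx["s"]):
        raise np.linalg.LinAlgError("sensory covariance block is singular")
    coef = {}
    for name in ("eta", "a", "mu"):
        coef[name] = S[np.ix_(idx[name], idx["s"])] @ np.linalg.inv(Sss)
    if np.linalg.matrix_rank(coef["mu"]) < len(idx["s"]):
        raise np.linalg.LinAlgError(
            "internal conditional-expectation map has deficient rank "
            "(vanishing internal-sensory coupling); synchronisation map "
            "not invertible"
        )
    sigma = coef["eta"] @ np.linalg.pinv(coef["mu"])
    H_eta_cond = ness.H[np.ix_(idx["eta"], idx["eta"])]
    return SynchronisationMap(
        partition=partition,
        coef_eta=coef["eta"],
        coef_a=coef["a"],
        coef_mu=coef["mu"],
        sigma=sigma,
        H_eta_cond=H_eta_cond,
        means=means,
    )


def conditional_expectations(
    ness: GaussianNESS, partition: ParticularPartition, s_value
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(eta_bar, a_bar, mu_bar) at the given sensory value."""
    m = synchronisation_map(ness, partition)
    return m.eta_bar(s_value), m.a_bar(s_value), m.mu_bar(s_value)


def _pi_prediction(ness, partition, pi_value):
    """Predicted particular state E[pi|s] with s read from pi itself."""
    idx, means = _blocks(ness, partition)
    pi_idx = idx["pi"]
    pi_value = np.asarray(pi_value, dtype=float)
    if pi_value.shape != (len(pi_idx),):
        raise ValueError(f"pi_value must have length {len(pi_idx)}")
    pos = {state: k for k, state in enumerate(pi_idx)}
    s_val = np.array([pi_value[pos[i]] for i in idx["s"]])
    m = synchronisation_map(ness, partition)
    pred = np.empty_like(pi_value)
    a_bar, mu_bar = m.a_bar(s_val), m.mu_bar(s_val)
    for k, state in enumerate(pi_idx):
        if state in partition.s:
            pred[k] = pi_value[k]  # the sensory prediction is the datum itself
        elif state in partition.a:
            pred[k] = a_bar[list(partition.a).index(state)]
        else:
            pred[k] = mu_bar[list(partition.mu).index(state)]
    return pi_value, pred, s_val, m, idx


def variational_free_energy(
    ness: GaussianNESS, partition: ParticularPartition, pi_value
) -> FreeEnergyReport:
    """Free energy of a particular state under the variational density.

    Accuracy is the precision-weighted squared prediction error of the
    particular states about their conditional expectations given sensory
    states; complexity the corresponding term for the implied external
    expectation.  Because the variational density equals the conditional
    density over external states, the divergence term vanishes and F
    equals the surprisal of the particular states up to a state-
    independent normalisation constant, reported separately.
    """
    pi_value, pred, s_val, m, idx = _pi_prediction(ness, partition, pi_value)
    H_pi_block = ness.H[np.ix_(idx["pi"], idx["pi"])]
    e = pi_value - pred
    accuracy = 0.5 * float(e @ H_pi_block @ e)
    eta_err = m.eta_bar(s_val) - m.means["eta"]
    # prior cost of the encoded belief: the implied external expectation
    # weighted by the inverse of its own steady-state (explained) covariance;
    # this is the term that makes F equal the surprisal of particular states
    Sss = ness.Sigma[np.ix_(idx["s"], idx["s"])]
    C_exp = m.coef_eta @ Sss @ m.coef_eta.T
    complexity = 0.5 * float(eta_err @ np.linalg.pinv(C_exp) @ eta_err)
    # marginal surprisal of particular states
    S_pi = ness.Sigma[np.ix_(idx["pi"], idx["pi"])]
    H_marg = np.linalg.inv(S_pi)
    d = pi_value - m.means["pi"]
    surprisal = 0.5 * float(d @ H_marg @ d)
    F = accuracy + complexity
    ga, gmu = free_energy_gradients(ness, partition, pi_value)
    return FreeEnergyReport(
        F=F,
        accuracy=accuracy,
        complexity=complexity,
        surprisal=surprisal,
        constant_offset=F - surprisal,
        gradient_a=ga,
        gradient_mu=gmu,
    )


def free_energy_gradients(
    ness: GaussianNESS, partition: ParticularPartition, pi_value
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of F over (active, internal) states, dual-route checked.

    Route one differentiates the conditional (accuracy + complexity)
    form; route two the marginal surprisal of particular states.  They
    agree identically for admissible partitions; disagreement beyond
    1e-8 raises, as it indicates a violated blanket condition.
    """
    pi_value, pred, s_val, m, idx = _pi_prediction(ness, partition, pi_value)
    pi_idx = idx["pi"]
    H_pi_block = ness.H[np.ix_(pi_idx, pi_idx)]
    grad_cond = H_pi_block @ (pi_value - pred)
    S_pi = ness.Sigma[np.ix_(pi_idx, pi_idx)]
    grad_marg = np.linalg.inv(S_pi) @ (pi_value - m.means["pi"])
    sel_a = [k for k, st in enumerate(pi_idx) if st in partition.a]
    sel_mu = [k for k, st in enumerate(pi_idx) if st in partition.mu]
    ga_c, gmu_c = grad_cond[sel_a], grad_cond[sel_mu]
    ga_m, gmu_m = grad_marg[sel_a], grad_marg[sel_mu]
    scale = max(np.max(np.abs(grad_cond)), 1.0)
    if max(np.max(np.abs(ga_c - ga_m), initial=0.0),
           np.max(np.abs(gmu_c - gmu_m), initial=0.0)) > 1e-8 * scale:
        raise AssertionError(
            "conditional and marginal free-energy gradients disagree; "
            "partition does not satisfy the blanket conditions"
        )
    return ga_c, gmu_c


def autonomous_flow(
    params: HelmholtzParams, partition: ParticularPartition, x
) -> dict:
    """Decompose the flow of autonomous states at x.

    Returns dissipative (-Gamma grad I), solenoidal (Q grad I) and
    correction (-Lambda) components restricted to the autonomous rows,
    their sum (the exact model flow there), and the free-energy gradient
    scaled by -Gamma, which equals the dissipative part whenever the
    active/internal rows of the precision have no external support.
    """
    x = np.asarray(x, dtype=float)
    n = params.n
    alpha = list(partition.autonomous)
    gradI = params.potential_grad(x)
    Om = flow_operator(params, x)
    Q = Om + np.diag(params.Gamma)
    Lam = correction_term(params, x)
    dissipative = -params.Gamma * gradI
    solenoidal = Q @ gradI
    correction = -Lam
    f, _ = model_flow(params, x)
    ness = gaussian_from_potential(params)
    pi_idx = list(partition.particular)
    pi_val = x[pi_idx]
    ga, gmu = free_energy_gradients(ness, partition, pi_val)
    gF = np.zeros(n)
    gF[list(partition.a)] = ga
    gF[list(partition.mu)] = gmu
    return {
        "dissipative": dissipative[alpha],
        "solenoidal": solenoidal[alpha],
        "correction": correction[alpha],
        "total": f[alpha],
        "free_energy_descent": (-params.Gamma * gF)[alpha],
    }


def worked_example_coefficients(params: HelmholtzParams) -> dict:
    """Closed-form map coefficients of the six-state worked system.

    For the coupled system partitioned as s = x1, eta = (x2, x3),
    a = x4, mu = (x5, x6), the scalar coefficients of the linear maps
    follow directly from individual potential coefficients (1-based
    indices of the canonical ordering):

        eta_bar = -h5/h6 * s
        mu_bar  =  h12 h20 / (h15 h21 - h20^2) * s
        a_bar   = -h12 h21 / (h15 h21 - h20^2) * s
        sigma   = (h20^2 - h15 h21) h5 / (h12 h20 h6)
        H_eta_cond = h6

    Used as a verification layer against the block computations.
    """
    basis = params.basis
    if basis.n != 6 or basis.m != 2:
        raise ValueError("closed forms apply to the six-state quadratic system")
    h = params.h

    def hi(k):  # 1-based coefficient access
        return h[k - 1]

    h5, h6, h12 = hi(5), hi(6), hi(12)
    h15, h20, h21 = hi(15), hi(20), hi(21)
    den = h15 * h21 - h20**2
    if den == 0 or h6 == 0 or h12 == 0 or h20 == 0:
        raise ZeroDivisionError("degenerate worked-example coefficients")
    return {
        "eta_coef": -h5 / h6,
        "mu_coef": h12 * h20 / den,
        "a_coef": -h12 * h21 / den,
        "sigma_coef": (h20**2 - h15 * h21) * h5 / (h12 * h20 * h6),
        "H_eta_cond": h6,
    }
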