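# Methods

## The model

A random dynamical system with state `x in R^n`,

    dx/dt = f(x) + omega,        <omega omega'> = 2 Gamma (diagonal),

has a stationary (nonequilibrium steady-state) density `p(x)` whenever the
Fokker-Planck operator `div(Gamma grad - f)` annihilates some normalisable
`p`.  Writing the surprisal `I(x) = -log p(x)`, the expected flow of any
such system admits a generalised Helmholtz decomposition

    f = Q grad I  -  Gamma grad I  -  Lambda,
    Q = -Q',      Lambda_i = sum_j d(Omega_ij)/dx_j,    Omega = Q - Gamma.

The three parts are solenoidal circulation on the isocontours of `p`
(breaking detailed balance), dissipative descent of the potential
(balancing the noise), and a housekeeping correction for state dependence
of the flow operator.  With constant `Gamma`, `p ~ exp(-I)` is *exactly*
stationary under this flow for any skew `Q(x)` and potential `I(x)`: the
package verifies this identity numerically and uses it as the decisive
check of the housekeeping-term sign (worked displays of such
decompositions sometimes carry the opposite sign on the bracketed
correction terms; the stationarity identity only holds for the
convention above).

Potential and operator entries are parameterised on a shared polynomial
basis of total degree at most `m` with factorial scaling (`x^k/k!` on pure
powers), ordered constant-first and last-variable-major; with that scaling
the basis is closed under differentiation with unit coefficients, so all
gradients, Hessians and operator divergences are exact table lookups.  At
`m = 2` the potential is quadratic, the steady state Gaussian with constant
precision `H = grad^2 I` (the Laplace regime), and zero entries of `H`
encode conditional independence between state pairs given the rest —
the basis of Markov-blanket discovery, particular partitions and the
Bayesian-mechanics layer.

## Units and study systems

The built-in study systems are the Lorenz convection equations
(`sigma = 10`, `rho = 32`, `beta = 8/3`) and two Lorenz systems coupled
through their first states (`chi = -1/2`).  All rates are expressed **per
integration bin of 1/64 s**: the flows are the textbook equations scaled
by 1/64, one time unit is one bin, and a reported "second" is 64 bins.
In these units the noise variances `2 Gamma = [1/8, 1/16, 1/32]` (per
three-state block) balance the drift, which is what makes a proper
Gaussian steady state attainable; expected Jacobian eigenvalues are
likewise rates per bin.

## Laplace exemplars: the construction pipeline

Fitting both `(q, h)` jointly to a flow field by least squares is a
bilinear problem whose best unconstrained optima turn out to be improper
(indefinite or degenerate Hessians): the flow field alone does not
determine the density scale once the operator can compensate.  The
package therefore constructs its proper Laplace exemplars by a fixed,
fully deterministic pipeline that separates density estimation from
operator estimation:

1. **Moments.**  The steady-state mean and covariance are estimated from
   a seeded Euler-Maruyama ensemble of the target system (16 realisations,
   40 000 bins, step 1/4 bin, 2 000-bin burn-in), restricted to the box
   over which the flow is subsequently sampled (half-width 8 around
   (0, 0, 28) per block).  The restriction reflects that a quadratic
   expansion is only asked to describe the density where the flow is
   fitted.
2. **Symmetry zeroing.**  Diagonal sign changes `S` with `f(Sx) = S f(x)`
   are detected numerically (for the Lorenz systems:
   `(x1, x2) -> (-x1, -x2)` per block).  The steady density is even under
   any such symmetry, so moment entries odd under `S` are set exactly to
   zero.
3. **Graphical projection.**  If one state nowhere influences another
   (a structurally zero Jacobian entry), the corresponding precision
   entry vanishes (the sparse-coupling rule).  The moment covariance is
   information-projected onto the Gaussian graphical model with those
   missing edges (iterative proportional scaling over the maximal
   cliques), which makes the implied conditional independencies exact
   rather than approximate.  For the coupled system this yields precisely
   the reference blanket structure: internal states {5, 6} have Markov
   boundary {4} (active), the autonomous set has boundary {1} (sensory),
   and states {2, 3} are external.
4. **Operator.**  With the potential fixed, the flow-matching residual is
   linear in the off-diagonal operator coefficients, so a single
   least-squares solve (restricted to the admissible parity sector of the
   detected symmetries) is exact and deterministic.  Diagonal operator
   blocks are held at zero, i.e. the noise amplitude is state-independent.

The resulting systems are proper, chaotic (leading expected Jacobian
eigenvalue positive), carry the reference conditional-independence
structure exactly, and regenerate bit-identically from `(name, seed)`.
The generic joint fit (`fit_decomposition`: alternating exact linear
solves plus damped Gauss-Newton with analytic Jacobians, from zero
operator and unit-curvature potential) remains available and is the right
tool when an exact decomposition exists — it recovers the closed-form
Lorenz decomposition to machine residual with free noise amplitudes, and
linear flows exactly.

Known limitation: the coupled exemplar's internal pair (4, 5) comes out
*more* strongly partially correlated (about +0.46 analytic) than the
reference worked example (-0.33), and the three-state exemplar's expected
eigenvalues are several-fold smaller in magnitude than the reference
triple, although the Kaplan-Yorke dimension (about 2.46 vs 2.48) and the
entire qualitative structure agree.  The reference systems were produced
by a regularised variational fitting scheme whose details (priors, flow
scaling, iteration) are not recoverable from the text; the pipeline here
is the package's own, chosen for determinism and for reproducing the
structural claims exactly.

## Spectra and dimensions

Expected Jacobian eigenvalues are computed by evaluating the analytic
flow Jacobian on a rectangular hypergrid (default 16 nodes per axis
spanning +-32 around (0, 0, 28)), sorting the real parts descending at
each node (complex pairs contribute their real part twice; no continuity
tracking), and averaging under the steady-state density renormalised over
the grid.  The Kaplan-Yorke dimension is `j + sum_{i<=j} lam_i /
|lam_{j+1}|` with `j` the largest index with nonnegative partial sum,
clamped to `[0, n]`.  Doubling the grid resolution moves each eigenvalue
by less than 0.005 in the worked example.

## Density dynamics

The Fokker-Planck equation is integrated in surprisal form.  Writing
`Delta = I_t - I`, the rate

    dI_t/dt = sum_i Gamma_i d2(Delta)/dxi2  +  w . grad Delta,
    w_i = -Gamma_i dI_t/dxi - (Q grad I)_i + Lambda_i,

vanishes identically at `Delta = 0`, so the steady state is an exact
fixed point of the discretisation (steady-state quantities are analytic,
not differenced).  Numerics: central differences; local Lax-Friedrichs
viscosity `|w_i| dx_i / 2` on the advective part (first-order, monotone —
plain central or linearised-upwind differencing is unstable here because
the solenoidal velocities exceed the physical diffusion by two orders of
magnitude); explicit Euler with CFL-limited substepping; renormalisation
every substep; `Delta` capped at 60 (a density floor of `e^-60` relative
to the steady state); boundary faces clamped to that floor (absorbing
boundaries — transient probability leaving the box is removed and
restored by renormalisation, so the box must cover the transient: the
worked example uses 5 standard deviations plus the initial support).
Transport velocities are clipped at the speed scale of the 3-4 sigma
shell; beyond it the polynomial flow is extrapolation and the capped
density carries no mass.  The surprisal-form discretisation is not
conservative: it loses mass at up to the percent-per-bin level during
fast transients (reconciled by the per-substep renormalisation, and
reported as the mass-drift diagnostics), which is well short of the
1e-3 conservation one would get from a flux-form solver.  Because the first-order viscosity broadens the
discrete stationary solution relative to `exp(-I)`, convergence
diagnostics (KL divergence, non-increase guard) are measured against the
*discrete* steady state obtained by relaxing `exp(-I)` under the scheme
itself; the analytic-reference KL is also reported.  The solver refuses
more than three dimensions.

In the worked example (initial Gaussian at (4, 4, 8), unit variance), the
KL divergence decays monotonically and falls below 0.05 after roughly
4 s (260 bins) — faster than the reference ~16 s, consistent with the
exemplar's stronger effective dissipation noted above — while the
marginal mode takes the expected circuitous route through state space.

Information length is accumulated as `sum dt sqrt(E_p[(dI/dt)^2])` with
the rate from finite differences of consecutive snapshots; for
Ornstein-Uhlenbeck mean relaxation it matches the Fisher-metric
quadrature oracle to a few percent and is invariant under refinement of
the time sampling.

## Bayesian mechanics

All conditional expectations are covariance regressions on the sensory
block; the synchronisation map is `sigma = C_eta pinv(C_mu)` between the
linear coefficient matrices, with composition consistency
`sigma(mu_bar(s)) = eta_bar(s)` holding identically whenever the internal
coefficient has full column rank (checked, not assumed).  The variational
free energy is reported as accuracy (precision-weighted prediction error
of particular states about their conditional expectations given sensory
states, with the joint-precision particular block) plus a prior cost of
the encoded external expectation weighted by the inverse of its own
steady-state (explained) covariance; with that weighting `F` equals the
surprisal of particular states exactly, and its gradients over active and
internal states coincide between the conditional and marginal routes to
round-off.  The six-state worked system additionally exposes the closed
forms of all map coefficients in individual potential coefficients as a
verification layer.

## Simulation conventions

Deterministic runs use fixed-step classical Runge-Kutta; stochastic runs
Euler-Maruyama, `x += f dt + sqrt(2 Gamma dt) N(0,1)`, one numpy
Generator per call seeded with a single integer (realisations share the
stream).  Euler-Maruyama at a full 1-bin step visibly biases precision-
matrix estimates of the chaotic exemplars (spurious partial correlations
of order 0.1 between structurally independent states), so ensemble
estimators integrate at a half-bin step and record one sample per bin;
covariance-consistency checks use a quarter- or eighth-bin step.  The
polynomial flows are not globally confining, so very long single
realisations can escape through the cubic tails; ensemble estimates
therefore use many moderate-length realisations (e.g. 32 x 32 000 bins).

## Degenerate and edge cases

Improper densities (e.g. the exact Lorenz decomposition, whose Hessian
has a zero and a negative eigenvalue and whose noise amplitudes are
partly negative) are flagged, kept for conditional-structure queries, and
refused by operations that need a normalisable density.  Rank-deficient
sample covariances, non-invertible synchronisation blocks, degenerate
Kronecker sums in the linear solver, and inadmissible internal sets
(violated blanket zero-blocks) all raise with named causes.  "Zero" for
analytic precision entries means a normalised magnitude below 1e-6;
sample-based zeros should be judged against their standard errors
instead.
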