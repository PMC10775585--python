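# Methods

## Model

`poolmove` fits a multi-state capture-recapture model in hidden-Markov form.
Live states are `M` river pools ordered along a linear chain (downstream to
upstream); state `M+1` is absorbing and conflates death, permanent
emigration, and tag failure, so the survival parameter is *apparent*
survival. Observations are monthly: the pool of the final detection within
the month, or the non-detection code `M+1`. The default design is the
six-pool Illinois River chain (Alton, La Grange, Peoria, Starved Rock,
Marseilles, Dresden Island) over 42 monthly occasions, March 2012 through
August 2015; any chain of ≥2 pools and any consecutive monthly calendar can
be configured.

Assumptions, all standard for this model class:

- first-order Markov movement: next pool depends only on the current pool;
- survival acts before movement within a month-step; with constant `φ` the
  order is immaterial, but the transition matrix keeps the
  `φ ψ_{j,k}` / `1−φ` composition explicitly;
- no false positives: a detection always reports the true pool;
- detections are independent across months given the state sequence;
- parameters are time-constant except detection, which varies by pool and
  meteorological season (Dec–Feb, Mar–May, Jun–Aug, Sep–Nov).

The release month contributes no observation term: the initial state is
known exactly (the fish was handled), so each history enters the likelihood
at the occasion after release, with one full transition per monthly step.

## Likelihood

The per-fish likelihood is evaluated with the scaled forward algorithm: the
forward vector is renormalized at every occasion and the log scale factors
accumulated, so underflow is impossible for any history length. A forward
mass below 1e-300 means the observation is impossible under the parameters
(e.g. a detection with zero detection probability) and yields `-inf` for
that fish rather than an exception. The recursion over fish and months is
JIT-compiled (numba); one evaluation of the full 525-fish, 42-month dataset
costs about half a millisecond, which is what makes finite-difference
optimization and long MCMC runs cheap.

Correctness is established in the test suite by exhaustive path
enumeration: on small instances (`M ≤ 3`, `T ≤ 6`) the forward value agrees
with the brute-force sum over all `(M+1)^(T−r)` state sequences to 1e-10,
and per-fish likelihoods summed over the whole observation space equal 1.

## Maximum likelihood

The free vector stacks the `M(M−1)` off-diagonal movement probabilities,
the `4M` seasonal detection probabilities, and `φ` — 55 values for the
six-pool model. Diagonals are derived as `ψ_{j,j} = 1 − Σ_{k≠j} ψ_{j,k}`,
which keeps each row on the simplex while every free coordinate lives in
the unit box. Because box constraints alone cannot express the simplex, a
start or step whose derived diagonal would be negative receives a large
penalty (`1e10` plus a quadratic term in the violation), steering the
quasi-Newton iteration back into the feasible region smoothly.

Optimization uses L-BFGS-B with bounds `[0,1]`, projected-gradient
tolerance `1e-8`, and up to 1000 iterations; these tolerances are
implementation defaults, not claims about any particular dataset.
Multi-start fitting is supported and recommended for sparse data: the fit
records every terminal negative log-likelihood and returns the best
optimum. The default start uses the same diagonal-heavy structure as the
informative prior (stay ≈ 0.63, adjacent ≈ 0.16, non-adjacent ≈ 0.015 per
row, renormalized; `ρ = 0.5`, `φ = 0.9`).

Uncertainty: the Hessian of the negative log-likelihood at the optimum is
computed by central finite differences (step 1e-5, stencil nudged inside
the box at boundary coordinates, symmetrized). Its inverse may be
indefinite when parameters sit on the boundary or are weakly identified; in
that case the covariance is replaced by the Frobenius-nearest positive
definite matrix (eigenvalues clipped at a small positive floor,
`1e-8 × max |eigenvalue|`). Derived diagonals get delta-method standard
errors: the gradient of `1 − Σ ψ_{j,k}` is −1 on each of the row's free
coordinates, so the variance is the sum of the corresponding covariance
sub-block. Standard errors for boundary estimates (movement probabilities
driven to zero) should be read as qualitative only.

## Priors and posterior sampling

Two prior modes:

- **uninformative** — Beta(1,1) on `φ` and every `ρ`, flat Dirichlet(1,…,1)
  on every movement row;
- **informative** — Beta(2,1) on `φ` and every `ρ` (weak preference for
  higher survival/detection), and per-row Gamma shapes proportional to 0.63
  (stay), 0.16 (each adjacent pool), 0.015 (each non-adjacent pool), scaled
  so each row's shapes sum to a total concentration (default 100).

The movement prior uses the Dirichlet-via-Gamma construction
(`ψ_{j,k} = γ_{j,k} / Σ_k γ_{j,k}`, `γ_{j,k} ~ Gamma(shape, common scale)`),
which is marginally Dirichlet with concentrations equal to the shapes. For
an interior pool (two neighbors) the normalized prior means are ≈ 63.3% /
16.1% / 1.5%. End pools have one neighbor, so the same weight pattern
cannot sum to ~1; normalization raises their self-transition prior mean to
≈ 74%. The total concentration of 100 per row makes the prior worth roughly
one hundred observed transitions — informative by design; scale it down for
weaker regularization.

Sampling operates on unconstrained coordinates — logit for `φ` and `ρ`,
log-Gamma coordinates for movement rows — with exact change-of-variable
corrections, so every draw maps back to a valid parameter set (simplex rows,
unit-interval probabilities) by construction. The hidden states are
marginalized by the forward algorithm; nothing is imputed. Each chain runs
coordinate-wise univariate slice sampling (stepping-out then shrinkage).
Twice during warmup the sweep directions are re-oriented along the
principal axes of the accumulated warmup draws, so correlated parameters
(e.g. movement-versus-detection trade-offs) are updated jointly; directions
and widths are frozen when sampling begins, so the retained chain is a
valid MCMC. All randomness derives from one seed; runs are exactly
reproducible. Default run length is 4 chains × (1000 warmup + 2000
retained); a 4 × (5000 + 10000) preset matches a full-scale analysis.

Diagnostics are split rank-normalized R-hat and bulk/tail effective sample
size (computed via ArviZ, i.e. the Vehtari et al. definitions), with a
convergence cutoff of R-hat < 1.01. A separate multimodality report flags
any parameter whose between-chain mean spread exceeds 5× the average
within-chain posterior SD and clusters the chains at the largest gap — the
signature of chains stuck at distinct solutions.

A sampler-dependence caveat: with this slice sampler, the sparse-pool
identifiability pathology does not usually manifest as chains stuck at
separate modes. The flat-prior posterior over "movement into an
almost-invisible pool" versus "detection there" is a connected ridge, and
the sampler traverses it within tens of sweeps, so independent chains
merge; the pathology instead appears as posterior marginals for the sparse
pool's parameters that remain nearly prior-wide while well-observed pools'
parameters pin down sharply. Stickier samplers at finite run length can
show the same pathology as split chains, which is what the multimodality
report is for.

## Stable distribution

The long-run pool occupancy implied by a movement matrix is its stationary
distribution: the left eigenvector at eigenvalue 1 (movement is read
row→column, so population fractions evolve as row-vector × matrix),
normalized to sum to one. Survival is deliberately excluded — the
projection isolates movement. The eigen solution is cross-checked
internally against power iteration run on `(I + ψ)/2` (same stationary
vector, aperiodic by construction, so periodic chains also converge).
Reducible matrices (more than one closed communicating class) have no
unique stationary distribution and raise an error naming the blocks.
Estimated rows whose sums drift slightly below 1 from numerical slack are
renormalized with a warning.

## Synthetic data

The simulator draws from exactly the generative process the model assumes:
release in a known pool at a staggered entry month, monthly
survive-then-move transitions, seasonal Bernoulli detection, absorbing
death emitting only non-detections. It returns both the capture histories
and the hidden true state sequences (the latter only for test harnesses).

Two ready-made configurations:

- `study_scale_fixture` — six pools, 42 occasions, per-pool release counts
  (72, 54, 111, 151, 133, 4; 525 fish total) with entry months uniform over
  the first half of the study. True movement stays in place with
  probability 0.8 (0.88 at end pools), splits the rest mostly across
  adjacent pools, and leaves ~0.01 total for long-distance jumps; `φ=0.95`;
  detection varies by pool and season within [0.2, 0.95], highest at
  Starved Rock/Marseilles and lowest at Dresden Island. The upstream pool is
  data-sparse by construction, mirroring the invasion front.
- `sparse_state_scenario` — a three-pool chain whose terminal pool has very
  low immigration (0.002 from its neighbor) and very low detection (0.05),
  with no releases there: the regime where maximum likelihood drives
  unobserved transitions to exactly zero while an informative-prior
  posterior keeps them small but positive.

What the simulator does *not* emulate: receiver-level detection (multiple
pings, lateral habitats), continuous-time movement within a month,
individual heterogeneity in any parameter, tag-battery dynamics as a
separate state, and density dependence. Passing tests on synthetic data
therefore demonstrate the estimators' correctness and behavior under the
model's own assumptions, not robustness to their violation in field data.

## Problem sizes and numerical choices

The test suite runs the maximum-likelihood recovery study at the full
simulated scale (525 fish, 42 occasions, 20 replicate datasets) and the
Bayesian recovery at a reduced two-pool scale (200 fish, 24 occasions,
4 chains × 1500 iterations), sizes chosen so the entire suite completes in
a few minutes on one core while leaving the estimators' operating
characteristics measurable. "Well-identified" parameters in the recovery
study are those with at least 20 expected realized events (at-risk months ×
true rate), computed from the simulator's hidden truth; parameters below
that threshold — notably the sparsest pool's detection probabilities — are
excluded from bias assertions, exactly because their information content is
the subject of the sparse-data analyses.

Other numerical details: movement-row sums are validated to 1e-8;
forward-mass floor 1e-300; Hessian step 1e-5; eigenvalue clip floor
`1e-8 × max |eigenvalue|`; stationary-distribution agreement tolerance
1e-8 between the eigen and power-iteration routes. Ties and degenerate
inputs raise informative errors rather than silently proceeding (reducible
movement matrices, all-zero Hessian rows, infeasible starts).

## Known limitations

- Time-varying survival or movement and covariates other than season on
  detection are out of scope.
- Standard errors from the pseudo-variance are approximations whose quality
  degrades at the boundary of the parameter space.
- The multinomial-logit link is available conceptually as an alternative to
  box constraints but is not implemented; the box-constraint path with a
  feasibility penalty is the supported estimator.
- The stable distribution ignores demography (births, deaths, immigration
  from outside the system) by definition.
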