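"""Bayesian estimation of the movement HMM via marginalized-likelihood MCMC.

The posterior is proportional to the forward-algorithm likelihood times the
prior — the hidden states are marginalized analytically, never imputed.
Priors:

* ``phi`` and each ``rho[k, s]`` get Beta priors — Beta(1, 1) in
  uninformative mode, Beta(2, 1) (a weak push toward higher survival and
  detection) in informative mode;
* each movement row gets the Dirichlet-via-Gamma construction
  ``psi[j, k] = gamma[j, k] / sum_k gamma[j, k]`` with independent
  ``gamma[j, k] ~ Gamma(shape[j, k], common scale)``, which makes the row
  marginally Dirichlet with concentrations equal to the shapes.  In
  informative mode the shapes per row are proportional to 0.63 for staying,
  0.16 per adjacent pool and 0.015 per non-adjacent pool, scaled to a total
  row concentration (default 100); an interior pool's prior mean is thus
  ~63% stay / ~16% per adjacent / ~1.5% per non-adjacent pool.

Sampling runs independent chains of coordinate-wise slice sampling on
unconstrained coordinates (logit for the Beta-distributed probabilities,
log-Gamma coordinates for the movement rows) with the exact
change-of-variable corrections, so every draw maps back to a valid
parameter set.  During warmup the sweep directions are re-oriented along
the principal axes of the accumulated draws (so correlated parameters are
updated jointly) and are frozen afterwards.  Convergence is assessed with
split rank-normalized R-hat and bulk/tail effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import numpy as np
from scipy.special import betaln, expit, gammaln

from .data import CaptureHistory, StudyDesign
from .hmm import ForwardEvaluator, N_SEASONS, ParameterSet
from .mle import free_parameter_names, n_free_parameters, pack

__all__ = [
    "PriorSpec",
    "PosteriorResult",
    "build_priors",
    "log_prior",
    "sample_posterior",
    "rhat",
    "ess",
    "detect_multimodality",
]

# Stay / adjacent / non-adjacent relative weights behind the informative
# movement prior (~63% / ~16% / ~1.5% prior means for an interior pool).
INFORMATIVE_WEIGHTS = {"stay": 0.63, "adjacent": 0.16, "nonadjacent": 0.015}
RHAT_CONVERGED = 1.01


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for one model configuration."""

    phi_beta: tuple[float, float]
    rho_beta: tuple[float, float]
    movement_shapes: np.ndarray  # (M, M) Gamma shapes, common scale
    mode: str

    def __post_init__(self) -> None:
        shapes = np.asarray(self.movement_shapes, dtype=float)
        object.__setattr__(self, "movement_shapes", shapes)
        if np.any(shapes <= 0):
            raise ValueError("movement shapes must be positive")
        if min(self.phi_beta) <= 0 or min(self.rho_beta) <= 0:
            raise ValueError("Beta parameters must be positive")

    def row_mean(self, j: int) -> np.ndarray:
        """Dirichlet prior mean of movement row ``j`` (1-based)."""
        row = self.movement_shapes[j - 1]
        return row / row.sum()


def build_priors(
    mode: str, design: StudyDesign, concentration: float = 100.0
) -> PriorSpec:
    """Construct the prior set for ``mode`` in {'uninformative', 'informative'}.

    Uninformative: Beta(1, 1) on phi and rho, flat Dirichlet(1, ..., 1) per
    movement row.  Informative: Beta(2, 1) on phi and rho; movement shapes
    proportional to stay/adjacent/non-adjacent weights 0.63/0.16/0.015,
    scaled so each row's shapes sum to ``concentration``.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    m = design.M
    if mode == "uninformative":
        return PriorSpec(
            phi_beta=(1.0, 1.0),
            rho_beta=(1.0, 1.0),
            movement_shapes=np.ones((m, m)),
            mode=mode,
        )
    if mode == "informative":
        adj = design.adjacency_matrix()
        shapes = np.empty((m, m))
        for j in range(m):
            w = np.where(adj[j], INFORMATIVE_WEIGHTS["adjacent"],
                         INFORMATIVE_WEIGHTS["nonadjacent"])
            w[j] = INFORMATIVE_WEIGHTS["stay"]
            shapes[j] = concentration * w / w.sum()
        return PriorSpec(
            phi_beta=(2.0, 1.0), rho_beta=(2.0, 1.0), movement_shapes=shapes, mode=mode
        )
    raise ValueError(f"unknown prior mode {mode!r}")


def _beta_logpdf(x: float, a: float, b: float) -> float:
    if x < 0.0 or x > 1.0:
        return -np.inf
    if x == 0.0:
        return -np.inf if a > 1 else (np.inf if a < 1 else -betaln(a, b))
    if x == 1.0:
        return -np.inf if b > 1 else (np.inf if b < 1 else -betaln(a, b))
    return float((a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b))


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    """Dirichlet log-density; boundary points give the +-inf limit, not an error."""
    x = np.asarray(x, dtype=float)
    logb = gammaln(alpha).sum() - gammaln(alpha.sum())
    terms = np.zeros_like(x)
    at_zero = x <= 0.0
    pos = ~at_zero
    terms[pos] = (alpha[pos] - 1.0) * np.log(x[pos])
    if at_zero.any():
        a0 = alpha[at_zero]
        if np.any(a0 > 1):
            return -np.inf
        if np.any(a0 < 1):
            return np.inf
    return float(terms.sum() - logb)


def log_prior(theta: ParameterSet, priors: PriorSpec) -> float:
    """Joint log prior density of a parameter set on the probability scale.

    Beta densities on phi and each rho, plus one Dirichlet density per
    movement row with concentrations equal to that row's Gamma shapes (the
    common-scale Gamma-ratio construction marginalizes to exactly this
    Dirichlet).  Boundary values return +-inf, never raise.
    """
    total = _beta_logpdf(theta.phi, *priors.phi_beta)
    for r in np.ravel(theta.rho):
        total += _beta_logpdf(float(r), *priors.rho_beta)
    for j in range(theta.n_pools):
        total += _dirichlet_logpdf(theta.psi[j], priors.movement_shapes[j])
    return total


# --------------------------------------------------------------------------
# Unconstrained parameterization used by the sampler.
#
# z = [u_phi, u_rho (4M, pool-major), w (M*M, row-major)] with
# phi = expit(u_phi), rho = expit(u_rho), gamma = exp(w),
# psi[j] = gamma[j] / sum(gamma[j]).
# --------------------------------------------------------------------------


def _z_to_theta(z: np.ndarray, m: int) -> ParameterSet:
    phi = float(expit(z[0]))
    rho = expit(z[1: 1 + N_SEASONS * m]).reshape(m, N_SEASONS)
    gamma = np.exp(z[1 + N_SEASONS * m:].reshape(m, m))
    psi = gamma / gamma.sum(axis=1, keepdims=True)
    return ParameterSet(phi=phi, psi=psi, rho=rho)


def _theta_to_z(theta: ParameterSet, priors: PriorSpec) -> np.ndarray:
    m = theta.n_pools
    eps = 1e-9
    logit = lambda p: np.log(np.clip(p, eps, 1 - eps) / (1 - np.clip(p, eps, 1 - eps)))
    # place gamma on the prior's row scale so psi rows normalize back exactly
    gamma = np.clip(theta.psi, eps, None) * priors.movement_shapes.sum(axis=1, keepdims=True)
    return np.concatenate([[logit(theta.phi)], logit(theta.rho).ravel(),
                           np.log(gamma).ravel()])


class _LogPosterior:
    """Unnormalized log posterior on the unconstrained scale, with Jacobians."""

    def __init__(
        self,
        evaluator: ForwardEvaluator | None,
        priors: PriorSpec,
        m: int,
    ):
        self.evaluator = evaluator
        self.priors = priors
        self.m = m
        self.n_z = 1 + N_SEASONS * m + m * m

    def __call__(self, z: np.ndarray) -> float:
        m = self.m
        a_phi, b_phi = self.priors.phi_beta
        a_rho, b_rho = self.priors.rho_beta
        # logit-Beta: log Beta(expit(u)) + log expit(u) + log expit(-u)
        u = z[: 1 + N_SEASONS * m]
        p = expit(u)
        ab = np.full_like(u, a_rho)
        bb = np.full_like(u, b_rho)
        ab[0], bb[0] = a_phi, b_phi
        lp = float(
            np.sum(ab * np.log(p) + bb * np.log1p(-p))
            - betaln(a_phi, b_phi)
            - (u.size - 1) * betaln(a_rho, b_rho)
        )
        # log-Gamma coordinates: Gamma(shape s, scale 1) density + Jacobian e^w
        w = z[1 + N_SEASONS * m:].reshape(m, m)
        s = self.priors.movement_shapes
        lp += float(np.sum(s * w - np.exp(w) - gammaln(s)))
        if not np.isfinite(lp):
            return -np.inf
        if self.evaluator is not None and self.evaluator.n_fish > 0:
            rho = p[1:].reshape(m, N_SEASONS)
            gamma = np.exp(w)
            psi = gamma / gamma.sum(axis=1, keepdims=True)
            lp += self.evaluator.log_likelihood_raw(float(p[0]), psi, rho)
        return lp


@dataclass
class PosteriorResult:
    """Posterior draws on the probability scale plus convergence diagnostics.

    ``draws`` has shape (chains, iterations, P) where P matches the ML free
    vector: off-diagonal psi row-major, rho pool-major, phi last.
    """

    draws: np.ndarray
    parameter_names: list[str]
    rhat: np.ndarray
    ess_bulk: np.ndarray
    ess_tail: np.ndarray
    posterior_mean: np.ndarray
    posterior_sd: np.ndarray
    accept_rate: np.ndarray
    n_warmup: int
    seed: int
    prior_mode: str

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def converged(self, cutoff: float = RHAT_CONVERGED) -> bool:
        return bool(np.all(self.rhat[np.isfinite(self.rhat)] < cutoff))

    def chain_means(self) -> np.ndarray:
        return self.draws.mean(axis=1)

    def within_chain_sd(self) -> np.ndarray:
        return self.draws.std(axis=1, ddof=1).mean(axis=0)


def rhat(draws: np.ndarray) -> float:
    """Split rank-normalized R-hat for one parameter (chains x iterations).

    Returns NaN (with a warning) for zero-variance chains.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    if np.allclose(draws.var(axis=1), 0.0):
        warnings.warn("zero-variance chains: R-hat undefined", RuntimeWarning)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset(draws))["x"].values)


def ess(draws: np.ndarray) -> tuple[float, float]:
    """(bulk, tail) effective sample size for one parameter (chains x iters)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 1 or draws.shape[1] < 4:
        raise ValueError("need chains x draws with >= 4 draws")
    ds = az.convert_to_dataset(draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bulk = float(az.ess(ds, method="bulk")["x"].values)
        tail = float(az.ess(ds, method="tail")["x"].values)
    return bulk, tail


def _slice_update(
    logpost, z: np.ndarray, lp: float, direction: np.ndarray, width: float,
    rng: np.random.Generator, max_stepout: int = 8,
) -> tuple[np.ndarray, float, bool]:
    """One univariate slice-sampling update along ``direction`` (stepping out
    then shrinkage); always leaves the target invariant and needs no
    step-size acceptance tuning."""
    log_y = lp + np.log(rng.random())
    u = rng.random()
    lo = -width * u
    hi = lo + width
    for _ in range(max_stepout):
        if logpost(z + lo * direction) <= log_y:
            break
        lo -= width
    for _ in range(max_stepout):
        if logpost(z + hi * direction) <= log_y:
            break
        hi += width
    while True:
        x = rng.uniform(lo, hi)
        z_new = z + x * direction
        lp_new = logpost(z_new)
        if lp_new > log_y:
            return z_new, lp_new, True
        if hi - lo < 1e-12 * width:
            return z, lp, False
        if x < 0:
            lo = x
        else:
            hi = x


def _init_z(
    priors: PriorSpec, m: int, rng: np.random.Generator, jitter: float = 0.2
) -> np.ndarray:
    phi = rng.beta(*priors.phi_beta)
    rho = rng.beta(*priors.rho_beta, size=(m, N_SEASONS))
    gamma = rng.gamma(shape=priors.movement_shapes, scale=1.0)
    psi = gamma / gamma.sum(axis=1, keepdims=True)
    theta = ParameterSet(phi=float(phi), psi=psi, rho=rho)
    z = _theta_to_z(theta, priors)
    return z + jitter * rng.standard_normal(z.size)


def sample_posterior(
    histories: Sequence[CaptureHistory],
    design: StudyDesign,
    priors: PriorSpec,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_iter: int = 2000,
    seed: int = 0,
    inits: Sequence[ParameterSet | np.ndarray] | None = None,
) -> PosteriorResult:
    """Draw from the posterior with independent slice-sampling chains.

    Each chain sweeps the unconstrained coordinates one at a time with
    univariate slice updates; during the ``n_warmup`` discarded iterations
    the sweep directions and widths are re-oriented twice along the
    principal axes of the accumulated draws, then frozen for the ``n_iter``
    retained iterations.  All randomness derives from ``seed``; identical
    seeds give identical draws.

    An empty ``histories`` list samples the prior alone, which is useful for
    prior-predictive checks.

    Raises
    ------
    ValueError
        If fewer than 2 chains are requested, or the posterior is non-finite
        at every initial point (try informative-prior draws as inits).
    """
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    m = design.M
    evaluator = ForwardEvaluator(list(histories), design) if len(histories) else None
    logpost = _LogPosterior(evaluator, priors, m)
    n_z = logpost.n_z
    p_out = n_free_parameters(m)
    draws = np.empty((n_chains, n_iter, p_out))
    accept = np.zeros(n_chains)

    for c in range(n_chains):
        rng = np.random.default_rng([int(seed), c])
        if inits is not None:
            init = inits[c % len(inits)]
            z = (
                _theta_to_z(init, priors)
                if isinstance(init, ParameterSet)
                else np.asarray(init, dtype=float).copy()
            )
        else:
            z = _init_z(priors, m, rng)
        lp = logpost(z)
        tries = 0
        while not np.isfinite(lp) and tries < 50:
            z = _init_z(priors, m, rng)
            lp = logpost(z)
            tries += 1
        if not np.isfinite(lp):
            raise ValueError(
                "non-finite posterior at every initial point; supply feasible "
                "inits (e.g. draws from the informative prior)"
            )
        widths = np.full(n_z, 1.0)
        directions = np.eye(n_z)  # replaced by posterior principal axes mid-warmup
        history = np.empty((n_warmup, n_z)) if n_warmup > 0 else None
        n_moved = 0
        n_total = 0
        for it in range(n_warmup + n_iter):
            warming = it < n_warmup
            for i in range(n_z):
                z, lp, moved = _slice_update(
                    logpost, z, lp, directions[:, i], widths[i], rng
                )
                if not warming:
                    n_moved += moved
                    n_total += 1
            if warming:
                history[it] = z
                # part-way through warmup, re-orient the sweep along the
                # principal axes of the recent warmup draws so correlated
                # coordinates are updated jointly (twice: the second pass
                # refines the covariance once the transient has died out)
                if it + 1 in (int(0.4 * n_warmup), int(0.8 * n_warmup)) and it + 1 >= 100:
                    seg = history[(it + 1) // 2: it + 1]
                    cov = np.cov(seg.T) + 1e-8 * np.eye(n_z)
                    eigval, eigvec = np.linalg.eigh(cov)
                    directions = eigvec
                    widths = 2.5 * np.sqrt(np.maximum(eigval, 1e-12))
            else:
                draws[c, it - n_warmup] = pack(_z_to_theta(z, m))
        accept[c] = n_moved / max(n_total, 1)

    rh = np.empty(p_out)
    eb = np.empty(p_out)
    et = np.empty(p_out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(p_out):
            x = draws[:, :, p]
            if np.allclose(x.var(axis=1), 0.0):
                rh[p], eb[p], et[p] = np.nan, np.nan, np.nan
                continue
            rh[p] = rhat(x)
            eb[p], et[p] = ess(x)
    return PosteriorResult(
        draws=draws,
        parameter_names=free_parameter_names(m),
        rhat=rh,
        ess_bulk=eb,
        ess_tail=et,
        posterior_mean=draws.reshape(-1, p_out).mean(axis=0),
        posterior_sd=draws.reshape(-1, p_out).std(axis=0, ddof=1),
        accept_rate=accept,
        n_warmup=n_warmup,
        seed=seed,
        prior_mode=priors.mode,
    )


def detect_multimodality(
    result: PosteriorResult, threshold: float = 5.0
) -> list[dict]:
    """Flag parameters whose chains disagree far beyond their within-chain spread.

    A parameter is flagged when the spread of per-chain posterior means
    exceeds ``threshold`` times the average within-chain posterior SD — the
    signature of chains stuck at distinct modes (e.g. a low-detection /
    high-movement solution versus a high-detection / low-movement one).
    Chains are clustered by splitting the sorted means at the largest gap.

    Returns a list of reports, one per flagged parameter, each naming the
    parameter, the per-chain means, the within-chain SD, and the two chain
    clusters (1-based chain ids).  An empty list means all chains agree.
    """
    means = result.chain_means()
    within = np.maximum(result.within_chain_sd(), 1e-12)
    reports = []
    for p, name in enumerate(result.parameter_names):
        spread = means[:, p].max() - means[:, p].min()
        if spread <= threshold * within[p]:
            continue
        order = np.argsort(means[:, p])
        gaps = np.diff(means[order, p])
        cut = int(np.argmax(gaps)) + 1
        lower = sorted((order[:cut] + 1).tolist())
        upper = sorted((order[cut:] + 1).tolist())
        reports.append(
            {
                "parameter": name,
                "chain_means": means[:, p].tolist(),
                "within_sd": float(within[p]),
                "spread": float(spread),
                "clusters": (lower, upper),
            }
        )
    return reports
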