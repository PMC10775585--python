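"""Box-constrained maximum-likelihood estimation with pseudo-variance.

The free parameter vector stacks, in order, the ``M(M-1)`` off-diagonal
movement probabilities (row-major), the ``4M`` seasonal detection
probabilities (pool-major), and the single apparent-survival probability —
55 values for the six-pool, four-season model.  Each row's self-transition
is derived as ``psi[j,j] = 1 - sum of off-diagonals``, which enforces the
simplex constraint inside the unit box; starts where a derived diagonal
would be negative receive a large quadratic penalty so the optimizer stays
feasible.

Standard errors come from the inverse of a finite-difference Hessian of the
negative log-likelihood at the optimum, replaced by its nearest positive
definite matrix when the raw inverse is indefinite (a pseudo-variance), and
the derived diagonals get delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .data import CaptureHistory, StudyDesign
from .hmm import ForwardEvaluator, N_SEASONS, ParameterSet

__all__ = [
    "FitResultML",
    "free_parameter_names",
    "n_free_parameters",
    "pack",
    "unpack",
    "negative_log_likelihood",
    "fit_mle",
    "default_init",
    "finite_difference_hessian",
    "pseudo_variance",
    "delta_method_se",
]

PENALTY_BASE = 1e10
PENALTY_SCALE = 1e6


def n_free_parameters(m: int) -> int:
    """M(M-1) off-diagonal movements + 4M detections + survival."""
    return m * (m - 1) + N_SEASONS * m + 1


def free_parameter_names(m: int) -> list[str]:
    """Stable 1-based names: psi[j,k] off-diagonals, rho[pool,season], phi."""
    names = [
        f"psi[{j},{k}]" for j in range(1, m + 1) for k in range(1, m + 1) if k != j
    ]
    names += [f"rho[{k},{s}]" for k in range(1, m + 1) for s in range(1, N_SEASONS + 1)]
    names.append("phi")
    return names


def _psi_offdiag_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    jj, kk = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    mask = jj != kk
    return jj[mask], kk[mask]


def pack(theta: ParameterSet) -> np.ndarray:
    """Flatten a ParameterSet into the free-parameter vector."""
    m = theta.n_pools
    jj, kk = _psi_offdiag_indices(m)
    return np.concatenate([theta.psi[jj, kk], theta.rho.ravel(), [theta.phi]])


def _split(vector: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, float]:
    n_psi = m * (m - 1)
    off = np.asarray(vector[:n_psi], dtype=float)
    rho = np.asarray(vector[n_psi: n_psi + N_SEASONS * m], dtype=float).reshape(m, N_SEASONS)
    phi = float(vector[-1])
    return off, rho, phi


def _diagonals(vector: np.ndarray, m: int) -> np.ndarray:
    off, _, _ = _split(vector, m)
    return 1.0 - off.reshape(m, m - 1).sum(axis=1)


def unpack(vector: np.ndarray, m: int) -> ParameterSet:
    """Rebuild a ParameterSet, deriving each diagonal ``1 - sum(off-diag)``.

    Raises
    ------
    ValueError
        If the vector has the wrong length, an entry is outside ``[0, 1]``,
        or a derived diagonal is negative (infeasible row).
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (n_free_parameters(m),):
        raise ValueError(
            f"expected free vector of length {n_free_parameters(m)}, got {vector.shape}"
        )
    if np.any(vector < 0) or np.any(vector > 1):
        raise ValueError("free parameters must lie in [0, 1]")
    diag = _diagonals(vector, m)
    if np.any(diag < -1e-12):
        bad = int(np.argmin(diag)) + 1
        raise ValueError(
            f"infeasible movement row {bad}: off-diagonals sum to {1 - diag[bad - 1]:.4f}"
        )
    off, rho, phi = _split(vector, m)
    psi = np.zeros((m, m))
    jj, kk = _psi_offdiag_indices(m)
    psi[jj, kk] = off
    np.fill_diagonal(psi, np.clip(diag, 0.0, 1.0))
    return ParameterSet(phi=phi, psi=psi, rho=rho)


def _nll_factory(evaluator: ForwardEvaluator) -> Callable[[np.ndarray], float]:
    m = evaluator.M

    def nll(vector: np.ndarray) -> float:
        v = np.clip(np.asarray(vector, dtype=float), 0.0, 1.0)
        diag = _diagonals(v, m)
        if np.any(diag < 0):
            viol = np.minimum(diag, 0.0)
            return PENALTY_BASE + PENALTY_SCALE * float(viol @ viol)
        theta = unpack(v, m)
        ll = evaluator.log_likelihood(theta)
        if not np.isfinite(ll):
            return PENALTY_BASE
        return -ll

    return nll


def negative_log_likelihood(
    vector: np.ndarray,
    histories: Sequence[CaptureHistory],
    design: StudyDesign,
) -> float:
    """Negative forward log-likelihood of the free vector (penalized if infeasible)."""
    return _nll_factory(ForwardEvaluator(histories, design))(np.asarray(vector))


def default_init(design: StudyDesign, rho: float = 0.5, phi: float = 0.9) -> np.ndarray:
    """Biologically informed start: diagonal-heavy movement, mid detection.

    Movement rows use the stay/adjacent/non-adjacent weights 0.63/0.16/0.015
    renormalized per row — the same structure as the informative prior.
    """
    m = design.M
    psi = np.empty((m, m))
    adj = design.adjacency_matrix()
    for j in range(m):
        w = np.where(adj[j], 0.16, 0.015)
        w[j] = 0.63
        psi[j] = w / w.sum()
    theta = ParameterSet(phi=phi, psi=psi, rho=np.full((m, N_SEASONS), rho))
    return pack(theta)


@dataclass
class FitResultML:
    """Outcome of a (possibly multi-start) box-constrained ML fit."""

    theta_hat: ParameterSet
    free_vector: np.ndarray
    parameter_names: list[str]
    neg_log_lik: float
    converged: bool
    message: str
    n_iterations: int
    all_neg_log_lik: list[float] = field(default_factory=list)
    covariance: np.ndarray | None = None
    se: np.ndarray | None = None
    se_derived: np.ndarray | None = None


def finite_difference_hessian(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    step: float = 1e-5,
    lower: float = 0.0,
    upper: float = 1.0,
) -> np.ndarray:
    """Central-difference Hessian with the stencil kept inside the box.

    Coordinates within ``step`` of a bound are nudged inside so every stencil
    point stays feasible; the result is symmetrized.
    """
    x0 = np.clip(np.asarray(x, dtype=float), lower + step, upper - step)
    n = x0.size
    h = np.zeros((n, n))
    ei = np.eye(n) * step
    f_plus = np.array([f(x0 + ei[i]) for i in range(n)])
    f_minus = np.array([f(x0 - ei[i]) for i in range(n)])
    f0 = f(x0)
    for i in range(n):
        h[i, i] = (f_plus[i] - 2.0 * f0 + f_minus[i]) / step**2
        for j in range(i + 1, n):
            fpp = f(x0 + ei[i] + ei[j])
            fmm = f(x0 - ei[i] - ei[j])
            h[i, j] = h[j, i] = (
                fpp - f_plus[i] - f_plus[j] + 2.0 * f0 - f_minus[i] - f_minus[j] + fmm
            ) / (2.0 * step**2)
    return 0.5 * (h + h.T)


def pseudo_variance(hessian: np.ndarray, floor_ratio: float = 1e-8) -> np.ndarray:
    """Covariance from an inverse Hessian, repaired to positive definiteness.

    The Hessian is symmetrized and inverted; if the inverse has eigenvalues
    below a small positive floor it is replaced by the Frobenius-nearest
    positive definite matrix (eigenvalues clipped at
    ``floor_ratio * max |eigenvalue|``).  An identically-zero row means the
    corresponding coordinate is not identified and is reported by index.
    """
    h = 0.5 * (np.asarray(hessian, dtype=float) + np.asarray(hessian, dtype=float).T)
    if not np.all(np.isfinite(h)):
        raise ValueError("Hessian contains non-finite entries")
    zero_rows = np.where(~h.any(axis=1))[0]
    if zero_rows.size:
        raise ValueError(
            f"singular Hessian: coordinate(s) {zero_rows.tolist()} not identified "
            "(all-zero row)"
        )
    try:
        inv = np.linalg.inv(h)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"Hessian not invertible: {err}") from err
    inv = 0.5 * (inv + inv.T)
    eigval, eigvec = np.linalg.eigh(inv)
    floor = floor_ratio * float(np.max(np.abs(eigval)))
    if eigval.min() >= floor:
        return inv
    clipped = np.maximum(eigval, floor)
    return eigvec @ np.diag(clipped) @ eigvec.T


def delta_method_se(covariance: np.ndarray, row: int, m: int) -> float:
    """Delta-method SE of the derived diagonal ``psi[row, row]``.

    The diagonal is ``1 - sum`` of the row's off-diagonals, so its gradient
    is -1 on each of those coordinates and the variance is the sum of the
    corresponding covariance sub-block.
    """
    if not 1 <= row <= m:
        raise ValueError(f"row {row} out of range 1..{m}")
    start = (row - 1) * (m - 1)
    idx = np.arange(start, start + m - 1)
    block = covariance[np.ix_(idx, idx)]
    var = float(block.sum())
    return float(np.sqrt(max(var, 0.0)))


def fit_mle(
    histories: Sequence[CaptureHistory],
    design: StudyDesign,
    init: np.ndarray | Sequence[np.ndarray] | None = None,
    max_iter: int = 1000,
    gtol: float = 1e-8,
    compute_se: bool = True,
    hessian_step: float = 1e-5,
) -> FitResultML:
    """Maximize the forward-algorithm likelihood with L-BFGS-B in the unit box.

    Parameters
    ----------
    init
        A feasible free vector, a list of them (multi-start: the best
        terminal optimum is returned and every terminal NLL recorded), or
        None for the informed default start.
    gtol
        Projected-gradient convergence tolerance.
    compute_se
        Also compute the finite-difference Hessian, pseudo-variance,
        per-parameter SEs and delta-method SEs of the derived diagonals.
    """
    evaluator = ForwardEvaluator(histories, design)
    m = design.M
    nll = _nll_factory(evaluator)
    if init is None:
        inits = [default_init(design)]
    elif isinstance(init, np.ndarray) and init.ndim == 1:
        inits = [init]
    else:
        inits = [np.asarray(v, dtype=float) for v in init]

    best = None
    all_nll: list[float] = []
    for x0 in inits:
        if not np.isfinite(nll(x0)) or nll(x0) >= PENALTY_BASE:
            raise ValueError(
                "non-finite or penalized objective at the initial vector; "
                "supply a feasible start (entries in [0,1], row sums <= 1)"
            )
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * x0.size,
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14},
        )
        all_nll.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    x_hat = np.clip(best.x, 0.0, 1.0)
    result = FitResultML(
        theta_hat=unpack(x_hat, m),
        free_vector=x_hat,
        parameter_names=free_parameter_names(m),
        neg_log_lik=float(best.fun),
        converged=bool(best.success),
        message=str(best.message),
        n_iterations=int(best.nit),
        all_neg_log_lik=all_nll,
    )
    if compute_se:
        hess = finite_difference_hessian(nll, x_hat, step=hessian_step)
        cov = pseudo_variance(hess)
        result.covariance = cov
        result.se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        result.se_derived = np.array(
            [delta_method_se(cov, j, m) for j in range(1, m + 1)]
        )
    return result
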