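"""Hidden Markov model core: matrices and the forward-algorithm likelihood.

The model has ``M`` live states (river pools) and one absorbing state
``M+1`` ("dead": mortality, permanent emigration, or tag failure — not
distinguishable, hence *apparent* survival).  Parameters:

* ``phi`` — apparent monthly survival, constant over pools and time;
* ``psi`` — ``M x M`` row-stochastic monthly movement matrix among live
  pools, conditional on survival;
* ``rho`` — ``M x 4`` detection probabilities by pool and season.

Observation model: no false positives.  A live fish in pool ``k`` during
season ``s`` is detected (emitting code ``k``) with probability
``rho[k, s]`` and otherwise emits the non-detection code ``M+1``; a dead
fish always emits ``M+1``.

The per-fish likelihood is the forward-algorithm product

    delta_i  Psi P(Y_2)  Psi P(Y_3) ... Psi P(Y_T)  1

where ``delta_i`` is the unit vector at the known release pool, ``Psi`` is
the survival-times-movement transition matrix and ``P(Y_t)`` is the
diagonal observation matrix for the coded observation at occasion ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .data import CaptureHistory, StudyDesign, season_of

__all__ = [
    "ParameterSet",
    "build_transition_matrix",
    "observation_vector",
    "forward_log_likelihood",
    "ForwardEvaluator",
]

ROW_SUM_TOL = 1e-10
N_SEASONS = 4


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter vector theta = (phi, psi, rho) of the movement HMM."""

    phi: float
    psi: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "rho", rho)
        m = psi.shape[0]
        if psi.shape != (m, m):
            raise ValueError(f"psi must be square, got {psi.shape}")
        if rho.ndim != 2 or rho.shape != (m, N_SEASONS):
            raise ValueError(f"rho must be {m}x{N_SEASONS}, got {rho.shape}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi={self.phi} outside [0, 1]")
        if np.any(psi < -ROW_SUM_TOL) or np.any(psi > 1 + ROW_SUM_TOL):
            raise ValueError("psi entries outside [0, 1]")
        if np.any(rho < 0) or np.any(rho > 1):
            raise ValueError("rho entries outside [0, 1]")
        rowsum = psi.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-8):
            raise ValueError(f"psi rows must sum to 1, got {rowsum}")

    @property
    def n_pools(self) -> int:
        return self.psi.shape[0]


def build_transition_matrix(theta: ParameterSet) -> np.ndarray:
    """(M+1)x(M+1) state transition matrix: survive-and-move, or die.

    Entry ``(j, k) = phi * psi[j, k]`` for live ``j, k``; the last column of
    each live row is ``1 - phi``; the dead state is absorbing.
    """
    m = theta.n_pools
    full = np.zeros((m + 1, m + 1))
    full[:m, :m] = theta.phi * theta.psi
    full[:m, m] = 1.0 - theta.phi
    full[m, m] = 1.0
    return full


def observation_vector(
    y: int, occasion: int, theta: ParameterSet, design: StudyDesign
) -> np.ndarray:
    """Emission probabilities ``Pr(Y = y | S = k)`` over states ``k = 1..M+1``.

    With no false positives a detection code ``y <= M`` can only come from
    state ``y`` (probability ``rho[y, season]``); the non-detection code
    ``M+1`` comes from any live state with probability ``1 - rho`` or from
    the dead state with probability 1.
    """
    m = theta.n_pools
    if not 1 <= y <= m + 1:
        raise ValueError(f"observation code {y} out of range 1..{m + 1}")
    s = season_of(occasion, design)
    out = np.zeros(m + 1)
    if y <= m:
        out[y - 1] = theta.rho[y - 1, s - 1]
    else:
        out[:m] = 1.0 - theta.rho[:, s - 1]
        out[m] = 1.0
    return out


class ForwardEvaluator:
    """Vectorized forward-algorithm evaluator for a fixed set of histories.

    Preprocessing (observation codes, release indices, per-occasion seasons)
    is done once; :meth:`log_likelihood` can then be called cheaply for many
    parameter values, which is what both the optimizer and the MCMC sampler
    need.  The forward vector is renormalized at every occasion and the log
    scale factors accumulated, so underflow cannot occur; a forward-vector
    sum below 1e-300 (an observation impossible under theta) yields -inf for
    that fish.
    """

    def __init__(self, histories: Sequence[CaptureHistory], design: StudyDesign):
        self.design = design
        self.n_fish = len(histories)
        m, t_max = design.M, design.T
        self.M = m
        for h in histories:
            h.validate(design)
        self.release_occ = np.array([h.release_occasion for h in histories], dtype=int)
        self.release_pool = np.array([h.release_pool for h in histories], dtype=int)
        # obs[i, t-1] = coded observation of fish i at occasion t (0 = before release)
        self.obs = np.zeros((self.n_fish, t_max), dtype=int)
        for i, h in enumerate(histories):
            r = h.release_occasion
            if h.observations:
                self.obs[i, r: r + len(h.observations)] = h.observations
        self.season = np.array([season_of(t, design) for t in range(1, t_max + 1)])

    def _emission_tables(self, theta: ParameterSet) -> np.ndarray:
        """B[s-1, y-1, k-1] = Pr(Y=y | S=k, season s); code/state M+1 included."""
        m = self.M
        b = np.zeros((N_SEASONS, m + 1, m + 1))
        for s in range(N_SEASONS):
            rho_s = theta.rho[:, s]
            b[s, np.arange(m), np.arange(m)] = rho_s
            b[s, m, :m] = 1.0 - rho_s
            b[s, m, m] = 1.0
        return b

    def per_fish_log_likelihood(self, theta: ParameterSet) -> np.ndarray:
        psi_full = build_transition_matrix(theta)
        b = self._emission_tables(theta)
        return _forward_core(
            psi_full, b, self.obs, self.release_occ, self.release_pool, self.season
        )

    def log_likelihood(self, theta: ParameterSet) -> float:
        return float(self.per_fish_log_likelihood(theta).sum())

    def log_likelihood_raw(
        self, phi: float, psi: np.ndarray, rho: np.ndarray
    ) -> float:
        """Total log-likelihood without ParameterSet validation (hot path for
        samplers; caller guarantees valid inputs)."""
        m = self.M
        psi_full = np.zeros((m + 1, m + 1))
        psi_full[:m, :m] = phi * psi
        psi_full[:m, m] = 1.0 - phi
        psi_full[m, m] = 1.0
        b = np.zeros((N_SEASONS, m + 1, m + 1))
        idx = np.arange(m)
        for s in range(N_SEASONS):
            b[s, idx, idx] = rho[:, s]
            b[s, m, :m] = 1.0 - rho[:, s]
            b[s, m, m] = 1.0
        return float(
            _forward_core(
                psi_full, b, self.obs, self.release_occ, self.release_pool, self.season
            ).sum()
        )


@njit(cache=True)
def _forward_core(psi_full, b, obs, release_occ, release_pool, season):
    """Scaled forward recursion over all fish (compiled inner kernel)."""
    n, t_max = obs.shape
    mp1 = psi_full.shape[0]
    out = np.zeros(n)
    alpha = np.zeros(mp1)
    tmp = np.zeros(mp1)
    for i in range(n):
        r = release_occ[i]
        if r >= t_max:
            continue
        for k in range(mp1):
            alpha[k] = 0.0
        alpha[release_pool[i] - 1] = 1.0
        ll = 0.0
        for t in range(r + 1, t_max + 1):
            s = season[t - 1] - 1
            y = obs[i, t - 1] - 1
            c = 0.0
            for k in range(mp1):
                acc = 0.0
                for j in range(mp1):
                    acc += alpha[j] * psi_full[j, k]
                acc *= b[s, y, k]
                tmp[k] = acc
                c += acc
            if c < 1e-300:
                ll = -np.inf
                break
            for k in range(mp1):
                alpha[k] = tmp[k] / c
            ll += np.log(c)
        out[i] = ll
    return out


def forward_log_likelihood(
    histories: Sequence[CaptureHistory],
    theta: ParameterSet,
    design: StudyDesign,
) -> float:
    """Total log-likelihood of the capture histories under theta.

    Sums, over fish, the log of the forward-algorithm product starting from
    the degenerate initial distribution at the known release pool.  Returns
    ``-inf`` if any history is impossible under ``theta`` (e.g. a detection
    with ``rho = 0``).
    """
    return ForwardEvaluator(histories, design).log_likelihood(theta)
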