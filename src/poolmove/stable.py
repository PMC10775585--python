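"""Stable pool distribution of the movement-only Markov chain.

Given an estimated row-stochastic movement matrix (movement from row pool
to column pool), the long-run proportion of a population in each pool —
ignoring births, deaths, and migration in or out of the system — is the
stationary distribution: the left eigenvector of the matrix at eigenvalue
1, normalized to sum to one.  Comparing this distribution across
parameterizations shows how much the choice of estimation method matters
for predicted occupancy, especially at sparsely observed pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = ["StableDistribution", "stable_distribution", "compare_stable_distributions"]


@dataclass(frozen=True)
class StableDistribution:
    proportions: np.ndarray
    dominant_eigenvalue: float
    converged: bool


def _closed_classes(psi: np.ndarray, tol: float = 1e-12) -> list[list[int]]:
    """Strongly connected components with no outgoing probability (recurrent)."""
    n_comp, labels = connected_components(psi > tol, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.where(labels == c)[0]
        outside = np.setdiff1d(np.arange(psi.shape[0]), members)
        if outside.size == 0 or psi[np.ix_(members, outside)].sum() <= tol:
            closed.append((members + 1).tolist())
    return closed


def _power_iteration(
    psi: np.ndarray, tol: float = 1e-13, max_iter: int = 200_000
) -> tuple[np.ndarray, bool]:
    # iterate on (I + psi)/2: same stationary vector, aperiodic by construction
    m = psi.shape[0]
    half = 0.5 * (np.eye(m) + psi)
    v = np.full(m, 1.0 / m)
    for _ in range(max_iter):
        nxt = v @ half
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - v)) < tol:
            return nxt, True
        v = nxt
    return v, False


def stable_distribution(psi: np.ndarray, renormalize_slack: bool = True) -> StableDistribution:
    """Stationary distribution of a row-stochastic movement matrix.

    Computed as the left eigenvector at the dominant eigenvalue (1 for any
    valid row-stochastic matrix) and cross-validated against power
    iteration.  Rows whose sums drift slightly below 1 (numerical slack in
    an estimated matrix) are renormalized with a warning.

    Raises
    ------
    ValueError
        If the eigenvalue-1 eigenspace has dimension > 1 (reducible chain —
        the disconnected recurrent blocks are named), or entries are invalid.
    RuntimeError
        If the eigenvector acquires negative mass or disagrees with power
        iteration beyond 1e-8.
    """
    psi = np.asarray(psi, dtype=float)
    m = psi.shape[0]
    if psi.shape != (m, m):
        raise ValueError(f"movement matrix must be square, got {psi.shape}")
    if np.any(psi < 0):
        raise ValueError("movement matrix entries must be non-negative")
    rowsum = psi.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-8):
        if renormalize_slack and np.all(rowsum > 0) and np.all(np.abs(rowsum - 1.0) < 0.05):
            import warnings

            warnings.warn(
                "movement rows do not sum to 1 (max slack "
                f"{np.max(np.abs(rowsum - 1)):.2e}); renormalizing",
                RuntimeWarning,
            )
            psi = psi / rowsum[:, None]
        else:
            raise ValueError(f"movement rows must sum to 1, got {rowsum}")

    eigval, left = np.linalg.eig(psi.T)
    near_one = np.where(np.abs(eigval - 1.0) < 1e-8)[0]
    if near_one.size > 1:
        blocks = _closed_classes(psi)
        raise ValueError(
            "stationary distribution is not unique: the chain is reducible "
            f"with closed blocks {blocks}"
        )
    if near_one.size == 0:
        raise RuntimeError("no eigenvalue near 1 for a row-stochastic matrix")
    k = near_one[0]
    vec = np.real(left[:, k])
    vec = vec / vec.sum()
    if np.any(vec < -1e-10):
        raise RuntimeError(f"negative stationary mass after normalization: {vec}")
    vec = np.clip(vec, 0.0, None)
    vec /= vec.sum()
    power, converged = _power_iteration(psi)
    if np.max(np.abs(power - vec)) > 1e-8:
        raise RuntimeError(
            "eigenvector and power-iteration stationary distributions disagree "
            f"by {np.max(np.abs(power - vec)):.2e}"
        )
    return StableDistribution(
        proportions=vec,
        dominant_eigenvalue=float(np.real(eigval[k])),
        converged=converged,
    )


def compare_stable_distributions(
    labeled_psis: Sequence[tuple[str, np.ndarray]],
    pool_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Side-by-side stable distributions for several movement estimates.

    Returns a DataFrame indexed by pool with one proportion column per label
    and one ``|A - B|`` column of per-pool absolute differences for each
    label pair.
    """
    if not labeled_psis:
        raise ValueError("need at least one labeled movement matrix")
    m = np.asarray(labeled_psis[0][1]).shape[0]
    cols = {}
    for label, psi in labeled_psis:
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (m, m):
            raise ValueError(
                f"{label!r}: expected {m}x{m} matrix, got {psi.shape}"
            )
        cols[label] = stable_distribution(psi).proportions
    index = list(pool_names) if pool_names is not None else [
        f"pool_{j}" for j in range(1, m + 1)
    ]
    table = pd.DataFrame(cols, index=pd.Index(index, name="pool"))
    labels = [label for label, _ in labeled_psis]
    for i, a in enumerate(labels):
        for b_lab in labels[i + 1:]:
            table[f"|{a}-{b_lab}|"] = np.abs(table[a] - table[b_lab])
    return table
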