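"""CSV / JSON / YAML plumbing for the pipeline stages.

File dialects:

* capture histories — one row per fish, header
  ``fish_id,release_occasion,release_pool,y_2,...,y_T``; cells at or before
  the release occasion are empty, observation codes are ``1..M+1``;
* detection events — ``fish_id,timestamp,pool`` with ISO-8601 timestamps
  and pools by name or 1-based index;
* releases — ``fish_id,release_date,release_pool``;
* ML fits — a parameter CSV (``parameter,estimate,se``) plus a JSON summary;
* posterior draws — long CSV ``chain,iteration,parameter,value`` plus a
  JSON diagnostics summary;
* study designs — YAML/JSON with pool names, start month, occasion count.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bayes import PosteriorResult
from .data import CaptureHistory, DetectionEvent, StudyDesign
from .mle import FitResultML

__all__ = [
    "read_histories",
    "write_histories",
    "read_events",
    "read_releases",
    "read_design",
    "write_design",
    "design_to_dict",
    "design_from_dict",
    "write_mle_result",
    "write_posterior",
    "read_psi_from_parameter_csv",
]


def design_to_dict(design: StudyDesign) -> dict:
    return {
        "pools": list(design.pools),
        "start": f"{design.start[0]:04d}-{design.start[1]:02d}",
        "n_occasions": design.n_occasions,
    }


def design_from_dict(d: dict) -> StudyDesign:
    year, month = (int(x) for x in str(d["start"]).split("-")[:2])
    return StudyDesign(
        pools=tuple(d["pools"]), start=(year, month), n_occasions=int(d["n_occasions"])
    )


def write_design(design: StudyDesign, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(design_to_dict(design)))


def read_design(path: str | Path) -> StudyDesign:
    return design_from_dict(yaml.safe_load(Path(path).read_text()))


def write_histories(
    histories: Sequence[CaptureHistory], design: StudyDesign, path: str | Path
) -> None:
    cols = ["fish_id", "release_occasion", "release_pool"] + [
        f"y_{t}" for t in range(2, design.T + 1)
    ]
    rows = []
    for h in histories:
        row: dict = {
            "fish_id": h.fish_id,
            "release_occasion": h.release_occasion,
            "release_pool": h.release_pool,
        }
        for i, y in enumerate(h.observations):
            row[f"y_{h.release_occasion + 1 + i}"] = y
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_histories(
    path: str | Path, design: StudyDesign
) -> list[CaptureHistory]:
    df = pd.read_csv(path)
    histories = []
    for irow, row in enumerate(df.itertuples(index=False)):
        try:
            r = int(row.release_occasion)
            obs = tuple(
                int(getattr(row, f"y_{t}")) for t in range(r + 1, design.T + 1)
            )
            h = CaptureHistory(
                fish_id=str(row.fish_id),
                release_occasion=r,
                release_pool=int(row.release_pool),
                observations=obs,
            )
            h.validate(design)
        except (ValueError, TypeError, AttributeError) as err:
            raise ValueError(f"{path}: bad history at data row {irow + 1}: {err}") from err
        histories.append(h)
    return histories


def _parse_pool(value, design: StudyDesign) -> int:
    try:
        return design.pool_index(int(value))
    except (TypeError, ValueError):
        return design.pool_index(str(value).strip())


def read_events(path: str | Path, design: StudyDesign) -> list[DetectionEvent]:
    df = pd.read_csv(path)
    events = []
    for irow, row in enumerate(df.itertuples(index=False)):
        try:
            events.append(
                DetectionEvent(
                    fish_id=str(row.fish_id),
                    timestamp=datetime.fromisoformat(str(row.timestamp)),
                    pool=_parse_pool(row.pool, design),
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: bad event at data row {irow + 1}: {err}") from err
    return events


def read_releases(
    path: str | Path, design: StudyDesign
) -> dict[str, tuple[datetime, int]]:
    df = pd.read_csv(path)
    releases = {}
    for irow, row in enumerate(df.itertuples(index=False)):
        try:
            releases[str(row.fish_id)] = (
                datetime.fromisoformat(str(row.release_date)),
                _parse_pool(row.release_pool, design),
            )
        except ValueError as err:
            raise ValueError(f"{path}: bad release at data row {irow + 1}: {err}") from err
    return releases


def write_mle_result(result: FitResultML, prefix: str | Path) -> None:
    """Write ``<prefix>_params.csv`` (parameter, estimate, se) and ``<prefix>_summary.json``."""
    prefix = Path(prefix)
    se = result.se if result.se is not None else np.full(result.free_vector.size, np.nan)
    df = pd.DataFrame(
        {
            "parameter": result.parameter_names,
            "estimate": result.free_vector,
            "se": se,
        }
    )
    m = result.theta_hat.n_pools
    if result.se_derived is not None:
        derived = pd.DataFrame(
            {
                "parameter": [f"psi[{j},{j}]" for j in range(1, m + 1)],
                "estimate": np.diag(result.theta_hat.psi),
                "se": result.se_derived,
            }
        )
        df = pd.concat([df, derived], ignore_index=True)
    df.to_csv(f"{prefix}_params.csv", index=False)
    summary = {
        "neg_log_lik": result.neg_log_lik,
        "converged": result.converged,
        "message": result.message,
        "n_iterations": result.n_iterations,
        "all_neg_log_lik": result.all_neg_log_lik,
    }
    Path(f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))


def write_posterior(
    result: PosteriorResult, prefix: str | Path, multimodality: list[dict] | None = None
) -> None:
    """Write ``<prefix>_draws.csv`` (long format) and ``<prefix>_diagnostics.json``."""
    prefix = Path(prefix)
    n_chains, n_iter, n_par = result.draws.shape
    chain = np.repeat(np.arange(1, n_chains + 1), n_iter * n_par)
    iteration = np.tile(np.repeat(np.arange(1, n_iter + 1), n_par), n_chains)
    parameter = np.tile(result.parameter_names, n_chains * n_iter)
    pd.DataFrame(
        {
            "chain": chain,
            "iteration": iteration,
            "parameter": parameter,
            "value": result.draws.ravel(),
        }
    ).to_csv(f"{prefix}_draws.csv", index=False)
    diagnostics = {
        "seed": result.seed,
        "prior_mode": result.prior_mode,
        "n_chains": n_chains,
        "n_warmup": result.n_warmup,
        "n_iterations": n_iter,
        "accept_rate": result.accept_rate.tolist(),
        "converged": result.converged(),
        "parameters": {
            name: {
                "mean": float(result.posterior_mean[p]),
                "sd": float(result.posterior_sd[p]),
                "rhat": _nan_to_none(result.rhat[p]),
                "ess_bulk": _nan_to_none(result.ess_bulk[p]),
                "ess_tail": _nan_to_none(result.ess_tail[p]),
            }
            for p, name in enumerate(result.parameter_names)
        },
    }
    if multimodality is not None:
        diagnostics["multimodality"] = multimodality
    Path(f"{prefix}_diagnostics.json").write_text(json.dumps(diagnostics, indent=2))


def read_draws(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a long-format draws CSV back into (chains, iterations, P) + names."""
    df = pd.read_csv(path, float_precision="round_trip")
    names = list(dict.fromkeys(df["parameter"]))
    chains = sorted(df["chain"].unique())
    iters = sorted(df["iteration"].unique())
    wide = df.pivot(index=["chain", "iteration"], columns="parameter", values="value")[
        names
    ]
    draws = wide.to_numpy().reshape(len(chains), len(iters), len(names))
    return draws, names


def read_psi_from_parameter_csv(path: str | Path, m: int) -> np.ndarray:
    """Assemble the full M x M movement matrix from a fit's parameter CSV."""
    df = pd.read_csv(path).set_index("parameter")["estimate"]
    psi = np.zeros((m, m))
    for j in range(1, m + 1):
        for k in range(1, m + 1):
            name = f"psi[{j},{k}]"
            if name in df.index:
                psi[j - 1, k - 1] = float(df.loc[name])
    missing_diag = np.diag(psi) == 0
    if missing_diag.any():
        psi[missing_diag, missing_diag] = 1.0 - psi[missing_diag].sum(axis=1)
    return psi


def _nan_to_none(x: float) -> float | None:
    return None if not np.isfinite(x) else float(x)
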