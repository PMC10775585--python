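"""Study design and capture-history data structures.

A multi-state capture-recapture study tracks tagged fish among ``M`` river
pools over ``T`` monthly survey occasions.  Each fish enters the study when
it is captured, tagged, and released in a known pool, and thereafter yields
one coded observation per month: the pool where it was last detected that
month (codes ``1..M``), or ``M+1`` if it went undetected the entire month.

This module holds the design (pool chain, occasion calendar, season map),
the per-fish capture history, and the preprocessing that turns raw acoustic
detection events into monthly histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "StudyDesign",
    "CaptureHistory",
    "DetectionEvent",
    "season_of",
    "bin_detections",
    "transition_counts",
    "illinois_design",
    "ILLINOIS_POOLS",
]

# Meteorological season index used for the seasonal detection parameters:
# 1 = Dec-Feb, 2 = Mar-May, 3 = Jun-Aug, 4 = Sep-Nov.
SEASON_OF_MONTH: dict[int, int] = {
    12: 1, 1: 1, 2: 1,
    3: 2, 4: 2, 5: 2,
    6: 3, 7: 3, 8: 3,
    9: 4, 10: 4, 11: 4,
}

#: Illinois River pools in geographic order, downstream to upstream.
ILLINOIS_POOLS: tuple[str, ...] = (
    "Alton",
    "La Grange",
    "Peoria",
    "Starved Rock",
    "Marseilles",
    "Dresden Island",
)


@dataclass(frozen=True)
class StudyDesign:
    """Pools, occasion calendar, and adjacency for one study.

    Pools are indexed ``1..M`` in geographic order along the river, so the
    adjacency relation is the simple path graph: pools ``j`` and ``k`` are
    adjacent iff ``|j - k| == 1``.  Occasions are consecutive calendar
    months, indexed ``1..T``.

    Parameters
    ----------
    pools
        Ordered pool names (index 1..M).
    start
        ``(year, month)`` of the first occasion.
    n_occasions
        Number of monthly occasions T.
    """

    pools: tuple[str, ...]
    start: tuple[int, int]
    n_occasions: int
    occasions: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.pools) < 2:
            raise ValueError("need at least two pools")
        if len(set(self.pools)) != len(self.pools):
            raise ValueError("pool names must be unique")
        if self.n_occasions < 1:
            raise ValueError("need at least one occasion")
        year, month = self.start
        if not 1 <= month <= 12:
            raise ValueError(f"start month out of range: {month}")
        cal = []
        for i in range(self.n_occasions):
            m0 = month - 1 + i
            cal.append((year + m0 // 12, m0 % 12 + 1))
        object.__setattr__(self, "occasions", tuple(cal))

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def M(self) -> int:  # noqa: N802 - conventional symbol
        return len(self.pools)

    @property
    def T(self) -> int:  # noqa: N802
        return self.n_occasions

    @property
    def nondetection_code(self) -> int:
        """Observation code for "not detected this month" (also the dead state)."""
        return self.M + 1

    def adjacent(self, j: int, k: int) -> bool:
        """True iff pools ``j`` and ``k`` (1-based) are neighbors on the chain."""
        self._check_pool(j)
        self._check_pool(k)
        return abs(j - k) == 1

    def adjacency_matrix(self) -> np.ndarray:
        m = self.M
        a = np.zeros((m, m), dtype=bool)
        idx = np.arange(m - 1)
        a[idx, idx + 1] = a[idx + 1, idx] = True
        return a

    def month_of(self, occasion: int) -> int:
        self._check_occasion(occasion)
        return self.occasions[occasion - 1][1]

    def occasion_of_date(self, when: datetime) -> int | None:
        """1-based occasion containing ``when``, or None if outside the window."""
        try:
            return self.occasions.index((when.year, when.month)) + 1
        except ValueError:
            return None

    def pool_index(self, pool: int | str) -> int:
        """Resolve a pool given by 1-based index or by name."""
        if isinstance(pool, str):
            try:
                return self.pools.index(pool) + 1
            except ValueError:
                raise ValueError(f"unknown pool name: {pool!r}") from None
        self._check_pool(pool)
        return int(pool)

    def _check_pool(self, j: int) -> None:
        if not 1 <= j <= self.M:
            raise ValueError(f"pool index {j} out of range 1..{self.M}")

    def _check_occasion(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise IndexError(f"occasion {t} out of range 1..{self.T}")


def illinois_design() -> StudyDesign:
    """The 6-pool Illinois River design: 42 monthly occasions, Mar 2012-Aug 2015."""
    return StudyDesign(pools=ILLINOIS_POOLS, start=(2012, 3), n_occasions=42)


def season_of(occasion: int, design: StudyDesign) -> int:
    """Season index (1..4) of a survey occasion.

    Dec/Jan/Feb -> 1, Mar/Apr/May -> 2, Jun/Jul/Aug -> 3, Sep/Oct/Nov -> 4.
    """
    return SEASON_OF_MONTH[design.month_of(occasion)]


@dataclass(frozen=True)
class CaptureHistory:
    """One fish's release record plus coded monthly observations.

    ``observations[i]`` is the coded observation at occasion
    ``release_occasion + 1 + i``; codes are pool indices ``1..M`` or ``M+1``
    for non-detection.  The release month itself yields no observation: the
    initial state is known exactly, so the history starts contributing at
    the following occasion.
    """

    fish_id: str
    release_occasion: int
    release_pool: int
    observations: tuple[int, ...]

    def validate(self, design: StudyDesign) -> None:
        if not 1 <= self.release_occasion <= design.T:
            raise ValueError(
                f"{self.fish_id}: release occasion {self.release_occasion} "
                f"out of range 1..{design.T}"
            )
        design._check_pool(self.release_pool)
        expected = design.T - self.release_occasion
        if len(self.observations) != expected:
            raise ValueError(
                f"{self.fish_id}: expected {expected} observations, "
                f"got {len(self.observations)}"
            )
        for y in self.observations:
            if not 1 <= y <= design.M + 1:
                raise ValueError(f"{self.fish_id}: observation code {y} out of range")


@dataclass(frozen=True)
class DetectionEvent:
    """A single acoustic detection: one fish at one receiver pool at one time."""

    fish_id: str
    timestamp: datetime
    pool: int


def bin_detections(
    events: Iterable[DetectionEvent],
    releases: Mapping[str, tuple[datetime, int]],
    design: StudyDesign,
) -> list[CaptureHistory]:
    """Convert raw detection events into monthly capture histories.

    For each fish and each occasion after its release month, the coded
    observation is the pool of the chronologically *last* detection in that
    month, or ``M+1`` if the fish was not detected at all during the month.
    Events at or before the release time — and any later events within the
    release month, whose state is already known — are discarded.

    Parameters
    ----------
    events
        Detection events; order does not matter.
    releases
        ``fish_id -> (release datetime, release pool index)`` for every fish
        to be returned (fish with zero detections still get a history).
    design
        Study design providing the occasion calendar.

    Raises
    ------
    ValueError
        If an event references a fish without a release record, a pool
        outside ``1..M``, or a timestamp outside the study window.
    """
    last: dict[str, dict[int, tuple[datetime, int]]] = {fid: {} for fid in releases}
    rel_occ: dict[str, int] = {}
    for fid, (when, pool) in releases.items():
        occ = design.occasion_of_date(when)
        if occ is None:
            raise ValueError(f"{fid}: release date {when} outside the study window")
        design._check_pool(pool)
        rel_occ[fid] = occ

    for ev in events:
        if ev.fish_id not in releases:
            raise ValueError(f"detection for unknown fish {ev.fish_id!r}")
        design._check_pool(ev.pool)
        occ = design.occasion_of_date(ev.timestamp)
        if occ is None:
            raise ValueError(
                f"{ev.fish_id}: detection at {ev.timestamp} outside the study window"
            )
        release_time, _ = releases[ev.fish_id]
        if ev.timestamp <= release_time or occ <= rel_occ[ev.fish_id]:
            continue
        best = last[ev.fish_id].get(occ)
        if best is None or ev.timestamp > best[0]:
            last[ev.fish_id][occ] = (ev.timestamp, ev.pool)

    histories = []
    none = design.nondetection_code
    for fid in releases:
        r = rel_occ[fid]
        _, pool = releases[fid]
        obs = tuple(
            last[fid][t][1] if t in last[fid] else none for t in range(r + 1, design.T + 1)
        )
        histories.append(
            CaptureHistory(
                fish_id=fid, release_occasion=r, release_pool=pool, observations=obs
            )
        )
    return histories


def transition_counts(
    histories: Sequence[CaptureHistory], design: StudyDesign
) -> np.ndarray:
    """Observed pool-to-pool transition frequencies between subsequent detections.

    Non-detection codes are removed from each history (the known release pool
    is prepended as the first detection) and consecutive detection pairs are
    counted, from-pool as row, to-pool as column, summed over fish.  Note the
    paired detections may be separated by any number of non-detection months.
    """
    m = design.M
    counts = np.zeros((m, m), dtype=int)
    for h in histories:
        seq = [h.release_pool] + [y for y in h.observations if y <= m]
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a - 1, b - 1] += 1
    return counts
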