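"""Two-step cumulative-weight interval sampling and pool-matched assembly.

Survey sampling weights estimate how many real-population members each
record represents. Selection works in two steps: the weights are cumulated
and normalized to a vector on (0, 1] whose interval widths are proportional
to the weights; uniform random numbers are then placed into those intervals
by binary search, so a record's selection probability equals its normalized
weight. Sampling is with replacement.

Household matching reuses the same machinery within each pool: all housing
(or energy) records sharing the person's pool index are candidates, and one
is drawn by its survey weight. When a pool has no candidates the key is
relaxed stepwise — income category first, then house type, then setting;
region and family category are never relaxed — and the relaxation level is
reported per row in ``fallback_level``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, MatchError
from .harmonize import decode_pool

#: Number of relaxation steps available when a pool is empty in a source.
MAX_FALLBACK_LEVEL = 3


@dataclass(frozen=True)
class WeightIntervals:
    """Normalized cumulative weight vector with parallel record ids."""

    cumulative: np.ndarray
    source_ids: np.ndarray

    def __post_init__(self):
        if len(self.cumulative) != len(self.source_ids):
            raise DomainError("cumulative and source_ids must be parallel")


def build_intervals(weights, ids=None) -> WeightIntervals:
    """Build the normalized cumulative interval vector from positive weights.

    ``cumulative[i] = sum(weights[:i+1]) / sum(weights)``; the last entry is
    1 (to floating tolerance) and interval widths are proportional to the
    weights. ``ids`` defaults to positional indices.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise DomainError("cannot build intervals from an empty weight vector")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise DomainError("all sampling weights must be positive and finite")
    ids = np.arange(w.size) if ids is None else np.asarray(ids)
    if ids.shape != w.shape:
        raise DomainError("ids must be parallel to weights")
    cum = np.cumsum(w)
    cum /= cum[-1]
    cum[-1] = 1.0  # guard against rounding drift
    return WeightIntervals(cumulative=cum, source_ids=ids)


def select_intervals(intervals: WeightIntervals, u) -> np.ndarray:
    """Map uniform draws on (0, 1) to record ids.

    Each ``u`` selects the first record whose cumulative value is >= u
    (binary search, left side), so a draw exactly equal to a boundary
    selects the lower-indexed record — fixed for bit-reproducibility.
    """
    u = np.asarray(u, dtype=float)
    pos = np.searchsorted(intervals.cumulative, u, side="left")
    pos = np.minimum(pos, len(intervals.cumulative) - 1)
    return intervals.source_ids[pos]


def draw_weighted(intervals: WeightIntervals, n: int, rng: np.random.Generator):
    """Draw ``n`` record ids with replacement, probabilities ∝ weights."""
    if n < 1:
        raise DomainError("n must be >= 1")
    return select_intervals(intervals, rng.random(n))


def sample_persons(persons: pd.DataFrame, n: int, rng: np.random.Generator,
                   weight_col: str = "weight") -> pd.DataFrame:
    """Sample ``n`` person rows with replacement by sampling weight.

    ``persons`` must already be filtered to the run's eligible records.
    The returned frame preserves all columns and records the source row in
    ``source_row``.
    """
    if len(persons) == 0:
        raise DomainError("cannot sample from an empty person table")
    intervals = build_intervals(persons[weight_col].to_numpy())
    picks = draw_weighted(intervals, n, rng)
    out = persons.iloc[picks].reset_index(drop=True)
    out["source_row"] = persons.index.to_numpy()[picks]
    return out


def _fallback_key(pool: int, level: int):
    """Candidate-set key for a pool at a given relaxation level.

    Level 0: exact pool; 1: income relaxed; 2: + house type relaxed;
    3: + setting relaxed. Region and family category always remain.
    """
    k = decode_pool(pool)
    if level == 0:
        return (k.setting, k.region, k.house_type, k.family_category, k.income_category)
    if level == 1:
        return (k.setting, k.region, k.house_type, k.family_category)
    if level == 2:
        return (k.setting, k.region, k.family_category)
    if level == 3:
        return (k.region, k.family_category)
    raise DomainError(f"invalid fallback level {level}")


class _PoolMatcher:
    """Weighted within-pool drawing from one household table."""

    def __init__(self, table: pd.DataFrame, weight_col: str = "weight"):
        self.table = table
        pools = table["pool"].to_numpy()
        comps = [decode_pool(int(p)) for p in pools]
        self._groups = [{} for _ in range(MAX_FALLBACK_LEVEL + 1)]
        for level in range(MAX_FALLBACK_LEVEL + 1):
            keys = {}
            for i, k in enumerate(comps):
                if level == 0:
                    key = (k.setting, k.region, k.house_type,
                           k.family_category, k.income_category)
                elif level == 1:
                    key = (k.setting, k.region, k.house_type, k.family_category)
                elif level == 2:
                    key = (k.setting, k.region, k.family_category)
                else:
                    key = (k.region, k.family_category)
                keys.setdefault(key, []).append(i)
            self._groups[level] = keys
        self._weights = table[weight_col].to_numpy(dtype=float)
        self._interval_cache = {}

    def plan(self, pool: int):
        """Return (level, intervals) for a person pool, or (None, None)."""
        for level in range(MAX_FALLBACK_LEVEL + 1):
            key = _fallback_key(pool, level)
            rows = self._groups[level].get(key)
            if rows:
                cache_key = (level, key)
                if cache_key not in self._interval_cache:
                    rows_arr = np.asarray(rows)
                    self._interval_cache[cache_key] = build_intervals(
                        self._weights[rows_arr], rows_arr
                    )
                return level, self._interval_cache[cache_key]
        return None, None


def match_households(persons: pd.DataFrame, housing: pd.DataFrame,
                     energy: pd.DataFrame, rng_housing: np.random.Generator,
                     rng_energy: np.random.Generator) -> pd.DataFrame:
    """Match one housing and one energy record to every sampled person.

    All inputs must carry a ``pool`` column (households also ``weight``).
    Returns a frame aligned with ``persons`` holding the matched row
    positions and the relaxation level used per source; ``fallback_level``
    is the maximum of the two. Raises :class:`MatchError`, listing the
    offending pools, if any pool is empty even at full relaxation.
    """
    n = len(persons)
    person_pools = persons["pool"].to_numpy()
    u_housing = rng_housing.random(n)
    u_energy = rng_energy.random(n)

    out = {
        "housing_row": np.empty(n, dtype=np.int64),
        "energy_row": np.empty(n, dtype=np.int64),
        "fallback_level_housing": np.empty(n, dtype=np.int64),
        "fallback_level_energy": np.empty(n, dtype=np.int64),
    }
    unmatched = {}
    for name, table, u in (("housing", housing, u_housing),
                           ("energy", energy, u_energy)):
        matcher = _PoolMatcher(table)
        for pool in np.unique(person_pools):
            rows = np.flatnonzero(person_pools == pool)
            level, intervals = matcher.plan(int(pool))
            if level is None:
                unmatched.setdefault(int(pool), []).append(name)
                continue
            out[f"{name}_row"][rows] = select_intervals(intervals, u[rows])
            out[f"fallback_level_{name}"][rows] = level
    if unmatched:
        detail = "; ".join(
            f"pool {p} empty in {', '.join(srcs)}" for p, srcs in sorted(unmatched.items())
        )
        raise MatchError(f"unmatched pools after full relaxation: {detail}")

    result = pd.DataFrame(out, index=persons.index)
    result["fallback_level"] = result[
        ["fallback_level_housing", "fallback_level_energy"]
    ].max(axis=1)
    return result
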