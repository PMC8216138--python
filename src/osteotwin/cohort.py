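"""Weighted combinatorial biopsy-cohort selection and baseline back-casting.

Selects k biopsies from a reference database so the subset's statistics
match a target clinical cohort.  Every combination is scored with the
normalized weighted error

    Error = sum_i  w_i * |set_point_i - value_i| / set_point_i

over mean BV/TV, mean age, SD of age and SD of BV/TV, plus a weighted
uniformity term rewarding evenly spaced BV/TV values (which has no set
point; see ``selection_error``).  Selection is two-step: the 50
lowest-error combinations are shortlisted, then the shortlist member whose
mean BV/TV lies closest to the target is chosen.

The default criteria reproduce the reference-cohort targets: mean BV/TV
13.1 %, mean age 72 y, SD age 5.2 y, SD BV/TV 4.1 % with weights
10/10/1/2 and uniformity weight 2, selecting k = 7 of 25
(C(25,7) = 480,700 combinations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BiopsyEntry:
    id: str
    bv_tv: float  # fraction
    age: float  # years

    def __post_init__(self) -> None:
        if not 0.0 < self.bv_tv < 1.0:
            raise ValueError("bv_tv must be a fraction in (0, 1)")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass
class SelectionCriteria:
    """Set points, weights and selection sizes.

    Set points are stored in the units they are reported in (percent for
    BV/TV); inputs as fractions are normalized at the boundary.
    """

    mean_bv_tv: float = 13.1  # percent
    mean_age: float = 72.0  # years
    sd_age: float = 5.2  # years
    sd_bv_tv: float = 4.1  # percent
    weights: dict = field(
        default_factory=lambda: {
            "mean_bv_tv": 10.0,
            "mean_age": 10.0,
            "sd_age": 1.0,
            "sd_bv_tv": 2.0,
            "uniformity": 2.0,
        }
    )
    k: int = 7
    shortlist: int = 50


def count_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k) in integer arithmetic."""
    if k < 0 or n < 0:
        raise ValueError("n and k must be non-negative")
    if k > n:
        raise ValueError("k must not exceed n")
    return math.comb(n, k)


def _subset_stats(bv_tv_pct: np.ndarray, ages: np.ndarray) -> dict:
    return {
        "mean_bv_tv": float(bv_tv_pct.mean()),
        "mean_age": float(ages.mean()),
        "sd_age": float(ages.std(ddof=1)),
        "sd_bv_tv": float(bv_tv_pct.std(ddof=1)),
    }


def _uniformity(bv_tv_pct: np.ndarray) -> float:
    """Coefficient of variation of sorted consecutive BV/TV increments.

    Zero for perfectly even spacing.  This criterion has no set point, so
    it enters the error sum as weight * CV without set-point
    normalization — CV is already dimensionless.
    """
    inc = np.diff(np.sort(bv_tv_pct))
    if len(inc) < 2:
        return 0.0
    m = inc.mean()
    if m == 0:
        return 0.0
    return float(inc.std(ddof=1) / m)


def selection_error(
    bv_tv: np.ndarray, ages: np.ndarray, criteria: SelectionCriteria
) -> float:
    """Normalized weighted error of one subset against the criteria.

    ``bv_tv`` may be fractions or percent; fractions are scaled to percent
    to match the set-point units.  Sample SDs use the n-1 denominator.
    """
    bv = np.asarray(bv_tv, dtype=float)
    if np.all(bv < 1.0):
        bv = bv * 100.0
    ages = np.asarray(ages, dtype=float)
    stats = _subset_stats(bv, ages)
    w = criteria.weights
    err = 0.0
    for name in ("mean_bv_tv", "mean_age", "sd_age", "sd_bv_tv"):
        set_point = getattr(criteria, name)
        if set_point == 0:
            raise ValueError(f"zero set point for {name}")
        err += w[name] * abs(set_point - stats[name]) / set_point
    err += w["uniformity"] * _uniformity(bv)
    return err


def select_cohort(
    database: list[BiopsyEntry], criteria: SelectionCriteria | None = None
) -> tuple[list[BiopsyEntry], pd.DataFrame]:
    """Two-step exhaustive selection of ``criteria.k`` biopsies.

    All C(n, k) combinations are scored (vectorized enumeration); the
    ``shortlist`` lowest-error combinations are kept, and among those the
    one whose mean BV/TV is closest to the set point wins.  Ties break by
    lexicographic id order.  Returns the chosen entries and the scored
    shortlist as a DataFrame.
    """
    criteria = criteria or SelectionCriteria()
    n = len(database)
    k = criteria.k
    if n < k:
        raise ValueError(f"database of {n} smaller than k={k}")
    order = np.argsort([e.id for e in database], kind="stable")
    entries = [database[i] for i in order]
    bv = np.array([e.bv_tv for e in entries]) * 100.0  # percent
    ages = np.array([e.age for e in entries])

    combos = np.array(list(combinations(range(n), k)), dtype=np.int64)
    bv_s = bv[combos]  # (n_combos, k)
    age_s = ages[combos]
    mean_bv = bv_s.mean(axis=1)
    mean_age = age_s.mean(axis=1)
    sd_bv = bv_s.std(axis=1, ddof=1)
    sd_age = age_s.std(axis=1, ddof=1)
    inc = np.diff(np.sort(bv_s, axis=1), axis=1)
    inc_mean = inc.mean(axis=1)
    inc_sd = inc.std(axis=1, ddof=1) if k > 2 else np.zeros(len(combos))
    with np.errstate(invalid="ignore", divide="ignore"):
        uni = np.where(inc_mean > 0, inc_sd / np.where(inc_mean > 0, inc_mean, 1), 0.0)
    w = criteria.weights
    err = (
        w["mean_bv_tv"] * np.abs(criteria.mean_bv_tv - mean_bv) / criteria.mean_bv_tv
        + w["mean_age"] * np.abs(criteria.mean_age - mean_age) / criteria.mean_age
        + w["sd_age"] * np.abs(criteria.sd_age - sd_age) / criteria.sd_age
        + w["sd_bv_tv"] * np.abs(criteria.sd_bv_tv - sd_bv) / criteria.sd_bv_tv
        + w["uniformity"] * uni
    )
    n_short = min(criteria.shortlist, len(combos))
    # stable rank: combinations enumerate in lexicographic index order, so
    # equal errors resolve to the lexicographically first subset
    short_idx = np.argsort(err, kind="stable")[:n_short]
    short_dev = np.abs(mean_bv[short_idx] - criteria.mean_bv_tv)
    best = short_idx[np.argmin(short_dev)]
    chosen = [entries[i] for i in combos[best]]
    shortlist = pd.DataFrame(
        {
            "rank": np.arange(n_short),
            "ids": [",".join(entries[i].id for i in combos[s]) for s in short_idx],
            "error": err[short_idx],
            "mean_bv_tv_pct": mean_bv[short_idx],
            "mean_age": mean_age[short_idx],
        }
    )
    return chosen, shortlist


def backcast_baseline(times, values, t0: float = 0.0) -> float:
    """Back-extrapolate a baseline by ordinary least squares.

    Fits a straight line to (time, value) follow-up data and evaluates it
    at ``t0`` — the procedure used to reconstruct the year-0 BV/TV from
    2.5-, 5- and 10-year treatment-arm measurements.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2 or len(t) != len(v):
        raise ValueError("need at least two (time, value) points")
    if np.all(t == t[0]):
        raise ValueError("times must not be all equal")
    slope, intercept = np.polyfit(t, v, 1)
    return float(slope * t0 + intercept)


def read_database(path) -> list[BiopsyEntry]:
    """Read a biopsy database CSV (id, bv_tv_pct, age_years)."""
    df = pd.read_csv(path)
    return [
        BiopsyEntry(str(r.id), float(r.bv_tv_pct) / 100.0, float(r.age_years))
        for r in df.itertuples()
    ]
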