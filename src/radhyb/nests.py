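"""Reproductive-output metrics and nonparametric group comparisons.

Per-nest metrics follow the excavation-count definitions: live
hatchlings = hatched eggshells - dead hatchlings; clutch size (CS) =
unhatched eggs + dead hatchlings + live hatchlings; hatching success
(HS) = 100 * live / CS; incubation period (IP) = whole days from
oviposition to emergence.  Groups are compared with the Mann-Whitney U
test: exact two-sided p by full enumeration of the rank-sum distribution
for small tie-free samples, otherwise a normal approximation with
midranks, tie correction and continuity correction.  The two-sided p is
twice the smaller exact tail, capped at 1.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class NestMetrics:
    live_hatchlings: int
    clutch_size: int
    hatching_success: float | None  # percent; None when CS = 0
    incubation_days: int | None


def _as_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    s = str(value).strip()
    return dt.date.fromisoformat(s) if s else None


def nest_metrics(record) -> NestMetrics:
    """Derive live hatchlings, CS, HS (%) and IP (days) from one record.

    ``record`` is a mapping/Series with eggshells, dead_hatchlings,
    unhatched_eggs and optionally oviposition_date / emergence_date.
    """
    eggshells = int(record["eggshells"])
    dead = int(record["dead_hatchlings"])
    unhatched = int(record["unhatched_eggs"])
    if min(eggshells, dead, unhatched) < 0:
        raise ValueError("counts must be non-negative")
    live = eggshells - dead
    if live < 0:
        warnings.warn("dead hatchlings exceed eggshells; flooring live count at 0")
        live = 0
    cs = unhatched + dead + live
    hs = 100.0 * live / cs if cs > 0 else None
    if hs is None:
        warnings.warn("clutch size is zero; hatching success undefined")
    ovip = _as_date(record.get("oviposition_date"))
    emerg = _as_date(record.get("emergence_date"))
    ip = None
    if ovip is not None and emerg is not None:
        if emerg < ovip:
            raise ValueError("emergence precedes oviposition")
        ip = (emerg - ovip).days
    return NestMetrics(live, cs, hs, ip)


def add_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Records plus live_hatchlings / clutch_size / hatching_success / incubation_days."""
    out = records.copy()
    metrics = [nest_metrics(row) for _, row in records.iterrows()]
    out["live_hatchlings"] = [m.live_hatchlings for m in metrics]
    out["clutch_size"] = [m.clutch_size for m in metrics]
    out["hatching_success"] = [m.hatching_success for m in metrics]
    out["incubation_days"] = [m.incubation_days for m in metrics]
    return out


# ------------------------------------------------------------- U test
@dataclass
class GroupComparison:
    u: float
    u_prime: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" | "normal"
    mean1: float
    mean2: float
    sd1: float
    sd2: float


def _rank_midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Two-sided exact p: enumerate all C(n1+n2, n1) group assignments of
    the pooled ranks, double the smaller one-sided tail, cap at 1."""
    pooled = np.concatenate([x, y])
    ranks = _rank_midranks(pooled)
    n1 = len(x)
    n = len(pooled)
    total = 0
    le = 0
    ge = 0
    for combo in combinations(range(n), n1):
        r1 = sum(ranks[list(combo)])
        u_c = r1 - n1 * (n1 + 1) / 2.0
        total += 1
        if u_c <= u:
            le += 1
        if u_c >= u:
            ge += 1
    one_sided = min(le, ge) / total
    return min(1.0, 2.0 * one_sided)


def mann_whitney_u(x, y, mode: str = "auto") -> GroupComparison:
    """Mann-Whitney U with exact enumeration or normal approximation.

    ``mode``: "auto" uses exact enumeration when n1+n2 <= 12 and the
    pooled sample has no ties; "exact" and "normal" force a method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _rank_midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    u_prime = n1 * n2 - u
    has_ties = len(np.unique(pooled)) < len(pooled)

    if mode == "auto":
        mode = "exact" if (n1 + n2 <= 12 and not has_ties) else "normal"
    if mode == "exact":
        p = _exact_p(x, y, u)
    elif mode == "normal":
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = float(2.0 * (1.0 - _norm_cdf(z)))
            p = min(1.0, max(p, np.nextafter(0, 1)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GroupComparison(
        u, u_prime, p, n1, n2, mode,
        float(x.mean()), float(y.mean()),
        float(x.std(ddof=1)) if n1 > 1 else float("nan"),
        float(y.std(ddof=1)) if n2 > 1 else float("nan"),
    )


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


# ------------------------------------------------------------ summaries
def group_summary(records: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-group mean +/- sample SD of HS, CS, IP (and CCL/CCW when
    present), plus n; SD is NaN for single-nest groups."""
    if len(records) == 0:
        raise ValueError("no records")
    df = add_metrics(records)
    cols = ["hatching_success", "clutch_size", "incubation_days"]
    for extra in ("ccl_m", "ccw_m"):
        if extra in df.columns:
            cols.append(extra)
    rows = []
    for group, sub in df.groupby(group_col):
        row: dict = {"group": group, "n": len(sub)}
        for c in cols:
            vals = pd.to_numeric(sub[c], errors="coerce").dropna()
            row[f"{c}_mean"] = vals.mean() if len(vals) else float("nan")
            row[f"{c}_sd"] = vals.std(ddof=1) if len(vals) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def monthly_distribution(records: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Nest counts per oviposition month and group."""
    df = records.copy()
    months = pd.to_datetime(df["oviposition_date"]).dt.to_period("M").astype(str)
    return (
        df.assign(month=months)
        .groupby(["month", group_col])
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )


def compare_groups(
    records: pd.DataFrame,
    group_a: str,
    group_b: str,
    metric: str = "hatching_success",
    group_col: str = "group",
) -> GroupComparison:
    df = add_metrics(records)
    x = pd.to_numeric(df.loc[df[group_col] == group_a, metric], errors="coerce").dropna()
    y = pd.to_numeric(df.loc[df[group_col] == group_b, metric], errors="coerce").dropna()
    return mann_whitney_u(x.values, y.values)


def nests_per_female(records: pd.DataFrame) -> float:
    """Mean nests per identified female, to one decimal."""
    ids = records["female_id"].astype(str)
    identified = records[(ids != "") & (ids.str.lower() != "nan")]
    if len(identified) == 0:
        raise ValueError("no nests with identified females")
    return round(len(identified) / identified["female_id"].nunique(), 1)


def females_per_season(
    nests_per_season: float, clutch_frequency: float = 4.0
) -> tuple[int, float]:
    """Season female count: nests / per-female clutch frequency.

    Returns (rounded estimate, unrounded value).
    """
    if clutch_frequency <= 0:
        raise ValueError("clutch frequency must be positive")
    if nests_per_season < 0:
        raise ValueError("nest count must be non-negative")
    raw = nests_per_season / clutch_frequency
    # half-up: 8.5 females rounds to "about nine", not banker's 8
    return int(math.floor(raw + 0.5)), raw
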