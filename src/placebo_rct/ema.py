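"""Ecological momentary assessment (EMA) outcomes.

Cleaning of twice-daily smartphone VAS pain ratings, permutation-based
responder stratification, magnitude / %analgesia summaries, placebo pill
effect sizes and response-rate contrasts.

The primary outcome of the trial design handled here is a stream of
time-stamped 0–10 VAS pain ratings per subject, segmented into five
periods: baseline (BL), two treatment periods (T1, T2) and two washout
periods (W1, W2). A subject is a *responder* when a within-subject
permutation test shows a significant diminution of pain in at least one
treatment period relative to baseline.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PERIODS = ("BL", "T1", "W1", "T2", "W2")

#: dedup window: ratings entered within 30 minutes are re-assessments,
#: only the last one is the subject's final judgement.
DEDUP_WINDOW = timedelta(minutes=30)


@dataclass
class RatingSeries:
    """One subject's cleaned, time-ordered VAS pain ratings.

    ``entries`` has columns ``timestamp`` (datetime64), ``vas`` (float in
    [0, 10]) and, once :func:`assign_periods` has run, ``period`` (one of
    BL/T1/W1/T2/W2).
    """

    subject_id: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"timestamp", "vas"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"entries must have columns {required}")
        vas = self.entries["vas"].to_numpy(dtype=float)
        if len(vas) and (np.nanmin(vas) < 0 or np.nanmax(vas) > 10):
            raise ValueError("VAS ratings must lie in [0, 10]")

    def period_values(self, period: str) -> np.ndarray:
        """VAS values labelled with ``period`` (empty array if none)."""
        if "period" not in self.entries.columns:
            return np.empty(0)
        mask = self.entries["period"] == period
        return self.entries.loc[mask, "vas"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class StratificationResult:
    subject_id: str
    t_t1: float
    p_t1: float
    t_t2: float
    p_t2: float
    label: str  # "Responder" | "NonResponder"
    n_permutations: int


@dataclass
class AnalgesiaSummary:
    subject_id: str
    magnitude_units: float
    pct_analgesia: float
    period_of_max: str


def subject_seed(cohort_seed: int, subject_id: str) -> int:
    """Stable per-subject RNG seed: results never depend on subject order."""
    return (int(cohort_seed) * 1_000_003 + zlib.crc32(str(subject_id).encode())) % (2**31)


def dedupe_ratings(
    raw: Sequence[tuple[datetime, float]], subject_id: str = ""
) -> RatingSeries:
    """Collapse runs of ratings entered within 30 minutes of each other.

    Ratings are scanned left-to-right in time order; each entry is compared
    to the previous *retained candidate*.  A chain of entries each within
    30 min of its predecessor therefore collapses to its final member —
    the subject's last word on their pain at that moment.  Gaps are left
    intact: no interpolation or resampling.
    """
    rows = sorted(raw, key=lambda r: r[0])
    kept: list[tuple[datetime, float]] = []
    for ts, vas in rows:
        if kept and ts - kept[-1][0] < DEDUP_WINDOW:
            kept[-1] = (ts, vas)  # supersedes the previous candidate
        else:
            kept.append((ts, vas))
    n_dropped = len(rows) - len(kept)
    if n_dropped:
        logger.info("dedupe_ratings[%s]: dropped %d duplicate ratings", subject_id, n_dropped)
    df = pd.DataFrame(kept, columns=["timestamp", "vas"])
    return RatingSeries(subject_id=subject_id, entries=df)


def assign_periods(series: RatingSeries, visit_dates: Sequence[datetime]) -> RatingSeries:
    """Label each rating with the trial period it falls in.

    ``visit_dates`` are the six visit date-times V1..V6.  Entry at time t
    gets the label of the half-open interval [V_k, V_{k+1}) containing it;
    an entry exactly at a visit time starts the later period.  Entries
    before V1 or at/after V6 are dropped (count logged).
    """
    if len(visit_dates) < 2:
        raise ValueError("need at least 2 visit dates")
    dates = pd.to_datetime(list(visit_dates))
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise ValueError("visit dates must be strictly increasing")
    if len(dates) != len(PERIODS) + 1:
        raise ValueError(f"expected {len(PERIODS) + 1} visit dates, got {len(dates)}")

    ts = pd.to_datetime(series.entries["timestamp"])
    # side="right" so an entry exactly at V_k belongs to the period starting at V_k
    idx = np.searchsorted(dates.values, ts.values, side="right") - 1
    in_range = (idx >= 0) & (idx < len(PERIODS))
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.warning(
            "assign_periods[%s]: dropped %d entries outside the visit window",
            series.subject_id, n_dropped,
        )
    out = series.entries.loc[in_range].copy()
    out["period"] = [PERIODS[i] for i in idx[in_range]]
    if out.empty:
        logger.warning("assign_periods[%s]: no entries within the visit window", series.subject_id)
    return RatingSeries(subject_id=series.subject_id, entries=out.reset_index(drop=True))


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample pooled-variance t statistic (x minus y)."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    diff = x.mean() - y.mean()
    if denom == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / denom)


def permutation_response_test(
    baseline: Sequence[float],
    treatment: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    welch: bool = False,
) -> tuple[float, float]:
    """Within-subject permutation test of baseline vs treatment ratings.

    The observed statistic is the two-sample t (baseline minus treatment,
    pooled variance by default, Welch optionally).  The null is built by
    randomly re-assigning the pooled ratings to the two periods ``n_perm``
    times.  The two-sided p is the fraction of permutations with
    ``|t_perm| >= |t_obs|``, with the (b+1)/(n_perm+1) add-one correction
    so a Monte-Carlo p is never exactly 0; ties count as exceeding.

    Returns ``(t_obs, p)``.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(treatment, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each period needs at least 2 ratings")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")

    if welch:
        def stat(a: np.ndarray, b: np.ndarray) -> float:
            return float(stats.ttest_ind(a, b, equal_var=False).statistic)
    else:
        stat = _pooled_t

    t_obs = stat(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # zero variance everywhere: nothing to test
        return 0.0, 1.0

    rng = np.random.default_rng(seed)
    nx = len(x)
    n = len(pooled)
    # vectorised shuffles: each row of `order` is one random permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_vals = pooled[order]
    a, b = perm_vals[:, :nx], perm_vals[:, nx:]
    if welch:
        t_perm = stats.ttest_ind(a, b, axis=1, equal_var=False).statistic
    else:
        na, nb = a.shape[1], b.shape[1]
        sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
            na + nb - 2
        )
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(denom > 0, (a.mean(axis=1) - b.mean(axis=1)) / denom, 0.0)

    if alternative == "two-sided":
        exceed = np.abs(t_perm) >= abs(t_obs) - 1e-12
    else:
        exceed = t_perm >= t_obs - 1e-12
    p = (int(exceed.sum()) + 1) / (n_perm + 1)
    return t_obs, min(p, 1.0)


def stratify(
    baseline: Sequence[float],
    t1: Sequence[float] | None,
    t2: Sequence[float] | None,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    subject_id: str = "",
) -> StratificationResult:
    """Label a subject Responder / NonResponder.

    Responder requires a *significant diminution*: permutation p below
    ``alpha`` in at least one treatment period AND that period's mean
    below the baseline mean.  A significant increase does not qualify.
    """
    base = np.asarray(baseline, dtype=float)
    if len(base) == 0:
        raise ValueError("baseline period has no ratings")
    if (t1 is None or len(t1) == 0) and (t2 is None or len(t2) == 0):
        raise ValueError("both treatment periods are empty")

    results: dict[str, tuple[float, float, bool]] = {}
    for name, period in (("T1", t1), ("T2", t2)):
        if period is None or len(period) == 0:
            results[name] = (np.nan, np.nan, False)
            logger.info("stratify[%s]: period %s absent, test skipped", subject_id, name)
            continue
        t, p = permutation_response_test(base, period, n_perm=n_perm, seed=seed)
        diminished = bool(p < alpha and np.mean(period) < base.mean())
        results[name] = (t, p, diminished)

    label = "Responder" if any(r[2] for r in results.values()) else "NonResponder"
    return StratificationResult(
        subject_id=subject_id,
        t_t1=results["T1"][0],
        p_t1=results["T1"][1],
        t_t2=results["T2"][0],
        p_t2=results["T2"][1],
        label=label,
        n_permutations=n_perm,
    )


def last_week_values(series: RatingSeries, period: str, visit_dates: Sequence[datetime]) -> np.ndarray:
    """Ratings from the final 7 calendar days of ``period``."""
    ends = {"T1": 2, "T2": 4}  # period k ends at visit index k+1
    if period not in ends:
        raise ValueError("last-week windows are defined for T1 and T2")
    end = pd.to_datetime(visit_dates[ends[period]])
    start = end - pd.Timedelta(days=7)
    df = series.entries
    mask = (df["period"] == period) & (pd.to_datetime(df["timestamp"]) >= start)
    return df.loc[mask, "vas"].to_numpy(dtype=float)


def magnitude_of_response(
    baseline: Sequence[float],
    t1_last_week: Sequence[float] | None,
    t2_last_week: Sequence[float] | None,
    subject_id: str = "",
) -> AnalgesiaSummary:
    """Magnitude and %analgesia of the stronger treatment period.

    magnitude = max over periods of (baseline mean − last-week mean);
    %analgesia = 100 × magnitude / baseline mean.
    """
    base = np.asarray(baseline, dtype=float)
    if len(base) == 0:
        raise ValueError("baseline period has no ratings")
    bl_mean = base.mean()
    if bl_mean <= 0:
        raise ValueError("baseline mean must be positive for %analgesia")

    diffs: dict[str, float] = {}
    for name, win in (("T1", t1_last_week), ("T2", t2_last_week)):
        if win is not None and len(win) > 0:
            diffs[name] = bl_mean - float(np.mean(win))
    if not diffs:
        raise ValueError("no last-week ratings in either treatment period")
    period = max(diffs, key=diffs.get)
    magnitude = diffs[period]
    return AnalgesiaSummary(
        subject_id=subject_id,
        magnitude_units=magnitude,
        pct_analgesia=100.0 * magnitude / bl_mean,
        period_of_max=period,
    )


def pill_effect_size(
    analgesia_ptx: Sequence[float], analgesia_notx: Sequence[float]
) -> float:
    """Placebo pill effect size.

    Difference of arm means divided by the sample standard deviation
    (n−1 denominator) of both arms pooled into one vector.
    """
    a = np.asarray(analgesia_ptx, dtype=float)
    b = np.asarray(analgesia_notx, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both arms must be nonempty")
    sd = np.concatenate([a, b]).std(ddof=1)
    if sd == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / sd)


def response_rate_chi2(
    resp_a: int, n_a: int, resp_b: int, n_b: int
) -> tuple[float, float]:
    """Pearson χ² (df=1, no continuity correction) on a 2×2 responder table."""
    for resp, n in ((resp_a, n_a), (resp_b, n_b)):
        if not (0 <= resp <= n) or n < 1:
            raise ValueError("need 0 <= responders <= n and n >= 1")
    table = np.array(
        [[resp_a, n_a - resp_a], [resp_b, n_b - resp_b]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a margin of the 2x2 table is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def exclude_outliers(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Single-pass k-SD outlier mask (True = keep).

    Mean and SD are computed once on all values; no re-iteration after
    exclusion.  With zero SD everything is kept.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(len(x), dtype=bool)
    return np.abs(x - x.mean()) <= k * sd
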