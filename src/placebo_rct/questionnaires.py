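"""Questionnaire subscale scoring, imputation, normalisation and screening.

The trial battery is 15 instruments with 38 subscales collected at
baseline.  The artifact works at subscale level: a generic scorer with
the >20%-missing rule and within-subscale mean imputation, leakage-safe
z-normalisation, and a Bonferroni-corrected univariate screen of every
subscale against responder labels and the magnitude of response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ema import exclude_outliers

logger = logging.getLogger(__name__)

MISSING_FRACTION_LIMIT = 0.2


@dataclass
class SubscaleTable:
    """Subjects × subscale scores with leakage-safe normalisation.

    Normalisation statistics (per-feature mean/SD) are computed from a
    designated training set only; applying them to held-out subjects uses
    those same statistics, never the held-out subjects' own.
    """

    data: pd.DataFrame  # index: subject_id; columns: subscales
    norm_mean: pd.Series | None = None
    norm_sd: pd.Series | None = None

    @property
    def subscales(self) -> list[str]:
        return list(self.data.columns)

    def fit_normalization(self, train_subjects: list[str]) -> "SubscaleTable":
        train = self.data.loc[train_subjects]
        sd = train.std(ddof=1).replace(0.0, 1.0)
        return SubscaleTable(data=self.data, norm_mean=train.mean(), norm_sd=sd)

    def normalized(self, subjects: list[str] | None = None) -> pd.DataFrame:
        if self.norm_mean is None:
            raise ValueError("call fit_normalization first")
        df = self.data if subjects is None else self.data.loc[subjects]
        return (df - self.norm_mean) / self.norm_sd


def score_subscale(
    item_responses: list[float | None], n_items: int | None = None,
    aggregate: str = "sum",
) -> float:
    """Score one subscale from its item responses.

    If more than 20% of the items are missing the subscale is not scored
    (NaN).  Otherwise missing items are filled with the mean of the
    answered items *within the subscale*, then summed (or averaged).
    """
    x = np.array(
        [np.nan if v is None else float(v) for v in item_responses], dtype=float
    )
    if n_items is None:
        n_items = len(x)
    if n_items < 1 or len(x) != n_items:
        raise ValueError("item_responses length must equal n_items >= 1")
    missing = np.isnan(x)
    if missing.all() or missing.mean() > MISSING_FRACTION_LIMIT:
        return float("nan")
    x[missing] = x[~missing].mean()
    if aggregate == "sum":
        return float(x.sum())
    if aggregate == "mean":
        return float(x.mean())
    raise ValueError("aggregate must be 'sum' or 'mean'")


def univariate_screen(
    table: SubscaleTable,
    labels: pd.Series,
    magnitude: pd.Series,
    m_comparisons: int = 37,
    alpha: float = 0.05,
    group_test: str = "t",
) -> pd.DataFrame:
    """Screen every subscale against response label and magnitude.

    Per subscale: a two-sample test of Responder vs NonResponder group
    difference, and a Pearson correlation with the magnitude of response
    (%analgesia).  Subjects that are 3-SD outliers on magnitude are
    excluded before either test.  Significance is Bonferroni-corrected:
    flags at p < alpha/m_comparisons (0.05/37 ≈ 0.0013 at study scale).

    Returns one row per subscale with columns
    ``t_group, p_group, r_mag, p_mag, sig_group, sig_mag, testable``.
    """
    common = table.data.index.intersection(labels.index).intersection(magnitude.index)
    if len(common) < 6:
        raise ValueError("need at least 3 subjects per group")
    data = table.data.loc[common]
    lab = labels.loc[common]
    mag = magnitude.loc[common].to_numpy(dtype=float)

    keep = exclude_outliers(mag)
    n_out = int((~keep).sum())
    if n_out:
        logger.info("univariate_screen: excluded %d magnitude outlier(s)", n_out)
    data, lab, mag = data.loc[keep], lab.loc[keep], mag[keep]

    is_resp = (lab == "Responder").to_numpy()
    if is_resp.sum() < 3 or (~is_resp).sum() < 3:
        raise ValueError("need at least 3 subjects per group after exclusions")
    thresh = alpha / m_comparisons

    rows = []
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            rows.append({"subscale": col, "testable": False,
                         "t_group": np.nan, "p_group": np.nan,
                         "r_mag": np.nan, "p_mag": np.nan,
                         "sig_group": False, "sig_mag": False})
            continue
        ok = ~np.isnan(x)
        if group_test == "t":
            t, p_g = stats.ttest_ind(x[ok & is_resp], x[ok & ~is_resp])
        elif group_test == "mannwhitney":
            t, p_g = stats.mannwhitneyu(x[ok & is_resp], x[ok & ~is_resp])
        else:
            raise ValueError("group_test must be 't' or 'mannwhitney'")
        r, p_r = stats.pearsonr(x[ok], mag[ok])
        rows.append({"subscale": col, "testable": True,
                     "t_group": float(t), "p_group": float(p_g),
                     "r_mag": float(r), "p_mag": float(p_r),
                     "sig_group": bool(p_g < thresh),
                     "sig_mag": bool(p_r < thresh)})
    out = pd.DataFrame(rows).set_index("subscale")
    out.attrs["bonferroni_threshold"] = thresh
    out.attrs["n_subjects"] = int(len(mag))
    out.attrs["n_outliers_excluded"] = n_out
    return out
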