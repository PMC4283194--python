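"""Test-retest reliability statistics and per-region report tables.

The statistics operate on paired (test, retest) estimates per subject and
region:

* signed percent difference, ``2 (retest - test) / (test + retest) * 100``;
* one-way random, single-measures intraclass correlation coefficient,
  ``ICC(1,1) = (MSBS - MSWS) / (MSBS + (k-1) MSWS)`` from the one-way ANOVA
  decomposition (k = 2 sessions); a variant denominator ``MSBS +
  df_WS * MSWS`` is available for comparison with sources that print it
  that way;
* between-subject coefficient of variation (sample SD over mean, in %);
* Bland-Altman mean-difference decomposition with 1.96 SD limits of
  agreement;
* the high/low-binding heterogeneity ratio (default pallidum over pons);
* Spearman correlation of test-retest differences with the inter-scan
  interval, Bonferroni-corrected over regions.

ICC values >= 0.75 are conventionally read as good reliability.  Negative
or otherwise implausible estimates (possible for unstable fits) are kept as
ordinary values; NaN estimates are excluded pairwise with exclusion counts
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "ICCResult", "BlandAltman", "ReliabilityTable",
    "percent_diff", "icc_oneway", "between_subject_cv", "bland_altman",
    "heterogeneity_ratio", "interval_correlation", "build_reliability_table",
    "ICC_GOOD_THRESHOLD",
]

#: conventional threshold for "good" reliability
ICC_GOOD_THRESHOLD = 0.75


def percent_diff(test_value, retest_value):
    """Signed test-retest percent difference (NaN where test+retest = 0).

    Antisymmetric under swapping the sessions and bounded in (-200, 200)
    for positive pairs.
    """
    test_value = np.asarray(test_value, dtype=float)
    retest_value = np.asarray(retest_value, dtype=float)
    denom = test_value + retest_value
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0,
                       2.0 * (retest_value - test_value) / denom * 100.0,
                       np.nan)
    return out if out.ndim else float(out)


@dataclass
class ICCResult:
    icc: float
    msbs: float
    msws: float
    df_ws: int
    n: int
    k: int
    variant: str = "one-way random, single measures"


def icc_oneway(values: np.ndarray, denominator: str = "standard") -> ICCResult:
    """One-way random, single-measures ICC of an (n subjects x k sessions)
    matrix of estimates.

    ``denominator="standard"`` uses ``MSBS + (k-1) MSWS`` (the usual
    ICC(1,1)); ``denominator="printed"`` uses ``MSBS + df_WS * MSWS`` with
    ``df_WS = n (k-1)``.  Rows containing NaN are dropped; at least 3
    complete rows are required.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D (subjects x sessions) array")
    values = values[~np.isnan(values).any(axis=1)]
    n, k = values.shape
    if n < 3:
        raise ValueError("need at least 3 complete subject pairs")
    grand = values.mean()
    subj_means = values.mean(axis=1)
    ss_bs = k * np.sum((subj_means - grand) ** 2)
    ss_ws = np.sum((values - subj_means[:, None]) ** 2)
    df_bs = n - 1
    df_ws = n * (k - 1)
    msbs = ss_bs / df_bs
    msws = ss_ws / df_ws
    if msbs == 0 and msws == 0:
        raise ValueError("zero total variance; ICC undefined")
    if denominator == "standard":
        icc = (msbs - msws) / (msbs + (k - 1) * msws)
    elif denominator == "printed":
        icc = (msbs - msws) / (msbs + df_ws * msws)
    else:
        raise ValueError("denominator must be 'standard' or 'printed'")
    return ICCResult(icc=float(icc), msbs=float(msbs), msws=float(msws),
                     df_ws=int(df_ws), n=int(n), k=int(k))


def between_subject_cv(values: np.ndarray, mode: str = "averaged") -> float:
    """Between-subject coefficient of variation (%), sample SD over mean.

    ``mode="averaged"`` (default) computes the CV of the per-subject means
    of test and retest; ``mode="per_session"`` averages the two per-session
    CVs.  Returns NaN when the relevant mean is non-positive.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D (subjects x sessions) array")
    values = values[~np.isnan(values).any(axis=1)]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 complete subjects")
    if mode == "averaged":
        m = values.mean(axis=1)
        if m.mean() <= 0:
            return float("nan")
        return float(100.0 * m.std(ddof=1) / m.mean())
    if mode == "per_session":
        cvs = []
        for j in range(values.shape[1]):
            col = values[:, j]
            if col.mean() <= 0:
                return float("nan")
            cvs.append(100.0 * col.std(ddof=1) / col.mean())
        return float(np.mean(cvs))
    raise ValueError("mode must be 'averaged' or 'per_session'")


@dataclass
class BlandAltman:
    mean: np.ndarray        # (v1 + v2) / 2
    difference: np.ndarray  # v1 - v2
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(values_method1, values_method2) -> BlandAltman:
    """Tukey mean-difference decomposition of two paired measure sets.

    By convention the second argument is the reference method (the
    one-tissue compartmental V_T when comparing V_T estimators), so the
    difference is ``method1 - reference``.
    """
    v1 = np.asarray(values_method1, dtype=float)
    v2 = np.asarray(values_method2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("paired value arrays must have equal length")
    mean = 0.5 * (v1 + v2)
    diff = v1 - v2
    bias = float(np.nanmean(diff))
    sd = float(np.nanstd(diff, ddof=1)) if diff.size > 1 else 0.0
    return BlandAltman(mean=mean, difference=diff, bias=bias,
                       loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def heterogeneity_ratio(region_values: Dict[str, np.ndarray],
                        high_label: str = "pallidum",
                        low_label: str = "pons") -> float:
    """Cohort-median estimate of the high-binding region over the low one."""
    for label in (high_label, low_label):
        if label not in region_values:
            raise KeyError(f"region {label!r} not present")
    hi = float(np.nanmedian(np.asarray(region_values[high_label], dtype=float)))
    lo = float(np.nanmedian(np.asarray(region_values[low_label], dtype=float)))
    if lo == 0:
        raise ZeroDivisionError("low-binding region median is zero")
    return hi / lo


def interval_correlation(percent_diffs, intervals,
                         n_comparisons: int = 8) -> Tuple[float, float, float]:
    """Spearman rho of |test-retest difference| predictors vs interval.

    Returns ``(rho, p, p_bonferroni)`` with the Bonferroni factor covering
    the number of regions examined.
    """
    pd_ = np.asarray(percent_diffs, dtype=float)
    iv = np.asarray(intervals, dtype=float)
    ok = ~(np.isnan(pd_) | np.isnan(iv))
    if ok.sum() < 5:
        raise ValueError("need at least 5 complete pairs")
    rho, p = spearmanr(pd_[ok], iv[ok])
    return float(rho), float(p), float(min(1.0, p * n_comparisons))


@dataclass
class ReliabilityTable:
    """Per-region test-retest report plus a cross-region footer.

    ``table`` rows are regions with columns: median, q25, q75, min, max,
    median_pdiff, pdiff_min, pdiff_max, bs_cv, icc, n, n_excluded.  The
    footer carries mean (SD) of median_pdiff, bs_cv and icc across regions
    and, when both labels are present, the high/low heterogeneity ratio.
    """

    method: str
    table: pd.DataFrame
    footer: Dict[str, float] = field(default_factory=dict)
    ratio: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def build_reliability_table(
    estimates: pd.DataFrame,
    method_label: str = "",
    value_col: str = "value",
    denominator: str = "standard",
    bscv_mode: str = "averaged",
    high_label: str = "pallidum",
    low_label: str = "pons",
) -> ReliabilityTable:
    """Assemble the per-region reliability report from long-format estimates.

    ``estimates`` must have columns ``subject_id``, ``session`` (test /
    retest), ``region_id`` and ``value_col``.  Regions missing a session
    for some subject keep those subjects excluded pairwise (counted in
    ``n_excluded``); a region with fewer than 3 complete pairs reports NaN
    statistics.
    """
    required = {"subject_id", "session", "region_id", value_col}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates table lacks columns: {sorted(missing)}")
    n_subjects = estimates["subject_id"].nunique()
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects with both sessions")
    rows = []
    region_medians = {}
    for region, grp in estimates.groupby("region_id", sort=False):
        wide = grp.pivot_table(index="subject_id", columns="session",
                               values=value_col, aggfunc="first")
        for col in ("test", "retest"):
            if col not in wide:
                wide[col] = np.nan
        pairs = wide[["test", "retest"]].to_numpy(dtype=float)
        complete = pairs[~np.isnan(pairs).any(axis=1)]
        n_excluded = n_subjects - complete.shape[0]
        all_vals = pairs[~np.isnan(pairs)]
        pdiffs = percent_diff(complete[:, 0], complete[:, 1]) if complete.size else np.array([])
        row = dict(region_id=region,
                   median=np.nan, q25=np.nan, q75=np.nan,
                   min=np.nan, max=np.nan,
                   median_pdiff=np.nan, pdiff_min=np.nan, pdiff_max=np.nan,
                   bs_cv=np.nan, icc=np.nan,
                   n=int(complete.shape[0]), n_excluded=int(n_excluded))
        if all_vals.size:
            row.update(median=float(np.median(all_vals)),
                       q25=float(np.percentile(all_vals, 25)),
                       q75=float(np.percentile(all_vals, 75)),
                       min=float(np.min(all_vals)),
                       max=float(np.max(all_vals)))
        if complete.shape[0] >= 3:
            pd_ok = pdiffs[~np.isnan(pdiffs)]
            if pd_ok.size:
                # reported median is of the |%diff| magnitudes; the range
                # stays signed
                row.update(median_pdiff=float(np.median(np.abs(pd_ok))),
                           pdiff_min=float(np.min(pd_ok)),
                           pdiff_max=float(np.max(pd_ok)))
            try:
                row["icc"] = icc_oneway(complete, denominator=denominator).icc
            except ValueError:
                pass
            try:
                row["bs_cv"] = between_subject_cv(complete, mode=bscv_mode)
            except ValueError:
                pass
        rows.append(row)
        region_medians[region] = all_vals if all_vals.size else np.array([np.nan])
    table = pd.DataFrame(rows).set_index("region_id")
    footer = {}
    for col in ("median_pdiff", "bs_cv", "icc"):
        vals = table[col].to_numpy(dtype=float)
        ok = vals[~np.isnan(vals)]
        footer[f"mean_{col}"] = float(np.mean(ok)) if ok.size else np.nan
        footer[f"sd_{col}"] = float(np.std(ok, ddof=1)) if ok.size > 1 else np.nan
    ratio = None
    if high_label in region_medians and low_label in region_medians:
        try:
            ratio = heterogeneity_ratio(region_medians, high_label, low_label)
        except ZeroDivisionError:
            ratio = None
    return ReliabilityTable(method=method_label, table=table, footer=footer,
                            ratio=ratio)
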