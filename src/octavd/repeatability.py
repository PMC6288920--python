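"""Test-retest repeatability statistics for paired density measurements.

For each region the analysis takes one pair of densities per subject
(scan 1, scan 2) and reports, with 95% confidence intervals:

* the mean difference between scans with a two-sided paired t-test;
* the within-subject standard deviation ``Sw = sqrt(sum(d_i^2) / (2n))``
  (the Bland-Altman two-replicate estimator, equal to the square root of
  the one-way within-subject mean square);
* the coefficient of variation ``CV = Sw / overall mean``, where the
  overall mean averages both scans' values;
* the repeatability coefficient ``1.96 * sqrt(2) * Sw``, the value below
  which the absolute difference of two repeated measurements falls with
  95% probability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .density import REGION_ORDER
from .preprocess import DISC_SEGMENTS, MACULA_SEGMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "REPEATABILITY_FACTOR",
    "MeanDifferenceResult",
    "within_subject_sd",
    "repeatability_coefficient",
    "coefficient_of_variation",
    "sw_confidence_interval",
    "mean_difference_test",
    "repeatability_report",
]

#: 1.96 * sqrt(2); multiplies Sw to give the repeatability coefficient.
REPEATABILITY_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class MeanDifferenceResult:
    mean_difference: float
    ci: Tuple[float, float]
    p_value: float
    degenerate: bool = False


def _paired_arrays(value_1, value_2) -> Tuple[np.ndarray, np.ndarray]:
    v1 = np.asarray(value_1, dtype=float)
    v2 = np.asarray(value_2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("value_1 and value_2 must be 1-D arrays of equal length")
    keep = np.isfinite(v1) & np.isfinite(v2)
    if not keep.all():
        logger.warning("excluding %d incomplete pair(s)", int((~keep).sum()))
    return v1[keep], v2[keep]


def within_subject_sd(value_1, value_2) -> float:
    """Two-replicate within-subject standard deviation.

    With per-subject differences ``d_i = value_1_i - value_2_i``,
    ``Sw = sqrt(sum(d_i^2) / (2n))``. Pairs with a missing member are
    excluded with a logged warning; fewer than two complete pairs is an
    error.
    """
    v1, v2 = _paired_arrays(value_1, value_2)
    n = v1.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = v1 - v2
    return math.sqrt(float(np.sum(d**2)) / (2.0 * n))


def repeatability_coefficient(sw: float) -> float:
    """Repeatability coefficient 1.96 * sqrt(2) * Sw."""
    if sw < 0:
        raise ValueError("sw must be >= 0")
    return REPEATABILITY_FACTOR * sw


def coefficient_of_variation(sw: float, overall_mean: float) -> float:
    """CV = Sw / overall mean (a fraction; multiply by 100 for percent)."""
    if overall_mean <= 0:
        raise ValueError("overall_mean must be > 0")
    return sw / overall_mean


def sw_confidence_interval(sw: float, n: int, method: str = "normal",
                           ) -> Tuple[float, float]:
    """95% confidence interval for the two-replicate Sw from n subjects.

    ``normal`` (default) uses the standard approximation
    ``sw * (1 -/+ 1.96 / sqrt(2 n (m-1)))`` with m = 2 replicates, floored
    at 0. ``chi2`` uses the exact interval from
    ``n * sw^2 / sigma_w^2 ~ chi-squared(n)`` (n degrees of freedom for
    two replicates per subject). CV and repeatability-coefficient CIs are
    their (linear) transforms of these bounds.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sw < 0:
        raise ValueError("sw must be >= 0")
    if method == "normal":
        half = 1.96 / math.sqrt(2.0 * n)
        return (max(sw * (1.0 - half), 0.0), sw * (1.0 + half))
    if method == "chi2":
        lo_q, hi_q = stats.chi2.ppf([0.975, 0.025], df=n)
        return (sw * math.sqrt(n / lo_q), sw * math.sqrt(n / hi_q))
    raise ValueError("method must be 'normal' or 'chi2'")


def mean_difference_test(value_1, value_2) -> MeanDifferenceResult:
    """Mean paired difference, its 95% t-interval and two-sided p-value.

    All-identical pairs are degenerate: the t statistic is undefined, so
    the result carries mean 0, interval (0, 0), p = 1 and a degenerate
    flag. A zero-variance nonzero difference (exact constant offset) is
    likewise flagged, with p = 0.
    """
    v1, v2 = _paired_arrays(value_1, value_2)
    n = v1.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = v1 - v2
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return MeanDifferenceResult(0.0, (0.0, 0.0), 1.0, degenerate=True)
        return MeanDifferenceResult(mean, (mean, mean), 0.0, degenerate=True)
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    half = float(stats.t.ppf(0.975, df=n - 1)) * se
    return MeanDifferenceResult(mean, (mean - half, mean + half), p)


_REPORT_COLUMNS = [
    "eye", "scan_type", "segment_label", "region", "n", "available",
    "overall_mean", "mean_difference", "md_ci_lo", "md_ci_hi", "p_value",
    "degenerate", "sw", "sw_ci_lo", "sw_ci_hi", "cv", "cv_ci_lo", "cv_ci_hi",
    "repeatability", "rep_ci_lo", "rep_ci_hi",
]


def repeatability_report(pairs: pd.DataFrame, ci_method: str = "normal",
                         ) -> pd.DataFrame:
    """Per-region repeatability table from tidy paired measurements.

    ``pairs`` needs columns ``subject_id, eye, scan_type, segment_label,
    region, value_1, value_2`` (one row per subject and region). One
    output row is emitted per (eye, segment, region) present, in
    deterministic order (OD before OS, segments in device order, regions
    segment/superior/inferior/nasal/temporal); a complete single-scan-type
    dataset yields 40 rows (2 eyes x 4 segments x 5 regions). Groups with
    fewer than two usable pairs are emitted with ``available=False`` and
    NaN statistics rather than silently dropped. An audit line reconciling
    input pairs with report rows is logged.
    """
    required = {"subject_id", "eye", "scan_type", "segment_label", "region",
                "value_1", "value_2"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table is missing columns: {sorted(missing)}")

    segment_rank = {s: i for i, s in enumerate(MACULA_SEGMENTS + DISC_SEGMENTS)}
    region_rank = {r: i for i, r in enumerate(REGION_ORDER)}
    keys = (pairs[["eye", "scan_type", "segment_label", "region"]]
            .drop_duplicates()
            .sort_values(["scan_type", "eye", "segment_label", "region"],
                         key=lambda col: (col.map(segment_rank) if col.name == "segment_label"
                                          else col.map(region_rank) if col.name == "region"
                                          else col))
            .reset_index(drop=True))

    grouped = pairs.groupby(["eye", "scan_type", "segment_label", "region"])
    rows = []
    used_pairs = 0
    for _, key in keys.iterrows():
        group = grouped.get_group(tuple(key))
        v1 = group["value_1"].to_numpy(dtype=float)
        v2 = group["value_2"].to_numpy(dtype=float)
        complete = np.isfinite(v1) & np.isfinite(v2)
        n = int(complete.sum())
        base = dict(eye=key["eye"], scan_type=key["scan_type"],
                    segment_label=key["segment_label"], region=key["region"], n=n)
        if n < 2:
            rows.append({**base, "available": False})
            continue
        used_pairs += n
        v1c, v2c = v1[complete], v2[complete]
        sw = within_subject_sd(v1c, v2c)
        overall_mean = float(np.mean(np.concatenate([v1c, v2c])))
        md = mean_difference_test(v1c, v2c)
        sw_ci = sw_confidence_interval(sw, n, method=ci_method)
        cv = coefficient_of_variation(sw, overall_mean)
        rep = repeatability_coefficient(sw)
        rows.append({
            **base, "available": True, "overall_mean": overall_mean,
            "mean_difference": md.mean_difference,
            "md_ci_lo": md.ci[0], "md_ci_hi": md.ci[1],
            "p_value": md.p_value, "degenerate": md.degenerate,
            "sw": sw, "sw_ci_lo": sw_ci[0], "sw_ci_hi": sw_ci[1],
            "cv": cv, "cv_ci_lo": sw_ci[0] / overall_mean,
            "cv_ci_hi": sw_ci[1] / overall_mean,
            "repeatability": rep,
            "rep_ci_lo": REPEATABILITY_FACTOR * sw_ci[0],
            "rep_ci_hi": REPEATABILITY_FACTOR * sw_ci[1],
        })
    report = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    logger.info("repeatability audit: %d input pair rows, %d usable pairs, "
                "%d report rows", len(pairs), used_pairs, len(report))
    return report
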