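"""Population statistics for single-vesicle intensity readouts.

A vesicle is called lipid-enriched when its averaged membrane reporter
intensity exceeds the mean plus two sample standard deviations of a
negative-control population (liposomes that cannot have synthesized the
lipid).  Under a Gaussian null this tolerates ~2.3% false positives.  The
module also provides the descriptive and inferential statistics reported
alongside: coefficient of variation, Welch's unequal-variance t-test,
Tukey-style box statistics and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "BoxStats",
    "enrichment_threshold",
    "classify_enriched",
    "classify_against_control",
    "coefficient_of_variation",
    "welch_test",
    "box_stats",
    "pearson_correlation",
    "pearson_over_repeats",
]


@dataclass(frozen=True)
class EnrichmentResult:
    threshold: float
    n_total: int
    n_enriched: int
    percent_enriched: float
    control_mean: float | None = None
    control_sd: float | None = None


@dataclass(frozen=True)
class BoxStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _as_finite_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def enrichment_threshold(control_intensities) -> float:
    """Mean + 2 x sample SD (n-1 denominator) of the negative control."""
    control = _as_finite_array(control_intensities, "control_intensities")
    if control.size < 2:
        raise ValueError("need >= 2 control intensities to set a threshold")
    return float(control.mean() + 2 * control.std(ddof=1))


def classify_enriched(intensities, threshold: float) -> EnrichmentResult:
    """Count vesicles strictly above the threshold.

    The comparison is a strict ``>``: a vesicle exactly at the threshold is
    not enriched.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    arr = _as_finite_array(intensities, "intensities")
    if arr.size == 0:
        raise ValueError("empty intensity set")
    n_enriched = int(np.sum(arr > threshold))
    return EnrichmentResult(
        threshold=float(threshold),
        n_total=int(arr.size),
        n_enriched=n_enriched,
        percent_enriched=100.0 * n_enriched / arr.size,
    )


def classify_against_control(test_intensities, control_intensities) -> EnrichmentResult:
    """Convenience: threshold from control, then classify the test set."""
    control = _as_finite_array(control_intensities, "control_intensities")
    threshold = enrichment_threshold(control)
    result = classify_enriched(test_intensities, threshold)
    return EnrichmentResult(
        threshold=result.threshold,
        n_total=result.n_total,
        n_enriched=result.n_enriched,
        percent_enriched=result.percent_enriched,
        control_mean=float(control.mean()),
        control_sd=float(control.std(ddof=1)),
    )


def coefficient_of_variation(values) -> float:
    """Sample SD divided by mean; requires a positive mean."""
    arr = _as_finite_array(values, "values")
    if arr.size < 2:
        raise ValueError("need >= 2 values for a CV")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for nonpositive mean")
    return float(arr.std(ddof=1) / mean)


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, two-sided p, Welch-Satterthwaite df)."""
    a = _as_finite_array(group_a, "group_a")
    b = _as_finite_array(group_b, "group_b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def box_stats(values) -> BoxStats:
    """Tukey box-plot statistics.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    data points within 1.5 x IQR of the box ends; everything beyond is an
    outlier.  Every data point is either inside the whiskers or an outlier.
    """
    arr = _as_finite_array(values, "values")
    if arr.size == 0:
        raise ValueError("need >= 1 value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = arr[(arr < whisker_low) | (arr > whisker_high)]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=tuple(float(x) for x in np.sort(outliers)),
    )


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    xa = _as_finite_array(x, "x")
    ya = _as_finite_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need n >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(xa, ya).statistic)


def pearson_over_repeats(pairs) -> tuple[float, float]:
    """Per-repeat Pearson rho, summarised as (mean, SD over repeats).

    ``pairs`` is an iterable of (x, y) arrays, one per independent repeat.
    """
    rhos = [pearson_correlation(x, y) for x, y in pairs]
    if len(rhos) < 2:
        raise ValueError("need >= 2 repeats to report mean +/- SD")
    arr = np.asarray(rhos)
    return float(arr.mean()), float(arr.std(ddof=1))
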