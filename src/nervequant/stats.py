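"""Method-agreement and diagnostic statistics.

These are the statistics used to validate an automated nerve-quantification
method against manual annotation and against clinical group labels:

* per-variable error summaries: RMSE = sqrt(mean(V^2)) and the sample SD of
  the per-image errors V_i = v_method,i - v_manual,i;
* intraclass correlation ICC(2,1) (two-way random effects, absolute
  agreement, single measures) with the conventional reliability bands
  (< 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, > 0.9 excellent);
* Bland-Altman limits of agreement (mean difference +/- 1.96 SD) with
  t-based 95% CIs for the mean and both limits;
* ROC analysis with trapezoid AUC and the Youden-index optimal cut-point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["MeasureSeries", "ErrorSummary", "AgreementReport", "ROCResult",
           "error_summary", "icc_absolute", "bland_altman",
           "agreement_report", "roc_analysis"]


@dataclass
class MeasureSeries:
    """Paired per-image values of one variable from two methods."""

    v_method: np.ndarray
    v_manual: np.ndarray
    variable_name: str = ""

    def __post_init__(self) -> None:
        self.v_method = np.asarray(self.v_method, dtype=float)
        self.v_manual = np.asarray(self.v_manual, dtype=float)
        if self.v_method.shape != self.v_manual.shape or self.v_method.ndim != 1:
            raise ValueError("v_method and v_manual must be equal-length 1-D arrays")
        if len(self.v_method) < 2:
            raise ValueError("need at least 2 paired values")


def _as_pair(series_or_method, v_manual=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series_or_method, MeasureSeries):
        return series_or_method.v_method, series_or_method.v_manual
    a = np.asarray(series_or_method, dtype=float)
    b = np.asarray(v_manual, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("method and manual series must be equal-length 1-D arrays")
    return a, b


@dataclass
class ErrorSummary:
    """RMSE and SD of the per-image error of a method vs manual annotation."""

    rmse: float
    sd: float
    v_bar: float
    n: int


def error_summary(series, v_manual=None) -> ErrorSummary:
    """RMSE = sqrt(mean V^2); SD = sample SD of V (n-1 denominator)."""
    method, manual = _as_pair(series, v_manual)
    if len(method) < 2:
        raise ValueError("need at least 2 paired values")
    v = method - manual
    return ErrorSummary(rmse=float(np.sqrt(np.mean(v ** 2))),
                        sd=float(np.std(v, ddof=1)),
                        v_bar=float(np.mean(v)), n=len(v))


def _icc_band(icc: float) -> str:
    if np.isnan(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def icc_absolute(series, v_manual=None) -> tuple[float, str]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares of the n-subjects x
    2-raters table.  Returns (icc, band); zero total variance gives
    (NaN, "undefined").
    """
    method, manual = _as_pair(series, v_manual)
    n = len(method)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    y = np.column_stack([method, manual])
    k = 2
    grand = y.mean()
    if np.allclose(y, grand):
        return float("nan"), "undefined"
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((y - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(icc), _icc_band(icc)


@dataclass
class AgreementReport:
    """ICC plus Bland-Altman agreement between a method and manual annotation."""

    icc: float
    icc_band: str
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    ci_mean: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    n: int


def bland_altman(series, v_manual=None) -> AgreementReport:
    """Bland-Altman limits of agreement with 95% CIs.

    LoA = mean difference +/- 1.96 SD of the differences; the CI of the mean
    uses SE = SD/sqrt(n) and the CIs of the limits use the classic
    approximation SE(LoA) = SD*sqrt(3/n), both with t(n-1) quantiles.
    The ICC fields of the returned report are filled in as well.
    """
    method, manual = _as_pair(series, v_manual)
    n = len(method)
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 paired values")
    d = method - manual
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = mean - 1.96 * sd, mean + 1.96 * sd
    t = float(sps.t.ppf(0.975, n - 1))
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    icc, band = icc_absolute(method, manual)
    return AgreementReport(
        icc=icc, icc_band=band,
        ba_mean_diff=mean, ba_loa_low=loa_low, ba_loa_high=loa_high,
        ci_mean=(mean - t * se_mean, mean + t * se_mean),
        ci_loa_low=(loa_low - t * se_loa, loa_low + t * se_loa),
        ci_loa_high=(loa_high - t * se_loa, loa_high + t * se_loa),
        n=n)


agreement_report = bland_altman


@dataclass
class ROCResult:
    """Empirical ROC curve with the Youden-index optimal cut-point.

    ``orientation`` is +1 when higher scores indicate the positive class and
    -1 when the scores were auto-flipped (e.g. nerve length is LOWER in
    neuropathy); with orientation -1 the decision rule at the cut is
    "score <= optimal_cut => positive".
    """

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_j: float
    optimal_cut: float
    sens_at_cut: float
    spec_at_cut: float
    orientation: int


def roc_analysis(scores, labels, positive_label=None) -> ROCResult:
    """Empirical ROC over all unique thresholds, trapezoid AUC, Youden cut.

    The score direction is auto-detected: if the raw AUC is below 0.5 the
    scores are negated (and ``orientation = -1`` recorded) so the reported
    AUC is always >= 0.5.  Ties of the Youden index are broken toward
    higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if positive_label is not None:
        y = (labels == positive_label).astype(int)
    else:
        y = labels.astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("roc_analysis requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    raw_auc = _sk_auc(fpr, tpr)
    orientation = 1
    if raw_auc < 0.5:
        orientation = -1
        fpr, tpr, thr = _sk_roc_curve(y, -scores)
    a = float(_sk_auc(fpr, tpr))
    j = tpr - fpr
    best = int(np.argmax(j))  # fpr ascending: first max has highest specificity
    cut = float(thr[best])
    if orientation == -1:
        cut = -cut
    return ROCResult(auc=a, thresholds=(thr if orientation == 1 else -thr),
                     sensitivity=tpr, specificity=1.0 - fpr,
                     youden_j=float(j[best]), optimal_cut=cut,
                     sens_at_cut=float(tpr[best]),
                     spec_at_cut=float(1.0 - fpr[best]),
                     orientation=orientation)
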