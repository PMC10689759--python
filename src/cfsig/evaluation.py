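"""Sample QC filtering and performance statistics.

QC exclusion mirrors standard WGMS thresholds: fewer than 150 million
uniquely mapped reads, mapping rate below 80%, duplication rate above
25%, or C-to-T conversion efficiency below 99% (all strict
inequalities) fail a sample.

Performance statistics: sensitivity/specificity/accuracy with exact
Clopper-Pearson 95% CIs, Mann-Whitney AUC with a DeLong variance CI,
McNemar's test for paired sensitivity comparisons (exact binomial for
few discordant pairs, continuity-corrected chi-square otherwise), and
multiclass confusion summaries for tissue-of-origin calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

QC_THRESHOLDS = {
    "uniquely_mapped_reads": 150e6,  # fail if below
    "mapping_rate": 0.80,  # fail if below
    "duplication_rate": 0.25,  # fail if above
    "conversion_efficiency": 0.99,  # fail if below
}


def qc_filter(metrics: pd.DataFrame) -> tuple[list[str], dict[str, list[str]]]:
    """Partition samples into QC pass/fail with per-sample failure reasons.

    ``metrics`` needs columns ``sample_id, uniquely_mapped_reads,
    mapping_rate, duplication_rate, conversion_efficiency``.  A sample
    fails iff reads < 1.5e8, mapping rate < 0.80, duplication rate >
    0.25, or conversion efficiency < 0.99 (values exactly at a
    threshold pass).  Returns (pass_ids, {sample_id: [reasons]}).
    """
    needed = ["sample_id", *QC_THRESHOLDS.keys()]
    for col in needed:
        if col not in metrics.columns:
            raise ValueError(f"QC metrics missing column {col!r}")
    for col in QC_THRESHOLDS:
        bad = metrics[metrics[col].isna()]
        if len(bad):
            raise ValueError(
                f"sample {bad['sample_id'].iloc[0]!r} missing QC metric {col!r}"
            )
    pass_ids: list[str] = []
    fail: dict[str, list[str]] = {}
    for _, row in metrics.iterrows():
        reasons = []
        if row["uniquely_mapped_reads"] < QC_THRESHOLDS["uniquely_mapped_reads"]:
            reasons.append("uniquely_mapped_reads")
        if row["mapping_rate"] < QC_THRESHOLDS["mapping_rate"]:
            reasons.append("mapping_rate")
        if row["duplication_rate"] > QC_THRESHOLDS["duplication_rate"]:
            reasons.append("duplication_rate")
        if row["conversion_efficiency"] < QC_THRESHOLDS["conversion_efficiency"]:
            reasons.append("conversion_efficiency")
        if reasons:
            fail[str(row["sample_id"])] = reasons
        else:
            pass_ids.append(str(row["sample_id"]))
    return pass_ids, fail


@dataclass(frozen=True)
class PerfSummary:
    """Binary-classification summary with exact 95% CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]


def _prop_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return (float(lo), float(hi))


def sens_spec(calls, truth) -> PerfSummary:
    """Sensitivity/specificity/accuracy with Clopper-Pearson 95% CIs.

    ``calls`` and ``truth`` are aligned binary vectors (1 = positive).
    With no positives in truth, sensitivity is NaN.
    """
    c = np.asarray(calls, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if c.shape != t.shape:
        raise ValueError("calls and truth have different lengths")
    tp = int(np.sum(c & t))
    fp = int(np.sum(c & ~t))
    tn = int(np.sum(~c & ~t))
    fn = int(np.sum(~c & t))
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / len(c) if len(c) else float("nan")
    return PerfSummary(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=_prop_ci(tp, n_pos),
        specificity_ci=_prop_ci(tn, n_neg),
        accuracy_ci=_prop_ci(tp + tn, len(c)),
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_ci(scores, truth, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with DeLong 95% CI (truncated to [0, 1]).

    Ties count half.  Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    pos, neg = s[t], s[~t]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for AUC")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(1 - alpha / 2.0)
    half = z * np.sqrt(var)
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def mcnemar(calls_a, calls_b, truth, exact_max: int = 25) -> float:
    """McNemar comparison of two classifiers' sensitivity on paired samples.

    Restricted to truth-positive samples: b counts samples only A
    detects, c samples only B detects.  p is the exact two-sided
    binomial when b + c <= ``exact_max``, else the continuity-corrected
    chi-square; b + c = 0 gives p = 1.
    """
    a = np.asarray(calls_a, dtype=bool)
    bb = np.asarray(calls_b, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    a, bb = a[t], bb[t]
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        return 1.0
    if b + c <= exact_max:
        return float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
    chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    return float(stats.chi2.sf(chi2, df=1))


def confusion(
    calls, truth, classes: tuple[str, ...]
) -> dict:
    """Multiclass confusion matrix with per-class recall/precision.

    Returns a dict with keys ``matrix`` (DataFrame, rows = truth,
    columns = call), ``recall``, ``precision`` (Series), ``accuracy``.
    """
    calls = pd.Series(list(calls))
    truth = pd.Series(list(truth))
    unknown = (set(calls) | set(truth)) - set(classes)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    from sklearn.metrics import confusion_matrix

    mat = confusion_matrix(truth, calls, labels=list(classes))
    df = pd.DataFrame(mat, index=list(classes), columns=list(classes))
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = pd.Series(np.diag(mat) / mat.sum(axis=1), index=list(classes))
        precision = pd.Series(np.diag(mat) / mat.sum(axis=0), index=list(classes))
    accuracy = float(np.trace(mat) / mat.sum()) if mat.sum() else float("nan")
    return {"matrix": df, "recall": recall, "precision": precision, "accuracy": accuracy}
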