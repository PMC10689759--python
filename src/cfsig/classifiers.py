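"""Multiclass classification, scores, and the cancer signature ensemble.

Each feature family (AMF markers, per-bin adjusted CNR, per-bin FSR)
feeds a linear-kernel support-vector classifier over five classes
(healthy, colon, liver, lung, prostate).  Class probabilities come from
one-vs-rest sigmoid calibration fit on out-of-fold decision values; the
regularization constant is tuned by internal stratified CV minimizing
misclassification.  A sample's *cancer score* is the sum of the four
cancer-class probabilities (1 - p_healthy); its tissue-of-origin (TOO)
conditional probabilities divide the four cancer-class probabilities by
the cancer score.  The ensemble (CSE) is the arithmetic mean of the
three per-feature cancer scores (detection) or TOO probability vectors.

The detection operating point is chosen post hoc: the lowest threshold
t such that calling score > t positive leaves strictly more than 95% of
healthy evaluation samples negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

CLASS_ORDER = ("healthy", "colon", "liver", "lung", "prostate")
CANCER_CLASSES = CLASS_ORDER[1:]
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)


def stratified_split(
    meta: pd.DataFrame,
    test_frac: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Assign cfDNA samples to train/test, balancing class, stage, sex, age.

    ``meta`` must have columns ``sample_id, class_label, sample_type,
    stage, age, sex`` and may have ``matched_tissue`` (bool).  Samples
    with a matched tissue are forced into the training set; tissue
    samples themselves are always train.  The rest are assigned by
    seeded sampling within (class x stage x sex x age-bin) strata,
    where age is binned at 50 years.  Returns a Series mapping
    sample_id to "train"/"test".
    """
    required = {"sample_id", "class_label", "sample_type", "stage", "age", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    meta = meta.copy()
    meta["age_bin"] = np.where(meta["age"].astype(float) < 50, "<50", ">=50")
    matched = (
        meta["matched_tissue"].fillna(False).astype(bool)
        if "matched_tissue" in meta.columns
        else pd.Series(False, index=meta.index)
    )
    forced = (meta["sample_type"] != "cfDNA") | matched
    for sid in meta.loc[forced, "sample_id"]:
        assignment[sid] = "train"
    free = meta[~forced]
    strata = free.groupby(
        ["class_label", "stage", "sex", "age_bin"], dropna=False, sort=True
    )
    for _, grp in strata:
        ids = sorted(grp["sample_id"])
        if len(ids) <= 1:
            for sid in ids:
                assignment[sid] = "train"
            if ids:
                logger.warning("stratum of size 1 assigned wholly to train: %s", ids[0])
            continue
        n_test = int(round(test_frac * len(ids)))
        order = rng.permutation(len(ids))
        for rank, i in enumerate(order):
            assignment[ids[i]] = "test" if rank < n_test else "train"
    out = pd.Series(assignment, name="split")
    out.index.name = "sample_id"
    return out.loc[meta["sample_id"]]


def make_folds(train_meta: pd.DataFrame, k: int = 4, seed: int = 0) -> pd.Series:
    """Class-stratified k-fold assignment (fold sizes within class differ <= 1)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    for cls, grp in train_meta.groupby("class_label", sort=True):
        ids = sorted(grp["sample_id"])
        if len(ids) < k:
            raise ValueError(f"class {cls!r} has {len(ids)} samples (< k={k})")
        order = rng.permutation(len(ids))
        for rank, i in enumerate(order):
            folds[ids[i]] = rank % k + 1
    out = pd.Series(folds, name="fold")
    out.index.name = "sample_id"
    return out.loc[train_meta["sample_id"]]


@dataclass
class FeatureClassifier:
    """A fitted per-feature multiclass model with its training contract."""

    pipeline: Pipeline
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    chosen_c: float
    seed: int

    def to_dict(self) -> dict:
        """Lightweight serializable description (for manifests, not refit)."""
        return {
            "n_features": len(self.feature_names),
            "classes": list(self.classes),
            "chosen_c": self.chosen_c,
            "seed": self.seed,
        }


def fit_multiclass(
    X: pd.DataFrame,
    y: pd.Series,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    seed: int = 0,
    n_calibration_folds: int = 4,
) -> FeatureClassifier:
    """Fit a linear-SVC multiclass model with calibrated probabilities.

    Features are z-scored on training statistics.  The regularization
    constant C is chosen from ``c_grid`` by internal stratified CV on
    misclassification rate (ties favor the smaller C); probabilities
    are one-vs-rest sigmoid calibrations fit on out-of-fold decision
    values.
    """
    if X.isna().any().any():
        raise ValueError("X contains missing values; impute first")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValueError("X contains non-finite values")
    classes = tuple(sorted(set(y), key=CLASS_ORDER.index))
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a classifier")

    Xv = X.to_numpy(dtype=np.float64)
    yv = y.to_numpy()
    min_class = int(pd.Series(yv).value_counts().min())
    n_cv = int(np.clip(min_class, 2, n_calibration_folds))
    cv = StratifiedKFold(n_splits=n_cv, shuffle=True, random_state=seed)

    def make_svc(c: float) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", LinearSVC(C=c, random_state=seed, max_iter=20000, dual="auto")),
            ]
        )

    best_c, best_acc = None, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in c_grid:
            acc = cross_val_score(make_svc(c), Xv, yv, cv=cv, scoring="accuracy").mean()
            if acc > best_acc + 1e-12:
                best_c, best_acc = c, acc
        calibrated = CalibratedClassifierCV(
            make_svc(best_c), method="sigmoid", cv=cv, ensemble=True
        )
        calibrated.fit(Xv, yv)
    pipe = Pipeline([("calibrated", calibrated)])
    return FeatureClassifier(
        pipeline=pipe,
        feature_names=tuple(map(str, X.columns)),
        classes=tuple(map(str, calibrated.classes_)),
        chosen_c=float(best_c),
        seed=seed,
    )


def predict_probs(model: FeatureClassifier, X: pd.DataFrame) -> pd.DataFrame:
    """Per-sample class probabilities in canonical class order.

    Features must match training by name and order; missing/extra
    features or non-finite values are errors.
    """
    got = tuple(map(str, X.columns))
    if got != model.feature_names:
        missing = sorted(set(model.feature_names) - set(got))
        extra = sorted(set(got) - set(model.feature_names))
        raise ValueError(
            f"feature mismatch with training: missing={missing[:5]} extra={extra[:5]}"
            + ("" if missing or extra else " (order differs)")
        )
    Xv = X.to_numpy(dtype=np.float64)
    if not np.isfinite(Xv).all():
        raise ValueError("X contains non-finite values")
    probs = model.pipeline.predict_proba(Xv)
    df = pd.DataFrame(probs, columns=model.classes, index=X.index)
    cols = [c for c in CLASS_ORDER if c in df.columns]
    df = df[cols]
    # calibration renormalizes, but guard the unit-sum contract anyway
    df = df.div(df.sum(axis=1), axis=0)
    return df


def cancer_score(probs: pd.DataFrame | pd.Series):
    """Sum of cancer-class probabilities (equivalently 1 - p_healthy)."""
    if isinstance(probs, pd.Series):
        return float(sum(probs[c] for c in CANCER_CLASSES if c in probs.index))
    cols = [c for c in CANCER_CLASSES if c in probs.columns]
    return probs[cols].sum(axis=1).rename("cancer_score")


def too_conditional(probs: pd.DataFrame, eps: float = 1e-12) -> pd.DataFrame:
    """Cancer-class probabilities conditioned on the sample being cancer.

    Divides each cancer-class probability by the cancer score; samples
    with cancer score below ``eps`` get a uniform vector (flagged via a
    ``degenerate`` boolean column).
    """
    cols = [c for c in CANCER_CLASSES if c in probs.columns]
    cs = probs[cols].sum(axis=1)
    out = probs[cols].div(cs.where(cs >= eps), axis=0)
    degenerate = cs < eps
    if degenerate.any():
        logger.warning("%d samples with ~zero cancer score; uniform TOO", int(degenerate.sum()))
        out.loc[degenerate, :] = 1.0 / len(cols)
    out["degenerate"] = degenerate
    return out


def ensemble_mean(per_classifier: list[pd.Series] | list[pd.DataFrame]):
    """Arithmetic mean of aligned per-classifier scores or TOO vectors."""
    if not per_classifier:
        raise ValueError("no classifier outputs to ensemble")
    first = per_classifier[0]
    for other in per_classifier[1:]:
        if not first.index.equals(other.index):
            raise ValueError("classifier outputs have misaligned sample ids")
        if isinstance(first, pd.DataFrame) and list(first.columns) != list(other.columns):
            raise ValueError("classifier outputs have misaligned columns")
    return sum(per_classifier) / len(per_classifier)


def select_threshold(
    healthy_scores: pd.Series | np.ndarray,
    target_spec: float = 0.95,
    min_n: int = 20,
) -> float:
    """Lowest threshold with strictly > ``target_spec`` specificity.

    A sample is called positive iff score > t, so specificity(t) is the
    fraction of healthy scores <= t.  Candidates are the unique healthy
    scores; if none qualifies the maximum score is returned (all
    healthy negative) with a warning.
    """
    scores = np.asarray(healthy_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no healthy scores supplied")
    if scores.size < min_n:
        raise ValueError(f"need >= {min_n} healthy scores, got {scores.size}")
    candidates = np.unique(scores)
    n = scores.size
    for t in candidates:
        if np.sum(scores <= t) / n > target_spec:
            return float(t)
    logger.warning("no threshold reaches specificity > %s; using max score", target_spec)
    return float(candidates[-1])


def call_too(cond: pd.DataFrame | pd.Series):
    """Tissue-of-origin call: argmax TOO probability, ties by canonical order."""
    cols = [c for c in CANCER_CLASSES]
    if isinstance(cond, pd.Series):
        vals = np.array([cond[c] for c in cols], dtype=float)
        return cols[int(np.argmax(vals))]
    mat = cond[cols].to_numpy(dtype=float)
    idx = np.argmax(mat, axis=1)  # first max wins -> canonical order tie-break
    return pd.Series([cols[i] for i in idx], index=cond.index, name="too_call")
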