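"""Splits/folds, SVC probability models, scores, ensemble, thresholding."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cfsig import classifiers as cl
from tests.conftest import make_meta


# ------------------------------------------------------------------ splits
def test_split_forces_matched_tissue_to_train():
    meta = make_meta()
    meta["matched_tissue"] = False
    meta.loc[:5, "matched_tissue"] = True
    split = cl.stratified_split(meta, seed=1)
    assert (split[meta.loc[:5, "sample_id"]] == "train").all()


def test_split_all_matched_all_train():
    meta = make_meta()
    meta["matched_tissue"] = True
    split = cl.stratified_split(meta, seed=1)
    assert (split == "train").all()


def test_split_balanced_within_stratum():
    rows = []
    for i in range(40):
        rows.append(
            {
                "sample_id": f"s{i}",
                "class_label": "healthy",
                "sample_type": "cfDNA",
                "stage": 0,
                "age": 60,
                "sex": "M",
            }
        )
    split = cl.stratified_split(pd.DataFrame(rows), test_frac=0.5, seed=3)
    assert (split == "test").sum() == 20


def test_split_deterministic():
    meta = make_meta()
    s1 = cl.stratified_split(meta, seed=9)
    s2 = cl.stratified_split(meta, seed=9)
    pd.testing.assert_series_equal(s1, s2)
    s3 = cl.stratified_split(meta, seed=10)
    assert not s1.equals(s3)


def test_make_folds_stratified_and_validated():
    meta = make_meta(n_per_class=12)
    folds = cl.make_folds(meta, k=4, seed=0)
    merged = meta.set_index("sample_id").join(folds)
    for _, grp in merged.groupby("class_label"):
        counts = grp["fold"].value_counts()
        assert counts.max() - counts.min() <= 1
    with pytest.raises(ValueError):
        cl.make_folds(meta, k=1)
    with pytest.raises(ValueError, match="< k"):
        cl.make_folds(make_meta(n_per_class=3), k=4)


# ------------------------------------------------------------------ fitting
def _toy_xy(n_per_class=20, n_features=2, sep=6.0, seed=0, classes=("healthy", "colon")):
    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for i, cls in enumerate(classes):
        Xs.append(rng.normal(i * sep, 1.0, (n_per_class, n_features)))
        ys.extend([cls] * n_per_class)
    X = pd.DataFrame(np.vstack(Xs), columns=[f"f{j}" for j in range(n_features)])
    return X, pd.Series(ys)


def test_fit_separable_toy_perfect():
    X, y = _toy_xy()
    model = cl.fit_multiclass(X, y, seed=0)
    probs = cl.predict_probs(model, X)
    pred = probs.idxmax(axis=1)
    assert (pred.to_numpy() == y.to_numpy()).mean() == 1.0


def test_fit_permuted_labels_near_chance():
    rng = np.random.default_rng(1)
    X, y = _toy_xy(n_per_class=30, sep=0.0, classes=("healthy", "colon", "liver", "lung", "prostate"))
    y = pd.Series(rng.permutation(y.to_numpy()))
    model = cl.fit_multiclass(X, y, seed=1)
    probs = cl.predict_probs(model, X)
    acc = (probs.idxmax(axis=1).to_numpy() == y.to_numpy()).mean()
    # 150 samples, null accuracy 0.2: generous 5-sigma binomial band
    assert acc < 0.2 + 5 * np.sqrt(0.2 * 0.8 / 150)


def test_fit_deterministic():
    X, y = _toy_xy(seed=4)
    m1 = cl.fit_multiclass(X, y, seed=5)
    m2 = cl.fit_multiclass(X, y, seed=5)
    assert m1.chosen_c == m2.chosen_c
    pd.testing.assert_frame_equal(cl.predict_probs(m1, X), cl.predict_probs(m2, X))


def test_fit_rejects_bad_input():
    X, y = _toy_xy()
    X_nan = X.copy()
    X_nan.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        cl.fit_multiclass(X_nan, y)
    with pytest.raises(ValueError, match="two classes"):
        cl.fit_multiclass(X, pd.Series(["healthy"] * len(X)))


def test_predict_feature_contract():
    X, y = _toy_xy()
    model = cl.fit_multiclass(X, y, seed=0)
    probs = cl.predict_probs(model, X)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert len(cl.predict_probs(model, X.iloc[[0]])) == 1
    with pytest.raises(ValueError, match="feature mismatch"):
        cl.predict_probs(model, X.rename(columns={"f0": "g0"}))
    bad = X.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        cl.predict_probs(model, bad)


# ------------------------------------------------------------------ scores
def _pv(vals):
    return pd.DataFrame([vals], columns=list(cl.CLASS_ORDER), index=["s0"])


@pytest.mark.parametrize(
    "probs,expected",
    [
        ((0.2, 0.2, 0.2, 0.2, 0.2), 0.8),
        ((1.0, 0.0, 0.0, 0.0, 0.0), 0.0),
        ((0.2, 0.4, 0.2, 0.1, 0.1), 0.8),
    ],
)
def test_cancer_score(probs, expected):
    assert cl.cancer_score(_pv(probs)).iloc[0] == pytest.approx(expected)


def test_cancer_score_complement_of_healthy():
    rng = np.random.default_rng(2)
    raw = rng.dirichlet(np.ones(5), size=50)
    probs = pd.DataFrame(raw, columns=list(cl.CLASS_ORDER))
    np.testing.assert_allclose(
        cl.cancer_score(probs), 1.0 - probs["healthy"], atol=1e-12
    )


def test_too_conditional_division_and_reconstruction():
    cond = cl.too_conditional(_pv((0.2, 0.4, 0.2, 0.1, 0.1)))
    np.testing.assert_allclose(
        cond[list(cl.CANCER_CLASSES)].iloc[0], [0.5, 0.25, 0.125, 0.125]
    )
    assert not cond["degenerate"].iloc[0]
    # conditional x cancer score reconstructs the raw cancer probabilities
    back = cond[list(cl.CANCER_CLASSES)].iloc[0] * 0.8
    np.testing.assert_allclose(back, [0.4, 0.2, 0.1, 0.1])


def test_too_conditional_degenerate_uniform():
    cond = cl.too_conditional(_pv((1.0, 0.0, 0.0, 0.0, 0.0)))
    np.testing.assert_allclose(cond[list(cl.CANCER_CLASSES)].iloc[0], [0.25] * 4)
    assert bool(cond["degenerate"].iloc[0])


def test_ensemble_mean_scalars_and_vectors():
    idx = pd.Index(["a", "b", "c"])
    s = [pd.Series([0.9, 0.6, 0.6], index=idx), pd.Series([0.6, 0.6, 0.9], index=idx),
         pd.Series([0.6, 0.9, 0.6], index=idx)]
    np.testing.assert_allclose(cl.ensemble_mean(s), 0.7)
    v1 = pd.DataFrame([[1, 0, 0, 0]], columns=list(cl.CANCER_CLASSES))
    v2 = pd.DataFrame([[0, 1, 0, 0]], columns=list(cl.CANCER_CLASSES))
    mean = cl.ensemble_mean([v1, v2])
    np.testing.assert_allclose(mean.iloc[0], [0.5, 0.5, 0, 0])
    assert mean.iloc[0].sum() == pytest.approx(1.0)


def test_ensemble_permutation_invariant_and_identity():
    idx = pd.Index(["a", "b"])
    s1, s2 = pd.Series([0.1, 0.9], index=idx), pd.Series([0.5, 0.5], index=idx)
    pd.testing.assert_series_equal(
        cl.ensemble_mean([s1, s2]), cl.ensemble_mean([s2, s1])
    )
    pd.testing.assert_series_equal(cl.ensemble_mean([s1, s1]), s1)


def test_ensemble_misaligned_ids_error():
    s1 = pd.Series([0.1], index=["a"])
    s2 = pd.Series([0.1], index=["b"])
    with pytest.raises(ValueError, match="misaligned"):
        cl.ensemble_mean([s1, s2])


# --------------------------------------------------------------- threshold
def test_threshold_enumeration_example():
    scores = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
    t = cl.select_threshold(scores)
    assert t == pytest.approx(0.96)  # 96/100 <= t -> specificity 0.96 > 0.95
    spec = np.mean(scores <= t)
    assert spec > 0.95


def test_threshold_strict_inequality_edge():
    scores = np.arange(1, 21) / 20.0  # 20 distinct scores
    t = cl.select_threshold(scores)
    assert t == pytest.approx(1.0)  # 19/20 = 0.95 is NOT > 0.95 -> max score


def test_threshold_all_zero_scores():
    t = cl.select_threshold(np.zeros(30))
    assert t == 0.0
    assert np.mean(np.zeros(30) <= t) == 1.0


def test_threshold_input_validation():
    with pytest.raises(ValueError):
        cl.select_threshold(np.array([]))
    with pytest.raises(ValueError, match=">= 20"):
        cl.select_threshold(np.arange(5) / 5)


def test_threshold_guarantee_random_scores():
    rng = np.random.default_rng(6)
    for _ in range(20):
        scores = rng.random(rng.integers(20, 200))
        t = cl.select_threshold(scores)
        assert np.mean(scores <= t) > 0.95


# ------------------------------------------------------------------- TOO call
def test_call_too():
    assert cl.call_too(pd.Series([0.5, 0.25, 0.125, 0.125], index=list(cl.CANCER_CLASSES))) == "colon"
    assert cl.call_too(pd.Series([0.25] * 4, index=list(cl.CANCER_CLASSES))) == "colon"
    assert cl.call_too(pd.Series([0, 0, 0.6, 0.4], index=list(cl.CANCER_CLASSES))) == "lung"
    df = pd.DataFrame([[0, 0.7, 0.3, 0]], columns=list(cl.CANCER_CLASSES))
    assert cl.call_too(df).iloc[0] == "liver"
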