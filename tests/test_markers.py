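"""Moderated t-statistic, top-marker selection, and marker set algebra.

The moderated t is checked two ways: against a scalar brute-force
reimplementation of the empirical-Bayes formulas, and against reference
values computed once with the R limma package (lmFit + eBayes) on the
same frozen fixture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma, polygamma

from cfsig import markers as mk
from cfsig.methylation import StableRegionSets


def _fixture_matrices():
    rng = np.random.default_rng(42)
    nA, nB, nreg = 5, 6, 8
    A = np.round(rng.normal(0, 1, (nA, nreg)) + np.array([0, 0, 1, 2, 0, 0.5, -1, 0]), 4)
    B = np.round(rng.normal(0, 1, (nB, nreg)), 4)
    cols = [f"r{i}" for i in range(nreg)]
    return pd.DataFrame(A, columns=cols), pd.DataFrame(B, columns=cols)


# values computed once with R limma 3.58.1: eBayes(lmFit(expr, design))
LIMMA_D0 = 11.73571
LIMMA_S0SQ = 0.4043026
LIMMA_T = [-0.78275946, -3.42740526, 6.32481240, 6.50383145, 0.57656763, 0.60118955, -0.58552080, -0.01954149]
LIMMA_P = [4.426167499e-01, 2.564483501e-03, 3.022857215e-06, 2.040494068e-06, 5.704381267e-01, 5.542297172e-01, 5.645163282e-01, 9.845959570e-01]


def test_moderated_t_matches_limma_reference():
    """t and p agree with the R reference engine to 1e-6 on a frozen fixture."""
    A, B = _fixture_matrices()
    res = mk.moderated_t(A, B)
    np.testing.assert_allclose(res["t_mod"], LIMMA_T, rtol=1e-6)
    np.testing.assert_allclose(res["p_value"], LIMMA_P, rtol=1e-5)
    assert res["df_total"].iloc[0] == pytest.approx(9 + LIMMA_D0, abs=1e-3)


def test_moderated_t_matches_scalar_brute_force():
    """Region-by-region scalar recomputation of the shrinkage formulas."""
    A, B = _fixture_matrices()
    res = mk.moderated_t(A, B)
    a, b = A.to_numpy(), B.to_numpy()
    nA, nB = a.shape[0], b.shape[0]
    d = nA + nB - 2
    s2 = np.array(
        [((nA - 1) * np.var(a[:, j], ddof=1) + (nB - 1) * np.var(b[:, j], ddof=1)) / d
         for j in range(a.shape[1])]
    )
    # scalar method-of-moments prior
    z = np.log(s2)
    e = z - digamma(d / 2) + np.log(d / 2)
    evar = np.var(e, ddof=1) - polygamma(1, d / 2)
    assert evar > 0
    lo, hi = 1e-3, 1e6
    for _ in range(200):  # bisection for trigamma inverse
        mid = np.sqrt(lo * hi)
        if polygamma(1, mid) > evar:
            lo = mid
        else:
            hi = mid
    d0 = 2 * lo
    s0sq = np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2))
    for j in range(a.shape[1]):
        s2post = (d0 * s0sq + d * s2[j]) / (d0 + d)
        t = (a[:, j].mean() - b[:, j].mean()) / np.sqrt(s2post * (1 / nA + 1 / nB))
        p = 2 * stats.t.sf(abs(t), d0 + d)
        assert res["t_mod"].iloc[j] == pytest.approx(t, rel=1e-6)
        assert res["p_value"].iloc[j] == pytest.approx(p, rel=1e-6)


def test_forced_zero_prior_is_ordinary_t():
    """With d0 forced to 0 the moderated t is the ordinary pooled t exactly."""
    A, B = _fixture_matrices()
    res = mk.moderated_t(A, B, prior_df=0)
    for j, col in enumerate(A.columns):
        t, p = stats.ttest_ind(A[col], B[col], equal_var=True)
        assert res["t_mod"].iloc[j] == pytest.approx(t, rel=1e-10)
        assert res["p_value"].iloc[j] == pytest.approx(p, rel=1e-10)


def test_constant_region_gets_finite_t():
    """A zero-variance region is rescued by the prior: finite moderated t."""
    rng = np.random.default_rng(0)
    data_a = pd.DataFrame(rng.normal(0, 1, (5, 20)))
    data_b = pd.DataFrame(rng.normal(0, 1, (5, 20)))
    data_a[0] = 1.0  # constant, mean difference 1
    data_b[0] = 0.0
    res = mk.moderated_t(data_a, data_b)
    assert np.isfinite(res["t_mod"].iloc[0])
    assert res["t_mod"].iloc[0] > 0


def test_insufficient_samples_give_na():
    A = pd.DataFrame({"r": [1.0, np.nan, np.nan]})
    B = pd.DataFrame({"r": [0.0, 0.5, 1.0]})
    res = mk.moderated_t(A, B)
    assert np.isnan(res["t_mod"].iloc[0])


def test_null_pvalues_super_uniform():
    """Type-I error of the moderated t at alpha = 0.01 over 2000 null regions."""
    rng = np.random.default_rng(99)
    A = pd.DataFrame(rng.normal(0, 1, (10, 2000)))
    B = pd.DataFrame(rng.normal(0, 1, (10, 2000)))
    res = mk.moderated_t(A, B)
    alpha = 0.01
    rate = (res["p_value"] < alpha).mean()
    mc_se = np.sqrt(alpha * (1 - alpha) / 2000)
    assert rate <= alpha + 3 * mc_se


def test_bh_matches_brute_force_step_up():
    """BH-adjusted p equal a literal step-up implementation on random vectors."""
    rng = np.random.default_rng(3)
    for n in (1, 5, 100, 1000):
        p = rng.uniform(0, 1, n)
        from statsmodels.stats.multitest import multipletests

        ours = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        brute = np.empty(n)
        prev = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            val = min(prev, p[i] * n / (rank + 1))
            brute[i] = val
            prev = val
        np.testing.assert_allclose(ours, brute, rtol=1e-12)


# ------------------------------------------------------------ selection
def _results_frame(p, lfc, fdr=None):
    n = len(p)
    df = pd.DataFrame(
        {
            "logFC": lfc,
            "t_mod": np.ones(n),
            "df_total": np.full(n, 10.0),
            "p_value": p,
            "fdr": fdr if fdr is not None else p,
            "n_a": 5,
            "n_b": 5,
        },
        index=pd.Index([f"m{i:03d}" for i in range(n)], name="region_id"),
    )
    return df


def test_select_top_dm_ranking_and_truncation():
    rng = np.random.default_rng(7)
    p = rng.uniform(0, 0.005, 12)
    res = _results_frame(p, lfc=np.full(12, 2.0))
    top = mk.select_top_dm(res, "hyper", top_n=10)
    expected = list(res.sort_values("p_value").index[:10])
    assert top == expected


def test_select_top_dm_filters():
    res = _results_frame([1e-5, 1e-5, 1e-5], lfc=[2.0, 0.5, -2.0], fdr=[1e-4, 1e-4, 1e-4])
    assert mk.select_top_dm(res, "hyper") == ["m000"]
    assert mk.select_top_dm(res, "hypo") == ["m002"]
    res_bad_fdr = _results_frame([1e-5] * 3, lfc=[2.0] * 3, fdr=[0.5] * 3)
    assert mk.select_top_dm(res_bad_fdr, "hyper") == []


def test_directional_sets_disjoint():
    rng = np.random.default_rng(8)
    lfc = rng.normal(0, 3, 50)
    res = _results_frame(np.full(50, 1e-6), lfc=lfc)
    up = set(mk.select_top_dm(res, "hyper"))
    down = set(mk.select_top_dm(res, "hypo"))
    assert not up & down


# ------------------------------------------------------------ set algebra
def test_derive_specific_sets_example():
    out = mk.derive_specific_sets({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
    assert out["tissue_specific"] == {"b"}
    assert out["cancer_specific"] == set()


def test_derive_specific_sets_edges():
    assert mk.derive_specific_sets({"a", "b"}, {"b"}, set())["tissue_specific"] == {"b"}
    assert mk.derive_specific_sets({"a"}, {"b"}, {"c"}) == {
        "tissue_specific": frozenset(),
        "cancer_specific": frozenset(),
    }


def test_set_algebra_idempotent_and_order_free():
    th, nh, tn = frozenset("abcde"), frozenset("bcd"), frozenset("ce")
    once = mk.derive_specific_sets(th, nh, tn)
    again = mk.derive_specific_sets(frozenset(th), frozenset(nh), frozenset(tn))
    assert once == again


def _stable():
    return StableRegionSets(
        unmethylated_ids=frozenset({"u1", "u2", "u3"}),
        methylated_ids=frozenset({"h1", "h2", "h3"}),
    )


def test_assemble_marker_sets_structure():
    comps_u = {"colon": mk.ComparisonSets(frozenset({"u1", "u2"}), frozenset({"u1"}), frozenset({"u2"}))}
    comps_m = {"colon": mk.ComparisonSets(frozenset({"h1", "h2"}), frozenset({"h1", "h2"}), frozenset({"h2"}))}
    sets = mk.assemble_marker_sets(_stable(), comps_u, comps_m)
    assert sets.detection_set == {"u1", "u2", "u3"}
    # methylated-stratum tissue-specific = {h1}; TOO = detection + {h1}
    assert sets.too_set == {"u1", "u2", "u3", "h1"}
    assert sets.specific["colon"]["unmethylated"]["tissue_specific"] == {"u1"}
    assert sets.specific["colon"]["unmethylated"]["cancer_specific"] == {"u2"}


def test_assemble_external_tn_union():
    comps_u = {"colon": mk.ComparisonSets(frozenset({"u1", "u2"}), frozenset({"u1", "u2"}), frozenset())}
    comps_m = {"colon": mk.ComparisonSets(frozenset(), frozenset(), frozenset())}
    no_ext = mk.assemble_marker_sets(_stable(), comps_u, comps_m)
    assert no_ext.specific["colon"]["unmethylated"]["tissue_specific"] == {"u1", "u2"}
    with_ext = mk.assemble_marker_sets(
        _stable(), comps_u, comps_m, external_tn={"colon": {"u2"}}
    )
    # external T-N evidence reclassifies u2: no longer tissue-specific
    assert with_ext.specific["colon"]["unmethylated"]["tissue_specific"] == {"u1"}
    assert with_ext.specific["colon"]["unmethylated"]["cancer_specific"] == frozenset()


def test_assemble_rejects_ids_outside_universe():
    comps_u = {"colon": mk.ComparisonSets(frozenset({"zz"}), frozenset(), frozenset())}
    comps_m = {"colon": mk.ComparisonSets(frozenset(), frozenset(), frozenset())}
    with pytest.raises(ValueError, match="outside the stable universe"):
        mk.assemble_marker_sets(_stable(), comps_u, comps_m)
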