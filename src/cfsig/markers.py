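"""Differential analysis and marker-set assembly.

Differential methylation (on logit AMF) and differential copy number
(on log2 CNR) use an empirical-Bayes moderated t-statistic: per-region
pooled variances are shrunk toward a common prior estimated by
method-of-moments on the log variances (Smyth 2004), the moderated t is
the mean difference over the shrunken standard error, and p-values use
the augmented degrees of freedom d0 + d.  FDR control is
Benjamini-Hochberg.

Marker-set algebra: for each cancer type, three contrasts are run —
tumor tissue vs healthy cfDNA (T-H), adjacent normal tissue vs healthy
cfDNA (N-H), and tumor vs normal tissue (T-N).  Tissue-specific markers
are (T-H ∩ N-H) \\ T-N; cancer-specific markers are (T-H ∩ T-N) \\ N-H.
The detection marker set is all healthy-unmethylated blocks; the
tissue-of-origin set additionally includes tissue-specific markers from
the healthy-methylated stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Given per-region sample variances ``s2`` with residual degrees of
    freedom ``df``, returns ``(d0, s0_squared)``; ``d0`` may be ``inf``
    when the variances are consistent with a single common value.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need at least 2 regions with positive variance to fit prior")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = np.sum((e - e_mean) ** 2) / (n - 1.0)
    resid_var = e_var - np.mean(polygamma(1, df / 2.0))
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def moderated_t(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    min_per_group: int = 2,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-region moderated two-sample t-test (group A minus group B).

    Parameters
    ----------
    matrix_a, matrix_b
        Samples x regions matrices on the analysis scale (logit AMF or
        log2 CNR), columns aligned.  Missing values are allowed; each
        region uses its non-missing samples.
    min_per_group
        Regions with fewer non-missing samples than this in either
        group receive NA results.
    prior_df
        Force the prior degrees of freedom d0 (0 recovers the ordinary
        pooled t exactly; ``None`` estimates d0 from the data).

    Returns
    -------
    DataFrame indexed by region id with columns ``logFC, t_mod,
    df_total, p_value, fdr, n_a, n_b``.
    """
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValueError("region columns of the two groups are not aligned")
    a = matrix_a.to_numpy(dtype=np.float64)
    b = matrix_b.to_numpy(dtype=np.float64)
    n_a = np.sum(~np.isnan(a), axis=0).astype(float)
    n_b = np.sum(~np.isnan(b), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=0)
        mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=0)
        var_a = _nanvar_ddof1(a)
        var_b = _nanvar_ddof1(b)
    valid = (n_a >= min_per_group) & (n_b >= min_per_group)
    d = n_a + n_b - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n_a - 1.0) * var_a + (n_b - 1.0) * var_b) / d
    logfc = mean_a - mean_b

    d0, s0_sq = _resolve_prior(s2, d, valid, prior_df)

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.full_like(s2, np.inf)
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
        se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
        t_mod = logfc / se

    from scipy import stats

    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(t_mod)),
            2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isfinite(df_total), df_total, 1.0)),
        )
    p = np.where(valid & np.isfinite(t_mod), p, np.nan)
    t_mod = np.where(valid, t_mod, np.nan)
    logfc = np.where(valid, logfc, np.nan)

    fdr = np.full_like(p, np.nan)
    has_p = np.isfinite(p)
    if has_p.any():
        fdr[has_p] = multipletests(p[has_p], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "logFC": logfc,
            "t_mod": t_mod,
            "df_total": np.where(valid, df_total, np.nan),
            "p_value": p,
            "fdr": fdr,
            "n_a": n_a,
            "n_b": n_b,
        },
        index=pd.Index(matrix_a.columns, name="region_id"),
    )


def _resolve_prior(
    s2: np.ndarray, d: np.ndarray, valid: np.ndarray, prior_df: float | None
) -> tuple[float, float]:
    """Estimate (or honor a forced) variance prior (d0, s0^2)."""
    if prior_df is not None and prior_df == 0:
        return 0.0, 1.0  # s0_sq unused at d0 = 0
    ok = valid & np.isfinite(s2) & (s2 > 0)
    if prior_df is None:
        try:
            return _fit_variance_prior(s2[ok], d[ok])
        except ValueError:
            logger.warning("too few regions to estimate variance prior; using ordinary t")
            return 0.0, 1.0
    d0 = float(prior_df)
    z = np.log(s2[ok])
    e = z - digamma(d[ok] / 2.0) + np.log(d[ok] / 2.0)
    if np.isinf(d0):
        return d0, float(np.exp(e.mean()))
    return d0, float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))


def _nanvar_ddof1(x: np.ndarray) -> np.ndarray:
    n = np.sum(~np.isnan(x), axis=0).astype(float)
    out = np.full(x.shape[1], np.nan)
    ok = n >= 2
    if ok.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.nanvar(x, axis=0, ddof=1)
        out[ok] = v[ok]
    return out


def select_top_dm(
    results: pd.DataFrame,
    direction: str = "hyper",
    lfc_min: float = 1.0,
    fdr_max: float = 0.01,
    top_n: int = 10000,
) -> list[str]:
    """Select the top differential regions in one direction.

    Regions pass if ``sign * logFC > lfc_min`` (sign +1 for "hyper",
    -1 for "hypo") and ``fdr < fdr_max``; passing regions are ranked by
    p-value ascending, ties broken by \\|logFC\\| descending then region
    id, and truncated to ``top_n``.  Returns an ordered id list (may be
    empty).
    """
    sign = {"hyper": 1.0, "up": 1.0, "hypo": -1.0, "down": -1.0}.get(direction)
    if sign is None:
        raise ValueError(f"direction must be hyper/hypo, got {direction!r}")
    r = results.dropna(subset=["logFC", "p_value", "fdr"])
    passing = r[(sign * r["logFC"] > lfc_min) & (r["fdr"] < fdr_max)].copy()
    passing["abs_lfc"] = passing["logFC"].abs()
    passing = passing.sort_values(
        by=["p_value", "abs_lfc", "region_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return list(passing.index[:top_n])


@dataclass(frozen=True)
class ComparisonSets:
    """Selected marker ids for the three contrasts of one cancer type."""

    th: frozenset[str]
    nh: frozenset[str]
    tn: frozenset[str]


def derive_specific_sets(
    th: frozenset[str] | set[str],
    nh: frozenset[str] | set[str],
    tn: frozenset[str] | set[str],
) -> dict[str, frozenset[str]]:
    """Set algebra for tissue- and cancer-specific markers.

    tissue_specific = (T-H ∩ N-H) \\ T-N ;  cancer_specific = (T-H ∩ T-N) \\ N-H.
    """
    th, nh, tn = frozenset(th), frozenset(nh), frozenset(tn)
    return {
        "tissue_specific": (th & nh) - tn,
        "cancer_specific": (th & tn) - nh,
    }


@dataclass(frozen=True)
class MarkerSets:
    """Final marker sets with per-class provenance.

    ``specific[class][stratum]`` holds the tissue- and cancer-specific
    sets derived on each stable stratum ("unmethylated": hyper
    direction; "methylated": hypo direction).
    """

    detection_set: frozenset[str]
    too_set: frozenset[str]
    specific: dict[str, dict[str, dict[str, frozenset[str]]]] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.too_set >= self.detection_set:
            raise ValueError("TOO set must contain the detection set")


def assemble_marker_sets(
    stable_sets,
    comparisons_unmeth: dict[str, ComparisonSets],
    comparisons_meth: dict[str, ComparisonSets],
    external_tn: dict[str, set[str]] | None = None,
) -> MarkerSets:
    """Assemble detection and TOO marker sets from per-class contrasts.

    Parameters
    ----------
    stable_sets
        :class:`cfsig.methylation.StableRegionSets`.
    comparisons_unmeth, comparisons_meth
        Per cancer class, the selected T-H/N-H/T-N sets from the
        healthy-unmethylated stratum (hyper direction) and the
        healthy-methylated stratum (hypo direction).
    external_tn
        Optional externally supplied (e.g. public tumor-vs-normal array
        data) marker ids unioned into each class's T-N set before the
        set algebra.

    Returns
    -------
    :class:`MarkerSets` with detection set = all healthy-unmethylated
    ids and TOO set = detection set plus the union of methylated-stratum
    tissue-specific markers.
    """
    universe = {
        "unmethylated": frozenset(stable_sets.unmethylated_ids),
        "methylated": frozenset(stable_sets.methylated_ids),
    }
    external_tn = external_tn or {}
    specific: dict[str, dict[str, dict[str, frozenset[str]]]] = {}
    for stratum, comps in (("unmethylated", comparisons_unmeth), ("methylated", comparisons_meth)):
        for cls, cs in comps.items():
            ext = frozenset(external_tn.get(cls, frozenset()))
            for name, ids in (("T-H", cs.th), ("N-H", cs.nh), ("T-N", cs.tn)):
                stray = frozenset(ids) - universe[stratum]
                if stray:
                    raise ValueError(
                        f"{cls} {stratum} {name}: ids outside the stable universe: "
                        f"{sorted(stray)[:5]}"
                    )
            # external T-N ids (e.g. array-derived) may fall outside the universe;
            # they can only subtract from tissue-specific / add to cancer-specific
            specific.setdefault(cls, {})[stratum] = derive_specific_sets(
                cs.th, cs.nh, frozenset(cs.tn) | ext
            )

    detection = universe["unmethylated"]
    too_extra: frozenset[str] = frozenset()
    for cls, strata in specific.items():
        if "methylated" in strata:
            too_extra |= strata["methylated"]["tissue_specific"]
    return MarkerSets(detection_set=detection, too_set=detection | too_extra, specific=specific)
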