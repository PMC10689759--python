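"""Fragment-size ratio (FSR) features.

cfDNA fragments are dominated by a mononucleosomal mode near 167 bp;
tumor-derived fragments are enriched below it.  The short/long (S/L)
ratio quantifies that enrichment: short fragments are 80-150 bp, long
fragments 151-220 bp.  Per 100-kb bin the raw S/L ratio is normalized
by the chromosome-level ratio and log2-transformed; the global S/L
ratio (genome totals) summarizes a whole sample — its median across
healthy cohorts is about 0.2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SHORT_RANGE = (80, 150)
LONG_RANGE = (151, 220)


def classify_length(length: int | np.ndarray):
    """Classify fragment length(s) as "short", "long", or "excluded".

    Short: 80-150 bp inclusive; long: 151-220 bp inclusive; anything
    else is excluded.  Accepts a scalar (returns str) or an array
    (returns an object array of labels).
    """
    scalar = np.isscalar(length)
    arr = np.atleast_1d(np.asarray(length))
    out = np.full(arr.shape, "excluded", dtype=object)
    out[(arr >= SHORT_RANGE[0]) & (arr <= SHORT_RANGE[1])] = "short"
    out[(arr >= LONG_RANGE[0]) & (arr <= LONG_RANGE[1])] = "long"
    return out[0] if scalar else out


def compute_fsr_profile(
    fragments: pd.DataFrame,
    bins: pd.DataFrame,
    min_bin_count: int = 50,
) -> tuple[pd.DataFrame, float]:
    """Per-bin normalized S/L profile and the sample's global S/L ratio.

    Fragments (BED3-like) are assigned to bins by midpoint.  Bins with
    fewer than ``min_bin_count`` short+long fragments are NA.  The
    normalized ratio divides each bin's raw short/long ratio by its
    chromosome's total short/long ratio; the log2 of the normalized
    ratio is the classifier input.  A chromosome with zero long
    fragments has all its bins NA (warned).

    Returns
    -------
    (profile, global_ratio)
        ``profile`` is indexed by bin id with columns ``short, long,
        raw_ratio, norm_ratio, log2_ratio``; ``global_ratio`` is the
        genome-wide short/long count ratio.
    """
    from cfsig.copynumber import count_fragments

    lengths = fragments["end"] - fragments["start"]
    short_frags = fragments[(lengths >= SHORT_RANGE[0]) & (lengths <= SHORT_RANGE[1])]
    long_frags = fragments[(lengths >= LONG_RANGE[0]) & (lengths <= LONG_RANGE[1])]
    short = count_fragments(short_frags, bins).to_numpy(dtype=np.float64)
    long = count_fragments(long_frags, bins).to_numpy(dtype=np.float64)

    chrom = bins["chrom"].to_numpy()
    raw = np.full(len(bins), np.nan)
    norm = np.full(len(bins), np.nan)
    for ch in pd.unique(chrom):
        sel = chrom == ch
        chrom_short, chrom_long = short[sel].sum(), long[sel].sum()
        if chrom_long == 0:
            logger.warning("chromosome %s has zero long fragments; its bins are NA", ch)
            continue
        chrom_ratio = chrom_short / chrom_long
        ok = sel & (short > 0) & (long > 0) & (short + long >= min_bin_count)
        raw[ok] = short[ok] / long[ok]
        norm[ok] = raw[ok] / chrom_ratio
    with np.errstate(invalid="ignore", divide="ignore"):
        log2r = np.log2(norm)
    profile = pd.DataFrame(
        {
            "short": short.astype(np.int64),
            "long": long.astype(np.int64),
            "raw_ratio": raw,
            "norm_ratio": norm,
            "log2_ratio": log2r,
        },
        index=pd.Index(bins["bin_id"].to_numpy(), name="bin_id"),
    )
    total_long = long.sum()
    if total_long == 0:
        raise ValueError("no long fragments in sample; global S/L undefined")
    global_ratio = float(short.sum() / total_long)
    return profile, global_ratio


def healthy_median_profile(
    profiles: list[pd.DataFrame] | dict[str, pd.DataFrame],
    max_na_frac: float = 0.5,
) -> pd.Series:
    """Bin-wise median of healthy normalized log2 FSR profiles.

    Bins NA in more than ``max_na_frac`` of the samples are NA in the
    reference.  Requires at least 3 profiles.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if len(profiles) < 3:
        raise ValueError(f"need >= 3 healthy profiles, got {len(profiles)}")
    mat = pd.concat([p["log2_ratio"] for p in profiles], axis=1)
    med = mat.median(axis=1, skipna=True)
    med[mat.isna().mean(axis=1) > max_na_frac] = np.nan
    med.name = "log2_ratio"
    return med


def profile_correlation(
    sample_profile: pd.Series | pd.DataFrame,
    reference_profile: pd.Series,
    min_shared_bins: int = 10,
) -> float:
    """Pearson correlation of a sample's log2 FSR profile with a reference.

    Computed over bins non-missing in both; fewer than
    ``min_shared_bins`` shared bins is an error.
    """
    if isinstance(sample_profile, pd.DataFrame):
        sample_profile = sample_profile["log2_ratio"]
    joined = pd.concat([sample_profile, reference_profile], axis=1, join="inner").dropna()
    if len(joined) < min_shared_bins:
        raise ValueError(f"only {len(joined)} jointly observed bins (< {min_shared_bins})")
    r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
    return float(r)
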