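"""Copy-number ratio (CNR) features from cfDNA fragment counts.

Fragments are counted into non-overlapping genomic bins (default 100 kb)
by midpoint, GC bias is corrected by median scaling within 1%-wide GC
strata, and counts are normalized to the autosomal median to yield a
per-bin linear copy-number ratio (1 = diploid).  The classifier input is
the *adjusted* CNR: counted from short (<150 bp) fragments, to enrich
tumor-derived molecules, with ratios inside the copy-neutral interval
[0.85, 1.05] suppressed to exactly 1.

Frequent copy-gain regions per cancer type are selected by a moderated-t
contrast of tumor vs normal tissue log2 CNR profiles; prostate cancer,
which lacks matched normal tissue, is contrasted against a pooled
composite of all other normals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cfsig import markers as _markers

logger = logging.getLogger(__name__)

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


def make_bins(
    chrom_sizes: dict[str, int],
    width: int = 100_000,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping bins of ``width`` bp.

    The final partial bin of each chromosome is kept and flagged
    (``partial``).  Bins whose overlap with the blacklist exceeds 50%
    of their length are ``masked``.

    Returns a DataFrame with columns ``bin_id, chrom, start, end,
    partial, masked`` (and a ``gc`` column once :func:`annotate_gc` has
    been applied).
    """
    if width < 1000:
        raise ValueError(f"bin width must be >= 1000 bp, got {width}")
    rows = []
    for chrom in chrom_sizes:
        size = int(chrom_sizes[chrom])
        if size < width:
            raise ValueError(f"chromosome {chrom} ({size} bp) shorter than bin width {width}")
        starts = np.arange(0, size, width, dtype=np.int64)
        for s in starts:
            e = min(s + width, size)
            rows.append((f"{chrom}:{s}-{e}", chrom, int(s), int(e), e - s < width))
    bins = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end", "partial"])
    masked = np.zeros(len(bins), dtype=bool)
    if blacklist is not None and len(blacklist):
        for i, row in bins.iterrows():
            bl = blacklist[blacklist["chrom"] == row["chrom"]]
            if not len(bl):
                continue
            ov = np.clip(
                np.minimum(bl["end"].to_numpy(), row["end"])
                - np.maximum(bl["start"].to_numpy(), row["start"]),
                0,
                None,
            ).sum()
            masked[i] = ov > 0.5 * (row["end"] - row["start"])
    bins["masked"] = masked
    return bins


def annotate_gc(bins: pd.DataFrame, fasta_path: str) -> pd.DataFrame:
    """Add a ``gc`` column (G+C fraction of each bin) from the reference."""
    from pyfaidx import Fasta

    fa = Fasta(fasta_path, read_ahead=None)
    gc = np.empty(len(bins))
    for chrom, grp in bins.groupby("chrom", sort=False):
        seq = str(fa[str(chrom)][:]).upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        cum = np.concatenate([[0], np.cumsum(is_gc)])
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        gc[grp.index] = (cum[e] - cum[s]) / (e - s)
    out = bins.copy()
    out["gc"] = gc
    return out


def count_fragments(
    fragments: pd.DataFrame,
    bins: pd.DataFrame,
    max_len: int | None = None,
) -> pd.Series:
    """Count fragments per bin by midpoint assignment.

    ``fragments`` is BED3-like (chrom, start, end).  If ``max_len`` is
    given, fragments with length >= ``max_len`` are excluded (the
    adjusted CNR uses ``max_len=150``: only fragments shorter than
    150 bp are counted).  Each fragment is counted at most once.

    Raises ``ValueError`` listing offending chromosomes if fragments
    reference chromosomes absent from the bin set.
    """
    known = set(bins["chrom"].unique())
    frag_chroms = set(fragments["chrom"].unique()) if len(fragments) else set()
    unknown = frag_chroms - known
    if unknown:
        raise ValueError(f"fragments on chromosomes without bins: {sorted(unknown)}")
    counts = np.zeros(len(bins), dtype=np.int64)
    if len(fragments):
        frags = fragments
        if max_len is not None:
            frags = frags[(frags["end"] - frags["start"]) < max_len]
        for chrom, grp in frags.groupby("chrom", sort=False):
            cb = bins[bins["chrom"] == chrom]
            # tiled bins: locate midpoint by dividing by the edge grid
            edges = np.concatenate([cb["start"].to_numpy(), [cb["end"].to_numpy()[-1]]])
            mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
            idx = np.searchsorted(edges, mids, side="right") - 1
            ok = (idx >= 0) & (idx < len(cb))
            np.add.at(counts, cb.index.to_numpy()[idx[ok]], 1)
    return pd.Series(counts, index=bins["bin_id"].to_numpy(), name="count")


def gc_correct_and_normalize(
    counts: pd.Series,
    bins: pd.DataFrame,
    gc_stratum_width: float = 0.01,
    min_stratum_bins: int = 20,
) -> pd.DataFrame:
    """GC-correct and median-normalize per-bin counts into a CNR profile.

    Bins are stratified by GC fraction in 1%-wide strata, adjacent
    strata being merged until each holds at least ``min_stratum_bins``
    unmasked bins; counts are scaled by global median / stratum median,
    then divided by the autosomal median to give a linear ratio
    (autosomal median exactly 1).  Masked bins, and bins in strata with
    zero median, are NA.

    Returns a DataFrame indexed by bin id with columns ``ratio`` and
    ``log2_ratio``.
    """
    if "gc" not in bins.columns:
        raise ValueError("bins lack a gc column; run annotate_gc first")
    usable = ~bins["masked"].to_numpy()
    if usable.sum() < 100:
        raise ValueError(f"need >= 100 unmasked bins, have {int(usable.sum())}")
    c = counts.to_numpy(dtype=np.float64)
    if not (c[usable] > 0).any():
        raise ValueError("all fragment counts are zero")

    gc = bins["gc"].to_numpy()
    strata = _gc_strata(gc, usable, gc_stratum_width, min_stratum_bins)
    global_med = np.median(c[usable])
    corrected = np.full(len(c), np.nan)
    for sid in np.unique(strata[strata >= 0]):
        members = (strata == sid) & usable
        med = np.median(c[members])
        if med > 0:
            corrected[members] = c[members] * global_med / med
    auto = usable & ~bins["chrom"].isin(SEX_CHROMS).to_numpy() & np.isfinite(corrected)
    auto_med = np.median(corrected[auto])
    if not auto_med > 0:
        raise ValueError("autosomal median of corrected counts is zero")
    ratio = corrected / auto_med
    ratio = np.where(ratio > 0, ratio, np.nan)  # zero-count bins are missing
    with np.errstate(invalid="ignore", divide="ignore"):
        log2r = np.log2(ratio)
    return pd.DataFrame(
        {"ratio": ratio, "log2_ratio": log2r},
        index=pd.Index(bins["bin_id"].to_numpy(), name="bin_id"),
    )


def _gc_strata(
    gc: np.ndarray, usable: np.ndarray, width: float, min_bins: int
) -> np.ndarray:
    """Assign each bin a GC-stratum id; strata merged rightward until big enough."""
    raw = np.clip((gc / width).astype(int), 0, int(1 / width))
    order = np.unique(raw[usable])
    mapping: dict[int, int] = {}
    current_members = 0
    current_id = 0
    for j, s in enumerate(order):
        mapping[s] = current_id
        current_members += int(((raw == s) & usable).sum())
        if current_members >= min_bins and j < len(order) - 1:
            current_id += 1
            current_members = 0
    # if the trailing stratum ended undersized, merge it into the previous one
    if current_members and current_members < min_bins and current_id > 0:
        for s, sid in mapping.items():
            if sid == current_id:
                mapping[s] = current_id - 1
    out = np.full(len(gc), -1, dtype=int)
    for s, sid in mapping.items():
        out[raw == s] = sid
    return out


def suppress_neutral(cnr: pd.DataFrame, lo: float = 0.85, hi: float = 1.05) -> pd.DataFrame:
    """Set linear ratios inside the closed copy-neutral interval to exactly 1.

    Values in [lo, hi] become 1.0 (log2 0); all others are unchanged.
    Applied to the normalized linear ratios before the log2 classifier
    input is taken.
    """
    if lo >= hi:
        raise ValueError(f"copy-neutral interval invalid: lo={lo} >= hi={hi}")
    out = cnr.copy()
    neutral = (out["ratio"] >= lo) & (out["ratio"] <= hi)
    out.loc[neutral, "ratio"] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["log2_ratio"] = np.log2(out["ratio"])
    return out


@dataclass(frozen=True)
class GainRegionSet:
    """Per-class frequently-gained bin ids with provenance."""

    by_class: dict[str, frozenset[str]]
    source: dict[str, dict[str, str]]  # class -> bin_id -> "internal" | "external"


DEFAULT_GAIN_THRESHOLDS = {
    "colon": {"lfc_min": 0.2, "fdr_max": 0.01},
    "liver": {"lfc_min": 0.2, "fdr_max": 0.01},
    "lung": {"lfc_min": 0.15, "fdr_max": 0.001},
    "prostate": {"lfc_min": 0.15, "fdr_max": 0.001},
}


def select_gain_regions(
    tumor_log2: dict[str, pd.DataFrame],
    normal_log2: dict[str, pd.DataFrame],
    thresholds_by_class: dict[str, dict[str, float]] | None = None,
    pooled_normals_for: frozenset[str] | set[str] = frozenset({"prostate"}),
    external_gains: dict[str, set[str]] | None = None,
) -> GainRegionSet:
    """Select bins with frequent copy-number gains per cancer type.

    ``tumor_log2[class]`` / ``normal_log2[class]`` are samples x bins
    log2 CNR matrices.  Classes in ``pooled_normals_for`` are contrasted
    against the concatenation of all available normal cohorts (composite
    normal); other classes require their own normals.  Thresholds
    default to log FC > 0.2 / FDR < 0.01 for colon and liver and
    log FC > 0.15 / FDR < 0.001 for lung and prostate.  Optional
    ``external_gains`` ids are unioned in with source tag "external".
    """
    thresholds_by_class = thresholds_by_class or DEFAULT_GAIN_THRESHOLDS
    external_gains = external_gains or {}
    pooled = (
        pd.concat(list(normal_log2.values()), axis=0) if normal_log2 else None
    )
    by_class: dict[str, frozenset[str]] = {}
    source: dict[str, dict[str, str]] = {}
    for cls, tum in tumor_log2.items():
        if cls in pooled_normals_for:
            if pooled is None:
                raise ValueError("pooled-normal contrast requested but no normals supplied")
            norm = pooled
        elif cls in normal_log2:
            norm = normal_log2[cls]
        else:
            raise ValueError(f"no normal cohort for class {cls!r}")
        thr = thresholds_by_class[cls]
        res = _markers.moderated_t(tum, norm[tum.columns])
        ids = _markers.select_top_dm(
            res,
            direction="hyper",
            lfc_min=thr["lfc_min"],
            fdr_max=thr["fdr_max"],
            top_n=len(res),
        )
        tags = {i: "internal" for i in ids}
        for i in external_gains.get(cls, set()):
            tags.setdefault(i, "external")
        by_class[cls] = frozenset(tags)
        source[cls] = tags
    return GainRegionSet(by_class=by_class, source=source)
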