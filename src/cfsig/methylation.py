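"""Block-level methylation quantification (AMF) and preprocessing.

The average methylation fraction of block *i* is

    AMF_i = sum_j C_j / sum_j (C_j + T_j),   j over the block's CpGs,

where C_j and T_j count cytosine (methylated) and thymine (converted,
unmethylated) base calls at CpG j.  A block's AMF is missing (NA) when
its mean per-CpG coverage — total base calls divided by the number of
CpGs in the block, uncovered CpGs included — is below 10x.

Downstream preprocessing: healthy-stable region calling (blocks whose
AMF is < 0.3 in at least 90% of healthy training samples are
*healthy-unmethylated*; > 0.7, *healthy-methylated*), a symmetric logit
transform with an epsilon clamp, and healthy-mean imputation of missing
values with discarding of markers missing in more than 10% of healthy
training controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cfsig.blocks import CpGBlock

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]


def _block_position_map(blocks: list[CpGBlock]) -> pd.DataFrame:
    """Map every block CpG (chrom, pos) to its block index."""
    chroms: list[str] = []
    pos: list[int] = []
    idx: list[int] = []
    for bi, b in enumerate(blocks):
        chroms.extend([b.chrom] * b.n_cpgs)
        pos.extend(b.cpg_positions)
        idx.extend([bi] * b.n_cpgs)
    return pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(pos, dtype=np.int64), "block_idx": idx}
    )


def aggregate_amf(
    records: pd.DataFrame,
    blocks: list[CpGBlock],
    min_mean_cov: float = 10.0,
) -> pd.DataFrame:
    """Aggregate per-CpG counts into block-level AMF values.

    Parameters
    ----------
    records
        Per-CpG counts with columns ``chrom, pos, n_meth, n_unmeth``
        (0-based C position).  Records at positions not belonging to any
        block are ignored (logged at debug level).
    blocks
        The block set defining aggregation units.  CpGs of a block with
        no record contribute zero to both sums but still count toward
        the block's CpG number in the mean-coverage rule.
    min_mean_cov
        Blocks whose mean per-CpG coverage is below this are NA.

    Returns
    -------
    DataFrame indexed by block id with columns ``sum_c, total,
    mean_cov, amf`` (amf is NaN where coverage is insufficient).
    """
    pos_map = _block_position_map(blocks)
    n_cpgs = np.array([b.n_cpgs for b in blocks], dtype=np.int64)

    sum_c = np.zeros(len(blocks), dtype=np.float64)
    total = np.zeros(len(blocks), dtype=np.float64)
    if len(records):
        meth = records["n_meth"].to_numpy(dtype=np.float64)
        unmeth = records["n_unmeth"].to_numpy(dtype=np.float64)
        if (meth < 0).any() or (unmeth < 0).any():
            raise ValueError("negative methylation counts")
        merged = records.merge(pos_map, on=["chrom", "pos"], how="left")
        orphan = merged["block_idx"].isna()
        if orphan.any():
            logger.debug("%d count records fell outside all blocks; ignored", int(orphan.sum()))
            merged = merged[~orphan]
        bi = merged["block_idx"].to_numpy(dtype=np.int64)
        np.add.at(sum_c, bi, merged["n_meth"].to_numpy(dtype=np.float64))
        np.add.at(
            total,
            bi,
            merged["n_meth"].to_numpy(dtype=np.float64)
            + merged["n_unmeth"].to_numpy(dtype=np.float64),
        )

    mean_cov = total / n_cpgs
    with np.errstate(invalid="ignore", divide="ignore"):
        amf = np.where(total > 0, sum_c / np.maximum(total, 1e-300), np.nan)
    amf = np.where(mean_cov >= min_mean_cov, amf, np.nan)
    return pd.DataFrame(
        {"sum_c": sum_c, "total": total, "mean_cov": mean_cov, "amf": amf},
        index=pd.Index([b.id for b in blocks], name="block_id"),
    )


def amf_matrix(
    sample_records: dict[str, pd.DataFrame],
    blocks: list[CpGBlock],
    min_mean_cov: float = 10.0,
) -> pd.DataFrame:
    """Build a samples x blocks AMF matrix from per-sample count tables."""
    cols = {
        sid: aggregate_amf(rec, blocks, min_mean_cov)["amf"]
        for sid, rec in sample_records.items()
    }
    mat = pd.DataFrame(cols).T
    mat.index.name = "sample_id"
    return mat


def logit_transform(values: pd.DataFrame | pd.Series, eps: float = 0.01):
    """Logit of AMF values after clamping into [eps, 1 - eps]; NA propagates."""
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must lie in (0, 0.5), got {eps}")
    clipped = values.clip(lower=eps, upper=1 - eps)
    return np.log(clipped / (1 - clipped))


@dataclass(frozen=True)
class StableRegionSets:
    """Block ids stably unmethylated / methylated across healthy training samples."""

    unmethylated_ids: frozenset[str]
    methylated_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.unmethylated_ids & self.methylated_ids:
            raise ValueError("stable sets must be disjoint")


def call_stable_regions(
    healthy_train_amf: pd.DataFrame,
    q: float = 0.90,
    low: float = 0.3,
    high: float = 0.7,
    min_nonmissing_frac: float = 0.8,
) -> StableRegionSets:
    """Call healthy-unmethylated and healthy-methylated blocks.

    A block is healthy-unmethylated iff at least fraction ``q`` of its
    non-missing healthy-training AMF values are below ``low``, and
    healthy-methylated iff at least ``q`` are above ``high``.  Blocks
    with fewer than ``min_nonmissing_frac`` non-missing values are
    excluded from both sets.

    ``healthy_train_amf`` is samples x blocks.
    """
    if healthy_train_amf.size == 0:
        raise ValueError("empty AMF matrix")
    if len(healthy_train_amf) < 5:
        raise ValueError(
            f"stable-region calling needs >= 5 healthy training samples, "
            f"got {len(healthy_train_amf)}"
        )
    n_obs = healthy_train_amf.notna().sum(axis=0)
    eligible = (n_obs / len(healthy_train_amf)) >= min_nonmissing_frac
    with np.errstate(invalid="ignore"):
        frac_low = (healthy_train_amf < low).sum(axis=0) / n_obs.replace(0, np.nan)
        frac_high = (healthy_train_amf > high).sum(axis=0) / n_obs.replace(0, np.nan)
    unmeth = frozenset(healthy_train_amf.columns[eligible & (frac_low >= q)])
    meth = frozenset(healthy_train_amf.columns[eligible & (frac_high >= q)])
    return StableRegionSets(unmethylated_ids=unmeth, methylated_ids=meth)


def impute_missing(
    matrix: pd.DataFrame,
    healthy_train_ids: list[str],
    max_missing_frac: float = 0.10,
) -> tuple[pd.DataFrame, list[str]]:
    """Healthy-mean imputation with high-missingness marker removal.

    Markers (columns) missing in more than ``max_missing_frac`` of the
    healthy training controls are discarded.  Remaining missing values —
    in any sample — are replaced by the mean over healthy training
    controls with observed values.

    Returns the imputed matrix (rows: all samples; columns: retained
    markers) and the list of dropped marker ids.
    """
    missing_rows = set(healthy_train_ids) - set(matrix.index)
    if missing_rows:
        raise ValueError(f"healthy training ids not in matrix: {sorted(missing_rows)}")
    healthy = matrix.loc[list(healthy_train_ids)]
    na_frac = healthy.isna().mean(axis=0)
    dropped = list(matrix.columns[na_frac > max_missing_frac])
    kept = matrix.drop(columns=dropped)
    healthy_kept = healthy.drop(columns=dropped)
    means = healthy_kept.mean(axis=0, skipna=True)
    if means.isna().any():
        bad = list(means.index[means.isna()])
        raise ValueError(f"markers with no observed healthy value cannot be imputed: {bad[:5]}")
    return kept.fillna(means), dropped


def read_methylation_counts(path: str) -> pd.DataFrame:
    """Read a bedGraph-dialect methylation count table.

    Columns: chrom, start, end, percent, n_meth, n_unmeth.  The percent
    column is ignored and recomputed downstream; ``start`` is taken as
    the 0-based C position.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "percent", "n_meth", "n_unmeth"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64),
            "n_meth": df["n_meth"].astype(np.int64),
            "n_unmeth": df["n_unmeth"].astype(np.int64),
        }
    )


def write_methylation_counts(records: pd.DataFrame, path: str) -> None:
    """Write per-CpG counts in the 6-column bedGraph dialect."""
    total = records["n_meth"] + records["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * records["n_meth"] / total, 0.0)
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["pos"],
            "end": records["pos"] + 1,
            "percent": np.round(pct, 2),
            "n_meth": records["n_meth"],
            "n_unmeth": records["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.2f")
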