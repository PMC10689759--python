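"""CpG-block region construction.

The unit of methylation quantification is the *CpG block*: a run of three
or more CpG sites in which consecutive sites are no more than 100 bp
apart.  Runs spanning 1 kb or more are divided into similar-sized
sub-blocks.  Blocks are built from a reference scan, optionally filtered
by a per-CpG coverage mask (sites with median healthy-training coverage
<= 3x are discarded before segmentation) and a genomic blacklist (blocks
overlapping a blacklisted interval by >= 1 bp are dropped), and sex
chromosomes are excluded by default.

Coordinates are 0-based half-open throughout; a block starts at its first
CpG's C and ends just past its last CpG's G (last position + 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass(frozen=True)
class CpGBlock:
    """A clustered-CpG genomic interval (0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.cpg_positions) < 1:
            raise ValueError(f"block {self.id}: no CpG positions")
        if self.start != self.cpg_positions[0] or self.end != self.cpg_positions[-1] + 2:
            raise ValueError(f"block {self.id}: bounds inconsistent with CpG positions")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def span(self) -> int:
        return self.end - self.start


def scan_cpg_sites(fasta_path: str) -> dict[str, np.ndarray]:
    """Scan a FASTA file for CG dinucleotides on the + strand.

    The scan is case-insensitive; IUPAC ambiguity codes never match.
    Returns, per chromosome, the sorted 0-based positions of the C of
    each CG.

    Raises
    ------
    ValueError
        If the FASTA is unreadable or contains no sequence.
    """
    try:
        fa = Fasta(fasta_path, rebuild=True, read_ahead=None)
    except Exception as exc:  # pyfaidx raises several types for bad input
        raise ValueError(f"cannot read FASTA {fasta_path!r}: {exc}") from exc
    if len(fa.keys()) == 0:
        raise ValueError(f"FASTA {fasta_path!r} contains no sequences")
    out: dict[str, np.ndarray] = {}
    for name in fa.keys():
        seq = str(fa[name][:]).upper()
        out[name] = scan_cpg_in_sequence(seq)
    return out


def scan_cpg_in_sequence(seq: str) -> np.ndarray:
    """Return sorted 0-based positions ``p`` with ``seq[p:p+2] == "CG"``."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    is_c = arr[:-1] == ord("C")
    is_g = arr[1:] == ord("G")
    return np.flatnonzero(is_c & is_g).astype(np.int64)


def _split_run(positions: np.ndarray, max_len: int, min_cpgs: int) -> list[np.ndarray]:
    """Split one CpG run into sub-runs each spanning < ``max_len`` bp.

    The run is cut at inter-CpG boundaries into ``k = ceil(span/max_len)``
    pieces with CpG counts as equal as possible; pieces left with fewer
    than ``min_cpgs`` CpGs are merged into their left neighbor.  Pieces
    still spanning >= max_len (possible for very uneven spacing) are
    split again recursively.
    """
    span = positions[-1] + 2 - positions[0]
    if span < max_len:
        return [positions]
    k = min(math.ceil(span / max_len), len(positions))
    pieces = [p for p in np.array_split(positions, k) if p.size > 0]
    # merge undersized pieces leftward
    merged: list[np.ndarray] = []
    for piece in pieces:
        if merged and piece.size < min_cpgs:
            merged[-1] = np.concatenate([merged[-1], piece])
        else:
            merged.append(piece)
    if merged and merged[0].size < min_cpgs and len(merged) > 1:
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged = merged[1:]
    out: list[np.ndarray] = []
    for piece in merged:
        piece_span = piece[-1] + 2 - piece[0]
        if piece_span >= max_len and piece.size >= 2 * min_cpgs and piece.size < len(positions):
            out.extend(_split_run(piece, max_len, min_cpgs))
        else:
            out.append(piece)
    return out


def build_blocks(
    cpg_positions: dict[str, np.ndarray],
    coverage_mask: pd.DataFrame | None = None,
    blacklist: pd.DataFrame | None = None,
    excluded_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS,
    max_gap: int = 100,
    min_cpgs: int = 3,
    max_len: int = 1000,
    min_mask_cov: float = 3.0,
) -> list[CpGBlock]:
    """Segment per-chromosome CpG positions into CpG blocks.

    Parameters
    ----------
    cpg_positions
        Per-chromosome sorted 0-based C positions of CG dinucleotides.
    coverage_mask
        Optional table (chrom, pos, median_cov); CpGs whose median
        healthy-training coverage is <= ``min_mask_cov`` are removed
        before segmentation.
    blacklist
        Optional BED-like table (chrom, start, end), half-open; blocks
        overlapping any interval by >= 1 bp are dropped.
    excluded_chroms
        Chromosomes dropped entirely (default: sex chromosomes).
    max_gap, min_cpgs, max_len
        A run requires consecutive CpG gaps <= ``max_gap`` and at least
        ``min_cpgs`` sites; runs spanning >= ``max_len`` bp are split.

    Returns
    -------
    list of :class:`CpGBlock`, sorted and non-overlapping.
    """
    mask_lookup: dict[str, set[int]] = {}
    if coverage_mask is not None and len(coverage_mask):
        low = coverage_mask[coverage_mask["median_cov"] <= min_mask_cov]
        for chrom, grp in low.groupby("chrom"):
            mask_lookup[str(chrom)] = set(grp["pos"].astype(int))

    bl_lookup: dict[str, np.ndarray] = {}
    if blacklist is not None and len(blacklist):
        for chrom, grp in blacklist.groupby("chrom"):
            ivs = grp[["start", "end"]].to_numpy(dtype=np.int64)
            bl_lookup[str(chrom)] = ivs[np.argsort(ivs[:, 0])]

    result: list[CpGBlock] = []
    for chrom in sorted(cpg_positions):
        if chrom in excluded_chroms:
            continue
        pos = np.asarray(cpg_positions[chrom], dtype=np.int64)
        if pos.size == 0:
            continue
        if chrom in mask_lookup:
            keep = ~np.isin(pos, np.fromiter(mask_lookup[chrom], dtype=np.int64))
            pos = pos[keep]
        if pos.size == 0:
            continue
        # split into runs at gaps > max_gap
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for run in np.split(pos, breaks):
            if run.size < min_cpgs:
                continue
            for piece in _split_run(run, max_len, min_cpgs):
                start = int(piece[0])
                end = int(piece[-1]) + 2
                if chrom in bl_lookup and _overlaps_any(start, end, bl_lookup[chrom]):
                    continue
                result.append(
                    CpGBlock(
                        id=f"{chrom}:{start}-{end}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        cpg_positions=tuple(int(p) for p in piece),
                    )
                )
    return result


def _overlaps_any(start: int, end: int, intervals: np.ndarray) -> bool:
    """True if [start, end) overlaps any sorted half-open interval by >= 1 bp."""
    i = np.searchsorted(intervals[:, 0], end, side="left")
    return bool((intervals[:i, 1] > start).any())


def blocks_to_frame(blocks: list[CpGBlock]) -> pd.DataFrame:
    """Tabulate blocks as a BED4-like DataFrame (chrom, start, end, id)."""
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start": [b.start for b in blocks],
            "end": [b.end for b in blocks],
            "id": [b.id for b in blocks],
        }
    )


def write_blocks_bed(blocks: list[CpGBlock], path: str) -> None:
    """Write blocks as BED4 (chrom, start, end, id), tab-separated."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.id}\n")


def read_blocks_bed(path: str) -> pd.DataFrame:
    """Read a BED4 block file; returns a sorted DataFrame.

    Unsorted input is sorted with a warning.  Malformed lines (wrong
    column count, non-integer or negative coordinates, end <= start)
    raise :class:`ValueError` naming the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            chrom, start_s, end_s, block_id = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            rows.append((chrom, start, end, block_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    sorted_df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        logger.warning("block BED %s was unsorted; sorted on read", path)
    return sorted_df
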