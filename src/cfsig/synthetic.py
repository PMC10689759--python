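"""Synthetic cfDNA cohort generator.

Real multi-cancer screening cohorts are not publicly available, so this
module generates cohorts with the statistical structure the analysis
assumes, together with full ground truth:

* a toy reference genome whose CpGs occur in clusters (so CpG blocks
  exist), written as FASTA;
* per-class *archetypes*: true block methylation for healthy plasma,
  tumor tissue, and adjacent normal tissue of each cancer type, with
  planted hyper-/hypomethylated markers (tissue-specific markers are
  shared by tumor and normal tissue of a class; cancer-specific markers
  are tumor-only), planted copy-number gain segments, and
  fragment-length mixture parameters;
* per-sample data: per-CpG methylation counts (negative-binomial
  coverage scaled by the local copy ratio ``1 + f(c/2 - 1)``,
  beta-binomial methylated counts with mean
  ``(1-f)*AMF_healthy + f*AMF_tumor``) and fragment records (lengths
  from a tumor-fraction mixture of two three-component length models,
  genomic placement proportional to copy ratio times an optional GC
  bias factor).

The healthy fragment-length model is a three-component mixture —
sub-nucleosomal component near 120 bp, mononucleosome mode at 167 bp
(sd 10), dinucleosome mode at 334 bp — with weights calibrated so the
median global short(80-150)/long(151-220) count ratio of a healthy
cohort is ~0.2.  The tumor model shifts the mononucleosome mode to
145 bp and doubles the sub-nucleosomal weight.

Everything is deterministic given seeds: identical design, identical
bytes on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cfsig import methylation as _meth
from cfsig.blocks import CpGBlock, scan_cpg_in_sequence

CANCER_CLASSES = ("colon", "liver", "lung", "prostate")
ALL_CLASSES = ("healthy",) + CANCER_CLASSES

#: stage -> central tumor fraction; realized f is drawn uniformly from
#: [0.5x, 1.5x] of the central value (override via make_cohort_design)
DEFAULT_STAGE_TUMOR_FRACTION = {1: 0.01, 2: 0.03, 3: 0.10, 4: 0.30}


@dataclass(frozen=True)
class FragLenParams:
    """Three-component normal mixture over fragment length (bp)."""

    weights: tuple[float, float, float]
    locs: tuple[float, float, float]
    scales: tuple[float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("fragment mixture weights must sum to 1")


# healthy weights calibrated to a global S/L ratio of ~0.2
HEALTHY_FRAG_PARAMS = FragLenParams(
    weights=(0.108, 0.742, 0.150), locs=(120.0, 167.0, 334.0), scales=(15.0, 10.0, 25.0)
)
# tumor: mononucleosome mode shifted short, sub-nucleosomal weight doubled
TUMOR_FRAG_PARAMS = FragLenParams(
    weights=(0.216, 0.634, 0.150), locs=(120.0, 145.0, 334.0), scales=(15.0, 10.0, 25.0)
)


@dataclass(frozen=True)
class ReferenceTruth:
    """Ground truth for a generated reference genome."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_cpgs(self) -> int:
        return int(sum(len(v) for v in self.cpg_positions.values()))


@dataclass(frozen=True)
class ClassArchetype:
    """True per-block methylation and genomic state for one class."""

    class_label: str
    block_amf: np.ndarray = field(repr=False)
    cnv_segments: tuple[tuple[str, int, int, int], ...]  # (chrom, start, end, cn)
    frag_len_params: FragLenParams

    def __post_init__(self) -> None:
        if ((self.block_amf < 0) | (self.block_amf > 1)).any():
            raise ValueError("block_amf outside [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, cn in self.cnv_segments:
            if cn < 0:
                raise ValueError("copy number must be >= 0")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{self.class_label}: overlapping CNV segments on {chrom}"
                    )


@dataclass(frozen=True)
class MarkerTruth:
    """Planted marker ids per cancer class.

    ``markers[class]`` has keys ``hyper_tissue, hyper_cancer,
    hypo_tissue, hypo_cancer`` (block-id frozensets); ``gain_segments``
    holds the planted copy-gain intervals per class.
    """

    markers: dict[str, dict[str, frozenset[str]]]
    gain_segments: dict[str, tuple[tuple[str, int, int, int], ...]]

    def planted(self, cls: str, category: str, direction: str) -> frozenset[str]:
        return self.markers[cls][f"{direction}_{category}"]


def make_reference(
    seed: int,
    n_chrom: int = 2,
    chrom_length_bp: int = 1_000_000,
    cpg_cluster_rate: float = 2e-4,
    fasta_path: str | None = None,
) -> tuple[ReferenceTruth, dict[str, str]]:
    """Generate a toy reference with clustered CpGs.

    ``cpg_cluster_rate`` is the expected number of CpG clusters per bp;
    each cluster holds 3-12 CpGs spaced 4-60 bp apart, so every cluster
    can seed a CpG block.  Background sequence is scrubbed of CG
    dinucleotides, making the planted clusters the only CpGs.

    Returns the truth object and the per-chromosome sequences; if
    ``fasta_path`` is given the FASTA is also written (byte-identical
    across runs with the same arguments).
    """
    if chrom_length_bp < 10_000:
        raise ValueError("chrom_length_bp must be >= 10,000")
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, str] = {}
    positions: dict[str, np.ndarray] = {}
    names = tuple(f"chr{i + 1}" for i in range(n_chrom))
    for name in names:
        arr = rng.choice(letters, size=chrom_length_bp)
        # scrub background CG dinucleotides
        cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        arr[1:][cg] = ord("A")
        n_clusters = rng.poisson(max(cpg_cluster_rate, 0.0) * chrom_length_bp)
        starts = np.sort(rng.integers(100, chrom_length_bp - 2000, size=n_clusters))
        prev_end = -10_000
        for s in starts:
            if s < prev_end + 200:  # keep clusters separated
                continue
            n_cpg = int(rng.integers(3, 13))
            gaps = rng.integers(4, 61, size=n_cpg - 1)
            pos = s + np.concatenate([[0], np.cumsum(gaps)])
            if pos[-1] + 2 > chrom_length_bp:
                continue
            arr[pos] = ord("C")
            arr[pos + 1] = ord("G")
            prev_end = int(pos[-1]) + 2
        seq = arr.tobytes().decode("ascii")
        seqs[name] = seq
        positions[name] = scan_cpg_in_sequence(seq)
    truth = ReferenceTruth(
        chrom_names=names,
        chrom_lengths={n: chrom_length_bp for n in names},
        cpg_positions=positions,
    )
    if truth.n_cpgs == 0:
        raise ValueError(
            "reference contains no CpGs; increase chrom_length_bp or cpg_cluster_rate"
        )
    if fasta_path is not None:
        write_fasta(seqs, fasta_path)
    return truth, seqs


def write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> None:
    """Write sequences as wrapped FASTA (deterministic bytes)."""
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _default_cnv_segments(
    chrom_sizes: dict[str, int],
) -> dict[str, tuple[tuple[str, int, int, int], ...]]:
    """Two non-overlapping gain segments (cn 4 and cn 3) per cancer class.

    Segments are laid out deterministically in distinct genome slots so
    classes have distinct copy-number signatures.
    """
    chroms = list(chrom_sizes)
    slots: list[tuple[str, int, int]] = []
    per_chrom = max(1, -(-8 // len(chroms)))  # ceil
    for chrom in chroms:
        size = chrom_sizes[chrom]
        slot_w = size // (per_chrom + 1)
        for j in range(per_chrom):
            s = int((j + 0.5) * slot_w)
            slots.append((chrom, s, min(s + slot_w // 2, size)))
    out: dict[str, tuple[tuple[str, int, int, int], ...]] = {}
    for i, cls in enumerate(CANCER_CLASSES):
        a = slots[(2 * i) % len(slots)]
        b = slots[(2 * i + 1) % len(slots)]
        segs = [(a[0], a[1], a[2], 4)]
        if b != a:
            segs.append((b[0], b[1], b[2], 3))
        out[cls] = tuple(segs)
    return out


def make_archetypes(
    seed: int,
    blocks: list[CpGBlock],
    chrom_sizes: dict[str, int],
    n_tissue_markers: int = 40,
    n_cancer_markers: int = 40,
    effect_logit: float = 3.0,
    cnv_spec: dict[str, tuple[tuple[str, int, int, int], ...]] | None = None,
    frag_spec: dict[str, FragLenParams] | None = None,
) -> tuple[dict[str, dict[str, ClassArchetype]], MarkerTruth]:
    """Build class archetypes with planted markers and CNV gains.

    Healthy block AMF is bimodal (logit modes near -3.5 and +3.5 plus
    intermediate mass).  Per cancer class, ``n_tissue_markers``
    tissue-specific and ``n_cancer_markers`` cancer-specific markers
    are planted, split evenly between hypermethylated markers (in
    healthy-unmethylated blocks) and hypomethylated markers (in
    healthy-methylated blocks); planted marker sets are disjoint across
    classes and categories.  Hyper markers raise logit(AMF) by at least
    ``effect_logit`` in the class's tumor archetype (and normal-tissue
    archetype iff tissue-specific); hypo markers are sign-flipped.

    Returns ``archetypes[class] = {"tumor": ..., "normal": ...}`` (for
    "healthy" a single entry "cfdna") and the :class:`MarkerTruth`.
    """
    rng = np.random.default_rng(seed)
    n_blocks = len(blocks)
    comp = rng.choice(3, size=n_blocks, p=[0.42, 0.42, 0.16])
    logit = np.where(
        comp == 0,
        rng.normal(-3.5, 0.5, n_blocks),
        np.where(comp == 1, rng.normal(3.5, 0.5, n_blocks), rng.normal(0.0, 1.2, n_blocks)),
    )
    healthy_amf = 1.0 / (1.0 + np.exp(-logit))
    block_ids = np.array([b.id for b in blocks])

    low_pool = list(np.flatnonzero(healthy_amf < 0.25))
    high_pool = list(np.flatnonzero(healthy_amf > 0.75))
    rng.shuffle(low_pool)
    rng.shuffle(high_pool)
    n_hyper = n_tissue_markers // 2 + n_cancer_markers // 2
    n_hypo = n_tissue_markers - n_tissue_markers // 2 + n_cancer_markers - n_cancer_markers // 2
    if len(low_pool) < 4 * n_hyper or len(high_pool) < 4 * n_hypo:
        raise ValueError(
            "not enough stable blocks to plant the requested markers: "
            f"{len(low_pool)} low / {len(high_pool)} high available"
        )

    cnv = cnv_spec or _default_cnv_segments(chrom_sizes)
    frag_spec = frag_spec or {"healthy": HEALTHY_FRAG_PARAMS, "tumor": TUMOR_FRAG_PARAMS}

    def take(pool: list[int], n: int) -> list[int]:
        out, pool[:] = pool[:n], pool[n:]
        return out

    archetypes: dict[str, dict[str, ClassArchetype]] = {
        "healthy": {
            "cfdna": ClassArchetype(
                class_label="healthy",
                block_amf=healthy_amf,
                cnv_segments=(),
                frag_len_params=frag_spec["healthy"],
            )
        }
    }
    markers: dict[str, dict[str, frozenset[str]]] = {}
    gains: dict[str, tuple[tuple[str, int, int, int], ...]] = {}
    for cls in CANCER_CLASSES:
        tumor_logit = logit.copy()
        normal_logit = logit.copy()
        sets: dict[str, frozenset[str]] = {}
        for direction, pool, sign in (("hyper", low_pool, 1.0), ("hypo", high_pool, -1.0)):
            n_t = n_tissue_markers // 2 if direction == "hyper" else n_tissue_markers - n_tissue_markers // 2
            n_c = n_cancer_markers // 2 if direction == "hyper" else n_cancer_markers - n_cancer_markers // 2
            tissue_idx = take(pool, n_t)
            cancer_idx = take(pool, n_c)
            for idx_list, category in ((tissue_idx, "tissue"), (cancer_idx, "cancer")):
                shift = sign * (effect_logit + rng.uniform(0.0, 0.5, size=len(idx_list)))
                tumor_logit[idx_list] = logit[idx_list] + shift
                if category == "tissue":
                    normal_logit[idx_list] = logit[idx_list] + shift
                sets[f"{direction}_{category}"] = frozenset(block_ids[idx_list])
        markers[cls] = sets
        gains[cls] = tuple(cnv[cls])
        archetypes[cls] = {
            "tumor": ClassArchetype(
                class_label=cls,
                block_amf=1.0 / (1.0 + np.exp(-tumor_logit)),
                cnv_segments=tuple(cnv[cls]),
                frag_len_params=frag_spec["tumor"],
            ),
            "normal": ClassArchetype(
                class_label=cls,
                block_amf=1.0 / (1.0 + np.exp(-normal_logit)),
                cnv_segments=(),
                frag_len_params=frag_spec["healthy"],
            ),
        }
    return archetypes, MarkerTruth(markers=markers, gain_segments=gains)


def _copy_ratio_at(
    chrom: np.ndarray, pos: np.ndarray, segments, f: float
) -> np.ndarray:
    """Local coverage ratio 1 + f(c/2 - 1) at given positions."""
    cr = np.ones(len(pos), dtype=np.float64)
    for seg_chrom, s, e, cn in segments:
        sel = (chrom == seg_chrom) & (pos >= s) & (pos < e)
        cr[sel] = 1.0 + f * (cn / 2.0 - 1.0)
    return cr


def simulate_methylation_counts(
    background: ClassArchetype,
    signal: ClassArchetype | None,
    f: float,
    mean_depth: float,
    blocks: list[CpGBlock],
    overdispersion: float = 0.02,
    nb_size: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-CpG methylation count table for one sample.

    The sample is a mixture of ``background`` (weight 1-f) and
    ``signal`` (weight f; pass None for a pure-background sample).
    Per-CpG coverage is negative-binomial with mean
    ``mean_depth * (1 + f(c/2 - 1))`` (c from the signal archetype's
    CNV segments) and dispersion size ``nb_size``; methylated counts
    are beta-binomial with mean ``(1-f)*AMF_bg + f*AMF_sig`` and
    intraclass correlation ``overdispersion``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"tumor fraction must lie in [0, 1], got {f}")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    sig = signal if signal is not None else background

    chroms_l: list[str] = []
    pos_l: list[int] = []
    m_l: list[np.ndarray] = []
    for bi, b in enumerate(blocks):
        chroms_l.extend([b.chrom] * b.n_cpgs)
        pos_l.extend(b.cpg_positions)
        m = (1.0 - f) * background.block_amf[bi] + f * sig.block_amf[bi]
        m_l.append(np.full(b.n_cpgs, m))
    chrom = np.array(chroms_l)
    pos = np.array(pos_l, dtype=np.int64)
    m = np.concatenate(m_l) if m_l else np.empty(0)

    cr = _copy_ratio_at(chrom, pos, sig.cnv_segments, f)
    mu = mean_depth * cr
    p_nb = nb_size / (nb_size + mu)
    cov = rng.negative_binomial(nb_size, p_nb)

    rho = overdispersion
    m_c = np.clip(m, 1e-9, 1 - 1e-9)
    a = m_c * (1.0 / rho - 1.0)
    bpar = (1.0 - m_c) * (1.0 / rho - 1.0)
    p_bb = rng.beta(a, bpar)
    n_meth = rng.binomial(cov, p_bb)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "n_meth": n_meth.astype(np.int64),
            "n_unmeth": (cov - n_meth).astype(np.int64),
        }
    )


def logistic_gc_bias(strength: float = 1.0, center: float = 0.40, slope: float = 10.0):
    """A per-bin GC bias factor: logistic in GC, scaled by ``strength``.

    strength 0 -> flat (factor 1 everywhere).
    """

    def factor(gc: np.ndarray) -> np.ndarray:
        logistic = 1.0 / (1.0 + np.exp(-slope * (np.asarray(gc) - center)))
        return 1.0 + strength * (logistic - 0.5)

    return factor


def regional_short_modulation(
    n_bins: int, amplitude: float = 0.4, seed: int = 101
) -> np.ndarray:
    """Fixed per-bin multiplier on the healthy short-component weight.

    Healthy cfDNA has a *shared* regional fragmentation profile: some
    bins are consistently short-enriched across individuals.  This
    lognormal pattern (unit mean) is a property of the reference, not
    of a sample, so the default seed is a constant — every sample drawn
    over the same bin set sees the same pattern.  Tumor-origin
    fragments do not follow it, which is what makes a cancer sample's
    regional S/L profile decorrelate from the healthy median profile as
    tumor fraction grows.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, n_bins)
    return np.exp(amplitude * z - amplitude**2 / 2.0)


def simulate_fragments(
    background: ClassArchetype,
    signal: ClassArchetype | None,
    f: float,
    n_fragments: int,
    bins: pd.DataFrame,
    chrom_sizes: dict[str, int],
    gc_bias=None,
    seed: int = 0,
    bin_short_modulation: np.ndarray | str | None = "auto",
) -> pd.DataFrame:
    """Simulate BED3 fragment records for one sample.

    Fragment lengths are drawn from the (1-f)/f mixture of the
    background and signal length models; genomic placement assigns each
    fragment's midpoint to a bin with probability proportional to the
    local copy ratio times the optional GC-bias factor, then uniformly
    within the bin.  Background-origin fragments additionally modulate
    their short-component weight by the shared regional pattern of
    :func:`regional_short_modulation` ("auto"; pass None to disable or
    an array to override).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"tumor fraction must lie in [0, 1], got {f}")
    rng = np.random.default_rng(seed)
    sig = signal if signal is not None else background

    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    chrom = bins["chrom"].to_numpy()
    weights = (bins["end"] - bins["start"]).to_numpy(dtype=np.float64) / (
        bins["end"] - bins["start"]
    ).max()
    weights = weights * _copy_ratio_at(chrom, mid, sig.cnv_segments, f)
    if gc_bias is not None:
        if "gc" not in bins.columns:
            raise ValueError("bins lack a gc column required for GC bias")
        weights = weights * gc_bias(bins["gc"].to_numpy())
    weights = weights / weights.sum()

    bin_of_frag = rng.choice(len(bins), size=n_fragments, p=weights)

    if isinstance(bin_short_modulation, str) and bin_short_modulation == "auto":
        modulation = regional_short_modulation(len(bins))
    else:
        modulation = bin_short_modulation

    # mixture of mixtures: tumor-origin indicator, then length component
    from_sig = rng.random(n_fragments) < f
    lengths = np.empty(n_fragments, dtype=np.int64)
    for params, sel, modulated in (
        (background.frag_len_params, ~from_sig, True),
        (sig.frag_len_params, from_sig, False),
    ):
        k = int(sel.sum())
        if k == 0:
            continue
        w = np.tile(np.asarray(params.weights), (k, 1))
        if modulated and modulation is not None:
            w[:, 0] *= modulation[bin_of_frag[sel]]
            w /= w.sum(axis=1, keepdims=True)
        u = rng.random(k)
        cum = np.cumsum(w, axis=1)
        comp = (u[:, None] >= cum[:, :2]).sum(axis=1)
        drawn = rng.normal(np.array(params.locs)[comp], np.array(params.scales)[comp])
        lengths[sel] = np.maximum(np.round(drawn).astype(np.int64), 30)

    b_start = bins["start"].to_numpy()[bin_of_frag]
    b_end = bins["end"].to_numpy()[bin_of_frag]
    mids = rng.integers(b_start, b_end)
    starts = mids - lengths // 2
    frag_chrom = chrom[bin_of_frag]
    sizes = np.array([chrom_sizes[c] for c in frag_chrom], dtype=np.int64)
    starts = np.clip(starts, 0, sizes - lengths)
    out = pd.DataFrame({"chrom": frag_chrom, "start": starts, "end": starts + lengths})
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return out


def make_cohort_design(
    seed: int,
    n_healthy: int = 40,
    n_per_cancer: int = 20,
    n_tumor_tissue: int = 10,
    n_normal_tissue: int = 10,
    classes: tuple[str, ...] = CANCER_CLASSES,
    skip_normal_for: tuple[str, ...] = ("prostate",),
    mean_depth: float = 30.0,
    n_fragments: int = 50_000,
    stage_tumor_fraction: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Build a cohort design table with per-sample seeds and tumor fractions.

    Cancer cfDNA samples cycle through stages 1-4; tumor fraction is
    drawn uniformly from [0.5x, 1.5x] of the stage's central value
    (defaults in :data:`DEFAULT_STAGE_TUMOR_FRACTION`).  Tumor tissue
    samples get f ~ U(0.4, 0.7); healthy and normal tissue have f = 0.
    Prostate cancer has no adjacent normal tissue by default, matching
    typical cohort availability.
    """
    stage_tf = stage_tumor_fraction or DEFAULT_STAGE_TUMOR_FRACTION
    rng = np.random.default_rng(seed)
    rows = []

    def new_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    for i in range(n_healthy):
        age = int(rng.integers(35, 80))
        rows.append(
            ("H%03d" % i, "healthy", "cfDNA", 0, 0.0, mean_depth, n_fragments, new_seed(), age)
        )
    for cls in classes:
        prefix = cls[:2].upper()
        for i in range(n_per_cancer):
            stage = (i % 4) + 1
            center = stage_tf[stage]
            f = float(rng.uniform(0.5 * center, 1.5 * center))
            age = int(rng.integers(40, 85))
            rows.append(
                (f"{prefix}{i:03d}", cls, "cfDNA", stage, f, mean_depth, n_fragments, new_seed(), age)
            )
        for i in range(n_tumor_tissue):
            stage = (i % 4) + 1
            f = float(rng.uniform(0.4, 0.7))
            age = int(rng.integers(40, 85))
            rows.append(
                (f"{prefix}T{i:03d}", cls, "tumor_tissue", stage, f, mean_depth, n_fragments, new_seed(), age)
            )
        if cls not in skip_normal_for:
            for i in range(n_normal_tissue):
                age = int(rng.integers(40, 85))
                rows.append(
                    (f"{prefix}N{i:03d}", cls, "normal_tissue", 0, 0.0, mean_depth, n_fragments, new_seed(), age)
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "class_label",
            "sample_type",
            "stage",
            "tumor_fraction",
            "mean_depth",
            "n_fragments",
            "seed",
            "age",
        ],
    )
    df["sex"] = np.where(rng.random(len(df)) < 0.5, "F", "M")
    _validate_design(df)
    return df


def _validate_design(design: pd.DataFrame) -> None:
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in design: {dups[:5]}")
    if len(design) and design["seed"].duplicated().any():
        raise ValueError("per-sample seeds must be unique")
    bad_f = design[
        (design["sample_type"].isin(["cfDNA"]))
        & (design["class_label"] == "healthy")
        & (design["tumor_fraction"] != 0)
    ]
    if len(bad_f):
        raise ValueError("healthy samples must have tumor fraction 0")
    bad_n = design[(design["sample_type"] == "normal_tissue") & (design["tumor_fraction"] != 0)]
    if len(bad_n):
        raise ValueError("normal tissue samples must have tumor fraction 0")
    bad_t = design[(design["sample_type"] == "tumor_tissue") & (design["tumor_fraction"] < 0.3)]
    if len(bad_t):
        raise ValueError("tumor tissue samples must have tumor fraction >= 0.3")


def sample_archetype_pair(
    archetypes: dict[str, dict[str, ClassArchetype]], class_label: str, sample_type: str
) -> tuple[ClassArchetype, ClassArchetype | None]:
    """(background, signal) archetypes for one designed sample.

    cfDNA mixes healthy plasma background with the class's tumor
    archetype; tumor tissue mixes the class's *normal tissue*
    background with its tumor archetype; normal tissue is the pure
    normal archetype.
    """
    healthy = archetypes["healthy"]["cfdna"]
    if class_label == "healthy":
        return healthy, None
    cls = archetypes[class_label]
    if sample_type == "cfDNA":
        return healthy, cls["tumor"]
    if sample_type == "tumor_tissue":
        return cls["normal"], cls["tumor"]
    if sample_type == "normal_tissue":
        return cls["normal"], None
    raise ValueError(f"unknown sample type {sample_type!r}")


def simulate_sample(
    row: pd.Series,
    archetypes: dict[str, dict[str, ClassArchetype]],
    blocks: list[CpGBlock],
    bins: pd.DataFrame,
    chrom_sizes: dict[str, int],
    gc_bias=None,
    overdispersion: float = 0.02,
    nb_size: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate (methylation counts, fragments) for one design row."""
    background, signal = sample_archetype_pair(
        archetypes, row["class_label"], row["sample_type"]
    )
    f = float(row["tumor_fraction"])
    seed = int(row["seed"])
    counts = simulate_methylation_counts(
        background,
        signal,
        f,
        float(row["mean_depth"]),
        blocks,
        overdispersion=overdispersion,
        nb_size=nb_size,
        seed=seed,
    )
    frags = simulate_fragments(
        background,
        signal,
        f,
        int(row["n_fragments"]),
        bins,
        chrom_sizes,
        gc_bias=gc_bias,
        seed=seed + 1,
    )
    return counts, frags


def simulate_cohort(
    design: pd.DataFrame,
    output_dir: str,
    archetypes: dict[str, dict[str, ClassArchetype]],
    marker_truth: MarkerTruth,
    blocks: list[CpGBlock],
    bins: pd.DataFrame,
    chrom_sizes: dict[str, int],
    gc_bias=None,
) -> pd.DataFrame:
    """Simulate and write a full cohort to ``output_dir``.

    Writes per sample ``<id>.meth.tsv`` (bedGraph count dialect) and
    ``<id>.frags.bed``, plus ``metadata.tsv`` and ``truth.json``
    (planted markers, gain segments, realized tumor fractions).
    Re-running with the same design is byte-identical.  An empty design
    writes an empty manifest without error.
    """
    import os

    _validate_design(design)
    os.makedirs(output_dir, exist_ok=True)
    for _, row in design.iterrows():
        counts, frags = simulate_sample(
            row, archetypes, blocks, bins, chrom_sizes, gc_bias=gc_bias
        )
        _meth.write_methylation_counts(counts, os.path.join(output_dir, f"{row['sample_id']}.meth.tsv"))
        frags.to_csv(
            os.path.join(output_dir, f"{row['sample_id']}.frags.bed"),
            sep="\t",
            header=False,
            index=False,
        )
    meta = design.copy()
    meta.to_csv(os.path.join(output_dir, "metadata.tsv"), sep="\t", index=False)
    truth = {
        "markers": {
            cls: {k: sorted(v) for k, v in sets.items()}
            for cls, sets in marker_truth.markers.items()
        },
        "gain_segments": {
            cls: [list(seg) for seg in segs]
            for cls, segs in marker_truth.gain_segments.items()
        },
        "tumor_fractions": dict(
            zip(design["sample_id"], (float(x) for x in design["tumor_fraction"]))
        ),
    }
    with open(os.path.join(output_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return meta
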