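"""Generator ground truth: reference, archetypes, mixtures, cohort files."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from cfsig import blocks as bl
from cfsig import methylation as me
from cfsig import synthetic as syn


# ---------------------------------------------------------------- reference
def test_reference_truth_matches_rescan(small_genome):
    truth, seqs = small_genome["truth"], small_genome["seqs"]
    for chrom, seq in seqs.items():
        rescanned = bl.scan_cpg_in_sequence(seq)
        np.testing.assert_array_equal(rescanned, truth.cpg_positions[chrom])
        for p in truth.cpg_positions[chrom][:200]:
            assert seq[p : p + 2] == "CG"


def test_reference_deterministic(tmp_path):
    p1, p2 = str(tmp_path / "a.fa"), str(tmp_path / "b.fa")
    syn.make_reference(seed=5, n_chrom=1, chrom_length_bp=50_000, cpg_cluster_rate=3e-4, fasta_path=p1)
    syn.make_reference(seed=5, n_chrom=1, chrom_length_bp=50_000, cpg_cluster_rate=3e-4, fasta_path=p2)
    assert open(p1, "rb").read() == open(p2, "rb").read()


def test_reference_degenerate_inputs():
    with pytest.raises(ValueError, match="no CpGs"):
        syn.make_reference(seed=1, n_chrom=1, chrom_length_bp=20_000, cpg_cluster_rate=0.0)
    with pytest.raises(ValueError, match="10,000"):
        syn.make_reference(seed=1, n_chrom=1, chrom_length_bp=500)


# ---------------------------------------------------------------- archetypes
def test_archetype_marker_structure(small_blocks, small_archetypes):
    """Tissue markers shift tumor AND normal; cancer markers shift tumor only."""
    arch = small_archetypes["archetypes"]
    mt = small_archetypes["marker_truth"]
    ids = {b.id: i for i, b in enumerate(small_blocks)}
    healthy = arch["healthy"]["cfdna"].block_amf

    def logit(x):
        return np.log(x / (1 - x))

    for cls in syn.CANCER_CLASSES:
        tumor = arch[cls]["tumor"].block_amf
        normal = arch[cls]["normal"].block_amf
        for mid in mt.planted(cls, "tissue", "hyper"):
            i = ids[mid]
            assert logit(tumor[i]) - logit(healthy[i]) >= 3.0 - 1e-9
            assert tumor[i] == pytest.approx(normal[i])
        for mid in mt.planted(cls, "cancer", "hyper"):
            i = ids[mid]
            assert logit(tumor[i]) - logit(healthy[i]) >= 3.0 - 1e-9
            assert normal[i] == pytest.approx(healthy[i])
        for mid in mt.planted(cls, "tissue", "hypo"):
            i = ids[mid]
            assert logit(tumor[i]) - logit(healthy[i]) <= -3.0 + 1e-9
            assert tumor[i] == pytest.approx(normal[i])


def test_archetype_sets_disjoint(small_archetypes):
    mt = small_archetypes["marker_truth"]
    seen: set[str] = set()
    for cls, sets in mt.markers.items():
        for ids in sets.values():
            assert not ids & seen
            seen |= ids


def test_planted_effect_sigmoid_arithmetic():
    """A +2 logit shift from logit -3 lands at sigmoid(-1) ~ 0.269."""
    assert 1 / (1 + np.exp(1)) == pytest.approx(0.2689, abs=1e-4)


def test_archetype_healthy_has_no_cnv(small_archetypes):
    assert small_archetypes["archetypes"]["healthy"]["cfdna"].cnv_segments == ()


def test_archetype_overlapping_cnv_rejected():
    with pytest.raises(ValueError, match="overlapping CNV"):
        syn.ClassArchetype(
            class_label="colon",
            block_amf=np.array([0.5]),
            cnv_segments=(("chr1", 0, 100, 4), ("chr1", 50, 150, 3)),
            frag_len_params=syn.HEALTHY_FRAG_PARAMS,
        )


# ------------------------------------------------------- methylation mixture
def _amf_of(counts, blocks):
    return me.aggregate_amf(counts, blocks, min_mean_cov=0)["amf"].to_numpy()


def test_methylation_mixture_endpoints(small_blocks, small_archetypes):
    """f=0 reproduces the healthy archetype; f=1 the tumor archetype."""
    arch = small_archetypes["archetypes"]
    healthy, tumor = arch["healthy"]["cfdna"], arch["colon"]["tumor"]
    c0 = syn.simulate_methylation_counts(healthy, tumor, 0.0, 60.0, small_blocks, seed=1)
    c1 = syn.simulate_methylation_counts(healthy, tumor, 1.0, 60.0, small_blocks, seed=2)
    a0, a1 = _amf_of(c0, small_blocks), _amf_of(c1, small_blocks)
    # block-averaged deviation from the archetype is small MC noise
    assert np.nanmean(np.abs(a0 - healthy.block_amf)) < 0.02
    assert np.nanmean(np.abs(a1 - tumor.block_amf)) < 0.02


def test_methylation_mixture_midpoint():
    """f=0.5 between AMF 0 and 1 gives expected AMF 0.5 within 3 MC SE."""
    b = bl.CpGBlock(id="b", chrom="chr1", start=0, end=52, cpg_positions=(0, 50))
    lo = syn.ClassArchetype("healthy", np.array([1e-9]), (), syn.HEALTHY_FRAG_PARAMS)
    hi = syn.ClassArchetype("colon", np.array([1 - 1e-9]), (), syn.TUMOR_FRAG_PARAMS)
    counts = syn.simulate_methylation_counts(lo, hi, 0.5, 10_000.0, [b], seed=3)
    total_c = counts["n_meth"].sum()
    total = (counts["n_meth"] + counts["n_unmeth"]).sum()
    amf = total_c / total
    # beta-binomial intraclass correlation inflates the binomial variance
    rho = 0.02
    se = np.sqrt(0.25 / total * (1 + (total / 2 - 1) * rho))
    assert abs(amf - 0.5) < 3 * se


def test_methylation_determinism(small_blocks, small_archetypes):
    arch = small_archetypes["archetypes"]
    h = arch["healthy"]["cfdna"]
    c1 = syn.simulate_methylation_counts(h, None, 0.0, 30.0, small_blocks, seed=9)
    c2 = syn.simulate_methylation_counts(h, None, 0.0, 30.0, small_blocks, seed=9)
    pd.testing.assert_frame_equal(c1, c2)


def test_methylation_validates_inputs(small_blocks, small_archetypes):
    h = small_archetypes["archetypes"]["healthy"]["cfdna"]
    with pytest.raises(ValueError):
        syn.simulate_methylation_counts(h, None, 1.5, 30.0, small_blocks)
    with pytest.raises(ValueError):
        syn.simulate_methylation_counts(h, None, 0.0, -1.0, small_blocks)


# -------------------------------------------------------------- fragments
def test_fragment_copy_gain_coverage_ratio(small_genome, small_bins, small_archetypes):
    """A planted cn=4 segment at f=0.1 lifts bin coverage by ~1.1x."""
    arch = small_archetypes["archetypes"]
    healthy, tumor = arch["healthy"]["cfdna"], arch["colon"]["tumor"]
    sizes = small_genome["truth"].chrom_lengths
    seg = next(s for s in tumor.cnv_segments if s[3] == 4)
    in_gain = (
        (small_bins["chrom"] == seg[0])
        & (small_bins["start"] >= seg[1])
        & (small_bins["end"] <= seg[2])
    ).to_numpy()
    assert in_gain.sum() >= 3
    n, reps = 200_000, 4
    obs = np.zeros(len(small_bins))
    for r in range(reps):
        frags = syn.simulate_fragments(healthy, tumor, 0.1, n, small_bins, sizes, seed=40 + r)
        from cfsig.copynumber import count_fragments

        obs += count_fragments(frags, small_bins).to_numpy()
    width = (small_bins["end"] - small_bins["start"]).to_numpy()
    full = width == width.max()
    rate_gain = obs[in_gain & full].mean()
    rate_base = obs[full & ~in_gain & ~_in_any_segment(small_bins, tumor.cnv_segments)].mean()
    ratio = rate_gain / rate_base
    se = ratio * np.sqrt(1 / obs[in_gain & full].sum() + 1 / obs[full & ~in_gain].sum())
    assert abs(ratio - 1.1) < max(3 * se, 0.01)


def _in_any_segment(bins, segments):
    hit = np.zeros(len(bins), dtype=bool)
    for chrom, s, e, _ in segments:
        hit |= (
            (bins["chrom"] == chrom) & (bins["end"] > s) & (bins["start"] < e)
        ).to_numpy()
    return hit


def test_fragment_sl_increases_with_tumor_mixture(small_genome, small_bins, small_archetypes):
    from cfsig.fragmentomics import compute_fsr_profile

    arch = small_archetypes["archetypes"]
    healthy, tumor = arch["healthy"]["cfdna"], arch["colon"]["tumor"]
    sizes = small_genome["truth"].chrom_lengths
    _, g0 = compute_fsr_profile(
        syn.simulate_fragments(healthy, tumor, 0.0, 30_000, small_bins, sizes, seed=1), small_bins
    )
    _, g1 = compute_fsr_profile(
        syn.simulate_fragments(healthy, tumor, 1.0, 30_000, small_bins, sizes, seed=1), small_bins
    )
    assert g1 > g0


# ------------------------------------------------------------------ cohort
def test_cohort_design_stage_bands():
    design = syn.make_cohort_design(seed=1, n_healthy=4, n_per_cancer=8)
    cancer = design[design["sample_type"] == "cfDNA"]
    cancer = cancer[cancer["class_label"] != "healthy"]
    for stage, band in syn.DEFAULT_STAGE_TUMOR_FRACTION.items():
        sel = cancer[cancer["stage"] == stage]
        assert ((sel["tumor_fraction"] >= 0.5 * band) & (sel["tumor_fraction"] <= 1.5 * band)).all()
    healthy = design[design["class_label"] == "healthy"]
    assert (healthy["tumor_fraction"] == 0).all()


def test_cohort_design_validation():
    design = syn.make_cohort_design(seed=1, n_healthy=4, n_per_cancer=2)
    dup = pd.concat([design, design.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate sample ids"):
        syn.simulate_cohort(dup, "/tmp/never", {}, None, [], None, {})


def test_simulate_cohort_files_and_determinism(
    tmp_path, small_genome, small_blocks, small_bins, small_archetypes
):
    design = syn.make_cohort_design(
        seed=3, n_healthy=2, n_per_cancer=1, n_tumor_tissue=1, n_normal_tissue=1,
        n_fragments=2000, classes=("colon",), skip_normal_for=()
    )
    kw = dict(
        archetypes=small_archetypes["archetypes"],
        marker_truth=small_archetypes["marker_truth"],
        blocks=small_blocks,
        bins=small_bins,
        chrom_sizes=small_genome["truth"].chrom_lengths,
    )
    d1, d2 = str(tmp_path / "run1"), str(tmp_path / "run2")
    syn.simulate_cohort(design, d1, **kw)
    syn.simulate_cohort(design, d2, **kw)
    import os

    names = sorted(os.listdir(d1))
    # 5 samples x 2 files + metadata + truth
    assert len([n for n in names if n.endswith(".meth.tsv")]) == 5
    assert len([n for n in names if n.endswith(".frags.bed")]) == 5
    assert "metadata.tsv" in names and "truth.json" in names
    for n in names:
        assert open(os.path.join(d1, n), "rb").read() == open(os.path.join(d2, n), "rb").read()
    truth = json.load(open(os.path.join(d1, "truth.json")))
    assert set(truth["markers"]) == set(syn.CANCER_CLASSES)


def test_simulate_cohort_empty_design(tmp_path, small_genome, small_blocks, small_bins, small_archetypes):
    design = syn.make_cohort_design(seed=4, n_healthy=0, n_per_cancer=0, n_tumor_tissue=0, n_normal_tissue=0)
    out = syn.simulate_cohort(
        design,
        str(tmp_path / "empty"),
        small_archetypes["archetypes"],
        small_archetypes["marker_truth"],
        small_blocks,
        small_bins,
        small_genome["truth"].chrom_lengths,
    )
    assert len(out) == 0
    assert (tmp_path / "empty" / "metadata.tsv").exists()
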