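"""Shared fixtures: a small synthetic genome, blocks, bins, archetypes,
and one moderately sized end-to-end pipeline run reused by several tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cfsig import blocks as bl
from cfsig import copynumber as cn
from cfsig import synthetic as syn
from cfsig import workflow as wf


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """Toy 2 x 1 Mb reference with clustered CpGs, written to FASTA."""
    d = tmp_path_factory.mktemp("genome")
    fasta = str(d / "ref.fa")
    truth, seqs = syn.make_reference(
        seed=11, n_chrom=2, chrom_length_bp=1_000_000, cpg_cluster_rate=3e-4, fasta_path=fasta
    )
    return {"truth": truth, "seqs": seqs, "fasta": fasta}


@pytest.fixture(scope="session")
def small_blocks(small_genome):
    return bl.build_blocks(small_genome["truth"].cpg_positions)


@pytest.fixture(scope="session")
def small_bins(small_genome):
    bins = cn.make_bins(small_genome["truth"].chrom_lengths, width=10_000)
    return cn.annotate_gc(bins, small_genome["fasta"])


@pytest.fixture(scope="session")
def small_archetypes(small_genome, small_blocks):
    archetypes, marker_truth = syn.make_archetypes(
        seed=7,
        blocks=small_blocks,
        chrom_sizes=small_genome["truth"].chrom_lengths,
        n_tissue_markers=20,
        n_cancer_markers=20,
    )
    return {"archetypes": archetypes, "marker_truth": marker_truth}


QUICK_CONFIG = {
    "seed": 20,
    "reference": {"n_chrom": 2, "chrom_length_bp": 2_000_000, "cpg_cluster_rate": 3e-4},
    "cohort": {
        "n_healthy": 56,
        "n_per_cancer": 16,
        "n_tumor_tissue": 8,
        "n_normal_tissue": 8,
        "mean_depth": 30.0,
        "n_fragments": 30_000,
    },
    "generator": {"n_tissue_markers": 20, "n_cancer_markers": 20},
    "bins": {"width": 10_000},
}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full simulate -> report run on a compact cohort."""
    outdir = str(tmp_path_factory.mktemp("pipeline"))
    manifest = wf.run("all", QUICK_CONFIG, outdir=outdir)
    return {"outdir": outdir, "manifest": manifest, "config": QUICK_CONFIG}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_meta(n_per_class: int = 12, classes=("healthy", "colon", "liver")) -> pd.DataFrame:
    """Small balanced cfDNA metadata table for split/fold tests."""
    rows = []
    rng_ = np.random.default_rng(5)
    for cls in classes:
        for i in range(n_per_class):
            rows.append(
                {
                    "sample_id": f"{cls[:2]}{i:02d}",
                    "class_label": cls,
                    "sample_type": "cfDNA",
                    "stage": 0 if cls == "healthy" else (i % 4) + 1,
                    "age": int(rng_.integers(35, 80)),
                    "sex": "F" if i % 2 else "M",
                }
            )
    return pd.DataFrame(rows)
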