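"""Pipeline configuration and orchestration.

Binds the stages into a reproducible simulate -> features -> markers ->
train -> predict -> evaluate -> report run.  Every constant of the
analysis is surfaced in the configuration with the standard value as
default (block gap 100 bp / >= 3 CpGs / < 1000 bp; AMF minimum mean
coverage 10x; stable-region rule 90% / <0.3 / >0.7; 10% imputation
cutoff; logFC > 1, FDR < 0.01, top 10,000 markers; copy-neutral
interval 0.85-1.05; short-fragment cutoff < 150 bp; S = 80-150, L =
151-220; low-count FSR bin < 50; 4-fold CV; >95% target specificity).

A single global seed fans out to per-stage seeds through fixed
offsets; re-running an unchanged configuration reproduces every output
byte and hash.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import pickle
from typing import Any

import numpy as np
import pandas as pd
import yaml

from cfsig import (
    blocks as bl,
    classifiers as cl,
    copynumber as cn,
    evaluation as ev,
    fragmentomics as fr,
    markers as mk,
    methylation as me,
    synthetic as syn,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "blocks",
    "methyl",
    "cnr",
    "fsr",
    "markers",
    "train",
    "predict",
    "evaluate",
    "report",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "outdir": "cfsig_run",
    "reference": {"n_chrom": 2, "chrom_length_bp": 2_000_000, "cpg_cluster_rate": 2.0e-4},
    "cohort": {
        "n_healthy": 30,
        "n_per_cancer": 8,
        "n_tumor_tissue": 6,
        "n_normal_tissue": 6,
        "mean_depth": 30.0,
        "n_fragments": 30_000,
    },
    "generator": {
        "effect_logit": 3.0,
        "n_tissue_markers": 40,
        "n_cancer_markers": 40,
        "overdispersion": 0.02,
        "nb_size": 10.0,
        "gc_bias_strength": 0.0,
    },
    "blocks": {"max_gap": 100, "min_cpgs": 3, "max_len": 1000},
    "bins": {"width": 100_000},
    "methylation": {
        "min_mean_cov": 10.0,
        "stable_q": 0.90,
        "stable_low": 0.3,
        "stable_high": 0.7,
        "min_nonmissing_frac": 0.8,
        "max_missing_frac": 0.10,
        "logit_eps": 0.01,
    },
    "markers": {"lfc_min": 1.0, "fdr_max": 0.01, "top_n": 10_000},
    "copynumber": {"short_max_len": 150, "neutral_lo": 0.85, "neutral_hi": 1.05},
    "fragmentomics": {"min_bin_count": 50},
    "classify": {
        "test_frac": 0.5,
        "k_folds": 4,
        "c_grid": [0.01, 0.1, 1.0, 10.0],
        "target_spec": 0.95,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


class ConfigError(ValueError):
    """Raised before any computation when a configuration is invalid."""


def load_config(path_or_dict: str | dict | None = None) -> dict:
    """Load a pipeline configuration (YAML path or dict) over defaults."""
    if path_or_dict is None:
        user: dict = {}
    elif isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _deep_merge(DEFAULT_CONFIG, user)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema-style validation of ranges and orderings; raises ConfigError."""
    try:
        unknown = set(cfg) - set(DEFAULT_CONFIG)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        if cfg["copynumber"]["neutral_lo"] >= cfg["copynumber"]["neutral_hi"]:
            raise ConfigError("copynumber.neutral_lo must be < neutral_hi")
        if not 0 < cfg["methylation"]["logit_eps"] < 0.5:
            raise ConfigError("methylation.logit_eps must lie in (0, 0.5)")
        if not 0 < cfg["classify"]["test_frac"] < 1:
            raise ConfigError("classify.test_frac must lie in (0, 1)")
        if not 0 < cfg["classify"]["target_spec"] < 1:
            raise ConfigError("classify.target_spec must lie in (0, 1)")
        if cfg["bins"]["width"] < 1000:
            raise ConfigError("bins.width must be >= 1000")
        if cfg["blocks"]["min_cpgs"] < 2:
            raise ConfigError("blocks.min_cpgs must be >= 2")
        for key in ("stable_q", "min_nonmissing_frac", "max_missing_frac"):
            if not 0 <= cfg["methylation"][key] <= 1:
                raise ConfigError(f"methylation.{key} must lie in [0, 1]")
    except KeyError as exc:
        raise ConfigError(f"missing config key: {exc}") from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """File-driven pipeline over a configured output directory."""

    def __init__(self, config: dict | str | None = None, outdir: str | None = None):
        self.cfg = load_config(config)
        self.outdir = outdir or self.cfg["outdir"]
        os.makedirs(self.outdir, exist_ok=True)

    # ---- path helpers -------------------------------------------------
    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def _require(self, name: str, producer: str) -> str:
        p = self.path(name)
        if not os.path.exists(p):
            raise FileNotFoundError(
                f"missing upstream output {name!r}; run stage {producer!r} first"
            )
        return p

    # ---- stages -------------------------------------------------------
    def run(self, stage: str = "all") -> dict:
        """Execute one stage or the full dependency chain; returns the manifest."""
        if stage == "all":
            todo = list(STAGES)
        elif stage in STAGES:
            todo = [stage]
        else:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
        for s in todo:
            logger.info("running stage %s", s)
            getattr(self, f"stage_{s}")()
        return self.write_manifest()

    def stage_simulate(self) -> None:
        cfg = self.cfg
        seed = cfg["seed"]
        ref_cfg = cfg["reference"]
        truth, seqs = syn.make_reference(
            seed=stage_seed(seed, "reference"),
            n_chrom=ref_cfg["n_chrom"],
            chrom_length_bp=ref_cfg["chrom_length_bp"],
            cpg_cluster_rate=ref_cfg["cpg_cluster_rate"],
            fasta_path=self.path("reference.fa"),
        )
        blocks = self._build_blocks(truth.cpg_positions)
        bl.write_blocks_bed(blocks, self.path("blocks.bed"))
        bins = cn.make_bins(truth.chrom_lengths, width=cfg["bins"]["width"])
        bins = cn.annotate_gc(bins, self.path("reference.fa"))
        bins.to_csv(self.path("bins.tsv"), sep="\t", index=False)

        gen = cfg["generator"]
        archetypes, marker_truth = syn.make_archetypes(
            seed=stage_seed(seed, "archetypes"),
            blocks=blocks,
            chrom_sizes=truth.chrom_lengths,
            n_tissue_markers=gen["n_tissue_markers"],
            n_cancer_markers=gen["n_cancer_markers"],
            effect_logit=gen["effect_logit"],
        )
        coh = cfg["cohort"]
        design = syn.make_cohort_design(
            seed=stage_seed(seed, "design"),
            n_healthy=coh["n_healthy"],
            n_per_cancer=coh["n_per_cancer"],
            n_tumor_tissue=coh["n_tumor_tissue"],
            n_normal_tissue=coh["n_normal_tissue"],
            mean_depth=coh["mean_depth"],
            n_fragments=coh["n_fragments"],
        )
        gc_bias = (
            syn.logistic_gc_bias(gen["gc_bias_strength"])
            if gen["gc_bias_strength"]
            else None
        )
        syn.simulate_cohort(
            design,
            self.path("sim"),
            archetypes,
            marker_truth,
            blocks,
            bins,
            truth.chrom_lengths,
            gc_bias=gc_bias,
        )

    def _build_blocks(self, cpg_positions) -> list[bl.CpGBlock]:
        b = self.cfg["blocks"]
        return bl.build_blocks(
            cpg_positions,
            max_gap=b["max_gap"],
            min_cpgs=b["min_cpgs"],
            max_len=b["max_len"],
        )

    def stage_blocks(self) -> None:
        fasta = self._require("reference.fa", "simulate")
        positions = bl.scan_cpg_sites(fasta)
        blocks = self._build_blocks(positions)
        bl.write_blocks_bed(blocks, self.path("blocks.bed"))

    def _load_blocks(self) -> list[bl.CpGBlock]:
        self._require("blocks.bed", "blocks")
        fasta = self._require("reference.fa", "simulate")
        positions = bl.scan_cpg_sites(fasta)
        return self._build_blocks(positions)

    def _load_meta(self) -> pd.DataFrame:
        p = self._require(os.path.join("sim", "metadata.tsv"), "simulate")
        return pd.read_csv(p, sep="\t", dtype={"sample_id": str})

    def _load_bins(self) -> pd.DataFrame:
        p = self._require("bins.tsv", "simulate")
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})

    def stage_methyl(self) -> None:
        blocks = self._load_blocks()
        meta = self._load_meta()
        min_cov = self.cfg["methylation"]["min_mean_cov"]
        records = {
            sid: me.read_methylation_counts(self.path(os.path.join("sim", f"{sid}.meth.tsv")))
            for sid in meta["sample_id"]
        }
        mat = me.amf_matrix(records, blocks, min_mean_cov=min_cov)
        mat.to_csv(self.path("amf_matrix.tsv"), sep="\t")

    def _fragments(self, sid: str) -> pd.DataFrame:
        p = self._require(os.path.join("sim", f"{sid}.frags.bed"), "simulate")
        return pd.read_csv(p, sep="\t", header=None, names=["chrom", "start", "end"], dtype={0: str})

    def stage_cnr(self) -> None:
        bins = self._load_bins()
        meta = self._load_meta()
        ccfg = self.cfg["copynumber"]
        rows, raw_rows = {}, {}
        for sid in meta["sample_id"]:
            frags = self._fragments(sid)
            counts = cn.count_fragments(frags, bins, max_len=ccfg["short_max_len"])
            prof = cn.gc_correct_and_normalize(counts, bins)
            raw_rows[sid] = prof["log2_ratio"]
            adj = cn.suppress_neutral(prof, lo=ccfg["neutral_lo"], hi=ccfg["neutral_hi"])
            rows[sid] = adj["log2_ratio"]
        mat = pd.DataFrame(rows).T
        mat.index.name = "sample_id"
        mat.to_csv(self.path("cnr_matrix.tsv"), sep="\t")
        raw = pd.DataFrame(raw_rows).T
        raw.index.name = "sample_id"
        # unsuppressed ratios back the tissue gain-region contrasts
        raw.to_csv(self.path("cnr_unsuppressed_matrix.tsv"), sep="\t")

    def stage_fsr(self) -> None:
        bins = self._load_bins()
        meta = self._load_meta()
        min_count = self.cfg["fragmentomics"]["min_bin_count"]
        rows, globals_ = {}, {}
        for sid in meta["sample_id"]:
            frags = self._fragments(sid)
            prof, g = fr.compute_fsr_profile(frags, bins, min_bin_count=min_count)
            rows[sid] = prof["log2_ratio"]
            globals_[sid] = g
        mat = pd.DataFrame(rows).T
        mat.index.name = "sample_id"
        mat.to_csv(self.path("fsr_matrix.tsv"), sep="\t")
        pd.Series(globals_, name="global_sl_ratio").rename_axis("sample_id").to_csv(
            self.path("global_fsr.tsv"), sep="\t"
        )

    # ---- marker selection --------------------------------------------
    def stage_markers(self) -> None:
        meta = self._load_meta()
        amf = pd.read_csv(self._require("amf_matrix.tsv", "methyl"), sep="\t", index_col=0)
        mcfg = self.cfg["methylation"]
        kcfg = self.cfg["markers"]
        split = cl.stratified_split(
            meta[meta["sample_type"] == "cfDNA"],
            test_frac=self.cfg["classify"]["test_frac"],
            seed=stage_seed(self.cfg["seed"], "split"),
        )
        split.to_csv(self.path("split.tsv"), sep="\t")

        healthy_train = [
            sid
            for sid in split[split == "train"].index
            if meta.set_index("sample_id").loc[sid, "class_label"] == "healthy"
        ]
        stable = me.call_stable_regions(
            amf.loc[healthy_train],
            q=mcfg["stable_q"],
            low=mcfg["stable_low"],
            high=mcfg["stable_high"],
            min_nonmissing_frac=mcfg["min_nonmissing_frac"],
        )
        logit = me.logit_transform(amf, eps=mcfg["logit_eps"])
        meta_idx = meta.set_index("sample_id")

        comparisons_unmeth: dict[str, mk.ComparisonSets] = {}
        comparisons_meth: dict[str, mk.ComparisonSets] = {}
        for cls in syn.CANCER_CLASSES:
            tumor_ids = meta_idx[
                (meta_idx["class_label"] == cls) & (meta_idx["sample_type"] == "tumor_tissue")
            ].index
            normal_ids = meta_idx[
                (meta_idx["class_label"] == cls) & (meta_idx["sample_type"] == "normal_tissue")
            ].index
            if len(normal_ids) == 0:
                # composite of all available normal tissues (e.g. prostate)
                normal_ids = meta_idx[meta_idx["sample_type"] == "normal_tissue"].index
            for stratum, ids, direction, store in (
                ("unmethylated", stable.unmethylated_ids, "hyper", comparisons_unmeth),
                ("methylated", stable.methylated_ids, "hypo", comparisons_meth),
            ):
                cols = sorted(ids)
                if not cols:
                    store[cls] = mk.ComparisonSets(frozenset(), frozenset(), frozenset())
                    continue
                t_mat = logit.loc[tumor_ids, cols]
                n_mat = logit.loc[normal_ids, cols]
                h_mat = logit.loc[healthy_train, cols]
                sets = {}
                for name, a_mat, b_mat in (
                    ("th", t_mat, h_mat),
                    ("nh", n_mat, h_mat),
                    ("tn", t_mat, n_mat),
                ):
                    res = mk.moderated_t(a_mat, b_mat)
                    sets[name] = frozenset(
                        mk.select_top_dm(
                            res,
                            direction=direction,
                            lfc_min=kcfg["lfc_min"],
                            fdr_max=kcfg["fdr_max"],
                            top_n=kcfg["top_n"],
                        )
                    )
                store[cls] = mk.ComparisonSets(**sets)
        marker_sets = mk.assemble_marker_sets(stable, comparisons_unmeth, comparisons_meth)
        payload = {
            "detection": sorted(marker_sets.detection_set),
            "too": sorted(marker_sets.too_set),
            "specific": {
                cls: {
                    stratum: {k: sorted(v) for k, v in cats.items()}
                    for stratum, cats in strata.items()
                }
                for cls, strata in marker_sets.specific.items()
            },
        }
        with open(self.path("marker_sets.json"), "w") as fh:
            json.dump(payload, fh, indent=1)
        self._select_gain_regions(meta_idx)

    def _select_gain_regions(self, meta_idx: pd.DataFrame) -> None:
        """Frequent copy-gain bins per class from tissue CNR contrasts."""
        raw = pd.read_csv(
            self._require("cnr_unsuppressed_matrix.tsv", "cnr"), sep="\t", index_col=0
        )
        tumor_log2: dict[str, pd.DataFrame] = {}
        normal_log2: dict[str, pd.DataFrame] = {}
        for cls in syn.CANCER_CLASSES:
            t_ids = meta_idx[
                (meta_idx["class_label"] == cls) & (meta_idx["sample_type"] == "tumor_tissue")
            ].index
            n_ids = meta_idx[
                (meta_idx["class_label"] == cls) & (meta_idx["sample_type"] == "normal_tissue")
            ].index
            if len(t_ids):
                tumor_log2[cls] = raw.loc[t_ids]
            if len(n_ids):
                normal_log2[cls] = raw.loc[n_ids]
        if not tumor_log2:
            return
        pooled_for = frozenset(set(tumor_log2) - set(normal_log2))
        gains = cn.select_gain_regions(tumor_log2, normal_log2, pooled_normals_for=pooled_for)
        with open(self.path("gain_regions.json"), "w") as fh:
            json.dump(
                {cls: sorted(ids) for cls, ids in gains.by_class.items()}, fh, indent=1
            )

    # ---- modelling ----------------------------------------------------
    def _feature_matrices(self):
        amf = pd.read_csv(self._require("amf_matrix.tsv", "methyl"), sep="\t", index_col=0)
        cnr = pd.read_csv(self._require("cnr_matrix.tsv", "cnr"), sep="\t", index_col=0)
        fsr = pd.read_csv(self._require("fsr_matrix.tsv", "fsr"), sep="\t", index_col=0)
        with open(self._require("marker_sets.json", "markers")) as fh:
            sets = json.load(fh)
        split = pd.read_csv(self._require("split.tsv", "markers"), sep="\t", index_col=0)["split"]
        meta = self._load_meta().set_index("sample_id")
        return amf, cnr, fsr, sets, split, meta

    def _prepare(self, matrix, cols, cfdna_ids, healthy_train):
        mcfg = self.cfg["methylation"]
        X = matrix.loc[cfdna_ids, cols]
        X, dropped = me.impute_missing(
            X, healthy_train, max_missing_frac=mcfg["max_missing_frac"]
        )
        return X, dropped

    def stage_train(self) -> None:
        amf, cnr, fsr, sets, split, meta = self._feature_matrices()
        ccfg = self.cfg["classify"]
        cfdna = split.index.tolist()
        train_ids = [s for s in cfdna if split[s] == "train"]
        healthy_train = [s for s in train_ids if meta.loc[s, "class_label"] == "healthy"]
        y = meta.loc[train_ids, "class_label"]

        models: dict[str, cl.FeatureClassifier] = {}
        feature_specs = {
            "amf_detection": (amf, sets["detection"]),
            "amf_too": (amf, sets["too"]),
            "cnr": (cnr, list(cnr.columns)),
            "fsr": (fsr, list(fsr.columns)),
        }
        seed = stage_seed(self.cfg["seed"], "train")
        imputed_cols: dict[str, list[str]] = {}
        for name, (matrix, cols) in feature_specs.items():
            X_all, _ = self._prepare(matrix, cols, cfdna, healthy_train)
            imputed_cols[name] = list(X_all.columns)
            model = cl.fit_multiclass(
                X_all.loc[train_ids],
                y,
                c_grid=tuple(ccfg["c_grid"]),
                seed=seed,
                n_calibration_folds=ccfg["k_folds"],
            )
            models[name] = model
        with open(self.path("models.pkl"), "wb") as fh:
            pickle.dump({"models": models, "columns": imputed_cols, "version": 1}, fh)
        with open(self.path("models.json"), "w") as fh:
            json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=1)

    def stage_predict(self) -> None:
        amf, cnr, fsr, sets, split, meta = self._feature_matrices()
        with open(self._require("models.pkl", "train"), "rb") as fh:
            bundle = pickle.load(fh)
        models, columns = bundle["models"], bundle["columns"]
        cfdna = split.index.tolist()
        healthy_train = [
            s for s in cfdna if split[s] == "train" and meta.loc[s, "class_label"] == "healthy"
        ]
        feature_specs = {
            "amf_detection": amf,
            "amf_too": amf,
            "cnr": cnr,
            "fsr": fsr,
        }
        probs: dict[str, pd.DataFrame] = {}
        for name, matrix in feature_specs.items():
            X_all, _ = self._prepare(matrix, columns[name], cfdna, healthy_train)
            probs[name] = cl.predict_probs(models[name], X_all)

        det_scores = {
            feat: cl.cancer_score(probs[src])
            for feat, src in (("amf", "amf_detection"), ("cnr", "cnr"), ("fsr", "fsr"))
        }
        ensemble_det = cl.ensemble_mean(list(det_scores.values()))
        too_conds = {
            feat: cl.too_conditional(probs[src]).drop(columns="degenerate")
            for feat, src in (("amf", "amf_too"), ("cnr", "cnr"), ("fsr", "fsr"))
        }
        ensemble_too = cl.ensemble_mean(list(too_conds.values()))

        out = pd.DataFrame(
            {
                "split": split,
                "class_label": meta.loc[cfdna, "class_label"],
                "amf_score": det_scores["amf"],
                "cnr_score": det_scores["cnr"],
                "fsr_score": det_scores["fsr"],
                "ensemble_score": ensemble_det,
            }
        )
        for c in ensemble_too.columns:
            out[f"too_{c}"] = ensemble_too[c]
        out.index.name = "sample_id"
        out.to_csv(self.path("scores.tsv"), sep="\t")

    def stage_evaluate(self) -> None:
        scores = pd.read_csv(self._require("scores.tsv", "predict"), sep="\t", index_col=0)
        target = self.cfg["classify"]["target_spec"]
        test = scores[scores["split"] == "test"]
        healthy_test = test[test["class_label"] == "healthy"]
        perf: dict[str, Any] = {"n_test": len(test), "n_healthy_test": len(healthy_test)}
        for col in ("amf_score", "cnr_score", "fsr_score", "ensemble_score"):
            thr = cl.select_threshold(healthy_test[col], target_spec=target)
            calls = test[col] > thr
            truth = test["class_label"] != "healthy"
            summary = ev.sens_spec(calls, truth)
            auc, ci = ev.auc_ci(test[col], truth)
            perf[col] = {
                "threshold": thr,
                "sensitivity": summary.sensitivity,
                "specificity": summary.specificity,
                "sensitivity_ci": summary.sensitivity_ci,
                "specificity_ci": summary.specificity_ci,
                "auc": auc,
                "auc_ci": ci,
            }
        # detection-gated TOO on test cancer samples
        thr = perf["ensemble_score"]["threshold"]
        detected = test[(test["ensemble_score"] > thr) & (test["class_label"] != "healthy")]
        too_cols = [c for c in scores.columns if c.startswith("too_")]
        if len(detected):
            cond = detected[too_cols].rename(columns=lambda c: c[4:])
            calls = cl.call_too(cond)
            conf = ev.confusion(
                calls, detected["class_label"], classes=syn.CANCER_CLASSES
            )
            perf["too"] = {
                "accuracy": conf["accuracy"],
                "recall": conf["recall"].to_dict(),
                "precision": {k: (None if pd.isna(v) else v) for k, v in conf["precision"].items()},
                "n_detected_cancer": len(detected),
            }
        with open(self.path("performance.json"), "w") as fh:
            json.dump(perf, fh, indent=1, default=float)

    def stage_report(self) -> None:
        scores = pd.read_csv(self._require("scores.tsv", "predict"), sep="\t", index_col=0)
        with open(self._require("performance.json", "evaluate")) as fh:
            perf = json.load(fh)
        thr = perf["ensemble_score"]["threshold"]
        report = build_report(scores, thr)
        report.to_csv(self.path("report.tsv"), sep="\t")

    def write_manifest(self) -> dict:
        files = {}
        for root, _, names in os.walk(self.outdir):
            for name in sorted(names):
                p = os.path.join(root, name)
                rel = os.path.relpath(p, self.outdir)
                if rel == "run_manifest.json":
                    continue
                files[rel] = _sha256(p)
        from cfsig import __version__

        manifest = {"version": __version__, "config": self.cfg, "files": files}
        with open(self.path("run_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest


def build_report(scores: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Per-sample report sheet: feature scores, call, detection-gated TOO.

    Samples not detected as suspected cancer have empty TOO columns
    (tissue-of-origin is only assessed for detection-positive samples).
    """
    if threshold is None:
        raise ValueError("detection threshold is required for the report")
    too_cols = [c for c in scores.columns if c.startswith("too_")]
    out = scores[["amf_score", "cnr_score", "fsr_score", "ensemble_score"]].copy()
    out["detection_call"] = np.where(scores["ensemble_score"] > threshold, "detected", "not_detected")
    for c in too_cols:
        out[c] = scores[c].where(out["detection_call"] == "detected")
    cond = scores[too_cols].rename(columns=lambda c: c[4:])
    too_call = cl.call_too(cond) if len(scores) else pd.Series(dtype=object)
    out["too_call"] = pd.Series(too_call, index=scores.index).where(
        out["detection_call"] == "detected", ""
    )
    out.index.name = "sample_id"
    return out


def run(stage: str = "all", config: dict | str | None = None, outdir: str | None = None) -> dict:
    """Convenience wrapper: run a stage (or everything) under a config."""
    return Pipeline(config, outdir=outdir).run(stage)
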