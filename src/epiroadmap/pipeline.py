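"""End-to-end orchestration of the five analysis stages from one config.

Every stage reads its inputs from files written by the previous stage (no
in-memory-only handoffs), so each is also runnable standalone. All
randomness derives from the single config seed; subsystem seeds are
``seed + stage index``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accessibility as acc
from . import broad as broad_mod
from . import cre as cre_mod
from . import nominate as nom
from .intervals import read_bed, read_genes
from .synthetic import ConfigError, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

ASSAY_FILES = ("ATAC", "H3K4me3", "H3K27ac", "H3K27me3")
REQUIRED_INPUTS = (
    "atac_counts.tsv",
    "bulk_fpkm.tsv",
    "cell_cluster_fpkm.tsv",
    "genes.tsv",
    "tf_catalogue.txt",
)


@dataclass
class RunConfig:
    """Resolved pipeline configuration; every parameter has a default."""

    outdir: str = "epiroadmap_out"
    seed: int = 42
    stages: tuple[str, ...] = ("hESC", "VMC", "EPC", "EC")
    synthetic: dict | None = field(default_factory=dict)  # {} -> defaults
    input_dir: str | None = None  # used when synthetic is None
    # accessibility
    k: int = 6
    min_fold: float = 1.0
    # broad domains
    top_frac: float = 0.05
    gap: int = 1_000
    bpa_target_stage: str = "EPC"
    # cre
    min_bp: int = 1
    # nomination
    target_stages: tuple[str, ...] = ("EPC", "EC")
    z_min: float = 1.5
    min_fpkm: float = 1.0
    endothelial_clusters: tuple[str, ...] = ("endothelial",)
    ratio_min: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "target_stages", "endothelial_clusters"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("stages", "target_stages", "endothelial_clusters"):
            d[key] = list(d[key])
        return d

    def validate(self) -> None:
        if self.synthetic is None:
            if self.input_dir is None:
                raise ConfigError("either a synthetic block or input_dir "
                                  "is required")
            indir = Path(self.input_dir)
            missing = [f for f in REQUIRED_INPUTS if not (indir / f).exists()]
            missing += [
                f"peaks/{s}_{a}.bed"
                for s in self.stages for a in ASSAY_FILES
                if not (indir / "peaks" / f"{s}_{a}.bed").exists()
            ]
            if missing:
                raise ConfigError(f"missing input files: {missing}")


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_genes(input_dir: Path):
    tf_ids = [
        line.strip()
        for line in (input_dir / "tf_catalogue.txt").read_text().splitlines()
        if line.strip()
    ]
    return read_genes(input_dir / "genes.tsv", tf_ids), tf_ids


def run_simulate(cfg: RunConfig, input_dir: Path) -> dict:
    overrides = dict(cfg.synthetic or {})
    syn_cfg = SyntheticConfig(**overrides)
    ds = generate_dataset(syn_cfg, seed=cfg.seed)
    ds.write(input_dir)
    return {
        "n_genes": syn_cfg.n_genes,
        "n_atac_elements": len(ds.atac_elements),
        "n_restricted_tfs": len(ds.truth.restricted_tfs),
        "seed": cfg.seed,
    }


def run_accessibility(cfg: RunConfig, input_dir: Path, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    counts = acc.read_counts_tsv(input_dir / "atac_counts.tsv")
    log2cpm = acc.normalize(counts, "log2cpm")
    coords, evr = acc.pca_samples(log2cpm)
    coords.to_csv(outdir / "sample_pca.tsv", sep="\t",
                  index_label="sample", float_format="%.6g")
    diff = acc.differential_peaks(log2cpm, min_fold=cfg.min_fold)
    rowz = acc.row_zscore(log2cpm.restrict(diff.index))
    assignment = acc.kmeans_peaks(rowz, k=cfg.k, seed=cfg.seed + 2)
    genes, _ = _load_genes(input_dir)
    cluster_gene_sets = {
        label: sorted(acc.cluster_genes(assignment, label, genes))
        for label in sorted(assignment.profiles.index)
    }
    assignment.labels.rename_axis("peak_id").to_frame().to_csv(
        outdir / "peak_clusters.tsv", sep="\t")
    assignment.profiles.to_csv(outdir / "cluster_profiles.tsv", sep="\t",
                               index_label="cluster", float_format="%.6g")
    _write_json(cluster_gene_sets, outdir / "cluster_genes.json")
    return {
        "n_peaks": int(counts.data.shape[0]),
        "n_differential": int(diff.shape[0]),
        "cluster_sizes": assignment.sizes(),
        "pca_explained": [round(float(v), 6) for v in evr[:4]],
    }


def run_broad(cfg: RunConfig, input_dir: Path, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    genes, _ = _load_genes(input_dir)
    bulk = pd.read_csv(input_dir / "bulk_fpkm.tsv", sep="\t", index_col=0)
    bpa_sets: dict[str, set[str]] = {}
    per_stage_counts = {}
    for stage in cfg.stages:
        ps = read_bed(input_dir / "peaks" / f"{stage}_H3K4me3.bed",
                      assay="H3K4me3", stage=stage)
        call = broad_mod.call_broad(ps, gap=cfg.gap, top_frac=cfg.top_frac,
                                    genes=genes)
        call.to_csv(outdir / f"{stage}_broad_domains.tsv", sep="\t",
                    index=False)
        bpa_sets[stage] = broad_mod.bpa_genes(call)
        per_stage_counts[stage] = {
            "n_domains": int(call.shape[0]),
            "n_broad": int(call["is_broad"].sum()),
            "n_exceeds_5kb": int(call["exceeds_5kb"].sum()),
        }
    venn = broad_mod.stage_overlap(bpa_sets)
    _write_json({s: sorted(v) for s, v in bpa_sets.items()},
                outdir / "bpa_genes.json")
    _write_json(venn, outdir / "bpa_venn.json")
    specific, _, medians = broad_mod.stage_specific_bpa_expression(
        bpa_sets, bulk, cfg.bpa_target_stage)
    _write_json({"target_stage": cfg.bpa_target_stage, "genes": specific,
                 "median_fpkm": {s: round(float(v), 6)
                                 for s, v in medians.items()}},
                outdir / "bpa_expression.json")
    return {
        "per_stage": per_stage_counts,
        "venn": venn,
        "n_target_specific_bpa": len(specific),
    }


def run_cre(cfg: RunConfig, input_dir: Path, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    genes, _ = _load_genes(input_dir)
    annotations = {}
    for stage in cfg.stages:
        sets = {
            assay: read_bed(input_dir / "peaks" / f"{stage}_{assay}.bed",
                            assay=assay, stage=stage)
            for assay in ASSAY_FILES
        }
        ann = cre_mod.classify(sets["ATAC"], sets["H3K4me3"], sets["H3K27ac"],
                               sets["H3K27me3"], min_bp=cfg.min_bp,
                               stage=stage, genes=genes)
        ann.to_csv(outdir / f"{stage}_cre.tsv", sep="\t", index=False)
        annotations[stage] = ann
    table = cre_mod.count_types(annotations)
    table.to_csv(outdir / "cre_type_counts.tsv", sep="\t",
                 index_label="stage")
    return {"type_counts": {s: {t: int(v) for t, v in row.items()}
                            for s, row in table.iterrows()}}


def run_nominate(cfg: RunConfig, input_dir: Path, acc_dir: Path,
                 outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    bulk = pd.read_csv(input_dir / "bulk_fpkm.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(input_dir / "cell_cluster_fpkm.tsv", sep="\t",
                           index_col=0)
    _, tf_ids = _load_genes(input_dir)
    cands = nom.stage_specific_tfs(bulk, tf_ids, cfg.target_stages,
                                   cfg.z_min, cfg.min_fpkm)
    funnel = nom.lineage_restriction(cands, clusters,
                                     cfg.endothelial_clusters, cfg.ratio_min) \
        if not cands.empty else cands.assign(restriction_ratio=np.nan,
                                             nominated=False)
    funnel_out = funnel.copy()
    if "specific_stages" in funnel_out.columns:
        funnel_out["specific_stages"] = funnel_out["specific_stages"].map(
            ",".join)
    funnel_out.to_csv(outdir / "tf_funnel.tsv", sep="\t",
                      index_label="gene", float_format="%.6g")
    nominated = sorted(funnel.index[funnel["nominated"]]) \
        if "nominated" in funnel.columns else []

    summary: dict[str, Any] = {
        "n_stage_specific": int(cands.shape[0]),
        "nominated": nominated,
    }

    # motif enrichment per accessibility cluster, when sequences are available
    seq_path = input_dir / "peak_sequences.tsv"
    motif_path = input_dir / "motifs.tsv"
    if seq_path.exists() and motif_path.exists():
        seqs = pd.read_csv(seq_path, sep="\t", index_col=0)["sequence"]
        motifs = pd.read_csv(motif_path, sep="\t", index_col=0)["iupac"]
        try:
            map_df = pd.read_csv(input_dir / "motif_tf_map.tsv", sep="\t",
                                 index_col=0)["tf_gene"]
            motif_tf_map = map_df.to_dict()
        except FileNotFoundError:
            motif_tf_map = {}
        labels = pd.read_csv(acc_dir / "peak_clusters.tsv", sep="\t",
                             index_col=0)["cluster"]
        universe = [p for p in labels.index if p in seqs.index]
        seq_map = seqs.loc[universe].to_dict()
        hits = pd.DataFrame({
            mid: (nom.scan_motifs(iupac, seq_map) > 0)
            for mid, iupac in motifs.items()
        })
        bulk_z = nom.row_zscore_table(bulk)
        top_rows = []
        for label in sorted(labels.unique()):
            members = [p for p in labels.index[labels == label]
                       if p in hits.index]
            if not members:
                continue
            enr = nom.motif_enrichment(members, universe, hits)
            conc = nom.motif_expression_concordance(enr, motif_tf_map, bulk_z,
                                                    cluster_label=label)
            conc.to_csv(outdir / f"motif_concordance_{label}.tsv", sep="\t",
                        index=False, float_format="%.6g")
            best = conc.iloc[0]
            top_rows.append({"cluster": label, "top_motif": best["motif"],
                             "q": round(float(best["q"]), 10),
                             "fold": round(float(best["fold"]), 6)})
        summary["top_motif_per_cluster"] = top_rows
    return summary


def run_all(cfg: RunConfig) -> dict:
    """Execute synthetic generation (optional) and the four analysis stages;
    returns the summary dict also written to ``<outdir>/summary.json``."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    summary: dict[str, Any] = {"config": cfg.to_dict()}
    if cfg.synthetic is not None:
        input_dir = out / "inputs"
        logger.info("stage: simulate -> %s", input_dir)
        summary["synthetic"] = run_simulate(cfg, input_dir)
    else:
        input_dir = Path(cfg.input_dir)
        summary["synthetic"] = None
    stage_dirs = {name: out / name for name in
                  ("accessibility", "broad_domains", "cre", "tf_nomination")}
    logger.info("stage: accessibility")
    summary["accessibility"] = run_accessibility(cfg, input_dir,
                                                 stage_dirs["accessibility"])
    logger.info("stage: broad_domains")
    summary["broad_domains"] = run_broad(cfg, input_dir,
                                         stage_dirs["broad_domains"])
    logger.info("stage: cre")
    summary["cre"] = run_cre(cfg, input_dir, stage_dirs["cre"])
    logger.info("stage: tf_nomination")
    summary["tf_nomination"] = run_nominate(
        cfg, input_dir, stage_dirs["accessibility"],
        stage_dirs["tf_nomination"])
    _write_json(summary, out / "summary.json")
    return summary
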