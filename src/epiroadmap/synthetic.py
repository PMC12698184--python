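"""Synthetic multi-stage chromatin + expression dataset with planted truth.

The generator emulates a stepwise endothelial differentiation time course
(hESC -> vascular mesoderm -> endothelial progenitor -> endothelial cell)
at the resolution the downstream analysis consumes: per-stage peak sets for
four assays (ATAC, H3K4me3, H3K27ac, H3K27me3), an ATAC count matrix over
consensus elements, bulk FPKM per stage, a pseudobulk cell-cluster expression
table standing in for intersected scRNA-seq references, motif-bearing peak
sequences, and a full ground-truth record for recovery tests.

Genes are drawn from archetypes that encode the regulatory behaviours the
analysis is designed to detect:

* ``housekeeping``       — constitutively open, active promoters (T1 everywhere).
* ``pluripotency``       — open/active in hESC, silenced (K27me3) later.
* ``mesoderm``           — transiently active in the mesoderm stage.
* ``identity_EPC_EC``    — endothelial identity genes: chromatin opens at or
  before the EPC stage, expression rises at the same or a later stage; a
  subset carries broad (>5 kb) H3K4me3 domains.
* ``bivalent_early``     — K4me3+K27me3 bivalent promoters in early stages
  that resolve to active on differentiation (a subset stays bivalent into EPC).
* ``restricted_TF``      — endothelial-restricted transcription factors, the
  planted answer of the nomination funnel.
* ``silent``             — no peaks, background expression.

Counts are negative-binomial around archetype means; peak boundaries are
jittered by shifting whole intervals (widths are part of the planted design
and are preserved); expression noise is multiplicative log-normal. With
``SyntheticConfig.noiseless()`` every emitted feature equals its template.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    interval_id,
    write_bed,
    write_genes,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid generator or pipeline configuration."""


STAGES = ("hESC", "VMC", "EPC", "EC")
CELL_CLUSTERS = ("endothelial", "mesenchymal", "cardiac", "other")

# mean FPKM per stage (hESC, VMC, EPC, EC)
EXPRESSION_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "housekeeping": (50.0, 50.0, 50.0, 50.0),
    "pluripotency": (80.0, 40.0, 2.0, 0.5),
    "mesoderm": (1.0, 60.0, 20.0, 5.0),
    "identity_EPC_EC": (0.5, 1.0, 10.0, 60.0),
    "bivalent_early": (1.0, 1.0, 5.0, 10.0),
    "restricted_TF": (0.2, 0.2, 5.0, 60.0),
    "silent": (0.05, 0.05, 0.05, 0.05),
}

# pseudobulk mean per cell cluster (endothelial, mesenchymal, cardiac, other)
CLUSTER_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "housekeeping": (30.0, 30.0, 30.0, 30.0),
    "pluripotency": (0.5, 1.0, 1.0, 20.0),
    "mesoderm": (1.0, 30.0, 50.0, 5.0),
    "identity_EPC_EC": (40.0, 35.0, 35.0, 10.0),
    "bivalent_early": (10.0, 10.0, 10.0, 10.0),
    "restricted_TF": (50.0, 0.3, 0.3, 0.3),
    "silent": (0.05, 0.05, 0.05, 0.05),
}

# Promoter chromatin rules per subtype: assay -> open/marked flag per stage.
# Subtypes refine archetypes where the time course differs within one archetype.
_R = {
    "housekeeping": {
        "atac_prom": (1, 1, 1, 1), "k4me3": (1, 1, 1, 1),
        "k27ac_prom": (1, 1, 1, 1), "k27me3": (0, 0, 0, 0), "distal": (0, 0, 0, 0),
    },
    "pluripotency": {
        "atac_prom": (1, 1, 0, 0), "k4me3": (1, 1, 0, 0),
        "k27ac_prom": (1, 1, 0, 0), "k27me3": (0, 0, 1, 1), "distal": (1, 0, 0, 0),
    },
    "mesoderm": {
        "atac_prom": (0, 1, 1, 0), "k4me3": (0, 1, 1, 0),
        "k27ac_prom": (0, 1, 1, 0), "k27me3": (0, 0, 0, 0), "distal": (0, 1, 0, 0),
    },
    "identity_early": {  # chromatin opens one stage before marks/expression
        "atac_prom": (0, 1, 1, 1), "k4me3": (0, 0, 1, 1),
        "k27ac_prom": (0, 0, 1, 1), "k27me3": (0, 0, 0, 0), "distal": (0, 0, 1, 1),
    },
    "identity_late": {
        "atac_prom": (0, 0, 1, 1), "k4me3": (0, 0, 1, 1),
        "k27ac_prom": (0, 0, 1, 1), "k27me3": (0, 0, 0, 0), "distal": (0, 0, 1, 1),
    },
    "identity_poised": {  # K4me3-only promoter at EPC (type 2a), active at EC
        "atac_prom": (0, 0, 1, 1), "k4me3": (0, 0, 1, 1),
        "k27ac_prom": (0, 0, 0, 1), "k27me3": (0, 0, 0, 0), "distal": (0, 0, 1, 1),
    },
    "bivalent_resolving": {
        "atac_prom": (1, 1, 1, 1), "k4me3": (1, 1, 1, 1),
        "k27ac_prom": (0, 0, 1, 1), "k27me3": (1, 1, 0, 0), "distal": (0, 0, 0, 0),
    },
    "bivalent_late": {  # stays bivalent through EPC (SOX17-like)
        "atac_prom": (1, 1, 1, 1), "k4me3": (1, 1, 1, 1),
        "k27ac_prom": (0, 0, 0, 1), "k27me3": (1, 1, 1, 0), "distal": (0, 0, 0, 0),
    },
    "restricted_TF": {
        "atac_prom": (0, 0, 1, 1), "k4me3": (0, 0, 1, 1),
        "k27ac_prom": (0, 0, 1, 1), "k27me3": (0, 0, 0, 0), "distal": (0, 0, 0, 0),
    },
    "silent": {
        "atac_prom": (0, 0, 0, 0), "k4me3": (0, 0, 0, 0),
        "k27ac_prom": (0, 0, 0, 0), "k27me3": (0, 0, 0, 0), "distal": (0, 0, 0, 0),
    },
}

# planted differential-accessibility profiles (fraction open per stage);
# canonical cluster names are derived from these by the same ordering rule
# the clustering module uses.
PLANTED_PROFILES: dict[str, tuple[int, int, int, int]] = {
    "P1": (1, 0, 0, 0),  # hESC-only (pluripotency enhancers)
    "P2": (1, 1, 0, 0),  # hESC+VMC (pluripotency promoters)
    "P3": (0, 1, 0, 0),  # VMC-only (mesoderm enhancers)
    "P4": (0, 1, 1, 0),  # VMC+EPC (mesoderm promoters)
    "P5": (0, 0, 1, 1),  # EPC+EC (endothelial identity program)
    "P6": (0, 1, 1, 1),  # early-opening identity promoters
}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_MOTIFS = {
    "ETS_core": "MGGAAGTG",   # ETS-family core, planted in the identity program
    "POU_core": "ATGCAAAT",   # OCT-like octamer, planted in hESC-specific peaks
    "EBOX_ctrl": "CACGTGAC",  # unplanted control
}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the standard study conditions."""

    stages: tuple[str, ...] = STAGES
    cell_clusters: tuple[str, ...] = CELL_CLUSTERS
    n_genes: int = 2000
    n_chroms: int = 4
    gene_spacing: int = 20_000
    gene_body: int = 8_000
    first_gene_offset: int = 10_000
    proportions: Mapping[str, float] = field(default_factory=lambda: {
        "housekeeping": 0.30,
        "pluripotency": 0.10,
        "mesoderm": 0.10,
        "identity_EPC_EC": 0.10,
        "bivalent_early": 0.10,
        "restricted_TF": 0.004,
        "silent": 0.296,
    })
    n_reps: int = 2
    open_mean: float = 100.0
    closed_mean: float = 3.0
    count_dispersion: float | None = 10.0  # NB size; None -> deterministic means
    jitter_bp: int = 50
    expression_cv: float = 0.2  # log-normal sigma; 0 -> exact archetype means
    broad_width: tuple[int, int] = (5_000, 15_000)
    narrow_width: tuple[int, int] = (500, 2_000)
    broad_identity_frac: float = 0.2   # identity genes carrying broad domains
    n_broad_pluripotency: int = 40     # broad domains at hESC
    n_broad_mesoderm: int = 40         # broad domains at VMC
    # TF catalogue composition (the nomination funnel's input universe)
    n_tf_identity: int = 50
    n_tf_housekeeping: int = 20
    n_tf_mesoderm: int = 20
    n_tf_pluripotency: int = 10
    # sequences/motifs
    peak_seq_len: int = 100
    motif_insert_rate: float = 0.8
    expressed_fpkm: float = 5.0  # threshold for "expressed" in invariants

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"archetype proportions sum to {total}, expected 1.0")
        if len(self.stages) != 4:
            raise ConfigError("generator models exactly four stages")

    @classmethod
    def noiseless(cls, **overrides) -> "SyntheticConfig":
        base = dict(jitter_bp=0, count_dispersion=None, expression_cv=0.0)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proportions"] = dict(self.proportions)
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth: what a perfect analysis should recover."""

    archetype: dict[str, str]            # gene -> archetype label
    subtype: dict[str, str]              # gene -> chromatin-rule subtype
    broad_genes: dict[str, list[str]]    # stage -> genes with planted broad domains
    cre_type: dict[str, dict[str, str]]  # gene -> stage -> planted promoter CRE type
    restricted_tfs: list[str]
    tf_catalogue: list[str]
    peak_profile: dict[str, str]         # differential peak id -> planted profile
    profile_cluster: dict[str, str]      # planted profile -> canonical C# name
    stage_specific_tf_truth: list[str]   # genes passing the bulk-specific stage
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=2, sort_keys=True))


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything the generator emits."""

    config: SyntheticConfig
    genes: list[GeneModel]
    peaks: dict[tuple[str, str], PeakSet]       # (stage, assay) -> PeakSet
    atac_elements: PeakSet                      # consensus element templates
    counts: pd.DataFrame                        # elements x (stage_rep) raw counts
    bulk_expression: pd.DataFrame               # genes x stages, FPKM
    cluster_expression: pd.DataFrame            # genes x cell clusters
    tf_catalogue: list[str]
    motifs: dict[str, str]                      # motif_id -> IUPAC
    motif_tf_map: dict[str, str]                # motif_id -> TF gene id
    sequences: dict[str, str]                   # element id -> sequence
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        """Serialize every table in the plain-text formats the pipeline reads."""
        out = Path(outdir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        for (stage, assay), ps in sorted(self.peaks.items()):
            write_bed(ps, out / "peaks" / f"{stage}_{assay}.bed")
        write_bed(self.atac_elements, out / "peaks" / "atac_elements.bed")
        self.counts.to_csv(out / "atac_counts.tsv", sep="\t",
                           index_label="peak_id")
        self.bulk_expression.to_csv(out / "bulk_fpkm.tsv", sep="\t",
                                    index_label="gene_id", float_format="%.6g")
        self.cluster_expression.to_csv(out / "cell_cluster_fpkm.tsv", sep="\t",
                                       index_label="gene_id", float_format="%.6g")
        write_genes(self.genes, out / "genes.tsv")
        (out / "tf_catalogue.txt").write_text(
            "\n".join(self.tf_catalogue) + "\n")
        pd.DataFrame(sorted(self.motifs.items()),
                     columns=["motif_id", "iupac"]).to_csv(
            out / "motifs.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(self.motif_tf_map.items()),
                     columns=["motif_id", "tf_gene"]).to_csv(
            out / "motif_tf_map.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(self.sequences.items()),
                     columns=["peak_id", "sequence"]).to_csv(
            out / "peak_sequences.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")
        (out / "config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True))


def canonical_cluster_names(profiles: Mapping[str, tuple]) -> dict[str, str]:
    """Order planted profiles the way the clustering module orders clusters:
    by last stage with above-average (z > 0) signal, then peak height
    descending, then the profile tuple."""
    def key(item):
        _, prof = item
        v = np.asarray(prof, dtype=float)
        z = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
        positive = np.flatnonzero(z > 0)
        last_on = int(positive[-1]) if len(positive) else -1
        return (last_on, -z.max(), tuple(v))
    ordered = sorted(profiles.items(), key=key)
    return {pid: f"C{i + 1}" for i, (pid, _) in enumerate(ordered)}


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return np.rint(mean).astype(np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(np.int64)


def _lognormal_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(shape)
    return rng.lognormal(mean=0.0, sigma=cv, size=shape)


def plant_broad_domain(rng: np.random.Generator, gene: GeneModel,
                       broad: bool, config: SyntheticConfig) -> GenomicInterval:
    """An H3K4me3 interval covering the TSS; width from the broad range
    [5000, 15000) for identity/broad genes, else the narrow range [500, 2000)."""
    lo, hi = config.broad_width if broad else config.narrow_width
    width = int(rng.integers(lo, hi))
    start = max(0, gene.tss - width // 2)
    return GenomicInterval(gene.chrom, start, start + width)


def _realize_motif(rng: np.random.Generator, iupac: str) -> str:
    return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in iupac)


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int = 42) -> SyntheticDataset:
    """Build the full labelled dataset. Deterministic given (config, seed)."""
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(seed)
    stages = list(cfg.stages)
    n_stage = len(stages)

    # --- gene layout -------------------------------------------------------
    genes_per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        pos = cfg.first_gene_offset + (i % genes_per_chrom) * cfg.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        gid = f"G{i:04d}"
        genes.append(GeneModel.from_body(gid, chrom, strand,
                                         pos, pos + cfg.gene_body))

    # --- archetype assignment ---------------------------------------------
    counts_per = {a: int(round(p * cfg.n_genes))
                  for a, p in cfg.proportions.items() if a != "silent"}
    order = rng.permutation(cfg.n_genes)
    archetype: dict[str, str] = {}
    cursor = 0
    for label in ("housekeeping", "pluripotency", "mesoderm",
                  "identity_EPC_EC", "bivalent_early", "restricted_TF"):
        n = counts_per.get(label, 0)
        for j in order[cursor:cursor + n]:
            archetype[genes[j].gene_id] = label
        cursor += n
    for j in order[cursor:]:
        archetype[genes[j].gene_id] = "silent"

    by_arch: dict[str, list[str]] = {}
    for gid in (g.gene_id for g in genes):
        by_arch.setdefault(archetype[gid], []).append(gid)
    for lst in by_arch.values():
        lst.sort()

    # --- subtypes ----------------------------------------------------------
    subtype: dict[str, str] = {}
    identity = by_arch.get("identity_EPC_EC", [])
    half = len(identity) // 2
    early, late = identity[:half], identity[half:]
    poised = late[: len(late) // 2]
    for gid in early:
        subtype[gid] = "identity_early"
    for gid in late:
        subtype[gid] = "identity_poised" if gid in set(poised) else "identity_late"
    bivalent = by_arch.get("bivalent_early", [])
    n_late_biv = len(bivalent) // 4
    for i, gid in enumerate(bivalent):
        subtype[gid] = "bivalent_late" if i < n_late_biv else "bivalent_resolving"
    for label in ("housekeeping", "pluripotency", "mesoderm",
                  "restricted_TF", "silent"):
        for gid in by_arch.get(label, []):
            subtype[gid] = label

    # --- broad-domain planting --------------------------------------------
    n_broad_identity = int(round(cfg.broad_identity_frac * len(identity)))
    broad_identity = list(rng.choice(identity, size=n_broad_identity,
                                     replace=False)) if n_broad_identity else []
    broad_identity.sort()
    epc_only = set(broad_identity[: len(broad_identity) // 2])
    restricted = by_arch.get("restricted_TF", [])
    pluri = by_arch.get("pluripotency", [])
    meso = by_arch.get("mesoderm", [])
    broad_pluri = sorted(rng.choice(pluri, size=min(cfg.n_broad_pluripotency,
                                                    len(pluri)), replace=False))
    broad_meso = sorted(rng.choice(meso, size=min(cfg.n_broad_mesoderm,
                                                  len(meso)), replace=False))
    broad_genes: dict[str, set[str]] = {s: set() for s in stages}
    broad_genes[stages[0]].update(broad_pluri)
    broad_genes[stages[1]].update(broad_meso)
    broad_genes[stages[2]].update(broad_identity)
    broad_genes[stages[2]].update(restricted)
    broad_genes[stages[3]].update(g for g in broad_identity if g not in epc_only)
    broad_genes[stages[3]].update(restricted)

    # --- TF catalogue ------------------------------------------------------
    def pick(pool: list[str], n: int) -> list[str]:
        return sorted(rng.choice(pool, size=min(n, len(pool)), replace=False))

    tf_identity = pick(identity, cfg.n_tf_identity)
    tf_hk = pick(by_arch.get("housekeeping", []), cfg.n_tf_housekeeping)
    tf_meso = pick(meso, cfg.n_tf_mesoderm)
    tf_pluri = pick(pluri, cfg.n_tf_pluripotency)
    tf_catalogue = sorted(set(restricted) | set(tf_identity) | set(tf_hk)
                          | set(tf_meso) | set(tf_pluri))
    gene_models = [dataclasses.replace(g, is_tf=g.gene_id in set(tf_catalogue))
                   for g in genes]
    gene_by_id = {g.gene_id: g for g in gene_models}

    # --- peak emission -----------------------------------------------------
    def jitter() -> int:
        return int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1)) \
            if cfg.jitter_bp > 0 else 0

    peak_lists: dict[tuple[str, str], list[GenomicInterval]] = {
        (s, a): [] for s in stages
        for a in ("ATAC", "H3K4me3", "H3K27ac", "H3K27me3")}

    # element templates for the ATAC count matrix
    element_rows: list[tuple[str, GenomicInterval, str, str, tuple]] = []
    # (element_id, template, gene, role, accessibility profile)

    # Pre-draw K4me3 widths per (gene, stage) so noiseless runs stay stable
    for g in gene_models:
        gid = g.gene_id
        rules = _R[subtype[gid]]
        prom = GenomicInterval(g.chrom, max(0, g.tss - 250), g.tss + 250)
        d_anchor = max(200, g.tss - 5_000)
        dist = GenomicInterval(g.chrom, d_anchor - 200, d_anchor + 200)
        atac_profile = rules["atac_prom"]
        if any(atac_profile):
            element_rows.append((interval_id(prom), prom, gid, "promoter",
                                 atac_profile))
        if any(rules["distal"]):
            element_rows.append((interval_id(dist), dist, gid, "distal",
                                 rules["distal"]))
        for si, stage in enumerate(stages):
            if atac_profile[si]:
                peak_lists[(stage, "ATAC")].append(prom.shifted(jitter()))
            if rules["distal"][si]:
                peak_lists[(stage, "ATAC")].append(dist.shifted(jitter()))
            if rules["k4me3"][si]:
                iv = plant_broad_domain(rng, g, gid in broad_genes[stage], cfg)
                peak_lists[(stage, "H3K4me3")].append(iv.shifted(jitter()))
            if rules["k27ac_prom"][si]:
                iv = GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 500)
                peak_lists[(stage, "H3K27ac")].append(iv.shifted(jitter()))
            if rules["distal"][si]:
                iv = GenomicInterval(g.chrom, max(0, d_anchor - 400),
                                     d_anchor + 400)
                peak_lists[(stage, "H3K27ac")].append(iv.shifted(jitter()))
            if rules["k27me3"][si]:
                iv = GenomicInterval(g.chrom, max(0, g.tss - 1_000), g.tss + 1_000)
                peak_lists[(stage, "H3K27me3")].append(iv.shifted(jitter()))

    peaks = {
        (s, a): PeakSet(ivs, assay=a, stage=s, name=f"{s}_{a}")
        for (s, a), ivs in peak_lists.items()
    }

    # --- ATAC count matrix over element templates --------------------------
    element_rows.sort(key=lambda r: (r[1].chrom, r[1].start, r[1].end))
    element_ids = [r[0] for r in element_rows]
    profiles = np.array([r[4] for r in element_rows], dtype=float)
    sample_names = [f"{s}_r{r + 1}" for s in stages for r in range(cfg.n_reps)]
    mean_mat = np.where(
        np.repeat(profiles, cfg.n_reps, axis=1) > 0, cfg.open_mean,
        cfg.closed_mean)
    counts = _nb_counts(rng, mean_mat, cfg.count_dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(element_ids, name="peak_id"),
                             columns=sample_names)
    atac_elements = PeakSet([r[1] for r in element_rows], assay="ATAC",
                            name="atac_elements")

    # --- expression tables -------------------------------------------------
    gene_ids = [g.gene_id for g in gene_models]
    bulk_means = np.array([EXPRESSION_PROFILES[archetype[gid]]
                           for gid in gene_ids])
    bulk = bulk_means * _lognormal_noise(rng, bulk_means.shape,
                                         cfg.expression_cv)
    bulk_df = pd.DataFrame(bulk, index=pd.Index(gene_ids, name="gene_id"),
                           columns=stages)
    clus_means = np.array([CLUSTER_PROFILES[archetype[gid]]
                           for gid in gene_ids])
    clus = clus_means * _lognormal_noise(rng, clus_means.shape,
                                         cfg.expression_cv)
    clus_df = pd.DataFrame(clus, index=pd.Index(gene_ids, name="gene_id"),
                           columns=list(cfg.cell_clusters))

    # --- planted CRE types (promoters with an ATAC peak) --------------------
    from .cre import cre_type  # local import to avoid a cycle

    cre_truth: dict[str, dict[str, str]] = {}
    for g in gene_models:
        gid = g.gene_id
        rules = _R[subtype[gid]]
        per_stage = {}
        for si, stage in enumerate(stages):
            if rules["atac_prom"][si]:
                per_stage[stage] = cre_type(bool(rules["k4me3"][si]),
                                            bool(rules["k27ac_prom"][si]),
                                            bool(rules["k27me3"][si]))
        if per_stage:
            cre_truth[gid] = per_stage

    # --- differential-peak cluster truth ------------------------------------
    peak_profile: dict[str, str] = {}
    prof_lookup = {v: k for k, v in PLANTED_PROFILES.items()}
    for eid, _, gid, role, prof in element_rows:
        key = prof_lookup.get(tuple(prof))
        if key is not None:
            peak_profile[eid] = key
    profile_cluster = canonical_cluster_names(PLANTED_PROFILES)

    # --- sequences with planted motifs --------------------------------------
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    motif_targets = {"P5": "ETS_core", "P1": "POU_core"}
    for eid, _tpl, _gid, _role, prof in element_rows:
        seq = "".join(bases[rng.integers(0, 4, size=cfg.peak_seq_len)])
        pid = prof_lookup.get(tuple(prof))
        motif_id = motif_targets.get(pid) if pid else None
        if motif_id and rng.random() < cfg.motif_insert_rate:
            inst = _realize_motif(rng, DEFAULT_MOTIFS[motif_id])
            pos = int(rng.integers(0, cfg.peak_seq_len - len(inst) + 1))
            seq = seq[:pos] + inst + seq[pos + len(inst):]
        sequences[eid] = seq

    motif_tf_map = {}
    if restricted:
        motif_tf_map["ETS_core"] = restricted[0]
    if tf_pluri:
        motif_tf_map["POU_core"] = tf_pluri[0]

    # TFs that the bulk-specificity stage should return (EPC/EC-specific):
    # restricted TFs plus identity-archetype catalogue members.
    stage_specific_truth = sorted(set(restricted) | set(tf_identity))

    truth = SyntheticTruth(
        archetype=archetype,
        subtype=subtype,
        broad_genes={s: sorted(v) for s, v in broad_genes.items()},
        cre_type=cre_truth,
        restricted_tfs=sorted(restricted),
        tf_catalogue=tf_catalogue,
        peak_profile=peak_profile,
        profile_cluster=profile_cluster,
        stage_specific_tf_truth=stage_specific_truth,
        seed=seed,
        config=cfg.to_dict(),
    )
    return SyntheticDataset(
        config=cfg,
        genes=gene_models,
        peaks=peaks,
        atac_elements=atac_elements,
        counts=counts_df,
        bulk_expression=bulk_df,
        cluster_expression=clus_df,
        tf_catalogue=tf_catalogue,
        motifs=dict(DEFAULT_MOTIFS),
        motif_tf_map=motif_tf_map,
        sequences=sequences,
        truth=truth,
    )
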