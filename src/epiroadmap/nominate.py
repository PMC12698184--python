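"""Stage-specific TF scoring, lineage-restriction filtering, TSS-window mark
matrices, consensus-motif scanning, and motif-expression concordance.

The nomination funnel mirrors the two-filter intersection logic used to go
from stage-specific candidates to lineage-restricted regulators:

1. *bulk specificity* — a catalogue TF is specific to a stage when its FPKM
   there is at least ``min_fpkm`` and its row z-score at least ``z_min``;
   candidates are TFs specific to at least one target stage (EPC or EC by
   default).
2. *lineage restriction* — in a pseudobulk cell-cluster table, the ratio of
   mean expression in endothelial clusters to the mean over all clusters
   must reach ``ratio_min``.

A TF is nominated iff it passes both filters (an AND over the two data
modalities). The funnel is monotone: raising either threshold never adds a
nominated TF.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .intervals import GeneModel, PeakSet
from .synthetic import IUPAC

logger = logging.getLogger(__name__)


def row_zscore_table(df: pd.DataFrame) -> pd.DataFrame:
    """Row z-score of an expression table; constant rows become all-zero."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    z = df.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z[sd == 0] = 0.0
    return z


def stage_specific_tfs(
    bulk: pd.DataFrame,
    tf_catalogue: Iterable[str],
    target_stages: Sequence[str] = ("EPC", "EC"),
    z_min: float = 1.5,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """TFs specific to at least one target stage in the bulk table.

    Returns a DataFrame indexed by gene with per-stage z columns, the list of
    ``specific_stages``, and FPKM at those stages. Constant-expression rows
    are skipped with a log notice (their z-score is undefined).
    """
    if bulk.shape[1] < 3:
        raise ValueError("stage specificity needs >= 3 stages")
    missing = [s for s in target_stages if s not in bulk.columns]
    if missing:
        raise ValueError(f"target stages not in table: {missing}")
    catalogue = sorted(set(tf_catalogue) & set(bulk.index))
    if not catalogue:
        raise ValueError("TF catalogue does not intersect the expression table")
    sub = bulk.loc[catalogue]
    constant = sub.std(axis=1, ddof=0) == 0
    if constant.any():
        logger.info("skipping %d constant-expression TFs", int(constant.sum()))
        sub = sub[~constant]
    z = row_zscore_table(sub)
    rows = []
    for gene in sub.index:
        specific = [s for s in bulk.columns
                    if sub.at[gene, s] >= min_fpkm and z.at[gene, s] >= z_min]
        hit = [s for s in specific if s in target_stages]
        if hit:
            rows.append({"gene": gene, "specific_stages": hit,
                         **{f"z_{s}": z.at[gene, s] for s in bulk.columns}})
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["specific_stages"]).rename_axis("gene")


def lineage_restriction(
    candidates: pd.DataFrame,
    clusters: pd.DataFrame,
    endothelial_clusters: Sequence[str] = ("endothelial",),
    ratio_min: float = 2.0,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Add ``restriction_ratio`` and ``nominated`` to candidate TFs.

    ratio = mean(expression in endothelial clusters) / (mean over all
    clusters + eps); nominated iff ratio >= ratio_min. Genes missing from
    the cluster table get ratio 0.
    """
    missing = [c for c in endothelial_clusters if c not in clusters.columns]
    if missing:
        raise ValueError(f"endothelial labels not in cluster table: {missing}")
    out = candidates.copy()
    ratios = []
    for gene in out.index:
        if gene not in clusters.index:
            logger.info("TF %s absent from cluster table; ratio 0", gene)
            ratios.append(0.0)
            continue
        row = clusters.loc[gene]
        endo = float(row[list(endothelial_clusters)].mean())
        overall = float(row.mean())
        ratios.append(endo / (overall + eps))
    out["restriction_ratio"] = ratios
    out["nominated"] = out["restriction_ratio"] >= ratio_min
    return out


def nominate_tfs(
    bulk: pd.DataFrame,
    clusters: pd.DataFrame,
    tf_catalogue: Iterable[str],
    target_stages: Sequence[str] = ("EPC", "EC"),
    z_min: float = 1.5,
    min_fpkm: float = 1.0,
    endothelial_clusters: Sequence[str] = ("endothelial",),
    ratio_min: float = 2.0,
) -> pd.DataFrame:
    """The full funnel: bulk specificity AND lineage restriction."""
    cands = stage_specific_tfs(bulk, tf_catalogue, target_stages, z_min,
                               min_fpkm)
    if cands.empty:
        cands["restriction_ratio"] = pd.Series(dtype=float)
        cands["nominated"] = pd.Series(dtype=bool)
        return cands
    return lineage_restriction(cands, clusters, endothelial_clusters,
                               ratio_min)


def tss_mark_matrix(
    marks: Mapping[tuple[str, str], PeakSet],
    genes: Sequence[GeneModel],
    halfwidth: int = 1_000,
) -> pd.DataFrame:
    """Genes x (stage, mark) z-scored mark signal in TSS +/- halfwidth windows.

    With peak sets as input the raw signal is the number of window bases
    covered by peaks, RPKM-normalized by window length and the mark's total
    covered bases in that stage, then row z-scored per gene (constant rows
    become all-zero). Windows at chromosome starts truncate at 0.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    cols = {}
    for (stage, mark), ps in sorted(marks.items()):
        by_chrom = ps.by_chrom()
        lib = sum(int((arr[:, 1] - arr[:, 0]).sum())
                  for arr in by_chrom.values())
        vals = np.zeros(len(genes))
        for i, g in enumerate(genes):
            lo = g.tss - halfwidth
            if lo < 0:
                logger.debug("window for %s truncated at chromosome start",
                             g.gene_id)
                lo = 0
            hi = g.tss + halfwidth
            arr = by_chrom.get(g.chrom)
            if arr is None:
                continue
            ov = np.minimum(arr[:, 1], hi) - np.maximum(arr[:, 0], lo)
            cov = int(ov[ov > 0].sum())
            if cov and lib:
                vals[i] = cov * 1e9 / ((hi - lo) * lib)
        cols[(stage, mark)] = vals
    df = pd.DataFrame(cols, index=pd.Index([g.gene_id for g in genes],
                                           name="gene_id"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["stage", "mark"])
    return row_zscore_table(df)


def _revcomp_iupac(motif: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in reversed(motif))


def _count_forward(pattern: str, seq: str) -> int:
    """Sliding-window IUPAC matches on the forward strand, overlaps counted."""
    sets = [IUPAC[c] for c in pattern]
    m, n = len(pattern), len(seq)
    return sum(
        all(seq[i + j] in sets[j] for j in range(m))
        for i in range(n - m + 1)
    )


def scan_motifs(consensus: str, sequences: Mapping[str, str]) -> pd.Series:
    """Occurrences of an IUPAC consensus per peak sequence, both strands.

    Convention: forward-strand matches of the motif plus forward-strand
    matches of its reverse complement (equivalently, matches of the motif on
    the minus strand); when the motif equals its own reverse complement the
    two strands give the same sites, which are counted once. Overlapping
    matches count. Sequences must be over A/C/G/T.
    """
    bad = set(consensus.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbol(s): {sorted(bad)}")
    motif = consensus.upper()
    rc = _revcomp_iupac(motif)
    counts = {}
    for pid, seq in sequences.items():
        s = seq.upper()
        c = _count_forward(motif, s)
        if rc != motif:
            c += _count_forward(rc, s)
        counts[pid] = c
    return pd.Series(counts, name=motif, dtype=int)


def motif_enrichment(
    cluster_ids: Iterable[str],
    universe_ids: Iterable[str],
    hit_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of motif hits in a peak cluster.

    ``hit_flags`` is peaks x motifs booleans (>=1 occurrence). For each motif
    with K hits among M universe peaks and k hits among the n cluster peaks,
    p = P[X >= k], X ~ Hypergeom(M, K, n); fold = cluster hit rate /
    universe hit rate; q = Benjamini-Hochberg across motifs.
    """
    cluster = set(cluster_ids)
    universe = set(universe_ids)
    if not cluster <= universe:
        raise ValueError("cluster peaks must be a subset of the universe")
    flags = hit_flags.loc[sorted(universe)]
    n = len(cluster)
    M = len(universe)
    in_cluster = flags.index.isin(cluster)
    rows = []
    for motif in flags.columns:
        col = flags[motif].to_numpy(dtype=bool)
        K = int(col.sum())
        k = int(col[in_cluster].sum())
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        cluster_rate = k / n if n else 0.0
        bg_rate = K / M if M else 0.0
        fold = cluster_rate / bg_rate if bg_rate > 0 else np.inf if k else 0.0
        rows.append({"motif": motif, "cluster_hits": k, "cluster_size": n,
                     "universe_hits": K, "universe_size": M,
                     "fold": fold, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("motif")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "p", "motif"])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def motif_expression_concordance(
    enrichment: pd.DataFrame,
    motif_tf_map: Mapping[str, str],
    bulk_z: pd.DataFrame,
    cluster_label: str = "",
) -> pd.DataFrame:
    """Join motif enrichment with the mapped TF's bulk expression z-profile,
    ranked by q ascending then fold descending. Unmapped motifs are retained
    with null TF fields and logged."""
    rows = []
    for motif, row in enrichment.iterrows():
        tf = motif_tf_map.get(motif)
        entry = {"motif": motif, "cluster": cluster_label, "tf": tf,
                 "fold": row["fold"], "p": row["p"], "q": row["q"]}
        if tf is None:
            logger.info("motif %s has no TF mapping", motif)
            for s in bulk_z.columns:
                entry[f"z_{s}"] = np.nan
        elif tf in bulk_z.index:
            for s in bulk_z.columns:
                entry[f"z_{s}"] = float(bulk_z.at[tf, s])
        else:
            logger.info("TF %s absent from expression table", tf)
            for s in bulk_z.columns:
                entry[f"z_{s}"] = np.nan
        rows.append(entry)
    if not rows:
        return pd.DataFrame(
            columns=["motif", "cluster", "tf", "fold", "p", "q"])
    out = pd.DataFrame(rows)
    return out.sort_values(["q", "fold", "motif"],
                           ascending=[True, False, True],
                           kind="stable").reset_index(drop=True)
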