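"""Chromatin-state classification of open-chromatin cis-regulatory elements.

Each ATAC peak is one CRE; its type is a pure function of which histone-mark
peak sets it overlaps:

=========  =======  =======  ========
type       H3K4me3  H3K27ac  H3K27me3
=========  =======  =======  ========
T1         yes      yes      (any)
T2a        yes      no       no
T2b        yes      no       yes
T3         no       yes      (any)
unmarked   no       no       (any)
=========  =======  =======  ========

T1 is the active-promoter state (accessible + H3K4me3 + H3K27ac), T2b the
bivalent (poised) state, T3 the enhancer-like state. H3K27me3 does not
demote T1 or T3 — active marks dominate — and the raw flag triple is kept in
the output so users can re-filter.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .intervals import GeneModel, PeakSet, nearest_tss_table, overlaps

logger = logging.getLogger(__name__)

CRE_TYPES = ("T1", "T2a", "T2b", "T3", "unmarked")


def cre_type(k4me3: bool, k27ac: bool, k27me3: bool) -> str:
    """The CRE truth table; deterministic and order-independent."""
    if k4me3 and k27ac:
        return "T1"
    if k4me3 and not k27ac:
        return "T2b" if k27me3 else "T2a"
    if k27ac:
        return "T3"
    return "unmarked"


def _check_assay(ps: PeakSet, expected: str, role: str) -> None:
    if ps.assay is not None and ps.assay != expected:
        raise ValueError(
            f"{role} peak set labelled {ps.assay!r}, expected {expected!r}")


def classify(
    atac: PeakSet,
    k4me3: PeakSet,
    k27ac: PeakSet,
    k27me3: PeakSet,
    min_bp: int = 1,
    stage: str | None = None,
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Classify every ATAC peak from its histone-mark overlaps (>= min_bp).

    Returns one row per ATAC peak: chrom/start/end/stage, the three boolean
    flags, ``cre_type``, and the nearest-TSS gene when models are given.
    """
    _check_assay(atac, "ATAC", "atac")
    _check_assay(k4me3, "H3K4me3", "k4me3")
    _check_assay(k27ac, "H3K27ac", "k27ac")
    _check_assay(k27me3, "H3K27me3", "k27me3")
    df = atac.to_dataframe()
    df["stage"] = stage if stage is not None else (atac.stage or "")
    df["k4me3"] = overlaps(atac, k4me3, min_bp)
    df["k27ac"] = overlaps(atac, k27ac, min_bp)
    df["k27me3"] = overlaps(atac, k27me3, min_bp)
    df["cre_type"] = [cre_type(a, b, c) for a, b, c in
                      zip(df["k4me3"], df["k27ac"], df["k27me3"])]
    if genes is not None:
        from .intervals import GenomicInterval
        ivs = [GenomicInterval(r.chrom, r.start, r.end)
               for r in df[["chrom", "start", "end"]].itertuples(index=False)]
        df["gene"] = nearest_tss_table(ivs, genes)["gene"].to_numpy()
    return df


def count_types(annotations: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stage x CRE-type integer table (unmarked reported as its own column)."""
    rows = {}
    for stage, ann in annotations.items():
        counts = ann["cre_type"].value_counts()
        rows[stage] = [int(counts.get(t, 0)) for t in CRE_TYPES]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CRE_TYPES))


def cre_gene_table(
    annotations: Mapping[str, pd.DataFrame],
) -> dict[str, dict[str, set[str]]]:
    """gene -> stage -> set of CRE types among the peaks assigned to it."""
    out: dict[str, dict[str, set[str]]] = {}
    for stage, ann in annotations.items():
        if "gene" not in ann.columns:
            raise ValueError("annotations must carry a gene column "
                             "(classify with gene models)")
        for gene, ctype in zip(ann["gene"], ann["cre_type"]):
            if gene == "unassigned":
                continue
            out.setdefault(gene, {}).setdefault(stage, set()).add(ctype)
    return out
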