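"""Broad H3K4me3 domain calling and broad-peak-associated (BPA) gene sets.

Unusually wide H3K4me3 domains preferentially mark cell-identity genes. Per
stage, H3K4me3 peaks are merged (default gap 1 kb) and the widest top
fraction (default 5%) is called broad, with an inclusive tie policy at the
cutoff width so the call is invariant to input order. A separate flag
records whether a domain exceeds 5 kb (strict inequality).
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    merge_intervals,
    nearest_tss_table,
)

logger = logging.getLogger(__name__)

BROAD_KB_THRESHOLD = 5_000  # ">5 kb" flag boundary, strict


def call_broad(
    k4me3: PeakSet | Sequence[GenomicInterval],
    gap: int = 1_000,
    top_frac: float = 0.05,
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Merge H3K4me3 peaks and mark the top ``top_frac`` widest as broad.

    Returns a DataFrame sorted by width descending (ties by chrom, start)
    with columns chrom/start/end/width/rank/is_broad/exceeds_5kb and, when
    gene models are supplied, the nearest-TSS gene of each domain centre.
    """
    if not (0 < top_frac < 1):
        raise ValueError(f"top_frac must be in (0, 1), got {top_frac}")
    merged = merge_intervals(list(k4me3), gap=gap)
    if not merged:
        logger.warning("call_broad: empty peak set, empty call returned")
        cols = ["chrom", "start", "end", "width", "rank", "is_broad",
                "exceeds_5kb", "gene"]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in merged],
            "start": [iv.start for iv in merged],
            "end": [iv.end for iv in merged],
        }
    )
    df["width"] = df["end"] - df["start"]
    df = df.sort_values(["width", "chrom", "start"],
                        ascending=[False, True, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    n_broad = math.ceil(top_frac * len(df))
    cutoff_width = int(df["width"].iloc[n_broad - 1])
    # inclusive tie policy: everything at the cutoff width is broad
    df["is_broad"] = df["width"] >= cutoff_width
    df["exceeds_5kb"] = df["width"] > BROAD_KB_THRESHOLD
    if genes is not None:
        ivs = [GenomicInterval(r.chrom, r.start, r.end)
               for r in df.itertuples(index=False)]
        df["gene"] = nearest_tss_table(ivs, genes)["gene"].to_numpy()
    else:
        df["gene"] = pd.NA
    return df


def bpa_genes(call: pd.DataFrame,
              genes: Sequence[GeneModel] | None = None) -> set[str]:
    """Deduplicated nearest-TSS genes of the broad domains; sentinel dropped."""
    broad = call[call["is_broad"]]
    if broad.empty:
        return set()
    if "gene" in broad.columns and broad["gene"].notna().all():
        assigned = broad["gene"]
    else:
        if genes is None:
            raise ValueError("gene models required when call lacks gene column")
        ivs = [GenomicInterval(r.chrom, r.start, r.end)
               for r in broad.itertuples(index=False)]
        assigned = nearest_tss_table(ivs, genes)["gene"]
    return set(assigned) - {"unassigned"}


def stage_overlap(bpa_sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Counts of every exclusive region of the n-set Venn (keys are
    '&'-joined stage names in the given stage order); regions sum to the
    union size."""
    stages = list(bpa_sets)
    universe = set().union(*bpa_sets.values()) if bpa_sets else set()
    regions: dict[str, int] = {}
    n = len(stages)
    for mask in range(1, 2 ** n):
        members = [stages[i] for i in range(n) if mask >> i & 1]
        inside = set.intersection(*(bpa_sets[s] for s in members))
        outside = set().union(*(bpa_sets[s] for s in stages if s not in members),
                              set())
        regions["&".join(members)] = len(inside - outside)
    assert sum(regions.values()) == len(universe)
    return regions


def stage_specific_bpa_expression(
    bpa_sets: Mapping[str, set[str]],
    expression: pd.DataFrame,
    target_stage: str,
) -> tuple[list[str], pd.DataFrame, dict[str, float]]:
    """Genes broad ONLY in ``target_stage`` and their per-stage expression.

    Returns (gene list, expression sub-table genes x stages, per-stage
    medians). Empty when no gene is specifically broad in the target.
    """
    if target_stage not in bpa_sets:
        raise ValueError(f"unknown stage {target_stage!r}")
    others = set().union(*(v for s, v in bpa_sets.items() if s != target_stage),
                         set())
    specific = sorted((bpa_sets[target_stage] - others)
                      & set(expression.index))
    if not specific:
        logger.warning("no stage-specific BPA genes for %s", target_stage)
        return [], expression.iloc[0:0], {}
    sub = expression.loc[specific]
    medians = sub.median(axis=0).to_dict()
    return specific, sub, medians
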