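"""Genomic interval primitives and the overlap/merge/nearest kernel.

All coordinates are 0-based, half-open (BED convention). Interval widths are
therefore ``end - start`` and two intervals sharing only a boundary base
(``[100, 200)`` and ``[200, 300)``) do not overlap but do *touch*, which
matters for :func:`merge_intervals` with ``gap=0``.

Peaks are unstranded; strand is carried only on gene models, where it fixes
the TSS at the 5' end of the gene body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSAYS = ("ATAC", "H3K4me3", "H3K27ac", "H3K27me3")

UNASSIGNED = "unassigned"


class BedParseError(ValueError):
    """A malformed line in a BED file, reported with its 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a chromosome.

    Ordering is lexicographic on (chrom, start, end), the canonical sort used
    throughout the package.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floored — the deterministic peak-centre convention."""
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        new_start = max(0, self.start + offset)
        return GenomicInterval(self.chrom, new_start, new_start + self.width,
                               self.strand, self.score)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_id(iv: GenomicInterval) -> str:
    return iv.name


def parse_interval_id(peak_id: str) -> GenomicInterval:
    chrom, _, span = peak_id.rpartition(":")
    start, _, end = span.partition("-")
    return GenomicInterval(chrom, int(start), int(end))


class PeakSet:
    """A sorted, deduplicated collection of intervals from one assay/stage.

    Construction always sorts by (chrom, start, end) and drops duplicate
    coordinate triples, so downstream kernels may assume both invariants.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        assay: str | None = None,
        stage: str | None = None,
        name: str = "",
    ) -> None:
        seen: dict[tuple[str, int, int], GenomicInterval] = {}
        for iv in intervals:
            seen.setdefault((iv.chrom, iv.start, iv.end), iv)
        self.intervals: tuple[GenomicInterval, ...] = tuple(sorted(seen.values()))
        self.assay = assay
        self.stage = stage
        self.name = name

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return (f"PeakSet(n={len(self)}, assay={self.assay!r}, "
                f"stage={self.stage!r}, name={self.name!r})")

    def chroms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(iv.chrom for iv in self.intervals))

    def by_chrom(self) -> dict[str, np.ndarray]:
        """chrom -> (n, 2) array of [start, end); used by vectorized kernels."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
            }
        )


def read_bed(path: str | Path, assay: str | None = None,
             stage: str | None = None) -> PeakSet:
    """Read a BED3+ file (tab-separated, no header) into a sorted PeakSet.

    Raises :class:`BedParseError` naming the offending 1-based line number on
    non-integer coordinates or ``start >= end``.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}"
                ) from exc
            if not (0 <= start < end):
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.append(GenomicInterval(chrom, start, end))
    return PeakSet(intervals, assay=assay, stage=stage, name=path.stem)


def write_bed(peaks: PeakSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (BED4 when intervals carry a score)."""
    with Path(path).open("w") as fh:
        for iv in peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose pairwise distance is <= ``gap`` bases.

    Overlapping and book-ended intervals (distance 0) always merge; with
    ``gap > 0`` the transitive closure over the "within gap" relation is
    taken, so the output is the minimal sorted set with pairwise gaps > gap.
    Idempotent for any fixed gap.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def overlaps(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean vector over ``a``: does a_i share >= min_bp bases with any b?

    Strand-blind. Uses a sorted sweep with a prefix-max of b ends, O((n+m) log m)
    per chromosome.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    out = np.zeros(len(a), dtype=bool)
    b_by_chrom = b.by_chrom()
    # precompute per-chrom start-sorted ends with prefix maxima; drop b
    # intervals narrower than min_bp — they can never contribute min_bp
    # shared bases, and excluding them makes the two sweep inequalities
    # below sufficient as well as necessary (the only counterexamples are
    # containments where the inner interval is narrower than min_bp)
    prep: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, arr in b_by_chrom.items():
        arr = arr[(arr[:, 1] - arr[:, 0]) >= min_bp]
        if arr.shape[0] == 0:
            continue
        order = np.argsort(arr[:, 0], kind="stable")
        starts = arr[order, 0]
        ends_cummax = np.maximum.accumulate(arr[order, 1])
        prep[chrom] = (starts, ends_cummax)
    for i, iv in enumerate(a.intervals):
        got = prep.get(iv.chrom)
        if got is None or iv.width < min_bp:
            continue
        starts, ends_cummax = got
        # need b.start <= iv.end - min_bp and b.end >= iv.start + min_bp
        hi = int(np.searchsorted(starts, iv.end - min_bp, side="right"))
        out[i] = hi > 0 and ends_cummax[hi - 1] >= iv.start + min_bp
    return out


@dataclass(frozen=True)
class GeneModel:
    """A gene anchor: TSS at the 5' end of the body, per strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} outside body "
                f"[{self.body.start}, {self.body.end})")

    @classmethod
    def from_body(cls, gene_id: str, chrom: str, strand: str,
                  body_start: int, body_end: int, is_tf: bool = False) -> "GeneModel":
        body = GenomicInterval(chrom, body_start, body_end, strand)
        tss = body_start if strand == "+" else body_end - 1
        return cls(gene_id, chrom, strand, tss, body, is_tf)


def nearest_tss(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    max_distance: int | None = None,
) -> tuple[str, int | None]:
    """Gene whose TSS is closest to the peak centre, same chromosome only.

    Distance is |centre - tss| with centre = floor((start+end)/2). Ties break
    to the lexicographically smallest gene_id. Returns ("unassigned", None)
    when no gene is eligible (wrong chromosome, or beyond ``max_distance``).
    """
    centre = peak.center
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = abs(centre - g.tss)
        if max_distance is not None and d > max_distance:
            continue
        key = (d, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return UNASSIGNED, None
    return best[1], best[0]


class _TssIndex:
    """Per-chromosome sorted TSS arrays for batch nearest lookups."""

    def __init__(self, genes: Sequence[GeneModel]) -> None:
        per: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            per.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        self.index: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, pairs in per.items():
            pairs.sort()
            self.index[chrom] = (
                np.asarray([p[0] for p in pairs], dtype=np.int64),
                [p[1] for p in pairs],
            )

    def nearest(self, chrom: str, centre: int,
                max_distance: int | None = None) -> tuple[str, int | None]:
        got = self.index.get(chrom)
        if got is None:
            return UNASSIGNED, None
        tss, ids = got
        j = int(np.searchsorted(tss, centre))
        cands = [j - 1, j, j + 1]
        best: tuple[int, str] | None = None
        for c in cands:
            if 0 <= c < len(ids):
                d = abs(centre - int(tss[c]))
                key = (d, ids[c])
                if best is None or key < best:
                    best = key
        # ties in distance may involve equal-tss neighbours beyond the probed
        # window; scan outward while distance is tied
        if best is not None:
            d0 = best[0]
            lo, hi = j - 2, j + 2
            while lo >= 0 and abs(centre - int(tss[lo])) == d0:
                best = min(best, (d0, ids[lo]))
                lo -= 1
            while hi < len(ids) and abs(centre - int(tss[hi])) == d0:
                best = min(best, (d0, ids[hi]))
                hi += 1
        if best is None or (max_distance is not None and best[0] > max_distance):
            return UNASSIGNED, None
        return best[1], best[0]


def nearest_tss_table(
    peaks: Iterable[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int | None = None,
) -> pd.DataFrame:
    """Vector form of :func:`nearest_tss`: one row per peak with gene/distance."""
    idx = _TssIndex(genes)
    rows = []
    for iv in peaks:
        gene, dist = idx.nearest(iv.chrom, iv.center, max_distance)
        rows.append((interval_id(iv), iv.chrom, iv.start, iv.end, gene, dist))
    return pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "gene", "distance"]
    )


def read_genes(path: str | Path, tf_ids: Iterable[str] = ()) -> list[GeneModel]:
    """Read the 6-column gene model TSV (header: gene_id, chrom, strand, tss,
    body_start, body_end); ``tf_ids`` flags catalogue members."""
    df = pd.read_csv(path, sep="\t")
    tfs = set(tf_ids)
    genes = []
    for row in df.itertuples(index=False):
        body = GenomicInterval(row.chrom, int(row.body_start), int(row.body_end),
                               row.strand)
        genes.append(GeneModel(str(row.gene_id), row.chrom, row.strand,
                               int(row.tss), body, str(row.gene_id) in tfs))
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "body_start": [g.body.start for g in genes],
            "body_end": [g.body.end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)
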