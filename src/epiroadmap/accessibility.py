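"""Peak-centred signal matrices, sample PCA, and k-means peak clustering.

The replacement for an affinity-score workflow is defined precisely here:
consensus peaks -> counts in +/- ``halfwidth`` bp windows around each peak
centre -> counts-per-million -> log2(cpm + 1) -> row z-score -> k-means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .intervals import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    interval_id,
    merge_intervals,
    nearest_tss_table,
    overlaps,
    parse_interval_id,
)

logger = logging.getLogger(__name__)

NORMALIZATION_STATES = ("raw_counts", "cpm", "log2cpm", "rowz")


@dataclass
class SignalMatrix:
    """Peaks x samples values with an explicit normalization state."""

    data: pd.DataFrame
    state: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.state not in NORMALIZATION_STATES:
            raise ValueError(f"unknown normalization state {self.state!r}")

    @property
    def peak_ids(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def restrict(self, peak_ids: Sequence[str]) -> "SignalMatrix":
        return SignalMatrix(self.data.loc[list(peak_ids)], self.state)


def stage_of_sample(sample: str) -> str:
    """Sample labels are ``<stage>_r<k>``; strip the replicate suffix."""
    stage, _, _ = sample.rpartition("_")
    return stage or sample


def stage_means(data: pd.DataFrame,
                stages: Mapping[str, str] | None = None) -> pd.DataFrame:
    mapping = {c: (stages[c] if stages else stage_of_sample(c))
               for c in data.columns}
    means = data.T.groupby(data.columns.map(mapping.get)).mean().T
    # preserve the stage order in which samples appear (the trajectory order)
    order = list(dict.fromkeys(mapping[c] for c in data.columns))
    return means[order]


def consensus_peaks(peaksets: Sequence[PeakSet], min_samples: int = 1) -> PeakSet:
    """Merged union of per-sample peaks, kept when supported (>=1 bp overlap)
    by at least ``min_samples`` of the inputs."""
    if len(peaksets) < 2:
        raise ValueError("consensus requires >= 2 peak sets")
    if not (1 <= min_samples <= len(peaksets)):
        raise ValueError(
            f"min_samples={min_samples} outside [1, {len(peaksets)}]")
    union = merge_intervals([iv for ps in peaksets for iv in ps], gap=0)
    union_ps = PeakSet(union)
    support = np.zeros(len(union_ps), dtype=int)
    for ps in peaksets:
        support += overlaps(union_ps, ps).astype(int)
    kept = [iv for iv, s in zip(union_ps, support) if s >= min_samples]
    return PeakSet(kept, assay=peaksets[0].assay, name="consensus")


def count_in_windows(
    consensus: PeakSet,
    tags_by_sample: Mapping[str, Mapping[str, np.ndarray]],
    halfwidth: int = 200,
) -> SignalMatrix:
    """Counts of single-base tag positions in [centre-halfwidth, centre+halfwidth)
    around each consensus peak centre, per sample.

    ``tags_by_sample`` maps sample -> chrom -> positions (need not be sorted).
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    ids = [interval_id(iv) for iv in consensus]
    centres = np.array([iv.center for iv in consensus], dtype=np.int64)
    chroms = [iv.chrom for iv in consensus]
    out = {}
    for sample, by_chrom in tags_by_sample.items():
        sorted_tags = {c: np.sort(np.asarray(p, dtype=np.int64))
                       for c, p in by_chrom.items()}
        col = np.zeros(len(ids), dtype=np.int64)
        for i, (chrom, centre) in enumerate(zip(chroms, centres)):
            pos = sorted_tags.get(chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, centre - halfwidth, side="left")
            hi = np.searchsorted(pos, centre + halfwidth, side="left")
            col[i] = hi - lo
        out[sample] = col
    df = pd.DataFrame(out, index=pd.Index(ids, name="peak_id"))
    return SignalMatrix(df, "raw_counts")


def normalize(matrix: SignalMatrix, method: str = "log2cpm") -> SignalMatrix:
    """cpm: value * 1e6 / column sum; log2cpm: log2(cpm + 1)."""
    if matrix.state != "raw_counts":
        raise ValueError(f"normalize expects raw_counts, got {matrix.state}")
    if method not in ("cpm", "log2cpm"):
        raise ValueError(f"unknown method {method!r}")
    colsum = matrix.data.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(
            f"zero total counts in sample(s): {', '.join(zero.index)}")
    cpm = matrix.data * 1e6 / colsum
    if method == "cpm":
        return SignalMatrix(cpm, "cpm")
    return SignalMatrix(np.log2(cpm + 1.0), "log2cpm")


def row_zscore(matrix: SignalMatrix) -> SignalMatrix:
    """Row z-score; constant rows become all-zero rows."""
    values = matrix.data
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    z = values.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z[sd == 0] = 0.0
    return SignalMatrix(z, "rowz")


def pca_samples(matrix: SignalMatrix,
                n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in peak space (rows centred internally).

    Returns (coordinates indexed by sample, explained-variance fractions
    ordered non-increasing).
    """
    if matrix.state not in ("log2cpm", "rowz", "cpm"):
        raise ValueError("pca_samples expects a normalized matrix")
    x = matrix.data.T.to_numpy(dtype=float)  # samples x peaks
    n_samples = x.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    if n_components is None:
        n_components = min(n_samples, x.shape[1])
    if n_components > n_samples:
        raise ValueError(
            f"requested {n_components} components with {n_samples} samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero-variance input divides by 0
        coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    # zero total variance (identical samples) yields NaN ratios in sklearn;
    # report 0 explained instead
    evr = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    return pd.DataFrame(coords, index=matrix.samples, columns=cols), evr


def differential_peaks(
    matrix: SignalMatrix,
    stages: Mapping[str, str] | None = None,
    min_fold: float | None = 1.0,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank peaks by max-vs-min stage-mean log2 fold change and select.

    On a log2cpm matrix the fold change is the difference of stage means; on
    cpm/raw it is log2((max + 1) / (min + 1)). Returns the selected rows of a
    DataFrame with a ``log2fc`` column, sorted by |log2fc| descending (ties:
    peak id ascending).
    """
    if min_fold is None and top_n is None:
        raise ValueError("set min_fold and/or top_n")
    sm = stage_means(matrix.data, stages)
    if sm.shape[1] < 2:
        raise ValueError("differential selection needs >= 2 stages")
    if matrix.state == "log2cpm":
        fc = sm.max(axis=1) - sm.min(axis=1)
    else:
        fc = np.log2((sm.max(axis=1) + 1.0) / (sm.min(axis=1) + 1.0))
    out = pd.DataFrame({"log2fc": fc})
    out = out.iloc[np.lexsort((out.index, -out["log2fc"].abs()))]
    if min_fold is not None:
        out = out[out["log2fc"].abs() >= min_fold]
    if top_n is not None:
        out = out.head(top_n)
    return out


@dataclass
class PeakClusterAssignment:
    """k-means result with canonicalized cluster names C1..Ck."""

    labels: pd.Series            # peak id -> "C#"
    k: int
    seed: int
    profiles: pd.DataFrame       # cluster x stage mean of the clustered values

    def cluster_peaks(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().sort_index().to_dict()


def _canonical_order(profiles: pd.DataFrame) -> list:
    """Order clusters by (last stage with above-average signal, peak height
    descending, profile tuple): stable, platform-independent names with the
    late-differentiation-high cluster in a fixed slot. Using the sign of the
    z profile rather than its argmax keeps plateau profiles (open across
    several stages) ordered consistently under small normalization asymmetry."""
    keys = []
    for label, row in profiles.iterrows():
        v = row.to_numpy(dtype=float)
        positive = np.flatnonzero(v > 0)
        last_on = int(positive[-1]) if len(positive) else -1
        keys.append(((last_on, -v.max(), tuple(np.round(v, 9))), label))
    keys.sort(key=lambda t: t[0])
    return [label for _, label in keys]


def kmeans_peaks(
    matrix: SignalMatrix,
    k: int = 6,
    seed: int = 0,
    stages: Mapping[str, str] | None = None,
    max_iter: int = 300,
) -> PeakClusterAssignment:
    """Lloyd k-means with k-means++ init at a fixed seed on row-z rows."""
    if matrix.state != "rowz":
        raise ValueError("kmeans_peaks expects row-z-scored input")
    n = matrix.data.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds row count {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(matrix.data.to_numpy(dtype=float))
    # stage-mean profile of each raw cluster
    smeans = stage_means(matrix.data, stages)
    prof = smeans.groupby(pd.Series(raw, index=matrix.data.index)).mean()
    order = _canonical_order(prof)
    rename = {old: f"C{i + 1}" for i, old in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw], index=matrix.data.index,
                       name="cluster")
    profiles = prof.rename(index=rename).sort_index(
        key=lambda ix: ix.str.slice(1).astype(int))
    return PeakClusterAssignment(labels=labels, k=k, seed=seed,
                                 profiles=profiles)


def cluster_genes(
    assignment: PeakClusterAssignment,
    label: str,
    genes: Sequence[GeneModel],
    max_distance: int | None = None,
) -> set[str]:
    """Deduplicated nearest-TSS gene set of one cluster's peaks."""
    ids = assignment.cluster_peaks(label)
    if not ids:
        return set()
    ivs = [parse_interval_id(pid) for pid in ids]
    table = nearest_tss_table(ivs, genes, max_distance)
    return set(table.loc[table["gene"] != "unassigned", "gene"])


def read_counts_tsv(path) -> SignalMatrix:
    """Read a peaks x samples raw-count TSV (first column peak_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignalMatrix(df, "raw_counts")
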