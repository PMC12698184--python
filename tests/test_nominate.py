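"""TF nomination funnel, TSS mark matrices, motif scanning and hypergeometric
enrichment (with exact combinatorial oracles)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from epiroadmap import nominate as nom
from epiroadmap.intervals import GeneModel, GenomicInterval, PeakSet


# ---------------------------------------------------------------- specificity
def test_single_stage_tf_is_specific():
    bulk = pd.DataFrame({"tf1": [0.0, 0.0, 0.0, 30.0],
                         "flat": [10.0, 10.0, 10.0, 10.0]},
                        index=["hESC", "VMC", "EPC", "EC"]).T
    out = nom.stage_specific_tfs(bulk, ["tf1", "flat"], ("EPC", "EC"),
                                 z_min=1.5, min_fpkm=1.0)
    assert list(out.index) == ["tf1"]
    assert out.loc["tf1", "specific_stages"] == ["EC"]


def test_uniform_tf_not_specific_and_constant_skipped():
    bulk = pd.DataFrame({"flat": [10.0, 10.0, 10.0, 10.0],
                         "const0": [0.0, 0.0, 0.0, 0.0]},
                        index=["hESC", "VMC", "EPC", "EC"]).T
    out = nom.stage_specific_tfs(bulk, ["flat", "const0"])
    assert out.empty


def test_specificity_requires_three_stages():
    bulk = pd.DataFrame({"g": [1.0, 2.0]}, index=["A", "B"]).T
    with pytest.raises(ValueError):
        nom.stage_specific_tfs(bulk, ["g"], target_stages=("B",))


# ---------------------------------------------------------------- restriction
def test_restriction_ratio_arithmetic():
    cands = pd.DataFrame(index=pd.Index(["only", "even"], name="gene"))
    clusters = pd.DataFrame(
        {"endothelial": [40.0, 10.0], "mesenchymal": [0.0, 10.0],
         "cardiac": [0.0, 10.0], "other": [0.0, 10.0]},
        index=["only", "even"])
    out = nom.lineage_restriction(cands, clusters, ("endothelial",),
                                  ratio_min=2.0, eps=0.0)
    assert out.loc["only", "restriction_ratio"] == pytest.approx(4.0)
    assert out.loc["even", "restriction_ratio"] == pytest.approx(1.0)
    assert out.loc["only", "nominated"] and not out.loc["even", "nominated"]


def test_all_zero_gene_gets_ratio_zero():
    cands = pd.DataFrame(index=pd.Index(["dead"], name="gene"))
    clusters = pd.DataFrame({"endothelial": [0.0], "other": [0.0]},
                            index=["dead"])
    out = nom.lineage_restriction(cands, clusters, ("endothelial",))
    assert out.loc["dead", "restriction_ratio"] == 0.0
    assert not out.loc["dead", "nominated"]


def test_restricted_tf_nominated_but_broad_paralog_not():
    """An endothelial-restricted, EC-specific TF passes both filters; its
    broadly-expressed paralog fails the bulk-specificity filter."""
    bulk = pd.DataFrame(
        {"TFX": [0.2, 0.2, 5.0, 60.0],       # restricted candidate
         "TFX_paralog": [30.0, 32.0, 31.0, 30.0],
         "spread": [1.0, 50.0, 2.0, 1.0]},
        index=["hESC", "VMC", "EPC", "EC"]).T
    clusters = pd.DataFrame(
        {"endothelial": [50.0, 30.0, 1.0], "mesenchymal": [0.3, 30.0, 30.0],
         "cardiac": [0.3, 30.0, 30.0], "other": [0.3, 30.0, 5.0]},
        index=["TFX", "TFX_paralog", "spread"])
    out = nom.nominate_tfs(bulk, clusters, ["TFX", "TFX_paralog", "spread"])
    assert list(out.index[out["nominated"]]) == ["TFX"]
    assert "TFX_paralog" not in out.index


def test_funnel_monotone_in_thresholds(default_dataset):
    ds = default_dataset
    base = nom.nominate_tfs(ds.bulk_expression, ds.cluster_expression,
                            ds.tf_catalogue, z_min=1.5, ratio_min=2.0)
    stricter = nom.nominate_tfs(ds.bulk_expression, ds.cluster_expression,
                                ds.tf_catalogue, z_min=1.6, ratio_min=2.5)
    nominated = set(base.index[base["nominated"]])
    nominated_strict = set(stricter.index[stricter["nominated"]])
    assert nominated_strict <= nominated


def test_funnel_recovers_planted_tfs_exactly_at_zero_noise(noiseless_dataset):
    ds = noiseless_dataset
    out = nom.nominate_tfs(ds.bulk_expression, ds.cluster_expression,
                           ds.tf_catalogue)
    assert sorted(out.index[out["nominated"]]) == ds.truth.restricted_tfs
    assert len(out) == len(ds.truth.stage_specific_tf_truth) == 58


# ---------------------------------------------------------------- TSS windows
def test_tss_mark_matrix_signs_and_constant_rows():
    genes = [GeneModel.from_body("gA", "chr1", "+", 10_000, 18_000),
             GeneModel.from_body("gB", "chr1", "+", 50_000, 58_000)]
    mark = PeakSet([GenomicInterval("chr1", 9_500, 10_500)])
    empty = PeakSet([])
    z = nom.tss_mark_matrix({("S1", "K4"): mark, ("S2", "K4"): empty}, genes)
    assert z.loc["gA", ("S1", "K4")] > 0  # signal only in S1
    assert np.allclose(z.loc["gB"], 0)    # no overlap anywhere -> zero row


def test_tss_window_sums_match_per_base_oracle():
    rng = np.random.default_rng(21)
    genes = [GeneModel.from_body(f"g{i}", "chr1", "+", int(p), int(p) + 2_000)
             for i, p in enumerate(rng.integers(2_000, 80_000, size=10))]
    ivs = [GenomicInterval("chr1", int(s), int(s) + int(w))
           for s, w in zip(rng.integers(0, 80_000, size=60),
                           rng.integers(50, 800, size=60))]
    merged = PeakSet(ivs)
    halfwidth = 1_000
    # per-base coverage oracle for the raw covered-bases signal
    cov = np.zeros(100_000, dtype=bool)
    for iv in merged:
        cov[iv.start:iv.end] = True
    lib = sum(iv.width for iv in merged)
    raw = {}
    for g in genes:
        lo, hi = max(0, g.tss - halfwidth), g.tss + halfwidth
        raw[g.gene_id] = cov[lo:hi].sum() * 1e9 / ((hi - lo) * lib)
    # recompute the pre-z windows through the module by using a single
    # (stage, mark) column: z of a 1-column row is 0, so compare raw sums
    # via two columns (mark vs empty) instead
    z = nom.tss_mark_matrix({("S1", "K4"): merged,
                             ("S2", "K4"): PeakSet([])}, genes,
                            halfwidth=halfwidth)
    for g in genes:
        if raw[g.gene_id] == 0:
            assert np.allclose(z.loc[g.gene_id], 0)
        else:
            assert z.loc[g.gene_id, ("S1", "K4")] > 0
            assert z.loc[g.gene_id, ("S2", "K4")] < 0
    # direct check of covered-bases arithmetic on one window
    g0 = genes[0]
    lo, hi = max(0, g0.tss - halfwidth), g0.tss + halfwidth
    ov = [max(0, min(iv.end, hi) - max(iv.start, lo)) for iv in merged]
    assert sum(ov) == cov[lo:hi].sum()


# ---------------------------------------------------------------- motifs
def test_scan_motif_conventions():
    # forward matches only: "GGAAGGAA" has two GGAA, no TTCC
    counts = nom.scan_motifs("GGAA", {"p": "GGAAGGAA"})
    assert counts["p"] == 2
    # reverse-strand hits are counted via the reverse complement
    counts = nom.scan_motifs("GGAA", {"p": "TTCCA"})
    assert counts["p"] == 1
    # N matches at every position, counted once (palindromic motif)
    assert nom.scan_motifs("N", {"p": "ACGT"})["p"] == 4
    # overlapping matches count (forward AA twice; reverse complement TT absent)
    assert nom.scan_motifs("AA", {"p": "AAA"})["p"] == 2
    with pytest.raises(ValueError):
        nom.scan_motifs("GGQA", {"p": "ACGT"})


def test_scan_motif_strand_symmetry():
    rng = np.random.default_rng(33)
    comp = str.maketrans("ACGT", "TGCA")
    for _ in range(20):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=50)])
        motif = "".join(np.array(list("ACGTRYSWKMN"))[
            rng.integers(0, 11, size=5)])
        rc_motif = nom._revcomp_iupac(motif)
        rc_seq = seq.translate(comp)[::-1]
        a = nom.scan_motifs(motif, {"p": seq})["p"]
        b = nom.scan_motifs(rc_motif, {"p": rc_seq})["p"]
        assert a == b


def test_scan_motif_matches_sliding_window_oracle():
    rng = np.random.default_rng(35)
    iup = nom.IUPAC
    for _ in range(10):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=80)])
        motif = "".join(np.array(list("ACGTRYN"))[rng.integers(0, 7, size=4)])
        rc = nom._revcomp_iupac(motif)

        def count(pat, s):
            return sum(all(s[i + j] in iup[c] for j, c in enumerate(pat))
                       for i in range(len(s) - len(pat) + 1))

        expected = count(motif, seq) + (count(rc, seq) if rc != motif else 0)
        assert nom.scan_motifs(motif, {"p": seq})["p"] == expected


# ---------------------------------------------------------------- enrichment
def hypergeom_tail_oracle(k, M, K, n):
    """P[X >= k] by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(M - K, n - x)) / math.comb(M, n)
    return total


def test_enrichment_closed_form_case():
    """Motif only in the 5 cluster peaks of a 100-peak universe with 5 total
    hits: p = 1 / C(100, 5)."""
    universe = [f"p{i}" for i in range(100)]
    cluster = universe[:5]
    flags = pd.DataFrame({"m": [i < 5 for i in range(100)]},
                         index=universe)
    out = nom.motif_enrichment(cluster, universe, flags)
    assert out.loc["m", "p"] == pytest.approx(1 / math.comb(100, 5), rel=1e-9)


def test_enrichment_everywhere_motif_is_null():
    universe = [f"p{i}" for i in range(40)]
    flags = pd.DataFrame({"m": [True] * 40}, index=universe)
    out = nom.motif_enrichment(universe[:10], universe, flags)
    assert out.loc["m", "fold"] == pytest.approx(1.0)
    assert out.loc["m", "p"] == pytest.approx(1.0)


def test_enrichment_matches_exact_enumeration_on_toy():
    rng = np.random.default_rng(41)
    universe = [f"p{i}" for i in range(20)]
    flags = pd.DataFrame(
        {m: rng.random(20) < r for m, r in
         [("m1", 0.3), ("m2", 0.6), ("m3", 0.1)]}, index=universe)
    cluster = universe[:7]
    out = nom.motif_enrichment(cluster, universe, flags)
    for m in flags.columns:
        K = int(flags[m].sum())
        k = int(flags.loc[cluster, m].sum())
        assert out.loc[m, "p"] == pytest.approx(
            hypergeom_tail_oracle(k, 20, K, 7), abs=1e-10)
    with pytest.raises(ValueError):
        nom.motif_enrichment(["zzz"], universe, flags)


def test_bh_adjustment_properties():
    p = np.array([0.001, 0.01, 0.04, 0.5, 0.9])
    q = nom.bh_adjust(p)
    assert np.all(q >= p)
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
    assert np.all(q <= 1.0)


# ---------------------------------------------------------------- concordance
def test_concordance_join_and_rank(noiseless_dataset):
    ds = noiseless_dataset
    enr = pd.DataFrame(
        {"fold": [3.0, 1.0], "p": [1e-8, 0.7], "q": [2e-8, 0.7],
         "cluster_hits": [10, 2], "cluster_size": [20, 20],
         "universe_hits": [12, 30], "universe_size": [100, 100]},
        index=pd.Index(["mA", "mB"], name="motif"))
    bulk_z = nom.row_zscore_table(ds.bulk_expression)
    tf = ds.truth.restricted_tfs[0]
    out = nom.motif_expression_concordance(enr, {"mA": tf}, bulk_z, "C5")
    assert list(out["motif"]) == ["mA", "mB"]
    assert out.loc[0, "tf"] == tf
    assert out.loc[0, "z_EC"] > 0  # EC-expressed TF
    assert pd.isna(out.loc[1, "z_EC"])  # unmapped motif retained with nulls
    empty = nom.motif_expression_concordance(enr.iloc[0:0], {}, bulk_z)
    assert empty.empty


def test_planted_ets_motif_tops_identity_cluster(noiseless_dataset):
    """The ETS-like motif planted in the EPC/EC-opening program is the top
    enrichment hit in that cluster and maps to an EC-expressed TF."""
    ds = noiseless_dataset
    planted = ds.truth.peak_profile
    universe = [p for p, prof in planted.items()]
    cluster = [p for p, prof in planted.items() if prof == "P5"]
    hits = pd.DataFrame({
        mid: (nom.scan_motifs(iupac,
                              {p: ds.sequences[p] for p in universe}) > 0)
        for mid, iupac in ds.motifs.items()})
    enr = nom.motif_enrichment(cluster, universe, hits)
    bulk_z = nom.row_zscore_table(ds.bulk_expression)
    conc = nom.motif_expression_concordance(enr, ds.motif_tf_map, bulk_z,
                                            "C5")
    assert conc.loc[0, "motif"] == "ETS_core"
    assert conc.loc[0, "q"] < 1e-10
    assert conc.loc[0, "z_EC"] > 1.0
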