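# Methods

This note records the computational model, the generator that defines the
study conditions, the numerical conventions, and the deliberate design
choices where the underlying method left room for interpretation.

## Coordinate and interval conventions

All intervals are 0-based, half-open `[start, end)` (BED convention). The
centre of an interval is `floor((start + end) / 2)`. Interval kernels are
implemented in `epiroadmap.intervals`:

- **merge** closes gaps ≤ `gap` bp within a chromosome (single sorted
  sweep); `gap = 0` merges only touching/overlapping intervals.
- **overlaps(a, b, min_bp)** asks whether each interval of `a` shares at
  least `min_bp` bases with some interval of `b`. The sorted sweep uses a
  prefix maximum of `b` ends; intervals narrower than `min_bp` on either
  side are excluded up front, which makes the two sweep inequalities
  (`b.start ≤ a.end − min_bp`, `b.end ≥ a.start + min_bp`) exactly
  equivalent to the overlap condition (the only counterexamples are
  containments in which the inner interval is narrower than `min_bp`).
- **nearest TSS** assigns a peak to the gene whose TSS is closest to the
  peak centre on the same chromosome; ties break lexicographically on gene
  id, and a peak on a chromosome with no genes is `"unassigned"`. A gene's
  TSS is the 5′ end of its body per strand.

These kernels are in-house rather than delegated to an external interval
library because their tie-breaking and threshold semantics are part of the
package contract and are verified against brute-force oracles in the test
suite.

## Synthetic study conditions

`SyntheticConfig()` defaults *are* the study conditions; they were fixed at
design time and are not tuned to analysis outcomes. Key parameters
(units in parentheses):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes over 4 chromosomes, spaced 20 kb, 8 kb bodies, alternating strands |
| `proportions` | hk .30, pluri .10, meso .10, identity .10, bivalent .10, restricted TF .004, silent .296 | archetype mix (sums to 1) |
| `n_reps` | 2 | ATAC replicates per stage |
| `open_mean` / `closed_mean` | 100 / 3 | mean counts (reads) for open/closed elements |
| `count_dispersion` | 10 | negative-binomial size; `None` → deterministic rounded means |
| `jitter_bp` | 50 | maximal uniform shift of whole peaks (widths preserved) |
| `expression_cv` | 0.2 | log-normal sigma on FPKM; 0 → exact archetype means |
| `broad_width` / `narrow_width` | 5–15 kb / 0.5–2 kb (bp) | H3K4me3 domain widths |
| `broad_identity_frac` | 0.2 | identity genes carrying broad domains |
| `n_broad_pluripotency` / `n_broad_mesoderm` | 40 / 40 | broad domains planted at hESC / VMC |
| `n_tf_identity/housekeeping/mesoderm/pluripotency` | 50/20/20/10 | TF catalogue composition beyond the restricted TFs |
| `peak_seq_len` / `motif_insert_rate` | 100 bp / 0.8 | sequence emission for motif scanning |

`SyntheticConfig.noiseless()` sets `jitter_bp = 0`,
`count_dispersion = None`, `expression_cv = 0`: every emitted feature equals
its template, enabling exact-recovery assertions.

Each gene draws an archetype, then a chromatin subtype (e.g. identity genes
split into early/late/poised openers; bivalent genes into resolving vs
late-resolving). Per subtype and stage, rule tables state whether the
promoter is accessible, K4me3-marked, K27ac-marked, or K27me3-marked, and
whether a distal element exists. From these rules the generator derives and
records the planted truth: promoter CRE type per stage, broad-domain gene
sets per stage, the differential profile of every dynamic element
(P1…P6 over the six planted stage patterns), the restricted-TF answer set,
and the canonical cluster name of each profile. Chromatin opening precedes
or coincides with expression for identity genes by construction.

The generator enforces design arithmetic rather than hoping for it: planted
broad domains at each stage stay below `ceil(0.05 · n_domains)` so the
top-5% call can recover them; the bulk expression profiles of identity and
restricted TFs put their target-stage z-scores ≈ 1.7 (threshold 1.5); the
cell-cluster profiles separate restricted TFs (endothelial/mean ratio ≈ 4)
from identity decoys (ratio ≈ 1.3) across the 2.0 cutoff.

## Analysis stages

**Accessibility.** Counts → CPM (per-sample ×10⁶/libsize) → log2(CPM+1).
Sample PCA uses scikit-learn's full SVD; explained-variance ratios are
reported as 0 when total variance is 0. Differential elements: on log2 data
the fold change is max − min of per-stage replicate means; elements with
|log2FC| ≥ `min_fold` (default 1.0) are kept, sorted by |log2FC| descending
with peak-id tie-break. Row z-scores (population σ; constant rows → 0) feed
k-means (`k = 6`, k-means++, `n_init = 1`, fixed seed). Clusters are renamed
canonically by (last stage with centroid z > 0, peak centroid height
descending): C1 is hESC-specific, C5 the EPC+EC identity cluster. This
sign-based key was chosen over "stage of maximum z" because plateau
profiles (e.g. hESC+VMC) break their internal tie arbitrarily under noise,
whereas the sign pattern is stable.

**Broad domains.** Per stage, H3K4me3 peaks are merged with `gap = 1000`;
domains are ranked by width and the top `top_frac = 0.05` fraction
(count `ceil(top_frac · N)`) is called broad, extended through all ties at
the cutoff width. `exceeds_5kb` is strict (`width > 5000`). BPA genes are
nearest-TSS assignments of broad domains. The stage Venn is a bitmask
decomposition whose region counts sum to the union size. Stage-specific BPA
genes (broad in exactly the target stage) are reported with per-stage
median bulk FPKM.

**CRE classification.** The universe is accessible elements plus marked
elements; overlap with each histone peak set requires ≥ `min_bp = 1` shared
bases. Types: K4me3∧K27ac → T1; K4me3 only → T2a; K4me3∧K27me3 (no K27ac)
→ T2b; K27ac without K4me3 → T3; otherwise unmarked. K27me3 co-occurrence
never demotes T1 or T3. The assignment partitions the universe.

**TF nomination.** Stage 1 (bulk): row z-score across the four stages
≥ 1.5 at a target stage (EPC or EC) and FPKM ≥ 1 there. Stage 2
(restriction): mean expression over endothelial cell clusters divided by
(mean over all clusters + ε), ε = 0.01; nominate at ratio ≥ 2.0. Motif
scanning matches IUPAC consensus strings on the forward strand plus the
forward matches of the reverse complement; palindromic motifs are counted
once per position. (Under this convention a motif of all `N`s matches every
position once.) Cluster enrichment is the hypergeometric upper tail
`P(X ≥ k)` computed as `scipy.stats.hypergeom.sf(k−1, M, K, n)`, fold is
the ratio of hit rates, and q-values are Benjamini–Hochberg with the usual
reverse cumulative-minimum. Concordance ranks motifs by (q ascending, fold
descending) joined to the bulk z of the mapped TF.

**Pipeline.** `run_all` executes simulate → accessibility → broad → cre →
nominate with file-based handoffs so every stage is independently rerunnable.
All randomness derives from one seed (subsystem seeds are `seed + offset`);
`summary.json` is written with sorted keys, making end-to-end reruns
byte-identical apart from the output path echoed in the config.

## Verification

All kernels are tested against brute-force oracles (quadratic interval
scans, transitive-closure merge, full-sort broad call, exact combinatorial
hypergeometric enumeration at 1e-10, per-tag window counting, a 1000-restart
k-means inertia bound) plus property tests (monotonicity, scale
equivariance, partition and strand-symmetry invariants). Recovery tests run
the analyses on generated data and compare to the planted truth: exact
differential set, ARI 1.0 and exact canonical naming at zero noise, 100%
promoter CRE recovery, exact funnel recovery (58 → 8), ≥ 90% broad-gene
recovery under the default noise. `scripts/acceptance.py` reproduces these
numbers from scratch at any seed.

## Scope and limitations

The generator is a study-shaped simulator, not a genome simulator: four
chromosomes, uniform gene spacing (20 kb, which isolates promoters from
neighbouring genes' elements), rectangular on/off chromatin rules, and
independent noise per feature. It contains no sequencing-level artefacts
(GC bias, duplicates, mappability), models exactly four stages, and emits
peak calls rather than reads. CRE truth is asserted for promoters only;
distal elements participate in accessibility clustering and motif analysis
but their per-stage type is not part of the planted contract. Problem sizes
are small by design (≈ 2·10³ genes, ≈ 2·10³ elements, seconds per full
run); all algorithms are `O(n log n)` in their inputs and have been run up
to 10⁴ domains / 10³ random intervals in the oracle tests.
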