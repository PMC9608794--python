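# Methods

## Overview

`cernet` infers a competing-endogenous-RNA (ceRNA) network from a two-group
expression study plus two miRNA interaction tables, then ranks lncRNAs by
network centrality. The stages, run in order by `cernet.pipeline.run`:

1. **Differential expression** — quantile normalization, per-gene Welch *t*,
   Benjamini–Hochberg (BH) adjustment, threshold filter, biotype split into
   DELs (lncRNAs) and DEGs (protein-coding mRNAs).
2. **Background construction** — reconcile the lncRNA→miRNA and mRNA→miRNA
   tables into one miRNA universe; clip target sets to it.
3. **Pair test / network** — hypergeometric upper-tail test on the shared
   miRNA count of every DEL × DEG pair; retained pairs form a bipartite graph.
4. **Topology** — degree and betweenness on the bipartite graph; hub lncRNAs
   are the top-*k* rank intersection.
5. **Subnetworks** — per hub, the tripartite lncRNA–miRNA–mRNA neighbourhood.
6. **Enrichment** (optional) — hypergeometric over-representation of the
   network's mRNAs in user-supplied GMT gene sets.

## Models and assumptions

**Pair statistic.** For a pair with shared-miRNA count *r*, lncRNA partner
count *n*, mRNA partner count *t* and universe size *m*, the score is
P(X ≥ r) with X ~ Hypergeometric(m, t, n). The null model is uniform random
targeting: the lncRNA's *n* partners are an unordered uniform draw from the
universe, independent of the mRNA's *t*. This ignores the heavy-tailed
degree distributions of real interaction databases (promiscuous miRNAs make
the null optimistic for high-degree nodes), which is the standard caveat of
this family of methods.

**Universe policy.** The hypergeometric *m* is defined by the mRNA-side
database (`mrna_db`, the default), with `union` and `intersection`
alternatives, because the two source databases generally cover different
miRNA sets and the choice is not canonical. lncRNA target sets are clipped
to the universe — required for n ≤ m — and entries emptied by clipping are
dropped and counted (never silently).

**Differential expression.** The per-gene test is Welch's unequal-variance
*t* on log2 intensities, chosen over a moderated/empirical-Bayes *t* to keep
the statistic self-contained and exactly testable; with ~10 samples per
group the moderation advantage is modest, but results on real microarray
data will differ from a limma analysis. Degenerate genes (zero variance in
both groups) get p = 1 when the group means are equal and p = 0 otherwise.
Matrices are assumed to be on log2 scale; `log2_offset` applies
log2(x + offset) only when explicitly requested (no auto-detection — silent
transforms are a reproducibility hazard). Duplicate gene ids collapse to the
row with the highest mean expression before testing.

**Hub calling.** Centralities are computed on the full bipartite network
(mRNA nodes included) but only lncRNAs are ranked. Betweenness is
undirected, unweighted and unnormalized, each unordered pair counted once,
endpoints excluded (normalization cancels in ranking; the convention is
stated so values compare across tools). Ranking uses competition ranks
(1 = highest, ties share the smallest rank) and the top-*k* retained set
includes **all** ties at the *k*-th value, so no node is excluded by an
arbitrary tie-break; consequently a heavily tied network can yield more than
*k* hubs. Hub output order is (betweenness desc, degree desc, id asc).

**Enrichment.** Same hypergeometric tail, applied to set overlaps, BH across
tested sets. The universe defaults to the union of all loaded set members;
supplying the measured-gene list is statistically preferable and supported.

## Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| `fdr_max` | 0.05 | BH-adjusted p threshold (strict <); `use_raw_p` switches to raw p |
| `lfc_min` | 1.0 | log2 fold-change magnitude threshold (strict >) |
| `pair_p_max` | 0.01 | pair-test threshold (strict <, raw p; no BH across pairs by default) |
| `min_shared` | 3 | edges need strictly more shared miRNAs (i.e. r ≥ 4) |
| `k` | 8 | rank cutoff per centrality for hub calling |
| `enrich_p_max` | 0.05 | ORA significance threshold (on FDR by default) |
| `universe_policy` | `mrna_db` | hypergeometric universe definition |

"More than 3" is the strict reading of the conventional count filter;
`min_shared` is exposed because methods prose of the form "counts > 3" is
sometimes intended inclusively. Raw pair p-values are the field's common
practice for this filter; `adjust_pairs`-style correction across pairs is
deliberately left to the caller via the exported edge table, which carries
every scored quantity (r, n, t, m, p, shared miRNA ids).

## Synthetic data generator

`simulate.SimConfig` defaults define the reference study: a 10-vs-10
two-group design (effect size 2.0 log2 units, i.i.d. Gaussian noise
sd 0.5, 15% of genes DE with 50/50 up/down directions), and an interaction
background of 600 miRNAs, 80 lncRNAs and 300 mRNAs with sparse uniform base
targeting (10 miRNAs per lncRNA, 8 per mRNA) — a deliberate scale reduction
of public interaction databases (hundreds to thousands of miRNAs, thousands
of targets) that keeps the full pipeline under a few seconds while
preserving the sparse-overlap regime in which the pair test operates.

Planted structure: 24 planted pairs grouped 6-per-lncRNA onto 4 hub
lncRNAs; each pair receives a dedicated block of 8 reserved miRNAs added to
both sides. Blocks are pairwise disjoint and excluded from base targeting,
so every planted pair shares ≥ 8 miRNAs by construction while decoy sharing
stays at chance level (mean < 1 under the defaults). The study generator
(`simulate_study`) forces all planted-pair genes into the DE set so that
recovery of the complete chain — DE gate, pair test, hub calling — can be
scored against `SimTruth`.

All randomness flows from `SimConfig.seed` through a single numpy
`Generator`; identical configs give byte-identical serialized outputs.

What the generator does **not** emulate: probe-level artifacts, batch
effects, intensity-dependent variance, correlated noise between genes,
degree heterogeneity of real miRNA databases, or miRNA sequence features.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated model, not performance on real microarrays.

## Numerical choices

- The hypergeometric tail is computed as the upper sum
  Σ_{i≥r} exp(log C(t,i) + log C(m−t,n−i) − log C(m,n)) using `gammaln`,
  not as 1 − (lower sum): the complement form loses all precision once the
  tail is ~1e−16. Agreement with exhaustive subset enumeration and with the
  exact-rational complement form is tested to 1e−12 for all m ≤ 15.
- P(X ≥ 0) is returned as exactly 1.0; results are clipped to [0, 1].
- BH step-up is the literal min-over-suffix construction, capped at 1,
  mapped back to input order; verified against the brute-force definition
  and against statsmodels.
- Quantile normalization: reference = row means of column-sorted matrix;
  ties within a column receive the mean of the reference values at the tied
  positions (dialects differ here; this is the common averaging rule).
  Consequence: a column containing ties does not carry the exact reference
  multiset — the exact-equality invariant applies to tie-free columns.
- Welch p-values come from `scipy.stats.ttest_ind(equal_var=False)` with the
  degenerate zero-variance rules applied afterwards.
- Betweenness is `networkx.betweenness_centrality(normalized=False)`
  (Brandes accumulation), cross-checked against a brute-force BFS
  shortest-path enumerator on small random bipartite graphs.
- Determinism: edges sort by (p, lnc, mrna), all writers emit sorted rows,
  JSON is dumped with sorted keys, and the run summary excludes the output
  location, so identically configured runs are byte-identical.

## Degenerate inputs

- Empty DE lists or an empty network stop the pipeline gracefully
  (`stopped_at` in the summary, exit code 3 from the CLI) with all upstream
  artifacts written.
- A gene id appearing as both DEL and DEG is an error (bipartiteness).
- Candidates missing from the background are skipped and counted; direct
  `score_pair` calls on missing ids raise.
- Interaction/GMT parsers report the offending line number; empty
  interaction files yield an empty map with a warning, an empty GMT is an
  error.

## Limitations

- The pair test inherits the uniform-targeting null; with strongly
  heterogeneous miRNA degrees it is anti-conservative for high-degree genes.
- No miRNA expression is used: an edge asserts shared targeting, not active
  competition in the profiled tissue.
- Welch *t* is not a moderated *t*; very small group sizes will lose power
  relative to empirical-Bayes approaches.
- Identifiers are matched verbatim across tables (no miRBase version
  harmonization); inputs must share a namespace.
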