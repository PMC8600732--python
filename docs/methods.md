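# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Module detection

The PPI network is an undirected graph over genes with per-edge confidence
in [0, 1]; only edges at or above `ppi_min_confidence` (default 0.4, the
conventional "medium confidence" operating point for STRING-style scores)
enter. Confidence is used **only** for this threshold — the module detector
is unweighted, matching the original Molecular Complex Detection algorithm.

Each vertex *v* is weighted by k·d, where the k-core decomposition of the
subgraph induced by *v*'s closed neighborhood is taken, k is the highest
core present and d = 2E/(V(V−1)) the density of that core; vertices whose
neighborhood has no 2-core weigh 0. Complexes grow greedily: seeds are
taken in decreasing weight (vertices with degree < `mcode_degree_cutoff`
cannot seed), expansion is breadth-first to `mcode_max_depth` hops,
including unassigned neighbors whose weight is at least
seed weight × (1 − `mcode_node_score_cutoff`), and each vertex joins at
most one complex — module membership therefore partitions. Each complex is
post-processed by retaining its `mcode_kcore`-core (default 2) and
discarded below 3 vertices; the floor of 3 reflects the smallest module
size this kind of analysis typically reports. The optional "haircut" and
"fluff" post-processing passes exist behind flags but default off: the
mandatory k-core filter subsumes haircut, and fluff would break the
partition property. The module score is density × size; ties in score are
broken by lexicographically smallest seed id so output order is
deterministic.

Module annotation is a flat over-representation test: upper-tail
hypergeometric p for the overlap between a query gene set and each GMT set
(both intersected with an explicit background), Benjamini–Hochberg FDR
across sets. No GO DAG structure or term propagation is involved.

## Competing-pair statistics

For a gene–lncRNA pair the shared-miRNA count x is referred to
Hypergeometric(M, K, N): M risk miRNAs in the universe, K interacting with
the gene, N with the lncRNA. The implemented default is the upper tail
P(X ≥ x): competition is evidenced by surprisingly **many** shared
miRNAs. The lower-tail cumulative form that circulates in the ceRNA
literature is available as `hyper_tail: lower_as_printed` for replicating
published pipelines, but it rewards sharing *few* miRNAs and is not a
sensible competition test, so it is not the default. Both tails are exact
(scipy's hypergeometric survival/cumulative functions, verified against
integer-arithmetic enumeration to 1e-12 in the test suite); pairs sharing
zero miRNAs are never tested — x = 0 is structurally meaningless for a
ceRNA.

M defaults to the *realized* universe — risk miRNAs present in at least one
filtered interaction table — because K and N are computed on those same
tables; `universe: curated` uses the full risk list instead. Pairs at
p < `hyper_p_max` (default 0.01) proceed to the co-expression gate:
Pearson r over all samples of the expression matrix, two-sided p from the
exact t transform t = r√((n−2)/(1−r²)), Benjamini–Hochberg FDR across all
tested pairs, retention iff r > `pcc_min` (0.7) and FDR < `fdr_max`
(0.01). The r threshold is one-sided by design: anti-correlated pairs are
not ceRNA candidates. Pairs with a missing or zero-variance transcript are
dropped with a log line rather than imputed — the correlation needs
complete pairs and imputation would manufacture co-expression. FDR is
computed globally across all candidate pairs (not per lncRNA family).

## Network assembly

Each significant pair (g, l) with shared miRNA set S expands into |S|
competing triplets (g, m, l); the tripartite network is the deduplicated
union of their gene–miRNA and miRNA–lncRNA edges. Triplets are stored
explicitly in the serialized GraphML because the lncRNA-to-module mapping
needs to know which gene each lncRNA competes with, and that is not
recoverable from the edge set alone. Per lncRNA, the primary count is its
incident miRNA–lncRNA edges and the secondary count is the distinct
miRNA–gene *edges* reachable through those miRNAs; counting distinct
*genes* instead is available via `count_genes` since both readings of
"secondary interaction pairs" appear in practice.

## Random walk with restart and permutation null

W is the column-normalized adjacency of the undirected, unweighted
tripartite graph; zero-degree columns (possible only in degenerate inputs)
receive a self-loop first so W stays column-stochastic. P⁰ is uniform over
the seed genes present in the network (`normalize_seeds: false` assigns
mass 1 per seed instead; scores scale linearly and rankings are
identical). The iteration stops when the L1 change drops below `rwr_tol`
(default 1e-10) or after `rwr_max_iter` steps; with a column-stochastic W
and normalized P⁰ the vector remains a probability distribution at every
step, and converged runs satisfy the stationary equation to well below
1e-8 in L1. The restart probability defaults to r = 0.7, the standard
choice in the network-propagation literature; it is exposed in config and
echoed in the ranking output. With r = 1 the update degenerates to P⁰
exactly.

The null model resamples seed sets of the same size without replacement
from the gene nodes, matching the seed degree multiset exactly whenever the
network allows it and by nearest degree (ties random, count logged)
otherwise. All n permutations (default 1000) share one walk matrix and are
iterated as a single batch. The empirical p-value is m/n with m the number
of permutations scoring *strictly* higher than observed — ties do not
count against a lncRNA, so a score matched by every permutation still gets
p = 0 rather than 1; a `pseudocount` option computes (m+1)/(n+1) for users
who need a nonzero floor. Comparison is per-lncRNA against that lncRNA's
own permuted scores, not against a pooled distribution. Candidates at
p < `perm_p_max` (0.05) are linked to every module containing a gene they
compete with; lncRNAs linked to `min_modules_flag` (default 3, i.e. "more
than two") or more modules are flagged as multi-module regulators.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the biology of any particular database snapshot:

* **Interactome** — 50 genes, 60 miRNAs, 40 lncRNAs, 50 risk miRNAs by
  default. Five planted triplet-families each wire one gene and one lncRNA
  to a disjoint block of 3 risk miRNAs; decoy edges are Erdős–Rényi at
  0.02. The prioritization positive is a *signal block*: the families
  covering 60% of the seed genes are merged — their genes and lncRNAs plus
  one extra signal lncRNA are all wired to the union of the block's
  miRNAs. This gives the signal lncRNA's pairs a large shared-miRNA
  overlap (x ≈ K ≈ N ≈ 9), which is what a genuine ceRNA hub looks like
  and what survives the hypergeometric gate robustly; wiring the signal
  lncRNA to each family's 3 miRNAs separately produces p-values straddling
  the 0.01 threshold (a lncRNA with many partners but only 3 shared with
  each gene is *not* a convincing competitor, and the test correctly says
  so). The block's cross pairs are genuine planted structure and are
  recorded in the ground truth.
* **Expression** — members of one planted group share a latent factor with
  loading √ρ (ρ = 0.9 by default, 100 samples), so every planted pair has
  population correlation ρ; everything else is independent standard
  normal. Marginals are standard normal because the Pearson statistic is
  location/scale-free; a log-normal transform exists for cosmetic realism
  only. Real expression data differ in ways that do not affect the tested
  statistics' null behavior but do affect power: heavy tails, shared
  technical covariates and tissue mixtures can inflate or deflate
  correlations, so recovery rates on real data will not match the
  benchmark's.
* **PPI** — planted cliques (sizes 6/5/4) with confidence U[0.7, 1.0] on
  consecutive gene blocks, background edges at p = 0.03 with confidence
  U[0.4, 1.0], and a sub-threshold noise tier U[0, 0.4) that must be
  removed by the confidence filter. The planted triplet genes are drawn
  from the clique genes so that the module restriction is exercised
  end to end.

Every generator is a pure function of (config, rng seed); regeneration is
byte-identical. A consequence of the compact benchmark worth knowing: the
significant pairs involve only planted genes, so all gene nodes of the
assembled network are seeds and every degree-matched permutation resamples
(essentially) the same seed set — permutation p-values in the end-to-end
benchmark are near-degenerate at 0. Calibration of the permutation test is
therefore checked separately on larger null networks with seeds drawn from
a proper subset of genes, where the empirical p-values are verified to be
approximately uniform.

## Numerical conventions and problem sizes

Tie-breaks are lexicographic everywhere (module seeds, pair sorting,
ranking output), all randomness flows through explicitly seeded numpy
generators, and floats are serialized with `repr` so reruns are
byte-identical. The test suite and the acceptance script size their
simulations for a single CPU: hypergeometric enumeration to M = 20, 200
random graphs for the weight oracle, 100 planted-clique trials, 20
calibration repetitions at 200 permutations, 50 null-expression replicates,
and 25 (tests) / 10 (script) end-to-end replicate runs.

## Known limitations

* Identifiers are verbatim and case-sensitive; no symbol/alias mapping.
* No MRE or seed-sequence prediction, CLIP-peak processing, partial
  correlation or conditional-mutual-information ceRNA scores; the
  competing-pair evidence is shared-partner counting plus marginal
  co-expression.
* Enrichment is flat set overlap; no GO ancestry or pathway topology.
* The random walk is single-layer, undirected and unweighted; no
  heterogeneous or multiplex propagation.
* Expression is used unstratified; if a tissue-specific signal matters the
  caller must supply a tissue-restricted matrix.
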