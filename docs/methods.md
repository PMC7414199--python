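# Methods

This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the protocol leaves the
design open.

## Differential-expression meta-analysis

Inputs are log2-scale expression matrices (post-RMA-style
normalization; normalization itself is out of scope).  Probe-level
matrices are collapsed to gene level by the arithmetic mean of a gene's
probes per sample; a probe mapped to several genes contributes to each
of them, and unmapped probes are dropped and counted in the log.

Per study, each gene is tested case vs control two-sided.  Two modes:

- **student** — pooled-variance Student *t* with n₁+n₂−2 df.
- **moderated** (default) — the gene's pooled variance is shrunk toward
  a prior variance, s̃² = (d₀s₀² + df·s²)/(d₀+df), and the statistic is
  referred to *t* with df+d₀ degrees of freedom.  (d₀, s₀²) are
  estimated once per study by moment matching of the gene-wise variance
  distribution under the scaled-F marginal s² ~ s₀²·F(df, d₀); when the
  observed variances are under-dispersed relative to χ²(df) the prior
  df is effectively infinite and the test falls back to full pooling
  (normal reference).  Setting the prior df to 0 recovers the Student
  test exactly, which is asserted in the tests.  This reproduces the
  intent of empirical-Bayes moderated testing without binding to any
  particular package's implementation.

Fold change is the case-minus-control mean difference on the log2
scale.  Combination across the K studies uses Fisher's sum of logs,
X = −2Σ ln pₖ with p from the χ²(2K) upper tail, applied to genes
common to all studies only; genes private to a study are reported
separately and never screened.  BH step-up adjustment is applied to the
combined p-values (delegated to `statsmodels`; the tests verify it
against a hand-written step-up rule).  The screen is strict at both
thresholds: BH-p < α (default 0.05) and |mean log2FC| > cut (default
0.5).  The mean log2FC weights each study by its total sample size
(the standard fixed-effect choice; the protocol does not specify one).

Direction handling is explicit because cross-study sign conflicts are
otherwise silent: a gene whose per-study fold changes disagree in sign
is labeled `conflict`, still gets a combined p, but is excluded from
the up/down lists (the conservative choice).  Zero-variance genes with
unequal group means get the smallest representable positive p and a
flag, so they cannot silently dominate rankings.

## Over-representation

One-sided Fisher exact test per gene set, identical to the
hypergeometric upper tail P(X ≥ a) on the 2×2 table of query/set
membership within the universe.  The universe defaults to all genes
present in the expression data after probe collapse — self-consistent
and reproducible without an external gene catalog — and can be
overridden.  BH adjustment is applied within each library separately,
never pooled across libraries, mirroring how per-library significance
is conventionally reported.  Depletion is out of scope.

## PPI networks and hub genes

Edge filters: BioGRID-like tables keep rows with ≥ 1 experimental
evidence; HIPPIE-like tables keep confidence scores in [0.63, 1]
(the published threshold sentence contains a typographical
impossibility, "0.63 ≥ score ≤ 1"; the interval consistent with
"medium and high confidence" is used).  Only edges incident to at least
one seed survive; self-loops are dropped, duplicates merged with
provenance concatenated, and isolated seeds retained.

Centralities on the full network (seeds plus interactors):

- degree — incident edge count;
- betweenness — Σ σ_st(v)/σ_st over unordered pairs, unnormalized
  (any monotone normalization leaves ranks, hence hubs, unchanged —
  asserted by test);
- stress — Σ σ_st(v), the count of shortest paths through v;
- closeness — (n_c−1)/Σ d(v,w) within v's component, 0 for isolates;
- EPC — mean over `epc_reps` Monte-Carlo realizations (each edge kept
  independently with probability `epc_retain_p`, default 1000 × 0.5) of
  the number of nodes still connected to v.  The p=1 and p=0 limits are
  exact (component size − 1, and 0) and anchor the tests; with 1000
  realizations the replicate spread on a 20-node graph stays below half
  a node.

Hub calling takes, for each of the five measures, the nodes with dense
rank ≤ n (so all ties at the cutoff are included), intersects the five
sets, and finally restricts to seed DEGs.  Ranking everything and
restricting afterwards (rather than ranking seeds only) is the reading
that reconciles "top n DEGs were ranked" with per-measure sets of
different sizes; both modes exist behind `restrict_to_seeds`.  By
default n is the number of seed DEGs present in the network
(`top_n_mode="n_seed_degs"`); an explicit n is available.

## Feed-forward-loop mining

Source dialects and their filters: miRWalk-like (score ≥ 0.95 **and**
3′UTR region **and** binding gap 1), Starbase-like (score ≥ 0.95;
these exports carry only a score), miRSearch-like (categorical
high-confidence flag), ChIPBase-like (binding site ≤ 1 kb upstream of
the TSS), Enrichr-TF-like (evidence p < 0.05), ITFP-like (no published
threshold; kept as-is).  Edges identical on (source, target, type,
species) are merged with provenance concatenated.

Conservation: a miRNA is retained iff its base name — species prefix
stripped, case-folded, arm suffix (-5p/-3p) kept by default as the
stricter identity, relaxable via `keep_arm=False` — appears as an edge
source in both the human and mouse filtered sets.  All miRNA edges of
non-conserved miRNAs are pruned; TF→gene edges are deliberately left
untouched (the protocol alters interactions "with respect to" the
final miRNAs only).  The filter is idempotent.

A feed-forward loop is a triple (m, T, g) with m→T, m→g, T→g all
present in the conserved edge set; enumeration is exact and verified
against a brute-force scan of all |M|·|T|·|G| triples.  The merged
network is the union of motif-participating edges (a flag can include
all filtered edges instead).  In the full pipeline the gene class is
the hub-gene output of the PPI stage.

Topology statistics run on the undirected projection (direction is
retained in the motif list): degree histogram; mean clustering
coefficient per degree class with C_v = 2e_v/(k_v(k_v−1)) and C_v = 0
for k_v < 2; topological coefficient T_v = avg_u J(v,u)/k_v over
partners u sharing ≥ 1 neighbor, J counting shared neighbors plus 1 if
u is adjacent to v (0 for k_v < 2); betweenness and closeness as above;
shortest-path histogram over connected pairs; and a power-law fit by
least squares of log₁₀(count) on log₁₀(k) over nonzero bins with R² —
the construction a network-analyzer degree plot uses, not a
maximum-likelihood tail fit (out of scope).

## Synthetic data

The generator emulates the structures the analysis assumes, not the
biology that produces them:

- **Expression** — per-gene baselines ~ Normal(7, 2) on the log2 scale
  (typical RMA intensity range), drawn once and shared by both studies;
  planted genes add ±`effect_lfc` to case means in every study;
  i.i.d. Gaussian noise.  Defaults are the desk-scale fixture: 500
  genes, 25 up + 25 down at |log2FC| = 1.5, noise SD 0.5, 10 vs 10 per
  study, seed 7.  Under these conditions the screen recovers ≥ 90% of
  planted genes with ≤ 5 false positives (measured, not assumed).
  Probe-level matrices give two probes to a subset of genes with
  identical values, so collapse restores the gene matrix exactly.
- **Gene sets** — libraries whose "enriched" sets draw most members
  from the planted DEGs (deterministic windows, so the designated hub
  genes are always covered) plus background sets.
- **PPI** — seeds form a clique with Poisson-distributed private leaf
  interactors (designated hubs get 3× the mean).  The clique gives
  every seed a wide centrality margin over the leaves, which is what
  makes hub calling insensitive to EPC Monte-Carlo noise — a designed
  property of the fixture, verified over 10 reseeded runs.  A
  configurable number of edges deliberately fail the evidence/score
  filters.
- **Regulatory layer** — planted (m, T, g) triples with passing scores;
  decoy edges rejection-sampled so they never complete an unplanted
  loop (a flag disables rejection); an equal number of failing-score
  rows exercises the filters; a `conserved_frac` of human miRNAs is
  mirrored into the mouse table with the `mmu-` prefix.
- **Exact-count mode** — a deterministic anchored construction
  reproduces prescribed per-class node counts and per-type edge counts
  with every node and edge in ≥ 1 loop: all miRNAs and most TFs target
  an anchor gene, dedicated TFs cover the remaining genes, required
  miRNA–TF pairs close the loops over non-anchor genes, and the rest of
  the miRNA–TF budget fills pairs over the anchored TF pool.
  Infeasible count requests raise an error stating the violated
  constraint.  At (26, 20, 5) nodes and (32, 21, 144) edges this
  reproduces the published 51-node, 197-edge network.

What the generator does **not** emulate: probe-level intensity
distributions, batch effects, correlated gene–gene structure, realistic
PPI topology beyond the seed/interactor split, or sequence-based miRNA
targeting.  Passing tests therefore demonstrate correctness of the
statistics and graph algorithms under the assumed model, not robustness
to the messiness of real microarray or interaction data.

## Determinism and numerics

One seeded `numpy` Generator drives each stochastic component (EPC and
the generators); the pipeline output is a pure function of inputs,
configuration and seed, and reports are written with a fixed float
format (`%.10g`) and sorted rows so reruns are byte-identical.  Fisher
combination refuses p ≤ 0 (log undefined) and p > 1.  All thresholds
are strict or inclusive exactly as printed in the protocol (BH-p
< 0.05, |log2FC| > 0.5, score ≥ 0.95, ≤ 1000 bp, p < 0.05,
score ≥ 0.63).  Problem sizes in tests and the acceptance script
(500-gene fixture, 20-node EPC graph, ≤ 7-node oracle graphs, 200
random tripartite replicates) were chosen as the smallest scales at
which every contract is exercised meaningfully.

## Known limitations

- The moderated test's moment-matching prior is a simple estimator;
  heavy-tailed variance distributions fall back to weak shrinkage
  rather than a robust fit.
- EPC is defined here operationally (percolation reachability mean);
  other tools may scale or define it differently — ranks, not absolute
  values, are the contract.
- The power-law fit is descriptive (log-log least squares), not a
  statistical test of scale-freeness.
- GO-style term relations are ignored: gene sets are flat, as in GMT
  exports.
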