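# Methods

This note records the models, defaults and numerical choices behind
`activemod`, and what the synthetic benchmarks do and do not demonstrate.

## Preprocessing

Four steps in fixed order: present-call filtering, quantile normalization,
array outlier detection, probe→gene collapse.

* **Present calls.** When no vendor call matrix is supplied, a probe is
  "present" in a sample if its log2 value exceeds that sample's 25th
  percentile (configurable). This is a summarized-matrix surrogate for
  detection calls computed from probe-level data; it deliberately marks the
  dimmest quartile absent, which is appropriate for real arrays but
  mislabels simulated data in which every gene is expressed — synthetic
  instances therefore ship an explicit all-present call matrix. Rows
  present in *fewer than* half the samples are removed; exactly half is
  retained (strict inequality).
* **Normalization** is quantile normalization on log2 values: each column
  is replaced by the across-sample means of the order statistics, so all
  columns share one value multiset. Probe-level background correction and
  median-polish summarization are out of scope; an externally normalized
  matrix passes through unchanged.
* **Outlier arrays.** For sample a, D_a = mean over b≠a of (1 − Pearson
  r(a,b)); a is flagged when D_a > Q3 + 1.5·IQR (Tukey fence, strict).
  Zero-variance samples are auto-flagged as degenerate. Every D_a is
  logged; removal is a config choice (`drop_outliers`, default on). The
  fence was fixed for reproducibility in place of multi-heuristic QC tools.
* **Collapse** averages probe rows per gene on the log2 scale (arithmetic
  mean, not median) and drops unannotated probes.

## Moderated t and prior estimation

Two-group design only. With group sizes n₁, n₂ and pooled residual
variance s² on d = n₁+n₂−2 df,

    s̃² = (d₀s₀² + d·s²)/(d₀+d),   t = Δmean / (s̃·√(1/n₁+1/n₂)),

two-sided p from t on d₀+d df (normal limit when d₀=∞; d₀=0 reproduces the
classical pooled t exactly). Hyperparameters are estimated by matching the
sample mean and variance of log s² to the scaled-F log moments:
e_g = log s² − ψ(d/2) + log(d/2); if var(e) exceeds ψ′(d/2) then
d₀ = 2·ψ′⁻¹(var(e) − ψ′(d/2)) and log s₀² = mean(e) + ψ(d₀/2) − log(d₀/2),
otherwise d₀ = ∞ with log s₀² = mean(e). The trigamma inverse is a Newton
iteration started at 0.5 + 1/x. Genes with zero variance and zero mean
difference get p = 1 by convention; p-values are floored at the smallest
positive double. Reported p is unadjusted (it feeds the network weights); a
Benjamini–Hochberg column is emitted for reporting only. Fold changes use
the signed display convention sign(logFC)·2^|logFC| (−1.53 = 1.53-fold
down), with logFC = 0 mapping to +1.

## Network handling

STRING-dialect edge lists (scores 0–1000, divided by 1000) are read into an
undirected graph; reciprocal duplicates keep the maximum score, self-loops
are dropped and counted. Confidence filtering keeps edges with score ≥
threshold (default 0.850; an edge exactly at threshold survives) and drops
isolates. The thresholded network is treated as unweighted topology —
confidence is never a path weight. Interactor order is breadth-first
shortest-path distance; the witness path is the lexicographically smallest
shortest path, chosen by a greedy forward walk over nodes certified (by
BFS distances from both endpoints) to lie on some shortest path.

## Module search

Node weights w = −log10(max(p, p_min)), p_min = 1e-300. The objective is
the best connected component of the selected set under Σ(w−λ); the empty
set scores 0, so returned modules always carry positive net evidence. The
penalty prevents the trivial whole-graph optimum; the default
λ = −log10(0.05) ≈ 1.301 makes a node pay its way only below p = 0.05. For
the end-to-end benchmark on ~300 tested genes the pipeline uses λ = 2
(≈ −log10(0.01)): with N nodes the largest null weight is around
−log10(1/N) ≈ 2.5, so λ = 1.301 would admit ~5% of null genes into the
optimum and the planted-truth comparison would measure differential-
expression false positives rather than search quality.

GA defaults: population 200, generations 300, uniform crossover 0.8,
per-bit mutation 1/|V|, tournament size 3, elitism 2, one explicit seed.
Half the population is initialized from the above-penalty node set plus a
sparse (5%) random subset of its neighbors — candidate bridges — with the
first individual the pure thresholded set; the other half is uniform
random. Sparseness matters: including all neighbors attaches many
net-negative nodes to the scored component and makes the seeded half
uncompetitive. Connectivity is enforced at scoring time (best component),
never by repair operators, which keeps the GA exactly comparable to the
exhaustive oracle. Fitness evaluation uses a flat union-find over the
selected edge set (~10⁵ evaluations per run). The exhaustive solver
enumerates all subsets by bitmask (guard: ≤18 nodes), checks connectivity
with bit-parallel BFS, and breaks score ties toward smaller node sets, then
lexicographically — so an all-zero-weight graph yields the empty module.

Seeded extraction (`extract_seeded_module`) delimits the part of a module
within a given graph radius of seed genes, measured inside the module's
induced subgraph, and re-certifies connectivity. Radius and seed list are
explicit knobs because no principled universal delimitation exists.

## Cohort statistics

* **Spearman**: Pearson correlation of average (tie-corrected) ranks;
  p two-sided from the t approximation on n−2 df for n ≥ 10 and from exact
  enumeration of all permutations below that (reproducibility over speed at
  cohort scale).
* **Independent groups**: tie-corrected Kruskal–Wallis; pairwise
  Mann–Whitney U only after global p < α, Bonferroni over the pair count.
  Mann–Whitney uses exact enumeration when the smaller group has n < 8 and
  there are no ties, else the normal approximation with continuity and tie
  correction.
* **Matched sites**: Friedman on within-patient ranks with tie correction,
  implemented in-package so that k = 2 works (it reduces to the sign-test
  structure); pairwise Wilcoxon signed-rank (zero differences dropped,
  average ranks) after a positive global test, Bonferroni over k(k−1)/2.
  Complete cases only; fewer than five complete cases is an error. The
  Bonferroni scope is the pairwise count by default (adjustment over genes
  is left to the caller).
* **IRS**: percent positive cells is binned half-up to a decile score 0–10
  and multiplied by intensity 0–3; range 0–30 by construction.

## Synthetic data

Generators are pure functions of (spec, seed); no global RNG state.

* **Expression**: gene baselines N(7, 1), within-group noise N(0, σ),
  default σ = 0.5; a round(de_fraction·n_genes) subset shifts the case mean
  by ±effect_log2 (random sign). The benchmark design is 12 cases vs 12
  controls, 1000 genes, 5% differential at 1.5 log2 units — a typical
  moderate-size two-group microarray contrast.
* **PPI graphs**: Barabási–Albert preferential attachment (m =
  avg_degree/2), reflecting the heavy-tailed degree distribution of
  high-confidence human interactomes; Erdős–Rényi available for sensitivity
  checks. The planted module is wired connected by a random spanning tree
  plus extra in-module edges (p = 0.25); −log10(p) node weights are sampled
  directly from the stated module/background normals truncated at 0, which
  controls separation exactly. Default separation N(3.0, 0.5) vs
  N(0.5, 0.3) corresponds to module p-values near 10⁻³ against a
  mostly-null background.
* **Cohorts**: per site, two gene values are exponentiated from a bivariate
  normal with Pearson correlation 2·sin(πρ/6), so the population Spearman
  correlation equals ρ exactly and values are strictly positive like
  arbitrary-unit qPCR ratios. Default sites (tumor, adjacent, distant),
  n = 56 patients in benchmarks.

What the benchmarks show: that each statistical procedure is implemented
correctly (oracle agreement), that the GA attains known optima on small
instances, and that the pipeline recovers a well-separated planted module.
What they do not show: performance on real arrays with probe-level
artifacts, batch effects, correlated genes, or STRING's true topology at
10⁴ nodes; the synthetic generator models none of these.

## Benchmark problem sizes

Simulation sizes were chosen so each check is statistically meaningful yet
quick: 10 GA runs on the 300-node planted instance, 50 twelve-node
oracle-equivalence instances, 10,000 genes for prior recovery, 1,000
replicates for type-I calibration (three groups of 20, matching a typical
control-arm size), 200 cohort replicates at n = 56. The acceptance script
completes in roughly two minutes on one CPU.

## Known limitations

* Two-group designs only; no design matrices, paired DE, or array weights.
* The exhaustive solver is limited to 18 nodes by construction.
* The GA is a heuristic: optimality is only certified against the oracle at
  small scale, and stochastic-restart behaviour on very large graphs is
  untested.
* Present-call surrogate and outlier fence are simplified stand-ins for
  probe-level QC pipelines.
* The Friedman chi-square approximation is coarse for very small n; no
  exact Friedman null is provided.
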