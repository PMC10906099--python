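# Methods

## The inference problem

A destructively sampled timecourse gives cross-sectional snapshots of a
differentiating cell population. `fatecourse` treats the population as a
stochastic process developing in expression space and estimates the coupling
between consecutive snapshots by unbalanced entropic optimal transport, with
per-cell growth rates accounting for proliferation and death. Everything
downstream — fate matrices, log-odds landscapes, descendant allocation,
query-cell fate prediction — is a deterministic function of those couplings.

## Transport model

Between time points $t$ and $t+\Delta t$, with source marginal $a$, target
marginal $b$ and cost $C_{ij}$ = squared Euclidean distance between
batch-corrected principal-component coordinates (divided by its median so
$\varepsilon$ is scale-free), the coupling minimizes

$\langle\gamma,C\rangle + \varepsilon\,\mathrm{KL}(\gamma\|a\otimes b)
 + \lambda_s\,\mathrm{KL}(\gamma\mathbf1\|a)
 + \lambda_t\,\mathrm{KL}(\gamma^\top\mathbf1\|b)$.

**Solver.** Log-domain Sinkhorn scaling with potentials $f,g$ and
$\gamma_{ij}=\exp((f_i+g_j-C_{ij})/\varepsilon)$; the damped updates use
$\tau=\lambda/(\lambda+\varepsilon)$, with $\tau=1$ (hard marginal) when
$\lambda=\infty$. Running entirely in the log domain keeps the solver stable
at arbitrarily small $\varepsilon$ (the test suite exercises
$\varepsilon=10^{-3}$ against an exact linear-program oracle). Iteration
stops when the largest change of either potential falls below `tolerance`
($10^{-8}$ by default) or at `max_iterations` (5000), in which case the
result is returned flagged non-converged with a warning rather than raised.

**Defaults** ($\varepsilon=0.05$ on the median-normalized cost,
$\lambda_s=1$, $\lambda_t=50$) mirror the published defaults of the
transport framework this analysis style is built on; they are fully exposed
in `TransportConfig`. A soft source marginal with a much harder target
marginal is what lets growth learning re-distribute source mass without
distorting the observed target composition.

**Growth learning.** Rates are initialized at 1/day (an optional hook accepts
user-supplied proliferation scores). Each of the (default three) iterations
sets $a_i\propto g_i^{\Delta t}$, solves, and re-estimates
$g_i=(\text{row mass}_i/\text{uniform mass})^{1/\Delta t}$, floored at
$10^{-3}$ to keep rates positive. $\Delta t$ comes from the declared time
grid in days.

**Composition and pushing.** Each coupling is row-normalized into a
transition matrix before chaining (transition-matrix semantics); forward
pushes use the row-normalized chain, backward pushes the column-normalized
chain reversed. Composed rows sum to 1 to within $10^{-9}$ by construction,
and the fate matrix re-normalizes accumulated floating error before
enforcing its strict row-sum contract.

## Fate statistics

A fate matrix toward named, disjoint terminal target sets sums each cell's
composed transition row within every set, the remainder going to an implicit
`other_fate` column; cells already at the reference time get indicator rows.
Fate bias is the natural-log odds $\ln(p/(1-p))$ of the summed probability
$p$ of the chosen fate subset, with $p$ clipped to $[10^{-12},1-10^{-12}]$
so the statistic stays finite at saturation. Landscape selection uses a
strict inequality (> 0, or relaxed thresholds such as −0.5 / −1 for complex
landscapes), so masks are nested across decreasing thresholds by
construction. Descendant allocation pushes each source population's
indicator forward and assigns every later cell to the population of maximal
pushed mass — unnormalized by default, with a switch for per-population-size
normalization; ties go to the lexicographically first population name and
are flagged.

## Preprocessing

- **QC** (for deep-coverage plate data): cells below 10,000 total counts or
  above 4% mitochondrial fraction are removed; the per-cell report records
  totals, genes detected, mitochondrial fraction and the failure reason.
- **Normalization**: library-size factors rescaled to geometric mean 1;
  normalized expression is $\log_2(\text{count}/sf + 1)$. Pooling-based
  deconvolution factors are out of scope; on data without severe
  composition bias the two coincide up to scale, and the centred-at-unity
  contract is preserved.
- **HVGs**: a tricube-weighted local-linear mean–variance trend (span 0.05
  of genes, floored at a 20-gene window so small panels don't interpolate,
  with two bisquare robustness passes so high-variance genes cannot drag the
  trend toward themselves), a scaled chi-square test of
  $(n-1)\,\mathrm{var}/\mathrm{trend}$, Benjamini–Hochberg correction at
  FDR 0.05, and exclusions for mean $<10^{-3}$ or a configurable blacklist
  (sex-linked genes, reporter constructs).
- **PCA**: exact SVD, components ordered by explained variance, signs fixed
  by the largest-magnitude-loading-positive convention; 50 components by
  default (75 for large integrated atlases), always capped by the data.
- **MNN correction**: batches merge sequentially (ascending earliest time
  point, then descending size). For each merge, mutual nearest neighbours
  (k = 20 each way) between the accumulated reference and the incoming batch
  define per-pair correction vectors, smoothed over incoming cells with a
  Gaussian kernel and applied; the first batch is never moved. Because
  pairs found while batches are still separated systematically under-estimate
  the displacement (they preferentially join the facing edges of the two
  clouds), each merge is *refined*: pairs are recomputed after applying the
  correction, up to 15 rounds, stopping when the mean pair vector is
  negligible — the aligned configuration is the fixed point of this
  iteration. The kernel bandwidth defaults to 0.5 × the mean pairwise
  distance; a substantially narrower kernel makes the correction act locally
  enough to deform rather than translate a batch, which stalls the
  refinement short of alignment.

## Atlas mapping

Reference and query counts are merged on shared genes, jointly normalized
and log-transformed, HVGs and PCA recomputed on the merge, and the query
MNN-rescaled into the reference space as the incoming batch. Queries larger
than 10,000 cells are split by seeded shuffle into contiguous chunks, each
merged independently (HVG/PCA recomputed per chunk merge) and concatenated
back in the original order. Labels transfer as the mode of the k nearest
reference neighbours (Euclidean, exact); ties go to the label of the nearest
tied neighbour, then lexicographic, so transfer is deterministic and
permutation-invariant in reference order. The nearest-reference-cell lookup
used for fate prediction is exact (brute-force equivalent), not approximate.

## Marker detection

Two parameterizations of the same question:

- *pairwise*: Welch t-tests of every cluster against every other cluster,
  one-sided for up-regulation, Simes-combined across comparisons, ranked by
  best rank across comparisons (dense ranks, so ties at the top-20 display
  boundary are all kept). BH adjustment runs over the pooled
  (cluster, gene) family so error control is experiment-wide — per-cluster
  adjustment inflates the any-false-positive rate in proportion to the
  number of clusters. Moderated variance estimation is approximated by the
  Welch tests; empirical-Bayes shrinkage is a documented simplification.
- *one-vs-rest*: Wilcoxon rank-sum per gene after discarding genes expressed
  in under 25% of the cluster or with log2 fold change under 0.25; BH over
  the genes actually tested.

The conventional reporting filter (FDR < 0.05, LFC > 0.5, top-20 ranks) is
`top_rank_display`.

## Synthetic timecourse generator

The generator emulates the statistical structure the analysis assumes, with
analytic ground truth:

- **Lineage tree**: rooted tree of states, each with a nonnegative per-gene
  program and a growth rate drawn from U(0.7, 2)/day; children appear at
  fixed branch times and sibling programs differ in ≥10% of genes
  (25% of genes redrawn per child by default).
- **Sampling**: at each grid time, cells occupy states in proportion to
  growth-weighted branch mass (root mass grows as $e^{gt}$ and splits
  equally among children at branch times); within a state the latent program
  interpolates linearly from the parent's program, so trajectories are
  transcriptionally continuous.
- **Counts**: negative-binomial via a gamma–Poisson mixture with variance
  $\mu + \phi\mu^2$ ($\phi=0.15$ by default, $\phi=0$ giving Poisson),
  scaled to a total depth of 2000 counts/cell.
- **Ground truth**: a cell in state $s$ at time $t$ is assigned terminal-fate
  probabilities proportional to its expected descendant mass per terminal
  state at the horizon (the last grid time), computed in closed form from
  the branching process; the test suite verifies both fates and occupancies
  against independent numerical integration of the growth ODEs.
- **Batch structure**: cells are split across batches; `inject_batch_effect`
  adds per-gene N(0, magnitude²) offsets on the log2 scale (multiplicative,
  re-rounded to counts) and stores the offsets for oracle checks.
- **Sections**: each depth-1 subtree carries one anatomical section label,
  mimicking sub-dissection of major lineages; the map is configurable.

**Default study conditions** (the generator's defaults, used by the test
suite and the acceptance script): a symmetric three-state tree whose root
splits at day 1.5 into two terminal branches; five time points over three
days; 500 cells per time point; 300 genes; two batches. These sizes keep a
full fit under a minute on one CPU while preserving the structure the method
needs (pre-branch ambiguity, post-branch commitment, differential growth).

What the simulation does *not* emulate: realistic gene-regulatory dynamics,
spatial coordinates, RNA velocity, ambient RNA, doublets, or the gene-gene
correlation structure of real transcriptomes. Passing tests therefore
demonstrate the pipeline's correctness and calibration on data satisfying
its own assumptions — not performance on real embryos, where state overlap,
unmodeled covariates and annotation noise all bite.

All stochastic operations take an explicit seed; preprocessing, transport
and everything downstream are seed-free and fully deterministic.

## Known limitations and open choices

- Growth initialization from proliferation gene signatures is supported only
  through the user hook; the synthetic data has no cell-cycle structure to
  derive one from.
- Whether "maximum mass" descendant allocation should be normalized by
  source-population size is genuinely ambiguous; both are implemented
  (`normalize_populations`), unnormalized being the default.
- Concordance between predicted and observed fate tables has no canonical
  metric; per-region cosine similarity and Spearman rank correlation are
  both reported, with a seeded region-permutation baseline, so neither is
  privileged.
- The per-chunk recomputation of HVGs/PCA during chunked query mapping makes
  chunked and unchunked embeddings agree only statistically (≥95% label
  agreement in the tests), not bitwise.
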