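# Methods

## Problem setting

Case/control genome-wide association data are a supervised classification
problem: `n` individuals, each described by `p` SNPs coded additively
(0/1/2 copies of the minor allele), with a binary disease phenotype.
Linkage disequilibrium (LD) means nearby SNPs are strongly correlated and
inherited together in haplotype blocks, and disease risk may depend on
multi-SNP combinations (haplotypes / super-alleles, or epistatic pairs)
that no univariate test sees. This package implements a block-aware
random-forest variant for such data — trees whose node tests are
themselves small randomized trees over SNP blocks — together with the
classic forest and linear baselines and a synthetic data generator that
makes every claim testable without access to restricted genotype
collections.

## Trees inside trees

The SNP index range is partitioned into disjoint blocks of `B` contiguous
SNPs (a `BlockMap`; the final block keeps the remainder, minimum size 1 —
the simplest testable rule when `p` is not divisible by `B`). An outer
decision tree is grown as in Random Forests, but the unit drawn at a node
is a *block*, not a SNP:

1. at each outer node, `m_try_blocks` candidate blocks are drawn without
   replacement (default `ceil(sqrt(#blocks))`);
2. for each candidate, an *inner tree* is grown on the block's SNPs using
   the samples present at the node: a single Extra-Tree (`k_internal`
   random candidate SNPs per inner node, default `ceil(sqrt(B))`, one
   uniform random cut-point each, best Gini gain kept) whose number of
   test nodes is capped by the internal complexity `IC`. Because of the
   cap, inner leaves are *not* expanded depth-first: the next leaf to
   expand is drawn uniformly at random from the frontier of expandable
   leaves, which avoids the degenerate chains depth-first expansion
   produces under a node budget. A leaf is expandable when it is impure,
   has at least 2 samples, and some block SNP is non-constant on it;
   when all of a leaf's SNPs are constant it is retired without consuming
   the budget.
3. each inner leaf stores the case fraction of the training samples that
   reach it (no smoothing by default; a Laplace `(c+a)/(n+2a)` option
   exists); the inner tree therefore maps every sample at the outer node
   to a case-probability score;
4. an exhaustive cut-point is fitted on that numeric score exactly as a
   standard RF fits thresholds (midpoints between distinct consecutive
   values, ties toward the lowest cut), and the candidate (block, inner
   tree, cut-point) with the largest impurity decrease is kept — ties go
   to the lowest block index. A node becomes a leaf when pure, smaller
   than `N_min`, or when no candidate achieves a positive decrease with
   two non-empty children.

An ensemble of `T` such trees is grown on per-tree bootstrap copies;
prediction averages leaf case-fractions over trees (soft voting — AUC
evaluation needs a continuous score; a hard-vote `predict` exists). With
`B = 1` and `IC = 1` the construction provably collapses to a univariate
threshold split, which the test suite checks as exact partition equality.

Inner trees are rebuilt per outer node with fresh randomness (no caching
across sibling nodes) and are trained on the outer node's bootstrap
samples without second-level resampling.

### Nested importances

Both measures are mean-decrease-impurity (MDI) sums, weighted by the
fraction of in-bag samples reaching the node and averaged over the `T`
trees:

* **SNP importance** — sums over all *inner* nodes testing the SNP,
  regardless of originating block;
* **block importance** — sums over all *outer* nodes testing the block.

Within one inner tree the per-SNP contributions sum exactly to the
tree's total weighted impurity decrease, and per outer tree the block
contributions sum to the total outer decrease; these conservation
identities are enforced to 1e-10 in the tests and fix the normalization
convention (divide by in-bag size and by `T`). A region-report utility
merges top-ranked SNPs separated by at most `G` SNPs (default 20).

## Baselines

* **RF / ET** (`tree_core`): CART-Gini induction on raw SNPs with the two
  classic randomization schemes — bootstrap + exhaustive cut-points over
  a random `m_try` subset (RF), or random cut-points without bootstrap
  (ET). Features must be small non-negative integer codes; the
  exhaustive search counts genotype levels, which is exact for ordinal
  data. Any valid split of an impure node is accepted even at zero gain
  (XOR-type interactions are unlearnable otherwise). Gini impurity is
  used throughout; it is the usual basis of MDI, and no alternative
  criterion is wired into the compiled kernels.
* **OR / OR-beta** (`linear_baselines`): per-SNP allelic log odds ratios
  from the 2x2 allele table (with the Haldane-Anscombe +0.5 correction on
  zero cells) or from per-SNP univariate logistic regressions (vectorized
  Newton/IRLS, tolerance 1e-8, slopes capped at |beta| = 10 under
  separation). An individual's score is the average of `g_j * log OR_j`
  over its non-missing SNPs. An optional utility masks SNPs by
  Cochran-Armitage trend p-value.
* **SGD-L1 / SGD-L2 / Logit**: a minimal stochastic subgradient
  optimizer for `(1/n) sum loss + lambda * penalty`, hinge or logistic
  loss. L2 uses the Pegasos step `eta_t = 1/(lambda t)`; L1 uses
  truncated gradient (soft-thresholding after each loss step) with the
  step offset `t0 = n`, since the plain L1 subgradient lacks the
  multiplicative shrinkage that stabilizes Pegasos's large early steps.
  50 epochs, seeded shuffling; genotypes enter raw (a standardize flag
  exists).

## Evaluation protocol

Stratified k-fold cross-validation with a serializable fold plan shared
across all compared methods; AUC is the exact Mann-Whitney probability
`P(score_case > score_control) + 0.5 P(tie)` from average ranks.
Stratification is the default (per-fold AUC needs both classes when the
case/control ratio is unbalanced); an unstratified flag exists. Missing
genotypes are imputed once on the full matrix before CV by drawing from
each SNP's observed genotype distribution pooled over cases and controls
(a per-fold re-imputation flag exists; the choice is a preprocessing
convention, not part of any fitted model).

## Synthetic data generator

Each block owns a pool of `H = 20` haplotypes built by a mosaic process:
a founder drawn per-SNP from a target MAF range (default 0.05-0.5), then
recombinant copies of two random earlier haplotypes spliced at a random
breakpoint with per-SNP mutation (default rate 0.05). Rejection (with a
bounded repair pass) keeps pooled allele frequencies in range. Individual
block genotypes are sums of two uniformly drawn pool haplotypes, so
within-block r² is high and decays with distance while distinct blocks
are exactly independent; an inbreeding-like parameter optionally deviates
from Hardy-Weinberg proportions. Phenotypes follow a logistic model whose
linear predictor sums the planted effects, centered on its sample mean so
the base rate is the log-odds of the average individual; the true
per-individual risk is returned for Bayes-AUC reference and written to a
sidecar file, never into the genotype file.

Effect types: `additive_snp` (beta * g), `haplotype_superallele`
(beta * copies of one designated pool haplotype) and `epistatic_pair`
(beta * 1[g_a >= 1 and g_b >= 1] across two blocks).

The super-allele needs care: a carrier indicator `1[h = R]` is an AND
of allele literals, hence always linearly separable at the *haplotype*
level, and with small pools it is nearly in the linear span of the
dosage columns — a purely linear score would then capture it and the
effect would not be a multivariate non-linear one. Genuine nonlinearity
at the *genotype* level comes from phase ambiguity, so the generator
plants it deliberately: after choosing a mid-frequency risk haplotype
`R` (pool frequency 0.15-0.35), several non-carrier pool rows are
replaced by the two complementary recombinants of `R` around a random
breakpoint (prefix-of-R + donor suffix, donor prefix + suffix-of-R).
Diplotypes pairing the two decoys then mimic `R`'s allele pattern in
trans; the carrier count remains recoverable from the joint block
genotype (the flanking alleles resolve phase) but not from any linear
function of dosages. All three quantities are computed exactly by
enumerating the H² diplotypes: the conditional-mean ("nonlinear") R²,
the best-linear R², and the largest single-SNP tag r². Among 32 seeded
draws per causal block the one with the largest nonlinear-over-linear
gap is kept, subject to tag r² ≤ 0.3; typical accepted blocks have
nonlinear R² ≈ 0.9 against linear R² ≈ 0.5-0.65.

Three bundled scenarios (the package's reference study conditions):

* **interaction** — n = 2000, 50 blocks x 10 SNPs, super-allele effects in
  blocks 10/25/40, beta = 2.38, giving a generating-model (Bayes) AUC of
  ~0.85 (calibrated once by large-sample Monte Carlo root-finding);
* **additive** — n = 3000, 20 blocks x 5 SNPs with weak LD (mutation 0.2,
  like an LD-pruned panel), one additive SNP in every second block,
  beta = 0.72, Bayes AUC ~0.80. The smaller, weaker-LD panel is
  deliberate: simple allelic-odds-ratio scores are near-optimal only when
  per-SNP estimation noise and LD-partner noise are small relative to the
  signal, and this scenario exists to probe exactly that regime;
* **null** — no effects; any method should be at chance.

What the generator does **not** emulate: population structure and
admixture, realistic recombination maps, genotyping batch artifacts, and
missingness that is informative rather than completely at random.
Passing tests on these simulations therefore demonstrate correctness of
the algorithms and the claimed qualitative orderings under block-LD
architectures, not calibrated performance on real cohorts — on real data
quality control (call rate, MAF, HWE filtering) strongly affects both
accuracy and locus identification, and this package deliberately applies
none.

## Numerical and implementation choices

* Induction kernels are numba-compiled over flat array tree
  representations; models serialize to JSON-lines text files with exact
  round-trips, and identical seeds give byte-identical model files.
  Per-tree seeds derive from the master seed via `SeedSequence`, so
  results do not depend on execution order.
* Exhaustive cut-points are midpoints between consecutive distinct
  values; ties in gain break toward the lowest cut-point, then the lowest
  variable (or block) index.
* Random cut-points are uniform strictly inside (min, max), so both
  children are always non-empty.
* Degenerate inputs: pure or single-sample inner nodes yield 0-test-node
  stumps carrying the root probability; all-constant candidate draws
  make a node a leaf without re-drawing; an all-missing SNP is an error
  naming the SNP.
* Default pruning: T-Trees resolve `N_min = None` to `n // 8` — strong
  pruning suits them (replicate AUC is flat within ±0.003 from `n//4` to
  `n//16`); the RF baseline default is fully grown (`N_min = 2`).

## Reference study sizes

The bundled studies (`ttrees.experiments`) use 10 replicate seeds, 5-fold
CV and T = 200 trees per ensemble, with the scenario sizes above: large
enough that the TT-vs-RF ordering, the contiguous-vs-shuffled contrast
and locus recovery are stable across seed sets, small enough to run on a
single CPU in minutes.
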