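# Methods

This note documents the statistical models and procedures implemented in
`guildscan`, the defaults and why they were chosen, the design decisions
taken where the method definition was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Preprocessing

**Rarefaction.** Each sample is subsampled *without replacement*
(multivariate hypergeometric) to a common depth, default 16,500 reads —
a typical choice for MiSeq 16S runs averaging ~32,000 reads per sample.
Samples below the depth are dropped and reported, never silently padded.
Each sample's random stream is derived from the master seed and a CRC of
the sample id, and draws are made in canonical (sorted) ASV order, so
results are invariant to row and column order of the input table.
Multiple rarefactions with averaging are out of scope.

**Prevalence filter.** ASVs present (count > 0) in at least
⌈threshold·n⌉ samples are retained; the default threshold is 0.2 and
"at least" is inclusive (with 10 samples an ASV present in exactly 2 is
kept). The filter runs once over all samples pooled across groups and
timepoints; per-subset filtering exists behind a flag but is off by
default. The report carries the per-sample fraction of reads retained,
the usual evidence that the filtered set still represents the
community. Default stage order is rarefy → filter; the reverse is
available, and on the synthetic data the two differ only in the rare
tail.

**Relative abundances** used for guild quantification are computed
against the *whole* rarefied sample total, so CAG abundances are
interpretable as fractions of the community and row sums stay ≤ 1 after
filtering.

## SparCC

Counts are compositional: only relative information survives
sequencing, and naive correlations of fractions are distorted by the
unit-sum constraint. SparCC works from log-ratio variances
t_ij = Var[log(x_i/x_j)], which are invariant to per-sample scaling, and
solves for basis variances ω under the sparsity approximation
t_ij ≈ ω_i + ω_j − 2ρ_ij√(ω_iω_j) with Σ_j ρ_ij ≈ 0. Implementation
details:

- **Zeros**: fractions are drawn from a Dirichlet posterior with unit
  pseudocounts (default 20 draws, element-wise median aggregation —
  which also makes the estimate invariant to draw order); a
  deterministic plug-in mode (count+1)/(total+D) exists for exact
  reproducibility in tests. The +1 pseudocount means scale invariance is
  exact in the fractions and asymptotic (not bit-exact) in raw counts.
- **Iterative exclusion**: up to 10 rounds, each removing the single
  strongest pair with |ρ| above 0.1 from the linear system
  (lexicographically smallest pair on ties, for determinism). Components
  excluded more than D−3 times are withdrawn from further exclusion to
  keep the system identifiable.
- **Identifiability**: the solve requires D ≥ 4; fewer components leave
  the ω system underdetermined and raise an error.
- **Degeneracies**: negative solved basis variances are floored at
  1e−12 and counted in the diagnostics; estimates outside [−1, 1] are
  clamped and counted.
- **Significance**: the permutation null shuffles each ASV's counts
  across samples independently (destroying co-abundance, preserving
  marginals), re-estimates ρ, and reports
  p = (1 + #{|ρ_b| ≥ |ρ_obs|}) / (1 + B) with B = 100 by default, so the
  smallest attainable p is 1/101. A resample-samples variant exists
  behind a flag. P-values annotate the network; the full ρ matrix (not a
  pruned one) feeds the clustering.

**Accuracy regime.** SparCC's accuracy guarantee is tied to its
sparsity assumption. On compositions with a few moderate-size planted
correlation blocks (e.g. three blocks of 5 among 30 taxa at ρ = 0.8,
n = 200) the median absolute estimation error is ≈ 0.08 and the
within-block mean exceeds the between-block mean by ≈ 0.8. When *every*
taxon sits in a large dense block (three blocks of 10 of 30), the
assumption Σ_j ρ_ij ≈ 0 fails badly (the row sum is 7.2, not 0) and the
solve provably underestimates the basis variances (w = 3.76 instead of
5 by symmetry), pushing between-block estimates to ≈ −0.33. This bias
is intrinsic to the method, not to the implementation; within/between
*separation* — what guild detection consumes — survives it, which is
why guild recovery works even on dense-block data.

## Ward clustering

The SparCC distance d = 1 − ρ (range [0, 2]) is clustered
agglomeratively under Ward's criterion via Lance–Williams updates on
squared dissimilarities (the ward.D2 dialect, identical to scipy's
`linkage(..., 'ward')`, against which it is cross-checked in the test
suite; heights are reported on the original distance scale). The
implementation is written in-package because the method needs a
deterministic lexicographic tie-break and an optional ward.D dialect
(the Lance–Williams recursion applied to raw dissimilarities, R hclust's
legacy behaviour) for sensitivity analysis. The O(n³) cost is irrelevant
at the few hundred ASVs a prevalence-filtered table contains.

## PERMANOVA and the tree cut

PERMANOVA partitions squared dissimilarities:
SS_total = (1/N)Σ_{i<j} d²_ij, SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²_ij,
pseudo-F = [(SS_total − SS_within)/(a−1)] / [SS_within/(N−a)]. p-values
are add-one-corrected permutation tails; an exhaustive mode enumerates
every distinct labeling for small problems and is verified exactly
against a brute-force oracle. Perfectly separated groups (SS_within = 0)
get F = +∞, which compares correctly under permutation.

**The cut.** Observations are ASVs and the distance is the SparCC
distance: from the root down, each internal node's two child clusters
are the two groups, and a node whose children do not separate becomes
one CAG. Two decisions deserve emphasis:

- **Strict boundary.** Descent stops only when p > α (default
  α = 0.001 with 999 permutations). Since the smallest attainable p is
  exactly 1/1000 = 0.001, a maximally significant node always recurses;
  the boundary is tested explicitly.
- **Permutation scope.** Ward has already chosen the most separated
  two-way split of the node's leaves, so permuting labels *within the
  node* is anti-conservative: on pure-noise 15-leaf clusters the
  selected split reaches p ≤ 0.001 about half the time, and a planted
  4-guild benchmark is over-split in most seeds. The default null
  therefore draws the two pseudo-clusters' members from **all** tree
  leaves — asking whether these child clusters separate more than random
  same-size leaf sets of the whole community — which is calibrated under
  the selection and recovers planted structure cleanly. The node-local
  null remains available (`permutation_scope="node"`). The two coincide
  at the root, which is why a *globally* homogeneous community still
  tends to be split at the top level: a fundamental limitation of
  top-down testing on the same distances the tree was built from, shared
  by any variant of this procedure. Degenerate exchangeable distances
  (all pairs equal) are the exception — every labeling gives the same F,
  p = 1, and one CAG is returned.
- Nodes with ≤ 2 leaves collapse untested: a 2-leaf node admits only one
  two-group split, so a permutation test is uninformative.
- Each node's permutation stream derives from (master seed, node id), so
  the partition is independent of traversal order.

CAG labels are assigned in depth-first discovery order (CAG1, CAG2, …).

## Community statistics

Shannon entropy is log base 2 ("bits"), matching the common QIIME2
convention; a base option covers natural-log conventions. Observed ASVs
counts strictly positive entries. Bray–Curtis uses
1 − 2Σmin(u,v)/(Σu + Σv) (scipy), and equals on relative abundances what
it is on the equal-depth counts they came from. PCoA eigendecomposes the
double-centered Gower matrix −½JD²J; negative eigenvalues (non-Euclidean
input) are *reported*, never silently dropped, while coordinates and
proportion-explained use positive eigenvalues only. Alpha diversity is
compared per timepoint with Kruskal–Wallis (exact permutation p for
total n ≤ 8, where the chi-square approximation is unreliable) and
BH-adjusted per metric; beta diversity with pairwise PERMANOVA (default
9,999 permutations), BH-adjusted within each timepoint. PCoA is run once
on all samples rather than per timepoint.

## Association

Spearman ρ uses average ranks for ties; two-sided p is computed by
exhaustive permutation enumeration for n ≤ 9 and the t-approximation
otherwise. Missing phenotype values are handled pairwise-complete, and
cells with < 3 complete pairs are marked untestable and excluded from
the BH family. The BH family for phenotype associations is the full
CAG × variable grid (mirroring a joint heatmap); for differential
abundance it is all CAGs within one group pair. These family boundaries
are configurable in the sense that the functions operate on whatever
subsets they are given. Mann–Whitney is exact when n₁·n₂ ≤ 400 with no
ties, otherwise a tie-corrected normal approximation. Associations
default to the last timepoint's samples (terminal phenotypes against
terminal community state, a 1:1 sample_id join), pooled across groups.
Z-scores standardise per-CAG group means by the mean and SD of the group
means; zero-SD rows return all-zero Z.

A single BH implementation (a thin wrapper over statsmodels'
`fdr_bh`, validated against the closed-form step-up) serves every
module.

## Synthetic data

Per sample s in group g, the log absolute abundance of ASV i in guild
k(i) is

log a_i(s) = μ_i + β(g, k(i)) + λ f_{k(i)}(s) + e_i(s),

with guild factors f_k ~ N(0,1), residuals e ~ N(0, σ²), and
λ = σ√(r/(1−r)) so the within-guild log-scale correlation — exactly the
basis correlation SparCC estimates — equals the target r. Fractions are
the softmax of the log abundances; depth is negative binomial (mean
32,000, dispersion 30, matching the read-count magnitude and spread of
a typical MiSeq run, so rarefaction at 16,500 occasionally drops a
sample); counts are multinomial. Phenotypes are linear in the *true*
guild relative abundances plus Gaussian noise, with configurable signs
so that negative couplings (e.g. a protective guild vs hepatic
triglyceride) can be planted.

Defaults model a 3-arm × 10-mouse × 5-timepoint feeding study: baseline
log abundances spread over ~3 log units so that a rare tail exists for
the prevalence filter (~125/150 ASVs retained at >99.9% of reads); group
effects are zeroed at the baseline timepoint (the intervention has not
started); one guild is promoted by both interventions (more strongly by
the time-restricted one) and couples positively to cecal SCFAs and
negatively to hepatic triglyceride and serum cholesterol, one guild is
suppressed with the opposite phenotype signs. The number of replicates
and problem sizes used in the validation benchmarks (e.g. 20 seeds at
D = 60/K = 4 for recovery, 60 null replicates for calibration) were
chosen as the smallest sizes at which the targeted proportions are
statistically decidable.

**What the generator does not emulate:** taxonomy, phylogeny,
sequencing-error/chimera processes, overdispersion beyond the log-normal
factor structure, temporal autocorrelation within a mouse, and cage
effects on composition (cage labels are emitted for interface
completeness only). Passing benchmarks therefore demonstrate
correctness of the statistical machinery and recoverability of planted
structure under the stated model — not performance on real data, where
block structure is weaker, depth confounds exist and guild membership is
not crisp.

## Numerical conventions

- All permutation p-values are add-one corrected; minimum p is
  1/(B+1).
- Distance/correlation matrices are symmetrised and validated at
  construction; correlations are clamped to [−1, 1] with a diagnostics
  count.
- Joins between tables are by sample_id and fail loudly on mismatched
  sample sets unless an explicit intersect flag is passed.
- One master seed per run; per-stage and per-node streams are derived
  deterministically (numpy `SeedSequence`), so identical config + seed
  reproduce byte-identical outputs regardless of execution order.

## Known limitations

- Top-down PERMANOVA cutting cannot certify global homogeneity (see
  above): a community with a single all-encompassing guild is still
  split at the root in most runs. Downstream association statistics are
  unaffected (sub-guilds of a true guild remain co-abundant), but the
  reported CAG count should be read as an upper bound on the number of
  truly distinct guilds.
- SparCC absolute accuracy degrades when correlation structure is dense
  (see the accuracy-regime paragraph); relative separation is robust.
- The Dirichlet draws make default SparCC output stochastic given a
  changed seed; fix the seed (or use plug-in mode) for exact
  reproducibility.
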