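# Methods

This note documents the statistical models, numerical choices and known
limitations behind `comod`, in the order the pipeline runs.

## Consensus differential expression

Each condition contributes a tumor-vs-normal DE analysis per method; a
gene enters a method's set when its Benjamini–Hochberg-adjusted p-value is
strictly below `alpha` (default 0.05) in at least `min_conditions`
conditions (default 4, intended for 8-condition panels; use 2 for
4-condition panels); the candidate set is the intersection of the
per-method sets; finally IDs are mapped to a canonical namespace, dropping
unmapped IDs and collapsing redundant ones (the lexicographically smallest
source ID is the kept representative — the choice is arbitrary in
substance, fixed for reproducibility).

Correction is applied per (condition, method). Pooling p-values across
conditions before correction would couple conditions with very different
sample sizes; the per-condition convention keeps each test's FDR
interpretable and makes imported single-condition DE tables exchangeable
with the built-in backend.

Published tools (limma, edgeR, DESeq, SAMseq) are consumed through
`import_de_table`; tool-specific settings (SAMseq permutation and resample
counts, limma's TMM + voom pipeline) belong to those tools and are carried
as metadata only. The two built-in backends exist so the pipeline is
testable end-to-end without external tools: a two-sided Wilcoxon rank-sum
(the statistic SAMseq itself builds on) and a Welch t on log2 counts.
Both operate on median-of-ratios-normalized counts. Plain library-size
scaling is insufficient here: a block of strongly induced genes inflates
the affected samples' totals and drags every background gene into apparent
depletion, which in our planted simulations turned a 40-gene truth into a
~200-gene call set. Median-of-ratios size factors (each sample's median
ratio to the gene-wise geometric mean, computed over genes expressed
everywhere) are robust as long as most genes are unchanged.

## The balance matrix and its right basis

With E_t = D_tᵀD_t (optionally gene-centered first), the balance matrix

    S = 1/(T(T−1)) Σ_{t<r} (E_t E_r⁻¹ + E_r E_t⁻¹)

has real eigenvalues ≥ 1 when every E_t is symmetric positive definite,
with λ = 1 exactly on directions whose weight is identical across
conditions. Inverses are realized as Cholesky solves (one factorization
per condition), never explicit inversion.

**Centering.** The default is gene-centering (`center="gene"`, i.e. E_t
is n_t times the covariance). With uncentered data the shared per-gene
mean level is by far the strongest direction in every E_t and its
cross-terms with sample-level factors leak mean signal across the leading
eigenvectors; on planted-module panels at realistic expression levels the
uncentered leading eigenvectors carry no module information at all, while
centered ones isolate the planted modules cleanly. `center="none"`
reproduces the cross-product formula verbatim for users who want it.

**Rank deficiency.** With p genes ≫ n_t samples, E_t is singular. A
relative ridge E_t + ε·(trace E_t/p)·I (default ε = 1e−6, the absolute
amount added is recorded in diagnostics) makes the eigensystem well-posed.
The leading eigenvectors are insensitive to ε over at least six orders of
magnitude (measured 1e−6…0.2 on the benchmark panels) because the module
directions live inside every condition's row space; only the meaningless
bulk spectrum rescales.

**Per-condition factors.** In the rank-deficient regime the eigenbasis of
S is inherently ill-conditioned in its (huge, near-degenerate) bulk —
measured condition numbers of 1e49–1e97 for every tested ridge — so
inverting V to obtain U_t and Σ_t is numerically meaningless. When
cond(V) exceeds `cond_limit` (1e12) the factor extraction is skipped and
flagged in diagnostics (`require_factors=True` turns this into an error).
For full-rank panels the factorization is exact: the recorded relative
reconstruction residual is at machine precision.

**Degeneracy and rotation.** Eigenvalues within the leading group differ
only through sampling fluctuation of per-condition module strengths (a
chi-square effect of order n_t^{−1/2}), so the individual eigenvectors of
the non-normal S returned by the solver can be arbitrary rotations within
the leading subspace — on two-module benchmark panels they are routinely
~45° mixtures, and the mixture angle varies by seed. The *subspace* is the
stable object. Two mechanisms address this:

* `right_basis` replaces tight eigenvalue clusters (relative gap < 0.1,
  cluster size ≤ 50) and complex-conjugate pairs by a real,
  varimax-rotated basis of the same invariant subspace;
* `call_all_modules(rotate="auto")` varimax-rotates the leading
  eigenvector block before calling, where the block is delimited by the
  deepest relative eigenvalue gap ≥ 0.2 within the top k. A spectrum with
  no such gap has no direction standing above the bulk and is left
  unrotated — this gate matters, because unconditionally rotating pure
  noise vectors optimizes their fourth moments and manufactures spurious
  extreme loadings.

Varimax is the natural representative here: module calling looks for
sparse, extreme loadings, and varimax picks exactly the
sparsity-maximizing orthonormal basis of the subspace, deterministically.
Signs are fixed by making each column's largest-magnitude entry positive;
eigenvalue ties keep solver order.

## Module calling: mixture and tail-area FDR

Loadings of one basis vector are standardized to zero median and unit MAD
(unit-norm columns make raw loadings scale like p^{−1/2}, so a scale-free
statistic is required), and oriented so their skewness is non-negative —
this makes every downstream quantity invariant to the eigenvector's
arbitrary sign. A two-component Gaussian mixture is fitted by EM
(tolerance 1e−8, at most 500 iterations) from 10 restarts whose second
component mean sweeps the 5th–95th percentile; all restarts run as one
vectorized computation. A converged restart always beats a non-converged
one; restarts whose component sd collapses are discarded, and if all
collapse the loadings carry no mixture structure (error). The
larger-weight component is the empirical null.

With s = |z − μ₀| / max(σ₀, 1) the tail-area false discovery rate is

    Fdr(s) = w₀ · 2(1 − Φ(s)) / max(F̂(s), 1/p),   clipped to [0, 1],

with F̂ the empirical fraction of genes at least as extreme, and the
q-value is the running minimum of Fdr over thresholds up to s — monotone
in s by construction. The null sd enters through max(σ₀, 1): the majority
component of a median/MAD-standardized vector cannot genuinely be
narrower than the bulk's robust scale, and without the floor the mixture
occasionally splits a unimodal null in half (w₀ ≈ 0.55, σ₀ ≈ 0.75) and
promotes single ordinary extremes to q ≤ 0.001. This estimator is
deliberately self-contained — it follows the mixture-plus-tail-area idea
of the R package fdrtool but does not reproduce its half-normal/Grenander
internals, so q-values are not numerically interchangeable with fdrtool's.

A module is every gene with q ≤ `q_cutoff` (default 0.001) on one basis
vector; empty modules are valid results, and overlaps between modules are
reported rather than resolved.

## Functional-network dissection

The module's induced subgraph on a user-supplied undirected edge list is
optionally extended with *linker* genes — non-module genes adjacent to at
least two module genes (the threshold is configurable; only linker-to-
module edges are kept, so linkers can only add connectivity). Sub-modules
are greedy-modularity communities computed per connected component (nodes
and edges sorted first, so tie-breaking is deterministic); isolated nodes
form the residual "unconnected" group. Hub genes are nodes with at least
`min_degree` (default 10) neighbors, reported with their module/linker
role. The connected fraction is the share of module genes with any edge.
The clustering is a stand-in for interaction-database plugins whose exact
algorithm is unpublished; with a different community algorithm the
sub-module boundaries, but not the connectivity statistics, may differ.

## Survival stratification

Tumor samples are grouped on the module-restricted expression matrix:
values are shifted by the matrix minimum, factorized by rank-k NMF
(multiplicative updates, tolerance 1e−6, 20 seeded restarts, best
reconstruction error kept), and patients are k-means-clustered on their
metagene coefficient rows scaled by each metagene's profile norm. The
classic dominant-metagene assignment is a special case: it agrees when
groups express distinct metagenes, but it is blind to groups that differ
in module *amplitude* (both then share the same dominant metagene — on
amplitude-separated benchmark blocks it recovers nothing), which
coefficient-space k-means handles. Single-gene modules skip NMF and
k-means the gene's values directly. k defaults to 2 (two-group
Kaplan–Meier comparison); selecting k by consensus/cophenetic criteria is
out of scope.

Groups are compared with the k-sample log-rank test; patients missing
from either the expression or the survival table are dropped and counted,
patients with repeated clinical rows were already removed at load time.
Per-gene prognostic value is the raw (uncorrected) Wald p of a univariate
Cox proportional-hazards fit (Efron tie handling, lifelines); fits that
fail to converge are reported as NA, never silently dropped, and fewer
than 10 events triggers a warning. Per (condition, module) failures —
zero events, a single surviving group, absent genes — are isolated and
reported as non-evaluable rows.

## Synthetic data

The generator produces every input with known truth, reproducibly from
one seed (independent numbered substreams per generator):

* **Counts**: negative binomial with log-normal gene means (meanlog 4,
  sdlog 1 — library-realistic skew) and fixed dispersion 0.1; planted DE
  sets multiply tumor means by 2^{log2FC} in chosen condition subsets.
  Defaults: 8 conditions, 20 + 20 samples, 200 genes, two 20-gene sets at
  log2FC = 2 covering overlapping 6-condition subsets.
* **log2-FPKM panels**: per-gene baselines U(2, 8) plus N(0, 0.3²) noise;
  module m assigns member g a loading a_g ~ U(0.6, 1) drawn once and
  shared by all conditions, multiplied by a per-sample factor
  N(0, 1) drawn independently per condition — the shared object is the
  loading pattern, not sample values, exactly the shared-right-basis /
  condition-specific-left-basis structure the decomposition targets.
  Defaults: 4 conditions, 80 samples, 1000 genes, modules of 40 and 30.
* **Survival**: exponential times with hazard 0.01·exp(effect·metagene)
  per day, the metagene being the per-condition standardized mean of one
  planted module (standardization keeps the baseline hazard
  interpretable); censoring is independent U(0, c) with the horizon c
  solved by bisection to hit the configured censoring rate (default 0.2).
* **Edges**: each planted module wired as a 30%-density noisy clique over
  a 0.2%-density background graph.

What the generator does *not* emulate: batch effects, tumor purity,
condition-specific (non-shared) modules, overlapping module memberships,
mean–variance trends in the log-FPKM noise, and informative censoring.
Passing recovery tests therefore demonstrates correctness of the
machinery under the model's own assumptions, not performance on TCGA-like
data.

## Problem sizes in the test and acceptance suites

Planted-module recovery runs at the demonstration scale (p = 1000, T = 4,
n_t = 80, 5 seeds); noise-calibration panels use p = 400 over 20 seeds —
the same code path at a size chosen to keep repeated runs fast; survival
calibration uses 1000 label permutations, a 500-gene Cox null at n = 200,
and coefficient recovery at n = 300. The full demo (all six stages)
completes in well under a minute on one CPU; the acceptance script in
about two minutes.

## Known limitations

* The leading-block rotation assumes shared modules produce eigenvalues
  separated from the bulk by ≥ 20% relative gap; very weak modules below
  that gap are left as possibly-mixed eigenvectors.
* The tail-FDR estimator controls the module-level false-call rate in the
  simulated regimes but carries no finite-sample guarantee; with p below
  a few hundred genes the empirical-tail denominator is coarse.
* Cox fits are univariate by design; confounders are out of scope.
* `condition number > cond_limit` disables U_t/Σ_t, so per-condition
  generalized singular values are only available for full-rank panels.
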