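# Methods

## Model and estimators

**Dirichlet-multinomial (DM).** Counts per sample are multinomial conditional
on the library size; a Dirichlet(α) prior on the composition makes the
marginal Dirichlet-multinomial with the same parameter vector α. We write
α₊ = Σⱼ αⱼ, prior mean φ = α/α₊, and over-dispersion θ = 1/(1+α₊) ∈ (0,1);
θ → 0 is the multinomial limit and larger θ means more extra-multinomial
variance. The empirical Bayes normalizer fits α once to the whole table by
maximum marginal likelihood (each sample conditioning on its own depth — no
subsampling) and replaces each row by the posterior mean
(x + α̂)/(N + α̂₊), a convex combination of the raw proportions and φ̂ with
data weight N/(N + α̂₊). Output is strictly positive, so the centered
log-ratio (CLR) transform applies without pseudocounts.

**Dirichlet-tree multinomial (DTM).** Given a rooted tree whose leaves are the
taxa, the multinomial factorizes over internal nodes into conditionally
independent splits of the subtree total among the child branches. Placing an
independent local Dirichlet prior at each split yields a product of local DMs;
fitting is an independent DM maximum-likelihood problem per node (order- and
parallelism-invariant by construction), and the posterior-mean abundance of a
leaf is the product of posterior-mean branch proportions along its root path.
Branch lengths are ignored: only topology enters the model. Multifurcations
are supported (any split arity ≥ 2). Unnamed internal nodes receive
deterministic ids by post-order position so results are reproducible across
runs. Nodes whose subtree receives no reads in any sample have a flat local
likelihood; they fall back to the uniform Dirichlet(1/2) local prior.

**Maximum-likelihood fitting.** The DM likelihood is optimized in log(α) space
(positivity by construction) with L-BFGS-B and the analytic digamma gradient;
the initializer matches pooled mean proportions and a moment estimate of θ.
Relative log-likelihood tolerance 1e-8, at most 1000 iterations. log(α) is
bounded above by 15 (α ≤ ~3.3e6): beyond that the likelihood is numerically
flat (the multinomial limit) and log-gamma differences lose precision. A run
that ends with a line-search abort but a gradient below 1e-3 is reported as
converged — it is at a stationary point or pinned to the boundary. Columns
with no reads anywhere drive their α̂ⱼ to zero; they are floored at 1e-10 with
a warning recommending upstream prevalence filtering. All densities are
computed through log-gamma functions; raw gamma ratios are never formed.

## Normalization registry

`none`, `tss`, `css` (divisor = sum of counts ≤ the per-sample q-th quantile
of its positive counts, default q = 0.5), `rarefying` (multivariate
hypergeometric subsampling to ⌊0.9 × min depth⌋, seeded), `ubay`
(posterior mean under Dirichlet(1/2)), `aldex2_mc` (Monte-Carlo draws from
Dirichlet(x + 1/2), CLR per instance; default 128 instances), `ebay`,
`ebay_tree`. Methods whose output can contain zeros get a pseudocount of one
before any CLR step; the Bayesian methods are strictly positive and never
need one. CLR is applied last, after any prevalence filter. Note that because
the CLR is invariant to per-row rescaling, `none`, `tss` and `css` coincide
after pseudocounting and CLR; they differ only when used without the
transform.

## Differential abundance testing

Per-taxon Welch t or Wilcoxon rank-sum tests (exact Wilcoxon null for
combined n ≤ 20 without ties, tie-corrected normal approximation otherwise)
on CLR-transformed normalized data, with Benjamini-Hochberg (BH) correction
and calls at q ≤ 0.05 (configurable). A Welch test on two constant equal
groups returns p = 1 by convention.

The tree-guided procedure:

1. **Local tests.** At each split, per-sample posterior-mean branch
   proportions are within-split log-ratio transformed
   (log b̂ minus the split mean of log b̂) and tested between groups. For a
   binary split the two children differ only in sign, so one test covers
   both. BH runs once over all local tests in the tree (tree-wide FDR).
2. **Propagation.** Every leaf below a differential branch is called.
3. **Degenerate correction.** A leaf with two or more differential ancestors
   may sit under cancelling effects. For each such leaf the procedure takes
   the split where the shallowest differential branch on its path fires
   (a node that is itself non-differential by minimality; the root if the
   root split fires), re-tests all leaves under that split at leaf level on
   the tree-normalized, CLR-transformed data (BH within that leaf set), and
   overwrites those leaves' calls. Local tests use posterior-mean branch
   proportions, consistent with the tree normalizer.

The naive comparator (`naive_tree_test`) simply runs the global per-leaf test
on tree-normalized CLR data; it is retained because the paired comparison
against it is one of the package's benchmark outputs.

## Simulation designs

All generators are bit-reproducible under their seed and return ground-truth
differential labels computed from the generating parameters, never hard-coded.

**Base composition.** Grids draw taxon proportions from a fixed 60-entry
vector frozen in source, emulating the rank-abundance profile of a real gut
community: one dominant taxon (~0.44), thirty intermediate taxa of a few
percent each, and a rare tail. The profile is constructed (seeded, drawn
once) rather than stick-broken because the designs constrain it from two
sides: the six-taxon additive perturbation needs many entries comfortably
above 0.05β (β up to 0.35), while the tree designs need a branch probability
inside (0.05β, 1 − 0.05β) at β up to 8 — a single geometric stick-breaking
profile cannot satisfy both. Users can substitute their own pool.

**DM design.** p = 40 taxa subsampled from the pool without replacement and
renormalized; groups of n₁ = n₂ = 50; depths uniform on {5000..50000};
θ = 0.15 by default via α = φ·(1−θ)/θ. Group 1 shifts taxa {1, 22, 23} up and
{7, 11, 40} down by 0.05β (1-based indices), group 2 mirrors; draws whose
down-shifted entries would go nonpositive are resampled. Truth is the six
perturbed taxa (empty at β = 0).

**DTM designs.** A random binary tree over p = 50 taxa (or a user tree); at
every split a branch probability φ₀ is drawn from the pool and shared between
groups; θ = 0.27 locally. The planted split is the shallowest non-root node
with an internal child and a subtree of 4 to p/2 leaves — planting near the
root keeps the perturbed clade at appreciable abundance, as benchmark designs
for this procedure do; its branch pair is shifted ±0.05β with groups
mirrored. The degenerate design additionally shifts a nested child split in
the opposite direction, scaled by the ratio of base branch probabilities so
the two effects cancel *exactly* on the leaves under the nested split's first
child; the nested split's base probability is drawn from the balanced part of
the pool (0.2–0.8) so the cancelling shift is a real, testable effect. Truth
is computed by comparing the two groups' exact leaf compositions (relative
difference above 1e-9). Because branch probabilities from the pool are mostly
small, some replicates route few reads into the planted clade; those low-power
replicates are part of the design and are averaged over, not discarded.

**Gamma-Poisson.** n₁ = 20 cases, n₂ = 30 controls, p = 100; Poisson means
μᵢⱼ ~ Gamma(200, 1); cases add u ~ U((δ−1)·30, δ·30) to features 1–5 and
subtract it from features 6–10 (means floored at zero), δ ∈ {1..5}. Truth is
those ten features.

**Zero-inflated log-normal.** n₁ = n₂ = 50, p = 100; per-taxon structural-zero
probability π₀ ~ U(0.2, 0.6) and log-normal abundance (log-mean ~ N(4, 1),
log-sd 1, rounded to counts); cases add/subtract (δ/50)·Nᵢ on five features
each (clamped at zero), δ ∈ {0.1..0.9}. The distributional constants are a
synthetic stand-in chosen to produce realistic sparsity (~40% zeros); its
zeros are structural, which is precisely the regime where posterior-mean
normalizers (which treat zeros as undersampling) are expected to fail.

**Evaluation.** Recall = TP/(TP+FN), precision = TP/(TP+FP); precision is
reported as undefined (NaN, excluded from averages) when nothing is called.
`run_benchmark` drives generate → normalize → test → evaluate over a design
grid and returns a tidy per-replicate table; per-replicate failures are
recorded in an `error` column rather than aborting the grid.

## What the synthetic data does and does not show

The generators emulate the designs' distributional shapes (over-dispersion,
uneven depths, compositional perturbations, tree-structured correlation,
structural zeros) but not taxonomic identity, real phylogenies, or
covariates. Passing benchmarks therefore demonstrates correctness of the
estimators and the qualitative orderings (shrinkage dominance over TSS, power
rising with effect size and falling with over-dispersion, the tree-guided
procedure's precision advantage in degenerate geometries, FDR control under
the null) — not performance guarantees on any particular real cohort.

## Problem sizes

The test suite and the acceptance script use 20 replicates per benchmark
condition (100 for the null-FDR check), n₁ = n₂ = 50 samples and p = 40–50
taxa for the DM/DTM designs, and a battery of 10 fixed seeds at n = 2000
samples for hyper-parameter recovery; these sizes give Monte-Carlo standard
errors small enough for the qualitative comparisons being made.

## Known limitations

- Zeros are modelled as undersampling; structural zeros (the ZILN regime)
  violate the prior and degrade the Bayesian normalizers by design.
- Exactly two groups; no covariates or longitudinal structure.
- Branch lengths are ignored by the tree model.
- The DM fit assumes one shared prior across all samples of the table; fitting
  is on the pooled table, not per group.
- Confidence intervals for α̂ are not provided.
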