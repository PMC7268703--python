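# ebaynorm

Empirical Bayes normalization and phylogeny-aware differential abundance
testing for microbiome count tables.

Marker-gene (16S) studies produce a samples × taxa table of read counts whose
library sizes vary by orders of magnitude, whose entries are sparse and
over-dispersed, and which carry only relative (compositional) information.
Analyses that divide by the library size (total sum scaling, TSS) produce
zeros that break log-ratio methods, and rarefying throws data away. This
package normalizes counts by **empirical Bayes shrinkage** instead, and builds
a differential abundance workflow on top, for researchers comparing taxon
abundances between two groups of samples (e.g. case vs control).

## The model

Counts for sample *i* are multinomial given its depth,
*x*ᵢ ∼ Mult(*π*ᵢ; *N*ᵢ), with a conjugate Dirichlet prior *π*ᵢ ∼ Dir(*α*).
The marginal of *x*ᵢ is then Dirichlet-multinomial, DM(*α*), with
over-dispersion *θ* = 1/(1 + *α*₊) where *α*₊ = Σⱼ *α*ⱼ. Fitting *α* to the
whole table by maximum marginal likelihood and plugging it into the posterior
mean gives the normalized composition

  E(*π*ᵢⱼ | *x*ᵢ, *α̂*) = (*x*ᵢⱼ + *α̂*ⱼ) / (*N*ᵢ + *α̂*₊)
   = w·(*x*ᵢⱼ/*N*ᵢ) + (1 − w)·*φ̂*ⱼ,  w = *N*ᵢ/(*N*ᵢ + *α̂*₊),

a strictly positive shrinkage of the raw proportions towards the *fitted*
prior mean *φ̂* = *α̂*/*α̂*₊ — unlike the uniform-prior Bayesian estimator
(`ubay`, *α* = ½), whose shrinking point is uninformative.

With a rooted phylogeny over the taxa the prior becomes a product of local
Dirichlet distributions, one per internal node, and the marginal is the
Dirichlet-tree multinomial (DTM): independent local DMs on the branch counts
at every split. Each node is fitted independently, and a leaf's normalized
abundance is the product of posterior-mean branch proportions along its
root-to-leaf path (`ebay_tree`).

Downstream, normalized compositions are centered-log-ratio (CLR) transformed
and tested per taxon (Welch t or Wilcoxon rank-sum) with Benjamini-Hochberg
FDR control. With a tree, `tree_guided_test` instead tests **locally at each
split** (log-ratios of posterior-mean branch proportions), propagates calls to
descendants, and applies a degenerate-case correction: when two differential
ancestors of a leaf can cancel, the leaves below the shallowest differential
split are re-tested at leaf level and their calls updated.

The registry also implements the standard comparators: `none`, `tss`, `css`
(cumulative sum scaling), `rarefying`, `ubay`, and `aldex2_mc` (Monte-Carlo
Dirichlet instances, CLR-transformed).

## Worked example

Simulate the over-dispersed two-group design (θ = 0.15, 50 + 50 samples,
40 taxa, six taxa shifted by ±0.05β with β = 0.25), fit the prior, test:

```python
from ebaynorm import (SimDesign, gen_dm, fit_dm,
                      DifferentialAbundanceTest, evaluate)

data = gen_dm(SimDesign(beta=0.25, theta=0.15, seed=42))
fit = fit_dm(data.counts)
print("theta_hat", round(fit.theta, 4))

est = DifferentialAbundanceTest(method="ebay", test="t")
est.fit(data.counts, data.labels)
print(est.results_[est.results_.call].to_string(index=False))
print("recall, precision:", evaluate(est.calls_, data.truth))
```

prints

```
theta_hat 0.1584
unit_id  statistic            p            q
 taxon0   3.666357 3.999828e-04 2.666552e-03
 taxon6  -6.473007 1.121326e-08 2.242652e-07
taxon10  -4.981760 2.717064e-06 2.368009e-05
taxon21   4.961984 2.960011e-06 2.368009e-05
taxon22   6.064984 2.636638e-08 3.515517e-07
taxon39  -6.446805 5.060606e-09 2.024242e-07
recall, precision: (1.0, 1.0)
```

The fitted over-dispersion (0.158) recovers the generating value 0.15, and the
six taxa called at q ≤ 0.05 are exactly the six planted ones (positive
statistics for the up-shifted taxa 0, 21, 22; negative for 6, 10, 39).

The same pipeline is scriptable from a shell:

```sh
ebaynorm simulate --family dm --beta 0.25 --seed 42 --out-dir sim/
ebaynorm test sim/counts.tsv --labels sim/labels.tsv --method ebay --out calls.tsv
ebaynorm test-tree sim/counts.tsv --labels sim/labels.tsv --tree sim/tree.nwk --out tree_calls.tsv
```

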