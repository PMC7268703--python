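"""Normalization methods for taxa count tables, plus the CLR transformation.

Implemented methods (all operate on a samples x taxa nonnegative integer
matrix):

====================  ==========================================================
``none``              raw counts (pseudocounted before CLR)
``tss``               total sum scaling: divide by library size
``css``               cumulative sum scaling: divide by the sum of counts up to
                      a per-sample quantile of the positive counts
``rarefying``         subsample without replacement to 0.90 x the minimum depth
``ubay``              Bayesian posterior mean under the uniform Dirichlet(1/2)
``aldex2_mc``         Monte-Carlo instances drawn from Dirichlet(x + 1/2), CLR'd
``ebay``              empirical Bayes posterior mean: the Dirichlet prior is
                      fitted to the whole table by DM maximum likelihood
``ebay_tree``         phylogeny-aware empirical Bayes posterior mean under the
                      Dirichlet-tree multinomial
====================  ==========================================================

The Bayesian methods never emit zeros, so they compose directly with the
centered log-ratio (CLR) transform; the others receive a pseudocount of one
before any log-ratio step.

Each method is exposed both as a function and as a scikit-learn style
transformer (``fit``/``transform``/``get_params``), so normalizers drop into
sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import dm as _dm
from . import tree as _tree

METHODS = ("none", "tss", "css", "rarefying", "ubay", "aldex2_mc", "ebay", "ebay_tree")


def _check_counts(counts) -> np.ndarray:
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2:
        raise ValueError("counts must be a 2-D samples x taxa matrix")
    if np.any(X < 0) or np.any(X != np.round(X)):
        raise ValueError("counts must be nonnegative integers")
    return X


def tss(counts) -> np.ndarray:
    """Total sum scaling: each row divided by its depth. Zeros are preserved."""
    X = _check_counts(counts)
    N = X.sum(axis=1)
    if np.any(N == 0):
        bad = np.flatnonzero(N == 0)
        raise ValueError(f"zero-depth sample(s) at row(s) {bad.tolist()}")
    return X / N[:, None]


def css(counts, quantile: float = 0.5) -> np.ndarray:
    """Cumulative sum scaling.

    Per sample, the divisor is the sum of counts less than or equal to the
    sample's ``quantile``-th empirical quantile of its positive counts;
    ``quantile=1`` recovers total sum scaling.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    X = _check_counts(counts)
    out = np.empty_like(X)
    for i, row in enumerate(X):
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(f"sample {i} has no positive counts")
        q = np.quantile(pos, quantile)
        divisor = row[row <= q].sum()
        if divisor == 0:
            raise ValueError(f"sample {i}: css divisor is zero at quantile {quantile}")
        out[i] = row / divisor
    return out


def rarefy(counts, fraction: float = 0.90, seed=None) -> np.ndarray:
    """Subsample each row without replacement to floor(fraction * min depth).

    Uses multivariate hypergeometric draws, so column expectations match
    ``target * x_ij / N_i`` exactly.
    """
    X = _check_counts(counts).astype(np.int64)
    target = int(np.floor(fraction * X.sum(axis=1).min()))
    if target < 1:
        raise ValueError("rarefaction target depth is below 1")
    rng = np.random.default_rng(seed)
    out = np.empty_like(X)
    for i, row in enumerate(X):
        if row.sum() == target:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, target)
    return out


def ubay(counts) -> np.ndarray:
    """Uniform-prior Bayesian normalization: posterior mean under Dirichlet(1/2)."""
    X = _check_counts(counts)
    post = X + 0.5
    return post / post.sum(axis=1, keepdims=True)


def ebay(counts, params: _dm.DirichletParams | None = None) -> np.ndarray:
    """Empirical Bayes normalization.

    The Dirichlet prior is estimated once from the whole table by maximizing
    the Dirichlet-multinomial marginal likelihood; each row is then replaced by
    its posterior-mean composition, shrinking raw proportions towards the
    fitted prior mean. Strictly positive output.
    """
    X = _check_counts(counts)
    if params is None:
        params = _dm.fit_dm(X)
    post = X + params.alpha
    return post / post.sum(axis=1, keepdims=True)


def ebay_tree(counts, tree: _tree.PhyloTree,
              params: _tree.DTMParams | None = None) -> np.ndarray:
    """Phylogeny-aware empirical Bayes normalization under the DTM.

    Local Dirichlet priors are fitted independently at every internal node of
    the tree; each leaf's estimate is the product of branch posterior means
    along its root path. On a star tree this is exactly `ebay`.
    """
    X = _check_counts(counts)
    if params is None:
        params = _tree.fit_dtm(X, tree)
    return _tree.leaf_posterior_means(X, tree, params)


def aldex2_mc(counts, n_instances: int = 128, seed=None) -> np.ndarray:
    """Monte-Carlo Dirichlet instances, CLR-transformed.

    Draws ``n_instances`` per-sample probability vectors from the posterior
    Dirichlet(x + 1/2) and CLR-transforms each; returns an array of shape
    (n_instances, n_samples, n_taxa).
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    X = _check_counts(counts)
    rng = np.random.default_rng(seed)
    out = np.empty((n_instances, *X.shape))
    for k in range(n_instances):
        draws = np.stack([rng.dirichlet(row + 0.5) for row in X])
        out[k] = clr(draws)
    return out


def clr(compositions) -> np.ndarray:
    """Centered log-ratio transform: log u_j minus the row mean of log u.

    Rows sum to zero; the transform is invariant to positive rescaling of a
    row, so it applies equally to compositions and to (pseudocounted) counts.
    """
    U = np.atleast_2d(np.asarray(compositions, dtype=float))
    if np.any(U <= 0):
        raise ValueError("clr requires strictly positive input; handle zeros upstream "
                         "(pseudocount or a Bayesian normalization)")
    logU = np.log(U)
    return logU - logU.mean(axis=1, keepdims=True)


class CountTransformer(BaseEstimator, TransformerMixin):
    """Base class for count-table normalizers; subclasses set ``_stateless``."""

    def fit(self, X, y=None):
        _check_counts(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def _more_tags(self):
        return {"requires_y": False}


class TSSNormalizer(CountTransformer):
    """Total-sum-scaling transformer."""

    def transform(self, X):
        return tss(X)


class CSSNormalizer(CountTransformer):
    """Cumulative-sum-scaling transformer with a configurable quantile."""

    def __init__(self, quantile: float = 0.5):
        self.quantile = quantile

    def transform(self, X):
        return css(X, quantile=self.quantile)


class Rarefier(CountTransformer):
    """Even-depth subsampling transformer (without replacement)."""

    def __init__(self, fraction: float = 0.90, seed: int | None = 0):
        self.fraction = fraction
        self.seed = seed

    def transform(self, X):
        return rarefy(X, fraction=self.fraction, seed=self.seed)


class UBayNormalizer(CountTransformer):
    """Uniform Dirichlet(1/2) posterior-mean transformer."""

    def transform(self, X):
        return ubay(X)


class EBayNormalizer(CountTransformer):
    """Empirical Bayes posterior-mean transformer.

    ``fit`` estimates the Dirichlet prior from the table by DM maximum
    likelihood; ``transform`` shrinks each row towards the fitted prior mean.

    Attributes
    ----------
    params_ : DirichletParams
        Fitted prior (alpha vector, over-dispersion ``params_.theta``).
    """

    def __init__(self, max_iter: int = 1000, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = _check_counts(X)
        self.n_features_in_ = X.shape[1]
        self.params_ = _dm.fit_dm(X, max_iter=self.max_iter, tol=self.tol)
        return self

    def transform(self, X):
        return ebay(X, params=self.params_)


class EBayTreeNormalizer(CountTransformer):
    """Phylogeny-aware empirical Bayes transformer over a rooted tree.

    Attributes
    ----------
    params_ : DTMParams
        Per-internal-node fitted Dirichlet concentrations.
    """

    def __init__(self, tree: _tree.PhyloTree = None, max_iter: int = 1000,
                 tol: float = 1e-8):
        self.tree = tree
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        if self.tree is None:
            raise ValueError("EBayTreeNormalizer requires a tree")
        X = _check_counts(X)
        self.n_features_in_ = X.shape[1]
        self.params_ = _tree.fit_dtm(X, self.tree, max_iter=self.max_iter,
                                     tol=self.tol)
        return self

    def transform(self, X):
        return _tree.leaf_posterior_means(_check_counts(X), self.tree, self.params_)


def normalize(counts, method: str, tree: _tree.PhyloTree | None = None,
              quantile: float = 0.5, fraction: float = 0.90,
              n_instances: int = 128, seed=None, apply_clr: bool = True) -> np.ndarray:
    """Dispatch a named normalization and (optionally) CLR-transform the result.

    Methods whose output can contain zeros (``none``, ``tss``, ``css``,
    ``rarefying``) receive a pseudocount of one before the CLR step; the
    Bayesian methods are strictly positive already. ``aldex2_mc`` returns the
    mean over Monte-Carlo CLR instances, collapsing the stack to one matrix for
    downstream testing.
    """
    X = _check_counts(counts)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "ebay_tree" and tree is None:
        raise ValueError("method 'ebay_tree' requires a tree")

    if method == "none":
        out, zeros = X, True
    elif method == "tss":
        out, zeros = tss(X), True
    elif method == "css":
        out, zeros = css(X, quantile=quantile), True
    elif method == "rarefying":
        out, zeros = rarefy(X, fraction=fraction, seed=seed), True
    elif method == "ubay":
        out, zeros = ubay(X), False
    elif method == "ebay":
        out, zeros = ebay(X), False
    elif method == "ebay_tree":
        out, zeros = ebay_tree(X, tree), False
    elif method == "aldex2_mc":
        return aldex2_mc(X, n_instances=n_instances, seed=seed).mean(axis=0)

    if not apply_clr:
        return out
    if zeros:
        # pseudocount of one, added to the counts feeding the method; by CLR
        # scale-invariance this equals CLR of the pseudocounted proportions
        base = out if method == "rarefying" else X
        return clr(base + 1)
    return clr(out)


def clr_with_pseudocount(counts) -> np.ndarray:
    """CLR of pseudocounted raw counts: clr(x + 1).

    By scale invariance of the CLR this equals the CLR of the pseudocounted
    TSS/CSS proportions, so it serves as the zero-safe CLR for every
    non-Bayesian method.
    """
    return clr(_check_counts(counts) + 1)
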