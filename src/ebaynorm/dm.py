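"""Dirichlet-multinomial core: densities, maximum-likelihood fitting, posterior means.

The Dirichlet-multinomial (DM) arises by compounding a multinomial likelihood
``x | pi ~ Mult(pi; N)`` with a conjugate Dirichlet prior ``pi ~ Dir(alpha)``.
Its marginal has the same parameter vector ``alpha`` as the prior, so maximizing
the marginal likelihood over a table of samples yields an empirical prior; the
posterior mean ``(x + alpha) / (N + alpha_+)`` then shrinks each sample's raw
proportions towards the prior mean ``phi = alpha / alpha_+``.

The over-dispersion parameter is ``theta = 1 / (1 + alpha_+)``: theta -> 0
recovers the multinomial, theta -> 1 is maximal extra-multinomial variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

ALPHA_FLOOR = 1e-10


@dataclass(frozen=True)
class DirichletParams:
    """Hyper-parameters of a Dirichlet prior with derived quantities.

    Attributes
    ----------
    alpha : ndarray
        Strictly positive concentration vector of length p.
    converged : bool
        Whether the fit that produced these parameters converged (True for
        directly constructed parameters).
    n_iter : int
        Optimizer iteration count (0 for directly constructed parameters).
    """

    alpha: np.ndarray
    converged: bool = True
    n_iter: int = 0
    message: str = field(default="", compare=False)

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.ndim != 1 or alpha.size < 2:
            raise ValueError("alpha must be a vector of length >= 2")
        if not np.all(alpha > 0):
            raise ValueError("all alpha entries must be strictly positive")
        object.__setattr__(self, "alpha", alpha)

    @property
    def alpha_plus(self) -> float:
        return float(self.alpha.sum())

    @property
    def phi(self) -> np.ndarray:
        """Prior mean composition alpha / alpha_+."""
        return self.alpha / self.alpha_plus

    @property
    def theta(self) -> float:
        """Over-dispersion theta = 1 / (1 + alpha_+), in (0, 1)."""
        return 1.0 / (1.0 + self.alpha_plus)

    def to_text(self) -> str:
        lines = [f"converged\t{self.converged}", f"n_iter\t{self.n_iter}",
                 f"theta\t{float(self.theta)!r}"]
        lines += [f"alpha_{j}\t{float(a)!r}" for j, a in enumerate(self.alpha)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DirichletParams":
        kv = dict(line.split("\t") for line in text.strip().splitlines())
        alpha = [float(v) for k, v in sorted(
            ((k, v) for k, v in kv.items() if k.startswith("alpha_")),
            key=lambda item: int(item[0].split("_")[1]))]
        return cls(np.array(alpha), converged=kv["converged"] == "True",
                   n_iter=int(kv["n_iter"]))


def _check_counts_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("count vector must be 1-D")
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("counts must be nonnegative integers")
    return x


def multinomial_log_pmf(x, pi) -> float:
    """Log pmf of Mult(pi; N) at counts ``x``.

    Cells with ``pi_j == 0`` and ``x_j == 0`` contribute nothing; a zero
    probability with a positive count returns ``-inf`` rather than raising.
    """
    x = _check_counts_vector(x)
    pi = np.asarray(pi, dtype=float)
    if pi.shape != x.shape:
        raise ValueError("x and pi must have the same length")
    if np.any((pi <= 0) & (x > 0)):
        return float("-inf")
    pos = x > 0
    n = x.sum()
    return float(gammaln(n + 1) - gammaln(x + 1).sum()
                 + (x[pos] * np.log(pi[pos])).sum())


def dm_log_pmf(x, params: DirichletParams | np.ndarray) -> float:
    """Log pmf of the Dirichlet-multinomial marginal at counts ``x``.

    Computed entirely through log-gamma functions, so it is finite for any
    valid count vector and any strictly positive ``alpha``.
    """
    alpha = params.alpha if isinstance(params, DirichletParams) else np.asarray(params, float)
    if np.any(alpha <= 0):
        raise ValueError("all alpha entries must be strictly positive")
    x = _check_counts_vector(x)
    if alpha.shape != x.shape:
        raise ValueError("x and alpha must have the same length")
    n = x.sum()
    a_plus = alpha.sum()
    return float(gammaln(n + 1) + gammaln(a_plus) - gammaln(n + a_plus)
                 + (gammaln(x + alpha) - gammaln(x + 1) - gammaln(alpha)).sum())


def _dm_neg_loglik_grad(log_alpha: np.ndarray, X: np.ndarray, N: np.ndarray):
    """Negative DM log-likelihood of a count matrix and its gradient in log(alpha).

    Terms not involving alpha (the multinomial coefficients) are dropped; they
    do not affect the maximizer.
    """
    alpha = np.exp(log_alpha)
    a_plus = alpha.sum()
    ll = (gammaln(a_plus) - gammaln(N + a_plus)).sum()
    ll += (gammaln(X + alpha) - gammaln(alpha)).sum()
    # d ll / d alpha_j, then chain rule through alpha = exp(log_alpha)
    g = (digamma(a_plus) - digamma(N + a_plus)).sum()
    grad = g + digamma(X + alpha).sum(axis=0) - X.shape[0] * digamma(alpha)
    return -ll, -grad * alpha


def _moment_init(X: np.ndarray) -> np.ndarray:
    """Method-of-moments initializer for the DM concentration vector.

    Matches the pooled mean proportions and a moment estimate of the
    over-dispersion derived from the across-sample variance of proportions.
    """
    N = X.sum(axis=1)
    X = X[N > 0]
    N = N[N > 0]
    P = X / N[:, None]
    phi = P.mean(axis=0)
    phi = np.clip(phi, 1e-12, None)
    phi /= phi.sum()
    if X.shape[0] < 2:
        theta = 0.1
    else:
        v = P.var(axis=0, ddof=1)
        denom = (phi * (1 - phi)).sum()
        theta = float(v.sum() / denom) if denom > 0 else 0.1
    theta = min(max(theta, 1e-4), 0.9)
    return phi * (1 - theta) / theta


def fit_dm(counts, max_iter: int = 1000, tol: float = 1e-8) -> DirichletParams:
    """Maximum-likelihood fit of the DM concentration vector to a count matrix.

    Parameters
    ----------
    counts : array-like of shape (n_samples, n_taxa)
        Nonnegative integer counts; samples may have different depths
        (the likelihood conditions on each sample's own total).
    max_iter : int
        Optimizer iteration cap; exceeding it yields ``converged=False``
        on the result rather than an exception.
    tol : float
        Relative tolerance on the log-likelihood passed to the optimizer.

    Returns
    -------
    DirichletParams
        The fitted vector with convergence flag and iteration count. The
        log-likelihood at the optimum is never below the method-of-moments
        starting point.

    Notes
    -----
    Optimization is unconstrained in log(alpha) with the analytic digamma
    gradient, so positivity holds by construction. Taxa observed in no sample
    drive their concentration to zero; such entries are floored at 1e-10 and
    a warning recommends prevalence filtering upstream.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("counts must be a 2-D matrix with >= 2 samples and >= 2 taxa")
    if np.any(X < 0) or np.any(X != np.round(X)):
        raise ValueError("counts must be nonnegative integers")
    N = X.sum(axis=1)
    if np.any(N == 0) and np.all(N == 0):
        raise ValueError("every sample has zero total count")
    zero_cols = X.sum(axis=0) == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} taxa have all-zero counts; their fitted "
            "alpha is floored at 1e-10 — consider prevalence filtering upstream",
            stacklevel=2)

    x0 = np.log(np.clip(_moment_init(X), ALPHA_FLOOR, None))
    # upper bound keeps log-gamma differences well conditioned; alpha ~ 3e6
    # is operationally the multinomial (theta -> 0) limit
    bounds = [(np.log(ALPHA_FLOOR), 15.0)] * X.shape[1]
    res = minimize(_dm_neg_loglik_grad, x0, args=(X, N), jac=True,
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": tol})
    if not res.success:
        retry = minimize(_dm_neg_loglik_grad, np.zeros(X.shape[1]), args=(X, N),
                         jac=True, method="L-BFGS-B", bounds=bounds,
                         options={"maxiter": max_iter, "ftol": tol})
        if retry.fun < res.fun:
            res = retry
    # line searches can abort at a stationary point (e.g. the multinomial
    # boundary alpha -> inf when samples show no over-dispersion); a tiny
    # gradient means the maximizer was reached regardless of the status flag
    converged = bool(res.success) or float(np.abs(res.jac).max()) < 1e-3
    alpha = np.clip(np.exp(res.x), ALPHA_FLOOR, None)
    return DirichletParams(alpha, converged=converged,
                           n_iter=int(res.nit), message=str(res.message))


def dm_loglik(counts, params: DirichletParams) -> float:
    """Total DM log-likelihood of a count matrix (including multinomial terms)."""
    X = np.asarray(counts, dtype=float)
    return float(sum(dm_log_pmf(x, params) for x in X))


def posterior_mean(x, params: DirichletParams) -> np.ndarray:
    """Posterior-mean composition ``(x + alpha) / sum(x + alpha)``.

    Strictly positive and unit-sum; with ``x = 0`` it returns the prior mean.
    """
    x = _check_counts_vector(x)
    if x.shape != params.alpha.shape:
        raise ValueError("x and alpha must have the same length")
    post = x + params.alpha
    return post / post.sum()


def shrinkage_weights(N: float, params: DirichletParams) -> tuple[float, float]:
    """Weights (data, prior) of the posterior mean as a convex combination.

    The posterior mean equals ``data_weight * (x/N) + prior_weight * phi`` with
    ``data_weight = N / (N + alpha_+)``; the two weights sum to one.
    """
    if N < 0:
        raise ValueError("N must be nonnegative")
    a_plus = params.alpha_plus
    return N / (N + a_plus), a_plus / (N + a_plus)
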