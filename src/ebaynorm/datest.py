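"""Two-group differential abundance testing, with and without a phylogeny.

Without a tree, testing is the standard pipeline: normalize, CLR-transform,
run a Welch t-test or Wilcoxon rank-sum test per taxon, and control FDR with
Benjamini-Hochberg (BH).

With a tree, the procedure tests locally at tree splits instead of globally at
the leaves, which prevents the estimation error of an ancestral split from
propagating into every leaf below it:

1. *Local tests.* At each internal node, per-sample posterior-mean branch
   proportions are log-ratio transformed within the split and tested between
   groups. BH runs once over all local tests in the tree.
2. *Propagation.* A differentially abundant branch makes every leaf below it
   differentially abundant.
3. *Degenerate correction.* Two differential ancestors of the same leaf can
   cancel, leaving the leaf itself non-differential. Any leaf with two or more
   differential ancestors on its root path triggers a correction: the most
   recent non-differential ancestor is located, leaf-level tests (on the
   phylogeny-aware normalized, CLR-transformed data) are run over all leaves of
   that ancestor, and those leaves' calls are overwritten by the re-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from . import tree as _tree
from .normalize import clr as _clr, normalize as _normalize

TESTS = ("t", "wilcoxon")


def _split_groups(labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    groups = np.unique(y)
    if groups.size != 2:
        raise ValueError(f"exactly two groups required, found {groups.size}")
    m1, m2 = y == groups[0], y == groups[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least two samples")
    return m1, m2


def two_group_test(values, labels, test: str = "t") -> tuple[float, float]:
    """Welch t-test or Wilcoxon rank-sum test between two groups of values.

    Returns ``(statistic, p)``. A Welch test on two constant, equal groups
    (zero variance everywhere) returns p = 1 by convention instead of NaN.
    Wilcoxon uses the exact null for combined n <= 20 without ties, otherwise
    the tie-corrected normal approximation.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    v = np.asarray(values, dtype=float)
    m1, m2 = _split_groups(labels)
    a, b = v[m1], v[m2]
    if test == "t":
        if np.var(a) == 0 and np.var(b) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        n = a.size + b.size
        has_ties = np.unique(v).size < n
        method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def global_test(normalized, labels, test: str = "t", level: float = 0.05,
                unit_ids=None) -> pd.DataFrame:
    """Per-taxon two-group tests on a CLR-transformed matrix, BH-corrected.

    Returns a frame with columns ``unit_id, stage, statistic, p, q, call``.
    """
    Z = np.asarray(normalized, dtype=float)
    if unit_ids is None:
        unit_ids = [f"taxon{j}" for j in range(Z.shape[1])]
    res = [two_group_test(Z[:, j], labels, test=test) for j in range(Z.shape[1])]
    stat, p = np.array(res).T
    q = bh_adjust(p)
    return pd.DataFrame({
        "unit_id": list(unit_ids), "stage": "global", "statistic": stat,
        "p": p, "q": q, "call": q <= level})


@dataclass
class TreeTestResult:
    """Leaf-level calls of the tree-guided procedure plus the per-node audit trail."""

    leaves: pd.DataFrame
    local: pd.DataFrame
    corrections: list[dict] = field(default_factory=list)

    @property
    def calls(self) -> np.ndarray:
        return self.leaves["call"].to_numpy()


def _local_tests(counts, tree: _tree.PhyloTree, params, labels, test: str):
    """Stage 1: within-split log-ratio tests of branch posterior means.

    For a split with children w_1..w_m, each child's per-sample value is the
    local CLR ``log b_Aw - mean_w' log b_Aw'``. For a binary split the two
    children carry the same information (values differ only in sign), so a
    single test covers both.
    """
    b = _tree.branch_posterior_means(counts, tree, params)
    rows = []
    for nid in tree.internal_ids:
        logb = np.log(b[nid])
        local_clr = logb - logb.mean(axis=1, keepdims=True)
        m = local_clr.shape[1]
        n_tests = 1 if m == 2 else m
        for k in range(n_tests):
            stat, p = two_group_test(local_clr[:, k], labels, test=test)
            rows.append((nid, k, stat, p))
    return pd.DataFrame(rows, columns=["node", "child_index", "statistic", "p"])


def tree_guided_test(counts, tree: _tree.PhyloTree, labels, test: str = "t",
                     level: float = 0.05, params=None,
                     normalized_clr=None) -> TreeTestResult:
    """Phylogeny-aware detection: local split tests, propagation, and the
    degenerate-case correction. See the module docstring for the three stages.

    Returns leaf calls plus every intermediate decision for auditability.
    """
    X = np.asarray(counts, dtype=float)
    if params is None:
        params = _tree.fit_dtm(X, tree)
    if not params.converged:
        raise RuntimeError(f"DM fit failed at nodes {params.failed_nodes()}")

    local = _local_tests(X, tree, params, labels, test)
    local["q"] = bh_adjust(local["p"].to_numpy())
    local["call"] = local["q"] <= level

    # branch-level differential flags: for binary splits the single test covers
    # both children
    diff_branch: dict[tuple[str, int], bool] = {}
    for nid in tree.internal_ids:
        sub = local[local["node"] == nid]
        m = len(tree.child_leaf_sets[nid])
        if m == 2:
            call = bool(sub["call"].iloc[0])
            diff_branch[(nid, 0)] = diff_branch[(nid, 1)] = call
        else:
            for _, r in sub.iterrows():
                diff_branch[(nid, int(r["child_index"]))] = bool(r["call"])

    # stage 2: propagate down root-to-leaf paths; also count differential
    # ancestors per leaf and remember, per leaf, the split node carrying the
    # first (shallowest) differential branch on its path — the most recent
    # ancestor above all the leaf's differential ancestry, itself
    # non-differential by construction (the root when the root split fires)
    p_leaves = tree.n_leaves
    calls = np.zeros(p_leaves, dtype=bool)
    n_diff_anc = np.zeros(p_leaves, dtype=int)
    first_diff_split: dict[int, str] = {}
    # walk internal nodes root-first (reverse post-order)
    for nid in reversed(tree.internal_ids):
        for k, leaf_set in enumerate(tree.child_leaf_sets[nid]):
            if diff_branch[(nid, k)]:
                calls[leaf_set] = True
                n_diff_anc[leaf_set] += 1
                for l in leaf_set:
                    first_diff_split.setdefault(int(l), nid)
    stage = np.where(calls, "propagated", "local")

    # stage 3: degenerate correction — re-test, at leaf level, every clade
    # whose leaves carry two or more differential ancestors
    corrections = []
    degenerate = np.flatnonzero(n_diff_anc >= 2)
    handled = set()
    if degenerate.size:
        Zclr = (normalized_clr if normalized_clr is not None
                else _clr(_tree.leaf_posterior_means(X, tree, params)))
        for l in degenerate:
            anc = first_diff_split[int(l)]
            if anc in handled:
                continue
            handled.add(anc)
            leaf_set = _leaves_under(tree, anc)
            res = global_test(Zclr[:, leaf_set], labels, test=test, level=level,
                              unit_ids=[tree.leaf_names[j] for j in leaf_set])
            calls[leaf_set] = res["call"].to_numpy()
            stage = stage.astype(object)
            stage[leaf_set] = "corrected"
            corrections.append({"ancestor": anc,
                                "leaves": [tree.leaf_names[j] for j in leaf_set],
                                "result": res})

    leaves = pd.DataFrame({"unit_id": tree.leaf_names, "stage": stage,
                           "call": calls})
    return TreeTestResult(leaves=leaves, local=local, corrections=corrections)


def _child_internal_id(tree: _tree.PhyloTree, nid: str, k: int) -> str:
    """Id of the k-th child of internal node ``nid`` (itself internal)."""
    child = tree.children[nid][k]
    if child not in tree.children:
        raise RuntimeError(f"child {k} of {nid} is a leaf")
    return child


def _leaves_under(tree: _tree.PhyloTree, nid: str) -> np.ndarray:
    return np.sort(np.concatenate(tree.child_leaf_sets[nid]))


def naive_tree_test(counts, tree: _tree.PhyloTree, labels, test: str = "t",
                    level: float = 0.05, params=None) -> pd.DataFrame:
    """Global leaf-level testing after phylogeny-aware normalization.

    The comparator to `tree_guided_test`: normalize with the tree, CLR, then
    per-leaf tests with BH — no local tests, no propagation.
    """
    X = np.asarray(counts, dtype=float)
    if params is None:
        params = _tree.fit_dtm(X, tree)
    Z = _clr(_tree.leaf_posterior_means(X, tree, params))
    return global_test(Z, labels, test=test, level=level, unit_ids=tree.leaf_names)


class DifferentialAbundanceTest(BaseEstimator):
    """Two-group differential abundance test on normalized count data.

    sklearn-style: ``fit(X, y)`` takes raw counts and binary group labels,
    normalizes with the configured method, CLR-transforms, and runs per-taxon
    tests with BH correction.

    Parameters
    ----------
    method : str
        Normalization method name (see `ebaynorm.normalize.METHODS`).
    test : {"t", "wilcoxon"}
        Welch t-test or Wilcoxon rank-sum test.
    level : float
        BH q-value threshold for calls.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-taxon unit_id, statistic, p, q, call.
    calls_ : ndarray of bool
        Final per-taxon calls.
    """

    def __init__(self, method: str = "ebay", test: str = "t", level: float = 0.05,
                 tree: _tree.PhyloTree = None, seed: int | None = 0):
        self.method = method
        self.test = test
        self.level = level
        self.tree = tree
        self.seed = seed

    def fit(self, X, y):
        Z = _normalize(X, self.method, tree=self.tree, seed=self.seed)
        self.results_ = global_test(Z, y, test=self.test, level=self.level)
        self.calls_ = self.results_["call"].to_numpy()
        self.pvalues_ = self.results_["p"].to_numpy()
        self.qvalues_ = self.results_["q"].to_numpy()
        return self


class TreeGuidedTest(BaseEstimator):
    """Phylogeny-aware differential abundance detection (local tests at splits,
    propagation, degenerate correction).

    Attributes
    ----------
    result_ : TreeTestResult
        Leaf calls plus the per-node audit trail.
    calls_ : ndarray of bool
        Final per-leaf calls, in count-column order.
    """

    def __init__(self, tree: _tree.PhyloTree = None, test: str = "t",
                 level: float = 0.05):
        self.tree = tree
        self.test = test
        self.level = level

    def fit(self, X, y):
        if self.tree is None:
            raise ValueError("TreeGuidedTest requires a tree")
        self.result_ = tree_guided_test(X, self.tree, y, test=self.test,
                                        level=self.level)
        self.calls_ = self.result_.calls
        return self
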