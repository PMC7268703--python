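"""Dirichlet-tree multinomial model over a rooted phylogeny.

The Dirichlet-tree multinomial (DTM) factorizes a multinomial over the internal
nodes of a rooted tree: at each internal node A the counts flowing into its
child branches, conditional on the subtree total, follow a local
Dirichlet-multinomial with its own concentration vector. Because the local
factors are independent, fitting is an independent DM fit per node, and the
posterior-mean proportion of a leaf is the product of branch posterior means
along its root path. Branch lengths play no role; only topology enters.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .dm import DirichletParams, dm_log_pmf, fit_dm, posterior_mean


class PhyloTree:
    """Rooted tree over taxa with deterministic internal-node ids.

    Wraps a ``skbio.TreeNode``. Leaf names are the taxa; unnamed internal
    nodes receive ids ``node{k}`` by post-order position (root last), so runs
    are reproducible regardless of input formatting. Every internal node must
    have at least two children (multifurcations allowed).
    """

    def __init__(self, root: TreeNode, taxa: list[str] | None = None):
        self._root = root
        k = 0
        for node in root.postorder():
            if node.is_tip():
                continue
            if len(node.children) < 2:
                raise ValueError(
                    f"internal node {node.name!r} has {len(node.children)} child(ren); "
                    "every internal node must have >= 2")
            if not node.name:
                node.name = f"node{k}"
            k += 1
        self.leaf_names = [tip.name for tip in root.tips()]
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("duplicate leaf labels in tree")
        if taxa is not None:
            extra = set(self.leaf_names) - set(taxa)
            missing = set(taxa) - set(self.leaf_names)
            if extra or missing:
                raise ValueError(
                    "tree leaves and count columns differ; only in tree: "
                    f"{sorted(extra)}, only in counts: {sorted(missing)}")
            self.leaf_names = list(taxa)
        self._leaf_index = {name: j for j, name in enumerate(self.leaf_names)}
        # post-order list of internal nodes; per node: child ids + leaf-column
        # index sets under each child
        self.internal_ids: list[str] = []
        self.children: dict[str, list[str]] = {}
        self.child_leaf_sets: dict[str, list[np.ndarray]] = {}
        below: dict[int, np.ndarray] = {}
        for node in root.postorder():
            if node.is_tip():
                below[id(node)] = np.array([self._leaf_index[node.name]])
                continue
            self.internal_ids.append(node.name)
            self.children[node.name] = [
                c.name if c.is_tip() or c.name else "" for c in node.children]
            sets = [below[id(c)] for c in node.children]
            self.child_leaf_sets[node.name] = sets
            below[id(node)] = np.concatenate(sets)
        self.root_id = self.internal_ids[-1]

    @classmethod
    def from_newick(cls, source: str, taxa: list[str] | None = None) -> "PhyloTree":
        """Parse a Newick string or file path into a PhyloTree."""
        if source.strip().endswith(";"):
            handle = _io.StringIO(source)
        else:
            handle = source
        return cls(TreeNode.read(handle), taxa=taxa)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def is_star(self) -> bool:
        return len(self.internal_ids) == 1

    def newick(self) -> str:
        out = _io.StringIO()
        self._root.write(out)
        return out.getvalue().strip()


@dataclass
class NodeCounts:
    """Branch-aggregated counts: per internal node, an (n_samples, n_children) matrix."""

    tables: dict[str, np.ndarray]

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.tables[node_id]


@dataclass
class DTMParams:
    """Per-internal-node Dirichlet concentration vectors over the child branches."""

    params: dict[str, DirichletParams]

    def __getitem__(self, node_id: str) -> DirichletParams:
        return self.params[node_id]

    @property
    def converged(self) -> bool:
        return all(p.converged for p in self.params.values())

    def failed_nodes(self) -> list[str]:
        return [nid for nid, p in self.params.items() if not p.converged]

    def to_frame(self):
        import pandas as pd
        rows = [(nid, w, a) for nid, p in self.params.items()
                for w, a in enumerate(p.alpha)]
        return pd.DataFrame(rows, columns=["node", "child_index", "alpha"])


def aggregate_counts(counts, tree: PhyloTree) -> NodeCounts:
    """Sum leaf counts into branch counts at every internal node.

    For internal node A with children w_1..w_m, column k of the node's table is
    the total count over the leaves under w_k, per sample. The root's row sums
    equal the sample depths.
    """
    X = np.atleast_2d(np.asarray(counts, dtype=float))
    if X.shape[1] != tree.n_leaves:
        raise ValueError("count columns do not match tree leaves")
    tables = {
        nid: np.stack([X[:, s].sum(axis=1) for s in tree.child_leaf_sets[nid]], axis=1)
        for nid in tree.internal_ids}
    return NodeCounts(tables)


def dtm_log_pmf(x, tree: PhyloTree, params: DTMParams) -> float:
    """DTM log pmf: sum over internal nodes of the local DM log pmfs."""
    node_counts = aggregate_counts(np.atleast_2d(x), tree)
    missing = [nid for nid in tree.internal_ids if nid not in params.params]
    if missing:
        raise ValueError(f"missing parameters for internal nodes {missing}")
    return float(sum(dm_log_pmf(node_counts[nid][0], params[nid])
                     for nid in tree.internal_ids))


def fit_dtm(counts, tree: PhyloTree, max_iter: int = 1000, tol: float = 1e-8) -> DTMParams:
    """Independent DM maximum-likelihood fit at every internal node.

    Node fits are independent, so processing order (or parallel execution)
    cannot change the estimates. Non-convergence is flagged per node id on the
    returned object, never raised.
    """
    import warnings

    node_counts = aggregate_counts(counts, tree)
    fitted = {}
    with warnings.catch_warnings():
        # all-zero child branches are routine deep in a tree; the flat-table
        # warning from fit_dm would only repeat per node
        warnings.simplefilter("ignore", UserWarning)
        for nid in tree.internal_ids:
            table = node_counts[nid]
            if table.sum() == 0:
                # no reads ever reach this subtree: the local likelihood is flat,
                # fall back to the uniform Dirichlet(1/2) prior
                fitted[nid] = DirichletParams(
                    np.full(table.shape[1], 0.5), converged=True,
                    message="no data at node; uniform prior default")
            else:
                fitted[nid] = fit_dm(table, max_iter=max_iter, tol=tol)
    return DTMParams(fitted)


def branch_posterior_means(counts, tree: PhyloTree, params: DTMParams) -> dict[str, np.ndarray]:
    """Posterior-mean branch proportions b_Aw per sample and internal node.

    For node A, row i of the returned table is
    ``(x_Aw + alpha_Aw) / sum_w'(x_Aw' + alpha_Aw')``; each row sums to one.
    """
    node_counts = aggregate_counts(counts, tree)
    out = {}
    for nid in tree.internal_ids:
        post = node_counts[nid] + params[nid].alpha
        out[nid] = post / post.sum(axis=1, keepdims=True)
    return out


def leaf_posterior_mean(x, tree: PhyloTree, params: DTMParams) -> np.ndarray:
    """Phylogeny-aware posterior-mean composition over the leaves.

    Each leaf's estimate is the product, over the branches on its root-to-leaf
    path, of the branch posterior means. Strictly positive; sums to one.
    """
    b = branch_posterior_means(np.atleast_2d(x), tree, params)
    out = np.ones(tree.n_leaves)
    for nid in tree.internal_ids:
        for k, leaf_set in enumerate(tree.child_leaf_sets[nid]):
            out[leaf_set] *= b[nid][0, k]
    return out


def leaf_posterior_means(counts, tree: PhyloTree, params: DTMParams) -> np.ndarray:
    """Vectorized `leaf_posterior_mean` over the rows of a count matrix."""
    X = np.atleast_2d(np.asarray(counts, dtype=float))
    b = branch_posterior_means(X, tree, params)
    out = np.ones_like(X, dtype=float)
    for nid in tree.internal_ids:
        for k, leaf_set in enumerate(tree.child_leaf_sets[nid]):
            out[:, leaf_set] *= b[nid][:, [k]]
    return out


def star_tree(taxa: list[str]) -> PhyloTree:
    """Single-split tree: the DTM on it is exactly the plain DM."""
    return PhyloTree.from_newick("(" + ",".join(taxa) + ");", taxa=taxa)


def random_binary_tree(taxa: list[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform-at-random binary topology over the given taxa (no branch lengths)."""
    nodes = [f"{t}" for t in taxa]
    nodes = [*nodes]
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes[i] = merged
        nodes.pop(j)
    return PhyloTree.from_newick(nodes[0] + ";", taxa=taxa)
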