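"""Synthetic microbiome count generators with ground-truth differential labels.

Four families, each returning a `SimDataset` (counts, two-group labels, truth):

- ``dm``: Dirichlet-multinomial counts with over-dispersion ``theta`` and an
  additive +-0.05*beta perturbation of six taxa (three up, three down, groups
  mirrored); library sizes uniform on {5000..50000}.
- ``dtm``: Dirichlet-tree multinomial counts on a binary tree with planted
  differential internal splits — one split (non-degenerate) or a nested pair
  whose effects cancel exactly on some leaves (degenerate).
- ``gamma_poisson``: Poisson counts with Gamma(200, 1) means; ten features get
  a uniform shift u ~ U((delta-1)*30, delta*30) added (5) or subtracted (5).
- ``ziln``: zero-inflated log-normal baseline counts; ten features get
  (delta/50) of the sample's depth added (5) or subtracted (5). The zeros are
  structural.

The base composition pool is a fixed 60-entry heavy-tailed vector drawn once
by a seeded stick-breaking scheme and frozen here, standing in for taxon
proportions estimated from a real gut cohort; callers may substitute their
own pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tree as _tree

_BASE_POOL_SEED = 20201696
_BASE_POOL_SIZE = 60


def _make_base_pool(size: int = _BASE_POOL_SIZE, seed: int = _BASE_POOL_SEED) -> np.ndarray:
    """Heavy-tailed 60-taxon composition emulating a gut rank-abundance curve.

    Drawn once with a frozen seed so every simulation grid is self-contained.
    Three blocks: one dominant taxon (~0.45), a band of intermediate taxa
    (each a few percent — these host the additive perturbations, which need
    proportions comfortably above 0.05*beta), and a rare tail. A dominant
    entry near one half is also what lets the tree designs place a valid
    branch probability at their largest effect sizes.
    """
    rng = np.random.default_rng(seed)
    n_mid = min(30, size - 2)
    n_tail = size - 1 - n_mid
    dominant = rng.uniform(0.41, 0.45)
    tail_mass = 0.02
    mid = rng.dirichlet(np.full(n_mid, 30.0)) * (1 - dominant - tail_mass)
    tail = rng.dirichlet(np.full(n_tail, 1.0)) * tail_mass
    pool = np.concatenate([[dominant], mid, tail])
    return np.sort(pool)[::-1]


BASE_POOL = _make_base_pool()


@dataclass
class SimDesign:
    """Parameters of one simulation condition."""

    family: str = "dm"
    n1: int = 50
    n2: int = 50
    p: int = 40
    theta: float = 0.15
    beta: float = 0.25
    delta: float = 1.0
    depth_range: tuple[int, int] = (5000, 50000)
    seed: int = 0
    base_pool: np.ndarray = field(default_factory=lambda: BASE_POOL)

    def labels(self) -> np.ndarray:
        return np.r_[np.ones(self.n1, int), np.full(self.n2, 2, int)]


@dataclass
class SimDataset:
    """A simulated two-group count table with ground truth."""

    counts: np.ndarray
    labels: np.ndarray
    truth: np.ndarray           # boolean mask over taxa
    design: SimDesign
    phi: dict | None = None     # true group compositions, when defined
    tree: "_tree.PhyloTree | None" = None

    @property
    def truth_indices(self) -> np.ndarray:
        return np.flatnonzero(self.truth)


def perturb_composition(phi, s, t, beta: float) -> np.ndarray:
    """Shift +0.05*beta onto the taxa in ``s`` and -0.05*beta off those in ``t``.

    The index sets must be disjoint and equal-sized so total mass is conserved
    exactly. Raises if any down-shifted entry would become nonpositive; the
    caller should resample its base composition in that case.
    """
    phi = np.asarray(phi, dtype=float).copy()
    s, t = np.asarray(s, int), np.asarray(t, int)
    if np.intersect1d(s, t).size:
        raise ValueError("up- and down-shift index sets must be disjoint")
    if s.size != t.size:
        raise ValueError("up- and down-shift index sets must have equal size")
    eps = 0.05 * beta
    if np.any(phi[t] - eps <= 0):
        raise ValueError("perturbation would produce a nonpositive proportion; "
                         "resample the base composition")
    phi[s] += eps
    phi[t] -= eps
    return phi


def _sample_depths(rng, design: SimDesign) -> np.ndarray:
    lo, hi = design.depth_range
    n = design.n1 + design.n2
    return rng.integers(lo, hi + 1, size=n)


def _dm_counts(rng, alpha: np.ndarray, depths: np.ndarray) -> np.ndarray:
    return np.stack([rng.multinomial(N, rng.dirichlet(alpha)) for N in depths])


DM_UP = np.array([0, 21, 22])    # taxa shifted up in group 1 (down in group 2)
DM_DOWN = np.array([6, 10, 39])  # taxa shifted down in group 1 (up in group 2)


def gen_dm(design: SimDesign, max_retries: int = 20000) -> SimDataset:
    """Dirichlet-multinomial two-group data with six perturbed taxa.

    The shared base composition is a random subsample of the 60-entry pool,
    renormalized; group 1 shifts three taxa up and three down by 0.05*beta and
    group 2 applies the mirror image. Concentrations are
    ``phi_k * (1 - theta) / theta`` so ``theta`` is the over-dispersion.
    """
    if not 0 < design.theta < 1:
        raise ValueError("theta must be in (0, 1)")
    rng = np.random.default_rng(design.seed)
    for _ in range(max_retries):
        base = rng.choice(design.base_pool, size=design.p, replace=False)
        base = base / base.sum()
        try:
            phi1 = perturb_composition(base, DM_UP, DM_DOWN, design.beta)
            phi2 = perturb_composition(base, DM_DOWN, DM_UP, design.beta)
            break
        except ValueError:
            continue
    else:
        raise RuntimeError("could not find a valid base composition; "
                           "beta too large for the pool")
    scale = (1 - design.theta) / design.theta
    depths = _sample_depths(rng, design)
    X1 = _dm_counts(rng, phi1 * scale, depths[:design.n1])
    X2 = _dm_counts(rng, phi2 * scale, depths[design.n1:])
    truth = np.zeros(design.p, bool)
    if design.beta > 0:
        truth[np.r_[DM_UP, DM_DOWN]] = True
    return SimDataset(np.vstack([X1, X2]), design.labels(), truth, design,
                      phi={1: phi1, 2: phi2})


def _pick_planted_splits(tree: _tree.PhyloTree) -> tuple[str, str]:
    """Deterministically choose the planted split A and a nested split B.

    A is the shallowest (root-first order) non-root internal node whose subtree
    holds between 4 leaves and half the taxa and that has an internal child B;
    the perturbations are applied at A and (degenerate design) at B. A shallow
    planted split keeps the perturbed clade at appreciable abundance, mirroring
    benchmark designs that plant the signal near the root.
    """
    p = tree.n_leaves
    for nid in reversed(tree.internal_ids):
        if nid == tree.root_id:
            continue
        size = sum(s.size for s in tree.child_leaf_sets[nid])
        if not 4 <= size <= max(4, p // 2):
            continue
        for k, child in enumerate(tree.children[nid]):
            if child in tree.children:  # internal child
                return nid, child
    raise ValueError("tree has no internal node suitable for planting a signal")


def gen_dtm(design: SimDesign, tree: _tree.PhyloTree | None = None,
            degenerate: bool = False, max_retries: int = 1000) -> SimDataset:
    """Dirichlet-tree multinomial two-group data with planted differential splits.

    At every split a branch probability ``phi0`` is drawn from the base pool
    and the pair is ``(phi0, 1 - phi0)``, shared between groups. At the planted
    split A the pair is shifted by +-0.05*beta with groups mirrored. In the
    degenerate design a second, nested split B (inside A's shifted branch) is
    shifted in the opposite direction, scaled so the two effects cancel exactly
    on the leaves under B's first child — those leaves are truly
    non-differential despite two differential ancestors. Truth is computed by
    comparing the two groups' exact leaf compositions, never hard-coded.
    """
    rng = np.random.default_rng(design.seed)
    if tree is None:
        taxa = [f"taxon{j}" for j in range(design.p)]
        tree = _tree.random_binary_tree(taxa, rng)
    if any(len(c) != 2 for c in tree.children.values()):
        raise ValueError("gen_dtm requires a binary tree")
    node_a, node_b = _pick_planted_splits(tree)
    eps = 0.05 * design.beta

    # branch probability of the first child at every split, per group
    b1: dict[str, float] = {}
    b2: dict[str, float] = {}
    for nid in tree.internal_ids:
        for _ in range(max_retries):
            phi0 = float(rng.choice(design.base_pool))
            if nid == node_a and not (eps < phi0 < 1 - eps):
                continue
            # the nested planted split needs a balanced base probability so
            # its opposing (cancelling) shift is a real, testable effect
            if degenerate and nid == node_b and not 0.2 < phi0 < 0.8:
                continue
            if 0 < phi0 < 1:
                break
        else:
            raise RuntimeError("could not sample a valid branch probability; "
                               "beta too large for the base pool")
        b1[nid] = b2[nid] = phi0
    base_a = b1[node_a]
    b1[node_a] = base_a + eps
    b2[node_a] = base_a - eps
    if degenerate:
        # B sits on one of A's child branches; shift its split in the opposite
        # direction, scaled by (branch prob of B's incoming branch), so the two
        # effects cancel exactly on the leaves under B's first child
        kb = tree.children[node_a].index(node_b)
        c = base_a if kb == 0 else 1 - base_a          # base prob of A -> B branch
        e1 = eps if kb == 0 else -eps                  # group-1 shift of that branch
        base_b = b1[node_b]
        delta = -e1 * base_b / c
        for _ in range(max_retries):
            if 0 < base_b + delta < 1 and 0 < base_b - delta < 1:
                break
            base_b = float(rng.choice(design.base_pool))
            delta = -e1 * base_b / c
        else:
            raise RuntimeError("could not place the degenerate split")
        b1[node_b] = base_b + delta
        b2[node_b] = base_b - delta

    def leaf_comp(b: dict[str, float]) -> np.ndarray:
        out = np.ones(tree.n_leaves)
        for nid in tree.internal_ids:
            probs = (b[nid], 1 - b[nid])
            for k, leaf_set in enumerate(tree.child_leaf_sets[nid]):
                out[leaf_set] *= probs[k]
        return out

    phi1, phi2 = leaf_comp(b1), leaf_comp(b2)
    # relative difference: planted effects are O(0.05*beta / phi0) while exact
    # cancellations differ only by floating-point rounding
    truth = np.abs(phi1 - phi2) > 1e-9 * (phi1 + phi2)

    scale = (1 - design.theta) / design.theta
    depths = _sample_depths(rng, design)
    labels = design.labels()
    X = np.zeros((labels.size, tree.n_leaves), dtype=np.int64)
    for i, (lab, N) in enumerate(zip(labels, depths)):
        b = b1 if lab == 1 else b2
        totals = {tree.root_id: int(N)}
        for nid in reversed(tree.internal_ids):  # root first
            m = totals[nid]
            alpha = np.array([b[nid], 1 - b[nid]]) * scale
            counts = rng.multinomial(m, rng.dirichlet(alpha)) if m > 0 else np.zeros(2, int)
            for k, child in enumerate(tree.children[nid]):
                if child in tree.children:
                    totals[child] = int(counts[k])
                else:
                    X[i, tree.child_leaf_sets[nid][k][0]] = counts[k]
    return SimDataset(X, labels, truth, design, phi={1: phi1, 2: phi2}, tree=tree)


def gen_gamma_poisson(design: SimDesign) -> SimDataset:
    """Gamma-Poisson two-group data: means Gamma(200, 1); in the case group the
    first five features gain, and the next five lose, u ~ U((delta-1)*30,
    delta*30) on the Poisson mean (floored at zero)."""
    rng = np.random.default_rng(design.seed)
    n, p = design.n1 + design.n2, design.p
    mu = rng.gamma(200.0, 1.0, size=(n, p))
    case = design.labels() == 1
    lo, hi = (design.delta - 1) * 30.0, design.delta * 30.0
    u = rng.uniform(lo, hi, size=(int(case.sum()), 10))
    mu[np.ix_(case, np.arange(5))] += u[:, :5]
    mu[np.ix_(case, np.arange(5, 10))] -= u[:, 5:]
    mu = np.clip(mu, 0.0, None)
    X = rng.poisson(mu)
    truth = np.zeros(p, bool)
    truth[:10] = True
    return SimDataset(X, design.labels(), truth, design)


def gen_ziln(design: SimDesign, pi0_range=(0.2, 0.6), logmean_loc=4.0,
             logmean_scale=1.0, logsd=1.0) -> SimDataset:
    """Zero-inflated log-normal two-group data with structural zeros.

    Per taxon, a structural-zero probability pi0 ~ U(0.2, 0.6) and a log-normal
    abundance (log-mean ~ N(4, 1), log-sd 1); counts are rounded draws. In the
    case group the first five features gain, and the next five lose,
    (delta/50) of the sample's total count, clamped at zero. Truth is those ten
    features. The distributional constants are a synthetic stand-in for the
    zero-inflated Gaussian benchmark family this design emulates.
    """
    rng = np.random.default_rng(design.seed)
    n, p = design.n1 + design.n2, design.p
    pi0 = rng.uniform(*pi0_range, size=p)
    logmu = rng.normal(logmean_loc, logmean_scale, size=p)
    present = rng.random((n, p)) >= pi0
    X = np.round(present * rng.lognormal(logmu, logsd, size=(n, p))).astype(np.int64)
    depths = X.sum(axis=1)
    case = design.labels() == 1
    shift = np.floor(design.delta / 50.0 * depths[case]).astype(np.int64)
    X[np.ix_(case, np.arange(5))] += shift[:, None]
    X[np.ix_(case, np.arange(5, 10))] = np.clip(
        X[np.ix_(case, np.arange(5, 10))] - shift[:, None], 0, None)
    truth = np.zeros(p, bool)
    truth[:10] = True
    return SimDataset(X, design.labels(), truth, design, phi={"pi0": pi0})


GENERATORS = {
    "dm": gen_dm,
    "dtm_nondegenerate": lambda d, **kw: gen_dtm(d, degenerate=False, **kw),
    "dtm_degenerate": lambda d, **kw: gen_dtm(d, degenerate=True, **kw),
    "gamma_poisson": lambda d, **kw: gen_gamma_poisson(d),
    "ziln": lambda d, **kw: gen_ziln(d),
}


def generate(design: SimDesign, **kwargs) -> SimDataset:
    """Dispatch on ``design.family``."""
    if design.family not in GENERATORS:
        raise ValueError(f"unknown family {design.family!r}; "
                         f"choose from {sorted(GENERATORS)}")
    return GENERATORS[design.family](design, **kwargs)


def evaluate(calls, truth) -> tuple[float, float]:
    """Recall and precision of boolean calls against boolean truth.

    Precision is NaN (undefined, not 0 or 1) when nothing is called; recall is
    NaN when nothing is truly differential.
    """
    calls = np.asarray(calls, bool)
    truth = np.asarray(truth, bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have the same shape")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return recall, precision


def run_benchmark(designs, methods, reps: int = 20, seed: int = 0,
                  test: str = "t", level: float = 0.05) -> pd.DataFrame:
    """Generate/normalize/test/evaluate over a grid and return a tidy table.

    ``methods`` are normalization method names (see `ebaynorm.normalize`), or
    the special names ``tree_guided`` / ``naive_tree`` for the phylogeny-aware
    procedures (DTM designs only). Per-rep failures are recorded, never abort
    the grid. Aggregation (mean and Monte-Carlo s.e. of recall/precision) is a
    one-line groupby on the returned per-rep table.
    """
    from . import datest as _datest

    rows = []
    ss = np.random.SeedSequence(seed)
    for design in designs:
        rep_seeds = ss.spawn(1)[0].generate_state(reps) % (2**31)
        for rep in range(reps):
            d = SimDesign(**{**design.__dict__, "seed": int(rep_seeds[rep])})
            data = generate(d)
            for method in methods:
                row = dict(family=d.family, beta=d.beta, theta=d.theta,
                           delta=d.delta, method=method, test=test, rep=rep)
                try:
                    if method == "tree_guided":
                        res = _datest.tree_guided_test(
                            data.counts, data.tree, data.labels, test=test,
                            level=level)
                        calls = res.calls
                    elif method == "naive_tree":
                        res = _datest.naive_tree_test(
                            data.counts, data.tree, data.labels, test=test,
                            level=level)
                        calls = res["call"].to_numpy()
                    else:
                        est = _datest.DifferentialAbundanceTest(
                            method=method, test=test, level=level,
                            tree=data.tree, seed=int(rep_seeds[rep]))
                        est.fit(data.counts, data.labels)
                        calls = est.calls_
                    recall, precision = evaluate(calls, data.truth)
                    row.update(recall=recall, precision=precision, error="")
                except Exception as exc:  # noqa: BLE001 - grid must survive
                    row.update(recall=float("nan"), precision=float("nan"),
                               error=f"{type(exc).__name__}: {exc}")
                rows.append(row)
    return pd.DataFrame(rows)
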