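"""Synthetic-data generators: distributional moments, ground-truth labels,
reproducibility, and the recall/precision evaluator."""

import numpy as np
import pytest

from ebaynorm import (BASE_POOL, SimDesign, evaluate, gen_dm, gen_dtm,
                      gen_gamma_poisson, gen_ziln, generate,
                      perturb_composition, run_benchmark, tss)
from ebaynorm.simulate import DM_DOWN, DM_UP


class TestPerturbComposition:
    def test_zero_effect_is_identity(self):
        phi = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(
            perturb_composition(phi, [0], [2], 0.0), phi)

    def test_six_taxa_shift_conserves_mass(self):
        rng = np.random.default_rng(1)
        phi = rng.dirichlet(np.full(40, 50.0))
        out = perturb_composition(phi, DM_UP, DM_DOWN, 0.25)
        changed = np.flatnonzero(out != phi)
        assert changed.size == 6
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out[DM_UP] - phi[DM_UP], 0.0125, atol=1e-12)
        np.testing.assert_allclose(phi[DM_DOWN] - out[DM_DOWN], 0.0125,
                                   atol=1e-12)

    def test_nonpositive_result_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            perturb_composition(np.array([0.01, 0.99]), [1], [0], 0.5)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            perturb_composition(np.array([0.5, 0.5]), [0], [0], 0.1)


class TestGenDm:
    def test_overdispersion_maps_to_concentration(self):
        # theta = 1 / (1 + alpha_plus) inverts to alpha_plus = (1-theta)/theta
        data = gen_dm(SimDesign(theta=0.15, seed=0))
        assert (1 - 0.15) / 0.15 == pytest.approx(17 / 3)

    def test_shapes_depths_and_truth(self):
        d = SimDesign(n1=50, n2=50, p=40, theta=0.15, beta=0.25, seed=5)
        data = gen_dm(d)
        assert data.counts.shape == (100, 40)
        depths = data.counts.sum(axis=1)
        assert depths.min() >= 5000 and depths.max() <= 50000
        assert data.truth.sum() == 6
        assert set(data.truth_indices) == set(np.r_[DM_UP, DM_DOWN])

    def test_empirical_proportions_match_group_compositions(self):
        d = SimDesign(n1=1000, n2=1000, theta=0.15, beta=0.25, seed=8)
        data = gen_dm(d)
        for grp in (1, 2):
            P = tss(data.counts[data.labels == grp])
            err = np.abs(P.mean(axis=0) - data.phi[grp])
            mcse = P.std(axis=0, ddof=1) / np.sqrt(P.shape[0])
            assert (err < 4 * mcse + 1e-3).all()

    def test_variance_exceeds_multinomial(self):
        # over-dispersed counts: per-taxon variance above multinomial variance
        d = SimDesign(n1=1000, n2=1000, theta=0.15, beta=0.0, seed=9)
        data = gen_dm(d)
        X = data.counts[data.labels == 1]
        N = X.sum(axis=1, keepdims=True)
        P = X / N
        phi = P.mean(axis=0)
        # compare variance of proportions to mean multinomial variance
        mult_var = (phi * (1 - phi) / N).mean(axis=0)
        heavy = phi > 0.01
        assert (P.var(axis=0, ddof=1)[heavy] > 2 * mult_var[heavy]).all()

    def test_seed_reproducibility(self):
        a = gen_dm(SimDesign(seed=12))
        b = gen_dm(SimDesign(seed=12))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_zero_effect_has_empty_truth(self):
        assert gen_dm(SimDesign(beta=0.0, seed=1)).truth.sum() == 0


class TestGenDtm:
    def test_truth_matches_planted_subtree(self):
        d = SimDesign(family="dtm_nondegenerate", p=30, theta=0.27, beta=4,
                      seed=20)
        data = gen_dtm(d)
        assert 0 < data.truth.sum() <= 15
        # truth equals exact group-composition difference
        diff = np.abs(data.phi[1] - data.phi[2]) > 1e-9 * (data.phi[1]
                                                           + data.phi[2])
        np.testing.assert_array_equal(data.truth, diff)

    def test_degenerate_truth_is_strict_subset_of_nondegenerate(self):
        seed = 24
        dn = gen_dtm(SimDesign(family="dtm_nondegenerate", p=30, theta=0.27,
                               beta=6, seed=seed))
        dd = gen_dtm(SimDesign(family="dtm_degenerate", p=30, theta=0.27,
                               beta=6, seed=seed), degenerate=True)
        assert 0 < dd.truth.sum() < dn.truth.sum() + dd.truth.sum()
        # the degenerate design has cancelling leaves: some leaves under the
        # planted clade carry exactly equal group compositions
        cancelled = ~dd.truth & dn.truth
        assert cancelled.sum() >= 1

    def test_null_design_groups_identical_in_law(self):
        d = SimDesign(family="dtm_nondegenerate", p=20, theta=0.27, beta=0.0,
                      seed=2)
        data = gen_dtm(d)
        assert data.truth.sum() == 0
        np.testing.assert_array_equal(data.phi[1], data.phi[2])

    def test_root_totals_match_depths_and_reproducible(self):
        d = SimDesign(family="dtm_nondegenerate", p=20, theta=0.27, beta=2,
                      seed=3)
        a, b = gen_dtm(d), gen_dtm(d)
        np.testing.assert_array_equal(a.counts, b.counts)
        depths = a.counts.sum(axis=1)
        assert depths.min() >= 5000 and depths.max() <= 50000

    def test_non_binary_tree_rejected(self):
        from ebaynorm import star_tree
        t = star_tree(["a", "b", "c"])
        with pytest.raises(ValueError, match="binary"):
            gen_dtm(SimDesign(family="dtm_nondegenerate", p=3, seed=0), tree=t)


class TestGenGammaPoisson:
    def test_mean_structure_and_truth(self):
        d = SimDesign(family="gamma_poisson", n1=20, n2=30, p=100, delta=3.0,
                      seed=4)
        data = gen_gamma_poisson(d)
        assert data.counts.shape == (50, 100)
        assert data.truth.sum() == 10 and data.truth[:10].all()
        # unperturbed features have Poisson(Gamma(200,1)) means around 200
        assert abs(data.counts[:, 20:].mean() - 200) < 2

    def test_delta_one_shift_bounded_by_thirty(self):
        d = SimDesign(family="gamma_poisson", n1=500, n2=2, p=100, delta=1.0,
                      seed=5)
        data = gen_gamma_poisson(d)
        case = data.counts[data.labels == 1]
        up = case[:, :5].mean() - case[:, 20:].mean()
        assert 0 < up < 31

    def test_case_group_shifts_in_planted_directions(self):
        d = SimDesign(family="gamma_poisson", n1=20, n2=30, p=100, delta=4.0,
                      seed=6)
        data = gen_gamma_poisson(d)
        case = data.counts[data.labels == 1]
        control = data.counts[data.labels == 2]
        assert case[:, :5].mean() > control[:, :5].mean()
        assert case[:, 5:10].mean() < control[:, 5:10].mean()


class TestGenZiln:
    def test_zero_fraction_tracks_structural_zero_probability(self):
        d = SimDesign(family="ziln", n1=400, n2=400, p=100, delta=0.0, seed=7)
        data = gen_ziln(d)
        pi0 = data.phi["pi0"]
        obs = (data.counts == 0).mean(axis=0)
        mcse = np.sqrt(pi0 * (1 - pi0) / data.counts.shape[0])
        # rounding of small log-normal draws adds a few extra zeros
        assert (obs >= pi0 - 4 * mcse).all()
        assert np.abs(obs.mean() - pi0.mean()) < 0.05

    def test_effect_vanishes_as_delta_goes_to_zero(self):
        lo = gen_ziln(SimDesign(family="ziln", delta=0.0, p=100, seed=8))
        hi = gen_ziln(SimDesign(family="ziln", delta=0.9, p=100, seed=8))
        gap = lambda d: (d.counts[d.labels == 1, :5].mean()
                         - d.counts[d.labels == 2, :5].mean())
        assert abs(gap(hi)) > abs(gap(lo))

    def test_seed_reproducibility_and_truth_size(self):
        d = SimDesign(family="ziln", delta=0.5, p=100, seed=9)
        a, b = gen_ziln(d), gen_ziln(d)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.truth.sum() == 10


class TestEvaluate:
    def test_perfect_calls(self):
        truth = np.array([True, False, True])
        assert evaluate(truth, truth) == (1.0, 1.0)

    def test_no_calls_gives_undefined_precision(self):
        truth = np.array([True, False])
        recall, precision = evaluate(np.zeros(2, bool), truth)
        assert recall == 0.0
        assert np.isnan(precision)

    def test_counts_arithmetic(self):
        truth = np.zeros(10, bool)
        truth[:6] = True
        calls = np.zeros(10, bool)
        calls[:4] = True     # TP=4, FN=2
        calls[9] = True      # FP=1
        recall, precision = evaluate(calls, truth)
        assert recall == pytest.approx(4 / 6)
        assert precision == pytest.approx(4 / 5)

    def test_taxa_permutation_invariance(self, rng):
        truth = rng.random(30) < 0.3
        calls = rng.random(30) < 0.4
        perm = rng.permutation(30)
        assert evaluate(calls, truth) == evaluate(calls[perm], truth[perm])


class TestRunBenchmark:
    def test_smoke_grid_emits_expected_rows(self):
        designs = [SimDesign(beta=0.2, theta=0.15), SimDesign(beta=0.3,
                                                              theta=0.15)]
        table = run_benchmark(designs, ["tss", "ebay"], reps=2, seed=1)
        assert len(table) == 2 * 2 * 2
        assert (table["error"] == "").all()
        assert {"recall", "precision", "method", "rep"} <= set(table.columns)

    def test_recall_increases_with_effect_size(self):
        designs = [SimDesign(beta=b, theta=0.15) for b in (0.01, 0.35)]
        table = run_benchmark(designs, ["ebay"], reps=5, seed=2)
        means = table.groupby("beta")["recall"].mean()
        assert means[0.35] > means[0.01]


def test_base_pool_is_frozen_and_valid():
    assert BASE_POOL.shape == (60,)
    assert BASE_POOL.sum() == pytest.approx(1.0, abs=1e-12)
    assert (BASE_POOL > 0).all()
    # regenerating gives the identical committed vector
    from ebaynorm.simulate import _make_base_pool
    np.testing.assert_array_equal(BASE_POOL, _make_base_pool())
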