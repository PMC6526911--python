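import numpy as np
import pytest

import pomopy as pp


@pytest.fixture(scope="module")
def four_taxon_data():
    """Simulation on a fixed 4-taxon tree with strong signal."""
    tree = pp.PhyloTree.from_newick("((A:0.3,B:0.3):0.4,(C:0.3,D:0.3):0.4);")
    cfg = pp.SimConfig(n_sites=4000, tree=tree, theta=0.005, K=1, seed=11)
    aln, _, truth = pp.simulate_alignment(cfg)
    return tree, aln, truth


@pytest.fixture(scope="module")
def start_model(four_taxon_data, space10):
    _, aln, _ = four_taxon_data
    pi = aln.empirical_frequencies()
    return pp.calibrate_heterozygosity(pp.MutationModel.hky(2.0, pi), space10, 0.004)


def test_all_frozen_returns_inputs(four_taxon_data, space10, start_model):
    tree, aln, _ = four_taxon_data
    opts = pp.FitOptions(
        free_branch_lengths=False, free_rates=False, free_theta=False,
        free_alpha=False,
    )
    with pytest.warns(UserWarning, match="no free parameters"):
        res = pp.fit(tree, aln, start_model, space=space10, options=opts)
    # frozen estimates equal the inputs bit-for-bit
    assert res.estimates["kappa"] == 2.0
    assert np.array_equal(res.estimates["branch_lengths"], tree.branch_lengths())
    assert res.n_free_parameters == 0
    assert np.isfinite(res.log_likelihood)


def test_partial_freezing(four_taxon_data, space10, start_model):
    tree, aln, _ = four_taxon_data
    opts = pp.FitOptions(free_rates=False, free_theta=False, max_sweeps=3)
    res = pp.fit(tree, aln, start_model, space=space10, options=opts)
    assert res.estimates["kappa"] == 2.0
    assert res.estimates["theta"] == pytest.approx(0.004)
    assert not np.array_equal(
        res.estimates["branch_lengths"], tree.branch_lengths()
    )


def test_multistart_consistency(four_taxon_data, space10):
    tree, aln, _ = four_taxon_data
    pi = aln.empirical_frequencies()
    opts = pp.FitOptions(tol_lnl=1e-5)
    lnls = []
    for kappa0, theta0 in [(2.0, 0.002), (10.0, 0.02)]:
        start = tree.copy()
        for n in start.postorder():
            if n.parent is not None:
                n.length = 0.15
        model = pp.calibrate_heterozygosity(
            pp.MutationModel.hky(kappa0, pi), space10, theta0
        )
        res = pp.fit(start, aln, model, space=space10, options=opts)
        lnls.append(res.log_likelihood)
    assert abs(lnls[0] - lnls[1]) < 1e-3


def test_kappa_recovery_small(four_taxon_data, space10, start_model):
    tree, aln, truth = four_taxon_data
    res = pp.fit(tree, aln, start_model, space=space10)
    # modest data: recovery within 20 percent sanity band
    assert res.estimates["kappa"] == pytest.approx(6.25, rel=0.2)
    assert res.estimates["theta"] == pytest.approx(0.005, rel=0.3)
    assert res.converged


class TestSearch:
    def test_three_taxa_trivial(self, space10):
        tree = pp.PhyloTree.from_newick("(A:0.2,(B:0.2,C:0.2):0.1);")
        cfg = pp.SimConfig(n_sites=500, tree=tree, theta=0.005, K=1, seed=3)
        aln, _, _ = pp.simulate_alignment(cfg)
        model = pp.calibrate_heterozygosity(
            pp.MutationModel.hky(6.25, aln.empirical_frequencies()), pp.StateSpace(10), 0.005
        )
        res = pp.search_topology(aln, model, space=space10, mode="exhaustive")
        assert set(res.tree.leaf_names()) == {"A", "B", "C"}
        assert res.tree.splits() == set()  # single unrooted topology

    def test_exhaustive_recovers_topology(self, four_taxon_data, space10, start_model):
        _, aln, _ = four_taxon_data
        res = pp.search_topology(aln, start_model, space=space10, mode="exhaustive")
        assert res.tree.splits() == {frozenset({"C", "D"})}

    def test_exhaustive_taxon_limit(self, space10, start_model):
        aln = pp.CountsAlignment(
            [f"p{k}" for k in range(9)], np.zeros((1, 9, 4), dtype=int)
        )
        with pytest.raises(ValueError, match="nni"):
            pp.search_topology(aln, start_model, space=space10, mode="exhaustive")

    def test_nni_from_truth_not_worse(self, four_taxon_data, space10, start_model):
        tree, aln, _ = four_taxon_data
        opts = pp.FitOptions(max_sweeps=2)
        fixed = pp.fit(tree, aln, start_model, space=space10, options=opts)
        searched = pp.search_topology(
            aln, start_model, space=space10, mode="nni",
            start_tree=tree, options=opts,
        )
        # hill climbing keeps the true topology and does not lose likelihood
        # (beyond coordinate-sweep granularity on the rerooted tree)
        assert searched.tree.splits() == tree.splits()
        assert searched.log_likelihood >= fixed.log_likelihood - 1e-3


class TestBootstrap:
    def test_supports_valid_and_reproducible(self, four_taxon_data, space10, start_model):
        tree, aln, _ = four_taxon_data
        opts = pp.FitOptions(max_sweeps=2)
        kwargs = dict(B=3, seed=7, space=space10, options=opts, search="none")
        t1 = pp.bootstrap(tree, aln, start_model, **kwargs)
        t2 = pp.bootstrap(tree, aln, start_model, **kwargs)
        assert t1.equals(t2)
        assert ((t1["support"] >= 0) & (t1["support"] <= 100)).all()

    def test_strong_signal_full_support(self, four_taxon_data, space10, start_model):
        tree, aln, _ = four_taxon_data
        opts = pp.FitOptions(max_sweeps=2)
        table = pp.bootstrap(
            tree, aln, start_model, B=5, seed=1, space=space10,
            options=opts, search="exhaustive",
        )
        assert (table["support"] >= 95).all()

    def test_invalid_b(self, four_taxon_data, start_model):
        tree, aln, _ = four_taxon_data
        with pytest.raises(ValueError):
            pp.bootstrap(tree, aln, start_model, B=0)


class TestRanking:
    def test_gtr_data_prefers_gtr(self, space10):
        tree = pp.PhyloTree.from_newick("((A:0.3,B:0.3):0.4,(C:0.3,D:0.3):0.4);")
        gtr = pp.calibrate_heterozygosity(
            pp.MutationModel.gtr([1, 8, 1, 1, 8, 1], [0.4, 0.1, 0.1, 0.4]),
            space10, 0.005,
        )
        cfg = pp.SimConfig(n_sites=6000, tree=tree, theta=0.005, model=gtr, K=1, seed=9)
        aln, _, _ = pp.simulate_alignment(cfg)
        pi = aln.empirical_frequencies()
        cands = [
            pp.Candidate("JC", pp.calibrate_heterozygosity(pp.MutationModel.jc(), space10, 0.005)),
            pp.Candidate("GTR", pp.calibrate_heterozygosity(pp.MutationModel.gtr(np.ones(6), pi), space10, 0.005)),
        ]
        opts = pp.FitOptions(max_sweeps=3)
        table = pp.rank_models(aln, tree, cands, "BIC", space10, options=opts)
        assert table.iloc[0]["name"] == "GTR"

    def test_scores_recomputable_and_stable(self, four_taxon_data, space10, start_model):
        tree, aln, _ = four_taxon_data
        opts = pp.FitOptions(max_sweeps=1)
        cands = [
            pp.Candidate("m1", start_model),
            pp.Candidate("m2", start_model),
        ]
        table = pp.rank_models(aln, tree, cands, "AIC", space10, options=opts)
        # identical candidates: identical scores, input order preserved
        assert list(table["name"]) == ["m1", "m2"]
        assert table["AIC"].iloc[0] == pytest.approx(table["AIC"].iloc[1])
        # formula audit
        for _, row in table.iterrows():
            assert row["AIC"] == pytest.approx(2 * row["k"] - 2 * row["lnL"])
            assert row["BIC"] == pytest.approx(
                row["k"] * np.log(aln.n_sites) - 2 * row["lnL"]
            )

    def test_needs_two_candidates(self, four_taxon_data, space10, start_model):
        tree, aln, _ = four_taxon_data
        with pytest.raises(ValueError):
            pp.rank_models(aln, tree, [pp.Candidate("only", start_model)])
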