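import numpy as np
import pytest
import scipy.stats

import pomopy as pp
from pomopy.likelihood import build_category_models
from pomopy.simulate import evolve_gillespie


def single_pop_tree(length=0.0):
    root = pp.Node()
    root.add_child(pp.Node("p1", length))
    return pp.PhyloTree(root)


class TestYule:
    def test_rate_examples(self):
        # n=12, h=0.01: lambda = (H_12 - 1)/h with H_12 ~ 3.10321
        assert pp.yule_rate(12, 0.01) == pytest.approx(210.321, abs=0.001)
        assert pp.yule_rate(2, 1.0) == pytest.approx(0.5)

    def test_rate_scales_inversely_with_height(self):
        assert pp.yule_rate(12, 0.005) == pytest.approx(2 * pp.yule_rate(12, 0.01))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            pp.yule_rate(1, 0.01)
        with pytest.raises(ValueError):
            pp.yule_rate(5, 0.0)

    def test_ultrametric_height(self):
        spec = pp.YuleSpec(12, 0.01)
        tree = pp.sample_yule_tree(spec, seed=5)
        for leaf in tree.leaves():
            depth = 0.0
            node = leaf
            while node.parent is not None:
                depth += node.length
                node = node.parent
            assert depth == pytest.approx(0.01, abs=1e-15)

    def test_determinism(self):
        spec = pp.YuleSpec(8, 0.5)
        assert (
            pp.sample_yule_tree(spec, seed=3).newick()
            == pp.sample_yule_tree(spec, seed=3).newick()
        )

    def test_leaf_count_distribution(self):
        # truncated pure birth from a root split: leaf count is the sum of two
        # geometric variables with mean exp(lambda * h) each
        spec = pp.YuleSpec(12, 0.01)
        rng = np.random.default_rng(0)
        counts = [len(pp.sample_yule_tree(spec, rng).leaves()) for _ in range(2000)]
        expected = 2 * np.exp(spec.rate * spec.height)
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)

    def test_condition_on_leaf_count(self):
        spec = pp.YuleSpec(12, 0.01)
        tree = pp.sample_yule_tree(spec, seed=9, condition_on_n=12)
        assert tree.n_leaves == 12


class TestSimulateAlignment:
    def test_stationary_state_frequencies(self, space10, hky_calibrated):
        # zero-length branch and exact (M=N hypergeometric) sampling: observed
        # counts reproduce the stationary state distribution
        cfg = pp.SimConfig(
            n_sites=200000, tree=single_pop_tree(0.0), theta=0.0025,
            sampling="hypergeometric", seed=21,
        )
        aln, _, _ = pp.simulate_alignment(cfg)
        stat = pp.stationary_closed_form(space10, hky_calibrated)
        # map observations back to states
        space = space10
        idx = np.zeros(aln.n_sites, dtype=int)
        for s in range(aln.n_sites):
            row = aln.counts[s, 0]
            nz = np.nonzero(row)[0]
            if len(nz) == 1:
                idx[s] = nz[0]
            else:
                a, b = space.alphabet.symbols[nz[0]], space.alphabet.symbols[nz[1]]
                idx[s] = space.polymorphic_index(a, b, int(row[nz[0]]))
        observed = np.bincount(idx, minlength=space.n_states)
        # chi-square against expected counts, pooling tiny-expectation states
        expected = stat * aln.n_sites
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        chi2 += (observed[~keep].sum() - expected[~keep].sum()) ** 2 / expected[~keep].sum()
        df = keep.sum()
        assert chi2 < scipy.stats.chi2.ppf(0.999, df=df)

    def test_heterozygosity_round_trip(self):
        # theta = 0.005: fraction of polymorphic leaf states within 3 MC SEs
        cfg = pp.SimConfig(
            n_sites=300000, tree=single_pop_tree(0.0), theta=0.005,
            sampling="hypergeometric", seed=33,
        )
        aln, _, _ = pp.simulate_alignment(cfg)
        frac = aln.polymorphic_fraction()
        se = np.sqrt(0.005 * 0.995 / cfg.n_sites)
        assert abs(frac - 0.005) < 3 * se

    def test_seed_determinism(self, tmp_path):
        from pomopy import io_formats as io

        tree = pp.PhyloTree.from_newick("((A:0.3,B:0.3):0.2,C:0.5);")
        files = []
        for run in range(2):
            cfg = pp.SimConfig(n_sites=500, tree=tree, theta=0.01, K=4, alpha=0.5, seed=17)
            aln, _, _ = pp.simulate_alignment(cfg)
            path = tmp_path / f"run{run}.cf"
            io.write_counts(aln, path)
            files.append(path.read_text())
        assert files[0] == files[1]

    def test_category_assignment_uniform(self):
        cfg = pp.SimConfig(
            n_sites=20000, tree=single_pop_tree(0.1), theta=0.01, K=4, alpha=0.5, seed=8
        )
        _, _, truth = pp.simulate_alignment(cfg)
        counts = np.asarray(truth["category_counts"])
        assert counts.sum() == 20000
        chi2 = ((counts - 5000.0) ** 2 / 5000.0).sum()
        assert chi2 < scipy.stats.chi2.ppf(0.999, df=3)

    def test_branch_length_monotonicity(self):
        # longer branches produce more observable differences between sisters
        tree_s = pp.PhyloTree.from_newick("(A:0.2,B:0.2);")
        tree_l = pp.PhyloTree.from_newick("(A:0.4,B:0.4);")
        diffs = {"short": [], "long": []}
        for seed in range(5):
            for name, tree in [("short", tree_s), ("long", tree_l)]:
                cfg = pp.SimConfig(n_sites=4000, tree=tree, theta=0.005, seed=seed)
                aln, _, _ = pp.simulate_alignment(cfg)
                a = aln.counts[:, 0].argmax(axis=1)
                b = aln.counts[:, 1].argmax(axis=1)
                diffs[name].append((a != b).mean())
        assert np.median(diffs["long"]) > np.median(diffs["short"])

    def test_truth_record_contents(self):
        cfg = pp.SimConfig(n_sites=10, yule=pp.YuleSpec(5, 0.2), theta=0.01, seed=2)
        aln, tree, truth = pp.simulate_alignment(cfg)
        assert truth["theta"] == 0.01
        assert truth["tree"] == tree.newick()
        assert truth["N"] == 10
        assert aln.n_sites == 10

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            pp.SimConfig(n_sites=0, yule=pp.YuleSpec(5, 0.2))
        with pytest.raises(ValueError):
            pp.SimConfig(n_sites=10)
        with pytest.raises(ValueError):
            pp.SimConfig(n_sites=10, yule=pp.YuleSpec(5, 0.2),
                         sampling="hypergeometric", samples_per_population=12)


def test_gillespie_matches_matrix_exponential(space4):
    """Event-by-event simulation agrees with exact endpoint sampling."""
    model = pp.MutationModel.jc(magnitude=0.2)
    QM = pp.build_mutation_matrix(space4, model)
    QD = pp.build_drift_matrix(space4)
    rs = pp.assemble_rate_matrix(QM, QD, normalize=False)
    t = 1.5
    start = space4.monomorphic_index("A")
    rng = np.random.default_rng(12)
    n_draws = 4000
    hits = np.zeros(space4.n_states)
    for _ in range(n_draws):
        hits[evolve_gillespie(start, t, rs.Q, rng)] += 1
    P = pp.transition_probabilities(rs, t)
    expected = P[start] * n_draws
    keep = expected > 5
    chi2 = ((hits[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    chi2 += max(0.0, hits[~keep].sum() - expected[~keep].sum()) ** 2 / max(
        expected[~keep].sum(), 1e-9
    )
    assert chi2 < scipy.stats.chi2.ppf(0.999, df=int(keep.sum()))
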