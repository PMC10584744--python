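import itertools

import dendropy
import numpy as np
import pytest

from chlorophylo import likelihood as lk, synthetic as sy, tree_compare as tc
from chlorophylo.trees import Tree
from conftest import random_unrooted_tree


def dendropy_rf(a: Tree, b: Tree) -> int:
    """Independent RF oracle via dendropy's bipartition machinery."""
    tns = dendropy.TaxonNamespace()
    da = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    db = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    da.encode_bipartitions()
    db.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(da, db)


class TestRFDistance:
    def test_identical_trees(self, rng):
        t = random_unrooted_tree("ABCDEF", rng)
        r = tc.rf_distance(t, t.copy())
        assert (r.rf, r.nrf_pct) == (0, 0.0)

    def test_five_taxon_worked_example(self):
        a = Tree.from_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        b = Tree.from_newick("((A:1,C:1):1,B:1,(D:1,E:1):1);")
        r = tc.rf_distance(a, b)
        assert r.rf == 2
        assert r.nrf_pct == pytest.approx(50.0)

    def test_matches_dendropy_on_random_trees(self):
        rngs = [np.random.default_rng(s) for s in range(12)]
        trees = [random_unrooted_tree("ABCDEFGH", r) for r in rngs]
        for a, b in itertools.combinations(trees, 2):
            assert tc.rf_distance(a, b).rf == dendropy_rf(a, b)

    def test_metric_axioms(self):
        trees = [random_unrooted_tree("ABCDEF", np.random.default_rng(s))
                 for s in range(8)]
        d = [[tc.rf_distance(a, b).rf if i != j else 0
              for j, b in enumerate(trees)] for i, a in enumerate(trees)]
        for i, j, k in itertools.permutations(range(len(trees)), 3):
            assert d[i][j] == d[j][i]
            assert d[i][k] <= d[i][j] + d[j][k]

    def test_maximally_different_binary_trees_reach_100(self):
        a = Tree.from_newick("((((A:1,B:1):1,C:1):1,D:1):1,(E:1,F:1):1);")
        b = Tree.from_newick("((((A:1,C:1):1,E:1):1,B:1):1,(D:1,F:1):1);")
        assert tc.rf_distance(a, b).nrf_pct == pytest.approx(100.0)

    def test_leaf_set_mismatch_errors(self, rng):
        a = random_unrooted_tree("ABCDE", rng)
        b = random_unrooted_tree("ABCDF", rng)
        with pytest.raises(ValueError):
            tc.rf_distance(a, b)


class TestCollapseSameSpecies:
    species_map = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B",
                   "c1": "C"}

    def test_conspecific_cherry_collapses(self):
        t = Tree.from_newick("(((a1:0.1,a2:0.1):0.2,c1:0.3):0.1,"
                             "(b1:0.1,(b2:0.1,b3:0.1):0.05):0.2);")
        out, nonmono = tc.collapse_same_species(t, self.species_map)
        assert nonmono == []
        assert out.leaf_labels() == {"A", "B", "C"}
        a_leaf = next(n for n in out.leaves() if n.label == "A")
        assert a_leaf.length == pytest.approx(0.2)    # stem length retained

    def test_scattered_species_reported_untouched(self):
        t = Tree.from_newick("(((a1:0.1,b1:0.1):0.2,c1:0.3):0.1,"
                             "(a2:0.1,(b2:0.1,b3:0.1):0.05):0.2);")
        out, nonmono = tc.collapse_same_species(t, self.species_map)
        assert nonmono == ["A", "B"]
        assert {"a1", "a2", "b1"} <= out.leaf_labels()

    def test_all_singletons_identity(self, rng):
        t = random_unrooted_tree("ABCDE", rng)
        out, nonmono = tc.collapse_same_species(t, {c: c for c in "ABCDE"})
        assert nonmono == []
        assert tc.rf_distance(t, out).rf == 0

    def test_induced_topology_unchanged(self):
        t = Tree.from_newick("(((a1:1,a2:1):1,c1:1):1,"
                             "((b1:1,b2:1):1,(d1:1,e1:1):1):1);")
        sp = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C",
              "d1": "D", "e1": "E"}
        out, _ = tc.collapse_same_species(t, sp)
        # induced splits on the collapsed label set are preserved
        assert out.leaf_labels() == {"A", "B", "C", "D", "E"}
        assert frozenset({"D", "E"}) in out.bipartitions()

    def test_missing_map_entries_error(self, rng):
        t = random_unrooted_tree("ABCDE", rng)
        with pytest.raises(ValueError):
            tc.collapse_same_species(t, {"A": "x"})


@pytest.fixture(scope="module")
def candidates():
    true = sy.simulate_species_tree(6, seed=5, height=0.4)
    n1, _ = sy.perturb_topology(true, 1, seed=1)
    n2, _ = sy.perturb_topology(true, 1, seed=3)
    return true, n1, n2


class TestSHTest:
    def site_lnls(self, trees, aln, model, optimize=False):
        packed = lk.pack_alignment(aln)
        out = {}
        for name, t in trees.items():
            t = t.copy().unroot()
            if optimize:
                lk.optimize_branch_lengths(t, packed, model)
            out[name] = lk.site_log_likelihoods(t, packed, model)
        return out

    def test_ml_candidate_gets_p_one(self, candidates, jc_model):
        true, n1, n2 = candidates
        aln = sy.simulate_alignment(true, jc_model, 2000, seed=11)
        slls = self.site_lnls({"true": true, "n1": n1, "n2": n2}, aln, jc_model)
        res = tc.sh_test(slls, n_rell=1000, seed=2)
        best = res.tree_labels[int(np.argmax(res.lnL))]
        p = dict(zip(res.tree_labels, res.p_values))
        d = dict(zip(res.tree_labels, res.delta))
        assert d[best] == 0.0
        assert p[best] == 1.0

    def test_wrong_topologies_rejected_with_strong_signal(self, candidates, jc_model):
        true, n1, n2 = candidates
        aln = sy.simulate_alignment(true, jc_model, 10_000, seed=13)
        slls = self.site_lnls({"true": true, "n1": n1, "n2": n2}, aln,
                              jc_model, optimize=True)
        res = tc.sh_test(slls, n_rell=1000, seed=3)
        p = dict(zip(res.tree_labels, res.p_values))
        assert p["true"] > 0.01
        assert p["n1"] < 0.01 and p["n2"] < 0.01

    def test_p_monotone_in_delta(self, candidates, jc_model):
        true, n1, n2 = candidates
        aln = sy.simulate_alignment(true, jc_model, 3000, seed=17)
        slls = self.site_lnls({"true": true, "n1": n1, "n2": n2}, aln, jc_model)
        res = tc.sh_test(slls, n_rell=2000, seed=5)
        order = np.argsort(res.delta)
        assert np.all(np.diff(res.p_values[order]) <= 1e-12)

    def test_deterministic_given_seed(self, candidates, jc_model):
        true, n1, _ = candidates
        aln = sy.simulate_alignment(true, jc_model, 500, seed=19)
        slls = self.site_lnls({"true": true, "n1": n1}, aln, jc_model)
        r1 = tc.sh_test(slls, n_rell=500, seed=7)
        r2 = tc.sh_test(slls, n_rell=500, seed=7)
        assert np.array_equal(r1.p_values, r2.p_values)

    def test_mismatched_sites_error(self, candidates, jc_model):
        true, n1, _ = candidates
        a1 = sy.simulate_alignment(true, jc_model, 100, seed=23)
        a2 = sy.simulate_alignment(true, jc_model, 101, seed=23)
        s1 = self.site_lnls({"true": true}, a1, jc_model)["true"]
        s2 = self.site_lnls({"n1": n1}, a2, jc_model)["n1"]
        with pytest.raises(ValueError):
            tc.sh_test({"a": s1, "b": s2})


class TestCongruenceMatrix:
    def test_diagonal_zero_and_symmetric(self, jc_model, rng):
        trees = {f"t{i}": random_unrooted_tree("ABCDEF", rng) for i in range(3)}
        nrf, sh, flags = tc.congruence_matrix(trees, {})
        assert np.allclose(np.diag(nrf.values), 0.0)
        assert np.allclose(nrf.values, nrf.values.T)
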