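import itertools

import numpy as np
import pytest

from chlorophylo import likelihood as lk, synthetic as sy, tree_compare as tc, \
    tree_inference as ti
from chlorophylo.trees import Tree
from conftest import random_unrooted_tree


class TestNJ:
    def test_three_taxa_three_point_formula(self):
        labels = ["A", "B", "C"]
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = ti.nj_tree(labels, D)
        lengths = {n.label: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_matrix_roundtrip(self):
        source = Tree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.05);")
        labels = ["A", "B", "C", "D"]
        patristic = {
            ("A", "B"): 0.3, ("A", "C"): 0.5, ("A", "D"): 0.6,
            ("B", "C"): 0.6, ("B", "D"): 0.7, ("C", "D"): 0.7}
        D = np.zeros((4, 4))
        for (a, b), d in patristic.items():
            i, j = labels.index(a), labels.index(b)
            D[i, j] = D[j, i] = d
        tree = ti.nj_tree(labels, D)
        assert tc.rf_distance(source, tree).rf == 0

    def test_identical_rows_join_first(self):
        labels = ["A", "B", "C", "D"]
        D = np.array([[0.0, 0.1, 0.5, 0.5],
                      [0.1, 0.0, 0.5, 0.5],
                      [0.5, 0.5, 0.0, 0.4],
                      [0.5, 0.5, 0.4, 0.0]])
        tree = ti.nj_tree(labels, D)
        assert frozenset({"A", "B"}) in tree.bipartitions() or \
            frozenset({"C", "D"}) in tree.bipartitions()

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            ti.nj_tree(["A", "B"], np.zeros((2, 2)))


class TestMLSearch:
    def test_four_taxon_matches_exhaustive(self, jc_model):
        # brute force: evaluate all three unrooted 4-taxon topologies
        topologies = ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
        true = Tree.from_newick("((A:0.1,B:0.1):0.15,(C:0.1,D:0.1):0.15);")
        aln = sy.simulate_alignment(true, jc_model, 2000, seed=5)
        packed = lk.pack_alignment(aln)
        scores = []
        for nwk in topologies:
            t = Tree.from_newick(nwk)
            for n in t.postorder():
                if n.parent is not None:
                    n.length = 0.1
            scores.append(lk.optimize_branch_lengths(t.unroot(), packed,
                                                     jc_model, rounds=3))
        brute_best = topologies[int(np.argmax(scores))]
        labels, D = ti.k2p_distance_matrix(aln)
        found, lnl = ti.ml_search(ti.nj_tree(labels, D), packed, jc_model)
        assert tc.rf_distance(found, Tree.from_newick(brute_best)).rf == 0
        assert lnl == pytest.approx(max(scores), abs=0.05)

    def test_topology_recovery_rate(self, jc_model):
        hits = 0
        for rep in range(6):
            true = sy.simulate_species_tree(6, seed=100 + rep, height=0.3)
            aln = sy.simulate_alignment(true, jc_model, 5000, seed=200 + rep)
            packed = lk.pack_alignment(aln)
            labels, D = ti.k2p_distance_matrix(aln)
            found, _ = ti.ml_search(ti.nj_tree(labels, D), packed, jc_model)
            hits += tc.rf_distance(found, true).rf == 0
        assert hits >= 5

    def test_lnl_not_below_start(self, jc_model):
        true = sy.simulate_species_tree(6, seed=7, height=0.3)
        aln = sy.simulate_alignment(true, jc_model, 1000, seed=8)
        packed = lk.pack_alignment(aln)
        start = true.copy().unroot()
        start_lnl = lk.log_likelihood(start, packed, jc_model)
        found, lnl = ti.ml_search(start, packed, jc_model)
        assert lnl >= start_lnl - 1e-9
        assert tc.rf_distance(found, true).rf == 0


class TestBootstrap:
    def test_deterministic_given_seed(self, six_taxon_sim):
        _, aln = six_taxon_sim
        r1 = ti.bootstrap_replicates(aln, n=2, seed=3)
        r2 = ti.bootstrap_replicates(aln, n=2, seed=3)
        assert [a.rows for a in r1] == [a.rows for a in r2]
        r3 = ti.bootstrap_replicates(aln, n=2, seed=4)
        assert [a.rows for a in r1] != [a.rows for a in r3]

    def test_replicate_lengths_preserved_per_partition(self, jc_model):
        from chlorophylo.alignment_ops import Alignment, concatenate
        a1 = Alignment(rows={"a": "ACGTAC", "b": "ACGTAC"}, marker="m1")
        a2 = Alignment(rows={"a": "GG", "b": "GG"}, marker="m2")
        sm = concatenate({"m1": a1, "m2": a2}, ["a", "b"], ("m1", "m2"),
                         models={"m1": jc_model, "m2": jc_model})
        for rep in ti.bootstrap_replicates(sm, n=5, seed=1):
            assert rep.alignment.n_columns == 8
            # within-partition resampling: m2 columns only contain m2 states
            assert set(rep.alignment.rows["a"][6:]) <= {"G"}

    def test_column_sampling_uniform(self):
        # encode the column index in base 4 across 3 rows: every column unique
        from chlorophylo.alignment_ops import Alignment
        n, n_reps = 64, 500
        digits = [(i // 16, (i // 4) % 4, i % 4) for i in range(n)]
        rows = {f"r{k}": "".join("ACGT"[d[k]] for d in digits) for k in range(3)}
        counts = np.zeros(n)
        for rep in ti.bootstrap_replicates(Alignment(rows=rows), n=n_reps, seed=9):
            for j in range(n):
                col = tuple("ACGT".index(rep.rows[f"r{k}"][j]) for k in range(3))
                counts[col[0] * 16 + col[1] * 4 + col[2]] += 1
        freq = counts / n_reps          # expected draws per column per replicate: 1
        sigma = 1.0 / np.sqrt(n_reps)   # multinomial per-column count has var ~ 1
        assert np.all(np.abs(freq - 1.0) < 4 * sigma + 0.05)


class TestSupports:
    def brute_transfer_index(self, split, tree):
        """Minimum leaf moves via exhaustive subset search (oracle)."""
        leaves = sorted(tree.leaf_labels())
        splits = set(tree.bipartitions(nontrivial_only=False))
        all_set = frozenset(leaves)

        def present(s):
            return s in splits or (all_set - s) in splits
        p = min(len(split), len(leaves) - len(split))
        for k in range(p):
            for moved in itertools.combinations(leaves, k):
                candidate = frozenset(split) ^ frozenset(moved)
                if present(candidate):
                    return k
        return p - 1   # moving p-1 leaves always trivializes the split

    def test_identical_replicates_full_support(self, rng):
        ref = random_unrooted_tree("ABCDEFG", rng)
        boots = [ref.copy() for _ in range(10)]
        fbp = ti.fbp_support(ref, boots)
        tbe = ti.tbe_support(ref, boots)
        assert all(v == 100.0 for v in fbp.values())
        assert all(v == 100.0 for v in tbe.values())

    def test_fbp_counts_fraction(self, rng):
        ref = random_unrooted_tree("ABCDEF", rng)
        other = random_unrooted_tree("ABCDEF", np.random.default_rng(99))
        boots = [ref.copy()] * 7 + [other.copy()] * 3
        fbp = ti.fbp_support(ref, boots)
        other_splits = set(other.bipartitions())
        for split, pct in fbp.items():
            expected = 70.0 if split not in other_splits else 100.0
            assert pct == pytest.approx(expected)

    def test_tbe_ge_fbp_and_cherry_equality(self, rng):
        for rep in range(20):
            local = np.random.default_rng(rep)
            ref = random_unrooted_tree("ABCDEFGH", local)
            boots = [random_unrooted_tree("ABCDEFGH", local) for _ in range(8)]
            fbp = ti.fbp_support(ref, boots)
            tbe = ti.tbe_support(ref, boots)
            n = 8
            for split in fbp:
                assert tbe[split] >= fbp[split] - 1e-9
                if min(len(split), n - len(split)) == 2:
                    assert tbe[split] == pytest.approx(fbp[split])

    def test_transfer_index_matches_bruteforce(self, rng):
        leaves = "ABCDEFGH"
        index = {c: i for i, c in enumerate(leaves)}
        for rep in range(15):
            local = np.random.default_rng(1000 + rep)
            ref = random_unrooted_tree(leaves, local)
            boot = random_unrooted_tree(leaves, local)
            M = ti._split_matrix(boot, index)
            for split in ref.bipartitions():
                v = np.zeros(len(leaves), dtype=bool)
                for leaf in split:
                    v[index[leaf]] = True
                assert ti.transfer_index(v, M) == \
                    self.brute_transfer_index(split, boot)

    def test_worked_transfer_example(self):
        # branch {A,B,C}|{D,E,F}; replicate where only C crossed sides
        ref = Tree.from_newick("(((A:1,B:1):1,C:1):1,((D:1,E:1):1,F:1):1);")
        rep = Tree.from_newick("((A:1,B:1):1,((D:1,(E:1,C:1):1):1,F:1):1);")
        tbe = ti.tbe_support(ref, [rep])
        split = frozenset({"D", "E", "F"}) if frozenset({"D", "E", "F"}) in tbe \
            else frozenset({"A", "B", "C"})
        assert tbe[split] == pytest.approx(50.0)   # 1 - 1/(3-1)

    def test_leafset_mismatch_errors(self, rng):
        ref = random_unrooted_tree("ABCDE", rng)
        boot = random_unrooted_tree("ABCDF", rng)
        with pytest.raises(ValueError):
            ti.fbp_support(ref, [boot])


class TestOutgroupRooting:
    def test_single_leaf_outgroup_midpoint(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,O:2):1);").unroot()
        rooted = ti.root_with_outgroup(t, {"O"})
        og = next(n for n in rooted.root.children if n.label == "O")
        assert og.length == pytest.approx(1.0)

    def test_two_leaf_outgroup_on_stem(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,(O1:1,O2:1):2):1);").unroot()
        rooted = ti.root_with_outgroup(t, {"O1", "O2"})
        sides = [frozenset(l.label for l in Tree(c).leaves()) if c.children
                 else frozenset({c.label}) for c in rooted.root.children]
        assert frozenset({"O1", "O2"}) in sides

    def test_nonmonophyletic_outgroup_errors(self):
        t = Tree.from_newick("((A:1,O1:1):1,(C:1,(B:1,O2:1):2):1);").unroot()
        with pytest.raises(ValueError, match="monophyletic"):
            ti.root_with_outgroup(t, {"O1", "O2"})
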