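import math

import numpy as np
import pytest

from chlorophylo import likelihood as lk, models, synthetic as sy
from chlorophylo.alignment_ops import Alignment, concatenate
from chlorophylo.models import SubstitutionModel, aicc, discrete_gamma_rates, \
    rate_matrix, transition_probabilities
from chlorophylo.trees import Tree


def random_gtr(rng):
    pi = rng.dirichlet([5, 5, 5, 5])
    return SubstitutionModel(family="GTR",
                             exchangeabilities=rng.uniform(0.3, 4.0, 6),
                             base_frequencies=pi)


class TestRateMatrix:
    def test_jc_off_diagonals(self):
        Q = rate_matrix(SubstitutionModel(family="JC"))
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)

    def test_stationarity(self, rng):
        m = random_gtr(rng)
        assert np.allclose(m.base_frequencies @ rate_matrix(m), 0.0, atol=1e-12)

    def test_rows_sum_to_zero_and_mean_rate_one(self, rng):
        m = random_gtr(rng)
        Q = rate_matrix(m)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -float(m.base_frequencies @ np.diag(Q)) == pytest.approx(1.0)

    def test_transition_matrices_stochastic_for_any_t(self, rng):
        m = random_gtr(rng)
        for t in (0.0, 0.01, 0.5, 3.0, 20.0):
            P = transition_probabilities(m, t)
            assert np.all(P >= 0)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_spectral_matches_expm(self, rng):
        from scipy.linalg import expm
        m = random_gtr(rng)
        Q = rate_matrix(m)
        for t in (0.05, 0.7):
            assert np.allclose(transition_probabilities(m, t), expm(Q * t),
                               atol=1e-10)

    def test_all_zero_exchangeabilities_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel(family="GTR", exchangeabilities=np.zeros(6))


class TestGammaRates:
    def test_mean_one(self):
        for alpha in (0.1, 0.5, 1.0, 5.0):
            assert discrete_gamma_rates(alpha).mean() == pytest.approx(1.0)

    def test_canonical_alpha_half_values(self):
        # standard equal-probability bin means for alpha = 0.5, 4 categories
        assert np.allclose(discrete_gamma_rates(0.5, 4),
                           [0.0334, 0.2519, 0.8203, 2.8944], atol=2e-4)

    def test_large_alpha_approaches_uniform(self):
        assert np.allclose(discrete_gamma_rates(500.0, 4), 1.0, atol=0.1)


class TestSiteLikelihoods:
    def test_two_taxon_jc_t0(self, jc_model):
        tree = Tree.from_newick("(A:0,B:0);")
        packed = lk.pack_alignment(Alignment(rows={"A": "A", "B": "A"}))
        assert lk.log_likelihood(tree, packed, jc_model) == \
            pytest.approx(math.log(0.25), abs=1e-9)

    def test_two_taxon_jc_closed_form(self, jc_model):
        # JC match probability at distance t: 1/4 + 3/4 e^{-4t/3}
        tree = Tree.from_newick("(A:0.05,B:0.05);")
        packed = lk.pack_alignment(Alignment(rows={"A": "A", "B": "A"}))
        expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * 0.1 / 3)))
        assert lk.log_likelihood(tree, packed, jc_model) == \
            pytest.approx(expected, abs=1e-9)

    def test_rerooting_invariance(self, rng):
        m = random_gtr(rng)
        tree = sy.simulate_species_tree(7, seed=3, height=0.4)
        aln = sy.simulate_alignment(tree, m, 300, seed=4)
        packed = lk.pack_alignment(aln)
        ref = lk.log_likelihood(tree, packed, m)
        internal = [n for n in tree.postorder()
                    if not n.is_leaf and n.parent is not None]
        for node in internal:
            rerooted = tree.reroot_on_edge(node, fraction=0.3)
            assert lk.log_likelihood(rerooted, packed, m) == \
                pytest.approx(ref, abs=1e-8)

    def test_pattern_compression_preserves_lnl(self, jc_model):
        tree = sy.simulate_species_tree(5, seed=9, height=0.3)
        aln = sy.simulate_alignment(tree, jc_model, 400, seed=10)
        packed = lk.pack_alignment(aln)
        # uncompressed reference: score each column as its own alignment
        total = 0.0
        for j in range(aln.n_columns):
            col = Alignment(rows={k: v[j] for k, v in aln.rows.items()})
            total += lk.log_likelihood(tree, lk.pack_alignment(col), jc_model)
        assert packed.n_patterns < aln.n_columns
        assert lk.log_likelihood(tree, packed, jc_model) == \
            pytest.approx(total, abs=1e-9)

    def test_ambiguity_codes_and_gaps(self, jc_model):
        tree = Tree.from_newick("(A:0.1,B:0.1);")
        # N/gap behaves as missing: lnL equals the single-taxon marginal
        packed = lk.pack_alignment(Alignment(rows={"A": "A", "B": "N"}))
        assert lk.log_likelihood(tree, packed, jc_model) == \
            pytest.approx(math.log(0.25), abs=1e-9)
        # R = {A, G}: sum of two state likelihoods
        packed_r = lk.pack_alignment(Alignment(rows={"A": "A", "B": "R"}))
        p_match = 0.25 + 0.75 * math.exp(-4 * 0.2 / 3)
        p_mismatch = (1 - p_match) / 3
        assert lk.log_likelihood(tree, packed_r, jc_model) == \
            pytest.approx(math.log(0.25 * (p_match + p_mismatch)), abs=1e-9)

    def test_leaf_mismatch_errors(self, jc_model):
        tree = Tree.from_newick("(A:0.1,C:0.1);")
        packed = lk.pack_alignment(Alignment(rows={"A": "A", "B": "A"}))
        with pytest.raises(ValueError, match="mismatch"):
            lk.log_likelihood(tree, packed, jc_model)


class TestPartitionedLikelihood:
    def make_supermatrix(self, jc_model, identical=False):
        tree = sy.simulate_species_tree(5, seed=21, height=0.3)
        a1 = sy.simulate_alignment(tree, jc_model, 120, seed=22)
        a2 = a1 if identical else sy.simulate_alignment(tree, jc_model, 80, seed=23)
        taxa = sorted(a1.rows)
        alns = {"m1": Alignment(rows=dict(a1.rows), marker="m1"),
                "m2": Alignment(rows=dict(a2.rows), marker="m2")}
        models_ = {"m1": jc_model, "m2": jc_model}
        return tree, alns, taxa, models_

    def test_single_partition_equals_plain(self, jc_model):
        tree, alns, taxa, models_ = self.make_supermatrix(jc_model)
        sm = concatenate({"m1": alns["m1"]}, taxa, ("m1",), models=models_)
        plain = lk.log_likelihood(tree, lk.pack_alignment(alns["m1"]), jc_model)
        assert lk.partitioned_log_likelihood(tree, sm).total == \
            pytest.approx(plain, abs=1e-9)

    def test_duplicate_partition_doubles_lnl(self, jc_model):
        tree, alns, taxa, models_ = self.make_supermatrix(jc_model, identical=True)
        sm = concatenate(alns, taxa, ("m1", "m2"), models=models_)
        single = lk.log_likelihood(tree, lk.pack_alignment(alns["m1"]), jc_model)
        assert lk.partitioned_log_likelihood(tree, sm).total == \
            pytest.approx(2 * single, abs=1e-8)

    def test_arrangement_invariance(self, jc_model):
        tree, alns, taxa, models_ = self.make_supermatrix(jc_model)
        totals = []
        for arrangement in (("m1", "m2"), ("m2", "m1")):
            sm = concatenate(alns, taxa, arrangement, models=models_)
            totals.append(lk.partitioned_log_likelihood(tree, sm).total)
        assert totals[0] == pytest.approx(totals[1], abs=1e-9)

    def test_partition_without_model_errors(self, jc_model):
        tree, alns, taxa, _ = self.make_supermatrix(jc_model)
        sm = concatenate(alns, taxa, ("m1", "m2"))
        with pytest.raises(ValueError, match="without"):
            lk.partitioned_log_likelihood(tree, sm)


class TestOptimize:
    def test_branch_length_recovery(self, jc_model):
        true = sy.simulate_species_tree(6, seed=31, height=0.4)
        aln = sy.simulate_alignment(true, jc_model, 10_000, seed=32)
        packed = lk.pack_alignment(aln)
        true = true.unroot()   # on the unrooted tree every edge is identifiable
        start = true.copy()
        for node in start.postorder():
            if node.parent is not None:
                node.length = 0.1
        lk.optimize_branch_lengths(start, packed, jc_model, rounds=3)
        est = {frozenset(s): n.length for s, n in start.bipartitions(False).items()}
        tru = {frozenset(s): n.length for s, n in true.bipartitions(False).items()}
        for split, t in tru.items():
            if t > 0.02:   # short branches carry little information
                assert est[split] == pytest.approx(t, rel=0.15)

    def test_lnl_never_decreases(self, jc_model):
        true = sy.simulate_species_tree(5, seed=41, height=0.3)
        aln = sy.simulate_alignment(true, jc_model, 500, seed=42)
        packed = lk.pack_alignment(aln)
        l0 = lk.log_likelihood(true, packed, jc_model)
        tree = true.copy()
        l1 = lk.optimize_branch_lengths(tree, packed, jc_model)
        l2 = lk.optimize_branch_lengths(tree, packed, jc_model)
        assert l0 <= l1 + 1e-9 <= l2 + 2e-9

    def test_gamma_shape_recovery(self):
        m = SubstitutionModel(family="JC", gamma_shape=0.5)
        true = sy.simulate_species_tree(5, seed=51, height=0.5)
        aln = sy.simulate_alignment(true, m, 20_000, seed=52)
        packed = lk.pack_alignment(aln)
        fit, _ = lk.optimize(true, packed,
                             SubstitutionModel(family="JC", gamma_shape=1.0),
                             tol=1e-4, max_rounds=6)
        assert 0.4 <= fit.model.gamma_shape <= 0.6

    def test_stationary_at_truth(self, jc_model):
        true = sy.simulate_species_tree(5, seed=61, height=0.4)
        aln = sy.simulate_alignment(true, jc_model, 5_000, seed=62)
        packed = lk.pack_alignment(aln)
        before = lk.log_likelihood(true, packed, jc_model)
        fit, _ = lk.optimize(true, packed, jc_model, tol=1e-6, max_rounds=3)
        # optimizing from near-truth barely moves the per-site lnL
        assert (fit.lnL - before) / aln.n_columns < 1e-3


class TestModelSelection:
    def test_aicc_arithmetic(self):
        assert aicc(-100.0, 1, 100) == pytest.approx(202.0408, abs=1e-4)

    def test_aicc_approaches_aic(self):
        k = 5
        assert aicc(-100.0, k, 10_000_000) == pytest.approx(200 + 2 * k, abs=1e-4)

    def test_aicc_singularity(self):
        with pytest.raises(ValueError):
            aicc(-100.0, 10, 11)

    def test_generating_family_recovered(self):
        true = sy.simulate_species_tree(5, seed=71, height=0.5)
        aln = sy.simulate_alignment(
            true, SubstitutionModel(family="JC"), 50_000, seed=72)
        best, table = lk.select_model(aln, true.copy().unroot())
        assert best.model.family in ("JC", "K80")
        assert table == sorted(table, key=lambda f: (f.aicc, f.k))
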