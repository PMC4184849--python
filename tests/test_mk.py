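import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from oracles import enum_site_likelihood
from mkphylo.mk import (
    MkParams,
    binary_transition_probability,
    discrete_gamma_rates,
    excluded_pattern_probability,
    matrix_log_likelihood,
    pattern_log_likelihoods,
    site_likelihood,
)
from mkphylo.simulate import MISSING, CharacterMatrix, generate_model_tree
from mkphylo.trees import parse_newick


class TestTransitionProbability:
    def test_zero_length_identity(self):
        assert binary_transition_probability(0, 0, 0.0) == 1.0
        assert binary_transition_probability(0, 1, 0.0) == 0.0

    def test_stationary_limit(self):
        assert binary_transition_probability(0, 1, 1e6) == pytest.approx(0.5)

    def test_matches_matrix_exponential(self):
        q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        for t in (0.1, 0.5, 2.3):
            p = expm(q * t)
            for i in (0, 1):
                for j in (0, 1):
                    assert binary_transition_probability(i, j, t) == pytest.approx(p[i, j])
        assert binary_transition_probability(0, 1, 0.5) == pytest.approx(0.316060, abs=1e-6)

    def test_rows_sum_to_one_and_chapman_kolmogorov(self, rng):
        for _ in range(20):
            t1, t2 = rng.exponential(1.0, size=2)
            p1 = np.array([[binary_transition_probability(i, j, t1) for j in (0, 1)]
                           for i in (0, 1)])
            p2 = np.array([[binary_transition_probability(i, j, t2) for j in (0, 1)]
                           for i in (0, 1)])
            p12 = np.array([[binary_transition_probability(i, j, t1 + t2) for j in (0, 1)]
                            for i in (0, 1)])
            assert np.allclose(p1.sum(axis=1), 1.0)
            assert np.allclose(p1 @ p2, p12)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            binary_transition_probability(0, 0, -0.1)


class TestDiscreteGamma:
    @pytest.mark.parametrize("shape", [0.2, 0.5, 1.0, 5.0])
    def test_category_rates_mean_one_and_increasing(self, shape):
        rates = discrete_gamma_rates(shape, 4)
        assert rates.mean() == pytest.approx(1.0)
        assert (np.diff(rates) > 0).all()

    def test_single_category_is_homogeneous(self):
        assert discrete_gamma_rates(0.7, 1) == pytest.approx([1.0])


class TestSiteLikelihood:
    def test_zero_length_constant_column_is_half(self):
        tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        assert site_likelihood(tree, np.zeros(4, np.int8), MkParams()) == pytest.approx(0.5)

    def test_two_taxon_mismatch_closed_form(self):
        tree = parse_newick("(A:0.2,B:0.3);")
        t = 0.5
        got = site_likelihood(tree, np.array([0, 1], np.int8), MkParams())
        assert got == pytest.approx(0.5 * (0.5 - 0.5 * np.exp(-2 * t)))

    def test_all_missing_is_exactly_one(self, tree20):
        column = np.full(20, MISSING, dtype=np.int8)
        assert site_likelihood(tree20, column, MkParams(gamma_shape=0.5)) == 1.0

    def test_invalid_state_rejected(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            site_likelihood(tree, np.array([0, 1, 2, 0], np.int8), MkParams())

    @pytest.mark.parametrize("gamma_shape", [None, 0.6])
    def test_pruning_equals_enumeration(self, rng, gamma_shape):
        params = MkParams(gamma_shape=gamma_shape)
        for trial in range(8):
            n = int(rng.integers(4, 6))
            tree = generate_model_tree(n, seed=int(rng.integers(10_000)),
                                       total_length=float(rng.uniform(0.3, 3.0)))
            column = rng.choice([0, 1, MISSING], size=n, p=[0.4, 0.4, 0.2]).astype(np.int8)
            rates = params.category_rates()
            got = site_likelihood(tree, column, params)
            expected = enum_site_likelihood(tree, tree.taxa, column, rates)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_rerooting(self):
        # two rooted representations of one unrooted tree with matched
        # unrooted edge lengths: A:2, B:3, C:4, D:5, internal:1
        t1 = parse_newick("((A:2,B:3):0.4,(C:4,D:5):0.6);")
        t2 = parse_newick("(A:1.5,(B:3,(C:4,D:5):1):0.5);")
        params = MkParams(gamma_shape=0.8)
        for column in itertools.product((0, 1), repeat=4):
            col = np.array(column, np.int8)
            assert site_likelihood(t1, col, params) == pytest.approx(
                site_likelihood(t2, col, params), rel=1e-12)


class TestAscertainment:
    def test_mode_none_zero(self, tree20):
        assert excluded_pattern_probability(tree20, MkParams()) == 0.0

    def test_zero_tree_all_mass_constant(self):
        tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        p = excluded_pattern_probability(tree, MkParams(ascertainment_mode="variable"))
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("gamma_shape", [None, 0.9])
    @pytest.mark.parametrize("mode", ["variable", "parsimony_informative"])
    def test_pattern_distribution_normalizes(self, rng, mode, gamma_shape):
        # sum over all 2^n patterns equals 1; the conditional distribution
        # over retained patterns normalizes after correction
        from mkphylo.simulate import classify_character, CharacterClass

        n = 5
        tree = generate_model_tree(n, seed=91, total_length=1.5)
        params = MkParams(ascertainment_mode=mode, gamma_shape=gamma_shape)
        patterns = np.array(list(itertools.product((0, 1), repeat=n))).T.astype(np.int8)
        lls = pattern_log_likelihoods(tree, tree.taxa, patterns,
                                      params.category_rates())
        assert np.exp(lls).sum() == pytest.approx(1.0)
        excluded = excluded_pattern_probability(tree, params)
        keep = []
        for j in range(patterns.shape[1]):
            cls = classify_character(patterns[:, j])
            if mode == "variable":
                keep.append(cls is not CharacterClass.INVARIANT)
            else:
                keep.append(cls is CharacterClass.PARSIMONY_INFORMATIVE)
        conditional = np.exp(lls[np.array(keep)]).sum() / (1.0 - excluded)
        assert conditional == pytest.approx(1.0, rel=1e-10)


class TestMatrixLogLikelihood:
    def test_uncorrected_is_sum_of_site_logs(self, tree20, matrix20):
        small = matrix20.subset_columns(np.arange(30))
        params = MkParams()
        total = matrix_log_likelihood(tree20, small, params)
        per_site = sum(np.log(site_likelihood(tree20, small.data[:, j], params))
                       for j in range(30))
        assert total == pytest.approx(per_site)

    def test_corrected_at_least_uncorrected(self, tree20, matrix20):
        from mkphylo.simulate import filter_matrix

        variable = filter_matrix(matrix20, "variable_only")
        plain = matrix_log_likelihood(tree20, variable, MkParams())
        corrected = matrix_log_likelihood(
            tree20, variable, MkParams(ascertainment_mode="variable"))
        assert corrected >= plain

    def test_misspecification_warns(self, tree20, matrix20):
        with pytest.warns(UserWarning, match="invariant"):
            matrix_log_likelihood(tree20, matrix20,
                                  MkParams(ascertainment_mode="variable"))

    def test_degenerate_tree_rejected(self):
        tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        m = CharacterMatrix(list("ABCD"), np.zeros((4, 2), np.int8), np.ones(2))
        with pytest.raises(ValueError, match="degenerate"):
            matrix_log_likelihood(tree, m, MkParams(ascertainment_mode="variable"))

    def test_taxon_order_irrelevant(self, tree20, matrix20):
        small = matrix20.subset_columns(np.arange(25))
        shuffled = small.reorder(list(reversed(small.taxa)))
        params = MkParams(gamma_shape=1.2)
        assert matrix_log_likelihood(tree20, small, params) == pytest.approx(
            matrix_log_likelihood(tree20, shuffled, params))
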