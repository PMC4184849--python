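import numpy as np
import pytest

from mkphylo.simulate import (
    MISSING,
    CharacterClass,
    CharacterMatrix,
    SimulationConfig,
    assign_rate_classes,
    classify_character,
    classify_matrix,
    delete_rate_class,
    filter_matrix,
    generate_model_tree,
    mask_fossil_cells,
    simulate_characters,
)
from mkphylo.trees import bipartitions, write_newick


class TestModelTree:
    def test_deterministic_under_seed(self):
        a = generate_model_tree(30, seed=11)
        b = generate_model_tree(30, seed=11)
        assert write_newick(a) == write_newick(b)
        assert a.fossil_labels == b.fossil_labels

    def test_resolved_with_requested_scale(self):
        tree = generate_model_tree(75, total_length=10.0, seed=4)
        assert len(bipartitions(tree)) == 72
        assert tree.total_length() == pytest.approx(10.0)

    def test_fossil_count_is_ceil(self):
        tree = generate_model_tree(21, fossil_fraction=0.2, seed=1)
        assert len(tree.fossil_labels) == 5  # ceil(4.2)

    def test_short_branch_bias_shortens_median(self):
        flat = generate_model_tree(40, short_branch_bias=1.0, seed=8)
        skew = generate_model_tree(40, short_branch_bias=4.0, seed=8)
        med = lambda t: np.median([n.length for n in t.postorder() if n.parent])
        assert med(skew) < med(flat)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            generate_model_tree(3)


class TestSimulateCharacters:
    def test_deterministic_and_shapes(self, tree20):
        config = SimulationConfig(n_characters=40, seed=3)
        a = simulate_characters(tree20, config)
        b = simulate_characters(tree20, config)
        assert (a.data == b.data).all() and np.allclose(a.true_rates, b.true_rates)
        assert a.n_taxa == 20 and a.n_characters == 40

    def test_vanishing_rate_gives_invariant_columns(self, tree20):
        config = SimulationConfig(n_characters=200, gamma_shape=None,
                                  mean_rate=1e-9, seed=5)
        matrix = simulate_characters(tree20, config)
        assert all(c is CharacterClass.INVARIANT for c in classify_matrix(matrix))

    def test_two_taxon_divergence_matches_closed_form(self):
        # fraction differing = (1 - exp(-2r)) / 2 for total path r
        from mkphylo.trees import parse_newick

        tree = parse_newick("(A:0.3,B:0.7);")
        r = 0.5
        config = SimulationConfig(n_characters=10_000, gamma_shape=None,
                                  mean_rate=r, seed=21)
        matrix = simulate_characters(tree, config)
        frac = (matrix.row("A") != matrix.row("B")).mean()
        expected = 0.5 * (1 - np.exp(-2 * r))
        assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / 10_000)

    def test_saturation_limit_half_different(self, tree20):
        config = SimulationConfig(n_characters=5000, gamma_shape=None,
                                  mean_rate=100.0, seed=6)
        matrix = simulate_characters(tree20, config)
        a, b = matrix.data[0], matrix.data[-1]
        assert abs((a != b).mean() - 0.5) < 0.03

    def test_stationary_state_frequencies(self, tree20):
        config = SimulationConfig(n_characters=3000, mean_rate=2.0, seed=8)
        matrix = simulate_characters(tree20, config)
        assert abs((matrix.data == 1).mean() - 0.5) < 0.02

    def test_per_character_mode_is_overdispersed(self, tree20):
        # gamma rate heterogeneity puts extra mass on slow characters,
        # inflating the invariant fraction relative to a single rate
        single = simulate_characters(tree20, SimulationConfig(
            n_characters=5000, rate_mode="single", gamma_shape=None,
            mean_rate=1.0, seed=9))
        hetero = simulate_characters(tree20, SimulationConfig(
            n_characters=5000, rate_mode="per_character", gamma_shape=1.0,
            mean_rate=1.0, seed=9))
        inv = lambda m: np.mean([c is CharacterClass.INVARIANT
                                 for c in classify_matrix(m)])
        assert inv(hetero) > inv(single)
        assert np.unique(hetero.true_rates).size > 1
        assert np.unique(single.true_rates).size == 1

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(mean_rate=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(rate_mode="per_character", gamma_shape=None)


class TestClassification:
    @pytest.mark.parametrize("column,expected", [
        ([0, 0, 0, 0], CharacterClass.INVARIANT),
        ([1, 0, 0, 0], CharacterClass.VARIABLE_UNINFORMATIVE),
        ([1, 1, 0, 0], CharacterClass.PARSIMONY_INFORMATIVE),
        ([1, 1, 0, MISSING], CharacterClass.VARIABLE_UNINFORMATIVE),
        ([MISSING] * 4, CharacterClass.INVARIANT),
    ])
    def test_examples(self, column, expected):
        assert classify_character(np.array(column)) is expected

    def test_invalid_state(self):
        with pytest.raises(ValueError):
            classify_character(np.array([0, 1, 2]))


class TestFiltration:
    def _toy(self):
        data = np.array([
            [0, 1, 1],
            [0, 0, 1],
            [0, 0, 0],
            [0, 0, 0],
        ], dtype=np.int8)  # columns: invariant, autapomorphy, informative
        return CharacterMatrix(list("ABCD"), data, np.array([0.1, 0.2, 0.3]))

    def test_unfiltered_is_identity(self):
        m = self._toy()
        out = filter_matrix(m, "unfiltered")
        assert (out.data == m.data).all()

    def test_variable_only_drops_invariant(self):
        out = filter_matrix(self._toy(), "variable_only")
        assert out.n_characters == 2
        assert np.allclose(out.true_rates, [0.2, 0.3])

    def test_informative_only_keeps_informative(self):
        out = filter_matrix(self._toy(), "parsimony_informative_only")
        assert out.n_characters == 1
        assert np.allclose(out.true_rates, [0.3])

    def test_schemes_are_nested(self, tree20):
        matrix = simulate_characters(tree20, SimulationConfig(
            n_characters=300, rate_mode="per_character", gamma_shape=1.0,
            mean_rate=1.0, seed=13))
        sets = {}
        for scheme in ("unfiltered", "variable_only", "parsimony_informative_only"):
            out = filter_matrix(matrix, scheme)
            sets[scheme] = set(map(tuple, out.data.T))
            if scheme == "parsimony_informative_only":
                assert all(classify_character(col) is CharacterClass.PARSIMONY_INFORMATIVE
                           for col in out.data.T)
        assert sets["parsimony_informative_only"] <= sets["variable_only"] <= sets["unfiltered"]

    def test_empty_result_warns(self):
        m = CharacterMatrix(list("ABCD"), np.zeros((4, 3), np.int8), np.ones(3))
        with pytest.warns(UserWarning):
            out = filter_matrix(m, "variable_only")
        assert out.n_characters == 0


class TestRateClasses:
    def _hetero(self, n, seed=17):
        tree = generate_model_tree(10, seed=2)
        return simulate_characters(tree, SimulationConfig(
            n_characters=n, rate_mode="per_character", gamma_shape=1.0,
            mean_rate=1.0, seed=seed))

    @pytest.mark.parametrize("n,sizes", [(350, (117, 117, 116)), (1000, (334, 333, 333))])
    def test_tertile_sizes(self, n, sizes):
        matrix = self._hetero(n)
        classes = assign_rate_classes(matrix)
        assert tuple((classes == c).sum() for c in ("slow", "intermediate", "fast")) == sizes

    def test_tiny_example_ordering(self):
        m = CharacterMatrix(list("ABCD"), np.zeros((4, 3), np.int8),
                            np.array([1.0, 0.1, 10.0]))
        classes = assign_rate_classes(m)
        assert list(classes) == ["intermediate", "slow", "fast"]

    def test_single_rate_errors(self):
        m = CharacterMatrix(list("ABCD"), np.zeros((4, 3), np.int8), np.full(3, 2.0))
        with pytest.raises(ValueError):
            assign_rate_classes(m)

    def test_delete_full_slow_class(self):
        matrix = self._hetero(350)
        out = delete_rate_class(matrix, "slow", 1.0, seed=0)
        assert out.n_characters == 233
        assert (assign_rate_classes(matrix) != "slow").sum() == 233

    def test_delete_third_of_fast_class(self):
        matrix = self._hetero(350)
        out = delete_rate_class(matrix, "fast", 1 / 3, seed=0)
        assert matrix.n_characters - out.n_characters == 39  # round_half_up(117/3)

    def test_delete_zero_identity_and_determinism(self):
        matrix = self._hetero(100)
        assert delete_rate_class(matrix, "slow", 0.0, seed=1).n_characters == 100
        a = delete_rate_class(matrix, "fast", 0.5, seed=3)
        b = delete_rate_class(matrix, "fast", 0.5, seed=3)
        assert (a.data == b.data).all()

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            delete_rate_class(self._hetero(30), "slow", 1.5, seed=0)


class TestFossilMasking:
    def test_masked_cell_count_rounds_half_up(self, tree20, matrix20):
        out = mask_fossil_cells(matrix20, tree20, 0.75, seed=3)
        for label in tree20.fossil_labels:
            assert (out.row(label) == MISSING).sum() == 263  # round_half_up(262.5)
        for label in set(matrix20.taxa) - tree20.fossil_labels:
            assert (out.row(label) == MISSING).sum() == 0

    def test_full_masking(self, tree20, matrix20):
        out = mask_fossil_cells(matrix20, tree20, 1.0, seed=3)
        for label in tree20.fossil_labels:
            assert (out.row(label) == MISSING).all()

    def test_no_fossils_errors(self, matrix20):
        bare = generate_model_tree(20, fossil_fraction=0.0, seed=5)
        with pytest.raises(ValueError):
            mask_fossil_cells(matrix20, bare, 0.5, seed=0)

    def test_commutes_with_taxon_reordering(self, tree20, matrix20):
        masked = mask_fossil_cells(matrix20, tree20, 0.5, seed=11)
        shuffled = matrix20.reorder(list(reversed(matrix20.taxa)))
        masked_shuffled = mask_fossil_cells(shuffled, tree20, 0.5, seed=11)
        assert (masked_shuffled.reorder(matrix20.taxa).data == masked.data).all()


class TestMatrixIO:
    def test_nexus_roundtrip(self, tree20, matrix20):
        masked = mask_fossil_cells(matrix20, tree20, 0.3, seed=2)
        back = CharacterMatrix.from_nexus(masked.to_nexus())
        assert (back.reorder(masked.taxa).data == masked.data).all()

    def test_tsv_roundtrip_with_rates(self, matrix20):
        back = CharacterMatrix.from_tsv(matrix20.to_tsv(), matrix20.rates_tsv())
        assert (back.data == matrix20.data).all()
        assert np.allclose(back.true_rates, matrix20.true_rates)

    def test_nexus_header_is_mrbayes_standard(self, matrix20):
        text = matrix20.to_nexus()
        assert "DATATYPE=STANDARD" in text and 'SYMBOLS="01"' in text
        assert "MISSING=?" in text
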