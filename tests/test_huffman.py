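import numpy as np
import pytest

import gramhuff as gh

from conftest import TABLE3_A0, TABLE3_A1, make_random_table


class TestBuildTree:
    def test_weighted_gram_tree_depths(self, table_a1):
        depths = gh.build_tree(table_a1).leaf_depths()
        assert depths == {"aaa": 1, "aa": 2, "a": 3, "aab": 4, "b": 5, "ab": 5}

    def test_single_entry_tree_is_root_leaf(self):
        tree = gh.build_tree({"x": 5})
        assert tree.root.is_leaf and tree.leaf_depths() == {"x": 0}

    def test_three_symbol_demo_depths(self, seq42):
        table = gh.estimate_frequencies(seq42, m=1, alpha=0)
        assert gh.build_tree(table).leaf_depths() == {"a": 1, "b": 2, "c": 2}

    def test_internal_weights_are_child_sums(self, table_a0):
        def walk(node):
            if node.is_leaf:
                return
            assert node.weight == node.left.weight + node.right.weight
            walk(node.left)
            walk(node.right)

        walk(gh.build_tree(table_a0).root)

    def test_empty_table_rejected(self):
        with pytest.raises(gh.EmptyInputError):
            gh.build_tree({})


class TestExtractCodewords:
    def test_weighted_codebook_bit_for_bit(self, book_a1):
        assert dict(book_a1) == TABLE3_A1

    def test_unweighted_codebook_bit_for_bit(self, book_a0):
        assert dict(book_a0) == TABLE3_A0

    def test_single_gram_codeword_is_zero_bit(self):
        book = gh.codebook_from_frequencies(gh.FrequencyTable({"x": 5}, m=1, alpha=0))
        assert dict(book) == {"x": "0"}

    def test_two_leaf_tree_smaller_weight_gets_zero(self):
        book = gh.extract_codewords(gh.build_tree({"p": 2, "q": 1}))
        assert book["q"] == "0" and book["p"] == "1"

    def test_codebook_rebuilds_identically_from_frequencies(self, table_a1, book_a1):
        # The canonical tie policy makes the codebook a pure function of the
        # (insertion-ordered) frequency table.
        again = gh.codebook_from_frequencies(
            gh.FrequencyTable(dict(table_a1), m=3, alpha=1)
        )
        assert dict(again) == dict(book_a1)


class TestEntropyAndLength:
    def test_demo_entropy_three_decimals(self):
        h = gh.first_order_entropy([22 / 42, 15 / 42, 5 / 42])
        assert round(h, 3) == 1.385

    def test_uniform_binary_entropy(self):
        assert gh.first_order_entropy([0.5, 0.5]) == pytest.approx(1.0)

    def test_degenerate_distribution_entropy(self):
        assert gh.first_order_entropy([1.0]) == pytest.approx(0.0)

    @pytest.mark.parametrize("bad", [[0.5, 0.0, 0.5], [-0.1, 1.1], [0.3, 0.3]])
    def test_invalid_probability_vectors_rejected(self, bad):
        with pytest.raises(ValueError):
            gh.first_order_entropy(bad)

    def test_demo_total_and_average_bits(self, seq42):
        table = gh.estimate_frequencies(seq42, m=1, alpha=0)
        book = gh.codebook_from_frequencies(table)
        assert gh.total_code_bits(book, table) == 62
        assert round(gh.average_code_length(book, table), 3) == 1.476

    def test_equiprobable_pair_averages_one_bit(self):
        table = gh.FrequencyTable({"a": 5, "b": 5}, m=1, alpha=0)
        book = gh.codebook_from_frequencies(table)
        assert gh.average_code_length(book, table) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def random_tables():
    rng = np.random.default_rng(2024)
    return [make_random_table(rng) for _ in range(200)]


class TestCodeOptimalityProperties:
    """Structural guarantees on randomly generated frequency tables."""

    def test_prefix_free_and_kraft_equality(self, random_tables):
        for table in random_tables:
            book = gh.codebook_from_frequencies(table)
            assert book.is_prefix_free()
            if len(book) >= 2:
                assert book.kraft_sum() == pytest.approx(1.0)

    def test_redundancy_bound(self, random_tables):
        """Average length exceeds entropy by at most p_max + 0.086."""
        for table in random_tables:
            total = table.total()
            probs = [c / total for c in table.values()]
            book = gh.codebook_from_frequencies(table)
            avg = gh.average_code_length(book, table)
            h = gh.first_order_entropy(probs)
            assert h <= avg + 1e-9
            assert avg - h <= max(probs) + 0.086 + 1e-9
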