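import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gramhuff as gh

from conftest import PATTERN8


class TestEstimateFrequencies:
    @pytest.mark.parametrize(
        "alpha,expected",
        [
            (0, {"a": 7, "b": 1, "aa": 6, "ab": 1, "aaa": 5, "aab": 1}),
            (1, {"a": 7, "b": 1, "aa": 12, "ab": 2, "aaa": 15, "aab": 3}),
        ],
    )
    def test_weighted_counts_on_run_with_break(self, alpha, expected):
        table = gh.estimate_frequencies(PATTERN8, m=3, alpha=alpha)
        assert dict(table) == expected
        # Exact integers, not floats, for whole-number alpha.
        assert all(isinstance(c, int) for c in table.values())

    def test_insertion_order_is_length_then_position(self):
        table = gh.estimate_frequencies(PATTERN8, m=3, alpha=0)
        assert table.grams() == ("a", "b", "aa", "ab", "aaa", "aab")

    def test_single_symbol_input(self):
        assert dict(gh.estimate_frequencies("x", m=1, alpha=0)) == {"x": 1}

    def test_three_letter_demo_counts(self, seq42):
        assert dict(gh.estimate_frequencies(seq42, m=1, alpha=0)) == {
            "a": 22,
            "b": 15,
            "c": 5,
        }

    def test_fractional_alpha_counts_are_floats(self):
        table = gh.estimate_frequencies("aaaa", m=2, alpha=0.5)
        assert table["aa"] == pytest.approx(3 * math.sqrt(2))

    def test_empty_pattern_rejected(self):
        with pytest.raises(gh.EmptyInputError, match="empty input"):
            gh.estimate_frequencies("", m=1, alpha=0)

    def test_m_larger_than_data_rejected(self):
        with pytest.raises(ValueError, match="m exceeds data size"):
            gh.estimate_frequencies("ab", m=3, alpha=0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            gh.estimate_frequencies("ab", m=1, alpha=-1)

    @settings(derandomize=True, max_examples=60)
    @given(
        pattern=st.text(alphabet="abc", min_size=1, max_size=40),
        m=st.integers(1, 4),
        alpha=st.sampled_from([0.0, 1.0, 2.0]),
    )
    def test_conservation_and_scaling(self, pattern, m, alpha):
        """Length-i counts sum to (n-i+1) * i^alpha; alpha only rescales."""
        m = min(m, len(pattern))
        table = gh.estimate_frequencies(pattern, m=m, alpha=alpha)
        base = gh.estimate_frequencies(pattern, m=m, alpha=0)
        n = len(pattern)
        for i in range(1, m + 1):
            total = sum(c for _, c in table.items_of_length(i))
            assert total == pytest.approx((n - i + 1) * i**alpha)
        for gram, count in table.items():
            assert count == pytest.approx(base[gram] * len(gram) ** alpha)

    def test_every_pattern_symbol_present(self):
        table = gh.estimate_frequencies("abcabcx", m=2, alpha=1)
        assert {"a", "b", "c", "x"} <= set(table.grams())


class TestPruneFrequencies:
    def test_identity_at_full_fraction(self, table_a1):
        assert gh.prune_frequencies(table_a1, 1.0) == table_a1

    def test_top_half_of_multigrams_survive(self, table_a1):
        pruned = gh.prune_frequencies(table_a1, 0.5)
        assert dict(pruned) == {"a": 7, "b": 1, "aa": 12, "aaa": 15}

    def test_zero_fraction_keeps_only_singles(self, table_a1):
        pruned = gh.prune_frequencies(table_a1, 0.0)
        assert set(pruned.grams()) == {"a", "b"}

    def test_ties_broken_by_insertion_order(self):
        table = gh.FrequencyTable({"a": 3, "xy": 2, "yz": 2, "zz": 2}, m=2, alpha=0)
        pruned = gh.prune_frequencies(table, 1 / 3)
        assert pruned.grams() == ("a", "xy")

    def test_survivor_order_and_counts_unchanged(self):
        table = gh.estimate_frequencies("abababab", m=3, alpha=1)
        pruned = gh.prune_frequencies(table, 0.4)
        survivors = pruned.grams()
        assert survivors == tuple(g for g in table.grams() if g in set(survivors))
        assert all(pruned[g] == table[g] for g in survivors)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, table_a1, bad):
        with pytest.raises(ValueError):
            gh.prune_frequencies(table_a1, bad)

    def test_random_tables_never_lose_singles(self):
        rng = np.random.default_rng(7)
        from conftest import make_random_table

        for _ in range(30):
            table = make_random_table(rng)
            frac = float(rng.uniform(0, 1))
            pruned = gh.prune_frequencies(table, frac)
            singles = {g for g in table if len(g) == 1}
            assert singles <= set(pruned.grams())


class TestSerialization:
    def test_tsv_roundtrip_integer_counts(self, tmp_path, table_a1):
        path = tmp_path / "freqs.tsv"
        gh.write_frequency_table(table_a1, path)
        assert gh.read_frequency_table(path) == table_a1

    def test_tsv_roundtrip_awkward_grams(self, tmp_path):
        table = gh.FrequencyTable({"\t": 2, "\\x": 1, "a\n": 4, "a": 1}, m=2, alpha=0)
        path = tmp_path / "freqs.tsv"
        gh.write_frequency_table(table, path)
        assert gh.read_frequency_table(path) == table
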