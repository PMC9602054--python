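import numpy as np
import pytest

import gramhuff as gh

# The 42-symbol three-letter demonstration sequence and its printed statistics.
SEQ42 = "aaaabbaaaabbbbbbaabcabbccabbaaaaabbccaaaaa"

# Printed gram->codeword tables for the 8-symbol run "aaaaaaab" at m=3,
# for the unweighted (alpha=0) and length-weighted (alpha=1) statistics.
TABLE3_A0 = {"a": "11", "b": "0010", "aa": "10", "ab": "0011", "aaa": "01", "aab": "000"}
TABLE3_A1 = {"a": "111", "b": "11010", "aa": "10", "ab": "11011", "aaa": "0", "aab": "1100"}

PATTERN8 = "aaaaaaab"


@pytest.fixture(scope="session")
def seq42() -> str:
    return SEQ42


@pytest.fixture(scope="session")
def table_a0() -> gh.FrequencyTable:
    return gh.estimate_frequencies(PATTERN8, m=3, alpha=0)


@pytest.fixture(scope="session")
def table_a1() -> gh.FrequencyTable:
    return gh.estimate_frequencies(PATTERN8, m=3, alpha=1)


@pytest.fixture(scope="session")
def book_a0(table_a0) -> gh.Codebook:
    return gh.codebook_from_frequencies(table_a0)


@pytest.fixture(scope="session")
def book_a1(table_a1) -> gh.Codebook:
    return gh.codebook_from_frequencies(table_a1)


def make_random_table(rng: np.random.Generator) -> gh.FrequencyTable:
    """A frequency table estimated from a random pattern over a small alphabet."""
    alpha = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
    letters = list("abcd"[: int(rng.integers(2, 5))])
    n = int(rng.integers(5, 60))
    pattern = "".join(rng.choice(letters, size=n))
    m = int(rng.integers(1, min(4, n) + 1))
    return gh.estimate_frequencies(pattern, m=m, alpha=alpha)


def make_random_codec(rng: np.random.Generator):
    """(codebook, m, random input drawn over the pattern's alphabet)."""
    letters = list("abc"[: int(rng.integers(2, 4))])
    pattern = "".join(rng.choice(letters, size=int(rng.integers(4, 40))))
    m = int(rng.integers(1, 4))
    m = min(m, len(pattern))
    book = gh.codebook_from_frequencies(gh.estimate_frequencies(pattern, m=m, alpha=1))
    data = "".join(rng.choice(sorted(set(pattern)), size=int(rng.integers(1, 201))))
    return book, m, data
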