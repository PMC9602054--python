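"""Synthetic corpora: trajectory symbol streams and the binary Fibonacci word.

These generators reproduce the two self-contained test corpora of the
study protocol, so every experiment runs without downloading anything:

* i.i.d. *trajectory* symbols over A = {a, b, c, d, e} with probabilities
  (0.88, 0.05, 0.01, 0.05, 0.01) — a relative movement-direction encoding
  in which 'a' means "keep going straight", which is why it dominates;
* the *binary Fibonacci word*, built by iterating a token-rewriting rule
  from the token list [a, b]: each token 'a' or 'ba' becomes the pair
  (a, b), each token 'b' becomes the single token 'ba'. Both symbols occur
  equally often and the word has only i + 1 distinct length-i factors,
  which makes it the ideal stress test for long-gram coding.
"""

from __future__ import annotations

from typing import List, Optional, Tuple, Union

import numpy as np

from .types import SymbolSequence, as_symbols

__all__ = [
    "TRAJECTORY_SYMBOLS",
    "TRAJECTORY_PROBS",
    "gen_trajectory",
    "fibonacci_tokens",
    "gen_fibonacci",
    "split_pattern_test",
]

TRAJECTORY_SYMBOLS: Tuple[str, ...] = ("a", "b", "c", "d", "e")
TRAJECTORY_PROBS: Tuple[float, ...] = (0.88, 0.05, 0.01, 0.05, 0.01)


def gen_trajectory(
    n: int, seed: Optional[Union[int, np.random.Generator]] = None
) -> SymbolSequence:
    """Draw ``n`` i.i.d. trajectory symbols; reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(len(TRAJECTORY_SYMBOLS), size=n, p=TRAJECTORY_PROBS)
    lookup = np.array(TRAJECTORY_SYMBOLS)
    return SymbolSequence("".join(lookup[draws]), alphabet=TRAJECTORY_SYMBOLS)


def fibonacci_tokens(iterations: int) -> List[str]:
    """Token list after ``iterations`` applications of the rewriting rule.

    Iteration 1 is the initial list [a, b]. The rule operates on *tokens*,
    not on the flattened string: the token 'ba' is rewritten as a unit,
    which is what distinguishes it from an adjacent 'b', 'a' pair.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    tokens = ["a", "b"]
    for _ in range(iterations - 1):
        nxt: List[str] = []
        for tok in tokens:
            if tok in ("a", "ba"):
                nxt.extend(("a", "b"))
            elif tok == "b":
                nxt.append("ba")
            else:  # pragma: no cover - rule is closed over {a, b, ba}
                raise AssertionError(f"unexpected token {tok!r}")
        tokens = nxt
    return tokens


def gen_fibonacci(
    iterations: Optional[int] = None,
    min_length: Optional[int] = None,
    truncate: bool = False,
) -> SymbolSequence:
    """Concatenated binary Fibonacci word.

    Exactly one of ``iterations`` / ``min_length`` must be given. With
    ``min_length`` the rule is iterated until the word reaches that length;
    ``truncate=True`` then cuts it to exactly ``min_length`` symbols.
    """
    if (iterations is None) == (min_length is None):
        raise ValueError("give exactly one of iterations / min_length")
    if iterations is not None:
        word = "".join(fibonacci_tokens(iterations))
    else:
        if min_length < 1:
            raise ValueError("min_length must be >= 1")
        tokens = ["a", "b"]
        k = 1
        while sum(map(len, tokens)) < min_length:
            k += 1
            tokens = fibonacci_tokens(k)
        word = "".join(tokens)
        if truncate:
            word = word[:min_length]
    return SymbolSequence(word, alphabet="ab")


def split_pattern_test(
    seq: Union[str, SymbolSequence], pattern_fraction: float
) -> Tuple[SymbolSequence, SymbolSequence]:
    """Contiguous prefix/remainder split into (pattern, test) sets."""
    if not 0.0 < pattern_fraction < 1.0:
        raise ValueError("pattern_fraction must lie strictly between 0 and 1")
    symbols = as_symbols(seq)
    cut = round(pattern_fraction * len(symbols))
    if cut == 0 or cut == len(symbols):
        raise ValueError("degenerate split: one side would be empty")
    return SymbolSequence(symbols[:cut]), SymbolSequence(symbols[cut:])
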