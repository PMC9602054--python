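"""Independent reference implementations used only as test oracles.

* ``stage_optimal`` is a literal transcription of the stage-by-stage
  multistage-graph procedure: it stores full code strings per node and
  revisits positions at every stage, exactly as the pseudocode does.
* ``brute_force_min_bits`` enumerates every segmentation of the input into
  codebook grams recursively and returns the minimum total bit length.

Both are deliberately naive and share no code with the package's
position-indexed dynamic program.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional


def stage_optimal(symbols: str, book: Mapping[str, str], m: int) -> Dict[int, str]:
    """Run the stage-based procedure; return the per-position best code strings.

    ``Dnodes[j]`` ends up holding the code string of a shortest parse of the
    first j symbols. Grams absent from the codebook contribute no edge.
    """
    n = len(symbols)
    dnodes: Dict[int, str] = {0: ""}
    for e in range(n):                          # stages 0 .. n-1
        for i in range(e, min(m * e, n) + 1):   # states reachable at stage e
            if i not in dnodes:
                continue
            for j in range(i + 1, min(i + m, n) + 1):
                gram = symbols[i:j]
                code = book.get(gram)
                if code is None:
                    continue
                candidate = dnodes[i] + code
                if j not in dnodes or len(dnodes[j]) > len(candidate):
                    dnodes[j] = candidate
    return dnodes


def brute_force_min_bits(
    symbols: str, book: Mapping[str, str], m: int
) -> Optional[int]:
    """Minimum bit length over all segmentations into codebook grams, or None."""
    n = len(symbols)
    best: list[Optional[int]] = [None]

    def recurse(i: int, bits: int) -> None:
        if i == n:
            if best[0] is None or bits < best[0]:
                best[0] = bits
            return
        for j in range(i + 1, min(i + m, n) + 1):
            code = book.get(symbols[i:j])
            if code is not None:
                recurse(j, bits + len(code))

    recurse(0, 0)
    return best[0]
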