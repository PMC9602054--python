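# Methods

## Model and procedure

`gramhuff` implements variable-to-variable entropy coding over *m-grams*:
contiguous runs of 1..m symbols drawn from a finite alphabet A. The
pipeline assumes a *pattern / test* discipline: gram statistics are
estimated on pattern data believed to be statistically representative of
the class of inputs, codewords are derived from those statistics alone,
and test data is then encoded out-of-sample. The scheme is only expected
to help on sources with stable, easily estimated run statistics
(trajectory-style streams, DNA, highly structured sequences); sources
whose statistics drift between pattern and test (natural-language text)
defeat it, and no adaptivity is attempted.

**Frequency estimation.** For each window length i = 1..m, every length-i
window of the pattern adds i^α to its gram's count. With α = 0 the counts
of length-i grams sum to n − i + 1 exactly; the table for general α is the
α = 0 table with length-i counts multiplied by i^α. Counts are kept as
exact integers whenever α is a whole number, so the small worked examples
reproduce bit-exactly; fractional α falls back to floats. Insertion order
(outer loop over length, inner over start position) is preserved and is
semantically load-bearing — see tie policy below.

**Pruning.** For large m the table is cut to the `ceil(keep_fraction · k)`
highest-count grams among the k grams of length ≥ 2; ties keep the
earlier-inserted gram; all length-1 grams survive unconditionally so that
any input over the alphabet remains encodable. The fraction counts grams,
not probability mass — the simplest deterministic reading of a
"percentage of the most frequent sequences" rule.

**Canonical Huffman construction.** Standard lightest-two merging over the
gram forest, with every tie pinned: nodes carry a creation index (leaves
first, in table insertion order, then merged nodes in merge order); the
forest is ordered by (weight, creation index); the first of the two nodes
popped in a merge becomes the '0'/left child. Bit assignment in Huffman
coding is otherwise arbitrary, and any valid tie-break gives the same
*weighted length*; pinning it buys two things: regression-stable codewords,
and a codebook that is a pure function of the insertion-ordered frequency
table, which is what makes the "frequencies" codebook file mode and the
frequency-embedding container mode lossless. A single-gram table receives
the 1-bit codeword "0" (the construction is otherwise undefined there),
and its decoder maps each '0' bit back to the lone gram.

**Optimal parsing.** Parses of the input into codebook grams are paths in
a DAG over positions 0..n with an edge i → j (i < j ≤ i + m) whenever
I[i:j] is in the codebook, weighted by codeword length. Since all edges
move forward, ascending position order is a topological order, and one
forward pass of strict-improvement relaxations computes the per-position
optimum f and a backpointer. This collapses the stage-by-stage multistage
formulation (which revisits each position at every stage it is reachable
from) without changing any value; a literal stage-based transcription is
kept in the test suite and asserted equal — codes, parses and path
lengths — on every binary string up to length 12 under both reference
codebooks. Ties keep the incumbent, i.e. the parse through the earliest
predecessor ("the first possibility"). Candidate grams at a position are
enumerated in a single walk of a trie over the codebook's grams; grams
missing from a pruned codebook simply contribute no edge.

**Greedy parsing.** At each position, among codebook grams starting there
(lengths 1..m, clamped at the end of the input), pick the one maximising
|S|/|codeword(S)| — the density rule of the fractional-knapsack heuristic —
emit its codeword and advance by |S|. The comparison is strictly
greater-than: on ratio ties the earlier, shorter candidate wins. This is
observable — on the unweighted 8-symbol worked example a ≥ comparison
would pick "ab" over "a" at position 6 and change the output, so the
10-bit result pins the rule. The greedy coder also enumerates candidates
via the trie; this is output-identical to the literal scan (same
candidates, same order, same tie rule) and makes the coder's work per
position proportional to the longest codebook match rather than to m.

**Decoding** inverts the prefix-free codebook into a bit-indexed binary
tree and emits the gram at each leaf reached. It is a left inverse of both
encoders and consumes exactly the payload bit count recorded in the
container; ending mid-codeword and walking off the tree are distinct
errors.

## Parameters

| parameter | meaning | default | notes |
| --- | --- | --- | --- |
| m | maximum gram length (symbols) | 8 (CLI) | larger m only helps when long runs repeat; table size grows with distinct grams |
| α | length-weighting exponent | 1 | α = 0 counts occurrences; α = 1 weights by length, favouring long grams; exposed as a flag everywhere since no single value is canonical for every corpus |
| keep_fraction | fraction of multi-symbol grams kept | 1.0 | singles always kept; use ≪ 1 for large m on rich alphabets |
| granularity | byte / char / bit | char | bit granularity reads MSB-first within each byte |
| pattern_fraction | contiguous prefix used as pattern data | 0.25 (split helper) | experiments may also use disjoint pattern/test corpora |

## Synthetic corpora

The generators reproduce the two self-contained study corpora. The
*trajectory* stream draws i.i.d. symbols over {a,b,c,d,e} with
probabilities (0.88, 0.05, 0.01, 0.05, 0.01) — a relative
movement-direction encoding dominated by "keep straight". It is i.i.d. by
construction, so it exercises codebook correctness and the closed-form
expected code length (Huffman depths {1,2,3,4,4} give Σpᵢlᵢ = 1.21
bits/symbol at m = 1) but says nothing about sources with memory. The
*binary Fibonacci word* iterates a token rewriting (token 'a' or 'ba' →
(a,b); token 'b' → ('ba')) from [a,b]; the rewrite operates on tokens, not
the flattened string, which is required to reproduce the published early
iterates. Its two symbols are equiprobable (m = 1 coding is pinned at
exactly 1.0 bits/symbol) while only i + 1 distinct length-i factors exist,
so long-gram coding compresses it dramatically — the ideal probe of the
m-dependence. Neither generator emulates real GPS tracks or real genomes;
passing tests demonstrate algorithmic correctness and the predicted
scaling behaviour, not field performance on natural data.

## Problem sizes and numerical choices

The packaged experiment reproductions run at desk scale, chosen so the
full suite completes in minutes while keeping sampling error far below
the asserted tolerances: the Fibonacci trend run uses a ≥10⁵-symbol word
split 50/50 into pattern and test with keep_fraction 1.0 (the full table
at m = 64 holds only ~2 300 grams, so no pruning is needed), and the
trajectory check uses 2·10⁵ symbols split 50/50, where the standard error
of the mean code length is ≈0.002 bits against a ±0.02 assertion. The
trend assertion is qualitative (strictly decreasing bits/symbol over
m = 1, 16, 64) because the corpus size at which the published mid-range
figures were measured is far larger, and exact mid-range values depend on
it.

Ratio comparisons in the greedy coder use floating division; equal
rational ratios compare equal in IEEE double (correctly rounded division
of small integers), so the tie rule is exact. Entropy validates its input
as a strictly positive vector summing to 1 within 1e-9. Reported figures
are rounded (3 decimals) only at display time.

## Container and file formats

Codebook and frequency files are line-oriented UTF-8 TSV with escaped
grams; the frequency mode stores the insertion-ordered table from which
the canonical policy rebuilds identical codewords. The encoded container
is a small binary framing (magic, version, granularity, m, α, embedded
codebook block or an "external" marker, exact payload bit count, payload
zero-padded to a byte boundary). The external mode exists because a
deployed encoder/decoder pair sharing fixed codewords need not pay the
codebook cost per message; all bits-per-symbol figures likewise exclude
codebook transmission. Bad magic, truncation and payload/bit-count
inconsistency raise distinct errors.

## Known limitations

- No adaptive or per-block statistics: the codebook is frozen after
  training, and drifting sources degrade gracefully but noticeably.
- The optimal parser is quadratic-ish in practice only through its memory
  of O(n) positions; it is intended for benchmarking the greedy coder and
  for short inputs, not bulk compression.
- Pruned codebooks remain decodable but may lengthen parses; no attempt is
  made to re-optimise codeword lengths after pruning.
- The PPM family is out of scope as a baseline; DEFLATE is available via
  the standard library codec for context.
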