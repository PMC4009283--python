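# Methods

## Model and data layout

The package solves the exact all-pairs suffix-prefix problem (APSP): for
every ordered pair (S_i, S_j), i ≠ j, the largest r with
S_i[|S_i|−r+1..] = S_j[1..r]. Everything is computed over one concatenated
text. String i is followed by a separator block: the base-c expansion of
i−1 over a strictly increasing separator alphabet of c characters, m =
min{m : c^m ≥ k} digits, most significant first. A block follows the last
string as well, so every string-suffix is terminated inside the text. All
separator characters must sort below every sequence character; the default
alphabet is the 32 printable ASCII characters `!`..`@`, which works for any
uppercase-letter sequence alphabet. Positions are 1-based in every public
interface.

The choice m = min{m : c^m ≥ k} makes the capacity arithmetic exact
(3 digits over a 200-character alphabet cover 200³ = 8,000,000 strings);
an extra guard digit would waste a character per string and changes no
algorithm.

Duplicate input strings are accepted — each still receives a distinct
separator block — and mutually overlap at full length, which is what the
definitional oracle reports as well.

## Index

* Suffix array: prefix doubling (Manber–Myers) on numpy arrays,
  O(n log² n) with small constants; adequate for the multi-megabase inputs
  this package targets. A naive sort is kept in the tests as the
  independent oracle.
* LCP: Kasai's algorithm, O(n).
* Tree: the suffix tree is represented only by its preorder
  parenthesisation (BP). Internal nodes are the lcp-intervals, enumerated
  by the standard stack pass over the LCP array; each node contributes an
  opening parenthesis before its leftmost leaf (shallower nodes first) and
  a closing parenthesis after its rightmost leaf. Leaves appear in
  suffix-array order. Navigation — parent, matching close, string depth,
  leaf rank/select — is precomputed into plain integer arrays keyed by BP
  position. This is deliberately functionality-faithful rather than
  space-faithful: no compressed suffix array, no 2n-bit LCP encoding, no
  o(n) rank/select directories. The contracts (what each operation answers)
  are those of a succinct BP index; the mechanism is ordinary arrays.

Leaf string depth is the full suffix length, so depth strictly increases on
every root-to-leaf path; this is asserted over random texts in the tests.

## Terminal leaves, effective parents, and a correctness subtlety

A leaf is *terminal* when its incoming edge begins with a separator
character; its suffix, truncated at the separator, is a complete suffix of
one input string (the *string-suffix*, length sl). With single-character
separators the terminal leaf hangs directly below the node at depth sl.
With m-character blocks, branching can occur *inside* the separator region,
so the leaf's contribution is attached to its *effective parent*: the
closest ancestor whose incoming edge is not terminal.

One consequence found by oracle testing and worth recording: the effective
parent's depth is always ≥ sl, but equality can fail. If two strings share
an identical suffix w and their separator blocks share leading digits, the
node where the climb stops has depth |w| + (shared digits) — its path label
crosses the string boundary. The usable match length is still sl = |w|, so
L-list entries carry (text position, sl) explicitly and sl is what the
stacks push and the reports write. When blocks diverge at their first digit
(always, for single-character separators) the recorded length equals the
effective parent's depth, recovering the textbook description. One can show
the stack order is still correct under this capping: for two live entries
of the same string at nested nodes the deeper node always carries the
longer string-suffix, so stack tops remain the longest matches.

## Method 1 and variants

Stage 1 walks leaves via select, skipping the k·m separator-start leaves,
and appends each terminal leaf's (position, sl) to its effective parent's
L list in scan order. Stage 2 is the three-case BP scan (push at `(` of an
internal node, report at a prefix leaf, pop at `)`), with the leaf's closing
parenthesis skipped. min_len is applied at reporting time only; pushes are
never pruned, which keeps all variants' internal states identical. The
diagonal is computed on the stacks but never reported. A stack-discipline
check (each pop must return the entry its L list predicts) runs in every
scan; full scans additionally assert empty stacks at the end.

Variant 1a (no lists, no stacks) and variant 1b (lists, no stacks) walk
each prefix leaf's ancestors from the effective-parent start upward; the
first (deepest) ancestor producing a value for an ordered pair wins. Both
are tested element-wise against method 1 and the oracle.

## Method 2

Separator-start suffixes occupy the lowest suffix-array ranks, so the
scanned (non-separator) leaves are rank-contiguous and the pop threshold
between consecutive scanned leaves is a single LCP entry. Pushing uses the
equivalent lcp-based condition lcp(leaf, next) ≥ sl rather than a
same-parent test: the parent test fails when the next leaf lies deeper
inside a sibling subtree even though the prefix relation holds. The
exception step at a prefix leaf of S scans *all* following terminal leaves
that share the whole of S (while lcp ≥ |S| and the character at offset |S|
is a separator), not just the immediate successor — two or more strings can
end with the whole of S and only the first would otherwise be found.

## Parallel execution

Both strategies reduce every work unit to "scan this range with prefilled
stacks", reusing the sequential scan code, which is what makes bit-identical
output a structural property rather than a testing accident:

* top-down: BFS expansion of the shallowest unit until ceil(γP) units exist
  or only leaves remain; separator-edge children are dropped at the root
  (their subtrees hold only separator-start leaves) but kept deeper, where
  terminal-edge subtrees contain reportable prefix leaves. Subtree units
  become BP ranges (method 1) or leaf-rank ranges (method 2).
* bottom-up: ceil(γP) equal slices of the BP vector (method 1; slice starts
  snapped to the next opening parenthesis) or of the non-separator leaf
  ranks (method 2). γ is applied to both strategies as the same
  oversubscription trick; the original description uses it only top-down.

Prefilling differs by method because their push points differ. Method 1
pushes a node's entire L list at its opening parenthesis, so a worker
starting at BP position b receives the full L lists of b's strictly
enclosing ancestors, root first — any close parenthesis inside the range
whose open lies before b belongs to an ancestor of b, so its pops find
exactly the prefilled entries. Method 2 pushes at terminal leaves, so a
worker starting at leaf rank r receives, per ancestor (skipping
separator-region ancestors, whose leaves belong to their effective parent),
the terminal-chain descendant leaves preceding r, FIFO from the root down;
this equals the live-entry state of the sequential scan at r and is checked
against instrumented sequential runs in the tests.

A solution column is written only at its string's prefix leaf, which lies in
exactly one unit, so results merge by disjoint column union (checked at
merge time). Variants 1a/1b parallelize by splitting the target strings.
Workers are threads over a shared queue; the contract tested and promised is
determinism and equality with the sequential run, not wall-clock speedup —
the scan loops are pure Python and hold the GIL.

## Synthetic data

`gen_random(k, total_len, seed)` emulates the random benchmark sets of the
APSP literature: uniform random DNA with k−1 cut points drawn uniformly
without replacement, so string lengths are random but sum exactly to
total_len. `gen_planted` tiles reads over a random mother sequence with a
fixed step so consecutive reads overlap by exactly `ov` — a positive
control whose expected edges are known by construction. Neither models
sequencing error, quality values, reverse complements, or the skewed
length/coverage distributions of real read sets, so passing tests certify
exact-overlap computation, not robustness to noisy data; mismatching or
reverse-complement overlaps are out of scope by design.

## Problem sizes and numerical choices

The test suite runs 200 random oracle-equivalence instances (k ≤ 20, total
length ≤ 2000), 200 structural-invariant texts (n ≤ 500), the full parallel
combination grid on a fixed k=10 / n=1000 instance, and one large agreement
run at k=1000, total length 1,000,000 — sizes chosen so the whole suite
completes in well under a minute per suite on one core while still
exercising multi-character separators, duplicate strings and both scan
orders. There is no floating point anywhere; all quantities are exact
integers, so no tolerances apply. Ties never arise: suffixes of one text
are pairwise distinct, and child edges of a node have distinct first
characters.

## Known limitations

* Space behaviour is that of plain integer arrays (~tens of bytes per input
  character), not of the compressed structures whose functionality is
  mirrored; this package is about the algorithms, not the succinct
  engineering.
* Suffix-array construction is O(n log² n); very large n would warrant an
  induced-sorting builder.
* Parallelism is correctness-shaped (deterministic decomposition and
  merging), not throughput-shaped, under the Python GIL.
* Alphabets whose characters do not all sort above some available separator
  range are rejected rather than remapped.
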