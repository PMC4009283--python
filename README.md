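# suffpref

All-pairs suffix-prefix overlaps over a generalized suffix tree navigated
through its balanced-parentheses (BP) representation.

## The problem

Given k strings S_1 … S_k over an ordered alphabet (DNA reads, typically),
the **all-pairs suffix-prefix problem (APSP)** asks, for every ordered pair
(S_i, S_j), for the largest r such that

    S_i[|S_i|−r+1 .. |S_i|] = S_j[1 .. r]

i.e. the longest suffix of S_i that equals a prefix of S_j. These overlap
lengths are the edges of the overlap graph that overlap-layout-consensus
genome assemblers build before layout and consensus. The package is for
people who need those k(k−1) overlap lengths exactly (not heuristically) from
a multi-FASTA read set, and for people studying the index structures behind
that computation.

## The method

All strings are concatenated into one text, each followed by a distinct
separator block that sorts below every sequence character (an m-character
block over a c-character separator alphabet encodes up to c^m separators —
3 characters over ~200 symbols already cover 8,000,000 strings). Over this
text the package builds a suffix array (prefix doubling), an LCP array
(Kasai) and the preorder parenthesisation **BP** of the suffix tree, whose
internal nodes are the lcp-intervals; navigation (parent, child, leaf
rank/select, edge characters, string depth) is answered from arrays keyed by
BP position.

Two algorithms then solve APSP, with identical output:

* **Method 1** — a leaf scan records, for every internal node v, the list
  L_v of *terminal* leaves hanging below it (complete string-suffixes);
  a second, parenthesis-by-parenthesis scan pushes L_v onto k per-string
  stacks at `(`, reads all stack tops when the leaf starting some string
  S_j is reached (tops are the longest live matches into S_j), and pops at
  `)`. Two space-optimized variants (`1a`, `1b`) replace the scan by
  per-string ancestor walks, without stacks.
* **Method 2** — a single pass over the leaves in suffix-array order.
  Terminal leaves sort immediately before the suffixes they prefix, so a
  terminal leaf whose string-suffix prefixes its successor is pushed, stale
  entries are popped lazily by an lcp threshold, and prefix leaves read the
  stack tops. One exception: a suffix equal to the *whole* of S_j sorts just
  after S_j's prefix leaf and is read off directly.

Both run in O(n log n + k²) here (n = total text length; the log comes from
suffix-array construction). Two parallel decompositions — top-down subtree
selection and bottom-up range splitting with exact stack prefilling — return
bit-identical matrices for every worker count.

## Worked example

The three-string example {AAC, GAG, TTA} with separators `#<$<%` produces the
text `AAC#GAG$TTA%` whose suffix tree serialises to
`(()()()(()()()())()(()())(()()))`; the only overlap is the suffix `A` of
`TTA` matching the prefix of `AAC`:

```
$ suffpref overlap --in t3.fa --method 1 --min-len 1
src_id	dst_id	overlap_len
TTA-read	AAC-read	1
```

A planted positive control — six 20-mers tiled with exact 8-base overlaps —
is recovered end to end:

```
$ suffpref simulate --k 6 --read-len 20 --planted-overlap 8 --seed 11 --out planted.fa
wrote planted.fa: k=6 total_len=120
$ suffpref overlap --in planted.fa --method 2 --min-len 5
src_id	dst_id	overlap_len
read1	read2	8
read2	read3	8
read3	read4	8
read4	read5	8
read5	read6	8
$ suffpref verify --in planted.fa
all methods agree
```

Each output row says: the last `overlap_len` characters of `src_id` equal
the first `overlap_len` characters of `dst_id`; pairs below `--min-len` (or
with no overlap) are omitted and mean 0. `--method {1,1a,1b,2}` selects the
algorithm, `--threads`, `--strategy {topdown,bottomup}` and `--gamma` control
parallel decomposition, `--dense` emits the full k×k matrix.

From Python:

```python
from suffpref import gen_random, compute_overlaps
S = gen_random(k=100, total_len=50_000, seed=7)
sol = compute_overlaps(S, method="2", min_len=15)
sol.get(3, 5)        # overlap length of the ordered pair (read3, read5)
```

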