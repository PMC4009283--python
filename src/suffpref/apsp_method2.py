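"""Second APSP method: a single leaf-order scan of the suffix tree.

Two orderings make this work.  Separator characters sort below the sequence
alphabet, so (a) all suffixes beginning inside separator blocks occupy the
first ranks of the suffix array and the remaining leaves form one contiguous
block, and (b) among suffixes sharing a prefix, terminal leaves (complete
string-suffixes) precede the suffixes they prefix.

The scan visits the non-separator leaves in rank order and keeps one stack
per string plus a global stack recording push order:

* POP -- before a leaf, every entry whose match length exceeds the lcp with
  the previous leaf can no longer prefix the current suffix and is removed
  (lazy, threshold-based popping; this scan never touches internal nodes).
* REPORT -- at a prefix leaf of string s the stack tops are the longest
  matches into s.  One exception: a suffix of another string equal to the
  *whole* of s sorts just after the prefix leaf (larger separator) and has
  not been pushed yet; those terminal leaves are read off directly.
* PUSH -- a terminal leaf whose complete string-suffix (length d) prefixes
  the next suffix (``lcp >= d``) pushes (text position, d).

Output is identical to Method 1 on every input.
"""

from __future__ import annotations

import numpy as np

from .text_builder import ConcatText
from .suffix_index import SuffixIndex
from .apsp_method1 import OverlapMatrix, StackSet

__all__ = ["run_method2", "lcp_between_leaves", "scan_leaf_range", "first_scan_rank"]


def first_scan_rank(idx: SuffixIndex, ct: ConcatText) -> int:
    """Rank of the first leaf whose suffix does not start with a separator.

    Exactly ``k * sep_len`` suffixes begin inside separator blocks and they
    occupy the lowest ranks.
    """
    return ct.k * ct.sep_len + 1


def lcp_between_leaves(idx: SuffixIndex, leaf_a: int, leaf_b: int) -> int:
    """Longest common prefix of the suffixes at two leaves, ``leaf_a``
    preceding ``leaf_b`` in suffix-array order: the minimum of the lcp array
    over the ranks in between (a single lookup for adjacent leaves)."""
    ra = idx.rank_leaf(leaf_a)
    rb = idx.rank_leaf(leaf_b)
    if not (idx.is_leaf(leaf_a) and idx.is_leaf(leaf_b)):
        raise ValueError("both arguments must be leaves")
    if ra >= rb:
        raise ValueError("leaf_a must precede leaf_b in suffix-array order")
    return int(np.min(idx.lcp[ra : rb]))


def run_method2(idx: SuffixIndex, ct: ConcatText, min_len: int = 1) -> OverlapMatrix:
    sol = OverlapMatrix.zeros(ct.k, min_len)
    stacks = StackSet(ct.k)
    r0 = first_scan_rank(idx, ct)
    scan_leaf_range(idx, ct, stacks, sol, r0, idx.n + 1, min_len)
    return sol


def scan_leaf_range(
    idx: SuffixIndex,
    ct: ConcatText,
    stacks: StackSet,
    sol: OverlapMatrix,
    r_from: int,
    r_to: int,
    min_len: int,
) -> None:
    """Scan leaves at ranks ``r_from .. r_to-1`` (all non-separator ranks).

    ``stacks`` must hold the live entries for the suffix at rank ``r_from``
    (empty when ``r_from`` is the first non-separator rank).  The first leaf
    of the range therefore pops nothing; later leaves pop by lcp threshold.
    The report's exception step may read leaves beyond ``r_to``; that is
    read-only and correct because those matches belong to columns owned by
    this range.
    """
    n = idx.n
    tb = ct.text_bytes
    seps = ct.sep_codes
    sa_l = idx.sa.tolist()
    lcp_l = idx.lcp.tolist()
    start_map = ct._start_map
    sid = ct.string_id
    ends = ct._ends
    k = ct.k
    per = stacks.stacks
    glob = stacks.global_stack
    vals = sol.values
    for r in range(r_from, r_to):
        p = sa_l[r - 1]
        if r > r_from:
            t = lcp_l[r - 1]
            while glob and glob[-1][1] > t:
                s_, _ = glob.pop()
                per[s_].pop()
        x = sid(p)
        sl = ends[x - 1] - p + 1  # length of this complete-or-partial string-suffix
        s = start_map.get(p)
        if s is not None:
            for j in range(1, k + 1):
                if j != s and per[j]:
                    d = per[j][-1][1]
                    if d >= min_len:
                        vals[j - 1, s - 1] = d
            # exception: whole-string matches sorting just after the prefix leaf
            q = r + 1
            while q <= n and lcp_l[q - 1] >= sl:
                pq = sa_l[q - 1]
                if tb[pq + sl - 1] not in seps:
                    break
                xq = sid(pq)
                if xq != s and sl >= min_len:
                    vals[xq - 1, s - 1] = sl
                q += 1
        if r < n and lcp_l[r] >= sl:
            per[x].append((p, sl))
            glob.append((x, sl))
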