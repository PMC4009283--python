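"""First APSP method: L-list filling by leaf scan, then a single preorder
scan of the BP vector with k stacks, plus two space-optimized variants.

Stage 1 walks the leaves in suffix-array order.  A leaf whose incoming edge
starts with a separator character (a *terminal leaf*) represents a complete
suffix of one input string; its text position is appended to the L list of
its *effective parent* -- the closest ancestor whose own incoming edge is not
terminal.  With single-character separators the effective parent is simply
the parent; multi-character separator blocks can interpose separator-only
branching nodes, which the climb skips.

Stage 2 scans the BP vector left to right.  Opening an internal node pushes
its L entries (text position, node string depth) onto the per-string stacks;
reaching a leaf that starts some string S_j reads the top of every other
stack as the longest suffix-prefix match into S_j; closing an internal node
pops its entries.  Ancestors push before descendants, so stack tops always
hold the deepest (longest) live match.

The two variants trade the scan for per-string ancestor walks: one drops both
the L lists and the stacks, the other keeps the L lists but reads them
directly during the walk.  All three produce identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .text_builder import ConcatText
from .suffix_index import SuffixIndex

__all__ = [
    "OverlapMatrix",
    "StackSet",
    "effective_parent",
    "fill_l_lists",
    "fill_l_entries",
    "run_method1",
    "run_method1_stackless",
    "run_method1_nostacks_with_lists",
]


@dataclass
class OverlapMatrix:
    """k x k longest suffix-prefix lengths.

    ``values[i-1, j-1]`` is the length of the longest suffix of string i that
    equals a prefix of string j, or 0 if below ``min_len`` or absent.  The
    diagonal is never reported (assembly semantics: self-overlaps excluded).
    """

    values: np.ndarray
    min_len: int = 1

    @classmethod
    def zeros(cls, k: int, min_len: int = 1) -> "OverlapMatrix":
        return cls(np.zeros((k, k), dtype=np.int64), min_len)

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def get(self, i: int, j: int) -> int:
        return int(self.values[i - 1, j - 1])

    def __eq__(self, other) -> bool:
        return isinstance(other, OverlapMatrix) and np.array_equal(
            self.values, other.values
        )

    def edges(self):
        """Yield (i, j, length) for every nonzero ordered pair, row order."""
        for i, j in zip(*np.nonzero(self.values)):
            yield int(i) + 1, int(j) + 1, int(self.values[i, j])


@dataclass
class StackSet:
    """k per-string stacks of (text position, match length) plus an optional
    global stack recording (string index, match length) in push order."""

    k: int
    stacks: list = field(default_factory=list)
    global_stack: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stacks:
            self.stacks = [[] for _ in range(self.k + 1)]  # 1-based

    def push(self, s: int, pos: int, length: int) -> None:
        self.stacks[s].append((pos, length))
        self.global_stack.append((s, length))

    def top_length(self, s: int) -> int:
        st = self.stacks[s]
        return st[-1][1] if st else 0


def _is_terminal_leaf(idx: SuffixIndex, ct: ConcatText, leaf: int) -> bool:
    p = idx.leaf_text_pos(leaf)
    dp = int(idx.depth_at[idx.parent_at[leaf]])
    return p + dp <= ct.n and ct.text_bytes[p + dp - 1] in ct.sep_codes


def effective_parent(idx: SuffixIndex, ct: ConcatText, leaf: int) -> int:
    """Closest ancestor of a terminal leaf whose incoming edge is not
    terminal (the root qualifies).  Equals ``parent(leaf)`` whenever
    separators are single characters."""
    if not idx.is_leaf(leaf):
        raise ValueError("effective_parent expects a leaf position")
    if not _is_terminal_leaf(idx, ct, leaf):
        raise ValueError("leaf does not have a terminal incoming edge")
    return _climb_terminal(idx, ct, int(idx.parent_at[leaf]))


def _climb_terminal(idx: SuffixIndex, ct: ConcatText, z: int) -> int:
    """Climb from node z while the edge pointing into z is terminal."""
    tb = ct.text_bytes
    seps = ct.sep_codes
    sa = idx.sa
    cumleaf = idx.cumleaf
    parent_at = idx.parent_at
    depth_at = idx.depth_at
    while z != SuffixIndex.ROOT:
        pz = int(parent_at[z])
        first = int(sa[int(cumleaf[z - 1])])  # leftmost leaf's text position
        if tb[first + int(depth_at[pz]) - 1] in seps:
            z = pz
        else:
            break
    return z


def fill_l_lists(idx: SuffixIndex, ct: ConcatText) -> dict[int, list[int]]:
    """Stage 1: map BP open position of each effective parent to the text
    positions of its terminal-(chain-)descendant leaves, in leaf-scan order.

    Leaves whose suffix starts with a separator character are skipped (the
    generalization of ignoring the first k leaves to m-character separators).
    """
    return {v: [p for p, _ in lst] for v, lst in fill_l_entries(idx, ct).items()}


def fill_l_entries(idx: SuffixIndex, ct: ConcatText) -> dict[int, list[tuple[int, int]]]:
    """As :func:`fill_l_lists`, but each entry is (text position, match
    length), the match length being the complete string-suffix length.

    The effective parent's string depth equals that length whenever separator
    blocks diverge at their first character (always true for single-character
    separators).  When multi-character blocks share leading digits, identical
    string-suffixes branch inside the separator region and the owner node can
    sit deeper than the string boundary; the usable match length is still the
    string-suffix length, so it is recorded explicitly.
    """
    tb = ct.text_bytes
    seps = ct.sep_codes
    n = idx.n
    sa_l = idx.sa.tolist()
    leaf_l = idx.leaf_pos.tolist()
    parent_l = idx.parent_at.tolist()
    depth_l = idx.depth_at.tolist()
    ends = ct._ends
    sid = ct.string_id
    L: dict[int, list[tuple[int, int]]] = {}
    for r in range(1, n + 1):
        p = sa_l[r - 1]
        if tb[p - 1] in seps:
            continue
        v = leaf_l[r - 1]
        par = parent_l[v]
        dp = depth_l[par]
        if p + dp <= n and tb[p + dp - 1] in seps:
            z = _climb_terminal(idx, ct, par)
            L.setdefault(z, []).append((p, ends[sid(p) - 1] - p + 1))
    return L


def _as_entries(ct: ConcatText, L: dict) -> dict:
    """Accept either position-only L lists or (position, length) entries."""
    ends = ct._ends
    sid = ct.string_id
    out = {}
    for v, lst in L.items():
        if lst and not isinstance(lst[0], tuple):
            lst = [(p, ends[sid(p) - 1] - p + 1) for p in lst]
        out[v] = lst
    return out


def run_method1(
    idx: SuffixIndex,
    ct: ConcatText,
    L: dict | None = None,
    min_len: int = 1,
) -> OverlapMatrix:
    """Full scan of the BP vector with k stacks (sequential reference)."""
    L = fill_l_entries(idx, ct) if L is None else _as_entries(ct, L)
    sol = OverlapMatrix.zeros(ct.k, min_len)
    stacks = StackSet(ct.k)
    scan_bp_range(idx, ct, L, stacks, sol, 1, idx.bp_len + 1, min_len)
    if any(stacks.stacks[s] for s in range(1, ct.k + 1)):
        raise RuntimeError("internal error: stacks not empty after full scan")
    return sol


def scan_bp_range(
    idx: SuffixIndex,
    ct: ConcatText,
    L: dict[int, list[tuple[int, int]]],
    stacks: StackSet,
    sol: OverlapMatrix,
    start: int,
    stop: int,
    min_len: int,
) -> None:
    """Scan BP positions ``start .. stop-1`` with the three-case rule.

    ``stacks`` must hold the state the sequential scan would have on arrival
    at ``start`` (empty for a full scan).  Reaching a leaf skips its closing
    parenthesis, mirroring the sequential scan's one-step jump.
    """
    bp_l = idx.bp.tolist()
    sa_l = idx.sa.tolist()
    ooc_l = idx.open_of_close.tolist()
    cumleaf = idx.cumleaf
    start_map = ct._start_map
    sid = ct.string_id
    k = ct.k
    per = stacks.stacks
    vals = sol.values
    i = start
    r = int(cumleaf[start - 1])  # leaves seen before this range
    while i < stop:
        if bp_l[i]:
            if bp_l[i + 1] == 0:  # leaf
                r += 1
                p = sa_l[r - 1]
                s = start_map.get(p)
                if s is not None:
                    for j in range(1, k + 1):
                        if j != s and per[j]:
                            d = per[j][-1][1]
                            if d >= min_len:
                                vals[j - 1, s - 1] = d
                i += 2
            else:
                lst = L.get(i)
                if lst:
                    for p, d in lst:
                        per[sid(p)].append((p, d))
                i += 1
        else:
            lst = L.get(ooc_l[i])
            if lst:
                for p, _ in reversed(lst):
                    entry = per[sid(p)].pop()
                    if entry[0] != p:  # pragma: no cover - invariant breach
                        raise RuntimeError("stack discipline violated")
            i += 1


def _prefix_leaf(idx: SuffixIndex, ct: ConcatText, s: int) -> int:
    """BP position of the leaf whose suffix starts at string s's first
    position."""
    p0 = int(ct.start_pos[s - 1])
    return int(idx.leaf_pos[int(idx.rank_of_pos[p0]) - 1])


def _walk_start(idx: SuffixIndex, ct: ConcatText, leaf: int) -> int:
    """First ancestor for the upward walk from a prefix leaf: the effective
    parent if the leaf's own incoming edge is terminal, else the parent."""
    par = int(idx.parent_at[leaf])
    if _is_terminal_leaf(idx, ct, leaf):
        return _climb_terminal(idx, ct, par)
    return par


def _subtree_leaf_positions(idx: SuffixIndex, z: int) -> list[int]:
    """Text positions of all leaves under node z (z may itself be a leaf),
    in suffix-array order."""
    lo = idx.first_leaf_rank(z)
    hi = int(idx.cumleaf[int(idx.close_at[z])])
    return [int(idx.sa[q - 1]) for q in range(lo, hi + 1)]


def run_method1_stackless(
    idx: SuffixIndex, ct: ConcatText, min_len: int = 1, cols=None
) -> OverlapMatrix:
    """Space optimization 1: no L lists, no stacks.

    For each string's prefix leaf, walk the ancestors towards the root; at
    each ancestor enumerate the children reached by terminal edges and read
    the leaf text positions below them.  The first (deepest) ancestor that
    yields a value for an ordered pair wins, realizing the longest match.

    ``cols`` restricts the walk to a subset of target strings (1-based);
    used by the parallel executor, where workers own disjoint columns.
    """
    sol = OverlapMatrix.zeros(ct.k, min_len)
    vals = sol.values
    tb = ct.text_bytes
    seps = ct.sep_codes
    ends = ct._ends
    k = ct.k
    for s in cols if cols is not None else range(1, k + 1):
        leaf = _prefix_leaf(idx, ct, s)
        v = _walk_start(idx, ct, leaf)
        seen = bytearray(k + 1)
        while v != 0 and v != SuffixIndex.ROOT:
            d = int(idx.depth_at[v])
            for z in idx.children(v):
                p1 = int(idx.sa[idx.first_leaf_rank(z) - 1])
                if tb[p1 + d - 1] not in seps:
                    continue
                for p in _subtree_leaf_positions(idx, z):
                    i_str = ct.string_id(p)
                    if i_str and i_str != s and not seen[i_str]:
                        seen[i_str] = 1
                        sl = ends[i_str - 1] - p + 1  # string-suffix length
                        if sl >= min_len:
                            vals[i_str - 1, s - 1] = sl
            v = int(idx.parent_at[v])
    return sol


def run_method1_nostacks_with_lists(
    idx: SuffixIndex,
    ct: ConcatText,
    L: dict | None = None,
    min_len: int = 1,
    cols=None,
) -> OverlapMatrix:
    """Space optimization 2: keep stage 1's L lists, drop the stacks; walk
    each prefix leaf's ancestors reading the L lists directly."""
    L = fill_l_entries(idx, ct) if L is None else _as_entries(ct, L)
    sol = OverlapMatrix.zeros(ct.k, min_len)
    vals = sol.values
    k = ct.k
    for s in cols if cols is not None else range(1, k + 1):
        leaf = _prefix_leaf(idx, ct, s)
        v = _walk_start(idx, ct, leaf)
        seen = bytearray(k + 1)
        while v != 0:
            for p, d in L.get(v, ()):
                i_str = ct.string_id(p)
                if i_str and i_str != s and not seen[i_str]:
                    seen[i_str] = 1
                    if d >= min_len:
                        vals[i_str - 1, s - 1] = d
            v = int(idx.parent_at[v])
    return sol
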