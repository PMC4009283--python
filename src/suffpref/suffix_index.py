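"""Generalized suffix structure: suffix array, LCP array and the
balanced-parentheses (BP) encoding of the suffix tree, with navigation.

The suffix tree is never materialised as a pointer structure.  Internal nodes
are the lcp-intervals of the suffix array; a single stack pass over the LCP
array enumerates them, and the tree's preorder parenthesisation is emitted
directly: one ``(`` when a node is entered, one ``)`` when it is left, leaves
appearing in suffix-array order.  Navigation (parent, child, leaf rank/select,
edge characters, string depth) is answered from plain integer arrays keyed by
BP position.  This is functionality-faithful to a succinct BP index, not
space-faithful: no o(n) rank/select directories are built.

Conventions: text positions, suffix-array ranks and BP positions are all
1-based; numpy arrays are indexed with ``value - 1`` unless noted.  BP-keyed
arrays carry a dummy slot at index 0 so that ``arr[bp_pos]`` works directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuffixIndex", "build_sa", "build_lcp", "build_bp"]


def _sa_doubling(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber–Myers), 0-based positions."""
    n = len(codes)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes.astype(np.int64)
    tmp = np.empty(n, dtype=np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - step] = rank[step:]
        sa = np.lexsort((key2, rank))
        tmp[sa[0]] = 0
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
        tmp[sa[1:]] = np.cumsum(changed)
        rank, tmp = tmp.copy(), rank
        if rank[sa[-1]] == n - 1:
            return sa
        step *= 2


def build_sa(text: str) -> np.ndarray:
    """Suffix array of ``text``: rank r (1-based) at index r-1, values are
    1-based suffix start positions, suffixes in strictly increasing
    lexicographic (byte) order."""
    if not text:
        raise ValueError("text must be non-empty")
    codes = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
    return (_sa_doubling(codes) + 1).astype(np.int64)


def build_lcp(text: str, sa: np.ndarray) -> np.ndarray:
    """LCP array (Kasai): index r-1 holds lcp of the suffixes at ranks r-1, r;
    the first entry is 0."""
    tb = text.encode("latin-1")
    n = len(tb)
    rank = np.empty(n + 1, dtype=np.int64)
    rank[np.asarray(sa, dtype=np.int64)] = np.arange(1, n + 1)
    rank_l = rank.tolist()
    sa_l = [0] + [int(x) for x in sa]  # sa_l[r] = start of rank-r suffix
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for p in range(1, n + 1):
        r = rank_l[p]
        if r > 1:
            q = sa_l[r - 1]
            while p + h <= n and q + h <= n and tb[p + h - 1] == tb[q + h - 1]:
                h += 1
            lcp[r - 1] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def _lcp_intervals(lcp_l: list, n: int):
    """Enumerate internal suffix-tree nodes as (left rank, string depth).

    Returns (node_lb, node_depth, closes) where closes[r] counts the internal
    nodes whose interval ends at rank r (emitted as ``)`` after leaf r).
    The root (depth 0) is excluded.  Unary compression is implicit: each
    distinct (interval, depth) on the stack is one branching node.
    """
    node_lb: list = []
    node_d: list = []
    closes = [0] * (n + 1)  # 1-based rank
    stack_d = [0]
    stack_lb = [1]
    for r in range(2, n + 1):
        l = lcp_l[r - 1]
        lb = r - 1
        while stack_d[-1] > l:
            node_d.append(stack_d.pop())
            lb = stack_lb.pop()
            node_lb.append(lb)
            closes[r - 1] += 1
        if stack_d[-1] < l:
            stack_d.append(l)
            stack_lb.append(lb)
    while stack_d[-1] > 0:
        node_d.append(stack_d.pop())
        node_lb.append(stack_lb.pop())
        closes[n] += 1
    return node_lb, node_d, closes


@dataclass
class SuffixIndex:
    """Suffix array + LCP + BP suffix-tree view of a concatenated text."""

    text: str
    sa: np.ndarray       # rank -> 1-based text position (index r-1)
    lcp: np.ndarray      # rank -> lcp with previous rank (index r-1)
    bp: np.ndarray       # uint8, 1-based positions; 1 = '(' , 0 = ')'
    depth_at: np.ndarray    # BP open position -> string depth (leaves: suffix length)
    parent_at: np.ndarray   # BP open position -> parent's open position (root: 0)
    close_at: np.ndarray    # BP open position -> matching close position
    open_of_close: np.ndarray
    cumleaf: np.ndarray     # cumleaf[i] = number of leaf opens at positions <= i
    leaf_pos: np.ndarray    # rank -> BP open position of that leaf (index r-1)
    rank_of_pos: np.ndarray  # 1-based text position -> rank (index pos)

    ROOT = 1

    # -- construction -----------------------------------------------------

    @classmethod
    def build(cls, ct_or_text) -> "SuffixIndex":
        text = ct_or_text if isinstance(ct_or_text, str) else ct_or_text.text
        sa = build_sa(text)
        lcp = build_lcp(text, sa)
        arrays = _build_bp_arrays(text, sa, lcp)
        return cls(text=text, sa=sa, lcp=lcp, **arrays)

    @property
    def n(self) -> int:
        return len(self.text)

    @property
    def bp_len(self) -> int:
        return len(self.bp) - 1

    def bp_string(self) -> str:
        return "".join("(" if b else ")" for b in self.bp[1:])

    # -- leaf rank / select -----------------------------------------------

    def select_leaf(self, j: int) -> int:
        """BP open position of the j-th leaf (leaves in suffix-array order)."""
        if not 1 <= j <= self.n:
            raise IndexError(f"leaf rank {j} out of range 1..{self.n}")
        return int(self.leaf_pos[j - 1])

    def rank_leaf(self, i: int) -> int:
        """Number of leaf opening parentheses at BP positions <= i."""
        if not 0 <= i <= self.bp_len:
            raise IndexError(f"BP position {i} out of range")
        return int(self.cumleaf[i])

    def next_leaf(self, bp_pos: int) -> int | None:
        """BP position of the first leaf strictly after ``bp_pos``."""
        r = int(self.cumleaf[bp_pos]) + 1
        return int(self.leaf_pos[r - 1]) if r <= self.n else None

    # -- structure --------------------------------------------------------

    def is_open(self, i: int) -> bool:
        if not 1 <= i <= self.bp_len:
            raise IndexError(f"BP position {i} out of range")
        return bool(self.bp[i])

    def is_leaf(self, i: int) -> bool:
        return bool(self.bp[i]) and i < self.bp_len and not self.bp[i + 1]

    def is_root(self, v: int) -> bool:
        return v == self.ROOT

    def parent(self, v: int) -> int | None:
        """Open position of v's parent; ``None`` for the root."""
        self._check_open(v)
        return None if v == self.ROOT else int(self.parent_at[v])

    def node_depth(self, v: int) -> int:
        """String depth: path-label length (suffix length for leaves)."""
        self._check_open(v)
        return int(self.depth_at[v])

    def first_leaf_rank(self, v: int) -> int:
        """Rank of the leftmost leaf in v's subtree (v itself if a leaf)."""
        return int(self.cumleaf[v - 1]) + 1

    def leaf_text_pos(self, bp_pos: int) -> int:
        """1-based text position of the suffix at a leaf."""
        if not self.is_leaf(bp_pos):
            raise ValueError(f"BP position {bp_pos} is not a leaf")
        return int(self.sa[self.first_leaf_rank(bp_pos) - 1])

    # -- edges ------------------------------------------------------------

    def edge_char(self, v: int, d: int) -> str:
        """d-th character (1-based) of the edge label pointing into v."""
        self._check_open(v)
        if v == self.ROOT:
            raise ValueError("the root has no incoming edge")
        pdepth = int(self.depth_at[self.parent_at[v]])
        elen = int(self.depth_at[v]) - pdepth
        if not 1 <= d <= elen:
            raise IndexError(f"edge offset {d} outside edge of length {elen}")
        p = int(self.sa[self.first_leaf_rank(v) - 1])
        return self.text[p + pdepth + d - 2]

    def child(self, v: int, c: str) -> int | None:
        """Child of internal node v whose incoming edge starts with c."""
        self._check_open(v)
        if self.is_leaf(v):
            raise ValueError("leaves have no children")
        end = int(self.close_at[v])
        ch = v + 1
        while ch < end:
            if self.edge_char(ch, 1) == c:
                return ch
            ch = int(self.close_at[ch]) + 1
        return None

    def children(self, v: int):
        """Yield the open positions of v's children, left to right."""
        end = int(self.close_at[v])
        ch = v + 1
        while ch < end:
            yield ch
            ch = int(self.close_at[ch]) + 1

    def _check_open(self, v: int) -> None:
        if not (1 <= v <= self.bp_len and self.bp[v]):
            raise ValueError(f"BP position {v} is not an opening parenthesis")


def _build_bp_arrays(text: str, sa: np.ndarray, lcp: np.ndarray) -> dict:
    n = len(text)
    lcp_l = [int(x) for x in lcp]
    sa_l = [int(x) for x in sa]
    node_lb, node_d, closes = _lcp_intervals(lcp_l, n)
    n_nodes = 1 + len(node_lb) + n
    L = 2 * n_nodes

    # group internal-node opens by left rank, shallower first
    order = np.lexsort((np.asarray(node_d, dtype=np.int64),
                        np.asarray(node_lb, dtype=np.int64)))
    lb_sorted = [node_lb[i] for i in order]
    d_sorted = [node_d[i] for i in order]

    bp = np.zeros(L + 1, dtype=np.uint8)
    depth_at = np.full(L + 1, -1, dtype=np.int64)
    parent_at = np.zeros(L + 1, dtype=np.int64)
    close_at = np.zeros(L + 1, dtype=np.int64)
    open_of_close = np.zeros(L + 1, dtype=np.int64)
    leaf_pos = np.zeros(n, dtype=np.int64)

    bp_l = [0] * (L + 1)
    depth_l = [-1] * (L + 1)
    parent_l = [0] * (L + 1)
    close_l = [0] * (L + 1)
    ooc_l = [0] * (L + 1)
    leaf_l = [0] * n

    stack = [1]          # open positions of currently-open nodes
    bp_l[1] = 1
    depth_l[1] = 0
    pos = 2
    ni = 0               # pointer into the sorted internal-node list
    n_int = len(lb_sorted)
    for r in range(1, n + 1):
        while ni < n_int and lb_sorted[ni] == r:
            bp_l[pos] = 1
            depth_l[pos] = d_sorted[ni]
            parent_l[pos] = stack[-1]
            stack.append(pos)
            pos += 1
            ni += 1
        # leaf for rank r
        bp_l[pos] = 1
        depth_l[pos] = n - sa_l[r - 1] + 1
        parent_l[pos] = stack[-1]
        leaf_l[r - 1] = pos
        close_l[pos] = pos + 1
        ooc_l[pos + 1] = pos
        pos += 2
        for _ in range(closes[r]):
            o = stack.pop()
            close_l[o] = pos
            ooc_l[pos] = o
            pos += 1
    o = stack.pop()
    assert o == 1 and not stack and pos == L, "unbalanced BP construction"
    close_l[1] = L
    ooc_l[L] = 1

    bp[:] = bp_l
    depth_at[:] = depth_l
    parent_at[:] = parent_l
    close_at[:] = close_l
    open_of_close[:] = ooc_l
    leaf_pos[:] = leaf_l

    is_leaf_open = np.zeros(L + 1, dtype=np.int64)
    is_leaf_open[leaf_pos] = 1
    cumleaf = np.cumsum(is_leaf_open)

    rank_of_pos = np.zeros(n + 1, dtype=np.int64)
    rank_of_pos[sa] = np.arange(1, n + 1)

    return dict(
        bp=bp,
        depth_at=depth_at,
        parent_at=parent_at,
        close_at=close_at,
        open_of_close=open_of_close,
        cumleaf=cumleaf,
        leaf_pos=leaf_pos,
        rank_of_pos=rank_of_pos,
    )


def build_bp(sa: np.ndarray, lcp: np.ndarray, text: str):
    """BP bit sequence plus per-node annotations for the suffix tree of
    ``text``; returns ``(bp_string, depth_at, annotations)``.

    Convenience wrapper over the array builder used by :class:`SuffixIndex`.
    """
    arrays = _build_bp_arrays(text, np.asarray(sa), np.asarray(lcp))
    bp_str = "".join("(" if b else ")" for b in arrays["bp"][1:])
    return bp_str, arrays["depth_at"], arrays
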