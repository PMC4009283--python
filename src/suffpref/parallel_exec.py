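"""Parallel work decomposition with a bit-identical-output contract.

Two strategies split the APSP scan into independent units:

* *top-down*: breadth-first expansion from the root selects ``ceil(gamma*P)``
  subtrees occupying the highest levels of the tree (separator-edge children
  of the root are ignored -- they hold no reportable leaves); each unit is
  one subtree.
* *bottom-up*: the BP vector (Method 1) or the non-separator leaf range
  (Method 2) is cut into ``ceil(gamma*P)`` equal slices, Method-1 slice
  starts snapped forward to the next opening parenthesis.

Before a worker starts mid-tree its stacks are prefilled with exactly the
state the sequential scan would hold at that point: for Method 1 the full L
list of every strictly enclosing ancestor, root first; for Method 2 the
terminal-chain descendants of each ancestor that precede the start leaf.
Workers share the index and L lists read-only and write disjoint columns of
the solution (a column is written only at its string's prefix leaf, which
belongs to exactly one unit), so the merge is a disjoint union and the
output is independent of P, gamma, strategy and scheduling order.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .text_builder import ConcatText
from .suffix_index import SuffixIndex
from . import apsp_method1 as m1
from . import apsp_method2 as m2
from .apsp_method1 import OverlapMatrix, StackSet

__all__ = [
    "WorkPlan",
    "decompose_top_down",
    "decompose_bottom_up",
    "prefill_stacks",
    "run_parallel",
]


@dataclass
class WorkPlan:
    """A set of independent work units for one APSP run.

    ``units`` holds subtree roots (BP open positions) for the top-down
    strategy, or half-open ranges (BP positions for Method 1, leaf ranks for
    Method 2) for the bottom-up strategy.
    """

    strategy: str           # "top_down" | "bottom_up"
    units: list = field(default_factory=list)
    gamma: float = 1.5
    P: int = 1

    @property
    def n_units(self) -> int:
        return len(self.units)


def _target_units(P: int, gamma: float) -> int:
    if P < 1:
        raise ValueError("P must be >= 1")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return max(1, math.ceil(gamma * P))


def decompose_top_down(
    idx: SuffixIndex, ct: ConcatText, P: int, gamma: float = 1.5
) -> WorkPlan:
    """Select subtree roots by breadth-first expansion from the root.

    The shallowest internal unit (leftmost on ties) is repeatedly replaced by
    its children until at least ``ceil(gamma*P)`` units exist or only leaves
    remain.  Separator-edge children are dropped when expanding the root;
    deeper terminal-edge children are kept, since their leaves are complete
    string-suffixes that a scan must still visit.
    """
    target = _target_units(P, gamma)
    units: list[int] = [SuffixIndex.ROOT]
    seps = ct.sep_codes
    tb = ct.text_bytes
    while len(units) < target:
        internals = [v for v in units if not idx.is_leaf(v)]
        if not internals:
            break
        v = min(internals, key=lambda u: (int(idx.depth_at[u]), u))
        children = list(idx.children(v))
        if v == SuffixIndex.ROOT:
            children = [
                z
                for z in children
                if tb[int(idx.sa[idx.first_leaf_rank(z) - 1]) - 1] not in seps
            ]
        units = [u for u in units if u != v] + children
    units.sort()
    return WorkPlan(strategy="top_down", units=units, gamma=gamma, P=P)


def decompose_bottom_up(
    idx: SuffixIndex, ct: ConcatText, P: int, gamma: float = 1.5, method: str = "2"
) -> WorkPlan:
    """Equal slices of the BP vector (Method 1) or leaf ranks (Method 2)."""
    target = _target_units(P, gamma)
    units: list[tuple[int, int]] = []
    if method.startswith("1"):
        L = idx.bp_len
        bp = idx.bp
        cuts = [1 + (L * i) // target for i in range(target)] + [L + 1]
        snapped = []
        for c in cuts[:-1]:
            while c <= L and not bp[c]:
                c += 1
            snapped.append(c)
        snapped.append(L + 1)
        for a, b in zip(snapped[:-1], snapped[1:]):
            if a < b:
                units.append((a, b))
    else:
        r0 = m2.first_scan_rank(idx, ct)
        n = idx.n
        span = n + 1 - r0
        cuts = [r0 + (span * i) // target for i in range(target)] + [n + 1]
        for a, b in zip(cuts[:-1], cuts[1:]):
            if a < b:
                units.append((a, b))
    return WorkPlan(strategy="bottom_up", units=units, gamma=gamma, P=P)


def _ancestors_root_down(idx: SuffixIndex, v: int) -> list[int]:
    """Strictly enclosing ancestors of BP open position v, root first."""
    chain = []
    u = int(idx.parent_at[v])
    while u:
        chain.append(u)
        u = int(idx.parent_at[u]) if u != SuffixIndex.ROOT else 0
    chain.reverse()
    return chain


def prefill_stacks(
    idx: SuffixIndex,
    ct: ConcatText,
    start,
    L: dict | None = None,
) -> StackSet:
    """Stack state the sequential scan would hold upon reaching ``start``.

    With ``L`` given (Method 1), ``start`` is a BP open position and the full
    L list of every strictly enclosing ancestor is pushed, root first --
    those pushes happened at the ancestors' opening parentheses.  Without
    ``L`` (Method 2), ``start`` is a leaf rank and each ancestor contributes
    the terminal-chain descendant leaves that precede the start leaf, pushed
    first-in-first-out from the root down; entries deeper in the tree carry
    longer matches, so every stack is length-sorted.
    """
    stacks = StackSet(ct.k)
    sid = ct.string_id
    if L is not None:
        for u in _ancestors_root_down(idx, start):
            for p, d in L.get(u, ()):
                stacks.push(sid(p), p, d)
        return stacks

    # Method 2: start is a leaf rank
    r0 = int(start)
    leaf = idx.select_leaf(r0)
    tb = ct.text_bytes
    seps = ct.sep_codes
    ends = ct._ends
    for u in _ancestors_root_down(idx, leaf):
        if u != SuffixIndex.ROOT:
            # skip separator-region ancestors; their leaves belong to the
            # closest ancestor with a non-terminal incoming edge
            first = int(idx.sa[idx.first_leaf_rank(u) - 1])
            pdepth = int(idx.depth_at[idx.parent_at[u]])
            if tb[first + pdepth - 1] in seps:
                continue
        d = int(idx.depth_at[u])
        for z in idx.children(u):
            p1 = int(idx.sa[idx.first_leaf_rank(z) - 1])
            if p1 + d > ct.n or tb[p1 + d - 1] not in seps:
                continue  # not a terminal edge
            lo = idx.first_leaf_rank(z)
            hi = int(idx.cumleaf[int(idx.close_at[z])])
            for q in range(lo, min(hi, r0 - 1) + 1):
                p = int(idx.sa[q - 1])
                s = sid(p)
                if s:  # separator-start leaves carry no string-suffix
                    stacks.push(s, p, ends[s - 1] - p + 1)
    return stacks


def _run_unit_method1(idx, ct, L, unit, min_len, k):
    sol = OverlapMatrix.zeros(k, min_len)
    a, b = unit
    stacks = prefill_stacks(idx, ct, a, L=L)
    m1.scan_bp_range(idx, ct, L, stacks, sol, a, b, min_len)
    return sol


def _run_unit_method2(idx, ct, unit, min_len, k):
    sol = OverlapMatrix.zeros(k, min_len)
    a, b = unit
    stacks = prefill_stacks(idx, ct, a)
    m2.scan_leaf_range(idx, ct, stacks, sol, a, b, min_len)
    return sol


def _subtree_to_range(idx, ct, v, method: str):
    """Convert a subtree-root unit into the scan range its worker executes."""
    if method.startswith("1"):
        return (v, int(idx.close_at[v]) + 1)
    lo = idx.first_leaf_rank(v)
    hi = int(idx.cumleaf[int(idx.close_at[v])])
    lo = max(lo, m2.first_scan_rank(idx, ct))
    return (lo, hi + 1)


def run_parallel(
    idx: SuffixIndex,
    ct: ConcatText,
    method: str,
    plan: WorkPlan,
    min_len: int = 1,
) -> OverlapMatrix:
    """Execute ``method`` ("1", "1a", "1b" or "2") over a work plan.

    Workers pull units from a shared queue (dynamic load balancing); results
    merge by disjoint column ownership, checked before merging.  Output is
    identical to the sequential run of the same method.
    """
    k = ct.k
    if method in ("1a", "1b"):
        return _run_parallel_walks(idx, ct, method, plan, min_len)
    if method == "1":
        L = m1.fill_l_entries(idx, ct)
        units = [
            u if isinstance(u, tuple) else _subtree_to_range(idx, ct, u, method)
            for u in plan.units
        ]
        worker = lambda u: _run_unit_method1(idx, ct, L, u, min_len, k)
    elif method == "2":
        units = [
            u if isinstance(u, tuple) else _subtree_to_range(idx, ct, u, method)
            for u in plan.units
        ]
        units = [u for u in units if u[0] < u[1]]
        worker = lambda u: _run_unit_method2(idx, ct, u, min_len, k)
    else:
        raise ValueError(f"unknown method {method!r}")

    if plan.P == 1:
        parts = [worker(u) for u in units]
    else:
        with ThreadPoolExecutor(max_workers=plan.P) as pool:
            parts = list(pool.map(worker, units))

    total = OverlapMatrix.zeros(k, min_len)
    owned = np.zeros(k, dtype=bool)
    for part in parts:
        cols = part.values.any(axis=0)
        if np.any(cols & owned):
            raise RuntimeError("internal error: overlapping column writes")
        owned |= cols
        np.maximum(total.values, part.values, out=total.values)
    return total


def _run_parallel_walks(idx, ct, method, plan, min_len):
    """Variants 1a/1b: the per-string ancestor walks are independent, so the
    target strings (solution columns) are split over the workers directly."""
    k = ct.k
    if method == "1a":
        worker = lambda cols: m1.run_method1_stackless(
            idx, ct, min_len=min_len, cols=cols
        )
    else:
        L = m1.fill_l_entries(idx, ct)
        worker = lambda cols: m1.run_method1_nostacks_with_lists(
            idx, ct, L, min_len=min_len, cols=cols
        )
    n_units = max(1, min(plan.n_units, k))
    bounds = [1 + (k * i) // n_units for i in range(n_units)] + [k + 1]
    chunks = [range(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if a < b]
    if plan.P == 1:
        parts = [worker(c) for c in chunks]
    else:
        with ThreadPoolExecutor(max_workers=plan.P) as pool:
            parts = list(pool.map(worker, chunks))
    total = OverlapMatrix.zeros(k, min_len)
    for part in parts:
        np.maximum(total.values, part.values, out=total.values)
    return total
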