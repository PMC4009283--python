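"""Brute-force reference solver and synthetic read-set generators.

The oracle works by direct character comparison on the raw strings -- no
suffix structures at all -- so it is maximally independent from the indexed
algorithms it is used to verify.
"""

from __future__ import annotations

import numpy as np

from .text_builder import StringSet
from .apsp_method1 import OverlapMatrix

__all__ = ["brute_force_apsp", "gen_random", "gen_planted"]

_DNA = "ACGT"


def brute_force_apsp(S: StringSet, min_len: int = 1) -> OverlapMatrix:
    """Definitional APSP: for each ordered pair (i, j), i != j, the largest
    r with ``S_i[-r:] == S_j[:r]``, zeroed below ``min_len``.  O(k^2 * l^2)."""
    k = S.k
    sol = OverlapMatrix.zeros(k, min_len)
    vals = sol.values
    for i in range(k):
        si = S.seqs[i]
        for j in range(k):
            if i == j:
                continue
            sj = S.seqs[j]
            for r in range(min(len(si), len(sj)), 0, -1):
                if si[-r:] == sj[:r]:
                    if r >= min_len:
                        vals[i, j] = r
                    break
    return sol


def gen_random(k: int, total_len: int, seed: int) -> StringSet:
    """k random DNA strings with uniformly random lengths summing to
    ``total_len`` (k-1 distinct cut points drawn uniformly), reproducible per
    seed."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if total_len < k:
        raise ValueError("total_len must be >= k (each string non-empty)")
    rng = np.random.default_rng(seed)
    if k > 1:
        cuts = np.sort(rng.choice(total_len - 1, size=k - 1, replace=False)) + 1
    else:
        cuts = np.empty(0, dtype=np.int64)
    bounds = np.concatenate([[0], cuts, [total_len]])
    chars = rng.integers(0, 4, size=total_len)
    letters = np.array(list(_DNA))
    text = "".join(letters[chars])
    seqs = [text[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    return StringSet.from_sequences(seqs)


def gen_planted(k: int, read_len: int, ov: int, seed: int) -> StringSet:
    """Reads tiled across a random mother sequence with step
    ``read_len - ov``, so consecutive reads overlap by exactly ``ov``
    positions (a positive control for the overlap detectors)."""
    if not 1 <= ov < read_len:
        raise ValueError("need 1 <= ov < read_len")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    step = read_len - ov
    mother_len = step * (k - 1) + read_len
    letters = np.array(list(_DNA))
    mother = "".join(letters[rng.integers(0, 4, size=mother_len)])
    seqs = [mother[i * step : i * step + read_len] for i in range(k)]
    return StringSet.from_sequences(seqs)
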