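"""Shared fixtures and independent naive oracles.

The oracles work by direct definition -- sorting suffix slices, comparing
characters, inserting suffixes into an explicit grouping tree -- and never
touch the package's index structures, so they can arbitrate correctness.
"""

from itertools import groupby

import pytest

from suffpref import StringSet, build_concat, SuffixIndex


# ---------------------------------------------------------------------------
# naive oracles


def naive_sa(text: str) -> list[int]:
    """1-based suffix array by sorting suffix slices."""
    return sorted(range(1, len(text) + 1), key=lambda i: text[i - 1 :])


def naive_lcp(text: str, sa: list[int]) -> list[int]:
    """LCP by character-by-character comparison of adjacent suffixes."""
    out = [0]
    for a, b in zip(sa, sa[1:]):
        sa_, sb = text[a - 1 :], text[b - 1 :]
        h = 0
        while h < min(len(sa_), len(sb)) and sa_[h] == sb[h]:
            h += 1
        out.append(h)
    return out


def naive_bp(text: str) -> str:
    """Preorder parenthesisation of an explicitly grouped suffix tree.

    Suffixes are sorted, then recursively grouped by their next character;
    maximal shared prefixes are extended before branching (path compression).
    Assumes no suffix is a prefix of another (true for the texts used).
    """
    sufs = naive_sa(text)
    out: list[str] = []

    def rec(group: list[int], d: int) -> None:
        out.append("(")
        if len(group) == 1:
            out.append(")")
            return
        while len({text[i - 1 + d] for i in group}) == 1:
            d += 1
        for _, sub in groupby(group, key=lambda i: text[i - 1 + d]):
            rec(list(sub), d + 1)
        out.append(")")

    rec(sufs, 0)
    return "".join(out)


def naive_overlap(si: str, sj: str) -> int:
    """Longest r with si[-r:] == sj[:r], by direct comparison."""
    for r in range(min(len(si), len(sj)), 0, -1):
        if si[-r:] == sj[:r]:
            return r
    return 0


# ---------------------------------------------------------------------------
# fixtures


TOY_TEXT = "AAC#GAG$TTA%"
TOY_BP = "(()()()(()()()())()(()())(()()))"


@pytest.fixture(scope="session")
def toy_set() -> StringSet:
    return StringSet.from_sequences(["AAC", "GAG", "TTA"],
                                    ids=["AAC-read", "GAG-read", "TTA-read"])


@pytest.fixture(scope="session")
def toy_ct(toy_set):
    return build_concat(toy_set, "#$%")


@pytest.fixture(scope="session")
def toy_idx(toy_ct):
    return SuffixIndex.build(toy_ct)
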