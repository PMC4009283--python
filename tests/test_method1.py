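"""Method 1: L-list filling, the stack scan, and the two space variants."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from suffpref import (
    StringSet,
    build_concat,
    SuffixIndex,
    effective_parent,
    fill_l_lists,
    fill_l_entries,
    run_method1,
    run_method1_stackless,
    run_method1_nostacks_with_lists,
    brute_force_apsp,
    gen_random,
)

dna_sets = st.lists(st.text(alphabet="ACGT", min_size=1, max_size=15),
                    min_size=1, max_size=8)


def _index(S, sep="!\"#$%&'()*+,-./0123456789:;<=>?@"):
    ct = build_concat(S, sep)
    return ct, SuffixIndex.build(ct)


class TestLLists:
    def test_toy_lists(self, toy_ct, toy_idx):
        L = fill_l_lists(toy_idx, toy_ct)
        assert L == {8: [11], 20: [7]}
        # position 11 belongs to string 3
        assert toy_ct.string_id(11) == 3

    def test_no_overlap_no_lists(self):
        ct, idx = _index(StringSet.from_sequences(["AC", "GT"]))
        assert fill_l_lists(idx, ct) == {}

    def test_single_string_no_lists(self):
        ct, idx = _index(StringSet.from_sequences(["AAC"]))
        assert fill_l_lists(idx, ct) == {}

    def test_entries_carry_string_suffix_lengths(self, toy_ct, toy_idx):
        entries = fill_l_entries(toy_idx, toy_ct)
        assert entries == {8: [(11, 1)], 20: [(7, 1)]}


class TestEffectiveParent:
    def test_single_char_separators_use_direct_parent(self, toy_ct, toy_idx):
        # leaf at bp 9 is the terminal "A%" leaf under the A-node at bp 8
        assert effective_parent(toy_idx, toy_ct, 9) == 8

    def test_non_terminal_leaf_rejected(self, toy_ct, toy_idx):
        with pytest.raises(ValueError):
            effective_parent(toy_idx, toy_ct, 11)  # "AAC#..." edge starts with 'A'
        with pytest.raises(ValueError):
            effective_parent(toy_idx, toy_ct, 8)  # internal node

    def test_multichar_separator_climbs_terminal_chain(self):
        # 3 strings sharing the suffix "CA"; with a 2-character separator
        # alphabet the blocks share digits, creating an internal node whose
        # incoming edge starts with a separator character.
        S = StringSet.from_sequences(["GCA", "TTCA", "GGCA", "AAAA", "CCCC"])
        ct, idx = _index(S, "!\"")
        assert ct.sep_len == 3
        L = fill_l_entries(idx, ct)
        # every entry's match length equals its string-suffix length and the
        # owner's incoming edge is not terminal
        for v, lst in L.items():
            for p, d in lst:
                s = ct.string_id(p)
                assert d == ct.string_end(s) - p + 1
                first = int(idx.sa[idx.first_leaf_rank(v) - 1])
                pdepth = int(idx.depth_at[idx.parent_at[v]])
                assert ct.text_bytes[first + pdepth - 1] not in ct.sep_codes

    def test_terminal_edge_to_internal_node_exists(self):
        """The multi-separator construction really produces a terminal edge
        pointing at an internal node, and the climb skips past it."""
        S = StringSet.from_sequences(["GCA", "TTCA", "GGCA", "AAAA", "CCCC"])
        ct, idx = _index(S, "!\"")
        found = False
        for r in range(1, idx.n + 1):
            leaf = idx.select_leaf(r)
            p = idx.leaf_text_pos(leaf)
            if ct.text_bytes[p - 1] in ct.sep_codes:
                continue
            par = int(idx.parent_at[leaf])
            dp = int(idx.depth_at[par])
            if p + dp <= ct.n and ct.text_bytes[p + dp - 1] in ct.sep_codes:
                ep = effective_parent(idx, ct, leaf)
                if ep != par:
                    found = True
                    assert idx.node_depth(ep) < idx.node_depth(par)
        assert found


class TestRunMethod1:
    def test_toy(self, toy_set, toy_ct, toy_idx):
        sol = run_method1(toy_idx, toy_ct, min_len=1)
        assert sol.get(3, 1) == 1
        assert int(sol.values.sum()) == 1

    def test_toy_min_len_2_all_zero(self, toy_ct, toy_idx):
        sol = run_method1(toy_idx, toy_ct, min_len=2)
        assert not sol.values.any()

    def test_acg_gacg(self):
        S = StringSet.from_sequences(["ACG", "GACG"])
        ct, idx = _index(S)
        sol = run_method1(idx, ct)
        assert sol.get(2, 1) == 3
        assert sol.get(1, 2) == 1

    def test_identical_strings_full_overlap(self):
        S = StringSet.from_sequences(["AA", "AA"])
        ct, idx = _index(S)
        sol = run_method1(idx, ct)
        assert sol.get(1, 2) == 2 and sol.get(2, 1) == 2

    def test_diagonal_never_reported(self):
        S = gen_random(6, 120, seed=11)
        ct, idx = _index(S)
        sol = run_method1(idx, ct)
        assert not np.diag(sol.values).any()


class TestVariantsAgree:
    @pytest.mark.parametrize("seed", range(3))
    def test_all_variants_equal_oracle(self, seed):
        rng = random.Random(seed)
        for t in range(25):
            k = rng.randint(1, 10)
            S = gen_random(k, rng.randint(k, 250), seed=900 + 100 * seed + t)
            min_len = rng.choice([1, 1, 2, 3])
            sep = "".join(chr(33 + i) for i in range(rng.choice([2, 3, 32])))
            ct, idx = _index(S, sep)
            L = fill_l_entries(idx, ct)
            oracle = brute_force_apsp(S, min_len)
            assert run_method1(idx, ct, L, min_len) == oracle
            assert run_method1_stackless(idx, ct, min_len) == oracle
            assert run_method1_nostacks_with_lists(idx, ct, L, min_len) == oracle

    @given(seqs=dna_sets, min_len=st.integers(1, 4))
    @settings(max_examples=40, deadline=None)
    def test_property_equivalence(self, seqs, min_len):
        S = StringSet.from_sequences(seqs)
        ct, idx = _index(S)
        oracle = brute_force_apsp(S, min_len)
        assert run_method1(idx, ct, min_len=min_len) == oracle
        assert run_method1_stackless(idx, ct, min_len=min_len) == oracle
        assert run_method1_nostacks_with_lists(idx, ct, min_len=min_len) == oracle


class TestInvariants:
    def test_min_len_monotonicity(self):
        S = gen_random(8, 200, seed=3)
        ct, idx = _index(S)
        prev = run_method1(idx, ct, min_len=1).values
        for ml in (2, 3, 5):
            cur = run_method1(idx, ct, min_len=ml).values
            assert (cur <= prev).all()
            prev = cur

    def test_bounded_by_string_lengths(self):
        S = gen_random(10, 300, seed=4)
        ct, idx = _index(S)
        sol = run_method1(idx, ct)
        lens = np.asarray(S.lengths)
        bound = np.minimum.outer(lens, lens)
        assert (sol.values <= bound).all()

    def test_push_pop_conservation(self, toy_ct, toy_idx):
        # run_method1 raises internally if stacks are non-empty at scan end;
        # a clean return certifies push/pop conservation
        run_method1(toy_idx, toy_ct)
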