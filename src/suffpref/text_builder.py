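"""Concatenated-text construction for generalized suffix indexing.

The k input strings are joined into a single text, each string followed by a
distinct *separator block*: ``m`` characters drawn from a small separator
alphabet whose every character sorts strictly below every sequence character.
String i receives the base-c expansion of ``i - 1`` (c = separator alphabet
size, most significant digit first), so separator blocks compare in input
order and a single separator alphabet of c characters suffices for up to
``c**m`` strings.

All text positions reported by this package are 1-based.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SEPARATOR",
    "DEFAULT_SEP_ALPHABET",
    "StringSet",
    "ConcatText",
    "sep_length",
    "build_concat",
    "string_id",
    "is_start",
]

#: Sentinel returned by :func:`string_id` for positions inside separator blocks.
SEPARATOR = 0

#: 32 printable ASCII characters ('!' .. '@'), all below 'A' and hence below
#: every character of the DNA alphabet (and of any uppercase-letter alphabet).
DEFAULT_SEP_ALPHABET = "".join(chr(c) for c in range(33, 65))


@dataclass(frozen=True)
class StringSet:
    """A set of k named strings over a common alphabet."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(self.seqs) < 1:
            raise ValueError("need at least one string")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("string ids must be unique")
        for sid, s in zip(self.ids, self.seqs):
            if not s:
                raise ValueError(f"sequence {sid!r} is empty")

    @classmethod
    def from_sequences(cls, seqs, ids=None) -> "StringSet":
        seqs = tuple(str(s) for s in seqs)
        if ids is None:
            ids = tuple(f"read{i}" for i in range(1, len(seqs) + 1))
        return cls(tuple(ids), seqs)

    @property
    def k(self) -> int:
        return len(self.seqs)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.seqs)


def sep_length(k: int, c: int) -> int:
    """Smallest m such that ``c**m >= k``: characters per separator block.

    With c distinct separator characters, m-character blocks can encode up to
    ``c**m`` distinct separators; e.g. 3 characters over a 200-character
    separator alphabet cover up to 200**3 = 8,000,000 strings.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if c < 2:
        raise ValueError("separator alphabet size must be >= 2")
    m, cap = 1, c
    while cap < k:
        cap *= c
        m += 1
    return m


@dataclass
class ConcatText:
    """The concatenation of a :class:`StringSet` with per-string separators.

    Attributes
    ----------
    text:
        The concatenated text, length ``n = sum(|S_i|) + k * sep_len``; a
        separator block follows every string, including the last.
    start_pos:
        1-based start position of each string in ``text`` (length k,
        strictly increasing, ``start_pos[0] == 1``).
    """

    text: str
    start_pos: np.ndarray
    lengths: np.ndarray
    sep_alphabet: str
    sep_len: int
    ids: tuple[str, ...] = ()

    # derived lookups, filled in __post_init__
    text_bytes: bytes = field(init=False, repr=False)
    sep_codes: frozenset = field(init=False, repr=False)
    _starts: list = field(init=False, repr=False)
    _ends: list = field(init=False, repr=False)
    _start_map: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.text_bytes = self.text.encode("latin-1")
        self.sep_codes = frozenset(self.sep_alphabet.encode("latin-1"))
        self._starts = [int(p) for p in self.start_pos]
        self._ends = [s + int(l) - 1 for s, l in zip(self._starts, self.lengths)]
        self._start_map = {p: i + 1 for i, p in enumerate(self._starts)}

    @property
    def k(self) -> int:
        return len(self._starts)

    @property
    def n(self) -> int:
        return len(self.text)

    def string_id(self, pos: int) -> int:
        """Source string (1..k) of text position ``pos``, or :data:`SEPARATOR`.

        Binary search over ``start_pos``; positions inside a separator block
        yield the :data:`SEPARATOR` sentinel (0) rather than an error, because
        index traversals legitimately touch separator-start suffixes.
        """
        if not 1 <= pos <= self.n:
            raise ValueError(f"position {pos} outside text of length {self.n}")
        i = bisect_right(self._starts, pos)
        return i if pos <= self._ends[i - 1] else SEPARATOR

    def is_start(self, pos: int) -> bool:
        """True iff ``pos`` is the first position of some input string."""
        if not 1 <= pos <= self.n:
            raise ValueError(f"position {pos} outside text of length {self.n}")
        return pos in self._start_map

    def string_end(self, i: int) -> int:
        """1-based position of the last character of string i."""
        return self._ends[i - 1]


def build_concat(S: StringSet, sep_alphabet: str = DEFAULT_SEP_ALPHABET) -> ConcatText:
    """Concatenate the strings of ``S`` with distinct separator blocks.

    ``sep_alphabet`` must be strictly increasing and every separator character
    must sort below every sequence character.
    """
    chars = list(sep_alphabet)
    if len(chars) < 2 and S.k > 1:
        raise ValueError("separator alphabet must contain at least 2 characters")
    if any(a >= b for a, b in zip(chars, chars[1:])):
        raise ValueError("separator alphabet must be strictly increasing")
    min_seq_char = min(min(s) for s in S.seqs)
    if chars and max(chars) >= min_seq_char:
        raise ValueError(
            f"separator {max(chars)!r} does not sort below sequence character "
            f"{min_seq_char!r}"
        )
    c = max(len(chars), 1)
    m = sep_length(S.k, c) if S.k > 1 else 1
    if not chars:
        raise ValueError("separator alphabet is empty")

    def block(i: int) -> str:
        digits = []
        x = i - 1
        for _ in range(m):
            digits.append(chars[x % c])
            x //= c
        return "".join(reversed(digits))

    pieces: list[str] = []
    starts: list[int] = []
    pos = 1
    for s in S.seqs:
        starts.append(pos)
        pieces.append(s)
        pos += len(s) + m
    blocks = [block(i) for i in range(1, S.k + 1)]
    if len(set(blocks)) != S.k:  # pragma: no cover - guarded by sep_length
        raise RuntimeError("internal error: duplicate separator blocks")
    text = "".join(p + b for p, b in zip(pieces, blocks))
    return ConcatText(
        text=text,
        start_pos=np.asarray(starts, dtype=np.int64),
        lengths=np.asarray(S.lengths, dtype=np.int64),
        sep_alphabet="".join(chars),
        sep_len=m,
        ids=S.ids,
    )


def string_id(ct: ConcatText, pos: int) -> int:
    return ct.string_id(pos)


def is_start(ct: ConcatText, pos: int) -> bool:
    return ct.is_start(pos)
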