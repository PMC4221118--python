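"""Bit-vector words: the primitive operation set and the chunking contract.

Bit ``i`` of a vector corresponds to column ``i`` (plus a layout offset) of
the alignment scoring matrix, with the low-order bit being the leftmost
column.  "Shift right" therefore means *toward higher column index*, which is
an arithmetic left shift of the payload; the operation is named by its column
semantics (:func:`bv_shift_right_in`) to avoid confusion.

Two interchangeable backends implement the same contract:

* :class:`WideEngine` -- a single arbitrary-width word (Python int).  Simple,
  and the reference semantics.
* :class:`ChunkedEngine` -- fixed-width machine words (default 64 bits)
  tiling the columns left to right, with explicit carry / evicted-bit
  chaining between chunks.  Sequences longer than one word run here.

The wide backend is the oracle for the chunked one: every composite
operation must produce bit-identical results on both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

__all__ = [
    "BitVector",
    "ChunkLayout",
    "MatchVectors",
    "bv_and",
    "bv_or",
    "bv_xor",
    "bv_not",
    "bv_add",
    "bv_shift_right_in",
    "popcount",
    "build_match_vectors",
    "WideEngine",
    "ChunkedEngine",
]


@dataclass(frozen=True)
class BitVector:
    """A canonical fixed-width word: no bits at or above ``width`` are set."""

    width: int
    value: int

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("width must be non-negative")
        if self.value < 0 or self.value >> self.width:
            raise ValueError(f"payload has bits outside [0, {self.width})")

    @classmethod
    def from_bits(cls, width: int, bits: Iterable[int]) -> "BitVector":
        v = 0
        for b in bits:
            v |= 1 << b
        return cls(width, v)

    def bits(self) -> Tuple[int, ...]:
        return tuple(i for i in range(self.width) if (self.value >> i) & 1)


def _check_widths(a: BitVector, b: BitVector) -> None:
    if a.width != b.width:
        raise ValueError(f"width mismatch: {a.width} != {b.width}")


def bv_and(a: BitVector, b: BitVector) -> BitVector:
    _check_widths(a, b)
    return BitVector(a.width, a.value & b.value)


def bv_or(a: BitVector, b: BitVector) -> BitVector:
    _check_widths(a, b)
    return BitVector(a.width, a.value | b.value)


def bv_xor(a: BitVector, b: BitVector) -> BitVector:
    _check_widths(a, b)
    return BitVector(a.width, a.value ^ b.value)


def bv_not(a: BitVector) -> BitVector:
    """Complement, masked back to the width (canonical form)."""
    return BitVector(a.width, a.value ^ ((1 << a.width) - 1))


def bv_add(a: BitVector, b: BitVector, carry_in: int = 0) -> Tuple[BitVector, int]:
    """Binary addition modulo ``2**width`` with explicit carry in/out.

    The carry bits let fixed-width words be chained into wider additions,
    which is exactly what the chunked backend does.
    """
    _check_widths(a, b)
    s = a.value + b.value + (carry_in & 1)
    return BitVector(a.width, s & ((1 << a.width) - 1)), s >> a.width


def bv_shift_right_in(a: BitVector, fill_bit: int = 0) -> Tuple[BitVector, int]:
    """Move every bit one column higher; bit 0 takes ``fill_bit``.

    Returns the shifted vector and the bit evicted past the top, for chunk
    chaining.
    """
    s = (a.value << 1) | (fill_bit & 1)
    return BitVector(a.width, s & ((1 << a.width) - 1)), s >> a.width


def popcount(a: BitVector) -> int:
    """Number of set bits."""
    return a.value.bit_count()


@dataclass(frozen=True)
class ChunkLayout:
    """How a sequence of columns tiles into fixed-width words."""

    word_width: int
    n_columns: int

    def __post_init__(self) -> None:
        if self.word_width < 1:
            raise ValueError("word_width must be positive")

    @property
    def n_chunks(self) -> int:
        return max(1, -(-self.n_columns // self.word_width))

    @property
    def last_chunk_fill(self) -> int:
        r = self.n_columns % self.word_width
        return self.word_width if (r == 0 and self.n_columns > 0) else r


MatchVectors = Dict[str, BitVector]


def build_match_vectors(
    X: str, alphabet: str = "ACGT", on_unknown: str = "ignore"
) -> MatchVectors:
    """One position mask per alphabet character, in a single pass over X.

    Bit ``i`` of ``Match[c]`` is set iff ``X[i] == c``.  Characters outside
    the alphabet either match nothing (``on_unknown="ignore"``, the
    conservative alignment semantics) or raise (``on_unknown="error"``).
    """
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    n = len(X)
    acc = {c: 0 for c in alphabet}
    for i, ch in enumerate(X):
        if ch in acc:
            acc[ch] |= 1 << i
        elif on_unknown == "error":
            raise ValueError(f"character {ch!r} at position {i} not in alphabet")
    return {c: BitVector(n, v) for c, v in acc.items()}


# ---------------------------------------------------------------------------
# engines: the raw-word backends the aligners run on.  Vectors are plain ints
# (wide) or tuples of ints (chunked) for speed; BitVector is the checked
# public wrapper above.
# ---------------------------------------------------------------------------


class WideEngine:
    """Arbitrary-width single-word backend (reference semantics)."""

    def __init__(self, width: int):
        self.width = width
        self.mask = (1 << width) - 1
        self.zero = 0

    def from_int(self, x: int) -> int:
        return x & self.mask

    def to_int(self, v: int) -> int:
        return v

    @staticmethod
    def and_(a: int, b: int) -> int:
        return a & b

    @staticmethod
    def or_(a: int, b: int) -> int:
        return a | b

    @staticmethod
    def xor(a: int, b: int) -> int:
        return a ^ b

    def not_(self, a: int) -> int:
        return a ^ self.mask

    def add(self, a: int, b: int) -> int:
        return (a + b) & self.mask

    def shift_up(self, a: int) -> int:
        """One column to the right (payload left shift)."""
        return (a << 1) & self.mask

    @staticmethod
    def shift_down(a: int) -> int:
        """One column to the left (payload right shift)."""
        return a >> 1

    @staticmethod
    def popcount(a: int) -> int:
        return a.bit_count()

    @staticmethod
    def test_bit(a: int, i: int) -> int:
        return (a >> i) & 1


class ChunkedEngine:
    """Fixed word width with explicit carry/evicted-bit chaining across chunks.

    Vectors are tuples of ``n_chunks`` words, low chunk first.  Addition
    ripples a carry from chunk to chunk; shifts chain the evicted top bit of
    one chunk into the bottom of the next.
    """

    def __init__(self, width: int, word_width: int = 64):
        self.width = width
        self.layout = ChunkLayout(word_width=word_width, n_columns=width)
        self.w = word_width
        self.nc = self.layout.n_chunks
        wm = (1 << word_width) - 1
        self.word_mask = wm
        top = width - word_width * (self.nc - 1)
        self.top_mask = (1 << top) - 1 if top < word_width else wm
        self.zero = (0,) * self.nc

    def from_int(self, x: int) -> Tuple[int, ...]:
        w, wm = self.w, self.word_mask
        out = []
        for i in range(self.nc):
            out.append((x >> (i * w)) & wm)
        out[-1] &= self.top_mask
        return tuple(out)

    def to_int(self, v: Tuple[int, ...]) -> int:
        x = 0
        for i, c in enumerate(v):
            x |= c << (i * self.w)
        return x

    @staticmethod
    def and_(a, b):
        return tuple(x & y for x, y in zip(a, b))

    @staticmethod
    def or_(a, b):
        return tuple(x | y for x, y in zip(a, b))

    @staticmethod
    def xor(a, b):
        return tuple(x ^ y for x, y in zip(a, b))

    def not_(self, a):
        wm = self.word_mask
        out = [c ^ wm for c in a]
        out[-1] &= self.top_mask
        return tuple(out)

    def add(self, a, b):
        wm, w = self.word_mask, self.w
        out = []
        carry = 0
        for x, y in zip(a, b):
            s = x + y + carry
            out.append(s & wm)
            carry = s >> w
        out[-1] &= self.top_mask
        return tuple(out)

    def shift_up(self, a):
        wm, w = self.word_mask, self.w
        out = []
        carry = 0
        for x in a:
            s = (x << 1) | carry
            out.append(s & wm)
            carry = s >> w
        out[-1] &= self.top_mask
        return tuple(out)

    def shift_down(self, a):
        w = self.w
        out = []
        for i, x in enumerate(a):
            nxt = a[i + 1] & 1 if i + 1 < self.nc else 0
            out.append((x >> 1) | (nxt << (w - 1)))
        return tuple(out)

    @staticmethod
    def popcount(a) -> int:
        return sum(c.bit_count() for c in a)

    def test_bit(self, a, i: int) -> int:
        return (a[i // self.w] >> (i % self.w)) & 1


def make_engine(width: int, word_width: int | None = None):
    """Engine factory: wide when word_width is None, chunked otherwise."""
    if word_width is None:
        return WideEngine(width)
    return ChunkedEngine(width, word_width)
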