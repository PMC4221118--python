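"""Packed variant: encodings, plane arithmetic, shared subexpressions,
and bit-identity with the standard variant."""

import pytest

from bitalign import (
    AlignmentMode,
    FixtureSpec,
    align_packed,
    align_score,
    align_score_packed,
    align_standard,
    build_pack_tree,
    build_unpack_tree,
    decode_last_row_packed,
    derive_bounds,
    make_fixtures,
    nw_score,
    pack_dv,
    packed_add,
    unpack_dh,
    validate_weights,
)
from bitalign.bitvector import WideEngine
from bitalign.standard import decode_last_row

from conftest import ALL_WEIGHTS, TABLE_WEIGHTS, all_modes

W235 = validate_weights(2, -3, -5)
B235 = derive_bounds(W235)


class TestPackUnpack:
    def test_all_min_gives_zero_planes(self):
        planes = pack_dv({B235.vmin: 0b111, **{v: 0 for v in range(-4, 8)}}, B235)
        assert planes == [0] * B235.packed_width

    def test_offset_digit_example(self):
        # dV = 5 at column 3: offset 10 = 01010b -> planes 1 and 3 carry bit 3
        dv = {v: 0 for v in range(B235.vmin, B235.vmax + 1)}
        dv[5] = 1 << 3
        dv[B235.vmin] = 0b10111  # fill the remaining columns 0,1,2,4
        planes = pack_dv(dv, B235, width=5)
        assert [(p >> 3) & 1 for p in planes] == [0, 1, 0, 1, 0]

    def test_unpack_twos_complement_example(self):
        # all five digit bits set encodes -1, i.e. dH = vmin + 1 = -4
        planes = [0b1, 0b1, 0b1, 0b1, 0b1]
        got = unpack_dh(planes, B235, values=[-4], width=1)
        assert got[-4] == 0b1
        assert unpack_dh([0] * 5, B235, values=[B235.vmin], width=3)[B235.vmin] == 0b111

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            pack_dv({-5: 0b11, -4: 0b10}, B235, width=2)

    def test_roundtrip_random_partitions(self, rng):
        values = list(range(B235.vmin, B235.vmax + 1))
        for _ in range(100):
            n = rng.randint(1, 40)
            cols = [rng.choice(values) for _ in range(n)]
            dv = {v: 0 for v in values}
            for j, v in enumerate(cols):
                dv[v] |= 1 << j
            planes = pack_dv(dv, B235, width=n)
            # use the dH two's-complement decoder through the dV mapping by
            # checking digits directly instead
            for j, v in enumerate(cols):
                raw = sum(((planes[p] >> j) & 1) << p for p in range(B235.packed_width))
                assert raw == v - B235.vmin


class TestPackedAdd:
    @pytest.mark.parametrize("triple", [(2, -3, -5), (0, -1, -1), (4, -7, -11)])
    def test_arithmetic_identity_exhaustive(self, triple):
        """Decoded sum offset equals dV - dH for every value pair."""
        w = validate_weights(*triple)
        b = derive_bounds(w)
        k = b.packed_width
        eng = WideEngine(1)
        for dv in range(b.vmin, b.vmax + 1):
            for dh in range(b.vmin, b.vmax + 1):
                a = [(dv - b.vmin) >> i & 1 for i in range(k)]
                enc = (b.vmin - dh) % (1 << k)
                bb = [(enc >> i) & 1 for i in range(k)]
                sums, sign = packed_add(a, bb, eng)
                raw = sum(s << i for i, s in enumerate(sums))
                val = raw if raw < (1 << (k - 1)) else raw - (1 << k)
                assert val == dv - dh
                assert sign == (1 if dv - dh < 0 else 0)

    def test_zone_b_and_identity_cases(self):
        # dV=5, dH=-4: 10 + (-1) = 9 -> output 9 + vmin = 4 (indel from left)
        eng = WideEngine(1)
        k = B235.packed_width
        a = [(5 - B235.vmin) >> i & 1 for i in range(k)]
        bb = [((B235.vmin - (-4)) % (1 << k)) >> i & 1 for i in range(k)]
        sums, sign = packed_add(a, bb, eng)
        assert sign == 0 and sum(s << i for i, s in enumerate(sums)) + B235.vmin == 4


class TestSubexprSharing:
    @pytest.mark.parametrize("triple", ALL_WEIGHTS)
    def test_never_worse_than_naive_and_no_duplicates(self, triple):
        w = validate_weights(*triple)
        b = derive_bounds(w)
        for tree in (
            build_pack_tree(b, list(range(b.vmin, b.vmax + 1))),
            build_unpack_tree(b, list(range(b.vmin, b.vmax + 1))),
        ):
            assert tree.op_count <= tree.naive_count
            fused = [frozenset((a, c)) for _d, a, c in tree.steps]
            assert len(fused) == len(set(fused)), "a primitive was computed twice"

    @pytest.mark.parametrize("triple", [t for t in ALL_WEIGHTS
                                        if derive_bounds(validate_weights(*t)).value_count >= 8])
    def test_strictly_better_for_large_tables(self, triple):
        # cross-plane sharing first becomes possible at eight distinct values
        w = validate_weights(*triple)
        b = derive_bounds(w)
        tree = build_pack_tree(b, list(range(b.vmin, b.vmax + 1)))
        assert tree.op_count < tree.naive_count
        tree = build_unpack_tree(b, list(range(b.vmin, b.vmax + 1)))
        assert tree.op_count < tree.naive_count


class TestCrossVariant:
    def test_scores_equal_standard_and_oracle(self):
        modes = all_modes()
        stream = make_fixtures(
            FixtureSpec(seed=77, max_len=50, n_items=120, weight_sets=tuple(ALL_WEIGHTS))
        )
        for i, (x, y, w) in enumerate(stream):
            mode = modes[i % len(modes)]
            sp = align_score_packed(x, y, w, mode)
            assert sp == align_score(x, y, w, mode)
            assert sp == nw_score(x, y, w, mode)[0]

    @pytest.mark.parametrize("triple", TABLE_WEIGHTS)
    def test_row_states_bit_identical_to_standard(self, rng, triple):
        w = validate_weights(*triple)
        for _ in range(4):
            x = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 35)))
            y = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 25)))
            std = align_standard(x, y, w, keep_states=True).row_states
            pkd = align_packed(x, y, w, keep_states=True).row_states
            for st, (pdv, pdh) in zip(std, pkd):
                assert {v: b for v, b in st.dv.items() if b} == pdv
                assert {v: b for v, b in st.dh.items() if b} == pdh

    def test_chunked_backend_matches(self, rng):
        w = validate_weights(4, -5, -9)
        x = "".join(rng.choice("ACGT") for _ in range(30))
        y = "".join(rng.choice("ACGT") for _ in range(18))
        s = align_score_packed(x, y, w)
        assert align_score_packed(x, y, w, word_width=8) == s
        assert align_score_packed(x, y, w, word_width=64) == s


class TestPackedDecode:
    def test_all_planes_zero_means_all_min(self):
        b = derive_bounds(W235)
        assert decode_last_row_packed([0] * b.packed_width, m=3, n=4, b=b, G=-5) == -35
        assert decode_last_row_packed([0] * b.packed_width, m=3, n=0, b=b, G=-5) == -15

    def test_equals_standard_decode_on_random_instances(self, rng):
        for _ in range(40):
            w = validate_weights(rng.randint(0, 4), rng.randint(-6, -1), -3)
            b = derive_bounds(w)
            x = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 30)))
            y = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 30)))
            std = align_standard(x, y, w)
            pkd = align_packed(x, y, w)
            assert decode_last_row_packed(
                pkd.final_dh_planes, len(y), len(x), b, w.G
            ) == decode_last_row(std.final_dh, len(y), len(x), w.G)
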