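"""Generated straight-line programs: semantics, determinism, op-count trends."""

from fractions import Fraction

import pytest
from scipy.stats import spearmanr

from bitalign import (
    AlignmentMode,
    BitProgram,
    FixtureSpec,
    Instruction,
    align_score,
    count_ops,
    derive_bounds,
    generate_program,
    make_fixtures,
    nw_score,
    run_alignment_program,
    run_program,
    table_size_standard,
    validate_weights,
)
from bitalign.proggen import OPCODES, parse_program, render_program

from conftest import ALL_WEIGHTS, TABLE_WEIGHTS

W235 = validate_weights(2, -3, -5)


class TestInterpreter:
    def test_single_xor_program_behaves_as_xor(self):
        prog = BitProgram(
            W235, "standard", ("a", "b"),
            (Instruction("XOR", ("a", "b"), "t1", "step1"),),
            {"r": "t1"},
        )
        assert run_program(prog, {"a": 0b1100, "b": 0b1010}, width=4) == {"r": 0b0110}

    def test_referential_transparency(self):
        prog = generate_program(W235, "standard")
        b = derive_bounds(W235)
        inputs = {f"dh[{v}]": 0 for v in range(b.vmin, b.vmax + 1)}
        inputs[f"dh[{b.vmin}]"] = 0b11110
        inputs.update({f"lm[{v}]": 0 for v in range(b.vmin, b.vmax + 1)})
        inputs[f"lm[{b.vmin}]"] = 1
        inputs.update({"match": 0b0100, "allcols": 0b11111, "cols": 0b11110})
        r1 = run_program(prog, inputs, width=6)
        r2 = run_program(prog, inputs, width=6)
        assert r1 == r2

    def test_unbound_slot_rejected(self):
        prog = generate_program(validate_weights(0, -1, -1), "standard")
        with pytest.raises(KeyError, match="unbound"):
            run_program(prog, {}, width=4)


class TestProgramShape:
    @pytest.mark.parametrize("variant", ["standard", "packed"])
    def test_deterministic_and_ssa_and_opcode_alphabet(self, variant):
        p1 = generate_program(W235, variant)
        p2 = generate_program(W235, variant)
        assert p1.instrs == p2.instrs
        seen = set(p1.inputs)
        for ins in p1.instrs:
            assert ins.op in OPCODES
            assert all(a in seen for a in ins.args), "read before write"
            assert ins.dest not in seen, "slot written twice"
            seen.add(ins.dest)

    def test_smaller_weights_give_shorter_programs(self):
        small = generate_program(validate_weights(0, -1, -1), "standard")
        large = generate_program(validate_weights(4, -7, -11), "standard")
        assert len(small) < len(large)


class TestCountOps:
    def test_empty_program(self):
        prog = BitProgram(W235, "standard", (), (), {})
        assert count_ops(prog).p == 0

    def test_four_op_recipe_efficiency_calibration(self):
        # the counting convention is calibrated so a 4-op row recipe at
        # w = 64 advances 16 cells per operation
        instrs = tuple(
            Instruction("AND", ("a", "a"), f"t{i}", "step1") for i in range(1, 5)
        )
        prog = BitProgram(W235, "standard", ("a",), instrs, {})
        rep = count_ops(prog, word_width=64)
        assert rep.p == 4 and rep.e == Fraction(16)

    def test_breakdown_sums_to_p(self):
        for variant in ("standard", "packed"):
            rep = count_ops(generate_program(W235, variant))
            assert sum(rep.breakdown.values()) == rep.p

    def test_standard_count_monotone_in_table_size(self):
        zs, ps = [], []
        for t in ALL_WEIGHTS:
            w = validate_weights(*t)
            zs.append(float(table_size_standard(w)))
            ps.append(count_ops(generate_program(w, "standard")).p)
        rho, _ = spearmanr(zs, ps)
        assert rho == 1.0

    def test_packed_grows_subquadratically_in_value_count(self):
        counts = {}
        for t in TABLE_WEIGHTS:
            w = validate_weights(*t)
            counts[derive_bounds(w).value_count] = count_ops(
                generate_program(w, "packed")
            ).p
        vc_small, vc_large = 13, 27
        ratio = counts[vc_large] / counts[vc_small]
        assert ratio < (vc_large / vc_small) ** 2

    def test_crossover_packed_wins_large_tables_only(self):
        p = {
            t: {
                v: count_ops(generate_program(validate_weights(*t), v)).p
                for v in ("standard", "packed")
            }
            for t in TABLE_WEIGHTS
        }
        assert p[(0, -1, -1)]["packed"] > p[(0, -1, -1)]["standard"]
        assert p[(4, -7, -11)]["packed"] < p[(4, -7, -11)]["standard"]


class TestSemanticEquivalence:
    """The generator is an alternative compilation path, not an alternative
    semantics: interpreted programs must reproduce the handwritten rows."""

    @pytest.mark.parametrize("variant", ["standard", "packed"])
    def test_whole_matrix_driver_matches_aligners(self, variant):
        sets = [(0, -1, -1), (2, -3, -5), (3, -4, -6), (4, -5, -9), (1, -2, -1), (2, -5, -3)]
        progs = {t: generate_program(validate_weights(*t), variant) for t in sets}
        modes = [
            AlignmentMode(fr, fc, "last_cell") for fr in ("gap", "free") for fc in ("gap", "free")
        ]
        stream = make_fixtures(
            FixtureSpec(seed=55, max_len=25, n_items=60, weight_sets=tuple(sets))
        )
        for i, (x, y, w) in enumerate(stream):
            mode = modes[i % 4]
            prog = progs[(w.M, w.I, w.G)]
            expected = align_score(x, y, w, mode)
            assert run_alignment_program(prog, x, y, mode) == expected
            assert nw_score(x, y, w, mode)[0] == expected

    def test_chunked_interpretation_matches_wide(self):
        prog = generate_program(W235, "packed")
        x, y = "GATTACAGATTACAGATT", "ACCATTGA"
        assert run_alignment_program(prog, x, y, word_width=8) == run_alignment_program(
            prog, x, y
        )


class TestListingRoundTrip:
    @pytest.mark.parametrize("variant", ["standard", "packed"])
    def test_parse_then_run_equals_run(self, variant):
        prog = generate_program(W235, variant)
        reparsed = parse_program(render_program(prog))
        assert reparsed.outputs == prog.outputs
        x, y = "ACGTGCA", "AGTC"
        assert run_alignment_program(reparsed, x, y) == run_alignment_program(prog, x, y)
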