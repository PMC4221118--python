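"""Per-weight straight-line programs of primitive word operations.

Every weight triple induces its own specialised row program (the function
table, hence the diagonal pair structure, is baked into the instruction
sequence).  :func:`generate_program` emits that program for either variant
as a branch-free instruction list over the six primitive opcodes -- AND, OR,
XOR, NOT, ADD, SHIFT -- in SSA form (every destination written once, reads
only of earlier slots).  :func:`run_program` interprets it on any engine
width, and :func:`count_ops` reports the operation count ``p`` and the
efficiency ``e = w / p`` (average matrix cells advanced per primitive
operation at word width ``w``).

Counting convention: each of the six opcodes counts as one operation; SHIFT
is counted as a logic op; stores/moves are never emitted, so they cost
nothing.  The convention is calibrated so that a four-operation row recipe
at ``w = 64`` scores ``e = 16``.

The generator is an alternative compilation path for the very same row
semantics as the handwritten modules; the suites assert bit-identical
outputs, and op counts are compared only as orderings and trends across
weight sets, since absolute counts are an artefact of emission style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

from .bitvector import make_engine
from .oracle import GLOBAL, AlignmentMode
from .packed import (
    _const_planes,
    build_pack_tree,
    build_unpack_tree,
    decode_last_row_packed,
    zone_a_dh_values,
)
from .scoring import Weights, derive_bounds
from .standard import decode_last_row

__all__ = [
    "Instruction",
    "BitProgram",
    "OpReport",
    "generate_program",
    "count_ops",
    "run_program",
    "run_alignment_program",
    "render_program",
    "parse_program",
]

OPCODES = ("AND", "OR", "XOR", "NOT", "ADD", "SHIFT")


@dataclass(frozen=True)
class Instruction:
    op: str
    args: Tuple[str, ...]
    dest: str
    tag: str
    shift_dir: int = 0  # +1 = one column right (toward higher index), -1 = back


@dataclass
class BitProgram:
    """Straight-line program specialised to one weight set and variant."""

    weights: Weights
    variant: str
    inputs: Tuple[str, ...]
    instrs: Tuple[Instruction, ...]
    outputs: Dict[str, str]  # output name -> slot holding it

    def __len__(self) -> int:
        return len(self.instrs)


@dataclass(frozen=True)
class OpReport:
    p: int
    w: int
    e: Fraction
    breakdown: Dict[str, int]


class _Emitter:
    def __init__(self, inputs: Sequence[str]):
        self.instrs: List[Instruction] = []
        self._n = 0
        self.tag = "setup"
        self.inputs = tuple(inputs)
        self._defined = set(inputs)

    def _dest(self) -> str:
        self._n += 1
        return f"t{self._n}"

    def emit(self, op: str, *args: str, shift_dir: int = 0) -> str:
        for a in args:
            if a not in self._defined:
                raise ValueError(f"slot {a!r} read before definition")
        d = self._dest()
        self.instrs.append(Instruction(op, tuple(args), d, self.tag, shift_dir))
        self._defined.add(d)
        return d

    def AND(self, a, b):
        return self.emit("AND", a, b)

    def OR(self, a, b):
        return self.emit("OR", a, b)

    def XOR(self, a, b):
        return self.emit("XOR", a, b)

    def NOT(self, a):
        return self.emit("NOT", a)

    def ADD(self, a, b):
        return self.emit("ADD", a, b)

    def SHL(self, a):  # one column to the right
        return self.emit("SHIFT", a, shift_dir=1)

    def SHR(self, a):  # one column back (unshift)
        return self.emit("SHIFT", a, shift_dir=-1)

    def fold(self, op, terms: List[str], empty: Optional[str] = None) -> str:
        if not terms:
            if empty is None:
                raise ValueError("empty fold with no identity slot")
            return empty
        acc = terms[0]
        for t in terms[1:]:
            acc = self.emit(op, acc, t)
        return acc


def _run_carry_ops(e: _Emitter, run_mask: str, shifted: str) -> str:
    seeds = e.AND(shifted, run_mask)
    return e.XOR(e.XOR(e.ADD(run_mask, seeds), run_mask), seeds)


def _emit_zone_a(
    e: _Emitter, w: Weights, dh_slot, lm_slot
) -> Tuple[Dict[int, str], Dict[int, str], str, str]:
    """Steps 1-2 shared by both variants.

    Returns (true IN slots, match-adjusted IN slots, out_max, not_matches);
    the match-adjusted vectors treat every match position as input vmax.
    """
    b = derive_bounds(w)
    vmin, vmid, vmax, G = b.vmin, b.vmid, b.vmax, w.G
    e.tag = "step1"
    seeds = e.AND("match", dh_slot(vmin))
    in_max = e.XOR(e.XOR(e.ADD(dh_slot(vmin), seeds), dh_slot(vmin)), seeds)
    out_max = e.SHR(in_max)
    dh_min_free = e.AND(dh_slot(vmin), e.NOT(out_max))
    not_matches = e.NOT("match")
    IN = {vmax: in_max}
    INp = {vmax: e.OR(in_max, "match")}
    e.tag = "step2"
    for v in range(vmax - 1, vmid, -1):
        terms = [e.AND(INp[u], dh_slot(u + G - v)) for u in range(v + 1, vmax + 1)]
        terms.append(lm_slot(v))
        pairs = e.fold("OR", terms)
        s = e.SHL(pairs)
        in_v = e.OR(s, _run_carry_ops(e, dh_min_free, s))
        IN[v] = in_v
        INp[v] = e.AND(in_v, not_matches)
    return IN, INp, out_max, not_matches


def _emit_standard(w: Weights) -> BitProgram:
    b = derive_bounds(w)
    vmin, vmid, vmax, G, I = b.vmin, b.vmid, b.vmax, w.G, w.I
    values = range(vmin, vmax + 1)
    inputs = (
        [f"dh[{v}]" for v in values]
        + [f"lm[{v}]" for v in values]
        + ["match", "allcols", "cols"]
    )
    e = _Emitter(inputs)
    dh_slot = lambda v: f"dh[{v}]"
    lm_slot = lambda v: f"lm[{v}]"
    IN, INp, out_max, not_matches = _emit_zone_a(e, w, dh_slot, lm_slot)

    out: Dict[int, str] = {}
    e.tag = "step2"
    out[vmax] = out_max
    for v in range(vmax - 1, vmid, -1):
        out[v] = e.SHR(IN[v])

    e.tag = "step3"
    high_union = e.fold("OR", [INp[v] for v in range(vmid + 1, vmax + 1)] + ["match"])
    no_high = e.NOT(high_union)
    for v in range(vmid, vmin, -1):
        terms = []
        for u in range(vmid + 1, vmax + 1):
            d = u + G - v
            if d <= vmax:
                terms.append(e.AND(INp[u], dh_slot(d)))
        terms.append(e.AND(dh_slot(I - v), no_high))
        acc = e.fold("OR", terms)
        out[v] = e.OR(acc, lm_slot(v))

    e.tag = "step4"
    union = e.fold("OR", [out[v] for v in range(vmin + 1, vmax + 1)])
    out[vmin] = e.AND("allcols", e.NOT(union))
    for v in range(vmin, vmid + 1):
        IN[v] = e.SHL(out[v])

    e.tag = "step5"
    dhd: Dict[int, str] = {}
    for d in range(vmid + 1, vmax):
        dhd[d] = e.AND(dh_slot(d), not_matches)
    dhd[vmax] = e.OR(dh_slot(vmax), "match")
    lows = e.fold("OR", [dh_slot(d) for d in range(vmin, vmid + 1)])
    dhd[vmid] = e.AND(lows, not_matches)
    new_dh: Dict[int, str] = {}
    union_terms: List[str] = []
    for v in range(vmax, vmin, -1):
        terms = []
        for u in range(vmin, vmax + 1):
            d = v - G + u
            if vmid <= d <= vmax:
                terms.append(e.AND(IN[u], dhd[d]))
        new_dh[v] = e.fold("OR", terms)
        union_terms.append(new_dh[v])
    union = e.fold("OR", union_terms)
    new_dh[vmin] = e.AND("cols", e.NOT(union))

    outputs = {f"out[{v}]": out[v] for v in values}
    outputs.update({f"dh'[{v}]": new_dh[v] for v in values})
    return BitProgram(w, "standard", tuple(inputs), tuple(e.instrs), outputs)


def _emit_packed(w: Weights) -> BitProgram:
    b = derive_bounds(w)
    vmin, vmid, vmax, G, k = b.vmin, b.vmid, b.vmax, w.G, b.packed_width
    unpack = build_unpack_tree(b, zone_a_dh_values(b, w))
    pack = build_pack_tree(b, list(range(vmid, vmax + 1)))
    inputs = (
        [f"dhp[{i}]" for i in range(k)]
        + [f"lm[{v}]" for v in range(vmid + 1, vmax + 1)]
        + [f"lmp[{i}]" for i in range(k)]
        + [f"midp[{i}]" for i in range(k)]   # enc(vmid) digit masks over cols
        + [f"maxp[{i}]" for i in range(k)]   # enc(vmax) digit masks over cols
        + [f"cmpp[{i}]" for i in range(k)]   # comparator constant digit masks
        + ["match", "cols", "zero"]
    )
    e = _Emitter(inputs)

    e.tag = "unpack"
    env: Dict[str, str] = {f"p{i}": f"dhp[{i}]" for i in range(k)}
    needed_negs = {nm for t in unpack.targets.values() for nm in t if nm.startswith("n")}
    for _dest, a, bb in unpack.steps:
        needed_negs |= {nm for nm in (a, bb) if nm.startswith("n")}
    for i in range(k):
        if f"n{i}" in needed_negs:
            env[f"n{i}"] = e.NOT(f"dhp[{i}]")
    for dest, a, bb in unpack.steps:
        env[dest] = e.AND(env[a], env[bb])
    dh_vals: Dict[int, str] = {}
    for t, operands in unpack.targets.items():
        d = int(t[1:])
        acc = e.fold("AND", [env[nm] for nm in operands], empty="cols")
        dh_vals[d] = e.AND(acc, "cols")

    _IN, INp, _out_max, not_matches = _emit_zone_a(
        e, w, lambda v: dh_vals[v], lambda v: f"lm[{v}]"
    )

    e.tag = "pack"
    high_union = e.fold("OR", list(INp.values()))
    venv: Dict[str, str] = {f"v{v}": INp[v] for v in INp}
    venv[f"v{vmid}"] = e.AND(e.NOT(high_union), "cols")
    for dest, a, bb in pack.steps:
        venv[dest] = e.OR(venv[a], venv[bb])
    dv_in = [
        e.fold("OR", [venv[nm] for nm in pack.targets[f"p{i}"]], empty="zero")
        for i in range(k)
    ]

    def adder(tag: str, a: List[str], bpl: List[str]) -> Tuple[List[str], str]:
        e.tag = tag
        out: List[str] = []
        carry = None
        for i in range(k):
            axb = e.XOR(a[i], bpl[i])
            if carry is None:
                out.append(axb)
                carry = e.AND(a[i], bpl[i])
            else:
                out.append(e.XOR(axb, carry))
                carry = e.OR(e.AND(a[i], bpl[i]), e.AND(carry, axb))
        return out, out[-1]

    sums, sign = adder("add", dv_in, [f"dhp[{i}]" for i in range(k)])
    e.tag = "clamp"
    nsign = e.NOT(sign)
    dv_out = [e.OR(e.AND(e.AND(sums[i], nsign), "cols"), f"lmp[{i}]") for i in range(k)]

    e.tag = "reencode"
    cmp_sums, cmp_sign = adder("reencode", [f"dhp[{i}]" for i in range(k)], [f"cmpp[{i}]" for i in range(k)])
    high = e.AND(cmp_sign, "cols")
    low = e.AND(e.NOT(high), "cols")
    e.tag = "reencode"
    dh_dag = []
    for i in range(k):
        kept = e.OR(e.AND(f"dhp[{i}]", high), e.AND(f"midp[{i}]", low))
        dh_dag.append(e.OR(e.AND(kept, not_matches), e.AND(f"maxp[{i}]", "match")))
    sv = [e.AND(e.SHL(p), "cols") for p in dv_out]
    sums2, sign2 = adder("add", sv, dh_dag)
    e.tag = "clamp"
    keep = e.AND(sign2, "cols")
    new_dhp = [e.AND(sums2[i], keep) for i in range(k)]

    outputs = {f"dvp[{i}]": dv_out[i] for i in range(k)}
    outputs.update({f"dhp'[{i}]": new_dhp[i] for i in range(k)})
    return BitProgram(w, "packed", tuple(inputs), tuple(e.instrs), outputs)


def generate_program(w: Weights, variant: str = "standard") -> BitProgram:
    """Emit the specialised row program for a weight set.

    Deterministic: the same weights and variant always yield an identical
    instruction list.
    """
    if variant == "standard":
        return _emit_standard(w)
    if variant == "packed":
        return _emit_packed(w)
    raise ValueError(f"unknown variant {variant!r}")


def count_ops(prog: BitProgram, word_width: int = 64) -> OpReport:
    """Count logic and addition operations and the efficiency e = w/p."""
    breakdown: Dict[str, int] = {}
    for ins in prog.instrs:
        breakdown[ins.tag] = breakdown.get(ins.tag, 0) + 1
    p = len(prog.instrs)
    return OpReport(
        p=p,
        w=word_width,
        e=Fraction(word_width, p) if p else Fraction(0),
        breakdown=breakdown,
    )


def run_program(prog: BitProgram, inputs: Dict[str, int], width: int,
                word_width: Optional[int] = None) -> Dict[str, int]:
    """Interpret a program over int payloads at the given vector width."""
    eng = make_engine(width, word_width)
    env = {}
    for name in prog.inputs:
        if name not in inputs:
            raise KeyError(f"unbound input slot {name!r}")
        env[name] = eng.from_int(inputs[name])
    for ins in prog.instrs:
        a = env[ins.args[0]]
        if ins.op == "AND":
            r = eng.and_(a, env[ins.args[1]])
        elif ins.op == "OR":
            r = eng.or_(a, env[ins.args[1]])
        elif ins.op == "XOR":
            r = eng.xor(a, env[ins.args[1]])
        elif ins.op == "NOT":
            r = eng.not_(a)
        elif ins.op == "ADD":
            r = eng.add(a, env[ins.args[1]])
        elif ins.op == "SHIFT":
            r = eng.shift_up(a) if ins.shift_dir > 0 else eng.shift_down(a)
        else:  # pragma: no cover
            raise ValueError(f"unknown opcode {ins.op}")
        env[ins.dest] = r
    return {name: eng.to_int(env[slot]) for name, slot in prog.outputs.items()}


def _standard_row_inputs(prog, b, n, dh, match_mask, leftmost):
    colmask = ((1 << n) - 1) << 1
    inputs = {f"dh[{v}]": dh[v] for v in range(b.vmin, b.vmax + 1)}
    inputs.update({f"lm[{v}]": (1 if leftmost == v else 0) for v in range(b.vmin, b.vmax + 1)})
    inputs.update({"match": match_mask, "allcols": colmask | 1, "cols": colmask})
    return inputs


def _packed_row_inputs(prog, b, n, dh_planes, match_mask, leftmost):
    colmask = ((1 << n) - 1) << 1
    k = b.packed_width
    mask_mod = 1 << k
    inputs = {f"dhp[{i}]": dh_planes[i] for i in range(k)}
    inputs.update({f"lm[{v}]": (1 if leftmost == v else 0)
                   for v in range(b.vmid + 1, b.vmax + 1)})
    lm_off = leftmost - b.vmin
    inputs.update({f"lmp[{i}]": (lm_off >> i) & 1 for i in range(k)})
    for name, const in (
        ("midp", (b.vmin - b.vmid) % mask_mod),
        ("maxp", (b.vmin - b.vmax) % mask_mod),
        ("cmpp", (b.vmid - b.vmin) % mask_mod),
    ):
        inputs.update({f"{name}[{i}]": (colmask if (const >> i) & 1 else 0) for i in range(k)})
    inputs.update({"match": match_mask, "cols": colmask, "zero": 0})
    return inputs


def run_alignment_program(
    prog: BitProgram,
    X: str,
    Y: str,
    mode: AlignmentMode = GLOBAL,
    word_width: Optional[int] = None,
) -> int:
    """Whole-matrix driver over the interpreter (last-cell score site).

    Exists to close the loop: interpreting the generated program row by row
    must reproduce the handwritten aligners exactly.
    """
    w = prog.weights
    b = derive_bounds(w)
    n, m = len(X), len(Y)
    width = n + 2
    colmask = ((1 << n) - 1) << 1
    match_masks: Dict[str, int] = {}
    for j, ch in enumerate(X):
        match_masks[ch] = match_masks.get(ch, 0) | (1 << (j + 1))
    leftmost = w.G if mode.first_column == "gap" else 0
    init_h = w.G if mode.first_row == "gap" else 0

    if prog.variant == "standard":
        dh = {v: 0 for v in range(b.vmin, b.vmax + 1)}
        dh[init_h] = colmask
        for i in range(1, m + 1):
            outs = run_program(
                prog,
                _standard_row_inputs(prog, b, n, dh, match_masks.get(Y[i - 1], 0), leftmost),
                width,
                word_width,
            )
            dh = {v: outs[f"dh'[{v}]"] for v in range(b.vmin, b.vmax + 1)}
        return decode_last_row(dh, m, n, w.G, mode.first_column)

    k = b.packed_width
    enc0 = (b.vmin - init_h) % (1 << k)
    planes = [colmask if (enc0 >> i) & 1 else 0 for i in range(k)]
    for i in range(1, m + 1):
        outs = run_program(
            prog,
            _packed_row_inputs(prog, b, n, planes, match_masks.get(Y[i - 1], 0), leftmost),
            width,
            word_width,
        )
        planes = [outs[f"dhp'[{i2}]"] for i2 in range(k)]
    return decode_last_row_packed(planes, m, n, b, w.G, mode.first_column)


def render_program(prog: BitProgram) -> str:
    """Readable pseudo-C listing of a program (documentation parity with the
    per-weight code generator the method calls for; the interpreter is the
    normative semantics)."""
    sym = {"AND": "&", "OR": "|", "XOR": "^", "ADD": "+"}
    lines = [
        f"/* weights (M={prog.weights.M}, I={prog.weights.I}, G={prog.weights.G}),"
        f" variant={prog.variant}, p={len(prog.instrs)} ops */"
    ]
    for ins in prog.instrs:
        if ins.op == "NOT":
            rhs = f"~{ins.args[0]}"
        elif ins.op == "SHIFT":
            rhs = f"{ins.args[0]} {'>>' if ins.shift_dir > 0 else '<<'} 1"
        else:
            rhs = f"{ins.args[0]} {sym[ins.op]} {ins.args[1]}"
        lines.append(f"{ins.dest} = {rhs};  /* {ins.tag} */")
    for name, slot in prog.outputs.items():
        lines.append(f"/* {name} := {slot} */")
    return "\n".join(lines) + "\n"


def parse_program(text: str) -> BitProgram:
    """Parse a :func:`render_program` listing back into a program.

    Inverse of the renderer (used to check that the emitted listing is a
    faithful serialisation: parse -> run must equal run).
    """
    import re

    head = re.search(
        r"weights \(M=(-?\d+), I=(-?\d+), G=(-?\d+)\),\s*variant=(\w+)", text
    )
    if not head:
        raise ValueError("missing program header")
    w = Weights(int(head.group(1)), int(head.group(2)), int(head.group(3)))
    variant = head.group(4)
    instrs: List[Instruction] = []
    outputs: Dict[str, str] = {}
    defined = set()
    inputs = set()

    def note(arg: str) -> str:
        if arg not in defined:
            inputs.add(arg)
        return arg

    for line in text.splitlines():
        line = line.strip()
        m = re.match(r"/\* (\S+) := (\S+) \*/$", line)
        if m:
            outputs[m.group(1)] = m.group(2)
            continue
        m = re.match(r"(\S+) = (.+);\s*/\* (\S+) \*/$", line)
        if not m:
            continue
        dest, rhs, tag = m.groups()
        shift = re.match(r"(\S+) (>>|<<) 1$", rhs)
        if shift:
            instrs.append(
                Instruction("SHIFT", (note(shift.group(1)),), dest, tag,
                            1 if shift.group(2) == ">>" else -1)
            )
        elif rhs.startswith("~"):
            instrs.append(Instruction("NOT", (note(rhs[1:]),), dest, tag))
        else:
            a, opsym, b = rhs.split(" ")
            op = {"&": "AND", "|": "OR", "^": "XOR", "+": "ADD"}[opsym]
            instrs.append(Instruction(op, (note(a), note(b)), dest, tag))
        defined.add(dest)
    return BitProgram(w, variant, tuple(sorted(inputs)), tuple(instrs), outputs)
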