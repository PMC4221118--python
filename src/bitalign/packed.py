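"""Packed bit-parallel variant: binary-digit planes instead of per-value vectors.

Instead of one vector per difference value, each column's value is spread as
binary digits across ``k = packed_width`` planes:

* dV is stored as the non-negative offset ``dV - vmin`` in ``[0, span]``;
* dH is stored as the non-positive offset ``vmin - dH`` in ``[-span, 0]``,
  two's complement at width ``k``.

With these encodings a single digit-serial plane addition computes, for every
column at once, ``(dV - vmin) + (vmin - dH) = dV - dH``, which is exactly the
indel-from-left output offset; negative sums (sign plane set) are zone D and
clamp to vmin.  Mismatch and indel-from-above cases fall out of the same add
once low dV inputs are re-binned to vmid and matches to vmax.  The zone-A
(high-value) computation is unchanged from the standard variant: those values
chain left-to-right through runs and are computed on unpacked vectors, then
packed.  The new dH row is a second addition against the re-encoded previous
dH (lows to vmid, matches to vmax), keeping only negative sums.

Packing (ORs over value vectors sharing a digit) and unpacking (ANDs of
plane literals selecting one encoded value) share intermediate vectors via
:class:`SubexprTree` so no primitive OR/AND is computed twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .bitvector import make_engine
from .oracle import GLOBAL, AlignmentMode
from .scoring import Bounds, Weights, derive_bounds

__all__ = [
    "PackedState",
    "SubexprTree",
    "build_pack_tree",
    "build_unpack_tree",
    "pack_dv",
    "unpack_dh",
    "packed_add",
    "clamp_negative_to_min",
    "reencode_low_to_mid",
    "align_score_packed",
    "align_packed",
    "decode_last_row_packed",
    "zone_a_dh_values",
]


@dataclass
class PackedState:
    """k dV digit planes (offsets) and k dH planes (two's-complement)."""

    dv_planes: List[int]
    dh_planes: List[int]
    k: int


# ---------------------------------------------------------------------------
# shared-subexpression plans for pack / unpack
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubexprTree:
    """A straight-line plan computing several OR- (or AND-) combinations.

    ``steps`` is an ordered list of fused binary ops ``(dest, a, b)`` over
    leaf names and earlier dests; ``targets`` maps each requested output to
    the operand set remaining after fusion (folded left-to-right at
    evaluation).  ``op_count`` counts every primitive binary op the plan
    performs; ``naive_count`` is what the unshared expansion would cost.
    """

    op: str
    steps: Tuple[Tuple[str, str, str], ...]
    targets: Dict[str, Tuple[str, ...]]
    op_count: int
    naive_count: int


def _greedy_cse(target_sets: Dict[str, FrozenSet[str]], op: str) -> SubexprTree:
    """Fuse the pair of operands co-occurring most often into a shared temp.

    Each fusion of a pair occurring in ``c >= 2`` target sets costs one op
    and saves ``c``, so the plan is never worse than the naive expansion and
    strictly better whenever any two targets share two operands.  Ties break
    lexicographically for determinism.
    """
    naive = sum(max(0, len(s) - 1) for s in target_sets.values())
    sets: Dict[str, FrozenSet[str]] = {t: frozenset(s) for t, s in target_sets.items()}
    steps: List[Tuple[str, str, str]] = []
    tmp_i = 0
    while True:
        counts: Dict[Tuple[str, str], int] = {}
        for s in sets.values():
            items = sorted(s)
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    p = (items[i], items[j])
                    counts[p] = counts.get(p, 0) + 1
        best = None
        for p, c in counts.items():
            if c >= 2 and (best is None or (c, p) > (best[1], best[0])):
                best = (p, c)
        if best is None:
            break
        (a, bnm), _c = best
        dest = f"_t{tmp_i}"
        tmp_i += 1
        steps.append((dest, a, bnm))
        pair = frozenset((a, bnm))
        sets = {
            t: (s - pair) | {dest} if pair <= s else s for t, s in sets.items()
        }
    op_count = len(steps) + sum(max(0, len(s) - 1) for s in sets.values())
    return SubexprTree(
        op=op,
        steps=tuple(steps),
        targets={t: tuple(sorted(s)) for t, s in sets.items()},
        op_count=op_count,
        naive_count=naive,
    )


def _eval_tree(tree: SubexprTree, eng, leaves: Dict[str, object]) -> Dict[str, object]:
    f = eng.or_ if tree.op == "OR" else eng.and_
    env = dict(leaves)
    for dest, a, b in tree.steps:
        env[dest] = f(env[a], env[b])
    out = {}
    for t, operands in tree.targets.items():
        if not operands:
            out[t] = eng.zero
            continue
        acc = env[operands[0]]
        for nm in operands[1:]:
            acc = f(acc, env[nm])
        out[t] = acc
    return out


def build_pack_tree(b: Bounds, values: Sequence[int]) -> SubexprTree:
    """Plan the OR-combinations turning value vectors into digit planes.

    Leaf names are ``v{value}``; targets are ``p{digit}`` = OR of the value
    vectors whose offset has that digit set.
    """
    targets = {
        f"p{p}": frozenset(
            f"v{v}" for v in values if ((v - b.vmin) >> p) & 1
        )
        for p in range(b.packed_width)
    }
    return _greedy_cse(targets, "OR")


def build_unpack_tree(b: Bounds, values: Sequence[int]) -> SubexprTree:
    """Plan the AND-combinations selecting specific encoded dH values.

    A column holds dH value ``d`` iff every plane digit matches the
    two's-complement encoding of ``vmin - d``; leaves are plane literals
    ``p{i}`` / ``n{i}`` (the latter complemented planes, counted once each
    where used).
    """
    k = b.packed_width
    targets = {}
    for d in values:
        enc = (b.vmin - d) % (1 << k)
        targets[f"d{d}"] = frozenset(
            (f"p{i}" if (enc >> i) & 1 else f"n{i}") for i in range(k)
        )
    return _greedy_cse(targets, "AND")


def pack_dv(dv: Dict[int, int], b: Bounds, width: Optional[int] = None) -> List[int]:
    """Pack a value->vector partition into digit planes (offset encoding).

    Checked convenience form over int payloads; the aligner evaluates the
    same plan on its engine.  Input must be a partition of the columns.
    """
    if width is None:
        width = max((x.bit_length() for x in dv.values()), default=0)
    mask = (1 << width) - 1
    union = 0
    for x in dv.values():
        if union & x:
            raise ValueError("dv vectors overlap: not a partition")
        union |= x
    if union != mask:
        raise ValueError("dv vectors do not cover all columns: not a partition")
    planes = [0] * b.packed_width
    for v, x in dv.items():
        off = v - b.vmin
        for p in range(b.packed_width):
            if (off >> p) & 1:
                planes[p] |= x
    return planes


def unpack_dh(planes: Sequence[int], b: Bounds, values: Sequence[int], width: int) -> Dict[int, int]:
    """Per requested dH value, the vector of columns carrying it."""
    mask = (1 << width) - 1
    out = {}
    for d in values:
        enc = (b.vmin - d) % (1 << b.packed_width)
        acc = mask
        for i in range(b.packed_width):
            pl = planes[i] if i < len(planes) else 0
            acc &= pl if (enc >> i) & 1 else (pl ^ mask)
        out[d] = acc
    return out


def packed_add(a_planes, b_planes, eng) -> Tuple[List[object], object]:
    """Digit-serial ripple addition of two plane sets; returns (sum, sign).

    k full-adder stages: ``s_i = a ^ b ^ c``; ``c' = (a & b) | (c & (a ^ b))``.
    The sign plane is the top sum digit (two's complement).
    """
    and_, or_, xor = eng.and_, eng.or_, eng.xor
    out = []
    carry = eng.zero
    for a, b2 in zip(a_planes, b_planes):
        axb = xor(a, b2)
        out.append(xor(axb, carry))
        carry = or_(and_(a, b2), and_(carry, axb))
    return out, out[-1]


def clamp_negative_to_min(sum_planes, sign, eng) -> List[object]:
    """Columns with the sign bit set are zone D: rewrite to offset 0 (vmin)."""
    ns = eng.not_(sign)
    return [eng.and_(p, ns) for p in sum_planes]


def _const_planes(value: int, k: int, mask_vec, eng) -> List[object]:
    """Planes encoding a two's-complement constant on every masked column."""
    enc = value % (1 << k)
    return [mask_vec if (enc >> i) & 1 else eng.zero for i in range(k)]


def reencode_low_to_mid(dh_planes, b: Bounds, eng, colmask_vec, matches=None):
    """Rewrite every column with dH <= vmid to vmid's encoding (and matches to vmax).

    High columns are detected with a k-stage constant-add comparator: the
    sign of ``enc + (I - 2G)`` is set exactly when ``dH > vmid``.  This keeps
    everything in plane form instead of unpacking each high value.
    """
    k = b.packed_width
    # enc >= 2G - I  <=>  dH <= mid ; comparator adds -(2G - I) = I - 2G >= 0
    cmp_const = _const_planes(b.span - (b.vmax - b.vmid), k, colmask_vec, eng)
    # span - (vmax - vmid) = vmid - vmin = I - 2G
    _s, sign = packed_add(dh_planes, cmp_const, eng)
    high = eng.and_(sign, colmask_vec)  # sign set <=> enc < 2G-I <=> dH > vmid
    low = eng.and_(eng.not_(high), colmask_vec)
    mid_digits = _const_planes(b.vmin - b.vmid, k, colmask_vec, eng)
    out = [
        eng.or_(eng.and_(p, high), eng.and_(md, low))
        for p, md in zip(dh_planes, mid_digits)
    ]
    if matches is not None:
        nm = eng.not_(matches)
        max_digits = _const_planes(b.vmin - b.vmax, k, colmask_vec, eng)
        out = [
            eng.or_(eng.and_(p, nm), eng.and_(xd, matches))
            for p, xd in zip(out, max_digits)
        ]
    return out


def zone_a_dh_values(b: Bounds, w: Weights) -> List[int]:
    """The dH values steps 1-2 actually consume, hence what gets unpacked.

    Step 1 needs vmin; step-2 diagonal pairs producing high output ``v`` from
    input ``u`` consume ``dH = u + G - v`` for ``vmid < v < u <= vmax``, i.e.
    every value in ``[vmin + 1, min(vmax, M - I + G - 1)]``.
    """
    hi = min(b.vmax, w.M - w.I + w.G - 1)
    return [b.vmin] + list(range(b.vmin + 1, hi + 1))


@dataclass
class _PackedPlans:
    unpack: SubexprTree
    pack: SubexprTree
    b: Bounds


def _make_plans(w: Weights) -> _PackedPlans:
    b = derive_bounds(w)
    unpack = build_unpack_tree(b, zone_a_dh_values(b, w))
    pack_values = list(range(b.vmid, b.vmax + 1))  # mid + the high values
    return _PackedPlans(unpack=unpack, pack=build_pack_tree(b, pack_values), b=b)


def _packed_row_update(eng, b: Bounds, w: Weights, plans: _PackedPlans,
                       dh_planes, matches, leftmost: int, colmask: int):
    """One packed row: previous dH planes -> (dV offset planes, new dH planes).

    Returns dV planes in *output* coordinates with bit 0 holding the leftmost
    value's offset digits.
    """
    from .standard import _run_carry, step1_dvmax  # zone A is shared by design

    vmid, vmax, vmin, k = b.vmid, b.vmax, b.vmin, b.packed_width
    G = w.G
    and_, or_, not_, shl = eng.and_, eng.or_, eng.not_, eng.shift_up
    cols = eng.from_int(colmask)
    one0 = eng.from_int(1)

    # unpack the dH values zone A consumes
    leaves = {f"p{i}": dh_planes[i] for i in range(k)}
    for i in range(k):
        leaves[f"n{i}"] = not_(dh_planes[i])
    dh_vals = _eval_tree(plans.unpack, eng, leaves)
    dh = {int(t[1:]): and_(vec, cols) for t, vec in dh_vals.items()}

    # zone A, standard form (steps 1 and 2)
    dh_min = dh[vmin]
    in_max = step1_dvmax(eng, dh_min, matches)
    out_max = eng.shift_down(in_max)
    dh_min_free = and_(dh_min, not_(out_max))
    not_matches = not_(matches)
    INp = {vmax: or_(in_max, matches)}
    for v in range(vmax - 1, vmid, -1):
        pairs = eng.zero
        for u in range(v + 1, vmax + 1):
            pairs = or_(pairs, and_(INp[u], dh[u + G - v]))
        if leftmost == v:
            pairs = or_(pairs, one0)
        s = shl(pairs)
        in_v = or_(s, _run_carry(eng, dh_min_free, s))
        INp[v] = and_(in_v, not_matches)

    # pack the dV inputs: high values as computed, matches as vmax,
    # everything else as vmid
    high_union = eng.zero
    for vec in INp.values():
        high_union = or_(high_union, vec)
    val_leaves = {f"v{v}": INp.get(v, eng.zero) for v in range(vmid + 1, vmax + 1)}
    val_leaves[f"v{vmid}"] = and_(not_(high_union), cols)
    packed_in = _eval_tree(plans.pack, eng, val_leaves)
    dv_in_planes = [packed_in[f"p{i}"] for i in range(k)]

    # first addition: dV outputs for zones B, C, D (and, consistently, A)
    sums, sign = packed_add(dv_in_planes, dh_planes, eng)
    dv_out = clamp_negative_to_min(sums, sign, eng)
    dv_out = [and_(p, cols) for p in dv_out]
    # leftmost offset digits occupy bit 0 of the output planes
    lm_off = leftmost - vmin
    for i in range(k):
        if (lm_off >> i) & 1:
            dv_out[i] = or_(dv_out[i], one0)

    # second addition: new dH from re-encoded previous dH and shifted dV
    dh_dag = reencode_low_to_mid(dh_planes, b, eng, cols, matches=matches)
    sv = [and_(shl(p), cols) for p in dv_out]
    sums2, sign2 = packed_add(sv, dh_dag, eng)
    keep = and_(sign2, cols)
    new_dh = [and_(p, keep) for p in sums2]
    return dv_out, new_dh


@dataclass
class PackedResult:
    score: int
    final_dh_planes: List[int]
    k: int
    row_states: Optional[List[Tuple[Dict[int, int], Dict[int, int]]]] = field(default=None)


def _decode_planes_to_values(planes: List[int], b: Bounds, positions, dh: bool) -> Dict[int, int]:
    """Test/inspection helper: planes -> value->bitmask dict (independent of
    the unpack plan; reads digits column by column)."""
    k = b.packed_width
    out: Dict[int, int] = {}
    for j in positions:
        raw = 0
        for i in range(k):
            raw |= ((planes[i] >> j) & 1) << i
        if dh:
            enc = raw if raw < (1 << (k - 1)) else raw - (1 << k)
            v = b.vmin - enc
        else:
            v = b.vmin + raw
        out.setdefault(v, 0)
        out[v] |= 1 << j
    return out


def align_packed(
    X: str,
    Y: str,
    w: Weights,
    mode: AlignmentMode = GLOBAL,
    word_width: Optional[int] = None,
    keep_states: bool = False,
) -> PackedResult:
    """Drive the packed row computation over all rows of Y."""
    b = derive_bounds(w)
    plans = _make_plans(w)
    n, m = len(X), len(Y)
    k = b.packed_width
    eng = make_engine(n + 2, word_width)
    colmask = ((1 << n) - 1) << 1

    alphabet = "".join(dict.fromkeys(X + Y)) or "A"
    match_masks = {c: 0 for c in alphabet}
    for j, ch in enumerate(X):
        match_masks[ch] |= 1 << (j + 1)
    match_vecs = {c: eng.from_int(v) for c, v in match_masks.items()}

    init_h = w.G if mode.first_row == "gap" else 0
    cols = eng.from_int(colmask)
    dh_planes = _const_planes(b.vmin - init_h, k, cols, eng)
    leftmost = w.G if mode.first_column == "gap" else 0

    s_corner = n * w.G if mode.first_row == "gap" else 0
    best_last_col = s_corner
    states = []
    for i in range(1, m + 1):
        mv = match_vecs.get(Y[i - 1], eng.zero)
        dv_out, dh_planes = _packed_row_update(
            eng, b, w, plans, dh_planes, mv, leftmost, colmask
        )
        if mode.score_site == "best_in_last_column" or keep_states:
            raw = 0
            for p in range(k):
                raw |= eng.test_bit(dv_out[p], n) << p
            s_corner += b.vmin + raw
            if s_corner > best_last_col:
                best_last_col = s_corner
        if keep_states:
            dv_ints = [eng.to_int(p) for p in dv_out]
            dh_ints = [eng.to_int(p) for p in dh_planes]
            states.append(
                (
                    _decode_planes_to_values(dv_ints, b, range(n + 1), dh=False),
                    _decode_planes_to_values(dh_ints, b, range(1, n + 1), dh=True),
                )
            )

    final = [eng.to_int(p) for p in dh_planes]
    if mode.score_site == "last_cell":
        score = decode_last_row_packed(final, m, n, b, w.G, mode.first_column)
    elif mode.score_site == "best_in_last_row":
        dhvals = _decode_planes_to_values(final, b, range(1, n + 1), dh=True)
        per_col = {}
        for v, bits in dhvals.items():
            for j in range(1, n + 1):
                if (bits >> j) & 1:
                    per_col[j] = v
        base = m * w.G if mode.first_column == "gap" else 0
        best = acc = base
        for j in range(1, n + 1):
            acc += per_col[j]
            if acc > best:
                best = acc
        score = best
    else:
        score = best_last_col
    return PackedResult(score=score, final_dh_planes=final, k=k,
                        row_states=states if keep_states else None)


def align_score_packed(
    X: str,
    Y: str,
    w: Weights,
    mode: AlignmentMode = GLOBAL,
    word_width: Optional[int] = None,
) -> int:
    """Exact optimal alignment score via the packed bit-parallel rows."""
    return align_packed(X, Y, w, mode, word_width).score


def decode_last_row_packed(
    planes: Sequence[int], m: int, n: int, b: Bounds, G: int, first_column: str = "gap"
) -> int:
    """Score at (m, n) from the final packed dH planes via k popcounts.

    The planes hold ``vmin - dH`` in two's complement, so the digit-weighted
    popcount sum is corrected by ``2^k`` per column with a nonzero (negative)
    encoding: ``S = base + n*G + 2^k * #nonzero - sum_i 2^i * popcount(plane_i)``.
    """
    base = m * G if first_column == "gap" else 0
    k = b.packed_width
    nonzero = 0
    for p in planes:
        nonzero |= p
    total = sum((1 << i) * planes[i].bit_count() for i in range(len(planes)))
    return base + n * G + (1 << k) * nonzero.bit_count() - total
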