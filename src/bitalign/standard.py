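"""Standard bit-parallel row computation: one bit-vector per difference value.

Layout used throughout: for a horizontal sequence X of length n, vectors are
``n + 2`` bits wide.  Bit ``j`` (1 <= j <= n) is column ``j`` of the scoring
matrix; bit 0 is the boundary column 0 (whose dV is the known ``leftmost``
value); bit ``n + 1`` only ever appears transiently in shifted vectors.

Two coordinate flavours appear per row:

* *output* (OUT) vectors -- bit j set means column j's dV equals the vector's
  value; bit 0 carries the leftmost value;
* *input* (IN) vectors -- OUT shifted one column right, so bit j means "the
  dV input entering column j is this value".  These are what the diagonal
  (dV, dH) pair intersections consume, exactly as the row recurrence does.

The row proceeds: Step 1 finds dV = vmax locations (matches on dH = vmin runs,
carried through the run by one addition); Step 2 fills the remaining high
values in descending order (diagonal pairs, then run carries); Step 3 fills
the low values from zone-B pairs and zone-C dH-only terms; Step 4 assigns
vmin to everything left; Step 5 produces the new dH row from the transposed
table after re-binning the previous row's dH (matches to vmax, lows to vmid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .bitvector import make_engine
from .oracle import GLOBAL, AlignmentMode
from .scoring import Bounds, Weights, derive_bounds

__all__ = [
    "RowStateStandard",
    "align_score",
    "align_standard",
    "AlignmentResult",
    "decode_last_row",
    "step1_dvmax",
]


@dataclass
class RowStateStandard:
    """Decoded per-row state: value -> set-bit int, plus bookkeeping."""

    dv: Dict[int, int]
    dh: Dict[int, int]
    row_index: int
    leftmost_dv: int


@dataclass
class AlignmentResult:
    score: int
    final_dh: Dict[int, int]
    row_states: Optional[List[RowStateStandard]] = field(default=None)


def step1_dvmax(eng, dh_min, matches):
    """Steps 1A/1B: locations whose dV output is vmax, already shifted right.

    Four operations: AND picks matches sitting on dH=vmin; ADD carries vmax
    through the remainder of each run (erroneously flipping bits between
    multiple matches of one run); XOR with dH_min complements the run
    interior; XOR with the initial match seeds repairs the erroneous flips
    and completes the one-column shift.
    """
    seeds = eng.and_(matches, dh_min)
    return eng.xor(eng.xor(eng.add(dh_min, seeds), dh_min), seeds)


def _run_carry(eng, dh_min_free, shifted_inputs):
    """Step 2B-style carry of one value through runs of dH=vmin.

    ``shifted_inputs`` holds the columns whose dV *input* is the value being
    processed.  ``dh_min_free`` is the dH=vmin mask with the columns already
    claimed by vmax removed -- removal *before* the addition truncates each
    run at a claimed match column, so the carry cannot ripple past it.  The
    two XORs trim the same artefacts as in step 1.  Result stays in shifted
    (input) coordinates.
    """
    seeds = eng.and_(shifted_inputs, dh_min_free)
    return eng.xor(eng.xor(eng.add(dh_min_free, seeds), dh_min_free), seeds)


def _row_update(eng, b: Bounds, w: Weights, dh, matches, leftmost: int, colmask: int):
    """One full row: previous-row dH vectors -> (OUT dv, IN dv, new dH).

    ``dh`` maps value -> engine vector over bits 1..n.  ``matches`` is the
    row's match mask over bits 1..n.  Returns (out, new_dh) with ``out`` in
    output coordinates (bit 0 = leftmost) and ``new_dh`` over bits 1..n.
    """
    vmin, vmid, vmax = b.vmin, b.vmid, b.vmax
    G = w.G
    and_, or_, xor, not_ = eng.and_, eng.or_, eng.xor, eng.not_
    shl, shr = eng.shift_up, eng.shift_down
    one0 = eng.from_int(1)  # bit 0

    dh_min = dh[vmin]
    # --- step 1: dV = vmax ------------------------------------------------
    in_max = step1_dvmax(eng, dh_min, matches)
    out_max = shr(in_max)
    dh_min_free = and_(dh_min, not_(out_max))  # min-columns not claimed by vmax
    not_matches = not_(matches)

    IN: Dict[int, object] = {vmax: in_max}
    # match-adjusted inputs: a match behaves as an input vmax regardless of
    # the true dV to its left.
    INp: Dict[int, object] = {vmax: or_(in_max, matches)}

    # --- step 2: remaining high values, descending ------------------------
    for v in range(vmax - 1, vmid, -1):
        pairs = eng.zero
        for u in range(v + 1, vmax + 1):
            d = u + G - v  # dH value on the shared diagonal
            pairs = or_(pairs, and_(INp[u], dh[d]))
        if leftmost == v:
            pairs = or_(pairs, one0)
        s = shl(pairs)
        carried = _run_carry(eng, dh_min_free, s)
        in_v = or_(s, carried)
        IN[v] = in_v
        INp[v] = and_(in_v, not_matches)

    # columns with no high dV input and no match: zone C applies there
    high_union = INp[vmax]
    for v in range(vmax - 1, vmid, -1):
        high_union = or_(high_union, INp[v])
    no_high = not_(or_(high_union, matches))

    out: Dict[int, object] = {v: shr(IN[v]) for v in IN}
    # --- step 3: low values (zones B and C) -------------------------------
    for v in range(vmid, vmin, -1):
        acc = eng.zero
        for u in range(vmid + 1, vmax + 1):  # zone B diagonal pairs
            d = u + G - v
            if d <= vmax:
                acc = or_(acc, and_(INp[u], dh[d]))
        acc = or_(acc, and_(dh[w.I - v], no_high))  # zone C: dH alone
        out[v] = acc
    # leftmost lands in output coordinates at bit 0 (high values already
    # received it through their shifted pair vectors; leftmost == vmin falls
    # out of the step-4 complement by itself)
    if vmin < leftmost <= vmid:
        out[leftmost] = or_(out[leftmost], one0)

    # --- step 4: dV = vmin everywhere still unassigned --------------------
    union = eng.zero
    for v in range(vmin + 1, vmax + 1):
        union = or_(union, out[v])
    allcols = eng.from_int(colmask | 1)  # columns 0..n
    out[vmin] = and_(allcols, not_(union))

    for v in range(vmin, vmid + 1):
        IN[v] = shl(out[v])

    # --- step 5: new dH row ----------------------------------------------
    # re-bin previous dH: matches -> vmax, all lows -> vmid
    dhd: Dict[int, object] = {}
    for d in range(vmid + 1, vmax):
        dhd[d] = and_(dh[d], not_matches)
    dhd[vmax] = or_(dh[vmax], matches)
    lows = dh[vmin]
    for d in range(vmin + 1, vmid + 1):
        lows = or_(lows, dh[d])
    dhd[vmid] = and_(lows, not_matches)

    new_dh: Dict[int, object] = {}
    union = eng.zero
    for v in range(vmax, vmin, -1):
        acc = eng.zero
        for u in range(vmin, vmax + 1):
            d = v - G + u  # dH-dagger value on the shared (transposed) diagonal
            if vmid <= d <= vmax:
                acc = or_(acc, and_(IN[u], dhd[d]))
        new_dh[v] = acc
        union = or_(union, acc)
    cols = eng.from_int(colmask)
    new_dh[vmin] = and_(cols, not_(union))
    return out, new_dh


def _decode_columns(eng, vec_map: Dict[int, object], positions: range) -> List[int]:
    """Per-column values from a value->vector partition (test/decode helper)."""
    vals: Dict[int, int] = {}
    for v, vec in vec_map.items():
        x = eng.to_int(vec)
        while x:
            low = x & -x
            vals[low.bit_length() - 1] = v
            x ^= low
    return [vals[j] for j in positions]


def decode_last_row(dh: Dict[int, int], m: int, n: int, G: int, first_column: str = "gap") -> int:
    """Score at (m, n) from the final dH row by popcounts.

    ``S[m,n] = m*G + sum_v v * popcount(dH_v)`` for a gap-initialised first
    column; a free first column replaces ``m*G`` with 0.  ``dh`` maps value
    -> int payload over bits 1..n.
    """
    base = m * G if first_column == "gap" else 0
    return base + sum(v * x.bit_count() for v, x in dh.items())


def align_standard(
    X: str,
    Y: str,
    w: Weights,
    mode: AlignmentMode = GLOBAL,
    word_width: Optional[int] = None,
    keep_states: bool = False,
    alphabet: Optional[str] = None,
    on_unknown: str = "ignore",
) -> AlignmentResult:
    """Drive the standard row computation over all rows of Y.

    X is the horizontal sequence (packed into bit positions), Y the vertical
    one.  ``word_width`` selects the chunked backend (None = single wide
    word).  With ``keep_states`` the decoded per-row dV/dH partitions are
    retained for inspection/testing.
    """
    b = derive_bounds(w)
    n, m = len(X), len(Y)
    eng = make_engine(n + 2, word_width)
    colmask = ((1 << n) - 1) << 1  # bits 1..n

    if alphabet is None:
        alphabet = "".join(dict.fromkeys(X + Y)) or "A"
    elif on_unknown == "error":
        bad = {c for c in X + Y if c not in alphabet}
        if bad:
            raise ValueError(f"characters outside alphabet: {sorted(bad)!r}")
    # match masks shifted into layout coords (bit j = column j, 1-based)
    match_masks = {c: 0 for c in alphabet}
    for j, ch in enumerate(X):
        if ch in match_masks:
            match_masks[ch] |= 1 << (j + 1)
    zero_match = eng.zero
    match_vecs = {c: eng.from_int(v) for c, v in match_masks.items()}

    init_h = w.G if mode.first_row == "gap" else 0
    dh = {v: eng.zero for v in range(b.vmin, b.vmax + 1)}
    dh[init_h] = eng.from_int(colmask)
    leftmost = w.G if mode.first_column == "gap" else 0

    s_corner = n * w.G if mode.first_row == "gap" else 0  # S[i, n] running value
    best_last_col = s_corner
    states: List[RowStateStandard] = []
    for i in range(1, m + 1):
        mv = match_vecs.get(Y[i - 1], zero_match)
        out, dh = _row_update(eng, b, w, dh, mv, leftmost, colmask)
        if mode.score_site == "best_in_last_column" or keep_states:
            # dV at column n for the last-column score chain
            for v, vec in out.items():
                if eng.test_bit(vec, n):
                    s_corner += v
                    break
            if s_corner > best_last_col:
                best_last_col = s_corner
        if keep_states:
            states.append(
                RowStateStandard(
                    dv={v: eng.to_int(vec) for v, vec in out.items()},
                    dh={v: eng.to_int(vec) for v, vec in dh.items()},
                    row_index=i,
                    leftmost_dv=leftmost,
                )
            )

    final_dh = {v: eng.to_int(vec) for v, vec in dh.items()}
    if mode.score_site == "last_cell":
        score = decode_last_row(final_dh, m, n, w.G, mode.first_column)
    elif mode.score_site == "best_in_last_row":
        base = m * w.G if mode.first_column == "gap" else 0
        best = acc = base
        for h in _decode_columns(eng, dh, range(1, n + 1)):
            acc += h
            if acc > best:
                best = acc
        score = best
    else:
        score = best_last_col
    return AlignmentResult(score=score, final_dh=final_dh, row_states=states if keep_states else None)


def align_score(
    X: str,
    Y: str,
    w: Weights,
    mode: AlignmentMode = GLOBAL,
    word_width: Optional[int] = None,
) -> int:
    """Exact optimal alignment score via the standard bit-parallel rows."""
    return align_standard(X, Y, w, mode, word_width).score
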