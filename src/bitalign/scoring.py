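"""Integer scoring model and the difference-value function table.

Global alignment with weights ``M`` (match, >= 0), ``I`` (mismatch, < 0) and
``G`` (gap/indel, < 0) never needs the score matrix ``S`` itself: adjacent
cells differ by a bounded amount, so it suffices to track the vertical and
horizontal differences

    dV[i, j] = S[i, j] - S[i-1, j]        dH[i, j] = S[i, j] - S[i, j-1]

both of which always lie in ``[G, M-G]``.  The update of a single cell is a
finite function of ``(dV to the left, dH above, match?)`` -- the *function
table* built here.  The table splits into zones by which recurrence candidate
wins: a high left value carried over (A), an indel from the left (B), a
mismatch, where the output depends on dH alone (C), or an indel from above,
where the output is pinned at ``G`` (D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

__all__ = [
    "Weights",
    "Bounds",
    "FunctionTable",
    "validate_weights",
    "derive_bounds",
    "build_delta_v_table",
    "transpose_table",
    "table_size_standard",
]

#: zone labels; "border" marks ties between zones (the numeric output is
#: unambiguous there, only the attribution is).
ZONE_LABELS = ("A", "B", "C", "D", "border")


@dataclass(frozen=True)
class Weights:
    """A validated (match, mismatch, gap) integer weight triple."""

    M: int
    I: int
    G: int

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError(f"match weight must satisfy M >= 0, got M={self.M}")
        if self.I >= 0:
            raise ValueError(f"mismatch weight must satisfy I < 0, got I={self.I}")
        if self.G >= 0:
            raise ValueError(f"gap weight must satisfy G < 0, got G={self.G}")
        if self.I < 2 * self.G:
            raise ValueError(
                f"mismatch must be no worse than two adjacent gaps, "
                f"I >= 2G violated ({self.I} < {2 * self.G})"
            )


def validate_weights(M: int, I: int, G: int) -> Weights:
    """Validate a weight triple, naming the violated inequality on rejection.

    The constraints are ``M >= 0``, ``I < 0``, ``G < 0`` and ``I >= 2G``
    (a mismatch may never cost more than a pair of adjacent gaps, one in
    each sequence, which could always replace it).
    """
    return Weights(int(M), int(I), int(G))


@dataclass(frozen=True)
class Bounds:
    """Derived constants of a weight set.

    vmin/vmid/vmax are the minimum, zone-boundary and maximum difference
    values (``G``, ``I-G``, ``M-G``); ``value_count`` is the number of
    distinct difference values (= vectors per difference matrix in the
    standard representation); ``packed_width`` is the number of binary-digit
    planes needed to hold sums in ``[-(vmax-vmin), vmax-vmin]`` in two's
    complement.
    """

    vmin: int
    vmid: int
    vmax: int
    value_count: int
    packed_width: int
    span: int


def derive_bounds(w: Weights) -> Bounds:
    """Compute the difference-value bounds for a weight set."""
    vmin = w.G
    vmid = w.I - w.G
    vmax = w.M - w.G
    span = vmax - vmin  # == M - 2G
    k = (2 * span + 1).bit_length()  # ceil(log2(2*span + 1)); 2*span+1 never a power of 2
    return Bounds(
        vmin=vmin,
        vmid=vmid,
        vmax=vmax,
        value_count=span + 1,
        packed_width=k,
        span=span,
    )


@dataclass
class FunctionTable:
    """Dense map ``(dv_left, dh_above, is_match) -> dv_out`` with zone labels.

    The transpose of this table (input roles swapped) gives the dH update.
    The table is materialised over the full value square, including pairs
    unreachable in valid alignments, which keeps transposition and
    brute-force checking trivial.
    """

    weights: Weights
    bounds: Bounds
    dv_out: Dict[Tuple[int, int, bool], int] = field(repr=False)
    zone: Dict[Tuple[int, int, bool], str] = field(repr=False)

    def __call__(self, dv_left: int, dh_above: int, is_match: bool) -> int:
        return self.dv_out[(dv_left, dh_above, bool(is_match))]


def _cell_candidates(w: Weights, dv: int, dh: int, is_match: bool):
    """Yield (value, zone_label) for every recurrence case whose condition holds.

    Cases mirror the difference recurrence: match (wins outright when present),
    mismatch when mid >= dv and mid >= dh, indel-from-above when dh dominates,
    indel-from-left when dv dominates.  On zone borders several cases fire;
    they provably agree numerically (asserted at build time).
    """
    mid = w.I - w.G
    if is_match:
        # A match dominates every alternative: M >= dh+G and M >= dv+G since
        # dh, dv <= M-G.  It behaves exactly like an input dv = vmax.
        out = w.M - dh
        yield out, ("A" if out > mid else "B")
        return
    if mid >= dh and mid >= dv:
        yield w.I - dh, "C"
    if dh >= mid and dh >= dv:
        yield w.G, "D"
    if dv >= mid and dv >= dh:
        out = dv + w.G - dh
        yield out, ("A" if out > mid else "B")


def build_delta_v_table(w: Weights) -> FunctionTable:
    """Build the dense dV function table for a weight set.

    Every output is the (unique) value of the applicable recurrence cases;
    where several cases apply (zone borders) they are checked to agree and
    the entry is labelled ``border``.
    """
    b = derive_bounds(w)
    dv_out: Dict[Tuple[int, int, bool], int] = {}
    zone: Dict[Tuple[int, int, bool], str] = {}
    values = range(b.vmin, b.vmax + 1)
    for dv in values:
        for dh in values:
            for is_match in (False, True):
                cands = list(_cell_candidates(w, dv, dh, is_match))
                outs = {v for v, _ in cands}
                if len(outs) != 1:
                    raise AssertionError(
                        f"zone border disagreement at (dv={dv}, dh={dh}): {cands}"
                    )
                (out,) = outs
                if not b.vmin <= out <= b.vmax:
                    raise AssertionError(f"output {out} escapes [{b.vmin}, {b.vmax}]")
                labels = {z for _, z in cands}
                dv_out[(dv, dh, is_match)] = out
                zone[(dv, dh, is_match)] = labels.pop() if len(labels) == 1 else "border"
    return FunctionTable(weights=w, bounds=b, dv_out=dv_out, zone=zone)


def transpose_table(t: FunctionTable) -> FunctionTable:
    """Swap the input roles of dV and dH; this drives the dH update (Step 5)."""
    dv_out = {(dh, dv, m): out for (dv, dh, m), out in t.dv_out.items()}
    zone = {(dh, dv, m): z for (dv, dh, m), z in t.zone.items()}
    return FunctionTable(weights=t.weights, bounds=t.bounds, dv_out=dv_out, zone=zone)


def table_size_standard(w: Weights):
    """A-priori size estimate for the standard variant's per-row work.

    Evaluates ((M-2G+1)^2 - (I-2G)^2) / 2 -- the combined size of zones A, B
    and C with C collapsed to one row.  This is an estimate used for scaling
    discussions only; operation counts are always measured on generated
    programs, never read off this formula.  Returns an int when the value is
    integral (it is whenever M - I is odd), else the exact .5 float.
    """
    a = w.M - 2 * w.G + 1
    c = w.I - 2 * w.G
    num = a * a - c * c
    return num // 2 if num % 2 == 0 else num / 2


def dump_table_tsv(t: FunctionTable, is_match: bool = False) -> str:
    """Debug dump: rows = dv_left, columns = dh_above, entries = dv_out."""
    b = t.bounds
    vals = list(range(b.vmin, b.vmax + 1))
    lines = ["dv\\dh\t" + "\t".join(map(str, vals))]
    for dv in vals:
        row = [str(t.dv_out[(dv, dh, is_match)]) for dh in vals]
        lines.append(f"{dv}\t" + "\t".join(row))
    return "\n".join(lines) + "\n"
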