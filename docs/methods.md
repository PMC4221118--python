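# Methods

## Model and assumptions

bitalign computes optimal global / semi-global pairwise alignment scores
under a three-weight integer scoring scheme: `M >= 0` for a match, `I < 0`
for a mismatch, `G < 0` for an indel, with the admissibility constraint
`I >= 2G` (otherwise a mismatch would always be replaced by two adjacent
gaps and the scheme degenerates). Both boundary cases are accepted: `I = 2G`
(no preference for mismatches over gap pairs; the mismatch zone of the
update function collapses) and `M = 0` (matches are free, the unit-cost
edit-distance family). Per-pair substitution tables (PAM/BLOSUM), affine
gaps, local alignment and traceback are out of scope: the method scores
alignments without reconstructing them.

Only score *differences* are stored: `dV[i,j] = S[i,j] - S[i-1,j]` and
`dH[i,j] = S[i,j] - S[i,j-1]`, which provably lie in `[G, M-G]`
(`vmin..vmax`, with `vmid = I - G` the boundary between the "low" and
"high" sub-ranges). The per-cell update is the finite function

```
dV_out(dv_left, dh_above, match) = max(sub, dh_above + G, dv_left + G) - dh_above
```

with `sub = M` on a match and `I` otherwise; the dH update is the same
function with the input roles swapped (the transposed function table). The
function table is materialised densely over the whole value square — also
at input pairs unreachable in real alignments — because that makes
transposition and brute-force validation trivial; unreachable entries cost
nothing at alignment time. Where several recurrence cases tie (zone
borders), all candidates are evaluated and asserted numerically equal; such
entries carry the zone label `border`.

One deliberate correction to a tempting generalisation: the `dH = vmin`
column of the table is an *identity* only for `dv_left >= vmid`. For
`dv_left < vmid` the mismatch candidate wins and the output is exactly
`vmid`. Both behaviours follow from the recurrence and are covered by
exhaustive table tests; the row algorithms rely on them separately (runs
propagate high values unchanged, while low values entering a run flatten to
`vmid` and are handled by the dH-only zone-C terms).

## Row computation

Vectors are `n + 2` bits wide for a horizontal sequence of length `n`:
bit `j` (1-based) is matrix column `j`, bit 0 is the boundary column
(holding the known leftmost dV of the row), and the top bit exists only so
that "shifted one column right" vectors never truncate. Outputs and inputs
of a row are the same vectors one shift apart; the diagonal
(dV, dH)-pair intersections that drive the update consume the shifted form.

The standard variant computes, per row: (1) the `vmax` locations — matches
sitting on `dH = vmin`, carried to the end of each run by one addition whose
artefact bits are repaired by two XORs; (2) the remaining high values in
descending order, each as an OR of diagonal pair intersections plus a run
carry — crucially, the run mask used for these additions has the columns
already claimed by `vmax` removed *before* the addition, which truncates
each run at a claimed match column so no carry can ripple past it; (3) the
low values from high-input diagonal pairs plus dH-only terms on columns
without a high input; (4) `vmin` everywhere still unassigned (complement);
(5) the new dH row from the transposed table after re-binning the previous
row's dH (matches to `vmax`, all lows to `vmid` — legitimate because the dH
update is constant on the low dH range).

The packed variant keeps steps 1–2 verbatim (they are inherently
sequential in value order) and replaces steps 3–5 by two's-complement
plane arithmetic: dV is encoded as the offset `dV - vmin in [0, span]`, dH
as `vmin - dH in [-span, 0]`, over `k = ceil(log2(2*span+1))` planes, so a
single digit-serial plane addition yields `dV - dH` per column — exactly
the indel-from-left output offset — with the sign plane marking zone-D
columns to clamp to `vmin`. A second addition against the re-encoded
previous dH produces the new dH planes (non-negative sums clamp to the `0`
encoding, i.e. `dH = vmin`). Design choices here:

* **Which dH values are unpacked for steps 1–2:** `vmin` plus the values a
  step-2 diagonal pair can actually consume, i.e. `[vmin+1, M-I+G-1]`
  (clamped to `vmax`). These are mostly *low* values; unpacking only the
  high range would starve the zone-A pairs. Established by derivation and
  enforced by the cross-variant bit-identity suite.
* **Low/high dH detection for the re-encoding** uses a k-stage constant-add
  comparator (sign of `enc + (I - 2G)`) instead of unpacking every high
  value — fewer operations, same result.
* **Adder:** a digit-serial ripple of full-adder stages; `k <= 8` for any
  sane weight set, so carry depth is negligible and the structure matches
  the straight-line program model.
* **Packed decode:** the planes encode non-positive offsets, so the
  digit-weighted popcount sum is applied to the two's-complement decode:
  `S[m,n] = base + n*G + 2^k * #nonzero - sum_i 2^i * popcount(plane_i)`,
  validated against the standard decode on every test instance.

Packing and unpacking share intermediate vectors through a deterministic
greedy common-pair extraction: the pair of operands co-occurring in the
most target combinations is fused into a temporary until no pair occurs
twice. Each fusion costs one operation and saves at least one, so the plan
is never worse than the naive expansion; it is strictly better once eight
or more distinct values exist (below that, no two digit planes share a
two-element subset and the naive expansion is already optimal). No
primitive OR/AND is ever computed twice.

## Initialisation, modes, decoding

Row 0 has `dH = G` everywhere (global) or `0` (free first row); the
leftmost dV of every row is `G` (global) or `0` (free first column). The
boundary column rides along as bit 0 of the dV vectors, which keeps the
vector width at exactly `n` real columns and feeds the first real column
through the same shift as every other. Scores are read at the last cell
(popcount decode), the best of the last row (prefix accumulation over the
final dH row), or the best of the last column (per-row accumulation of the
column-`n` dV during the drive); the free-first-column decode replaces the
`m*G` base with 0. Empty sequences are legal — the score is forced by the
initialisation alone.

## Backends and chunking

All row code is written against a minimal engine interface. The wide
backend (one arbitrary-precision word) is the reference semantics; the
chunked backend tiles columns into fixed-width words (default 64, any
width >= 1) and chains additions by carry and shifts by evicted bit across
chunk boundaries. The run-carry addition crosses chunk boundaries through
exactly this carry chain, so no special inter-chunk logic exists anywhere
in the row code. The suites run both backends (widths 8 and 64, forcing
multi-chunk layouts on short sequences) and require bit-identical row
states.

Characters outside the alphabet (e.g. `N`) match nothing by default —
the conservative alignment semantics — and can be rejected outright with
the strict policy.

## Per-weight programs and operation counting

`generate_program` emits, for a weight triple and variant, the entire row
computation as a branch-free SSA instruction list over the six primitives
(AND, OR, XOR, NOT, ADD, SHIFT). The interpreter is the normative
semantics; a pseudo-C rendering exists for inspection and round-trips
through a parser. Conventions: every primitive (including SHIFT) counts as
one operation; moves are never emitted and never counted; the efficiency is
`e = w/p` at word width `w` (default 64), calibrated so a four-operation
row recipe scores `e = 16`. Absolute counts depend on emission style, so
tests and reported results use only orderings and trends: the standard
count grows monotonically with the function-table size
`z = ((M-2G+1)^2 - (I-2G)^2)/2` (a half-integer for some weight sets —
it is an a-priori estimate, never an acceptance quantity), and the
packed/standard ordering crosses over between unit-cost weights (packed
loses) and wide-range weights like `(4, -7, -11)` (packed wins). Published
wall-clock speedups and implementation-specific counts for the original C
generator are not reproduced; they are hardware- and emitter-specific.

## Synthetic data

The fixture stream draws uniform random sequences over `ACGT` with lengths
in a configurable range (default 0–200, matching the regime the per-word
algorithms target), and weights from `M in [0,6]`, `G in [-12,-1]`,
`I in [2G,-1]` — every triple admissible by construction. The first ten
items are forced corner cases: empty sequences on either side, all-match
and all-mismatch pairs, single characters, and lengths at exactly a 64-bit
word boundary (63/64/65). Real sequencing data differs in composition bias
and repeat structure, but the scoring recurrence is
composition-independent: passing these suites establishes *correctness* of
the score computation for any input over the alphabet, not throughput
claims on real workloads.

## Problem sizes used in verification

The main agreement sweep runs 1000 seeded instances (lengths 0–200, nine
weight sets including the five benchmark triples and the `I = 2G`
boundary, all four initialisation combinations, three score sites, wide
plus rotating chunked backends); row-level bit identity runs 200 instances;
the edit-distance law 200 pairs; generator equivalence 100 random rows per
weight set across six weight sets. These sizes keep the whole suite around
half a minute on one CPU while exercising every code path; all counts are
driven by seeded generators and are reproducible.

## Known limitations

* Scores only — no traceback, no local alignment.
* Integer three-weight schemes only; no affine gaps or substitution
  matrices.
* Pure-Python engines: the point is a verified, inspectable reference of
  the bit-parallel method and its per-weight program structure, not raw
  throughput; the generated programs are the artifact a native
  implementation would compile.
* Operation counts measure the emitted straight-line programs, which make
  no attempt at cross-step common-subexpression elimination beyond the
  pack/unpack sharing described above.
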