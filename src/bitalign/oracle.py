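"""Independent ground-truth implementations and the synthetic fixture stream.

Everything here is deliberately naive O(nm) integer dynamic programming with
no bit tricks and no shared code with the bit-parallel engines, so that it
can serve as an oracle for them:

* :func:`nw_score` -- the classical score-matrix recurrence;
* :func:`delta_matrices` -- dV/dH difference grids extracted from a matrix;
* :func:`delta_recurrence_score` -- the score computed cell-by-cell from the
  difference recurrence alone, never materialising S (a second oracle);
* :func:`levenshtein` -- textbook Wagner-Fischer edit distance;
* :func:`make_fixtures` -- a seeded stream of (X, Y, Weights) instances with
  forced corner cases.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

from .scoring import Weights, build_delta_v_table, derive_bounds, validate_weights

__all__ = [
    "AlignmentMode",
    "GLOBAL",
    "ScoreMatrix",
    "FixtureSpec",
    "nw_score",
    "delta_matrices",
    "delta_recurrence_score",
    "levenshtein",
    "make_fixtures",
]


@dataclass(frozen=True)
class AlignmentMode:
    """Initialisation and score-site policy.

    ``first_row`` / ``first_column`` are ``"gap"`` (successive gap weights,
    fully global) or ``"free"`` (zero-initialised, end-gap free).
    ``score_site`` is where the score is read: ``"last_cell"``,
    ``"best_in_last_row"`` or ``"best_in_last_column"``.
    """

    first_row: str = "gap"
    first_column: str = "gap"
    score_site: str = "last_cell"

    def __post_init__(self) -> None:
        if self.first_row not in ("gap", "free"):
            raise ValueError(f"first_row must be 'gap' or 'free', got {self.first_row!r}")
        if self.first_column not in ("gap", "free"):
            raise ValueError(
                f"first_column must be 'gap' or 'free', got {self.first_column!r}"
            )
        if self.score_site not in ("last_cell", "best_in_last_row", "best_in_last_column"):
            raise ValueError(f"unknown score_site {self.score_site!r}")


GLOBAL = AlignmentMode()


@dataclass
class ScoreMatrix:
    """A fully materialised (m+1) x (n+1) score grid."""

    S: List[List[int]]

    @property
    def m(self) -> int:
        return len(self.S) - 1

    @property
    def n(self) -> int:
        return len(self.S[0]) - 1


def _site_score(S: List[List[int]], mode: AlignmentMode) -> int:
    if mode.score_site == "last_cell":
        return S[-1][-1]
    if mode.score_site == "best_in_last_row":
        return max(S[-1])
    return max(row[-1] for row in S)


def nw_score(
    X: str, Y: str, w: Weights, mode: AlignmentMode = GLOBAL
) -> Tuple[int, ScoreMatrix]:
    """Classical dynamic-programming global/semi-global alignment score.

    Returns the score at the mode's score site together with the full matrix
    (rows indexed by Y, columns by X).
    """
    n, m = len(X), len(Y)
    M, I, G = w.M, w.I, w.G
    row0 = [0] * (n + 1)
    if mode.first_row == "gap":
        for j in range(1, n + 1):
            row0[j] = j * G
    S = [row0]
    prev = row0
    for i in range(1, m + 1):
        yc = Y[i - 1]
        left = i * G if mode.first_column == "gap" else 0
        cur = [left]
        for j in range(1, n + 1):
            sub = M if X[j - 1] == yc else I
            diag = prev[j - 1] + sub
            up = prev[j] + G
            lf = left + G
            best = diag
            if up > best:
                best = up
            if lf > best:
                best = lf
            cur.append(best)
            left = best
        S.append(cur)
        prev = cur
    return _site_score(S, mode), ScoreMatrix(S)


def delta_matrices(sm: ScoreMatrix) -> Tuple[List[List[int]], List[List[int]]]:
    """Extract the dV and dH difference grids from a score matrix.

    ``dV[i][j] = S[i][j] - S[i-1][j]`` for i in 1..m (rows of the result are
    indexed 0..m-1), j in 0..n; ``dH[i][j] = S[i][j] - S[i][j-1]`` for
    i in 0..m, j in 1..n (columns indexed 0..n-1).
    """
    S = sm.S
    m, n = sm.m, sm.n
    dv = [[S[i][j] - S[i - 1][j] for j in range(n + 1)] for i in range(1, m + 1)]
    dh = [[S[i][j] - S[i][j - 1] for j in range(1, n + 1)] for i in range(m + 1)]
    return dv, dh


def delta_recurrence_score(
    X: str, Y: str, w: Weights, mode: AlignmentMode = GLOBAL
) -> int:
    """Score via the difference recurrence only, cell by cell.

    Maintains one row of dH values and a scalar running dV; S itself is never
    stored.  The final score is reconstructed from the boundary score plus
    the telescoped differences at the mode's score site.
    """
    n, m = len(X), len(Y)
    table = build_delta_v_table(w)
    f = table.dv_out
    G = w.G
    dh = [G if mode.first_row == "gap" else 0] * n
    leftmost = G if mode.first_column == "gap" else 0

    # score bookkeeping for the three sites
    s_corner = n * G if mode.first_row == "gap" else 0  # S[0, n]
    best_last_col = s_corner
    for i in range(1, m + 1):
        yc = Y[i - 1]
        dv = leftmost
        new_dh = dh  # reused in place
        for j in range(n):
            is_match = X[j] == yc
            h = dh[j]
            out_v = f[(dv, h, is_match)]
            # transpose table: dH out = dV table with input roles swapped
            out_h = f[(h, dv, is_match)]
            new_dh[j] = out_h
            dv = out_v
        s_corner += dv if n > 0 else leftmost
        if s_corner > best_last_col:
            best_last_col = s_corner
        dh = new_dh
    base = m * G if mode.first_column == "gap" else 0
    if mode.score_site == "last_cell":
        return base + sum(dh)
    if mode.score_site == "best_in_last_row":
        best = acc = base
        for h in dh:
            acc += h
            if acc > best:
                best = acc
        return best
    return best_last_col


def levenshtein(a: str, b: str) -> int:
    """Textbook Wagner-Fischer unit-cost edit distance."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the seeded synthetic instance stream.

    Weight sampling rule: M in [0, 6], G in [-12, -1], I in [2G, -1]; every
    sampled triple passes validation by construction.  The first ten items
    are forced corner cases (empty sequences, all-match, all-mismatch, single
    characters, lengths exactly at/around a 64-bit word).
    """

    seed: int = 0
    min_len: int = 0
    max_len: int = 200
    alphabet: str = "ACGT"
    n_items: Optional[int] = None
    weight_sets: Tuple[Tuple[int, int, int], ...] = field(default=())


def _sample_weights(rng: random.Random) -> Weights:
    M = rng.randint(0, 6)
    G = rng.randint(-12, -1)
    I = rng.randint(2 * G, -1)
    return validate_weights(M, I, G)


def make_fixtures(spec: FixtureSpec) -> Iterator[Tuple[str, str, Weights]]:
    """Seeded, reproducible stream of (X, Y, Weights) test instances."""
    rng = random.Random(spec.seed)
    ab = spec.alphabet

    def seq(k: int) -> str:
        return "".join(rng.choice(ab) for _ in range(k))

    def pick_w() -> Weights:
        if spec.weight_sets:
            return validate_weights(*rng.choice(spec.weight_sets))
        return _sample_weights(rng)

    hi = max(spec.max_len, 2)
    s = seq(min(hi, 65))
    corners = [
        ("", "", pick_w()),
        ("", seq(min(hi, 7)), pick_w()),
        (seq(min(hi, 7)), "", pick_w()),
        (s[:5], s[:5], pick_w()),                      # all match
        ("A" * 6, "C" * 6, pick_w()),                  # all mismatch
        (seq(1), seq(1), pick_w()),
        (s[:63], seq(min(hi, 63)), pick_w()),          # length w - 1
        (s[:64], seq(min(hi, 64)), pick_w()),          # length exactly w
        (s[:65], seq(min(hi, 65)), pick_w()),          # length w + 1
        (seq(2), seq(min(hi, 40)), pick_w()),
    ]
    count = 0
    for item in corners:
        if spec.n_items is not None and count >= spec.n_items:
            return
        yield item
        count += 1
    while spec.n_items is None or count < spec.n_items:
        X = seq(rng.randint(spec.min_len, spec.max_len))
        Y = seq(rng.randint(spec.min_len, spec.max_len))
        yield X, Y, pick_w()
        count += 1
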