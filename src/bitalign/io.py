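"""FASTA input and the batch pairwise-scoring driver.

Batches score every query against every target (the all-vs-all design used
for bulk sequence comparison), with a selectable compute path: the standard
or packed bit-parallel variant, or the plain dynamic-programming oracle for
ground-truth runs.  Output is a headered TSV with deterministic, query-major
row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd
from Bio import SeqIO

from .oracle import GLOBAL, AlignmentMode, nw_score
from .packed import align_score_packed
from .scoring import Weights
from .standard import align_score

__all__ = ["BatchJob", "FastaError", "read_fasta", "run_batch", "write_batch"]

logger = logging.getLogger("bitalign")


class FastaError(ValueError):
    """Malformed FASTA input (carries the offending line number)."""


@dataclass
class BatchJob:
    queries: List[Tuple[str, str]]
    targets: List[Tuple[str, str]]
    weights: Weights
    mode: AlignmentMode = field(default_factory=AlignmentMode)
    variant: str = "standard"
    word_width: Optional[int] = None
    strict_alphabet: bool = False
    alphabet: str = "ACGT"


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read (id, sequence) pairs: ids up to first whitespace, sequences
    uppercased, multi-line records concatenated.

    A sequence line before any header is rejected with its line number.
    """
    text = Path(path).read_text()
    seen_header = False
    for lineno, line in enumerate(text.splitlines(), 1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise FastaError(
                f"{path}: sequence data before any '>' header at line {lineno}"
            )
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


_VARIANTS = {
    "standard": lambda X, Y, w, mode, ww: align_score(X, Y, w, mode, ww),
    "packed": lambda X, Y, w, mode, ww: align_score_packed(X, Y, w, mode, ww),
    "oracle": lambda X, Y, w, mode, ww: nw_score(X, Y, w, mode)[0],
}


def run_batch(job: BatchJob) -> pd.DataFrame:
    """Score every (query, target) pair; one row each, query-major order."""
    if job.variant not in _VARIANTS:
        raise ValueError(f"unknown variant {job.variant!r}")
    score = _VARIANTS[job.variant]
    if job.strict_alphabet:
        for name, seq in job.queries + job.targets:
            bad = {c for c in seq if c not in job.alphabet}
            if bad:
                raise ValueError(f"sequence {name!r} has characters outside "
                                 f"alphabet {job.alphabet!r}: {sorted(bad)}")
    rows = []
    for qid, q in job.queries:
        for tid, t in job.targets:
            rows.append(
                (qid, tid, score(q, t, job.weights, job.mode, job.word_width), job.variant)
            )
    logger.info(
        "scored %d pairs (%d queries x %d targets) weights=(%d,%d,%d) variant=%s",
        len(rows), len(job.queries), len(job.targets),
        job.weights.M, job.weights.I, job.weights.G, job.variant,
    )
    return pd.DataFrame(rows, columns=["query_id", "target_id", "score", "variant"])


def write_batch(df: pd.DataFrame, path) -> None:
    """Write the scores table as headered TSV (atomically: a failed batch
    never leaves a partial file because scoring happens before this call)."""
    df.to_csv(path, sep="\t", index=False)
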