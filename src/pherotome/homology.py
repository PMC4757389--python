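"""Homology filtering: Smith-Waterman local alignment with Karlin-Altschul
e-values against a bundled protein reference panel.

Retention re-expresses "at least one match with an e-value of at most 1e-5"
as explicit computation: the optimal local alignment score S under BLOSUM62
with affine gaps (open 11, extend 1; a gap of length g costs 11 + g), and
E = K * m * n * exp(-lambda * S) with m the query length and n the total
panel residue count (database-style, no edge-effect correction).  The gapped
Karlin-Altschul parameters are the published BLOSUM62/11/1 values
lambda = 0.267, K = 0.041.

The DP fill runs in a numba kernel; the traceback (for alignment spans) is
done in Python on the returned matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from numba import njit

from .util import read_fasta

__all__ = ["AlignmentHit", "smith_waterman", "sw_score", "evalue", "bit_score", "filter_by_homology"]

GAP_OPEN = 11
GAP_EXTEND = 1
LAMBDA = 0.267
K_PARAM = 0.041

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_X_INDEX = len(_AA_ORDER)  # any unknown/ambiguous residue scores 0 vs all


def _build_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ORDER) + 1
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            mat[i, j] = int(blosum[a][b])
    return mat


BLOSUM62 = _build_matrix()
_ENCODE = {aa: i for i, aa in enumerate(_AA_ORDER)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENCODE.get(c, _X_INDEX) for c in seq.upper()], dtype=np.int64)


@njit(cache=False)
def _sw_fill(q, s, mat, go, ge):  # pragma: no cover - exercised via wrapper
    m, n = q.shape[0], s.shape[0]
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - go - ge
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - go - ge
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@dataclass
class AlignmentHit:
    """Best local alignment of a query against a subject.

    ``bit_score``/``evalue`` are filled when the database context (effective
    lengths) is known, i.e. by :func:`filter_by_homology`.
    """

    query_id: str
    subject_id: str
    raw_score: int
    query_span: tuple[int, int]  # half-open residue interval on the query
    subject_span: tuple[int, int]
    bit_score: float | None = None
    evalue: float | None = None


def _traceback(H, E, F, bi, bj, q, s, mat, go, ge) -> tuple[int, int]:
    """Start cell (query, subject) of the optimal alignment ending at (bi, bj).

    Deterministic move preference: diagonal, then gap-in-subject (up), then
    gap-in-query (left).
    """
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]:
                i, j = i - 1, j - 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # unreachable for a well-formed fill
                break
        elif state == "F":
            if F[i, j] == H[i - 1, j] - go - ge:
                i, state = i - 1, "H"
            else:
                i = i - 1
        else:  # state == "E"
            if E[i, j] == H[i, j - 1] - go - ge:
                j, state = j - 1, "H"
            else:
                j = j - 1
    return i, j


def smith_waterman(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> AlignmentHit:
    """Optimal local alignment under BLOSUM62 with affine gaps.

    Unknown residues (incl. X) score 0 against everything.  An empty sequence
    yields a score-0 hit with empty spans.
    """
    if not query or not subject:
        return AlignmentHit(query_id, subject_id, 0, (0, 0), (0, 0))
    q, s = _encode(query), _encode(subject)
    H, E, F, best, bi, bj = _sw_fill(q, s, BLOSUM62, gap_open, gap_extend)
    if best == 0:
        return AlignmentHit(query_id, subject_id, 0, (0, 0), (0, 0))
    qi, sj = _traceback(H, E, F, bi, bj, q, s, BLOSUM62, gap_open, gap_extend)
    return AlignmentHit(query_id, subject_id, int(best), (qi, bi), (sj, bj))


def sw_score(query: str, subject: str, gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND) -> int:
    """Score-only Smith-Waterman (same DP as :func:`smith_waterman`)."""
    if not query or not subject:
        return 0
    _H, _E, _F, best, _bi, _bj = _sw_fill(
        _encode(query), _encode(subject), BLOSUM62, gap_open, gap_extend
    )
    return int(best)


def evalue(S: float, m: int, n: int, lambda_: float = LAMBDA, K: float = K_PARAM) -> float:
    """Karlin-Altschul expect value E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("effective lengths must be >= 1")
    return K * m * n * math.exp(-lambda_ * S)


def bit_score(S: float, lambda_: float = LAMBDA, K: float = K_PARAM) -> float:
    return (lambda_ * S - math.log(K)) / math.log(2)


def filter_by_homology(
    queries: Sequence[tuple[str, str]],
    panel: Sequence[tuple[str, str]] | str | Path,
    e_max: float = 1e-5,
) -> tuple[list[str], pd.DataFrame]:
    """Retain queries whose best panel hit has E <= e_max.

    ``queries`` and ``panel`` are (id, protein) pairs; ``panel`` may also be
    a FASTA path.  Returns the retained query ids (input order) and a
    BLAST-tabular-like table with the best hit per query.
    """
    if isinstance(panel, (str, Path)):
        panel = read_fasta(panel)
    panel = list(panel)
    if not panel:
        raise ValueError("reference panel is empty: nothing to match against")
    n_db = sum(len(seq) for _sid, seq in panel)
    rows = []
    retained: list[str] = []
    for qid, qseq in queries:
        best: AlignmentHit | None = None
        for sid, sseq in panel:
            hit = smith_waterman(qseq, sseq, qid, sid)
            if best is None or hit.raw_score > best.raw_score:
                best = hit
        assert best is not None
        best.evalue = evalue(best.raw_score, max(1, len(qseq)), n_db)
        best.bit_score = bit_score(best.raw_score)
        keep = best.evalue <= e_max
        if keep:
            retained.append(qid)
        rows.append(
            (
                qid,
                best.subject_id,
                best.raw_score,
                round(best.bit_score, 2),
                best.evalue,
                best.query_span[0],
                best.query_span[1],
                best.subject_span[0],
                best.subject_span[1],
                keep,
            )
        )
    hits = pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "score", "bitscore", "evalue",
            "qstart", "qend", "sstart", "send", "retained",
        ],
    )
    return retained, hits
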