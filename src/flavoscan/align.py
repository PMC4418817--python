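"""Affine-gap local protein alignment (Smith-Waterman).

Replaces an external BLAST step for desk-scale proteomes while preserving
the identity/coverage contract used to accept transporter orthologs:
``identity`` is matches over aligned columns (gap columns count) and
``coverage`` is the fraction of the *subject* (prototype) length spanned by
the local alignment.

Conventions
-----------
* A gap of length ``g`` costs ``gap_open + g * gap_extend`` (BLAST-style
  "existence 11, extension 1" with the default 11/1).
* The optimal end cell is the highest-scoring cell with the smallest
  ``(row, col)``; traceback prefers diagonal, then vertical (gap in the
  subject), then horizontal (gap in the query). These tie-breaks make the
  reported alignment deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

NEG_INF = float("-inf")

_BLOSUM62 = None


def blosum62() -> tuple[np.ndarray, str]:
    """Return (matrix, alphabet) for BLOSUM62, cached."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        m = substitution_matrices.load("BLOSUM62")
        alphabet = str(m.alphabet)
        _BLOSUM62 = (np.asarray(m, dtype=float), alphabet)
    return _BLOSUM62


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment between a query and a subject protein."""

    query: str
    subject: str
    score: float
    identity: float
    coverage: float
    aligned_span: tuple[int, int, int, int]  # qstart, qend, sstart, send (0-based, half-open)
    n_columns: int
    n_matches: int
    query_aln: str
    subject_aln: str


def _encode(seq: str, alphabet: str, name: str) -> np.ndarray:
    idx = np.fromiter((alphabet.find(c) for c in seq.upper()), dtype=np.int64, count=len(seq))
    if (idx < 0).any():
        bad = sorted({c for c in seq.upper() if c not in alphabet})
        raise ValueError(f"sequence {name!r} contains non-amino-acid characters: {bad}")
    return idx


def align_local(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
    coverage_on: str = "subject",
) -> AlignmentResult:
    """Optimal affine-gap Smith-Waterman alignment of ``a`` (query) vs ``b`` (subject).

    ``coverage_on`` selects the denominator of the coverage fraction:
    ``"subject"`` (default; the prototype in an ortholog search), ``"query"``
    or ``"mutual"`` (the smaller of the two fractions).
    """
    if not a or not b:
        raise ValueError("align_local requires non-empty sequences "
                         f"({query_id!r} len {len(a)}, {subject_id!r} len {len(b)})")
    if matrix is None:
        matrix, alphabet = blosum62()
    else:
        alphabet = blosum62()[1]
    ai = _encode(a, alphabet, query_id)
    bi = _encode(b, alphabet, subject_id)
    n, m = len(ai), len(bi)
    oe = gap_open + gap_extend
    ext = gap_extend

    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)  # vertical: gap in subject (consumes query residue)
    F = np.full((n + 1, m + 1), NEG_INF)  # horizontal: gap in query (consumes subject residue)
    Sm = matrix

    for i in range(1, n + 1):
        E[i, 1:] = np.maximum(H[i - 1, 1:] - oe, E[i - 1, 1:] - ext)
        diag = H[i - 1, :-1] + Sm[ai[i - 1], bi]
        h0 = np.maximum(np.maximum(diag, E[i, 1:]), 0.0)
        hrow = H[i]
        frow = F[i]
        f = NEG_INF
        prev_h = 0.0
        for j in range(1, m + 1):
            cand = prev_h - oe
            f = cand if cand > f - ext else f - ext
            frow[j] = f
            h = h0[j - 1]
            if f > h:
                h = f
            hrow[j] = h
            prev_h = h

    flat = int(np.argmax(H))  # first occurrence = smallest (row, col)
    bi_, bj_ = divmod(flat, m + 1)
    score = float(H[bi_, bj_])
    if score <= 0.0:
        return AlignmentResult(query_id, subject_id, 0.0, 0.0, 0.0, (0, 0, 0, 0), 0, 0, "", "")

    # traceback
    i, j = bi_, bj_
    qa: list[str] = []
    sa: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0.0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + Sm[ai[i - 1], bi[j - 1]]:
                qa.append(a[i - 1])
                sa.append(b[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qa.append(a[i - 1])
            sa.append("-")
            if E[i, j] == H[i - 1, j] - oe:
                state = "H"
            i -= 1
        else:  # F
            qa.append("-")
            sa.append(b[j - 1])
            if F[i, j] == H[i, j - 1] - oe:
                state = "H"
            j -= 1

    qa.reverse()
    sa.reverse()
    qaln = "".join(qa)
    saln = "".join(sa)
    n_cols = len(qaln)
    n_match = sum(1 for x, y in zip(qaln, saln) if x == y and x != "-")
    identity = n_match / n_cols if n_cols else 0.0
    qstart, qend = i, bi_
    sstart, send = j, bj_
    cov_subject = (send - sstart) / m
    cov_query = (qend - qstart) / n
    if coverage_on == "subject":
        coverage = cov_subject
    elif coverage_on == "query":
        coverage = cov_query
    elif coverage_on == "mutual":
        coverage = min(cov_subject, cov_query)
    else:
        raise ValueError(f"unknown coverage_on mode {coverage_on!r}")
    return AlignmentResult(
        query=query_id,
        subject=subject_id,
        score=score,
        identity=identity,
        coverage=coverage,
        aligned_span=(qstart, qend, sstart, send),
        n_columns=n_cols,
        n_matches=n_match,
        query_aln=qaln,
        subject_aln=saln,
    )
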