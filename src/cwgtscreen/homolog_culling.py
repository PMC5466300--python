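"""Candidate culling over homology-search hits.

The crop-library selection starts from a large homology hit list and keeps
only subjects with at least 40% identity to their query (diversity floor)
and a length between 85% and 115% of the query (to favour full-length
sequences and exclude extra-domain architectures).  When the hit table
does not carry an identity column, identity is computed here from an
optimal global alignment.

The aligner is a standard Needleman-Wunsch/Gotoh affine-gap dynamic
program under BLOSUM62.  Traceback tie-breaking is fixed (prefer the
substitution move, then a gap in the subject, then a gap in the query) so
alignments — and therefore identities and culling decisions — are fully
deterministic.  A gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import HomologHit, ProteinRecord

__all__ = ["AlignmentResult", "global_align", "cull_candidates", "CullReport"]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment: gapped sequences, score and column identity."""

    aligned_query: str
    aligned_subject: str
    score: float
    identity: float  # identical columns / total alignment columns

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("gapped sequences differ in length")


def _substitution_score(a: str, b: str) -> float:
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return float(_BLOSUM62["X", "X"]) if a == "X" or b == "X" else 0.0


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment of ``a`` against ``b``.

    BLOSUM62 substitution scores; affine gap penalty
    ``gap_open + length * gap_extend``.  Ties during traceback prefer the
    diagonal (substitution) move, then a gap in ``b`` (consume an ``a``
    residue), then a gap in ``a``.
    """
    s, t = a.residues, b.residues
    if not s or not t:
        raise ValueError("cannot align empty sequences")
    n, m = len(s), len(t)

    # M: s[i] aligned to t[j]; X: gap in t (vertical); Y: gap in s (horizontal)
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_extend)

    for i in range(1, n + 1):
        sub_row = [_substitution_score(s[i - 1], c) for c in t]
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + sub_row[j - 1]
            X[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend,
                X[i - 1, j] - gap_extend,
                Y[i - 1, j] - gap_open - gap_extend,
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend,
                Y[i, j - 1] - gap_extend,
                X[i, j - 1] - gap_open - gap_extend,
            )

    # Traceback; preference order at every tie: M (diagonal), X (up), Y (left).
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    score = max(finals)
    state = "MXY"[finals.index(score)]
    qa: list[str] = []
    sa: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            qa.append(s[i - 1])
            sa.append(t[j - 1])
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = "MXY"[prev.index(max(prev))]
            i, j = i - 1, j - 1
        elif state == "X":
            qa.append(s[i - 1])
            sa.append("-")
            val = X[i, j]
            if np.isclose(val, M[i - 1, j] - gap_open - gap_extend):
                state = "M"
            elif np.isclose(val, X[i - 1, j] - gap_extend):
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            qa.append("-")
            sa.append(t[j - 1])
            val = Y[i, j]
            if np.isclose(val, M[i, j - 1] - gap_open - gap_extend):
                state = "M"
            elif np.isclose(val, X[i, j - 1] - gap_open - gap_extend):
                state = "X"
            else:
                state = "Y"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"

    aligned_query = "".join(reversed(qa))
    aligned_subject = "".join(reversed(sa))
    identical = sum(
        1 for x, y in zip(aligned_query, aligned_subject) if x == y and x != "-"
    )
    return AlignmentResult(
        aligned_query=aligned_query,
        aligned_subject=aligned_subject,
        score=float(score),
        identity=identical / len(aligned_query),
    )


@dataclass(frozen=True)
class CullReport:
    """Outcome of :func:`cull_candidates`: kept hits plus one rejection
    reason per discarded hit ("identity", "length" or "duplicate")."""

    kept: tuple[HomologHit, ...]
    rejected: tuple[tuple[HomologHit, str], ...]


def cull_candidates(
    hits: list[HomologHit],
    parent: ProteinRecord,
    min_identity: float = 0.40,
    min_len_ratio: float = 0.85,
    max_len_ratio: float = 1.15,
) -> CullReport:
    """Apply the identity and length-window filters to a hit list.

    A hit is kept iff identity >= ``min_identity`` (computed by
    :func:`global_align` when the table did not carry it) and its
    subject/parent length ratio lies in
    [``min_len_ratio``, ``max_len_ratio``], boundaries inclusive.
    Exact-duplicate subjects (identical residues) are collapsed to the
    first occurrence.  Each rejected hit carries exactly one reason, with
    identity checked first.
    """
    if not parent.residues:
        raise ValueError("parent sequence must be non-empty")
    kept: list[HomologHit] = []
    rejected: list[tuple[HomologHit, str]] = []
    seen_residues: set[str] = set()
    for hit in hits:
        identity = hit.identity
        if identity is None:
            identity = global_align(parent, hit.subject).identity
        length_ratio = len(hit.subject.residues) / len(parent.residues)
        resolved = HomologHit(
            query_id=hit.query_id,
            subject=hit.subject,
            identity=identity,
            length_ratio=length_ratio,
        )
        if identity < min_identity:
            rejected.append((resolved, "identity"))
            continue
        if not min_len_ratio <= length_ratio <= max_len_ratio:
            rejected.append((resolved, "length"))
            continue
        if hit.subject.residues in seen_residues:
            rejected.append((resolved, "duplicate"))
            continue
        seen_residues.add(hit.subject.residues)
        kept.append(resolved)
    return CullReport(kept=tuple(kept), rejected=tuple(rejected))
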