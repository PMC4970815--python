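"""Karlin-Altschul statistics, final thresholding and ranking.

E-values are computed against the *whole* database residue count, never a
chunk's, so chunked and unchunked runs of the same database produce
identical statistics.  No effective-length (edge effect) correction is
applied; this is a documented divergence from NCBI BLAST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SearchSpace", "GAPPED_LAMBDA", "GAPPED_K", "evalue", "bit_score", "rank_and_threshold"]

# Field-standard gapped constants for BLOSUM62 with gap open 11 / extend 1.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041


@dataclass(frozen=True)
class SearchSpace:
    """Search-space parameters for one (query segment, database) pair."""

    query_length: int  # m, residues
    db_residues: int  # n, total residues of the whole database
    lam: float = GAPPED_LAMBDA
    K: float = GAPPED_K

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be > 0")
        if self.query_length < 1 or self.db_residues < 1:
            raise ValueError("m and n must be >= 1")


def evalue(score: int, space: SearchSpace) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    if score < 0:
        raise ValueError("raw score must be >= 0")
    return space.K * space.query_length * space.db_residues * math.exp(-space.lam * score)


def bit_score(score: int, space: SearchSpace) -> float:
    """S' = (lambda * S - ln K) / ln 2 — invariant under database chunking."""
    return (space.lam * score - math.log(space.K)) / math.log(2)


def rank_and_threshold(hits: list, e_cut: float = 10.0, max_targets: int = 25) -> list:
    """Per-query thresholding, ranking and truncation of finished hits.

    ``hits`` are records with attributes ``query_id``, ``subject_id``,
    ``evalue`` and ``bits`` (see :mod:`txsearch.scheduler`).  Hits with
    E > ``e_cut`` are dropped; survivors are sorted per query by bit score
    descending, then E-value ascending, then subject id ascending, and
    truncated to ``max_targets`` distinct subjects (every HSP of a kept
    subject is reported).
    """
    if e_cut <= 0:
        raise ValueError("e_cut must be > 0")
    if max_targets < 1:
        raise ValueError("max_targets must be >= 1")
    by_query: dict[str, list] = {}
    order: list[str] = []
    for h in hits:
        if h.evalue > e_cut:
            continue
        if h.query_id not in by_query:
            by_query[h.query_id] = []
            order.append(h.query_id)
        by_query[h.query_id].append(h)
    out = []
    for q in order:
        ranked = sorted(by_query[q], key=lambda h: (-h.bits, h.evalue, h.subject_id))
        subjects: set[str] = set()
        for h in ranked:
            if h.subject_id not in subjects:
                if len(subjects) == max_targets:
                    continue
                subjects.add(h.subject_id)
            out.append(h)
    return out
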