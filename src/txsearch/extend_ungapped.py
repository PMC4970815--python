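"""X-dropoff ungapped extension of seeds.

A seed's ten aligned columns are scored with the substitution matrix, then
extended residue-by-residue in both directions.  Extension in a direction
stops when the running score falls more than ``X_u`` below the best score
seen so far in that direction, or when either sequence runs out (query
segment boundary or database delimiter).  The returned segment ends at the
prefix achieving the directional maximum (ties broken toward the shortest
extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .seq_codec import AA_ORDER, CODE_DELIM, CODE_X, EncodedSequenceStore
from .seeding_filter import SeedHit

__all__ = ["ScoringParams", "UngappedSegment", "blosum62_matrix", "extend_one_direction", "ungapped_extend"]


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a 22x22 int32 matrix over txsearch codes.

    Codes 0..19 are the canonical residues, 20 is X (clamped to <= 0
    against everything), 21 the delimiter (never scored; extension stops
    before reading it).
    """
    bl = substitution_matrices.load("BLOSUM62")
    m = np.zeros((22, 22), dtype=np.int32)
    letters = AA_ORDER + "X"
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            v = int(bl[a][b])
            if a == "X" or b == "X":
                v = min(v, 0)
            m[i, j] = v
    m[CODE_DELIM, :] = -(2**15)
    m[:, CODE_DELIM] = -(2**15)
    return m


@dataclass(frozen=True)
class ScoringParams:
    """Substitution scores, gap penalties and dropoff/cutoff thresholds.

    A gap of length g costs ``gap_open + g * gap_extend``.
    """

    matrix: np.ndarray = field(default_factory=blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    xdrop_ungapped: int = 20  # X_u
    xdrop_gapped: int = 38  # X_g
    min_ungapped_score: int = 20  # S_u

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.xdrop_ungapped <= 0 or self.xdrop_gapped <= 0:
            raise ValueError("dropoff thresholds must be > 0")
        if not np.array_equal(self.matrix[:21, :21], self.matrix[:21, :21].T):
            raise ValueError("substitution matrix must be symmetric")
        if (self.matrix[CODE_X, :21] > 0).any():
            raise ValueError("X must not score positively")


@dataclass(frozen=True, slots=True)
class UngappedSegment:
    """A gap-free scored segment (0-based half-open coordinates)."""

    segment_id: int
    qstart: int
    qend: int
    dstart: int  # global position in the chunk store
    dend: int
    score: int

    @property
    def diagonal(self) -> int:
        return self.dstart - self.qstart

    @property
    def length(self) -> int:
        return self.qend - self.qstart


def extend_one_direction(
    qcodes: np.ndarray,
    dcodes: np.ndarray,
    qstart: int,
    dstart: int,
    direction: int,
    params: ScoringParams,
) -> tuple[int, int]:
    """Walk aligned residue pairs from (qstart, dstart) in ``direction``
    (+1 right / -1 left), inclusive of the start pair.

    Returns ``(best_offset, best_delta)``: the number of pairs in the
    best-scoring prefix (0 = extend nothing) and its score.  Terminates on
    the X-dropoff rule, the query array bounds, or a database delimiter.
    """
    matrix = params.matrix
    X_u = params.xdrop_ungapped
    best_offset = 0
    best = 0
    running = 0
    k = 0
    nq = len(qcodes)
    while True:
        qi = qstart + k * direction
        di = dstart + k * direction
        if qi < 0 or qi >= nq or di < 0 or di >= len(dcodes):
            break
        if dcodes[di] == CODE_DELIM or qcodes[qi] == CODE_DELIM:
            break
        running += int(matrix[qcodes[qi], dcodes[di]])
        k += 1
        if running > best:
            best = running
            best_offset = k
        elif running < best - X_u:
            break
    return best_offset, best


def ungapped_extend(
    seed: SeedHit,
    segment_codes: np.ndarray,
    store: EncodedSequenceStore,
    params: ScoringParams,
    L: int = 10,
) -> UngappedSegment | None:
    """Extend one seed in both directions; ``None`` if the extended score
    falls below the ungapped cutoff ``S_u``."""
    q, d = segment_codes, store.codes
    qpos, dpos = seed.qpos, seed.dpos
    seed_score = int(params.matrix[q[qpos : qpos + L], d[dpos : dpos + L]].sum())
    off_l, delta_l = extend_one_direction(q, d, qpos - 1, dpos - 1, -1, params)
    off_r, delta_r = extend_one_direction(q, d, qpos + L, dpos + L, +1, params)
    score = seed_score + delta_l + delta_r
    if score < params.min_ungapped_score:
        return None
    return UngappedSegment(
        segment_id=seed.segment_id,
        qstart=qpos - off_l,
        qend=qpos + L + off_r,
        dstart=dpos - off_l,
        dend=dpos + L + off_r,
        score=score,
    )
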