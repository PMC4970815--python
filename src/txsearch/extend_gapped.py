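"""X-dropoff gapped extension from surviving ungapped segments.

The extension anchors on the central column of the segment's best-scoring
11-residue window and runs an affine-gap dynamic program outward in both
directions.  Cells whose score falls more than ``X_g`` below the running
maximum are pruned, so the live band shrinks adaptively and the DP
terminates early.  The score-only pass keeps one row of the matrix at a
time (memory linear in the shorter side); a separate traceback pass re-runs
the identical DP with full matrices only for hits that will be reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extend_ungapped import ScoringParams, UngappedSegment
from .seq_codec import CODE_DELIM, EncodedSequenceStore, decode

__all__ = ["GappedResult", "AlignmentInconsistencyError", "xdrop_dp_score", "gapped_extend", "traceback_align"]

_NEG = -(2**30)


class AlignmentInconsistencyError(RuntimeError):
    """Traceback recomputation disagreed with the score-only pass."""


@dataclass(frozen=True)
class GappedResult:
    """A gapped alignment (score-only until :func:`traceback_align`)."""

    segment_id: int
    score: int
    qstart: int
    qend: int
    dstart: int  # global position in the chunk store
    dend: int
    anchor_q: int  # anchor column (needed to reproduce the DP in traceback)
    anchor_d: int
    aligned_query: str | None = None
    aligned_subject: str | None = None
    midline: str | None = None

    @property
    def has_alignment(self) -> bool:
        return self.aligned_query is not None


def _xdrop_dp_py(q, d, matrix, goe, ge, Xg):
    """Reference X-drop extension DP (score-only, two rows of storage).

    Aligns prefixes of ``q`` against prefixes of ``d`` (both already
    oriented in the direction of extension), cell (i, j) = i residues of q
    and j of d consumed, H(0,0) = 0.  Returns (best, best_i, best_j), best
    over all live cells; ties go to the first cell in (i asc, j asc) order.
    """
    nq, nd = len(q), len(d)
    H_prev = np.full(nd + 1, _NEG, dtype=np.int64)
    F_prev = np.full(nd + 1, _NEG, dtype=np.int64)
    H_cur = np.full(nd + 1, _NEG, dtype=np.int64)
    F_cur = np.full(nd + 1, _NEG, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    # row 0: leading gap in the query
    H_prev[0] = 0
    lo, hi = 0, 0
    j = 1
    while j <= nd:
        v = -(goe + (j - 1) * ge)
        if v < best - Xg:
            break
        H_prev[j] = v
        hi = j
        j += 1
    for i in range(1, nq + 1):
        qc = q[i - 1]
        row = matrix[qc]
        new_lo, new_hi = -1, -1
        e = _NEG
        h_left = _NEG
        j = lo
        while True:
            if j > nd:
                break
            # stop once past the previous live band with nothing to carry
            if j > hi + 1 and e == _NEG:
                break
            diag = H_prev[j - 1] if (j >= 1 and lo <= j - 1 <= hi) else _NEG
            h_diag = diag + row[d[j - 1]] if (j >= 1 and diag > _NEG) else _NEG
            hp = H_prev[j] if lo <= j <= hi else _NEG
            fp = F_prev[j] if lo <= j <= hi else _NEG
            f = max(hp - goe if hp > _NEG else _NEG, fp - ge if fp > _NEG else _NEG)
            if h_left > _NEG or e > _NEG:
                e = max(h_left - goe if h_left > _NEG else _NEG, e - ge if e > _NEG else _NEG)
            else:
                e = _NEG
            h = max(h_diag, e, f)
            if h < best - Xg:
                h = _NEG
                f = _NEG
                e_out = _NEG
            else:
                e_out = e
                if h > best:
                    best, bi, bj = h, i, j
            H_cur[j] = h
            F_cur[j] = f
            e = e_out
            h_left = h
            if h > _NEG:
                if new_lo < 0:
                    new_lo = j
                new_hi = j
            j += 1
        if new_lo < 0:
            break  # whole row pruned: extension terminated
        H_prev, H_cur = H_cur, H_prev
        F_prev, F_cur = F_cur, F_prev
        lo, hi = new_lo, new_hi
    return int(best), int(bi), int(bj)


# row-0 diagonal special case: cell (1, j) may use diag from (0, j-1); the
# generic code above covers it because row 0's band always contains j = 0.

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _xdrop_dp_nb = njit(cache=True)(_xdrop_dp_py)
except Exception:  # pragma: no cover
    _xdrop_dp_nb = None


def xdrop_dp_score(
    q: np.ndarray, d: np.ndarray, params: ScoringParams, use_numba: bool = True
) -> tuple[int, int, int]:
    """Best extension score aligning prefixes of ``q`` vs ``d``.

    Returns ``(score, q_consumed, d_consumed)``; (0, 0, 0) when no positive
    extension exists.
    """
    q = np.ascontiguousarray(q, dtype=np.uint8)
    d = np.ascontiguousarray(d, dtype=np.uint8)
    goe = params.gap_open + params.gap_extend
    fn = _xdrop_dp_nb if (use_numba and _xdrop_dp_nb is not None) else _xdrop_dp_py
    return fn(q, d, params.matrix, goe, params.gap_extend, params.xdrop_gapped)


def _xdrop_dp_traceback(q, d, matrix, goe, ge, Xg, stop_i, stop_j):
    """Full-matrix twin of the score DP; traces back from (stop_i, stop_j).

    Returns (score at stop cell, ops) where ops is a list of
    ('M'|'I'|'D') moves from (0,0) to the stop cell; 'I' consumes query
    only (gap in subject), 'D' consumes subject only.
    """
    nq, nd = len(q), len(d)
    H = np.full((nq + 1, nd + 1), _NEG, dtype=np.int64)
    E = np.full((nq + 1, nd + 1), _NEG, dtype=np.int64)
    F = np.full((nq + 1, nd + 1), _NEG, dtype=np.int64)
    best = 0
    H[0, 0] = 0
    lo, hi = 0, 0
    for j in range(1, nd + 1):
        v = -(goe + (j - 1) * ge)
        if v < best - Xg:
            break
        H[0, j] = v
        E[0, j] = v
        hi = j
    for i in range(1, nq + 1):
        row = matrix[q[i - 1]]
        new_lo, new_hi = -1, -1
        e = _NEG
        h_left = _NEG
        j = lo
        while True:
            if j > nd:
                break
            if j > hi + 1 and e == _NEG:
                break
            diag = H[i - 1, j - 1] if (j >= 1 and lo <= j - 1 <= hi) else _NEG
            h_diag = diag + row[d[j - 1]] if (j >= 1 and diag > _NEG) else _NEG
            hp = H[i - 1, j] if lo <= j <= hi else _NEG
            fp = F[i - 1, j] if lo <= j <= hi else _NEG
            f = max(hp - goe if hp > _NEG else _NEG, fp - ge if fp > _NEG else _NEG)
            if h_left > _NEG or e > _NEG:
                e = max(h_left - goe if h_left > _NEG else _NEG, e - ge if e > _NEG else _NEG)
            else:
                e = _NEG
            h = max(h_diag, e, f)
            if h < best - Xg:
                h, f, e_out = _NEG, _NEG, _NEG
            else:
                e_out = e
                if h > best:
                    best = h
            H[i, j] = h
            E[i, j] = e_out
            F[i, j] = f
            e = e_out
            h_left = h
            if h > _NEG:
                if new_lo < 0:
                    new_lo = j
                new_hi = j
            j += 1
        if new_lo < 0:
            break
        lo, hi = new_lo, new_hi
    # traceback
    ops: list[str] = []
    i, j = stop_i, stop_j
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if H[i, j] == E[i, j]:
                state = "E"
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            ops.append("M")
            i, j = i - 1, j - 1
        elif state == "E":  # gap in query, consumes subject
            ops.append("D")
            prev_from_h = H[i, j - 1] - goe
            if E[i, j] == prev_from_h:
                state = "H"
            j -= 1
        else:  # F: gap in subject, consumes query
            ops.append("I")
            prev_from_h = H[i - 1, j] - goe
            if F[i, j] == prev_from_h:
                state = "H"
            i -= 1
    ops.reverse()
    return int(H[stop_i, stop_j]), ops


def _anchor_column(
    segment: UngappedSegment, segment_codes: np.ndarray, store: EncodedSequenceStore, params: ScoringParams
) -> int:
    """Offset (within the segment) of the anchor column: the central column
    of the segment's highest-scoring 11-residue window (ties -> leftmost)."""
    n = segment.length
    col_scores = params.matrix[
        segment_codes[segment.qstart : segment.qend],
        store.codes[segment.dstart : segment.dend],
    ].astype(np.int64)
    w = min(11, n)
    sums = np.convolve(col_scores, np.ones(w, dtype=np.int64), mode="valid")
    win_start = int(np.argmax(sums))  # argmax returns the leftmost maximum
    return win_start + w // 2


def _db_bounds(store: EncodedSequenceStore, dpos: int) -> tuple[int, int]:
    seq = store.sequence_of(dpos)
    start = int(store.offsets[seq])
    return start, start + store.sequence_length(seq)


def gapped_extend(
    segment: UngappedSegment,
    segment_codes: np.ndarray,
    store: EncodedSequenceStore,
    params: ScoringParams,
    use_numba: bool = True,
) -> GappedResult:
    """Score-only gapped extension outward from the segment's anchor."""
    off = _anchor_column(segment, segment_codes, store, params)
    qa = segment.qstart + off
    da = segment.dstart + off
    anchor_score = int(params.matrix[segment_codes[qa], store.codes[da]])
    d_lo, d_hi = _db_bounds(store, da)
    q_right = segment_codes[qa + 1 :]
    d_right = store.codes[da + 1 : d_hi]
    sr, ir, jr = xdrop_dp_score(q_right, d_right, params, use_numba)
    q_left = segment_codes[:qa][::-1]
    d_left = store.codes[d_lo:da][::-1]
    sl, il, jl = xdrop_dp_score(q_left, d_left, params, use_numba)
    return GappedResult(
        segment_id=segment.segment_id,
        score=anchor_score + sl + sr,
        qstart=qa - il,
        qend=qa + 1 + ir,
        dstart=da - jl,
        dend=da + 1 + jr,
        anchor_q=qa,
        anchor_d=da,
    )


_GAP = "-"


def traceback_align(
    result: GappedResult,
    segment_codes: np.ndarray,
    store: EncodedSequenceStore,
    params: ScoringParams,
) -> GappedResult:
    """Recompute the extension DP with full matrices and attach the
    alignment strings; raises :class:`AlignmentInconsistencyError` if the
    recomputed score differs from the score-only result."""
    qa, da = result.anchor_q, result.anchor_d
    goe = params.gap_open + params.gap_extend
    d_lo, d_hi = _db_bounds(store, da)
    sr, ops_r = _xdrop_dp_traceback(
        np.ascontiguousarray(segment_codes[qa + 1 :]),
        np.ascontiguousarray(store.codes[da + 1 : d_hi]),
        params.matrix, goe, params.gap_extend, params.xdrop_gapped,
        result.qend - qa - 1, result.dend - da - 1,
    )
    sl, ops_l = _xdrop_dp_traceback(
        np.ascontiguousarray(segment_codes[:qa][::-1]),
        np.ascontiguousarray(store.codes[d_lo:da][::-1]),
        params.matrix, goe, params.gap_extend, params.xdrop_gapped,
        qa - result.qstart, da - result.dstart,
    )
    anchor_score = int(params.matrix[segment_codes[qa], store.codes[da]])
    total = sl + anchor_score + sr
    if total != result.score:
        raise AlignmentInconsistencyError(
            f"traceback score {total} != score-only result {result.score}"
        )
    ops = [*reversed(ops_l), "M", *ops_r]
    aq, asub, mid = [], [], []
    qi, di = result.qstart, result.dstart
    for op in ops:
        if op == "M":
            qc, dc = segment_codes[qi], store.codes[di]
            a, b = decode([qc]), decode([dc])
            aq.append(a)
            asub.append(b)
            if qc == dc and qc != CODE_DELIM:
                mid.append(a)
            elif params.matrix[qc, dc] > 0:
                mid.append("+")
            else:
                mid.append(" ")
            qi += 1
            di += 1
        elif op == "I":
            aq.append(decode([segment_codes[qi]]))
            asub.append(_GAP)
            mid.append(" ")
            qi += 1
        else:
            aq.append(_GAP)
            asub.append(decode([store.codes[di]]))
            mid.append(" ")
            di += 1
    if qi != result.qend or di != result.dend:
        raise AlignmentInconsistencyError("traceback did not span the reported coordinates")
    return GappedResult(
        segment_id=result.segment_id,
        score=result.score,
        qstart=result.qstart,
        qend=result.qend,
        dstart=result.dstart,
        dend=result.dend,
        anchor_q=qa,
        anchor_d=da,
        aligned_query="".join(aq),
        aligned_subject="".join(asub),
        midline="".join(mid),
    )
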