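"""Thinning of extended segments before gapped extension.

Redundant ungapped segments — near-diagonal duplicates and query-contained
shadows of a stronger segment on the same database sequence — would each
trigger a gapped extension converging to the same alignment.  The filter
keeps, per neighborhood, only the strongest segment.

Rule (deterministic): consider segments in order of score descending (ties:
qstart, then dstart ascending).  A segment is dropped iff an already-kept
segment on the same database sequence either lies within ``band`` diagonals
of it, or fully contains its query interval.  Output is the kept list in
that order.
"""

from __future__ import annotations

from .extend_ungapped import UngappedSegment
from .seq_codec import EncodedSequenceStore

__all__ = ["chain_filter"]


def chain_filter(
    segments: list[UngappedSegment],
    store: EncodedSequenceStore,
    band: int = 16,
) -> list[UngappedSegment]:
    """Filter one query segment's extended segments (single chunk).

    The global maximum-score segment always survives; the operation is
    idempotent.
    """
    if len(segments) <= 1:
        return list(segments)
    order = sorted(segments, key=lambda s: (-s.score, s.qstart, s.dstart))
    kept: list[UngappedSegment] = []
    kept_seq: list[int] = []
    for seg in order:
        seq_id = store.sequence_of(seg.dstart)
        drop = False
        for k, k_seq in zip(kept, kept_seq):
            if k_seq != seq_id:
                continue
            if abs(k.diagonal - seg.diagonal) <= band:
                drop = True
                break
            if k.qstart <= seg.qstart and seg.qend <= k.qend:
                drop = True
                break
        if not drop:
            kept.append(seg)
            kept_seq.append(seq_id)
    return kept
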