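"""Six-frame translation of DNA reads into protein query segments.

Each read is translated in all six frames (three per strand) with the
standard genetic code.  Translations are split at stop codons into maximal
stop-free segments; segments shorter than ``min_len`` residues are dropped
because they cannot seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seq_codec import CODE_X, encode

__all__ = ["QuerySegment", "six_frame_translate", "reverse_complement", "segment_read_coords"]

_TABLE = unambiguous_dna_by_id[1]
_CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QuerySegment:
    """A stop-free translated stretch of one read in one frame.

    ``offset`` is the 0-based nucleotide offset of the segment's first codon
    within the strand-oriented sequence (the read itself for + frames, its
    reverse complement for - frames), so ``3*len(codes) + offset <=
    read_length`` always holds.
    """

    read_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    offset: int
    codes: np.ndarray
    read_length: int

    def __len__(self) -> int:
        return len(self.codes)


def _translate_frame(strand_seq: str, shift: int) -> tuple[str, int]:
    """Translate one frame; returns (aa string with '*' stops, nt offset)."""
    n_codons = (len(strand_seq) - shift) // 3
    aas = []
    for c in range(n_codons):
        codon = strand_seq[shift + 3 * c : shift + 3 * c + 3]
        aas.append(_CODON_AA.get(codon, "X"))
    return "".join(aas), shift


def six_frame_translate(read_id: str, read: str, min_len: int = 10) -> list[QuerySegment]:
    """Translate ``read`` in all six frames and split at stop codons.

    Parameters
    ----------
    read_id:
        Identifier propagated into every emitted segment.
    read:
        DNA string over ``{A,C,G,T,N}``, case-insensitive.
    min_len:
        Minimum segment length in residues (>= 1).

    Returns
    -------
    Segments in frame order (+1,+2,+3,-1,-2,-3), each a maximal stop-free
    run of length >= ``min_len``.  Codons containing N translate to X.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    read = read.upper()
    if set(read) - set("ACGTN"):
        bad = sorted(set(read) - set("ACGTN"))
        raise ValueError(f"read {read_id!r} contains non-DNA characters: {bad}")
    segments: list[QuerySegment] = []
    rc = reverse_complement(read)
    for frame in (1, 2, 3, -1, -2, -3):
        strand_seq = read if frame > 0 else rc
        aa, nt_off = _translate_frame(strand_seq, abs(frame) - 1)
        start = 0
        for chunk in aa.split("*"):
            if len(chunk) >= min_len:
                segments.append(
                    QuerySegment(
                        read_id=read_id,
                        frame=frame,
                        offset=nt_off + 3 * start,
                        codes=encode(chunk),
                        read_length=len(read),
                    )
                )
            start += len(chunk) + 1
    return segments


def segment_read_coords(segment: QuerySegment, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map a half-open residue interval of a segment to 1-based nucleotide
    coordinates on the original read.

    Reverse-frame intervals are reported on the minus strand in BLASTX
    convention, i.e. ``qstart > qend``.
    """
    nt_lo = segment.offset + 3 * aa_start  # strand-oriented, 0-based
    nt_hi = segment.offset + 3 * aa_end  # exclusive
    if segment.frame > 0:
        return nt_lo + 1, nt_hi
    return segment.read_length - nt_lo, segment.read_length - nt_hi + 1
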