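"""Amino-acid encoding, reduced-alphabet projection, and the
delimiter-concatenated sequence store used by every downstream stage.

All residues of a database (or of a batch of query segments) live in one
flat ``uint8`` array, with individual sequences separated by a delimiter
code.  Extension routines can then walk left/right without bounds checks:
they stop when they meet a delimiter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AA_ORDER",
    "CODE_X",
    "CODE_DELIM",
    "GROUP_X",
    "GROUP_DELIM",
    "N_GROUPS",
    "REDUCED_GROUPS",
    "encode",
    "decode",
    "reduce_codes",
    "EncodedSequenceStore",
    "build_store",
]

#: Canonical residues in code order (code = index, alphabetical one-letter).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

CODE_X = 20  #: ambiguous / non-canonical residue
CODE_DELIM = 21  #: sequence separator inside a store

_CHAR_TO_CODE = np.full(256, CODE_X, dtype=np.uint8)
for _i, _aa in enumerate(AA_ORDER):
    _CHAR_TO_CODE[ord(_aa)] = _i
    _CHAR_TO_CODE[ord(_aa.lower())] = _i

_CODE_TO_CHAR = np.array(list(AA_ORDER + "X|"), dtype="U1")

# Murphy-style 10-group partition of the canonical residues, plus one group
# each for X and the delimiter.  This is the metric space used for window
# clustering and seed filtering; it is a tool parameter, not a property of
# the input data.
_GROUP_DEF = [
    "AST",  # 0
    "C",  # 1
    "DN",  # 2
    "EQ",  # 3
    "FWY",  # 4
    "G",  # 5
    "H",  # 6
    "ILMV",  # 7
    "KR",  # 8
    "P",  # 9
]
GROUP_X = 10
GROUP_DELIM = 11
N_GROUPS = 12

REDUCED_GROUPS = np.empty(22, dtype=np.uint8)
for _g, _members in enumerate(_GROUP_DEF):
    for _aa in _members:
        REDUCED_GROUPS[AA_ORDER.index(_aa)] = _g
REDUCED_GROUPS[CODE_X] = GROUP_X
REDUCED_GROUPS[CODE_DELIM] = GROUP_DELIM


def encode(sequence: str) -> np.ndarray:
    """Encode an amino-acid string into codes 0..20.

    Non-canonical characters (B, Z, J, U, O, ...) map to ``CODE_X``.
    The delimiter code is never produced here.

    Parameters
    ----------
    sequence:
        Non-empty amino-acid string, case-insensitive.

    Returns
    -------
    numpy.ndarray of uint8, same length as ``sequence``.
    """
    if len(sequence) == 0:
        raise ValueError("cannot encode an empty sequence")
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CHAR_TO_CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (codes 0..21; delimiter renders as ``|``)."""
    codes = np.asarray(codes)
    if codes.size and (codes.min() < 0 or codes.max() > CODE_DELIM):
        raise ValueError("codes out of range 0..21")
    return "".join(_CODE_TO_CHAR[codes])


def reduce_codes(codes: np.ndarray) -> np.ndarray:
    """Project residue codes onto the 12-group reduced alphabet."""
    codes = np.asarray(codes)
    if codes.size and (codes.min() < 0 or codes.max() > CODE_DELIM):
        raise ValueError("codes out of range 0..21")
    return REDUCED_GROUPS[codes]


@dataclass
class EncodedSequenceStore:
    """All sequences of one collection as a single delimiter-separated array.

    Layout: ``[DELIM, seq0..., DELIM, seq1..., DELIM]`` — the array starts
    and ends with a delimiter and consecutive sequences share one.

    Attributes
    ----------
    codes:
        Flat uint8 array of residue codes plus delimiters.
    offsets:
        Start index of each sequence within ``codes`` (ascending).
    names:
        Per-sequence identifiers, parallel to ``offsets``.
    """

    codes: np.ndarray
    offsets: np.ndarray
    names: list[str]
    groups: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.groups = REDUCED_GROUPS[self.codes]

    @property
    def n_sequences(self) -> int:
        return len(self.offsets)

    @property
    def total_residues(self) -> int:
        return int(len(self.codes) - self.n_sequences - 1)

    def sequence_length(self, i: int) -> int:
        end = self.offsets[i + 1] - 1 if i + 1 < self.n_sequences else len(self.codes) - 1
        return int(end - self.offsets[i])

    def sequence_codes(self, i: int) -> np.ndarray:
        return self.codes[self.offsets[i] : self.offsets[i] + self.sequence_length(i)]

    def sequence_of(self, position: int) -> int:
        """Index of the sequence containing global ``position``.

        ``position`` must not point at a delimiter.
        """
        if self.codes[position] == CODE_DELIM:
            raise ValueError(f"position {position} is a delimiter")
        return int(np.searchsorted(self.offsets, position, side="right") - 1)

    def position_of(self, seq_index: int, residue_index: int) -> int:
        """Global position of residue ``residue_index`` of sequence ``seq_index``."""
        if not 0 <= residue_index < self.sequence_length(seq_index):
            raise IndexError("residue index out of range")
        return int(self.offsets[seq_index] + residue_index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EncodedSequenceStore):
            return NotImplemented
        return (
            np.array_equal(self.codes, other.codes)
            and np.array_equal(self.offsets, other.offsets)
            and self.names == other.names
        )


def build_store(sequences: list[tuple[str, str]]) -> EncodedSequenceStore:
    """Concatenate named amino-acid sequences into an
    :class:`EncodedSequenceStore`.

    Duplicate names are disambiguated deterministically by appending
    ``.2``, ``.3``, ... to later occurrences (with a warning).
    """
    if not sequences:
        raise ValueError("build_store requires at least one sequence")
    total = sum(len(s) for _, s in sequences) + len(sequences) + 1
    codes = np.empty(total, dtype=np.uint8)
    offsets = np.empty(len(sequences), dtype=np.int64)
    names: list[str] = []
    seen: dict[str, int] = {}
    pos = 0
    codes[pos] = CODE_DELIM
    pos += 1
    for i, (name, seq) in enumerate(sequences):
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            warnings.warn(f"duplicate sequence name {name!r}; renamed to {new!r}")
            name = new
        else:
            seen[name] = 1
        names.append(name)
        offsets[i] = pos
        codes[pos : pos + len(seq)] = encode(seq)
        pos += len(seq)
        codes[pos] = CODE_DELIM
        pos += 1
    return EncodedSequenceStore(codes=codes, offsets=offsets, names=names)
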