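"""Database preprocessing: fixed-length subsequence extraction, greedy
clustering in the reduced metric space, lookup-table construction, database
chunking and index serialization.

Clustering groups similar length-``L`` database windows so that at search
time only one representative per cluster needs a full distance computation;
members are screened by a triangle-inequality lower bound from their
precomputed representative distance.

Three lookup tables are built per chunk:

* ``B_e`` — hash key -> positions of singleton-cluster representatives;
* ``B_r`` — hash key -> cluster ids of non-singleton representatives;
* ``B_m`` — cluster id -> cluster (members + distances).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq_codec import (
    CODE_DELIM,
    EncodedSequenceStore,
    build_store,
)

__all__ = [
    "IndexParams",
    "Cluster",
    "IndexTables",
    "DatabaseChunk",
    "extract_subsequences",
    "hamming_distance",
    "hash_key",
    "window_keys",
    "greedy_cluster",
    "build_tables",
    "build_chunk",
    "partition_sequences",
    "chunk_database",
    "save_index",
    "load_index",
    "load_chunk",
    "IndexFormatError",
]

_MAGIC = b"TXSIDX01"
_MANIFEST_VERSION = 1


class IndexFormatError(RuntimeError):
    """Raised when an index file is missing, corrupt, or was built with
    incompatible parameters."""


@dataclass(frozen=True)
class IndexParams:
    """Tunable parameters of the clustered index.

    The subsequence length, clustering threshold, hash-key prefix length and
    reduced alphabet are all tool parameters; they must match between build
    and search time.
    """

    subseq_len: int = 10  # L
    cluster_threshold: int = 1  # T_c; negative forces all-singleton clusters
    key_len: int = 5  # k_h
    alphabet: str = "murphy10"

    def __post_init__(self) -> None:
        if self.subseq_len < 1:
            raise ValueError("subseq_len must be >= 1")
        if self.key_len < 1 or self.key_len > self.subseq_len:
            raise ValueError("key_len must be in 1..subseq_len")
        if self.alphabet != "murphy10":
            raise ValueError(f"unknown reduced alphabet {self.alphabet!r}")


@dataclass
class Cluster:
    """A group of database windows within ``cluster_threshold`` of one
    representative window (reduced-Hamming distance)."""

    representative: int  # global position of the representative window
    members: np.ndarray  # global positions, excluding the representative
    member_distances: np.ndarray  # d(r, m), parallel to members

    @property
    def size(self) -> int:
        return 1 + len(self.members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cluster):
            return NotImplemented
        return (
            self.representative == other.representative
            and np.array_equal(self.members, other.members)
            and np.array_equal(self.member_distances, other.member_distances)
        )


@dataclass
class IndexTables:
    """The three seed-lookup tables of one chunk."""

    b_e: dict[int, np.ndarray]  # key -> singleton representative positions
    b_r: dict[int, np.ndarray]  # key -> non-singleton cluster ids
    b_m: dict[int, Cluster]  # cluster id -> cluster

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IndexTables):
            return NotImplemented
        if set(self.b_e) != set(other.b_e) or set(self.b_r) != set(other.b_r):
            return False
        return (
            all(np.array_equal(self.b_e[k], other.b_e[k]) for k in self.b_e)
            and all(np.array_equal(self.b_r[k], other.b_r[k]) for k in self.b_r)
            and self.b_m == other.b_m
        )


@dataclass
class DatabaseChunk:
    """One independently searchable slice of the database."""

    chunk_id: int
    store: EncodedSequenceStore
    tables: IndexTables
    seq_id_offset: int  # global id of this chunk's first sequence
    params: IndexParams = field(default_factory=IndexParams)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatabaseChunk):
            return NotImplemented
        return (
            self.chunk_id == other.chunk_id
            and self.store == other.store
            and self.tables == other.tables
            and self.seq_id_offset == other.seq_id_offset
            and self.params == other.params
        )


def extract_subsequences(store: EncodedSequenceStore, L: int = 10) -> np.ndarray:
    """Positions of all delimiter-free windows of length ``L``, ascending."""
    if L < 1:
        raise ValueError("L must be >= 1")
    delim = (store.codes == CODE_DELIM).astype(np.int64)
    if len(store.codes) < L:
        return np.empty(0, dtype=np.int64)
    csum = np.concatenate(([0], np.cumsum(delim)))
    window_delims = csum[L:] - csum[:-L]  # delimiters inside window at each start
    return np.nonzero(window_delims == 0)[0].astype(np.int64)


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Number of positions at which two group arrays differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def hash_key(groups: np.ndarray, k_h: int = 5) -> int | None:
    """Base-10 positional key of the first ``k_h`` group ids
    (most-significant-first); ``None`` if the prefix is unkeyable
    (contains the X or delimiter group)."""
    if len(groups) < k_h:
        raise ValueError("group array shorter than key length")
    key = 0
    for g in groups[:k_h]:
        if g > 9:
            return None
        key = key * 10 + int(g)
    return key


def window_keys(groups: np.ndarray, positions: np.ndarray, k_h: int) -> np.ndarray:
    """Vectorized :func:`hash_key` for many windows of one group array.

    Returns an int64 array parallel to ``positions``; unkeyable windows get
    key -1.
    """
    if len(positions) == 0:
        return np.empty(0, dtype=np.int64)
    idx = positions[:, None] + np.arange(k_h)[None, :]
    prefix = groups[idx].astype(np.int64)
    bad = (prefix > 9).any(axis=1)
    weights = 10 ** np.arange(k_h - 1, -1, -1, dtype=np.int64)
    keys = prefix @ weights
    keys[bad] = -1
    return keys


def greedy_cluster(
    subsequences: np.ndarray,
    store: EncodedSequenceStore,
    T_c: int = 1,
    L: int = 10,
    k_h: int = 5,
) -> list[Cluster]:
    """Single-pass greedy clustering of database windows.

    Windows are processed in ascending position order.  Each window joins
    the first existing cluster (creation order) that shares its hash key and
    whose representative is within ``T_c`` reduced-Hamming distance over all
    ``L`` positions; otherwise it founds a new cluster.  Windows whose key
    prefix contains the X or delimiter group are skipped entirely.

    ``T_c < 0`` forces every window into its own singleton cluster (used to
    measure the benefit of clustering).
    """
    groups = store.groups
    keys = window_keys(groups, subsequences, k_h)
    reps: list[int] = []
    rep_windows: list[np.ndarray] = []
    members: list[list[int]] = []
    distances: list[list[int]] = []
    by_key: dict[int, list[int]] = {}
    for pos, key in zip(subsequences.tolist(), keys.tolist()):
        if key < 0:
            continue
        win = groups[pos : pos + L]
        joined = False
        if T_c >= 0:
            for cid in by_key.get(key, ()):
                d = int(np.count_nonzero(win != rep_windows[cid]))
                if d <= T_c:
                    members[cid].append(pos)
                    distances[cid].append(d)
                    joined = True
                    break
        if not joined:
            cid = len(reps)
            reps.append(pos)
            rep_windows.append(win)
            members.append([])
            distances.append([])
            by_key.setdefault(key, []).append(cid)
    return [
        Cluster(
            representative=reps[i],
            members=np.array(members[i], dtype=np.int64),
            member_distances=np.array(distances[i], dtype=np.int64),
        )
        for i in range(len(reps))
    ]


def build_tables(
    clusters: list[Cluster], store: EncodedSequenceStore, params: IndexParams
) -> IndexTables:
    """Partition clusters into the B_e / B_r / B_m lookup tables."""
    b_e: dict[int, list[int]] = {}
    b_r: dict[int, list[int]] = {}
    b_m: dict[int, Cluster] = {}
    for cid, cluster in enumerate(clusters):
        key = hash_key(
            store.groups[cluster.representative : cluster.representative + params.subseq_len],
            params.key_len,
        )
        assert key is not None  # unkeyable windows never become clusters
        if cluster.size == 1:
            b_e.setdefault(key, []).append(cluster.representative)
        else:
            b_r.setdefault(key, []).append(cid)
            b_m[cid] = cluster
    return IndexTables(
        b_e={k: np.array(v, dtype=np.int64) for k, v in b_e.items()},
        b_r={k: np.array(v, dtype=np.int64) for k, v in b_r.items()},
        b_m=b_m,
    )


def build_chunk(
    sequences: list[tuple[str, str]],
    chunk_id: int,
    seq_id_offset: int,
    params: IndexParams,
) -> DatabaseChunk:
    """Encode, cluster and index one chunk's worth of sequences."""
    store = build_store(sequences)
    subs = extract_subsequences(store, params.subseq_len)
    clusters = greedy_cluster(
        subs, store, params.cluster_threshold, params.subseq_len, params.key_len
    )
    tables = build_tables(clusters, store, params)
    return DatabaseChunk(
        chunk_id=chunk_id,
        store=store,
        tables=tables,
        seq_id_offset=seq_id_offset,
        params=params,
    )


def partition_sequences(
    sequences: list[tuple[str, str]], chunk_bytes: int
) -> list[list[tuple[str, str]]]:
    """Greedy in-order assignment of sequences to chunks.

    A chunk closes when adding the next sequence would exceed
    ``chunk_bytes`` at 1 byte per residue.  A single sequence larger than
    the budget is an error.
    """
    chunks: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    used = 0
    for name, seq in sequences:
        if len(seq) > chunk_bytes:
            raise ValueError(
                f"sequence {name!r} ({len(seq)} residues) exceeds chunk size {chunk_bytes}"
            )
        if current and used + len(seq) > chunk_bytes:
            chunks.append(current)
            current = []
            used = 0
        current.append((name, seq))
        used += len(seq)
    if current:
        chunks.append(current)
    return chunks


def chunk_database(
    sequences: list[tuple[str, str]],
    chunk_bytes: int = 1 << 30,
    params: IndexParams | None = None,
) -> list[DatabaseChunk]:
    """Partition the database and build one indexed chunk per slice."""
    params = params or IndexParams()
    parts = partition_sequences(sequences, chunk_bytes)
    chunks = []
    offset = 0
    for cid, part in enumerate(parts):
        chunks.append(build_chunk(part, cid, offset, params))
        offset += len(part)
    return chunks


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _write_array(fh, arr: np.ndarray, dtype: str) -> None:
    arr = np.ascontiguousarray(arr, dtype=dtype)
    fh.write(struct.pack("<q", arr.size))
    fh.write(arr.tobytes())


def _read_array(fh, dtype: str) -> np.ndarray:
    (n,) = struct.unpack("<q", fh.read(8))
    itemsize = np.dtype(dtype).itemsize
    buf = fh.read(n * itemsize)
    if len(buf) != n * itemsize:
        raise IndexFormatError("truncated index file")
    return np.frombuffer(buf, dtype=dtype).copy()


def _save_chunk(chunk: DatabaseChunk, path: Path) -> None:
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        header = {
            "subseq_len": chunk.params.subseq_len,
            "cluster_threshold": chunk.params.cluster_threshold,
            "key_len": chunk.params.key_len,
            "alphabet": chunk.params.alphabet,
            "chunk_id": chunk.chunk_id,
            "seq_id_offset": chunk.seq_id_offset,
            "names": chunk.store.names,
        }
        blob = json.dumps(header, sort_keys=True).encode()
        fh.write(struct.pack("<q", len(blob)))
        fh.write(blob)
        _write_array(fh, chunk.store.codes, "uint8")
        _write_array(fh, chunk.store.offsets, "<i8")
        t = chunk.tables
        for table in (t.b_e, t.b_r):
            keys = sorted(table)
            _write_array(fh, np.array(keys, dtype=np.int64), "<i8")
            for k in keys:
                _write_array(fh, table[k], "<i8")
        cids = sorted(t.b_m)
        _write_array(fh, np.array(cids, dtype=np.int64), "<i8")
        for cid in cids:
            c = t.b_m[cid]
            fh.write(struct.pack("<q", c.representative))
            _write_array(fh, c.members, "<i8")
            _write_array(fh, c.member_distances, "<i8")


def load_chunk(path: str | Path, expected: IndexParams | None = None) -> DatabaseChunk:
    """Load one chunk file; validates magic bytes and index parameters."""
    path = Path(path)
    if not path.exists():
        raise IndexFormatError(f"missing chunk file: {path}")
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise IndexFormatError(f"{path}: not a txsearch index chunk (bad magic)")
        (hlen,) = struct.unpack("<q", fh.read(8))
        header = json.loads(fh.read(hlen))
        params = IndexParams(
            subseq_len=header["subseq_len"],
            cluster_threshold=header["cluster_threshold"],
            key_len=header["key_len"],
            alphabet=header["alphabet"],
        )
        if expected is not None and params != expected:
            raise IndexFormatError(
                f"{path}: index parameters {params} do not match expected {expected}"
            )
        codes = _read_array(fh, "uint8")
        offsets = _read_array(fh, "<i8")
        store = EncodedSequenceStore(codes=codes, offsets=offsets, names=header["names"])
        tables: list[dict[int, np.ndarray]] = []
        for _ in range(2):
            keys = _read_array(fh, "<i8")
            tables.append({int(k): _read_array(fh, "<i8") for k in keys})
        cids = _read_array(fh, "<i8")
        b_m: dict[int, Cluster] = {}
        for cid in cids:
            (rep,) = struct.unpack("<q", fh.read(8))
            members = _read_array(fh, "<i8")
            dists = _read_array(fh, "<i8")
            b_m[int(cid)] = Cluster(rep, members, dists)
        return DatabaseChunk(
            chunk_id=header["chunk_id"],
            store=store,
            tables=IndexTables(b_e=tables[0], b_r=tables[1], b_m=b_m),
            seq_id_offset=header["seq_id_offset"],
            params=params,
        )


def save_index(chunks: list[DatabaseChunk], prefix: str | Path) -> Path:
    """Write all chunk files plus a JSON manifest; returns the manifest path."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    chunk_files = []
    total_residues = 0
    total_sequences = 0
    for chunk in chunks:
        fname = f"{prefix.name}.c{chunk.chunk_id:04d}.idx"
        _save_chunk(chunk, prefix.parent / fname)
        chunk_files.append(fname)
        total_residues += chunk.store.total_residues
        total_sequences += chunk.store.n_sequences
    p = chunks[0].params
    manifest = {
        "format": "txsearch-index",
        "version": _MANIFEST_VERSION,
        "params": {
            "subseq_len": p.subseq_len,
            "cluster_threshold": p.cluster_threshold,
            "key_len": p.key_len,
            "alphabet": p.alphabet,
        },
        "total_residues": total_residues,
        "total_sequences": total_sequences,
        "chunks": chunk_files,
    }
    mpath = prefix.parent / f"{prefix.name}.manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return mpath


def load_index(prefix: str | Path) -> tuple[dict, list[Path]]:
    """Read a manifest; returns (manifest dict, ordered chunk paths).

    Chunks themselves are loaded lazily via :func:`load_chunk` so the
    scheduler can stream them.
    """
    prefix = Path(prefix)
    mpath = prefix.parent / f"{prefix.name}.manifest.json"
    if not mpath.exists():
        raise IndexFormatError(f"missing index manifest: {mpath}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "txsearch-index" or manifest.get("version") != _MANIFEST_VERSION:
        raise IndexFormatError(f"{mpath}: unsupported index format/version")
    return manifest, [mpath.parent / c for c in manifest["chunks"]]
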