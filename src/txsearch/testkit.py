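"""Oracles and synthetic fixtures.

This module is first-class, tested code: a full Smith-Waterman reference
(independent of every pipeline code path), an unpruned extension-DP oracle,
brute-force clustering/seeding oracles, and a seeded read simulator that
emulates short metagenomic reads sampled from protein-coding regions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .db_index import DatabaseChunk, hash_key
from .extend_ungapped import ScoringParams
from .seeding_filter import FilterParams, lookup_keys
from .seq_codec import AA_ORDER, EncodedSequenceStore, encode, reduce_codes
from .translate import _CODON_AA

__all__ = [
    "SimConfig",
    "SimData",
    "simulate",
    "write_sim_files",
    "smith_waterman",
    "sw_score",
    "extension_best",
    "brute_force_cluster",
    "exact_seed_set",
    "top_hit_agreement",
]

_NEG = -(2**30)


# ---------------------------------------------------------------------------
# read simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset (identical seed -> identical data)."""

    seed: int = 42
    n_proteins: int = 200
    protein_len_range: tuple[int, int] = (100, 400)
    n_reads: int = 200
    read_length: int = 150
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    decoy_fraction: float = 0.0


@dataclass
class SimData:
    proteins: list[tuple[str, str]]
    reads: list[tuple[str, str]]
    # read id -> (protein id, aa window start, aa window end, strand, n_sub, n_indel)
    truth: dict[str, tuple[str, int, int, str, int, int]]


_CODONS_FOR: dict[str, list[str]] = defaultdict(list)
for _codon, _aa in sorted(_CODON_AA.items()):
    if _aa != "*":
        _CODONS_FOR[_aa].append(_codon)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate(config: SimConfig) -> SimData:
    """Generate proteins, reads sampled from their coding regions, and a
    truth table.

    Proteins are i.i.d. uniform over the 20 residues.  Each non-decoy read
    reverse-translates a random protein window (uniform codon choice), takes
    a random strand, then mutates at the DNA level: substitutions replace a
    base with a different one; indels insert a random base or delete one.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_len_range
    proteins = []
    for i in range(config.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(AA_ORDER[c] for c in rng.integers(0, 20, size=n))
        proteins.append((f"prot{i:05d}", seq))
    reads = []
    truth: dict[str, tuple[str, int, int, str, int, int]] = {}
    aa_len = config.read_length // 3
    n_decoys = int(round(config.decoy_fraction * config.n_reads))
    for i in range(config.n_reads):
        rid = f"read{i:05d}"
        if i < n_decoys:
            dna = "".join(_BASES[b] for b in rng.integers(0, 4, size=config.read_length))
            reads.append((rid, dna))
            continue
        pi = int(rng.integers(0, config.n_proteins))
        pname, pseq = proteins[pi]
        start = int(rng.integers(0, len(pseq) - aa_len + 1))
        window = pseq[start : start + aa_len]
        dna = "".join(
            _CODONS_FOR[aa][int(rng.integers(0, len(_CODONS_FOR[aa])))] for aa in window
        )
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            dna = dna.translate(_COMPLEMENT)[::-1]
        out = []
        n_sub = 0
        n_indel = 0
        for base in dna:
            r = rng.random()
            if r < config.substitution_rate:
                alt = _BASES[int(rng.integers(0, 3))]
                if alt == base:
                    alt = _BASES[3]
                out.append(alt)
                n_sub += 1
            elif r < config.substitution_rate + config.indel_rate:
                n_indel += 1
                if rng.random() < 0.5:
                    out.append(_BASES[int(rng.integers(0, 4))])
                    out.append(base)
                # else: deletion, emit nothing
            else:
                out.append(base)
        reads.append((rid, "".join(out)))
        truth[rid] = (pname, start, start + aa_len, strand, n_sub, n_indel)
    return SimData(proteins=proteins, reads=reads, truth=truth)


def write_sim_files(data: SimData, outdir: str | Path) -> tuple[Path, Path, Path]:
    """Write protein FASTA, read FASTQ and the TSV truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fa = outdir / "proteins.fasta"
    fq = outdir / "reads.fastq"
    tsv = outdir / "truth.tsv"
    with open(fa, "w") as fh:
        for name, seq in data.proteins:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(fq, "w") as fh:
        for rid, dna in data.reads:
            fh.write(f"@{rid}\n{dna}\n+\n{'I' * len(dna)}\n")
    with open(tsv, "w") as fh:
        fh.write("read_id\tprotein_id\taa_start\taa_end\tstrand\tn_sub\tn_indel\n")
        for rid, (pid, s, e, strand, ns, ni) in data.truth.items():
            fh.write(f"{rid}\t{pid}\t{s}\t{e}\t{strand}\t{ns}\t{ni}\n")
    return fa, fq, tsv


# ---------------------------------------------------------------------------
# Smith-Waterman reference (independent of the pipeline DP code)
# ---------------------------------------------------------------------------


def smith_waterman(
    query: str, subject: str, params: ScoringParams | None = None
) -> tuple[int, tuple[int, int, int, int], tuple[str, str]]:
    """Exact affine-gap local alignment with full-matrix traceback.

    Gap of length g costs ``gap_open + g * gap_extend``.  Returns
    ``(score, (qstart, qend, sstart, send), (aligned_query, aligned_subject))``
    with 0-based half-open coordinates; a best score of 0 yields empty
    coordinates and strings.
    """
    params = params or ScoringParams()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q = encode(query)
    s = encode(subject)
    nq, ns = len(q), len(s)
    goe = params.gap_open + params.gap_extend
    ge = params.gap_extend
    m = params.matrix
    H = np.zeros((nq + 1, ns + 1), dtype=np.int64)
    E = np.full((nq + 1, ns + 1), _NEG, dtype=np.int64)
    F = np.full((nq + 1, ns + 1), _NEG, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, nq + 1):
        for j in range(1, ns + 1):
            E[i, j] = max(H[i, j - 1] - goe, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - goe, F[i - 1, j] - ge)
            h = max(0, H[i - 1, j - 1] + int(m[q[i - 1], s[j - 1]]), E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return 0, (0, 0, 0, 0), ("", "")
    aq, asub = [], []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == E[i, j]:
                state = "E"
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            aq.append(query[i - 1])
            asub.append(subject[j - 1])
            i, j = i - 1, j - 1
        elif state == "E":
            aq.append("-")
            asub.append(subject[j - 1])
            if E[i, j] == H[i, j - 1] - goe:
                state = "H"
            j -= 1
        else:
            aq.append(query[i - 1])
            asub.append("-")
            if F[i, j] == H[i - 1, j] - goe:
                state = "H"
            i -= 1
    aq.reverse()
    asub.reverse()
    return best, (i, bi, j, bj), ("".join(aq), "".join(asub))


def _sw_score_impl(q, s, matrix, goe, ge):
    nq, ns = len(q), len(s)
    H = np.zeros(ns + 1, dtype=np.int64)
    E = np.full(ns + 1, _NEG, dtype=np.int64)
    best = 0
    for i in range(nq):
        diag = 0
        f = _NEG
        row = matrix[q[i]]
        for j in range(1, ns + 1):
            E[j] = max(H[j] - goe, E[j] - ge)
            f = max(H[j - 1] - goe, f - ge)
            h = diag + row[s[j - 1]]
            if E[j] > h:
                h = E[j]
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


try:  # pragma: no cover
    from numba import njit

    _sw_score_nb = njit(cache=True)(_sw_score_impl)
except Exception:  # pragma: no cover
    _sw_score_nb = None


def sw_score(query: str, subject: str, params: ScoringParams | None = None, use_numba: bool = True) -> int:
    """Smith-Waterman score only (linear memory; numba-accelerated)."""
    params = params or ScoringParams()
    q = np.ascontiguousarray(encode(query))
    s = np.ascontiguousarray(encode(subject))
    fn = _sw_score_nb if (use_numba and _sw_score_nb is not None) else _sw_score_impl
    return int(fn(q, s, params.matrix, params.gap_open + params.gap_extend, params.gap_extend))


def best_subject_by_sw(
    reads: list[tuple[str, str]],
    proteins: list[tuple[str, str]],
    params: ScoringParams | None = None,
    min_len: int = 10,
    use_numba: bool = True,
) -> dict[str, tuple[int, set[str]]]:
    """Exhaustive Smith-Waterman oracle over a read set.

    For each read, scores every six-frame segment (length >= ``min_len``)
    against every protein and returns the best score with the set of
    co-optimal subjects.  Reads whose best score is 0 are omitted.
    """
    from .translate import six_frame_translate

    params = params or ScoringParams()
    fn = _sw_score_nb if (use_numba and _sw_score_nb is not None) else _sw_score_impl
    goe = params.gap_open + params.gap_extend
    prot_codes = [
        (name, np.ascontiguousarray(encode(seq))) for name, seq in proteins
    ]
    out: dict[str, tuple[int, set[str]]] = {}
    for rid, dna in reads:
        segments = [
            np.ascontiguousarray(s.codes)
            for s in six_frame_translate(rid, dna, min_len)
        ]
        best = 0
        subjects: set[str] = set()
        for pname, pcodes in prot_codes:
            p_best = 0
            for seg in segments:
                sc = int(fn(seg, pcodes, params.matrix, goe, params.gap_extend))
                if sc > p_best:
                    p_best = sc
            if p_best > best:
                best, subjects = p_best, {pname}
            elif p_best == best and best > 0:
                subjects.add(pname)
        if best > 0:
            out[rid] = (best, subjects)
    return out


def extension_best(q: np.ndarray, d: np.ndarray, params: ScoringParams) -> tuple[int, int, int]:
    """Unpruned extension oracle: full quadratic affine DP aligning prefixes
    of ``q`` vs ``d`` (H(0,0)=0, leading gaps charged), best over all cells.

    Independent of the pipeline's banded X-drop implementation.
    """
    nq, nd = len(q), len(d)
    goe = params.gap_open + params.gap_extend
    ge = params.gap_extend
    m = params.matrix
    H = np.full((nq + 1, nd + 1), _NEG, dtype=np.int64)
    E = np.full((nq + 1, nd + 1), _NEG, dtype=np.int64)
    F = np.full((nq + 1, nd + 1), _NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, nd + 1):
        E[0, j] = max(H[0, j - 1] - goe, E[0, j - 1] - ge)
        H[0, j] = E[0, j]
    for i in range(1, nq + 1):
        F[i, 0] = max(H[i - 1, 0] - goe, F[i - 1, 0] - ge)
        H[i, 0] = F[i, 0]
        for j in range(1, nd + 1):
            E[i, j] = max(H[i, j - 1] - goe, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - goe, F[i - 1, j] - ge)
            H[i, j] = max(H[i - 1, j - 1] + int(m[q[i - 1], d[j - 1]]), E[i, j], F[i, j])
    best, bi, bj = 0, 0, 0
    for i in range(nq + 1):
        for j in range(nd + 1):
            if H[i, j] > best:
                best, bi, bj = int(H[i, j]), i, j
    return best, bi, bj


# ---------------------------------------------------------------------------
# brute-force index/seeding oracles
# ---------------------------------------------------------------------------


def brute_force_cluster(
    subsequences: np.ndarray,
    store: EncodedSequenceStore,
    T_c: int,
    L: int = 10,
    k_h: int = 5,
) -> list[tuple[int, list[int], list[int]]]:
    """Straightforward re-implementation of the greedy clustering rule
    without hash tables: scan all existing clusters in creation order,
    restrict to equal hash key, join the first within ``T_c``.

    Returns ``(representative, members, distances)`` triples.
    """
    clusters: list[tuple[int, list[int], list[int]]] = []
    for pos in subsequences.tolist():
        win = reduce_codes(store.codes[pos : pos + L])
        key = hash_key(win, k_h)
        if key is None:
            continue
        placed = False
        if T_c >= 0:
            for rep, members, dists in clusters:
                rep_win = reduce_codes(store.codes[rep : rep + L])
                if hash_key(rep_win, k_h) != key:
                    continue
                d = sum(1 for a, b in zip(win, rep_win) if a != b)
                if d <= T_c:
                    members.append(pos)
                    dists.append(d)
                    placed = True
                    break
        if not placed:
            clusters.append((pos, [], []))
    return clusters


def exact_seed_set(
    segment_codes: np.ndarray, chunk: DatabaseChunk, params: FilterParams
) -> set[tuple[int, int]]:
    """Key-reachable (qpos, dpos) pairs whose *true* reduced distance is
    <= T_f — the set the clustered filter must never reject.

    A database window is key-reachable from a query window when the hash
    key under which it is indexed (its own key for singletons, its
    representative's key for cluster members) is among the query's lookup
    keys.
    """
    L = chunk.params.subseq_len
    k_h = chunk.params.key_len
    qgroups = reduce_codes(segment_codes)
    dgroups = chunk.store.groups
    out: set[tuple[int, int]] = set()
    # indexed positions -> key under which they are reachable
    reach: dict[int, int] = {}
    for key, positions in chunk.tables.b_e.items():
        for p in positions.tolist():
            reach[p] = key
    for key, cids in chunk.tables.b_r.items():
        for cid in cids.tolist():
            c = chunk.tables.b_m[cid]
            reach[c.representative] = key
            for mpos in c.members.tolist():
                reach[mpos] = key
    for qpos in range(len(segment_codes) - L + 1):
        qwin = qgroups[qpos : qpos + L]
        keys = set(lookup_keys(qwin, k_h, params.lookup_radius))
        if not keys:
            continue
        for dpos, key in reach.items():
            if key not in keys:
                continue
            d = int(np.count_nonzero(dgroups[dpos : dpos + L] != qwin))
            if d <= params.filter_threshold:
                out.add((qpos, dpos))
    return out


# ---------------------------------------------------------------------------
# sensitivity metric
# ---------------------------------------------------------------------------


def top_hit_agreement(
    pipeline_hits: list,
    oracle_best: dict[str, tuple[int, set[str]]],
    e_cut: float = 1e-5,
    restrict_to: set[str] | None = None,
) -> float | None:
    """Fraction of queries whose pipeline top subject matches the oracle's.

    ``pipeline_hits`` are ranked records with ``query_id``, ``subject_id``,
    ``score`` and ``evalue`` attributes; ``oracle_best`` maps query id to
    ``(best score, co-optimal subject ids)``.  The denominator is the set
    of queries with at least one pipeline hit at E <= ``e_cut`` (optionally
    intersected with ``restrict_to``); oracle ties count as correct when
    the pipeline reports any co-optimal subject at its top score.  Returns
    ``None`` (undefined, distinct from 0) for an empty denominator.
    """
    best_by_query: dict[str, tuple[int, set[str]]] = {}
    for h in pipeline_hits:
        if h.evalue > e_cut:
            continue
        if restrict_to is not None and h.query_id not in restrict_to:
            continue
        score, subjects = best_by_query.get(h.query_id, (None, set()))
        if score is None or h.score > score:
            best_by_query[h.query_id] = (h.score, {h.subject_id})
        elif h.score == score:
            subjects.add(h.subject_id)
    if not best_by_query:
        return None
    n_correct = 0
    for qid, (_, subjects) in best_by_query.items():
        oracle = oracle_best.get(qid)
        if oracle is not None and subjects & oracle[1]:
            n_correct += 1
    return n_correct / len(best_by_query)
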