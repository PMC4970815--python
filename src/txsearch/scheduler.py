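"""Two-phase batched execution over database chunks.

Phase 1 (per chunk): seed search + similarity filtering + ungapped
extension, per query segment.  Phase 2: chain filtering, then gapped
extension of the survivors in budgeted batches, each batch dispatched in
ascending query-segment-length order (a load-balancing device that must not
— and does not — affect results).  Chunks are processed sequentially; the
next chunk may be prefetched on a background thread while the current one
is searched.

All parallel/batched paths are contractually equivalent to the serial
composition of the stage functions; every merge step sorts on
chunk-independent keys so worker count, batch budget, chunk count and
prefetch can never change the output.
"""

from __future__ import annotations

import hashlib
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from .chain_filter import chain_filter
from .db_index import DatabaseChunk, load_chunk
from .extend_gapped import GappedResult, gapped_extend, traceback_align
from .extend_ungapped import ScoringParams, UngappedSegment, ungapped_extend
from .seeding_filter import FilterParams, SearchStats, search_seeds
from .stats_evalue import SearchSpace, bit_score, evalue, rank_and_threshold
from .translate import QuerySegment, segment_read_coords, six_frame_translate

__all__ = ["SearchConfig", "Hit", "run_phase1", "run_phase2", "run_search", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed for a specific query segment."""


@dataclass(frozen=True)
class SearchConfig:
    """All knobs of one search run."""

    filter: FilterParams = field(default_factory=FilterParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    min_segment_len: int = 10
    chain_band: int = 16
    e_cut: float = 10.0
    max_targets: int = 25
    lam: float = 0.267
    K: float = 0.041
    workers: int = 1
    batch_budget: int = 1 << 16
    prefetch: bool = True
    use_numba: bool = True


@dataclass(frozen=True)
class Hit:
    """One reported HSP, ready for tabular output."""

    query_id: str
    query_index: int  # read order, for stable per-query grouping
    subject_id: str
    frame: int
    score: int  # raw score
    bits: float
    evalue: float
    length: int  # alignment columns
    n_ident: int
    mismatch: int
    gapopen: int
    gaps: int
    qstart: int  # 1-based nucleotide coords on the read (qstart > qend on -)
    qend: int
    sstart: int  # 1-based amino-acid coords on the subject
    send: int
    aligned_query: str
    aligned_subject: str
    midline: str

    @property
    def pident(self) -> float:
        return 100.0 * self.n_ident / self.length


def _phase1_one(
    segment: QuerySegment, segment_id: int, chunk: DatabaseChunk, config: SearchConfig
) -> tuple[list[UngappedSegment], SearchStats]:
    stats = SearchStats()
    try:
        seeds = search_seeds(segment.codes, segment_id, chunk, config.filter, stats)
        out: list[UngappedSegment] = []
        seen: set[tuple[int, int, int, int]] = set()
        for seed in seeds:
            seg = ungapped_extend(
                seed, segment.codes, chunk.store, config.scoring, chunk.params.subseq_len
            )
            if seg is None:
                continue
            key = (seg.qstart, seg.qend, seg.dstart, seg.dend)
            if key not in seen:
                seen.add(key)
                out.append(seg)
        return out, stats
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"phase 1 failed for query segment {segment_id}") from exc


def run_phase1(
    segments: list[QuerySegment],
    chunk: DatabaseChunk,
    config: SearchConfig,
    stats: SearchStats | None = None,
    log: list[str] | None = None,
) -> dict[int, list[UngappedSegment]]:
    """Seed + filter + ungapped-extend every query segment against a chunk.

    Returns a map from segment id (index into ``segments``) to its
    surviving ungapped segments.  Equal to the serial composition of the
    stage functions for any worker count.
    """
    ids = list(range(len(segments)))
    if config.workers > 1 and len(segments) > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            results = list(
                pool.map(lambda i: _phase1_one(segments[i], i, chunk, config), ids)
            )
    else:
        results = [_phase1_one(segments[i], i, chunk, config) for i in ids]
    out: dict[int, list[UngappedSegment]] = {}
    for i, (segs, st) in zip(ids, results):
        if segs:
            out[i] = segs
        if stats is not None:
            stats.merge(st)
    if log is not None:
        log.append(
            f"phase=1 chunk={chunk.chunk_id} segments={len(segments)} "
            f"tasks={sum(len(v) for v in out.values())}"
        )
    return out


def _dispatch_batch(
    batch: list[tuple[int, UngappedSegment]],
    segments: list[QuerySegment],
    chunk: DatabaseChunk,
    config: SearchConfig,
    log: list[str] | None,
) -> list[GappedResult]:
    # load-balancing sort: query segment length ascending (ties: stable ids)
    batch = sorted(
        batch, key=lambda t: (len(segments[t[0]]), t[0], t[1].qstart, t[1].dstart)
    )
    if log is not None:
        order = ",".join(str(t[0]) for t in batch)
        digest = hashlib.sha256(order.encode()).hexdigest()[:12]
        log.append(
            f"phase=2 chunk={chunk.chunk_id} tasks={len(batch)} order_hash={digest} "
            f"lengths={'|'.join(str(len(segments[t[0]])) for t in batch)}"
        )

    def one(task: tuple[int, UngappedSegment]) -> GappedResult:
        sid, seg = task
        try:
            return gapped_extend(
                seg, segments[sid].codes, chunk.store, config.scoring, config.use_numba
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"phase 2 failed for query segment {sid}") from exc

    if config.workers > 1 and len(batch) > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            return list(pool.map(one, batch))
    return [one(t) for t in batch]


def run_phase2(
    phase1_out: dict[int, list[UngappedSegment]],
    segments: list[QuerySegment],
    chunk: DatabaseChunk,
    config: SearchConfig,
    log: list[str] | None = None,
) -> list[GappedResult]:
    """Chain-filter phase-1 segments and gapped-extend the survivors.

    Tasks are dispatched in budgeted batches; results are re-sorted on
    task-intrinsic keys, so batch budget and worker count are invisible in
    the output.
    """
    tasks: list[tuple[int, UngappedSegment]] = []
    for sid in sorted(phase1_out):
        for seg in chain_filter(phase1_out[sid], chunk.store, config.chain_band):
            tasks.append((sid, seg))
    results: list[GappedResult] = []
    buffer: list[tuple[int, UngappedSegment]] = []
    for task in tasks:
        buffer.append(task)
        if len(buffer) >= config.batch_budget:
            results.extend(_dispatch_batch(buffer, segments, chunk, config, log))
            buffer = []
    if buffer:
        results.extend(_dispatch_batch(buffer, segments, chunk, config, log))
    results.sort(key=lambda r: (r.segment_id, r.qstart, r.dstart, r.qend, r.dend, -r.score))
    return results


def _hits_from_chunk(
    gapped: list[GappedResult],
    segments: list[QuerySegment],
    read_index: dict[str, int],
    chunk: DatabaseChunk,
    total_db_residues: int,
    config: SearchConfig,
) -> list[Hit]:
    hits: list[Hit] = []
    for res in gapped:
        segment = segments[res.segment_id]
        space = SearchSpace(
            query_length=len(segment), db_residues=total_db_residues, lam=config.lam, K=config.K
        )
        e = evalue(res.score, space)
        if e > config.e_cut:
            continue
        full = traceback_align(res, segment.codes, chunk.store, config.scoring)
        seq = chunk.store.sequence_of(res.dstart)
        soff = int(chunk.store.offsets[seq])
        qs, qe = segment_read_coords(segment, res.qstart, res.qend)
        n_ident = sum(
            1 for a, b in zip(full.aligned_query, full.aligned_subject) if a == b
        )
        gaps = full.aligned_query.count("-") + full.aligned_subject.count("-")
        gapopen = 0
        prev_gap = False
        for a, b in zip(full.aligned_query, full.aligned_subject):
            is_gap = a == "-" or b == "-"
            if is_gap and not prev_gap:
                gapopen += 1
            prev_gap = is_gap
        length = len(full.aligned_query)
        hits.append(
            Hit(
                query_id=segment.read_id,
                query_index=read_index[segment.read_id],
                subject_id=chunk.store.names[seq],
                frame=segment.frame,
                score=res.score,
                bits=bit_score(res.score, space),
                evalue=e,
                length=length,
                n_ident=n_ident,
                mismatch=length - n_ident - gaps,
                gapopen=gapopen,
                gaps=gaps,
                qstart=qs,
                qend=qe,
                sstart=res.dstart - soff + 1,
                send=res.dend - soff,
                aligned_query=full.aligned_query,
                aligned_subject=full.aligned_subject,
                midline=full.midline or "",
            )
        )
    return hits


def _iter_chunks(chunk_sources, config: SearchConfig):
    """Yield loaded chunks; when sources are paths and prefetch is on, the
    next chunk loads on a background thread during the current search."""

    def load(src):
        return src if isinstance(src, DatabaseChunk) else load_chunk(Path(src))

    if not config.prefetch:
        for src in chunk_sources:
            yield load(src)
        return
    pending: dict[int, DatabaseChunk] = {}
    thread: threading.Thread | None = None
    for i, src in enumerate(chunk_sources):
        if thread is not None:
            thread.join()
            current = pending.pop(i)
        else:
            current = load(src)
        if i + 1 < len(chunk_sources):
            nxt = chunk_sources[i + 1]

            def worker(j=i + 1, s=nxt):
                pending[j] = load(s)

            thread = threading.Thread(target=worker)
            thread.start()
        else:
            thread = None
        yield current


def run_search(
    reads: list[tuple[str, str]],
    chunk_sources: list,
    config: SearchConfig = SearchConfig(),
    total_db_residues: int | None = None,
    stats: SearchStats | None = None,
    log: list[str] | None = None,
) -> list[Hit]:
    """Full search of DNA reads against an indexed database.

    ``chunk_sources`` may be in-memory :class:`DatabaseChunk` objects or
    paths to serialized chunk files.  ``total_db_residues`` must be the
    whole database's residue count when chunks are streamed from disk;
    it defaults to the sum over the provided chunks.
    """
    segments: list[QuerySegment] = []
    read_index: dict[str, int] = {}
    for i, (rid, dna) in enumerate(reads):
        read_index[rid] = i
        segments.extend(six_frame_translate(rid, dna, config.min_segment_len))
    all_hits: list[Hit] = []
    chunks_seen = 0
    residues = 0
    loaded = list(_iter_chunks(chunk_sources, config))
    if total_db_residues is None:
        total_db_residues = sum(c.store.total_residues for c in loaded)
    for chunk in loaded:
        chunks_seen += 1
        residues += chunk.store.total_residues
        p1 = run_phase1(segments, chunk, config, stats, log)
        gapped = run_phase2(p1, segments, chunk, config, log)
        all_hits.extend(
            _hits_from_chunk(gapped, segments, read_index, chunk, total_db_residues, config)
        )
    # chunk-count-independent canonical order, then rank/threshold
    all_hits.sort(
        key=lambda h: (
            h.query_index,
            -h.bits,
            h.evalue,
            h.subject_id,
            h.qstart,
            h.qend,
            h.sstart,
            h.send,
        )
    )
    deduped: list[Hit] = []
    seen: set[tuple] = set()
    for h in all_hits:
        key = (h.query_id, h.subject_id, h.qstart, h.qend, h.sstart, h.send, h.score)
        if key not in seen:
            seen.add(key)
            deduped.append(h)
    return rank_and_threshold(deduped, config.e_cut, config.max_targets)
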