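"""Seed search of query windows against the clustered index, with
triangle-inequality similarity filtering.

For every query window the index is probed (exact hash key plus optional
radius-1 neighborhood).  Singleton representatives (``B_e``) and cluster
representatives (``B_r``) get a full reduced-Hamming distance computation;
cluster members are screened only by the lower bound
``|D(q,r) - d(r,m)|`` derived from the triangle inequality, avoiding a full
distance computation per member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .db_index import DatabaseChunk, hash_key
from .seq_codec import reduce_codes

__all__ = ["FilterParams", "SearchStats", "SeedHit", "lookup_keys", "similarity_filter", "search_seeds"]


@dataclass(frozen=True)
class FilterParams:
    """Search-time seeding knobs."""

    filter_threshold: int = 2  # T_f, reduced-Hamming over the full window
    lookup_radius: int = 1  # r_h: 0 = exact key only, 1 = +1-mismatch keys

    def __post_init__(self) -> None:
        if self.filter_threshold < 0:
            raise ValueError("filter_threshold must be >= 0")
        if self.lookup_radius not in (0, 1):
            raise ValueError("lookup_radius must be 0 or 1")


@dataclass
class SearchStats:
    """Instrumentation counters (full distance evaluations etc.)."""

    distance_evals: int = 0
    member_screens: int = 0
    seeds_emitted: int = 0

    def merge(self, other: "SearchStats") -> None:
        self.distance_evals += other.distance_evals
        self.member_screens += other.member_screens
        self.seeds_emitted += other.seeds_emitted


@dataclass(frozen=True, slots=True)
class SeedHit:
    """A candidate (query window, database window) pair that survived
    similarity filtering."""

    segment_id: int
    qpos: int  # residue offset within the query segment
    dpos: int  # global position within the chunk store
    provenance: str  # "singleton" | "representative" | "member"
    lower_bound: int  # lower bound on d(q, m) that admitted this seed


def lookup_keys(groups: np.ndarray, k_h: int = 5, radius: int = 1) -> list[int]:
    """Hash keys to probe for one query window.

    Returns the exact key first, then (for ``radius == 1``) all keys whose
    decoded prefix differs in exactly one of the ``k_h`` positions, in
    ascending order.  Unkeyable prefixes yield an empty list.
    """
    exact = hash_key(groups, k_h)
    if exact is None:
        return []
    if radius == 0:
        return [exact]
    neighbors = []
    for i in range(k_h):
        weight = 10 ** (k_h - 1 - i)
        digit = (exact // weight) % 10
        for alt in range(10):
            if alt != digit:
                neighbors.append(exact + (alt - digit) * weight)
    neighbors.sort()
    return [exact] + neighbors


def similarity_filter(
    D_qr: int, member_distances: np.ndarray, T_f: int
) -> tuple[np.ndarray, np.ndarray]:
    """Triangle-inequality screen of one cluster's members.

    Returns ``(pass mask, lower bounds)`` where the lower bound for member
    ``m`` is ``|D(q,r) - d(r,m)| <= d(q,m)``; a member passes iff its lower
    bound is <= ``T_f``.
    """
    lb = np.abs(int(D_qr) - np.asarray(member_distances, dtype=np.int64))
    return lb <= T_f, lb


def search_seeds(
    segment_codes: np.ndarray,
    segment_id: int,
    chunk: DatabaseChunk,
    params: FilterParams = FilterParams(),
    stats: SearchStats | None = None,
) -> list[SeedHit]:
    """All seeds of one query segment against one chunk.

    Pure function of its inputs; output ordered by (qpos, dpos).
    """
    if stats is None:
        stats = SearchStats()
    L = chunk.params.subseq_len
    k_h = chunk.params.key_len
    T_f = params.filter_threshold
    qgroups = reduce_codes(segment_codes)
    dgroups = chunk.store.groups
    b_e, b_r, b_m = chunk.tables.b_e, chunk.tables.b_r, chunk.tables.b_m
    hits: list[SeedHit] = []
    for qpos in range(len(segment_codes) - L + 1):
        qwin = qgroups[qpos : qpos + L]
        keys = lookup_keys(qwin, k_h, params.lookup_radius)
        if not keys:
            continue
        emitted: list[tuple[int, str, int]] = []  # (dpos, provenance, lb)
        for key in keys:
            positions = b_e.get(key)
            if positions is not None:
                # singleton representatives: exact distance decides
                wins = dgroups[positions[:, None] + np.arange(L)]
                dists = np.count_nonzero(wins != qwin, axis=1)
                stats.distance_evals += len(positions)
                for dpos, d in zip(positions.tolist(), dists.tolist()):
                    if d <= T_f:
                        emitted.append((dpos, "singleton", int(d)))
            cids = b_r.get(key)
            if cids is not None:
                for cid in cids.tolist():
                    cluster = b_m[cid]
                    rep = cluster.representative
                    D_qr = int(
                        np.count_nonzero(dgroups[rep : rep + L] != qwin)
                    )
                    stats.distance_evals += 1
                    if D_qr <= T_f:
                        emitted.append((rep, "representative", D_qr))
                    ok, lb = similarity_filter(D_qr, cluster.member_distances, T_f)
                    stats.member_screens += len(cluster.members)
                    for m, passed, bound in zip(
                        cluster.members.tolist(), ok.tolist(), lb.tolist()
                    ):
                        if passed:
                            emitted.append((m, "member", int(bound)))
        if emitted:
            seen: set[int] = set()
            for dpos, prov, lb_val in sorted(emitted):
                if dpos in seen:
                    continue
                seen.add(dpos)
                hits.append(SeedHit(segment_id, qpos, dpos, prov, lb_val))
    stats.seeds_emitted += len(hits)
    return hits
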