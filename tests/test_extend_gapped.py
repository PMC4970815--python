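from dataclasses import replace

import numpy as np
import pytest

from txsearch.extend_gapped import (
    AlignmentInconsistencyError,
    gapped_extend,
    traceback_align,
    xdrop_dp_score,
    _xdrop_dp_py,
)
from txsearch.extend_ungapped import ScoringParams, UngappedSegment, blosum62_matrix
from txsearch.seq_codec import AA_ORDER, build_store, encode
from txsearch.testkit import extension_best, smith_waterman, sw_score

SATURATED = 10**6


def random_codes(rng, n):
    return rng.integers(0, 20, size=n).astype(np.uint8)


def score_alignment(aq, asub, params):
    """Independent recount of an alignment's score from its strings."""
    m = params.matrix
    total = 0
    in_gap = False
    for a, b in zip(aq, asub):
        if a == "-" or b == "-":
            total -= params.gap_extend + (params.gap_open if not in_gap else 0)
            in_gap = True
        else:
            total += int(m[encode(a)[0], encode(b)[0]])
            in_gap = False
    return total


class TestXdropScore:
    def test_identical_flanks_no_gaps(self):
        params = replace(ScoringParams(), xdrop_gapped=SATURATED)
        q = encode("ARNDCQEGHIKLM")
        s, i, j = xdrop_dp_score(q, q, params)
        assert i == j == len(q)
        assert s == sum(int(params.matrix[c, c]) for c in q)

    def test_empty_extension(self):
        params = ScoringParams()
        s, i, j = xdrop_dp_score(np.empty(0, dtype=np.uint8), encode("ARND"), params)
        assert (s, i, j) == (0, 0, 0)

    def test_numba_matches_python_reference(self, rng):
        params = ScoringParams()
        for _ in range(100):
            q = random_codes(rng, int(rng.integers(1, 50)))
            d = random_codes(rng, int(rng.integers(1, 50)))
            assert xdrop_dp_score(q, d, params, use_numba=True) == _xdrop_dp_py(
                q, d, params.matrix, params.gap_open + params.gap_extend,
                params.gap_extend, params.xdrop_gapped,
            )

    def test_saturating_xg_equals_full_matrix_oracle_100_pairs(self, rng):
        base = ScoringParams()
        saturated = replace(base, xdrop_gapped=SATURATED)
        for _ in range(100):
            q = random_codes(rng, int(rng.integers(1, 80)))
            d = random_codes(rng, int(rng.integers(1, 80)))
            s, _, _ = xdrop_dp_score(q, d, saturated)
            expected, _, _ = extension_best(q, d, base)
            assert s == expected

    def test_monotone_in_xg_and_convergence(self, rng):
        base = ScoringParams()
        for _ in range(30):
            q = random_codes(rng, 40)
            d = random_codes(rng, 40)
            prev = -1
            xg = 4
            scores = []
            while xg <= 2**12:
                s, _, _ = xdrop_dp_score(q, d, replace(base, xdrop_gapped=xg))
                scores.append(s)
                assert s >= prev
                prev = s
                xg *= 2
            unpruned, _, _ = extension_best(q, d, base)
            assert scores[-1] == unpruned  # converged to the optimum


def _identity_setup(seq, params=None):
    """Ungapped segment covering an exact copy of a database sequence."""
    store = build_store([("p", seq)])
    q = encode(seq)
    m = (params or ScoringParams()).matrix
    score = int(m[q, q].sum())
    seg = UngappedSegment(0, 0, len(seq), 1, 1 + len(seq), score)
    return store, q, seg


class TestGappedExtend:
    def test_identical_sequences_full_score(self):
        params = replace(ScoringParams(), xdrop_gapped=SATURATED)
        seq = "ARNDCQEGHIKLMFPSTWYV"
        store, q, seg = _identity_setup(seq, params)
        res = gapped_extend(seg, q, store, params)
        assert res.score == seg.score
        assert (res.qstart, res.qend) == (0, len(seq))
        assert (res.dstart, res.dend) == (1, 1 + len(seq))

    def test_anchor_adjacent_to_delimiters(self):
        params = ScoringParams()
        store, q, seg = _identity_setup("ARNDCQEGHI")
        res = gapped_extend(seg, q, store, params)
        # nothing to extend beyond the sequence: score equals segment score
        assert res.score == seg.score

    def test_score_at_least_ungapped_when_xg_dominates(self, rng):
        params = ScoringParams()  # X_g = 38 >= X_u = 20
        for _ in range(50):
            seq = "".join(AA_ORDER[c] for c in rng.integers(0, 20, size=60))
            store = build_store([("p", seq)])
            q = encode(seq).copy()
            # mutate the query a little
            for pos in rng.integers(0, 60, size=4):
                q[pos] = rng.integers(0, 20)
            qs = int(rng.integers(0, 30))
            seg_score = int(params.matrix[q[qs : qs + 20], store.codes[1 + qs : 1 + qs + 20]].sum())
            seg = UngappedSegment(0, qs, qs + 20, 1 + qs, 1 + qs + 20, seg_score)
            res = gapped_extend(seg, q, store, params)
            assert res.score >= seg.score

    def test_score_bounded_by_smith_waterman(self, rng):
        params = ScoringParams()
        for _ in range(30):
            seq = "".join(AA_ORDER[c] for c in rng.integers(0, 20, size=70))
            qseq = list(seq[5:65])
            for pos in rng.integers(0, len(qseq), size=5):
                qseq[pos] = AA_ORDER[rng.integers(0, 20)]
            qseq = "".join(qseq)
            store = build_store([("p", seq)])
            q = encode(qseq)
            seg_score = int(params.matrix[q[:20], store.codes[6:26]].sum())
            seg = UngappedSegment(0, 0, 20, 6, 26, seg_score)
            res = gapped_extend(seg, q, store, params)
            assert res.score <= sw_score(qseq, seq, params)

    def test_order_independence(self, rng):
        params = ScoringParams()
        seq = "".join(AA_ORDER[c] for c in rng.integers(0, 20, size=80))
        store = build_store([("p", seq)])
        q = encode(seq[10:70])
        segs = []
        for qs in (0, 10, 20, 30):
            sc = int(params.matrix[q[qs : qs + 15], store.codes[11 + qs : 11 + qs + 15]].sum())
            segs.append(UngappedSegment(0, qs, qs + 15, 11 + qs, 11 + qs + 15, sc))
        forward = [gapped_extend(s, q, store, params) for s in segs]
        backward = [gapped_extend(s, q, store, params) for s in reversed(segs)]
        assert forward == list(reversed(backward))


class TestTraceback:
    def test_identity_alignment(self):
        params = ScoringParams()
        seq = "ARNDCQEGHIKLMNPQRST"
        store, q, seg = _identity_setup(seq, params)
        res = traceback_align(gapped_extend(seg, q, store, params), q, store, params)
        assert res.aligned_query == seq
        assert res.aligned_subject == seq
        assert res.midline == seq  # all identities
        assert score_alignment(res.aligned_query, res.aligned_subject, params) == res.score

    def test_single_insertion_costs_open_plus_extend(self):
        params = replace(ScoringParams(), xdrop_gapped=SATURATED)
        subject = "ARNDCQEGHIKLMFPSTWYVARNDCQEGHI"
        query = subject[:15] + "W" + subject[15:]  # one inserted residue
        store = build_store([("p", subject)])
        q = encode(query)
        seg_score = int(params.matrix[q[:10], store.codes[1:11]].sum())
        seg = UngappedSegment(0, 0, 10, 1, 11, seg_score)
        res = traceback_align(gapped_extend(seg, q, store, params), q, store, params)
        n_gap_cols = res.aligned_subject.count("-") + res.aligned_query.count("-")
        assert n_gap_cols == 1
        ident = sum(int(params.matrix[c, c]) for c in encode(subject))
        assert res.score == ident - (params.gap_open + params.gap_extend)
        assert score_alignment(res.aligned_query, res.aligned_subject, params) == res.score

    def test_random_hits_score_recount(self, rng):
        params = ScoringParams()
        for _ in range(40):
            seq = "".join(AA_ORDER[c] for c in rng.integers(0, 20, size=80))
            store = build_store([("p", seq)])
            q = encode(seq[10:70]).copy()
            for pos in rng.integers(0, 60, size=5):
                q[pos] = rng.integers(0, 20)
            seg_score = int(params.matrix[q[5:25], store.codes[16:36]].sum())
            seg = UngappedSegment(0, 5, 25, 16, 36, seg_score)
            res = traceback_align(gapped_extend(seg, q, store, params), q, store, params)
            assert score_alignment(res.aligned_query, res.aligned_subject, params) == res.score
            # removing gaps reproduces the residues
            assert res.aligned_query.replace("-", "") == "".join(
                AA_ORDER[c] for c in q[res.qstart : res.qend]
            )

    def test_inconsistency_is_raised_not_patched(self):
        params = ScoringParams()
        store, q, seg = _identity_setup("ARNDCQEGHIKLMN")
        res = gapped_extend(seg, q, store, params)
        tampered = replace(res, score=res.score + 1)
        with pytest.raises(AlignmentInconsistencyError):
            traceback_align(tampered, q, store, params)
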