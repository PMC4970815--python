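import itertools

import numpy as np
import pytest

from txsearch.db_index import (
    Cluster,
    IndexFormatError,
    IndexParams,
    build_chunk,
    build_tables,
    chunk_database,
    extract_subsequences,
    greedy_cluster,
    hamming_distance,
    hash_key,
    load_chunk,
    load_index,
    partition_sequences,
    save_index,
    window_keys,
)
from txsearch.seq_codec import AA_ORDER, build_store, reduce_codes
from txsearch.testkit import brute_force_cluster


def random_proteins(rng, n, lo=15, hi=60):
    return [
        (f"p{i}", "".join(AA_ORDER[c] for c in rng.integers(0, 20, size=rng.integers(lo, hi))))
        for i in range(n)
    ]


class TestExtractSubsequences:
    def test_exact_length(self):
        store = build_store([("s", "A" * 10)])
        assert len(extract_subsequences(store, 10)) == 1

    def test_too_short(self):
        store = build_store([("s", "A" * 9)])
        assert len(extract_subsequences(store, 10)) == 0

    def test_per_sequence_counts(self):
        store = build_store([("a", "A" * 12), ("b", "C" * 15)])
        subs = extract_subsequences(store, 10)
        assert len(subs) == 3 + 6

    def test_windows_delimiter_free_and_sorted(self, rng):
        store = build_store(random_proteins(rng, 20, 5, 25))
        subs = extract_subsequences(store, 10)
        assert (np.diff(subs) > 0).all()
        for p in subs.tolist():
            assert (store.codes[p : p + 10] != 21).all()


class TestHammingDistance:
    def test_identical(self):
        a = np.zeros(10, dtype=np.uint8)
        assert hamming_distance(a, a) == 0

    def test_single_mismatch(self):
        a = np.zeros(10, dtype=np.uint8)
        b = a.copy()
        b[9] = 1
        assert hamming_distance(a, b) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance(np.zeros(3), np.zeros(4))

    def test_metric_properties_10k_triples(self, rng):
        a = rng.integers(0, 12, size=(10_000, 10))
        b = rng.integers(0, 12, size=(10_000, 10))
        c = rng.integers(0, 12, size=(10_000, 10))
        dab = (a != b).sum(axis=1)
        dbc = (b != c).sum(axis=1)
        dac = (a != c).sum(axis=1)
        assert (dac <= dab + dbc).all()  # triangle inequality
        assert (dab == (b != a).sum(axis=1)).all()  # symmetry
        assert ((a != a).sum(axis=1) == 0).all()  # identity


class TestHashKey:
    def test_all_zero_prefix(self):
        assert hash_key(np.zeros(10, dtype=np.uint8), 5) == 0

    def test_most_significant_first(self):
        g = np.zeros(10, dtype=np.uint8)
        g[0] = 1
        assert hash_key(g, 5) == 10_000

    def test_unkeyable_prefix(self):
        g = np.zeros(10, dtype=np.uint8)
        g[2] = 10  # X group inside the prefix
        assert hash_key(g, 5) is None

    def test_injective_over_all_prefixes(self):
        # exhaustive enumeration of all 10^5 keyable prefixes
        prefixes = np.array(list(itertools.product(range(10), repeat=5)), dtype=np.uint8)
        weights = 10 ** np.arange(4, -1, -1)
        keys = prefixes @ weights
        assert len(np.unique(keys)) == 10**5

    def test_window_keys_matches_scalar(self, rng):
        store = build_store(random_proteins(rng, 10))
        subs = extract_subsequences(store, 10)
        vec = window_keys(store.groups, subs, 5)
        for pos, key in zip(subs.tolist(), vec.tolist()):
            scalar = hash_key(store.groups[pos : pos + 10], 5)
            assert key == (-1 if scalar is None else scalar)


class TestGreedyCluster:
    def test_identical_windows_one_cluster(self):
        store = build_store([(f"s{i}", "ARNDCQEGHI") for i in range(5)])
        subs = extract_subsequences(store, 10)
        clusters = greedy_cluster(subs, store, T_c=1)
        assert len(clusters) == 1
        assert clusters[0].size == 5
        assert clusters[0].member_distances.tolist() == [0, 0, 0, 0]

    def test_distant_windows_stay_singleton(self):
        # same key prefix (first 5 residues), distance 5 in the suffix
        store = build_store([("a", "ARNDCQEGHI"), ("b", "ARNDCHIKLM")])
        subs = extract_subsequences(store, 10)
        clusters = greedy_cluster(subs, store, T_c=1)
        assert [c.size for c in clusters] == [1, 1]

    def test_forced_singleton_mode(self):
        store = build_store([(f"s{i}", "ARNDCQEGHI") for i in range(4)])
        subs = extract_subsequences(store, 10)
        clusters = greedy_cluster(subs, store, T_c=-1)
        assert [c.size for c in clusters] == [1, 1, 1, 1]

    def test_member_distances_recomputable(self, rng):
        store = build_store(random_proteins(rng, 30))
        subs = extract_subsequences(store, 10)
        clusters = greedy_cluster(subs, store, T_c=3)
        for c in clusters:
            rep = store.groups[c.representative : c.representative + 10]
            for m, d in zip(c.members.tolist(), c.member_distances.tolist()):
                win = store.groups[m : m + 10]
                assert hamming_distance(rep, win) == d <= 3

    def test_matches_brute_force_oracle_200_windows(self, rng):
        store = build_store(random_proteins(rng, 8, 20, 45))
        subs = extract_subsequences(store, 10)[:200]
        got = greedy_cluster(subs, store, T_c=1)
        expected = brute_force_cluster(subs, store, T_c=1)
        assert len(got) == len(expected)
        for g, (rep, members, dists) in zip(got, expected):
            assert g.representative == rep
            assert g.members.tolist() == members
            assert g.member_distances.tolist() == dists

    def test_determinism(self, rng):
        store = build_store(random_proteins(rng, 20))
        subs = extract_subsequences(store, 10)
        a = greedy_cluster(subs, store, T_c=1)
        b = greedy_cluster(subs, store, T_c=1)
        assert a == b


class TestBuildTables:
    def _params(self):
        return IndexParams()

    def test_singleton_goes_to_be(self):
        store = build_store([("s", "ARNDCQEGHI")])
        clusters = greedy_cluster(extract_subsequences(store, 10), store)
        tables = build_tables(clusters, store, self._params())
        assert sum(len(v) for v in tables.b_e.values()) == 1
        assert not tables.b_r and not tables.b_m

    def test_cluster_of_three(self):
        store = build_store([(f"s{i}", "ARNDCQEGHI") for i in range(3)])
        clusters = greedy_cluster(extract_subsequences(store, 10), store)
        tables = build_tables(clusters, store, self._params())
        assert not tables.b_e
        assert sum(len(v) for v in tables.b_r.values()) == 1
        (cluster,) = tables.b_m.values()
        assert len(cluster.members) == 2

    def test_membership_partition_invariant(self, rng):
        store = build_store(random_proteins(rng, 40))
        subs = extract_subsequences(store, 10)
        params = self._params()
        clusters = greedy_cluster(subs, store, T_c=2)
        tables = build_tables(clusters, store, params)
        indexed = []
        for v in tables.b_e.values():
            indexed.extend(v.tolist())
        for cids in tables.b_r.values():
            for cid in cids.tolist():
                c = tables.b_m[cid]
                indexed.append(c.representative)
                indexed.extend(c.members.tolist())
        keyable = [
            p
            for p, k in zip(subs.tolist(), window_keys(store.groups, subs, params.key_len).tolist())
            if k >= 0
        ]
        assert sorted(indexed) == sorted(keyable)
        assert len(indexed) == len(set(indexed))


class TestChunking:
    def test_single_chunk(self):
        assert len(partition_sequences([("a", "A" * 10)], 1 << 30)) == 1

    def test_greedy_closure(self):
        seqs = [(f"s{i}", "A" * 100) for i in range(3)]
        assert len(partition_sequences(seqs, 150)) == 3

    def test_oversized_sequence_error_names_it(self):
        with pytest.raises(ValueError, match="big"):
            partition_sequences([("big", "A" * 200)], 100)

    def test_chunks_reproduce_database(self, rng):
        seqs = random_proteins(rng, 30, 10, 80)
        chunks = chunk_database(seqs, chunk_bytes=500)
        assert len(chunks) > 1
        reassembled = []
        for c in chunks:
            assert c.seq_id_offset == len(reassembled)
            for i in range(c.store.n_sequences):
                reassembled.append((c.store.names[i], c.store.sequence_codes(i).tolist()))
        from txsearch.seq_codec import encode

        assert [n for n, _ in reassembled] == [n for n, _ in seqs]
        for (_, codes), (_, eseq) in zip(reassembled, seqs):
            assert codes == encode(eseq).tolist()


class TestSerialization:
    def test_roundtrip_small(self, tmp_path):
        chunks = chunk_database([("a", "ARNDCQEGHIKL"), ("b", "ARNDCQEGHIKL")])
        save_index(chunks, tmp_path / "idx")
        manifest, paths = load_index(tmp_path / "idx")
        assert manifest["total_residues"] == 24
        loaded = load_chunk(paths[0])
        assert loaded == chunks[0]

    def test_param_mismatch_error(self, tmp_path):
        chunks = chunk_database([("a", "ARNDCQEGHIKL")], params=IndexParams(subseq_len=10))
        save_index(chunks, tmp_path / "idx")
        _, paths = load_index(tmp_path / "idx")
        with pytest.raises(IndexFormatError, match="parameters"):
            load_chunk(paths[0], expected=IndexParams(subseq_len=12, key_len=5))

    def test_missing_manifest_error(self, tmp_path):
        with pytest.raises(IndexFormatError, match="manifest"):
            load_index(tmp_path / "nope")

    def test_corrupt_magic(self, tmp_path):
        p = tmp_path / "bad.idx"
        p.write_bytes(b"NOTANIDX" + b"\0" * 32)
        with pytest.raises(IndexFormatError, match="magic"):
            load_chunk(p)

    def test_double_save_byte_identical_500_sequences(self, rng, tmp_path):
        seqs = random_proteins(rng, 500, 10, 30)
        chunks = chunk_database(seqs, chunk_bytes=4000)
        save_index(chunks, tmp_path / "one" / "idx")
        save_index(chunks, tmp_path / "two" / "idx")
        m1, p1 = load_index(tmp_path / "one" / "idx")
        m2, p2 = load_index(tmp_path / "two" / "idx")
        assert m1 == m2
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()
        # and a load->save of the loaded index is byte-identical too
        reloaded = [load_chunk(p) for p in p1]
        save_index(reloaded, tmp_path / "three" / "idx")
        _, p3 = load_index(tmp_path / "three" / "idx")
        for a, b in zip(p1, p3):
            assert a.read_bytes() == b.read_bytes()
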