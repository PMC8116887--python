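"""Chunked key-value store: format, index, filters, one-read contract."""

import numpy as np
import pytest

from breakseek.count import write_histogram
from breakseek.kvstore import (
    ABSENT,
    RECORD_BYTES,
    ROOT_RECORD_DTYPE,
    ChunkedStore,
    StoreConfig,
    bloom_fp_rate,
    build_index,
    build_store,
    fold_root_records,
    store_payload_gib,
)
from breakseek.sort_reduce import UPDATE_DTYPE


def make_store(tmp_path, entries, k=10, cfg=None, name="s"):
    hist = write_histogram(tmp_path / f"{name}.kmh", entries, k, (0, 4 ** (k - 2)))
    return build_store(hist, tmp_path / f"{name}.kvr", cfg)


def entries_for_roots(roots, variant=3, n=2, t=1):
    arr = np.zeros(len(roots), dtype=UPDATE_DTYPE)
    arr["key"] = (np.asarray(roots, dtype=np.uint64) << np.uint64(5)) | np.uint64(variant)
    arr["n"] = n
    arr["t"] = t
    return arr


class TestRecordFormat:
    def test_record_is_136_bytes_with_64_counters(self):
        assert RECORD_BYTES == 136
        assert ROOT_RECORD_DTYPE["counters"].shape == (64,)

    def test_chunk_capacity_is_30(self):
        assert StoreConfig().records_per_chunk == 4096 // 136 == 30

    def test_31_roots_need_two_chunks(self, tmp_path):
        store = make_store(tmp_path, entries_for_roots(range(31)))
        assert store.n_chunks == 2
        store.close()

    def test_counter_slot_layout(self, tmp_path):
        store = make_store(tmp_path, entries_for_roots([7], variant=3, n=2, t=1))
        rec = store.lookup(7)
        assert rec.counters[6] == 2 and rec.counters[7] == 1
        assert rec.counters.sum() == 3
        store.close()

    def test_payload_sizing_helper(self):
        # 1 billion 8B+128B items ~ 127 binary GB
        assert store_payload_gib(10**9) == pytest.approx(127, abs=0.5)


class TestMultiLevelIndex:
    def test_level_sizes_exact_fanout(self):
        idx = build_index(np.arange(256, dtype=np.uint64), 16)
        assert [l.size for l in idx.levels] == [256, 16, 1]

    def test_level_sizes_ceil(self):
        idx = build_index(np.arange(257, dtype=np.uint64), 16)
        assert [l.size for l in idx.levels] == [257, 17, 2, 1]

    def test_below_first_key_locates_chunk_zero(self):
        idx = build_index(np.array([10, 20, 30], dtype=np.uint64), 2)
        assert idx.locate(5) == 0

    @pytest.mark.parametrize("fanout", [2, 3, 16])
    def test_descent_equals_flat_binary_search(self, fanout):
        rng = np.random.default_rng(fanout)
        first_keys = np.unique(rng.integers(0, 10**6, 1000).astype(np.uint64))
        idx = build_index(first_keys, fanout)
        probes = rng.integers(0, 10**6, 10_000)
        for p in probes:
            flat = max(int(np.searchsorted(first_keys, int(p), side="right")) - 1, 0)
            assert idx.locate(int(p)) == flat

    def test_monotone(self):
        idx = build_index(np.array([5, 10, 15, 20], dtype=np.uint64), 2)
        locs = [idx.locate(x) for x in range(25)]
        assert locs == sorted(locs)


@pytest.fixture(scope="module")
def populated(tmp_path_factory, random_histogram_entries):
    entries, k = random_histogram_entries
    tmp = tmp_path_factory.mktemp("kv")
    hist = write_histogram(tmp / "h.kmh", entries, k, (0, 4 ** (k - 2)))
    store = build_store(hist, tmp / "s.kvr")
    oracle = {int(r["root"]): r["counters"].copy() for r in fold_root_records(entries)}
    yield store, oracle, k
    store.close()


class TestLookup:
    def test_every_present_root_returns_exact_record(self, populated):
        store, oracle, _k = populated
        for root, counters in oracle.items():
            rec = store.lookup(root)
            assert rec is not ABSENT
            assert (rec.counters == counters).all()

    def test_absent_roots_and_no_bloom_false_negatives(self, populated):
        store, oracle, k = populated
        rng = np.random.default_rng(1)
        probes = rng.integers(0, 4 ** (k - 2), 10_000)
        for p in probes:
            got = store.lookup(int(p))
            assert (got is not ABSENT) == (int(p) in oracle)

    def test_band_pass_rejects_without_chunk_read(self, populated):
        store, _oracle, k = populated
        reads0 = store.chunk_reads
        assert store.lookup(store.max_root + 1) is ABSENT
        assert store.chunk_reads == reads0

    def test_at_most_one_chunk_read_per_lookup(self, populated):
        store, oracle, k = populated
        rng = np.random.default_rng(2)
        reads0, lookups0 = store.chunk_reads, store.lookups
        present = list(oracle)
        for p in present[:2000]:
            store.lookup(p)
        for p in rng.integers(0, 4 ** (k - 2), 2000):
            store.lookup(int(p))
        assert store.chunk_reads - reads0 <= store.lookups - lookups0

    def test_bloom_fp_rate_within_2x_of_formula(self, populated):
        """Empirical false-positive rate of in-range absent probes vs
        the (1 - e^(-h n/m))^h estimate (~0.0082 at 10 bits, 7 hashes)."""
        store, oracle, k = populated
        rng = np.random.default_rng(3)
        theory = bloom_fp_rate(store.bloom_bits_per_key, store.bloom_hashes)
        assert theory == pytest.approx(0.0082, abs=0.0005)
        tried = fp = 0
        for p in rng.integers(store.min_root, store.max_root + 1, 60_000):
            p = int(p)
            if p in oracle:
                continue
            tried += 1
            reads0 = store.chunk_reads
            assert store.lookup(p) is ABSENT
            fp += store.chunk_reads - reads0
        rate = fp / tried
        assert 0.5 * theory <= rate <= 2.0 * theory

    def test_batch_equals_sequential(self, populated):
        store, oracle, k = populated
        rng = np.random.default_rng(4)
        roots = [int(r) for r in rng.integers(0, 4 ** (k - 2), 3000)]
        roots += list(oracle)[:1000] + list(oracle)[:10]  # duplicates too
        tagged = list(enumerate(roots))
        batch = {tag: (None if res is ABSENT else res.counters.tobytes())
                 for tag, res in store.lookup_batch(tagged)}
        seq = {tag: (lambda r: None if r is ABSENT else r.counters.tobytes())(store.lookup(root))
               for tag, root in tagged}
        assert batch == seq

    def test_empty_batch(self, populated):
        store, _o, _k = populated
        assert list(store.lookup_batch([])) == []

    def test_reopen_reproduces_lookups(self, populated):
        store, oracle, _k = populated
        again = ChunkedStore.open(store.path)
        some = list(oracle.items())[::37]
        for root, counters in some:
            assert (again.lookup(root).counters == counters).all()
        assert [l.size for l in again.index.levels] == [l.size for l in store.index.levels]
        again.close()


class TestBench:
    def test_positive_bench(self, populated):
        store, _oracle, _k = populated
        rep = store.bench_random_lookups(5000, threads=2, queue_depth=8, seed=9)
        assert rep["found"] == rep["lookups"] == 5000
        assert rep["chunk_reads"] <= 5000
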