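"""Immutable chunked key-value store for root-format histogram records.

The Label unit issues billions of random histogram look-ups.  This
store serves them from secondary storage under a hard contract of **at
most one data-chunk read per look-up**, which is what makes flash-page
(4 KB) storage practical: there is no tree walk on disk, no overflow
chains, no second probe.

Layout of a store file (little-endian):

* chunk 0 — header (magic ``KVR1``, geometry, key range, Bloom params);
* a Bloom-filter bitmap region, padded to whole chunks;
* data chunks of ``chunk_bytes`` (default 4096), each packing up to 30
  fixed 136-byte records (u64 root + 64 x u16 counters) followed by
  zero padding; records sorted by root globally, none spanning chunks.

Look-up pipeline: a *band-pass filter* (min/max root seen at build
time) rejects out-of-range keys for free; a *Bloom filter* (no false
negatives) short-circuits most absent keys; a purely in-memory
*multi-level implicit index* — layered arrays of chunk first-keys with
fixed fan-out, where array position encodes the child range so no
pointers are stored — locates the single chunk that could hold the
key; one chunk read and an in-chunk binary search finish the job.
Bloom false positives cost exactly one wasted chunk read.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .count import Histogram, read_histogram

__all__ = [
    "ROOT_RECORD_DTYPE",
    "RECORD_BYTES",
    "StoreConfig",
    "RootRecord",
    "MultiLevelIndex",
    "build_index",
    "ChunkedStore",
    "build_store",
    "fold_root_records",
    "store_payload_gib",
    "bloom_fp_rate",
]

#: root-format record: 8-byte root + 64 saturating 16-bit counters.
#: For variant v, counters[2v] is the normal count, counters[2v+1] tumoral.
ROOT_RECORD_DTYPE = np.dtype([("root", "<u8"), ("counters", "<u2", (64,))])
RECORD_BYTES = ROOT_RECORD_DTYPE.itemsize  # 136

_MAGIC = b"KVR1"
_HEADER = struct.Struct("<4sHHIQQQQIIQQQI")


@dataclass(frozen=True)
class StoreConfig:
    """Store geometry and filter parameters.

    chunk_bytes: data-chunk size; a flash page (4 KB) so a chunk costs
    one device read.  index_fanout: keys per node of the implicit
    index.  bloom_bits_per_key / bloom_hashes: filter sizing (defaults
    10 bits and 7 hashes give ~0.8% false positives).  bloom_seeds:
    the two 64-bit seeds of the double-hashing scheme, persisted in the
    header so the bitmap is reproducible.
    """

    chunk_bytes: int = 4096
    index_fanout: int = 16
    bloom_bits_per_key: int = 10
    bloom_hashes: int = 7
    bloom_seeds: Tuple[int, int] = (0x5851F42D4C957F2D, 0x9E3779B97F4A7C15)

    def __post_init__(self) -> None:
        if self.chunk_bytes < RECORD_BYTES:
            raise ValueError("chunk_bytes must hold at least one record")
        if self.index_fanout < 2:
            raise ValueError("index_fanout must be >= 2")

    @property
    def records_per_chunk(self) -> int:
        return self.chunk_bytes // RECORD_BYTES


@dataclass(frozen=True)
class RootRecord:
    root: int
    counters: np.ndarray  # (64,) uint16

    def counter_pair(self, v: int) -> Tuple[int, int]:
        """(normal, tumoral) counts of variant v."""
        return int(self.counters[2 * v]), int(self.counters[2 * v + 1])


# ---------------------------------------------------------------------------
# multi-level implicit index
# ---------------------------------------------------------------------------


@dataclass
class MultiLevelIndex:
    """Layered first-key arrays with fixed fan-out F.

    ``levels[0]`` is the per-chunk first-key array; each level above
    keeps every F-th key of the one below, so the i-th key of a level
    covers children ``F*i .. F*(i+1)-1`` — the array index is the
    pointer.  A look-up descends top-down scanning at most F keys per
    level, touching one cache line's worth of keys per step.
    """

    levels: List[np.ndarray]
    fanout: int

    def locate(self, key: int) -> int:
        """Chunk id whose range covers ``key``: the unique i with
        first_keys[i] <= key < first_keys[i+1] (0 below the first key,
        the last chunk at or above the top key).  Equivalent to a flat
        binary search on the bottom level, but scans at most F
        contiguous keys per level."""
        F = self.fanout
        pos = 0
        for depth, level in enumerate(reversed(self.levels)):
            lo = 0 if depth == 0 else pos * F
            hi = level.size if depth == 0 else min(lo + F, level.size)
            window = level[lo:hi]
            idx = int(np.searchsorted(window, key, side="right")) - 1
            pos = lo + max(idx, 0)
        return pos


def build_index(first_keys: np.ndarray, fanout: int) -> MultiLevelIndex:
    """Build the implicit index over a sorted first-key array."""
    first_keys = np.asarray(first_keys, dtype=np.uint64)
    levels = [first_keys]
    while levels[-1].size > 1:
        levels.append(levels[-1][::fanout].copy())
    return MultiLevelIndex(levels=levels, fanout=fanout)


# ---------------------------------------------------------------------------
# bloom filter
# ---------------------------------------------------------------------------


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """SplitMix64-style avalanche of uint64 keys (vectorized).

    This fixed, documented mixer plus double hashing
    ``h_i = h1 + i * h2`` generates the Bloom probe positions; the
    seeds live in the store header, so any implementation of the same
    mixer reproduces the bitmap bit-for-bit.
    """
    x = x.astype(np.uint64) ^ np.uint64(seed)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _bloom_positions(keys: np.ndarray, m_bits: int, n_hashes: int,
                     seeds: Tuple[int, int]) -> np.ndarray:
    """(len(keys), n_hashes) array of bit positions."""
    h1 = _mix64(keys, seeds[0])
    h2 = _mix64(keys, seeds[1]) | np.uint64(1)
    i = np.arange(n_hashes, dtype=np.uint64)
    return ((h1[:, None] + i[None, :] * h2[:, None]) % np.uint64(m_bits))


def _bloom_build(keys: np.ndarray, bits_per_key: int, n_hashes: int,
                 seeds: Tuple[int, int]) -> np.ndarray:
    m_bits = max(8, int(bits_per_key) * max(1, keys.size))
    bitmap = np.zeros((m_bits + 7) // 8, dtype=np.uint8)
    if keys.size:
        pos = _bloom_positions(keys, m_bits, n_hashes, seeds).ravel()
        np.bitwise_or.at(bitmap, pos // 8, (np.uint8(1) << (pos % 8).astype(np.uint8)))
    return bitmap


def _bloom_query(bitmap: np.ndarray, m_bits: int, key: int, n_hashes: int,
                 seeds: Tuple[int, int]) -> bool:
    pos = _bloom_positions(np.array([key], dtype=np.uint64), m_bits, n_hashes, seeds)[0]
    byte = bitmap[pos // 8]
    return bool(np.all((byte >> (pos % 8).astype(np.uint8)) & 1))


def bloom_fp_rate(bits_per_key: float, n_hashes: int) -> float:
    """Classical Bloom false-positive estimate (1 - e^(-h n/m))^h."""
    return (1.0 - np.exp(-n_hashes / bits_per_key)) ** n_hashes


# ---------------------------------------------------------------------------
# store build / open / lookup
# ---------------------------------------------------------------------------


def fold_root_records(entries: np.ndarray) -> np.ndarray:
    """Fold sorted k-mer-indexed histogram entries into root records.

    Consecutive entries of one root fill the counter slots addressed by
    their variant index (low 5 bits of the sort key)."""
    out = np.zeros(0, dtype=ROOT_RECORD_DTYPE)
    if entries.size == 0:
        return out
    keys = entries["key"].astype(np.uint64)
    if keys.size > 1 and (np.diff(keys) <= 0).any():
        raise ValueError("histogram entries must be sorted strictly by key")
    roots = keys >> np.uint64(5)
    v = (keys & np.uint64(0x1F)).astype(np.int64)
    new_root = np.concatenate(([True], roots[1:] != roots[:-1]))
    root_idx = np.cumsum(new_root) - 1
    n_roots = int(root_idx[-1]) + 1
    out = np.zeros(n_roots, dtype=ROOT_RECORD_DTYPE)
    out["root"] = roots[new_root]
    out["counters"][root_idx, 2 * v] = entries["n"]
    out["counters"][root_idx, 2 * v + 1] = entries["t"]
    return out


def build_store(
    histogram: Union[Histogram, str, Path],
    out_path: Union[str, Path],
    cfg: Optional[StoreConfig] = None,
) -> "ChunkedStore":
    """Build an immutable store file from a sorted, singleton-free
    histogram and open it."""
    cfg = cfg or StoreConfig()
    if not isinstance(histogram, Histogram):
        histogram = read_histogram(histogram)
    records = fold_root_records(histogram.load())
    out_path = Path(out_path)

    rpc = cfg.records_per_chunk
    n_records = records.size
    n_chunks = -(-n_records // rpc) if n_records else 0
    roots = records["root"]
    min_root = int(roots[0]) if n_records else 0
    max_root = int(roots[-1]) if n_records else 0

    bitmap = _bloom_build(roots.astype(np.uint64), cfg.bloom_bits_per_key,
                          cfg.bloom_hashes, cfg.bloom_seeds)
    bloom_chunks = -(-bitmap.nbytes // cfg.chunk_bytes)

    with open(out_path, "wb") as fh:
        header = _HEADER.pack(
            _MAGIC, histogram.k, rpc, cfg.chunk_bytes,
            n_records, n_chunks, min_root, max_root,
            cfg.bloom_bits_per_key, cfg.bloom_hashes,
            cfg.bloom_seeds[0], cfg.bloom_seeds[1],
            bitmap.nbytes, cfg.index_fanout,
        )
        fh.write(header)
        fh.write(b"\x00" * (cfg.chunk_bytes - len(header)))
        fh.write(bitmap.tobytes())
        fh.write(b"\x00" * (bloom_chunks * cfg.chunk_bytes - bitmap.nbytes))
        for c in range(n_chunks):
            block = records[c * rpc:(c + 1) * rpc]
            fh.write(block.tobytes())
            fh.write(b"\x00" * (cfg.chunk_bytes - block.nbytes))
    return ChunkedStore.open(out_path)


class Absent:
    """Sentinel result for a key not in the store."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "Absent"

    def __bool__(self) -> bool:
        return False


ABSENT = Absent()


class ChunkedStore:
    """Read-only handle over a store file.

    The first-key array and multi-level index are rebuilt from the data
    chunks on open (cheap, and avoids trusting persisted pointers).
    ``chunk_reads`` and ``lookups`` instrument the one-read contract.
    """

    def __init__(self, path: Path, k: int, rpc: int, chunk_bytes: int,
                 n_records: int, n_chunks: int, min_root: int, max_root: int,
                 bloom_bits_per_key: int, bloom_hashes: int,
                 bloom_seeds: Tuple[int, int], bitmap: np.ndarray,
                 data_offset: int, index_fanout: int,
                 first_keys: np.ndarray):
        self.path = path
        self.k = k
        self.records_per_chunk = rpc
        self.chunk_bytes = chunk_bytes
        self.n_records = n_records
        self.n_chunks = n_chunks
        self.min_root = min_root
        self.max_root = max_root
        self.bloom_bits_per_key = bloom_bits_per_key
        self.bloom_hashes = bloom_hashes
        self.bloom_seeds = bloom_seeds
        self._bitmap = bitmap
        self._m_bits = max(8, bloom_bits_per_key * max(1, n_records))
        self._data_offset = data_offset
        self.index_fanout = index_fanout
        self.first_keys = first_keys
        self.index = build_index(first_keys, index_fanout)
        self._fh = open(path, "rb")
        self.chunk_reads = 0
        self.lookups = 0
        self.bloom_rejects = 0
        self.bandpass_rejects = 0

    # -- lifecycle ----------------------------------------------------

    @classmethod
    def open(cls, path: Union[str, Path]) -> "ChunkedStore":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = fh.read(_HEADER.size)
            (magic, k, rpc, chunk_bytes, n_records, n_chunks, min_root,
             max_root, bpk, nh, seed1, seed2, bloom_bytes, fanout) = _HEADER.unpack(raw)
            if magic != _MAGIC:
                raise ValueError(f"{path}: not a store file")
            bloom_chunks = -(-bloom_bytes // chunk_bytes) if bloom_bytes else 0
            fh.seek(chunk_bytes)
            bitmap = np.frombuffer(fh.read(bloom_bytes), dtype=np.uint8).copy()
            data_offset = chunk_bytes * (1 + bloom_chunks)
            first_keys = np.empty(n_chunks, dtype=np.uint64)
            for c in range(n_chunks):
                fh.seek(data_offset + c * chunk_bytes)
                first_keys[c] = np.frombuffer(fh.read(8), dtype="<u8")[0]
        return cls(path, k, rpc, chunk_bytes, n_records, n_chunks, min_root,
                   max_root, bpk, nh, (seed1, seed2), bitmap, data_offset,
                   fanout, first_keys)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "ChunkedStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- look-up pipeline ---------------------------------------------

    def _read_chunk(self, chunk_id: int) -> np.ndarray:
        self.chunk_reads += 1
        self._fh.seek(self._data_offset + chunk_id * self.chunk_bytes)
        raw = self._fh.read(self.chunk_bytes)
        n_in = min(self.records_per_chunk,
                   self.n_records - chunk_id * self.records_per_chunk)
        return np.frombuffer(raw, dtype=ROOT_RECORD_DTYPE, count=n_in)

    def lookup(self, root_code: int) -> Union[RootRecord, Absent]:
        """Band-pass -> Bloom -> index descent -> one chunk read ->
        in-chunk binary search."""
        self.lookups += 1
        if self.n_records == 0 or not (self.min_root <= root_code <= self.max_root):
            self.bandpass_rejects += 1
            return ABSENT
        if not _bloom_query(self._bitmap, self._m_bits, root_code,
                            self.bloom_hashes, self.bloom_seeds):
            self.bloom_rejects += 1
            return ABSENT
        chunk_id = self.index.locate(root_code)
        block = self._read_chunk(chunk_id)
        pos = int(np.searchsorted(block["root"], root_code))
        if pos < block.size and int(block["root"][pos]) == root_code:
            return RootRecord(root=root_code, counters=block["counters"][pos].copy())
        return ABSENT

    def lookup_batch(
        self, tagged_roots: Iterable[Tuple[object, int]]
    ) -> Iterator[Tuple[object, Union[RootRecord, Absent]]]:
        """Resolve a batch of (tag, root) probes.

        Semantically identical to per-item :meth:`lookup`; results are
        yielded in submission order here, but callers must not rely on
        ordering — a concurrent implementation may complete out of
        order (concurrency degree is configuration, not semantics).
        """
        for tag, root in tagged_roots:
            yield tag, self.lookup(root)

    def iter_roots(self) -> Iterator[int]:
        for c in range(self.n_chunks):
            for r in self._read_chunk(c)["root"]:
                yield int(r)

    # -- benchmarking ---------------------------------------------------

    def bench_random_lookups(self, n_lookups: int, threads: int = 1,
                             queue_depth: int = 1, seed: int = 0) -> dict:
        """Random positive look-up benchmark (shape of a label-unit
        workload): draw ``n_lookups`` present roots with a seeded RNG
        and resolve them all, reporting look-ups, chunk reads and wall
        time.  ``threads``/``queue_depth`` are recorded in the report
        for parity with asynchronous deployments; this implementation
        resolves probes sequentially."""
        import time

        rng = np.random.default_rng(seed)
        present = np.fromiter(self.iter_roots(), dtype=np.uint64, count=self.n_records)
        probes = present[rng.integers(0, present.size, size=n_lookups)]
        reads0 = self.chunk_reads
        t0 = time.perf_counter()
        found = 0
        for p in probes:
            if self.lookup(int(p)) is not ABSENT:
                found += 1
        elapsed = time.perf_counter() - t0
        return {
            "lookups": n_lookups,
            "found": found,
            "chunk_reads": self.chunk_reads - reads0,
            "elapsed_s": elapsed,
            "threads": threads,
            "queue_depth": queue_depth,
        }


def store_payload_gib(n_items: int, key_bytes: int = 8, value_bytes: int = 128) -> float:
    """Analytic payload size in binary GiB of a store of ``n_items``
    fixed-width entries (defaults: 8-byte root key + 128-byte counter
    block, i.e., one billion items is ~127 GiB)."""
    return n_items * (key_bytes + value_bytes) / 2**30
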