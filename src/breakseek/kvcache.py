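"""Static in-memory cache of the most-frequently-looked-up roots.

A histogram's counters *are* its access forecast: the Label unit looks
every read k-mer up once per occurrence, so the roots with the largest
counter totals will be probed the most.  The cache is therefore built
once, right after counting, from the histogram itself — no admission
policy, no eviction — and holds whole roots in the compact k-mer
indexed format (12 accounted bytes per observed variant: 8-byte key
plus two 2-byte counters), unlike the store's dense 136-byte record.

A hit reconstructs the full 64-counter record, so the caller cannot
tell a cache hit from a store read: caching never changes results,
only storage traffic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple, Union

import numpy as np

from .count import Histogram
from .kvstore import ABSENT, Absent, ROOT_RECORD_DTYPE, RootRecord

__all__ = ["CacheConfig", "KvCache", "build_cache", "MISS"]

#: accounted bytes per cached k-mer entry (key + normal + tumoral)
ENTRY_BYTES = 12


class Miss:
    """Sentinel for a root not in the cache (fall through to store)."""

    __slots__ = ()

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:  # pragma: no cover
        return "Miss"


MISS = Miss()


@dataclass(frozen=True)
class CacheConfig:
    budget_bytes: int = 0

    def __post_init__(self) -> None:
        if self.budget_bytes < 0:
            raise ValueError("cache budget must be >= 0")


@dataclass
class KvCache:
    """root_code -> (variant indices, normal counts, tumoral counts)."""

    entries: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    accounted_bytes: int = 0
    hits: int = 0
    misses: int = 0

    def lookup(self, root_code: int) -> Union[RootRecord, Miss]:
        """Reconstruct the full 64-counter record on a hit."""
        got = self.entries.get(root_code)
        if got is None:
            self.misses += 1
            return MISS
        self.hits += 1
        v, n, t = got
        counters = np.zeros(64, dtype=np.uint16)
        counters[2 * v] = n
        counters[2 * v + 1] = t
        return RootRecord(root=root_code, counters=counters)

    def hit_stats(self, probes: Iterable[int]) -> Tuple[int, int, float]:
        """(hits, misses, hit_fraction) over a probe stream."""
        hits = misses = 0
        for p in probes:
            if int(p) in self.entries:
                hits += 1
            else:
                misses += 1
        total = hits + misses
        return hits, misses, (hits / total if total else 0.0)


def cache_lookup(root_code: int, cache: KvCache) -> Union[RootRecord, Miss]:
    return cache.lookup(root_code)


def build_cache(
    histogram: Union[Histogram, np.ndarray], budget_bytes: int
) -> KvCache:
    """Greedy frequency-ranked admission.

    Roots are ranked by total count (both samples, all variants)
    descending, ties broken by ascending root code; each is admitted
    whole if its k-mer entries fit the remaining budget, else skipped
    and ranking continues.  A root is entirely cached or not at all —
    a partial root would still cost a storage read, making the cached
    half worthless.
    """
    entries = histogram.load() if isinstance(histogram, Histogram) else histogram
    cache = KvCache()
    if entries.size == 0 or budget_bytes <= 0:
        return cache
    keys = entries["key"].astype(np.uint64)
    roots = keys >> np.uint64(5)
    new_root = np.concatenate(([True], roots[1:] != roots[:-1]))
    starts = np.flatnonzero(new_root)
    counts = np.diff(np.concatenate((starts, [entries.size])))
    totals = np.add.reduceat(
        entries["n"].astype(np.uint64) + entries["t"].astype(np.uint64), starts
    )
    uroots = roots[new_root]
    order = np.lexsort((uroots, -totals.astype(np.int64)))
    used = 0
    for i in order:
        size = int(counts[i]) * ENTRY_BYTES
        if used + size > budget_bytes:
            continue
        s, c = int(starts[i]), int(counts[i])
        block = entries[s:s + c]
        v = (block["key"] & np.uint64(0x1F)).astype(np.int64)
        cache.entries[int(uroots[i])] = (
            v, block["n"].copy(), block["t"].copy()
        )
        used += size
    cache.accounted_bytes = used
    return cache
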