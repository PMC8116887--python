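"""Label unit: find interesting k-mers and reads, build the database.

A k-mer is *tumoral-interesting* when the histogram shows it well
supported in the tumor sample (t >= Tmin), essentially absent from the
normal sample (n <= Nmax), **and** some almost-matching variant of the
same root is well supported in the normal sample (n >= Wmin for some
other variant).  The witness requirement is what makes the k-mer
usable: an imbalanced k-mer alone marks a locus, but only a shared
stem lets normal and tumor reads be aligned across samples to
reconstruct the mutation.  ``symmetric_mode`` applies the mirrored rule
to normal-only k-mers as well.

Tmin operationalizes "seen multiple times" (a k-mer seen once is
almost always a read error), Nmax tolerates tumor-in-normal bleed, and
all three thresholds are configuration, not constants.

Interestingness is a function of the histogram alone, so labeling is a
single streaming pass over the reads: every read k-mer's root is
resolved through cache -> band-pass/Bloom -> store, the record's
interesting variants are derived once per root, and any read touching
a root with at least one interesting variant is written to the
database with all its hits on such roots.  Recording the touching
reads from *both* samples (not only those carrying the interesting
variant itself) is deliberate: the grouping unit needs the normal
witness reads to build a two-sample consensus.

The database is a pair of sorted TSV tables (gzip, fixed mtime so
equal content means equal bytes): reads keyed by read id, k-mers keyed
by k-mer.  Databases built from disjoint root partitions merge by
concatenating k-mer tables and unioning read entries.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .count import PartitionSpec, read_fastq_batches
from .kmer_model import decode, encode, seq_to_codes, sort_keys_from_kmers, window_codes
from .kvcache import KvCache, MISS
from .kvstore import ABSENT, ChunkedStore, RootRecord

__all__ = [
    "LabelConfig",
    "classify_kmer",
    "interesting_variants",
    "ReadEntry",
    "KmerEntry",
    "InterestingDB",
    "label_reads",
    "merge_dbs",
]


@dataclass(frozen=True)
class LabelConfig:
    """Interestingness thresholds.

    min_tumor_support (Tmin): minimum tumoral count of the candidate
    k-mer; >= 2 or a single read error qualifies.  max_normal_count
    (Nmax): maximum normal count tolerated for a tumor-exclusive k-mer.
    min_witness_count (Wmin): minimum normal count some *other* variant
    of the root must reach to serve as the cross-sample anchor.
    symmetric_mode: also flag normal-only k-mers (roles swapped).
    """

    min_tumor_support: int = 4
    max_normal_count: int = 1
    min_witness_count: int = 4
    symmetric_mode: bool = False

    def __post_init__(self) -> None:
        if self.min_tumor_support < 2:
            raise ValueError("min_tumor_support must be >= 2 (singletons are noise)")
        if self.max_normal_count < 0 or self.min_witness_count < 1:
            raise ValueError("invalid thresholds")


def interesting_variants(counters: np.ndarray, cfg: LabelConfig) -> np.ndarray:
    """Boolean mask over the 32 variant slots of one root record."""
    n = counters[0::2].astype(np.int64)
    t = counters[1::2].astype(np.int64)
    n_wit = n >= cfg.min_witness_count
    wit_count = int(n_wit.sum())
    mask = (
        (t >= cfg.min_tumor_support)
        & (n <= cfg.max_normal_count)
        & ((wit_count - n_wit.astype(np.int64)) >= 1)
    )
    if cfg.symmetric_mode:
        t_wit = t >= cfg.min_witness_count
        twc = int(t_wit.sum())
        mask |= (
            (n >= cfg.min_tumor_support)
            & (t <= cfg.max_normal_count)
            & ((twc - t_wit.astype(np.int64)) >= 1)
        )
    return mask


def classify_kmer(record: RootRecord, v: int, cfg: LabelConfig) -> bool:
    """Is variant ``v`` of this root record interesting?"""
    return bool(interesting_variants(record.counters, cfg)[v])


# ---------------------------------------------------------------------------
# interesting reads / k-mers database
# ---------------------------------------------------------------------------


@dataclass
class ReadEntry:
    sample: str  # 'N' or 'T'
    seq: str
    desc: str = ""
    hits: List[Tuple[int, int]] = field(default_factory=list)  # (pos, kmer code)


@dataclass
class KmerEntry:
    root: int
    n: int
    t: int
    read_ids: List[str] = field(default_factory=list)


@dataclass
class InterestingDB:
    k: int
    reads: Dict[str, ReadEntry] = field(default_factory=dict)
    kmers: Dict[int, KmerEntry] = field(default_factory=dict)

    # -- serialization --------------------------------------------------

    def write(self, prefix: Union[str, Path]) -> Tuple[Path, Path]:
        """Write ``{prefix}.reads.tsv.gz`` and ``{prefix}.kmers.tsv.gz``,
        rows sorted by key, gzip mtime fixed at zero."""
        prefix = str(prefix)
        reads_path = Path(prefix + ".reads.tsv.gz")
        kmers_path = Path(prefix + ".kmers.tsv.gz")
        with _gz_text(reads_path) as out:
            out.write("read_id\tsample\tsequence\tdesc\thits\n")
            for rid in sorted(self.reads):
                e = self.reads[rid]
                hits = ";".join(
                    f"{pos}:{decode(code, self.k)}" for pos, code in sorted(e.hits)
                )
                out.write(f"{rid}\t{e.sample}\t{e.seq}\t{e.desc}\t{hits}\n")
        with _gz_text(kmers_path) as out:
            out.write("kmer\troot\tn\tt\tread_ids\n")
            for code in sorted(self.kmers):
                e = self.kmers[code]
                out.write(
                    f"{decode(code, self.k)}\t{decode(e.root, self.k - 2)}\t"
                    f"{e.n}\t{e.t}\t{','.join(sorted(e.read_ids))}\n"
                )
        return reads_path, kmers_path

    @classmethod
    def read(cls, prefix: Union[str, Path], k: int) -> "InterestingDB":
        db = cls(k=k)
        with gzip.open(str(prefix) + ".reads.tsv.gz", "rt") as fh:
            next(fh)
            for line in fh:
                rid, sample, seq, desc, hits = line.rstrip("\n").split("\t")
                entry = ReadEntry(sample=sample, seq=seq, desc=desc)
                if hits:
                    for h in hits.split(";"):
                        pos, kmer = h.split(":")
                        entry.hits.append((int(pos), encode(kmer)))
                db.reads[rid] = entry
        with gzip.open(str(prefix) + ".kmers.tsv.gz", "rt") as fh:
            next(fh)
            for line in fh:
                kmer, root, n, t, rids = line.rstrip("\n").split("\t")
                db.kmers[encode(kmer)] = KmerEntry(
                    root=encode(root), n=int(n), t=int(t),
                    read_ids=rids.split(",") if rids else [],
                )
        return db


def _gz_text(path: Path):
    raw = open(path, "wb")
    gz = gzip.GzipFile(fileobj=raw, mode="wb", mtime=0)
    return io.TextIOWrapper(gz, encoding="ascii", write_through=True)


# ---------------------------------------------------------------------------
# labeling pass
# ---------------------------------------------------------------------------


class _RootResolver:
    """Memoizing cache -> store resolution of root records plus their
    interesting-variant masks.  Look-ups reach the store through
    ``lookup_batch`` and each distinct root is resolved at most once."""

    def __init__(self, store: ChunkedStore, cache: Optional[KvCache], cfg: LabelConfig):
        self.store = store
        self.cache = cache
        self.cfg = cfg
        self.records: Dict[int, Optional[np.ndarray]] = {}
        self.masks: Dict[int, np.ndarray] = {}
        self.interesting_roots: set = set()

    def resolve(self, roots: np.ndarray) -> None:
        new = [int(r) for r in np.unique(roots) if int(r) not in self.records]
        pending = []
        for r in new:
            if self.cache is not None:
                got = self.cache.lookup(r)
                if got is not MISS:
                    self._admit(r, got.counters)
                    continue
            pending.append(r)
        for r, res in self.store.lookup_batch((r, r) for r in pending):
            self._admit(r, None if res is ABSENT else res.counters)

    def _admit(self, root: int, counters: Optional[np.ndarray]) -> None:
        self.records[root] = counters
        if counters is not None:
            mask = interesting_variants(counters, self.cfg)
            if mask.any():
                self.masks[root] = mask
                self.interesting_roots.add(root)


def _windows_of_batch(seqs: Sequence[str], k: int):
    """(read_idx, pos, kmer codes) of all valid windows in a read batch."""
    joined = "\x00".join(seqs)
    codes = seq_to_codes(joined)
    starts, kmers = window_codes(codes, k)
    if kmers.size == 0:
        return (np.empty(0, np.int64),) * 2 + (kmers,)
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    offsets = np.concatenate(([0], np.cumsum(lens + 1)))[:-1]
    read_idx = np.searchsorted(offsets, starts, side="right") - 1
    pos = starts - offsets[read_idx]
    return read_idx, pos, kmers


def label_reads(
    normal_fastq: Union[str, Path],
    tumoral_fastq: Union[str, Path],
    store: ChunkedStore,
    cache: Optional[KvCache],
    cfg: LabelConfig,
    partition: Optional[PartitionSpec] = None,
    batch_size: int = 4096,
) -> InterestingDB:
    """One streaming pass over both samples for one root partition."""
    k = store.k
    lo = hi = None
    if partition is not None:
        lo, hi = partition.bounds(k)
    resolver = _RootResolver(store, cache, cfg)
    db = InterestingDB(k=k)

    for path, sample in ((normal_fastq, "N"), (tumoral_fastq, "T")):
        for batch in read_fastq_batches(path, batch_size):
            titles = [t for t, _s in batch]
            seqs = [s for _t, s in batch]
            read_idx, pos, kmers = _windows_of_batch(seqs, k)
            if kmers.size == 0:
                continue
            keys = sort_keys_from_kmers(kmers, k)
            roots = keys >> np.uint64(5)
            if lo is not None:
                keep = (roots >= lo) & (roots < hi)
                read_idx, pos, kmers = read_idx[keep], pos[keep], kmers[keep]
                keys, roots = keys[keep], roots[keep]
                if kmers.size == 0:
                    continue
            resolver.resolve(roots)
            if not resolver.interesting_roots:
                continue
            iroots = np.fromiter(
                resolver.interesting_roots, dtype=np.uint64,
                count=len(resolver.interesting_roots),
            )
            iroots.sort()
            loc = np.searchsorted(iroots, roots)
            loc[loc == iroots.size] = 0
            touch = np.flatnonzero(iroots[np.minimum(loc, iroots.size - 1)] == roots)
            for j in touch:
                root = int(roots[j])
                ridx = int(read_idx[j])
                rid = titles[ridx].split(None, 1)[0]
                entry = db.reads.get(rid)
                if entry is None:
                    parts = titles[ridx].split(None, 1)
                    entry = ReadEntry(
                        sample=sample, seq=seqs[ridx],
                        desc=parts[1] if len(parts) > 1 else "",
                    )
                    db.reads[rid] = entry
                hit = (int(pos[j]), int(kmers[j]))
                entry.hits.append(hit)
                v = int(keys[j] & np.uint64(0x1F))
                if resolver.masks[root][v]:
                    code = int(kmers[j])
                    kent = db.kmers.get(code)
                    if kent is None:
                        counters = resolver.records[root]
                        kent = KmerEntry(
                            root=root,
                            n=int(counters[2 * v]),
                            t=int(counters[2 * v + 1]),
                        )
                        db.kmers[code] = kent
                    if rid not in kent.read_ids:
                        kent.read_ids.append(rid)
    for entry in db.reads.values():
        entry.hits = sorted(set(entry.hits))
    return db


def merge_dbs(dbs: Sequence[InterestingDB]) -> InterestingDB:
    """Union of per-partition databases: k-mer tables concatenate (keys
    disjoint by construction), read entries with the same id merge
    their hit lists; sequence and sample must agree."""
    if not dbs:
        raise ValueError("nothing to merge")
    out = InterestingDB(k=dbs[0].k)
    for db in dbs:
        if db.k != out.k:
            raise ValueError("k mismatch across databases")
        for rid, e in db.reads.items():
            have = out.reads.get(rid)
            if have is None:
                out.reads[rid] = ReadEntry(
                    sample=e.sample, seq=e.seq, desc=e.desc, hits=list(e.hits)
                )
            else:
                if have.seq != e.seq or have.sample != e.sample:
                    raise ValueError(f"conflicting entries for read {rid}")
                have.hits.extend(e.hits)
        for code, ke in db.kmers.items():
            have_k = out.kmers.get(code)
            if have_k is None:
                out.kmers[code] = KmerEntry(
                    root=ke.root, n=ke.n, t=ke.t, read_ids=list(ke.read_ids)
                )
            else:
                if (have_k.root, have_k.n, have_k.t) != (ke.root, ke.n, ke.t):
                    raise ValueError("conflicting k-mer table entries")
                have_k.read_ids = sorted(set(have_k.read_ids) | set(ke.read_ids))
    for e in out.reads.values():
        e.hits = sorted(set(e.hits))
    for ke in out.kmers.values():
        ke.read_ids = sorted(set(ke.read_ids))
    return out
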