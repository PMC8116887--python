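"""Bounded-memory external Sort-Reduce over (key, counter-pair) updates.

Counting billions of k-mers as random read-modify-writes to a giant
table thrashes whatever medium holds the table.  Sort-Reduce instead
treats every increment as an *update record*, sorts updates by key in
DRAM-sized blocks, merges records with equal keys on the fly using an
associative, commutative reduction, spills the sorted-and-reduced runs
to disk, and finally k-way merges the runs (again reducing) until a
single fully sorted run remains.  All storage traffic is sequential and
the reduction shrinks data at every stage.

The engine is generic over the reduction; the pipeline instantiates it
with saturating addition of a (normal, tumoral) 16-bit counter pair.

Run files are little-endian: a 16-byte header (magic ``SRR1``, u32
reserved, u64 record count) followed by fixed 12-byte records (u64 key,
u16 normal, u16 tumoral), strictly increasing by key.
"""

from __future__ import annotations

import os
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

__all__ = [
    "UPDATE_DTYPE",
    "RECORD_BYTES",
    "COUNTER_MAX",
    "Run",
    "SortReduceConfig",
    "SortReduceEngine",
    "sort_reduce",
    "read_run",
    "write_run",
    "saturating_counter_reduce",
]

UPDATE_DTYPE = np.dtype([("key", "<u8"), ("n", "<u2"), ("t", "<u2")])
RECORD_BYTES = UPDATE_DTYPE.itemsize  # 12
COUNTER_MAX = np.uint16(0xFFFF)
_MAGIC = b"SRR1"
_HEADER_BYTES = 16


@dataclass(frozen=True)
class Run:
    """A sorted, internally reduced spill file."""

    path: Path
    count: int


@dataclass
class SortReduceConfig:
    """Engine knobs.

    mem_budget_bytes
        Phase-1 sort buffer limit; at least one record.  The merge phase
        splits the same budget across its input-run read buffers.
    merge_fanin
        Maximum runs merged per pass (>= 2).  The merge is repeated in
        passes until one run remains.
    spill_dir
        Working directory for run files.
    keep_intermediates
        Keep per-pass run files instead of deleting them (debugging).
    """

    mem_budget_bytes: int = 64 * 1024 * 1024
    merge_fanin: int = 16
    spill_dir: Path = Path(".")
    keep_intermediates: bool = False

    def __post_init__(self) -> None:
        self.spill_dir = Path(self.spill_dir)
        if self.mem_budget_bytes < RECORD_BYTES:
            raise ValueError("mem_budget_bytes must hold at least one record")
        if self.merge_fanin < 2:
            raise ValueError("merge_fanin must be >= 2")

    @property
    def buffer_records(self) -> int:
        return max(1, self.mem_budget_bytes // RECORD_BYTES)


def saturating_counter_reduce(
    sorted_records: np.ndarray,
) -> Tuple[np.ndarray, bool]:
    """Merge equal-key runs of a key-sorted record array by saturating
    16-bit addition of both counters.  Returns (reduced, saturated?).
    """
    if sorted_records.size == 0:
        return sorted_records, False
    keys = sorted_records["key"]
    boundary = np.concatenate(([True], keys[1:] != keys[:-1]))
    starts = np.flatnonzero(boundary)
    out = np.empty(starts.size, dtype=UPDATE_DTYPE)
    out["key"] = keys[starts]
    saturated = False
    for fld in ("n", "t"):
        sums = np.add.reduceat(sorted_records[fld].astype(np.uint64), starts)
        if (sums > COUNTER_MAX).any():
            saturated = True
        out[fld] = np.minimum(sums, np.uint64(COUNTER_MAX)).astype(np.uint16)
    return out, saturated


Reducer = Callable[[np.ndarray], Tuple[np.ndarray, bool]]


def write_run(path: Path, records: np.ndarray) -> Run:
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write((0).to_bytes(4, "little"))
        fh.write(int(records.size).to_bytes(8, "little"))
        records.astype(UPDATE_DTYPE, copy=False).tofile(fh)
    return Run(path=Path(path), count=int(records.size))


def read_run(path: Path) -> np.ndarray:
    """Load a whole run file (tests / small inputs only)."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a run file")
        fh.read(4)
        count = int.from_bytes(fh.read(8), "little")
        recs = np.fromfile(fh, dtype=UPDATE_DTYPE, count=count)
    if recs.size != count:
        raise ValueError(f"{path}: truncated run")
    return recs


class _RunReader:
    """Block-buffered reader over a run file, verifying key monotonicity."""

    def __init__(self, run: Run, block_records: int):
        self.path = run.path
        self.remaining = run.count
        self.block = max(1, block_records)
        self.fh = open(run.path, "rb")
        self.fh.seek(_HEADER_BYTES)
        self.buf = np.empty(0, dtype=UPDATE_DTYPE)
        self.last_key = -1

    def refill(self) -> None:
        if self.buf.size or self.remaining == 0:
            return
        want = min(self.block, self.remaining)
        recs = np.fromfile(self.fh, dtype=UPDATE_DTYPE, count=want)
        if recs.size != want:
            raise IOError(f"{self.path}: truncated run")
        keys = recs["key"]
        if (keys[1:] <= keys[:-1]).any() or int(keys[0]) <= self.last_key:
            raise ValueError(f"{self.path}: corrupt run (non-monotone keys)")
        self.last_key = int(keys[-1])
        self.remaining -= want
        self.buf = recs

    @property
    def exhausted(self) -> bool:
        return self.buf.size == 0 and self.remaining == 0

    def close(self) -> None:
        self.fh.close()


class SortReduceEngine:
    """Two-phase external sort with on-the-fly reduction.

    Instrumentation: ``peak_buffer_records`` tracks the largest number
    of records resident in engine buffers at any instant (phase-1 sort
    buffer, or the sum of merge read buffers), ``bytes_spilled`` the
    intermediate bytes written, and ``saturated`` whether any counter
    clamped.
    """

    def __init__(self, cfg: SortReduceConfig, reducer: Reducer = saturating_counter_reduce):
        self.cfg = cfg
        self.reducer = reducer
        self.peak_buffer_records = 0
        self.bytes_spilled = 0
        self.saturated = False

    def _note_buffer(self, records: int) -> None:
        if records > self.peak_buffer_records:
            self.peak_buffer_records = records

    def _tmp_path(self, tag: str) -> Path:
        return self.cfg.spill_dir / f"sr_{tag}_{uuid.uuid4().hex[:12]}.run"

    # -- phase 1 ------------------------------------------------------

    def phase1_spill(self, stream: Iterable[np.ndarray]) -> List[Run]:
        """Sort/reduce DRAM-sized blocks of the update stream into runs.

        ``stream`` yields arrays of UPDATE_DTYPE (any sizes); batches
        are split as needed so the buffer never exceeds the budget.
        """
        os.makedirs(self.cfg.spill_dir, exist_ok=True)
        cap = self.cfg.buffer_records
        runs: List[Run] = []
        pending: List[np.ndarray] = []
        pending_n = 0

        def flush() -> None:
            nonlocal pending, pending_n
            if pending_n == 0:
                return
            block = np.concatenate(pending) if len(pending) > 1 else pending[0]
            pending, pending_n = [], 0
            block = np.sort(block, order="key")
            reduced, sat = self.reducer(block)
            self.saturated |= sat
            path = self._tmp_path("p1")
            runs.append(write_run(path, reduced))
            self.bytes_spilled += reduced.nbytes

        for batch in stream:
            batch = np.asarray(batch, dtype=UPDATE_DTYPE)
            while batch.size:
                room = cap - pending_n
                take = batch[:room]
                batch = batch[room:]
                pending.append(take)
                pending_n += take.size
                self._note_buffer(pending_n)
                if pending_n >= cap:
                    flush()
        flush()
        return runs

    # -- phase 2 ------------------------------------------------------

    def _merge_group(self, runs: Sequence[Run], out_path: Path) -> Run:
        """Merge <= fan-in sorted runs into one, reducing equal keys.

        Streams block-wise: each pass emits every buffered record whose
        key is <= the smallest 'last buffered key' over the runs, which
        guarantees no key can still arrive from any run.
        """
        block = max(1, self.cfg.buffer_records // max(1, len(runs)))
        readers = [_RunReader(r, block) for r in runs]
        total = 0
        with open(out_path, "wb") as fh:
            fh.write(_MAGIC + (0).to_bytes(4, "little") + (0).to_bytes(8, "little"))
            while True:
                for rd in readers:
                    rd.refill()
                active = [rd for rd in readers if rd.buf.size]
                if not active:
                    break
                self._note_buffer(sum(rd.buf.size for rd in readers))
                # safe emission threshold
                safe = min(
                    int(rd.buf["key"][-1]) for rd in active if rd.remaining
                ) if any(rd.remaining for rd in active) else None
                parts = []
                for rd in active:
                    if safe is None:
                        cut = rd.buf.size
                    else:
                        cut = int(np.searchsorted(rd.buf["key"], safe, side="right"))
                    if cut:
                        parts.append(rd.buf[:cut])
                        rd.buf = rd.buf[cut:]
                if not parts:
                    continue
                merged = np.sort(np.concatenate(parts), order="key")
                reduced, sat = self.reducer(merged)
                self.saturated |= sat
                reduced.tofile(fh)
                total += reduced.size
            fh.seek(8)
            fh.write(total.to_bytes(8, "little"))
        for rd in readers:
            rd.close()
        self.bytes_spilled += total * RECORD_BYTES
        return Run(path=out_path, count=total)

    def merge_runs(self, runs: Sequence[Run]) -> Run:
        """Repeated fan-in-bounded merge passes until one run remains."""
        os.makedirs(self.cfg.spill_dir, exist_ok=True)
        runs = list(runs)
        if not runs:
            return write_run(self._tmp_path("empty"), np.empty(0, dtype=UPDATE_DTYPE))
        while len(runs) > 1:
            group = runs[: self.cfg.merge_fanin]  # oldest first
            rest = runs[self.cfg.merge_fanin:]
            merged = self._merge_group(group, self._tmp_path("m"))
            if not self.cfg.keep_intermediates:
                for r in group:
                    try:
                        os.unlink(r.path)
                    except OSError:
                        pass
            runs = rest + [merged]
        return runs[0]

    def sort_reduce(self, stream: Iterable[np.ndarray]) -> Run:
        return self.merge_runs(self.phase1_spill(stream))


def sort_reduce(
    stream: Iterable[np.ndarray],
    cfg: SortReduceConfig,
    reducer: Reducer = saturating_counter_reduce,
) -> Run:
    """One-shot convenience wrapper around :class:`SortReduceEngine`."""
    return SortReduceEngine(cfg, reducer).sort_reduce(stream)
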