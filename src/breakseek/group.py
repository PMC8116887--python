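"""Group unit: cluster interesting reads, align, call break-points.

Reads sharing any k-mer of one interesting root cover the same locus,
so each such root seeds a *read group*.  Reads whose hit lies on the
reverse-complement stem are flipped so every member contains the
anchor literally; members are then laid out gaplessly, shifted so the
anchor occurrence starts at column 0.  Per column and per sample a
majority consensus is taken, and a maximal run of columns where both
samples are covered (>= Cmin) but disagree is reported as a candidate
break-point at the run's first column, with local context from both
consensi.

Gapless anchoring is the minimal faithful alignment for this data
model: a point mutation shows up as a single divergent column, while
insertions and deletions appear as divergent *runs* beginning at the
break-point rather than as gapped columns — a documented limitation,
sufficient for locating the event.

When reads carry simulation provenance (``pos=.. strand=.. origin=..``
descriptions), calls can be mapped back to reference coordinates and
scored against the injected-mutation manifest.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kmer_model import canonical_root, decode, revcomp, stem_of
from .label import InterestingDB
from .simulate import Mutation, MutationManifest

__all__ = [
    "GroupMember",
    "ReadGroup",
    "Layout",
    "BreakpointCall",
    "group_reads",
    "build_layout",
    "call_breakpoints",
    "render_report",
    "evaluate_calls",
]


@dataclass(frozen=True)
class GroupMember:
    read_id: str
    sample: str
    seq: str        # oriented so the anchor stem matches the root literally
    offset: int     # 0-based start of the anchor k-mer in the oriented read
    flipped: bool   # True if the stored sequence is the reverse complement
    desc: str = ""


@dataclass
class ReadGroup:
    root: int
    members: List[GroupMember]


@dataclass
class Layout:
    """Gapless column layout of one group, anchored at column 0."""

    root: int
    start_col: int            # column index of array position 0
    cons: Dict[str, str]      # per-sample consensus ('N' on ties)
    cov: Dict[str, np.ndarray]
    members: List[GroupMember]

    def column(self, col: int) -> int:
        return col - self.start_col


@dataclass(frozen=True)
class BreakpointCall:
    root: int
    column: int          # first divergent column, relative to the anchor
    run_length: int
    n_normal: int        # normal coverage at the break-point column
    n_tumor: int
    normal_context: str
    tumor_context: str


def group_reads(db: InterestingDB, k: int) -> List[ReadGroup]:
    """One group per interesting root; members are every database read
    whose hit list touches the root, oriented onto the root's own stem.

    A read hitting a root several times is anchored at its first
    (lowest-position) hit.  Groups with identical member-id sets are
    deduplicated, keeping the lowest root.
    """
    interesting_roots = {entry.root for entry in db.kmers.values()}
    touches: Dict[int, Dict[str, Tuple[int, int]]] = {r: {} for r in interesting_roots}
    for rid, entry in db.reads.items():
        for pos, code in entry.hits:
            stem = stem_of(code, k)
            root = canonical_root(stem, k - 2)
            if root not in touches:
                continue
            if rid not in touches[root] or pos < touches[root][rid][0]:
                touches[root][rid] = (pos, code)

    groups: List[ReadGroup] = []
    for root in sorted(interesting_roots):
        members = []
        for rid in sorted(touches[root]):
            pos, code = touches[root][rid]
            entry = db.reads[rid]
            stem = stem_of(code, k)
            if stem == root:
                members.append(GroupMember(rid, entry.sample, entry.seq, pos,
                                           False, entry.desc))
            else:
                members.append(GroupMember(
                    rid, entry.sample, revcomp(entry.seq),
                    len(entry.seq) - k - pos, True, entry.desc,
                ))
        if members:
            groups.append(ReadGroup(root=root, members=members))

    seen: Dict[frozenset, int] = {}
    out = []
    for g in groups:  # roots ascend, so first occurrence keeps lowest root
        key = frozenset(m.read_id for m in g.members)
        if key in seen:
            continue
        seen[key] = g.root
        out.append(g)
    return out


def build_layout(group: ReadGroup) -> Layout:
    """Shift every member so its anchor occurrence starts at column 0
    and take per-column, per-sample majority consensus."""
    if not group.members:
        raise ValueError("empty group")
    starts = [-m.offset for m in group.members]
    start_col = min(starts)
    end_col = max(s + len(m.seq) for s, m in zip(starts, group.members))
    ncols = end_col - start_col
    counts = {s: np.zeros((ncols, 4), dtype=np.int32) for s in "NT"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s, m in zip(starts, group.members):
        off = s - start_col
        for i, ch in enumerate(m.seq):
            b = base_idx.get(ch)
            if b is not None:
                counts[m.sample][off + i, b] += 1
    cons = {}
    cov = {}
    for sample in "NT":
        c = counts[sample]
        cov[sample] = c.sum(axis=1)
        best = c.argmax(axis=1)
        bestc = c[np.arange(ncols), best]
        tie = (c == bestc[:, None]).sum(axis=1) > 1
        letters = np.array(list("ACGT"))[best]
        letters[(bestc == 0) | tie] = "N"
        cons[sample] = "".join(letters)
    return Layout(root=group.root, start_col=start_col, cons=cons, cov=cov,
                  members=group.members)


def call_breakpoints(
    layout: Layout, cmin: int = 3, context: int = 56, merge_gap: int = 10
) -> List[BreakpointCall]:
    """Maximal divergent regions of the layout, one call per region.

    A column is divergent when both samples reach coverage Cmin yet
    their (unambiguous) consensi disagree.  Past a true break-point a
    gapless layout compares shifted sequence, where ~1/4 of columns
    match again by chance, so divergent runs separated by gaps of at
    most ``merge_gap`` columns are merged into one region; chance gaps
    longer than that are vanishingly rare while distinct mutations sit
    far apart.

    The reported break-point is the region edge nearest the anchor —
    the column where divergence *begins*: the first column for a region
    at or right of the anchor start, the last column for a region
    entirely to its left.  ``context`` is the half-width of the
    reported consensus windows (2k bases at the default k = 28).
    """
    ncols = len(layout.cons["N"])
    cn = np.frombuffer(layout.cons["N"].encode(), dtype=np.uint8)
    ct = np.frombuffer(layout.cons["T"].encode(), dtype=np.uint8)
    amb = ord("N")
    div = (
        (layout.cov["N"] >= cmin)
        & (layout.cov["T"] >= cmin)
        & (cn != ct)
        & (cn != amb)
        & (ct != amb)
    )
    # maximal True runs as half-open [i, j)
    runs: List[Tuple[int, int]] = []
    i = 0
    while i < ncols:
        if not div[i]:
            i += 1
            continue
        j = i
        while j < ncols and div[j]:
            j += 1
        runs.append((i, j))
        i = j
    merged: List[Tuple[int, int]] = []
    for i, j in runs:
        if merged and i - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], j)
        else:
            merged.append((i, j))
    calls = []
    for i, j in merged:
        first_col = i + layout.start_col
        last_col = j - 1 + layout.start_col
        bp = first_col if first_col >= 0 else last_col
        at = layout.column(bp)
        lo = max(0, at - context)
        hi = min(ncols, at + context + 1)
        calls.append(BreakpointCall(
            root=layout.root,
            column=bp,
            run_length=j - i,
            n_normal=int(layout.cov["N"][at]),
            n_tumor=int(layout.cov["T"][at]),
            normal_context=layout.cons["N"][lo:hi],
            tumor_context=layout.cons["T"][lo:hi],
        ))
    return calls


def render_report(
    calls: Sequence[BreakpointCall],
    layouts: Dict[int, Layout],
    k: int,
) -> Tuple[str, str]:
    """Human-readable blocks plus a machine TSV, both deterministic."""
    calls = sorted(calls, key=lambda c: (c.root, c.column))
    tsv_lines = [
        "group_id\tanchor_root\tbreakpoint_offset\trun_length"
        "\tn_normal_reads\tn_tumor_reads\tnormal_context\ttumor_context"
    ]
    blocks = []
    for c in calls:
        root_str = decode(c.root, k - 2)
        layout = layouts[c.root]
        n_members = {"N": 0, "T": 0}
        for m in layout.members:
            n_members[m.sample] += 1
        tsv_lines.append(
            f"{c.root}\t{root_str}\t{c.column}\t{c.run_length}"
            f"\t{n_members['N']}\t{n_members['T']}"
            f"\t{c.normal_context}\t{c.tumor_context}"
        )
        lines = [f"group {c.root} anchor_root={root_str} breakpoint_col={c.column}"
                 f" run={c.run_length}"]
        pad = -layout.start_col
        for m in sorted(layout.members, key=lambda m: (m.sample, m.read_id)):
            shift = pad - m.offset
            lines.append(f"  {m.sample} {' ' * shift}{m.seq}  {m.read_id}"
                         f"{' (rc)' if m.flipped else ''}")
        lines.append(f"  N {layout.cons['N']}")
        lines.append(f"  T {layout.cons['T']}")
        lines.append(f"    {' ' * layout.column(c.column)}⋆")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else ""), "\n".join(tsv_lines) + "\n"


# ---------------------------------------------------------------------------
# scoring against simulation truth
# ---------------------------------------------------------------------------


def _parse_desc(desc: str) -> Dict[str, str]:
    out = {}
    for tok in desc.split():
        if "=" in tok:
            key, val = tok.split("=", 1)
            out[key] = val
    return out


def call_ref_position(call: BreakpointCall, layout: Layout) -> Optional[int]:
    """Map a break-point column to a 0-based reference coordinate using
    the provenance of normal-origin members; median over members."""
    positions = []
    for m in layout.members:
        meta = _parse_desc(m.desc)
        if meta.get("origin") != "N" or "pos" not in meta:
            continue
        i = call.column + m.offset  # index within the oriented read
        if not 0 <= i < len(m.seq):
            continue
        net_flip = m.flipped != (meta.get("strand") == "-")
        p = int(meta["pos"])
        positions.append(p + (len(m.seq) - 1 - i) if net_flip else p + i)
    if not positions:
        return None
    return int(statistics.median(positions))


def evaluate_calls(
    calls: Sequence[BreakpointCall],
    layouts: Dict[int, Layout],
    manifest: MutationManifest,
    k: int,
    tolerance: Optional[int] = None,
) -> Dict[str, object]:
    """Recall/precision of calls against the injected mutations.

    A truth mutation is recovered if some call maps within ``tolerance``
    (default k) bases of its position; a call is correct if it maps
    within tolerance of some truth mutation.  Calls that cannot be
    mapped to reference coordinates count against precision.
    """
    tol = k if tolerance is None else tolerance
    truth = [(m.kind, m.pos - 1) for m in manifest]
    mapped: List[Optional[int]] = [
        call_ref_position(c, layouts[c.root]) for c in calls
    ]
    recovered = set()
    correct_calls = 0
    for cp in mapped:
        ok = False
        if cp is not None:
            for idx, (_kind, tp) in enumerate(truth):
                if abs(cp - tp) <= tol:
                    recovered.add(idx)
                    ok = True
        correct_calls += ok
    by_kind: Dict[str, Tuple[int, int]] = {}
    for idx, (kind, _tp) in enumerate(truth):
        got, tot = by_kind.get(kind, (0, 0))
        by_kind[kind] = (got + (idx in recovered), tot + 1)
    recall = len(recovered) / len(truth) if truth else 1.0
    precision = correct_calls / len(calls) if calls else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_calls": len(calls),
        "n_truth": len(truth),
        "recall_by_kind": {
            kind: (got / tot if tot else 1.0) for kind, (got, tot) in by_kind.items()
        },
        "call_positions": mapped,
    }
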