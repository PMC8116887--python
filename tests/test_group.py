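"""Group unit: clustering, anchored layout, break-point calls."""

import numpy as np
import pytest

from breakseek import kmer_model as km
from breakseek.group import (
    BreakpointCall,
    GroupMember,
    ReadGroup,
    build_layout,
    call_breakpoints,
    call_ref_position,
    evaluate_calls,
    group_reads,
    render_report,
)
from breakseek.label import InterestingDB, KmerEntry, ReadEntry
from breakseek.simulate import Mutation


K = 6


def db_with(reads, kmers):
    return InterestingDB(k=K, reads=reads, kmers=kmers)


def hit(seq, pos, k=K):
    return (pos, km.encode(seq[pos:pos + k]))


class TestGrouping:
    def test_reads_sharing_root_form_one_group(self):
        # anchor k-mer AGTGGT; its stem GTGG canonicalizes to root CCAC
        seqs = {
            "t1": ("T", "AGTGGTCC"), "t2": ("T", "CAGTGGTC"),
            "n1": ("N", "AGTGGTAC"), "n2": ("N", "TAGTGGTA"), "n3": ("N", "AAGTGGTT"),
        }
        reads = {}
        for rid, (sample, seq) in seqs.items():
            pos = seq.index("AGTGGT")
            reads[rid] = ReadEntry(sample, seq, "", [hit(seq, pos)])
        root = km.encode(km.canonical_root("GTGG"))
        kmers = {km.encode("AGTGGT"): KmerEntry(root, 0, 9, ["t1", "t2"])}
        groups = group_reads(db_with(reads, kmers), K)
        assert len(groups) == 1
        assert {m.read_id for m in groups[0].members} == set(seqs)

    def test_reverse_hit_is_flipped_with_recomputed_offset(self):
        # anchor CAAAAG: stem AAAA is its own root, so the forward read
        # is kept as-is and the reverse-complement read must flip
        fwd = "CAAAAGTC"
        rev = km.revcomp(fwd)  # GACTTTTG, carries CTTTTG at position 2
        pos = rev.index(km.revcomp("CAAAAG"))
        reads = {
            "a": ReadEntry("T", fwd, "", [hit(fwd, 0)]),
            "b": ReadEntry("T", rev, "", [hit(rev, pos)]),
        }
        root = km.encode("AAAA")
        kmers = {km.encode("CAAAAG"): KmerEntry(root, 0, 9, ["a"])}
        (group,) = group_reads(db_with(reads, kmers), K)
        by_id = {m.read_id: m for m in group.members}
        assert not by_id["a"].flipped and by_id["b"].flipped
        assert by_id["b"].seq == fwd
        assert by_id["b"].offset == len(rev) - K - pos == 0

    def test_identical_member_sets_deduplicated(self):
        seq = "AGTGGTCC"
        reads = {"a": ReadEntry("T", seq, "", [hit(seq, 0), hit(seq, 1)])}
        root1 = km.canonical_root(km.stem_of(km.encode(seq[0:K]), K), K - 2)
        root2 = km.canonical_root(km.stem_of(km.encode(seq[1:1 + K]), K), K - 2)
        kmers = {
            km.encode(seq[0:K]): KmerEntry(root1, 0, 9, ["a"]),
            km.encode(seq[1:1 + K]): KmerEntry(root2, 0, 9, ["a"]),
        }
        groups = group_reads(db_with(reads, kmers), K)
        assert len(groups) == 1
        assert groups[0].root == min(root1, root2)


class TestLayout:
    def test_one_column_shift(self):
        """Reads anchored on the same stem align with the right shift."""
        g = ReadGroup(km.encode("GTGG"), [
            GroupMember("a", "N", "AGTGGTCC", 0, False),
            GroupMember("b", "N", "GTGGTCC", -1, False),  # anchor starts before read
        ])
        lay = build_layout(g)
        assert lay.start_col == 0
        assert lay.cons["N"] == "AGTGGTCC"

    def test_single_read_layout_is_the_read(self):
        g = ReadGroup(0, [GroupMember("a", "T", "ACGTAC", 0, False)])
        lay = build_layout(g)
        assert lay.cons["T"] == "ACGTAC"
        assert lay.cons["N"] == "N" * 6
        assert lay.cov["T"].tolist() == [1] * 6

    def test_majority_and_tie_consensus(self):
        g = ReadGroup(0, [
            GroupMember("a", "N", "AAAA", 0, False),
            GroupMember("b", "N", "AAAC", 0, False),
            GroupMember("c", "N", "AACC", 0, False),
            GroupMember("d", "N", "ACCC", 0, False),
        ])
        lay = build_layout(g)
        assert lay.cons["N"] == "AANC"  # column 2 ties 2:2


def snv_layout(cov_n=4, cov_t=4):
    """Normal ...GTGGT..., tumoral ...GTGGA...: single point divergence."""
    normal, tumor = "CAGTGGTAC", "CAGTGGAAC"
    members = (
        [GroupMember(f"n{i}", "N", normal, 2, False) for i in range(cov_n)]
        + [GroupMember(f"t{i}", "T", tumor, 2, False) for i in range(cov_t)]
    )
    return build_layout(ReadGroup(km.encode("GTGG"), members))


class TestCallBreakpoints:
    def test_single_point_mutation_single_column(self):
        calls = call_breakpoints(snv_layout(), cmin=3)
        assert len(calls) == 1
        c = calls[0]
        assert c.run_length == 1
        assert c.column == 4  # divergent base sits 4 right of anchor start
        assert c.n_normal == 4 and c.n_tumor == 4

    def test_identical_consensi_no_calls(self):
        g = ReadGroup(0, [
            GroupMember("n", "N", "ACGTACGT", 0, False),
            GroupMember("n2", "N", "ACGTACGT", 0, False),
            GroupMember("n3", "N", "ACGTACGT", 0, False),
            GroupMember("t", "T", "ACGTACGT", 0, False),
            GroupMember("t2", "T", "ACGTACGT", 0, False),
            GroupMember("t3", "T", "ACGTACGT", 0, False),
        ])
        assert call_breakpoints(build_layout(g)) == []

    def test_coverage_below_cmin_suppresses_call(self):
        calls = call_breakpoints(snv_layout(cov_n=2), cmin=3)
        assert calls == []

    def test_insertion_shows_divergent_run_from_insertion_point(self):
        """A 5-base tumor insertion in a gapless layout diverges from the
        insertion column onward; the call lands at that column."""
        rng = np.random.default_rng(0)
        flank_l = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        flank_r = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        ins = "TTTTT"
        normal = flank_l + flank_r
        tumor = flank_l + ins + flank_r
        members = (
            [GroupMember(f"n{i}", "N", normal, 10, False) for i in range(4)]
            + [GroupMember(f"t{i}", "T", tumor, 10, False) for i in range(4)]
        )
        lay = build_layout(ReadGroup(0, members))
        calls = call_breakpoints(lay, cmin=3)
        assert len(calls) == 1
        # first divergent read position: the insertion point plus however
        # many inserted bases happen to equal the displaced normal bases
        shared = 0
        while (ins + flank_r)[shared] == flank_r[shared]:
            shared += 1
        assert calls[0].column == 30 + shared - 10
        assert calls[0].run_length >= len(ins)

    def test_merge_gap_fuses_chance_rematches(self):
        # divergent, 3 matching columns by construction, divergent again
        normal = "CCCCC" + "AAA" + "GGGGG"
        tumor_ = "TTTTT" + "AAA" + "CCCCC"
        members = (
            [GroupMember(f"n{i}", "N", normal, 0, False) for i in range(3)]
            + [GroupMember(f"t{i}", "T", tumor_, 0, False) for i in range(3)]
        )
        lay = build_layout(ReadGroup(0, members))
        assert len(call_breakpoints(lay, cmin=3, merge_gap=5)) == 1
        assert len(call_breakpoints(lay, cmin=3, merge_gap=0)) == 2


class TestReport:
    def test_one_block_and_row_per_call(self):
        lay = snv_layout()
        calls = call_breakpoints(lay, cmin=3)
        text, tsv = render_report(calls, {lay.root: lay}, K)
        assert text.count("group ") == len(calls) == 1
        assert len(tsv.rstrip("\n").split("\n")) == 1 + len(calls)
        assert "⋆" in text

    def test_empty_calls_header_only(self):
        text, tsv = render_report([], {}, K)
        assert text == ""
        assert tsv.startswith("group_id\t") and tsv.count("\n") == 1

    def test_deterministic_ordering(self):
        lay = snv_layout()
        calls = call_breakpoints(lay, cmin=3)
        a = render_report(calls, {lay.root: lay}, K)
        b = render_report(list(reversed(calls)), {lay.root: lay}, K)
        assert a == b


class TestEvaluate:
    def test_call_within_tolerance_recovers_truth(self):
        lay = snv_layout()
        # attach provenance: normal reads start at reference position 5000
        members = [
            GroupMember(m.read_id, m.sample, m.seq, m.offset, False,
                        "pos=5000 strand=+ origin=N" if m.sample == "N" else "origin=T")
            for m in lay.members
        ]
        lay2 = build_layout(ReadGroup(lay.root, members))
        calls = call_breakpoints(lay2, cmin=3)
        assert call_ref_position(calls[0], lay2) == 5000 + 6  # divergent read index
        truth = [Mutation("SNV", 5007, "T", "A")]
        ev = evaluate_calls(calls, {lay2.root: lay2}, truth, k=28)
        assert ev["recall"] == 1.0 and ev["precision"] == 1.0

    def test_reverse_strand_provenance_maps_back(self):
        lay = snv_layout()
        members = []
        for m in lay.members:
            if m.sample == "N":
                # pretend the sequencer read the minus strand; the group
                # flipped it back, so net orientation is forward
                members.append(GroupMember(
                    m.read_id, "N", m.seq, m.offset, True,
                    "pos=5000 strand=- origin=N"))
            else:
                members.append(m)
        lay2 = build_layout(ReadGroup(lay.root, members))
        calls = call_breakpoints(lay2, cmin=3)
        assert call_ref_position(calls[0], lay2) == 5000 + 6

    def test_no_calls_zero_recall(self):
        truth = [Mutation("SNV", 100, "A", "C")]
        ev = evaluate_calls([], {}, truth, k=28)
        assert ev["recall"] == 0.0 and ev["n_calls"] == 0

    def test_orientation_invariance_of_calls(self, clean_patient, clean_store, clean_histogram):
        """Reverse-complementing every read leaves call columns at the
        same reference positions (strand symmetry end to end)."""
        import gzip as _gz
        from breakseek.count import build_histogram
        from breakseek.kvstore import build_store
        from breakseek.label import LabelConfig, label_reads
        import tempfile
        from pathlib import Path

        tmp = Path(tempfile.mkdtemp())

        def flip(path_in, path_out):
            with _gz.open(path_in, "rt") as fi, _gz.open(path_out, "wt") as fo:
                while True:
                    t = fi.readline()
                    if not t:
                        break
                    s = fi.readline().strip()
                    fi.readline(); fi.readline()
                    fo.write(f"{t.strip()}\n{km.revcomp(s)}\n+\n{'I' * len(s)}\n")

        flip(clean_patient["paths"]["normal"], tmp / "n.fastq.gz")
        flip(clean_patient["paths"]["tumor"], tmp / "t.fastq.gz")
        hist = build_histogram(tmp / "n.fastq.gz", tmp / "t.fastq.gz", 28, tmp / "h.kmh")
        # per-root totals are strand-invariant (variants permute inside roots)
        def root_totals(entries):
            roots = entries["key"] >> np.uint64(5)
            totals = {}
            for r, n, t in zip(roots, entries["n"], entries["t"]):
                a, b = totals.get(int(r), (0, 0))
                totals[int(r)] = (a + int(n), b + int(t))
            return totals
        assert root_totals(hist.load()) == root_totals(clean_histogram.load())
        store = build_store(hist, tmp / "s.kvr")
        db = label_reads(tmp / "n.fastq.gz", tmp / "t.fastq.gz", store, None, LabelConfig())
        store.close()
        groups = group_reads(db, 28)
        layouts = {g.root: build_layout(g) for g in groups}
        flipped_calls = {
            (c.root, c.column, c.run_length)
            for root in layouts for c in call_breakpoints(layouts[root])
        }
        db0 = label_reads(clean_patient["paths"]["normal"], clean_patient["paths"]["tumor"],
                          clean_store, None, LabelConfig())
        groups0 = group_reads(db0, 28)
        layouts0 = {g.root: build_layout(g) for g in groups0}
        calls0 = {
            (c.root, c.column, c.run_length)
            for root in layouts0 for c in call_breakpoints(layouts0[root])
        }
        assert flipped_calls == calls0
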