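"""End-to-end driver wiring the units: count -> store -> label -> merge
-> group -> evaluate, partition by partition.

Each root partition gets its own histogram, store, cache and database;
the merged database and the final report are invariant to the number
of partitions.  Every stage logs a machine-parsable summary line and
the full configuration is serialized next to the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Union

from .count import PartitionSpec, build_histogram, read_histogram
from .group import build_layout, call_breakpoints, evaluate_calls, group_reads, render_report
from .kvcache import build_cache
from .kvstore import StoreConfig, build_store, ChunkedStore
from .label import InterestingDB, LabelConfig, label_reads, merge_dbs
from .simulate import SimConfig, make_patient, read_truth_vcf
from .sort_reduce import SortReduceConfig

__all__ = ["PipelineConfig", "run_pipeline", "file_sha256"]

log = logging.getLogger("breakseek")


@dataclass
class PipelineConfig:
    k: int = 28
    partitions: int = 1
    mem_budget_bytes: int = 64 * 1024 * 1024
    merge_fanin: int = 16
    chunk_bytes: int = 4096
    index_fanout: int = 16
    bloom_bits_per_key: int = 10
    bloom_hashes: int = 7
    cache_budget_bytes: int = 8 * 1024 * 1024
    min_tumor_support: int = 4
    max_normal_count: int = 1
    min_witness_count: int = 4
    symmetric_mode: bool = False
    cmin: int = 3
    context: Optional[int] = None  # breakpoint context half-width; default 2k
    seed: int = 1

    def label_config(self) -> LabelConfig:
        return LabelConfig(
            min_tumor_support=self.min_tumor_support,
            max_normal_count=self.max_normal_count,
            min_witness_count=self.min_witness_count,
            symmetric_mode=self.symmetric_mode,
        )

    def store_config(self) -> StoreConfig:
        return StoreConfig(
            chunk_bytes=self.chunk_bytes,
            index_fanout=self.index_fanout,
            bloom_bits_per_key=self.bloom_bits_per_key,
            bloom_hashes=self.bloom_hashes,
        )


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(
    normal_fastq: Union[str, Path],
    tumoral_fastq: Union[str, Path],
    out_dir: Union[str, Path],
    cfg: PipelineConfig,
    truth_vcf: Optional[Union[str, Path]] = None,
) -> Dict[str, object]:
    """Run count/store/label per partition, merge, group and (when a
    truth VCF is given) evaluate.  Returns a result summary including
    checksums of the deterministic outputs."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    (out_dir / "pipeline_config.json").write_text(
        json.dumps(asdict(cfg), indent=2) + "\n"
    )

    dbs: List[InterestingDB] = []
    stage_stats: List[Dict[str, object]] = []
    for p in range(cfg.partitions):
        part = PartitionSpec(p, cfg.partitions) if cfg.partitions > 1 else None
        hist_path = out_dir / f"hist_p{p}.kmh"
        hist = build_histogram(
            normal_fastq, tumoral_fastq, cfg.k, hist_path, partition=part,
            sr_cfg=SortReduceConfig(
                mem_budget_bytes=cfg.mem_budget_bytes,
                merge_fanin=cfg.merge_fanin,
                spill_dir=out_dir,
            ),
        )
        store = build_store(hist, out_dir / f"store_p{p}.kvr", cfg.store_config())
        cache = build_cache(hist, cfg.cache_budget_bytes)
        db = label_reads(
            normal_fastq, tumoral_fastq, store, cache,
            cfg.label_config(), partition=part,
        )
        db.write(out_dir / f"db_p{p}")
        log.info(
            "partition=%d entries=%d cached_roots=%d cache_hits=%d "
            "lookups=%d chunk_reads=%d interesting_kmers=%d db_reads=%d",
            p, hist.n_entries, len(cache.entries), cache.hits,
            store.lookups, store.chunk_reads, len(db.kmers), len(db.reads),
        )
        stage_stats.append({
            "partition": p,
            "histogram_entries": hist.n_entries,
            "cache_roots": len(cache.entries),
            "cache_hits": cache.hits,
            "store_lookups": store.lookups,
            "chunk_reads": store.chunk_reads,
            "interesting_kmers": len(db.kmers),
            "db_reads": len(db.reads),
        })
        store.close()
        dbs.append(db)

    merged = merge_dbs(dbs)
    reads_path, kmers_path = merged.write(out_dir / "db_merged")

    groups = group_reads(merged, cfg.k)
    layouts = {g.root: build_layout(g) for g in groups}
    context = cfg.context if cfg.context is not None else 2 * cfg.k
    calls = []
    for root in sorted(layouts):
        calls.extend(call_breakpoints(layouts[root], cmin=cfg.cmin, context=context))
    text, tsv = render_report(calls, layouts, cfg.k)
    report_path = out_dir / "report.txt"
    calls_path = out_dir / "calls.tsv"
    report_path.write_text(text)
    calls_path.write_text(tsv)

    result: Dict[str, object] = {
        "n_groups": len(groups),
        "n_calls": len(calls),
        "stages": stage_stats,
        "checksums": {
            "db_merged.reads": file_sha256(reads_path),
            "db_merged.kmers": file_sha256(kmers_path),
            "calls.tsv": file_sha256(calls_path),
            "report.txt": file_sha256(report_path),
        },
        "paths": {
            "report": str(report_path),
            "calls": str(calls_path),
            "db_reads": str(reads_path),
            "db_kmers": str(kmers_path),
        },
    }
    if truth_vcf is not None:
        manifest = read_truth_vcf(truth_vcf)
        ev = evaluate_calls(calls, layouts, manifest, cfg.k)
        ev_out = {k: v for k, v in ev.items() if k != "call_positions"}
        (out_dir / "evaluation.json").write_text(json.dumps(ev_out, indent=2) + "\n")
        result["evaluation"] = ev
    log.info("pipeline done: groups=%d calls=%d", len(groups), len(calls))
    return result


def simulate_and_run(
    sim_cfg: SimConfig, pipe_cfg: PipelineConfig, out_dir: Union[str, Path]
) -> Dict[str, object]:
    """Generate a synthetic patient and push it through the pipeline."""
    out_dir = Path(out_dir)
    sim = make_patient(sim_cfg, out_dir / "sim")
    res = run_pipeline(
        sim["paths"]["normal"], sim["paths"]["tumor"], out_dir,
        pipe_cfg, truth_vcf=sim["paths"]["truth"],
    )
    res["simulation"] = {k: v for k, v in sim.items() if k != "manifest"}
    return res
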