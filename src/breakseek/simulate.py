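"""Synthetic tumor/normal patient generator with ground truth.

Emulates the idealized sequencing model the pipeline is built around:
the normal genome N is an i.i.d. uniform random A/C/G/T sequence; the
tumor genome T is N with point mutations, insertions and deletions
injected at well-separated sites; both are sampled by uniform-length
reads at mean coverage alpha, drawn uniformly from both strands
(reverse-strand reads are emitted as reverse complements), with
independent per-base substitution errors at rate epsilon.  A fraction
of the tumor sample may be contaminated with reads drawn from N, as
happens when a biopsy contains healthy tissue.

Every operation is deterministic per seed.  The injected mutations are
written as a minimal VCF so downstream calls can be scored against the
truth (parameter recovery).

Deliberate simplifications: substitution-only read errors (no
sequencer indels), haploid genomes, single-end reads, uniform coverage
with no GC bias.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .kmer_model import BASES

__all__ = [
    "SimConfig",
    "Mutation",
    "MutationManifest",
    "make_reference",
    "apply_mutations",
    "apply_manifest",
    "simulate_reads",
    "make_patient",
    "write_truth_vcf",
    "read_truth_vcf",
]

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic patient.

    Defaults are the desk-scale smoke setting: a 200 kb genome at 30x
    coverage with 100 bp reads, a 0.1% substitution error rate, 20
    SNVs, 3 insertions and 3 deletions of 2-20 bp, 5% tumor-sample
    contamination by normal reads, and mutation sites kept >= 3k bases
    apart so each mutation's k-mer context is independent.
    """

    L: int = 200_000
    alpha: float = 30.0
    r: int = 100
    error_rate: float = 0.001
    n_snv: int = 20
    n_ins: int = 3
    n_del: int = 3
    indel_len: Tuple[int, int] = (2, 20)
    min_separation: int = 84  # 3k at the default k=28
    contamination: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if self.L <= self.r:
            raise ValueError("reference must be longer than a read")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must be in [0, 1)")
        if self.indel_len[0] < 1 or self.indel_len[1] < self.indel_len[0]:
            raise ValueError("invalid indel length range")


@dataclass(frozen=True)
class Mutation:
    """One injected mutation in reference coordinates (1-based,
    VCF-style anchored REF/ALT for indels)."""

    kind: str  # SNV | INS | DEL
    pos: int   # 1-based reference position of REF[0]
    ref: str
    alt: str


MutationManifest = List[Mutation]


def make_reference(L: int, seed: int) -> str:
    """I.i.d. uniform random genome of length L."""
    rng = np.random.default_rng(seed)
    return _codes_to_str(rng.integers(0, 4, size=L, dtype=np.uint8))


def _codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.zeros(raw.size, dtype=np.uint8)
    out[raw == ord("C")] = 1
    out[raw == ord("G")] = 2
    out[raw == ord("T")] = 3
    return out


def _draw_sites(rng: np.random.Generator, L: int, n: int,
                min_separation: int, margin: int) -> np.ndarray:
    """n positions in [margin, L - margin) pairwise >= min_separation
    apart: sorted uniform draws in the gap-deflated space, re-inflated
    by i * min_separation (uniform over all valid placements)."""
    lo, hi = margin, L - margin
    sep = max(1, min_separation)
    slack = (hi - lo) - (n - 1) * sep
    if n > 0 and slack < n:
        raise ValueError("mutations do not fit the reference with the "
                         "requested separation")
    base = np.sort(rng.integers(0, slack, size=n))
    return lo + base + np.arange(n) * sep


def apply_mutations(ref: str, cfg: SimConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[str, MutationManifest]:
    """Inject cfg.n_snv SNVs, cfg.n_ins insertions and cfg.n_del
    deletions into ``ref`` and return (tumor sequence, manifest)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = cfg.n_snv + cfg.n_ins + cfg.n_del
    manifest: MutationManifest = []
    if n == 0:
        return ref, manifest
    margin = cfg.r + cfg.indel_len[1] + 1
    sites = _draw_sites(rng, cfg.L, n, cfg.min_separation, margin)
    kinds = np.array(["SNV"] * cfg.n_snv + ["INS"] * cfg.n_ins + ["DEL"] * cfg.n_del)
    rng.shuffle(kinds)
    for pos0, kind in zip(sites, kinds):
        pos0 = int(pos0)
        if kind == "SNV":
            old = ref[pos0]
            new = BASES[(BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
            manifest.append(Mutation("SNV", pos0 + 1, old, new))
        elif kind == "INS":
            ln = int(rng.integers(cfg.indel_len[0], cfg.indel_len[1] + 1))
            ins = _codes_to_str(rng.integers(0, 4, size=ln, dtype=np.uint8))
            manifest.append(Mutation("INS", pos0 + 1, ref[pos0], ref[pos0] + ins))
        else:
            ln = int(rng.integers(cfg.indel_len[0], cfg.indel_len[1] + 1))
            manifest.append(
                Mutation("DEL", pos0 + 1, ref[pos0:pos0 + ln + 1], ref[pos0])
            )
    return apply_manifest(ref, manifest), manifest


def apply_manifest(ref: str, manifest: MutationManifest) -> str:
    """Replay a manifest on the reference (the constructive definition
    of the tumor genome; also the round-trip check)."""
    pieces = []
    cursor = 0
    for mut in sorted(manifest, key=lambda m: m.pos):
        i = mut.pos - 1
        if ref[i:i + len(mut.ref)] != mut.ref:
            raise ValueError(f"manifest REF mismatch at {mut.pos}")
        pieces.append(ref[cursor:i])
        pieces.append(mut.alt)
        cursor = i + len(mut.ref)
    pieces.append(ref[cursor:])
    return "".join(pieces)


def simulate_reads(
    seq: str,
    tag: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    n_reads: Optional[int] = None,
    origin: Optional[str] = None,
    id_offset: int = 0,
) -> List[Tuple[str, str]]:
    """Sample reads of length cfg.r from ``seq`` at coverage cfg.alpha.

    Returns (title, sequence) pairs; titles are
    ``sim_{tag}_{i} pos={start} strand={+|-} origin={origin}`` with the
    0-based forward-strand start on the origin sequence.  Reverse-
    strand reads are reverse-complemented; each base is then
    substituted with probability cfg.error_rate to a uniformly chosen
    different base.
    """
    codes = _str_to_codes(seq)
    r = cfg.r
    if n_reads is None:
        n_reads = int(round(cfg.alpha * len(seq) / r))
    if n_reads == 0:
        return []
    origin = origin or tag
    starts = rng.integers(0, len(seq) - r + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    mat = codes[starts[:, None] + np.arange(r)[None, :]]
    rev = strands == 1
    mat[rev] = (3 - mat[rev])[:, ::-1]
    err = rng.random(mat.shape) < cfg.error_rate
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shift) % 4
    chars = _CODE_TO_BASE[mat]
    out = []
    for i in range(n_reads):
        title = (f"sim_{tag}_{id_offset + i} pos={int(starts[i])} "
                 f"strand={'-' if strands[i] else '+'} origin={origin}")
        out.append((title, chars[i].tobytes().decode("ascii")))
    return out


def _write_fastq_gz(path: Path, reads: List[Tuple[str, str]], qual_char: str = "I") -> None:
    # mtime=0 so identical content gives identical bytes
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            with io.TextIOWrapper(gz, encoding="ascii") as txt:
                for title, seq in reads:
                    txt.write(f"@{title}\n{seq}\n+\n{qual_char * len(seq)}\n")


def write_truth_vcf(path: Path, manifest: MutationManifest, contig: str = "ref",
                    contig_len: Optional[int] = None) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##source=breakseek-sim',
    ]
    if contig_len is not None:
        lines.append(f"##contig=<ID={contig},length={contig_len}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, mut in enumerate(sorted(manifest, key=lambda m: m.pos)):
        lines.append(
            f"{contig}\t{mut.pos}\t{mut.kind}{i}\t{mut.ref}\t{mut.alt}\t.\tPASS\tTYPE={mut.kind}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_vcf(path: Union[str, Path]) -> MutationManifest:
    manifest: MutationManifest = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        _chrom, pos, vid, ref, alt, *_rest = line.split("\t")
        kind = "SNV" if len(ref) == len(alt) == 1 else ("INS" if len(alt) > len(ref) else "DEL")
        manifest.append(Mutation(kind, int(pos), ref, alt))
    return manifest


def make_patient(cfg: SimConfig, out_dir: Union[str, Path]) -> dict:
    """Generate one synthetic patient.

    Writes ``normal.fastq.gz``, ``tumor.fastq.gz``, ``truth.vcf``,
    ``reference.txt`` and a JSON copy of the configuration to
    ``out_dir``; returns a dict of the paths plus basic counts.  The
    tumor sample mixes (1 - contamination) tumor-origin reads with
    contamination normal-origin reads.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    rng_mut, rng_n, rng_t, rng_c = (np.random.default_rng(s) for s in ss.spawn(4))
    ref = make_reference(cfg.L, cfg.seed)
    tumor_seq, manifest = apply_mutations(ref, cfg, rng_mut)

    normal_reads = simulate_reads(ref, "N", cfg, rng_n, origin="N")
    n_tumor_total = int(round(cfg.alpha * len(tumor_seq) / cfg.r))
    n_contam = int(round(cfg.contamination * n_tumor_total))
    tumor_reads = simulate_reads(
        tumor_seq, "T", cfg, rng_t, n_reads=n_tumor_total - n_contam, origin="T"
    )
    tumor_reads += simulate_reads(
        ref, "T", cfg, rng_c, n_reads=n_contam, origin="N",
        id_offset=n_tumor_total - n_contam,
    )

    paths = {
        "normal": out_dir / "normal.fastq.gz",
        "tumor": out_dir / "tumor.fastq.gz",
        "truth": out_dir / "truth.vcf",
        "reference": out_dir / "reference.txt",
        "config": out_dir / "sim_config.json",
    }
    _write_fastq_gz(paths["normal"], normal_reads)
    _write_fastq_gz(paths["tumor"], tumor_reads)
    write_truth_vcf(paths["truth"], manifest, contig_len=cfg.L)
    paths["reference"].write_text(ref + "\n")
    cfg_dict = asdict(cfg)
    cfg_dict["indel_len"] = list(cfg.indel_len)
    paths["config"].write_text(json.dumps(cfg_dict, indent=2) + "\n")
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "n_normal_reads": len(normal_reads),
        "n_tumor_reads": len(tumor_reads),
        "n_contaminated_reads": n_contam,
        "n_mutations": len(manifest),
        "manifest": manifest,
    }
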