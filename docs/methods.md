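# Methods

## Problem model

Two read sets are drawn from a normal genome N and a tumor genome T,
where T is N with a small number of point mutations, insertions and
deletions. Reads have uniform length *r*, cover each position *α*
times on average, come from both strands (reverse-strand reads appear
as reverse complements), and carry independent per-base substitution
errors at rate *ε*. A k-mer seen in only one sample marks a mutation
site, but cannot by itself align reads across samples; alignment is
enabled by *almost-matching* k-mers — identical middle *k − 2* bases
(the stem), different end bases. Provided *k* is large enough, a stem
occurs at a single genomic locus, so almost-matching k-mers from the
two samples anchor the same place. Reverse complements are folded by
canonicalizing each stem to a *root* (the alphabetically smaller of
stem and reverse complement), effectively doubling coverage.

Useful *k* sits in a window: large enough that k-mers are locus-unique
(for human-scale genomes, above ~24), small enough that the chance of
a read error inside a k-mer stays low (below ~32). The default is 28.
Packed 2-bit codes assign A=0, C=1, G=2, T=3 so numeric code order
equals alphabetical order and canonicalization is an integer `min`.
The root-major sort key `(root << 5) | (stem_flag << 4) | (first << 2)
| last` needs `2(k−2) + 5` bits; the counting pipeline therefore
requires k ≤ 31 so keys fit in 64 bits (the model functions accept
k ≤ 32).

## Counting: external Sort-Reduce

Histogram updates (one per read k-mer, a (normal, tumoral) unit count)
are streamed through a two-phase external sort with on-the-fly
reduction: phase 1 fills a buffer of `mem_budget_bytes`, sorts it,
merges equal keys by saturating 16-bit addition, and spills a run;
phase 2 merges up to `merge_fanin` (default 16) runs per pass until
one sorted run remains. The merge is block-wise and vectorized: each
round emits every buffered record with key ≤ the smallest
last-buffered key among unexhausted runs, which no future record can
undercut. The engine instruments its peak buffered record count
(never above budget plus one read-ahead block per run), bytes spilled,
and whether any counter saturated (recorded in the histogram header).
The reduction is pluggable; any associative, commutative merge works.

Singleton roots — total count 1 across both samples and all variants —
are dropped after the final merge. With one occurrence per read this
is exactly "root seen in a single read", i.e. overwhelmingly a
sequencing error. Within a read, a k-mer is counted once per
occurrence (a 28-mer virtually never repeats inside a 100 bp read).

The histogram is k-mer-indexed (12 B per observed variant: 8 B sort
key + two 2 B counters) rather than root-indexed (136 B dense record);
on data where most of a root's 32 variants are absent this saves ~90%.
Root-range partitioning (P contiguous shards of the root-code space,
each a full pass over the reads) trades passes for working-set size;
concatenating per-partition histograms reproduces the P = 1 output
bit-for-bit, and the partition invariance of the whole pipeline is
tested end to end via output checksums.

## Serving look-ups: chunked store, filters, cache

The Label unit performs one histogram look-up per read k-mer, which is
the workload that dominates everything; the store is built for it.

* **Root-format records.** A store record is a root plus 64 16-bit
  counters (normal and tumoral for each of the 32 variants), 136 bytes,
  so one record read answers the whole-root query the labeling rule
  needs. Palindromic stems use the same 64-slot layout with the
  stem-flag-1 half permanently zero — fixed record size beats the ~1%
  of space a variable layout would save.
* **Chunks.** Records are packed 30 to a 4096-byte chunk (a flash
  page), zero-padded, sorted globally. Look-ups read at most one data
  chunk, ever: there is no tree on disk and no overflow chain.
* **Implicit index.** The per-chunk first-key array lives in memory;
  above it, every F-th key (F = 16) forms the next level, so array
  position i covers children F·i … F·(i+1)−1 and no pointers are
  stored. Descent scans ≤ F contiguous keys per level — one cache
  line's worth — and is property-tested equal to a flat binary search.
  The index is rebuilt from the data chunks on open rather than
  persisted.
* **Negative look-ups.** A band-pass filter (min/max root seen at
  build) rejects out-of-range keys for free — especially effective
  under root-space partitioning, where each shard's band is narrow.
  A Bloom filter (10 bits/key, 7 hashes ⇒ theoretical false-positive
  rate (1 − e^(−h·n/m))^h ≈ 0.82%) short-circuits most of the rest.
  Hashing is double hashing h₁ + i·h₂ over two SplitMix64-style mixes
  of the root code; the two seeds are persisted in the store header so
  the bitmap is reproducible. False positives cost one wasted chunk
  read and resolve to Absent; false negatives are impossible and
  hard-asserted in tests.
* **Cache.** The histogram's counters are also its access forecast
  (each stored occurrence is one future look-up), so a static cache is
  built once from the histogram: roots ranked by total count, admitted
  whole (a partial root would still cost a storage read) into a byte
  budget accounted in the compact 12 B/variant k-mer format. The cache
  reconstructs full 64-counter records on hit, so caching is invisible
  to results — asserted by re-running labeling at budget 0. Per-
  partition execution gives each shard the whole budget, which can
  only raise the aggregate hit fraction; tested on Zipf(1.0)-skewed
  probes.
* **Batch look-ups.** `lookup_batch` is semantically a multiset of
  independent look-ups; ordering and concurrency are configuration.
  This implementation resolves sequentially; the batch ≡ sequential
  equivalence is the tested contract. The labeling pass additionally
  memoizes resolved roots, so each distinct root costs at most one
  store look-up per partition — a pure I/O optimization with no effect
  on output.

## Labeling

Interestingness is a function of the histogram alone. Variant v of a
root is tumoral-interesting iff

    t_v ≥ Tmin  and  n_v ≤ Nmax  and  ∃ w ≠ v with n_w ≥ Wmin,

defaults Tmin = 4 (a k-mer must be seen several times — expected count
of an error k-mer is ≈ 1, and Tmin ≥ 2 is enforced), Nmax = 1
(tolerates stray normal reads in the tumor sample), Wmin = 4 (the
witness variant must itself be trustworthy). `symmetric_mode` applies
the mirrored rule for normal-exclusive k-mers (germline-style events);
it is provided but untuned. All thresholds are configuration: the
appropriate operating point depends on coverage and intended use, and
a research setting deliberately labels liberally.

A read enters the database when it touches *any* root with ≥ 1
interesting variant — not only when it carries the interesting variant
itself. The normal-sample witness reads carry the frequent variant,
never the interesting one, yet the grouping stage needs them to build
a two-sample consensus; restricting the read table to carriers of
interesting k-mers would make every group single-sample and no
break-point callable. The k-mer table keys only the interesting
k-mers. The database is a pair of sorted TSV.gz tables (gzip mtime
fixed to 0, so identical content means identical bytes); per-partition
databases merge by k-mer-table concatenation and read-entry union,
with conflicting sequences rejected.

One caveat measured during development: with ~30× coverage, a window's
coverage on one strand is Poisson(~11), so ≈ 2^-10 of windows see one
orientation of a normal k-mer zero times while the tumor covers it;
such a variant can pass the rule without any mutation. These
strand-fluctuation positives are harmless downstream — their groups
produce identical consensi and no call — but they are why interesting
*k-mer* counts exceed 2× the mutation count.

## Grouping and break-point calls

Each interesting root seeds a group containing every database read
whose hit list touches it. Reads whose hit lies on the non-canonical
stem are reverse-complemented (offset remapped to `len − k − pos`), so
anchors match literally; a read with several hits on the root anchors
at the lowest position; groups with identical member sets are
deduplicated keeping the lowest root. Members are laid out gaplessly,
anchor at column 0, and each column gets a per-sample majority
consensus ('N' on ties) and coverage.

A column *diverges* when both samples reach coverage Cmin (default 3)
and their unambiguous consensi differ. Divergent runs separated by ≤
`merge_gap` = 10 columns are merged into one region: past a true
break-point a gapless layout compares shifted sequence in which ~1/4
of columns re-match by chance (expected chance-gap length 4/3; a gap
of 10 has probability ≈ 4^-10 per site), while distinct mutations are
separated by ≥ 3k columns under the default study conditions. The
reported break-point is the region edge nearest the anchor — where
divergence begins — i.e. the first column of a region at/right of the
anchor and the last column of a region entirely left of it. A point
mutation yields a single-column region; insertions and deletions yield
long regions whose anchor-side edge is the junction (gapless layouts
show indels as mismatch runs, not gapped columns — a documented
limitation; the event's extent is not sized, only located).

When reads carry simulation provenance, a call is mapped to reference
coordinates through its normal-origin members (median over members,
orientation-aware), and recall/precision are computed against the
injected manifest at tolerance k: a truth mutation is recovered if
some call maps within k bases; a call is correct if it maps within k
bases of some truth mutation; unmappable calls count against
precision.

## Synthetic data

`SimConfig` defaults define the study conditions: L = 200 kb genome,
α = 30, r = 100 bp, ε = 0.001 substitutions/base, 20 SNVs + 3
insertions + 3 deletions (indel lengths 2–20), 5% contamination of the
tumor sample by normal-origin reads, mutation sites ≥ 3k = 84 bases
apart (keeping each mutation's k-mer context independent so
per-mutation recovery is well defined), seed 1. Sites are drawn
uniformly over all valid spaced placements via gap-deflated sorted
uniforms; infeasible configurations raise. Reads are single-end,
uniformly placed, strand-uniform; errors substitute a uniformly chosen
different base. Every stage is deterministic per seed (child seeds are
spawned from one SeedSequence), and FASTQ/TSV outputs are
byte-reproducible.

What the generator does *not* emulate: diploidy and heterozygous
germline variation, GC-biased or otherwise non-uniform coverage,
sequencer indel errors and quality-score structure, repetitive
sequence (the reference is i.i.d. uniform, so k-mer uniqueness is far
cleaner than in a real genome), and multi-breakpoint structural
events. Passing recovery tests therefore demonstrates the machinery —
counting, serving, labeling, anchoring, calling — under the model's
own assumptions, not calling performance on real tumors; in particular
repeat-rich genomes would need the interestingness thresholds re-tuned
and would stress the locus-uniqueness assumption.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full default patient
(two ~6000-read samples per arm, ~8.8 M k-mer windows per sample
pair) plus a noiseless control, and verify partition invariance
(P ∈ {1, 2, 4}) on a 50 kb patient — the property is scale-free, and
this keeps the triple run brief. Oracle comparisons use 10^5 updates
over 10^3 keys (Sort-Reduce) and ~4000 roots with 10^4 absent probes
(store). The billion-item store size is computed analytically
(10^9 × 136 B = 126.6 GiB ≈ 127), never materialized.

Counters saturate at 65535 rather than overflow (flagged in the
histogram header); at default coverage real counts are ~30. Ties are
fixed everywhere they could vary output: cache admission breaks total
ties by ascending root, group dedupe keeps the lowest root, consensus
ties are 'N', reports sort by (root, column). Reads with non-ACGT
characters keep their valid windows; nothing else is quality-aware.
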