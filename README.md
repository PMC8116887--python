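# breakseek

Reference-free somatic mutation detection at desk scale.

Somatic mutations — the changes a tumor acquires relative to the
patient's own healthy genome — are normally found by aligning reads to
a reference genome, which biases against exactly the structurally
variant reads one is looking for. `breakseek` instead compares the
tumor and normal read sets directly through k-mer statistics, and is
engineered the way large reference-free pipelines are run on machines
with little DRAM: every large intermediate structure lives in flat,
immutable files with storage-friendly access patterns.

## The method

For k-mer length *k* (default 28), each k-mer is grouped by its middle
*k − 2* bases (its **stem**); stems and their reverse complements are
folded into a canonical **root**, so up to 32 k-mers (16 per stem, two
stems) share one root. Two k-mers of the same root that differ in an
end base are *almost matching*: they mark the same genomic locus on
either side of a candidate break-point, and they are what lets normal
and tumor reads be aligned to each other without any reference.

The pipeline has four units:

1. **Count** — one update per read k-mer is pushed through an
   external-memory *Sort-Reduce* (DRAM-sized sorted spills with
   on-the-fly merging of equal keys, then fan-in-bounded merge passes)
   keyed by a root-major integer sort key, producing a sorted,
   k-mer-indexed histogram of (normal, tumoral) counts. Roots seen
   only once in total (sequencing noise) are dropped. Indexing by
   k-mer instead of by dense 64-counter root records shrinks the
   histogram by ~90%.
2. **Label** — every read k-mer's root is looked up in the histogram,
   served by an immutable chunked key-value store (4 KB chunks, 30 ×
   136-byte root records per chunk; band-pass and Bloom filters for
   negative probes; an in-memory multi-level implicit index; at most
   **one** storage read per look-up) fronted by a static cache of the
   counter-heaviest roots. A k-mer is *interesting* when it is well
   supported in the tumor (t ≥ Tmin), absent from the normal (n ≤
   Nmax), and an almost-matching variant is well supported in the
   normal sample (witness, n ≥ Wmin). Reads touching interesting
   roots go into the interesting read/k-mer database.
3. **Merge** — databases from disjoint root-space partitions are
   concatenated (k-mer tables) and unioned (read tables).
4. **Group** — reads sharing an interesting root are clustered,
   oriented, anchor-aligned gaplessly, and the per-sample consensus
   divergence is reported as candidate break-points with local
   context, plus recall/precision against the simulated truth.

A synthetic-data module generates the study conditions end to end:
random reference, mutated tumor genome (SNVs, insertions, deletions),
uniform-coverage stranded reads with substitution errors, optional
contamination of the tumor sample by normal reads, and a truth VCF.

## Worked example

```bash
breakseek run-all --seed 1 --out runs/demo
```

simulates the default patient (200 kb genome, 30× coverage, 100 bp
reads, 0.1% substitution errors, 20 SNVs + 3 insertions + 3 deletions,
5% tumor-sample contamination) and runs the full pipeline. It prints:

```json
{
  "n_groups": 91,
  "n_calls": 62,
  "recall": 1.0,
  "precision": 1.0,
  ...
}
```

meaning 91 read groups were anchored on interesting roots, 62
break-point calls were made, every injected mutation had a call within
k bases of its true position (recall 1.0) and every call mapped back
to within k bases of an injected mutation (precision 1.0). The run
directory contains the truth VCF, the histogram and store files, the
merged database, `report.txt` (human-readable aligned blocks with the
break-point column starred) and `calls.tsv`.

Individual units are exposed as `breakseek simulate / count /
build-store / label / merge / group / kv-bench / evaluate / inspect`;
`kv-bench` runs the random positive look-up benchmark against a built
store, and `inspect` dumps a store's geometry and index level sizes.

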