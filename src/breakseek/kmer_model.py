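"""Encodings and combinatorics of k-mers, stems and roots.

The mutation-detection pipeline compares tumor and normal read sets by
counting k-mers and grouping them three levels deep:

* a **k-mer** is a length-``k`` window of a read, packed 2 bits per base
  (A=0, C=1, G=2, T=3, leftmost base most significant);
* its **stem** is the middle ``k - 2`` bases — two k-mers with the same
  stem but different end bases are *almost matching* and mark the same
  genomic locus on either side of a candidate mutation;
* its **root** is the canonical form of the stem: the alphabetically
  smaller of the stem and its reverse complement.  Roots fold the two
  DNA strands together, so up to 32 k-mers (16 per stem, two stems) map
  to one root; a palindromic stem has a single stem and only 16.

Because the 2-bit packing respects alphabetical base order, canonical
selection is an integer ``min`` and lexicographic string order equals
numeric code order throughout.

The module is pure and in-memory.  Scalar functions accept either DNA
strings or packed integer codes; the vectorized helpers (suffix
``_codes`` / plural names) operate on ``numpy`` ``uint64`` arrays and are
the hot path used by the counting and labeling units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Tuple, Union

import numpy as np

__all__ = [
    "KmerConfig",
    "encode",
    "decode",
    "revcomp",
    "revcomp_code",
    "stem_of",
    "canonical_root",
    "sort_key",
    "kmer_from_sort_key",
    "variant_index",
    "kmers_of_root",
    "kmers_of_read",
    "seq_to_codes",
    "window_codes",
    "revcomp_codes",
    "sort_keys_from_kmers",
    "roots_from_kmers",
    "KMERS_PER_STEM",
    "VARIANTS_PER_ROOT",
]

BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

#: number of k-mers sharing one stem (4 choices of first base x 4 of last)
KMERS_PER_STEM = 16
#: counter slots reserved per root (two stems x 16 variants)
VARIANTS_PER_ROOT = 32

# byte value -> byte with its four 2-bit fields in reversed order,
# used to reverse the base order of a packed code 8 bases at a time
_REV8 = np.array(
    [
        ((b & 0x03) << 6) | ((b & 0x0C) << 2) | ((b & 0x30) >> 2) | ((b & 0xC0) >> 6)
        for b in range(256)
    ],
    dtype=np.uint64,
)

# ASCII byte -> base code, 255 for anything that is not A/C/G/T
_ASCII_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ASCII_CODE[ord(_b)] = _c
    _ASCII_CODE[ord(_b.lower())] = _c


@dataclass(frozen=True)
class KmerConfig:
    """K-mer length configuration.

    ``k`` must lie in [4, 32] so that a k-mer fits a 64-bit code and a
    stem exists.  The practically useful window for mutation detection
    on genome-scale data is 24 < k < 32 (28 by default): shorter k-mers
    recur too often to pin a locus, longer ones accumulate read errors.
    Small even/odd values remain valid for testing.
    """

    k: int = 28

    def __post_init__(self) -> None:
        if not 4 <= self.k <= 32:
            raise ValueError(f"k must be in [4, 32], got {self.k}")

    @property
    def stem_len(self) -> int:
        return self.k - 2

    @property
    def n_roots(self) -> int:
        """Size of the stem-code space, 4^(k-2) (upper bound on roots)."""
        return 4 ** (self.k - 2)


def encode(seq: str) -> int:
    """Pack a DNA string (length <= 32) into a 2-bit-per-base integer.

    Raises ``ValueError`` on non-ACGT characters; callers scanning reads
    skip the offending window.
    """
    if len(seq) > 32:
        raise ValueError("cannot pack more than 32 bases into one code")
    code = 0
    for ch in seq:
        try:
            code = (code << 2) | _BASE_CODE[ch.upper()]
        except KeyError:
            raise ValueError(f"invalid base {ch!r} in {seq!r}") from None
    return code


def decode(code: int, n: int) -> str:
    """Inverse of :func:`encode` for an n-base code."""
    if code < 0 or code >= 4**n:
        raise ValueError(f"code {code} out of range for {n} bases")
    out = []
    for shift in range(2 * (n - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, order reversed).

    Any length; characters outside ACGT are rejected as in encode."""
    if any(ch not in "ACGTacgt" for ch in seq):
        raise ValueError(f"invalid base in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_code(code: int, n: int) -> int:
    """Reverse complement of an n-base packed code."""
    mask = (1 << (2 * n)) - 1
    comp = (code ^ mask) & mask
    out = 0
    for _ in range(n):
        out = (out << 2) | (comp & 3)
        comp >>= 2
    return out


Seq = Union[str, int]


def _as_code(x: Seq, n: int) -> int:
    return encode(x) if isinstance(x, str) else x


def _like(x: Seq, code: int, n: int) -> Seq:
    return decode(code, n) if isinstance(x, str) else code


def stem_of(kmer: Seq, k: int) -> Seq:
    """Middle ``k - 2`` bases of a k-mer (string in, string out)."""
    if k < 4:
        raise ValueError("stems require k >= 4")
    code = _as_code(kmer, k)
    stem = (code >> 2) & ((1 << (2 * (k - 2))) - 1)
    return _like(kmer, stem, k - 2)


def canonical_root(stem: Seq, m: int | None = None) -> Seq:
    """Canonical (root) form of a stem: min of stem and its reverse
    complement in alphabetical order.  Idempotent.

    ``m`` (stem length in bases) is required when ``stem`` is a packed
    code; it is inferred for strings.
    """
    if isinstance(stem, str):
        m = len(stem)
    elif m is None:
        raise ValueError("stem length m required for packed codes")
    code = _as_code(stem, m)
    root = min(code, revcomp_code(code, m))
    return _like(stem, root, m)


def sort_key(kmer: Seq, k: int) -> int:
    """Root-major integer sort key for a k-mer.

    ``key = (root << 5) | (stem_flag << 4) | (first_base << 2) | last_base``
    where ``stem_flag`` is 0 when the k-mer's stem already equals its
    root.  Sorting by this key lays all variants of a root out
    contiguously, in a fixed order, which is what lets the histogram be
    k-mer-indexed while preserving root locality.
    """
    code = _as_code(kmer, k)
    stem = (code >> 2) & ((1 << (2 * (k - 2))) - 1)
    root = min(stem, revcomp_code(stem, k - 2))
    flag = 0 if stem == root else 1
    first = code >> (2 * (k - 1))
    last = code & 3
    return (root << 5) | (flag << 4) | (first << 2) | last


def variant_index(kmer: Seq, k: int) -> int:
    """Position of a k-mer among the 32 variants of its root: the low
    five bits of :func:`sort_key` (stem_flag, first base, last base).
    Fixes the counter layout of the root-format store record."""
    return sort_key(kmer, k) & 0x1F


def kmer_from_sort_key(key: int, k: int) -> int:
    """Invert :func:`sort_key` back to the packed k-mer code."""
    root = key >> 5
    flag = (key >> 4) & 1
    first = (key >> 2) & 3
    last = key & 3
    stem = root if flag == 0 else revcomp_code(root, k - 2)
    return (first << (2 * (k - 1))) | (stem << 2) | last


def kmers_of_root(root: Seq, k: int) -> List[int]:
    """All k-mer codes whose stem canonicalizes to ``root``, in sort-key
    order: 32 for a normal root, 16 when the stem is palindromic."""
    root_code = _as_code(root, k - 2)
    if canonical_root(root_code, k - 2) != root_code:
        raise ValueError("not a canonical root")
    rc = revcomp_code(root_code, k - 2)
    stems = [root_code] if rc == root_code else [root_code, rc]
    out = []
    for stem in stems:  # stems ordered (flag 0, flag 1)
        for first in range(4):
            for last in range(4):
                out.append((first << (2 * (k - 1))) | (stem << 2) | last)
    return out


def kmers_of_read(seq: str, k: int) -> Iterator[Tuple[int, int]]:
    """Yield ``(position, kmer_code)`` for every valid length-k window
    of a read, left to right, 0-based half-open.  Windows containing a
    non-ACGT character are skipped (the rest of the read still counts).
    """
    mask = (1 << (2 * k)) - 1
    code = 0
    run = 0  # length of current valid run ending here
    for i, ch in enumerate(seq):
        c = _BASE_CODE.get(ch.upper())
        if c is None:
            run = 0
            code = 0
            continue
        code = ((code << 2) | c) & mask
        run += 1
        if run >= k:
            yield i - k + 1, code


# ---------------------------------------------------------------------------
# vectorized helpers (numpy uint64), used by the counting/labeling hot paths
# ---------------------------------------------------------------------------


def seq_to_codes(seq: Union[str, bytes]) -> np.ndarray:
    """Map a DNA string to a uint8 array of base codes (255 = invalid)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ASCII_CODE[np.frombuffer(seq, dtype=np.uint8)]


def _reverse_base_order64(x: np.ndarray) -> np.ndarray:
    """Reverse the 32 2-bit fields of each uint64."""
    out = np.zeros_like(x)
    for i in range(8):
        byte = (x >> np.uint64(8 * i)) & np.uint64(0xFF)
        out |= _REV8[byte] << np.uint64(8 * (7 - i))
    return out


def revcomp_codes(codes: np.ndarray, n: int) -> np.ndarray:
    """Vectorized :func:`revcomp_code` on a uint64 array of n-base codes."""
    x = np.asarray(codes, dtype=np.uint64)
    comp = x ^ np.uint64((1 << (2 * n)) - 1)
    return _reverse_base_order64(comp) >> np.uint64(64 - 2 * n)


def window_codes(base_codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """All valid k-windows of a base-code array.

    Returns ``(starts, kmers)``: 0-based start positions (int64) and the
    packed uint64 codes of every window free of invalid bases.  A
    sentinel-separated concatenation of many reads can be passed in one
    call; windows straddling a 255 sentinel are dropped automatically.
    """
    n = base_codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    bad = (base_codes > 3).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0  # window [i, i+k) clean
    windows = np.lib.stride_tricks.sliding_window_view(base_codes, k)
    pows = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    starts = np.flatnonzero(valid).astype(np.int64)
    kmers = (windows[starts].astype(np.uint64) * pows).sum(axis=1, dtype=np.uint64)
    return starts, kmers


def sort_keys_from_kmers(kmers: np.ndarray, k: int) -> np.ndarray:
    """Vectorized :func:`sort_key`. Requires k <= 31 so the key fits u64."""
    if k > 31:
        raise ValueError("sort keys of k > 31 exceed 64 bits")
    km = np.asarray(kmers, dtype=np.uint64)
    stem_mask = np.uint64((1 << (2 * (k - 2))) - 1)
    stems = (km >> np.uint64(2)) & stem_mask
    rc = revcomp_codes(stems, k - 2)
    roots = np.minimum(stems, rc)
    flag = (stems != roots).astype(np.uint64)
    first = km >> np.uint64(2 * (k - 1))
    last = km & np.uint64(3)
    return (roots << np.uint64(5)) | (flag << np.uint64(4)) | (first << np.uint64(2)) | last


def roots_from_kmers(kmers: np.ndarray, k: int) -> np.ndarray:
    """Vectorized canonical root codes for an array of k-mer codes."""
    km = np.asarray(kmers, dtype=np.uint64)
    stem_mask = np.uint64((1 << (2 * (k - 2))) - 1)
    stems = (km >> np.uint64(2)) & stem_mask
    return np.minimum(stems, revcomp_codes(stems, k - 2))
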