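"""Vectorized canonical k-mer extraction shared by binning and recruitment.

K-mers are 2-bit packed into int64 (k <= 31) with a rolling update across
columns, so a whole batch of equal-length reads is processed with O(L)
vector operations.  The canonical form of a k-mer is the lexicographic
minimum of its forward and reverse-complement encodings; windows containing
an ambiguous base are dropped.
"""

from __future__ import annotations

import numpy as np

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

MAX_K = 31


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int64 codes (A,C,G,T -> 0..3; other -> -1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _forward_codes_1d(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Window codes of one long sequence via strided windows + matmul."""
    m = arr.size - k + 1
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    clean = np.where(arr < 0, 0, arr)
    win = np.lib.stride_tricks.sliding_window_view(clean, k)
    codes = np.empty(m, dtype=np.int64)
    chunk = 1 << 18
    for a in range(0, m, chunk):
        codes[a : a + chunk] = win[a : a + chunk] @ powers
    neg = np.concatenate([[0], np.cumsum(arr < 0)])
    valid = (neg[k:] - neg[:-k]) == 0
    return codes, valid


def _forward_codes(arr2d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit codes for every window of each row.

    Returns (codes, valid) of shape (n, L-k+1); a window is valid when it
    contains no ambiguous base.  Short rows in bulk use a column-rolling
    update (O(L) vector steps over all rows at once); long rows use a
    strided per-row path.
    """
    n, length = arr2d.shape
    m = length - k + 1
    if m <= 0:
        return (np.empty((n, 0), np.int64), np.empty((n, 0), bool))
    if length > 1000 or n == 1:
        codes = np.empty((n, m), dtype=np.int64)
        valid = np.empty((n, m), dtype=bool)
        for i in range(n):
            codes[i], valid[i] = _forward_codes_1d(arr2d[i], k)
        return codes, valid
    mask = np.int64((1 << (2 * k)) - 1)
    codes = np.empty((n, m), dtype=np.int64)
    code = np.zeros(n, dtype=np.int64)
    run = np.zeros(n, dtype=np.int64)  # unambiguous-base run length
    valid = np.empty((n, m), dtype=bool)
    for i in range(length):
        base = arr2d[:, i]
        ambiguous = base < 0
        run = np.where(ambiguous, 0, run + 1)
        code = ((code << 2) | np.where(ambiguous, 0, base)) & mask
        if i >= k - 1:
            codes[:, i - k + 1] = code
            valid[:, i - k + 1] = run >= k
    return codes, valid


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Batch-encode equal-length sequences into one (n, L) code matrix."""
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw].reshape(len(seqs), -1)


def canonical_codes(arr2d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes and validity mask for each window of each row."""
    if not (1 <= k <= MAX_K):
        raise ValueError(f"k must be in [1, {MAX_K}]")
    fwd, valid = _forward_codes(arr2d, k)
    rc_arr = np.where(arr2d >= 0, 3 - arr2d, -1)[:, ::-1]
    rev, _ = _forward_codes(rc_arr, k)
    rc = rev[:, ::-1]
    return np.minimum(fwd, rc), valid


def kmer_set(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a single sequence."""
    arr = encode(seq)[None, :]
    codes, valid = canonical_codes(arr, k)
    return np.unique(codes[valid])


def kmer_set_many(seqs: list[str], k: int) -> np.ndarray:
    """Sorted unique canonical k-mers pooled across several sequences."""
    parts = [kmer_set(s, k) for s in seqs if len(s) >= k]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def membership(codes: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    """Boolean mask: which codes occur in the sorted reference array."""
    if sorted_ref.size == 0:
        return np.zeros(codes.shape, dtype=bool)
    idx = np.searchsorted(sorted_ref, codes)
    idx = np.clip(idx, 0, sorted_ref.size - 1)
    return sorted_ref[idx] == codes


def match_counts(
    seqs: list[str], k: int, sorted_ref: np.ndarray
) -> np.ndarray:
    """Per-sequence count of valid windows whose canonical k-mer is in the
    reference set.  Sequences are batched by length for vectorization."""
    counts = np.zeros(len(seqs), dtype=np.int64)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for length, idxs in by_len.items():
        if length < k:
            continue
        arr = encode_matrix([seqs[i] for i in idxs])
        codes, valid = canonical_codes(arr, k)
        hits = membership(codes, sorted_ref) & valid
        counts[idxs] = hits.sum(axis=1)
    return counts
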