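"""Vectorized 2-bit k-mer encoding.

Shared by read baiting, k-mer-spectrum error correction, the de Bruijn
assembler, and back-mapping QC.  k-mers are packed into uint64 (k <= 31);
the *canonical* form of a k-mer is the numerically smaller of the forward
and reverse-complement encodings, so both strands hash identically.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "seq_to_codes",
    "kmer_codes",
    "canonical_kmers",
    "batch_canonical",
    "genome_kmer_set",
    "count_canonical",
    "in_sorted",
    "decode_kmer",
]

_LUT = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i
    _LUT[ord(chr(b).lower())] = i

_BASES = "ACGT"


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _roll(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rolling forward / reverse-complement codes along the last axis.

    ``b`` is a uint8 array (..., L) of base codes; returns ``(fwd, rc,
    valid)`` each of shape (..., L-k+1).  Positions whose window contains a
    non-ACGT base are flagged invalid (their codes are arbitrary).
    """
    L = b.shape[-1]
    n_pos = L - k + 1
    if n_pos <= 0:
        shape = b.shape[:-1] + (0,)
        return (
            np.zeros(shape, dtype=np.uint64),
            np.zeros(shape, dtype=np.uint64),
            np.zeros(shape, dtype=bool),
        )
    bad = b >= 4
    b4 = np.where(bad, 0, b).astype(np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    shift_hi = np.uint64(2 * (k - 1))
    two = np.uint64(2)
    comp = np.uint64(3) - b4

    fwd = np.empty(b.shape[:-1] + (n_pos,), dtype=np.uint64)
    rc = np.empty_like(fwd)
    # first window
    f = np.zeros(b.shape[:-1], dtype=np.uint64)
    r = np.zeros_like(f)
    for j in range(k):
        f = ((f << two) | b4[..., j]) & mask
        r = (r >> two) | (comp[..., j] << shift_hi)
    fwd[..., 0] = f
    rc[..., 0] = r
    for i in range(1, n_pos):
        f = ((f << two) | b4[..., i + k - 1]) & mask
        r = (r >> two) | (comp[..., i + k - 1] << shift_hi)
        fwd[..., i] = f
        rc[..., i] = r

    if bad.any():
        cum = np.cumsum(bad, axis=-1, dtype=np.int32)
        pad = np.zeros(b.shape[:-1] + (1,), dtype=np.int32)
        cum = np.concatenate([pad, cum], axis=-1)
        valid = (cum[..., k:] - cum[..., :-k]) == 0
    else:
        valid = np.ones(b.shape[:-1] + (n_pos,), dtype=bool)
    return fwd, rc, valid


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position ``(forward, revcomp, valid)`` codes for one sequence."""
    return _roll(seq_to_codes(seq), k)


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes of one sequence (invalid positions dropped)."""
    fwd, rc, valid = kmer_codes(seq, k)
    return np.minimum(fwd, rc)[valid]


def batch_canonical(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for many sequences at once.

    Returns ``(codes, owner)`` where ``owner[i]`` is the index of the
    sequence that contributed ``codes[i]``.  Sequences are processed in
    equal-length groups so the rolling hash is fully vectorized.
    """
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    codes_parts = []
    owner_parts = []
    for L, idxs in by_len.items():
        if L < k:
            continue
        mat = np.empty((len(idxs), L), dtype=np.uint8)
        for row, i in enumerate(idxs):
            mat[row] = _LUT[np.frombuffer(seqs[i].encode(), dtype=np.uint8)]
        fwd, rc, valid = _roll(mat, k)
        canon = np.minimum(fwd, rc)
        idx_arr = np.asarray(idxs, dtype=np.int64)
        owner = np.broadcast_to(idx_arr[:, None], canon.shape)
        codes_parts.append(canon[valid])
        owner_parts.append(owner[valid])
    if not codes_parts:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    return np.concatenate(codes_parts), np.concatenate(owner_parts)


def genome_kmer_set(seqs, k: int, circular: bool = False) -> np.ndarray:
    """Sorted unique canonical k-mers of one or more genome sequences.

    For circular sequences the first ``k-1`` bases are appended so
    origin-spanning k-mers are included.
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    parts = []
    for s in seqs:
        if circular and len(s) > k:
            s = s + s[: k - 1]
        parts.append(canonical_kmers(s, k))
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def count_canonical(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """(sorted unique canonical k-mers, occurrence counts) over sequences."""
    codes, _ = batch_canonical(seqs, k)
    if codes.size == 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    return np.unique(codes, return_counts=True)


def in_sorted(queries: np.ndarray, sorted_codes: np.ndarray) -> np.ndarray:
    """Membership mask of ``queries`` in a sorted code array."""
    if sorted_codes.size == 0:
        return np.zeros(queries.shape, dtype=bool)
    pos = np.searchsorted(sorted_codes, queries)
    pos = np.minimum(pos, sorted_codes.size - 1)
    return sorted_codes[pos] == queries


def decode_kmer(code: int, k: int) -> str:
    """Inverse of the 2-bit packing (forward orientation)."""
    out = []
    code = int(code)
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))
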