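"""Read preprocessing: sliding-window quality trimming, adapter clipping,
and k-mer-spectrum error correction.

The trimmer mirrors the common SLIDINGWINDOW strategy: scanning from the
5' end, the read is cut at the first window whose mean quality drops below
the cutoff.  The corrector uses a k-mer spectrum rule: a base whose
covering k-mers are all *solo* (count 1) is replaced by the single
alternative base that makes every covering k-mer *solid* (count >= a
threshold), if exactly one such alternative exists.
"""

from __future__ import annotations

import numpy as np

from . import kmers
from .reads import ReadSet

__all__ = ["preprocess_reads", "correct_reads"]

_BASES = "ACGT"


def _trim_read(seq: str, qual: str, cutoff: int, window: int) -> tuple[str, str]:
    if len(seq) != len(qual):
        raise ValueError("malformed quality string: length mismatch")
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33
    if q.size >= window:
        # fast path: nothing below cutoff anywhere
        if q.min() >= cutoff:
            return seq, qual
        means = np.convolve(q, np.ones(window), "valid") / window
        bad = np.flatnonzero(means < cutoff)
        if bad.size:
            cut = int(bad[0])
            # within the failing window, cut before the first low base
            while cut < q.size and q[cut] >= cutoff:
                cut += 1
            return seq[:cut], qual[:cut]
    return seq, qual


def _clip_adapter(seq: str, qual: str, adapter: str, min_match: int) -> tuple[str, str]:
    """Clip a 3' adapter: the read suffix matching an adapter prefix of
    >= ``min_match`` bases exactly is removed."""
    max_ov = min(len(seq), len(adapter))
    for ov in range(max_ov, min_match - 1, -1):
        if seq.endswith(adapter[:ov]):
            return seq[:-ov], qual[:-ov]
    return seq, qual


def preprocess_reads(
    reads: ReadSet,
    quality_cutoff: int = 15,
    adapters: tuple[str, ...] = (),
    correct: bool = False,
    k: int = 21,
    min_length: int = 50,
    window: int = 4,
    solid_threshold: int = 5,
) -> ReadSet:
    """Trim, clip, optionally error-correct, and length-filter read pairs.

    Pairs where either trimmed mate is shorter than ``min_length`` are
    dropped whole.  With ``correct=True`` the k-mer spectrum of the
    surviving reads is used to fix isolated substitution errors (``k`` must
    be odd, 15-31).
    """
    if correct and (k % 2 == 0 or not 15 <= k <= 31):
        raise ValueError("correction k must be odd and in [15, 31]")
    out = ReadSet(read_length=reads.read_length, insert_range=reads.insert_range)
    for rid, s1, q1, s2, q2 in reads.iter_pairs():
        s1, q1 = _trim_read(s1, q1, quality_cutoff, window)
        s2, q2 = _trim_read(s2, q2, quality_cutoff, window)
        for ad in adapters:
            s1, q1 = _clip_adapter(s1, q1, ad, 10)
            s2, q2 = _clip_adapter(s2, q2, ad, 10)
        if len(s1) < min_length or len(s2) < min_length:
            continue
        out.ids.append(rid)
        out.seq1.append(s1)
        out.qual1.append(q1)
        out.seq2.append(s2)
        out.qual2.append(q2)
    if correct:
        correct_reads(out, k=k, solid_threshold=solid_threshold)
    return out


def correct_reads(reads: ReadSet, k: int = 21, solid_threshold: int = 5) -> int:
    """In-place k-mer-spectrum correction of isolated substitutions.

    Returns the number of corrected bases.  A position is a candidate when
    the k-mers covering it are solo (count 1); the correction is accepted
    when exactly one substitute base turns all covering k-mers solid.
    """
    seqs = reads.all_sequences()
    codes_sorted, counts = kmers.count_canonical(seqs, k)
    if codes_sorted.size == 0:
        return 0
    solid = codes_sorted[counts >= solid_threshold]
    solo = codes_sorted[counts == 1]
    n_fixed = 0
    n_pairs = len(reads)
    for i, seq in enumerate(seqs):
        fixed = None
        for _ in range(3):  # reads may carry more than one error
            trial = _correct_one(fixed or seq, k, solid, solo)
            if trial is None:
                break
            fixed = trial
        if fixed is not None:
            n_fixed += 1
            if i < n_pairs:
                reads.seq1[i] = fixed
            else:
                reads.seq2[i - n_pairs] = fixed
    return n_fixed


def _correct_one(
    seq: str, k: int, solid: np.ndarray, solo: np.ndarray
) -> str | None:
    if len(seq) < k:
        return None
    canon = np.minimum(*kmers.kmer_codes(seq, k)[:2])
    is_solo = kmers.in_sorted(canon, solo)
    if not is_solo.any():
        return None
    first = int(np.argmax(is_solo))
    last = int(len(is_solo) - 1 - np.argmax(is_solo[::-1]))
    # single substitution at p covers k-mers [p-k+1, p]; infer p from the run
    candidates = set()
    if first == 0:
        candidates.add(last)  # error may sit before the first full window
    if last == len(is_solo) - 1:
        candidates.add(first + k - 1)
    candidates.add(last)
    if last - first == k - 1:
        candidates.add(first + k - 1)
    best = None
    for p in sorted(c for c in candidates if 0 <= c < len(seq)):
        for b in _BASES:
            if b == seq[p]:
                continue
            trial = seq[:p] + b + seq[p + 1 :]
            lo = max(0, p - k + 1)
            hi = min(len(trial) - k + 1, p + 1)
            window = trial[lo : hi + k - 1]
            tc = np.minimum(*kmers.kmer_codes(window, k)[:2])
            if bool(kmers.in_sorted(tc, solid).all()):
                if best is not None and best != trial:
                    return None  # ambiguous
                best = trial
        if best is not None:
            return best
    return best
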