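"""Bait-based recruitment of candidate prey mitochondrial read pairs.

A read pair is recruited when either mate shares at least
``min_shared_kmers`` canonical k-mers with any genome of the reference
panel.  This replaces alignment-based baiting (the classical BLAST step)
with exact k-mer containment: at the default k=25 and threshold 2, a
250 bp read up to ~15% divergent from the panel is still recruited, while
the chance of recruiting an unrelated random read is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kmers
from .reads import ReadSet
from .seqio import AnnotatedGenome, SequenceRecord

__all__ = ["BaitResult", "bait_reads", "shared_kmer_counts"]


@dataclass
class BaitResult:
    reads: ReadSet
    indices: np.ndarray  # recruited pair indices into the input ReadSet
    recall: float | None = None
    precision: float | None = None


def _panel_sequences(panel) -> list[tuple[str, bool]]:
    seqs = []
    for g in panel:
        if isinstance(g, AnnotatedGenome):
            seqs.append((g.record.seq, g.record.circular))
        elif isinstance(g, SequenceRecord):
            seqs.append((g.seq, g.circular))
        else:
            seqs.append((str(g), False))
    return seqs


def shared_kmer_counts(
    seqs: list[str], panel_codes: np.ndarray, k: int, chunk: int = 20_000
) -> np.ndarray:
    """Per-sequence count of canonical k-mers present in a sorted panel set."""
    out = np.zeros(len(seqs), dtype=np.int32)
    for lo in range(0, len(seqs), chunk):
        sub = seqs[lo : lo + chunk]
        codes, owner = kmers.batch_canonical(sub, k)
        if codes.size == 0:
            continue
        hit = kmers.in_sorted(codes, panel_codes)
        if hit.any():
            out[lo : lo + len(sub)] = np.bincount(
                owner[hit], minlength=len(sub)
            ).astype(np.int32)
    return out


def bait_reads(
    reads: ReadSet,
    panel,
    min_shared_kmers: int = 2,
    k_bait: int = 25,
    truth_prey_ids: set[str] | None = None,
    origins: dict[str, str] | None = None,
) -> BaitResult:
    """Recruit read pairs sharing k-mers with a reference panel.

    Parameters
    ----------
    panel : list of AnnotatedGenome / SequenceRecord / str.
    truth_prey_ids, origins : optional truth for recall/precision reporting;
        ``origins`` maps read id -> genome id of origin.
    """
    if not 17 <= k_bait <= 31:
        raise ValueError("k_bait must be in [17, 31]")
    seqs = _panel_sequences(panel)
    if not seqs:
        raise ValueError("empty reference panel")
    panel_codes = np.unique(
        np.concatenate(
            [kmers.genome_kmer_set(s, k_bait, circular=c) for s, c in seqs]
        )
    )
    c1 = shared_kmer_counts(reads.seq1, panel_codes, k_bait)
    c2 = shared_kmer_counts(reads.seq2, panel_codes, k_bait)
    mask = (c1 >= min_shared_kmers) | (c2 >= min_shared_kmers)
    idx = np.flatnonzero(mask)
    result = BaitResult(reads=reads.subset(idx.tolist()), indices=idx)

    if truth_prey_ids is not None and origins is not None:
        is_prey = np.array(
            [origins.get(r, "") in truth_prey_ids for r in reads.ids], dtype=bool
        )
        tp = int((mask & is_prey).sum())
        fn = int((~mask & is_prey).sum())
        fp = int((mask & ~is_prey).sum())
        result.recall = tp / (tp + fn) if tp + fn else float("nan")
        result.precision = tp / (tp + fp) if tp + fp else float("nan")
    return result
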