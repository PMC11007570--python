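"""Seed assembly and iterative contig extension.

Initial contigs come from a de Bruijn graph built over a cascade of k-mer
sizes (largest k first; reads already represented by accepted unitigs are
withheld from the smaller-k graphs, so the largest k that resolves a
component wins).  Contig ends are then lengthened iteratively: reads
overlapping a contig end are recruited, and bases are appended one at a
time by a strict base-majority consensus.  Extension stops at a fork --
a position where no base reaches the majority threshold, which is the
signature of a haplotype boundary -- rather than branching, so contigs
never switch between co-occurring haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kmers
from .reads import ReadSet
from .seqio import revcomp

__all__ = ["Contig", "debruijn_unitigs", "assemble_and_extend"]

_MAJORITY = 0.80


@dataclass
class Contig:
    """An assembled sequence with per-base support.

    ``support`` is the approximate per-base read depth; ``provenance``
    records the extension iteration at which each base was added (0 for
    bases from the initial de Bruijn unitig).
    """

    seq: str
    support: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = np.zeros(len(self.seq), dtype=np.int16)
        if "N" in self.seq:
            raise ValueError("contigs must not contain N")
        if len(self.support) != len(self.seq) or len(self.provenance) != len(self.seq):
            raise ValueError("support/provenance length mismatch")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_depth(self) -> float:
        return float(np.mean(self.support))

    def canonical(self) -> str:
        rc = revcomp(self.seq)
        return self.seq if self.seq <= rc else rc


# ---------------------------------------------------------------------------
# de Bruijn unitigs
# ---------------------------------------------------------------------------


def _auto_cutoff(count_values: np.ndarray) -> int:
    """Coverage-adaptive solid-k-mer threshold.

    Error k-mers sit at count 1, with a secondary mass at counts 2-3 from
    pairs of reads sharing an error; genuine k-mers sit near the per-base
    coverage.  A cutoff at a quarter of the median count of the repeated
    k-mers separates the two without assuming a coverage level.
    """
    rep = count_values[count_values >= 2]
    if rep.size == 0:
        return 1
    med = float(np.median(rep))
    return max(2, int(round(0.25 * med)))


def debruijn_unitigs(
    seqs: list[str], k: int, min_count: int | str = "auto"
) -> list[Contig]:
    """Non-branching paths of the (both-strand) de Bruijn graph.

    Nodes are k-mers observed at least ``min_count`` times (the default
    ``"auto"`` picks a coverage-adaptive solid threshold) across the
    sequences and their reverse complements; unitigs are maximal paths
    whose interior nodes have in- and out-degree one.  Because no read
    spans two haplotypes, chimeric k-mers do not exist in the input and
    unitigs cannot switch haplotypes.
    """
    counts: dict[str, int] = {}
    for s in seqs:
        if len(s) < k:
            continue
        for variant in (s, revcomp(s)):
            for i in range(len(variant) - k + 1):
                km = variant[i : i + k]
                counts[km] = counts.get(km, 0) + 1
    if not counts:
        return []
    if min_count == "auto":
        min_count = _auto_cutoff(np.fromiter(counts.values(), dtype=np.int64))
    if min_count > 1:
        counts = {km: c for km, c in counts.items() if c >= min_count}
    if not counts:
        return []

    def successors(km: str):
        core = km[1:]
        return [core + b for b in "ACGT" if core + b in counts]

    def predecessors(km: str):
        core = km[:-1]
        return [b + core for b in "ACGT" if b + core in counts]

    starts = []
    for km in counts:
        preds = predecessors(km)
        if len(preds) != 1 or len(successors(preds[0])) != 1:
            starts.append(km)

    visited: set[str] = set()
    unitigs: list[tuple[str, list[int]]] = []

    def walk(start: str) -> tuple[str, list[int]]:
        path = [start]
        depth = [counts[start]]
        visited.add(start)
        cur = start
        while True:
            succs = successors(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if len(predecessors(nxt)) != 1 or nxt in visited:
                break
            visited.add(nxt)
            path.append(nxt)
            depth.append(counts[nxt])
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        return seq, depth

    for km in starts:
        if km not in visited:
            unitigs.append(walk(km))
    # isolated cycles (perfectly covered circular molecules) have no starts
    for km in counts:
        if km not in visited:
            unitigs.append(walk(km))

    out: dict[str, Contig] = {}
    for seq, depth in unitigs:
        support = np.empty(len(seq), dtype=np.int32)
        support[: len(depth)] = depth
        support[len(depth) :] = depth[-1]
        c = Contig(seq, support)
        key = c.canonical()
        if key not in out or len(seq) > len(out[key]):
            out[key] = c
    return sorted(out.values(), key=lambda c: (-len(c), c.seq))


def _contained_fraction(seq: str, accepted_codes: np.ndarray, k: int = 31) -> float:
    codes = kmers.canonical_kmers(seq, k)
    if codes.size == 0:
        return 0.0
    return float(kmers.in_sorted(codes, accepted_codes).mean())


def _uncontained(
    seqs: list[str], accepted_codes: np.ndarray, threshold: float, k: int = 31
) -> list[str]:
    """Sequences whose 31-mer containment in the accepted set is below
    ``threshold`` (batch computation)."""
    if accepted_codes.size == 0 or not seqs:
        return seqs
    codes, owner = kmers.batch_canonical(seqs, k)
    if codes.size == 0:
        return seqs
    hit = kmers.in_sorted(codes, accepted_codes)
    n_tot = np.bincount(owner, minlength=len(seqs))
    n_hit = np.bincount(owner[hit], minlength=len(seqs))
    frac = np.where(n_tot > 0, n_hit / np.maximum(n_tot, 1), 0.0)
    return [s for i, s in enumerate(seqs) if frac[i] < threshold]


def _cascade_assemble(
    pool: list[str],
    k_list: tuple[int, ...],
    read_length: int,
    min_count: int | str = "auto",
    rescue_min_len: int = 150,
) -> list[Contig]:
    ks = sorted(k_list, reverse=True)
    accepted: list[Contig] = []
    accepted_codes = np.empty(0, dtype=np.uint64)
    remaining = pool
    min_len = 2 * read_length

    def refresh_codes():
        nonlocal accepted_codes
        parts = [kmers.canonical_kmers(c.seq, 31) for c in accepted]
        accepted_codes = (
            np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=np.uint64)
        )

    for ki, k in enumerate(ks):
        if not remaining:
            break
        for u in debruijn_unitigs(remaining, k, min_count=min_count):
            if len(u) >= min_len and _contained_fraction(u.seq, accepted_codes) < 0.95:
                accepted.append(u)
                accepted_codes = np.unique(
                    np.concatenate([accepted_codes, kmers.canonical_kmers(u.seq, 31)])
                )
        refresh_codes()
        remaining = _uncontained(remaining, accepted_codes, 0.90)
    # pre-rescue at the largest k: co-occurring haplotypes at a few percent
    # divergence fragment into specific unitigs shorter than 2x read length
    # (breaks at every shared segment); keep them rather than lose the
    # haplotypes -- extension and scaffolding take it from there
    if remaining:
        for u in debruijn_unitigs(remaining, ks[0], min_count=min_count):
            if len(u) >= rescue_min_len and _contained_fraction(
                u.seq, accepted_codes
            ) < 0.95:
                accepted.append(u)
                accepted_codes = np.unique(
                    np.concatenate([accepted_codes, kmers.canonical_kmers(u.seq, 31)])
                )
        remaining = _uncontained(remaining, accepted_codes, 0.90)
    # final rescue for components too thin for solid unitigs (sub-1x prey)
    if remaining:
        for u in debruijn_unitigs(remaining, ks[-1], min_count=1):
            if len(u) >= rescue_min_len and _contained_fraction(
                u.seq, accepted_codes
            ) < 0.95:
                accepted.append(u)
    return accepted


# ---------------------------------------------------------------------------
# Iterative consensus extension
# ---------------------------------------------------------------------------

_IDX_K = 31


class _ReadIndex:
    """Forward k-mer index over both orientations of every read."""

    def __init__(self, reads: ReadSet, k: int = _IDX_K):
        self.k = k
        self.strings: list[str] = []
        for s in reads.seq1:
            self.strings.append(s)
            self.strings.append(revcomp(s))
        for s in reads.seq2:
            self.strings.append(s)
            self.strings.append(revcomp(s))
        codes_parts, owner_parts, pos_parts = [], [], []
        for i, s in enumerate(self.strings):
            fwd, _, valid = kmers.kmer_codes(s, k)
            codes_parts.append(fwd[valid])
            n = int(valid.sum())
            owner_parts.append(np.full(n, i, dtype=np.int32))
            pos_parts.append(np.flatnonzero(valid).astype(np.int32))
        if codes_parts:
            codes = np.concatenate(codes_parts)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.owner = np.concatenate(owner_parts)[order]
            self.pos = np.concatenate(pos_parts)[order]
        else:
            self.codes = np.empty(0, dtype=np.uint64)
            self.owner = np.empty(0, dtype=np.int32)
            self.pos = np.empty(0, dtype=np.int32)

    def candidates(self, query: str) -> dict[tuple[int, int], None]:
        """(string index, implied string start offset) pairs for reads
        sharing a forward k-mer with ``query`` (offsets relative to the
        query start; may be negative)."""
        fwd, _, valid = kmers.kmer_codes(query, self.k)
        fwd = fwd[valid]
        qpos = np.flatnonzero(valid)
        out: dict[tuple[int, int], None] = {}
        lo = np.searchsorted(self.codes, fwd, side="left")
        hi = np.searchsorted(self.codes, fwd, side="right")
        for qp, a, b in zip(qpos, lo, hi):
            for j in range(a, b):
                out[(int(self.owner[j]), int(qp) - int(self.pos[j]))] = None
        return out


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _extend_right(
    contig: str,
    index: _ReadIndex,
    iteration: int,
    min_overlap: int,
    min_identity: float,
) -> tuple[str, list[int], list[int]]:
    """One extension round on the right end; returns (new bases, support,
    provenance)."""
    tail_len = min(len(contig), 2 * min_overlap)
    tail = contig[-tail_len:]
    tail_start = len(contig) - tail_len
    overhangs: list[tuple[str, int]] = []  # (read string, contig start coord)
    for (si, off) in index.candidates(tail):
        s = index.strings[si]
        start = tail_start + off  # contig coordinate of read start
        end = start + len(s)
        if end <= len(contig):
            continue  # no overhang
        ov_lo = max(start, 0)
        ov_len = len(contig) - ov_lo
        if ov_len < min_overlap:
            continue
        read_lo = ov_lo - start
        mism = _mismatches(s[read_lo : read_lo + ov_len], contig[ov_lo:])
        if ov_len and 1 - mism / ov_len >= min_identity:
            overhangs.append((s, start))
    if not overhangs:
        return "", [], []
    new: list[str] = []
    support: list[int] = []
    pos = len(contig)
    while True:
        votes: dict[str, int] = {}
        for s, start in overhangs:
            i = pos - start
            if 0 <= i < len(s):
                votes[s[i]] = votes.get(s[i], 0) + 1
        total = sum(votes.values())
        if total == 0:
            break
        best = min(votes, key=lambda b: (-votes[b], b))
        if votes[best] / total < _MAJORITY:
            break  # fork: likely haplotype boundary
        new.append(best)
        support.append(votes[best])
        pos += 1
    return "".join(new), support, [iteration] * len(new)


def _extend_contig(
    c: Contig,
    index: _ReadIndex,
    iteration: int,
    min_overlap: int,
    min_identity: float,
) -> Contig:
    seq, sup, prov = c.seq, c.support, c.provenance
    add, s_add, p_add = _extend_right(seq, index, iteration, min_overlap, min_identity)
    if add:
        seq = seq + add
        sup = np.concatenate([sup, np.asarray(s_add, dtype=sup.dtype)])
        prov = np.concatenate([prov, np.asarray(p_add, dtype=prov.dtype)])
    # left end: extend the reverse complement's right end
    rc_seq = revcomp(seq)
    add, s_add, p_add = _extend_right(rc_seq, index, iteration, min_overlap, min_identity)
    if add:
        seq = revcomp(rc_seq + add)
        sup = np.concatenate([np.asarray(s_add[::-1], dtype=sup.dtype), sup])
        prov = np.concatenate([np.asarray(p_add[::-1], dtype=prov.dtype), prov])
    return Contig(seq, sup, prov)


_ANCHOR = 31


def _contains_exact(a: str, b: str) -> bool:
    """Is ``b`` an exact substring of ``a``?  Anchored on b's first 31-mer
    so the scan stays linear even for long near-periodic sequences."""
    if len(b) > len(a):
        return False
    if len(b) <= _ANCHOR:
        return b in a
    anchor = b[:_ANCHOR]
    pos = a.find(anchor)
    while pos != -1:
        if a[pos : pos + len(b)] == b:
            return True
        pos = a.find(anchor, pos + 1)
    return False


def _suffix_prefix(a: str, b: str, min_overlap: int) -> int:
    """Length of the longest exact overlap of a's suffix with b's prefix
    (0 if below ``min_overlap``)."""
    if min(len(a), len(b)) < min_overlap:
        return 0
    if len(b) <= _ANCHOR:
        for ov in range(min(len(a), len(b)), min_overlap - 1, -1):
            if a.endswith(b[:ov]):
                return ov
        return 0
    anchor = b[:_ANCHOR]
    lo = max(0, len(a) - len(b))
    pos = a.find(anchor, lo)
    while pos != -1:
        ov = len(a) - pos
        if ov >= min_overlap and a[pos:] == b[:ov]:
            return ov
        pos = a.find(anchor, pos + 1)
    # short overlaps (below the anchor size) when min_overlap allows them
    if min_overlap < _ANCHOR:
        for ov in range(min(_ANCHOR - 1, len(a), len(b)), min_overlap - 1, -1):
            if a.endswith(b[:ov]):
                return ov
    return 0


def _junction_supported(
    seq: str,
    ov_start: int,
    ov_end: int,
    index: "_ReadIndex",
    flank: int = 20,
    min_identity: float = 0.98,
) -> bool:
    """Is a candidate merge junction covered by at least one read running
    from before the overlap into the sequence beyond it?

    Two co-occurring haplotypes can end in an identical shared segment;
    gluing them on that exact overlap would create a chimera.  Genuine
    same-molecule joins are always spanned by reads (no sequenced fragment
    crosses haplotypes), so a merge without a spanning read is rejected.
    """
    lo = max(0, ov_start - index.k)
    hi = min(len(seq), ov_end + index.k)
    window = seq[lo:hi]
    for (si, off) in index.candidates(window):
        s = index.strings[si]
        start = lo + off
        end = start + len(s)
        if start > ov_start - flank or end < ov_end + flank:
            continue
        a, b = max(start, 0), min(end, len(seq))
        mism = _mismatches(s[a - start : b - start], seq[a:b])
        if b > a and 1 - mism / (b - a) >= min_identity:
            return True
    return False


def _oriented(c: Contig, orient: str) -> tuple[str, np.ndarray, np.ndarray]:
    if orient == "+":
        return c.seq, c.support, c.provenance
    return revcomp(c.seq), c.support[::-1], c.provenance[::-1]


def _merge_exact_overlaps(
    contigs: list[Contig], min_overlap: int, index: "_ReadIndex | None" = None
) -> list[Contig]:
    """Merge contigs with *unambiguous* exact suffix/prefix overlaps and
    drop contigs contained verbatim in another.

    Where two co-occurring haplotypes break at a shared identical segment,
    several contig ends carry the same shared sequence and more than one
    merge is possible; such ambiguous joins are the chimera vector, so an
    end is only merged when it has exactly one overlap partner and that
    partner's end likewise has exactly one (the overlap-layout uniqueness
    rule: stop at forks rather than guess).  With a read index a junction-
    spanning read is additionally required.
    """
    work = sorted(contigs, key=lambda c: (-len(c), c.seq))
    # containment removal first (also collapses reverse-complement twins)
    kept: list[Contig] = []
    for c in work:
        if any(
            _contains_exact(k.seq, c.seq) or _contains_exact(k.seq, revcomp(c.seq))
            for k in kept
        ):
            continue
        kept.append(c)
    work = kept

    changed = True
    while changed:
        changed = False
        # every unordered end pair appears exactly once: a is the left part
        # and the four orientation combinations cover aR-bL, aR-bR, aL-bL,
        # aL-bR joins
        cands: list[tuple[int, str, int, str, int]] = []
        for i, a in enumerate(work):
            for j, b in enumerate(work):
                if j <= i:
                    continue
                for oi in "+-":
                    asq = _oriented(a, oi)[0]
                    for oj in "+-":
                        bsq = _oriented(b, oj)[0]
                        ov = _suffix_prefix(asq, bsq, min_overlap)
                        if ov:
                            cands.append((i, oi, j, oj, ov))
        end_uses: dict[tuple[int, str], int] = {}

        def ends(i, oi, j, oj):
            return (
                (i, "R" if oi == "+" else "L"),
                (j, "L" if oj == "+" else "R"),
            )

        for i, oi, j, oj, _ in cands:
            for e in ends(i, oi, j, oj):
                end_uses[e] = end_uses.get(e, 0) + 1
        for i, oi, j, oj, ov in sorted(cands, key=lambda t: (-t[4], t[0], t[2])):
            ea, eb = ends(i, oi, j, oj)
            if end_uses[ea] != 1 or end_uses[eb] != 1:
                continue
            asq, sup_a, prov_a = _oriented(work[i], oi)
            bsq, sup_b, prov_b = _oriented(work[j], oj)
            merged_seq = asq + bsq[ov:]
            if index is not None and not _junction_supported(
                merged_seq, len(asq) - ov, len(asq), index
            ):
                continue
            merged = Contig(
                merged_seq,
                np.concatenate([sup_a, sup_b[ov:]]),
                np.concatenate([prov_a, prov_b[ov:]]),
            )
            work = [c for k, c in enumerate(work) if k not in (i, j)]
            work.append(merged)
            changed = True
            break  # recompute candidates after each accepted merge
    return sorted(work, key=lambda c: (-len(c), c.seq))


def assemble_and_extend(
    baited: ReadSet,
    k_list: tuple[int, ...] = (33, 55, 77),
    iterations: int = 10,
    min_overlap: int = 50,
    min_identity: float = 0.98,
    seeds: list[str] | None = None,
) -> list[Contig]:
    """Assemble baited reads and iteratively extend the contigs.

    ``seeds``, if given, replace the de Bruijn stage (used for targeted
    re-extension of known fragments).  Deterministic: consensus ties are
    broken lexicographically and output contigs are sorted by length then
    sequence.  Contig length never decreases across iterations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if seeds is not None:
        contigs = [
            Contig(s, np.ones(len(s), dtype=np.int32)) for s in seeds if s
        ]
    else:
        pool = baited.all_sequences()
        contigs = _cascade_assemble(pool, tuple(k_list), baited.read_length)
    if not contigs:
        return []
    index = _ReadIndex(baited)
    for it in range(1, iterations + 1):
        contigs = [
            _extend_contig(c, index, it, min_overlap, min_identity) for c in contigs
        ]
    contigs = _merge_exact_overlaps(contigs, min_overlap, index)
    return _drop_contained(contigs)


def _drop_contained(contigs: list[Contig], threshold: float = 0.95) -> list[Contig]:
    """Drop contigs nearly contained (by canonical 31-mers) in longer ones;
    removes reverse-complement and overlap redundancy left by extension."""
    kept: list[Contig] = []
    codes = np.empty(0, dtype=np.uint64)
    for c in sorted(contigs, key=lambda c: (-len(c), c.seq)):
        if codes.size and _contained_fraction(c.seq, codes) >= threshold:
            continue
        kept.append(c)
        codes = np.unique(np.concatenate([codes, kmers.canonical_kmers(c.seq, 31)]))
    return kept
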