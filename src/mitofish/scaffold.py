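"""Reference-guided scaffolding: contig anchoring, overlap merging, local
gap re-assembly, N-fill, and back-mapping QC.

The reference orders and orients contigs but never contributes sequence:
regions the contigs do not cover stay as N runs whose lengths are taken
from the reference alignment (hence reported gap lengths and completeness
are approximations in exactly the sense assemblies scaffolded against a
related species are).  Completeness is the percentage of the reference
covered by non-N scaffold bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from . import kmers
from .assembly import Contig, assemble_and_extend
from .baiting import shared_kmer_counts
from .preprocess import correct_reads
from .reads import ReadSet
from .seqio import AnnotatedGenome, SequenceRecord, revcomp

__all__ = [
    "Placement",
    "Gap",
    "ScaffoldResult",
    "QCRow",
    "QCReport",
    "anchor_contigs",
    "merge_and_close",
    "finalize_scaffold",
    "backmap_qc",
]

_EQUALITIES = [("N", b) for b in "ACGT"]


@dataclass
class Placement:
    contig_index: int
    reference_id: str
    start: int  # reference coords; end may exceed L when the contig wraps
    end: int
    orientation: str  # + / -
    identity: float
    oriented_seq: str = ""
    mean_depth: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1:
            raise ValueError("identity out of range")


@dataclass
class Gap:
    ref_start: int
    ref_end: int

    @property
    def fill_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class ScaffoldResult:
    seq: str
    gaps: list[Gap]
    reference_id: str
    completeness: float = 0.0
    coverage: dict[str, float] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)
    pieces: list[tuple[int, str, float]] = field(default_factory=list)
    # pieces: (ref_start, sequence, mean_depth) in reference order

    @property
    def scaffold_id(self) -> str:
        return f"scaffold_{self.reference_id}"


def _align_infix(query: str, target: str) -> tuple[int, int, int]:
    """Best infix alignment of query in target: (edit distance, start, end)."""
    res = edlib.align(query, target, mode="HW", task="locations",
                      additionalEqualities=_EQUALITIES)
    loc = res["locations"][0]
    return res["editDistance"], loc[0] or 0, loc[1] + 1


def anchor_contigs(
    contigs: list[Contig],
    reference: AnnotatedGenome | SequenceRecord,
    min_identity: float = 0.75,
) -> list[Placement]:
    """Place each contig on the reference by best infix alignment.

    Orientation is normalized to the reference forward strand; circular
    references are handled by aligning against the doubled sequence.
    Contigs below ``min_identity`` are left unplaced (not returned).
    """
    rec = reference.record if isinstance(reference, AnnotatedGenome) else reference
    L = len(rec.seq)
    target = rec.seq + rec.seq if rec.circular else rec.seq
    placements = []
    for ci, c in enumerate(contigs):
        c_seq = c.seq
        if len(c_seq) > L:
            # contig ran around the circle; keep one turn plus slack so the
            # closure step can trim the duplicated junction
            if not rec.circular:
                continue
            c_seq = c_seq[: L + 100]
        best = None
        for orient, seq in (("+", c_seq), ("-", revcomp(c_seq))):
            dist, s, e = _align_infix(seq, target)
            ident = 1 - dist / max(len(seq), 1)
            if best is None or ident > best[0]:
                best = (ident, orient, seq, s, e)
        ident, orient, seq, s, e = best
        if ident < min_identity:
            continue
        if s >= L:
            s -= L
            e -= L
        placements.append(
            Placement(ci, rec.id, s, e, orient, ident, seq, c.mean_depth)
        )
    placements.sort(key=lambda p: (p.start, -len(p.oriented_seq)))
    return placements


def _overlap_identity(a_tail: str, b_head: str) -> float:
    if not a_tail or not b_head:
        return 0.0
    d = edlib.align(a_tail, b_head, mode="NW",
                    additionalEqualities=_EQUALITIES)["editDistance"]
    return 1 - d / max(len(a_tail), len(b_head))


def _merge_pass(
    placements: list[Placement],
    L: int,
    min_merge_overlap: int = 30,
    min_merge_identity: float = 0.99,
) -> tuple[list[tuple[int, str, float]], list[Gap], list[str]]:
    """Merge reference-adjacent overlapping placements into pieces.

    Returns (pieces, gaps, conflict warnings); pieces are (ref_start, seq,
    depth) in reference order.  Contig sequence always wins over the
    reference; where two contigs disagree (< 99% identity over the
    overlap) they are left unmerged and a haplotype-conflict warning is
    recorded.
    """
    conflicts: list[str] = []
    pieces: list[tuple[int, str, float]] = []
    if not placements:
        return pieces, [Gap(0, L)], conflicts

    cur_start, cur_seq, cur_depth = (
        placements[0].start, placements[0].oriented_seq, placements[0].mean_depth,
    )
    for p in placements[1:]:
        cur_end = cur_start + len(cur_seq)  # approximate ref coord of piece end
        ov = cur_end - p.start
        if ov >= min_merge_overlap:
            ov = min(ov, len(cur_seq), len(p.oriented_seq))
            ident = _overlap_identity(cur_seq[-ov:], p.oriented_seq[:ov])
            if ident >= min_merge_identity:
                # overlap bases from the deeper contig
                if p.mean_depth > cur_depth:
                    merged = cur_seq[:-ov] + p.oriented_seq
                else:
                    merged = cur_seq + p.oriented_seq[ov:]
                n = len(cur_seq) + len(p.oriented_seq) - ov
                cur_depth = (
                    cur_depth * len(cur_seq) + p.mean_depth * len(p.oriented_seq)
                ) / max(len(cur_seq) + len(p.oriented_seq), 1)
                cur_seq = merged
                continue
            if p.start + len(p.oriented_seq) <= cur_end:
                # fully overlapped alternative: likely the other haplotype
                conflicts.append(
                    f"contig {p.contig_index} conflicts with scaffold piece at "
                    f"ref {p.start}-{p.start + len(p.oriented_seq)} "
                    f"(identity {ident:.3f} < {min_merge_identity}); not merged"
                )
                continue
            conflicts.append(
                f"contig {p.contig_index} overlap at ref {p.start}-{cur_end} has "
                f"identity {ident:.3f} < {min_merge_identity}; treated as gap "
                "(haplotype conflict)"
            )
        pieces.append((cur_start, cur_seq, cur_depth))
        cur_start, cur_seq, cur_depth = p.start, p.oriented_seq, p.mean_depth
    pieces.append((cur_start, cur_seq, cur_depth))

    gaps = []
    for (s1, seq1, _), (s2, _, _) in zip(pieces, pieces[1:]):
        e1 = s1 + len(seq1)
        if s2 > e1:
            gaps.append(Gap(e1, s2))
    # wrap-around gap on the circle
    first_start = pieces[0][0]
    last_end = pieces[-1][0] + len(pieces[-1][1])
    if last_end < L + first_start:
        gaps.append(Gap(last_end, L + first_start))
    return pieces, gaps, conflicts


def merge_and_close(
    placements: list[Placement],
    contigs: list[Contig],
    reference: AnnotatedGenome | SequenceRecord,
    reads: ReadSet | None = None,
    flank: int = 300,
    k_list: tuple[int, ...] = (33, 55, 77),
    max_rounds: int = 3,
    min_anchor_identity: float = 0.75,
    panel: list | None = None,
) -> ScaffoldResult:
    """Merge anchored contigs and close gaps by local re-assembly.

    For each reference gap, reads sharing k-mers with the gap region plus
    ``flank`` bases of context on both sides are recruited, re-assembled
    over ``k_list``, re-anchored, and the merge repeated, up to
    ``max_rounds`` rounds or until no gap closes.  When the full reference
    ``panel`` is supplied, gap-fill contigs are kept only if this
    reference is their best anchor -- otherwise reads of a co-occurring
    lineage that resemble the gap region would be scaffolded in.
    """
    rec = reference.record if isinstance(reference, AnnotatedGenome) else reference
    L = len(rec.seq)
    placements = sorted(placements, key=lambda p: (p.start, -len(p.oriented_seq)))
    all_contigs = list(contigs)
    pieces, gaps, conflicts = _merge_pass(placements, L)

    rounds = 0
    while reads is not None and gaps and rounds < max_rounds:
        rounds += 1
        windows = []
        for g in gaps:
            if g.fill_length <= 0:
                continue
            if rec.circular:
                start = (g.ref_start - flank) % L
                length = min(g.fill_length + 2 * flank, L - 1)
                win = rec.fetch(start, start + length)
            else:
                win = rec.seq[max(0, g.ref_start - flank) : min(L, g.ref_end + flank)]
            windows.append(SequenceRecord(f"gapwin_{g.ref_start}", win))
        if not windows:
            break
        win_codes = np.unique(
            np.concatenate([kmers.genome_kmer_set(w.seq, 25) for w in windows])
        )
        c1 = shared_kmer_counts(reads.seq1, win_codes, 25)
        c2 = shared_kmer_counts(reads.seq2, win_codes, 25)
        idx = np.flatnonzero((c1 >= 2) | (c2 >= 2))
        if idx.size == 0:
            break
        recruited = reads.subset(idx.tolist())
        correct_reads(recruited)
        new_contigs = assemble_and_extend(
            recruited, k_list=k_list, iterations=2
        )
        if not new_contigs:
            break
        if panel is not None:
            kept = []
            for c in new_contigs:
                scores = {}
                for other in panel:
                    pls = anchor_contigs([c], other, min_anchor_identity)
                    if pls:
                        scores[pls[0].reference_id] = pls[0].identity
                if scores and max(scores, key=scores.get) == rec.id:
                    kept.append(c)
            new_contigs = kept
            if not new_contigs:
                break
        offset = len(all_contigs)
        all_contigs.extend(new_contigs)
        new_pl = anchor_contigs(new_contigs, reference, min_anchor_identity)
        for p in new_pl:
            p.contig_index += offset
        if not new_pl:
            break
        placements = sorted(
            placements + new_pl, key=lambda p: (p.start, -len(p.oriented_seq))
        )
        new_pieces, new_gaps, new_conflicts = _merge_pass(placements, L)
        if sum(g.fill_length for g in new_gaps) >= sum(g.fill_length for g in gaps):
            pieces, gaps = new_pieces, new_gaps
            conflicts = conflicts + new_conflicts
            break
        pieces, gaps, conflicts = new_pieces, new_gaps, conflicts + new_conflicts

    result = ScaffoldResult(
        seq="", gaps=gaps, reference_id=rec.id, conflicts=conflicts, pieces=pieces
    )
    return result


def finalize_scaffold(
    pre: ScaffoldResult, reference: AnnotatedGenome | SequenceRecord
) -> ScaffoldResult:
    """Emit the scaffold in the reference frame starting at position 0.

    Residual gaps are filled with one N per missing reference base.  If
    the scaffold ends overlap on the circle at >= 99% identity over >= 30
    bases, the molecule is closed (the duplicated overlap is trimmed).
    Non-N bases are never altered.
    """
    rec = reference.record if isinstance(reference, AnnotatedGenome) else reference
    L = len(rec.seq)
    pieces = sorted(pre.pieces, key=lambda t: t[0])
    conflicts = list(pre.conflicts)
    if not pieces:
        return ScaffoldResult(
            "N" * L, [Gap(0, L)], rec.id, 0.0, {}, conflicts, []
        )

    # circular closure: a piece running past L may overlap the first piece
    if rec.circular and pieces:
        s0, seq0, _ = pieces[0]
        sl, seql, dl = pieces[-1]
        ov = (sl + len(seql)) - (L + s0)
        if 30 <= ov <= min(len(seql), len(seq0)):
            if _overlap_identity(seql[-ov:], seq0[:ov]) >= 0.99:
                pieces[-1] = (sl, seql[:-ov], dl)

    # split origin-wrapping pieces so all segments live in [0, L)
    segs: list[tuple[int, str, float]] = []
    for s, seq, d in pieces:
        s %= L
        if s + len(seq) <= L or not rec.circular:
            segs.append((s, seq, d))
        else:
            cut = L - s
            segs.append((s, seq[:cut], d))
            if seq[cut:]:
                segs.append((0, seq[cut:], d))
    segs.sort(key=lambda t: (t[0], -len(t[1])))

    out: list[str] = []
    gaps = []
    covered = 0
    cursor = 0
    for s, seq, _ in segs:
        if s > cursor:
            gaps.append(Gap(cursor, s))
            out.append("N" * (s - cursor))
            cursor = s
        trim = cursor - s
        if trim >= len(seq):
            continue
        if trim > 0:
            seq = seq[trim:]
        out.append(seq)
        covered += len(seq)
        cursor += len(seq)
    if cursor < L:
        gaps.append(Gap(cursor, L))
        out.append("N" * (L - cursor))
    seq = "".join(out)

    return ScaffoldResult(
        seq=seq,
        gaps=gaps,
        reference_id=rec.id,
        completeness=100.0 * min(covered, L) / L,
        coverage=dict(pre.coverage),
        conflicts=conflicts,
        pieces=pieces,
    )


# ---------------------------------------------------------------------------
# Back-mapping QC
# ---------------------------------------------------------------------------


@dataclass
class QCRow:
    scaffold_id: str
    library: str
    n_pairs: int
    mean_coverage: float


@dataclass
class QCReport:
    rows: list[QCRow]
    conflict_positions: dict[str, list[int]]  # scaffold id -> flagged positions
    cross_assignment_fraction: float | None = None

    @property
    def has_conflicts(self) -> bool:
        return any(v for v in self.conflict_positions.values())


class _ScaffoldIndex:
    def __init__(self, seq: str, k: int = 31):
        self.k = k
        self.seq = seq
        self.kmap: dict[int, int] = {}
        fwd, _, valid = kmers.kmer_codes(seq, k)
        for i in np.flatnonzero(valid):
            code = int(fwd[i])
            if code not in self.kmap:
                self.kmap[code] = int(i)

    def locate(self, read: str) -> tuple[int, str] | None:
        """(scaffold offset of read start, orientation) via first k-mer hit."""
        for orient, s in (("+", read), ("-", revcomp(read))):
            fwd, _, valid = kmers.kmer_codes(s, self.k)
            for i in np.flatnonzero(valid):
                pos = self.kmap.get(int(fwd[i]))
                if pos is not None:
                    return pos - int(i), orient
        return None


def _aligned_span(
    index: _ScaffoldIndex, read: str, min_identity: float
) -> tuple[int, int, list[int], str] | None:
    loc = index.locate(read)
    if loc is None:
        return None
    off, orient = loc
    s = read if orient == "+" else revcomp(read)
    lo = max(off, 0)
    hi = min(off + len(s), len(index.seq))
    if hi - lo < 31:
        return None
    sub = index.seq[lo:hi]
    rsub = s[lo - off : hi - off]
    mism = [i for i, (x, y) in enumerate(zip(rsub, sub)) if x != y and y != "N"]
    if 1 - len(mism) / len(sub) < min_identity:
        return None
    return lo, hi, [lo + m for m in mism], orient


def backmap_qc(
    scaffolds: list[ScaffoldResult],
    reads_by_library: dict[str, ReadSet],
    min_identity: float = 0.90,
    conflict_fraction: float = 0.20,
    min_conflict_depth: int = 5,
    origins: dict[str, str] | None = None,
    truth_assignment: dict[str, str] | None = None,
) -> QCReport:
    """Assign read pairs to their best scaffold and report coverage and
    positions where spanning reads disagree with the consensus.

    A pair is assigned to the scaffold sharing the most 25-mers with its
    mates (both mates considered; ties to the first scaffold in order).
    Positions where more than ``conflict_fraction`` of covering reads
    mismatch the scaffold base (at depth >= ``min_conflict_depth``) are
    flagged as potential chimera / haplotype-mixing sites.

    With ``origins`` (read id -> source genome) and ``truth_assignment``
    (source genome -> expected scaffold id), the fraction of prey pairs
    assigned to the wrong scaffold is also reported.
    """
    if not scaffolds:
        raise ValueError("at least one scaffold required")
    scaff_codes = [
        kmers.genome_kmer_set(s.seq.replace("N", ""), 25) for s in scaffolds
    ]
    indexes = [_ScaffoldIndex(s.seq) for s in scaffolds]
    rows: list[QCRow] = []
    cov_sum = {s.scaffold_id: np.zeros(len(s.seq), dtype=np.int32) for s in scaffolds}
    mism_sum = {s.scaffold_id: np.zeros(len(s.seq), dtype=np.int32) for s in scaffolds}
    n_cross = 0
    n_truth = 0

    for lib, reads in reads_by_library.items():
        counts = []
        for codes in scaff_codes:
            c1 = shared_kmer_counts(reads.seq1, codes, 25)
            c2 = shared_kmer_counts(reads.seq2, codes, 25)
            counts.append(c1 + c2)
        counts = np.stack(counts)  # (n_scaffolds, n_pairs)
        best = np.argmax(counts, axis=0)
        best_count = counts[best, np.arange(counts.shape[1])]
        n_pairs_per = {s.scaffold_id: 0 for s in scaffolds}
        bases_per = {s.scaffold_id: 0 for s in scaffolds}
        for pi in np.flatnonzero(best_count >= 2):
            si = int(best[pi])
            sc = scaffolds[si]
            ok = 0
            for mate in (reads.seq1[pi], reads.seq2[pi]):
                span = _aligned_span(indexes[si], mate, min_identity)
                if span is None:
                    continue
                lo, hi, mism, _ = span
                cov_sum[sc.scaffold_id][lo:hi] += 1
                for m in mism:
                    mism_sum[sc.scaffold_id][m] += 1
                bases_per[sc.scaffold_id] += hi - lo
                ok += 1
            if ok:
                n_pairs_per[sc.scaffold_id] += 1
            if origins is not None and truth_assignment is not None:
                src = origins.get(reads.ids[pi])
                expected = truth_assignment.get(src) if src else None
                if expected is not None:
                    n_truth += 1
                    if expected != sc.scaffold_id:
                        n_cross += 1
        for s in scaffolds:
            non_n = max(len(s.seq.replace("N", "")), 1)
            rows.append(
                QCRow(s.scaffold_id, lib, n_pairs_per[s.scaffold_id],
                      bases_per[s.scaffold_id] / non_n)
            )

    conflict_positions = {}
    for s in scaffolds:
        cov = cov_sum[s.scaffold_id]
        mism = mism_sum[s.scaffold_id]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(cov > 0, mism / np.maximum(cov, 1), 0.0)
        flagged = np.flatnonzero((cov >= min_conflict_depth) & (frac > conflict_fraction))
        conflict_positions[s.scaffold_id] = flagged.tolist()
    cross = (n_cross / n_truth) if n_truth else None
    return QCReport(rows, conflict_positions, cross)
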