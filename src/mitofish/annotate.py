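"""Annotation transfer, ORF validation, and gene-order rearrangement calls.

Gene models are projected from an annotated reference onto a new scaffold
through a global pairwise alignment; projected protein-coding genes are
then re-validated as open reading frames under translation table 4.
Gene orders of two annotated genomes are compared as signed circular
permutations to call inversions and translocations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqio import (
    AnnotatedGenome,
    DEFAULT_START_CODONS,
    Feature,
    InternalStopError,
    SequenceRecord,
    extract_feature,
    translate_cds,
)

__all__ = [
    "TransferReport",
    "RearrangementCall",
    "OrfStatus",
    "transfer_annotations",
    "validate_orfs",
    "detect_rearrangements",
]

_EQUALITIES = [("N", b) for b in "ACGT"]


@dataclass
class OrfStatus:
    name: str
    status: str  # ok | incomplete | fail
    reason: str = ""
    codon_index: int | None = None


@dataclass
class TransferReport:
    transferred: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)  # entirely in N gaps
    failed: list[OrfStatus] = field(default_factory=list)
    frame_snaps: dict[str, int] = field(default_factory=dict)
    alignment_identity: float = 1.0

    @property
    def attempted(self) -> int:
        return len(self.transferred) + len(self.missing) + len(self.failed)


@dataclass
class RearrangementCall:
    kind: str  # inversion | translocation
    features: tuple[str, ...]  # features contained in / moved by the event

    def __str__(self) -> str:
        return f"{self.kind}({','.join(self.features)})"


# ---------------------------------------------------------------------------
# Annotation transfer
# ---------------------------------------------------------------------------


def _coordinate_map(ref_seq: str, target_seq: str) -> tuple[np.ndarray, float]:
    """Projection of reference coordinates into target coordinates.

    Returns ``(pos_map, identity)`` where ``pos_map`` has length
    ``len(ref_seq) + 1`` and maps every reference boundary to a target
    boundary through the global alignment (N in either sequence matches
    anything).
    """
    res = edlib.align(ref_seq, target_seq, mode="NW", task="path",
                      additionalEqualities=_EQUALITIES)
    dist = res["editDistance"]
    identity = 1 - dist / max(len(ref_seq), len(target_seq))
    pos_map = np.empty(len(ref_seq) + 1, dtype=np.int64)
    ri = ti = 0
    pos_map[0] = 0
    import re

    for m in re.finditer(r"(\d+)([=XIDM])", res["cigar"]):
        n, op = int(m.group(1)), m.group(2)
        if op in "=XM":
            for j in range(n):
                pos_map[ri + j + 1] = ti + j + 1
            ri += n
            ti += n
        elif op == "I":  # present in reference, absent from target
            for j in range(n):
                pos_map[ri + j + 1] = ti
            ri += n
        elif op == "D":  # present in target only
            ti += n
            pos_map[ri] = ti
    pos_map[ri] = ti
    return pos_map, identity


def transfer_annotations(
    target: SequenceRecord,
    reference: AnnotatedGenome,
    min_identity: float = 0.60,
    snap_window: int = 6,
) -> tuple[AnnotatedGenome, TransferReport]:
    """Project the reference gene models onto a target sequence.

    The target must be in the reference coordinate frame (scaffolding
    output).  Exons landing entirely inside N gaps are reported missing;
    projected CDS whose length breaks the reading frame are snapped to the
    nearest in-frame boundary within ``snap_window`` nt.

    Raises ``ValueError`` if the global alignment identity falls below
    ``min_identity`` (wrong reference).
    """
    Lr = len(reference.record)
    pos_map, identity = _coordinate_map(reference.record.seq, target.seq)
    report = TransferReport(alignment_identity=identity)
    if identity < min_identity:
        raise ValueError(
            f"alignment identity {identity:.2f} below {min_identity:.2f}; "
            f"{reference.id} is not a suitable reference for {target.id}"
        )

    features: list[Feature] = []
    for f in reference.features:
        exons = []
        n_chars = 0
        gap_chars = 0
        for (s, e) in f.exons:
            pieces = [(s, e)] if e > s else [(s, Lr), (0, e)]
            for (ps, pe) in pieces:
                ts, te = int(pos_map[ps]), int(pos_map[pe])
                if te <= ts:
                    continue
                exons.append((ts, te))
                seg = target.seq[ts:te]
                n_chars += len(seg)
                gap_chars += seg.count("N")
        if not exons or n_chars == 0 or gap_chars == n_chars:
            report.missing.append(f.name)
            continue
        if f.strand == "-":
            exons = sorted(exons, key=lambda x: -x[0])
        if f.kind in ("CDS", "ORF"):
            total = sum(e - s for s, e in exons)
            snap = (-total) % 3
            if snap:
                d = _frame_snap(total, snap_window)
                if d is None:
                    report.failed.append(
                        OrfStatus(f.name, "fail", "cannot restore reading frame")
                    )
                    continue
                exons = _adjust_last_exon(exons, f.strand, d, len(target.seq))
                report.frame_snaps[f.name] = d
        features.append(Feature(f.name, f.kind, exons, f.strand, f.transl_table))
        report.transferred.append(f.name)
    genome = AnnotatedGenome(target, features)
    return genome, report


def _frame_snap(total: int, window: int) -> int | None:
    """Smallest |d| with (total + d) divisible by 3 and |d| <= window."""
    for ad in range(0, window + 1):
        for d in (ad, -ad):
            if (total + d) % 3 == 0 and total + d > 0:
                return d
    return None


def _adjust_last_exon(
    exons: list[tuple[int, int]], strand: str, d: int, L: int
) -> list[tuple[int, int]]:
    """Extend/shrink the 3'-most exon by ``d`` nt."""
    exons = list(exons)
    s, e = exons[-1]
    if strand == "+":
        e = min(max(e + d, s + 1), L)
    else:
        s = max(min(s - d, e - 1), 0)
    exons[-1] = (s, e)
    return exons


# ---------------------------------------------------------------------------
# ORF validation
# ---------------------------------------------------------------------------


def validate_orfs(
    genome: AnnotatedGenome,
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS,
) -> TransferReport:
    """Check every CDS/ORF: frame, start codon, internal stops, terminal
    stop.  A CDS truncated by an N gap is reported ``incomplete``, not
    failed."""
    report = TransferReport()
    stops = ("TAA", "TAG")
    for f in genome.features:
        if f.kind not in ("CDS", "ORF"):
            continue
        seq = extract_feature(genome, f)
        touches_gap = "N" in seq
        if len(seq) % 3 != 0:
            report.failed.append(
                OrfStatus(f.name, "fail", f"length {len(seq)} not divisible by 3")
            )
            continue
        if touches_gap and (seq.startswith("N") or seq.endswith("N")):
            report.missing.append(f.name)
            report.failed.append(OrfStatus(f.name, "incomplete", "gap-truncated"))
            continue
        try:
            translate_cds(seq, f.transl_table)
        except InternalStopError as exc:
            report.failed.append(
                OrfStatus(f.name, "fail", "internal stop", exc.codon_index)
            )
            continue
        if seq[:3] not in start_codons and not seq[:3].count("N"):
            report.failed.append(
                OrfStatus(f.name, "fail", f"unexpected start codon {seq[:3]}")
            )
            continue
        if seq[-3:] not in stops:
            if touches_gap:
                report.failed.append(OrfStatus(f.name, "incomplete", "gap-truncated"))
            else:
                report.failed.append(OrfStatus(f.name, "fail", "no terminal stop"))
            continue
        report.transferred.append(f.name)
    return report


# ---------------------------------------------------------------------------
# Rearrangement detection
# ---------------------------------------------------------------------------


def _signed_order(g: AnnotatedGenome, shared: set[str], anchor: str) -> list[tuple[str, int]]:
    feats = [f for f in g.feature_order() if f.name in shared]
    order = [(f.name, 1 if f.strand == "+" else -1) for f in feats]
    names = [n for n, _ in order]
    i = names.index(anchor)
    order = order[i:] + order[:i]
    if order[0][1] == -1:  # orient so the anchor reads forward
        order = [(n, -s) for n, s in reversed(order)]
        order = order[-1:] + order[:-1]
    return order


def detect_rearrangements(
    a: AnnotatedGenome, b: AnnotatedGenome, anchor: str = "COX1"
) -> list[RearrangementCall]:
    """Compare gene orders as signed circular permutations.

    Both genomes are rotated to a shared anchor gene; maximal contiguous
    reversed blocks are reported as inversions and single features whose
    neighbours changed as translocations.  Returns an empty list when the
    orders coincide up to rotation.
    """
    names_a = {f.name for f in a.features}
    names_b = {f.name for f in b.features}
    shared = names_a & names_b
    if len(shared) < 0.8 * max(len(names_a), len(names_b)):
        raise ValueError(
            f"genomes share only {len(shared)} features; gene-order comparison "
            "needs >= 80% shared"
        )
    if anchor not in shared:
        anchor = sorted(shared)[0]
    oa = _signed_order(a, shared, anchor)
    ob = _signed_order(b, shared, anchor)
    calls: list[RearrangementCall] = []
    for _ in range(4):
        if oa == ob:
            return calls
        ev = _match_single_event(oa, ob)
        if ev is None:
            break
        call, oa, ob = ev
        calls.append(call)
    if oa != ob:
        calls.append(
            RearrangementCall("complex", tuple(n for n, _ in oa))
        )
    return calls


def _match_single_event(oa, ob):
    """Try to explain the order difference by one inversion or one
    translocation; returns (call, new_oa, new_ob) with the event undone."""
    # inversion: strip common prefix/suffix, test reversed+negated middle
    n = len(oa)
    lo = 0
    while lo < n and oa[lo] == ob[lo]:
        lo += 1
    hi = n
    while hi > lo and oa[hi - 1] == ob[hi - 1]:
        hi -= 1
    mid_a, mid_b = oa[lo:hi], ob[lo:hi]
    if mid_a and [(x, -s) for x, s in reversed(mid_b)] == mid_a:
        call = RearrangementCall("inversion", tuple(x for x, _ in mid_a))
        return call, oa, oa  # undone
    # translocation: one element whose removal reconciles the orders
    for name in sorted({x for x, _ in oa}):
        ra = [(x, s) for x, s in oa if x != name]
        rb = [(x, s) for x, s in ob if x != name]
        if ra == rb:
            return RearrangementCall("translocation", (name,)), ra, rb
    return None
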